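"""Noise suppression for 4D Flow CMR velocity data.

Air has essentially no MR signal, so its phase (velocity) values are random;
left alone they light up the angiogram.  Two thresholding rules deal with
this:

* **magnitude rule** — voxels whose magnitude is below a fraction (default
  10%) of the global magnitude maximum are suppressed;
* **velocity rule** — voxels where a velocity component exceeds a multiple
  (default 1.5) of the VENC are suppressed; genuine flow cannot exceed the
  encoding limit by that much, so these are wraps or noise.

Suppression zeroes the velocity vector (so the voxel contributes nothing to
any angiogram formula) and leaves the magnitude intact, keeping array shapes
and registration inputs unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .flow_data import FlowDataError, FlowDataset

__all__ = [
    "SuppressionMask",
    "magnitude_noise_mask",
    "velocity_outlier_mask",
    "apply_suppression",
]


@dataclass
class SuppressionMask:
    """Boolean keep-mask over all frames with per-rule suppression counts."""

    keep: np.ndarray  # (N, X, Y, Z) bool
    n_suppressed_magnitude: int = 0
    n_suppressed_velocity: int = 0
    rule: str = ""

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.keep.ndim != 4:
            raise FlowDataError(f"keep mask must be 4D, got {self.keep.shape}")

    @property
    def n_suppressed(self) -> int:
        return int(np.count_nonzero(~self.keep))

    def write(self, path: str | Path, affine: np.ndarray | None = None) -> Path:
        """Export the keep mask as a uint8 4D NIfTI for inspection."""
        path = Path(path)
        arr = np.moveaxis(self.keep.astype(np.uint8), 0, 3)
        if affine is None:
            affine = np.eye(4)
        nib.save(nib.Nifti1Image(arr, affine), str(path))
        return path


def magnitude_noise_mask(ds: FlowDataset, fraction: float = 0.10) -> SuppressionMask:
    """Suppress voxels with magnitude below ``fraction`` of the global maximum.

    The maximum is taken over all frames, consistent with
    :func:`~pcmrca.flow_data.normalize_magnitude`.  Voxels strictly below the
    threshold are suppressed.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    threshold = fraction * float(ds.magnitude.max())
    keep = ds.magnitude >= threshold
    return SuppressionMask(
        keep=keep,
        n_suppressed_magnitude=int(np.count_nonzero(~keep)),
        rule="magnitude",
    )


def velocity_outlier_mask(
    ds: FlowDataset, factor: float = 1.5, mode: str = "component"
) -> SuppressionMask:
    """Suppress voxels whose velocity exceeds ``factor`` × VENC.

    ``mode='component'`` (default) suppresses where any single component's
    absolute value strictly exceeds the limit — VENC bounds each encoded
    direction separately, and wraps manifest per component.  ``mode='speed'``
    tests the Euclidean speed instead.
    """
    if not factor > 1:
        raise ValueError(f"factor must be > 1, got {factor}")
    limit = factor * ds.venc
    if mode == "component":
        keep = ~np.any(np.abs(ds.velocity) > limit, axis=1)
    elif mode == "speed":
        keep = ds.speed() <= limit
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SuppressionMask(
        keep=keep,
        n_suppressed_velocity=int(np.count_nonzero(~keep)),
        rule="velocity",
    )


def apply_suppression(
    ds: FlowDataset, masks: "list[SuppressionMask] | SuppressionMask"
) -> FlowDataset:
    """Zero the velocity at every voxel failing any mask; magnitude untouched.

    Idempotent: re-applying the same masks changes nothing.
    """
    if isinstance(masks, SuppressionMask):
        masks = [masks]
    out = ds.copy()
    if not masks:
        return out
    keep = np.ones(ds.magnitude.shape, dtype=bool)
    for m in masks:
        if m.keep.shape != ds.magnitude.shape:
            raise FlowDataError(
                f"mask shape {m.keep.shape} does not match dataset "
                f"{ds.magnitude.shape}"
            )
        keep &= m.keep
    out.velocity[~keep[:, None].repeat(3, axis=1)] = 0.0
    return out
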