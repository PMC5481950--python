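"""Domain types and NIfTI I/O for 4D Flow CMR data.

A 4D Flow CMR acquisition yields, for each of ``N`` timeframes of the cardiac
cycle, one magnitude volume and three velocity-component volumes (velocities in
cm/s, bounded in practice by the velocity-encoding limit VENC).  This module
defines the in-memory containers used throughout the package and round-trips
them through NIfTI-1 files plus a small YAML metadata sidecar.

Array conventions
-----------------
* magnitude: ``(N, X, Y, Z)`` float
* velocity: ``(N, 3, X, Y, Z)`` float, cm/s, component order (x, y, z)
* On disk each channel is a 4D NIfTI with frame as the 4th axis
  (``X, Y, Z, N``); a single 5D file ``(X, Y, Z, N, 3)`` is accepted on load
  for the velocity channel.
* Voxel indices are 0-based; world coordinates are ``index * spacing`` (no
  oblique orientation support; affines are carried through verbatim).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "FlowDataset",
    "AngioVolume",
    "CardioAngio4D",
    "load_flow_dataset",
    "write_flow_dataset",
    "normalize_magnitude",
    "write_angio_volume",
    "load_angio_volume",
]

logger = logging.getLogger(__name__)

_SIDECAR_NAME = "meta.yaml"


class FlowDataError(ValueError):
    """Raised for structurally invalid flow data or mismatched inputs."""


@dataclass
class FlowDataset:
    """One cardiac cycle of 4D Flow CMR data.

    Parameters
    ----------
    magnitude : ndarray, shape (N, X, Y, Z)
        Signal magnitude, arbitrary non-negative units.
    velocity : ndarray, shape (N, 3, X, Y, Z)
        Three-directional velocity in cm/s.
    venc : float
        Velocity-encoding limit in cm/s.
    spacing : ndarray, shape (3,)
        Voxel spacing in mm.
    temporal_resolution : float
        Time between frames in ms.
    frame_times : ndarray, shape (N,), optional
        Frame onset times in ms from the R-wave.
    affine : ndarray, shape (4, 4), optional
        NIfTI affine carried through to outputs.  Defaults to
        ``diag(spacing, 1)``.
    """

    magnitude: np.ndarray
    velocity: np.ndarray
    venc: float
    spacing: np.ndarray
    temporal_resolution: float = 0.0
    frame_times: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=np.float64)
        self.velocity = np.asarray(self.velocity, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        if self.magnitude.ndim != 4:
            raise FlowDataError(
                f"magnitude must be (N, X, Y, Z), got shape {self.magnitude.shape}"
            )
        if self.velocity.ndim != 5 or self.velocity.shape[1] != 3:
            raise FlowDataError(
                f"velocity must be (N, 3, X, Y, Z), got shape {self.velocity.shape}"
            )
        n, *spatial = self.magnitude.shape
        if n < 2:
            raise FlowDataError(f"need at least 2 timeframes, got N={n}")
        vshape = (self.velocity.shape[0],) + self.velocity.shape[2:]
        if vshape != self.magnitude.shape:
            raise FlowDataError(
                "magnitude/velocity shape mismatch: magnitude "
                f"{self.magnitude.shape} vs velocity frames {vshape}"
            )
        n_bad = int(np.count_nonzero(~np.isfinite(self.magnitude)))
        n_bad += int(np.count_nonzero(~np.isfinite(self.velocity)))
        if n_bad:
            raise FlowDataError(f"{n_bad} non-finite voxel values in input")
        if np.any(self.magnitude < 0):
            raise FlowDataError("magnitude contains negative values")
        if not self.venc > 0:
            raise FlowDataError(f"venc must be > 0, got {self.venc}")
        if np.any(self.spacing <= 0):
            raise FlowDataError(f"spacing must be positive, got {self.spacing}")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
            if self.frame_times.shape != (n,):
                raise FlowDataError("frame_times length must equal frame count")
        if self.affine is None:
            self.affine = np.diag(np.append(self.spacing, 1.0))
        else:
            self.affine = np.asarray(self.affine, dtype=np.float64).reshape(4, 4)

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.magnitude.shape[1:]

    def speed(self, t: int | None = None) -> np.ndarray:
        """Euclidean velocity magnitude (cm/s) per voxel, one frame or all."""
        v = self.velocity if t is None else self.velocity[t]
        return np.sqrt(np.sum(v**2, axis=-4))

    def copy(self) -> "FlowDataset":
        return dataclasses.replace(
            self,
            magnitude=self.magnitude.copy(),
            velocity=self.velocity.copy(),
            spacing=self.spacing.copy(),
            frame_times=None if self.frame_times is None else self.frame_times.copy(),
            affine=self.affine.copy(),
        )


@dataclass
class AngioVolume:
    """A single 3D angiographic volume with provenance.

    ``provenance`` tags which formula produced it: ``eq1`` (time-averaged
    magnitude²·speed), ``eq2`` (root-mean-square), ``eq3_frame`` (per-frame
    gamma-corrected PC-MRA) or ``mrca3d`` (temporally fused cardioangiogram).
    """

    data: np.ndarray
    spacing: np.ndarray
    provenance: str = "eq3_frame"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        if self.data.ndim != 3:
            raise FlowDataError(f"AngioVolume data must be 3D, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise FlowDataError("AngioVolume contains non-finite values")
        if np.any(self.data < 0):
            raise FlowDataError("AngioVolume contains negative intensities")
        if self.affine is None:
            self.affine = np.diag(np.append(self.spacing, 1.0))


@dataclass
class CardioAngio4D:
    """Time-resolved cardioangiogram: one fused angiogram warped to every frame.

    ``frames[reference_frame]`` is the fused angiogram itself (identity
    transform at the reference); all other frames are the fused volume warped
    into that timeframe's geometry.
    """

    frames: list[AngioVolume]
    reference_frame: int
    gamma: float
    fusion_mode: str = "max"

    def __post_init__(self) -> None:
        if not 0 <= self.reference_frame < len(self.frames):
            raise FlowDataError(
                f"reference_frame {self.reference_frame} out of range "
                f"for {len(self.frames)} frames"
            )
        if self.fusion_mode not in ("max", "mean"):
            raise FlowDataError(f"unknown fusion mode {self.fusion_mode!r}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def as_array(self) -> np.ndarray:
        """Stack frames into an ``(N, X, Y, Z)`` array."""
        return np.stack([f.data for f in self.frames])


# ---------------------------------------------------------------------------
# NIfTI I/O


def _load_nifti(path: Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), np.asarray(img.affine)


def load_flow_dataset(
    magnitude_path: str | Path,
    velocity_paths: "list[str | Path] | str | Path",
    meta: dict | str | Path | None = None,
) -> FlowDataset:
    """Load a :class:`FlowDataset` from NIfTI files plus a metadata sidecar.

    Parameters
    ----------
    magnitude_path
        4D NIfTI ``(X, Y, Z, N)``.
    velocity_paths
        Either three 4D NIfTI paths (x, y, z components) or a single 5D file
        ``(X, Y, Z, N, 3)``.
    meta
        Mapping (or path to a YAML file) with keys ``venc_cms``,
        ``spacing_mm`` (optional; NIfTI header wins on conflict) and
        ``temporal_resolution_ms`` / ``frame_times_ms`` (optional).
    """
    magnitude_path = Path(magnitude_path)
    if isinstance(meta, (str, Path)):
        with open(meta) as fh:
            meta = yaml.safe_load(fh)
    meta = dict(meta or {})
    if "venc_cms" not in meta:
        raise FlowDataError("metadata must supply venc_cms")

    mag, affine = _load_nifti(magnitude_path)
    if mag.ndim != 4:
        raise FlowDataError(f"magnitude file must be 4D, got shape {mag.shape}")
    mag = np.moveaxis(mag, 3, 0)  # -> (N, X, Y, Z)

    if isinstance(velocity_paths, (str, Path)):
        vel, _ = _load_nifti(Path(velocity_paths))
        if vel.ndim != 5 or vel.shape[4] != 3:
            raise FlowDataError(
                f"5D velocity file must be (X, Y, Z, N, 3), got {vel.shape}"
            )
        vel = np.moveaxis(np.moveaxis(vel, 4, 0), 4, 1)  # -> (3, N, ...) -> swap
        vel = np.swapaxes(vel, 0, 1)
    else:
        comps = []
        for p in velocity_paths:
            arr, _ = _load_nifti(Path(p))
            if arr.ndim != 4:
                raise FlowDataError(f"velocity file {p} must be 4D, got {arr.shape}")
            comps.append(np.moveaxis(arr, 3, 0))
        vel = np.stack(comps, axis=1)  # (N, 3, X, Y, Z)

    if vel.shape[0] != mag.shape[0] or vel.shape[2:] != mag.shape[1:]:
        raise FlowDataError(
            f"shape mismatch between channels: magnitude {mag.shape} vs "
            f"velocity {(vel.shape[0],) + vel.shape[2:]}"
        )

    header_spacing = np.abs(np.diag(affine)[:3])
    spacing = header_spacing
    if "spacing_mm" in meta:
        meta_spacing = np.broadcast_to(
            np.atleast_1d(np.asarray(meta["spacing_mm"], dtype=float)), (3,)
        )
        if not np.allclose(meta_spacing, header_spacing, rtol=1e-4):
            warnings.warn(
                f"sidecar spacing {meta_spacing} disagrees with NIfTI header "
                f"{header_spacing}; using header",
                stacklevel=2,
            )
        # NIfTI header wins on conflict
        if np.allclose(header_spacing, 1.0) and not np.allclose(meta_spacing, 1.0):
            # header looks unset; trust the sidecar
            spacing = meta_spacing

    frame_times = meta.get("frame_times_ms")
    return FlowDataset(
        magnitude=mag,
        velocity=vel,
        venc=float(meta["venc_cms"]),
        spacing=spacing,
        temporal_resolution=float(meta.get("temporal_resolution_ms", 0.0)),
        frame_times=None if frame_times is None else np.asarray(frame_times),
        affine=affine,
    )


def write_flow_dataset(ds: FlowDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a :class:`FlowDataset` as four 4D NIfTI files plus a YAML sidecar.

    Volumes are stored as float32 (lossless reload within float32 precision).
    Returns a manifest mapping channel names to the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    def _save(name: str, arr4d: np.ndarray) -> None:
        img = nib.Nifti1Image(
            np.moveaxis(arr4d, 0, 3).astype(np.float32), ds.affine
        )
        path = out_dir / f"{name}.nii"
        nib.save(img, str(path))
        manifest[name] = path

    _save("magnitude", ds.magnitude)
    for i, comp in enumerate("xyz"):
        _save(f"velocity_{comp}", ds.velocity[:, i])

    meta = {
        "venc_cms": float(ds.venc),
        "spacing_mm": [float(s) for s in ds.spacing],
        "temporal_resolution_ms": float(ds.temporal_resolution),
    }
    if ds.frame_times is not None:
        meta["frame_times_ms"] = [float(t) for t in ds.frame_times]
    sidecar = out_dir / _SIDECAR_NAME
    with open(sidecar, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    manifest["meta"] = sidecar
    return manifest


def load_flow_dataset_dir(in_dir: str | Path) -> FlowDataset:
    """Load a dataset previously written by :func:`write_flow_dataset`."""
    in_dir = Path(in_dir)
    return load_flow_dataset(
        in_dir / "magnitude.nii",
        [in_dir / f"velocity_{c}.nii" for c in "xyz"],
        in_dir / _SIDECAR_NAME,
    )


def normalize_magnitude(ds: FlowDataset) -> FlowDataset:
    """Rescale magnitude linearly to [0, 1] by its global maximum over all frames.

    The global (not per-frame) maximum preserves relative frame brightness.
    Velocities are untouched.  Idempotent once the maximum is exactly 1.
    """
    mmax = float(ds.magnitude.max())
    if mmax <= 0:
        raise FlowDataError("cannot normalize an all-zero magnitude image")
    out = ds.copy()
    out.magnitude = out.magnitude / mmax
    return out


def write_angio_volume(vol: AngioVolume, path: str | Path) -> Path:
    """Write an :class:`AngioVolume` as a 3D NIfTI with a provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine), str(path))
    sidecar = path.with_suffix(".yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump({"provenance": vol.provenance}, fh)
    return path


def load_angio_volume(path: str | Path) -> AngioVolume:
    data, affine = _load_nifti(Path(path))
    sidecar = Path(path).with_suffix(".yaml")
    provenance = "eq3_frame"
    if sidecar.exists():
        with open(sidecar) as fh:
            provenance = (yaml.safe_load(fh) or {}).get("provenance", provenance)
    return AngioVolume(
        data=data,
        spacing=np.abs(np.diag(affine)[:3]),
        provenance=provenance,
        affine=affine,
    )
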