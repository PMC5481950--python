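"""Visualization: rotating maximum-intensity projections and isosurfaces.

Angiographic volumes are conventionally inspected as maximum-intensity
projections (MIPs) from a sweep of view angles — 36 projections at 10°
spacing per timeframe by default — and as marching-cubes isosurface meshes.
Rotation resamples the volume (linear interpolation, zero fill outside, so
rotated corners never beat anatomy in the max) and then reduces along a
fixed projection axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .flow_data import AngioVolume, CardioAngio4D, FlowDataError

__all__ = ["ProjectionSpec", "mip_project", "mip_series", "isosurface", "save_mesh"]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class ProjectionSpec:
    """How to build a rotating-MIP series.

    ``rotation_axis`` names the axis the volume spins about; the projection
    direction is the second of the two remaining axes (e.g. axis ``y`` for
    rotation about ``z``).
    """

    n_angles: int = 36
    rotation_axis: str = "z"
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if self.rotation_axis not in _AXES:
            raise ValueError(f"unknown rotation axis {self.rotation_axis!r}")
        if self.interpolation not in ("linear", "nearest"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")

    @property
    def plane_axes(self) -> tuple[int, int]:
        return tuple(i for i in range(3) if i != _AXES[self.rotation_axis])

    @property
    def projection_axis(self) -> int:
        return self.plane_axes[1]


def _as_array(volume) -> np.ndarray:
    if isinstance(volume, AngioVolume):
        return volume.data
    return np.asarray(volume, dtype=np.float64)


def mip_project(
    volume, angle_deg: float, spec: ProjectionSpec | None = None
) -> np.ndarray:
    """Rotate the volume about ``spec.rotation_axis`` and take the max.

    Returns a 2D image.  At angle 0 with nearest interpolation this is
    exactly the axis-aligned maximum.
    """
    spec = spec or ProjectionSpec()
    arr = _as_array(volume)
    if arr.ndim != 3:
        raise FlowDataError(f"expected a 3D volume, got shape {arr.shape}")
    order = 1 if spec.interpolation == "linear" else 0
    if angle_deg % 360 != 0:
        arr = ndimage.rotate(
            arr,
            angle_deg,
            axes=spec.plane_axes,
            reshape=False,
            order=order,
            mode="constant",
            cval=0.0,
        )
    return arr.max(axis=spec.projection_axis)


def mip_series(
    mrca: CardioAngio4D,
    spec: ProjectionSpec | None = None,
    frames: "list[int] | None" = None,
) -> np.ndarray:
    """Rotating-MIP stacks for animation export.

    Returns an array ``(n_frames, n_angles, H, W)`` with ``n_angles``
    projections at uniform angular spacing over 360° per requested
    timeframe (all frames by default).
    """
    spec = spec or ProjectionSpec()
    frames = list(range(mrca.n_frames)) if frames is None else list(frames)
    angles = np.arange(spec.n_angles) * (360.0 / spec.n_angles)
    stacks = [
        np.stack([mip_project(mrca.frames[t], a, spec) for a in angles])
        for t in frames
    ]
    return np.stack(stacks)


def isosurface(volume, level: float, spacing=None) -> trimesh.Trimesh:
    """Marching-cubes surface of the volume at ``level``, vertices in mm.

    ``level`` must lie strictly inside the volume's intensity range.
    Deterministic: identical input yields an identical mesh.
    """
    arr = _as_array(volume)
    if spacing is None:
        spacing = volume.spacing if isinstance(volume, AngioVolume) else (1.0,) * 3
    if not arr.min() < level < arr.max():
        raise ValueError(
            f"isosurface level {level} outside intensity range "
            f"[{arr.min():.4g}, {arr.max():.4g}]"
        )
    verts, faces, _normals, _values = measure.marching_cubes(
        arr, level=level, spacing=tuple(float(s) for s in spacing)
    )
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def default_isosurface_level(volume) -> float:
    """50% of the 99.5th intensity percentile — a robust angiogram default."""
    arr = _as_array(volume)
    return 0.5 * float(np.percentile(arr, 99.5))


def save_mesh(mesh: trimesh.Trimesh, path: str | Path) -> Path:
    """Write a mesh as STL or OBJ (chosen by the file extension)."""
    path = Path(path)
    if path.suffix.lower() not in (".stl", ".obj"):
        raise ValueError(f"unsupported mesh format {path.suffix!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(str(path))
    return path
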