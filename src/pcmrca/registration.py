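"""Morphon-style non-rigid registration with diffeomorphic accumulation.

The Morphon estimates local displacement from *local phase* differences
rather than intensity differences, which makes it robust to smooth contrast
variation.  Each image is filtered with a bank of 3D quadrature filters —
complex-valued, orientation-selective band-pass filters — along six
directions with icosahedral symmetry.  The phase of the product
``q_moving · conj(q_fixed)`` measures, per voxel and orientation, how far
structure has shifted along that filter's direction; the filter magnitude
product provides a certainty weight.  A per-voxel weighted least-squares
solve combines the six 1D estimates into a 3D displacement update.

Per iteration the update is smoothed with a Gaussian of ``sigma_fluid``
(fluid regularization, certainty-normalized), composed into the running
field (diffeomorphic accumulation), and the accumulated field is smoothed
with ``sigma_elastic`` (elastic regularization).  The procedure runs
coarse-to-fine over ``n_scales`` octaves.

Displacement-field convention: a field ``B`` registered with ``fixed`` frame
``f`` and ``moving`` frame ``m`` maps fixed-frame voxel coordinates to
sample positions in the moving frame, i.e. ``warp(m, B)(x) = m(x + B(x)) ≈
f(x)``.  Vectors are in voxel units of the registered grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from functools import lru_cache
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .flow_data import AngioVolume, FlowDataError

__all__ = [
    "RegistrationParams",
    "DisplacementField",
    "register",
    "warp",
    "compose",
    "inverse_consistency_error",
    "jacobian_determinant",
]

# Six filter orientations: the antipodal vertex pairs of an icosahedron.
_PHI = (1.0 + np.sqrt(5.0)) / 2.0
_DIRECTIONS = np.array(
    [
        (0.0, 1.0, _PHI),
        (0.0, -1.0, _PHI),
        (1.0, _PHI, 0.0),
        (-1.0, _PHI, 0.0),
        (_PHI, 0.0, 1.0),
        (_PHI, 0.0, -1.0),
    ]
)
_DIRECTIONS /= np.linalg.norm(_DIRECTIONS, axis=1, keepdims=True)

#: quadrature filter center frequency (radians/voxel) and bandwidth (octaves)
CENTER_FREQUENCY = np.pi / 3.0
BANDWIDTH_OCTAVES = 2.0

#: updates are zeroed where the summed filter certainty falls below this
#: fraction of its 99th percentile: local phase is amplitude-invariant, so
#: without a floor pure-noise regions (air) produce confident-looking but
#: meaningless displacement estimates
CERTAINTY_FLOOR = 0.01


@dataclass
class RegistrationParams:
    """Tuning parameters of the multi-scale Morphon.

    Defaults: 2 scales, 3 iterations per scale, Gaussian σ of 1.5 voxels for
    both the fluid (update) and elastic (accumulated field) regularization.
    """

    n_scales: int = 2
    iterations_per_scale: int = 3
    sigma_fluid: float = 1.5
    sigma_elastic: float = 1.5

    def __post_init__(self) -> None:
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if self.iterations_per_scale < 1:
            raise ValueError("iterations_per_scale must be >= 1")
        if self.sigma_fluid <= 0 or self.sigma_elastic <= 0:
            raise ValueError("regularization sigmas must be positive")


@dataclass
class DisplacementField:
    """Dense displacement field, ``vectors`` shaped (3, X, Y, Z) in voxels.

    ``direction`` is a semantic tag: the field maps fixed-frame coordinates
    to sample positions in the moving frame.
    """

    vectors: np.ndarray
    direction: str = "fixed_to_moving"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[0] != 3:
            raise FlowDataError(
                f"field vectors must be (3, X, Y, Z), got {self.vectors.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise FlowDataError("displacement field contains non-finite values")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[1:]

    def norm(self) -> np.ndarray:
        return np.sqrt(np.sum(self.vectors**2, axis=0))

    @classmethod
    def zeros(cls, shape: tuple[int, int, int], **kw) -> "DisplacementField":
        return cls(vectors=np.zeros((3,) + tuple(shape)), **kw)

    def write(self, path: str | Path, spacing=(1.0, 1.0, 1.0)) -> Path:
        """Serialize as a 4D NIfTI (3 components on the 4th axis, voxels)."""
        path = Path(path)
        affine = np.diag(np.append(np.asarray(spacing, dtype=float), 1.0))
        arr = np.moveaxis(self.vectors, 0, 3).astype(np.float32)
        nib.save(nib.Nifti1Image(arr, affine), str(path))
        with open(path.with_suffix(".yaml"), "w") as fh:
            fh.write(f"direction: {self.direction}\n")
        return path


# ---------------------------------------------------------------------------
# Quadrature filter bank


@lru_cache(maxsize=8)
def _filter_bank(shape: tuple[int, int, int]) -> np.ndarray:
    """Frequency-domain quadrature filters, shape (6, X, Y, Z), real-valued.

    Log-normal radial envelope centered at ``CENTER_FREQUENCY`` with a
    2-octave relative bandwidth, times a ``cos²`` angular function that is
    zero on the hemisphere opposite each direction (the single-sided support
    makes the spatial filter a quadrature pair).
    """
    freqs = np.meshgrid(
        *[2 * np.pi * np.fft.fftfreq(n) for n in shape], indexing="ij"
    )
    u = np.stack(freqs)  # (3, X, Y, Z)
    rho = np.sqrt(np.sum(u**2, axis=0))
    with np.errstate(divide="ignore"):
        lnr = np.log(rho / CENTER_FREQUENCY)
    radial = np.exp(-(4.0 / (BANDWIDTH_OCTAVES**2 * np.log(2.0))) * lnr**2)
    radial[rho == 0] = 0.0

    bank = np.empty((len(_DIRECTIONS),) + shape)
    for k, n_hat in enumerate(_DIRECTIONS):
        cos_ang = np.tensordot(n_hat, u, axes=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_ang = np.where(rho > 0, cos_ang / rho, 0.0)
        directional = np.where(cos_ang > 0, cos_ang**2, 0.0)
        bank[k] = radial * directional
    return bank


def _quadrature_responses(image: np.ndarray) -> np.ndarray:
    """Complex filter responses, shape (6, X, Y, Z)."""
    spectrum = np.fft.fftn(image)
    bank = _filter_bank(image.shape)
    return np.fft.ifftn(spectrum[None] * bank, axes=(1, 2, 3))


# ---------------------------------------------------------------------------
# Field algebra


def _as_array(volume) -> np.ndarray:
    if isinstance(volume, AngioVolume):
        return volume.data
    return np.asarray(volume, dtype=np.float64)


def _sample(volume: np.ndarray, field_vectors: np.ndarray, order: int) -> np.ndarray:
    coords = np.indices(volume.shape, dtype=np.float64) + field_vectors
    return ndimage.map_coordinates(volume, coords, order=order, mode="nearest")


def warp(volume, field: DisplacementField, interpolation: str = "linear") -> np.ndarray:
    """Resample ``volume`` at ``x + field(x)``.

    Out-of-bounds samples replicate the nearest border voxel, which keeps
    maximum-intensity projections free of dark halos at the volume edge.
    """
    vol = _as_array(volume)
    if vol.shape != field.spatial_shape:
        raise FlowDataError(
            f"volume shape {vol.shape} does not match field {field.spatial_shape}"
        )
    order = {"linear": 1, "nearest": 0}[interpolation]
    return _sample(vol, field.vectors, order)


def compose(field_a: DisplacementField, field_b: DisplacementField) -> DisplacementField:
    """Composition ``(A ∘ B)(x) = B(x) + A(x + B(x))``.

    Warping by the composite equals warping by ``A`` first, then ``B``:
    ``warp(v, A∘B) ≈ warp(warp(v, A), B)``.  The zero field is the identity
    element on either side.
    """
    if field_a.spatial_shape != field_b.spatial_shape:
        raise FlowDataError(
            f"field shapes differ: {field_a.spatial_shape} vs {field_b.spatial_shape}"
        )
    vecs = np.empty_like(field_b.vectors)
    for i in range(3):
        vecs[i] = field_b.vectors[i] + _sample(field_a.vectors[i], field_b.vectors, 1)
    return DisplacementField(vectors=vecs, direction=field_a.direction)


def jacobian_determinant(field: DisplacementField) -> np.ndarray:
    """Determinant of the Jacobian of ``x ↦ x + field(x)`` (central differences).

    Values > 0 indicate a locally invertible (orientation-preserving)
    mapping; the fraction of positive interior values is the package's
    diffeomorphism proxy.
    """
    grads = [np.gradient(field.vectors[i]) for i in range(3)]
    jac = np.empty(field.spatial_shape + (3, 3))
    for i in range(3):
        for j in range(3):
            jac[..., i, j] = grads[i][j] + (1.0 if i == j else 0.0)
    return np.linalg.det(jac)


def inverse_consistency_error(
    image,
    backward: DisplacementField,
    forward: DisplacementField,
    margin: int = 4,
) -> float:
    """Mean per-voxel squared intensity error of the B-then-F round trip.

    The image is warped by the backward field, then by the forward field, and
    compared with the original over an interior mask excluding ``margin``
    voxels at each border.  Intensities must lie in [0, 1] so the maximum
    possible per-voxel error is 1.
    """
    img = _as_array(image)
    if img.min() < 0 or img.max() > 1 + 1e-9:
        raise FlowDataError(
            "inverse_consistency_error expects intensities in [0, 1]; "
            f"got range [{img.min():.3g}, {img.max():.3g}]"
        )
    round_trip = warp(warp(img, backward), forward)
    interior = tuple(slice(margin, n - margin) for n in img.shape)
    diff = (img - round_trip)[interior]
    return float(np.mean(diff**2))


# ---------------------------------------------------------------------------
# The Morphon iteration


def _displacement_update(
    q_fixed: np.ndarray, q_moving: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One phase-difference displacement estimate.

    Returns ``(update, certainty)`` with ``update`` shaped (3, X, Y, Z) in
    voxels and ``certainty`` the summed per-orientation weight.
    """
    prod = q_moving * np.conj(q_fixed)
    dphi = np.angle(prod)
    # confidence: strong filter response on both images, penalized for large
    # phase disagreement (cos² of the half-angle)
    certainty = np.abs(prod) * np.cos(dphi / 2.0) ** 2
    # structure shifted by +d along n gives phase difference -f0·(n·d)
    d_along = -dphi / CENTER_FREQUENCY  # voxels, per orientation

    n = _DIRECTIONS
    # normal equations of the per-voxel weighted least squares
    a_mat = np.einsum("k...,ki,kj->...ij", certainty, n, n)
    b_vec = np.einsum("k...,k...,ki->...i", certainty, d_along, n)

    trace = np.trace(a_mat, axis1=-2, axis2=-1)
    reg = 1e-9 * (trace.mean() + 1e-30)
    a_reg = a_mat + reg * np.eye(3)
    update = np.linalg.solve(a_reg, b_vec[..., None])[..., 0]

    # zero the update where the normal matrix is ill-conditioned or the
    # total certainty is negligible relative to the image's own distribution
    total_certainty = certainty.sum(axis=0)
    eigvals = np.linalg.eigvalsh(a_mat)
    ill = (eigvals[..., 0] <= eigvals[..., -1] / 1e3) | (
        total_certainty < CERTAINTY_FLOOR * np.percentile(total_certainty, 99)
    )
    update[ill] = 0.0
    total_certainty = np.where(ill, 0.0, total_certainty)
    return np.moveaxis(update, -1, 0), total_certainty


def _normalized_smooth(
    vectors: np.ndarray, certainty: np.ndarray, sigma: float
) -> np.ndarray:
    """Certainty-weighted Gaussian smoothing (normalized convolution)."""
    denom = ndimage.gaussian_filter(certainty, sigma)
    eps = 1e-6 * float(certainty.mean()) + 1e-30
    out = np.empty_like(vectors)
    for i in range(3):
        out[i] = ndimage.gaussian_filter(vectors[i] * certainty, sigma) / (
            denom + eps
        )
    return out


def _downsample(img: np.ndarray) -> np.ndarray:
    smoothed = ndimage.gaussian_filter(img, sigma=1.0)
    return ndimage.zoom(smoothed, 0.5, order=1)


def _upsample_field(vectors: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    out = np.empty((3,) + tuple(shape))
    factors = [s / c for s, c in zip(shape, vectors.shape[1:])]
    for i in range(3):
        out[i] = ndimage.zoom(vectors[i], factors, order=1) * factors[i]
    return out


def register(
    fixed,
    moving,
    params: RegistrationParams | None = None,
) -> DisplacementField:
    """Estimate the field ``B`` with ``moving(x + B(x)) ≈ fixed(x)``.

    Runs the Morphon coarse-to-fine over ``params.n_scales`` octaves with
    ``params.iterations_per_scale`` iterations each.  Deterministic: no
    randomness enters anywhere.  Constant (featureless) inputs short-circuit
    to a zero field with a warning.
    """
    params = params or RegistrationParams()
    fixed_arr = _as_array(fixed)
    moving_arr = _as_array(moving)
    if fixed_arr.shape != moving_arr.shape:
        raise FlowDataError(
            f"fixed/moving shape mismatch: {fixed_arr.shape} vs {moving_arr.shape}"
        )
    if np.ptp(fixed_arr) == 0 or np.ptp(moving_arr) == 0:
        warnings.warn(
            "constant image passed to register(); returning zero field",
            stacklevel=2,
        )
        return DisplacementField.zeros(fixed_arr.shape)

    # image pyramid, coarsest first
    pyramid = [(fixed_arr, moving_arr)]
    for _ in range(params.n_scales - 1):
        f, m = pyramid[0]
        pyramid.insert(0, (_downsample(f), _downsample(m)))

    field_vecs: np.ndarray | None = None
    for fixed_s, moving_s in pyramid:
        if field_vecs is None:
            field_vecs = np.zeros((3,) + fixed_s.shape)
        elif field_vecs.shape[1:] != fixed_s.shape:
            field_vecs = _upsample_field(field_vecs, fixed_s.shape)
        q_fixed = _quadrature_responses(fixed_s)
        running = DisplacementField(vectors=field_vecs)
        for _ in range(params.iterations_per_scale):
            warped = _sample(moving_s, running.vectors, order=1)
            q_moving = _quadrature_responses(warped)
            update, certainty = _displacement_update(q_fixed, q_moving)
            update = _normalized_smooth(update, certainty, params.sigma_fluid)
            # cap the per-iteration step to keep the accumulation invertible
            step_norm = np.sqrt(np.sum(update**2, axis=0))
            cap = np.pi / CENTER_FREQUENCY
            excess = step_norm > cap
            if np.any(excess):
                scale = np.where(excess, cap / (step_norm + 1e-30), 1.0)
                update = update * scale[None]
            increment = DisplacementField(vectors=update)
            running = compose(running, increment)
            for i in range(3):
                running.vectors[i] = ndimage.gaussian_filter(
                    running.vectors[i], params.sigma_elastic
                )
        field_vecs = running.vectors
    return DisplacementField(vectors=field_vecs)
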