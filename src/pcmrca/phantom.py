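"""Synthetic 4D Flow CMR phantom with exact ground-truth motion.

No public 4D Flow CMR dataset ships with voxel-wise ground-truth deformation,
so validation uses an analytic digital phantom: a beating ellipsoidal chamber
(a cartoon ventricle) and a curved tube with pulsatile parabolic
through-plane flow (a cartoon aorta), embedded in tissue and air.

The chamber motion is a radial scaling about the chamber center whose
amplitude follows ``sin⁴`` of the cycle phase: zero displacement at the
configured diastasis frame, a flat quiescent plateau around it (so automatic
diastasis detection has a well-defined minimum), and a sharp systolic
contraction half a cycle away.  Because the map is a monotone radial scaling
it is diffeomorphic by construction and its inverse is obtained by a 1D
monotone table inversion, so frame images, Eulerian velocities, and the
dense deformation fields are all mutually consistent and exact.

Air voxels carry Gaussian velocity noise plus, in a configurable fraction of
them, uniform super-threshold outliers, so both noise-suppression rules have
work to do.  All randomness derives from ``noise_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .flow_data import FlowDataError, FlowDataset, write_flow_dataset
from .registration import DisplacementField

__all__ = ["PhantomConfig", "PhantomTruth", "generate_phantom", "truth_endpoint_error"]


@dataclass
class PhantomConfig:
    """Geometry, motion and acquisition parameters of the digital phantom.

    Spatial and velocity-encoding defaults emulate a typical clinical 4D Flow
    CMR protocol: 2.7 mm isotropic voxels, VENC 120 cm/s, ~53 ms temporal
    resolution, 20 timeframes per cycle.
    """

    grid: tuple[int, int, int] = (48, 48, 48)
    n_frames: int = 20
    spacing_mm: float = 2.7
    venc_cms: float = 120.0
    temporal_resolution_ms: float = 52.8
    # beating chamber
    chamber_center: tuple[float, float, float] = (15.0, 24.0, 24.0)
    chamber_axes: tuple[float, float, float] = (9.0, 8.0, 8.0)
    contraction_amplitude: float = 0.25  # fractional radius change per cycle
    reference_frame: int = 5  # diastasis: zero motion here
    peak_chamber_speed_cms: float = 25.0
    # curved vessel (tube along z, sinusoidal bend in x)
    vessel_center_xy: tuple[float, float] = (37.0, 24.0)
    vessel_bend_vox: float = 2.5
    vessel_radius_vox: float = 4.0
    peak_vessel_speed_cms: float = 100.0
    # intensities and noise
    tissue_magnitude: float = 0.3
    blood_magnitude: float = 1.0
    air_magnitude: float = 0.02
    air_noise_sigma: float = 0.02
    air_velocity_sigma_frac: float = 0.05  # ×VENC, Gaussian air velocity noise
    outlier_fraction: float = 0.01  # fraction of air voxels with wrap-like noise
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.contraction_amplitude < 0.5:
            raise FlowDataError(
                f"contraction_amplitude must be in [0, 0.5), got "
                f"{self.contraction_amplitude}"
            )
        limit = 1.5 * self.venc_cms
        if not (
            self.peak_vessel_speed_cms < limit
            and self.peak_chamber_speed_cms < limit
        ):
            raise FlowDataError(
                "peak speeds must stay below 1.5 × VENC so true lumen voxels "
                "survive suppression"
            )
        if not 0 <= self.reference_frame < self.n_frames:
            raise FlowDataError("reference_frame out of range")
        if self.n_frames < 2:
            raise FlowDataError("need at least 2 frames")


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside the synthetic dataset.

    ``deformation_to_reference[t]`` maps reference-frame voxel coordinates to
    the corresponding position in frame ``t`` — the same convention as the
    backward registration fields ``B_t``, so the two compare directly.
    Masks are per-frame and pairwise disjoint.
    """

    deformation_to_reference: list[DisplacementField]
    chamber_mask: np.ndarray  # (N, X, Y, Z) bool
    vessel_mask: np.ndarray
    air_mask: np.ndarray
    reference_frame: int
    n_injected_outliers: int = 0

    def foreground_mask(self, t: int | None = None) -> np.ndarray:
        """Non-air region (chamber + tissue + vessel) of frame ``t`` or the
        reference frame."""
        t = self.reference_frame if t is None else t
        return ~self.air_mask[t]

    def write(self, out_dir: str | Path, spacing: float = 1.0) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        affine = np.diag([spacing, spacing, spacing, 1.0])
        fields = np.stack(
            [np.moveaxis(f.vectors, 0, 3) for f in self.deformation_to_reference]
        )  # (N, X, Y, Z, 3)
        nib.save(
            nib.Nifti1Image(
                np.moveaxis(fields, 0, 3).astype(np.float32), affine
            ),
            str(out_dir / "truth_fields.nii"),
        )
        for name in ("chamber_mask", "vessel_mask", "air_mask"):
            arr = np.moveaxis(getattr(self, name).astype(np.uint8), 0, 3)
            nib.save(nib.Nifti1Image(arr, affine), str(out_dir / f"{name}.nii"))


def _motion_profile(cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Radial scale ``s_t`` and its per-frame rate ``ds/dt`` over the cycle.

    ``s_t = 1 − A·sin⁴(π (t − t_ref) / N)``: equals 1 (no deformation) at the
    diastasis frame, is quartically flat there, and reaches the full
    contraction ``1 − A`` half a cycle later.
    """
    t = np.arange(cfg.n_frames, dtype=float)
    theta = np.pi * (t - cfg.reference_frame) / cfg.n_frames
    s = 1.0 - cfg.contraction_amplitude * np.sin(theta) ** 4
    ds = (
        -cfg.contraction_amplitude
        * 4.0
        * np.sin(theta) ** 3
        * np.cos(theta)
        * np.pi
        / cfg.n_frames
    )
    return s, ds


#: radial falloff of the chamber deformation: full inside the lumen (r0 ≤ 1),
#: smooth cos² decay to zero across the surrounding tissue shell
_R_DECAY_OUT = 1.6


def _falloff(r0: np.ndarray) -> np.ndarray:
    w = np.zeros_like(r0)
    w[r0 <= 1.0] = 1.0
    shell = (r0 > 1.0) & (r0 < _R_DECAY_OUT)
    w[shell] = np.cos(0.5 * np.pi * (r0[shell] - 1.0) / (_R_DECAY_OUT - 1.0)) ** 2
    return w


def _scale_factor(r0: np.ndarray, s: float) -> np.ndarray:
    """λ(r0): multiplier of the centered coordinate at scale state ``s``."""
    return 1.0 + (s - 1.0) * _falloff(r0)


def _invert_radius(r_t: np.ndarray, s: float) -> np.ndarray:
    """Invert the monotone radial map ``r0 ↦ r0·λ(r0)`` by table lookup."""
    r0_grid = np.linspace(0.0, 6.0, 2001)
    rt_grid = r0_grid * _scale_factor(r0_grid, s)
    return np.interp(r_t, rt_grid, r0_grid)


def _magnitude_profile(r0: np.ndarray, cfg: PhantomConfig) -> np.ndarray:
    """Chamber intensity vs normalized elliptical radius (reference frame)."""
    knots = np.array([0.0, 0.92, 1.08, 1.30, 1.55, _R_DECAY_OUT + 0.2])
    values = np.array(
        [
            cfg.blood_magnitude,
            cfg.blood_magnitude,
            cfg.tissue_magnitude,
            cfg.tissue_magnitude,
            cfg.air_magnitude,
            cfg.air_magnitude,
        ]
    )
    return np.interp(r0, knots, values)


def generate_phantom(cfg: PhantomConfig | None = None) -> tuple[FlowDataset, PhantomTruth]:
    """Render the beating phantom and its exact ground truth.

    Returns the :class:`~pcmrca.flow_data.FlowDataset` (magnitude in
    [~0, 1], velocity in cm/s) and the matching :class:`PhantomTruth`.
    Deterministic for a fixed config including ``noise_seed``.
    """
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(cfg.noise_seed)
    nx, ny, nz = cfg.grid
    n = cfg.n_frames
    x, y, z = np.meshgrid(
        np.arange(nx, dtype=float),
        np.arange(ny, dtype=float),
        np.arange(nz, dtype=float),
        indexing="ij",
    )
    cx, cy, cz = cfg.chamber_center
    ax, ay, az = cfg.chamber_axes
    centered = np.stack([x - cx, y - cy, z - cz])

    # vessel geometry (static): axis offset in x varies sinusoidally with z
    vx0, vy0 = cfg.vessel_center_xy
    bend = cfg.vessel_bend_vox * np.sin(np.pi * z / max(nz - 1, 1))
    rho_vessel = np.sqrt((x - (vx0 + bend)) ** 2 + (y - vy0) ** 2)
    slope = (
        cfg.vessel_bend_vox * np.pi / max(nz - 1, 1) * np.cos(np.pi * z / max(nz - 1, 1))
    )
    tangent_norm = np.sqrt(1.0 + slope**2)
    vessel_lumen = rho_vessel <= cfg.vessel_radius_vox

    # vessel magnitude profile vs distance from the axis
    rv = cfg.vessel_radius_vox
    v_knots = np.array([0.0, rv - 0.6, rv + 0.6, rv + 2.0, rv + 3.2, rv + 4.0])
    v_values = np.array(
        [
            cfg.blood_magnitude,
            cfg.blood_magnitude,
            cfg.tissue_magnitude,
            cfg.tissue_magnitude,
            cfg.air_magnitude,
            cfg.air_magnitude,
        ]
    )
    vessel_intensity = np.interp(rho_vessel, v_knots, v_values)

    # pulsatile flow waveform: peaks at exactly 1 half a cycle from diastasis
    t_idx = np.arange(n)
    t_sys = (cfg.reference_frame + n // 2) % n
    pulse = 0.15 + 0.85 * np.cos(np.pi * (t_idx - t_sys) / n) ** 2
    parabola = np.clip(1.0 - (rho_vessel / rv) ** 2, 0.0, None)

    s_t, ds_t = _motion_profile(cfg)
    # voxel/frame -> cm/s: ×(mm/voxel) / (ms/frame) = mm/ms = m/s = 100 cm/s
    vox_per_frame_to_cms = 100.0 * cfg.spacing_mm / cfg.temporal_resolution_ms

    magnitude = np.empty((n, nx, ny, nz))
    velocity = np.zeros((n, 3, nx, ny, nz))
    chamber_mask = np.empty((n, nx, ny, nz), dtype=bool)
    vessel_mask = np.empty_like(chamber_mask)
    air_mask = np.empty_like(chamber_mask)
    truth_fields: list[DisplacementField] = []
    chamber_vel_raw = np.zeros((n, 3, nx, ny, nz))

    r_ref = np.sqrt(
        (centered[0] / ax) ** 2 + (centered[1] / ay) ** 2 + (centered[2] / az) ** 2
    )
    for t in range(n):
        s = float(s_t[t])
        r_t = r_ref  # elliptical radius of the evaluation point, frame-t coords
        r0 = _invert_radius(r_t, s)
        # chamber intensity rendered by pulling back to reference coordinates
        chamber_intensity = _magnitude_profile(r0, cfg)
        mag = np.maximum(chamber_intensity, vessel_intensity)
        air = (chamber_intensity <= cfg.air_magnitude + 1e-12) & (
            vessel_intensity <= cfg.air_magnitude + 1e-12
        )
        mag = np.where(
            air, cfg.air_magnitude + np.abs(rng.normal(0, cfg.air_noise_sigma, mag.shape)), mag
        )
        magnitude[t] = mag

        # ground-truth field B_t: reference coords -> frame-t coords
        lam_ref = _scale_factor(r_ref, s)
        disp = centered * (lam_ref - 1.0)
        truth_fields.append(
            DisplacementField(vectors=disp.copy(), direction="fixed_to_moving")
        )

        # Eulerian wall/blood motion velocity at frame-t coordinates: the
        # material point at elliptical radius r_t originated at r0; its
        # radial scale rate is ds/dt · falloff(r0)
        lam_t = _scale_factor(r0, s)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = float(ds_t[t]) * _falloff(r0) / np.where(lam_t > 0, lam_t, 1.0)
        chamber_vel_raw[t] = centered * rate * vox_per_frame_to_cms

        # vessel flow: parabolic through-plane profile along the local tangent
        vz_speed = cfg.peak_vessel_speed_cms * pulse[t] * parabola
        velocity[t, 0] += np.where(vessel_lumen, vz_speed * slope / tangent_norm, 0.0)
        velocity[t, 2] += np.where(vessel_lumen, vz_speed / tangent_norm, 0.0)

        chamber_mask[t] = r_t <= s  # lumen boundary at r0 = 1 maps to r_t = s
        vessel_mask[t] = vessel_lumen & ~chamber_mask[t]
        air_mask[t] = air

    # scale chamber velocities so the cycle peak equals peak_chamber_speed;
    # intra-chamber blood moves faster than the wall this field derives from
    in_chamber = chamber_mask[:, None].repeat(3, axis=1)
    chamber_vel_raw[~in_chamber] = 0.0
    peak = np.sqrt(np.sum(chamber_vel_raw**2, axis=1)).max()
    if peak > 0:
        velocity += chamber_vel_raw * (cfg.peak_chamber_speed_cms / peak)

    # air velocity noise: Gaussian background plus wrap-like uniform outliers
    n_outliers = 0
    for t in range(n):
        air = air_mask[t]
        n_air = int(air.sum())
        if n_air == 0:
            continue
        noise = rng.normal(
            0.0, cfg.air_velocity_sigma_frac * cfg.venc_cms, size=(3, n_air)
        )
        n_out = int(round(cfg.outlier_fraction * n_air))
        if n_out:
            pick = rng.choice(n_air, size=n_out, replace=False)
            amp = 1.5 * cfg.venc_cms * 1.2
            noise[:, pick] = rng.uniform(-amp, amp, size=(3, n_out))
        for i in range(3):
            velocity[t, i][air] = noise[i]
        n_outliers += int(
            np.count_nonzero(np.any(np.abs(noise) > 1.5 * cfg.venc_cms, axis=0))
        )

    ds = FlowDataset(
        magnitude=magnitude,
        velocity=velocity,
        venc=cfg.venc_cms,
        spacing=np.full(3, cfg.spacing_mm),
        temporal_resolution=cfg.temporal_resolution_ms,
        frame_times=np.arange(n) * cfg.temporal_resolution_ms,
    )
    truth = PhantomTruth(
        deformation_to_reference=truth_fields,
        chamber_mask=chamber_mask,
        vessel_mask=vessel_mask,
        air_mask=air_mask,
        reference_frame=cfg.reference_frame,
        n_injected_outliers=n_outliers,
    )
    return ds, truth


def truth_endpoint_error(
    field: DisplacementField,
    truth_field: DisplacementField,
    mask: np.ndarray,
) -> float:
    """Mean Euclidean norm (voxels) of ``field − truth`` over ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != field.spatial_shape:
        raise FlowDataError("mask shape does not match field")
    if not mask.any():
        raise FlowDataError("empty evaluation mask")
    diff = field.vectors - truth_field.vectors
    norms = np.sqrt(np.sum(diff**2, axis=0))
    return float(norms[mask].mean())


def write_phantom(
    cfg: PhantomConfig, out_dir: str | Path
) -> tuple[FlowDataset, PhantomTruth]:
    """Generate and write the phantom dataset, truth and echoed config."""
    out_dir = Path(out_dir)
    ds, truth = generate_phantom(cfg)
    write_flow_dataset(ds, out_dir)
    truth.write(out_dir / "truth", spacing=cfg.spacing_mm)
    with open(out_dir / "phantom_config.yaml", "w") as fh:
        yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(cfg).items()},
            fh,
            sort_keys=True,
        )
    return ds, truth
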