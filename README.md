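# pcmrca — time-resolved cardioangiography from 4D Flow CMR

4D Flow CMR acquires, for every timeframe of the cardiac cycle, a magnitude
volume M(t) and three-directional blood-flow velocities V(t) = (Vx, Vy, Vz).
Classical phase-contrast MR angiography (PC-MRA) collapses this into one
static volume by averaging over the cycle,

    3D PC-MRA (eq1) = (1/N) Σₜ M²(t) · |V(t)|
    3D PC-MRA (eq2) = sqrt( (1/N) Σₜ M²(t) · |V(t)|² )

which blurs every moving wall and darkens the heart chambers, where
velocities are low.  `pcmrca` instead builds a **4D phase-contrast MR
cardioangiography (4D PC-MRCA)**:

1. a per-frame angiogram  PC-MRA(t) = M(t) · (Vx² + Vy² + Vz²)^γ  with
   γ = 0.2, so low chamber velocities stay visible next to arterial jets;
2. non-rigid (Morphon) registration of every magnitude frame to a quiescent
   mid-diastolic reference, giving N−1 backward fields Bₜ;
3. each frame's angiogram warped to the reference geometry by Bₜ;
4. fusion by a voxelwise **maximum over time** — bright wherever high flow
   occurs at least once in the cycle, sharp because every frame is in the
   same geometry;
5. a second registration pass (reference → every frame, fields Fₜ) warps the
   fused angiogram back out, yielding one angiogram per timeframe whose
   walls move with the heart.

The package is aimed at researchers post-processing 4D Flow CMR: it provides
the full pipeline, the classical PC-MRA baselines, velocity noise
suppression (magnitude < 10% of max; any |Vᵢ| > 1.5·VENC), rotating
maximum-intensity projections and isosurface meshes, and a digital
beating-heart phantom with exact analytic ground-truth deformation fields
for validation.

## Worked example

```python
import numpy as np
from pcmrca import (PhantomConfig, generate_phantom, normalize_magnitude,
                    magnitude_noise_mask, velocity_outlier_mask, apply_suppression,
                    select_reference_frame, backward_fields, forward_fields,
                    fuse_mrca3d, build_mrca, pcmra_eq2, inverse_consistency_error)

cfg = PhantomConfig(noise_seed=0)           # 48³ voxels, 20 timeframes
ds, truth = generate_phantom(cfg)

ds = normalize_magnitude(ds)
masks = [magnitude_noise_mask(ds), velocity_outlier_mask(ds)]
ds = apply_suppression(ds, masks)
print(f"suppressed by velocity rule: {masks[1].n_suppressed_velocity} voxels")

ref = select_reference_frame(ds, mode="auto")
print(f"diastasis reference frame: {ref}")

B = backward_fields(ds, ref)                # N-1 fields, frame t -> reference
F = forward_fields(ds, ref)                 # N-1 fields, reference -> frame t
fused = fuse_mrca3d(ds, B, ref)             # 3D PC-MRCA at diastasis
mrca = build_mrca(ds, ref, b_fields=B, f_fields=F)   # 4D PC-MRCA

ice = np.mean([inverse_consistency_error(ds.magnitude[t], B[t], F[t]) for t in B])
print(f"mean inverse-consistency error: {ice:.2e}")

chamber = truth.chamber_mask[ref]
eq2 = pcmra_eq2(ds)
print(f"chamber mean / image peak:  MRCA {fused.data[chamber].mean()/fused.data.max():.3f}"
      f"  vs  PC-MRA {eq2.data[chamber].mean()/eq2.data.max():.3f}")
```

prints (about two minutes on one CPU):

```
suppressed by velocity rule: 7824 voxels
diastasis reference frame: 5
mean inverse-consistency error: 1.27e-04
chamber mean / image peak:  MRCA 0.448  vs  PC-MRA 0.125
```

The velocity rule removes exactly the injected wrap-like air outliers; the
stillness heuristic finds the phantom's configured diastasis frame (5);
round-tripping each magnitude frame through Bₜ then Fₜ changes it by ~1e-4
mean squared intensity on a [0, 1] scale where 1 is the maximum possible
error; and relative to each image's own peak, the fused cardioangiogram
keeps the chamber about 3.6× brighter than the time-averaged PC-MRA — the
mechanism that makes the heart chambers visible.

The same pipeline is scriptable from a shell via the `pcmrca` console
command (`phantom`, `pcmra`, `mrca`, `render` subcommands), driven by a
single YAML config; `pcmrca mrca -c config.yaml` writes the 4D PC-MRCA, the
baselines, and a JSON run-log with timings and per-frame diagnostics.

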