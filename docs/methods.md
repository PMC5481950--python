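# Methods

## The pipeline

A 4D Flow CMR dataset is a series of N timeframes, each holding a magnitude
volume M(t) and three velocity volumes Vx(t), Vy(t), Vz(t) in cm/s, bounded
in practice by the velocity-encoding limit VENC.  The package assumes phase
unwrapping and background-phase correction have been applied upstream, as is
standard in 4D Flow post-processing chains.

The time-resolved cardioangiogram is constructed in five steps: per-frame
angiograms (gamma-corrected, below); backward registration of every
magnitude frame to a diastasis reference; warping of each angiogram into the
reference geometry; temporal fusion; forward registration and warping of the
fused volume into every frame.  The reference frame participates in fusion
unwarped, so N terms enter the fusion and the reference frame of the output
is bit-identical to the fused 3D volume.

### Angiogram formulas and units

Three formulas are implemented:

* eq1: (1/N) Σₜ M²(t)·|V(t)| — strong background suppression, vessel-weighted;
* eq2: sqrt((1/N) Σₜ M²(t)·|V(t)|²) — the RMS variant, which retains more
  chamber intensity and serves as the comparison baseline;
* per-frame: M(t)·(Vx²+Vy²+Vz²)^γ with γ = 0.2 by default.

The γ power is applied to squared speed **in cm/s**.  It is unit-sensitive:
(|V|²)^0.2 in cm/s is not a rescaling of the same expression in m/s, so all
velocities in this package are kept in the units the VENC is quoted in.
γ = 0.2 compresses the dynamic range so that chamber velocities of tens of
cm/s and arterial velocities of ~1 m/s end up within a factor of ~2 rather
than ~10; γ = 0.5 recovers M·|V| exactly.  The pipeline normalizes magnitude
to [0, 1] by its global maximum over all frames (global, so relative frame
brightness is preserved) before registration and angiogram computation;
normalization is exposed as an explicit step because scanner exports carry
arbitrary magnitude units.

### Noise suppression

Air has no MR signal, so its phase — hence velocity — is random.  Two rules
run before any angiogram is computed:

* magnitude rule: voxels with M below 10% of the global maximum are
  suppressed (threshold strict: values exactly at 10% are kept);
* velocity rule: voxels where any single component satisfies |Vᵢ| >
  1.5·VENC are suppressed (strict: exactly 1.5·VENC is kept).  The
  per-component reading is the default because the VENC bounds each encoded
  direction separately and wraps manifest per component; a `speed` mode
  testing ‖V‖ is available.

Both thresholds use the global (all-frames) maximum, consistent with
normalization.  Suppression zeroes the three velocity components and leaves
magnitude intact, so suppressed voxels contribute exactly zero to every
angiogram formula while array shapes and registration inputs are unchanged.
Applying the same masks twice is a no-op.

## Morphon registration

Registration is driven by local phase, not intensity, making it robust to
the smooth contrast variation typical of MR magnitude images.

**Filter bank.**  Six complex quadrature filters along the antipodal vertex
pairs of an icosahedron, constructed directly in the frequency domain at the
full volume size: a log-normal radial envelope with center frequency π/3
radians/voxel and 2-octave relative bandwidth, times cos² of the angle to
the filter direction, zeroed on the opposite hemisphere (single-sided
support is what makes the spatial filter a quadrature pair).  Frequency-
domain construction avoids the truncation ripple of small spatial kernels.

**Update estimation.**  Per voxel and orientation k, the phase of
q_moving·conj(q_fixed) measures structure shift along direction nₖ; the
displacement estimate is dₖ = −Δφₖ/f₀ voxels.  A certainty
cₖ = |q_m·q̄_f|·cos²(Δφₖ/2) weights a per-voxel 3×3 least-squares solve for
the 3D update.  Updates are zeroed where the normal matrix has condition
number above 10³ and — important in practice — where the summed certainty
falls below 1% of its own 99th percentile: local phase is amplitude-
invariant, so without this floor pure-noise regions (air) produce
confident-looking but meaningless displacements that bleed onto anatomy
through the regularization.

**Regularization and accumulation.**  The update is smoothed by a Gaussian
of σ_fluid = 1.5 voxels using certainty-normalized convolution (fluid
step), capped at π/f₀ = 3 voxels per iteration, composed into the running
field — compose(A, B)(x) = B(x) + A(x + B(x)), so warping by the composite
equals warping by A then B — and the accumulated field is smoothed with
σ_elastic = 1.5 voxels (elastic step).  Accumulation by composition rather
than addition is what keeps the field a diffeomorphism in practice; the
positivity of the Jacobian determinant of x ↦ x + u(x) on interior voxels
is checked as the diffeomorphism proxy (100% on all phantom registrations).
No scaling-and-squaring is used.

**Multi-scale schedule.**  Two octave scales, three iterations per scale,
coarse-to-fine; images are downsampled by 2 with Gaussian anti-aliasing
(σ = 1), fields are upsampled linearly with vectors scaled by the zoom
factor.  These defaults (2 scales, 3 iterations, σ = 1.5 for both
regularizers) are appropriate for cardiac-scale motion of a few voxels at
~2.7 mm resolution; larger motion or finer grids warrant more scales.
Registration is fully deterministic — no randomness enters anywhere — and
constant (featureless) images short-circuit to a zero field with a warning.

**Field convention.**  A field maps fixed-frame voxel coordinates to sample
positions in the moving frame: warp(moving, B)(x) = moving(x + B(x)).
Warping uses linear (or nearest) interpolation with replicate-border
sampling, which keeps maximum-intensity projections free of dark halos at
the volume edge.  The forward fields Fₜ come from a genuine second
registration pass (reference as moving), not from inverting Bₜ; inverse
consistency of the two passes is measured, not assumed, as the mean
per-voxel squared difference between each [0, 1]-normalized magnitude frame
and its B-then-F round trip over an interior mask (4-voxel border margin).
On that scale the maximum possible error is 1; the phantom pipeline
measures ~1.3e-4.

### Reference-frame selection

Diastasis is the mid-diastolic quiescent phase.  The automatic heuristic
picks the frame minimizing the mean absolute magnitude difference to its
cyclic temporal neighbors over the central half-volume; ties break to the
lowest index.  The heuristic targets healthy-volunteer-like cycles; for
pathological rhythms the reference is a config knob (`ref_frame: <int>`),
not hard-coded.

### Fusion

Voxelwise maximum over the N aligned angiograms by default; maximum rather
than average preserves chamber visibility, since chambers are bright in
only part of the cycle.  Mean fusion is available for noisy input.  Voxels
suppressed in some frames contribute zero there, so the maximum comes from
the unsuppressed frames.  Max-fusion dominates mean-fusion voxelwise by
construction.

## The digital phantom

No public 4D Flow dataset carries voxel-wise ground-truth deformation, so
validation uses an analytic phantom emulating a clinical protocol: 48³
voxels at 2.7 mm isotropic, 20 timeframes at 52.8 ms, VENC 120 cm/s.  It
contains a beating ellipsoidal chamber (radial scaling with a sin⁴ cycle
profile: zero displacement and a flat quiescent plateau at the configured
diastasis frame, full contraction — 25% of the radius — half a cycle away)
and a static curved tube with pulsatile parabolic through-plane flow
peaking at exactly 100 cm/s, in tissue (magnitude 0.3) and air (~0.02 with
Gaussian noise).  Air velocities carry Gaussian noise (σ = 0.05·VENC) plus
wrap-like uniform outliers in ±1.8·VENC injected into 1% of air voxels, so
both suppression rules have work to do.  All randomness derives from a
single seed.

Because the chamber map is a monotone radial scaling, it is diffeomorphic
by construction, its inverse is a 1D table inversion, and the rendered
frame images, the Eulerian velocity fields, and the dense truth deformation
fields are mutually consistent and exact.  The truth fields use the same
convention as Bₜ, so recovered and true fields compare directly; the
endpoint-error metric is the mean Euclidean norm of their difference over
the non-air foreground.  Chamber blood velocities are the analytic
wall-motion field rescaled so the cycle peak equals 25 cm/s (intra-chamber
blood moves faster than the wall the field derives from); vessel flow is
divergence-free in straight tube sections up to discretization.

**What the phantom does not emulate** — and hence what passing tests do not
show about clinical data: MRI signal formation (k-space sampling, partial
volume, eddy currents), through-plane chamber inflow/outflow, valve and jet
physics, signal voids, breathing or gating artifacts, anatomical
variability, and contrast-agent effects.  The phantom establishes that the
implementation recovers known motion (mean endpoint error ~0.07 voxels,
worst frame ~0.14), that the two registration passes are mutually
consistent, and that the pipeline's algebra (fusion, collapse in the
motion-free limit, reference-frame identity) is exact — not that the method
attains any particular accuracy on patient data.

## Numerical choices and degenerate inputs

* Interpolation: linear for warping and MIP rotation by default; nearest is
  exact for integer shifts and axis-aligned projections and is used where
  bit-exactness matters.
* MIP rotation resamples the volume with zero fill, so rotated corners
  never beat anatomy in the maximum; 36 projection angles per frame by
  default.
* Isosurfaces use marching cubes with vertices scaled to mm; the default
  level is 50% of the 99.5th intensity percentile (robust to hot voxels).
* Degenerate inputs: all-zero magnitude cannot be normalized (error);
  constant images register to a zero field (warning); an empty evaluation
  mask for endpoint error is an error; fusion with a missing field names
  the missing frames.
* Datasets require N ≥ 2 frames; all validation happens at construction.
* End-to-end determinism: identical config and seed give bit-identical
  NIfTI bytes; per-frame registrations are independent, so parallelizing
  them cannot change results (the reference implementation runs serially).

## Validation problem sizes

The test suite and the acceptance script run the default 48³ × 20-frame
phantom for registration recovery, inverse consistency, fusion and chamber
visibility; a 32³ × 8-frame zero-motion, noise-free variant for the
motion-free collapse identity (with per-frame air noise the frames are not
identical datasets and exact collapse is not expected — residuals of ~2e-2
concentrate on the handful of noise voxels that survive suppression); and
24³ × 4-frame phantoms for CLI round-trip and determinism checks.  The full
default pipeline (two registration passes of 19 frames each, fusion, 4D
warp) takes about one minute on one CPU.

## Known limitations

* No orientation-matrix (oblique slab) support: world coordinates are
  index × spacing; affines are carried through verbatim.
* Per-component velocity thresholding may keep a wrapped voxel whose
  components all fall below 1.5·VENC.
* The certainty floor that silences air can also silence genuinely
  low-contrast anatomy; on low-SNR acquisitions it may need lowering.
* Structures near the volume border rely on replicate-border sampling and
  can deform less reliably there.
* Exact field inversion (deriving Fₜ from Bₜ) would halve registration
  cost but is intentionally not implemented; the second pass is the
  reference behavior.
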