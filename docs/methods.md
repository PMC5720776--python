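# Methods

`selfgate3d` implements retrospective self-gating for 3D radial (stack-of-
stars) cardiac MRI of the mouse, together with a digital phantom that stands
in for the scanner. This note records the model, the defaults and the
reasoning behind the choices that were genuinely open.

## Acquisition model

The sequence is a golden-angle stack-of-stars gradient echo: Cartesian
phase encoding along the slab (kz, "partitions") combined with full radial
spokes in-plane. All partitions of one projection angle are acquired
back-to-back (partition-first ordering) and the angle then advances by
180°/φ ≈ 111.246°, which keeps the angular coverage close to uniform for
any spoke count. Defaults mirror the small-animal protocol: TR 4.2 ms,
10 partitions, 1600 projections (a ≈ 67 s scan), FOV 58 × 58 × 15 mm at
0.3 × 0.3 × 1.5 mm nominal resolution, four receive coils. Because the
central kz line of each projection passes through the k-space center, the
acquisition re-measures a "self-gating profile" every
TR × n_partitions = 42 ms, i.e. the gating signal is sampled at 23.8 Hz.

k-space coordinates are normalized to cycles/pixel in [−0.5, 0.5); spokes
span the full diameter with 2× readout oversampling (n_readout = 2 ×
matrix, an open choice — the protocol does not state it — made because
oversampled readouts are standard radial practice and reduce gridding
aliasing). With an even readout length the DC sample sits at index
n_readout//2 and is exactly zero.

## Digital phantom

The phantom emulates a post-contrast T1-weighted short-axis mouse thorax.
Intensities encode the contrast directly (blood 1.0, remote myocardium
0.35, hyperenhanced infarct 0.85, body-wall ring 0.25, lung 0.04, liver
0.70); no Bloch simulation is performed because the gating/realignment/
reconstruction chain operates downstream of contrast generation.

Components:

* a z-uniform static part — a thin elliptical body-wall ring (semi-axes
  11 × 9 mm, 1.8 mm thick) around near-dark lungs. Thoraces are mostly
  air; modelling the chest as a filled disk would bury the cardiac motion
  signal under static mass;
* the left ventricle — a cylinder over ~6 of the 10 slices: bright cavity
  blood inside a myocardial annulus (outer radius 4.2 mm, wall 1.3 mm)
  with a hyperenhanced sector of configurable arc (default 90°) fixed to
  the wall;
* a bright liver slab at the opposite end of the slab from the heart.

Cardiac motion has three mechanisms, all real contributors to in-vivo
self-gating signals:

1. radial contraction — the endocardial radius falls by
   `contraction_fraction` (default 0.30, a ~50 % area ejection fraction)
   over a raised-sine systolic pulse occupying `systolic_fraction` = 0.4 of
   the cycle, leaving late diastole quiescent;
2. longitudinal shortening — the basal end of the ventricle moves 1.5 mm
   toward the apex at peak systole (murine mitral-annular excursion scale);
   this is the dominant through-slab term in the z center of mass;
3. inflow enhancement — cavity-blood brightness is modulated by a zero-mean
   first harmonic of amplitude `blood_inflow_mod` = 0.45, emulating
   flow-related enhancement of unsaturated spins entering the slab in a
   short-TR gradient-echo acquisition.

Respiration translates the heart and liver along z with a Gaussian
inspiration bump (amplitude 1.2 mm, width 0.2 of the breath) so that most
of each breath is spent near end-expiration, as in ventilated rodents.
Cardiac cycle lengths are drawn per cycle from a truncated normal with
fractional SD `arrhythmia_jitter` (default 0.02); this is the knob that
exercises the ±30 % cycle-rejection rule. Rates default to the cohort
means of the protocol: 430 bpm and 78 breaths/min.

### Exact k-space evaluation

Every (projection, partition) line is evaluated at its own timestamp. The
frame decomposes as `static(x,y) + h(z;t)·dyn(x,y;r(t)) + g(z;t)·liver(x,y)`
with partial-volume z-occupancy profiles h, g, so each line's samples are
cached-NUFFT spoke lookups times analytic kz weights. The endocardial
radius is quantized to `n_radius_levels` = 32 precomputed states (sub-voxel
steps); `render_frame` applies the same quantization, so rendered frames and
simulated k-space describe exactly the same object. Against a
direct-summation DFT oracle the simulator is accurate to ~1e−7 relative.
Complex Gaussian noise is added with SD `noise_sigma` × the peak sample
magnitude (default 0.05). Coil sensitivities are smooth 2D Gaussian
profiles with linear phase placed around the FOV (constant along z); the
sum-of-squares magnitude is positive everywhere.

What the generator does **not** emulate: in-plane cardiac translation,
B0/eddy-current and gradient-delay artifacts, flow displacement artifacts,
anatomical texture, through-plane coil variation, and drift in the
respiratory baseline. Passing tests therefore demonstrate correctness of
the processing chain under idealized periodic motion with white complex
noise — not robustness to every artifact of real raw data.

## Self-gating

Per projection, the DC readout samples of all partitions are inverse-DFT'd
along kz into a z intensity profile per coil; the intensity-weighted mean
z position (center of mass, COM) gives one motion sample per 42 ms. A
virtual channel (sum-of-squares of the per-coil profiles) is appended.
Respiration and heartbeat are separated by zero-phase (forward–backward)
4th-order Butterworth band-passes at 1.0–2.5 Hz and 6.7–9.2 Hz — the
murine 60–150 breaths/min and 400–550 bpm ranges. Zero-phase filtering was
chosen so gating timing is not shifted relative to the acquisition
timestamps. The cardiac band's upper edge (9.2 Hz) must stay below the
profile Nyquist rate (11.9 Hz at 42 ms spacing); configurations that
violate it are rejected, and a warning is emitted below 2× the edge since
the heartbeat is then sampled at barely more than 3 profiles per beat.

Peak/valley detection starts from an initial rate taken as the dominant
in-band periodogram frequency, clipped into the physiological range.
A fixed mid-range starting rate is unreliable at realistic noise: spurious
local maxima between true beats inflate the rate estimate, and the
0.7×-interval minimum-distance rule then admits even more of them. The
spectral peak anchors the iteration; detection then proceeds exactly as a
rate-adaptive scheme — minimum peak spacing 0.7× the current mean
interval, rate re-estimated from the detected peaks (end-to-end, so
interior quantization errors telescope), repeated until the peak set is
stable (≤ 5 passes). The first and last 2 s are excluded from rate
estimation to avoid filter edge effects.

Channel selection follows stability criteria: the respiratory channel
minimizes the variance of the trace level at detected valleys (steadiness
of the end-expiration baseline — "valley position" is interpreted as the
amplitude at the valley instants), the cardiac channel minimizes the
variance of R–R intervals; ties break to the lowest channel index and
channels where detection fails are excluded. On simulated data the virtual
sum-of-squares channel usually wins both roles, as its noise is ~√n_coils
lower.

## Realignment

A projection's time is the timestamp of its middle partition line.
Projections are split into six equal-width bins of the filtered respiratory
amplitude between the robust (2nd–98th percentile) extremes; the most
populated bin is kept (ties resolve toward the lowest-amplitude bin,
nearest end-expiration). Cardiac cycles are delimited peak-to-peak, because
the quiescent phase is defined as the phase right before the next waveform
peak (near end-diastole). The number of cardiac phases is the rounded mean
number of projections per R–R interval; cycles outside [0.7, 1.3] × that
mean are discarded, with the mean computed once over all cycles
(single-pass; an iterative re-mean after discarding is available behind a
flag but off by default, the simplest faithful reading). Within a kept
cycle, a projection at cycle fraction f maps to phase ⌊f · n_phases⌋.
At 430 bpm and 42 ms profiles this yields 3 phases and, for a 1600-
projection scan, on the order of 50–115 spokes per phase in the selected
bin — far below the in-plane Nyquist count (π/2 × matrix), which is what
motivates the compressed-sensing reconstruction.

## Reconstruction

kz is fully sampled, so a centered inverse DFT along the partition axis
decouples the volume into independent 2D radial problems per slice, each
reconstructed per coil and combined by sum of squares (no SENSE/ESPIRiT
calibration, keeping the chain purely data-driven).

**Regridding** uses the adjoint NUFFT with density-compensation weights
initialized to the analytic ramp (|k| cell area; the shared DC sample gets
half the first ring's weight) and refined by 8 Pipe–Menon iterations
(w ← w/|F Fᴴ w|), with growth capped at 2× the ramp so weights cannot blow
up inside azimuthally undersampled gaps. The plain ramp leaves ~10 %
residual shading on a fully sampled phantom; the capped refinement reaches
~3.5 %, and on undersampled data it behaves no worse than the ramp.

**Compressed sensing** solves, per slice and coil,
argmin λ‖Tρ‖₁ s.t. ‖d − P F ρ‖₂² < ε, with T the *cyclic* temporal
total-variation operator along the cardiac-phase axis (the cardiac cycle is
periodic; a non-cyclic variant is a one-line change). The solver is a
Bregman-type iteration: each round runs up to 30 proximal-gradient steps —
a density-weighted data-consistency gradient (the smooth ramp weights act
as a preconditioner that equalizes convergence across spatial frequencies;
the step size comes from a deterministic power-iteration estimate of
‖FᴴWF‖) followed by the temporal-TV proximal map (4 Chambolle dual
iterations) — and then adds the k-space residual back onto the data
(2 rounds by default), restoring contrast lost to shrinkage. The inner
loop stops early once the residual decay stalls (two consecutive
iterations shrinking by < 3 %) or the ε-ball is reached. This
discrepancy-style stopping is essential: iterating the data term to
convergence forces measurement noise and intra-phase motion inconsistency
into the undersampled angular gaps (the residual keeps falling while the
image degrades). λ defaults to 0.05 × the peak of the density-weighted
adjoint image, configurable; no rigorous selection criterion is claimed.
The data-consistency residual is logged per round and must be
non-increasing; five consecutive rises raise a solver error. With λ = 0
the solver agrees with a conjugate-gradient least-squares oracle to
< 0.1 % on consistent data.

NUFFT: Kaiser–Bessel gridding, oversampling 2.0, kernel width 8, Beatty
shape parameter, analytic sinh deapodization. Forward/adjoint agree with
direct summation to < 1e−7 relative and pass an adjoint dot-product test at
machine precision; coordinates at the ±0.5 boundary wrap periodically.

Reported image errors use NRMSE after an optimal global intensity scaling,
since magnitude reconstructions carry arbitrary absolute scale; references
for dynamic comparisons are phase-window means of finely sampled noiseless
frames multiplied by the coil sum-of-squares profile.

## Quantification

CNR = (mean cavity − mean wall)/√(SD²cavity + SD²wall) with ROI-local
statistics (iterative reconstructions have spatially varying noise).
Infarct size is the enhanced fraction of the wall,
area_infarct/(area_infarct + area_healthy), segmented by Otsu's threshold
inside a wall mask (scale-invariant); a fixed threshold or an explicit
infarct mask can override it, which replaces interactive manual outlining.
ROI masks generated from phantom geometry shrink the wall ring radially by
a configurable margin so partial-volume voxels at the blood/wall interface
do not contaminate the ROI — the automated analogue of drawing the ROI
inside the wall. Agreement between two sets of measurements uses ordinary
least squares plus Bland–Altman bias and 95 % limits (bias ± 1.96 SD of
the differences).

## Problem sizes

The test-suite and acceptance runs use a 128² in-plane matrix for the
protocol-scale gating study (1600 projections × 10 partitions × 4 coils,
~15 s to simulate) and a 64², single-partition, 3-phase × ~60-spoke
problem for the reconstruction comparison; these sizes preserve the
spokes-per-phase regime of the full protocol while keeping a complete run
in tens of seconds. All stages accept the full 192² protocol matrix.

## Known limitations

* Coil sensitivities are constant along z; through-slab coil variation
  would add further gating channels but also break the simulator's exact
  static/dynamic decomposition.
* Respiratory binning acts on the band-passed COM trace, so bin edges are
  defined on the oscillatory component rather than the raw baseline.
* The CS solver reconstructs coils independently; joint-coil models
  (SENSE-type) would improve conditioning at higher acceleration.
* Cardiac phases are few (3 at 430 bpm / 42 ms profiles); temporal TV has
  correspondingly coarse leverage, and intra-phase motion blur is part of
  the reconstruction error floor by construction.
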