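# Methods

`megdeep` is a simulation-driven re-implementation of a generative-model
MEG analysis for detecting deep-brain (hippocampus/amygdala)
contributions to sensor data during a two-condition (CS+/CS−) delay
threat-conditioning design. This note documents the models, the
synthetic-data conditions, the numerical choices, and what the tests do
and do not establish about real data.

## Source spaces and the desk-scale head

The source space is a set of labelled closed triangular meshes: a
cortical shell and four ellipsoidal deep structures (bilateral
hippocampus and amygdala). Sources sit at mesh vertices, oriented along
the outward vertex normal. Coordinates are head-centred millimetres
(+x right, +y anterior, +z superior); vertex indexing is 0-based.

The default geometry is a *scaled-down head* (~0.42 of adult linear
dimensions, cortex mean radius 32 mm). The scale reconciles two
requirements that are incompatible at life size: a realistic mesh
resolution (mean edge ≈ 4.5 mm cortex, ≈ 3.5 mm hippocampus, the
resolution regime of MRI-derived surface meshes) and a source count
(~640 cortical + ~110 deep vertices) that keeps hundreds of full
Bayesian inversions tractable. Uniform scaling preserves the relative
depth, size and neighbour relations that shape the inverse problem; the
deep-structure volumes are scaled accordingly (hippocampus 487 mm³,
amygdala 145 mm³, both exact against the analytic ellipsoid volume by
construction). The cortical shell is a sphere deformed by a seeded sum
of smooth radial bumps (amplitude 6 mm, angular concentration κ = 12):
the deformation is what gives cortical normals a tangential component
(mean ≈ 14° from radial), without which cortical sources would be
silent in the spherical conductor.

Rigid mesh displacement moves vertices only — no remeshing — so edge
lengths, normals and volumes are preserved exactly and displacement is
exactly invertible.

## Forward model

The conductor is a single homogeneous sphere fitted to the cortical
vertices by linear least squares. Dipole fields use the closed form for
a current dipole in a conducting sphere, with the constant prefactor
dropped (consistent arbitrary units throughout). The radial dipole
component is exactly silent — the characteristic blindness of MEG
sphere models — and tangentialisation is therefore implicit, not a
modelling step. Axial gradiometers are the difference of the axial
field at the pickup coil and at a second coil 50 mm further out along
the coil axis; ~100 radially oriented sensors sit on a Fibonacci
lattice over a 55 mm helmet cap.

The patch basis (the spatial extent of a "sparse prior") is the matrix
exponential `G = exp(σ(A_n − I))` per mesh, with `A_n` the
degree-normalised adjacency `D^-1/2 A D^-1/2`. The symmetric
normalisation (rather than the row-normalised random-walk operator) is
used so each block is symmetric positive definite; the two are
spectrally equivalent. Blocks are independent per mesh, so no patch
straddles two structures. Default σ = 0.6, the conventional smoothing
of sparse-patch inversions; the construction and σ are configurable
because no published value pins them down.

## Synthetic experiments: the study conditions

The generator emulates the design whose analysis this package
implements: 4 s visual cues, two conditions with equal counts per block
(blocks of 40 trials, 10 blocks per phase), an auditory US at 3.5 s on
50% of CS+ trials during maintenance and never during extinction,
epochs −1..4 s at 600 Hz (downsampled to 300 Hz in preprocessing).

Source structure, per trial:

- **Deep theta (5 Hz)**: baseline amplitude 3.6 until 130 ms post-cue,
  then a 50 ms ramp to the condition amplitude — CS− 4.5, CS+ 3.0
  (safety > threat, the direction reported for humans). Left and right
  hemispheres of each deep region share one signal so the injected
  effects survive hemisphere selection downstream.
- **Deep gamma**: 40 and 90 Hz components (amplitudes 1.2/0.9),
  condition-independent.
- **Hippocampus→amygdala coupling**: the amygdala theta phase is the
  hippocampal phase minus π/4 plus von-Mises jitter redrawn each theta
  cycle. The concentration is solved so the *expected per-trial phase
  lag index equals the requested coupling strength* — a closed-form
  oracle. Strength is 0.1 on CS− trials and grows linearly by 0.07 per
  block on CS+ trials only (0.1 → 0.73), clipped to [0, 1].
- **Cortical background**: a diffuse field of 100 cortical patch
  sources of 1/f noise (0.45 RMS each — the same total background
  variance as ~20 unit-RMS sources, spread thinly), the competing
  activity the cortex-only model should explain. A background this
  diffuse matters: a handful of strong point-like generators on the
  desk-scale cortex makes the free energy hinge on whether a random
  prior draw happens to cover each generator, swamping the anatomical
  comparison with placement luck that has no analogue at realistic
  cortical mesh sizes.
- **US burst**: a broadband 500 ms burst (amplitude 2.0) on reinforced
  trials, after the analysis windows' 3.5 s endpoint.
- **Sensor noise**: white, scaled to a trial-average signal-to-noise
  variance ratio of 0 dB by default.

Two generator properties are deliberate physiological commitments
rather than conveniences. First, simulated sources are *extended
patches* (unit-norm Green's-function columns), not point dipoles: the
premise for measurable deep MEG signals is an activated volume of
coherently oriented, dense tissue, and patch sources also match the
spatial model class of the inversion, as in published simulation
studies of deep-source recovery. Cortical background patches use the
inversion's σ = 0.6; the deep sources use a much smaller extent
(σ = 0.2), because the activated deep volume the detectability argument
rests on is ~0.2–0.3 cm³ — essentially a vertex neighbourhood at desk
scale. The deep extent matters for the displacement analysis: a deep
source as smooth as a cortical patch is nearly position-tolerant at
millimetre displacements, and on a miniature head an anteriorly
displaced deep mesh can even gain generic explanatory power as it
approaches the cortical shell (a confound documented under
limitations). Second, active deep
vertices are drawn from the sensor-visible half of each deep mesh
(patch lead-field norm above the within-mesh median): a near-radial
patch in a spherical conductor is silent *by physics*, and the study
being emulated presumes a measurable deep signal. Without this rule a
noticeable fraction of seeds simulates an essentially invisible deep
source — a statement about the sphere model's blind axis, not about the
analysis.

The deep theta amplitudes put roughly half to three quarters of the
noiseless sensor variance in the deep sources under the default
geometry (the exact share depends on the seeded vertex draw). This is
the "strong deep signal" regime the
original high-precision recordings were designed to reach; the
detectability and displacement results below should be read as
conditional on it. What the generator does *not* emulate: realistic
evoked-response morphology, correlated sensor noise, head movement,
coregistration error, volume-conduction errors of realistic head
shapes, or behavioural responses. Passing tests therefore demonstrate
the *internal* correctness and sensitivity of the analysis under its
own assumptions, not field performance on real recordings.

## Preprocessing and data reduction

Zero-phase filtering throughout (forward–backward application): a
second-order IIR notch at 50 Hz (Q = 35; narrow, to leave theta
untouched), polyphase anti-aliased downsampling 600 → 300 Hz, and a
4th-order Butterworth 1–15 Hz pass for eyeblink flagging (trials whose
designated frontal channel exceeds 4 SD of the pooled distribution are
flagged but never removed).

Before inversion the data are reduced to `min(120, N_channels)` spatial
modes (leading left singular vectors of the gain matrix) and 4 temporal
modes. The temporal basis is computed from the *trial-averaged*,
spatially projected data over the analysis window and applied to every
trial: a single shared basis is required for a common covariance model.
(The basis is completed to a full orthonormal set when more temporal
modes than the average's rank are requested, so full-mode reduction is
lossless.) The sample covariance is the running average over trials,
normalised by trials × temporal modes — the effective sample count
N_t used in the free energy.

## Inversion and model scoring

Hyperparameters of the covariance mixture (one rank-one component per
patch plus an identity noise term; all components trace-normalised so
the shrinkage prior is scale-relative) are optimised by Fisher-scoring
restricted maximum likelihood on the log scale, with Gaussian priors
N(−4, 16) per log hyperparameter (ARD: unsupported components collapse
to the prior). Steps are backtracked until the free energy does not
decrease, so trajectories are monotone; convergence is ΔF < 1e-3 within
128 iterations; covariance inverses use Cholesky with escalating jitter
only on numerical failure. The free energy splits into an accuracy term
(expected Gaussian log likelihood of the reduced data) minus a
complexity term (KL divergence of the hyperparameter posterior from its
prior, with the posterior covariance taken as the inverse Fisher
information).

MSP restarts redraw the pseudorandom patch seeds 16 times under the
model's fixed allocation (C: 100% cortex; H/A: 90/10; HA: 80/10/10,
deep shares split evenly between hemispheres) and keep the restart with
maximal F. At this desk scale the restart-to-restart F spread is large
(the evidence landscape over patch placements is rugged), which is
exactly why the max-over-restarts convention matters; restart seeds are
shared across compared models to cancel placement luck from the
comparison. All MSP variants share one head model and one lead field —
a variant is purely a prior allocation — so equal complexity across
models holds by construction. EBB subsets the source space instead
(cortex plus the included deep meshes) and uses two hyperparameters:
the beamformer-power empirical prior `q_v = 1/(l_v' C_y^{-1} l_v)` and
noise.

Model comparison sums F across participants (fixed-effects convention)
and calls |ΔF| ≥ 3 (~20:1) decisive. The displacement sweep rigidly
translates the deep meshes (default {1, 2, 3, 5, 10} mm; the tested
grid is configurable because the original step sizes are not published
beyond the 3 mm statement), rebuilds the lead field, reuses the same
prior seed vertices (sources ride with the meshes; the patch basis is
topology-only and hence translation-invariant), and records F relative
to the true anatomy.

## Oscillation, connectivity and statistical analyses

Posterior currents for time-resolved analyses are read out by applying
the spatial inverse operator M to the full-band spatially projected
data. The rank-4 temporal-mode expansion is also available, but a
4-dimensional temporal subspace cannot carry 1–120 Hz single-trial
content, so the full-band read-out (the reference convention for this
family of inversions) feeds the spectral analyses. The per-region time
course is the vertex with maximal trial-averaged RMS current over the
analysis window, all conditions pooled (no condition-dependent
selection; ties break to the lowest index), with a region-average mode
as the alternative.

Morlet decomposition: 7 cycles at all frequencies, power of the
analytic coefficients on the fixed grid 1–120 Hz × (−1000..3500 ms in
3 ms steps). The coefficients are computed on the native 300 Hz grid
and linearly interpolated to the 3 ms grid (the stated resolution is
finer than the sampling interval; interpolation of the analytic signal
is the configurable choice made here). Wavelet envelopes are truncated
at ±3.5 SD or the epoch length, whichever is shorter — relevant below
~2 Hz on 5 s epochs, where the kernel is gently truncated rather than
refused; the 1 s pre-cue baseline absorbs edge effects. Band summaries
(theta 1–8, low gamma 30–70, high gamma 70–120 Hz; the printed band
edges overlap at 70 Hz and 70 is included in both gamma bands) average
power over band bins and 0–3500 ms first, then take the natural log.
Normalisation divides by the participant-wide maximum single-trial
power.

PLI: theta bandpass (4th-order bidirectional Butterworth over the full
epoch), Hilbert phases, phase differences wrapped to (−π, π] before
taking the sign, averaged over 0–3500 ms per trial, modulus last. The
wrap is required for the sign to be meaningful, and the modulus is
required by the statistic's [0, 1] range; sign(0) = 0, so identical
signals score 0 — zero-lag (volume-conduction-like) coupling is
invisible by design. The PLI window matches the band-power interval.

Cluster inference: per-bin unpaired two-sample t tests on log power,
two-sided bin threshold p < .05, 4-connected clusters scored by Σ|t|,
compared against the permutation null of the maximum cluster mass over
1000 trial-label reshuffles (p = (1 + #{null ≥ obs}) / (1 + N)).
Zero-variance bins get t = 0 with a warning.

Mixed models use REML (statsmodels MixedLM): band power ~ CS × Time ×
Region with a random intercept and Region slope per participant
(amygdala is the reference region, fixed for reproducibility; Time is
the raw block number 1..10); PLI ~ CS × Time with a random intercept.
Reported tests are marginal Wald F tests per fixed term (all terms here
have numerator df 1; denominator df is the observation count minus the
fixed-effect rank — the residual-scale convention). Band-level p
values are Bonferroni-corrected ×3. Non-convergence is flagged on the
result, never raised. The post-hoc within-condition trend is
value ~ Time with a random intercept.

## Problem sizes used in validation

The validation suites run the full pipeline at the desk scale chosen
for this package: ~100 sensors, ~750 sources, 200-trial phases (10
blocks × 20 trials — half the full 40-trial blocks, which remain the
generator default), 5 participants for the cohort analyses, 10 seeded
runs for the detectability and displacement experiments (displacement
at 100 trials and 8 restarts; paired seeds make the within-sweep
comparison far less restart-sensitive than the between-model one), and
reduced grids (30 trials, 12 × 40 bins, 150 permutations, 200
repetitions) for the type-I-error study of the cluster test. The
acceptance script's displacement target uses the full 200-trial, 16-
restart setting.

## Known limitations

- The single-sphere conductor exaggerates the radial blind spot
  relative to realistic head models; detectability numbers are specific
  to the simulated geometry and SNR and are not field estimates.
- Free-energy magnitudes (thousands of log units) are much larger than
  on real recordings, because the generator's source structure lies
  inside the model class and N_t is large; only differences and their
  signs are meaningful.
- Bilateral deep sources share a time course by design; the pipeline
  therefore cannot (and does not claim to) resolve hemispheric
  asymmetries.
- The LME denominator df convention is residual-scale and will not
  reproduce any particular published integer df; F statistics and p
  values are the package's own.
- EBB is implemented with a diagonal empirical source prior (no
  off-diagonal local covariance), as one defensible reading of the
  beamformer prior.
- In the displacement sweep, a displaced deep mesh changes not only its
  match to the true sources but also its generic usefulness as a basis
  (fields strengthen toward the cortical shell). On the miniature head
  this confound is visible for individual datasets at large anterior
  displacements; the reported statistic is therefore the median curve
  over seeded datasets, which is dominated by the mismatch effect.
- PLI values computed on windows without surrounding context (no
  baseline/tail) carry a percent-level edge bias from the finite-window
  Hilbert transform.
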