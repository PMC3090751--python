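# Methods

This note records the models the package implements, the defaults it
ships, and the choices made where the design was genuinely open.

## Containers and conventions

Head-centered coordinates in cm (x right, y anterior, z superior);
0-based sample indices; epoch time `t = t0 + i/fs` with negative times
pre-stimulus; EEG in µV, MEG magnetometer data in fT, source moments in
nA·m. The internal epoch container is a directory (YAML header +
little-endian float32 payload, trial-major; condition table and layout
as editable text). Text is authoritative: hand-editing the condition
file changes what is read back. float32 matches acquisition precision
and halves disk cost.

## EDF/BDF

The readers/writers implement the published 16-bit EDF and 24-bit
Biosemi BDF layouts directly. Physical scaling is the affine
digital↔physical map per signal header; the writer re-parses its own
serialized ASCII range fields before quantizing, so write→read agrees
to one quantization step. BDF data are re-referenced to Cz on read
(Biosemi recordings are stored against the CMS electrode and must be
re-referenced); a BDF file without a Cz channel is an error listing the
labels present. Trigger events are emitted wherever the status sequence
changes to a new nonzero value; a nonzero value at sample 0 counts as a
change from the rest state 0.

## Filtering and preprocessing

Filtering applies to continuous data only, before epoching — this
avoids per-epoch edge artifacts and keeps sub-hertz high-pass cutoffs
usable. Families: Butterworth IIR (applied forward–backward when
zero-phase is requested, squaring the magnitude response), Kaiser-window
and least-squares FIR (odd length, linear phase; one-pass application
compensates the group delay). Each realized filter carries a
transfer-function evaluator so settings can be inspected before use.

Ocular correction is regression-based: condition averages are first
subtracted from every trial so event-related activity cannot bias the
fit; EEG residuals are regressed on EOG residuals pooled over trials
and time; the scaled raw EOG is subtracted from the raw EEG. By
construction the coefficients are invariant to any event-locked
component (verified by a property test). Blinks and saccades are not
distinguished — one pooled propagation coefficient per EOG/EEG channel
pair. An identically-zero EOG channel yields zero coefficients and
unchanged data; a constant-nonzero (or collinear) EOG is rejected as
singular.

Condition recoding: `balance` keeps the chronologically first k trials
per code (k = smallest per-code count) — deterministic, no RNG in
preprocessing; `odd_even` maps successive occurrences of code c to
10c+1 / 10c+2, collision-safe for codes below 10.

## Artifact control

Statistics per trial × sensor: absolute maximum amplitude, SD over time
(n−1 denominator), maximum absolute first difference; optionally per
user-defined time interval (the per-interval maxima feed the
thresholds).

Automatic thresholds: `median + k·max(IQR, 0.35·median)` over trials,
k = 3. The proportional floor exists because per-trial *maximum*
statistics are extreme-value distributed: their IQR underestimates the
tail enough that a pure median+3·IQR rule flags roughly 1% of perfectly
clean sensor-trials (measured on Gaussian fixtures). The floor sets the
smallest deviation treated as artifactual to about k·35% of the typical
statistic; `relative_floor=0` restores the pure IQR rule. Thresholds
serialize to an editable text file and are re-read after review; the
global (whole-trial) limit applies the same rule to each trial's
across-channel median.

Interpolation feasibility: for every sensor, the forward field of a
unit radial source directly beneath it at 80% of the head radius (a
peaked, sensor-specific map; tangential for MEG, where radial sources
are silent) is reconstructed at the bad sensors from the good ones.
The error is the RMS mismatch at the deleted sensors normalized by the
*whole topography's* RMS — normalizing by the deleted subset alone
would divide by near-zero for topographies peaked far away and fail
even single-sensor deletions. A trial passes when at most 10% of
topographies exceed 20% error (both configurable). On a 64-channel
whole-head layout this passes isolated deletions and fails a contiguous
quarter-array patch at the cap edge; a 32-channel array legitimately
fails single deletions of these focal test maps — its spatial sampling
cannot recover them.

Repair weights each contributing sensor by `w = 1/(1+z)`, z being the
robust z-score of its SD within the trial's distribution (clipped at
0): noisy-but-unflagged sensors influence the fit less. Weighted
fitting enters as inverse-variance scaling of the minimum-norm solve.

Two-pass referencing: pass 1 in the recording reference (sensor
artifacts cannot contaminate all channels through the average), flagged
sensors interpolated, data re-referenced to the average, pass 2
re-derives thresholds and flags; final flags are the union. MEG and
single-reference analyses use one pass.

## Forward models

EEG: four concentric spherical shells. Defaults: boundary radii
8.4/8.8/9.2/9.6 cm and conductivities 0.33/1.0/0.0042/0.33 S/m
(brain/CSF/skull/scalp, standard literature values). The potential is
expanded per Legendre degree; for each degree a 7-unknown linear system
(interface continuity of potential and radial current, outer Neumann
condition, per-layer radius normalization for numerical stability)
gives the scalp gain. The series is truncated adaptively when the
largest term falls below 1e−6 of the accumulated value (cap 200
degrees; exceeding the cap raises, reporting the achieved tolerance).
With equal conductivities the solve reproduces the classical
homogeneous-sphere series — the acceptance suite checks this against an
independently derived closed form. Sensors are radially projected onto
the scalp sphere; lead fields are average-referenced (every column sums
to zero).

The source grid (2/4/6/8 cm shells, 655 points each) is kept separate
from the conductor geometry: all source shells lie strictly inside the
innermost conductor boundary, which keeps the series convergent even
for the most superficial (8 cm) shell. Default active shells are the
outer two; single-shell analyses default to 8 cm.

MEG: the closed-form field of a current dipole in a spherically
symmetric conductor, projected on each coil normal. Only the conductor
*center* enters the formula; the acceptance oracle (a surface-integral
quadrature of the boundary potential added to the primary dipole field)
confirms both the field values (<2%) and their independence of the
assumed conductor radius. Radial dipoles produce identically zero
field, so MEG source models carry tangential orientations only.

Equidistant sphere points: Fibonacci-spiral initialization refined by a
fixed schedule of inverse-square repulsion steps (300 iterations up to
256 points, 200 beyond; step projected tangentially, linearly decaying,
normalized by the largest force). Deterministic by construction; n=2
returns the exact antipodal pair, n=4 converges to the regular
tetrahedron within 0.1°, and larger sets reach ≥80% of the hexagonal
packing asymptote.

## Inverse, interpolation, CSD

`W = Lᵀ(LLᵀ + λ²_abs I)⁻¹` with `λ_abs = λ·sqrt(trace(LLᵀ)/n_sensors)`
— λ is unit-free and portable across modalities. No depth weighting or
noise normalization: this is the classical minimum norm; extensions are
out of scope. Consequences the user should know: localization is
biased toward superficial sources, and at low λ (≲0.02) residual noise
can dominate weakly-seen rim sources — λ = 0.05 is the working default
for measured data, 0.01 for noiseless benchmarks.

Interpolation is inverse-forward: minimum-norm fit on the outermost
source shell from the available sensors, forward projection to the
target positions. The "stiffness" of the interpolant is therefore
governed by the physical lead field and λ, not an abstract spline
order. For EEG the fit is referenced to the good-sensor mean and the
offset restored on prediction, so the caller's reference convention is
preserved. CSD re-expands the fitted sources with each degree scaled
by −ℓ(ℓ+1)/R² (the angular Laplacian on the scalp sphere, µV/cm²); a
constant map yields exactly zero because the average-referenced lead
field annihilates it.

Minimum-norm localization benchmarks use a 128-channel layout: the
655-point source shell at 83% of the scalp radius is spatially aliased
by a 64-channel array (flat power plateaus around the peak), while 128
channels recover 50/50 noiseless superficial tangential dipoles within
two grid neighbors.

## Statistics

The ANOVA engine evaluates all main effects and interactions of up to
six crossed within factors and three between factors, point-by-point
over arbitrary trailing axes. Effects are inclusion–exclusion
(Möbius) combinations of marginal cell means; each within effect (and
its between interactions) is tested against the matching
within×subject-within-groups interaction, between effects against
subjects-within-groups. Balanced designs reproduce pingouin exactly
and satisfy the F = t² identities to 1e−9. Unbalanced between groups
use unweighted (harmonic-mean) cell means; this reproduces sum-contrast
Type III repeated-measures ANOVA (verified against an external
reference and frozen as a fixture). Sphericity is not corrected by
default; the Greenhouse–Geisser epsilon is available on request.
Zero-variance t tests return ±inf with p=0 (or t=0, p=1 for zero
effect) plus a degeneracy flag instead of NaN.

Permutation tests: sign flips (paired) or group relabelings
(independent t, one-way F); exact enumeration up to a configurable cap,
otherwise seeded Monte-Carlo with the add-one estimator
`p = (1+#{perm ≥ obs})/(1+n_perm)`. Only single-factor permutation
schemes are provided; multi-factor permutation is a known limitation.

Post-hoc spatiotemporal filtering keeps a significant point only if it
lies in a run of ≥ m consecutive significant samples on its sensor and,
at that moment, the sensor plus its graph neighbors contribute ≥ s
significant sensors. Adjacency = pairs within 1.3× the median
nearest-neighbor distance, configurable.

## Time-frequency

Morlet wavelets `σ_t = m/(2πf)`, default m = 7 cycles, truncated at
±3σ_t, unit energy. Total power averages single-trial magnitude
squares; evoked power transforms the average; induced = total − evoked,
floored at zero (the flooring only acts on numerical noise — the
identity is exact beforehand). The average-subtraction estimator of
induced power is intentionally not the default. Samples within 2σ_t
of the epoch edges are flagged invalid rather than zero-padded
silently. Frequency grids default to logarithmic spacing when the
range spans more than a factor of 4.

## Synthetic data

The generator is the package's ground-truth instrument, and its
defaults are the study conditions of the validation suite: 250 Hz
sampling, epochs −0.2…0.6 s, 20 trials, Gaussian-pulse sources (center
150 ms, SD 30 ms, 20 nA·m) on scalp-sphere layouts (EEG 8 cm covering
the upper 3/4 of the sphere with the vertex sensor as Cz reference;
MEG 10 cm radial magnetometers). Four noise classes: white
(iid/sensor/sample), temporally correlated (AR(1), one shared random
topography — what distinguishes it from sensor noise), sensor noise
(iid with per-sensor lognormal amplitude spread), brain noise (fresh
random dipoles per trial through the forward model — spatially
correlated like real background EEG). Ocular artifacts are 400 ms
raised-cosine blinks from a dipole pair above the eyes, Poisson-timed,
frontal-positive. All randomness flows from one mandatory seed through
numpy's PCG64.

What the simulator does not emulate: realistic head geometry,
sensor-specific drift/line noise, non-stationary background rhythms,
muscle artifacts. Passing tests therefore demonstrate correctness of
the algorithms under the spherical model and Gaussian-family noise, not
performance on any particular recording system.

## Problem sizes in the validation suite

The acceptance tests use 64–128 sensors, 300–655-point source grids,
20–50 replications or test sources, 500–1000-point null simulations for
the statistical calibration checks, and a 20-replication end-to-end run
(simulate → filter → epoch → SCADS → average → inverse) scored by
peak-to-truth angular distance ≤ 2 grid spacings. The whole suite runs
in well under a minute of compute per module on one core.

## Known limitations

* Spherical conductors only; no BEM/FEM, no MRI coregistration.
* Classical minimum norm only (no LORETA/beamformer/depth weighting).
* Gratton correction does not separate blinks from saccades.
* Permutation tests cover single-factor designs.
* Heavily unbalanced between designs get unweighted-means Type III
  analysis; cell-weighted alternatives are not provided.
* EDF writing targets plain EDF (no EDF+ annotations).
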