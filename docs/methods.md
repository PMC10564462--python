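# Methods

## The estimation problem

The package estimates, per time point, how distinctly each binary task
variable of a factorial decision-making design is represented in
trial-wise multichannel activity. All variables are analyzed jointly over
the *unique conditions* — the occupied combinations of the included
variables (32 in the full design: task × stimulus × choice × mapping ×
confidence, with response and accuracy deterministic given the others).
Working at the condition level is what makes the estimates mutually
confound-free: the contrast for one variable is balanced over the levels
of every other included variable, so, e.g., choice information cannot be
driven by stimulus or motor-response patterns even though choices
correlate with both.

## Cross-validated MANOVA

Within each cross-validation fold, condition patterns are the per-condition
trial means (`B = X⁺Y` with an indicator design `X`). Distinctness is

    D = (g / n_test) · δ_train Σ⁻¹ δ_test',      δ = C'B,

where `C` is scaled ±1/q_half so `δ` is the difference of level-averaged
condition-mean patterns, and

    g = √((C_tr' X'X C_tr)(C_te' X'X C_te)) / ((C_tr'C_tr)(C_te'C_te))

with `X'X` the diagonal matrix of test-fold condition counts. Properties
worth knowing:

* For `C_train = C_test` the expression is algebraically identical to the
  trace form `tr(B_tr' P (X'X) P B_te Σ⁻¹)/n`, `P = C(C'C)⁺C'` — the
  classical cross-validated MANOVA statistic. The acceptance suite checks
  this equivalence against dense-matrix evaluation on 200 random instances.
* For distinct contrasts (cross-variable, cross-context) the trace form
  degenerates: its condition-space factor `C_tr'X'X C_te` vanishes whenever
  the two contrasts have disjoint support or are orthogonal under a
  balanced design, which would make cross-context decoding identically
  zero regardless of the data. The geometric-mean scale `g` is the
  continuous extension that (i) reduces exactly to the classical statistic
  in the within case, (ii) is invariant to contrast scaling, and
  (iii) makes cross- and within-context values directly comparable, so the
  cross/within ratio is 1 when the two contexts share one pattern.
* Because `δ_train` and `δ_test` come from independent data and
  `E[Σ̂⁻¹] ∝ Σ⁻¹`, `D` has mean zero under the null; negative estimates
  are legitimate and are never clipped.

**Noise precision.** `Σ⁻¹` is estimated per training fold from a baseline
time point (default −0.5 s, before the first cue): residuals after removing
condition means give `S = Ξ'Ξ`, shrunk as `(1−λ)S + λ(tr(S)/p)·I`
(λ = 0.05) and inverted with the scale `fE − p − 1`, `fE = n_train −
rank(X)`, which makes the inverse-Wishart mean exact under Gaussian noise.
Shrinkage targets the *scaled* identity so the estimator is invariant to
the overall data scale; exact invariance to arbitrary invertible channel
transforms holds at λ = 0 (tested), and approximately at the default λ.
The regularization is applied to `S`, not to `Ξ` — with the identity-target
convention the two differ only in parameterization.

**Folds and seeds.** The fold count equals the lowest per-condition trial
count; within each condition trials are dealt round-robin after a seeded
shuffle, so every fold's training and test sets contain every condition.
Each analysis additionally requires `N + K + 1` trials (`N` channels, `K`
independent variables). Analyses are repeated over 10 random fold
partitions by default and averaged before smoothing; asymmetric requests
are averaged over both train/test direction assignments.

**Smoothing.** Unit-sum Hann kernels: 500 ms FWHM for time courses, 100 ms
separable for time × time generalization matrices, applied after seed
averaging and before group statistics; edges renormalize over the kernel's
valid support, so constants are preserved.

## Preprocessing

Robust piecewise polynomial detrending (600 s pieces; linear then
10th-order fits, each with ≤3 reweighting iterations masking samples beyond
3 robust SDs — constants the cited detrending literature leaves free),
zero-phase order-4 Butterworth low-pass at 10 Hz followed by integer-factor
decimation to 20 Hz (the cutoff may equal the output Nyquist, matching the
standard choice for this design), per-run z-scoring of every
(channel, time) cell over trials, and PCA retaining the k = 75 leading
components of the pooled trial × time data, computed once and applied to
all time points.

## Group inference

Cluster-based sign-permutation tests: per-point one-sample t over subjects,
cluster-forming at p < 0.05 (per requested tail), cluster mass = sum of
t-values, and a max-mass null over 10,000 random ±1 subject sign flips with
the +1 finite-sample correction (p-resolution 1/(n_perm+1)). 2D grids use
4-neighborhood contiguity. Whether two representations differ is tested by
comparing empirical cross-decoding against `E12` (one-tailed for deficits)
on the window where information exists — where both within-context values
are at noise level the comparison is meaningless, and near-zero `D`s make
`E12`'s sign bookkeeping slightly anticonservative for the deficit tail.

## Single-trial readouts and geometry

The projection axis is the whitened training contrast `Σ⁻¹δ_train`,
applied to held-out trials only — the linear statistic whose
train × test product averages to `D`, which keeps single-trial and
aggregate readouts consistent. Stimulus predictability is the fraction of
trials whose projection sign matches the stimulus class. The four
choice × accuracy cells are placed on the choice axis from signed
`√D` distances of three cell pairs (train-on-all-choices model),
least-squares embedded on a line and normalized to correct-no = −1,
correct-yes = +1. Representational layouts use length `√D` and angle
`arccos(D_cross/√(D1·D2))`.

## Behavioral model

Equal-variance SDT: `d′ = z(H) − z(FA)`, `c = −(z(H)+z(FA))/2`, with a
1/(2N) boundary correction for extreme rates; the criterion is reported as
standard `c` with the relative `c′ = c/d′` also exposed. meta-d′ is the
maximum-likelihood type-2 fit: confidence criteria around the type-1
criterion held at its fitted relative position, multinomial likelihood of
confidence counts conditional on (stimulus, response), optimized over
meta-d′ and the two type-2 criteria (Nelder–Mead; the profile likelihood
at meta-d′ = d′ is returned for diagnostics).

## Synthetic data

The generator emulates the study conditions: two task contexts (pre/post
cue) with balanced stimulus and mapping, 240 trials per context over 2
runs, 75 channels, a −1.0…6.5 s epoch at 20 Hz. Behavior follows a scalar
decision variable `DV = prior + d′·1[signal] + sequential·prev_choice +
N(0,1)` with latent `d′ = 1.35` and an unbiased criterion — ≈74% correct —
plus a small pre-stimulus bias (SD 0.2) and a magnitude-variable
previous-choice pull (SD 0.2; sign-variable available). Choice, response,
accuracy and confidence are exact functions of the DV and the mapping.
Neural data sum planted unit patterns per variable (orthonormal by
default; designated pairs rotated to exact angles) under per-variable
temporal envelopes tied to the trial structure, with the choice amplitude
scaled by `1 + dv_gain·|DV − c|` (default 0.5) so choice-signal strength
carries the decision variable's confidence/accuracy signature. Noise is
Gaussian with exponentially decaying channel correlation (ρ = 0.3),
i.i.d. over time samples.

What the generator does *not* emulate: realistic forward models and
sensor-level mixing, temporally autocorrelated or oscillatory noise,
artifacts, non-stationary criteria, or metacognitive noise (confidence is
ideally coupled to the DV, so recovered meta-d′ ≈ d′ by design; degraded
metacognition is exercised by adding type-2 noise at the evidence level in
the studies). Passing tests therefore certify estimator correctness and
calibration under the assumed statistical structure, not robustness to
real-data pathologies.

## Scaled-down studies

`cvdecode.studies` runs the package's self-characterization experiments at
desk scale: short epochs (−0.6…1.6 s at 20 Hz, effect onset 0.1 s), 6
channels, 128–600 trials, and replicate counts of 100–500 chosen so each
study's Monte-Carlo error is small relative to the property it checks
while the whole battery runs in about a minute. Simultaneous Monte-Carlo
null checks (many variables × time points) use Šidák-corrected intervals
so the familywise false-alarm rate of the check itself is 5%. Rare draws
whose behavioral sampling leaves a design cell with fewer than two trials
are redrawn with a fresh seed; occupancy is independent of the estimator
properties measured. Full-length epochs and 75 channels change runtimes,
not the properties under test.

## Known limitations

* The geometric-mean cross-decoding scale is one of several defensible
  conventions; within-contrast values are convention-free.
* meta-d′ supports binary confidence (one type-2 criterion per response).
* 2D layouts preserve angles to the first vector exactly; three or more
  vectors are generally not simultaneously embeddable in the plane.
* The searchlight geometry is a labeled spherical lattice, not an
  anatomical atlas; it preserves grouping and adjacency structure only.
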