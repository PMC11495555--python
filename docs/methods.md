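# Methods

This note documents the models, estimators and numerical choices behind
`msbridge`, what the synthetic-data generator does and does not emulate,
and the limits of what the test suite can establish.

## Preprocessing and GFP peaks

Recordings are bandpass filtered with a 4th-order Butterworth applied
forward-backward (zero phase; the effective magnitude response is the
square of the single-pass response, which is within 5% of unity across
most of the 1–40 Hz default band) and downsampled with an anti-aliased
polyphase resampler; the output is truncated to
`floor(n * target / srate)` samples and annotation intervals are rescaled
with floor rounding on half-open bounds. Defaults are 1–40 Hz and 250 Hz.

Global field power is the population (divide-by-N) standard deviation of
the average-referenced map at each sample — the standard microstate
convention; all maps are average-referenced before GFP, clustering and
back-fitting. GFP peaks are strict interior local maxima; `min_separation`
(default 1, i.e. no thinning) greedily keeps the larger of two nearby
peaks, ties to the earlier index. Per subject, `n_peaks` (default 10000)
peak maps are drawn uniformly without replacement.

## Modified k-means and K selection

Microstate polarity flips with oscillatory phase, so clustering must
ignore sign. Assignment maximizes the squared projection
`(a_k . v_i)^2` (ties to the lowest index); the template update is the
principal eigenvector of the members' scatter matrix `sum v v^T`,
re-normalized to zero mean and unit norm with a deterministic sign
convention (largest-magnitude channel positive). Iteration stops when the
relative change in GEV falls below `tol = 1e-6` or after `max_iter = 300`
iterations; the best of `restarts = 50` random initializations by GEV is
kept. An empty cluster is re-seeded from the currently worst-fit map and
logged. GEV is the GFP^2-weighted squared spatial correlation between maps
and their assigned templates, normalized by total GFP^2.

The two-level fit clusters each subject's peak maps, pools the subject
templates with unit weight, and clusters the pool again with the same K
(subject-level and group-level K are kept equal). With a single subject
the pooled templates are exactly K maps and are returned as the group maps
directly. Group diagnostics (GEV, residual noise) are recomputed against
the pooled peak maps rather than the intermediate templates.

K is selected by minimizing `CV(K) = sigma^2 ((C-1)/(C-1-K))^2` with
`sigma^2 = sum_i (v_i.v_i - (a_{L_i}.v_i)^2) / (n(C-1))`; ties break to
the smaller K, and K >= C−1 (undefined CV) is skipped with a warning.
Tiny negative `sigma^2` from exact fits is clamped to zero so that the
noiseless case ties at CV = 0 and resolves to the smallest K.

Back-fitting labels each sample by highest absolute spatial correlation
(equivalently minimum Euclidean distance up to polarity), ties to the
lowest template index, no temporal smoothing.

## Coverage, joint matrix, asymmetry

The resting phase is divided into consecutive 2-second windows (the trial
duration); a trailing partial window is dropped. Coverage pools samples
over all segments of a condition; with boundary exclusion (default on for
coverage, off for Q) the first and last maximal same-label run of every
segment are removed, because runs truncated by a segment edge carry no
duration information. A segment that is a single run is dropped entirely;
if nothing remains the distribution is reported as degenerate rather than
silently renormalized.

`Q_ij` counts ordered consecutive pairs strictly within segments — never
across window or trial boundaries — normalized by the pair count. The
asymmetry test runs a paired two-tailed t-test of `Q_ij − Q_ji` across
subjects for each unordered pair. Zero-variance differences are split: a
zero mean is undefined (flagged, non-significant); a nonzero constant
difference is a perfectly consistent asymmetry and is reported as
`t = ±inf`, `p = 0`.

## The bridge solver

The transition cost solves `min D_KL(P || Q)` over couplings with
marginals `pi^0` (rest) and `pi^T` (task). The entropic-regularization
weight is identically 1 — the Gibbs kernel is exactly Q — so no epsilon
parameter is exposed. Sinkhorn alternates `u <- pi^0 / (Qv)`,
`v <- pi^T / (Q^T u)` until the largest marginal violation of
`P = diag(u) Q diag(v)` is below `tol = 1e-10` (default
`max_iter = 1e5`); if any multiplier exceeds 1e30 the iteration restarts
in the log domain with log-sum-exp updates. Costs use natural logarithms
(nats); `0 log 0 = 0` throughout, and a cost within rounding error below
zero is clamped to 0.

`pi^0` is the coverage-based resting distribution (with the same boundary
exclusion as the task distributions), not Q's row marginal; the two differ
slightly when boundary runs are excluded, and the solver checks
feasibility explicitly. Zero entries of Q give infinite transportation
costs; by default this raises a feasibility error when a marginal needs
mass on a zero-support row or column, and a Laplace pseudocount on the
pair counts (`pseudocount = 1` is a reasonable choice for sparse synthetic
data) is available to restore feasibility. Real resting joint matrices at
K = 7 are dense, so the default pseudocount is 0.

The divergence baseline is reported as `D_KL(pi_task || pi_rest)`; the
reverse direction is computable with the same function, as the literature
is not unanimous on orientation.

## Statistics

Contrast codes follow the conflict-task convention: congruency −.5
(incongruent) / +.5 (congruent); proportion-of-congruency −.5 / 0 / +.5
for PC25/PC50/PC75; interaction is their product. The chance coverage
level is 1/K. One-sample t-tests report Cohen's d as the mean difference
over the sample standard deviation. BH-FDR uses the step-up procedure with
monotonicity enforcement (delegated to statsmodels behind the package's
interface); the FDR family for per-microstate models is all fixed effects
across models — 4 effects x K microstates, 28 tests at K = 7.

Full linear mixed-effects inference (random slopes, Satterthwaite degrees
of freedom) is deliberately out of scope: the package exports the
long-format table these tools consume and provides per-outcome OLS effect
tables and a pooled OLS cost–RT slope (PC-level intercepts) as summaries.

## Synthetic cohorts

The generator emulates the study design the pipeline targets: a resting
session plus six task conditions (congruent/incongruent x PC25/PC50/PC75)
of 2-second trials, defaulting to 44 subjects, 64 channels, 7 states,
250 Hz, 240 s of rest and 24 trials per condition.

* Topographies are rejection-sampled zero-mean unit-norm maps with
  pairwise |corr| < 0.6.
* Label dynamics are metastable Markov chains
  `T = p_stay I + (1 − p_stay) 1 pi^T`, whose stationary distribution is
  exactly `pi` and whose dwell times are geometric. The default
  `p_stay = 0.95` gives mean dwells near 80 ms at 250 Hz, inside the
  canonical 60–120 ms microstate duration range.
* Condition effects tilt the resting stationary distribution,
  `pi_c ∝ pi exp(shift)`, with `p_stay` fixed — coverage moves,
  metastability does not. The default shifts share one fixed zero-sum
  direction with scale `0.35 + 0.20 pc` for incongruent and
  `0.20 − 0.10 pc` for congruent conditions (pc = −.5/0/+.5), so
  incongruent conditions sit farther from rest and the congruency gap
  widens with PC — the qualitative pattern the cost measure is meant to
  detect.
* EEG rendering: `v_t = ±s_t a_{k_t} + noise` with a strictly positive
  rectified 10 Hz sinusoid envelope (`0.2 + |sin|`, GFP peaks resembling
  alpha-band dynamics), per-sample polarity flips, and i.i.d. Gaussian
  channel noise scaled to the target overall amplitude ratio `snr`.
  Inter-trial gaps (0.5 s) are noise-only and annotated for exclusion.
* All randomness flows from one root seed through spawned seed sequences
  (template / per-subject chain / per-subject rendering), so cohorts are
  bit-reproducible.

What the generator does **not** emulate: volume-conduction forward
models, artifacts (blinks, muscle), non-geometric dwell distributions,
inter-subject topography variability, or drifting condition effects.
Passing recovery tests therefore establishes the pipeline's correctness
under the generative model, not the validity of the microstate model for
any particular real recording.

## Numerical calibrations and test design

Tests and the acceptance script run scaled-down designs chosen so that
the quantity under test dominates its own sampling noise: rendered
cohorts use 6 subjects, 16 channels, 4 states, 80 s of rest at 125 Hz and
snr 10 (1e4 rest samples per subject, enough for template recovery at
|corr| >= 0.95 and back-fit accuracy >= 0.99); label-level cohorts for
cost analyses use 10 subjects, 5 states, 24 trials per condition and
`p_stay = 0.9`.

Two calibrations matter when comparing estimates to generating truth:

* **Effective sample size.** Consecutive samples of a metastable chain
  are strongly autocorrelated; the variance of empirical pair frequencies
  exceeds the i.i.d. binomial value by roughly
  `(1 + lambda2) / (1 − lambda2)` where `lambda2` is the chain's second
  eigenvalue (`p_stay` for the chains used here). Sampling-error bounds
  on the estimated Q therefore use
  `n_eff = n (1 − lambda2) / (1 + lambda2)`; the plain binomial bound is
  violated by construction for self-pairs at these dwell times.
* **Null-cost envelope.** Even with identical rest and task dynamics the
  estimated bridge cost is positive, because the estimated marginals
  fluctuate around the true ones and the cost is locally quadratic in
  them. The expected null cost is predicted from the generating chain as
  `0.5 tr(H Sigma)` per marginal — H the numerical Hessian of the cost at
  the population distributions, Sigma the multinomial covariance at
  `n_eff` — and the null-cohort test asserts the observed mean below this
  envelope. The envelope is conservative (windowing shortens the
  autocorrelation the `n_eff` formula assumes), typically by a factor
  near two.

Degenerate inputs have documented behavior rather than silent defaults:
single-channel GFP, empty peak lists, all-boundary segments, zero pair
counts, zero-variance t statistics, constant association predictors and
infeasible marginals all raise typed errors (see `msbridge.exceptions`),
and the CLI maps them to exit codes (2 configuration, 3 data,
4 convergence).

## Known limitations

* The CV criterion's selected K is noise-level dependent; on very clean
  data it ties at the smallest K by construction.
* The coordinate tie-breaks (lowest index) make results deterministic but
  arbitrary under exact symmetry.
* Template label order is fit-internal; no canonical A–G matching is
  attempted, so labels must be aligned (e.g. by Hungarian assignment on
  |corr|) before comparing fits.
* The pooled OLS cost–RT slope understates uncertainty relative to a full
  random-slope mixed model; it is a summary, not a replacement.
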