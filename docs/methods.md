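# Methods

This note documents the models and estimators implemented in `popdisorg`,
the conventions chosen where the procedure admits more than one reading,
the synthetic generators' assumptions, and what the validation experiments
do and do not demonstrate.

## Data model and conventions

Positions are degrees of visual angle, screen-centered, x rightward, y
upward; times are milliseconds from trial start. A session is one
experimental day of a single task, with an integer `day` relative to
disease onset (day 0 = induction) and optional simultaneously recorded
spikes. Fixations are assigned to discrete display locations by nearest
center within a configurable radius (default 2.0°, roughly matching an
invisible reward zone around each stimulus; ties break to the lowest
location id). Fixations near no stimulus are kept with an explicit
"elsewhere" state rather than dropped, so each metric decides its own
handling. Session bundles serialize to a single JSON document
(`popdisorg-session/1`), or to a directory with a columnar parquet spike
table when spike data are large; writes are byte-stable.

## Transition entropy and its shuffle null

Consecutive same-location fixations are collapsed into visits; transitions
are counted between on-stimulus visits that are adjacent within a trial
("elsewhere" visits break the chain — no transition is invented across
them); counts are pooled across a session's completed trials (≥ 20
required) and rows are normalized. Entropy is the sum of row entropies
(`row-sum`, the literal reading of `H = −Σ_ij p_ij log₂ p_ij` with
row-conditional `p_ij`); an occupancy-weighted entropy rate is available
as an option. The z-scoring against the shuffle null makes the two
conventions nearly interchangeable in practice, which is why either is
defensible.

The null permutes the visit order independently within every trial and
recomputes the pooled entropy. One subtlety matters: a collapsed visit
sequence *cannot* contain adjacent duplicates, but an unconstrained
permutation can; re-collapsing those duplicates shrinks the shuffled
transition count and biases the null entropy downward (measured bias in
the mean z of random foragers: about +0.6). The null therefore samples
uniformly from permutations with no adjacent duplicates (rejection
sampling; the observed order witnesses that at least one exists). With
this constraint the random-forager calibration is clean (|mean z| < 0.1
across 100 sessions) while deterministic foragers score z ≪ −2. When the
null has zero spread (e.g. a single pair of visits) the z-score is
reported as undefined alongside H and the null moments.

## Behavioral metrics

*Gap task*: a superfluous saccade is one launched strictly inside the
(fixation-spot offset, target onset) interval whose landing point lies
more than 1.0° from the fixation spot — the fixation window's radius —
so small corrective movements do not count. The rate is the fraction of
completed trials containing at least one.

*Foraging*: reward per fixation = rewarded fixations / on-stimulus
fixations; inter-fixation distance is measured between consecutive
*visits* (no saccade separates two fixations collapsed into one visit);
revisit rate is the fraction of on-stimulus visits whose location was
already visited earlier in the same trial.

*Preferential looking*: novelty preference is the novel fraction of total
image-dwell time pooled over trials (the formula is not standardized; this
is the simplest occupancy reading); switches are consecutive fixation
pairs on the two different images; duration averages exclude off-image
fixations.

## Noise correlations and rate matching

r_SC is the Pearson correlation of baseline-window (200 ms stable
fixation) spike counts across trials, averaged over pairs within V4,
within 7a, or across areas; zero-variance units are dropped and logged.
To remove rate confounds, units are subsampled until the mean baseline
rate lies in 20–30 sp/s: while the mean is above the band a uniformly
random unit with rate *above the current mean* is removed, and symmetric
below — a directed variant of random dropping that provably terminates or
fails explicitly (band unreachable, or the population would fall below a
minimum size).

The validation oracle is a doubly stochastic Poisson model: counts
`N_i | g ~ Poisson(λ_i t g)` with a gamma trial gain (mean 1, variance
σ_g²) shared across units, giving the closed form
`ρ_ij = λ_iλ_j t² σ_g² / √((λ_i t + λ_i²t²σ_g²)(λ_j t + λ_j²t²σ_g²))`
(ρ ≈ 0.0476 at λt = 5, σ_g² = 0.01). The estimator reproduces this within
±0.01 at 5,000 trials.

## Intrinsic timescale

For each unit, spike trains in the 200 ms baseline window are binned
(1 ms default) and the within-trial lagged coincidence histogram is
corrected by the expected histogram when spike trains are paired across
*different* trials; by default the correction is the exact average over
all ordered cross-trial pairings (closed form), with random trial
shuffles available as an option. Values are normalized per bin pair by
the squared mean count, so an Ornstein–Uhlenbeck rate modulation of depth
m and timescale τ leaves a profile ≈ m²·exp(−lag/τ).

The timescale is the τ of `A·exp(−lag/τ) + B` fitted over lags 3–100 ms
(start at 3 ms to avoid refractory structure; τ bounded in (1, 500) ms;
three τ initializations, best SSR kept). The constant B is retained
because shared-gain variability adds a genuine lag-independent offset to
the corrected autocorrelogram. Units are included only when R² > 0.5;
homogeneous-Poisson units are excluded by this rule > 90% of the time.
Session summaries either average τ over included units ("units", the
default) or fit the unit-averaged autocorrelogram ("population"). At the
trial counts of the synthetic study (tens of trials per unit) individual
autocorrelograms essentially never pass the R² criterion, so the study
pipeline uses the population fit with 2 ms bins; τ recovery accuracy is
validated on the pooled fit over 200 unit-sessions (±20% of τ = 50 ms).
A caveat discovered during design: within a 200 ms window, decays with
τ ≳ 60 ms are poorly identifiable (τ trades off against B), producing
heavy-tailed fits no matter how much data is pooled — timescales reported
from short windows should be read with this in mind.

## Population decoding, feature axes, ablation

Decoding is ridge regression (neurons as regressors, counts standardized,
intercept unpenalized, λ = 1.0 by default since units can outnumber
trials; λ = 0 is refused in that regime) with exact leave-one-out
predictions computed from the hat-matrix identity rather than n refits.
Standardization uses the full trial set; the unit tests verify the
closed form against an explicit per-fold ridge loop. The score is the
Pearson correlation between held-out predictions and the true feature;
categorical features use one-hot targets and the mean per-dimension
correlation. A permutation null (feature shuffled against responses) is
provided and is cheap because the hat matrix is reused.

Feature axes: PCA on stimulus-mean responses retaining ≥ 90% variance
(configurable), one regression direction per feature (color, shape) in
PCA space mapped back to unit space, then QR orthogonalization (color
column first, signs fixed by a positive-diagonal R). Projections are
scaled per session by subtracting the mean and dividing by the maximum
response magnitude so sessions are comparable. Collinear feature codes
are refused as unidentifiable.

Ablation: for each requested number of removed dimensions, random subsets
are dropped and the remaining features decoded; a label concentrated in 2
of 50 dimensions collapses far below a label distributed across all
dimensions once 80% of dimensions are removed.

## Longitudinal statistics

Each metric's per-day values (sessions sharing a day are averaged) form a
series tested by OLS against the intercept-only null,
`F = (RSS₀ − RSS₁)/(RSS₁/(n−2))`; exact collinearity is reported as
p below machine precision, constant series as F = 0, p = 1. The test's
type-I error calibrates to 0.05 ± 0.01 over 2,000 null series, and slope
and F match a normal-equations solution to 1e-10. The segmented
comparison fits `a + b·day + c·I(day≥onset) + d·day·I(day≥onset)` and
F-tests d = 0: the intercept jump c is always allowed, so a sharp level
shift at treatment onset with unchanged drift does not count as a slope
change — matching the scientific claim that pre/post drift *rates* are
indistinguishable even when the level drops at onset. P-values are
reported per metric without multiplicity correction (a Benjamini–Hochberg
helper is provided but off by default).

## Synthetic generators

All generators are exact functions of their seed and attach their ground
truth to the returned object's `meta`.

- *Foraging*: 3×3 grid (5° spacing), trials of 9 fixations; the structure
  parameter s mixes a nearest-unvisited-neighbor policy (s = 1,
  deterministic given the start) with uniform choice among the other 8
  locations (s = 0); first target visits are rewarded. Fixation positions
  jitter 0.3° around item centers; durations ~250 ± 50 ms.
- *Gap*: fixed 500 ms fixation epoch, configurable gap, superfluous
  saccades injected i.i.d. per trial with exact probability p; every trial
  ends with a rewarded target saccade within 400 ms of target onset.
- *Preferential*: alternating exponential dwell segments whose means are
  set so the long-run novel fraction equals `pref_novel` and switches per
  second equal `switch_rate`; each trial accumulates the 1000 ms viewing
  criterion.
- *Shared-gain Poisson counts* and *OU-modulated spike trains* as above
  (OU discretized exactly at 1 ms; spikes by per-bin Poisson draws with
  uniform within-bin placement; rates clipped at zero).
- *Tuned population*: Gaussian color×shape tuning per unit; the disruption
  d scales the across-population linear color/shape signal by (1−d) and
  adds matched-variance isotropic trial noise, so linear decodability
  collapses with d while signal orthogonal to those axes (units'
  idiosyncratic nonlinear tuning) survives — the dissociation between
  preserved single-unit selectivity and degraded population organization.
  Responses are float-valued so the noiseless limit is exact.
- *Longitudinal study*: per-day generator parameters drift linearly from
  healthy baselines (superfluous p 0.10, structure 0.85, novelty
  preference 0.75, gain variance 0.02, τ 45 ms) with one-year defaults
  reaching 0.40 / 0.25 / 0.57 / 0.005 / 21 ms; each day yields a gap, a
  foraging (with a 60 V4 + 12 7a unit OU/shared-gain population, 60
  trials, and a 1.5× visually evoked stimulus-epoch response) and a
  preferential session. The baseline τ of 45 ms keeps the whole τ
  trajectory in the regime identifiable within the 200 ms window (see
  above). An optional treatment adds a fixed offset to the structure
  parameter from its onset day while the drift continues, emulating a
  partial restoration of organized foraging with unchanged drift rate.

What these generators do **not** emulate: saccade kinematics and
main-sequence constraints, reward-history dependence of scanning,
non-Poisson spiking (refractoriness, bursting), rate nonstationarity
within sessions, electrode drift and unit turnover across days, or
correlated timescale/gain structure across areas. Passing validation
therefore demonstrates estimator correctness under these models, not
robustness to every property of real recordings.

## Validation problem sizes

The validation battery (`popdisorg.validation`, reused by
`scripts/acceptance.py` and the acceptance tests) uses: 100 sessions per
entropy calibration arm with 300-shuffle nulls; 5,000 trials × 50 units
for the r_SC oracle; 1,000 random rate vectors for matching; 200 OU
unit-sessions (50 trials each) pooled for τ recovery and 200 null units
for exclusion; 20-seed disruption sweeps with 1,000-permutation nulls;
50 paired ablation repeats (8 internal draws each); 2,000 null series for
F-test calibration and 500 for the segmented null; and 10 replicates of a
45-day compressed study spanning the full one-year start-to-end severity
(chosen so the battery completes in a few minutes on one CPU). Sign
recovery in the study is assessed on the fitted slope's sign for the five
headline metrics (entropy z, superfluous rate, novelty preference, V4
r_SC, τ).
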