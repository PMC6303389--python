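# Methods

## The perception model

The model treats audiovisual syllable perception as Bayesian causal
inference in a two-dimensional feature space (auditory feature on x, visual
feature on y), in four stages.

**Encoding.** A token t presented in modality m is encoded as
x_m ~ N(μ_t, Σ_m). The prototypes are fixed at ba = (0, 0),
da = (0.5, 0.5), ga = (1, 1) on a dimensionless unit square. Only the
relative layout matters scientifically ("da" intermediate between "ba" and
"ga" on both axes); the symmetric diagonal placement makes the linear
decision boundaries the parallel lines x + y = 0.5 and x + y = 1.5, so
category probabilities have closed forms. The default covariances are
axis-aligned, Σ_A = diag(0.02, 0.18) and Σ_V = diag(0.18, 0.02)
(variances in squared feature units): each modality is three times more
precise (in SD) along its own axis, and the scale is set so that a
congruent token is identified correctly on the large majority of trials
while a McGurk stimulus produces a genuinely uncertain fused percept.

**Integration.** Under a common cause the two encodings are fused by
precision weighting: Σ_AV = (Σ_A⁻¹ + Σ_V⁻¹)⁻¹,
μ_AV = Σ_AV(Σ_A⁻¹ x_A + Σ_V⁻¹ x_V). Both differences Σ_m − Σ_AV are
positive semidefinite (fusion never loses precision); this is a tested
invariant.

**Causal inference.** The posterior probability that both streams come
from one talker is computed on the log-odds scale:

    logit P(C=1) = logit(p_c) + n_eff · λ_sync − κ_content · d²,

with p_c the common-cause prior, n_eff the number of co-articulated
repetitions (n_eff = 1 for isolated repetitions), λ_sync ≥ 0 the per-
repetition temporal-synchrony evidence, κ_content ≥ 0 the weight of the
content-disparity penalty, and d the distance between the two encodings.
This is the simplest additive form with the required structure: the
content incongruity counts against a common cause identically at every
repetition count, while synchrony evidence accumulates linearly with
co-articulated repetitions. Gating n_eff on co-articulation encodes the
empirical null result for isolated repetition as a model constraint.
Defaults: p_c = 0.5 (uninformative), λ_sync = 0.35, κ_content = 0.8.
With these values the expected squared disparity of a McGurk stimulus
(≈ 2.4 in feature units²) puts P(C=1) near 0.17 at one repetition and
near 0.55 at six, which is the regime where repetition visibly moves the
percept; the published figure panels are illustrative only, so these
constants are a calibration choice of this package, not measured values.

The disparity d is Euclidean by default; a Mahalanobis variant (whitened
by Σ_A + Σ_V) is available via `disparity_metric="mahalanobis"`. An
alternative reading of the causal computation would base it on the
position of the integrated representation rather than the unisensory
disparity; the disparity form is implemented because it makes the
two-talker evidence explicit and keeps the posterior independent of the
prototype origin.

**Decision.** The final location is the model average
P(C=1)·μ_AV + (1 − P(C=1))·x_A. Model averaging (not model selection) is
used because the final representation must move continuously between the
auditory and integrated representations as the common-cause posterior
changes. Under C = 2 the percept is based on the auditory encoding alone,
audition being the most reliable unisensory cue for speech. A nearest-
prototype rule (equivalently, linear category boundaries) yields the
reported syllable; exact ties — a probability-zero event under continuous
noise — are broken deterministically in the order ba > da > ga, putting
the auditory-consistent category first.

`predict_percept_distribution` runs this pipeline by Monte Carlo
(bit-reproducible given a seed). When κ_content = 0 the common-cause
weight is constant, the final location is Gaussian, and
`gaussian_percept_distribution` evaluates the category probabilities
analytically as bivariate-normal measures of the Voronoi cells; the test
suite requires the two routes to agree within Monte Carlo error across
random model configurations.

**Degenerate inputs.** The public `integrate` raises on singular
covariances. The Monte Carlo path additionally supports noiseless limits
(used in tests and sanity analyses) by regularizing exactly singular
covariances with 1e-10·I inside the fusion step, which yields the natural
limits: both covariances zero → midpoint fusion; one zero → that modality
exact. The prior accepts the closed interval [0, 1]; the endpoints are
degenerate regimes (forced segregation / forced fusion) that short-circuit
the corresponding pipeline stages.

## The synthetic-behavior generator

`simulate_trials` emulates the statistical structure that binomial
mixed-model analyses of McGurk prevalence assume. For participant i and
stimulus j,

    p_ij = expit(β₀ + condition effect + slope·reps + group effect + b_i + s_j),
    b_i ~ N(0, τ_participant²),  s_j ~ N(0, τ_stimulus²),
    n_da/tha ~ Binomial(n_trials, p_ij),

with non-"da/tha" trials split "ba"/"ga" at a 0.95/0.05 ratio (visual-only
responses to McGurk stimuli are rare) and congruent controls answered
correctly with probability 0.97. Defaults: τ_participant = 2.0 on the
logit scale — large enough that individual participants span the full
0–100% prevalence range, the hallmark inter-individual spread of McGurk
data — and τ_stimulus = 0.3, modest within-study stimulus heterogeneity.
Both are calibration choices, not measured values.

The four designs follow the canonical experiments: (1) N = 76, two
counterbalancing groups, one 1-repetition and one 6-repetition
co-articulated McGurk stimulus from different talkers plus a reference
stimulus, 10 trials each; (2) N = 40, eight stimuli in a 2-talker ×
{1, 2, 3, 6}-repetition design without co-articulation; (3) N = 60,
familiar vs unfamiliar talker, counterbalanced; (4) 160 online + 60
in-person participants with eight McGurk stimuli. Congruent controls are
presented 3 or 4 times each, randomly determined. Experiment-specific
default generators (`default_generator_params`) are calibrated to the
published group means (e.g. experiment 1: logit(0.48) baseline, repetition
effect log 3.1, reference stimulus near 73%; experiments 2–4 null
manipulations).

`simulate_from_cims` instead draws every trial from the perception model,
with optional per-participant jitter of the common-cause prior (logit
scale) and of the noise magnitude (log-normal), linking the generative
model to the analyzable count format.

What the generator deliberately does **not** emulate: reaction times,
trial-order and carry-over effects, learning across the familiarization
phase, lapses/guessing, and talker-specific idiosyncrasies beyond a scalar
stimulus intercept. Passing recovery tests on these data therefore shows
that the estimators are correct under the assumed random-intercept
binomial structure, not that real McGurk data satisfy that structure.

## Estimation and inference

**Binomial GLMM.** `fit_glmm` maximizes the Laplace-approximate marginal
likelihood of a logit-link binomial model with crossed Gaussian random
intercepts. The inner step is a Newton ascent for the conditional mode of
the random effects; the outer step is bounded L-BFGS-B over the fixed
effects and the log random-effect standard deviations (bounds [−8, 4],
fixed starting values: coefficients 0, variances 1, objective tolerance
1e-10), so the fixed effects see the full Laplace objective including the
log-determinant term — the same scheme as glmer's nAGQ = 1 default, and
the test suite verifies agreement with lme4 to ~1e-2 on all estimates.
Wald covariance for the fixed effects is the Schur complement of the
joint penalized Hessian at the mode, conditional on the estimated variance
components (again as in glmer). Adaptive Gauss–Hermite quadrature
(`n_agq > 1`) is available for models with a single random factor, the
same restriction lme4 imposes; crossed designs use the Laplace
approximation. A variance component may be pinned to zero, and pinning
all of them reduces the estimator to ordinary logistic regression (tested
against an independent IRLS fit to 1e-6). Complete separation is reported
through a `ConvergenceWarning`; a variance estimate at the boundary is
flagged as a singular fit, not an error.

**BIC.** BIC = k·ln(n) − 2·logLik with n the number of binomial count
records (participant × stimulus rows) and k the number of fixed effects
plus estimated variance components, mirroring lme4's counting. ΔBIC ≥ 10
is labeled decisive and exp(ΔBIC/2) reported as the approximate evidence
ratio. One structural caveat, visible in the synthetic repetition
experiment: when a condition is realized by only two stimuli per level,
the baseline model's stimulus random intercepts can partially absorb a
genuine condition shift, so the BIC margin for the effect model is far
smaller than its Wald z would suggest, even though the preference
direction remains reliable. Large published ΔBIC values on real data are
therefore not recoverable from effect sizes alone.

**Marginal prevalence.** Population-average probabilities integrate
expit(linear predictor + Σ random effects) over the fitted Gaussian
random-effect distributions with 20 Gauss–Hermite nodes per factor
(tensor product for crossed factors); with all variances zero this reduces
exactly to the conditional expit.

**Variance LMM.** The repetition-precision analysis converts each record
to its binomial variance n·p·q and fits Gaussian LMMs (statsmodels
MixedLM, crossed variance components, ML rather than REML so fixed-effect
BICs are comparable) with and without a linear repetition term.

**t-tests.** Paired (df = n − 1) and independent two-sample tests, both
pooled (df = n₁ + n₂ − 2) and Welch–Satterthwaite, are provided; published
McGurk analyses are inconsistent about which independent-samples df they
use, so both variants are exposed. An identically-zero paired difference
is reported as t = 0 rather than NaN.

## Simulation studies and problem sizes

The acceptance-level suites use: 20,000 Monte Carlo trials for the
repetition-monotonicity predictions; 24 random model configurations at
10,000 trials each for the Monte-Carlo-vs-analytic check (3 binomial SEs);
200 replicates of the full 76-participant repetition design for estimator
bias and 95%-CI coverage (accepted band 0.90–0.98); and 100 replicates
each for the null and strong-effect BIC preference rates. Recovery and
BIC studies simulate with τ_participant = 2.0 and τ_stimulus = 0 while the
fitted models still estimate both variance components: the condition
contrast is identified from only two stimuli per level, so with
stimulus-level noise it has four effective clusters and no Wald interval
attains its nominal level — the recovery study targets the regime the
Wald theory assumes, and the few-cluster limitation is acknowledged here
instead of being averaged into the coverage band.

## Known limitations

- The perception model's constants are illustrative calibrations; only
  qualitative orderings (more co-articulated repetitions → more fusion;
  isolated repetition inert) are empirically anchored.
- Temporal structure is reduced to a scalar synchrony-evidence term; no
  explicit asynchrony modeling.
- The GLMM provides Wald z inference only — no profile likelihood,
  parametric bootstrap, or small-sample df corrections — and no random
  slopes or REML.
- With very few stimulus levels, variance components and stimulus-level
  fixed effects are weakly identified; singular fits are common and are
  reported as such.
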