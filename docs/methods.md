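# Methods

## Measurements and derived quantities

A participant's record is a time-ordered list of images (days from
treatment start; pretreatment times are negative).  Each image carries, per
lesion, the two perpendicular diameters (cm) and/or segmentation volumes
(cm³): a solid-tumor base volume, the intratumoral cyst volume inside it,
and optionally a whole-tumor volume (cyst and peritumoral edema included).
Derived quantities:

* 2D area = d₁ × d₂ (per lesion, summed over lesions per image);
* solid volume = base volume − intratumoral cyst volume (summed over
  lesions);
* percent change = 100 (current − baseline)/baseline.

The baseline is the earliest pretreatment image; when several pretreatment
images exist the earliest is used, and when none exists the earliest
available image is taken with a warning.  A follow-up missing a measure
yields an explicit missing marker, never a silent drop, so label streams
stay aligned with the imaging schedule.  Zero solid volume (cyst filling
the whole segmented base) is legal but flagged; percent change from a
non-positive baseline is an error.

## Response criteria

Thresholds follow the printed rule tables exactly.  Boundary convention:
"≥" thresholds are inclusive toward the non-stable label; the minor-response
band covers decreases in [25%, 50%) on the 2D scale ([35%, 65%) on the
extrapolated volumetric scale), with PR owning the deeper boundary.  A new
lesion forces PD regardless of the measured change.

The volumetric thresholds of the extrapolated rule sets derive from the 2D
ones by the spherical map v = (1 + a)^(3/2) − 1 (area scales as the 2/3
power of volume for a uniformly scaling sphere): +25% → +39.75%,
−50% → −64.64%, −25% → −35.05%.  By default the rounded values (+40, −65,
−35) are applied, matching how the thresholds are used in practice; the
exact values are available via `build_criteria(name,
exact_extrapolation=True)` since the printed tables do not say which form a
given analysis applied.

BT-RADS scores enter only as an ordinal reference label stream; the visual
scoring logic itself (enhancement, mass effect, treatment-related
phenomena) is out of scope.  Since the visual scale has no minor-response
category, MinR is grouped with PR whenever rule-set labels are compared
against visual labels.

## Concordance statistics

Scores are signed percent changes; for progression detection the raw change
is used, for response detection the negated change, so a positive call is
always "score ≥ threshold" (threshold inclusive, mirroring the "≥" rule
convention).  Choices that matter:

* **AUC** is computed as the Mann–Whitney statistic by midrank counting —
  identical to the area under the empirical ROC curve, which is verified in
  tests by the trapezoid rule and by exhaustive pair counting.
* **Confidence intervals** are percentile intervals over class-stratified
  bootstrap resampling (positives and negatives resampled separately,
  preserving class counts; 2,000 replicates by default).  Percentile
  intervals for AUC slightly undercover near the [0, 1] boundary at small n
  (~88% actual coverage at n = 30 in our simulations); BCa is not
  implemented.
* **DeLong's paired test** uses placement values: per-positive and
  per-negative mean placements give the AUC covariance of two score vectors
  measured on the same images; the difference is referred to a normal. With
  zero estimated variance and a nonzero difference, p = 0 is reported with
  a warning.
* **Threshold sweep**: median sensitivity/specificity and 95% percentile
  intervals over the stratified bootstrap, on grids of +15…+40% (for PD)
  and −15…−65% (for PR) in 5-point steps; thresholds below 15% are not
  considered because a 10% measurement uncertainty is assumed.  A threshold
  is "selected" when its sensitivity CI contains the 80% target
  (inclusive).
* **Weighted kappa** uses linear disagreement weights by default over the
  ordinal order 1a < 1b < 2 < 3a < 3b < 3c < 4 (quadratic available); raw
  observed agreement is reported alongside.  BT-0 (unscorable) is rejected.
* Friedman, one-way ANOVA and Wilcoxon rank-sum delegate to scipy; the
  rank-sum test uses exact enumeration when both groups have ≤ 10
  untied observations.  No multiplicity correction is applied across the
  pairwise DeLong tests (raw p-values are reported).

## Growth-response model

Solid-tumor volume after treatment start follows

    dV/dt = (λ − γ₀ e^(−εt)) V,   V(0) = V_b,

the canonical regression–regrowth form combining exponential growth (λ,
day⁻¹), treatment-induced shrinkage (γ₀, day⁻¹) and exponential waning of
the treatment effect as resistance develops (ε, day⁻¹).  It integrates in
closed form to V(t) = V_b exp(λt − (γ₀/ε)(1 − e^(−εt))); the ε → 0 limit
V_b e^((λ−γ₀)t) is substituted below ε = 10⁻¹².  When γ₀ > λ the trajectory
dips to its minimum at t_Vmin = ln(γ₀/λ)/ε; with γ₀ ≤ λ there is no
shrinkage phase (t_Vmin = 0), and with λ = 0 the volume decreases
monotonically (t_Vmin = +∞ sentinel).  This functional form is a modelling
choice: it is the simplest mechanism producing the observed
optional-dip-then-regrowth shapes.

**Likelihood and priors.** Volumes are observed with multiplicative error:
log V_obs ~ Normal(log V(t), σ) with σ equal to the assumed measurement
coefficient of variation (0.10 by default).  Priors: λ log-uniform on
[10⁻⁵, 0.05] d⁻¹, γ₀ uniform on [0, 0.2] d⁻¹, ε log-uniform on
[10⁻⁴, 0.1] d⁻¹, and log V_b normal, centred on the log of the first
observed volume with spread 0.2.  These are weakly informative ranges
spanning the doubling times plausible for low-grade glioma (growth
e-folding ≥ 20 days at the extreme) and are configurable.

**Sampling.** Affine-invariant ensemble MCMC (emcee) over (log λ, γ₀,
log ε, log V_b); 32 walkers × 2,000 steps by default with the first half
discarded as burn-in.  An acceptance fraction outside [0.1, 0.9] flags the
fit (warning, not fatal).  All sampling is seeded; identical seeds give
identical sample arrays.  Measurement uncertainty is propagated by a
bootstrap (200 replicates by default): each replicate multiplies every
observed volume by an independent lognormal factor with CV 0.10 and refits;
the post-burn-in posteriors of all replicates are pooled, and t_Vmin /
V_min distributions are derived per pooled sample.  Pooling MCMC and
bootstrap draws (rather than bootstrapping point estimates) was an open
choice; pooling propagates both uncertainty sources into every derived
quantile.

**Shared growth rate.** Low-grade gliomas grow at broadly similar intrinsic
rates, so the cohort-level model (`CohortGrowthModel`) treats λ as common
to all participants (jointly sampled with per-participant γ₀, ε, V_b).  A
joint fit repeated inside every bootstrap replicate is not tractable, so
the pipeline composes the two stages: the joint fit supplies the shared-λ
posterior median, and per-series bootstrap refits then run with λ frozen at
that value.  A free-λ per-series mode exists and is used in unit tests.

**Trajectory classification.** An evaluation image at time t_eval is PD
when t_eval exceeds the 75th percentile of the pooled t_Vmin distribution
(the tumor has clearly passed its minimum and is regrowing); otherwise SD
when every observed volume up to t_eval stays within the measurement
uncertainty band (±100·CV %) around the pretreatment volume; otherwise PR.
Precedence is PD → SD → PR.  Classification requires at least 3 prior
images and is invariant to rescaling all volumes by a positive constant
(the V_b prior is centred on the data).

**Responder comparison.** Fits are split at a posterior-median t_Vmin of
one year (responding ≥ 365 d); each parameter's per-fit posterior medians
are compared between groups with the Wilcoxon rank-sum test.  Empty groups
skip the tests.

## Synthetic cohort generator

The generator emulates the statistical structure of a pLGG targeted-therapy
trial cohort, not its biology in detail:

* 43 participants on a 61-day imaging cadence with baseline at treatment
  start; per-participant follow-up counts are drawn so the cohort median is
  ~4 (range 1–10, horizon 700 d).
* Every participant has an early assessment image (the follow-up nearest
  6 months) and a 22-participant subset a late assessment (last follow-up):
  65 assessed images whose response-class mix is fixed by stratified
  assignment at exactly 14 PR / 23 SD / 28 PD.  Late class equals early
  class; classes allocate to early/late slots by largest-remainder
  apportionment.
* Per-class growth-parameter ranges are a calibration (no published
  values exist): PR draws strong shrinkage with slow resistance, SD draws
  near-balanced growth/shrinkage, PD mixes monotone growers with
  dip-then-regrow trajectories.  Parameters are rejection-sampled until the
  noiseless trajectory lands in the assigned class at every assessment time
  under the extrapolated volumetric rules (MinR grouped with PR).
* Observed solid volumes carry 10% lognormal noise.  Baseline solid volume
  is lognormal (median 18 cm³, log-SD 1.15), putting the mean whole-tumor
  volume near the reported cohort scale (~56 cm³).
* 2D diameters are distorted spherical proxies: the equivalent-sphere
  diameter (6V/π)^(1/3) times per-lesion fixed lognormal factors
  (CV = `shape_distortion_cv`, default 0.15) times per-visit jitter
  (CV = 1.5 × the distortion CV).  The per-visit jitter is what degrades
  longitudinal 2D change; it is calibrated so the sign of 2D and 3D solid
  change agrees on ~69–75% of follow-ups at default settings, and so 2D
  discrimination is strictly worse than solid-volume discrimination.
* Whole volume = solid + cyst + a stable edema margin anchored at 50% of
  the baseline solid volume; cyst (present in 79% of participants) and
  edema follow slow independent multiplicative random walks (CV 4% and 8%
  per visit).  This dilutes whole-volume change relative to solid change,
  reproducing why whole volume discriminates progression worse than solid
  volume.
* New lesions appear in 15% of progressing participants at their early
  assessment.  Two BT-RADS reader streams: reader 1 maps the true class to
  a plausible score (PR → 1a; SD → 2/3a/3b; PD → 3c/4); reader 2 differs on
  a fraction of images (11/65 by default), landing one response category
  away — which puts the linear weighted kappa near the mid-0.8s, i.e.
  substantial but imperfect agreement.

What passing tests on this generator do **not** show: robustness to real
segmentation variability (contouring error is modelled as stationary
lognormal noise), scanner/site effects, irregular imaging schedules,
multi-lesion disease (one lesion per participant is simulated), or visual
scoring driven by enhancement and mass effect rather than volume.

## Problem sizes and numerical choices

* Unit/acceptance tests run reduced chains (12–16 walkers × 150–900 steps)
  and small bootstrap counts; parameter recovery is assessed on 20 seeded
  replicates of a 10-visit, 5%-noise dip-then-regrow trajectory with λ held
  at its generating value, mirroring the shared-λ design.  The pipeline's
  default configuration uses 20 bootstrap refits × 600 steps per series and
  an 800-step joint cohort fit; library defaults keep the full study
  settings (200 × 2,000).
* ROC confidence intervals default to 2,000 stratified bootstrap
  replicates.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; rerunning any command with the same root seed
  reproduces structured outputs byte-identically (a single timestamp
  metadata field is set only when a report is written to disk).
* Ties in ROC scores are grouped at one operating point (midrank
  convention); Friedman with all-constant blocks returns statistic 0,
  p = 1; ANOVA with zero within-group variance reports F = ∞.

## Known limitations

* The growth model assumes a single exponential-growth/waning-shrinkage
  mechanism; Gompertz or logistic saturation and hierarchical shrinkage
  across participants are out of scope.
* ε is weakly identified when the volume minimum falls outside the observed
  window; posterior medians can then miss the generating value by far more
  than the nominal noise level.  The bootstrap widens, but cannot correct,
  such posteriors.
* Percentile bootstrap intervals slightly undercover for AUC at small
  sample sizes (see above).
* The consensus visual label is taken as reader 1's score; a third-reader
  adjudication is not representable in the two-read table schema.
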