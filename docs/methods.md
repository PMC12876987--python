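# Methods

This note documents the models, estimation rules, simulation design and
numerical choices implemented in `itcmed`, in enough detail to audit any
number the package prints.

## 1. Behavioural model and discount-rate estimation

### Hyperbolic discounting and trial-level indifference points

Each intertemporal-choice (ITC) trial offers a smaller-sooner reward
(amount A1, delay D1 days) against a larger-later one (A2, D2).  Under the
hyperbolic value function V = A / (1 + kD), each trial has a unique
*indifference* discount rate — the k at which both options are worth the
same:

    k_indiff = (A2 − A1) / (A1·D2 − A2·D1),

the closed-form root of A1/(1+k·D1) = A2/(1+k·D2).  Trials with
A1·D2 ≤ A2·D1 have no positive indifference rate and are rejected as
degenerate.  D1 = 0 (an immediate SS option) is valid; the denominator
reduces to A1·D2.

### The 32-trial grid

The canonical trial list is reconstructed, not copied: amounts are
log-spaced over the stated ranges (SS €8–€35, LL €10–€96; food trials use
truffle counts of equal unit value), crossed with the delay sets SS ∈ {0,
14, 28} d and LL ∈ {14, 28, 42} d, filtered to valid trials, and the 32
combinations are chosen quantile-spaced along the implied log k_indiff
axis.  The resulting grid spans ≈ 3.6 decades of k (0.0007–2.4 per day),
which is what identifies discount rates over the clinically relevant
range.  The grid is deterministic given its configuration.

### Logistic indifference-point fit

For each participant and reward type we fit, by maximum likelihood,

    P(choose LL) = logistic(α + β · log k_indiff),

and read the discount rate off the 50% point: log k = −α/β.  The
regression runs on *log* k_indiff (k spans orders of magnitude; the paper-
style fit on raw k is dominated by the largest trials).  Numerical rules:

* Perfect monotone separation (a noiseless chooser) leaves log k
  identified only up to the gap between adjacent grid points; we return
  the gap midpoint with a capped slope (β = 50) and a `separated` flag.
* Perfect anti-monotone separation, or a fitted β ≤ 0, signals an
  inconsistent pattern (handled by imputation, below).
* All-identical choice vectors are non-identifiable.
* The fitted 50% point is clipped to the grid's log-k support: a
  shallow-slope fit can place −α/β far outside the range any trial probes,
  and the data carry no information there.
* Fits use L-BFGS on the stable log-likelihood with standardized
  predictors; if the unpenalized fit fails, a small ridge on the
  standardized slope (1e−2) is used as fallback.

### Responder classification and imputation

Each (participant, reward) choice vector is classified:

* `all_ss` / `all_ll`: 100% / 0% smaller-sooner choices (mono-choice);
* `inconsistent`: the probability of choosing LL *decreases* with LL
  amount — operationalized as a one-sided test (amount-only logistic,
  slope < 0, p < 0.05).  The threshold deliberately tolerates small
  negative slopes from noise; as with any α-level screen, roughly that
  fraction of honest noisy choosers may still be flagged;
* `fit_ok` otherwise.

Missing log k values are imputed within each group (patients and controls
separately), from the group's successfully fitted members:

* `all_ll` → the group minimum fitted log k;
* `all_ss` → the group maximum fitted log k;
* `inconsistent` → the value predicted by an OLS line of fitted log k on
  %SS choice, evaluated at the participant's %SS.

The interpolation runs on log k by default (numerically stable and the
scale of all downstream statistics); a raw-k variant is config-switchable.
Because min/max commute with the monotone log transform, the mono-choice
rules are scale-indifferent.  log k is the natural logarithm throughout
(log k = −2.11 ↔ k = 0.12).

### Sensitivity to the larger-later reward

A second, assumption-light outcome: a per-participant logistic regression
of LL choice on LL amount and LL delay.  The LL-amount coefficient
(log-odds per reward unit) is the sensitivity; lower values mean choices
ignore how large the delayed reward is.  Complete separation (including
mono-choice vectors) falls back to a ridge-penalized fit with slopes
clipped to ±1 and `converged=False`.

### Outlier removal

Extreme outliers — outside [Q1 − 3·IQR, Q3 + 3·IQR], quartiles by the
linear-interpolation (type-7) convention — are removed once, pooled over
both groups, separately per outcome and reward type, before correlation
and mediation analyses.

## 2. Group and symptom statistics

* **Group comparisons** use the two-sample Wilcoxon rank-sum test.  The
  reported statistic W counts (x, y) pairs with x > y (ties half).  The
  two-sided p is exact (dynamic-programming null distribution of the
  rank-sum) for combined samples ≤ 12 without ties, and a tie-corrected
  normal approximation with continuity correction otherwise.  The effect
  size is r = |Z|/√(n1+n2) — a common convention; the source analyses do
  not name theirs, so this is a documented assumption rather than a
  reconstruction.
* **Age adjustment**: OLS of the outcome on the group indicator plus age;
  the group coefficient B and its two-sided p are reported.
* **Spearman correlations** carry 95% CIs from the Fisher z transform
  with variance 1.06/(n−3) (Fieller's adjustment for rank correlations); a
  percentile-bootstrap CI is available as an option.  The exact CI recipe
  is likewise an assumption, not a reconstruction.
* **Multiple testing**: the symptom battery tests each task outcome
  against 4 symptom scores (Hayling errors, FAB, EBI, DAS-Executive) × 2
  reward types = 8 correlations, Bonferroni-corrected with m = 8
  (p_corr = min(1, 8p)).
* **Residualized coupling**: discount rate and LL sensitivity are each
  residualized on the group indicator by OLS; the Spearman correlation of
  the residuals checks that higher discounting goes with lower LL
  sensitivity within groups (negative by construction in the simulator,
  negative in fitted estimates as a recovery property).
* **Power**: (a) empirical power of the two-sided Wilcoxon test by
  simulation under a normal location-shift alternative with
  δ = √2·Φ⁻¹(P(X>Y)) in unit-variance normals — at n = 22 vs 16 and
  P(X>Y) = 0.76 this lands a little above 80%; rejection uses the exact
  rank-sum p at α = 0.05.  (b) The mediation effect-size conversion
  r = Z/√(Z² + df).

## 3. Whole-brain mediation

For every in-mask voxel, with X the binary patient indicator, M the
voxel's grey-matter density (GMD) and Y a scalar behavioural outcome:

    M = i1 + a·X            (path a: atrophy)
    Y = i2 + c′·X + b·M     (path b; c′ = direct effect)
    Y = i3 + c·X            (path c: total effect)
    ab = a·b                (indirect effect)

Optional covariates enter all three models identically, which preserves
the exact decomposition ab = c − c′ (verified to 1e−10 at every voxel).
Point fits use closed-form weighted normal equations vectorized over
voxels; c′ comes from an explicit full solve, not from the identity.
Voxels whose GMD is (numerically) collinear with the design — zero
residual variance — are marked invalid and excluded; their (b, c′) split
is not identified.

**Inference** is a percentile bootstrap over participants: replicates are
drawn once from the seed as a multinomial count matrix (replicates that
lose an entire group are redrawn, capped), every replicate re-fits all
paths at all voxels, and the two-sided p of a statistic is
2·min(#{θ* ≤ 0}, #{θ* ≥ 0})/n_boot, floored at 2/n_boot, zeros counted on
both sides.  Because the resampling plan precedes any voxel work, results
are independent of voxel order and chunk size.  The plain (not
bias-corrected) percentile method is used.  Canonical n_boot is 10,000;
desk-scale runs in this repository use 2,000.

**Thresholding**: Benjamini–Hochberg FDR at q = 0.05 applied *once* to the
pooled in-mask p-values of paths a, b and ab (3V values per outcome
model), yielding a single realized voxel-level cutoff shared by the three
paths — the reading consistent with a single reported voxel-level
threshold; per-path BH is available as an option.  Whether pooling should
also span the two reward outcomes is ambiguous in the source; we pool per
outcome.

**Conjunction**: mediating regions are voxels significant on all three
paths with matching signs — for the discount rate a<0, b<0, ab>0 (atrophy
that raises discounting); for LL sensitivity a<0, b>0, ab<0.  Constraint
sets violating sign(a)·sign(b) = sign(ab) are rejected.  Clusters are
26-connected components of the conjunction mask, size-filtered (default
minimum 5 voxels), reported with peak-|coefficient| voxel and sign.

No covariates enter the mediation by default (age is supported as an
option); participants missing the outcome are listwise-dropped and logged.

## 4. Synthetic cohort

The generator's defaults are the study conditions:

* **Sizes**: 22 patients, 17 controls.
* **True log k** (natural log), per group × reward:
  money −2.25 (SD 0.58) vs −3.33 (1.80); food −1.63 (0.46) vs −2.40
  (1.09); money and food latents correlate at ρ = 0.7.
* **Choice noise**: P(LL) = logistic(τ·(V_LL − V_SS)) with hyperbolic
  values in reward units — the standard softmax discrete-choice model
  consistent with the logistic estimation stage.  τ is log-normal with
  median 2.0 (σ_log = 0.4) per reward unit: at the grid's value
  differences this yields mostly reliable but imperfect choices and >0.9
  true-vs-estimated log k correlation among fit-ok agents.
* **Degenerate responders** (per-participant class, shared across
  rewards): patients 30% all-SS + 22% inconsistent; controls 12% all-SS —
  the observed rates of mono-choice and incoherent patterns.  Inconsistent
  agents choose LL with probability *decreasing* in LL amount.
* **Clinical scores**: Gaussian marginals per group matching the study's
  demographics table (Hayling errors 19.8 ± 13.7 vs 3.3 ± 2.5; FAB 12.1 ±
  3.4 vs 17.4 ± 0.9; EBI 13.1 ± 6.2 vs 1.4 ± 1.9; DAS-Executive 10.0 ±
  4.6 vs 4.2 ± 3.6; age, education, MMSE, sex likewise), coupled to the
  latent log k by a Gaussian copula.  Target Spearman correlations
  (within-group, vs the money latent unless noted): Hayling +0.6, FAB
  −0.45, EBI +0.2, EBI food-approach +0.4 (food latent), DAS-Executive
  +0.1, MMSE −0.2 — signs and rough sizes of the study's symptom
  correlations.  The Pearson latent correlation uses the exact
  bivariate-normal inversion ρ = 2·sin(π·ρ_s/6).  Marginals are not
  truncated at instrument bounds; rank structure is what the analyses
  consume.
* **Volumes**: 24³ grids (16³ in the validation suites), 4 mm voxels,
  identity-scaled affine, box mask two voxels in from the edge.  GMD =
  0.55 baseline + planted per-region atrophy (a = −0.08 in patients) +
  a per-region shared fluctuation (SD 0.04) + voxel noise (SD 0.03).  The
  shared regional fluctuation is what makes region-level structure
  detectable voxel-wise without smoothing; Gaussian smoothing is available
  but off by default (real smoothing belongs to VBM preprocessing, which
  is out of scope).  Default regions: a true mediator (a = −0.08,
  b = −6.0), an atrophy-only region (a = −0.08, b = 0) and a
  coupling-only region (a = 0, b = −6.0) — the last two are the
  specificity controls.  The scalar outcome is intercept −3.3 + direct
  effect c′ = 0.5·patient + Σ_regions b·(region-mean GMD − baseline) +
  noise (SD 0.3).
* **End-to-end coupling**: `simulate_study` maps that structural outcome
  monotonically (per-group standardization) onto the cohort's money log-k
  marginals before choices are simulated, so the mediation planted in the
  volumes survives the full behavioural estimation path.  Within-group
  rank order is exactly preserved by construction.

What the generator does **not** emulate: scanner physics, registration,
DARTEL template effects, spatially realistic atrophy topographies,
response times, instrument floors/ceilings, or missing-data mechanisms.
Passing recovery tests therefore demonstrates the statistical machinery is
correct under the assumed generative model, not that the clinical effects
would replicate in new patients.

## 5. Validation suite design and problem sizes

* Indifference-rate formula vs bisection root: 1,000 random trials,
  relative error < 1e−8.
* Exact Wilcoxon p vs full enumeration: all sample-size pairs with
  n1 + n2 ≤ 10.
* Mediation point estimates vs direct normal-equation solves (1e−8);
  ab = c − c′ at every voxel (1e−10).
* log-k recovery: 200 clean agents (100/group), correlation of true vs
  estimated log k > 0.9 among fit-ok participants.
* FDR calibration: 200 fully-null cohorts (n = 30/group, 16³ grid,
  n_boot = 2,000); empirical FDR ≤ q + 2 Monte-Carlo SE.  FDR control does
  not depend on sample size, so the null suite runs at the small n.
* Mediator recovery: 10 runs at n = 120/group (the study's own n = 38 is
  underpowered for voxel-wise mediation, as its authors note); planted
  mediator sensitivity ≥ 0.8 per run, and the atrophy-only control region
  contributes no cluster-sized (≥ 5 voxels) false conjunction in ≥ 95% of
  runs.

## 6. Known limitations

* The 32-trial grid is a principled stand-in for the unpublished trial
  list, not a reconstruction; absolute log k estimates depend on the grid.
* The bootstrap p floor (2/n_boot) makes tiny p-values grid-valued;
  pooled-BH cutoffs inherit that granularity.
* Mono-choice imputation compresses true between-group differences by
  construction (group max/min bounds), which can understate group effects
  at study scale — visible in the desk-scale worked example.
* Per-group standardization in the end-to-end coupling fixes the log-k
  marginals exactly at the expense of a small nonlinearity in the
  structural-behavioural link across groups.
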