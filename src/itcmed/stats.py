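"""Group comparisons, symptom correlations, and power computations.

Conventions follow common nonparametric practice for small clinical samples:

* two-sample Wilcoxon rank-sum tests report the Mann-Whitney statistic W
  (number of (x, y) pairs with x > y, ties counted half) with an exact
  two-sided p when the combined sample is small and tie-free, and a
  tie-corrected normal approximation otherwise; the effect size is
  r = |Z| / sqrt(n1 + n2);
* Spearman correlations carry Fisher-z confidence intervals with the
  1.06/(n-3) variance adjustment (a bootstrap CI is available as an option);
* multiple testing over the symptom battery uses Bonferroni with m = 8
  (4 symptoms x 2 reward types per task outcome);
* the mediation effect-size conversion is r = Z / sqrt(Z^2 + df);
* Wilcoxon power is estimated by simulation under a normal location-shift
  alternative calibrated to a target P(X > Y).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.stats import norm


@dataclass
class GroupTestResult:
    statistic: float  # Mann-Whitney W for the first sample
    p: float
    effect_size_r: float
    n1: int
    n2: int
    z: float
    exact: bool


@dataclass
class CorrelationResult:
    rho: float
    p: float
    p_corrected: float | None
    ci_low: float
    ci_high: float
    n: int


@dataclass
class PowerResult:
    n1: int
    n2: int
    p_xy: float
    alpha: float
    reps: int
    power: float


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


@lru_cache(maxsize=32)
def _exact_u_pmf(n1: int, n2: int) -> np.ndarray:
    """Null pmf of the Mann-Whitney U statistic (no ties), by counting
    rank subsets with a dynamic program."""
    N = n1 + n2
    max_sum = sum(range(N - n1 + 1, N + 1))
    dp = np.zeros((n1 + 1, max_sum + 1))
    dp[0, 0] = 1.0
    for i in range(1, N + 1):
        for k in range(min(i, n1), 0, -1):
            dp[k, i:] += dp[k - 1, :-i]
    min_sum = n1 * (n1 + 1) // 2
    pmf = dp[n1, min_sum: min_sum + n1 * n2 + 1]
    return pmf / pmf.sum()


def exact_u_pvalues(n1: int, n2: int) -> np.ndarray:
    """Two-sided exact p for every U in 0..n1*n2: p = 2*min(P(U<=u), P(U>=u))."""
    pmf = _exact_u_pmf(n1, n2)
    cdf = np.cumsum(pmf)
    sf = np.cumsum(pmf[::-1])[::-1]  # P(U >= u)
    return np.minimum(1.0, 2.0 * np.minimum(cdf, sf))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(x[:, None] > y[None, :]) + 0.5 * np.sum(x[:, None] == y[None, :]))


def _tie_corrected_z(u: float, x: np.ndarray, y: np.ndarray,
                     continuity: bool) -> float:
    n1, n2 = len(x), len(y)
    N = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (N * (N - 1)) if N > 1 else 0.0
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return 0.0
    d = u - mu
    if continuity and d != 0:
        d -= 0.5 * np.sign(d)
    return float(d / np.sqrt(var))


def wilcoxon_group_test(x, y, exact_max_n: int = 12) -> GroupTestResult:
    """Two-sided two-sample Wilcoxon rank-sum test.

    Exact enumeration when n1 + n2 <= ``exact_max_n`` and the data are
    tie-free; tie-corrected normal approximation (with continuity
    correction) otherwise.  Effect size r = |Z| / sqrt(n1 + n2), with Z
    from the (uncorrected-continuity) normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    u = _u_statistic(x, y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
    exact = (n1 + n2 <= exact_max_n) and not has_ties
    if exact:
        p = float(exact_u_pvalues(n1, n2)[int(u)])
    else:
        zp = _tie_corrected_z(u, x, y, continuity=True)
        p = float(2 * norm.sf(abs(zp)))
    z = _tie_corrected_z(u, x, y, continuity=False)
    r = abs(z) / np.sqrt(n1 + n2)
    return GroupTestResult(u, min(p, 1.0), float(r), n1, n2, z, exact)


# ---------------------------------------------------------------------------
# regressions and correlations


def age_adjusted_group_effect(outcome, group, age) -> tuple[float, float]:
    """OLS outcome ~ group + age; returns (group coefficient B, two-sided p)."""
    outcome = np.asarray(outcome, dtype=float)
    g = np.asarray(group)
    # encode bvftd (or the lexicographically first label) as 1
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError("group must have exactly two levels")
    x_group = (g == ("bvftd" if "bvftd" in labels else labels[0])).astype(float)
    age = np.asarray(age, dtype=float)
    if np.allclose(age, age[0]) or x_group.min() == x_group.max():
        raise ValueError("constant predictor: rank-deficient design")
    X = sm.add_constant(np.column_stack([x_group, age]))
    fit = sm.OLS(outcome, X).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def spearman_with_ci(x, y, m: int | None = None, ci_method: str = "fisher",
                     n_boot: int = 2000, seed: int | None = 0) -> CorrelationResult:
    """Spearman rho with two-sided p and a 95% CI.

    CI by Fisher-z on rho with the 1.06/(n-3) variance adjustment, or by
    nonparametric bootstrap (``ci_method='bootstrap'``).  ``m`` applies a
    Bonferroni correction to the p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("constant vector: correlation undefined")
    res = sps.spearmanr(x, y)
    rho, p = float(res.statistic), float(res.pvalue)
    if ci_method == "fisher":
        if n > 3 and abs(rho) < 1:
            zr = np.arctanh(rho)
            se = np.sqrt(1.06 / (n - 3))
            ci = (float(np.tanh(zr - 1.959963985 * se)),
                  float(np.tanh(zr + 1.959963985 * se)))
        else:
            ci = (rho, rho)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        boots = np.array([sps.spearmanr(x[i], y[i]).statistic for i in idx])
        ci = tuple(np.nanpercentile(boots, [2.5, 97.5]))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    corrected = bonferroni(p, m) if m else None
    return CorrelationResult(rho, p, corrected, ci[0], ci[1], n)


def bonferroni(p: float, m: int = 8) -> float:
    """min(1, m*p)."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    return min(1.0, m * p)


def group_residual_correlation(x, y, group, **kwargs) -> CorrelationResult:
    """Spearman correlation of x and y after residualizing each on group.

    Removes the between-group shift so the correlation reflects
    within-sample coupling only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    g = np.asarray(group)
    labels = np.unique(g)
    if len(labels) < 2 or any((g == lab).sum() == 0 for lab in labels):
        raise ValueError("need two non-empty groups")
    X = sm.add_constant((g == labels[0]).astype(float))
    rx = sm.OLS(x, X).fit().resid
    ry = sm.OLS(y, X).fit().resid
    return spearman_with_ci(rx, ry, **kwargs)


def mediation_power_r(Z: float, df: float) -> float:
    """Effect-size conversion r = Z / sqrt(Z^2 + df)."""
    if df <= 0:
        raise ValueError("df must be positive")
    return float(Z / np.sqrt(Z ** 2 + df))


def wilcoxon_power_sim(n1: int, n2: int, p_xy: float, alpha: float = 0.05,
                       reps: int = 10_000, seed: int | None = 0) -> PowerResult:
    """Empirical power of the two-sided rank-sum test by simulation.

    Samples are unit-variance normals with location shift
    delta = sqrt(2) * Phi^{-1}(p_xy), the shift at which P(X > Y) = p_xy.
    Rejection uses the exact (tie-free) two-sided p at the given alpha.
    """
    if reps < 1000:
        raise ValueError("need reps >= 1000")
    if not 0.5 <= p_xy < 1.0:
        raise ValueError("p_xy must be in [0.5, 1)")
    rng = np.random.default_rng(seed)
    delta = np.sqrt(2.0) * norm.ppf(p_xy)
    pvals = exact_u_pvalues(n1, n2)
    x = rng.standard_normal((reps, n1)) + delta
    y = rng.standard_normal((reps, n2))
    u = (x[:, :, None] > y[:, None, :]).sum(axis=(1, 2))
    rejections = pvals[u] < alpha
    return PowerResult(n1, n2, p_xy, alpha, reps, float(rejections.mean()))


# ---------------------------------------------------------------------------
# batteries over the estimates table

SYMPTOMS = ("hayling", "fab", "ebi", "das_exec")
OUTCOMES = ("log_k", "beta_amount")
REWARDS = ("money", "food")


def _outcome_vector(estimates: pd.DataFrame, outcome: str, reward: str,
                    drop_interpolated: bool = False) -> pd.Series:
    sub = estimates[estimates["reward_type"] == reward]
    if drop_interpolated and outcome == "log_k":
        sub = sub[sub["method"] != "interpolate_pct_ss"]
    return sub.set_index("participant_id")[outcome].dropna()


def group_comparison_battery(estimates: pd.DataFrame, clinical: pd.DataFrame,
                             outcomes=OUTCOMES, rewards=REWARDS,
                             drop_interpolated: bool = False) -> pd.DataFrame:
    """Wilcoxon group tests plus age-adjusted OLS for every outcome x reward.

    ``drop_interpolated`` reruns the discount-rate comparisons without the
    %SS-interpolated (inconsistent-responder) estimates, the robustness
    variant of the main group test.
    """
    groups = estimates.drop_duplicates("participant_id").set_index(
        "participant_id")["group"]
    ages = clinical.set_index("participant_id")["age"]
    rows = []
    for outcome in outcomes:
        for reward in rewards:
            vec = _outcome_vector(estimates, outcome, reward, drop_interpolated)
            g = groups.loc[vec.index]
            x = vec[g == "bvftd"].to_numpy()
            y = vec[g == "control"].to_numpy()
            res = wilcoxon_group_test(x, y)
            B, p_age = age_adjusted_group_effect(
                vec.to_numpy(), g.to_numpy(), ages.loc[vec.index].to_numpy())
            rows.append({
                "outcome": outcome, "reward_type": reward,
                "W": res.statistic, "p": res.p, "effect_size_r": res.effect_size_r,
                "n_bvftd": res.n1, "n_control": res.n2,
                "age_adjusted_B": B, "age_adjusted_p": p_age,
            })
    return pd.DataFrame(rows)


def symptom_correlation_battery(estimates: pd.DataFrame, clinical: pd.DataFrame,
                                symptoms=SYMPTOMS, outcomes=OUTCOMES,
                                rewards=REWARDS, group: str = "bvftd",
                                m: int | None = None) -> pd.DataFrame:
    """Spearman correlations of each task outcome with each symptom score.

    Runs symptoms x rewards tests per outcome within the given group
    (8 with the defaults) and Bonferroni-corrects with m = that count
    unless ``m`` is given.
    """
    clin = clinical[clinical["group"] == group].set_index("participant_id")
    rows = []
    for outcome in outcomes:
        n_tests = m if m is not None else len(symptoms) * len(rewards)
        for reward in rewards:
            vec = _outcome_vector(estimates, outcome, reward)
            vec = vec[vec.index.isin(clin.index)]
            for symptom in symptoms:
                scores = clin.loc[vec.index, symptom]
                res = spearman_with_ci(vec.to_numpy(), scores.to_numpy(), m=n_tests)
                rows.append({
                    "outcome": outcome, "reward_type": reward, "symptom": symptom,
                    "rho": res.rho, "p": res.p, "p_corrected": res.p_corrected,
                    "ci_low": res.ci_low, "ci_high": res.ci_high, "n": res.n,
                })
    return pd.DataFrame(rows)
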