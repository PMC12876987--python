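"""Discount-rate and LL-sensitivity estimation from trial-level choices.

For each participant and reward type the pipeline:

1. computes every trial's *indifference* discount rate
   k = (A2 - A1) / (A1*D2 - A2*D1), the root of A1/(1+k*D1) = A2/(1+k*D2);
2. fits a logistic curve of P(choose LL) on log k_indiff and reads the
   participant's log(k) off the 50% point, log_k = -alpha/beta;
3. classifies degenerate responders (all-SS, all-LL, amount-inconsistent)
   and imputes their log(k) from the fitted members of their own group
   (group max for all-SS, group min for all-LL, a %SS linear interpolation
   for inconsistent patterns);
4. fits a second logistic of choice on LL amount and LL delay; the LL-amount
   coefficient is the participant's sensitivity to LL reward;
5. removes extreme outliers (beyond 3*IQR fences) pooled over the sample.

log(k) is the natural logarithm throughout (e.g. log k = -2.11 <-> k = 0.12).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import norm

from .design import TrialDesign

__all__ = [
    "DegenerateTrialError",
    "InvalidTrialError",
    "NonIdentifiableError",
    "InconsistentPatternError",
    "CannotImputeError",
    "DiscountEstimate",
    "SensitivityEstimate",
    "indifference_k",
    "fit_indifference_point",
    "classify_pattern",
    "impute_log_k",
    "estimate_sensitivity",
    "log_k_to_k",
    "remove_extreme_outliers",
    "estimate_participants",
]

RESPONDER_CLASSES = ("fit_ok", "all_ss", "all_ll", "inconsistent")

# slope assigned when the indifference-point fit is perfectly separated
_SEPARATION_BETA = 50.0
# cap (absolute value) for sensitivity slopes under separation fallback
_SENSITIVITY_CAP = 1.0


class DegenerateTrialError(ValueError):
    """Indifference k undefined (denominator A1*D2 - A2*D1 not positive)."""


class InvalidTrialError(ValueError):
    """Trial violates LL > SS ordering."""


class NonIdentifiableError(RuntimeError):
    """Logistic indifference-point fit has no usable solution."""


class InconsistentPatternError(RuntimeError):
    """Choice probability decreases where it should increase (beta <= 0)."""


class CannotImputeError(RuntimeError):
    """No fitted group members available as an imputation reference."""


@dataclass
class DiscountEstimate:
    participant_id: str
    reward_type: str
    log_k: float
    method: str  # logistic_fit | impute_min | impute_max | interpolate_pct_ss
    pct_ss: float
    alpha: float = np.nan
    beta: float = np.nan
    converged: bool = False
    separated: bool = False


@dataclass
class SensitivityEstimate:
    participant_id: str
    reward_type: str
    beta_amount: float
    beta_delay: float
    intercept: float
    converged: bool


def indifference_k(trial: TrialDesign) -> float:
    """Per-day discount rate at which the SS and LL options are equivalent.

    Closed form of the root of A1/(1+k*D1) = A2/(1+k*D2) under hyperbolic
    discounting: k = (A2 - A1) / (A1*D2 - A2*D1).
    """
    a1, d1, a2, d2 = trial.ss_amount, trial.ss_delay, trial.ll_amount, trial.ll_delay
    if a2 <= a1:
        raise InvalidTrialError(f"LL amount {a2} must exceed SS amount {a1}")
    denom = a1 * d2 - a2 * d1
    if denom <= 0:
        raise DegenerateTrialError(
            f"A1*D2 - A2*D1 = {denom}: no positive indifference k for this trial"
        )
    return (a2 - a1) / denom


def log_k_to_k(log_k: float) -> float:
    """k = e^log_k (log k is a natural log)."""
    return float(np.exp(log_k))


def _logit_fit(X: np.ndarray, y: np.ndarray, ridge: float = 0.0):
    """Penalized logistic MLE with internally standardized predictors.

    Returns (params, se, converged): params = (intercept, slopes...) on the
    original predictor scale; ridge (if any) penalizes standardized slopes
    only, so the fallback is scale-invariant.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    y = np.asarray(y, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = np.column_stack([np.ones(len(y)), (X - mu) / sd])

    def nll(beta):
        eta = Z @ beta
        # log(1+e^eta) - y*eta, stable form
        val = np.logaddexp(0.0, eta) - y * eta
        return val.sum() + 0.5 * ridge * np.dot(beta[1:], beta[1:])

    def grad(beta):
        p = expit(Z @ beta)
        g = Z.T @ (p - y)
        g[1:] += ridge * beta[1:]
        return g

    res = optimize.minimize(nll, np.zeros(Z.shape[1]), jac=grad, method="L-BFGS-B",
                            options={"maxiter": 500, "gtol": 1e-8})
    beta_std = res.x
    p = expit(Z @ beta_std)
    w = p * (1 - p)
    H = (Z * w[:, None]).T @ Z
    H[1:, 1:] += ridge * np.eye(Z.shape[1] - 1)
    try:
        cov = np.linalg.inv(H)
        se_std = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_std = np.full(Z.shape[1], np.nan)

    slopes = beta_std[1:] / sd
    intercept = beta_std[0] - np.dot(slopes, mu)
    params = np.concatenate([[intercept], slopes])
    se = np.concatenate([[np.nan], se_std[1:] / sd])  # intercept SE unused
    clean = bool(res.success) and np.all(np.isfinite(beta_std)) \
        and np.all(np.abs(beta_std) < 30) and np.all(np.isfinite(se_std))
    return params, se, clean


def fit_indifference_point(choices, indifference_ks,
                           participant_id: str = "", reward_type: str = "") -> DiscountEstimate:
    """Fit P(choose LL) = logistic(alpha + beta * log k_indiff); log_k = -alpha/beta.

    A perfectly separated but monotone pattern (noiseless chooser) is
    identified up to the gap between adjacent trial indifference points; the
    returned log_k is the gap midpoint with a capped slope and
    ``separated=True``.  All-identical choices raise NonIdentifiableError;
    a negative-slope fit raises InconsistentPatternError.
    """
    y = np.asarray(choices, dtype=float)
    ks = np.asarray(indifference_ks, dtype=float)
    if len(y) != len(ks):
        raise ValueError("choices and indifference_ks length mismatch")
    if np.any(ks <= 0) or len(np.unique(ks)) < 2:
        raise ValueError("need >= 2 distinct positive indifference-k values")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("choices must be binary (1 = LL chosen)")
    pct_ss = float(1.0 - y.mean())
    if y.min() == y.max():
        raise NonIdentifiableError("all choices identical: 50% point undefined")

    x = np.log(ks)
    hi0, lo1 = x[y == 0].max(), x[y == 1].min()
    if lo1 > hi0:  # perfect monotone separation: LL only above a threshold
        log_k = 0.5 * (hi0 + lo1)
        beta = _SEPARATION_BETA
        return DiscountEstimate(participant_id, reward_type, float(log_k),
                                "logistic_fit", pct_ss, alpha=-beta * log_k,
                                beta=beta, converged=True, separated=True)
    if x[y == 1].max() < x[y == 0].min():  # perfect anti-monotone separation
        raise InconsistentPatternError("LL chosen only at the lowest indifference k")

    params, _se, clean = _logit_fit(x[:, None], y, ridge=0.0)
    if not clean:
        params, _se, clean = _logit_fit(x[:, None], y, ridge=1e-2)
        if not clean:
            raise NonIdentifiableError("logistic indifference-point fit did not converge")
    alpha, beta = float(params[0]), float(params[1])
    if beta <= 0:
        raise InconsistentPatternError(f"non-positive slope ({beta:.3g}) on log k_indiff")
    # the grid only identifies the 50% point within its own log-k support;
    # shallow-slope fits can otherwise extrapolate wildly
    log_k = float(np.clip(-alpha / beta, x.min(), x.max()))
    return DiscountEstimate(participant_id, reward_type, log_k,
                            "logistic_fit", pct_ss, alpha=alpha, beta=beta,
                            converged=True)


def classify_pattern(choices, ll_amounts, alpha: float = 0.05) -> str:
    """Responder class: all_ss / all_ll / inconsistent / fit_ok.

    "Inconsistent" means the probability of choosing LL *decreases* with the
    LL amount: a one-sided test (amount-only logistic, slope < 0) at the
    given alpha.
    """
    y = np.asarray(choices, dtype=float)
    amounts = np.asarray(ll_amounts, dtype=float)
    if y.min() == y.max():
        return "all_ss" if y[0] == 0 else "all_ll"
    # perfect anti-monotone separation on amount: LL only for the smallest amounts
    if amounts[y == 1].max() < amounts[y == 0].min():
        return "inconsistent"
    params, se, clean = _logit_fit(amounts[:, None], y, ridge=0.0)
    if not clean:
        params, se, clean = _logit_fit(amounts[:, None], y, ridge=1e-2)
        if not clean or not np.isfinite(se[1]) or se[1] == 0:
            return "fit_ok"
    z = params[1] / se[1]
    if params[1] < 0 and norm.cdf(z) < alpha:
        return "inconsistent"
    return "fit_ok"


def impute_log_k(responder_class: str, fitted_group_log_ks, pct_ss: float | None = None,
                 group_pct_ss_table: pd.DataFrame | None = None) -> tuple[float, str]:
    """Impute log(k) for a degenerate responder from fitted group members.

    all_ll -> group minimum fitted log k; all_ss -> group maximum;
    inconsistent -> OLS line of fitted log k on %SS within the group,
    evaluated at the participant's %SS.  Returns (log_k, method).
    """
    ref = np.asarray(fitted_group_log_ks, dtype=float)
    if responder_class not in ("all_ss", "all_ll", "inconsistent"):
        raise ValueError(f"no imputation rule for class {responder_class!r}")
    if len(ref) < 2 or not np.all(np.isfinite(ref)):
        raise CannotImputeError("need >= 2 fitted group members for imputation")
    if responder_class == "all_ll":
        return float(ref.min()), "impute_min"
    if responder_class == "all_ss":
        return float(ref.max()), "impute_max"
    if pct_ss is None or group_pct_ss_table is None:
        raise ValueError("inconsistent-pattern imputation needs pct_ss and the group table")
    tab = group_pct_ss_table
    xs = np.asarray(tab["pct_ss"], dtype=float)
    ys = np.asarray(tab["log_k"], dtype=float)
    if len(xs) < 2 or np.allclose(xs, xs[0]):
        raise CannotImputeError("group %SS values carry no slope information")
    slope, intercept = np.polyfit(xs, ys, 1)
    return float(intercept + slope * pct_ss), "interpolate_pct_ss"


def estimate_sensitivity(choices, design: pd.DataFrame,
                         participant_id: str = "", reward_type: str = "") -> SensitivityEstimate:
    """Logistic fit of LL choice on LL amount and LL delay.

    ``beta_amount`` is the sensitivity to LL reward (log-odds per reward
    unit).  Under complete separation (or a constant choice vector) the fit
    falls back to a ridge-penalized estimate with slopes capped to a
    sign-consistent bound and ``converged=False``.
    """
    y = np.asarray(choices, dtype=float)
    X = np.column_stack([np.asarray(design["ll_amount"], dtype=float),
                         np.asarray(design["ll_delay"], dtype=float)])
    if np.allclose(X[:, 0], X[0, 0]) or np.allclose(X[:, 1], X[0, 1]):
        raise ValueError("LL amount and LL delay must both vary across trials")
    params, _se, clean = _logit_fit(X, y, ridge=0.0)
    if clean:
        return SensitivityEstimate(participant_id, reward_type,
                                   float(params[1]), float(params[2]),
                                   float(params[0]), converged=True)
    params, _se, _ = _logit_fit(X, y, ridge=1.0)
    b_amt = float(np.clip(params[1], -_SENSITIVITY_CAP, _SENSITIVITY_CAP))
    b_del = float(np.clip(params[2], -_SENSITIVITY_CAP, _SENSITIVITY_CAP))
    return SensitivityEstimate(participant_id, reward_type, b_amt, b_del,
                               float(params[0]), converged=False)


def remove_extreme_outliers(values) -> tuple[np.ndarray, np.ndarray]:
    """Drop values outside [Q1 - 3*IQR, Q3 + 3*IQR] (pooled sample, once).

    Quartiles use the linear-interpolation convention (numpy default,
    type 7).  Returns (kept values, removed indices).  Refuses (with a
    warning) on fewer than 4 finite values.
    """
    values = np.asarray(values, dtype=float)
    if np.sum(np.isfinite(values)) < 4:
        warnings.warn("fewer than 4 finite values: outlier fences not applied")
        return values, np.array([], dtype=int)
    q1, q3 = np.percentile(values[np.isfinite(values)], [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 3 * iqr, q3 + 3 * iqr
    removed = np.where((values < lo) | (values > hi))[0]
    kept = np.delete(values, removed)
    return kept, removed


def estimate_participants(choices: pd.DataFrame, inconsistency_alpha: float = 0.05,
                          interpolation_scale: str = "log") -> pd.DataFrame:
    """Run the full per-participant estimation over a long choice table.

    ``choices`` columns: participant_id, group, reward_type, ss_amount,
    ss_delay, ll_amount, ll_delay, chose_ll.  Returns one row per
    (participant, reward type) with log_k, method provenance, pct_ss,
    fit diagnostics and LL-sensitivity coefficients.

    ``interpolation_scale`` selects whether the %SS interpolation for
    inconsistent responders runs on log k (default) or raw k.
    """
    if interpolation_scale not in ("log", "raw"):
        raise ValueError("interpolation_scale must be 'log' or 'raw'")
    rows = []
    for (pid, group, reward), sub in choices.groupby(
            ["participant_id", "group", "reward_type"], sort=True):
        y = sub["chose_ll"].to_numpy(dtype=float)
        ks = np.array([
            indifference_k(TrialDesign(r.ss_amount, r.ss_delay, r.ll_amount, r.ll_delay))
            for r in sub.itertuples()
        ])
        responder = classify_pattern(y, sub["ll_amount"].to_numpy(), alpha=inconsistency_alpha)
        log_k, method, a, b, conv, sep = np.nan, None, np.nan, np.nan, False, False
        if responder == "fit_ok":
            try:
                est = fit_indifference_point(y, ks, pid, reward)
                log_k, method = est.log_k, est.method
                a, b, conv, sep = est.alpha, est.beta, est.converged, est.separated
            except InconsistentPatternError:
                responder = "inconsistent"
            except NonIdentifiableError:
                responder = "inconsistent"  # unusable fit: fall back to %SS interpolation
        sens = estimate_sensitivity(y, sub, pid, reward)
        rows.append({
            "participant_id": pid, "group": group, "reward_type": reward,
            "responder_class": responder, "log_k": log_k, "method": method,
            "pct_ss": float(1 - y.mean()), "alpha": a, "beta": b,
            "converged": conv, "separated": sep,
            "beta_amount": sens.beta_amount, "beta_delay": sens.beta_delay,
            "sens_intercept": sens.intercept, "sens_converged": sens.converged,
        })
    est = pd.DataFrame(rows)

    # group-wise imputation for degenerate responders
    for (group, reward), sub in est.groupby(["group", "reward_type"]):
        fitted = sub[sub["method"] == "logistic_fit"]
        need = sub[sub["method"].isna()]
        if need.empty:
            continue
        ref_log = fitted["log_k"].to_numpy()
        tab = fitted[["pct_ss", "log_k"]].copy()
        if interpolation_scale == "raw":
            tab = tab.assign(log_k=np.exp(tab["log_k"]))
        for idx, row in need.iterrows():
            try:
                if row["responder_class"] == "inconsistent":
                    val, method = impute_log_k("inconsistent", ref_log,
                                               pct_ss=row["pct_ss"], group_pct_ss_table=tab)
                    if interpolation_scale == "raw":
                        val = float(np.log(max(val, 1e-12)))
                else:
                    val, method = impute_log_k(row["responder_class"], ref_log)
            except CannotImputeError:
                continue
            est.loc[idx, "log_k"] = val
            est.loc[idx, "method"] = method
    return est
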