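"""Intertemporal-choice trial design.

A trial offers a smaller-sooner (SS) reward against a larger-later (LL)
reward.  Under hyperbolic discounting, V = A / (1 + k*D), each trial has a
single *indifference* discount rate -- the k at which both options carry
equal discounted value -- which is the quantity participants' choices are
regressed on downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InvalidDesignError(ValueError):
    """Raised when a trial or design configuration violates SS/LL ordering."""


@dataclass(frozen=True)
class TrialDesign:
    """One SS-vs-LL offer.

    Amounts are in reward units (euros, or truffle counts of equal unit
    value); delays are in days.
    """

    ss_amount: float
    ss_delay: float
    ll_amount: float
    ll_delay: float

    def __post_init__(self) -> None:
        if not (self.ll_amount > self.ss_amount > 0):
            raise InvalidDesignError(
                f"need ll_amount > ss_amount > 0, got {self.ll_amount} vs {self.ss_amount}"
            )
        if not (self.ll_delay > self.ss_delay >= 0):
            raise InvalidDesignError(
                f"need ll_delay > ss_delay >= 0, got {self.ll_delay} vs {self.ss_delay}"
            )


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the 32-trial grid.

    Defaults follow the task: SS amounts 8-35, LL amounts 10-96,
    SS delays {0, 14, 28} d, LL delays {14, 28, 42} d.
    """

    ss_amount_range: tuple[float, float] = (8.0, 35.0)
    ll_amount_range: tuple[float, float] = (10.0, 96.0)
    ss_delays: tuple[float, ...] = (0.0, 14.0, 28.0)
    ll_delays: tuple[float, ...] = (14.0, 28.0, 42.0)
    n_trials: int = 32
    n_amounts: int = 8
    integer_amounts: bool = True


def _candidate_amounts(lo: float, hi: float, n: int, integer: bool) -> np.ndarray:
    if not (0 < lo < hi):
        raise InvalidDesignError(f"invalid amount range ({lo}, {hi})")
    amounts = np.geomspace(lo, hi, n)
    if integer:
        amounts = np.unique(np.round(amounts))
    return amounts


def build_design_grid(config: DesignConfig | None = None) -> list[TrialDesign]:
    """Build the deterministic trial grid.

    Enumerates a factorial pool of (SS amount, LL amount, SS delay, LL delay)
    combinations with log-spaced amounts over the configured ranges, keeps the
    combinations with a well-defined positive indifference k, and selects
    ``n_trials`` of them spread evenly over the pooled log-indifference-k
    range so the grid spans several orders of magnitude of k.
    """
    from .estimation import indifference_k  # local import: avoid cycle

    config = config or DesignConfig()
    ss_amounts = _candidate_amounts(*config.ss_amount_range, config.n_amounts,
                                    config.integer_amounts)
    ll_amounts = _candidate_amounts(*config.ll_amount_range, config.n_amounts,
                                    config.integer_amounts)

    candidates: list[tuple[float, TrialDesign]] = []
    for d1 in config.ss_delays:
        for d2 in config.ll_delays:
            if d2 <= d1:
                continue
            for a1 in ss_amounts:
                for a2 in ll_amounts:
                    if a2 <= a1:
                        continue
                    denom = a1 * d2 - a2 * d1
                    if denom <= 0:
                        continue
                    trial = TrialDesign(float(a1), float(d1), float(a2), float(d2))
                    candidates.append((float(np.log(indifference_k(trial))), trial))

    if len(candidates) < config.n_trials:
        raise InvalidDesignError(
            f"only {len(candidates)} valid trials available, need {config.n_trials}"
        )

    # sort by implied log k and pick quantile-spaced entries -> maximal spread
    candidates.sort(key=lambda lt: (lt[0], lt[1].ss_amount, lt[1].ll_amount,
                                    lt[1].ss_delay, lt[1].ll_delay))
    idx = np.unique(np.round(np.linspace(0, len(candidates) - 1,
                                         config.n_trials)).astype(int))
    # rounding collisions are impossible while pool >= n_trials, but guard anyway
    pos = 0
    while len(idx) < config.n_trials:
        if pos not in idx:
            idx = np.sort(np.append(idx, pos))
        pos += 1
    return [candidates[i][1] for i in idx]


def design_to_frame(trials: list[TrialDesign]):
    """Trial list as a DataFrame (one row per trial, columns as CSV schema)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "ss_amount": [t.ss_amount for t in trials],
            "ss_delay": [t.ss_delay for t in trials],
            "ll_amount": [t.ll_amount for t in trials],
            "ll_delay": [t.ll_delay for t in trials],
        }
    )
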