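"""Hyperbolic temporal discounting: adaptive task simulation and MLE fit.

The intertemporal-choice task offers repeated choices between a
smaller-sooner reward (20 currency units now) and larger-but-later
rewards at delays of 2, 7, 14, 30, 90 or 180 days.  The task is
adaptive: after two successive smaller-sooner choices at a delay, the
larger-later amount at that delay is raised; after two successive
larger-later choices it is lowered (each delay's staircase runs
independently).

Choices are modeled with a hyperbolic value function SV = A / (1 + k*D)
(k > 0 the subject's discount rate, D the delay in days) combined with a
logistic (softmax) choice rule: P(LL) = 1 / (1 + exp(-beta * (SV_LL -
SV_SS))).  The likelihood model for fitting is this same softmax — the
field-standard choice; other choice kernels are out of scope.  Because
fitted k values are right-skewed across subjects, downstream analyses
use sqrt(k).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit

__all__ = [
    "DELAYS_DAYS",
    "AMOUNT_SS",
    "ChoiceTrial",
    "StaircaseConfig",
    "DiscountFit",
    "hyperbolic_sv",
    "simulate_adaptive_task",
    "fit_discounting",
    "trials_to_frame",
    "trials_from_frame",
]

#: Delays of the larger-later option, in days.
DELAYS_DAYS = (2, 7, 14, 30, 90, 180)
#: Fixed smaller-sooner amount, available immediately.
AMOUNT_SS = 20.0


@dataclass(frozen=True)
class ChoiceTrial:
    delay_days: int
    amount_ss: float
    amount_ll: float
    choice: str  # "SS" or "LL"

    def __post_init__(self):
        if self.delay_days not in DELAYS_DAYS:
            raise ValueError(f"delay {self.delay_days} not in {DELAYS_DAYS}")
        if self.amount_ss <= 0 or self.amount_ll <= 0:
            raise ValueError("amounts must be positive")
        if self.choice not in ("SS", "LL"):
            raise ValueError(f"choice must be SS or LL, got {self.choice!r}")


@dataclass(frozen=True)
class StaircaseConfig:
    """Adaptive-task plumbing: initial larger-later amount, multiplicative
    step (fraction of the current amount), a floor keeping LL > SS, and
    trials per delay."""

    initial_ll: float = 40.0
    step_fraction: float = 0.10
    floor: float = 20.5
    n_trials_per_delay: int = 12


@dataclass(frozen=True)
class DiscountFit:
    k: float
    beta: float
    loglik: float
    boundary: bool = False  # all choices one-sided or beta ~ 0

    @property
    def sqrt_k(self) -> float:
        return math.sqrt(self.k)


def hyperbolic_sv(A: float, k: float, D: float) -> float:
    """Subjective value A / (1 + k*D) of amount A delayed by D days."""
    if A <= 0:
        raise ValueError("amount must be positive")
    if k < 0 or D < 0:
        raise ValueError("k and D must be nonnegative")
    return A / (1.0 + k * D)


def simulate_adaptive_task(k_true: float, beta: float,
                           delays: Sequence[int] = DELAYS_DAYS,
                           config: StaircaseConfig = StaircaseConfig(),
                           seed: int | np.random.Generator = 0) -> list[ChoiceTrial]:
    """Simulate an agent with discount rate ``k_true`` and choice
    sensitivity ``beta`` on the adaptive task.

    Per delay, trials alternate nowhere — each delay runs its own
    staircase for ``n_trials_per_delay`` trials: two successive SS
    choices raise the LL amount by ``step_fraction`` of its current
    value, two successive LL choices lower it likewise (never below the
    floor).  Deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trials: list[ChoiceTrial] = []
    for delay in delays:
        amount_ll = config.initial_ll
        run_choice, run_length = None, 0
        for _ in range(config.n_trials_per_delay):
            sv_ll = hyperbolic_sv(amount_ll, k_true, delay)
            p_ll = expit(beta * (sv_ll - AMOUNT_SS))
            choice = "LL" if rng.random() < p_ll else "SS"
            trials.append(ChoiceTrial(delay, AMOUNT_SS, amount_ll, choice))
            if choice == run_choice:
                run_length += 1
            else:
                run_choice, run_length = choice, 1
            if run_length == 2:
                step = config.step_fraction * amount_ll
                if run_choice == "SS":
                    amount_ll += step
                else:
                    amount_ll = max(config.floor, amount_ll - step)
                run_choice, run_length = None, 0
    return trials


def _neg_loglik(params: np.ndarray, delays: np.ndarray, amounts_ll: np.ndarray,
                chose_ll: np.ndarray) -> float:
    log_k, log_beta = params
    k, beta = math.exp(log_k), math.exp(log_beta)
    sv_ll = amounts_ll / (1.0 + k * delays)
    z = beta * (sv_ll - AMOUNT_SS)
    # log P(observed) via the numerically stable log-logistic
    ll = np.where(chose_ll, log_expit(z), log_expit(-z))
    return -float(ll.sum())


def fit_discounting(trials: Sequence[ChoiceTrial],
                    n_starts_per_axis: int = 5) -> DiscountFit:
    """Maximum-likelihood hyperbolic fit of observed choices.

    Optimizes the Bernoulli log-likelihood under the softmax choice rule
    over (log k, log beta) — the log scale enforces positivity — with a
    multistart grid of ``n_starts_per_axis``^2 initial values spanning
    k in [1e-4, 1] and beta in [0.05, 20].  One-sided choice data yield
    a boundary-flagged fit.
    """
    if not trials:
        raise ValueError("no trials")
    delays = np.array([t.delay_days for t in trials], dtype=float)
    amounts_ll = np.array([t.amount_ll for t in trials], dtype=float)
    chose_ll = np.array([t.choice == "LL" for t in trials])

    one_sided = chose_ll.all() or (~chose_ll).all()
    k_starts = np.log(np.logspace(-4, 0, n_starts_per_axis))
    beta_starts = np.log(np.logspace(np.log10(0.05), np.log10(20), n_starts_per_axis))
    best = None
    for lk in k_starts:
        for lb in beta_starts:
            res = minimize(_neg_loglik, x0=np.array([lk, lb]),
                           args=(delays, amounts_ll, chose_ll),
                           method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
            if best is None or res.fun < best.fun:
                best = res
    k, beta = math.exp(best.x[0]), math.exp(best.x[1])
    boundary = one_sided or beta < 1e-3
    return DiscountFit(k=k, beta=beta, loglik=-best.fun, boundary=boundary)


def trials_to_frame(trials: Sequence[ChoiceTrial]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.delay_days, t.amount_ss, t.amount_ll, t.choice) for t in trials],
        columns=["delay_days", "amount_ss", "amount_ll", "choice"],
    )


def trials_from_frame(frame: pd.DataFrame) -> list[ChoiceTrial]:
    return [
        ChoiceTrial(int(r.delay_days), float(r.amount_ss), float(r.amount_ll), str(r.choice))
        for r in frame.itertuples(index=False)
    ]
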