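"""Optimality analyses built on the Bayesian learner benchmark.

Two analyses are provided:

1. *Optimal-learner regression weights*: for one session, the
   forward-filtered prediction series of an optimal learner that uses
   only the primary source, and of one that uses only the secondary
   source (advice-converted), are each regressed against the observed
   choices with single-predictor binomial logistic regressions.  The
   standardised slopes (``beta_optimal``) index how strongly choices
   follow each information source.

2. *Optimal learning rates*: the dual-source delta-rule model is fitted
   to choices generated by the Bayesian optimal learner on many fresh
   synthetic task datasets; the averaged fitted learning rates define
   the optimal learning rate for each source x phase slot, and
   ``alpha_diff = alpha - alpha_optimal`` scores how far an estimate
   sits from that benchmark.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bayes_learner import GridSpec, optimal_prediction_series
from .fitting import (FULL_MODEL, FittingError, PriorConfig, fit_map)
from .rw_model import choice_probability, replace_choices
from .schedules import (ScheduleConfig, TrialSequence, counterbalanced_configs,
                        generate_schedule, sample_trials)

logger = logging.getLogger(__name__)

#: logistic-regression slopes are capped at this magnitude under separation
BETA_CAP = 10.0

_SLOTS = ("alpha_primary_stable", "alpha_primary_volatile",
          "alpha_secondary_stable", "alpha_secondary_volatile")


@dataclass
class OptimalBetas:
    """Standardised logistic slopes of choices on the two optimal learners."""

    beta_primary: float
    beta_secondary: float
    se_primary: float
    se_secondary: float
    separation_primary: bool = False
    separation_secondary: bool = False


def _single_logit(y: np.ndarray, x: np.ndarray) -> tuple[float, float, bool]:
    """Slope and SE of a one-predictor logistic regression on standardised x."""
    sd = np.std(x)
    if sd == 0:
        raise ValueError("predictor series is constant")
    z = (x - np.mean(x)) / sd
    X = sm.add_constant(z)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation warnings are handled
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        coef, se = float(res.params[1]), float(res.bse[1])
    except Exception:  # perfect separation or non-convergence
        coef, se = np.nan, np.nan
    if not np.isfinite(coef) or abs(coef) > BETA_CAP:
        sign = np.sign(coef) if np.isfinite(coef) and coef != 0 else (
            1.0 if np.corrcoef(z, y)[0, 1] >= 0 else -1.0)
        return float(sign * BETA_CAP), float("nan"), True
    return coef, se, False


def optimal_learner_betas(trials: TrialSequence,
                          spec: GridSpec | None = None) -> OptimalBetas:
    """Regress one session's choices on both optimal prediction series."""
    y = np.asarray(trials.y, dtype=float)
    mask = ~np.isnan(y)
    if not mask.any():
        raise ValueError("no choices to regress")
    primary = optimal_prediction_series(trials, "primary", spec).p_hat
    secondary = optimal_prediction_series(trials, "secondary", spec).p_hat
    b1, se1, sep1 = _single_logit(y[mask], primary[mask])
    b2, se2, sep2 = _single_logit(y[mask], secondary[mask])
    return OptimalBetas(b1, b2, se1, se2, sep1, sep2)


def attach_optimal_predictions(trials: TrialSequence,
                               spec: GridSpec | None = None) -> pd.DataFrame:
    """Trial table with the two optimal prediction series as extra columns."""
    df = trials.to_frame()
    df["p_hat_primary"] = optimal_prediction_series(trials, "primary", spec).p_hat
    df["p_hat_secondary_converted"] = optimal_prediction_series(
        trials, "secondary", spec).p_hat
    return df


@dataclass
class OptimalAlphas:
    """Simulation-derived optimal learning rates per source x phase slot."""

    alpha_opt_primary_stable: float
    alpha_opt_primary_volatile: float
    alpha_opt_secondary_stable: float
    alpha_opt_secondary_volatile: float
    se: dict[str, float] = field(default_factory=dict)
    n_datasets: int = 0
    n_failed: int = 0
    seed: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            "alpha_primary_stable": self.alpha_opt_primary_stable,
            "alpha_primary_volatile": self.alpha_opt_primary_volatile,
            "alpha_secondary_stable": self.alpha_opt_secondary_stable,
            "alpha_secondary_volatile": self.alpha_opt_secondary_volatile,
        }


def simulate_optimal_agent(schedule_config: ScheduleConfig, seed: int,
                           beta: float = 10.0, zeta: float = 0.5,
                           spec: GridSpec | None = None,
                           mode: str = "choices") -> TrialSequence:
    """One synthetic dataset whose choices come from the optimal learner.

    The learner's primary and advice-converted secondary predictions are
    mixed with weight ``zeta`` and passed through the unit-square
    sigmoid with a high inverse temperature ``beta``.  In ``"choices"``
    mode binary choices are sampled from the resulting probabilities; in
    ``"trajectories"`` mode the probabilities themselves are stored as
    soft targets.
    """
    rng = np.random.default_rng(seed)
    s_sched, s_trials, s_choice = rng.integers(2 ** 31, size=3)
    schedule = generate_schedule(schedule_config.with_seed(int(s_sched)))
    trials = sample_trials(schedule, int(s_trials))
    primary = optimal_prediction_series(trials, "primary", spec).p_hat
    secondary = optimal_prediction_series(trials, "secondary", spec).p_hat
    combined = zeta * secondary + (1.0 - zeta) * primary
    p_choice = np.array([choice_probability(v, beta) for v in combined])
    if mode == "choices":
        y = (np.random.default_rng(int(s_choice)).random(len(p_choice))
             < p_choice).astype(float)
    elif mode == "trajectories":
        y = p_choice
    else:
        raise ValueError("mode must be 'choices' or 'trajectories'")
    return replace_choices(trials, y)


def compute_optimal_alphas(schedule_config: ScheduleConfig | list[ScheduleConfig]
                           | None = None,
                           n_datasets: int = 100, seed: int = 0,
                           beta: float = 10.0, zeta: float = 0.5,
                           spec: GridSpec | None = None,
                           mode: str = "choices",
                           priors: PriorConfig | None = None,
                           n_starts: int = 10) -> OptimalAlphas:
    """Average learning rates recovered from optimal-learner behaviour.

    Each dataset uses a freshly randomised schedule and outcome
    realisation; by default the datasets rotate through the four
    counterbalanced block orders (so no source x phase slot is
    systematically early or late in the session).  The full dual-source
    model is MAP-fitted to the optimal learner's choices and the four
    learning rates are averaged across datasets.  Fit failures are
    excluded with a logged count.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    if schedule_config is None:
        configs = counterbalanced_configs()
    elif isinstance(schedule_config, ScheduleConfig):
        configs = [schedule_config]
    else:
        configs = list(schedule_config)
    rng = np.random.default_rng(seed)
    estimates: list[dict[str, float]] = []
    n_failed = 0
    for i in range(n_datasets):
        s_data, s_fit = rng.integers(2 ** 31, size=2)
        trials = simulate_optimal_agent(configs[i % len(configs)], int(s_data),
                                        beta=beta, zeta=zeta, spec=spec,
                                        mode=mode)
        try:
            fit = fit_map(trials, priors=priors, n_starts=n_starts,
                          seed=int(s_fit), variant=FULL_MODEL)
        except FittingError as err:
            logger.warning("optimal-alpha dataset %d failed: %s", i, err)
            n_failed += 1
            continue
        estimates.append({k: fit.natural[k] for k in _SLOTS})
    if not estimates:
        raise FittingError("all optimal-learner fits failed")
    table = pd.DataFrame(estimates)
    mean = table.mean()
    se = (table.std(ddof=1) / np.sqrt(len(table))).to_dict() if len(table) > 1 else {}
    return OptimalAlphas(
        alpha_opt_primary_stable=float(mean["alpha_primary_stable"]),
        alpha_opt_primary_volatile=float(mean["alpha_primary_volatile"]),
        alpha_opt_secondary_stable=float(mean["alpha_secondary_stable"]),
        alpha_opt_secondary_volatile=float(mean["alpha_secondary_volatile"]),
        se=se, n_datasets=len(table), n_failed=n_failed, seed=seed)


def alpha_diff(estimates: pd.DataFrame, optimal: OptimalAlphas) -> pd.DataFrame:
    """Element-wise ``alpha - alpha_optimal`` for the four learning-rate slots.

    ``estimates`` must contain the four untransformed learning-rate
    columns; all other columns are passed through unchanged.
    """
    missing = [c for c in _SLOTS if c not in estimates.columns]
    if missing:
        raise KeyError(f"estimates table lacks columns {missing}")
    out = estimates.copy()
    for slot, opt in optimal.as_dict().items():
        out[slot] = estimates[slot] - opt
    return out
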