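"""Dual-source Rescorla-Wagner learning with a unit-square-sigmoid response rule.

Two delta-rule predictors run side by side: one tracks the probability
that the primary-congruent option is rewarded (from the outcomes
``r(t)``), the other tracks the probability that the secondary source's
advice is correct (from the correctness indicator ``r(t) XOR advice(t)``).
Each predictor has separate learning rates for stable and volatile
schedule phases, giving four learning rates in the full model:

    V(i+1) = V(i) + alpha * (outcome(i) - V(i))

The response model converts the secondary belief into a belief about the
primary-congruent option through the advice weighting

    V_aw = |advice - V_secondary|

mixes the two sources with the weight ``zeta``

    V_combined = zeta * V_aw + (1 - zeta) * V_primary

and maps the combined belief to a choice probability with the
unit-square sigmoid

    P(y = 1 | V) = V**beta / (V**beta + (1 - V)**beta)

where ``beta`` is the inverse decision temperature.  Choices are coded
1 for the primary-congruent option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .schedules import STABLE, VOLATILE, TrialSequence

#: beliefs are clipped to [EPS, 1 - EPS] before the sigmoid to avoid 0**beta
EPS = 1e-6


@dataclass(frozen=True)
class RWParams:
    """Free parameters of the dual-source model and its reduced variants.

    The four learning rates and ``zeta`` live in (0, 1); ``beta`` is a
    positive inverse decision temperature.  ``v0`` (the initial belief)
    is fixed at 0.5 and never fitted.  The three flags select the model
    variant: when a split flag is off, the corresponding learning-rate
    entries must be equal; when ``zeta_free`` is off, ``zeta`` is fixed
    at 0.5 (equal weighting of the two sources).
    """

    alpha_primary_stable: float = 0.3
    alpha_primary_volatile: float = 0.3
    alpha_secondary_stable: float = 0.3
    alpha_secondary_volatile: float = 0.3
    zeta: float = 0.5
    beta: float = 4.0
    v0: float = 0.5
    split_alpha_by_source: bool = True
    split_alpha_by_volatility: bool = True
    zeta_free: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha_primary_stable", "alpha_primary_volatile",
                     "alpha_secondary_stable", "alpha_secondary_volatile"):
            a = getattr(self, name)
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"{name}={a} outside [0, 1]")
        if not 0.0 <= self.zeta <= 1.0:
            raise ValueError("zeta outside [0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0.0 < self.v0 < 1.0:
            raise ValueError("v0 must lie in (0, 1)")
        if not self.split_alpha_by_source:
            if (self.alpha_primary_stable != self.alpha_secondary_stable
                    or self.alpha_primary_volatile != self.alpha_secondary_volatile):
                raise ValueError("source split disabled but source alphas differ")
        if not self.split_alpha_by_volatility:
            if (self.alpha_primary_stable != self.alpha_primary_volatile
                    or self.alpha_secondary_stable != self.alpha_secondary_volatile):
                raise ValueError("volatility split disabled but phase alphas differ")
        if not self.zeta_free and self.zeta != 0.5:
            raise ValueError("zeta fixed variant requires zeta = 0.5")

    @property
    def alphas(self) -> dict[str, float]:
        return {
            "alpha_primary_stable": self.alpha_primary_stable,
            "alpha_primary_volatile": self.alpha_primary_volatile,
            "alpha_secondary_stable": self.alpha_secondary_stable,
            "alpha_secondary_volatile": self.alpha_secondary_volatile,
        }


@dataclass
class BeliefTrajectory:
    """Per-trial belief values, choice probabilities and prediction errors."""

    v_primary: np.ndarray
    v_secondary: np.ndarray
    v_advice_weighted: np.ndarray
    v_combined: np.ndarray
    p_choice: np.ndarray
    pe_primary: np.ndarray
    pe_secondary: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.p_choice)


def update_value(v: float, r: int, alpha: float) -> float:
    """Delta-rule update ``v + alpha * (r - v)``."""
    if not 0.0 < v < 1.0:
        raise ValueError("v must lie in (0, 1)")
    if r not in (0, 1):
        raise ValueError("outcome must be binary")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return v + alpha * (r - v)


def advice_weighted_value(advice: int, v_secondary: float) -> float:
    """Probability the primary-congruent option is rewarded, per the advice.

    ``|advice - V_secondary|``: with advice = 0 (endorsing the
    primary-congruent option) this is the estimated advice accuracy
    itself; with advice = 1 it is its complement.
    """
    if advice not in (0, 1):
        raise ValueError("advice must be binary")
    if not 0.0 < v_secondary < 1.0:
        raise ValueError("v_secondary must lie in (0, 1)")
    return abs(advice - v_secondary)


def combine_values(v_primary: float, v_advice_weighted: float, zeta: float) -> float:
    """Convex combination ``zeta * V_aw + (1 - zeta) * V_primary``."""
    if not 0.0 <= zeta <= 1.0:
        raise ValueError("zeta must lie in [0, 1]")
    if not 0.0 < v_primary < 1.0:
        raise ValueError("v_primary must lie in (0, 1)")
    if not 0.0 <= v_advice_weighted <= 1.0:
        raise ValueError("v_advice_weighted must lie in [0, 1]")
    return zeta * v_advice_weighted + (1.0 - zeta) * v_primary


def choice_probability(v: float, beta: float) -> float:
    """Unit-square sigmoid ``v**beta / (v**beta + (1-v)**beta)``.

    The belief is clipped to ``[EPS, 1 - EPS]`` first so that extreme
    beliefs with large ``beta`` remain numerically defined.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    v = min(max(v, EPS), 1.0 - EPS)
    # work in log space for numerical stability at large beta
    z = beta * (math.log1p(-v) - math.log(v))
    if z >= 0:
        e = math.exp(-z) if z < 745 else 0.0
        p = e / (1.0 + e)
    else:
        p = 1.0 / (1.0 + math.exp(z))
    return _clip(p)


def _clip(v: float) -> float:
    """Keep a belief strictly inside (0, 1); extreme learning rates can
    otherwise push it onto the boundary in floating point."""
    return min(max(v, EPS), 1.0 - EPS)


def _phase_mask(labels: np.ndarray) -> np.ndarray:
    """1 where the phase label is volatile, 0 where stable."""
    mask = np.asarray(labels) == VOLATILE
    if not np.all(mask | (np.asarray(labels) == STABLE)):
        raise ValueError("phase labels must be 'stable' or 'volatile'")
    return mask.astype(int)


def run_model(params: RWParams, trials: TrialSequence) -> BeliefTrajectory:
    """Forward-run the dual-source model over one session.

    Beliefs start at ``v0`` for both sources.  On each trial the choice
    probability is computed from the current (pre-outcome) beliefs; the
    outcome then updates the primary belief with the learning rate of
    the primary source's current phase, and the inferred advice
    correctness updates the secondary belief with the learning rate of
    the secondary source's current phase.
    """
    n = trials.n_trials
    r = trials.r
    advice = trials.advice
    correct = trials.secondary_correct
    vol_pri = _phase_mask(trials.phase_primary)
    vol_sec = _phase_mask(trials.phase_secondary)
    a_pri = (params.alpha_primary_stable, params.alpha_primary_volatile)
    a_sec = (params.alpha_secondary_stable, params.alpha_secondary_volatile)

    vp = np.empty(n)
    vs = np.empty(n)
    vaw = np.empty(n)
    vc = np.empty(n)
    pch = np.empty(n)
    pep = np.empty(n)
    pes = np.empty(n)

    v_pri = params.v0
    v_sec = params.v0
    zeta = params.zeta
    beta = params.beta
    for t in range(n):
        vp[t] = v_pri
        vs[t] = v_sec
        aw = abs(int(advice[t]) - v_sec)
        vaw[t] = aw
        comb = zeta * aw + (1.0 - zeta) * v_pri
        vc[t] = comb
        pch[t] = choice_probability(comb, beta)
        pep[t] = r[t] - v_pri
        pes[t] = correct[t] - v_sec
        v_pri = _clip(v_pri + a_pri[vol_pri[t]] * (r[t] - v_pri))
        v_sec = _clip(v_sec + a_sec[vol_sec[t]] * (correct[t] - v_sec))
    return BeliefTrajectory(vp, vs, vaw, vc, pch, pep, pes)


def negative_log_likelihood(params: RWParams, trials: TrialSequence) -> float:
    """Bernoulli negative log-likelihood of the observed choices.

    Trials with a missing choice still drive belief updating (the
    outcome was shown) but contribute nothing to the likelihood.
    """
    y = trials.y
    mask = ~np.isnan(y)
    if not mask.any():
        raise ValueError("no non-missing choices to score")
    return _nll_arrays(
        _param_tuple(params),
        trials.r, trials.advice, trials.secondary_correct,
        _phase_mask(trials.phase_primary), _phase_mask(trials.phase_secondary),
        y, mask)


def _param_tuple(params: RWParams) -> tuple[float, ...]:
    return (params.alpha_primary_stable, params.alpha_primary_volatile,
            params.alpha_secondary_stable, params.alpha_secondary_volatile,
            params.zeta, params.beta, params.v0)


def _nll_arrays(theta, r, advice, correct, vol_pri, vol_sec, y, mask) -> float:
    """Likelihood kernel on plain Python floats (hot path for fitting)."""
    aps, apv, ass_, asv, zeta, beta, v0 = theta
    a_pri = (aps, apv)
    a_sec = (ass_, asv)
    r = r.tolist()
    advice = advice.tolist()
    correct = correct.tolist()
    vol_pri = vol_pri.tolist()
    vol_sec = vol_sec.tolist()
    y = y.tolist()
    mask = mask.tolist()
    v_pri = v0
    v_sec = v0
    log = math.log
    exp = math.exp
    log1p = math.log1p
    nll = 0.0
    for t in range(len(r)):
        if mask[t]:
            comb = zeta * abs(advice[t] - v_sec) + (1.0 - zeta) * v_pri
            if comb < EPS:
                comb = EPS
            elif comb > 1.0 - EPS:
                comb = 1.0 - EPS
            # log p and log(1-p) of the unit-square sigmoid
            z = beta * (log1p(-comb) - log(comb))
            if z > 0:
                log_p1 = -z - log1p(exp(-z))
                log_p0 = -log1p(exp(-z))
            else:
                log_p1 = -log1p(exp(z))
                log_p0 = z - log1p(exp(z))
            nll -= y[t] * log_p1 + (1.0 - y[t]) * log_p0
        v_pri += a_pri[vol_pri[t]] * (r[t] - v_pri)
        v_sec += a_sec[vol_sec[t]] * (correct[t] - v_sec)
        if v_pri < EPS:
            v_pri = EPS
        elif v_pri > 1.0 - EPS:
            v_pri = 1.0 - EPS
        if v_sec < EPS:
            v_sec = EPS
        elif v_sec > 1.0 - EPS:
            v_sec = 1.0 - EPS
    return nll


def simulate_choices(params: RWParams, trials: TrialSequence,
                     seed: int) -> TrialSequence:
    """Sample choices ``y(t) ~ Bernoulli(p_choice(t))`` from the model."""
    traj = run_model(params, trials)
    rng = np.random.default_rng(seed)
    y = (rng.random(trials.n_trials) < traj.p_choice).astype(float)
    return replace_choices(trials, y)


def replace_choices(trials: TrialSequence, y: np.ndarray) -> TrialSequence:
    """Copy of ``trials`` with the choice column replaced."""
    new = TrialSequence(
        r=trials.r.copy(), advice=trials.advice.copy(),
        phase_primary=trials.phase_primary, phase_secondary=trials.phase_secondary,
        y=np.asarray(y, dtype=float),
        p_primary=trials.p_primary, p_secondary=trials.p_secondary,
        subject=trials.subject, group=trials.group, drug=trials.drug,
        session=trials.session)
    return new
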