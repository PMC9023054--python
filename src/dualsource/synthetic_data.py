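"""Synthetic study cohorts for the two-source probabilistic learning task.

Generates complete datasets with the structure of a within-subject
pharmacological crossover: two groups of subjects (differing in whether
the primary information source is individual or social), each tested in
two drug sessions (haloperidol, HAL, and placebo, PLA) on the same
pseudo-randomised schedules with fresh trial-by-trial outcomes.

Generative learning-rate distributions are anchored to the reported
group means and standard errors of the fitted model under each drug:
per source x phase slot, subjects' learning rates are logit-normal with
the location chosen (by quadrature inversion) so the natural-space mean
matches the group mean, and the logit-scale spread matched to the
cross-subject SD (SEM x sqrt(n)) by the delta method.  The programmed
drug effect is therefore a decrease of the primary-source learning
rates under HAL with essentially unchanged secondary-source rates --
the drug x information-source signature the analysis pipeline is meant
to detect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .fitting import (FULL_MODEL, FitResult, FittingError, ModelVariant,
                      PriorConfig, fit_map, log_model_evidence)
from .rw_model import RWParams, simulate_choices
from .schedules import (ScheduleConfig, TaskSchedule, TrialSequence,
                        counterbalanced_configs, generate_schedule,
                        sample_trials, write_trials)

logger = logging.getLogger(__name__)

GROUPS = ("individual-primary", "social-primary")
DRUGS = ("PLA", "HAL")

_SLOTS = ("alpha_primary_stable", "alpha_primary_volatile",
          "alpha_secondary_stable", "alpha_secondary_volatile")

#: reported group mean (SEM) of each untransformed learning rate, n = 31
REPORTED_ALPHA_MEANS = {
    "PLA": {"alpha_primary_volatile": 0.184, "alpha_primary_stable": 0.290,
            "alpha_secondary_volatile": 0.187, "alpha_secondary_stable": 0.151},
    "HAL": {"alpha_primary_volatile": 0.169, "alpha_primary_stable": 0.218,
            "alpha_secondary_volatile": 0.200, "alpha_secondary_stable": 0.202},
}
REPORTED_ALPHA_SEMS = {
    "PLA": {"alpha_primary_volatile": 0.018, "alpha_primary_stable": 0.041,
            "alpha_secondary_volatile": 0.028, "alpha_secondary_stable": 0.025},
    "HAL": {"alpha_primary_volatile": 0.029, "alpha_primary_stable": 0.033,
            "alpha_secondary_volatile": 0.023, "alpha_secondary_stable": 0.026},
}
REPORTED_N = 31


def _logitnormal_location(target_mean: float, sd: float) -> float:
    """Location m with E[expit(Normal(m, sd^2))] = target_mean (bisection
    with Gauss-Hermite quadrature)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(41)
    weights = weights / weights.sum()

    def mean_at(m: float) -> float:
        return float(weights @ expit(m + sd * nodes))

    lo, hi = -12.0, 12.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_at(mid) < target_mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _slot_distributions() -> dict[str, dict[str, tuple[float, float]]]:
    """Per drug x slot: (logit location, logit sd) from the reported table."""
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for drug in DRUGS:
        out[drug] = {}
        for slot in _SLOTS:
            m_nat = REPORTED_ALPHA_MEANS[drug][slot]
            sd_nat = REPORTED_ALPHA_SEMS[drug][slot] * np.sqrt(REPORTED_N)
            sd_logit = sd_nat / (m_nat * (1.0 - m_nat))  # delta method
            out[drug][slot] = (_logitnormal_location(m_nat, sd_logit), sd_logit)
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Design of one synthetic cohort.

    ``alpha_locations`` maps drug -> slot -> (logit location, logit sd);
    subjects share a random intercept across drug sessions, so the drug
    effect is the within-subject shift of the slot locations.  ``zeta``
    and ``beta`` are drug-independent.  ``sd_scale`` rescales all
    between-subject spreads (0 gives a delta-function cohort).
    """

    n_subjects: dict[str, int] = field(
        default_factory=lambda: {"individual-primary": 16, "social-primary": 15})
    alpha_locations: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_slot_distributions)
    zeta_mean: float = 0.45
    zeta_sd_logit: float = 0.5
    beta_mean: float = 8.0
    beta_sd_log: float = 0.3
    sd_scale: float = 1.0
    schedule_config: ScheduleConfig = field(default_factory=ScheduleConfig)
    n_schedule_variants: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_scale < 0:
            raise ValueError("sd_scale must be nonnegative")
        if not 0 < self.zeta_mean < 1 or self.beta_mean <= 0:
            raise ValueError("zeta_mean must be in (0,1) and beta_mean positive")


@dataclass
class Cohort:
    """Simulated sessions plus the generating (ground-truth) parameters."""

    sequences: list[TrialSequence]
    truth: pd.DataFrame
    spec: CohortSpec

    def write(self, trials_path, truth_path) -> None:
        write_trials(self.sequences, trials_path)
        self.truth.to_csv(truth_path, index=False)


def simulate_agent(params: RWParams, schedule: TaskSchedule, seed: int,
                   **metadata) -> TrialSequence:
    """Sample a trial sequence from a schedule and the agent's choices from
    the forward-run model."""
    rng = np.random.default_rng(seed)
    s_trials, s_choices = rng.integers(2 ** 31, size=2)
    trials = sample_trials(schedule, int(s_trials), **metadata)
    return simulate_choices(params, trials, int(s_choices))


def _subject_params(spec: CohortSpec, drug: str, intercepts: dict[str, float],
                    zeta: float, beta: float) -> RWParams:
    values = {}
    for slot in _SLOTS:
        loc, sd = spec.alpha_locations[drug][slot]
        values[slot] = float(expit(loc + spec.sd_scale * sd * intercepts[slot]))
    return RWParams(zeta=zeta, beta=beta, **values)


def generate_cohort(spec: CohortSpec | None = None) -> Cohort:
    """Sample a full crossover cohort.

    Each subject keeps one pseudo-randomised schedule pair (drawn from
    ``n_schedule_variants`` variants) for both sessions; outcomes and
    choices are re-realised per session.  Drug order alternates by
    subject index.  Deterministic given ``spec.seed``.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    schedule_seeds = rng.integers(2 ** 31, size=spec.n_schedule_variants)
    if spec.schedule_config == ScheduleConfig():
        # default task: rotate the four counterbalanced block orders
        variant_configs = counterbalanced_configs(seed=int(schedule_seeds[0]))
    else:
        variant_configs = [spec.schedule_config.with_seed(int(s))
                           for s in schedule_seeds]
    sequences: list[TrialSequence] = []
    truth_rows = []
    idx = 0
    for group in GROUPS:
        for j in range(spec.n_subjects.get(group, 0)):
            subject = f"{'ip' if group == GROUPS[0] else 'sp'}{j:03d}"
            intercepts = {slot: float(rng.standard_normal()) for slot in _SLOTS}
            zeta = float(expit(logit(spec.zeta_mean)
                               + spec.sd_scale * spec.zeta_sd_logit
                               * rng.standard_normal()))
            beta = float(spec.beta_mean
                         * np.exp(spec.sd_scale * spec.beta_sd_log
                                  * rng.standard_normal()))
            schedule = generate_schedule(
                variant_configs[idx % len(variant_configs)])
            drug_order = DRUGS if idx % 2 == 0 else DRUGS[::-1]
            for session, drug in enumerate(drug_order, start=1):
                params = _subject_params(spec, drug, intercepts, zeta, beta)
                seq = simulate_agent(params, schedule,
                                     int(rng.integers(2 ** 31)),
                                     subject=subject, group=group, drug=drug,
                                     session=session)
                sequences.append(seq)
                row = {"subject": subject, "group": group, "drug": drug,
                       "session": session, "zeta": zeta, "beta": beta}
                row.update({slot: getattr(params, slot) for slot in _SLOTS})
                truth_rows.append(row)
            idx += 1
    return Cohort(sequences, pd.DataFrame(truth_rows), spec)


def fit_cohort(sequences: list[TrialSequence],
               priors: PriorConfig | None = None, n_starts: int = 10,
               seed: int = 0, variant: ModelVariant = FULL_MODEL,
               evidence: bool = False) -> tuple[pd.DataFrame, list[FitResult]]:
    """MAP-fit every session; return a tidy parameter table and the fits."""
    rng = np.random.default_rng(seed)
    rows = []
    fits = []
    for seq in sequences:
        fit = fit_map(seq, priors=priors, n_starts=n_starts,
                      seed=int(rng.integers(2 ** 31)), variant=variant)
        if evidence:
            log_model_evidence(fit, seq, priors=priors)
        fits.append(fit)
        row = {"subject": seq.subject, "group": seq.group, "drug": seq.drug,
               "session": seq.session, "nll": fit.nll,
               "log_evidence": fit.log_evidence}
        row.update(fit.natural)
        rows.append(row)
    return pd.DataFrame(rows), fits
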