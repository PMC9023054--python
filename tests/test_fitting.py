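"""MAP fitting, Laplace evidence, and parameter recovery."""

import numpy as np
import pytest

from dualsource import (FittingError, ModelVariant, PriorConfig, RWParams,
                        ScheduleConfig, fit_map, generate_schedule,
                        log_model_evidence, run_recovery, sample_trials,
                        simulate_choices)
from dualsource.fitting import transform, untransform
from dualsource.rw_model import negative_log_likelihood, replace_choices


class TestTransforms:
    @pytest.mark.parametrize("name,value", [
        ("alpha_primary_stable", 0.013), ("alpha_primary_stable", 0.7),
        ("zeta", 0.45), ("beta", 0.3), ("beta", 17.0),
    ])
    def test_round_trip_identity(self, name, value):
        assert untransform(name, transform(name, value)) == pytest.approx(
            value, abs=1e-12)


class TestFitMap:
    def test_deterministic_given_seed(self, agent_trials):
        _, tr = agent_trials
        a = fit_map(tr, seed=3, n_starts=3)
        b = fit_map(tr, seed=3, n_starts=3)
        assert a.theta == b.theta
        assert a.nll == b.nll

    def test_map_likelihood_beats_prior_mean(self, agent_trials):
        _, tr = agent_trials
        fit = fit_map(tr, seed=0, n_starts=3)
        priors = PriorConfig()
        prior_mean = RWParams(
            **{n: untransform(n, priors.moments(n)[0])
               for n in ("alpha_primary_stable", "alpha_primary_volatile",
                         "alpha_secondary_stable", "alpha_secondary_volatile",
                         "zeta", "beta")})
        assert fit.nll <= negative_log_likelihood(prior_mean, tr) + 1e-9
        for name, value in fit.natural.items():
            assert 0 < value if name == "beta" else 0 < value < 1

    def test_random_choices_shrink_toward_prior(self, default_trials):
        rng = np.random.default_rng(8)
        tr = replace_choices(default_trials,
                             (rng.random(120) < 0.5).astype(float))
        fit = fit_map(tr, seed=1, n_starts=5)
        assert fit.natural["beta"] < 1.5     # little evidence for determinism
        for slot in ("alpha_primary_stable", "alpha_primary_volatile",
                     "alpha_secondary_stable", "alpha_secondary_volatile"):
            assert abs(fit.natural[slot] - 0.3) < 0.25  # near the prior mode

    def test_insufficient_choices_rejected(self, default_trials):
        y = np.full(120, np.nan)
        y[:10] = 1.0
        tr = replace_choices(default_trials, y)
        with pytest.raises(FittingError, match="choices"):
            fit_map(tr)

    def test_fixed_parameters_are_pinned(self, agent_trials):
        _, tr = agent_trials
        fit = fit_map(tr, seed=0, n_starts=2, fixed={"zeta": 0.4})
        assert fit.natural["zeta"] == 0.4
        assert "zeta" not in fit.theta


class TestLogModelEvidence:
    def test_fully_fixed_model_evidence_is_log_likelihood(self, agent_trials):
        params, tr = agent_trials
        fixed = {"alpha_primary_stable": 0.2, "alpha_primary_volatile": 0.3,
                 "alpha_secondary_stable": 0.15,
                 "alpha_secondary_volatile": 0.25, "zeta": 0.4, "beta": 5.0}
        fit = fit_map(tr, fixed=fixed)
        assert log_model_evidence(fit, tr) == pytest.approx(
            -negative_log_likelihood(params, tr), rel=1e-9)
        assert fit.evidence_method == "exact"

    def test_evidence_finite_and_below_max_log_likelihood(self, agent_trials):
        _, tr = agent_trials
        fit = fit_map(tr, seed=0, n_starts=3)
        ev = log_model_evidence(fit, tr)
        assert np.isfinite(ev)
        assert ev < -fit.nll + 1e-6  # complexity penalty is positive

    def test_occams_razor_on_null_data(self):
        """When data come from a single learning rate, the evidence should on
        average favour the variant without the source/volatility splits."""
        simple = ModelVariant(split_alpha_by_source=False,
                              split_alpha_by_volatility=False, zeta_free=True)
        gen = RWParams(alpha_primary_stable=0.25, alpha_primary_volatile=0.25,
                       alpha_secondary_stable=0.25,
                       alpha_secondary_volatile=0.25, zeta=0.45, beta=5.0)
        rng = np.random.default_rng(21)
        diffs = []
        for _ in range(20):
            s1, s2, s3 = rng.integers(2 ** 31, size=3)
            sch = generate_schedule(ScheduleConfig(seed=int(s1)))
            tr = simulate_choices(gen, sample_trials(sch, int(s2)), int(s3))
            f_full = fit_map(tr, seed=int(s3), n_starts=3)
            f_simple = fit_map(tr, seed=int(s3), n_starts=3, variant=simple)
            diffs.append(log_model_evidence(f_simple, tr)
                         - log_model_evidence(f_full, tr))
        assert np.mean(diffs) > 0


class TestRunRecovery:
    def test_reproducible_under_fixed_seed(self):
        grid = [RWParams(zeta=0.4, beta=5.0)]
        cfg = ScheduleConfig()
        a = run_recovery(grid, cfg, n_reps=2, seed=4, n_starts=2)
        b = run_recovery(grid, cfg, n_reps=2, seed=4, n_starts=2)
        assert a.table.equals(b.table)

    def test_zeta_zero_agents_recovered_near_zero(self):
        grid = [RWParams(alpha_primary_stable=0.2, alpha_primary_volatile=0.25,
                         alpha_secondary_stable=0.2,
                         alpha_secondary_volatile=0.25, zeta=0.0, beta=6.0)]
        report = run_recovery(grid, ScheduleConfig(), n_reps=6, seed=5,
                              n_starts=3)
        zeta = report.table.query("parameter == 'zeta'")["recovered"]
        assert zeta.median() < 0.15

    def test_longer_sessions_reduce_rmse(self):
        grid = [RWParams(alpha_primary_stable=0.15, alpha_primary_volatile=0.3,
                         alpha_secondary_stable=0.2,
                         alpha_secondary_volatile=0.25, zeta=0.4, beta=6.0),
                RWParams(alpha_primary_stable=0.35, alpha_primary_volatile=0.2,
                         alpha_secondary_stable=0.3,
                         alpha_secondary_volatile=0.15, zeta=0.55, beta=4.0)]
        short_cfg = ScheduleConfig()
        long_cfg = ScheduleConfig(
            n_trials=1200,
            blocks_primary=tuple(b for _ in range(10)
                                 for b in ScheduleConfig().blocks_primary),
            blocks_secondary=tuple(b for _ in range(10)
                                   for b in ScheduleConfig().blocks_secondary))
        short = run_recovery(grid, short_cfg, n_reps=4, seed=6, n_starts=2)
        long = run_recovery(grid, long_cfg, n_reps=4, seed=6, n_starts=2)
        alpha_rows = lambda rep: rep.summary().filter(like="alpha", axis=0)
        assert alpha_rows(long)["rmse"].mean() < alpha_rows(short)["rmse"].mean()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            run_recovery([], ScheduleConfig())
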