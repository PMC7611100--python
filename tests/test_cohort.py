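"""Synthetic cohorts: stratified BFNE sampling and the covariate-linked population layer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

import selearn as sl
from selearn.cohort import BfneDesign, ParameterPopulation, PopulationConfig
from selearn.errors import ConfigurationError


def small_assoc_config(n=30, **w):
    params = {
        "lam": ParameterPopulation(w.get("lam", 0.0), -0.85, 0.4),
        "tau": ParameterPopulation(w.get("tau", 0.0), -1.2, 0.3),
        "rho": ParameterPopulation(w.get("rho", 0.0), 0.1, 0.15),
        "q0_pos": ParameterPopulation(w.get("q0_pos", 0.0), 0.2, 0.2),
    }
    return PopulationConfig(family="assoc", variant="general_1l", params=params, n_subjects=n)


class TestSampleBfne:
    def test_exact_thirds(self, rng):
        design = BfneDesign()
        scores = sl.sample_bfne(99, design, rng)
        assert len(scores) == 99
        q1, q3 = 12 + 0.25 * 48, 12 + 0.75 * 48
        assert (scores <= q1).sum() == 33
        assert (scores >= q3).sum() == 33

    def test_support(self, rng):
        scores = sl.sample_bfne(200, BfneDesign(), rng)
        assert scores.min() >= 12 and scores.max() <= 60

    def test_stratified_inflates_variance(self):
        # oversampling the extremes makes the sample more dispersed
        rng = np.random.default_rng(0)
        wins = 0
        for _ in range(100):
            strat = sl.sample_bfne(99, BfneDesign(stratified=True), rng)
            plain = sl.sample_bfne(99, BfneDesign(stratified=False), rng)
            wins += strat.var() > plain.var()
        assert wins > 80

    def test_too_small(self, rng):
        with pytest.raises(ValueError):
            sl.sample_bfne(2, BfneDesign(), rng)


class TestSampleParameters:
    def test_zero_slope_independence(self):
        rng = np.random.default_rng(1)
        cfg = small_assoc_config(n=200)
        hits = 0
        reps = 20
        for _ in range(reps):
            bfne = sl.sample_bfne(200, cfg.bfne, rng)
            table = sl.sample_parameters(cfg, bfne, rng)
            rho, _ = spearmanr(bfne, table["lam"])
            hits += abs(rho) < 0.2
        assert hits >= int(0.95 * reps) - 1

    def test_degenerate_population_is_constant(self, rng):
        cfg = small_assoc_config(n=50)
        cfg = cfg.with_updates(
            params={n: ParameterPopulation(0.0, p.theta0, 0.0) for n, p in cfg.params.items()}
        )
        bfne = sl.sample_bfne(50, cfg.bfne, rng)
        table = sl.sample_parameters(cfg, bfne, rng)
        for name in table.columns:
            assert table[name].nunique() == 1

    @pytest.mark.parametrize("w,expect_positive", [(0.5, True), (-0.5, False)])
    def test_slope_sign_transfers_to_native_scale(self, w, expect_positive, rng):
        cfg = small_assoc_config(n=200, lam=w)
        bfne = sl.sample_bfne(200, cfg.bfne, rng)
        table = sl.sample_parameters(cfg, bfne, rng)
        rho, p = spearmanr(bfne, table["lam"])
        assert (rho > 0) == expect_positive
        assert p < 0.01

    @given(scale=st.floats(0.5, 8.0), seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_native_parameters_always_valid(self, scale, seed):
        # range-safe transforms: any unconstrained draw maps into the model's domain
        rng = np.random.default_rng(seed)
        cfg = small_assoc_config(n=20)
        cfg = cfg.with_updates(
            params={n: ParameterPopulation(0.0, p.theta0, scale) for n, p in cfg.params.items()}
        )
        bfne = sl.sample_bfne(20, cfg.bfne, rng)
        table = sl.sample_parameters(cfg, bfne, rng)
        assert np.all((table["lam"] > 0) & (table["lam"] < 1))
        assert np.all(table["tau"] > 0)


class TestGenerateCohort:
    def test_smoke_and_round_trip(self, tmp_path):
        cohort = sl.generate_cohort(small_assoc_config(n=10), 5)
        assert len(cohort.sessions) == 10
        assert len(cohort.true_params) == 10
        cohort.save(tmp_path)
        back = sl.read_sessions(tmp_path / "sessions.csv")
        assert len(back) == 10
        assert [s.participant_id for s in back] == [s.participant_id for s in cohort.sessions]
        assert back[0].blocks == cohort.sessions[0].blocks
        cfg2 = PopulationConfig.from_yaml(tmp_path / "population.yaml")
        assert cfg2.params == cohort.config.params

    def test_determinism(self):
        a = sl.generate_cohort(small_assoc_config(n=6), 42)
        b = sl.generate_cohort(small_assoc_config(n=6), 42)
        assert a.true_params.equals(b.true_params)
        assert all(
            x.blocks == y.blocks for x, y in zip(a.sessions, b.sessions)
        )

    def test_reduced_self_positivity_shows_in_choices(self):
        # strongly negative slope on the positive self-evidence: high-BFNE
        # subjects choose fewer positive words in self blocks
        base = sl.demo_belief_population(n_subjects=200)
        params = dict(base.params)
        params["alpha_self"] = ParameterPopulation(w=-0.8, theta0=np.log(5.0), sigma=0.3)
        cfg = base.with_updates(params=params)
        wins = 0
        reps = 8
        for rep in range(reps):
            cohort = sl.generate_cohort(cfg, 1000 + rep)
            med = np.median(cohort.true_params["bfne"])
            lo_pct, hi_pct = [], []
            for sess in cohort.sessions:
                pct = np.mean(
                    [
                        sl.percent_positive(b)
                        for b in sess.blocks
                        if sess.personas[b[0].persona_index].referent == "self"
                    ]
                )
                (hi_pct if sess.bfne > med else lo_pct).append(pct)
            wins += np.mean(lo_pct) > np.mean(hi_pct)
        assert wins >= int(0.9 * reps)

    def test_null_slopes_balance_self_other(self):
        cfg = small_assoc_config(n=300)
        cohort = sl.generate_cohort(cfg, 9)
        diffs = []
        for sess in cohort.sessions:
            self_pct = np.mean(
                [sl.percent_positive(b) for b in sess.blocks
                 if sess.personas[b[0].persona_index].referent == "self"]
            )
            other_pct = np.mean(
                [sl.percent_positive(b) for b in sess.blocks
                 if sess.personas[b[0].persona_index].referent == "other"]
            )
            diffs.append(self_pct - other_pct)
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se + 1e-9

    def test_config_must_cover_all_parameters(self):
        with pytest.raises(ConfigurationError):
            PopulationConfig(
                family="assoc", variant="general_1l",
                params={"lam": ParameterPopulation(0, 0, 1)},
            )
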