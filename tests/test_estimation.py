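"""EM / Baum-Welch estimation behaviour."""

import numpy as np
import pandas as pd
import pytest

import betapairhmm as bp
from betapairhmm.estimation import DegenerateDataError, pairs_from_probe_table
from betapairhmm.model_core import ModelError
from betapairhmm.io_preprocess import sample_probe_table


def _assert_monotone(trace, slack=1e-8):
    diffs = np.diff(np.asarray(trace))
    assert np.all(diffs >= -slack * (np.abs(trace[:-1]) + 1.0)), (
        f"log-likelihood decreased: min step {diffs.min()}"
    )


class TestSingleProbeMixture:
    def test_recovers_known_three_component_mixture(self):
        rng = np.random.default_rng(42)
        n = 5000
        omega_true = np.array([0.55, 0.25, 0.20])
        shapes = [(1.5, 18.0), (8.0, 8.0), (15.0, 1.8)]
        k = rng.choice(3, size=n, p=omega_true)
        a = np.array([s[0] for s in shapes])[k]
        b = np.array([s[1] for s in shapes])[k]
        x = rng.beta(a, b)

        em, omega, trace = bp.fit_single_probe_mixture(x, "S", bp.FitConfig(seed=0))
        np.testing.assert_allclose(omega, omega_true, atol=0.03)
        for state, (at, bt) in zip(("L", "M", "H"), shapes):
            p = em.params_by_state[state]
            assert p.alpha == pytest.approx(at, rel=0.20)
            assert p.beta == pytest.approx(bt, rel=0.20)
        _assert_monotone(trace)

    def test_single_population_collapses_or_matches_moments(self):
        # data from one Beta(2,5); a 2-component fit (class I) should either
        # hand nearly all weight to one component or drive both to the
        # pooled method-of-moments solution
        rng = np.random.default_rng(1)
        x = rng.beta(2.0, 5.0, size=4000)
        em, omega, _ = bp.fit_single_probe_mixture(x, "I", bp.FitConfig(seed=1))

        m, v = x.mean(), x.var()
        c = m * (1 - m) / v - 1
        mom = (m * c, (1 - m) * c)  # independent pooled-data oracle
        if omega.max() < 0.95:
            for k in ("L", "M"):
                p = em.params_by_state[k]
                assert p.alpha == pytest.approx(mom[0], rel=0.35)
                assert p.beta == pytest.approx(mom[1], rel=0.35)

    def test_trace_non_decreasing_on_irregular_input(self):
        rng = np.random.default_rng(9)
        x = np.concatenate(
            [rng.beta(0.8, 4, 300), rng.uniform(0.3, 0.7, 100), rng.beta(9, 1, 150)]
        )
        _, _, trace = bp.fit_single_probe_mixture(x, "O", bp.FitConfig(seed=2))
        _assert_monotone(trace)

    def test_identical_values_raise(self):
        with pytest.raises(DegenerateDataError):
            bp.fit_single_probe_mixture(np.full(200, 0.4), "S")

    def test_small_sample_warns(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="unstable"):
            bp.fit_single_probe_mixture(rng.beta(2, 5, 30), "I")

    def test_medium_state_stays_symmetric(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.beta(1.5, 18, 800), rng.beta(7, 9, 800)])
        em, _, _ = bp.fit_single_probe_mixture(x, "I", bp.FitConfig(seed=0))
        m = em.params_by_state["M"]
        assert m.alpha == m.beta

    def test_restarts_never_worsen_the_fit(self):
        rng = np.random.default_rng(10)
        x = np.concatenate([rng.beta(1.5, 18, 600), rng.beta(8, 8, 300), rng.beta(15, 1.8, 200)])
        _, _, t0 = bp.fit_single_probe_mixture(x, "S", bp.FitConfig(seed=5, n_restarts=0))
        _, _, t3 = bp.fit_single_probe_mixture(x, "S", bp.FitConfig(seed=5, n_restarts=3))
        assert t3[-1] >= t0[-1] - 1e-6


class TestPairHMM:
    @staticmethod
    def _make_pairs(rng, pm, em1, em2, n):
        k1 = rng.choice(len(pm.omega_init), size=n, p=pm.omega_init)
        a1, b1 = em1.shape_arrays()
        a2, b2 = em2.shape_arrays()
        cum = np.cumsum(pm.transition, axis=1)
        k2 = (rng.random(n)[:, None] > cum[k1]).sum(axis=1)
        x1 = np.clip(rng.beta(a1[k1], b1[k1]), 1e-9, 1 - 1e-9)
        x2 = np.clip(rng.beta(a2[k2], b2[k2]), 1e-9, 1 - 1e-9)
        return [
            bp.ProbePair(f"g{i}", float(u), float(v), pm.pair_class)
            for i, (u, v) in enumerate(zip(x1, x2))
        ]

    def test_degenerate_chain_recovered(self, normal_model):
        # all pairs in state (L,L) with sharply low emissions
        em = normal_model.emissions["S"]
        pm = bp.PairClassModel(
            "SS", np.array([1.0, 0.0, 0.0]), np.eye(3)
        )
        rng = np.random.default_rng(0)
        pairs = self._make_pairs(rng, pm, em, em, 500)
        fit = bp.fit_pair_hmm(pairs, em, em)
        assert fit.omega_init[0] >= 0.99
        assert fit.transition[0, 0] >= 0.99

    def test_recovers_known_transition_structure(self, normal_model):
        em = normal_model.emissions["S"]
        pm = normal_model.pair_models["SS"]
        rng = np.random.default_rng(0)
        pairs = self._make_pairs(rng, pm, em, em, 2000)
        fit = bp.fit_pair_hmm(pairs, em, em)
        np.testing.assert_allclose(fit.omega_init, pm.omega_init, atol=0.05)
        np.testing.assert_allclose(fit.transition, pm.transition, atol=0.05)

    def test_empty_pair_list_raises(self, normal_model):
        em = normal_model.emissions["S"]
        with pytest.raises(ValueError):
            bp.fit_pair_hmm([], em, em)

    def test_emission_class_mismatch_raises(self, normal_model):
        pairs = [bp.ProbePair("g", 0.2, 0.4, "SS")]
        with pytest.raises(ModelError):
            bp.fit_pair_hmm(pairs, normal_model.emissions["I"], normal_model.emissions["S"])


class TestFitSample:
    def test_full_sample_has_37_parameters(self, small_simulated):
        betas, ann, _ = small_simulated
        tbl = sample_probe_table(ann, betas, "sim")
        result = bp.fit_sample(tbl, bp.FitConfig(seed=0))
        assert bp.count_free_parameters(result.model)["total"] == 37
        for trace in result.traces.values():
            _assert_monotone(trace)

    def test_missing_pair_class_shrinks_budget(self, normal_model):
        spec = bp.SimSpec(
            model=normal_model,
            n_pairs={"II": 300, "SS": 200, "SI": 200, "OO": 0},
            n_singletons={"I": 60, "S": 60, "O": 200},
            seed=2,
        )
        betas, ann, _ = bp.simulate_sample(spec)
        tbl = sample_probe_table(ann, betas, "sim")
        with pytest.warns(UserWarning, match="OO"):
            result = bp.fit_sample(tbl, bp.FitConfig(seed=0))
        # O emissions still fitted from singleton probes, but the (O,O)
        # initial distribution (2) and transitions (6) are gone
        assert bp.count_free_parameters(result.model)["total"] == 37 - 8

    def test_no_catastrophic_underfit(self, normal_model):
        spec = bp.SimSpec(
            model=normal_model,
            n_pairs={pc: 700 for pc in bp.PAIR_CLASSES},
            n_singletons={},
            seed=5,
        )
        betas, ann, _ = bp.simulate_sample(spec)
        tbl = sample_probe_table(ann, betas, "sim")
        result = bp.fit_sample(tbl, bp.FitConfig(seed=0))
        pairs = pairs_from_probe_table(tbl)
        ll_fit = sum(bp.pair_log_likelihood(p, result.model) for p in pairs)
        ll_gen = sum(bp.pair_log_likelihood(p, normal_model) for p in pairs)
        assert ll_fit >= ll_gen - 0.01 * len(pairs)

    def test_probe_order_does_not_change_the_fit(self, small_simulated):
        betas, ann, _ = small_simulated
        tbl = sample_probe_table(ann, betas, "sim")
        shuffled = tbl.sample(frac=1.0, random_state=123).reset_index(drop=True)
        r1 = bp.fit_sample(tbl, bp.FitConfig(seed=0))
        r2 = bp.fit_sample(shuffled, bp.FitConfig(seed=0))
        for pc in bp.PAIR_CLASSES:
            np.testing.assert_allclose(
                r1.model.pair_models[pc].transition,
                r2.model.pair_models[pc].transition,
                atol=1e-9,
            )
        for a in bp.LOCATION_CLASSES:
            a1, b1 = r1.model.emissions[a].shape_arrays()
            a2, b2 = r2.model.emissions[a].shape_arrays()
            np.testing.assert_allclose(a1, a2, atol=1e-6)
            np.testing.assert_allclose(b1, b2, atol=1e-6)


class TestPairAssemblyFromTable:
    def test_island_shore_pair_is_swapped(self):
        tbl = pd.DataFrame(
            {
                "probe_id": ["p1", "p2"],
                "gene_id": ["g", "g"],
                "location_class": ["I", "S"],
                "position": [100, 200],
                "beta": [0.3, 0.7],
            }
        )
        (pair,) = pairs_from_probe_table(tbl)
        assert pair.pair_class == "SI"
        assert (pair.x1, pair.x2) == (0.7, 0.3)

    def test_first_two_probes_by_coordinate(self):
        tbl = pd.DataFrame(
            {
                "probe_id": ["a", "b", "c"],
                "gene_id": ["g"] * 3,
                "location_class": ["S", "S", "S"],
                "position": [300, 100, 200],
                "beta": [0.9, 0.1, 0.5],
            }
        )
        (pair,) = pairs_from_probe_table(tbl)
        assert (pair.x1, pair.x2) == (0.1, 0.5)

    def test_mixed_outside_pairs_excluded(self):
        tbl = pd.DataFrame(
            {
                "probe_id": ["p1", "p2"],
                "gene_id": ["g", "g"],
                "location_class": ["O", "S"],
                "position": [100, 200],
                "beta": [0.3, 0.7],
            }
        )
        assert pairs_from_probe_table(tbl) == []

    def test_missing_member_drops_pair(self):
        tbl = pd.DataFrame(
            {
                "probe_id": ["p1", "p2"],
                "gene_id": ["g", "g"],
                "location_class": ["S", "S"],
                "position": [100, 200],
                "beta": [np.nan, 0.7],
            }
        )
        assert pairs_from_probe_table(tbl) == []


class TestEstimatorInterface:
    def test_sklearn_style_fit_predict(self, small_simulated):
        betas, ann, truth = small_simulated
        tbl = sample_probe_table(ann, betas, "sim")
        est = bp.BetaPairHMM(seed=0, sample_id="sim").fit(tbl)
        assert est.n_parameters_ == 37
        pairs = pairs_from_probe_table(tbl)[:50]
        states = est.predict(pairs)
        assert len(states) == 50
        assert set("".join(states)) <= set("LMH")
        assert np.isfinite(est.score(pairs))

    def test_get_set_params_round_trip(self):
        est = bp.BetaPairHMM(max_iter=50, tol=1e-6)
        params = est.get_params()
        clone = bp.BetaPairHMM(**params)
        assert clone.get_params() == params
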