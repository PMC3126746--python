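"""Group state summaries, change tabulation and the permutation test."""

import numpy as np
import pandas as pd
import pytest

import betapairhmm as bp
from betapairhmm.group_analysis import CHANGE_TYPES, ChangeRecord, change_records_for_pair


def _decoded_frame(states: dict[str, str], pair_class: dict[str, str]) -> pd.DataFrame:
    """Minimal decode-shaped table from pair_id -> 'LM' joint-state strings."""
    return pd.DataFrame(
        {
            "pair_id": list(states),
            "pair_class": [pair_class[p] for p in states],
            "viterbi_k1": [s[0] for s in states.values()],
            "viterbi_k2": [s[1] for s in states.values()],
        }
    )


class TestGroupOverallStates:
    def _table(self, sample_states, groups):
        classes = {p: "SS" for p in next(iter(sample_states.values()))}
        decoded = {s: _decoded_frame(st, classes) for s, st in sample_states.items()}
        return bp.group_overall_states(decoded, groups)

    def test_majority_wins(self):
        t = self._table(
            {"s1": {"g1": "LL"}, "s2": {"g1": "LL"}, "s3": {"g1": "MM"}},
            {"s1": "A", "s2": "A", "s3": "A"},
        )
        assert t.pair_states.loc["g1", "A"] == "LL"

    def test_tie_breaks_toward_smaller_state(self):
        t = self._table(
            {"s1": {"g1": "MM"}, "s2": {"g1": "LL"}},
            {"s1": "A", "s2": "A"},
        )
        assert t.pair_states.loc["g1", "A"] == "LL"

    def test_single_sample_group(self):
        t = self._table({"s1": {"g1": "MH"}}, {"s1": "A"})
        assert t.pair_states.loc["g1", "A"] == "MH"

    def test_probe_level_modes(self):
        # componentwise modes can differ from the modal joint state
        t = self._table(
            {"s1": {"g1": "LM"}, "s2": {"g1": "ML"}, "s3": {"g1": "MM"}},
            {"s1": "A", "s2": "A", "s3": "A"},
        )
        assert t.probe_states.loc[("g1", 1), "A"] == "M"
        assert t.probe_states.loc[("g1", 2), "A"] == "M"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            self._table({"s1": {"g1": "LL"}}, {})


class TestChangeTabulation:
    def _two_group_table(self, a_states, b_states, classes=None):
        classes = classes or {p: "SS" for p in a_states}
        decoded = {
            "sa": _decoded_frame(a_states, classes),
            "sb": _decoded_frame(b_states, classes),
        }
        return bp.group_overall_states(decoded, {"sa": "A", "sb": "B"})

    def test_identical_tables_count_nothing(self):
        t = self._two_group_table({"g1": "LM", "g2": "HH"}, {"g1": "LM", "g2": "HH"})
        counts = bp.tabulate_state_changes(t, "A", "B")
        assert counts.sum() == 0

    def test_pair_change_counted_per_probe(self):
        t = self._two_group_table({"g1": "LL"}, {"g1": "MM"})
        counts = bp.tabulate_state_changes(t, "A", "B", significant={"g1"})
        assert counts["L->M"] == 2
        assert counts.sum() == 2

    def test_counts_match_independent_tally(self):
        rng = np.random.default_rng(0)
        states = ["LL", "LM", "ML", "MM", "MH", "HM", "HH", "LH", "HL"]
        a = {f"g{i}": states[rng.integers(9)] for i in range(200)}
        b = {f"g{i}": states[rng.integers(9)] for i in range(200)}
        t = self._two_group_table(a, b)
        counts = bp.tabulate_state_changes(t, "A", "B")
        # independent brute-force tally over probes
        tally = {c: 0 for c in CHANGE_TYPES}
        for g in a:
            for slot in (0, 1):
                if a[g][slot] != b[g][slot]:
                    tally[f"{a[g][slot]}->{b[g][slot]}"] += 1
        assert dict(counts) == tally

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(4)
        states = ["LL", "LM", "MM", "HM", "HH"]
        a = {f"g{i}": states[rng.integers(5)] for i in range(100)}
        b = {f"g{i}": states[rng.integers(5)] for i in range(100)}
        t = self._two_group_table(a, b)
        ab = bp.tabulate_state_changes(t, "A", "B")
        ba = bp.tabulate_state_changes(t, "B", "A")
        assert ab["L->M"] == ba["M->L"]
        assert ab["M->H"] == ba["H->M"]
        assert ab["L->H"] == ba["H->L"]

    def test_unknown_group_rejected(self):
        t = self._two_group_table({"g1": "LL"}, {"g1": "MM"})
        with pytest.raises(KeyError):
            bp.tabulate_state_changes(t, "A", "C")


class TestRegionTabulation:
    def test_all_in_islands(self):
        recs = [ChangeRecord(f"p{i}", "I", "L", "M") for i in range(10)]
        out = bp.tabulate_changes_by_region(recs)
        assert out.loc["I", "count"] == 10
        assert out.loc["I", "percent"] == pytest.approx(100.0)

    def test_mixed_regions(self):
        recs = (
            [ChangeRecord("a", "I", "L", "M"), ChangeRecord("b", "I", "M", "H")]
            + [ChangeRecord("c", "S", "L", "M")]
            + [ChangeRecord("d", "O", "H", "L")]
        )
        out = bp.tabulate_changes_by_region(recs)
        assert list(out["percent"]) == pytest.approx([50.0, 25.0, 25.0])
        assert out["percent"].sum() == pytest.approx(100.0)

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(1)
        regions = np.array(["I", "S", "O"])[rng.integers(3, size=300)]
        recs = [ChangeRecord(f"p{i}", r, "L", "M") for i, r in enumerate(regions)]
        out = bp.tabulate_changes_by_region(recs)
        for a in ("I", "S", "O"):
            assert out.loc[a, "count"] == int(np.sum(regions == a))
        assert out["percent"].sum() == pytest.approx(100.0)


class TestFisherPermutationTest:
    def test_statistic_invariant_to_within_group_relabeling(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 5))
        y = np.array(["a"] * 6 + ["b"] * 6)
        s1 = bp.fisher_statistic(X, y)
        perm = np.r_[rng.permutation(6), 6 + rng.permutation(6)]
        s2 = bp.fisher_statistic(X[perm], y[perm])
        assert s1 == pytest.approx(s2, rel=1e-10)

    def test_separated_groups_reach_minimal_p(self):
        rng = np.random.default_rng(1)
        X = np.vstack(
            [rng.uniform(0, 0.1, size=(6, 4)), rng.uniform(0.9, 1.0, size=(6, 4))]
        )
        y = np.array(["a"] * 6 + ["b"] * 6)
        stat, p = bp.fisher_permutation_test(X, y, n_perm=999, seed=3)
        assert p <= 5 / 1000
        assert stat > 0

    def test_null_p_values_are_super_uniform(self):
        # identical group distributions: P(p <= t) <= t + 1/(1+n_perm)
        rng = np.random.default_rng(2)
        pvals = []
        for rep in range(200):
            X = rng.normal(size=(12, 4))
            y = np.array(["a"] * 6 + ["b"] * 6)
            _, p = bp.fisher_permutation_test(X, y, n_perm=199, seed=1000 + rep)
            pvals.append(p)
        pvals = np.array(pvals)
        for t in (0.05, 0.1, 0.25):
            bound = t + 1 / 200
            # 3-sigma binomial slack on 200 repetitions
            slack = 3 * np.sqrt(bound * (1 - bound) / 200)
            assert (pvals <= t).mean() <= bound + slack

    def test_group_size_requirements(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            bp.fisher_permutation_test(X, np.array(["a", "a", "a", "b"]), n_perm=100)


class TestSelectDifferentialPairs:
    @staticmethod
    def _decoded_with_posteriors(rng, n_pairs, shift_pairs, group, strength=0.97):
        """Decode-shaped frame: shifted pairs are LL in group A, MM in B."""
        rows = {}
        cols = [f"p_{k1}{k2}" for k1 in "LMH" for k2 in "LMH"]
        data = {c: [] for c in cols}
        ids, vits = [], []
        for i in range(n_pairs):
            pid = f"g{i}"
            shifted = pid in shift_pairs and group == "B"
            target = "p_MM" if shifted else "p_LL"
            probs = rng.dirichlet(np.ones(9)) * (1 - strength)
            probs[cols.index(target)] += strength
            for c, v in zip(cols, probs):
                data[c].append(v)
            ids.append(pid)
            vits.append("MM" if shifted else "LL")
        df = pd.DataFrame(
            {
                "pair_id": ids,
                "pair_class": "SS",
                "viterbi_k1": [v[0] for v in vits],
                "viterbi_k2": [v[1] for v in vits],
            }
        )
        return pd.concat([df, pd.DataFrame(data)], axis=1)

    def _cohort(self, n_pairs=40, planted=("g1", "g5"), seed=0):
        rng = np.random.default_rng(seed)
        decoded, groups = {}, {}
        for g in ("A", "B"):
            for i in range(4):
                s = f"{g}{i}"
                decoded[s] = self._decoded_with_posteriors(rng, n_pairs, set(planted), g)
                groups[s] = g
        return decoded, groups

    def test_planted_shifts_are_recovered(self):
        planted = {"g1", "g5", "g7"}
        decoded, groups = self._cohort(planted=tuple(planted), seed=3)
        records, stats = bp.select_differential_pairs(
            decoded, groups, "A", "B", alpha=0.05, n_perm=199, seed=0
        )
        sig = set(stats.loc[stats["significant"], "pair_id"])
        assert sig == planted
        # each planted LL->MM pair contributes two L->M probe records
        assert len(records) == 2 * len(planted)
        assert all(r.change_type == "L->M" for r in records)

    def test_no_differing_states_means_empty(self):
        decoded, groups = self._cohort(planted=(), seed=4)
        records, stats = bp.select_differential_pairs(
            decoded, groups, "A", "B", alpha=0.05, n_perm=199, seed=0
        )
        assert records == []
        assert len(stats) == 0

    def test_alpha_zero_selects_nothing(self):
        decoded, groups = self._cohort(seed=5)
        records, stats = bp.select_differential_pairs(
            decoded, groups, "A", "B", alpha=0.0, n_perm=199, seed=0
        )
        assert records == []
        assert not stats["significant"].any()

    def test_change_records_name_probe_and_region(self):
        recs = change_records_for_pair("g9", "SI", "LM", "ML")
        assert [r.probe_id for r in recs] == ["g9:1", "g9:2"]
        assert [r.location_class for r in recs] == ["S", "I"]
        assert [r.change_type for r in recs] == ["L->M", "M->L"]
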