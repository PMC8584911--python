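import numpy as np
import pytest

from mrcae.aggregate import (
    FrequencyTable,
    build_frequency_table,
    consensus_union,
    frequent_features,
    read_feature_set,
    stability_report,
    top_n,
    write_stable_set,
)
from mrcae.cae import CAEConfig, CharacteristicTrace, RunResult


def _pseudo_run(features, seed=0):
    """A RunResult carrying only a selected set (for aggregation tests)."""
    features = list(features)
    tr = CharacteristicTrace(*(np.zeros(1) for _ in range(4)))
    return RunResult(
        selected_unique=set(features),
        per_node_pick=features,
        trace=tr,
        val_mse=0.0,
        config=CAEConfig(k=max(len(features), 1)),
        seed=seed,
    )


class TestFrequencyTable:
    def test_two_run_tally(self):
        t = build_frequency_table([_pseudo_run({"f1", "f2"}), _pseudo_run({"f2", "f3"})])
        assert t.counts == {"f1": 1, "f2": 2, "f3": 1}
        assert t.total_runs == 2

    def test_identical_runs_all_max_count(self):
        s = {"a", "b", "c"}
        t = build_frequency_table([_pseudo_run(s, i) for i in range(7)])
        assert set(t.counts.values()) == {7}
        assert len(t.counts) == 3

    def test_empty_run_list_rejected(self):
        with pytest.raises(ValueError):
            build_frequency_table([])

    def test_within_run_duplicates_count_once(self):
        r = _pseudo_run(["x", "x", "y"])
        t = build_frequency_table([r])
        assert t.counts == {"x": 1, "y": 1}

    def test_matches_brute_force_tally_on_random_pseudo_runs(self):
        """Exact agreement with a naive nested-loop recount, 100 trials."""
        rng = np.random.default_rng(42)
        universe = [f"lnc{i:03d}" for i in range(534)]
        for _ in range(100):
            n_runs = int(rng.integers(2, 101))
            runs = [
                _pseudo_run(rng.choice(universe, size=100, replace=False))
                for _ in range(n_runs)
            ]
            table = build_frequency_table(runs)
            brute = {}
            for feat in universe:
                c = 0
                for run in runs:
                    if feat in run.selected_unique:
                        c += 1
                if c:
                    brute[feat] = c
            assert table.counts == brute
            assert sum(table.counts.values()) == sum(
                len(r.selected_unique) for r in runs
            )

    def test_permutation_invariant(self):
        rng = np.random.default_rng(1)
        runs = [
            _pseudo_run(rng.choice([f"g{i}" for i in range(50)], 10, replace=False))
            for _ in range(20)
        ]
        fwd = build_frequency_table(runs).counts
        rev = build_frequency_table(runs[::-1]).counts
        assert fwd == rev


class TestTopN:
    def test_tie_broken_lexicographically(self):
        t = FrequencyTable({"a": 5, "b": 3, "c": 3, "d": 1}, total_runs=5)
        assert top_n(t, 2).ranked == [("a", 5), ("b", 3)]

    def test_full_ranking_when_n_equals_size(self):
        t = FrequencyTable({"a": 2, "b": 1}, total_runs=2)
        assert top_n(t, 2).ranked == [("a", 2), ("b", 1)]

    def test_pure_tie_takes_first_id(self):
        t = FrequencyTable({"b": 1, "a": 1}, total_runs=1)
        assert top_n(t, 1).ranked == [("a", 1)]

    def test_oversized_n_returns_everything(self):
        t = FrequencyTable({"a": 1}, total_runs=1)
        assert len(top_n(t, 10).ranked) == 1

    def test_frequencies_non_increasing(self):
        rng = np.random.default_rng(0)
        counts = {f"f{i}": int(rng.integers(1, 30)) for i in range(40)}
        ranked = top_n(FrequencyTable(counts, 30), 25).ranked
        freqs = [c for _, c in ranked]
        assert freqs == sorted(freqs, reverse=True)


class TestStabilityReport:
    def test_identical_runs_degenerate_ranges(self):
        runs = [_pseudo_run({"a", "b", "c"}, i) for i in range(10)]
        rep = stability_report([build_frequency_table(runs)], [2])
        all_row = rep[rep.scope == "all"].iloc[0]
        assert all_row.n_features == 3
        assert all_row.min_freq == 10 and all_row.max_freq == 10
        top_row = rep[rep.scope == "top_2"].iloc[0]
        assert (top_row.min_freq, top_row.max_freq) == (10, 10)

    def test_top_ranges_nested(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(60)]
        runs = [
            _pseudo_run(rng.choice(universe, 20, replace=False), i) for i in range(30)
        ]
        rep = stability_report([build_frequency_table(runs)], [10, 40])
        small = rep[rep.scope == "top_10"].iloc[0]
        large = rep[rep.scope == "top_40"].iloc[0]
        assert small.min_freq >= large.min_freq
        assert small.max_freq <= large.max_freq


class TestConsensusAndFiltering:
    def test_union_of_overlapping_sets(self):
        a = top_n(FrequencyTable({"a": 2, "b": 1}, 2), 2)
        b = top_n(FrequencyTable({"b": 2, "c": 1}, 2), 2)
        assert consensus_union([a, b]) == {"a", "b", "c"}

    def test_nested_sets_union_is_largest(self):
        big = top_n(FrequencyTable({"a": 3, "b": 2, "c": 1}, 3), 3)
        small = top_n(FrequencyTable({"a": 3, "b": 2}, 3), 2)
        assert consensus_union([small, big]) == big.as_set()

    def test_frequent_features_threshold(self):
        t = FrequencyTable({"a": 5, "b": 1, "c": 2}, 5)
        assert frequent_features(t) == {"a", "c"}

    def test_stable_set_tsv_roundtrip(self, tmp_path):
        s = top_n(FrequencyTable({"a": 3, "b": 1}, 3), 2)
        p = tmp_path / "stable.tsv"
        write_stable_set(s, p)
        assert read_feature_set(p) == {"a", "b"}


class TestFrequencyProperties:
    """Structural invariants of aggregation under arbitrary run collections."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    run_sets = st.lists(
        st.sets(st.sampled_from([f"g{i}" for i in range(25)]), min_size=1),
        min_size=1,
        max_size=30,
    )

    @given(run_sets)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_counts_bounded_and_mass_conserved(self, sets):
        runs = [_pseudo_run(s, i) for i, s in enumerate(sets)]
        table = build_frequency_table(runs)
        assert set(table.counts) == set().union(*sets)
        assert all(1 <= c <= len(runs) for c in table.counts.values())
        assert sum(table.counts.values()) == sum(len(s) for s in sets)

    @given(run_sets, st.integers(min_value=1, max_value=40))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_top_n_is_sorted_prefix(self, sets, n):
        runs = [_pseudo_run(s, i) for i, s in enumerate(sets)]
        table = build_frequency_table(runs)
        ranked = top_n(table, n).ranked
        assert len(ranked) == min(n, len(table.counts))
        full = top_n(table, len(table.counts)).ranked
        assert ranked == full[: len(ranked)]
        freqs = [c for _, c in ranked]
        assert freqs == sorted(freqs, reverse=True)


class TestRunPersistence:
    def test_interrupted_systems_resume_from_disk(self, tiny_cohort, tmp_path):
        """Runs persisted as JSON are reloaded, not retrained, and nested
        systems share a common pool as exact prefixes."""
        from mrcae.aggregate import run_mrcae

        _, m, labels, _ = tiny_cohort
        cfg = CAEConfig(k=3, epochs=25, hidden_sizes=(32, 32))
        two = run_mrcae(m, cfg, 2, base_seed=50, labels=labels, out_dir=tmp_path)
        assert sorted(p.name for p in tmp_path.glob("run_*.json")) == [
            "run_50.json",
            "run_51.json",
        ]
        three = run_mrcae(m, cfg, 3, base_seed=50, labels=labels, out_dir=tmp_path)
        for cached, fresh in zip(two, three):
            assert cached.selected_unique == fresh.selected_unique
            assert cached.val_mse == fresh.val_mse
        assert len(list(tmp_path.glob("run_*.json"))) == 3
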