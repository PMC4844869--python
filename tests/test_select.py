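import numpy as np
import pytest

from mirocc import (
    OUTLIER,
    TARGET,
    combine_selections,
    rank_by_gain,
    select_features,
    select_hic,
    select_hig,
    select_lig,
    select_pcf,
    select_rfc,
    select_rfs,
    select_sfc,
    select_znf,
    zero_norm_count,
)
from mirocc.cluster import cluster_features
from mirocc.select import SelectionResult

from conftest import make_table

ALL_METHODS = ["hig", "lig", "rfs", "rfc", "sfc", "hic", "znf", "pcf"]


def _params(method, k=6):
    return {"k": k} if method in ("rfc", "sfc", "hic") else {}


class TestContracts:
    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_size_uniqueness_and_determinism(self, planted_table, method):
        n = 12
        r1 = select_features(planted_table, method, n=n, seed=7, **_params(method, k=20))
        r2 = select_features(planted_table, method, n=n, seed=7, **_params(method, k=20))
        assert r1.selected == r2.selected
        assert len(r1.selected) == len(set(r1.selected))
        if method != "sfc":  # SFC may legitimately fall short of n
            # RFC/HIC draw from at most k cluster representatives
            assert len(r1.selected) == min(n, planted_table.n_features)
        assert set(r1.selected) <= set(planted_table.feature_names)

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_n_larger_than_feature_count_returns_everything(self, tiny_table, method):
        # k >= n_features makes every cluster a singleton, so RFC/HIC can
        # also return the complete feature list
        r = select_features(
            tiny_table, method, n=100, seed=0, **_params(method, k=10)
        )
        if method == "sfc":
            assert set(r.selected) <= set(tiny_table.feature_names)
        else:
            assert sorted(r.selected) == sorted(tiny_table.feature_names)


class TestZeroNorm:
    def test_worked_example(self):
        assert zero_norm_count([0.4, 0, 0.6, 0, 0, 0.8, 0, 1, 1.4]) == 5

    def test_all_zero_and_no_zero(self):
        assert zero_norm_count([0.0, 0.0, 0.0]) == 0
        assert zero_norm_count([1, 2, 3]) == 3

    def test_tolerance(self):
        assert zero_norm_count([1e-9, 0.5, -1e-9], tolerance=1e-6) == 1

    def test_survivor_count_caps_selection(self):
        # exactly 3 features have any nonzero target value
        values = np.zeros((6, 8))
        values[:3, 0] = 1.0
        values[:3, 3] = [0.0, 2.0, 0.0]
        values[:3, 5] = 0.5
        values[3:, 6] = 9.0  # outlier rows only: still all-zero over targets
        labels = [TARGET] * 3 + [OUTLIER] * 3
        table = make_table(values, labels)
        r = select_znf(table, n=50)
        assert sorted(r.selected) == ["f0", "f3", "f5"]

    def test_threshold_zero_only_drops_all_zero_features(self):
        rng = np.random.default_rng(0)
        values = np.abs(rng.standard_normal((10, 5)))
        values[:, 2] = 0.0
        table = make_table(values, [TARGET] * 6 + [OUTLIER] * 4)
        r0 = select_znf(table, n=5, threshold=0)
        r1 = select_znf(table, n=5, threshold=1)
        assert r0.selected == r1.selected
        assert "f2" not in r0.selected

    def test_raising_threshold_never_grows_selection(self, planted_table):
        sizes = [
            len(select_znf(planted_table, n=100, threshold=t).selected)
            for t in range(0, 70, 10)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestInfoGainSelectors:
    def test_hig_equals_head_of_ranking(self, planted_table):
        r = select_hig(planted_table, n=10)
        ranking = rank_by_gain(planted_table, n_bins=10)
        assert list(r.selected) == [s.feature_name for s in ranking[:10]]

    def test_hig_contains_planted_separator(self, tiny_table):
        # 2 bins: only the planted separator is informative after binning
        assert "f0" in select_hig(tiny_table, n=1, n_bins=2).selected

    def test_lig_prefers_pure_noise(self):
        # noise features are exactly uninformative by construction: every
        # discretization bin holds one target and one outlier
        n = 12
        labels = [TARGET, OUTLIER] * (n // 2)
        rng = np.random.default_rng(5)
        cols, names = [], []
        for j in range(3):  # exactly-zero-gain features
            v = np.repeat(np.arange(n // 2, dtype=float), 2)
            cols.append(v)
            names.append(f"flat_{j}")
        for j in range(5):  # separating features
            v = np.array([1.0 + 0.01 * i if l == TARGET else 0.0 + 0.01 * i
                          for i, l in enumerate(labels)])
            cols.append(v)
            names.append(f"sep_{j}")
        table = make_table(np.column_stack(cols), labels, feature_names=names)
        r = select_lig(table, n=3)
        assert sorted(r.selected) == ["flat_0", "flat_1", "flat_2"]

    def test_lig_full_tie_falls_back_to_name_order(self):
        values = np.ones((8, 5))
        labels = [TARGET] * 4 + [OUTLIER] * 4
        table = make_table(values, labels)
        r = select_lig(table, n=3)
        assert list(r.selected) == ["f0", "f1", "f2"]

    def test_hig_and_lig_are_disjoint_on_planted_data(self, planted_table):
        n = 10
        hig = set(select_hig(planted_table, n=n).selected)
        lig = set(select_lig(planted_table, n=n).selected)
        assert not hig & lig

    def test_lig_ordered_by_ascending_gain(self, planted_table):
        r = select_lig(planted_table, n=8)
        gains = [r.scores[f] for f in r.selected]
        assert gains == sorted(gains)


class TestRandomSelectors:
    def test_rfs_same_seed_same_set(self, planted_table):
        assert (
            select_rfs(planted_table, n=10, seed=3).selected
            == select_rfs(planted_table, n=10, seed=3).selected
        )

    def test_rfs_n_equals_feature_count(self, tiny_table):
        r = select_rfs(tiny_table, n=3, seed=0)
        assert sorted(r.selected) == sorted(tiny_table.feature_names)

    def test_rfs_selection_frequency_is_uniform(self):
        rng_table = make_table(
            np.random.default_rng(0).standard_normal((8, 20)),
            [TARGET] * 4 + [OUTLIER] * 4,
        )
        n, d, trials = 5, 20, 1000
        counts = {f: 0 for f in rng_table.feature_names}
        for seed in range(trials):
            for f in select_rfs(rng_table, n=n, seed=seed).selected:
                counts[f] += 1
        p = n / d
        se = np.sqrt(p * (1 - p) / trials)
        for f, c in counts.items():
            assert abs(c / trials - p) < 5 * se, f


class TestClusterSelectors:
    def _dup_table(self):
        rng = np.random.default_rng(8)
        groups = [rng.standard_normal(24) for _ in range(4)]
        cols, names = [], []
        for g, base in enumerate(groups):
            for j in range(3):
                cols.append(base)  # exact duplicates within each group
                names.append(f"g{g}_{j}")
        labels = [TARGET] * 16 + [OUTLIER] * 8
        return make_table(np.column_stack(cols), labels, feature_names=names)

    def test_rfc_representatives_never_repeat_a_duplicate_group(self):
        table = self._dup_table()
        r = select_rfc(table, n=4, k=4, seed=2)
        assert len({f.split("_")[0] for f in r.selected}) == len(r.selected)

    def test_rfc_fewer_clusters_than_n_returns_all_representatives(self):
        table = self._dup_table()
        r = select_rfc(table, n=50, k=4, seed=2)
        assert len(r.selected) == 4

    def test_hic_selects_cluster_argmax_by_gain(self, planted_table):
        k = 6
        r = select_hic(planted_table, n=k, k=k, seed=1)
        ca = cluster_features(planted_table, k=k, seed=1)
        gains = {s.feature_name: s.gain for s in rank_by_gain(planted_table)}
        members = ca.members()
        for f in r.selected:
            cid = ca.assignment[f]
            assert gains[f] == max(gains[m] for m in members[cid])

    def test_hic_equals_hig_with_singleton_clusters(self, planted_table):
        n = 10
        hic = select_hic(planted_table, n=n, k=planted_table.n_features, seed=0)
        hig = select_hig(planted_table, n=n, seed=0)
        assert hic.selected == hig.selected

    def test_hic_picks_at_most_one_per_duplicate_group(self):
        table = self._dup_table()
        r = select_hic(table, n=4, k=4, seed=0)
        assert len({f.split("_")[0] for f in r.selected}) == len(r.selected)

    def test_sfc_spans_at_most_three_clusters(self, planted_table):
        k = 8
        r = select_sfc(planted_table, n=30, k=k, seed=9)
        ca = cluster_features(planted_table, k=k, seed=9)
        spanned = {ca.assignment[f] for f in r.selected}
        assert len(spanned) <= 3

    def test_sfc_giant_cluster_serves_all_n(self):
        # one duplicated mega-group ensures the first visited cluster is huge
        rng = np.random.default_rng(1)
        base = rng.standard_normal(24)
        cols = [base + 1e-9 * rng.standard_normal(24) for _ in range(12)]
        cols.append(rng.standard_normal(24))
        names = [f"big_{j:02d}" for j in range(12)] + ["lone"]
        table = make_table(
            np.column_stack(cols), [TARGET] * 16 + [OUTLIER] * 8, feature_names=names
        )
        r = select_sfc(table, n=5, k=2, seed=3)
        assert len(r.selected) == 5

    def test_sfc_deterministic_replay(self, planted_table):
        r1 = select_sfc(planted_table, n=20, k=8, seed=4)
        r2 = select_sfc(planted_table, n=20, k=8, seed=4)
        assert r1.selected == r2.selected and r1.shortfall == r2.shortfall


class TestPCF:
    def test_prefers_the_independent_feature(self):
        rng = np.random.default_rng(12)
        a = rng.standard_normal(30)
        c = rng.standard_normal(30)
        values = np.column_stack([a, a, c])
        table = make_table(
            values, [TARGET] * 20 + [OUTLIER] * 10, feature_names=["a1", "a2", "c"]
        )
        r = select_pcf(table, n=2)
        assert "c" in r.selected
        assert sorted(r.selected) != ["a1", "a2"]

    def test_never_selects_both_duplicates_while_alternatives_remain(self):
        rng = np.random.default_rng(13)
        cols = [rng.standard_normal(40) for _ in range(5)]
        dup = cols[0]
        values = np.column_stack(cols + [dup])
        names = [f"x{j}" for j in range(5)] + ["x0_dup"]
        table = make_table(values, [TARGET] * 30 + [OUTLIER] * 10, feature_names=names)
        r = select_pcf(table, n=5)
        assert not {"x0", "x0_dup"} <= set(r.selected)

    def test_orthogonal_features_follow_tie_rules(self):
        # exactly orthogonal columns: selection is deterministic and complete
        values = np.eye(4)
        values -= values.mean(axis=0)
        table = make_table(values, [TARGET] * 4)
        r = select_pcf(table, n=4)
        assert sorted(r.selected) == ["f0", "f1", "f2", "f3"]

    def test_requires_two_target_rows(self):
        table = make_table([[1.0, 2.0]], [TARGET])
        with pytest.raises(ValueError, match="target rows"):
            select_pcf(table, n=1)


class TestPlantedRecovery:
    def test_recovery_ordering_across_strategies(self):
        """Mean planted-informative recovery over 20 seeds is ordered
        HIG >= HIC > RFS > LIG on the default planted benchmark."""
        from mirocc import SyntheticSpec, gen_feature_table, informative_recovery

        recov = {"hig": [], "hic": [], "rfs": [], "lig": []}
        for seed in range(20):
            table = gen_feature_table(SyntheticSpec(seed=seed))
            for method in recov:
                params = {"k": 100} if method == "hic" else {}
                sel = select_features(table, method, n=50, seed=seed, **params)
                recov[method].append(informative_recovery(sel))
        hig, hic, rfs, lig = (
            float(np.mean(recov[m])) for m in ("hig", "hic", "rfs", "lig")
        )
        assert hig >= hic
        assert hic > rfs + 0.1  # cluster representatives keep the signal
        assert rfs > lig  # random picks beat the lowest-gain control


class TestCombine:
    def _sel(self, names, method="HIG", seed=0):
        return SelectionResult(method=method, selected=names, seed=seed, n_requested=len(names))

    def test_identical_selections_are_idempotent(self):
        s = ["a", "b", "c"]
        comb = combine_selections([self._sel(s), self._sel(s)], n=3)
        assert list(comb.selected) == s

    def test_frequency_dominates_rank(self):
        r1 = self._sel(["a", "b", "x"])
        r2 = self._sel(["b", "a", "y"])
        r3 = self._sel(["c", "a", "b"])
        comb = combine_selections([r1, r2, r3], n=2)
        assert set(comb.selected) == {"a", "b"}

    def test_hand_tallied_three_dataset_toy(self):
        # counts: a=3, b=2, c=2, d=1, e=1; mean rank b=1.5 < c=2.5
        r1 = self._sel(["a", "b", "d"])
        r2 = self._sel(["b", "c", "a"])
        r3 = self._sel(["a", "c", "e"])
        comb = combine_selections([r1, r2, r3], n=3)
        assert list(comb.selected) == ["a", "b", "c"]
        assert comb.scores == {"a": 3.0, "b": 2.0, "c": 2.0}

    def test_candidate_size_truncates_long_inputs(self):
        long1 = self._sel([f"f{i}" for i in range(10)])
        long2 = self._sel([f"f{i}" for i in range(5, 15)])
        comb = combine_selections([long1, long2], n=20, candidate_size=5)
        # only the first 5 of each are tallied: f0..f4 and f5..f9
        assert set(comb.selected) == {f"f{i}" for i in range(10)}

    def test_mixed_methods_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            combine_selections(
                [self._sel(["a"]), self._sel(["a"], method="LIG")], n=1
            )

    def test_needs_at_least_two_inputs(self):
        with pytest.raises(ValueError):
            combine_selections([self._sel(["a"])], n=1)
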