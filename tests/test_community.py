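"""Shannon diversity, Bray-Curtis, ANOSIM, boundary delineation, UPGMA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hyporheic.community import (
    anosim,
    bray_curtis,
    cluster_layers,
    delineate_boundary,
    dissimilarity_matrix,
    linkage_to_newick,
    shannon,
)
from hyporheic.simulate import abundance_table


class TestShannon:
    def test_uniform_maximum(self):
        assert shannon([1.0] * 10) == pytest.approx(math.log(10), abs=1e-12)

    def test_single_taxon_zero(self):
        assert shannon([5.0, 0.0, 0.0]) == 0.0

    def test_hand_value_2_1_1(self):
        expected = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        assert shannon([2.0, 1.0, 1.0]) == pytest.approx(expected, abs=1e-12)
        assert shannon([2.0, 1.0, 1.0]) == pytest.approx(1.039721, abs=1e-6)

    def test_all_zero_undefined(self):
        assert math.isnan(shannon([0.0, 0.0]))

    @given(st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=2,
                    max_size=10).filter(lambda x: sum(x) > 0),
           st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_scale_invariance(self, x, c):
        assert shannon(np.asarray(x) * c) == pytest.approx(shannon(x), abs=1e-9)

    def test_matches_scikit_bio(self):
        from skbio.diversity.alpha import shannon as skbio_shannon
        counts = np.array([5, 3, 9, 1, 0, 2])
        assert shannon(counts) == pytest.approx(
            float(skbio_shannon(counts, base=math.e)), abs=1e-12
        )


class TestBrayCurtis:
    def test_identity_zero(self):
        assert bray_curtis([3.0, 1.0], [3.0, 1.0]) == 0.0

    def test_disjoint_support_one(self):
        assert bray_curtis([1.0, 0.0], [0.0, 2.0]) == 1.0

    def test_hand_value(self):
        assert bray_curtis([6, 4, 0], [3, 4, 3]) == pytest.approx(0.30, abs=1e-12)

    def test_both_zero_undefined(self):
        assert math.isnan(bray_curtis([0.0, 0.0], [0.0, 0.0]))

    def test_matches_scipy(self):
        from scipy.spatial.distance import braycurtis as scipy_bc
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.poisson(5, size=(2, 8)).astype(float)
            if (x + y).sum() == 0:
                continue
            assert bray_curtis(x, y) == pytest.approx(scipy_bc(x, y), abs=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=50), min_size=3, max_size=8),
           st.lists(st.floats(min_value=0, max_value=50), min_size=3, max_size=8))
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_bounds(self, x, y):
        n = min(len(x), len(y))
        x, y = np.asarray(x[:n]), np.asarray(y[:n])
        if (x + y).sum() == 0:
            return
        d = bray_curtis(x, y)
        assert 0.0 <= d <= 1.0

    def test_matrix_structure(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.poisson(4, size=(5, 6)).astype(float))
        d = dissimilarity_matrix(table).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert np.nanmax(d) <= 1.0


class TestAnosim:
    @staticmethod
    def _separated():
        # two tight clusters with all between > all within
        a = np.array([[10, 0, 0], [11, 1, 0], [10, 0, 1], [12, 0, 0],
                      [11, 0, 0]], float)
        b = np.array([[0, 10, 9], [0, 11, 10], [1, 10, 10], [0, 12, 9],
                      [0, 10, 10]], float)
        table = pd.DataFrame(np.vstack([a, b]))
        groups = np.repeat(["a", "b"], 5)
        return dissimilarity_matrix(table), groups

    def test_perfect_separation_r_one(self):
        d, groups = self._separated()
        res = anosim(d, groups, n_permutations=999, seed=0)
        assert res.r_statistic == pytest.approx(1.0, abs=1e-12)
        # only a relabelling reproducing the split (prob 2/252) ties R = 1
        assert res.p_value < 0.05

    def test_statistic_matches_scikit_bio(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import anosim as skbio_anosim
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.poisson(6, size=(10, 5)).astype(float) + 0.5)
        d = dissimilarity_matrix(table)
        groups = np.repeat(["x", "y"], 5)
        ours = anosim(d, groups, n_permutations=999, seed=1)
        theirs = skbio_anosim(
            DistanceMatrix(d.to_numpy()), list(groups), permutations=999
        )
        assert ours.r_statistic == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_null_p_uniformish(self):
        # groups from one distribution: p should rarely be small
        rng = np.random.default_rng(3)
        rejections = 0
        for i in range(60):
            table = pd.DataFrame(rng.poisson(8, size=(12, 6)).astype(float) + 0.1)
            d = dissimilarity_matrix(table)
            res = anosim(d, np.repeat(["a", "b"], 6), n_permutations=199, seed=i)
            rejections += res.p_value < 0.05
        assert rejections <= 9  # ~5% expected; generous binomial bound

    def test_label_permutation_invariance(self):
        d, groups = self._separated()
        res1 = anosim(d, groups, n_permutations=200, seed=7)
        res2 = anosim(d, np.where(groups == "a", "b", "a"), n_permutations=200, seed=7)
        assert res1.p_value == res2.p_value
        assert res1.r_statistic == res2.r_statistic

    def test_singleton_group_rejected(self):
        d, _ = self._separated()
        with pytest.raises(ValueError, match="2 members"):
            anosim(d, ["a"] + ["b"] * 9, n_permutations=9, seed=0)

    def test_r_near_zero_under_random_labels(self):
        rng = np.random.default_rng(4)
        rs = []
        for i in range(300):
            table = pd.DataFrame(rng.poisson(6, size=(10, 5)).astype(float) + 0.1)
            d = dissimilarity_matrix(table)
            rs.append(anosim(d, rng.permutation(np.repeat(["a", "b"], 5)),
                             n_permutations=1, seed=i).r_statistic)
        assert abs(np.mean(rs)) < 0.02


class TestBoundaryDelineation:
    def test_planted_boundaries_recovered(self, small_community):
        scenario, df = small_community
        table = abundance_table(df)
        expected = {"UW": (1, 2), "DW": (2, 3)}
        for condition, truth in expected.items():
            sub = table[table.index.get_level_values("condition") == condition]
            res = delineate_boundary(sub, condition=condition, seed=5, holm=True)
            assert res.boundary_interval == truth
            assert res.boundary_depth_cm == truth[1] * 5.0

    def test_dw_boundary_deeper_than_uw(self, small_community):
        _, df = small_community
        table = abundance_table(df)
        depths = {}
        for condition in ("UW", "DW"):
            sub = table[table.index.get_level_values("condition") == condition]
            res = delineate_boundary(sub, condition=condition, seed=6, holm=True)
            depths[condition] = res.boundary_depth_cm
        assert depths["DW"] > depths["UW"]

    def test_cumulative_mode_finds_boundary(self, small_community):
        _, df = small_community
        table = abundance_table(df)
        sub = table[table.index.get_level_values("condition") == "UW"]
        res = delineate_boundary(sub, condition="UW", mode="cumulative",
                                 seed=8, holm=True)
        assert res.boundary_interval == (1, 2)

    def test_homogeneous_composition_rarely_flags_boundary(self):
        # flat profile, no turnover within range: Holm-controlled scan
        # should report no boundary in >= 95% of replicates
        from hyporheic.simulate import CommunityScenario, GroupProfile, simulate_community
        detected = 0
        n_rep = 40
        for seed in range(n_rep):
            scenario = CommunityScenario(
                site_conditions={"A": "UW", "B": "UW", "C": "UW"},
                n_dates=2,
                groups={"ciliate": GroupProfile(60.0, 0.001)},
                boundary_depth={"UW": 34.9},  # effectively below the profile
                turnover_sharpness=8.0,
                site_effect_sd=0.15,
                seed=seed,
            )
            table = abundance_table(simulate_community(scenario))
            res = delineate_boundary(table, n_permutations=199, seed=seed,
                                     holm=True)
            detected += res.boundary_interval is not None and res.boundary_interval[1] < 6
        assert detected / n_rep <= 0.05

    def test_empty_strata_truncate_scan(self):
        rng = np.random.default_rng(9)
        rows = []
        for layer in range(4):
            for rep in range(3):
                abund = rng.poisson(8, 4).astype(float) if layer < 2 else np.zeros(4)
                rows.append(("S1", f"d{rep}", "UW", layer, *abund))
        df = pd.DataFrame(rows, columns=["site", "date", "condition", "layer",
                                         "t1", "t2", "t3", "t4"])
        table = df.set_index(["site", "date", "condition", "layer"])
        with pytest.warns(UserWarning, match="truncated"):
            res = delineate_boundary(table, n_permutations=49, seed=0)
        assert all(t.lower_layer <= 2 for t in res.pair_tests)


class TestClustering:
    def test_closest_pair_merges_first(self):
        d = pd.DataFrame(
            [[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        Z, labels = cluster_layers(d)
        assert sorted(int(i) for i in Z[0, :2]) == [0, 1]  # A and B
        assert Z[0, 2] == pytest.approx(0.1)

    def test_ultrametric_heights_reproduced(self):
        # ultrametric input: UPGMA heights equal the ultrametric exactly
        labels = list("ABCD")
        d = pd.DataFrame(0.0, index=labels, columns=labels)
        d.loc["A", "B"] = d.loc["B", "A"] = 0.2
        for x in "AB":
            d.loc[x, "C"] = d.loc["C", x] = 0.6
        for x in "ABC":
            d.loc[x, "D"] = d.loc["D", x] = 0.8
        Z, _ = cluster_layers(d)
        assert list(Z[:, 2]) == pytest.approx([0.2, 0.6, 0.8])

    def test_label_order_invariance(self):
        rng = np.random.default_rng(10)
        table = pd.DataFrame(rng.poisson(5, size=(6, 8)).astype(float) + 0.2,
                             index=list("ABCDEF"))
        d = dissimilarity_matrix(table)
        Z1, _ = cluster_layers(d)
        perm = list("FEDCBA")
        Z2, _ = cluster_layers(d.loc[perm, perm])
        assert sorted(Z1[:, 2]) == pytest.approx(sorted(Z2[:, 2]))

    def test_nan_entries_refused(self):
        d = pd.DataFrame(np.zeros((3, 3)), index=list("ABC"), columns=list("ABC"))
        d.iloc[0, 1] = d.iloc[1, 0] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            cluster_layers(d)

    def test_newick_serialization(self):
        d = pd.DataFrame(
            [[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        Z, labels = cluster_layers(d)
        nwk = linkage_to_newick(Z, labels)
        assert nwk.endswith(";")
        import dendropy
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == set("ABC")
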