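"""Diversity, distances, ordination, and differential-genus detection."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from lifehist import synthetic
from lifehist.ecology import (
    DistanceMatrix,
    aggregate_by_genus,
    alpha_diversity,
    bh_adjust,
    bray_curtis,
    nb_wald_test,
    nmds,
    rarefy,
    size_factors,
    weighted_unifrac,
)

from conftest import make_table


def brute_unifrac(counts: pd.DataFrame, newick: str, s1: str, s2: str) -> float:
    """Independent oracle: explicit enumeration of every branch."""
    tree = TreeNode.read(io.StringIO(newick))
    p1 = counts[s1] / counts[s1].sum()
    p2 = counts[s2] / counts[s2].sum()
    num = den = 0.0
    for node in tree.traverse(include_self=False):
        bl = node.length or 0.0
        tips = [t.name for t in node.tips()] or [node.name]
        a = sum(p1.get(t, 0.0) for t in tips)
        b = sum(p2.get(t, 0.0) for t in tips)
        num += bl * abs(a - b)
        den += bl * (a + b)
    return num / den


class TestRarefy:
    def test_full_depth_keeps_counts(self, community_bundle):
        table, _, _ = community_bundle
        depth = int(table.counts.sum(axis=0).min())
        rare = rarefy(table, depth, seed=1)
        low = table.counts.sum(axis=0) == depth
        for s in table.counts.columns[low]:
            assert (rare.counts[s] == table.counts[s]).all()

    def test_exact_depth_and_determinism(self, community_bundle):
        table, _, _ = community_bundle
        rare1 = rarefy(table, 1000, seed=7)
        rare2 = rarefy(table, 1000, seed=7)
        assert (rare1.counts.sum(axis=0) == 1000).all()
        pd.testing.assert_frame_equal(rare1.counts, rare2.counts)
        assert (rare1.counts <= table.counts).all().all()  # without replacement

    def test_shallow_samples_dropped_with_warning(self):
        table = make_table(
            {"a": {"s1": 10, "s2": 100}, "b": {"s1": 5, "s2": 100}},
            {"a": {"genus": "a"}, "b": {"genus": "b"}},
        )
        with pytest.warns(UserWarning):
            rare = rarefy(table, 50, seed=0)
        assert list(rare.counts.columns) == ["s2"]

    def test_invalid_depth(self, community_bundle):
        with pytest.raises(ValueError):
            rarefy(community_bundle[0], 0, seed=0)

    def test_proportions_unbiased(self):
        """Subsampled expectations track the original proportions
        (chi-square goodness of fit not rejected at alpha=0.01)."""
        table = make_table(
            {k: {"s": v} for k, v in {"a": 5000, "b": 3000, "c": 1500, "d": 500}.items()},
            {k: {"genus": k} for k in "abcd"},
        )
        p = table.counts["s"] / table.counts["s"].sum()
        rejected = 0
        for seed in range(50):
            rare = rarefy(table, 2000, seed=seed)
            # hypergeometric ~ multinomial here; chi-square test as screen
            chi2 = (((rare.counts["s"] - 2000 * p) ** 2) / (2000 * p)).sum()
            # finite-population correction for sampling without replacement
            fpc = (10000 - 2000) / (10000 - 1)
            rejected += (chi2 / fpc) > stats.chi2.ppf(0.99, df=3)
        assert rejected <= 4  # ~0.5 expected, allow slack


class TestAlphaDiversity:
    def test_uniform_shannon_maximum(self):
        table = make_table(
            {k: {"s": 25} for k in "abcd"}, {k: {"genus": k} for k in "abcd"}
        )
        res = alpha_diversity(table)
        assert res.loc["s", "shannon"] == pytest.approx(np.log(4))
        assert res.loc["s", "observed"] == 4

    def test_chao1_no_singletons_equals_observed(self):
        table = make_table(
            {k: {"s": 5} for k in "abc"}, {k: {"genus": k} for k in "abc"}
        )
        assert alpha_diversity(table).loc["s", "chao1"] == 3.0

    def test_chao1_formula(self):
        # 10 taxa: 4 singletons, 2 doubletons, 4 abundant
        counts = {f"t{i}": {"s": c} for i, c in enumerate([1, 1, 1, 1, 2, 2, 9, 9, 9, 9])}
        table = make_table(counts, {k: {"genus": k} for k in counts})
        res = alpha_diversity(table)
        assert res.loc["s", "chao1"] == pytest.approx(10 + 4 * 3 / (2 * 3))
        classic = alpha_diversity(table, chao1_bias_corrected=False)
        assert classic.loc["s", "chao1"] == pytest.approx(10 + 16 / 4)


class TestDistances:
    def test_bray_curtis_cases(self):
        table = make_table(
            {"a": {"s1": 3, "s2": 1, "s3": 2, "s4": 0},
             "b": {"s1": 1, "s2": 3, "s3": 6, "s4": 5}},
            {"a": {"genus": "a"}, "b": {"genus": "b"}},
        )
        d = bray_curtis(table).to_frame()
        assert d.loc["s1", "s1"] == 0.0
        assert d.loc["s1", "s2"] == pytest.approx(0.5)  # (3,1) vs (1,3) proportions
        assert d.loc["s1", "s3"] == pytest.approx(0.5)  # proportions equal to s2
        assert d.loc["s4", "s4"] == 0.0

    def test_unifrac_identical_samples_zero(self):
        table = make_table(
            {"a": {"s1": 5, "s2": 5}, "b": {"s1": 3, "s2": 3}},
            {"a": {"genus": "a"}, "b": {"genus": "b"}},
        )
        nwk = "(a:1.0,b:2.0);"
        assert weighted_unifrac(table, nwk).to_frame().loc["s1", "s2"] == pytest.approx(0.0)

    def test_unifrac_disjoint_star_tree_maximal(self):
        table = make_table(
            {"a": {"s1": 10, "s2": 0}, "b": {"s1": 0, "s2": 10}},
            {"a": {"genus": "a"}, "b": {"genus": "b"}},
        )
        nwk = "(a:1.0,b:1.0);"
        assert weighted_unifrac(table, nwk).to_frame().loc["s1", "s2"] == pytest.approx(1.0)

    def test_missing_leaf_rejected(self):
        table = make_table(
            {"a": {"s1": 1, "s2": 2}, "zzz": {"s1": 1, "s2": 1}},
            {"a": {"genus": "a"}, "zzz": {"genus": "z"}},
        )
        with pytest.raises(ValueError, match="zzz"):
            weighted_unifrac(table, "(a:1.0,b:1.0);")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_unifrac_matches_branch_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_leaf = 8
        leaves = [f"L{i}" for i in range(n_leaf)]
        nwk = synthetic.random_tree(leaves, seed=seed + 100)
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(n_leaf, 3)) + (rng.random((n_leaf, 3)) < 0.5),
            index=leaves, columns=["s1", "s2", "s3"],
        ).astype(int)
        counts.iloc[0] += 1
        table = make_table(
            {a: dict(counts.loc[a]) for a in leaves}, {a: {"genus": a} for a in leaves}
        )
        dm = weighted_unifrac(table, nwk).to_frame()
        for x, y in [("s1", "s2"), ("s1", "s3"), ("s2", "s3")]:
            assert dm.loc[x, y] == pytest.approx(
                brute_unifrac(table.counts, nwk, x, y), rel=1e-10
            )


class TestNmds:
    def test_planar_configuration_recovered(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 1.2], [1.4, 0.9]])
        D = squareform(pdist(pts))
        ord_ = nmds(DistanceMatrix([f"p{i}" for i in range(4)], D), seed=3)
        assert ord_.stress < 1e-3

    def test_stress_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        pts = rng.random((7, 3))
        D = squareform(pdist(pts))
        ids = [f"p{i}" for i in range(7)]
        s1 = nmds(DistanceMatrix(ids, D), seed=5).stress
        s2 = nmds(DistanceMatrix(ids, np.sqrt(D)), seed=5).stress
        s3 = nmds(DistanceMatrix(ids, D**2 + np.sign(D) * 0.1), seed=5).stress
        assert s1 == s2 == s3

    def test_deterministic_and_centred(self):
        rng = np.random.default_rng(9)
        D = squareform(pdist(rng.random((6, 4))))
        ids = list("abcdef")
        o1 = nmds(DistanceMatrix(ids, D), seed=2)
        o2 = nmds(DistanceMatrix(ids, D), seed=2)
        pd.testing.assert_frame_equal(o1.coordinates, o2.coordinates)
        assert np.allclose(o1.coordinates.mean(), 0.0, atol=1e-9)
        assert (o1.coordinates.iloc[0] >= 0).all()  # orientation convention


class TestSizeFactors:
    def test_identical_columns_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 5], "s2": [10, 20, 5]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_column_factor_two(self):
        counts = pd.DataFrame({"s1": [10, 20, 5], "s2": [20, 40, 10]})
        sf = size_factors(counts)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)

    def test_matches_median_of_ratios_oracle(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(50, 10)),
            columns=[f"s{j}" for j in range(10)],
        )
        sf = size_factors(counts)
        logc = np.log(counts.to_numpy(dtype=float))
        gm = np.exp(logc.mean(axis=1))
        for j, s in enumerate(counts.columns):
            ratios = counts[s].to_numpy() / gm
            assert sf[s] == pytest.approx(np.median(ratios), rel=1e-12)

    def test_requires_all_nonzero_genus(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(counts)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_arithmetic(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 40)
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestGenusAggregation:
    def test_unresolved_genus_grouped_by_family(self):
        table = make_table(
            {"a1": {"s": 1}, "a2": {"s": 2}, "a3": {"s": 4}},
            {
                "a1": {"family": "F1", "genus": "G1"},
                "a2": {"family": "F1", "genus": ""},
                "a3": {"family": "F1", "genus": "G1"},
            },
        )
        g = aggregate_by_genus(table)
        assert g.loc["G1", "s"] == 5
        assert g.loc["unclassified_F1", "s"] == 2


class TestNbWaldTest:
    def test_relabelling_flips_log2fc_sign(self):
        counts, groups, _ = synthetic.gen_nb_counts(30, 10, 0.1, seed=4)
        a = nb_wald_test(counts, groups, reference="pristine")
        b = nb_wald_test(counts, groups, reference="cropland")
        assert np.allclose(a["log2fc"], -b["log2fc"])
        assert np.allclose(a["p"], b["p"])

    def test_all_zero_genus_excluded_and_logged(self):
        counts, groups, _ = synthetic.gen_nb_counts(10, 8, 0.1, seed=5)
        counts.iloc[3] = 0
        res = nb_wald_test(counts, groups)
        assert "g003" not in res.index
        assert res.attrs["excluded"] == ["g003"]

    def test_responsive_rule(self):
        counts, groups, _ = synthetic.gen_nb_counts(
            100, 20, 0.01, fold_changes={0: 4.0}, seed=6
        )
        res = nb_wald_test(counts, groups, reference="pristine")
        assert bool(res.loc["g000", "responsive"])
        assert res.loc["g000", "log2fc"] == pytest.approx(2.0, abs=0.5)
        assert (res["padj"] >= res["p"] - 1e-15).all()
        flagged = res[res["responsive"]]
        assert ((flagged["log2fc"].abs() > 1) & (flagged["padj"] < 0.05)).all()

    def test_requires_two_groups(self):
        counts, groups, _ = synthetic.gen_nb_counts(10, 8, 0.1, seed=7)
        with pytest.raises(ValueError):
            nb_wald_test(counts, pd.Series("x", index=counts.columns))
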