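"""RPKM, expression thresholds, correlation analyses, dosage dependency."""

import numpy as np
import pandas as pd
import pytest

from aqpscan.expression_analysis import (DesignError, call_degs,
                                         coexpression_network,
                                         dosage_classify, dosage_correlation,
                                         expressed_filter,
                                         hierarchical_cluster, pearson_r,
                                         rpkm_normalize, subfamily_aggregate)


def _matrix(data, genes, samples):
    return pd.DataFrame(np.asarray(data, dtype=float), index=genes,
                        columns=samples)


# ---------------------------------------------------------------------------
# RPKM
# ---------------------------------------------------------------------------

class TestRpkm:
    def test_formula_identity(self):
        # count 10 on a 1 kb gene in a 1M-read library -> RPKM 10
        counts = _matrix([[10], [999_990]], ["g1", "filler"], ["s1"])
        lengths = pd.Series({"g1": 1000, "filler": 50_000})
        rpkm = rpkm_normalize(counts, lengths)
        assert rpkm.loc["g1", "s1"] == pytest.approx(10.0)

    def test_library_scaling_invariance(self, rng):
        counts = _matrix(rng.integers(0, 500, size=(8, 3)),
                         [f"g{i}" for i in range(8)], list("abc"))
        lengths = pd.Series(rng.integers(500, 3000, size=8),
                            index=counts.index)
        doubled = counts.copy()
        doubled["b"] = counts["b"] * 7
        r1 = rpkm_normalize(counts, lengths)
        r2 = rpkm_normalize(doubled, lengths)
        pd.testing.assert_frame_equal(r1, r2)

    def test_all_zero_gene_is_zero_everywhere(self):
        counts = _matrix([[0, 0], [10, 20]], ["silent", "g"], ["a", "b"])
        lengths = pd.Series({"silent": 1000, "g": 1000})
        rpkm = rpkm_normalize(counts, lengths)
        assert (rpkm.loc["silent"] == 0).all()

    def test_zero_library_total_rejected(self):
        counts = _matrix([[0], [0]], ["g1", "g2"], ["empty"])
        lengths = pd.Series({"g1": 1000, "g2": 1000})
        with pytest.raises(DesignError, match="empty"):
            rpkm_normalize(counts, lengths)


# ---------------------------------------------------------------------------
# Expressed filter
# ---------------------------------------------------------------------------

class TestExpressedFilter:
    def test_threshold_is_strict(self):
        rpkm = _matrix([[2.0, 1.0], [2.1, 0.0], [0.5, 1.9]],
                       ["at", "above", "below"], ["a", "b"])
        flags = expressed_filter(rpkm, threshold=2.0)
        assert not flags["at"]       # exactly 2.0 is not > 2
        assert flags["above"]
        assert not flags["below"]

    def test_idempotent_and_order_independent(self, dosage_run):
        rpkm, _, _ = dosage_run
        flags = expressed_filter(rpkm)
        shuffled = rpkm.sample(frac=1.0, random_state=0)
        flags2 = expressed_filter(shuffled)
        assert flags.sort_index().equals(flags2.sort_index())

    def test_planted_silent_genes_recovered(self, dosage_run):
        rpkm, _, truth = dosage_run
        flags = expressed_filter(rpkm)
        silent = truth.loc[truth.silent, "gene"]
        assert not flags.loc[silent].any()
        loud = truth.loc[truth.is_aqp & (truth.base_rpkm >= 5), "gene"]
        assert flags.loc[loud].all()


# ---------------------------------------------------------------------------
# Differential calls
# ---------------------------------------------------------------------------

def _two_condition_design():
    return pd.DataFrame({
        "sample": ["c1", "c2", "t1", "t2"],
        "condition": ["control", "control", "drought", "drought"],
    })


class TestDegCalls:
    def test_zero_means_no_call(self):
        rpkm = _matrix([[0, 0, 0, 0]], ["g"], ["c1", "c2", "t1", "t2"])
        res = call_degs(rpkm, _two_condition_design(), "control", "drought")
        assert res[0].log2fc == 0 and not res[0].is_deg

    def test_hand_computed_fold_change(self):
        rpkm = _matrix([[2, 2, 20, 20]], ["g"], ["c1", "c2", "t1", "t2"])
        res = call_degs(rpkm, _two_condition_design(), "control", "drought")
        assert res[0].log2fc == pytest.approx(np.log2(21 / 3), abs=1e-12)
        assert res[0].is_deg and res[0].direction == "up"

    def test_unknown_condition_rejected(self):
        rpkm = _matrix([[1, 1, 1, 1]], ["g"], ["c1", "c2", "t1", "t2"])
        with pytest.raises(DesignError):
            call_degs(rpkm, _two_condition_design(), "control", "heat")


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson_r(x, -x).r == pytest.approx(-1.0)

    def test_matches_two_pass_oracle(self, rng):
        for _ in range(50):
            x = rng.normal(size=rng.integers(3, 40))
            y = rng.normal(size=len(x))
            got = pearson_r(x, y).r
            # naive two-pass product-moment formula
            xc, yc = x - x.mean(), y - y.mean()
            want = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
            assert got == pytest.approx(want, abs=1e-12)

    def test_zero_variance_flagged(self):
        res = pearson_r([1, 1, 1, 1], [1, 2, 3, 4])
        assert not res.defined and np.isnan(res.r)


# ---------------------------------------------------------------------------
# Co-expression network
# ---------------------------------------------------------------------------

class TestCoexpression:
    def test_vacuous_thresholds_keep_every_edge(self, rng):
        rpkm = _matrix(rng.lognormal(3, 1, size=(12, 6)),
                       [f"g{i}" for i in range(12)], list("abcdef"))
        net = coexpression_network(rpkm, ["g0"], lower_pct=0, upper_pct=100)
        # percentile 0/100 bound the distribution, so min/max always pass;
        # every other gene must clear one of the bounds or equal them
        assert net.graph.degree("g0") >= 2

    def test_identical_columns_are_degenerate(self):
        rpkm = _matrix([[5, 5, 5], [1, 1, 1]], ["g0", "g1"], list("abc"))
        net = coexpression_network(rpkm, ["g0"])
        assert set(net.degenerate_genes) == {"g0", "g1"}
        assert net.graph.number_of_edges() == 0

    def test_planted_module_edges_retained(self, dosage_run):
        rpkm, _, truth = dosage_run
        members = truth.loc[truth.module == 0, "gene"].tolist()
        bait = members[0]
        net = coexpression_network(rpkm, [bait])
        neighbors = set(net.graph.neighbors(bait))
        assert set(members[1:]) <= neighbors

    def test_every_edge_satisfies_its_threshold(self, dosage_run):
        rpkm, _, _ = dosage_run
        baits = list(rpkm.index[:5])
        net = coexpression_network(rpkm, baits)
        for u, v, d in net.graph.edges(data=True):
            lo, hi = net.thresholds[d["bait"]]
            assert d["r"] <= lo or d["r"] >= hi

    def test_gene_order_invariance(self, dosage_run):
        rpkm, _, _ = dosage_run
        bait = rpkm.index[0]
        net1 = coexpression_network(rpkm, [bait])
        net2 = coexpression_network(rpkm.iloc[::-1], [bait])
        canon = lambda g: {frozenset(e) for e in g.edges()}
        assert canon(net1.graph) == canon(net2.graph)


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

class TestHierarchicalClustering:
    def test_two_genes_single_merge_at_distance(self):
        rpkm = _matrix([[1, 2, 3, 4], [4, 3, 2, 1]], ["a", "b"], list("wxyz"))
        tree = hierarchical_cluster(rpkm)
        assert tree.linkage.shape == (1, 4)
        assert tree.linkage[0, 2] == pytest.approx(2.0)  # 1 - (-1)

    def test_anticorrelated_blocks_bipartition(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0, 1, 8)
        up = np.vstack([10 * t + rng.normal(0, .05, 8) for _ in range(4)])
        down = np.vstack([10 * (1 - t) + rng.normal(0, .05, 8)
                          for _ in range(4)])
        genes = [f"up{i}" for i in range(4)] + [f"dn{i}" for i in range(4)]
        tree = hierarchical_cluster(_matrix(np.vstack([up, down]), genes,
                                            [f"s{i}" for i in range(8)]))
        cut = tree.cut(2)
        assert len({cut[g] for g in genes[:4]}) == 1
        assert len({cut[g] for g in genes[4:]}) == 1
        assert cut[genes[0]] != cut[genes[4]]

    def test_merge_heights_non_decreasing(self, dosage_run):
        rpkm, _, truth = dosage_run
        panel = truth.loc[truth.is_aqp, "gene"]
        tree = hierarchical_cluster(rpkm.loc[panel])
        heights = tree.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_newick_contains_all_genes(self):
        rpkm = _matrix([[1, 2, 3], [3, 2, 1], [1, 3, 2]],
                       ["a", "b", "c"], list("xyz"))
        nwk = hierarchical_cluster(rpkm).newick()
        assert nwk.endswith(";")
        for g in "abc":
            assert g in nwk


# ---------------------------------------------------------------------------
# Dosage dependency
# ---------------------------------------------------------------------------

def _dosage_design():
    rows = []
    for geno, a in (("AA", 1.0), ("AC", 0.5), ("AAC", 0.66), ("CCA", 0.33),
                    ("CCAA", 0.5)):
        for rep in (1, 2):
            rows.append({"sample": f"{geno}_r{rep}", "condition": geno,
                         "a_fraction": a})
    return pd.DataFrame(rows)


class TestDosage:
    def test_proportional_gene_is_dependent_with_r_one(self):
        design = _dosage_design()
        a = design["a_fraction"].to_numpy()
        rpkm = _matrix([100 * a], ["prop"], design["sample"])
        res = dosage_correlation(rpkm, design)[0]
        assert res.r == pytest.approx(1.0)
        assert res.dosage_dependent

    def test_constant_gene_is_independent(self):
        design = _dosage_design()
        rpkm = _matrix([np.full(len(design), 7.0)], ["flat"],
                       design["sample"])
        res = dosage_correlation(rpkm, design)[0]
        assert np.isnan(res.r) and not res.dosage_dependent

    def test_constant_composition_rejected(self):
        design = _dosage_design()
        design["a_fraction"] = 0.5
        rpkm = _matrix([[1.0] * len(design)], ["g"], design["sample"])
        with pytest.raises(DesignError):
            dosage_correlation(rpkm, design)

    def test_dependency_rule_p_and_sign(self, dosage_run):
        rpkm, design, truth = dosage_run
        panel = truth.loc[truth.is_aqp, "gene"]
        for res in dosage_correlation(rpkm.loc[panel], design):
            expected = (not np.isnan(res.p_value)) and \
                res.p_value < 0.01 and res.r > 0
            assert res.dosage_dependent == expected

    def test_summary_fractions(self):
        design = _dosage_design()
        a = design["a_fraction"].to_numpy()
        rpkm = _matrix([100 * a, 100 * (1.2 - a), np.full(len(a), 3.0)],
                       ["dep", "anti", "flat"], design["sample"])
        summary = dosage_classify(dosage_correlation(rpkm, design))
        assert summary["n_genes"] == 3
        assert summary["fraction_dependent"] == pytest.approx(1 / 3)
        assert summary["fraction_positive_r"] == pytest.approx(1 / 2)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

class TestAggregation:
    def test_single_gene_group_mean_and_zero_se(self):
        rpkm = _matrix([[4, 8]], ["g1"], ["a", "b"])
        ann = pd.DataFrame({"gene": ["g1"], "subfamily": ["PIP"],
                            "group": ["PIP1"]})
        agg, unann = subfamily_aggregate(rpkm, ann)
        assert unann == []
        row = agg.set_index(["label", "sample"]).loc[("PIP", "a")]
        assert row["mean"] == 4 and row["se"] == 0

    def test_permutation_invariance(self, dosage_run):
        rpkm, _, truth = dosage_run
        panel = truth.loc[truth.is_aqp]
        ann = panel[["gene", "subfamily", "group"]]
        a1, _ = subfamily_aggregate(rpkm.loc[panel.gene], ann)
        a2, _ = subfamily_aggregate(rpkm.loc[panel.gene[::-1]], ann)
        key = ["label", "sample"]
        pd.testing.assert_frame_equal(a1.sort_values(key).reset_index(drop=True),
                                      a2.sort_values(key).reset_index(drop=True))

    def test_unannotated_genes_listed(self):
        rpkm = _matrix([[1, 2], [3, 4]], ["g1", "mystery"], ["a", "b"])
        ann = pd.DataFrame({"gene": ["g1"], "subfamily": ["TIP"],
                            "group": ["TIP3"]})
        _, unann = subfamily_aggregate(rpkm, ann)
        assert unann == ["mystery"]
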