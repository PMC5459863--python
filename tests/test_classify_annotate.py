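"""Screening, classification, naming, specificity rules, NJ tree."""

import numpy as np
import pytest

from aqpscan.classify_annotate import (AqpAnnotation, CandidateFilterReport,
                                       assign_genome_and_name,
                                       build_feature_table, classify_subfamily,
                                       load_specificity_rules,
                                       neighbor_joining_tree,
                                       predict_specificity, screen_candidates)
from aqpscan.feature_scan import (MotifPair, NpaMotif, SelectivityFilter,
                                  scan_npa_candidates)
from aqpscan.seq_core import GeneModel, ProteinRecord, predict_tm_segments


def _features(records):
    tm = {r.id: predict_tm_segments(r) for r in records}
    mot = {r.id: scan_npa_candidates(r) for r in records}
    return tm, mot


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

class TestScreening:
    def test_fragment_too_short(self):
        rec = ProteinRecord("frag", "MKVILFW" * 9)  # 63 residues
        reports = screen_candidates([rec], *_features([rec]))
        assert not reports[0].kept
        assert "too_short" in reports[0].reasons

    def test_full_aqp_kept(self, cohort):
        records, _, truth = cohort
        aqp_ids = set(truth.loc[truth.kind == "aqp", "id"])
        full = [r for r in records if r.id in aqp_ids]
        reports = screen_candidates(full, *_features(full))
        kept = sum(r.kept for r in reports)
        assert kept / len(reports) >= 0.95

    def test_hydrophilic_decoy_missing_tm(self, cohort):
        records, _, truth = cohort
        decoys = set(truth.loc[truth.kind == "non_aqp", "id"])
        recs = [r for r in records if r.id in decoys]
        reports = screen_candidates(recs, *_features(recs))
        assert all(not r.kept and "missing_tm" in r.reasons for r in reports)

    def test_order_independence(self, cohort):
        records, _, _ = cohort
        subset = records[:10]
        tm, mot = _features(subset)
        fwd = screen_candidates(subset, tm, mot)
        rev = screen_candidates(subset[::-1], tm, mot)
        assert {r.record_id: r for r in fwd} == \
            {r.record_id: r for r in rev[::-1]}

    def test_kept_flag_consistency_enforced(self):
        with pytest.raises(ValueError):
            CandidateFilterReport("x", kept=True, reasons=("too_short",))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

class TestClassification:
    def test_reference_classifies_as_itself(self, profile):
        ref = profile.get("RefTIP3")
        res = classify_subfamily(ProteinRecord("q", ref.sequence), profile)
        assert (res.subfamily, res.group) == ("TIP", "TIP3")
        assert res.identity == 1.0

    def test_shuffled_sequence_unclassified(self, profile, rng):
        ref = profile.get("RefPIP1")
        shuffled = "".join(rng.permutation(list(ref.sequence)))
        res = classify_subfamily(ProteinRecord("q", shuffled), profile)
        assert not res.classified

    def test_empty_profile_rejected(self, profile):
        from aqpscan.feature_scan import ReferenceProfile
        with pytest.raises(ValueError):
            classify_subfamily(ProteinRecord("q", "MKVIL"),
                               ReferenceProfile(entries=[]))


# ---------------------------------------------------------------------------
# Genome assignment and naming
# ---------------------------------------------------------------------------

def _ann(gene_id, group="NIP5"):
    sub = group[:3]
    return AqpAnnotation(gene_id=gene_id, subfamily=sub, group=group)


class TestNaming:
    def test_chromosome_prefix_sets_genome(self):
        ann = _ann("g1")
        models = {"g1": GeneModel("g1", "A03", "+", ((100, 500),))}
        assign_genome_and_name([ann], models)
        assert ann.genome == "A"
        assert ann.name == "BnaANIP5-1a"

    def test_paralog_letters_follow_chromosome_order(self):
        anns = [_ann("g_late"), _ann("g_early")]
        models = {"g_late": GeneModel("g_late", "A03", "+", ((5, 400),)),
                  "g_early": GeneModel("g_early", "A02", "+", ((900, 1300),))}
        assign_genome_and_name(anns, models)
        names = {a.gene_id: a.name for a in anns}
        assert names["g_early"] == "BnaANIP5-1a"  # A02 before A03
        assert names["g_late"] == "BnaANIP5-1b"

    def test_scaffold_gene_assigned_to_best_progenitor(self, profile):
        ref = profile.get("RefNIP5")
        rec = ProteinRecord("sc1", ref.sequence)
        ann = _ann("sc1")
        progenitors = {"A": [], "C": [ref]}
        assign_genome_and_name([ann], {}, progenitor_profiles=progenitors,
                               sequences={"sc1": rec})
        assert ann.genome == "C_random"
        assert ann.name == "BnaCNIP5-1a"


# ---------------------------------------------------------------------------
# Substrate specificity
# ---------------------------------------------------------------------------

def _annotation_with(sf, spacing):
    ann = AqpAnnotation(gene_id="g")
    ann.selectivity_filter = SelectivityFilter(*sf)
    if spacing is not None:
        lb = NpaMotif("NPA", 100)
        le = NpaMotif("NPA", 100 + 3 + spacing)
        ann.motif_pair = MotifPair(lb=lb, le=le, spacing=spacing)
    return ann


class TestSpecificity:
    def test_pip_filter_predicts_water_tier1(self):
        pred = predict_specificity(_annotation_with("FHTR", 118))
        assert ("water", 1) in pred.substrates

    def test_lsi1_signature_requires_spacing_108(self):
        with_108 = predict_specificity(_annotation_with("GSGR", 108))
        with_116 = predict_specificity(_annotation_with("GSGR", 116))
        assert "silicic acid" in with_108.substrate_names()
        assert "silicic acid" not in with_116.substrate_names()

    def test_nip_II_boric_not_silicic(self):
        pred = predict_specificity(_annotation_with("AIGR", 108))
        assert "boric acid" in pred.substrate_names()
        assert "silicic acid" not in pred.substrate_names()

    def test_undefined_positions_lower_tier(self):
        defined = predict_specificity(_annotation_with("FHTR", 118))
        undef = predict_specificity(_annotation_with(("F", "H", "-", "R"),
                                                     118))
        assert "undefined_filter_positions" in undef.flags
        if undef.substrates:
            assert min(t for _, t in undef.substrates) > \
                min(t for _, t in defined.substrates)

    def test_silicic_never_without_signature(self, rng):
        rules = load_specificity_rules()
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(300):
            sf = tuple(rng.choice(letters, size=4))
            spacing = int(rng.integers(85, 150))
            pred = predict_specificity(_annotation_with(sf, spacing), rules)
            if "silicic acid" in pred.substrate_names():
                assert sf == ("G", "S", "G", "R") and spacing == 108


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

class TestFeatureTable:
    def test_row_per_planted_aqp(self, annotated_cohort):
        reports, annotations, truth = annotated_cohort
        table = build_feature_table(annotations)
        n_aqp = int((truth.kind == "aqp").sum())
        # single-motif decoys survive screening (flagged) but every
        # planted aquaporin must have a row
        aqp_ids = set(truth.loc[truth.kind == "aqp", "id"])
        assert aqp_ids <= set(table.gene_id)
        assert len(table) >= n_aqp

    def test_empty_annotations_header_only(self):
        table = build_feature_table([])
        assert len(table) == 0
        assert "npa_distance" in table.columns

    def test_deterministic_row_order(self, annotated_cohort):
        _, annotations, _ = annotated_cohort
        t1 = build_feature_table(annotations)
        t2 = build_feature_table(list(reversed(annotations)))
        assert t1.equals(t2)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        import skbio

        # d(ab)=3, d(ac)=5, d(bc)=6 -> a=(3+5-6)/2=1, b=2, c=4
        d = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], dtype=float)
        newick = neighbor_joining_tree(["a", "b", "c"], distances=d)
        tree = skbio.TreeNode.read([newick])
        tips = {t.name: t.length for t in tree.tips()}
        total = {n: tree.find(n).accumulate_to_ancestor(tree.root())
                 for n in "abc"}
        assert total["a"] + total["b"] == pytest.approx(3)
        assert total["a"] + total["c"] == pytest.approx(5)
        assert total["b"] + total["c"] == pytest.approx(6)

    def test_four_taxa_additive_topology_recovered(self):
        import skbio

        # additive tree: ((a,b),(c,d)) with internal branch 2
        #   a-b: 1+1=2 ; c-d: 1.5+1 = 2.5 ; cross pairs include +2
        d = np.array([
            [0.0, 2.0, 4.5, 4.0],
            [2.0, 0.0, 4.5, 4.0],
            [4.5, 4.5, 0.0, 2.5],
            [4.0, 4.0, 2.5, 0.0],
        ])
        newick = neighbor_joining_tree(["a", "b", "c", "d"], distances=d)
        tree = skbio.TreeNode.read([newick])
        # four-point condition: a,b side of the split excludes c,d
        lca = tree.lowest_common_ancestor(["a", "b"])
        assert {t.name for t in lca.tips()} in ({"a", "b"}, {"c", "d"})

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining_tree(["a", "b"],
                                  distances=np.zeros((2, 2)))

    def test_subfamily_clades_on_templates(self, profile):
        # PIP1/PIP2 should be each other's nearest relatives, likewise
        # the two SIPs; use a small subset to keep alignments cheap
        entries = [profile.get(n) for n in
                   ("RefPIP1", "RefPIP2", "RefSIP1", "RefSIP2", "RefTIP1",
                    "RefTIP2")]
        import skbio
        newick = neighbor_joining_tree([e.name for e in entries],
                                       [e.sequence for e in entries])
        tree = skbio.TreeNode.read([newick])
        dist = {}
        for a in entries:
            for b in entries:
                if a.name < b.name:
                    dist[(a.name, b.name)] = tree.find(a.name).distance(
                        tree.find(b.name))
        pip_pair = dist[("RefPIP1", "RefPIP2")]
        assert pip_pair < dist[("RefPIP1", "RefSIP1")]
        assert pip_pair < dist[("RefPIP1", "RefTIP1")]
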