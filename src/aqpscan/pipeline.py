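"""End-to-end cohort annotation: screen, scan, classify, extract, name.

The one-call driver behind the CLI and the analysis scripts. Each kept
candidate is aligned against the reference profile once; the winning
alignment serves classification, selectivity-filter extraction and
Froger-residue extraction alike.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .classify_annotate import (AqpAnnotation, CandidateFilterReport,
                                assign_genome_and_name, classify_subfamily,
                                screen_candidates)
from .config import PipelineConfig
from .feature_scan import (ReferenceProfile, extract_froger_residues,
                           extract_selectivity_filter,
                           load_substitution_matrix, scan_npa_candidates,
                           select_motif_pair)
from .seq_core import GeneModel, ProteinRecord, predict_tm_segments

#: subfamily-typical NPA-NPA spacings used as pair-selection expectations
EXPECTED_SPACING = {"PIP": 118, "TIP": 111, "NIP": 112, "SIP": 110}


def annotate_cohort(records: Sequence[ProteinRecord],
                    profile: ReferenceProfile,
                    gene_models: Optional[Sequence[GeneModel]] = None,
                    config: Optional[PipelineConfig] = None,
                    progenitor_profiles: Optional[dict] = None
                    ) -> tuple[list, list]:
    """Run the full annotation pipeline on a protein cohort.

    Returns (filter_reports, annotations); annotations cover kept
    records only.
    """
    cfg = config or PipelineConfig()
    substitution = load_substitution_matrix(cfg.align.matrix)
    tm_map = {r.id: predict_tm_segments(r, cfg.tm.window, cfg.tm.threshold,
                                        cfg.tm.min_length, cfg.tm.merge_gap)
              for r in records}
    motif_map = {r.id: scan_npa_candidates(r, cfg.motif.variants)
                 for r in records}
    reports = screen_candidates(records, tm_map, motif_map, cfg)
    kept_ids = {rep.record_id for rep in reports if rep.kept}

    annotations = []
    sequences = {r.id: r for r in records}
    for rec in records:
        if rec.id not in kept_ids:
            continue
        cls = classify_subfamily(rec, profile, cfg, substitution)
        ann = AqpAnnotation(gene_id=rec.id, subfamily=cls.subfamily,
                            group=cls.group, tm_count=len(tm_map[rec.id]),
                            length=len(rec), score=cls.score,
                            identity=cls.identity)
        expected = EXPECTED_SPACING.get(cls.subfamily or "", None)
        pair = select_motif_pair(motif_map[rec.id],
                                 (cfg.motif.spacing_min, cfg.motif.spacing_max),
                                 expected_spacing=expected)
        ann.motif_pair = pair
        if pair is None:
            ann.flags.append("needs_review_motif_pair")
        if cls.classified:
            ref = profile.get(cls.reference)
            ann.selectivity_filter = extract_selectivity_filter(
                rec, ref, cls.alignment)
            ann.froger = extract_froger_residues(rec, ref, cls.alignment)
            if cls.identity < cfg.classify.low_identity_flag:
                ann.flags.append("low_identity_extraction")
        else:
            ann.flags.append("unclassified")
        annotations.append(ann)

    model_map = {m.gene_id: m for m in (gene_models or [])}
    assign_genome_and_name(annotations, model_map,
                           progenitor_profiles=progenitor_profiles,
                           config=cfg, substitution=substitution,
                           sequences=sequences)
    return reports, annotations
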