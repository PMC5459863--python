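"""Candidate screening, subfamily classification, naming and annotation.

The screening step reproduces the family-identification logic of a
genome-wide aquaporin survey: full-length channels are ~250-300 residues
with six transmembrane helices and at least one NPA-type motif, so
fragments, motif-less proteins and TM-poor candidates are excluded with
explicit reason codes. Classification assigns each survivor to one of
the four higher-plant subfamilies (PIP, TIP, NIP, SIP) and a group
within it by best global-alignment score against an annotated reference
profile; names follow the amphidiploid convention
``Bna<genome><group>-<homolog><paralog>`` (e.g. BnaANIP5-1a), with
scaffold-only genes assigned to a progenitor genome as A_random or
C_random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .feature_scan import (AlignmentResult, FrogerResidues, MotifPair,
                           ReferenceEntry, ReferenceProfile,
                           SelectivityFilter, extract_froger_residues,
                           extract_selectivity_filter, global_align,
                           load_substitution_matrix, select_motif_pair)
from .seq_core import GeneModel, ProteinRecord, TMSegment

REASON_CODES = ("too_short", "too_long", "missing_tm", "missing_motif",
                "low_score")


@dataclass(frozen=True)
class CandidateFilterReport:
    record_id: str
    kept: bool
    reasons: tuple

    def __post_init__(self) -> None:
        if self.kept != (len(self.reasons) == 0):
            raise ValueError("kept flag inconsistent with reason list")


@dataclass
class ClassificationResult:
    subfamily: Optional[str]
    group: Optional[str]
    reference: Optional[str]
    score: float
    identity: float
    alignment: Optional[AlignmentResult] = None

    @property
    def classified(self) -> bool:
        return self.subfamily is not None


@dataclass
class AqpAnnotation:
    """One feature-table row: everything known about one aquaporin gene."""

    gene_id: str
    name: str = ""
    subfamily: Optional[str] = None
    group: Optional[str] = None
    genome: str = ""
    motif_pair: Optional[MotifPair] = None
    selectivity_filter: Optional[SelectivityFilter] = None
    froger: Optional[FrogerResidues] = None
    tm_count: int = 0
    length: int = 0
    score: float = 0.0
    identity: float = 0.0
    chromosome: str = ""
    start: int = 0
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.subfamily and self.group and not self.group.startswith(self.subfamily):
            raise ValueError(f"{self.gene_id}: group {self.group} inconsistent "
                             f"with subfamily {self.subfamily}")


@dataclass(frozen=True)
class SpecificityPrediction:
    substrates: tuple  # of (substrate, tier) pairs
    flags: tuple = ()

    def substrate_names(self) -> tuple:
        return tuple(s for s, _ in self.substrates)


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def screen_candidates(records: Sequence[ProteinRecord],
                      tm_segments: dict,
                      motifs: dict,
                      config: PipelineConfig | None = None
                      ) -> list[CandidateFilterReport]:
    """Pass/fail each candidate with full reason codes.

    ``tm_segments`` and ``motifs`` map record id to the precomputed
    :class:`TMSegment` and motif lists. Defaults: length within
    [150, 450], at least 5 TM helices, at least one NPA-type motif.
    """
    cfg = (config or PipelineConfig()).screening
    reports = []
    for rec in records:
        reasons = []
        if len(rec) < cfg.min_length:
            reasons.append("too_short")
        if len(rec) > cfg.max_length:
            reasons.append("too_long")
        if len(tm_segments.get(rec.id, [])) < cfg.min_tm:
            reasons.append("missing_tm")
        if len(motifs.get(rec.id, [])) < cfg.min_motifs:
            reasons.append("missing_motif")
        reports.append(CandidateFilterReport(record_id=rec.id,
                                             kept=not reasons,
                                             reasons=tuple(reasons)))
    return reports


# ---------------------------------------------------------------------------
# Classification by reference similarity
# ---------------------------------------------------------------------------

def _self_score(ref: ReferenceEntry, substitution: np.ndarray) -> float:
    idx = np.frombuffer(ref.sequence.encode(), dtype=np.uint8).astype(int) - 65
    return float(substitution[idx, idx].sum())


def classify_subfamily(query: ProteinRecord, profile: ReferenceProfile,
                       config: PipelineConfig | None = None,
                       substitution: Optional[np.ndarray] = None
                       ) -> ClassificationResult:
    """Best-scoring reference decides subfamily and group.

    Ties broken by higher identity, then by reference name order. A best
    score below ``min_score_fraction`` of the winning reference's
    self-alignment score leaves the query unclassified.
    """
    cfg = config or PipelineConfig()
    if len(profile) == 0:
        raise ValueError("empty reference profile")
    if substitution is None:
        substitution = load_substitution_matrix(cfg.align.matrix)
    best: Optional[tuple] = None
    for ref in profile:  # profile iterates in name order
        aln = global_align(query.sequence, ref.sequence, substitution,
                           cfg.align.gap_open, cfg.align.gap_extend)
        key = (aln.score, aln.identity)
        if best is None or key > best[0]:
            best = (key, ref, aln)
    (_, _), ref, aln = best[0], best[1], best[2]
    threshold = cfg.classify.min_score_fraction * _self_score(ref, substitution)
    if aln.score < threshold:
        return ClassificationResult(subfamily=None, group=None, reference=None,
                                    score=aln.score, identity=aln.identity,
                                    alignment=aln)
    return ClassificationResult(subfamily=ref.subfamily, group=ref.group,
                                reference=ref.name, score=aln.score,
                                identity=aln.identity, alignment=aln)


# ---------------------------------------------------------------------------
# Genome assignment and nomenclature
# ---------------------------------------------------------------------------

def _genome_from_chromosome(chromosome: str) -> Optional[str]:
    """A03 -> A, C07 -> C; scaffolds (Ann/Cnn/unplaced) -> None."""
    if len(chromosome) >= 2 and chromosome[0] in "AC" and chromosome[1:3].isdigit():
        return chromosome[0]
    return None


def assign_genome_and_name(annotations: Sequence[AqpAnnotation],
                           gene_models: dict,
                           progenitor_profiles: Optional[dict] = None,
                           config: PipelineConfig | None = None,
                           substitution: Optional[np.ndarray] = None,
                           sequences: Optional[dict] = None) -> None:
    """Assign genome labels and Bna-style names in place.

    Chromosome-anchored genes take their genome letter from the
    chromosome prefix. Scaffold-only genes are assigned to the progenitor
    (A or C) whose reference profile aligns best, labelled ``A_random`` /
    ``C_random``. Paralog letters a, b, c... are assigned within each
    (genome letter, group) set ordered by chromosome, then start
    coordinate, then gene id.
    """
    cfg = config or PipelineConfig()
    for ann in annotations:
        model = gene_models.get(ann.gene_id)
        if model is not None:
            ann.chromosome = model.chromosome
            ann.start = model.exons[0][0]
        genome = _genome_from_chromosome(ann.chromosome)
        if genome is not None:
            ann.genome = genome
        elif progenitor_profiles and sequences and ann.gene_id in sequences:
            if substitution is None:
                substitution = load_substitution_matrix(cfg.align.matrix)
            best_genome, best_score = None, -np.inf
            for letter in sorted(progenitor_profiles):
                for ref in progenitor_profiles[letter]:
                    aln = global_align(sequences[ann.gene_id].sequence,
                                       ref.sequence, substitution,
                                       cfg.align.gap_open, cfg.align.gap_extend)
                    if aln.score > best_score:
                        best_genome, best_score = letter, aln.score
            ann.genome = f"{best_genome}_random"
        else:
            ann.genome = "unplaced"
            ann.flags.append("no_genome_assignment")

    groups: dict = {}
    for ann in annotations:
        if ann.group is None:
            continue  # unclassified entries keep an empty name
        key = (ann.genome.split("_")[0], ann.group)
        groups.setdefault(key, []).append(ann)
    for (genome, group), members in sorted(groups.items()):
        members.sort(key=lambda a: (a.chromosome or "~", a.start, a.gene_id))
        for i, ann in enumerate(members):
            letter = chr(ord("a") + i) if i < 26 else f"z{i}"
            # group "NIP5" renders as NIP5-1; homolog number fixed at 1
            # unless the reference name carries one (e.g. NIP5-1)
            ann.name = f"Bna{genome}{group}-1{letter}"


# ---------------------------------------------------------------------------
# Substrate-specificity rules
# ---------------------------------------------------------------------------

def load_specificity_rules(path: str | Path | None = None) -> list[dict]:
    """Load the substrate rule table (YAML, packaged default).

    Each rule: ``sf`` is a 4-element list of allowed-residue strings
    ("*" matches anything), optional ``spacing`` pins the NPA-NPA
    spacing, and ``substrates`` lists (substrate, tier) predictions.
    """
    import yaml

    if path is None:
        from importlib import resources
        ref = resources.files("aqpscan.data").joinpath("specificity_rules.yaml")
        with resources.as_file(ref) as p:
            with open(p) as fh:
                data = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    return data["rules"]


def _sf_matches(sf: SelectivityFilter, pattern: Sequence[str]) -> bool:
    for residue, allowed in zip(sf.as_tuple(), pattern):
        if allowed == "*":
            continue
        if residue not in allowed:
            return False
    return True


def predict_specificity(annotation: AqpAnnotation,
                        rules: Optional[list] = None) -> SpecificityPrediction:
    """Rule-table lookup from ar/R filter and NPA-NPA spacing.

    The first matching rule wins. Undefined filter residues ('-') lower
    every predicted tier by one and flag the prediction. Silicic acid is
    never emitted unless the filter is exactly G-S-G-R with spacing 108
    (the Lsi1-type channel signature), regardless of rule content.
    """
    if rules is None:
        rules = load_specificity_rules()
    sf = annotation.selectivity_filter
    if sf is None:
        return SpecificityPrediction(substrates=(), flags=("no_filter",))
    spacing = annotation.motif_pair.spacing if annotation.motif_pair else None
    flags = []
    undefined = "-" in sf.as_tuple()
    if undefined:
        flags.append("undefined_filter_positions")
    chosen: tuple = ()
    for rule in rules:
        if not _sf_matches(sf, rule["sf"]):
            continue
        if "spacing" in rule and spacing != rule["spacing"]:
            continue
        chosen = tuple((s["substrate"], int(s["tier"]) + (1 if undefined else 0))
                       for s in rule["substrates"])
        break
    is_lsi1 = sf.as_tuple() == ("G", "S", "G", "R") and spacing == 108
    if not is_lsi1:
        chosen = tuple((s, t) for s, t in chosen if s != "silicic acid")
    if not chosen:
        flags.append("no_rule_matched")
    return SpecificityPrediction(substrates=chosen, flags=tuple(flags))


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["gene_id", "name", "npa_lb", "npa_le", "h2", "h5", "le1",
                  "le2", "npa_distance", "lc", "froger", "substrates",
                  "tm_count", "length", "identity", "flags"]


def build_feature_table(annotations: Sequence[AqpAnnotation],
                        rules: Optional[list] = None) -> pd.DataFrame:
    """Emit the published table's column order plus appended columns.

    Rows are ordered deterministically by (genome, subfamily, group, name).
    """
    if rules is None and annotations:
        rules = load_specificity_rules()
    rows = []
    for ann in annotations:
        mp, sf = ann.motif_pair, ann.selectivity_filter
        pred = predict_specificity(ann, rules) if sf else None
        rows.append({
            "gene_id": ann.gene_id,
            "name": ann.name,
            "npa_lb": f"{mp.lb.variant}({mp.lb.position})" if mp else "-",
            "npa_le": f"{mp.le.variant}({mp.le.position})" if mp else "-",
            "h2": sf.h2 if sf else "-",
            "h5": sf.h5 if sf else "-",
            "le1": sf.le1 if sf else "-",
            "le2": sf.le2 if sf else "-",
            "npa_distance": mp.spacing if mp else pd.NA,
            "lc": sf.lc if sf else "-",
            "froger": str(ann.froger) if ann.froger else "-",
            "substrates": ";".join(f"{s}:{t}" for s, t in pred.substrates)
            if pred else "",
            "tm_count": ann.tm_count,
            "length": ann.length,
            "identity": round(ann.identity, 3),
            "flags": ";".join(ann.flags),
            "_sort": (ann.genome, ann.subfamily or "~", ann.group or "~",
                      ann.name),
        })
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS + ["_sort"])
    if len(df):
        df = df.sort_values("_sort").drop(columns="_sort").reset_index(drop=True)
    else:
        df = df.drop(columns="_sort")
    return df


# ---------------------------------------------------------------------------
# Neighbor-joining QC tree
# ---------------------------------------------------------------------------

def neighbor_joining_tree(names: Sequence[str],
                          sequences: Optional[Sequence[str]] = None,
                          config: PipelineConfig | None = None,
                          substitution: Optional[np.ndarray] = None,
                          distances: Optional[np.ndarray] = None) -> str:
    """Unrooted NJ tree (Newick) on 1 - fractional-identity distances.

    A quality-control stand-in for a full phylogeny: members of a
    subfamily should form coherent clades. Branch lengths are clipped at
    zero. Requires at least 3 taxa. A precomputed symmetric distance
    matrix may be passed instead of sequences.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if len(names) < 3:
        raise ValueError("neighbor joining requires at least 3 sequences")
    cfg = config or PipelineConfig()
    n = len(names)
    if distances is not None:
        dist = np.asarray(distances, dtype=float)
    else:
        if sequences is None:
            raise ValueError("either sequences or distances required")
        if substitution is None:
            substitution = load_substitution_matrix(cfg.align.matrix)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                aln = global_align(sequences[i], sequences[j], substitution,
                                   cfg.align.gap_open, cfg.align.gap_extend)
                dist[i, j] = dist[j, i] = 1.0 - aln.identity
    tree = nj(DistanceMatrix(dist, ids=list(names)))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()
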