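"""Sequence and gene-model primitives for aquaporin annotation.

Protein records, gene models, and the per-protein computations the
pipeline needs before any family-specific logic: molecular weight,
isoelectric point, hydropathy-based transmembrane (TM) segment calling,
and intron counting from exon structure.

All residue coordinates in this package are 1-based and inclusive, the
convention used throughout plant aquaporin feature tables (a motif
written ``NPA(114)`` starts at residue 114).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: Canonical amino acids plus the ambiguity code X.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = set(AMINO_ACIDS) | {"X"}

# Average residue (i.e. water-subtracted) masses in daltons, ExPASy values.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
AVERAGE_RESIDUE_MASS["X"] = sum(AVERAGE_RESIDUE_MASS.values()) / 20.0
WATER_MASS = 18.01528

# EMBOSS-style pKa constants (iep defaults). Recorded in pI result metadata
# because predicted pI values shift by a few tenths between pKa sets.
PKA_SET_NAME = "EMBOSS"
PKA_POSITIVE = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}

# Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


class FastaFormatError(ValueError):
    """A FASTA record violated the accepted protein alphabet or format."""


class InvalidModelError(ValueError):
    """A gene model violated its structural invariants."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: a text identifier plus an amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("protein record with empty identifier")
        if not self.sequence:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise FastaFormatError(
                f"record {self.id!r} contains illegal residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A gene's placement and exon structure.

    ``exons`` are 1-based inclusive [start, end] intervals on the
    chromosome, sorted by start and non-overlapping.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise InvalidModelError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise InvalidModelError(f"{self.gene_id}: gene model has zero exons")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise InvalidModelError(
                    f"{self.gene_id}: exon [{start},{end}] has start > end"
                )
            if start <= prev_end:
                raise InvalidModelError(
                    f"{self.gene_id}: exons overlap or are unsorted at [{start},{end}]"
                )
            prev_end = end


@dataclass(frozen=True)
class TMSegment:
    """A predicted transmembrane helix: 1-based inclusive residue span."""

    start: int
    end: int
    mean_hydropathy: float

    def __len__(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and trailing ``*`` stop characters stripped.
    Raises :class:`FastaFormatError` naming the offending record on illegal
    residues or duplicate identifiers; an empty file yields an empty list
    with a logged warning.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        if rec.id in seen:
            raise FastaFormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        log.warning("FASTA file %s contained no records", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records to ``path`` in wrapped FASTA."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (exon features grouped by Parent) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    by_parent: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", []) or ["?"]
        for parent in parents:
            entry = by_parent.setdefault(
                parent, {"chrom": exon.seqid, "strand": exon.strand, "exons": []}
            )
            entry["exons"].append((exon.start, exon.end))
    models = []
    for gene_id in sorted(by_parent):
        entry = by_parent[gene_id]
        exons = tuple(sorted(entry["exons"]))
        strand = entry["strand"] if entry["strand"] in {"+", "-"} else "+"
        models.append(GeneModel(gene_id=gene_id, chromosome=entry["chrom"],
                                strand=strand, exons=exons))
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as gene/mRNA/exon features in GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            start = m.exons[0][0]
            end = m.exons[-1][1]
            fh.write(f"{m.chromosome}\taqpscan\tgene\t{start}\t{end}\t.\t"
                     f"{m.strand}\t.\tID={m.gene_id}\n")
            mrna = f"{m.gene_id}.1"
            fh.write(f"{m.chromosome}\taqpscan\tmRNA\t{start}\t{end}\t.\t"
                     f"{m.strand}\t.\tID={mrna};Parent={m.gene_id}\n")
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(f"{m.chromosome}\taqpscan\texon\t{s}\t{e}\t.\t"
                         f"{m.strand}\t.\tID={mrna}.exon{i};Parent={mrna}\n")


def count_introns(model: GeneModel) -> int:
    """Number of introns = number of exons minus one."""
    return len(model.exons) - 1


# ---------------------------------------------------------------------------
# Physicochemical properties
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MassResult:
    kda: float
    approximate: bool  # True when X residues contributed an averaged mass


def compute_mw(p: ProteinRecord) -> MassResult:
    """Average molecular mass in kilodaltons (residue masses + one water).

    X residues contribute the mean of the 20 canonical residue masses and
    flag the result as approximate.
    """
    total = sum(AVERAGE_RESIDUE_MASS[aa] for aa in p.sequence) + WATER_MASS
    return MassResult(kda=total / 1000.0, approximate="X" in p.sequence)


def net_charge(sequence: str, ph: float) -> float:
    """Net charge of a protein at a given pH (Henderson-Hasselbalch).

    Termini always ionize; side chains per the EMBOSS pKa set.
    """
    counts: dict[str, int] = {}
    for aa in sequence:
        counts[aa] = counts.get(aa, 0) + 1
    charge = 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE["Cterm"] - ph))
    for aa, pka in PKA_POSITIVE.items():
        if aa in counts:
            charge += counts[aa] / (1.0 + 10 ** (ph - pka))
    for aa, pka in PKA_NEGATIVE.items():
        if aa in counts:
            charge -= counts[aa] / (1.0 + 10 ** (pka - ph))
    return charge


@dataclass(frozen=True)
class PiResult:
    pi: float
    pka_set: str = PKA_SET_NAME


def compute_pi(p: ProteinRecord, tol: float = 0.01, max_iter: int = 60) -> PiResult:
    """Isoelectric point by bisection on the monotone net-charge function.

    Terminates when the bracket is narrower than ``tol`` (at most
    ``max_iter`` bisections); |net charge| at the returned pH is <= 0.01
    for any sequence whose charge actually crosses zero.
    """
    lo, hi = 0.0, 14.0
    for _ in range(max_iter):
        if hi - lo < tol / 2:
            break
        mid = (lo + hi) / 2.0
        if net_charge(p.sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    return PiResult(pi=round((lo + hi) / 2.0, 3))


# ---------------------------------------------------------------------------
# Transmembrane segment prediction (Kyte-Doolittle sliding window)
# ---------------------------------------------------------------------------

def hydropathy_profile(sequence: str, window: int = 19) -> list[float | None]:
    """Centered Kyte-Doolittle window means, one per residue (1-based order).

    Windows are truncated at the sequence termini (mean over the residues
    that fit), so N- and C-terminal helices are scored too. X residues
    are excluded from the window mean (mean over defined residues only);
    an all-X window gives None.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    half = window // 2
    n = len(sequence)
    scores: list[float | None] = [None] * n
    for center in range(n):
        lo = max(0, center - half)
        hi = min(n, center + half + 1)
        total, count = 0.0, 0
        for aa in sequence[lo:hi]:
            if aa in KYTE_DOOLITTLE:
                total += KYTE_DOOLITTLE[aa]
                count += 1
        scores[center] = total / count if count else None
    return scores


def predict_tm_segments(p: ProteinRecord, window: int = 19,
                        threshold: float = 1.6, min_length: int = 15,
                        merge_gap: int = 3) -> list[TMSegment]:
    """Call TM helices as maximal runs of residues with window mean >= threshold.

    Runs separated by fewer than ``merge_gap`` residues are merged; runs
    shorter than ``min_length`` are discarded. A sequence shorter than the
    window yields an empty list with a warning.
    """
    if len(p.sequence) < window:
        warnings.warn(f"sequence {p.id} shorter than hydropathy window; "
                      "no TM prediction", stacklevel=2)
        return []
    scores = hydropathy_profile(p.sequence, window)
    runs: list[list[int]] = []
    for i, s in enumerate(scores):
        if s is not None and s >= threshold:
            if runs and i == runs[-1][-1] + 1:
                runs[-1].append(i)
            else:
                runs.append([i])
    # merge runs separated by < merge_gap residues
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][-1] - 1 < merge_gap:
            merged[-1].extend(range(merged[-1][-1] + 1, run[0]))
            merged[-1].extend(run)
        else:
            merged.append(run)
    segments = []
    for run in merged:
        if len(run) < min_length:
            continue
        vals = [scores[i] for i in run if scores[i] is not None]
        segments.append(TMSegment(start=run[0] + 1, end=run[-1] + 1,
                                  mean_hydropathy=sum(vals) / len(vals)))
    return segments


def property_table(records: Sequence[ProteinRecord], window: int = 19,
                   threshold: float = 1.6):
    """Per-protein property table (length, mw, pI, TM count) as a DataFrame."""
    import pandas as pd

    rows = []
    for r in records:
        mw = compute_mw(r)
        rows.append({
            "id": r.id,
            "length": len(r),
            "mw_kda": round(mw.kda, 3),
            "mw_approximate": mw.approximate,
            "pi": compute_pi(r).pi,
            "tm_count": len(predict_tm_segments(r, window, threshold)),
        })
    return pd.DataFrame(rows, columns=["id", "length", "mw_kda",
                                       "mw_approximate", "pi", "tm_count"])
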