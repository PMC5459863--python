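"""NPA-motif detection and alignment-guided feature extraction.

Aquaporin pores are built around two short Asn-Pro-x motifs ("NPA
motifs") in loops B and E; the residue count between them (the NPA-NPA
spacing) and the four aromatic/arginine (ar/R) selectivity-filter
positions H2, H5, LE1, LE2 - plus a fifth contributing loop-C residue
(Lc) and the five Froger positions - together predict what a channel
transports. This module finds the motifs, picks the loop-B/loop-E pair,
and transfers annotated feature positions from a reference protein onto
a query via deterministic affine-gap global alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .seq_core import ProteinRecord

#: Third-position letters accepted in an NPA-type motif.
DEFAULT_MOTIF_VARIANTS = "ASVLCTG"

#: Default spacing window (residues between motifs) for loop-B/loop-E pairing.
DEFAULT_SPACING_WINDOW = (85, 150)

GAP = "-"


class SpacingOrderError(ValueError):
    """Loop-E motif does not start at least 3 residues after loop B."""


@dataclass(frozen=True)
class NpaMotif:
    """One N-P-x motif occurrence; ``position`` is the 1-based index of N."""

    variant: str
    position: int

    def __post_init__(self) -> None:
        if len(self.variant) != 3 or self.variant[0] != "N" or self.variant[1] != "P":
            raise ValueError(f"not an NPA-type variant: {self.variant!r}")


@dataclass(frozen=True)
class MotifPair:
    """The selected loop-B / loop-E motif pair and their spacing."""

    lb: NpaMotif
    le: NpaMotif
    spacing: int

    def __post_init__(self) -> None:
        if self.spacing != npa_spacing(self.lb.position, self.le.position):
            raise ValueError("spacing inconsistent with motif positions")


@dataclass(frozen=True)
class SelectivityFilter:
    """ar/R selectivity filter residues; '-' marks an undefined position."""

    h2: str
    h5: str
    le1: str
    le2: str
    lc: str = GAP

    def as_tuple(self) -> tuple[str, str, str, str]:
        return (self.h2, self.h5, self.le1, self.le2)

    def __str__(self) -> str:
        return "".join(self.as_tuple())


@dataclass(frozen=True)
class FrogerResidues:
    """The five Froger positions P1-P5 ('-' where undefined)."""

    residues: tuple[str, str, str, str, str]

    def __str__(self) -> str:
        return "".join(self.residues)


FEATURE_KEYS = ("lb", "le", "h2", "h5", "le1", "le2", "lc",
                "p1", "p2", "p3", "p4", "p5")


@dataclass(frozen=True)
class ReferenceEntry:
    """An annotated reference aquaporin anchoring extraction/classification.

    ``positions`` maps feature keys (lb, le, h2, h5, le1, le2, lc, p1-p5)
    to 1-based residue indices in ``sequence``.
    """

    name: str
    subfamily: str
    group: str
    sequence: str
    positions: dict

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for key, pos in self.positions.items():
            if not 1 <= pos <= n:
                raise ValueError(f"{self.name}: {key} position {pos} outside sequence")
        for key in ("lb", "le"):
            pos = self.positions.get(key)
            if pos is not None:
                triplet = self.sequence[pos - 1: pos + 2]
                if not (len(triplet) == 3 and triplet[0] == "N" and triplet[1] == "P"):
                    raise ValueError(
                        f"{self.name}: {key} position {pos} does not carry an "
                        f"N-P-x triplet (found {triplet!r})")


@dataclass
class ReferenceProfile:
    """A collection of annotated references, ordered by name."""

    entries: list

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e.name)
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("duplicate reference names in profile")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, name: str) -> ReferenceEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Motif scanning and pairing
# ---------------------------------------------------------------------------

def scan_npa_candidates(p: ProteinRecord,
                        variants: str = DEFAULT_MOTIF_VARIANTS) -> list[NpaMotif]:
    """All N-P-[variants] occurrences in position order (overlaps included)."""
    seq = p.sequence
    hits = []
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 1] == "P" and seq[i + 2] in variants:
            hits.append(NpaMotif(variant=seq[i: i + 3], position=i + 1))
    return hits


def npa_spacing(lb_position: int, le_position: int) -> int:
    """Residues between two NPA-type motifs: le_pos - lb_pos - 3.

    This is the convention under which every complete row of the packaged
    B. napus feature table satisfies its printed distance column.
    """
    if le_position <= lb_position + 2:
        raise SpacingOrderError(
            f"loop-E motif at {le_position} does not follow loop-B motif at "
            f"{lb_position}")
    return le_position - lb_position - 3


def select_motif_pair(motifs: Sequence[NpaMotif],
                      spacing_window: tuple[int, int] = DEFAULT_SPACING_WINDOW,
                      expected_spacing: Optional[int] = None
                      ) -> Optional[MotifPair]:
    """Pick the loop-B/loop-E pair among candidate motifs.

    Considers all ordered pairs whose spacing falls inside
    ``spacing_window``. With an ``expected_spacing`` (e.g. the subfamily-
    typical value) the pair closest to it wins, ties broken by leftmost
    loop-B; otherwise the pair with leftmost loop-B wins, ties broken by
    smaller spacing. Returns None when no pair qualifies - the caller
    treats that as a needs-review condition, not an error.
    """
    lo, hi = spacing_window
    candidates = []
    for i, lb in enumerate(motifs):
        for le in motifs[i + 1:]:
            if le.position <= lb.position + 2:
                continue
            spacing = npa_spacing(lb.position, le.position)
            if lo <= spacing <= hi:
                candidates.append(MotifPair(lb=lb, le=le, spacing=spacing))
    if not candidates:
        return None
    if expected_spacing is not None:
        key = lambda mp: (abs(mp.spacing - expected_spacing), mp.lb.position)
    else:
        key = lambda mp: (mp.lb.position, mp.spacing)
    return min(candidates, key=key)


# ---------------------------------------------------------------------------
# Global alignment (Needleman-Wunsch with Gotoh affine gaps)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentResult:
    """A global alignment with per-column reference->query position map.

    ``ref_to_query[i]`` (1-based reference position i) gives the 1-based
    query position aligned to reference residue i, or 0 when that residue
    aligns to a gap.
    """

    aligned_query: str
    aligned_ref: str
    score: float
    ref_to_query: tuple

    @property
    def identity(self) -> float:
        """Fraction of alignment columns with identical residues."""
        same = sum(1 for a, b in zip(self.aligned_query, self.aligned_ref)
                   if a == b and a != GAP)
        return same / len(self.aligned_query)


def load_substitution_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """A 26x26 integer substitution table indexed by ord(letter) - 65."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load(name)
    table = np.full((26, 26), -4, dtype=np.int64)
    for a in mat.alphabet:
        for b in mat.alphabet:
            if a.isalpha() and b.isalpha():
                table[ord(a) - 65, ord(b) - 65] = int(mat[a, b])
    return table


def simple_substitution_matrix(match: int, mismatch: int) -> np.ndarray:
    table = np.full((26, 26), mismatch, dtype=np.int64)
    np.fill_diagonal(table, match)
    return table


def _gotoh_python(q, r, sub, go, ge):
    """Pure-Python Gotoh fill + traceback (fallback when numba is absent)."""
    n, m = len(q), len(r)
    NEG = -10 ** 9
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in reference (up)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (left)
    PM = [[0] * (m + 1) for _ in range(n + 1)]
    PX = [[0] * (m + 1) for _ in range(n + 1)]
    PY = [[0] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = -(go + (i - 1) * ge)
        PX[i][0] = 1
    for j in range(1, m + 1):
        Y[0][j] = -(go + (j - 1) * ge)
        PY[0][j] = 2
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            s = sub[qi][r[j - 1]]
            # tie preference: diagonal(M)=0, up(X)=1, left(Y)=2
            best, arg = M[i - 1][j - 1], 0
            if X[i - 1][j - 1] > best:
                best, arg = X[i - 1][j - 1], 1
            if Y[i - 1][j - 1] > best:
                best, arg = Y[i - 1][j - 1], 2
            M[i][j] = best + s
            PM[i][j] = arg
            best, arg = M[i - 1][j] - go, 0
            if X[i - 1][j] - ge > best:
                best, arg = X[i - 1][j] - ge, 1
            if Y[i - 1][j] - go > best:
                best, arg = Y[i - 1][j] - go, 2
            X[i][j] = best
            PX[i][j] = arg
            best, arg = M[i][j - 1] - go, 0
            if X[i][j - 1] - go > best:
                best, arg = X[i][j - 1] - go, 1
            if Y[i][j - 1] - ge > best:
                best, arg = Y[i][j - 1] - ge, 2
            Y[i][j] = best
            PY[i][j] = arg
    best, state = M[n][m], 0
    if X[n][m] > best:
        best, state = X[n][m], 1
    if Y[n][m] > best:
        best, state = Y[n][m], 2
    moves = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            prev = PM[i][j]
            moves.append(0)
            i, j = i - 1, j - 1
        elif state == 1:
            prev = PX[i][j]
            moves.append(1)
            i -= 1
        else:
            prev = PY[i][j]
            moves.append(2)
            j -= 1
        state = prev
    moves.reverse()
    return best, moves


try:  # optional acceleration; identical semantics to the fallback above
    from numba import njit

    @njit(cache=False)
    def _gotoh_numba(q, r, sub, go, ge):  # pragma: no cover - numba path
        n, m = q.shape[0], r.shape[0]
        NEG = -(10 ** 9)
        M = np.full((n + 1, m + 1), NEG, dtype=np.int64)
        X = np.full((n + 1, m + 1), NEG, dtype=np.int64)
        Y = np.full((n + 1, m + 1), NEG, dtype=np.int64)
        PM = np.zeros((n + 1, m + 1), dtype=np.int8)
        PX = np.zeros((n + 1, m + 1), dtype=np.int8)
        PY = np.zeros((n + 1, m + 1), dtype=np.int8)
        M[0, 0] = 0
        for i in range(1, n + 1):
            X[i, 0] = -(go + (i - 1) * ge)
            PX[i, 0] = 1
        for j in range(1, m + 1):
            Y[0, j] = -(go + (j - 1) * ge)
            PY[0, j] = 2
        for i in range(1, n + 1):
            qi = q[i - 1]
            for j in range(1, m + 1):
                s = sub[qi, r[j - 1]]
                best, arg = M[i - 1, j - 1], 0
                if X[i - 1, j - 1] > best:
                    best, arg = X[i - 1, j - 1], 1
                if Y[i - 1, j - 1] > best:
                    best, arg = Y[i - 1, j - 1], 2
                M[i, j] = best + s
                PM[i, j] = arg
                best, arg = M[i - 1, j] - go, 0
                if X[i - 1, j] - ge > best:
                    best, arg = X[i - 1, j] - ge, 1
                if Y[i - 1, j] - go > best:
                    best, arg = Y[i - 1, j] - go, 2
                X[i, j] = best
                PX[i, j] = arg
                best, arg = M[i, j - 1] - go, 0
                if X[i, j - 1] - go > best:
                    best, arg = X[i, j - 1] - go, 1
                if Y[i, j - 1] - ge > best:
                    best, arg = Y[i, j - 1] - ge, 2
                Y[i, j] = best
                PY[i, j] = arg
        best, state = M[n, m], 0
        if X[n, m] > best:
            best, state = X[n, m], 1
        if Y[n, m] > best:
            best, state = Y[n, m], 2
        moves = np.empty(n + m, dtype=np.int8)
        k = 0
        i, j = n, m
        while i > 0 or j > 0:
            if state == 0:
                prev = PM[i, j]
                moves[k] = 0
                i -= 1
                j -= 1
            elif state == 1:
                prev = PX[i, j]
                moves[k] = 1
                i -= 1
            else:
                prev = PY[i, j]
                moves[k] = 2
                j -= 1
            state = prev
            k += 1
        return best, moves[:k][::-1].copy()

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def global_align(query: str, reference: str,
                 substitution: Optional[np.ndarray] = None,
                 gap_open: int = 10, gap_extend: int = 1) -> AlignmentResult:
    """Optimal global alignment under affine gaps.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend`` (positive
    costs, negated internally). Traceback is deterministic: on score
    ties, diagonal is preferred over a gap in the reference ("up"), which
    is preferred over a gap in the query ("left").
    """
    if not query or not reference:
        raise ValueError("global_align requires non-empty sequences")
    if substitution is None:
        substitution = load_substitution_matrix("BLOSUM62")
    if _HAVE_NUMBA:
        q = np.frombuffer(query.encode(), dtype=np.uint8).astype(np.int64) - 65
        r = np.frombuffer(reference.encode(), dtype=np.uint8).astype(np.int64) - 65
        score, moves = _gotoh_numba(q, r, substitution, gap_open, gap_extend)
        moves = list(moves)
    else:
        sub = {i: {j: int(substitution[i, j]) for j in range(26)}
               for i in range(26)}
        q = [ord(c) - 65 for c in query]
        r = [ord(c) - 65 for c in reference]
        score, moves = _gotoh_python(q, r, sub, gap_open, gap_extend)

    aq, ar = [], []
    ref_to_query = [0] * len(reference)
    i = j = 0  # consumed so far
    for mv in moves:
        if mv == 0:
            aq.append(query[i])
            ar.append(reference[j])
            ref_to_query[j] = i + 1
            i += 1
            j += 1
        elif mv == 1:
            aq.append(query[i])
            ar.append(GAP)
            i += 1
        else:
            aq.append(GAP)
            ar.append(reference[j])
            j += 1
    return AlignmentResult(aligned_query="".join(aq), aligned_ref="".join(ar),
                           score=float(score), ref_to_query=tuple(ref_to_query))


def map_positions(a: AlignmentResult, ref_positions: Sequence[int]) -> list:
    """Query positions aligned to the given 1-based reference positions.

    Returns, per reference position, the 1-based query index or '-' when
    the reference residue aligns to a gap.
    """
    out = []
    for pos in ref_positions:
        if not 1 <= pos <= len(a.ref_to_query):
            raise IndexError(f"reference position {pos} out of range")
        q = a.ref_to_query[pos - 1]
        out.append(q if q else GAP)
    return out


# ---------------------------------------------------------------------------
# Feature extraction against a reference
# ---------------------------------------------------------------------------

def _residue_at(p: ProteinRecord, mapped) -> str:
    return GAP if mapped == GAP else p.sequence[mapped - 1]


def extract_selectivity_filter(p: ProteinRecord, ref: ReferenceEntry,
                               a: AlignmentResult) -> SelectivityFilter:
    """ar/R filter residues of ``p`` at the positions mapped from ``ref``."""
    keys = ["h2", "h5", "le1", "le2"]
    mapped = map_positions(a, [ref.positions[k] for k in keys])
    residues = dict(zip(keys, (_residue_at(p, m) for m in mapped)))
    lc = GAP
    if "lc" in ref.positions:
        lc = _residue_at(p, map_positions(a, [ref.positions["lc"]])[0])
    return SelectivityFilter(lc=lc, **residues)


def extract_froger_residues(p: ProteinRecord, ref: ReferenceEntry,
                            a: AlignmentResult) -> FrogerResidues:
    """Froger P1-P5 residues of ``p`` at the positions mapped from ``ref``."""
    keys = ["p1", "p2", "p3", "p4", "p5"]
    mapped = map_positions(a, [ref.positions[k] for k in keys])
    return FrogerResidues(residues=tuple(_residue_at(p, m) for m in mapped))


# ---------------------------------------------------------------------------
# Reference profile I/O (TSV)
# ---------------------------------------------------------------------------

_PROFILE_COLUMNS = ["name", "subfamily", "group", "sequence",
                    "lb_pos", "le_pos", "h2_pos", "h5_pos", "le1_pos",
                    "le2_pos", "lc_pos", "p1_pos", "p2_pos", "p3_pos",
                    "p4_pos", "p5_pos"]


def write_reference_profile(profile: ReferenceProfile, path: str | Path) -> None:
    import pandas as pd

    rows = []
    for e in profile:
        row = {"name": e.name, "subfamily": e.subfamily, "group": e.group,
               "sequence": e.sequence}
        for key in FEATURE_KEYS:
            row[f"{key}_pos"] = e.positions.get(key, 0)
        rows.append(row)
    pd.DataFrame(rows, columns=_PROFILE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_reference_profile(path: str | Path) -> ReferenceProfile:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    entries = []
    for _, row in df.iterrows():
        positions = {}
        for key in FEATURE_KEYS:
            pos = int(row[f"{key}_pos"])
            if pos > 0:
                positions[key] = pos
        entries.append(ReferenceEntry(
            name=row["name"], subfamily=row["subfamily"], group=row["group"],
            sequence=row["sequence"], positions=positions))
    return ReferenceProfile(entries=entries)
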