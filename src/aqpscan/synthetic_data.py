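"""Synthetic aquaporin cohorts and expression matrices with planted truth.

Every pipeline input has a generator here: AQP-like proteins built from
per-group templates (planted NPA motifs, spacings, selectivity filters,
Froger residues and six transmembrane blocks) plus decoys; GFF3 gene
models with group-typical intron counts; and RPKM/count matrices with
planted differential genes, co-expressed modules, genome-dosage slopes
and a seed-development trajectory. Each generator returns a
machine-readable truth table so tests can score recovery.

Group templates are parameterized from the published canola feature
table: motif variants, typical loop-B positions, spacings and ar/R
filters per group (e.g. NIP5: NPS/NPV, spacing 108, A-I-G-R). The Lc
letter is published for TIPs only (TIP1/3 F, TIP2/4 H, TIP5 Y); other
subfamilies use F as a template choice. Froger sets are
literature-typical per subfamily. Background residues are uniform over
the 20 amino acids; TM blocks are runs of {I,L,V,F,A} of length 21,
which guarantees detection at the default hydropathy settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .feature_scan import ReferenceEntry, ReferenceProfile
from .seq_core import GeneModel, ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
#: residues drawn inside TM blocks; strongly hydrophobic so a
#: 21-residue block always clears the hydropathy threshold with margin
TM_RESIDUES = "ILV"
#: residues used in the short loops between helices, so adjacent TM
#: blocks never fuse into one hydropathy run
LOOP_RESIDUES = "STGNQDE"
TM_LEN = 21

#: group -> (subfamily, lb_variant, le_variant, lb_pos, spacing,
#:           (h2, h5, le1, le2), lc, intron_count)
GROUP_TEMPLATES = {
    "PIP1": ("PIP", "NPA", "NPA", 114, 118, ("F", "H", "T", "R"), "F", 3),
    "PIP2": ("PIP", "NPA", "NPA", 105, 118, ("F", "H", "T", "R"), "F", 3),
    "TIP1": ("TIP", "NPA", "NPA", 86, 111, ("H", "I", "A", "V"), "F", 2),
    "TIP2": ("TIP", "NPA", "NPA", 83, 111, ("H", "I", "G", "R"), "H", 2),
    "TIP3": ("TIP", "NPA", "NPA", 93, 111, ("H", "I", "A", "R"), "F", 2),
    "TIP4": ("TIP", "NPA", "NPA", 79, 111, ("A", "I", "A", "R"), "H", 2),
    "TIP5": ("TIP", "NPA", "NPA", 87, 110, ("N", "V", "G", "C"), "Y", 2),
    "NIP1": ("NIP", "NPA", "NPG", 114, 116, ("W", "V", "A", "R"), "F", 4),
    "NIP2": ("NIP", "NPA", "NPA", 104, 116, ("V", "V", "A", "R"), "F", 4),
    "NIP3": ("NIP", "NPA", "NPA", 99, 116, ("W", "I", "A", "R"), "F", 4),
    "NIP4": ("NIP", "NPA", "NPA", 102, 109, ("W", "V", "A", "R"), "F", 4),
    "NIP5": ("NIP", "NPS", "NPV", 134, 108, ("A", "I", "G", "R"), "F", 4),
    "NIP6": ("NIP", "NPA", "NPV", 139, 108, ("A", "I", "A", "R"), "F", 4),
    "NIP7": ("NIP", "NPS", "NPA", 104, 109, ("A", "V", "G", "R"), "F", 4),
    "SIP1": ("SIP", "NPT", "NPA", 69, 112, ("T", "V", "P", "I"), "F", 11),
    "SIP2": ("SIP", "NPL", "NPA", 69, 108, ("S", "H", "G", "A"), "F", 2),
}

FROGER_BY_SUBFAMILY = {
    "PIP": ("Q", "S", "A", "F", "W"),
    "TIP": ("T", "S", "A", "Y", "W"),
    "NIP": ("F", "S", "A", "Y", "L"),
    "SIP": ("V", "A", "A", "Y", "W"),
}

CHROMOSOMES = tuple(f"A{i:02d}" for i in range(1, 11)) + \
    tuple(f"C{i:02d}" for i in range(1, 10)) + ("Ann", "Cnn")


@dataclass
class SequenceSimSpec:
    """Conditions for the protein-cohort generator."""

    groups: dict = field(default_factory=lambda: {g: 3 for g in GROUP_TEMPLATES})
    mutation_rate: float = 0.05
    n_fragment_decoys: int = 2
    n_single_motif_decoys: int = 2
    n_non_aqp_decoys: int = 2

    def validate(self) -> None:
        problems = []
        if not 0 <= self.mutation_rate <= 0.2:
            problems.append("mutation_rate must be in [0, 0.2]")
        for g in self.groups:
            if g not in GROUP_TEMPLATES:
                problems.append(f"unknown group {g!r}")
        if any(n < 0 for n in self.groups.values()):
            problems.append("group counts must be non-negative")
        if problems:
            raise ValueError("; ".join(problems))


def _template_layout(lb_pos: int, spacing: int) -> dict:
    """Feature and TM-block positions (1-based) for one group template."""
    le_pos = lb_pos + 3 + spacing
    return {
        "lb": lb_pos, "le": le_pos,
        "h2": lb_pos - 20, "h5": le_pos - 15,
        "le1": le_pos + 5, "le2": le_pos + 7,
        "lc": lb_pos + 34,
        "p1": le_pos - 33, "p2": le_pos + 34, "p3": le_pos + 36,
        "p4": le_pos + 38, "p5": le_pos + 40,
        "tm_blocks": ((lb_pos - 68, lb_pos - 48), (lb_pos - 35, lb_pos - 15),
                      (lb_pos + 8, lb_pos + 28), (lb_pos + 44, lb_pos + 64),
                      (le_pos - 28, le_pos - 8), (le_pos + 11, le_pos + 31)),
        "length": le_pos + 45,
    }


def _protected_positions(layout: dict) -> set:
    protected = set()
    for key in ("lb", "le"):
        protected.update(range(layout[key], layout[key] + 3))
    for key in ("h2", "h5", "le1", "le2", "lc", "p1", "p2", "p3", "p4", "p5"):
        protected.add(layout[key])
    return protected


def _build_template(group: str, rng: np.random.Generator) -> tuple[str, dict]:
    subfamily, lbv, lev, lb_pos, spacing, sf, lc, _ = GROUP_TEMPLATES[group]
    layout = _template_layout(lb_pos, spacing)
    n = layout["length"]
    seq = list(rng.choice(list(AA), size=n))
    for start, end in layout["tm_blocks"]:
        for i in range(start, end + 1):
            seq[i - 1] = rng.choice(list(TM_RESIDUES))
    # hydrophilic inter-helix loops: the gaps between consecutive TM
    # blocks are short, and random hydrophobic loop residues would let
    # the sliding window bridge two helices
    blocks = layout["tm_blocks"]
    for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
        for i in range(e1 + 1, s2):
            seq[i - 1] = rng.choice(list(LOOP_RESIDUES))
    seq[layout["lb"] - 1: layout["lb"] + 2] = list(lbv)
    seq[layout["le"] - 1: layout["le"] + 2] = list(lev)
    for key, residue in zip(("h2", "h5", "le1", "le2"), sf):
        seq[layout[key] - 1] = residue
    seq[layout["lc"] - 1] = lc
    for key, residue in zip(("p1", "p2", "p3", "p4", "p5"),
                            FROGER_BY_SUBFAMILY[subfamily]):
        seq[layout[key] - 1] = residue
    # scrub accidental NPA-type motifs outside the planted pair so the
    # loop-B/loop-E selection is unambiguous on clean templates
    protected = _protected_positions(layout)
    for i in range(n - 2):
        if (i + 1) not in protected and seq[i] == "N" and seq[i + 1] == "P":
            if (i + 2) not in protected:
                seq[i + 1] = "Q"
    return "".join(seq), layout


def simulate_reference_profile(spec: Optional[SequenceSimSpec] = None,
                               seed: int = 0) -> ReferenceProfile:
    """One clean, fully annotated reference per requested group."""
    spec = spec or SequenceSimSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    entries = []
    for group in sorted(spec.groups):
        subfamily = GROUP_TEMPLATES[group][0]
        sequence, layout = _build_template(group, rng)
        positions = {k: layout[k] for k in ("lb", "le", "h2", "h5", "le1",
                                            "le2", "lc", "p1", "p2", "p3",
                                            "p4", "p5")}
        entries.append(ReferenceEntry(name=f"Ref{group}", subfamily=subfamily,
                                      group=group, sequence=sequence,
                                      positions=positions))
    return ReferenceProfile(entries=entries)


#: substitutions tolerated inside a membrane helix (conservative set)
TM_TOLERATED = "ILVFAM"


def _mutate(sequence: str, protected: set, rate: float,
            rng: np.random.Generator, tm_blocks: tuple = ()) -> str:
    """Point-mutate outside protected columns.

    Positions inside TM blocks mutate conservatively (within the
    hydrophobic set), mirroring the substitution constraint of a
    membrane-spanning helix; elsewhere any other residue is allowed.
    """
    in_tm = set()
    for start, end in tm_blocks:
        in_tm.update(range(start, end + 1))
    seq = list(sequence)
    for i in range(len(seq)):
        if (i + 1) in protected:
            continue
        if rng.random() < rate:
            pool = TM_TOLERATED if (i + 1) in in_tm else AA
            choices = [a for a in pool if a != seq[i]]
            seq[i] = choices[rng.integers(len(choices))]
    return "".join(seq)


def simulate_aqp_sequences(spec: Optional[SequenceSimSpec] = None,
                           profile: Optional[ReferenceProfile] = None,
                           seed: int = 0
                           ) -> tuple[list, list, pd.DataFrame]:
    """Mutated per-group AQPs plus decoys, gene models and a truth table.

    Truth columns: id, kind (aqp | fragment | single_motif | non_aqp),
    subfamily, group, lb/le variants and positions, spacing, sf residues,
    lc, froger, intron_count, chromosome.
    """
    spec = spec or SequenceSimSpec()
    spec.validate()
    if profile is None:
        profile = simulate_reference_profile(spec, seed=seed)
    rng = np.random.default_rng(seed + 1)
    records, models, truth_rows = [], [], []
    gene_index = 0
    for group in sorted(spec.groups):
        subfamily, lbv, lev, lb_pos, spacing, sf, lc, introns = GROUP_TEMPLATES[group]
        ref = profile.get(f"Ref{group}")
        layout = _template_layout(lb_pos, spacing)
        protected = _protected_positions(layout)
        for k in range(spec.groups[group]):
            gene_index += 1
            gid = f"syn{gene_index:04d}_{group}"
            seq = _mutate(ref.sequence, protected, spec.mutation_rate, rng,
                          tm_blocks=layout["tm_blocks"])
            records.append(ProteinRecord(id=gid, sequence=seq))
            chrom = CHROMOSOMES[int(rng.integers(len(CHROMOSOMES)))]
            start = int(rng.integers(10_000, 30_000_000))
            exons = _exon_layout(start, len(seq) * 3, introns + 1, rng)
            models.append(GeneModel(gene_id=gid, chromosome=chrom, strand="+",
                                    exons=exons))
            truth_rows.append({
                "id": gid, "kind": "aqp", "subfamily": subfamily,
                "group": group, "lb_variant": lbv, "lb_pos": layout["lb"],
                "le_variant": lev, "le_pos": layout["le"], "spacing": spacing,
                "h2": sf[0], "h5": sf[1], "le1": sf[2], "le2": sf[3],
                "lc": lc,
                "froger": "".join(FROGER_BY_SUBFAMILY[subfamily]),
                "intron_count": introns, "chromosome": chrom,
            })

    decoys = []
    pip_ref = profile.entries[0]
    for k in range(spec.n_fragment_decoys):
        gene_index += 1
        decoys.append((f"syn{gene_index:04d}_fragment", "fragment",
                       pip_ref.sequence[:120]))
    for k in range(spec.n_single_motif_decoys):
        gene_index += 1
        seq = list(pip_ref.sequence)
        le = pip_ref.positions["le"]
        seq[le - 1: le + 2] = "QQQ"  # destroy the loop-E motif
        decoys.append((f"syn{gene_index:04d}_single", "single_motif",
                       "".join(seq)))
    hydrophilic = "DEKRSTNQGH"
    for k in range(spec.n_non_aqp_decoys):
        gene_index += 1
        seq = "".join(rng.choice(list(hydrophilic), size=300))
        decoys.append((f"syn{gene_index:04d}_nonaqp", "non_aqp", seq))
    for gid, kind, seq in decoys:
        records.append(ProteinRecord(id=gid, sequence=seq))
        truth_rows.append({"id": gid, "kind": kind, "subfamily": "",
                           "group": "", "lb_variant": "", "lb_pos": 0,
                           "le_variant": "", "le_pos": 0, "spacing": 0,
                           "h2": "", "h5": "", "le1": "", "le2": "", "lc": "",
                           "froger": "", "intron_count": 0, "chromosome": ""})
    truth = pd.DataFrame(truth_rows)
    return records, models, truth


def _exon_layout(start: int, cds_len: int, n_exons: int,
                 rng: np.random.Generator) -> tuple:
    """Split a coding length into exons with random intron gaps."""
    cuts = sorted(rng.choice(np.arange(1, cds_len), size=n_exons - 1,
                             replace=False)) if n_exons > 1 else []
    bounds = [0] + [int(c) for c in cuts] + [cds_len]
    exons = []
    pos = start
    for i in range(n_exons):
        exon_len = bounds[i + 1] - bounds[i]
        exons.append((pos, pos + exon_len - 1))
        pos += exon_len + int(rng.integers(80, 500))  # intron
    return tuple(exons)


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

#: genotype -> A-genome fraction in the allopolyploid dosage series
A_FRACTION = {"AA": 1.0, "AC": 0.5, "AAC": 0.66, "CCA": 0.33, "CCAA": 0.5}


@dataclass
class ExpressionSimSpec:
    """Conditions for the expression-matrix generator.

    ``design`` picks the emulated experiment: "dosage" (6 genotypes x 2
    replicates), "seed" (4 timepoints x 3 replicates) or "drought"
    (2 tissues x control/drought x 3 replicates).
    """

    n_genes: int = 120          # the aquaporin panel
    n_background: int = 600     # rest-of-transcriptome genes in each library
    design: str = "dosage"
    replicates: int = 2
    dependent_fraction: float = 0.30
    dosage_slope: float = 1.0   # exponent: mean scales as a_fraction**slope
    deg_fraction: float = 0.15
    deg_log2fc: float = 3.0
    module_sizes: tuple = (10, 8)
    module_r: float = 0.95
    silent_fraction: float = 0.10
    sigma: float = 0.2
    base_log_mean: float = np.log(50.0)
    base_log_sd: float = 1.0
    library_size: int = 20_000_000
    count_noise: bool = True  # False: deterministic rounded count means

    def validate(self) -> None:
        problems = []
        for name, frac in (("dependent_fraction", self.dependent_fraction),
                           ("deg_fraction", self.deg_fraction)):
            if not 0 <= frac <= 1:
                problems.append(f"{name} must be in [0, 1]")
        if self.design not in {"dosage", "seed", "drought"}:
            problems.append(f"unknown design {self.design!r}")
        if self.sigma < 0:
            problems.append("sigma must be >= 0")
        if problems:
            raise ValueError("; ".join(problems))


def _make_design(spec: ExpressionSimSpec) -> pd.DataFrame:
    rows = []
    if spec.design == "dosage":
        for genotype in ("AA", "AC", "AAC", "CCA", "CCAA"):
            for rep in range(1, spec.replicates + 1):
                rows.append({"sample": f"{genotype}_r{rep}", "tissue": "leaf",
                             "condition": genotype, "timepoint": 0,
                             "replicate": rep,
                             "a_fraction": A_FRACTION[genotype]})
    elif spec.design == "seed":
        for wap in (2, 4, 6, 8):
            for rep in range(1, max(spec.replicates, 3) + 1):
                rows.append({"sample": f"seed_w{wap}_r{rep}", "tissue": "seed",
                             "condition": f"WAP{wap}", "timepoint": wap,
                             "replicate": rep, "a_fraction": np.nan})
    else:  # drought
        for tissue in ("leaf", "root"):
            for condition in ("control", "drought"):
                for rep in range(1, max(spec.replicates, 3) + 1):
                    rows.append({"sample": f"{tissue}_{condition}_r{rep}",
                                 "tissue": tissue, "condition": condition,
                                 "timepoint": 0, "replicate": rep,
                                 "a_fraction": np.nan})
    return pd.DataFrame(rows)


def simulate_expression(spec: Optional[ExpressionSimSpec] = None,
                        seed: int = 0
                        ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame,
                                   pd.DataFrame]:
    """Counts, gene lengths (bp), sample design and per-gene truth.

    Baseline per-gene means are lognormal; planted effects multiply the
    mean: differential genes gain 2**log2fc under the treatment
    condition, dosage-dependent genes scale as a_fraction**slope
    (proportional to A-genome copy number at the default slope 1),
    module genes share a latent log-normal factor tuned to the target
    correlation, and the seed design plants a rising TIP3-like and a
    falling PIP1-like trajectory. A constant background transcriptome
    (``n_background`` genes) fills out each library so that planted
    effects on the panel do not shift the per-sample totals RPKM divides
    by. Counts are Poisson around the RPKM-implied means.

    Truth columns: gene, is_aqp, group, subfamily, base_rpkm, silent,
    is_deg, log2fc, module, dosage_dependent.
    """
    spec = spec or ExpressionSimSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    design = _make_design(spec)
    n_samples = len(design)
    n_total = spec.n_genes + spec.n_background
    genes = [f"gene{idx:04d}" for idx in range(1, spec.n_genes + 1)] + \
        [f"bg{idx:04d}" for idx in range(1, spec.n_background + 1)]
    group_cycle = list(GROUP_TEMPLATES)
    gene_groups = [group_cycle[i % len(group_cycle)]
                   for i in range(spec.n_genes)] + [""] * spec.n_background

    base = np.exp(rng.normal(spec.base_log_mean, spec.base_log_sd,
                             size=n_total))
    n_silent = int(round(spec.silent_fraction * spec.n_genes))
    silent_idx = rng.choice(spec.n_genes, size=n_silent, replace=False)
    base[silent_idx] = 0.2  # well under the >2 RPKM expressed rule
    lengths = pd.Series(rng.integers(800, 1800, size=n_total),
                        index=genes, name="length_bp")
    # RPKM self-consistency: recovered RPKM equals the target only when
    # the library's total rpkm * length mass is 1e9, as in a full
    # transcriptome; the background genes absorb the missing mass
    if spec.n_background:
        len_arr = lengths.to_numpy(dtype=float)
        panel_mass = float(np.sum(base[:spec.n_genes] * len_arr[:spec.n_genes]))
        bg_mass = float(np.sum(base[spec.n_genes:] * len_arr[spec.n_genes:]))
        if bg_mass > 0 and panel_mass < 1e9:
            base[spec.n_genes:] *= (1e9 - panel_mass) / bg_mass

    truth = pd.DataFrame({"gene": genes, "group": gene_groups})
    truth["is_aqp"] = [i < spec.n_genes for i in range(n_total)]
    truth["subfamily"] = [GROUP_TEMPLATES[g][0] if g else ""
                          for g in gene_groups]
    truth["base_rpkm"] = base
    truth["silent"] = False
    truth.loc[silent_idx, "silent"] = True
    truth["is_deg"] = False
    truth["log2fc"] = 0.0
    truth["module"] = -1
    truth["dosage_dependent"] = False

    log_mu = np.log(base)[:, None] * np.ones((1, n_samples))
    # effects are planted on non-silent panel genes only
    panel = np.array([i for i in range(spec.n_genes) if i not in set(silent_idx)])

    if spec.design == "dosage":
        a = design["a_fraction"].to_numpy()
        n_dep = int(round(spec.dependent_fraction * spec.n_genes))
        dep_idx = rng.choice(panel, size=min(n_dep, len(panel)), replace=False)
        truth.loc[dep_idx, "dosage_dependent"] = True
        scale = spec.dosage_slope * (np.log(a) - np.mean(np.log(a)))
        for gi in dep_idx:
            log_mu[gi] += scale
    elif spec.design == "drought":
        treated = (design["condition"] == "drought").to_numpy()
        # differential genes are planted on well-expressed baselines so a
        # threshold rule with pseudocount 1 sees the full fold change
        expressed = panel[base[panel] >= 5.0]
        n_deg = min(int(round(spec.deg_fraction * spec.n_genes)), len(expressed))
        deg_idx = rng.choice(expressed, size=n_deg, replace=False)
        truth.loc[deg_idx, "is_deg"] = True
        truth.loc[deg_idx, "log2fc"] = spec.deg_log2fc
        for gi in deg_idx:
            log_mu[gi, treated] += spec.deg_log2fc * np.log(2.0)
    else:  # seed trajectory
        wap = design["timepoint"].to_numpy().astype(float)
        rising = (truth["group"] == "TIP3") & ~truth["silent"]
        falling = (truth["group"] == "PIP1") & ~truth["silent"]
        # several-fold monotone change from 2 to 8 weeks after pollination
        slope_per_wap = np.log(2.0) / 2.0
        for gi in np.where(rising)[0]:
            log_mu[gi] += slope_per_wap * (wap - 2.0)
        for gi in np.where(falling)[0]:
            log_mu[gi] -= slope_per_wap * (wap - 2.0)

    # co-expressed modules: shared latent factor on the log scale
    if spec.module_sizes:
        lam = spec.sigma * np.sqrt(spec.module_r / (1.0 - spec.module_r))
        free = [i for i in panel
                if not truth.loc[i, "dosage_dependent"]
                and not truth.loc[i, "is_deg"]]
        offset = 0
        for mod_id, size in enumerate(spec.module_sizes):
            members = free[offset: offset + size]
            offset += size
            factor = rng.normal(0.0, 1.0, size=n_samples)
            for gi in members:
                truth.loc[gi, "module"] = mod_id
                log_mu[gi] += lam * factor

    noise = rng.normal(0.0, spec.sigma, size=(n_total, n_samples))
    rpkm_target = np.exp(log_mu + noise)
    count_mean = rpkm_target * lengths.to_numpy()[:, None] * spec.library_size / 1e9
    if spec.count_noise:
        counts = rng.poisson(count_mean).astype(np.int64)
    else:
        counts = np.round(count_mean).astype(np.int64)
    counts_df = pd.DataFrame(counts, index=genes,
                             columns=design["sample"].tolist())
    return counts_df, lengths, design, truth
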