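"""RNA-seq threshold analyses for aquaporin expression profiling.

Implements the expression computations the annotation pipeline feeds
on: RPKM normalization, the expressed-gene rule (>2 RPKM in at least
one library), threshold-based differential calls (|log2 fold change| >
2 with mean >= 2 RPKM), average-linkage hierarchical clustering on
correlation distance, percentile-thresholded co-expression networks,
and genome-dosage dependency (Pearson correlation of expression with
the A-genome fraction across allopolyploid genotypes, two-sided t test
with n - 2 degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .config import ExpressionConfig


class DesignError(ValueError):
    """Sample design inconsistent with the requested analysis."""


# ---------------------------------------------------------------------------
# Normalization and filters
# ---------------------------------------------------------------------------

def rpkm_normalize(counts: pd.DataFrame, lengths_bp: pd.Series) -> pd.DataFrame:
    """Reads per kilobase of exon per million mapped fragments.

    value = 1e9 * count / (gene_length_bp * sample_total). Doubling every
    count in a sample doubles its total too, so RPKM is invariant to
    library-wide scaling.
    """
    lengths = lengths_bp.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DesignError(f"zero library total in sample(s) {list(zero.index)}")
    return 1e9 * counts.div(lengths, axis=0).div(totals, axis=1)


def expressed_filter(rpkm: pd.DataFrame, threshold: float = 2.0) -> pd.Series:
    """Boolean per gene: max over samples strictly exceeds the threshold."""
    return rpkm.max(axis=1) > threshold


# ---------------------------------------------------------------------------
# Differential expression (threshold rule)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DegResult:
    gene: str
    log2fc: float
    mean_control: float
    mean_treatment: float
    is_deg: bool
    direction: str  # "up", "down" or "none"


def call_degs(rpkm: pd.DataFrame, design: pd.DataFrame,
              control: str, treatment: str,
              config: Optional[ExpressionConfig] = None) -> list[DegResult]:
    """Threshold differential calls between two condition labels.

    log2fc = log2((mean_treatment + c) / (mean_control + c)) with
    pseudocount c (default 1); a gene is differential iff |log2fc|
    strictly exceeds the cutoff and the larger condition mean is at
    least the minimum RPKM.
    """
    cfg = config or ExpressionConfig()
    known = set(design["condition"])
    for label in (control, treatment):
        if label not in known:
            raise DesignError(f"condition {label!r} not in design")
    c_samples = design.loc[design["condition"] == control, "sample"]
    t_samples = design.loc[design["condition"] == treatment, "sample"]
    mean_c = rpkm[list(c_samples)].mean(axis=1)
    mean_t = rpkm[list(t_samples)].mean(axis=1)
    c = cfg.log_pseudocount
    log2fc = np.log2((mean_t + c) / (mean_c + c))
    results = []
    for gene in rpkm.index:
        lfc = float(log2fc[gene])
        is_deg = (abs(lfc) > cfg.deg_log2fc
                  and max(mean_t[gene], mean_c[gene]) >= cfg.deg_min_rpkm)
        direction = "none" if not is_deg else ("up" if lfc > 0 else "down")
        results.append(DegResult(gene=gene, log2fc=lfc,
                                 mean_control=float(mean_c[gene]),
                                 mean_treatment=float(mean_t[gene]),
                                 is_deg=is_deg, direction=direction))
    return results


# ---------------------------------------------------------------------------
# Correlation primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    defined: bool


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided t p-value (df n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson_r needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(r=np.nan, p_value=np.nan, defined=False)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p_value=float(p), defined=True)


# ---------------------------------------------------------------------------
# Co-expression network
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionNetwork:
    graph: nx.Graph
    lower_percentile: float
    upper_percentile: float
    percentile_method: str
    null: str
    thresholds: dict  # bait -> (lower r value, upper r value)
    degenerate_genes: list = field(default_factory=list)


def coexpression_network(rpkm: pd.DataFrame, baits: Sequence[str],
                         lower_pct: float = 5.0, upper_pct: float = 95.0,
                         null: str = "per_bait") -> CoexpressionNetwork:
    """Bait-centred co-expression edges beyond percentile rank thresholds.

    For each bait the null distribution is the set of its correlations
    against every other gene (or the pooled set of all bait correlations
    with ``null="global"``); edges are kept when r is at or below the
    lower-percentile value or at or above the upper-percentile value.
    Percentiles use the linear-interpolation convention, recorded in the
    result. Zero-variance genes are excluded and listed.
    """
    missing = [b for b in baits if b not in rpkm.index]
    if missing:
        raise KeyError(f"bait gene(s) not in matrix: {missing}")
    if rpkm.shape[1] < 3:
        raise DesignError("co-expression needs at least 3 samples")
    values = rpkm.to_numpy(dtype=float)
    variable = values.std(axis=1) > 0
    degenerate = list(rpkm.index[~variable])
    genes = list(rpkm.index[variable])
    idx = {g: i for i, g in enumerate(genes)}
    sub = values[variable]
    # row-standardize once; pairwise r is then a dot product
    z = (sub - sub.mean(axis=1, keepdims=True))
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    z = z / norms
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    per_bait: dict = {}
    usable_baits = [b for b in baits if b in idx]
    corr_sets = {}
    for bait in usable_baits:
        r = z @ z[idx[bait]]
        corr_sets[bait] = r
    if null == "global":
        pooled = np.concatenate([
            np.delete(corr_sets[b], idx[b]) for b in usable_baits
        ]) if usable_baits else np.array([])
    for bait in usable_baits:
        r = corr_sets[bait]
        others = np.delete(r, idx[bait])
        dist = others if null == "per_bait" else pooled
        if len(dist) == 0:
            continue
        lo = float(np.percentile(dist, lower_pct, method="linear"))
        hi = float(np.percentile(dist, upper_pct, method="linear"))
        per_bait[bait] = (lo, hi)
        for gene in genes:
            if gene == bait:
                continue
            rv = float(r[idx[gene]])
            if rv <= lo or rv >= hi:
                graph.add_edge(bait, gene, r=rv,
                               sign="+" if rv >= 0 else "-", bait=bait)
    return CoexpressionNetwork(graph=graph, lower_percentile=lower_pct,
                               upper_percentile=upper_pct,
                               percentile_method="linear", null=null,
                               thresholds=per_bait,
                               degenerate_genes=degenerate)


def write_edge_list(network: CoexpressionNetwork, path) -> None:
    rows = [{"source": u, "target": v, "r": round(d["r"], 6), "sign": d["sign"]}
            for u, v, d in sorted(network.graph.edges(data=True))]
    pd.DataFrame(rows, columns=["source", "target", "r", "sign"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Hierarchical clustering on correlation distance
# ---------------------------------------------------------------------------

@dataclass
class ClusterTree:
    genes: list
    linkage: np.ndarray  # scipy linkage matrix
    excluded: list

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.genes[node.id]
            left, right = render(node.left), render(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:.6f},{right}:{dr:.6f})"

        return render(tree) + ";"

    def cut(self, k: int) -> dict:
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.genes, labels.tolist()))


def hierarchical_cluster(rpkm: pd.DataFrame) -> ClusterTree:
    """Average-linkage agglomeration on distance 1 - Pearson r.

    Zero-variance genes have undefined correlations and are excluded
    (listed in the result). Merge heights are non-decreasing.
    """
    values = rpkm.to_numpy(dtype=float)
    variable = values.std(axis=1) > 0
    excluded = list(rpkm.index[~variable])
    genes = list(rpkm.index[variable])
    if len(genes) < 2:
        raise ValueError("clustering needs >= 2 genes with defined correlations")
    sub = values[variable]
    corr = np.corrcoef(sub)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    condensed = dist[np.triu_indices(len(genes), k=1)]
    linkage = hierarchy.linkage(condensed, method="average")
    return ClusterTree(genes=genes, linkage=linkage, excluded=excluded)


# ---------------------------------------------------------------------------
# Genome-dosage dependency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DosageResult:
    gene: str
    r: float
    p_value: float
    dosage_dependent: bool


def dosage_correlation(rpkm: pd.DataFrame, design: pd.DataFrame,
                       alpha: float = 0.01) -> list[DosageResult]:
    """Per-gene Pearson correlation of expression with A-genome fraction.

    Replicates are treated as independent samples. A gene is
    dosage-dependent iff p < alpha and r > 0; constant genes have
    undefined r and are classified independent.
    """
    if design["a_fraction"].isna().any():
        raise DesignError("a_fraction undefined for some samples")
    if len(design) < 4:
        raise DesignError("dosage analysis needs at least 4 samples")
    a = design.set_index("sample")["a_fraction"]
    if a.nunique() < 2:
        raise DesignError("a_fraction is constant across the design")
    ordered = rpkm[list(a.index)]
    results = []
    for gene in ordered.index:
        cr = pearson_r(ordered.loc[gene].to_numpy(), a.to_numpy()) \
            if ordered.loc[gene].nunique() > 1 else \
            CorrelationResult(r=np.nan, p_value=np.nan, defined=False)
        dependent = cr.defined and cr.p_value < alpha and cr.r > 0
        results.append(DosageResult(gene=gene, r=cr.r, p_value=cr.p_value,
                                    dosage_dependent=dependent))
    return results


def dosage_classify(results: Sequence[DosageResult]) -> dict:
    """Summary: fractions of positive-r and dosage-dependent genes."""
    n = len(results)
    defined = [r for r in results if not np.isnan(r.r)]
    positive = sum(1 for r in defined if r.r > 0)
    dependent = sum(1 for r in results if r.dosage_dependent)
    return {
        "n_genes": n,
        "n_defined": len(defined),
        "fraction_positive_r": positive / len(defined) if defined else np.nan,
        "fraction_dependent": dependent / n if n else np.nan,
    }


# ---------------------------------------------------------------------------
# Subfamily / group aggregation
# ---------------------------------------------------------------------------

def subfamily_aggregate(rpkm: pd.DataFrame, annotation: pd.DataFrame,
                        by: str = "subfamily") -> tuple[pd.DataFrame, list]:
    """Mean RPKM and standard error per subfamily (or group) per sample.

    ``annotation`` maps gene -> subfamily/group (columns: gene, subfamily,
    group). Unannotated genes are excluded and returned separately.
    Returns a long-format frame: label, sample, mean, se, n_genes.
    """
    ann = annotation.set_index("gene")
    unannotated = [g for g in rpkm.index
                   if g not in ann.index or not ann.loc[g, by]]
    rows = []
    for label, genes in ann.groupby(by).groups.items():
        members = [g for g in genes if g in rpkm.index]
        if not members or not label:
            continue
        block = rpkm.loc[members]
        n = len(members)
        means = block.mean(axis=0)
        se = block.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else means * 0.0
        for sample in rpkm.columns:
            rows.append({"label": label, "sample": sample,
                         "mean": float(means[sample]),
                         "se": float(se[sample]), "n_genes": n})
    return pd.DataFrame(rows, columns=["label", "sample", "mean", "se",
                                       "n_genes"]), unannotated
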