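"""Assembly of signed eGRNs from cistromes and edge tables.

Region-to-gene edges are first dichotomized into activating/repressing
classes by the sign of their Spearman correlation (|rho| below the threshold
discards the edge).  Within each sign class, per-gene candidate regions are
pruned by several rules (a minimum-variance two-group split of the importance
vector, per-gene importance quantiles, and per-gene top-k); each pruned
subset, intersected with a TF's cistrome, proposes a gene set that is tested
by GSEA against the TF's TF-to-gene importance ranking.  Leading-edge genes
(and their regions) from all pruning rules are unified into one eGRN per
(TF, annotation class, sign).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SignRule",
    "GSEAResult",
    "EGRN",
    "sign_edges",
    "split_threshold_1d",
    "prune_region_gene",
    "gsea_leading_edge",
    "assemble_egrns",
    "PRUNING_METHODS",
]

QUANTILES = (0.75, 0.80, 0.85, 0.90, 0.95)
TOP_KS = (5, 10, 15)
PRUNING_METHODS = (
    ("basc",)
    + tuple(f"q{int(q * 100)}" for q in QUANTILES)
    + tuple(f"top{k}" for k in TOP_KS)
)


@dataclass
class SignRule:
    """Spearman-rho dichotomization threshold (must be > 0)."""

    rho_threshold: float = 0.03

    def __post_init__(self):
        if not self.rho_threshold > 0:
            raise ValueError("rho_threshold must be > 0")


def sign_edges(edge_table: pd.DataFrame, rule: SignRule | None = None):
    """Split edges into activating (rho > +t) and repressing (rho < -t).

    Edges with |rho| <= t or undefined rho are discarded; the number of
    undefined-rho edges is returned alongside the two tables.
    """
    rule = rule or SignRule()
    t = rule.rho_threshold
    rho = edge_table["rho"]
    n_undefined = int(rho.isna().sum())
    act = edge_table[rho > t].reset_index(drop=True)
    rep = edge_table[rho < -t].reset_index(drop=True)
    return act, rep, n_undefined


def split_threshold_1d(values):
    """Deterministic two-group split of a 1-D vector by minimum within-group
    sum of squared deviations (exhaustive scan over the n-1 sorted cuts).

    Returns ``(threshold, high_mask)``: the boundary (midpoint between the
    two groups' adjacent order statistics) and a boolean mask over the input
    marking the high group.  All-equal input is an error.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(v) == 0:
        raise ValueError("all values equal: no two-group split exists")
    s = np.sort(v)
    n = s.size
    csum = np.cumsum(s)
    csq = np.cumsum(s ** 2)
    best = (np.inf, None)
    for c in range(1, n):  # low group = s[:c]
        sse_lo = csq[c - 1] - csum[c - 1] ** 2 / c
        sum_hi = csum[-1] - csum[c - 1]
        sse_hi = (csq[-1] - csq[c - 1]) - sum_hi ** 2 / (n - c)
        sse = sse_lo + sse_hi
        if sse < best[0] - 1e-15:
            best = (sse, c)
    c = best[1]
    threshold = (s[c - 1] + s[c]) / 2.0
    return float(threshold), v > threshold


def prune_region_gene(edge_table: pd.DataFrame) -> dict:
    """Nine per-gene pruning rules over region importances.

    For each gene's candidate regions: the minimum-variance two-group split
    keeps the high group ("basc"); quantile rules keep regions whose
    importance reaches the per-gene q-quantile (linear interpolation,
    numpy default); top-k rules keep the k most important regions (all, when
    the gene has fewer).  Returns a dict method name -> edge-table subset.
    Genes whose importances are all equal are kept whole by the split rule
    (no informative cut exists).
    """
    subsets = {m: [] for m in PRUNING_METHODS}
    for gene, sub in edge_table.groupby("target", sort=True):
        imp = sub["importance"].to_numpy(dtype=float)
        # minimum-variance split
        if len(imp) < 2 or np.ptp(imp) == 0:
            subsets["basc"].append(sub)
        else:
            _, high = split_threshold_1d(imp)
            subsets["basc"].append(sub[high])
        for q in QUANTILES:
            cut = np.quantile(imp, q)
            subsets[f"q{int(q * 100)}"].append(sub[imp >= cut])
        order = np.argsort(-imp, kind="stable")
        for k in TOP_KS:
            subsets[f"top{k}"].append(sub.iloc[order[:k]])
    cols = list(edge_table.columns)
    return {m: (pd.concat(parts).reset_index(drop=True) if parts
                else pd.DataFrame(columns=cols))
            for m, parts in subsets.items()}


@dataclass
class GSEAResult:
    """Weighted Kolmogorov-Smirnov enrichment of a gene set in a ranking."""

    es: float
    leading_edge: list
    weight_exponent: float
    ranking: list
    running_sum: np.ndarray = None


def gsea_leading_edge(ranking: pd.Series, gene_set,
                      weight_exponent: float = 1.0) -> GSEAResult:
    """GSEA running-sum statistic with leading-edge extraction.

    ``ranking`` maps gene -> importance; genes are ordered by decreasing
    importance with ties broken by gene identifier.  Hits increment the
    running sum by importance**p (normalized over set members); misses
    decrement by 1/(N - |S|).  ES is the signed extremum; the leading edge is
    the set members ranked at or before the positive maximum (empty when
    ES <= 0).
    """
    genes = np.asarray(ranking.index)
    imp = ranking.to_numpy(dtype=float)
    order = np.lexsort((genes, -imp))
    genes, imp = genes[order], imp[order]
    gene_set = set(gene_set)
    unknown = gene_set - set(genes)
    if unknown:
        raise ValueError(f"gene set members absent from ranking: "
                         f"{sorted(unknown)[:5]}")
    n = len(genes)
    s = len(gene_set)
    if s == 0 or s == n:
        raise ValueError("gene set must be a nonempty proper subset "
                         "of the ranked universe")
    is_hit = np.array([g in gene_set for g in genes])
    w = np.abs(imp) ** weight_exponent
    w_hits = np.where(is_hit, w, 0.0)
    total = w_hits.sum()
    if total > 0:
        inc = w_hits / total
    else:  # all set weights zero: fall back to unweighted increments
        inc = np.where(is_hit, 1.0 / s, 0.0)
    dec = np.where(is_hit, 0.0, 1.0 / (n - s))
    running = np.cumsum(inc - dec)
    hi, lo = float(running.max()), float(running.min())
    # signed extremum; a magnitude tie (to rounding) resolves positive
    es = hi if hi >= -lo - 1e-12 else lo
    if es > 0:
        i_max = int(np.argmax(running))
        leading = [g for g in genes[: i_max + 1] if g in gene_set]
    else:
        leading = []
    return GSEAResult(es, leading, weight_exponent, list(genes), running)


@dataclass
class EGRN:
    """A signed enhancer regulatory network for one TF.

    ``sign`` is the class of the region-gene edges that built the network;
    the activator/repressor call assigned later from TF-activity correlation
    is stored in ``role``.
    """

    tf: str
    annotation_class: str  # 'direct' | 'extended'
    sign: str  # 'activating' | 'repressing' (edge dichotomization)
    target_genes: set = field(default_factory=set)
    target_regions: set = field(default_factory=set)
    edges: set = field(default_factory=set)  # (tf, region, gene)
    provenance: dict = field(default_factory=dict)  # edge -> set of methods
    role: str = None  # TF-activity-based activator/repressor call
    tf_rho: float = None

    @property
    def name(self) -> str:
        return f"{self.tf}_{self.annotation_class}_{self.sign}"


def assemble_egrns(cistromes, pruned_by_sign: dict, tf_gene_table: pd.DataFrame,
                   weight_exponent: float = 1.0, log=None) -> list:
    """Unify leading-edge region-gene edges into one eGRN per (TF, class, sign).

    ``pruned_by_sign`` maps sign -> pruning method -> region-gene edge table
    (from :func:`prune_region_gene` applied to each sign class).  For every
    cistrome, sign and pruning rule, the pruned edges whose region belongs to
    the cistrome propose a gene set; genes in the GSEA leading edge (against
    the TF's TF-to-gene importance ranking) are retained with their regions,
    and the union over pruning rules forms the eGRN.  TFs with an empty
    cistrome, or combinations with non-positive enrichment, contribute
    nothing.
    """
    rankings = {}
    for tf, sub in tf_gene_table.groupby("source"):
        rankings[tf] = pd.Series(
            sub["importance"].to_numpy(), index=sub["target"].to_numpy())
    egrns = {}
    skipped = []
    for cis in cistromes:
        ranking = rankings.get(cis.tf)
        if ranking is None or not cis.regions:
            skipped.append((cis.tf, cis.klass, "no ranking or empty cistrome"))
            continue
        for sign, pruned in pruned_by_sign.items():
            for method, table in pruned.items():
                edges_m = table[table["source"].isin(cis.regions)]
                gene_set = set(edges_m["target"]) & set(ranking.index)
                if not gene_set or len(gene_set) >= len(ranking):
                    continue
                res = gsea_leading_edge(ranking, gene_set, weight_exponent)
                if res.es <= 0 or not res.leading_edge:
                    continue
                keep = edges_m[edges_m["target"].isin(res.leading_edge)]
                key = (cis.tf, cis.klass, sign)
                eg = egrns.setdefault(
                    key, EGRN(cis.tf, cis.klass, sign))
                for _, row in keep.iterrows():
                    edge = (cis.tf, row["source"], row["target"])
                    eg.edges.add(edge)
                    eg.target_genes.add(row["target"])
                    eg.target_regions.add(row["source"])
                    eg.provenance.setdefault(edge, set()).add(method)
    if log is not None:
        log.extend(skipped)
    return [egrns[k] for k in sorted(egrns)]


def egrns_to_gmt(egrns, kind: str = "genes") -> str:
    """GMT-style serialization: one line per eGRN — name, description, then
    the member genes (``kind='genes'``) or regions (``kind='regions'``)."""
    if kind not in ("genes", "regions"):
        raise ValueError("kind must be 'genes' or 'regions'")
    lines = []
    for eg in egrns:
        members = sorted(eg.target_genes if kind == "genes"
                         else eg.target_regions)
        desc = f"{eg.tf}|{eg.annotation_class}|{eg.sign}|{eg.role or '.'}"
        lines.append("\t".join([eg.name, desc] + members))
    return "\n".join(lines) + ("\n" if lines else "")


def egrns_to_frame(egrns) -> pd.DataFrame:
    """Flat TSV-ready edge list (tf, region, gene, sign, class, provenance)."""
    rows = []
    for eg in egrns:
        for (tf, region, gene) in sorted(eg.edges):
            rows.append((tf, region, gene, eg.sign, eg.annotation_class,
                         ",".join(sorted(eg.provenance.get(
                             (tf, region, gene), set()))),
                         eg.role if eg.role else "."))
    return pd.DataFrame(rows, columns=["tf", "region", "gene", "sign",
                                       "class", "provenance", "role"])
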