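"""Cell/cluster quality control, normalization and consensus peak construction.

QC combines RNA-side filters (detected genes, mitochondrial fraction) with
ATAC-side filters (sequencing depth, fraction of reads in peaks, TSS
enrichment).  Consensus regions are built from fixed-width scored peaks by
iterative overlap merging: keep the best remaining peak, drop everything it
touches, repeat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QCThresholds",
    "ScoredPeak",
    "filter_cells",
    "filter_low_quality_clusters",
    "lognormalize",
    "merge_peaks_iterative",
]

MITO_PREFIXES = ("mt:", "mt-", "MT-")


@dataclass
class QCThresholds:
    """Cell-level QC thresholds.

    ``fragment_filter_literal`` selects the reading of the depth filter:
    by default the threshold applies to log10(total fragments) (>= 3.5,
    i.e. >= ~3,162 fragments); the literal reading treats 10**min value
    directly as a fragment count.
    """

    min_genes_per_cell: int = 200
    max_mito_fraction: float = 0.15
    min_cells_per_gene: int = 3
    min_log10_fragments: float = 3.5
    min_frip: float = 0.60
    min_tss_enrichment: float = 2.0
    mito_prefixes: tuple = MITO_PREFIXES
    fragment_filter_literal: bool = False

    def __post_init__(self):
        if not (0 <= self.max_mito_fraction <= 1 and 0 <= self.min_frip <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.min_genes_per_cell < 0 or self.min_cells_per_gene < 0:
            raise ValueError("counts must be >= 0")


def filter_cells(dataset, thresholds: QCThresholds | None = None):
    """Apply all RNA and ATAC cell filters; a cell must pass every one.

    Returns ``(retained_barcodes, report)`` where the report is a DataFrame of
    per-criterion failure counts (a cell can fail several criteria).
    """
    thr = thresholds or QCThresholds()
    barcodes = np.asarray(dataset.cell_barcodes)
    if len(barcodes) == 0:
        raise ValueError("dataset has no cells")
    rna = np.asarray(dataset.rna_counts)
    genes = np.asarray(dataset.gene_ids)

    detected = (rna > 0).sum(axis=0)
    mito_mask = np.array(
        [any(g.startswith(p) for p in thr.mito_prefixes) for g in genes])
    totals = rna.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            totals > 0, rna[mito_mask].sum(axis=0) / np.maximum(totals, 1), 0.0)

    qc = dataset.qc_metrics.set_index("barcode").loc[barcodes]
    frags = qc["total_fragments"].to_numpy(dtype=float)
    if thr.fragment_filter_literal:
        frag_ok = frags >= thr.min_log10_fragments
    else:
        frag_ok = np.log10(np.maximum(frags, 1)) >= thr.min_log10_fragments

    checks = {
        "min_genes_per_cell": detected >= thr.min_genes_per_cell,
        "max_mito_fraction": mito_frac <= thr.max_mito_fraction,
        "min_fragments": frag_ok,
        "min_frip": qc["frip"].to_numpy() >= thr.min_frip,
        "min_tss_enrichment":
            qc["tss_enrichment"].to_numpy() >= thr.min_tss_enrichment,
    }
    keep = np.ones(len(barcodes), dtype=bool)
    rows = []
    for name, ok in checks.items():
        rows.append((name, int((~ok).sum())))
        keep &= ok
    report = pd.DataFrame(rows, columns=["criterion", "n_failed"])
    report.loc[len(report)] = ("total_removed", int((~keep).sum()))
    return list(barcodes[keep]), report


def filter_genes(rna_counts, gene_ids, min_cells_per_gene: int = 3):
    """Drop genes detected in fewer than ``min_cells_per_gene`` cells."""
    rna = np.asarray(rna_counts)
    keep = (rna > 0).sum(axis=1) >= min_cells_per_gene
    return rna[keep], [g for g, k in zip(gene_ids, keep) if k]


def filter_low_quality_clusters(rna_counts, cluster_labels,
                                per_cluster_means: bool = False):
    """Remove clusters with mean detected genes below (global mean - 1 SD).

    The global mean and SD are computed over cells by default; set
    ``per_cluster_means`` to compute them over cluster means instead.
    Returns ``(retained_cluster_labels_set, per_cluster_table)``.
    """
    rna = np.asarray(rna_counts)
    labels = np.asarray(cluster_labels)
    detected = (rna > 0).sum(axis=0).astype(float)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        warnings.warn("single cluster: nothing to compare, returned unchanged")
        table = pd.DataFrame({"cluster": uniq,
                              "mean_detected": [detected.mean()],
                              "removed": [False]})
        return set(uniq), table
    means = {u: detected[labels == u].mean() for u in uniq}
    if per_cluster_means:
        vals = np.array(list(means.values()))
        cutoff = vals.mean() - vals.std(ddof=1)
    else:
        cutoff = detected.mean() - detected.std(ddof=1)
    retained = {u for u in uniq if means[u] >= cutoff}
    table = pd.DataFrame({
        "cluster": list(uniq),
        "mean_detected": [means[u] for u in uniq],
        "removed": [u not in retained for u in uniq],
    })
    return retained, table


def lognormalize(rna_counts, target_sum: float = 1e4):
    """Per-cell total-count normalization to ``target_sum``, then log1p.

    Input is gene x cell non-negative counts; an all-zero cell is an error
    (such cells are removed by QC).
    """
    rna = np.asarray(rna_counts, dtype=float)
    totals = rna.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("all-zero cell encountered; run QC filtering first")
    return np.log1p(rna / totals * target_sum)


@dataclass(order=True)
class ScoredPeak:
    """Fixed-width peak centred on a summit, with a significance score."""

    chrom: str
    start: int
    end: int
    score: float = field(compare=False)

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError("peak must be 0-based half-open with start < end")


def standardize_peaks(summits, width: int = 500):
    """500 bp (by default) peaks centred on (chrom, summit, score) triples."""
    half = width // 2
    peaks = []
    for chrom, pos, score in summits:
        start = max(0, int(pos) - half)
        peaks.append(ScoredPeak(chrom, start, start + width, float(score)))
    return peaks


def merge_peaks_iterative(peaks):
    """Iterative overlap merging: greedily keep the best remaining peak.

    Repeatedly retain the highest-scoring remaining peak and discard every
    peak overlapping it by >= 1 bp; ties in score are broken by
    (chrom, start) order.  The result is sorted and pairwise non-overlapping.
    """
    if not peaks:
        return []
    order = sorted(range(len(peaks)),
                   key=lambda i: (-peaks[i].score, peaks[i].chrom,
                                  peaks[i].start))
    kept = []
    # kept intervals per chromosome, as parallel sorted lists of (start, end)
    by_chrom: dict = {}
    for i in order:
        p = peaks[i]
        ivs = by_chrom.setdefault(p.chrom, [])
        if any(p.start < e and s < p.end for s, e in ivs):
            continue
        ivs.append((p.start, p.end))
        kept.append(p)
    kept.sort(key=lambda p: (p.chrom, p.start))
    return kept


def peaks_to_frame(peaks) -> pd.DataFrame:
    """BED4 frame (name = rank in sorted order)."""
    return pd.DataFrame({
        "chrom": [p.chrom for p in peaks],
        "start": [p.start for p in peaks],
        "end": [p.end for p in peaks],
        "name": [f"peak{i:05d}" for i in range(len(peaks))],
    })
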