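"""Topic modelling of chromatin accessibility and differential accessibility.

A collapsed-Gibbs LDA treats cells as documents and accessible regions as
words; the fitted cell-topic (theta) and topic-region (phi) distributions
yield a denoised "imputed accessibility" matrix (theta @ phi), which is the
accessibility proxy used downstream.  Differential accessible regions (DARs)
are called per cell group with Wilcoxon rank-sum tests; pseudo-bulk tracks
support a Poisson log-likelihood-ratio differential caller between two
conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._gibbs import _run_gibbs

__all__ = [
    "TopicModel",
    "DARResult",
    "DifferentialRegions",
    "binarize",
    "fit_lda",
    "select_model",
    "impute_accessibility",
    "detect_dars",
    "pseudobulk_tracks",
    "diff_tracks",
]


@dataclass
class TopicModel:
    """Fitted LDA: theta (cell x topic) and phi (topic x region) simplices."""

    T: int
    theta: np.ndarray
    phi: np.ndarray
    alpha: float
    beta: float
    n_iterations: int
    seed: int
    log_likelihood_trace: np.ndarray
    coherence_per_topic: np.ndarray = None
    cell_index: list = None
    region_index: list = None

    @property
    def median_coherence(self) -> float:
        return float(np.median(self.coherence_per_topic))


def binarize(counts) -> np.ndarray:
    """0/1 matrix from counts (any positive entry is accessible)."""
    return (np.asarray(counts) > 0).astype(np.int8)


def fit_lda(binary_matrix, T: int, alpha: float | None = None,
            beta: float = 0.1, n_iterations: int = 300, seed: int = 0,
            coherence_top_n: int = 10) -> TopicModel:
    """Collapsed Gibbs LDA on a binarized region x cell matrix.

    ``binary_matrix`` is region x cell with entries in {0, 1}; cells are
    documents.  Priors default to alpha = 50/T and beta = 0.1.  Empty cells or
    regions are dropped with a warning (their theta/phi rows are returned as
    uniform).  ``T = 1`` is handled analytically: theta is all ones and phi is
    the global region frequency distribution.
    """
    B = np.asarray(binary_matrix)
    if not np.isin(B, (0, 1)).all():
        raise ValueError("matrix must be binarized (entries in {0,1})")
    if alpha is None:
        alpha = 50.0 / T
    n_regions, n_cells = B.shape

    if T == 1:
        freq = B.sum(axis=1).astype(float)
        phi = (freq / freq.sum())[None, :]
        theta = np.ones((n_cells, 1))
        model = TopicModel(1, theta, phi, alpha, beta, 0, seed,
                           np.zeros(0))
        model.coherence_per_topic = umass_coherence(B, phi, coherence_top_n)
        return model

    empty_cells = B.sum(axis=0) == 0
    empty_regions = B.sum(axis=1) == 0
    if empty_cells.any() or empty_regions.any():
        warnings.warn(
            f"{int(empty_cells.sum())} empty cells and "
            f"{int(empty_regions.sum())} empty regions carry no tokens")

    regions_tok, cells_tok = np.nonzero(B)
    z, n_ct, n_tr, n_t, len_c, ll = _run_gibbs(
        cells_tok.astype(np.int64), regions_tok.astype(np.int64),
        n_cells, n_regions, T, float(alpha), float(beta),
        int(n_iterations), int(seed) % (2 ** 31))
    theta = (n_ct + alpha) / (len_c[:, None] + T * alpha)
    phi = (n_tr + beta) / (n_t[:, None] + n_regions * beta)
    model = TopicModel(T, theta, phi, alpha, beta, n_iterations, seed, ll)
    model.coherence_per_topic = umass_coherence(B, phi, coherence_top_n)
    return model


def umass_coherence(binary_matrix, phi, top_n: int = 10) -> np.ndarray:
    """UMass topic coherence over each topic's top-``top_n`` regions.

    Co-occurrence counts are taken over cells (documents) of the binarized
    matrix: C_t = sum_{m<l} log((D(r_l, r_m) + 1) / D(r_m)) with regions
    ordered by decreasing phi.
    """
    B = np.asarray(binary_matrix).astype(bool)
    scores = np.empty(phi.shape[0])
    for t in range(phi.shape[0]):
        top = np.argsort(-phi[t], kind="stable")[:top_n]
        c = 0.0
        for m in range(1, len(top)):
            for l in range(m):
                d_m = int(B[top[l]].sum())
                d_lm = int((B[top[l]] & B[top[m]]).sum())
                if d_m > 0:
                    c += np.log((d_lm + 1) / d_m)
        scores[t] = c
    return scores


def select_model(models) -> TopicModel:
    """Pick the candidate with the best (highest) median topic coherence."""
    models = list(models)
    if not models:
        raise ValueError("no candidate models")
    meds = [m.median_coherence for m in models]
    return models[int(np.argmax(meds))]


def model_selection_table(models) -> pd.DataFrame:
    return pd.DataFrame({
        "T": [m.T for m in models],
        "median_coherence": [m.median_coherence for m in models],
    })


def impute_accessibility(model: TopicModel) -> np.ndarray:
    """Cell x region accessibility probabilities: theta @ phi.

    Every cell's row sums to 1 because theta rows and phi rows are simplices.
    """
    return model.theta @ model.phi


def detect_dars(imputed, labels, group, reference=None,
                p_adj_threshold: float = 5e-3, lfc_threshold: float = 1.5,
                eps: float = 1e-8, region_ids=None) -> pd.DataFrame:
    """Wilcoxon rank-sum DARs of ``group`` cells against ``reference`` cells.

    ``imputed`` is cell x region; ``labels`` assigns each cell a group.
    ``reference=None`` means all other cells.  Per region: two-sided
    rank-sum p-value, Benjamini-Hochberg adjustment across regions, and
    log2FC = log2((mean_group + eps) / (mean_ref + eps)).  A region passes
    when p_adj < ``p_adj_threshold`` and log2FC > ``lfc_threshold``.
    """
    X = np.asarray(imputed, dtype=float)
    labels = np.asarray(labels)
    gmask = np.isin(labels, np.atleast_1d(group))
    if reference is None:
        rmask = ~gmask
    else:
        rmask = np.isin(labels, np.atleast_1d(reference))
    if gmask.sum() < 2 or rmask.sum() < 2:
        raise ValueError("group and reference must each contain >= 2 cells")
    if (gmask & rmask).any():
        raise ValueError("group and reference must be disjoint")

    xg, xr = X[gmask], X[rmask]
    res = stats.mannwhitneyu(xg, xr, axis=0, alternative="two-sided",
                             method="asymptotic")
    pvals = np.asarray(res.pvalue, dtype=float)
    pvals = np.nan_to_num(pvals, nan=1.0)
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    log2fc = np.log2((xg.mean(axis=0) + eps) / (xr.mean(axis=0) + eps))
    names = (list(region_ids) if region_ids is not None
             else [f"r{j}" for j in range(X.shape[1])])
    out = pd.DataFrame({
        "region": names,
        "group": str(group),
        "log2FC": log2fc,
        "p_value": pvals,
        "p_adj": p_adj,
    })
    out["passes"] = (out["p_adj"] < p_adj_threshold) & \
                    (out["log2FC"] > lfc_threshold)
    return out


def dars_per_group(imputed, labels, region_ids=None, **kwargs):
    """DARs of every group against the rest; dict group -> DARResult frame."""
    return {g: detect_dars(imputed, labels, g, region_ids=region_ids, **kwargs)
            for g in pd.unique(np.asarray(labels))}


def dar_contrasts(imputed, labels, region_ids=None, pairwise: bool = True,
                  complements: bool = True, **kwargs) -> dict:
    """DAR tables for group-vs-rest, group-vs-group and rest-vs-group
    contrasts; dict contrast name -> DARResult frame.

    Pairwise and complement (rest-vs-group) contrasts expose regions that are
    broadly accessible but shut in one group — e.g. chromatin closed by a
    repressor — which group-vs-rest tests dilute.
    """
    labels = np.asarray(labels)
    groups = list(pd.unique(labels))
    out = {}
    for g in groups:
        out[f"{g}_vs_rest"] = detect_dars(imputed, labels, g,
                                          region_ids=region_ids, **kwargs)
    if complements and len(groups) > 2:
        for g in groups:
            rest = [h for h in groups if h != g]
            out[f"rest_vs_{g}"] = detect_dars(
                imputed, labels, rest, g, region_ids=region_ids, **kwargs)
    if pairwise and len(groups) > 2:
        for g in groups:
            for h in groups:
                if g == h:
                    continue
                out[f"{g}_vs_{h}"] = detect_dars(
                    imputed, labels, g, h, region_ids=region_ids, **kwargs)
    return out


@dataclass
class Track:
    """Binned single-chromosome coverage with its sequencing depth."""

    values: np.ndarray
    bin_size: int
    depth: float
    chrom: str = "chrS"


def pseudobulk_tracks(atac_counts, labels, regions, bin_size: int,
                      genome_length: int | None = None) -> dict:
    """Per-group binned coverage: each region's counts go to its midpoint bin.

    Returns a dict of group label -> :class:`Track`; a track's ``depth`` is
    its total count mass, recorded for cross-track normalization.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    A = np.asarray(atac_counts)
    labels = np.asarray(labels)
    if len(labels) != A.shape[1]:
        raise ValueError("labels must cover all cells")
    mid = ((regions["start"].to_numpy() + regions["end"].to_numpy()) // 2)
    if genome_length is None:
        genome_length = int(regions["end"].max())
    n_bins = int(np.ceil(genome_length / bin_size))
    bins = np.minimum(mid // bin_size, n_bins - 1).astype(np.int64)
    chrom = str(regions["chrom"].iloc[0]) if len(regions) else "chrS"
    out = {}
    for g in pd.unique(labels):
        per_region = A[:, labels == g].sum(axis=1).astype(float)
        vals = np.bincount(bins, weights=per_region, minlength=n_bins)
        out[g] = Track(vals, bin_size, float(per_region.sum()), chrom)
    return out


@dataclass
class DifferentialRegions:
    """Intervals preferentially accessible in one of two conditions."""

    condition1: pd.DataFrame
    condition2: pd.DataFrame
    common: pd.DataFrame


def _merge_bins(idx, llr, bin_size, max_gap, min_length, chrom):
    """Merge flagged bin indices across gaps <= max_gap bp; drop short runs."""
    rows = []
    if len(idx):
        start = prev = idx[0]
        members = [llr[idx[0]]]
        for b in idx[1:]:
            gap_bp = (b - prev - 1) * bin_size
            if gap_bp <= max_gap:
                members.append(llr[b])
                prev = b
            else:
                rows.append((start, prev, members))
                start = prev = b
                members = [llr[b]]
        rows.append((start, prev, members))
    recs = []
    for s, e, members in rows:
        length = (e - s + 1) * bin_size
        if length >= min_length:
            recs.append((chrom, s * bin_size, (e + 1) * bin_size,
                         float(np.mean(np.abs(members)))))
    return pd.DataFrame(recs, columns=["chrom", "start", "end", "mean_llr"])


def diff_tracks(track1: Track, track2: Track, llr_threshold: float = 1.5,
                max_gap: int = 150, min_length: int = 300,
                background_quantile: float = 0.10) -> DifferentialRegions:
    """Poisson log-likelihood-ratio differential regions between two tracks.

    Counts are depth-normalized to the shallower track.  Per bin, with
    normalized x1, x2 and m = (x1 + x2)/2, the signed statistic is
    sign(x1 - x2) * [x1 ln(x1/m) + x2 ln(x2/m)] / ln 10 (0 ln 0 := 0).
    Bins with |LLR| above the threshold are assigned to the higher condition;
    same-sign bins are merged across gaps <= ``max_gap`` bp and merged
    intervals shorter than ``min_length`` bp are dropped.  Bins where both
    normalized tracks exceed a background level (the ``background_quantile``
    of nonzero bin means) without being differential form the common set.
    """
    if track1.values.shape != track2.values.shape \
            or track1.bin_size != track2.bin_size:
        raise ValueError("tracks must share identical bins")
    x1 = track1.values.astype(float)
    x2 = track2.values.astype(float)
    if track1.depth > 0 and track2.depth > 0:
        # scale the deeper track down to the shallower one
        if track1.depth > track2.depth:
            x1 = x1 * (track2.depth / track1.depth)
        elif track2.depth > track1.depth:
            x2 = x2 * (track1.depth / track2.depth)

    m = (x1 + x2) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(x1 > 0, x1 * np.log(np.where(x1 > 0, x1, 1) /
                                          np.where(m > 0, m, 1)), 0.0)
        t2 = np.where(x2 > 0, x2 * np.log(np.where(x2 > 0, x2, 1) /
                                          np.where(m > 0, m, 1)), 0.0)
    llr = np.sign(x1 - x2) * (t1 + t2) / np.log(10)

    bs = track1.bin_size
    idx1 = np.nonzero(llr > llr_threshold)[0]
    idx2 = np.nonzero(llr < -llr_threshold)[0]
    means = (x1 + x2) / 2.0
    nz = means[means > 0]
    bg = float(np.quantile(nz, background_quantile)) if nz.size else 0.0
    common_mask = (x1 > bg) & (x2 > bg) & (np.abs(llr) <= llr_threshold)
    idxc = np.nonzero(common_mask)[0]

    return DifferentialRegions(
        condition1=_merge_bins(idx1, llr, bs, max_gap, min_length,
                               track1.chrom),
        condition2=_merge_bins(idx2, llr, bs, max_gap, min_length,
                               track1.chrom),
        common=_merge_bins(idxc, llr, bs, max_gap, min_length, track1.chrom),
    )
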