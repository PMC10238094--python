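"""Region-to-gene and TF-to-gene link scoring.

Candidate region-gene pairs are restricted to a TSS-distance window
(100 bp - 50 kb by default).  Each gene's expression is regressed on its
candidate regions' imputed accessibility (and, at the TF level, every gene on
all TF expression profiles) with a seeded gradient-boosting ensemble;
per-predictor split-gain shares are the importance scores.  Spearman rank
correlations accompany every edge and later decide its sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor
from scipy import stats

__all__ = [
    "GBMParams",
    "candidate_pairs",
    "region_gene_scores",
    "tf_gene_adjacencies",
]


@dataclass
class GBMParams:
    """Arboreto-style gradient-boosting preset."""

    n_estimators: int = 500
    learning_rate: float = 0.01
    max_depth: int = 3
    feature_fraction: float = 0.9  # per boosting round
    subsample: float = 1.0  # no row bagging: keeps cell-order invariance


def candidate_pairs(regions: pd.DataFrame, tss_table: pd.DataFrame,
                    min_dist: int = 100, max_dist: int = 50_000,
                    ) -> pd.DataFrame:
    """All (region, gene) pairs whose TSS distance lies in the window.

    Distance is the minimum over the region's endpoints of |endpoint - TSS|,
    and 0 when the region covers the TSS (0-based half-open region, 0-based
    TSS point); strand is ignored.  Output ordered by (gene, distance).
    """
    rows = []
    tss = tss_table.dropna(subset=["position"])
    by_chrom = {c: sub for c, sub in tss.groupby("chrom")}
    for _, reg in regions.iterrows():
        sub = by_chrom.get(reg["chrom"])
        if sub is None:
            continue
        pos = sub["position"].to_numpy(dtype=np.int64)
        start, end = int(reg["start"]), int(reg["end"])
        dist = np.minimum(np.abs(start - pos), np.abs(end - 1 - pos))
        dist = np.where((pos >= start) & (pos < end), 0, dist)
        ok = (dist >= min_dist) & (dist <= max_dist)
        for g, d in zip(sub["gene"].to_numpy()[ok], dist[ok]):
            rows.append((reg["name"], g, int(d)))
    out = pd.DataFrame(rows, columns=["region", "gene", "distance"])
    return out.sort_values(["gene", "distance"],
                           kind="mergesort").reset_index(drop=True)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho; NaN when either profile has < 2 distinct values."""
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        return np.nan
    return float(stats.spearmanr(x, y).statistic)


def _gbm_importances(X: np.ndarray, y: np.ndarray, seed: int,
                     params: GBMParams) -> np.ndarray:
    """Normalized split-gain importances of a seeded LightGBM regressor."""
    if y.std() == 0:
        return np.zeros(X.shape[1])
    model = LGBMRegressor(
        n_estimators=params.n_estimators,
        learning_rate=params.learning_rate,
        max_depth=params.max_depth,
        colsample_bytree=params.feature_fraction if X.shape[1] > 1 else 1.0,
        subsample=params.subsample,
        subsample_freq=1 if params.subsample < 1.0 else 0,
        min_child_samples=10,
        importance_type="gain",
        random_state=int(seed) % (2 ** 31),
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbosity=-1,
    )
    model.fit(X, y)
    imp = model.feature_importances_.astype(float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    elif X.shape[1] == 1:
        # a single predictor carries all the (possibly zero-gain) credit
        imp = np.ones(1)
    return imp


def region_gene_scores(imputed_accessibility, normalized_expression,
                       pairs: pd.DataFrame, gene_ids, region_ids,
                       seed: int = 0, params: GBMParams | None = None,
                       ) -> pd.DataFrame:
    """Per gene, regress expression on candidate regions' accessibility.

    ``imputed_accessibility`` is cell x region; ``normalized_expression`` is
    gene x cell.  Importance of (region, gene) is the region's share of total
    split gain in that gene's ensemble; ``rho`` is the Spearman correlation of
    the two profiles across cells.  Zero-variance genes get importance 0 and
    undefined rho (flagged via the ``zero_variance`` column).
    """
    params = params or GBMParams()
    acc = np.asarray(imputed_accessibility, dtype=float)
    expr = np.asarray(normalized_expression, dtype=float)
    gidx = {g: i for i, g in enumerate(gene_ids)}
    ridx = {r: j for j, r in enumerate(region_ids)}
    rows = []
    for gene, sub in pairs.groupby("gene", sort=True):
        if gene not in gidx:
            continue
        y = expr[gidx[gene]]
        regs = [r for r in sub["region"] if r in ridx]
        if not regs:
            continue
        X = acc[:, [ridx[r] for r in regs]]
        zero_var = y.std() == 0
        imp = _gbm_importances(X, y, seed, params)
        dist = dict(zip(sub["region"], sub["distance"]))
        for r, w in zip(regs, imp):
            rho = np.nan if zero_var else _spearman(X[:, regs.index(r)], y)
            rows.append((r, gene, float(w), rho, dist[r], zero_var))
    out = pd.DataFrame(rows, columns=["source", "target", "importance",
                                      "rho", "distance", "zero_variance"])
    out.attrs["level"] = "region->gene"
    return out


def tf_gene_adjacencies(normalized_expression, gene_ids, tf_list,
                        seed: int = 0, params: GBMParams | None = None,
                        ) -> pd.DataFrame:
    """Per gene, regress expression on all TFs' expression (self excluded)."""
    params = params or GBMParams()
    expr = np.asarray(normalized_expression, dtype=float)
    gidx = {g: i for i, g in enumerate(gene_ids)}
    tfs = [t for t in tf_list if t in gidx]
    if len(tfs) < 2:
        raise ValueError("need at least 2 TFs present in the expression matrix")
    tf_mat = expr[[gidx[t] for t in tfs]].T  # cell x tf
    rows = []
    for gene in gene_ids:
        y = expr[gidx[gene]]
        use = [k for k, t in enumerate(tfs) if t != gene]
        if not use:
            continue
        X = tf_mat[:, use]
        zero_var = y.std() == 0
        imp = _gbm_importances(X, y, seed, params)
        for k, w in zip(use, imp):
            rho = np.nan if zero_var else _spearman(tf_mat[:, k], y)
            rows.append((tfs[k], gene, float(w), rho, zero_var))
    out = pd.DataFrame(rows, columns=["source", "target", "importance",
                                      "rho", "zero_variance"])
    out.attrs["level"] = "TF->gene"
    return out
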