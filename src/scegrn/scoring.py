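"""Per-cell eGRN activity, pseudo-bulks, specificity and signature statistics.

An eGRN's activity in a cell is the normalized area under the recovery curve
of its target-feature set along the cell's feature ranking (gene expression
or imputed region accessibility).  Activities are stabilized on pseudo-bulks
(means of small random cell samples per group); eGRNs whose activity tracks
their TF's expression (|Pearson rho| above a threshold) are retained and
labelled activating/repressing by the correlation sign.  Specificity per cell
group is the regulon specificity score, 1 - sqrt of the base-2
Jensen-Shannon divergence between the normalized activity distribution and
the group indicator distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import jensenshannon

__all__ = [
    "aucell",
    "aucell_matrix",
    "PseudobulkSet",
    "make_pseudobulks",
    "filter_egrns",
    "rss",
    "signature_enrichment",
    "overlap_test",
]


def aucell(values, feature_ids, feature_set, top_fraction: float = 0.05,
           ) -> np.ndarray:
    """Per-cell recovery AUC of a feature set.

    ``values`` is feature x cell; per cell, features are ranked by decreasing
    value with ties broken by feature index.  With cutoff R = max(1,
    floor(top_fraction * n_features)) and H(k) hits among the top k,
    AUC = sum_k H(k) / sum_k min(k, |S|) in [0, 1].
    """
    V = np.asarray(values, dtype=float)
    n_features, n_cells = V.shape
    fidx = {f: i for i, f in enumerate(feature_ids)}
    members = [fidx[f] for f in feature_set if f in fidx]
    if not members:
        raise ValueError("empty feature set")
    mask = np.zeros(n_features, dtype=bool)
    mask[members] = True
    R = max(1, int(np.floor(top_fraction * n_features)))
    k = np.arange(1, R + 1)
    denom = np.minimum(k, len(members)).sum()
    order = np.argsort(-V, axis=0, kind="stable")  # stable = ties by index
    top = order[:R, :]
    hits = np.cumsum(mask[top], axis=0)
    return hits.sum(axis=0) / denom


def aucell_matrix(values, feature_ids, feature_sets: dict,
                  top_fraction: float = 0.05) -> pd.DataFrame:
    """AUCell for many sets at once: set-name x cell DataFrame."""
    out = {name: aucell(values, feature_ids, fs, top_fraction)
           for name, fs in feature_sets.items()}
    return pd.DataFrame(out).T


@dataclass
class PseudobulkSet:
    """Mean profiles of small random cell samples, per group."""

    values: np.ndarray  # feature x profile
    profile_groups: np.ndarray  # group label per profile
    sampling_log: dict  # (group, profile index) -> list of cell indices
    with_replacement_groups: list
    seed: int


def make_pseudobulks(values, labels, n_pseudobulks: int = 150,
                     cells_per_pseudobulk: int = 15, seed: int = 0,
                     ) -> PseudobulkSet:
    """Per group, ``n_pseudobulks`` profiles of ``cells_per_pseudobulk`` cells.

    Cells are drawn without replacement within a profile when the group has
    at least ``cells_per_pseudobulk`` cells, with replacement otherwise
    (recorded).  A profile is the arithmetic mean of its cells' values.
    """
    V = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    profiles, groups_out = [], []
    log, with_repl = {}, []
    for g in pd.unique(labels):
        cells = np.nonzero(labels == g)[0]
        if cells.size == 0:
            raise ValueError(f"empty group {g!r}")
        replace = cells.size < cells_per_pseudobulk
        if replace:
            with_repl.append(g)
        for i in range(n_pseudobulks):
            pick = rng.choice(cells, size=cells_per_pseudobulk,
                              replace=replace)
            log[(g, i)] = pick.tolist()
            profiles.append(V[:, pick].mean(axis=1))
            groups_out.append(g)
    return PseudobulkSet(np.column_stack(profiles), np.asarray(groups_out),
                         log, with_repl, seed)


def filter_egrns(egrns, tf_expression: pd.DataFrame, auc_matrix: pd.DataFrame,
                 rho_min: float = 0.2):
    """Quality-filter eGRNs by TF-expression / activity correlation.

    ``tf_expression``: gene x pseudo-bulk expression; ``auc_matrix``: eGRN
    name x pseudo-bulk AUC (same profile order).  An eGRN is retained when
    |Pearson rho| > ``rho_min``; the correlation sign becomes its
    activator/repressor call (``role``).  When any direct eGRN of a TF
    survives, that TF's extended eGRNs are dropped (direct evidence
    supersedes extended).  Zero-variance profiles drop the eGRN with a flag.
    Returns (kept list, report frame).
    """
    rows = []
    surviving = []
    for eg in egrns:
        flag = ""
        rho = np.nan
        if eg.name not in auc_matrix.index or eg.tf not in tf_expression.index:
            flag = "missing profiles"
        else:
            x = tf_expression.loc[eg.tf].to_numpy(dtype=float)
            y = auc_matrix.loc[eg.name].to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                flag = "zero variance"
            else:
                rho = float(stats.pearsonr(x, y).statistic)
        passed = (not flag) and abs(rho) > rho_min
        if passed:
            eg.tf_rho = rho
            eg.role = "activating" if rho > 0 else "repressing"
            surviving.append(eg)
        rows.append((eg.name, eg.tf, eg.annotation_class, eg.sign, rho,
                     passed, flag))
    # direct-over-extended de-duplication (any direct eGRN of the TF wins)
    direct_tfs = {eg.tf for eg in surviving
                  if eg.annotation_class == "direct"}
    kept = [eg for eg in surviving
            if eg.annotation_class == "direct" or eg.tf not in direct_tfs]
    dropped_ext = {eg.name for eg in surviving if eg not in kept}
    report = pd.DataFrame(rows, columns=["egrn", "tf", "class", "sign",
                                         "rho", "passed", "flag"])
    report["dropped_for_direct"] = report["egrn"].isin(dropped_ext)
    return kept, report


def rss(auc_matrix: pd.DataFrame, labels) -> pd.DataFrame:
    """Regulon specificity scores: eGRN x group table in [0, 1].

    Per (eGRN, group): P is the eGRN's AUC vector over cells normalized to
    sum 1; Q is uniform over the group's cells (0 elsewhere);
    RSS = 1 - sqrt(JSD(P, Q)) with base-2 Jensen-Shannon divergence.
    An all-zero AUC vector yields NaN for that eGRN.
    """
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    out = pd.DataFrame(index=auc_matrix.index, columns=groups, dtype=float)
    for name, row in auc_matrix.iterrows():
        a = row.to_numpy(dtype=float)
        total = a.sum()
        if total <= 0:
            out.loc[name] = np.nan
            continue
        p = a / total
        for g in groups:
            q = (labels == g).astype(float)
            q /= q.sum()
            with np.errstate(invalid="ignore"):
                d = float(jensenshannon(p, q, base=2))
            if np.isnan(d):  # tiny negative rounding inside the sqrt
                d = 0.0
            out.loc[name, g] = 1.0 - d
    return out


def signature_enrichment(values: pd.Series, groups, comparisons,
                         alternative: str = "greater", paired: bool = False,
                         ) -> pd.DataFrame:
    """t-tests between group pairs with Bonferroni adjustment.

    ``comparisons`` is a list of (group_a, group_b) label pairs; each test is
    a one-tailed two-sample t-test by default (or a paired t-test when
    ``paired``).  Degenerate variance flags the row with p = NaN.
    """
    v = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    rows = []
    m = len(comparisons)
    for ga, gb in comparisons:
        a, b = v[groups == ga], v[groups == gb]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs >= 2 observations")
        if a.std() == 0 and b.std() == 0 and np.allclose(a.mean(), b.mean()):
            rows.append((ga, gb, 0.0, np.nan, np.nan, "degenerate variance"))
            continue
        if paired:
            res = stats.ttest_rel(a, b, alternative=alternative)
        else:
            res = stats.ttest_ind(a, b, alternative=alternative)
        p = float(res.pvalue)
        rows.append((ga, gb, float(res.statistic), p, min(1.0, m * p), ""))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p_value",
                                       "p_bonferroni", "flag"])


def overlap_test(set_a, set_b, universe):
    """Two-sided Fisher's exact test of set overlap within a universe.

    Returns ``(odds_ratio, p_value)``; the odds ratio is ``inf`` for a
    degenerate table with an empty off-diagonal.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set(set_a) & universe, set(set_b) & universe
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(universe) - n11 - n12 - n21
    odds, p = stats.fisher_exact([[n11, n12], [n21, n22]],
                                 alternative="two-sided")
    return float(odds), float(p)
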