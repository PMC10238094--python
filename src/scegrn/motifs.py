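"""Recovery-curve motif enrichment and TF cistrome construction.

For each motif, database regions are ranked by decreasing motif score.  The
enrichment of a query region set is the normalized area under its recovery
curve over the top ``auc_fraction`` of the ranking; AUCs are standardized
across all motifs of the database into a normalized enrichment score (NES).
Enriched motifs (NES above threshold) contribute "hit" regions — query
regions ranked within the top ``rank_fraction`` — to their annotated TF's
cistrome: the direct cistrome uses only directly annotated motifs, the
extended cistrome adds similarity- and orthology-annotated ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MotifDatabase",
    "MotifEnrichmentResult",
    "Cistrome",
    "rank_regions",
    "recovery_auc",
    "motif_nes",
    "enrich_motifs",
    "build_cistromes",
    "score_feature_map",
]

SIMILARITY_FDR_MAX = 0.001
ORTHOLOGY_IDENTITY_MIN = 0.6


@dataclass
class MotifDatabase:
    """Region x motif scores with per-motif region rankings and annotations.

    ``annotations`` columns: motif, tf, class (direct/similarity/orthology),
    similarity_fdr, orthology_identity, group (merged-consensus group id).
    """

    scores: pd.DataFrame  # region x motif
    annotations: pd.DataFrame
    rankings: pd.DataFrame = None  # rank x motif -> region index

    def __post_init__(self):
        if self.rankings is None:
            self.rankings = rank_regions(self.scores)
        self._check_annotation_classes()

    def _check_annotation_classes(self):
        ann = self.annotations
        sim = ann[ann["class"] == "similarity"]
        if (sim["similarity_fdr"] > SIMILARITY_FDR_MAX).any():
            raise ValueError("similarity annotations must satisfy "
                             f"FDR <= {SIMILARITY_FDR_MAX}")
        orth = ann[ann["class"] == "orthology"]
        if (orth["orthology_identity"] < ORTHOLOGY_IDENTITY_MIN).any():
            raise ValueError("orthology annotations must satisfy "
                             f"identity >= {ORTHOLOGY_IDENTITY_MIN}")

    @property
    def region_ids(self):
        return list(self.scores.index)

    @property
    def motif_ids(self):
        return list(self.scores.columns)


def rank_regions(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-motif total order of regions by decreasing score.

    Ties are broken by region index ascending.  Returned frame: one column per
    motif; row k holds the integer index (into ``scores.index``) of the region
    at rank k (0-based).
    """
    vals = scores.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("motif scores must be finite")
    order = np.argsort(-vals, axis=0, kind="stable")
    return pd.DataFrame(order, columns=scores.columns)


def recovery_auc(ranking, query_mask, auc_fraction: float = 0.005,
                 min_ranks: int = 1) -> float:
    """Normalized area under the recovery curve of a query set.

    ``ranking`` is the ordered region indices for one motif; ``query_mask`` a
    boolean array over regions.  With cutoff R = max(min_ranks, 1,
    floor(auc_fraction * n_regions)) and H(k) = |query among top k|,
    AUC = sum_k H(k) / sum_k min(k, |query|), so the best possible
    arrangement scores exactly 1.  ``min_ranks`` floors the integration depth
    for small databases, where a pure fraction leaves too few ranks for the
    statistic to discriminate.
    """
    ranking = np.asarray(ranking)
    query_mask = np.asarray(query_mask, dtype=bool)
    n = len(ranking)
    q = int(query_mask.sum())
    if q == 0:
        raise ValueError("empty query set")
    R = min(n, max(1, int(min_ranks), int(np.floor(auc_fraction * n))))
    hits = np.cumsum(query_mask[ranking[:R]])
    k = np.arange(1, R + 1)
    denom = np.minimum(k, q).sum()
    return float(hits.sum() / denom)


def motif_nes(aucs) -> np.ndarray:
    """Standardize AUCs across motifs: (AUC - mean) / sample SD (n-1)."""
    a = np.asarray(aucs, dtype=float)
    if a.size < 3:
        raise ValueError("NES needs at least 3 motifs")
    if np.ptp(a) == 0:
        raise ValueError("degenerate motif database: all AUCs identical")
    sd = a.std(ddof=1)
    return (a - a.mean()) / sd


@dataclass
class MotifEnrichmentResult:
    """Per-motif AUC/NES for one query set, with hit regions when enriched."""

    table: pd.DataFrame  # motif, auc, nes, enriched, n_hits
    hits: dict  # motif -> list of query region ids within the rank cutoff
    query_regions: list
    nes_threshold: float
    auc_fraction: float
    rank_fraction: float


def enrich_motifs(db: MotifDatabase, query_regions,
                  auc_fraction: float = 0.005, rank_fraction: float = 0.05,
                  nes_threshold: float = 3.0,
                  min_auc_ranks: int = 1) -> MotifEnrichmentResult:
    """AUC + NES of one query region set against every motif in the database.

    Hit regions of an enriched motif are the query regions ranked within the
    top ``rank_fraction`` of that motif's ranking.  ``min_auc_ranks`` floors
    the recovery-curve depth (see :func:`recovery_auc`).
    """
    region_ids = db.region_ids
    pos = {r: i for i, r in enumerate(region_ids)}
    missing = [r for r in query_regions if r not in pos]
    if missing:
        raise ValueError(f"query regions absent from database: {missing[:5]}")
    mask = np.zeros(len(region_ids), dtype=bool)
    mask[[pos[r] for r in query_regions]] = True

    rank_mat = db.rankings.to_numpy()
    aucs = np.array([
        recovery_auc(rank_mat[:, j], mask, auc_fraction, min_auc_ranks)
        for j in range(rank_mat.shape[1])])
    nes = motif_nes(aucs)
    enriched = nes > nes_threshold

    n = len(region_ids)
    depth = max(1, int(np.floor(rank_fraction * n)))
    hits = {}
    for j, motif in enumerate(db.motif_ids):
        if not enriched[j]:
            continue
        top = rank_mat[:depth, j]
        hits[motif] = [region_ids[i] for i in top if mask[i]]
    table = pd.DataFrame({
        "motif": db.motif_ids, "auc": aucs, "nes": nes,
        "enriched": enriched,
        "n_hits": [len(hits.get(m, [])) for m in db.motif_ids],
    })
    return MotifEnrichmentResult(table, hits, list(query_regions),
                                 nes_threshold, auc_fraction, rank_fraction)


@dataclass
class Cistrome:
    """A TF's enriched-and-hit region set (direct or extended evidence)."""

    tf: str
    klass: str  # 'direct' | 'extended'
    regions: set = field(default_factory=set)
    contributing_motifs: set = field(default_factory=set)


def build_cistromes(enrichment: MotifEnrichmentResult,
                    annotations: pd.DataFrame) -> list:
    """Union enriched motifs' hit regions into per-TF cistromes.

    The direct cistrome of a TF uses only its class='direct' motifs; the
    extended cistrome unions direct, similarity and orthology annotations.
    Motifs sharing a merged-consensus group contribute once (the group's
    first enriched member in motif order).  Motifs without a TF annotation
    are skipped.
    """
    ann = annotations.set_index("motif")
    enriched_motifs = list(
        enrichment.table.loc[enrichment.table["enriched"], "motif"])
    seen_groups = set()
    per_tf: dict = {}
    for motif in enriched_motifs:
        if motif not in ann.index:
            continue  # unannotated motif: no TF to credit
        rows = ann.loc[[motif]]
        for _, row in rows.iterrows():
            group = row.get("group", motif)
            gkey = (row["tf"], group)
            if gkey in seen_groups:
                continue
            seen_groups.add(gkey)
            hits = set(enrichment.hits.get(motif, []))
            if not hits:
                continue
            key_ext = (row["tf"], "extended")
            cis = per_tf.setdefault(
                key_ext, Cistrome(row["tf"], "extended"))
            cis.regions |= hits
            cis.contributing_motifs.add(motif)
            if row["class"] == "direct":
                key_dir = (row["tf"], "direct")
                cis = per_tf.setdefault(
                    key_dir, Cistrome(row["tf"], "direct"))
                cis.regions |= hits
                cis.contributing_motifs.add(motif)
    return [per_tf[k] for k in sorted(per_tf, key=lambda k: (k[0], k[1]))]


def score_feature_map(regions, motif_groups: dict, scores: pd.DataFrame,
                      min_score: float = 6.0) -> pd.DataFrame:
    """Binary region x motif-group hit table.

    A group hits a region when the maximum score among the group's member
    motifs reaches ``min_score``.
    """
    out = {}
    for gname, members in motif_groups.items():
        missing = [m for m in members if m not in scores.columns]
        if missing:
            raise KeyError(f"unknown motifs in group {gname}: {missing}")
        sub = scores.loc[list(regions), list(members)]
        out[gname] = (sub.max(axis=1) >= min_score).astype(int)
    return pd.DataFrame(out, index=list(regions))
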