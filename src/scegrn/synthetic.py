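"""Seeded synthetic multiome generator with planted regulatory structure.

Produces paired RNA/ATAC count matrices over shared cells, a motif-score
database, cell annotations, a genome layout, and a ground truth of planted
TF -> region -> gene edges (activating and repressing), so that every
downstream inference stage can be validated against known structure.

The generative model (all distributional choices are this module's own):

1.  Cell types with fixed sizes; each type has a topic mixture concentrated on
    one "home" topic; per-cell mixtures are Dirichlet draws centred on the
    type mixture.
2.  Per-topic region distributions put most of their mass on a disjoint block
    of regions; baseline accessibility probability is the cell-topic x
    topic-region product, rescaled to a target mean accessibility.
3.  TF expression counts are negative-binomial with a type-specific mean
    (high in the TF's home type).  For each planted (tf, region) edge the
    accessibility probability is shifted on the logit scale by
    weight x standardised log TF expression; repressor edges carry negative
    weights.  ATAC counts are Binomial(2, p), mimicking near-binary
    fragment counts.
4.  A target gene's negative-binomial mean is multiplicatively scaled by the
    standardised accessibility probability of its linked regions
    (exp(link_strength x mean z)), realising TF -> region -> gene
    co-variability.
5.  Each TF has one primary motif scoring high (mean ``motif_signal_mean``)
    in its target regions and at background elsewhere, one weaker
    similarity-annotated motif, plus unannotated decoy motifs.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from scipy.special import expit, logit

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "MultiomeDataset",
    "generate_truth",
    "simulate_multiome",
    "write_dataset",
    "read_dataset",
]

# recoverable TSS-distance window for region-gene links (bp)
WINDOW_MIN = 100
WINDOW_MAX = 50_000

CHROM = "chrS"

# stage keys for child-seed derivation from the one global seed
_STAGE_TRUTH = 0
_STAGE_SIM = 1
_STAGE_MOTIF = 2
_STAGE_QC = 3


class ConfigurationError(ValueError):
    pass


class LayoutError(ValueError):
    pass


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    """One global seed expands to fixed per-stage child seeds."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic multiome study.

    Defaults realise the package's reference study conditions: ~2,000 cells in
    5 cell types (one rare, 3%), 5 accessibility topics, 400 genes of which
    10 are TFs (2 repressors), 800 candidate regions, and a motif database of
    10 planted TF motifs (plus similarity variants) among 200 decoys.
    """

    n_cell_types: int = 5
    cells_per_type: tuple = (600, 500, 450, 390, 60)
    n_topics: int = 5
    n_genes: int = 400
    n_tfs: int = 10
    n_regions: int = 800
    n_decoy_motifs: int = 200
    n_repressor_tfs: int = 2
    regulatory_effect_size: float = 2.5  # logit-scale weight magnitude
    link_strength: float = 1.0  # expression-scale effect of accessibility
    nb_dispersion: float = 10.0  # NB size parameter; var = mu + mu^2/size
    motif_signal_mean: float = 10.0
    motif_noise_mean: float = 1.0
    genome_length: int = 12_000_000
    tss_min_gap: int = 25_000
    seed: int = 0

    # secondary knobs (documented, rarely moved)
    targets_per_tf: int = 8
    out_of_window_fraction: float = 0.15
    mean_accessibility: float = 0.12
    dirichlet_concentration: float = 50.0
    # most regions are accessible in every cell type (housekeeping chromatin);
    # only a minority is topic/type-specific, as in real tissue atlases
    shared_region_fraction: float = 0.7
    shared_mass: float = 0.5
    own_block_mass: float = 0.45
    tf_mean_home: float = 20.0
    tf_mean_away: float = 2.0

    def __post_init__(self):
        counts = dict(
            n_cell_types=self.n_cell_types, n_topics=self.n_topics,
            n_genes=self.n_genes, n_tfs=self.n_tfs, n_regions=self.n_regions,
            n_decoy_motifs=self.n_decoy_motifs,
        )
        for name, v in counts.items():
            if v < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {v}")
        if self.n_tfs > self.n_genes:
            raise ConfigurationError("n_tfs cannot exceed n_genes")
        if len(self.cells_per_type) != self.n_cell_types:
            raise ConfigurationError(
                "cells_per_type length must equal n_cell_types")
        if self.n_repressor_tfs < 0 or self.n_repressor_tfs > self.n_tfs:
            raise ConfigurationError("n_repressor_tfs must be in [0, n_tfs]")
        for name in ("regulatory_effect_size", "link_strength"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")

    @property
    def n_cells(self) -> int:
        return int(sum(self.cells_per_type))

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["cells_per_type"] = list(self.cells_per_type)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "cells_per_type" in d:
            d["cells_per_type"] = tuple(d["cells_per_type"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted regulatory structure: the answer key for the pipeline."""

    tf_list: list
    # rows: tf, region, gene, sign ('activating'/'repressing'), weight,
    #       out_of_window (bool)
    edges: pd.DataFrame
    cell_type_of_cell: pd.Series  # barcode -> type label
    topic_region_distributions: np.ndarray  # n_topics x n_regions, rows sum 1
    motif_of_tf: dict  # tf -> primary (direct) motif id
    gene_ids: list = field(default_factory=list)
    region_ids: list = field(default_factory=list)
    regions: pd.DataFrame = None  # chrom, start, end, name (0-based half-open)
    tss_table: pd.DataFrame = None  # gene, chrom, position, strand
    tf_home_type: dict = field(default_factory=dict)
    # repressors are expressed everywhere except this type (absent for
    # activators)
    tf_repressed_type: dict = field(default_factory=dict)

    def targets_of(self, tf: str, within_window: bool = True) -> set:
        """Planted target genes of a TF (by default only recoverable links)."""
        e = self.edges[self.edges["tf"] == tf]
        if within_window:
            e = e[~e["out_of_window"]]
        return set(e["gene"])

    def regions_of(self, tf: str, within_window: bool = True) -> set:
        e = self.edges[self.edges["tf"] == tf]
        if within_window:
            e = e[~e["out_of_window"]]
        return set(e["region"])

    def to_json_dict(self) -> dict:
        return {
            "tf_list": list(self.tf_list),
            "edges": self.edges.to_dict(orient="list"),
            "cell_type_of_cell": {
                "barcode": list(self.cell_type_of_cell.index),
                "cell_type": list(self.cell_type_of_cell.values),
            },
            "topic_region_distributions":
                self.topic_region_distributions.tolist(),
            "motif_of_tf": dict(self.motif_of_tf),
            "gene_ids": list(self.gene_ids),
            "region_ids": list(self.region_ids),
            "regions": self.regions.to_dict(orient="list"),
            "tss_table": self.tss_table.to_dict(orient="list"),
            "tf_home_type": dict(self.tf_home_type),
            "tf_repressed_type": dict(self.tf_repressed_type),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruth":
        ct = pd.Series(
            d["cell_type_of_cell"]["cell_type"],
            index=d["cell_type_of_cell"]["barcode"],
        )
        return cls(
            tf_list=list(d["tf_list"]),
            edges=pd.DataFrame(d["edges"])[
                ["tf", "region", "gene", "sign", "weight", "out_of_window"]],
            cell_type_of_cell=ct,
            topic_region_distributions=np.asarray(
                d["topic_region_distributions"], dtype=float),
            motif_of_tf=dict(d["motif_of_tf"]),
            gene_ids=list(d["gene_ids"]),
            region_ids=list(d["region_ids"]),
            regions=pd.DataFrame(d["regions"])[
                ["chrom", "start", "end", "name"]],
            tss_table=pd.DataFrame(d["tss_table"])[
                ["gene", "chrom", "position", "strand"]],
            tf_home_type=dict(d["tf_home_type"]),
            tf_repressed_type=dict(d.get("tf_repressed_type", {})),
        )


@dataclass
class MultiomeDataset:
    """Paired RNA and ATAC matrices over a shared, ordered cell barcode list."""

    rna_counts: np.ndarray  # gene x cell, non-negative integers
    atac_counts: np.ndarray  # region x cell, non-negative integers
    gene_ids: list
    region_ids: list
    cell_barcodes: list
    regions: pd.DataFrame  # chrom, start, end, name; 0-based half-open
    tss_table: pd.DataFrame  # gene, chrom, position, strand
    motif_scores: pd.DataFrame  # region x motif, non-negative reals
    motif_annotations: pd.DataFrame  # motif, tf, class, fdr, identity, group
    cell_annotations: pd.DataFrame  # barcode, cell_type, condition
    qc_metrics: pd.DataFrame  # barcode, total_fragments, frip, tss_enrichment

    def __post_init__(self):
        if self.rna_counts.shape[1] != self.atac_counts.shape[1]:
            raise ValueError("RNA and ATAC must share the cell axis")
        if (self.motif_scores.values < 0).any():
            raise ValueError("motif scores must be non-negative")
        ends = self.regions["end"].to_numpy()
        starts = self.regions["start"].to_numpy()
        if (starts < 0).any() or (starts >= ends).any():
            raise ValueError("regions must be 0-based half-open with start < end")

    @property
    def n_cells(self) -> int:
        return len(self.cell_barcodes)


def _place_tss(rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray:
    """Random TSS positions with a minimum pairwise gap, margin at both ends."""
    margin = WINDOW_MAX + 10_000
    slack = cfg.genome_length - 2 * margin - (cfg.n_genes - 1) * cfg.tss_min_gap
    if slack <= 0:
        raise LayoutError(
            f"genome_length={cfg.genome_length} too short to place "
            f"{cfg.n_genes} TSSs with tss_min_gap={cfg.tss_min_gap}")
    u = np.sort(rng.uniform(0, slack, size=cfg.n_genes))
    pos = margin + u + np.arange(cfg.n_genes) * cfg.tss_min_gap
    return pos.astype(np.int64)


def generate_truth(config: SyntheticConfig) -> GroundTruth:
    """Plant cell types, topics, and TF -> region -> gene edges.

    Deterministic given ``config.seed``. Each TF receives one primary motif,
    at least three target regions, and each planted region is linked to 1-3
    genes. About ``out_of_window_fraction`` of links are deliberately placed
    outside the recoverable 100 bp - 50 kb TSS window and flagged.
    """
    cfg = config
    rng = _stage_rng(cfg.seed, _STAGE_TRUTH)

    gene_ids = [f"gene{i:04d}" for i in range(cfg.n_genes)]
    tf_list = gene_ids[: cfg.n_tfs]
    region_ids = [f"region{i:04d}" for i in range(cfg.n_regions)]

    tss_pos = _place_tss(rng, cfg)
    strands = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")
    tss_table = pd.DataFrame({
        "gene": gene_ids, "chrom": CHROM,
        "position": tss_pos, "strand": strands,
    })

    # topic-region distributions: a large shared (housekeeping) block every
    # topic draws from, plus small topic-specific blocks
    phi = np.full((cfg.n_topics, cfg.n_regions), np.nan)
    n_shared = int(round(cfg.shared_region_fraction * cfg.n_regions))
    shared_idx = np.arange(n_shared)
    blocks = np.array_split(np.arange(n_shared, cfg.n_regions), cfg.n_topics)
    cross_mass = max(0.0, 1.0 - cfg.shared_mass - cfg.own_block_mass)
    for t in range(cfg.n_topics):
        w = np.zeros(cfg.n_regions)
        w_sh = rng.uniform(0.5, 1.5, size=n_shared)
        w[shared_idx] = cfg.shared_mass * w_sh / w_sh.sum()
        for b in range(cfg.n_topics):
            mass = cfg.own_block_mass if b == t else \
                cross_mass / max(cfg.n_topics - 1, 1)
            if len(blocks[b]) == 0:
                continue
            w_b = rng.uniform(0.5, 1.5, size=len(blocks[b]))
            w[blocks[b]] = mass * w_b / w_b.sum()
        phi[t] = w / w.sum()

    # cell type labels
    barcodes = [f"cell{i:05d}" for i in range(cfg.n_cells)]
    type_labels = []
    for k, n in enumerate(cfg.cells_per_type):
        type_labels += [f"type{k}"] * int(n)
    cell_type = pd.Series(type_labels, index=barcodes, name="cell_type")

    # Activators are expressed in one home type (round-robin).  A repressor
    # is broadly expressed: present in every type except one, whose program
    # it keeps shut wherever it is present — so its "repressed type" is where
    # its absence lets the targets open.
    repressor_set = set(tf_list[cfg.n_tfs - cfg.n_repressor_tfs:]) \
        if cfg.n_repressor_tfs else set()
    tf_home = {}
    tf_repressed_type = {}
    for i, tf in enumerate(tf_list):
        if tf in repressor_set:
            r = i % cfg.n_cell_types
            tf_repressed_type[tf] = f"type{r}"
            tf_home[tf] = f"type{(r + 1) % cfg.n_cell_types}"  # nominal
        else:
            tf_home[tf] = f"type{i % cfg.n_cell_types}"

    # target genes: disjoint across TFs, never TFs themselves
    non_tf = np.array(gene_ids[cfg.n_tfs:])
    need = cfg.n_tfs * cfg.targets_per_tf
    if need > len(non_tf):
        raise ConfigurationError(
            "not enough non-TF genes for the requested targets_per_tf")
    chosen = rng.choice(len(non_tf), size=need, replace=False)
    repressors = repressor_set

    gene_pos = dict(zip(gene_ids, tss_pos))
    # Enhancer placement encodes the causal story.  An activator's targets
    # carry a flat (shared-block) baseline and are opened by the TF itself,
    # so with zero effect size there is no TF-region association.  A
    # repressor's targets are the repressed type's own enhancers (its topic
    # block): they open where the broadly-expressed repressor is absent, and
    # they form one coherent differential set for the motif step.
    shared_pool = list(rng.permutation(shared_idx))
    block_pools = [list(rng.permutation(b)) for b in blocks]
    if cfg.n_tfs * cfg.targets_per_tf > cfg.n_regions:
        raise ConfigurationError("not enough regions to plant all TF targets")

    def _draw_region(pool) -> int:
        if pool:
            return int(pool.pop())
        for other in [shared_pool] + block_pools:
            if other:
                return int(other.pop())
        raise ConfigurationError("not enough regions to plant all TF targets")
    region_start = {}  # region id -> start
    rows = []
    for i, tf in enumerate(tf_list):
        sign = -1.0 if tf in repressors else 1.0
        sign_label = "repressing" if tf in repressors else "activating"
        if sign < 0:
            repressed_topic = int(tf_repressed_type[tf][4:]) % cfg.n_topics
        targets = non_tf[chosen[i * cfg.targets_per_tf:(i + 1) * cfg.targets_per_tf]]
        for g in targets:
            pool = shared_pool if sign > 0 else block_pools[repressed_topic]
            rid = region_ids[_draw_region(pool)]
            out = bool(rng.random() < cfg.out_of_window_fraction)
            if out:
                dist = int(rng.uniform(WINDOW_MAX + 5_000, WINDOW_MAX + 30_000))
            else:
                dist = int(rng.uniform(500, 40_000))
            side = 1 if rng.random() < 0.5 else -1
            # place the 500 bp region so its nearest edge sits `dist` from TSS
            tss = gene_pos[g]
            if side > 0:
                start = tss + dist
            else:
                start = tss - dist - 500
            start = int(np.clip(start, 0, cfg.genome_length - 500))
            region_start[rid] = start
            weight = sign * cfg.regulatory_effect_size * rng.uniform(0.9, 1.1)
            rows.append((tf, rid, g, sign_label, weight, out))
            # the region may also regulate 1-2 more of the same TF's targets
            # whose TSS falls inside the window
            extra = 0
            for g2 in targets:
                if g2 == g or extra >= 2:
                    continue
                d2 = min(abs(start - gene_pos[g2]),
                         abs(start + 500 - gene_pos[g2]))
                if start <= gene_pos[g2] < start + 500:
                    d2 = 0
                if WINDOW_MIN <= d2 <= WINDOW_MAX:
                    rows.append((tf, rid, g2, sign_label, weight, False))
                    extra += 1

    edges = pd.DataFrame(
        rows, columns=["tf", "region", "gene", "sign", "weight",
                       "out_of_window"])

    # background regions placed uniformly, avoiding collisions is unnecessary
    # (regions may overlap in a synthetic genome)
    starts = np.empty(cfg.n_regions, dtype=np.int64)
    for j, rid in enumerate(region_ids):
        if rid in region_start:
            starts[j] = region_start[rid]
        else:
            starts[j] = int(rng.integers(0, cfg.genome_length - 500))
    regions = pd.DataFrame({
        "chrom": CHROM, "start": starts, "end": starts + 500,
        "name": region_ids,
    })

    motif_of_tf = {tf: f"motif_{tf}_direct" for tf in tf_list}

    return GroundTruth(
        tf_list=tf_list, edges=edges, cell_type_of_cell=cell_type,
        topic_region_distributions=phi, motif_of_tf=motif_of_tf,
        gene_ids=gene_ids, region_ids=region_ids, regions=regions,
        tss_table=tss_table, tf_home_type=tf_home,
        tf_repressed_type=tf_repressed_type,
    )


def _nb_draw(rng, mean, size_param, shape=None):
    """Negative binomial with var = mu + mu^2/size."""
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=shape)


def simulate_multiome(truth: GroundTruth, config: SyntheticConfig,
                      rng: np.random.Generator | None = None,
                      ) -> MultiomeDataset:
    """Draw paired counts realising the planted structure (see module docs).

    Accessibility probabilities that leave (0, 1) after the planted logit
    shift are clamped to [1e-6, 1-1e-6]; this is recorded, never an error.
    """
    cfg = config
    if rng is None:
        rng = _stage_rng(cfg.seed, _STAGE_SIM)
    n_cells = cfg.n_cells
    n_types = cfg.n_cell_types
    barcodes = list(truth.cell_type_of_cell.index)
    type_of = truth.cell_type_of_cell.values
    type_names = [f"type{k}" for k in range(n_types)]
    type_idx = np.array([type_names.index(t) for t in type_of])

    # per-type topic mixtures, concentrated on the home topic
    mixtures = np.full((n_types, cfg.n_topics),
                       (1 - 0.8) / max(cfg.n_topics - 1, 1))
    for k in range(n_types):
        if cfg.n_topics == 1:
            mixtures[k, :] = 1.0
        else:
            mixtures[k, k % cfg.n_topics] = 0.8
    theta = np.empty((n_cells, cfg.n_topics))
    for c in range(n_cells):
        theta[c] = rng.dirichlet(mixtures[type_idx[c]]
                                 * cfg.dirichlet_concentration)

    phi = truth.topic_region_distributions
    p0 = theta @ phi
    p = p0 * (cfg.mean_accessibility / p0.mean())
    p = np.clip(p, 1e-6, 1 - 1e-6)

    # TF expression first (drives the planted shifts)
    gene_index = {g: i for i, g in enumerate(truth.gene_ids)}
    region_index = {r: j for j, r in enumerate(truth.region_ids)}
    tf_counts = np.zeros((len(truth.tf_list), n_cells), dtype=np.int64)
    for i, tf in enumerate(truth.tf_list):
        if tf in truth.tf_repressed_type:
            # broadly expressed repressor, absent from the repressed type
            absent = truth.tf_repressed_type[tf]
            mu = np.where(type_of == absent, cfg.tf_mean_away,
                          cfg.tf_mean_home)
        else:
            home = truth.tf_home_type[tf]
            mu = np.where(type_of == home, cfg.tf_mean_home,
                          cfg.tf_mean_away)
        tf_counts[i] = _nb_draw(rng, mu, cfg.nb_dispersion)

    tf_z = np.empty_like(tf_counts, dtype=float)
    for i in range(len(truth.tf_list)):
        x = np.log1p(tf_counts[i].astype(float))
        sd = x.std()
        tf_z[i] = (x - x.mean()) / sd if sd > 0 else 0.0

    # planted logit shifts, one per distinct (tf, region) pair
    lp = logit(p)
    n_clamped = 0
    seen = set()
    for _, row in truth.edges.iterrows():
        key = (row["tf"], row["region"])
        if key in seen:
            continue
        seen.add(key)
        ti = truth.tf_list.index(row["tf"])
        rj = region_index[row["region"]]
        lp[:, rj] += row["weight"] * tf_z[ti]
    p = expit(lp)
    n_clamped = int(((p <= 1e-6) | (p >= 1 - 1e-6)).sum())
    p = np.clip(p, 1e-6, 1 - 1e-6)

    atac = rng.binomial(2, p.T).astype(np.int64)  # region x cell

    # standardised accessibility per region (drives target genes)
    z_acc = (p - p.mean(axis=0)) / np.maximum(p.std(axis=0), 1e-12)

    # gene expression
    base = rng.lognormal(mean=np.log(2.0), sigma=0.5, size=cfg.n_genes)
    type_mult = rng.lognormal(mean=0.0, sigma=0.3,
                              size=(cfg.n_genes, n_types))
    mu_gc = base[:, None] * type_mult[np.arange(cfg.n_genes)[:, None],
                                      type_idx[None, :]]
    in_edges = truth.edges
    for g, sub in in_edges.groupby("gene"):
        gi = gene_index[g]
        rjs = [region_index[r] for r in sub["region"].unique()]
        shift = z_acc[:, rjs].mean(axis=1)
        mu_gc[gi] = mu_gc[gi] * np.exp(cfg.link_strength * shift)

    rna = _nb_draw(rng, mu_gc, cfg.nb_dispersion).astype(np.int64)
    # TFs keep the counts that generated the shifts
    for i, tf in enumerate(truth.tf_list):
        rna[gene_index[tf]] = tf_counts[i]

    motif_scores, motif_annotations = simulate_motif_database(truth, cfg)

    # QC metrics simulated directly (no fragment-level simulation)
    qrng = _stage_rng(cfg.seed, _STAGE_QC)
    log10_frag = qrng.normal(4.0, 0.25, size=n_cells)
    qc = pd.DataFrame({
        "barcode": barcodes,
        "total_fragments": np.round(10 ** log10_frag).astype(np.int64),
        "frip": qrng.beta(24, 6, size=n_cells),
        "tss_enrichment": qrng.gamma(8.0, 0.5, size=n_cells),
    })

    conditions = np.where(
        np.isin(type_of, type_names[-2:]), "perturbed", "control")
    cell_annotations = pd.DataFrame({
        "barcode": barcodes, "cell_type": type_of, "condition": conditions,
    })

    ds = MultiomeDataset(
        rna_counts=rna, atac_counts=atac,
        gene_ids=list(truth.gene_ids), region_ids=list(truth.region_ids),
        cell_barcodes=barcodes, regions=truth.regions.copy(),
        tss_table=truth.tss_table.copy(), motif_scores=motif_scores,
        motif_annotations=motif_annotations,
        cell_annotations=cell_annotations, qc_metrics=qc,
    )
    ds.n_clamped_probabilities = n_clamped
    return ds


def simulate_motif_database(truth: GroundTruth, cfg: SyntheticConfig):
    """Region x motif scores plus annotations (direct + similarity + decoys).

    Standalone entry point for motif-step studies that do not need the count
    matrices; :func:`simulate_multiome` uses the same draw.
    """
    rng = _stage_rng(cfg.seed, _STAGE_MOTIF)
    region_index = {r: j for j, r in enumerate(truth.region_ids)}
    motifs, ann_rows = [], []
    cols = {}
    for tf in truth.tf_list:
        targets = [region_index[r] for r in
                   truth.edges.loc[truth.edges["tf"] == tf, "region"].unique()]
        for suffix, strength, klass in (
                ("direct", 1.0, "direct"), ("sim", 0.7, "similarity")):
            mid = f"motif_{tf}_{suffix}"
            col = rng.exponential(cfg.motif_noise_mean, size=cfg.n_regions)
            col[targets] = np.maximum(
                rng.normal(cfg.motif_signal_mean * strength, 1.0,
                           size=len(targets)), 0.0)
            motifs.append(mid)
            cols[mid] = col
            ann_rows.append((
                mid, tf, klass,
                0.0005 if klass == "similarity" else np.nan,
                np.nan, mid))
    for d in range(cfg.n_decoy_motifs):
        mid = f"motif_decoy{d:04d}"
        motifs.append(mid)
        cols[mid] = rng.exponential(cfg.motif_noise_mean, size=cfg.n_regions)
        # decoys carry no TF annotation
    scores = pd.DataFrame(cols, index=truth.region_ids)
    ann = pd.DataFrame(
        ann_rows,
        columns=["motif", "tf", "class", "similarity_fdr",
                 "orthology_identity", "group"])
    return scores, ann


# ---------------------------------------------------------------------------
# on-disk layout


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_dataset(dataset: MultiomeDataset, truth: GroundTruth | None,
                  out_dir: str, force: bool = False) -> dict:
    """Write a dataset (and optional truth) as plain-text files + manifest.

    MatrixMarket for the count matrices, TSV for tables, BED4 for regions,
    JSON for the ground truth.  Refuses a non-empty directory unless
    ``force`` is set.  Returns the manifest (file -> sha256).
    """
    os.makedirs(out_dir, exist_ok=True)
    existing = [f for f in os.listdir(out_dir) if not f.startswith(".")]
    if existing and not force:
        raise FileExistsError(
            f"{out_dir} is not empty; pass force=True to overwrite")

    def path(name):
        return os.path.join(out_dir, name)

    spio.mmwrite(path("rna_counts.mtx"),
                 sparse.coo_matrix(dataset.rna_counts), field="integer")
    spio.mmwrite(path("atac_counts.mtx"),
                 sparse.coo_matrix(dataset.atac_counts), field="integer")
    _write_lines(path("barcodes.tsv"), dataset.cell_barcodes)
    _write_lines(path("genes.tsv"), dataset.gene_ids)
    _write_lines(path("region_ids.tsv"), dataset.region_ids)
    reg = dataset.regions.sort_values(["chrom", "start"], kind="mergesort")
    reg[["chrom", "start", "end", "name"]].to_csv(
        path("regions.bed"), sep="\t", header=False, index=False)
    dataset.tss_table.to_csv(path("tss.tsv"), sep="\t", index=False,
                             na_rep=".")
    dataset.motif_scores.to_csv(path("motif_scores.tsv"), sep="\t",
                                index_label="region", na_rep=".")
    dataset.motif_annotations.to_csv(path("motif_annotations.tsv"), sep="\t",
                                     index=False, na_rep=".")
    dataset.cell_annotations.to_csv(path("cell_annotations.tsv"), sep="\t",
                                    index=False, na_rep=".")
    dataset.qc_metrics.to_csv(path("qc_metrics.tsv"), sep="\t", index=False,
                              na_rep=".")
    if truth is not None:
        with open(path("truth.json"), "w") as fh:
            json.dump(truth.to_json_dict(), fh, sort_keys=True)

    files = sorted(f for f in os.listdir(out_dir)
                   if f != "manifest.json" and not f.startswith("."))
    manifest = {f: _sha256(path(f)) for f in files}
    with open(path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return manifest


def _write_lines(path, items):
    with open(path, "w") as fh:
        for it in items:
            fh.write(f"{it}\n")


def read_dataset(in_dir: str):
    """Read a dataset directory written by :func:`write_dataset`.

    Returns ``(MultiomeDataset, GroundTruth or None)``.
    """
    def path(name):
        return os.path.join(in_dir, name)

    rna = np.asarray(spio.mmread(path("rna_counts.mtx")).todense(),
                     dtype=np.int64)
    atac = np.asarray(spio.mmread(path("atac_counts.mtx")).todense(),
                      dtype=np.int64)
    barcodes = _read_lines(path("barcodes.tsv"))
    genes = _read_lines(path("genes.tsv"))
    region_ids = _read_lines(path("region_ids.tsv"))
    regions = pd.read_csv(path("regions.bed"), sep="\t", header=None,
                          names=["chrom", "start", "end", "name"])
    # restore the matrix row order
    regions = regions.set_index("name").loc[region_ids].reset_index()
    regions = regions[["chrom", "start", "end", "name"]]
    tss = pd.read_csv(path("tss.tsv"), sep="\t", na_values=".")
    motif_scores = pd.read_csv(path("motif_scores.tsv"), sep="\t",
                               index_col="region", na_values=".")
    ann = pd.read_csv(path("motif_annotations.tsv"), sep="\t", na_values=".")
    cell_ann = pd.read_csv(path("cell_annotations.tsv"), sep="\t",
                           na_values=".")
    qc = pd.read_csv(path("qc_metrics.tsv"), sep="\t", na_values=".")
    truth = None
    if os.path.exists(path("truth.json")):
        with open(path("truth.json")) as fh:
            truth = GroundTruth.from_json_dict(json.load(fh))
    ds = MultiomeDataset(
        rna_counts=rna, atac_counts=atac, gene_ids=genes,
        region_ids=region_ids, cell_barcodes=barcodes, regions=regions,
        tss_table=tss, motif_scores=motif_scores, motif_annotations=ann,
        cell_annotations=cell_ann, qc_metrics=qc,
    )
    return ds, truth


def _read_lines(path):
    with open(path) as fh:
        return [ln.rstrip("\n") for ln in fh]
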