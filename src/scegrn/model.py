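"""Model/Results surface over the full eGRN inference pipeline.

``EGRNModel`` is built from a :class:`~scegrn.synthetic.MultiomeDataset`
(real or synthetic); ``fit()`` runs QC, topic modelling, motif enrichment,
link scoring, eGRN assembly, activity scoring and specificity, and returns an
:class:`EGRNResults` carrying the fitted objects, diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assembly, links, motifs, preprocessing, scoring, topics

__all__ = ["EGRNModel", "EGRNResults"]


class EGRNModel:
    """Enhancer-GRN inference model over a paired RNA/ATAC dataset.

    Parameters
    ----------
    dataset : MultiomeDataset
        Paired matrices with annotations, motif scores and a TSS table.
    tf_list : list of str
        Genes to treat as transcription factors.
    topic_grid : sequence of int
        Candidate topic counts for LDA model selection.
    apply_qc : bool
        Run cell/gene QC before fitting (synthetic data is usually clean).
    """

    def __init__(self, dataset, tf_list, topic_grid=(8,),
                 qc_thresholds=None, apply_qc: bool = True,
                 lda_iterations: int = 150,
                 nes_threshold: float = 3.0, rank_fraction: float = 0.05,
                 auc_fraction: float = 0.005, min_auc_ranks: int = 20,
                 sign_rule: assembly.SignRule | None = None,
                 gbm_params: links.GBMParams | None = None,
                 n_pseudobulks: int = 150, cells_per_pseudobulk: int = 15,
                 rho_min: float = 0.2, aucell_top_fraction: float = 0.05,
                 dar_p_adj: float = 5e-3, dar_lfc: float = 1.5,
                 pairwise_dars: bool = True):
        self.dataset = dataset
        self.tf_list = list(tf_list)
        self.topic_grid = tuple(topic_grid)
        self.qc_thresholds = qc_thresholds or preprocessing.QCThresholds()
        self.apply_qc = apply_qc
        self.lda_iterations = lda_iterations
        self.nes_threshold = nes_threshold
        self.rank_fraction = rank_fraction
        self.auc_fraction = auc_fraction
        self.min_auc_ranks = min_auc_ranks
        self.sign_rule = sign_rule or assembly.SignRule()
        self.gbm_params = gbm_params or links.GBMParams()
        self.n_pseudobulks = n_pseudobulks
        self.cells_per_pseudobulk = cells_per_pseudobulk
        self.rho_min = rho_min
        self.aucell_top_fraction = aucell_top_fraction
        self.dar_p_adj = dar_p_adj
        self.dar_lfc = dar_lfc
        self.pairwise_dars = pairwise_dars

    @classmethod
    def from_dataset(cls, dataset, tf_list=None, **kwargs):
        """Build a model from a dataset, inferring TFs from motif annotations
        when ``tf_list`` is not given."""
        if tf_list is None:
            tf_list = list(pd.unique(dataset.motif_annotations["tf"].dropna()))
        return cls(dataset, tf_list, **kwargs)

    def fit(self, seed: int = 0) -> "EGRNResults":
        ds = self.dataset
        log: list = []

        # --- QC ------------------------------------------------------------
        if self.apply_qc:
            kept, qc_report = preprocessing.filter_cells(ds, self.qc_thresholds)
            keep_mask = np.isin(np.asarray(ds.cell_barcodes), kept)
        else:
            kept = list(ds.cell_barcodes)
            qc_report = None
            keep_mask = np.ones(len(ds.cell_barcodes), dtype=bool)
        rna = np.asarray(ds.rna_counts)[:, keep_mask]
        atac = np.asarray(ds.atac_counts)[:, keep_mask]
        rna, gene_ids = preprocessing.filter_genes(
            rna, ds.gene_ids, self.qc_thresholds.min_cells_per_gene)
        cell_types = ds.cell_annotations.set_index("barcode").loc[
            kept, "cell_type"].to_numpy()

        expr = preprocessing.lognormalize(rna)

        # --- topic model ---------------------------------------------------
        binary = topics.binarize(atac)
        candidates = [
            topics.fit_lda(binary, T, n_iterations=self.lda_iterations,
                           seed=seed + 1000 + T)
            for T in self.topic_grid
        ]
        topic_model = topics.select_model(candidates)
        selection = topics.model_selection_table(candidates)
        imputed = topics.impute_accessibility(topic_model)

        # --- DARs and motif enrichment --------------------------------------
        dar_tables = topics.dar_contrasts(
            imputed, cell_types, region_ids=ds.region_ids,
            pairwise=self.pairwise_dars,
            p_adj_threshold=self.dar_p_adj, lfc_threshold=self.dar_lfc)
        db = motifs.MotifDatabase(ds.motif_scores, ds.motif_annotations)
        cistromes: dict = {}
        enrichments = {}
        queries = {name: list(table.loc[table["passes"], "region"])
                   for name, table in dar_tables.items()}
        for group, query in queries.items():
            if not query:
                log.append((group, "no DARs pass"))
                continue
            enr = motifs.enrich_motifs(
                db, query, auc_fraction=self.auc_fraction,
                rank_fraction=self.rank_fraction,
                nes_threshold=self.nes_threshold,
                min_auc_ranks=self.min_auc_ranks)
            enrichments[group] = enr
            for cis in motifs.build_cistromes(enr, ds.motif_annotations):
                key = (cis.tf, cis.klass)
                if key in cistromes:
                    cistromes[key].regions |= cis.regions
                    cistromes[key].contributing_motifs |= \
                        cis.contributing_motifs
                else:
                    cistromes[key] = cis
        cistrome_list = [cistromes[k] for k in sorted(cistromes)]

        # --- link scoring ----------------------------------------------------
        pairs = links.candidate_pairs(ds.regions, ds.tss_table)
        pairs = pairs[pairs["gene"].isin(gene_ids)]
        rg = links.region_gene_scores(
            imputed, expr, pairs, gene_ids, ds.region_ids, seed=seed,
            params=self.gbm_params)
        tfs_present = [t for t in self.tf_list if t in gene_ids]
        tg = links.tf_gene_adjacencies(expr, gene_ids, tfs_present, seed=seed,
                                       params=self.gbm_params)

        # --- assembly --------------------------------------------------------
        act, rep, n_undef = assembly.sign_edges(rg, self.sign_rule)
        pruned_by_sign = {
            "activating": assembly.prune_region_gene(act),
            "repressing": assembly.prune_region_gene(rep),
        }
        egrns = assembly.assemble_egrns(cistrome_list, pruned_by_sign, tg,
                                        log=log)

        # --- activity scoring -------------------------------------------------
        pb = scoring.make_pseudobulks(
            expr, cell_types, self.n_pseudobulks, self.cells_per_pseudobulk,
            seed=seed + 7)
        gene_sets = {eg.name: eg.target_genes for eg in egrns
                     if eg.target_genes}
        if gene_sets:
            auc_pb = scoring.aucell_matrix(pb.values, gene_ids, gene_sets,
                                           self.aucell_top_fraction)
        else:
            auc_pb = pd.DataFrame(index=[], columns=range(pb.values.shape[1]))
        tf_expr_pb = pd.DataFrame(pb.values, index=gene_ids)
        final_egrns, corr_report = scoring.filter_egrns(
            egrns, tf_expr_pb, auc_pb, self.rho_min)

        final_sets_genes = {eg.name: eg.target_genes for eg in final_egrns}
        final_sets_regions = {eg.name: eg.target_regions for eg in final_egrns}
        if final_sets_genes:
            auc_gene = scoring.aucell_matrix(
                expr, gene_ids, final_sets_genes, self.aucell_top_fraction)
            rss_gene = scoring.rss(auc_gene, cell_types)
            auc_region = scoring.aucell_matrix(
                imputed.T, ds.region_ids, final_sets_regions,
                self.aucell_top_fraction)
            rss_region = scoring.rss(auc_region, cell_types)
        else:
            auc_gene = auc_region = pd.DataFrame()
            rss_gene = rss_region = pd.DataFrame()

        return EGRNResults(
            model=self, seed=seed, cell_barcodes=kept, gene_ids=gene_ids,
            cell_types=cell_types, qc_report=qc_report,
            normalized_expression=expr, topic_model=topic_model,
            model_selection=selection, imputed_accessibility=imputed,
            dar_tables=dar_tables, enrichments=enrichments,
            cistromes=cistrome_list, region_gene_table=rg,
            tf_gene_table=tg, n_undefined_rho=n_undef,
            all_egrns=egrns, egrns=final_egrns,
            correlation_report=corr_report, pseudobulks=pb,
            auc_pseudobulk=auc_pb, auc_gene=auc_gene, auc_region=auc_region,
            rss_gene=rss_gene, rss_region=rss_region, log=log,
        )


@dataclass
class EGRNResults:
    """Fitted eGRN inference results with diagnostics."""

    model: EGRNModel
    seed: int
    cell_barcodes: list
    gene_ids: list
    cell_types: np.ndarray
    qc_report: pd.DataFrame | None
    normalized_expression: np.ndarray
    topic_model: topics.TopicModel
    model_selection: pd.DataFrame
    imputed_accessibility: np.ndarray
    dar_tables: dict
    enrichments: dict
    cistromes: list
    region_gene_table: pd.DataFrame
    tf_gene_table: pd.DataFrame
    n_undefined_rho: int
    all_egrns: list
    egrns: list  # quality-filtered
    correlation_report: pd.DataFrame
    pseudobulks: scoring.PseudobulkSet
    auc_pseudobulk: pd.DataFrame
    auc_gene: pd.DataFrame
    auc_region: pd.DataFrame
    rss_gene: pd.DataFrame
    rss_region: pd.DataFrame
    log: list = field(default_factory=list)

    def summary(self) -> str:
        """Human-readable overview of the fitted networks."""
        lines = [
            "eGRN inference results",
            "=" * 54,
            f"cells: {len(self.cell_barcodes)}   genes: {len(self.gene_ids)}"
            f"   topics: {self.topic_model.T}",
            f"candidate eGRNs: {len(self.all_egrns)}   "
            f"high-quality eGRNs: {len(self.egrns)}",
            "",
            f"{'eGRN':<34}{'role':<12}{'genes':>6}{'regions':>8}"
            f"{'rho':>8}  top RSS type",
        ]
        for eg in self.egrns:
            top = ""
            if len(self.rss_gene) and eg.name in self.rss_gene.index:
                row = self.rss_gene.loc[eg.name]
                if row.notna().any():
                    top = str(row.idxmax())
            lines.append(
                f"{eg.name:<34}{(eg.role or '.'):<12}"
                f"{len(eg.target_genes):>6}{len(eg.target_regions):>8}"
                f"{(eg.tf_rho if eg.tf_rho is not None else float('nan')):>8.3f}"
                f"  {top}")
        return "\n".join(lines)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for eg in self.egrns:
            top = None
            if len(self.rss_gene) and eg.name in self.rss_gene.index:
                row = self.rss_gene.loc[eg.name]
                if row.notna().any():
                    top = row.idxmax()
            rows.append((eg.name, eg.tf, eg.annotation_class, eg.sign,
                         eg.role, len(eg.target_genes),
                         len(eg.target_regions), eg.tf_rho, top))
        return pd.DataFrame(rows, columns=[
            "egrn", "tf", "class", "sign", "role", "n_genes", "n_regions",
            "tf_rho", "top_rss_group"])

    def edge_frame(self) -> pd.DataFrame:
        return assembly.egrns_to_frame(self.egrns)
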