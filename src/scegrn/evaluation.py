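"""Recovery metrics of fitted eGRNs against a planted ground truth.

Used by the simulation studies: per-TF target-gene precision/recall, the
activator/repressor call of each TF's primary (highest-|rho|) network, and
whether each TF's specificity peaks in its most-expressing cell type.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "target_gene_recovery",
    "primary_egrn",
    "repressor_call_accuracy",
    "rss_home_type_hits",
]


def primary_egrn(egrns, tf):
    """A TF's primary network: the one whose activity tracks it best."""
    cand = [eg for eg in egrns if eg.tf == tf and eg.tf_rho is not None]
    if not cand:
        return None
    return max(cand, key=lambda e: abs(e.tf_rho))


def target_gene_recovery(egrns, truth) -> pd.DataFrame:
    """Per-TF precision/recall of recovered target genes vs planted links.

    Recovered genes are the union over the TF's final eGRNs; the reference is
    the planted target set restricted to recoverable (in-window) links.
    """
    rows = []
    for tf in truth.tf_list:
        true_genes = truth.targets_of(tf, within_window=True)
        found = set()
        for eg in egrns:
            if eg.tf == tf:
                found |= eg.target_genes
        tp = len(found & true_genes)
        rows.append((
            tf,
            tp / len(found) if found else 0.0,
            tp / len(true_genes) if true_genes else np.nan,
            len(found), len(true_genes),
        ))
    return pd.DataFrame(rows, columns=["tf", "precision", "recall",
                                       "n_recovered", "n_true"])


def repressor_call_accuracy(egrns, truth):
    """Fraction of planted repressors whose primary eGRN is called repressing.

    Returns ``(fraction, per-TF table)``; a repressor without any final eGRN
    counts as a miss.
    """
    repressors = sorted(truth.tf_repressed_type) if truth.tf_repressed_type \
        else [tf for tf in truth.tf_list
              if (truth.edges.loc[truth.edges["tf"] == tf, "sign"]
                  == "repressing").any()]
    rows = []
    for tf in repressors:
        eg = primary_egrn(egrns, tf)
        rows.append((tf, eg.role if eg else None,
                     bool(eg and eg.role == "repressing")))
    table = pd.DataFrame(rows, columns=["tf", "role", "correct"])
    frac = float(table["correct"].mean()) if len(table) else np.nan
    return frac, table


def rss_home_type_hits(egrns, rss_table: pd.DataFrame, truth):
    """Count TFs whose primary eGRN has maximal RSS in the home cell type.

    Broadly expressed repressors have no single most-expressing type, so they
    are the expected misses of this check.
    """
    hits = 0
    for tf in truth.tf_list:
        eg = primary_egrn(egrns, tf)
        if eg is None or not len(rss_table) \
                or eg.name not in rss_table.index:
            continue
        row = rss_table.loc[eg.name]
        if row.notna().any() and row.idxmax() == truth.tf_home_type[tf]:
            hits += 1
    return hits, len(truth.tf_list)
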