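"""Edge dichotomization, pruning rules, GSEA leading edge, eGRN unification."""

import numpy as np
import pandas as pd
import pytest

from scegrn.assembly import (EGRN, PRUNING_METHODS, SignRule, assemble_egrns,
                             egrns_to_frame, gsea_leading_edge,
                             prune_region_gene, sign_edges,
                             split_threshold_1d)
from scegrn.motifs import Cistrome


def _edges(rows):
    return pd.DataFrame(rows, columns=["source", "target", "importance",
                                       "rho"])


class TestSignEdges:
    def test_threshold_cases(self):
        table = _edges([("r1", "g1", 1.0, 0.05),
                        ("r2", "g1", 1.0, -0.05),
                        ("r3", "g1", 1.0, 0.01)])
        act, rep, n_undef = sign_edges(table)
        assert act["source"].tolist() == ["r1"]
        assert rep["source"].tolist() == ["r2"]
        assert n_undef == 0

    def test_undefined_rho_counted(self):
        table = _edges([("r1", "g1", 1.0, np.nan)])
        act, rep, n_undef = sign_edges(table)
        assert len(act) == 0 and len(rep) == 0 and n_undef == 1

    def test_negating_profile_flips_signs(self, rng):
        rho = rng.uniform(-0.5, 0.5, 30)
        table = _edges([(f"r{i}", "g", 1.0, r) for i, r in enumerate(rho)])
        flipped = table.assign(rho=-table["rho"])
        a1, r1, _ = sign_edges(table)
        a2, r2, _ = sign_edges(flipped)
        assert set(a1["source"]) == set(r2["source"])
        assert set(r1["source"]) == set(a2["source"])

    def test_zero_threshold_rejected(self):
        with pytest.raises(ValueError):
            SignRule(rho_threshold=0.0)


def brute_force_split(values):
    """Exhaustive 1-D two-cluster assignment by minimal total within-SS."""
    v = np.sort(np.asarray(values, dtype=float))
    best, best_c = np.inf, None
    for c in range(1, len(v)):
        lo, hi = v[:c], v[c:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if sse < best - 1e-15:
            best, best_c = sse, c
    return set(v[best_c:])


class TestSplitThreshold:
    def test_obvious_groups(self):
        thr, high = split_threshold_1d([1, 1, 1, 10, 10])
        assert sorted(np.asarray([1, 1, 1, 10, 10])[high]) == [10, 10]
        assert 1 < thr < 10

    def test_two_values(self):
        thr, high = split_threshold_1d([0, 5])
        assert np.asarray([0, 5])[high].tolist() == [5]

    def test_all_equal_is_error(self):
        with pytest.raises(ValueError):
            split_threshold_1d([2.0, 2.0, 2.0])

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 13))
            v = rng.random(n) * rng.choice([1, 10, 100])
            if np.ptp(v) == 0:
                continue
            _, high = split_threshold_1d(v)
            assert set(v[high]) == brute_force_split(v)


class TestPruneRegionGene:
    def test_topk_keeps_all_when_fewer(self):
        table = _edges([(f"r{i}", "g", float(i), 0.1) for i in range(4)])
        out = prune_region_gene(table)
        assert len(out["top5"]) == 4

    def test_quantile_rule(self):
        imp = [0.9, 0.5, 0.1, 0.05]
        table = _edges([(f"r{i}", "g", w, 0.1) for i, w in enumerate(imp)])
        out = prune_region_gene(table)
        cut = np.quantile(imp, 0.75)  # type-7 interpolation
        expected = {f"r{i}" for i, w in enumerate(imp) if w >= cut}
        assert set(out["q75"]["source"]) == expected == {"r0"}

    def test_every_subset_contained_in_input(self, rng):
        rows = [(f"r{i}", f"g{i % 3}", float(rng.random()), 0.1)
                for i in range(30)]
        table = _edges(rows)
        out = prune_region_gene(table)
        all_edges = set(zip(table["source"], table["target"]))
        assert set(out) == set(PRUNING_METHODS)
        for sub in out.values():
            assert set(zip(sub["source"], sub["target"])) <= all_edges

    def test_basc_high_group(self):
        table = _edges([("r0", "g", 1.0, 0.1), ("r1", "g", 1.0, 0.1),
                        ("r2", "g", 10.0, 0.1)])
        out = prune_region_gene(table)
        assert set(out["basc"]["source"]) == {"r2"}

    def test_basc_keeps_gene_whole_when_unsplittable(self):
        table = _edges([("r0", "g", 1.0, 0.1), ("r1", "g", 1.0, 0.1)])
        out = prune_region_gene(table)
        assert set(out["basc"]["source"]) == {"r0", "r1"}


def brute_force_es(order_importance, is_hit, p):
    """Plain cumulative walk of the weighted KS statistic."""
    w = np.abs(order_importance) ** p
    tot = w[is_hit].sum()
    n, s = len(is_hit), int(is_hit.sum())
    run, runs = 0.0, []
    for i in range(n):
        if is_hit[i]:
            run += w[i] / tot if tot > 0 else 1.0 / s
        else:
            run -= 1.0 / (n - s)
        runs.append(run)
    runs = np.array(runs)
    hi, lo = runs.max(), runs.min()
    return hi if hi >= -lo - 1e-12 else lo  # positive on magnitude ties


class TestGSEA:
    def test_unweighted_worked_example(self):
        ranking = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0],
                            index=list("abcde"))
        res = gsea_leading_edge(ranking, {"a", "b"}, weight_exponent=0)
        np.testing.assert_allclose(res.running_sum,
                                   [0.5, 1.0, 2 / 3, 1 / 3, 0.0], atol=1e-12)
        assert res.es == pytest.approx(1.0)
        assert set(res.leading_edge) == {"a", "b"}

    def test_bottom_set_has_negative_es_and_empty_leading_edge(self):
        ranking = pd.Series(np.arange(10, 0, -1, dtype=float),
                            index=[f"g{i}" for i in range(10)])
        res = gsea_leading_edge(ranking, {"g8", "g9"})
        assert res.es < 0
        assert res.leading_edge == []

    def test_ties_break_by_gene_identifier(self):
        ranking = pd.Series([1.0, 1.0, 1.0], index=["c", "a", "b"])
        res = gsea_leading_edge(ranking, {"a"})
        assert res.ranking == ["a", "b", "c"]

    def test_empty_or_full_set_errors(self):
        ranking = pd.Series([2.0, 1.0], index=["a", "b"])
        with pytest.raises(ValueError):
            gsea_leading_edge(ranking, set())
        with pytest.raises(ValueError):
            gsea_leading_edge(ranking, {"a", "b"})

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 51))
            genes = [f"g{i:03d}" for i in range(n)]
            imp = rng.random(n)
            ranking = pd.Series(imp, index=genes)
            s = int(rng.integers(1, n))
            gene_set = set(rng.choice(genes, size=s, replace=False))
            p = float(rng.choice([0.0, 1.0, 2.0]))
            res = gsea_leading_edge(ranking, gene_set, weight_exponent=p)
            order = np.lexsort((np.asarray(genes), -imp))
            is_hit = np.array([genes[i] in gene_set for i in order])
            expected = brute_force_es(imp[order], is_hit, p)
            assert res.es == pytest.approx(expected, abs=1e-12)


def _tf_gene_table(tf, importances):
    return pd.DataFrame({
        "source": tf,
        "target": list(importances),
        "importance": list(importances.values()),
        "rho": 0.5,
    })


class TestAssembleEGRNs:
    def test_disjoint_cistrome_gives_no_egrn(self):
        cis = [Cistrome("tfA", "direct", {"rX"})]
        act = _edges([("r1", "g1", 0.9, 0.5)])
        pruned = {"activating": prune_region_gene(act)}
        tg = _tf_gene_table("tfA", {"g1": 0.9, "g2": 0.1})
        assert assemble_egrns(cis, pruned, tg) == []

    def test_minimal_assembly(self):
        cis = [Cistrome("tfA", "direct", {"r1"})]
        act = _edges([("r1", "g1", 0.9, 0.5)])
        pruned = {"activating": prune_region_gene(act)}
        tg = _tf_gene_table("tfA", {"g1": 0.9, "g2": 0.1, "g3": 0.05})
        egrns = assemble_egrns(cis, pruned, tg)
        assert len(egrns) == 1
        eg = egrns[0]
        assert eg.target_genes == {"g1"} and eg.target_regions == {"r1"}
        assert eg.sign == "activating" and eg.annotation_class == "direct"
        frame = egrns_to_frame(egrns)
        assert frame.loc[0, ["tf", "region", "gene"]].tolist() == \
            ["tfA", "r1", "g1"]

    def test_union_monotone_in_pruning_methods(self, rng):
        genes = [f"g{i}" for i in range(8)]
        regions = [f"r{i}" for i in range(8)]
        act = _edges([(regions[i], genes[i % 4], float(rng.random()) + 0.1,
                       0.5) for i in range(8)])
        cis = [Cistrome("tfA", "direct", set(regions))]
        tg = _tf_gene_table(
            "tfA", {g: 1.0 - 0.1 * i for i, g in enumerate(genes)})
        full = prune_region_gene(act)
        sub = {k: full[k] for k in ("top5", "q75")}
        egrns_sub = assemble_egrns(cis, {"activating": sub}, tg)
        egrns_full = assemble_egrns(cis, {"activating": full}, tg)
        edges_sub = egrns_sub[0].edges if egrns_sub else set()
        edges_full = egrns_full[0].edges if egrns_full else set()
        assert edges_sub <= edges_full

    def test_sign_classes_stay_disjoint(self):
        act = _edges([("r1", "g1", 0.9, 0.5)])
        rep = _edges([("r2", "g2", 0.8, -0.5)])
        cis = [Cistrome("tfA", "direct", {"r1", "r2"})]
        tg = _tf_gene_table("tfA", {"g1": 0.9, "g2": 0.8, "g3": 0.1})
        egrns = assemble_egrns(cis, {
            "activating": prune_region_gene(act),
            "repressing": prune_region_gene(rep)}, tg)
        by_sign = {eg.sign: eg for eg in egrns}
        assert by_sign["activating"].edges.isdisjoint(
            by_sign["repressing"].edges)

    def test_gmt_serialization(self):
        from scegrn.assembly import egrns_to_gmt
        eg = EGRN("tfA", "direct", "activating",
                  target_genes={"g2", "g1"}, target_regions={"r1"})
        lines = egrns_to_gmt([eg]).splitlines()
        assert lines[0].split("\t") == [
            "tfA_direct_activating", "tfA|direct|activating|.", "g1", "g2"]
        regions = egrns_to_gmt([eg], kind="regions").splitlines()
        assert regions[0].endswith("\tr1")
        with pytest.raises(ValueError):
            egrns_to_gmt([eg], kind="edges")

    def test_provenance_records_methods(self):
        cis = [Cistrome("tfA", "direct", {"r1"})]
        act = _edges([("r1", "g1", 0.9, 0.5)])
        tg = _tf_gene_table("tfA", {"g1": 0.9, "g2": 0.1, "g3": 0.05})
        eg = assemble_egrns(cis, {"activating": prune_region_gene(act)},
                            tg)[0]
        prov = eg.provenance[("tfA", "r1", "g1")]
        assert prov == set(PRUNING_METHODS)
        assert isinstance(eg, EGRN)
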