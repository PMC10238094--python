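"""AUCell activity, pseudo-bulks, eGRN quality filter, RSS and statistics."""

import numpy as np
import pandas as pd
import pytest

from scegrn.assembly import EGRN
from scegrn.scoring import (aucell, aucell_matrix, filter_egrns,
                            make_pseudobulks, overlap_test, rss,
                            signature_enrichment)


def brute_force_aucell(values_one_cell, member_mask, R):
    order = np.argsort(-values_one_cell, kind="stable")
    hits, num, den = 0, 0, 0
    s = int(member_mask.sum())
    for k in range(1, R + 1):
        if member_mask[order[k - 1]]:
            hits += 1
        num += hits
        den += min(k, s)
    return num / den


class TestAUCell:
    def test_worked_example(self):
        # 10 features; set members at ranks 1 and 4; R = 5 -> AUC = 7/9
        vals = np.arange(10, 0, -1, dtype=float)[:, None]
        features = [f"f{i}" for i in range(10)]
        auc = aucell(vals, features, {"f0", "f3"}, top_fraction=0.5)
        assert auc[0] == pytest.approx(7 / 9, abs=1e-15)

    def test_maximal_and_minimal(self):
        vals = np.arange(20, 0, -1, dtype=float)[:, None]
        features = [f"f{i}" for i in range(20)]
        assert aucell(vals, features, {"f0", "f1"}, 0.5)[0] == 1.0
        assert aucell(vals, features, {"f18", "f19"}, 0.25)[0] == 0.0

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError):
            aucell(np.ones((3, 1)), ["a", "b", "c"], set())

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 51))
            vals = rng.random((n, 4))
            frac = float(rng.uniform(0.1, 1.0))
            R = max(1, int(np.floor(frac * n)))
            members = rng.choice(n, size=int(rng.integers(1, n)),
                                 replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[members] = True
            features = [f"f{i}" for i in range(n)]
            fset = {features[i] for i in members}
            got = aucell(vals, features, fset, frac)
            for c in range(4):
                assert got[c] == pytest.approx(
                    brute_force_aucell(vals[:, c], mask, R), abs=1e-12)

    def test_matrix_wrapper_shape(self, rng):
        vals = rng.random((30, 6))
        features = [f"f{i}" for i in range(30)]
        out = aucell_matrix(vals, features, {"s1": {"f0"}, "s2": {"f1", "f2"}})
        assert out.shape == (2, 6)
        assert ((out.values >= 0) & (out.values <= 1)).all()


class TestPseudobulks:
    def test_group_of_exactly_k_cells_gives_group_mean(self, rng):
        V = rng.random((5, 15))
        pb = make_pseudobulks(V, ["g"] * 15, n_pseudobulks=20,
                              cells_per_pseudobulk=15, seed=0)
        assert pb.values.shape == (5, 20)
        for j in range(20):
            np.testing.assert_allclose(pb.values[:, j], V.mean(axis=1),
                                       atol=1e-12)
        assert pb.with_replacement_groups == []

    def test_small_group_samples_with_replacement(self, rng):
        V = rng.random((3, 5))
        pb = make_pseudobulks(V, ["g"] * 5, n_pseudobulks=4,
                              cells_per_pseudobulk=15, seed=0)
        assert pb.with_replacement_groups == ["g"]

    def test_same_seed_same_sampling_log(self, rng):
        V = rng.random((4, 40))
        labels = ["a"] * 25 + ["b"] * 15
        pb1 = make_pseudobulks(V, labels, 10, 5, seed=3)
        pb2 = make_pseudobulks(V, labels, 10, 5, seed=3)
        assert pb1.sampling_log == pb2.sampling_log
        np.testing.assert_array_equal(pb1.values, pb2.values)

    def test_profile_means_track_group_mean(self, rng):
        V = rng.normal(0, 1, size=(1, 200))
        devs = []
        for seed in range(20):
            pb = make_pseudobulks(V, ["g"] * 200, 150, 15, seed=seed)
            devs.append(pb.values.mean() - V.mean())
        # SE of a mean of 150 pseudo-bulk profiles of 15 cells each
        se = V.std() / np.sqrt(15 * 150)
        assert abs(np.mean(devs)) < 2 * se

    def test_empty_group_is_error(self, rng):
        with pytest.raises(ValueError):
            make_pseudobulks(rng.random((2, 0)), [], 5, 3)


def _egrn(tf, klass, sign="activating", name_genes=("g1",)):
    return EGRN(tf, klass, sign, target_genes=set(name_genes),
                target_regions={"r1"}, edges={(tf, "r1", g)
                                              for g in name_genes})


def _profiles_with_rho(rho, n=60, seed=0):
    """Two vectors with exactly the requested Pearson correlation."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    z = rng.normal(0, 1, n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= (z @ x) / (x @ x) * x  # orthogonalize
    z /= z.std()
    y = rho * x + np.sqrt(1 - rho ** 2) * z
    return x, y


class TestFilterEGRNs:
    def _run(self, rho, klass="direct"):
        x, y = _profiles_with_rho(rho)
        eg = _egrn("tfA", klass)
        tf_expr = pd.DataFrame([x], index=["tfA"])
        auc = pd.DataFrame([y], index=[eg.name])
        return filter_egrns([eg], tf_expr, auc)

    def test_rho_threshold_is_strict(self):
        kept, report = self._run(0.19)
        assert kept == []
        kept, report = self._run(0.21)
        assert len(kept) == 1
        assert kept[0].role == "activating"
        assert report.loc[0, "rho"] == pytest.approx(0.21, abs=1e-9)

    def test_negative_correlation_labels_repressor(self):
        kept, _ = self._run(-0.8)
        assert kept[0].role == "repressing"

    def test_direct_supersedes_extended(self):
        x, y = _profiles_with_rho(0.9)
        direct = _egrn("tfA", "direct")
        extended = _egrn("tfA", "extended")
        tf_expr = pd.DataFrame([x], index=["tfA"])
        auc = pd.DataFrame([y, y], index=[direct.name, extended.name])
        kept, report = filter_egrns([direct, extended], tf_expr, auc)
        assert [eg.name for eg in kept] == [direct.name]
        assert report.set_index("egrn").loc[extended.name,
                                            "dropped_for_direct"]

    def test_zero_variance_flagged(self):
        eg = _egrn("tfA", "direct")
        tf_expr = pd.DataFrame([np.ones(10)], index=["tfA"])
        auc = pd.DataFrame([np.arange(10.0)], index=[eg.name])
        kept, report = filter_egrns([eg], tf_expr, auc)
        assert kept == []
        assert report.loc[0, "flag"] == "zero variance"

    def test_profile_order_invariance(self):
        x, y = _profiles_with_rho(0.5)
        perm = np.random.default_rng(5).permutation(len(x))
        eg = _egrn("tfA", "direct")
        k1, r1 = filter_egrns([eg], pd.DataFrame([x], index=["tfA"]),
                              pd.DataFrame([y], index=[eg.name]))
        eg2 = _egrn("tfA", "direct")
        k2, r2 = filter_egrns([eg2], pd.DataFrame([x[perm]], index=["tfA"]),
                              pd.DataFrame([y[perm]], index=[eg2.name]))
        assert r1.loc[0, "rho"] == pytest.approx(r2.loc[0, "rho"], abs=1e-12)


def jsd_base2(p, q):
    """Direct Jensen-Shannon divergence, base 2."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    m = (p + q) / 2

    def kl(a, b):
        mask = a > 0
        return float((a[mask] * np.log2(a[mask] / b[mask])).sum())

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


class TestRSS:
    def test_identical_distribution_scores_one(self):
        auc = pd.DataFrame([[0.5, 0.5, 0.0, 0.0]], index=["e"])
        out = rss(auc, ["a", "a", "b", "b"])
        assert out.loc["e", "a"] == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_support_scores_zero(self):
        auc = pd.DataFrame([[0.0, 0.0, 0.4, 0.6]], index=["e"])
        out = rss(auc, ["a", "a", "b", "b"])
        assert out.loc["e", "a"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_jsd_example(self):
        # P = (.5, 0, .5, 0), Q = (.5, .5, 0, 0) -> JSD = 0.5
        auc = pd.DataFrame([[0.5, 0.0, 0.5, 0.0]], index=["e"])
        labels = ["a", "a", "b", "b"]
        out = rss(auc, labels)
        assert out.loc["e", "a"] == pytest.approx(1 - np.sqrt(0.5),
                                                  abs=1e-12)

    def test_matches_direct_jsd_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 11))
            auc = rng.random((1, n))
            labels = rng.choice(["a", "b"], size=n)
            if (labels == "a").sum() == 0 or (labels == "b").sum() == 0:
                continue
            out = rss(pd.DataFrame(auc, index=["e"]), labels)
            p = auc[0] / auc[0].sum()
            for g in ("a", "b"):
                q = (labels == g) / (labels == g).sum()
                expected = 1 - np.sqrt(jsd_base2(p, q))
                assert out.loc["e", g] == pytest.approx(expected, abs=1e-12)

    def test_permutation_equivariance(self, rng):
        auc = rng.random((2, 12))
        labels = np.array(["a", "b", "c"] * 4)
        perm = rng.permutation(12)
        out1 = rss(pd.DataFrame(auc, index=["e1", "e2"]), labels)
        out2 = rss(pd.DataFrame(auc[:, perm], index=["e1", "e2"]),
                   labels[perm])
        pd.testing.assert_frame_equal(out1, out2[out1.columns])

    def test_all_zero_vector_is_nan(self):
        out = rss(pd.DataFrame([[0.0, 0.0]], index=["e"]), ["a", "b"])
        assert out.loc["e"].isna().all()


class TestSignatureEnrichment:
    def test_identical_groups_are_null(self, rng):
        v = rng.normal(0, 1, 40)
        values = np.concatenate([v, v])
        groups = ["a"] * 40 + ["b"] * 40
        out = signature_enrichment(values, groups, [("a", "b")])
        assert out.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[0, "p_value"] == pytest.approx(0.5, abs=1e-9)

    def test_planted_shift_is_detected(self, rng):
        a = rng.normal(3.0, 1.0, 50)
        b = rng.normal(0.0, 1.0, 50)
        out = signature_enrichment(np.concatenate([a, b]),
                                   ["a"] * 50 + ["b"] * 50, [("a", "b")])
        assert out.loc[0, "p_bonferroni"] < 1e-3

    def test_bonferroni_definition(self, rng):
        a = rng.normal(0.5, 1.0, 30)
        b = rng.normal(0.0, 1.0, 30)
        values = np.concatenate([a, b])
        groups = ["a"] * 30 + ["b"] * 30
        single = signature_enrichment(values, groups, [("a", "b")])
        five = signature_enrichment(values, groups, [("a", "b")] * 5)
        p = single.loc[0, "p_value"]
        assert five.loc[0, "p_bonferroni"] == pytest.approx(min(1, 5 * p),
                                                            abs=1e-12)

    def test_degenerate_variance_flagged(self):
        values = np.array([1.0] * 5 + [1.0] * 5)
        out = signature_enrichment(values, ["a"] * 5 + ["b"] * 5,
                                   [("a", "b")])
        assert np.isnan(out.loc[0, "p_value"])
        assert out.loc[0, "flag"] == "degenerate variance"

    def test_paired_mode(self, rng):
        base = rng.normal(0, 1, 30)
        values = np.concatenate([base + 1.0, base])
        out = signature_enrichment(values, ["a"] * 30 + ["b"] * 30,
                                   [("a", "b")], paired=True,
                                   alternative="greater")
        assert out.loc[0, "p_value"] < 1e-6


class TestOverlapTest:
    def test_hypergeometric_enumeration(self):
        universe = [f"u{i}" for i in range(8)]
        set_a = universe[:4]
        set_b = universe[1:4] + [universe[5]]  # overlap 3
        odds, p = overlap_test(set_a, set_b, universe)
        assert p == pytest.approx(34 / 70, abs=1e-12)

    def test_identical_half_sets(self):
        universe = [f"u{i}" for i in range(8)]
        odds, p = overlap_test(universe[:4], universe[:4], universe)
        assert odds == np.inf
        assert p == pytest.approx(2 / 70, abs=1e-12)

    def test_complementary_sets_have_zero_odds(self):
        universe = [f"u{i}" for i in range(8)]
        odds, _ = overlap_test(universe[:4], universe[4:], universe)
        assert odds == 0.0

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError):
            overlap_test({"a"}, {"b"}, set())
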