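import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from sctme.io import LRDatabase
from sctme.lr import (
    SubclusterPair,
    build_lr_db,
    count_interactions,
    estimate_variance_prior,
    lr_contrast,
    lr_mean_statistic,
    lr_test_sample,
    moderated_variance,
    permutation_test,
    significant_means,
)

from conftest import make_normalized


def pairs_df(pairs, source="src"):
    return pd.DataFrame(
        [{"ligand": l, "receptor": r, "source": source} for l, r in pairs]
    )


class TestBuildLrDb:
    def test_union_with_overlap(self):
        a = [(f"L{i}", f"R{i}") for i in range(10)]
        b = [(f"L{i}", f"R{i}") for i in range(5, 13)]
        db = build_lr_db([pairs_df(a, "a"), pairs_df(b, "b")])
        assert len(db) == 13

    def test_single_source_identity(self):
        a = [("L1", "R1"), ("L2", "R2")]
        db = build_lr_db([pairs_df(a, "only")])
        assert set(db.pair_tuples()) == set(a)
        assert set(db.pairs["source"]) == {"only"}

    def test_provenance_concatenated(self):
        db = build_lr_db([pairs_df([("L", "R")], "a"), pairs_df([("L", "R")], "b")])
        assert db.pairs.loc[0, "source"] == "a+b"

    def test_randomized_union_oracle(self):
        rng = np.random.default_rng(0)
        sources = []
        expected = set()
        for s in range(4):
            pairs = [
                (f"L{rng.integers(0, 20)}", f"R{rng.integers(0, 20)}")
                for _ in range(30)
            ]
            expected |= set(pairs)
            sources.append(pairs_df(pairs, f"s{s}"))
        db = build_lr_db(sources)
        assert set(db.pair_tuples()) == expected

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError):
            build_lr_db([])


def two_cluster_nm(rng, n_genes=6, n_a=10, n_b=10, boost=None):
    vals = rng.uniform(0.5, 1.5, size=(n_genes, n_a + n_b))
    if boost:
        for (gi, cluster), amount in boost.items():
            cols = slice(0, n_a) if cluster == "A" else slice(n_a, None)
            vals[gi, cols] += amount
    nm = make_normalized(vals)
    labels = pd.Series(["A"] * n_a + ["B"] * n_b, index=nm.cell_ids)
    return nm, labels


class TestLrMeanStatistic:
    def test_arithmetic(self):
        vals = np.zeros((2, 4))
        vals[0, :2] = 2.0  # ligand in sender cluster A
        vals[1, 2:] = 1.0  # receptor in receiver cluster B
        nm = make_normalized(vals, genes=["LIG", "REC"])
        labels = pd.Series(["A", "A", "B", "B"], index=nm.cell_ids)
        sc = SubclusterPair("A", "B", 2, 2)
        stat = lr_mean_statistic(nm, ("LIG", "REC"), sc, labels)
        assert stat == pytest.approx(1.5)

    def test_expression_fraction_gate(self):
        vals = np.zeros((2, 40))
        vals[0, 0] = 5.0  # ligand detected in 1/20 = 5% of sender cells
        vals[1, 20:] = 1.0
        nm = make_normalized(vals, genes=["LIG", "REC"])
        labels = pd.Series(["A"] * 20 + ["B"] * 20, index=nm.cell_ids)
        sc = SubclusterPair("A", "B", 20, 20)
        assert lr_mean_statistic(nm, ("LIG", "REC"), sc, labels) is None

    def test_absent_gene_undefined(self):
        nm = make_normalized(np.ones((2, 4)), genes=["LIG", "REC"])
        labels = pd.Series(["A", "A", "B", "B"], index=nm.cell_ids)
        sc = SubclusterPair("A", "B", 2, 2)
        assert lr_mean_statistic(nm, ("LIG", "NOPE"), sc, labels) is None

    def test_against_bruteforce_means(self):
        rng = np.random.default_rng(1)
        nm, labels = two_cluster_nm(rng, n_genes=8, n_a=15, n_b=25)
        sc = SubclusterPair("A", "B", 15, 25)
        stat = lr_mean_statistic(
            nm, (nm.gene_ids[2], nm.gene_ids[5]), sc, labels
        )
        lig_mean = nm.values[2, :15].mean()
        rec_mean = nm.values[5, 15:].mean()
        assert stat == pytest.approx((lig_mean + rec_mean) / 2, abs=1e-12)


class TestPermutationTest:
    def test_identical_cells_p_one(self):
        vals = np.ones((2, 12))
        nm = make_normalized(vals, genes=["LIG", "REC"])
        labels = pd.Series(["A"] * 6 + ["B"] * 6, index=nm.cell_ids)
        sc = SubclusterPair("A", "B", 6, 6)
        p = permutation_test(nm, ("LIG", "REC"), sc, labels, n_perm=200, seed=0)
        assert p == 1.0

    def test_planted_enrichment_small_p(self):
        rng = np.random.default_rng(2)
        nm, labels = two_cluster_nm(
            rng, n_genes=2, n_a=30, n_b=30, boost={(0, "A"): 3.0, (1, "B"): 3.0}
        )
        sc = SubclusterPair("A", "B", 30, 30)
        p = permutation_test(
            nm, (nm.gene_ids[0], nm.gene_ids[1]), sc, labels,
            n_perm=999, seed=0,
        )
        assert p == pytest.approx(1 / 1000)

    def test_exhaustive_enumeration_oracle_6_cells(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.2, 2.0, size=(2, 6))
        nm = make_normalized(vals, genes=["LIG", "REC"])
        lab = ["A", "A", "A", "B", "B", "B"]
        labels = pd.Series(lab, index=nm.cell_ids)
        sc = SubclusterPair("A", "B", 3, 3)
        obs = lr_mean_statistic(nm, ("LIG", "REC"), sc, labels)
        # exact null over all 720 label-vector permutations
        stats = []
        lab_arr = np.array(lab)
        for perm in itertools.permutations(range(6)):
            permuted = lab_arr[list(perm)]
            s = (vals[0, permuted == "A"].mean() + vals[1, permuted == "B"].mean()) / 2
            stats.append(s)
        p_exact = np.mean(np.array(stats) >= obs - 1e-12)
        p_mc = permutation_test(nm, ("LIG", "REC"), sc, labels,
                                n_perm=10_000, seed=4)
        assert abs(p_mc - p_exact) < 0.02

    def test_monotonicity_in_observed_statistic(self):
        # with a fixed permutation null, a larger observed statistic can
        # never yield a larger p
        rng = np.random.default_rng(5)
        null = rng.normal(0, 1, size=1000)
        def p_of(obs):
            return (1 + int((null >= obs - 1e-12).sum())) / (1 + len(null))
        obs_values = np.sort(rng.normal(0, 1, size=50))
        ps = [p_of(o) for o in obs_values]
        assert all(ps[i] >= ps[i + 1] for i in range(len(ps) - 1))

    def test_low_n_perm_warns(self, caplog):
        vals = np.ones((2, 8))
        nm = make_normalized(vals, genes=["LIG", "REC"])
        labels = pd.Series(["A"] * 4 + ["B"] * 4, index=nm.cell_ids)
        sc = SubclusterPair("A", "B", 4, 4)
        with caplog.at_level("WARNING"):
            permutation_test(nm, ("LIG", "REC"), sc, labels, n_perm=50, seed=0)
        assert any("low" in r.message for r in caplog.records)

    def test_batch_matches_single_pair_api(self):
        rng = np.random.default_rng(6)
        nm, labels = two_cluster_nm(rng, n_genes=4, n_a=20, n_b=20)
        db = LRDatabase(pairs_df([(nm.gene_ids[0], nm.gene_ids[1])]))
        res = lr_test_sample(nm, labels, db, n_perm=500, seed=9)
        row = res.table.set_index(["sender", "receiver"]).loc[("A", "B")]
        sc = SubclusterPair("A", "B", 20, 20)
        stat = lr_mean_statistic(nm, (nm.gene_ids[0], nm.gene_ids[1]), sc, labels)
        assert row["statistic"] == pytest.approx(stat, abs=1e-12)
        assert 0 < row["p_value"] <= 1


class TestSignificantMeans:
    @staticmethod
    def result_from_rows(rows):
        from sctme.lr import LRTestResult
        return LRTestResult(pd.DataFrame(rows), "s", 1000)

    def test_p_above_alpha_zeroed(self):
        res = self.result_from_rows([dict(
            ligand="L", receptor="R", sender="A", receiver="B",
            n_sender=60, n_receiver=80, statistic=1.3, p_value=0.2,
        )])
        M = significant_means(res)
        assert M.loc["L_R", "A>B"] == 0.0

    def test_small_subcluster_zeroed_regardless_of_p(self):
        res = self.result_from_rows([dict(
            ligand="L", receptor="R", sender="A", receiver="B",
            n_sender=49, n_receiver=80, statistic=1.3, p_value=0.001,
        )])
        assert significant_means(res).loc["L_R", "A>B"] == 0.0

    def test_significant_entry_kept(self):
        res = self.result_from_rows([dict(
            ligand="L", receptor="R", sender="A", receiver="B",
            n_sender=60, n_receiver=80, statistic=1.3, p_value=0.01,
        )])
        assert significant_means(res).loc["L_R", "A>B"] == 1.3

    def test_randomized_rule_table_oracle(self):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(300):
            rows.append(dict(
                ligand=f"L{i}", receptor=f"R{i}", sender="A", receiver="B",
                n_sender=int(rng.integers(10, 120)),
                n_receiver=int(rng.integers(10, 120)),
                statistic=float(rng.uniform(0.1, 5)),
                p_value=float(rng.uniform(0, 1)),
            ))
        res = self.result_from_rows(rows)
        M = significant_means(res, alpha=0.05, min_cells=50)
        for row in rows:
            expected = row["statistic"] if (
                row["p_value"] < 0.05
                and row["n_sender"] >= 50
                and row["n_receiver"] >= 50
            ) else 0.0
            assert M.loc[f"{row['ligand']}_{row['receptor']}", "A>B"] == expected

    def test_bh_adjustment_flag(self):
        rows = [dict(ligand=f"L{i}", receptor="R", sender="A", receiver="B",
                     n_sender=60, n_receiver=60, statistic=1.0,
                     p_value=p) for i, p in enumerate([0.001, 0.04, 0.9])]
        res = self.result_from_rows(rows)
        raw = significant_means(res)
        adj = significant_means(res, adjust="within-sample-bh")
        assert raw.loc["L1_R", "A>B"] == 1.0  # 0.04 < 0.05 raw
        assert adj.loc["L1_R", "A>B"] == 0.0  # BH-adjusted 0.06


class TestCountInteractions:
    def test_all_zero(self):
        M = pd.DataFrame(0.0, index=["a", "b"], columns=["A>B", "B>A"])
        assert count_interactions(M, by="sample") == 0
        assert (count_interactions(M, by="subcluster_pair") == 0).all()

    def test_three_nonzero(self):
        M = pd.DataFrame(
            [[1.0, 0.0], [2.0, 3.0]], index=["a", "b"], columns=["A>B", "B>A"]
        )
        assert count_interactions(M, by="sample") == 3
        counts = count_interactions(M, by="subcluster_pair")
        assert counts["A>B"] == 2 and counts["B>A"] == 1

    def test_random_sparse_oracle(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(0, 1, size=(20, 6)) * (rng.random((20, 6)) < 0.3)
        M = pd.DataFrame(vals, index=[f"l{i}" for i in range(20)],
                         columns=[f"S{i}>R{i}" for i in range(6)])
        assert count_interactions(M, by="sample") == int((vals != 0).sum())


class TestModeratedContrast:
    @staticmethod
    def simulate(rng, n_pairs=50, n_per_group=6, n_planted=5, effect_sd=2.0):
        X = rng.normal(1.0, 1.0, size=(2 * n_per_group, n_pairs)).clip(min=0.01)
        planted = list(range(n_planted))
        X[:n_per_group, planted] += effect_sd  # effect in group "g1"
        samples = [f"s{i}" for i in range(2 * n_per_group)]
        M = pd.DataFrame(X, index=samples,
                         columns=[f"L{i}_R{i}" for i in range(n_pairs)])
        groups = pd.Series(["g1"] * n_per_group + ["g2"] * n_per_group,
                           index=samples)
        return M, groups, [f"L{i}_R{i}" for i in planted]

    def test_d0_zero_equals_ordinary_t(self):
        rng = np.random.default_rng(9)
        M, groups, _ = self.simulate(rng)
        fit = lr_contrast(M, groups, contrast="g1", d0_override=0.0)
        X = M.to_numpy()
        for i, r in enumerate(fit.results):
            t_ref, _ = scipy.stats.ttest_ind(X[:6, i], X[6:, i], equal_var=True)
            assert r.t_statistic == pytest.approx(t_ref, rel=1e-8)

    def test_d0_inf_uses_prior_variance(self):
        rng = np.random.default_rng(10)
        M, groups, _ = self.simulate(rng)
        fit = lr_contrast(M, groups, contrast="g1", d0_override=np.inf)
        se_scale = np.sqrt(1 / 6 + 1 / 6)
        X = M.to_numpy()
        for i, r in enumerate(fit.results):
            coef = X[:6, i].mean() - X[6:, i].mean()
            t_ref = coef / (se_scale * np.sqrt(fit.s0_sq))
            assert r.t_statistic == pytest.approx(t_ref, rel=1e-8)
            assert r.s2_post == pytest.approx(fit.s0_sq, rel=1e-12)

    def test_shrinkage_formula_oracle(self):
        rng = np.random.default_rng(11)
        M, groups, _ = self.simulate(rng)
        fit = lr_contrast(M, groups, contrast="g1")
        d = 10  # 6 + 6 - 2
        assert np.isfinite(fit.d0)  # this draw has excess variance spread
        for r in fit.results:
            expected = (fit.d0 * fit.s0_sq + d * r.s2) / (fit.d0 + d)
            assert r.s2_post == pytest.approx(expected, abs=1e-10)
            lo, hi = sorted((r.s2, fit.s0_sq))
            if hi - lo > 1e-12 and np.isfinite(fit.d0) and fit.d0 > 0:
                assert lo < r.s2_post < hi

    def test_planted_effects_rank_top5(self):
        rng = np.random.default_rng(12)
        M, groups, planted = self.simulate(rng)
        fit = lr_contrast(M, groups, contrast="g1")
        ranked = sorted(fit.results, key=lambda r: -abs(r.t_statistic))
        assert {r.lr_pair for r in ranked[:5]} == set(planted)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(13)
        M, groups, _ = self.simulate(rng)
        fit1 = lr_contrast(M, groups, contrast="g1")
        perm = rng.permutation(len(M))
        fit2 = lr_contrast(M.iloc[perm], groups, contrast="g1")
        for a, b in zip(fit1.results, fit2.results):
            assert a.t_statistic == pytest.approx(b.t_statistic, rel=1e-12)

    def test_contrast_flip_negates(self):
        rng = np.random.default_rng(14)
        M, groups, _ = self.simulate(rng)
        f1 = lr_contrast(M, groups, contrast="g1")
        f2 = lr_contrast(M, groups, contrast="g2")
        for a, b in zip(f1.results, f2.results):
            assert a.coefficient == pytest.approx(-b.coefficient)
            assert a.t_statistic == pytest.approx(-b.t_statistic, rel=1e-12)

    def test_degenerate_all_zero_variances(self):
        M = pd.DataFrame(
            np.ones((6, 3)), index=[f"s{i}" for i in range(6)],
            columns=["a", "b", "c"],
        )
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=M.index)
        with pytest.raises(ValueError, match="degenerate"):
            lr_contrast(M, groups, contrast="g1")

    def test_all_zero_pairs_dropped(self):
        rng = np.random.default_rng(15)
        M, groups, _ = self.simulate(rng, n_pairs=10)
        M["dead_pair"] = 0.0
        fit = lr_contrast(M, groups, contrast="g1")
        assert "dead_pair" not in {r.lr_pair for r in fit.results}

    def test_positive_signature_extraction(self):
        rng = np.random.default_rng(16)
        M, groups, planted = self.simulate(rng, effect_sd=4.0)
        fit = lr_contrast(M, groups, contrast="g1")
        assert set(planted) <= set(fit.signature)
        for r in fit.results:
            if r.lr_pair in fit.signature:
                assert r.coefficient > 0 and r.p_adjusted < 0.05


class TestVariancePrior:
    def test_recovers_known_prior(self):
        # s2 ~ s0^2 * chi2_d / d scaled by prior draws from inv-chi2(d0)
        rng = np.random.default_rng(17)
        d0_true, s0_true, d = 8.0, 2.0, 10
        n = 5000
        true_var = d0_true * s0_true / (2 * rng.gamma(d0_true / 2, 1.0, size=n))
        s2 = true_var * rng.chisquare(d, size=n) / d
        d0_hat, s0_hat = estimate_variance_prior(s2, df=d)
        assert d0_hat == pytest.approx(d0_true, rel=0.2)
        assert s0_hat == pytest.approx(s0_true, rel=0.1)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            estimate_variance_prior(np.zeros(10), df=4)

    def test_moderated_variance_formula(self):
        s2 = np.array([1.0, 4.0])
        out = moderated_variance(s2, df=6, d0=4, s0_sq=2.0)
        np.testing.assert_allclose(out, (4 * 2.0 + 6 * s2) / 10)

    def test_infinite_d0(self):
        out = moderated_variance(np.array([1.0, 4.0]), df=6, d0=np.inf, s0_sq=2.0)
        np.testing.assert_allclose(out, 2.0)
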