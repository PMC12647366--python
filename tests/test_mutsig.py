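"""Context catalogs, KL-NMF extraction, reference matching, refitting."""

import numpy as np
import pandas as pd
import pytest

import pathsub as ps
from pathsub.mutsig import (CONTEXT_CLASSES, SUBSTITUTION_TYPES,
                            _catalog_from_frame, _rank1_kl)


def maf_frame(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt",
                                       "variant_type", "ref_context"]).astype(str)


class TestContextEnumeration:
    def test_class_counts_and_uniqueness(self):
        assert len(SUBSTITUTION_TYPES) == 6
        assert len(CONTEXT_CLASSES) == 96
        assert len(set(CONTEXT_CLASSES)) == 96
        assert all(c[2] in "CT" for c in CONTEXT_CLASSES)

    def test_substitution_major_order(self):
        assert CONTEXT_CLASSES[0] == "A[C>A]A"
        assert CONTEXT_CLASSES[15] == "T[C>A]T"
        assert CONTEXT_CLASSES[16] == "A[C>G]A"
        assert CONTEXT_CLASSES[-1] == "T[T>G]T"


class TestReadMaf:
    def test_toy_parse(self, tmp_path):
        df = maf_frame([("s1", "chr1", 1, "C", "T", "SNP", "ACG"),
                        ("s1", "chr1", 2, "T", "G", "SNP", "ATA"),
                        ("s2", "chr2", 3, "G", "A", "SNP", "CGT")])
        p = tmp_path / "x.maf.tsv"
        df.to_csv(p, sep="\t", index=False)
        cat = ps.read_maf(p)
        assert len(cat.records) == 3
        assert cat.records["is_snv"].all()

    def test_missing_column_rejects_file(self, tmp_path):
        p = tmp_path / "bad.tsv"
        maf_frame([("s1", "c", 1, "C", "T", "SNP", "ACG")]).drop(
            columns="ref_context").to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="ref_context"):
            ps.read_maf(p)

    def test_context_mismatch_rejected_and_counted(self):
        cat = _catalog_from_frame(maf_frame(
            [("s1", "c", 1, "C", "T", "SNP", "AAG"),     # middle != ref
             ("s1", "c", 2, "C", "T", "SNP", "ACG")]))
        assert len(cat.records) == 1
        assert cat.rejected["context_ref_mismatch"] == 1

    def test_ambiguous_base_skipped(self):
        cat = _catalog_from_frame(maf_frame(
            [("s1", "c", 1, "C", "T", "SNP", "NCG"),
             ("s1", "c", 2, "C", "T", "SNP", "ACG")]))
        assert len(cat.records) == 1
        assert cat.rejected["ambiguous_base"] == 1

    def test_doublets_pass_through_flagged(self):
        cat = _catalog_from_frame(maf_frame(
            [("s1", "c", 1, "CC", "TT", "DNP", "ACC"),
             ("s1", "c", 2, "C", "T", "SNP", "ACG")]))
        assert len(cat.records) == 2
        assert cat.records["is_snv"].tolist() == [False, True]


class TestBuildContextMatrix:
    def test_pyrimidine_reference_direct(self):
        cat = _catalog_from_frame(maf_frame([("s1", "c", 1, "C", "T", "SNP", "ACG")]))
        M = ps.build_context_matrix(cat)
        assert M.counts.loc["A[C>T]G", "s1"] == 1
        assert M.counts["s1"].sum() == 1

    def test_purine_reference_reverse_complemented(self):
        # G>A in context C-G-T reverse-complements to A[C>T]G
        cat = _catalog_from_frame(maf_frame([("s1", "c", 1, "G", "A", "SNP", "CGT")]))
        M = ps.build_context_matrix(cat)
        assert M.counts.loc["A[C>T]G", "s1"] == 1

    def test_column_sums_equal_snv_counts(self):
        model = ps.make_signature_model(3, 8, seed=0)
        maf = ps.make_mutation_catalog(model, 25, seed=1)
        cat = _catalog_from_frame(maf.astype(str))
        M = ps.build_context_matrix(cat)
        per_sample = cat.records[cat.records["is_snv"]].groupby("sample").size()
        assert (M.counts.sum(axis=0).sort_index() == per_sample.sort_index()).all()


class TestExtractSignatures:
    def test_exact_low_rank_recovery(self):
        gen = np.random.default_rng(5)
        W0 = gen.dirichlet(np.full(96, 0.05), size=2).T
        H0 = gen.uniform(50, 300, size=(2, 30))
        H0[0, :5] = 0.0                # pure samples make the factorisation
        H0[1, 5:10] = 0.0              # identifiable up to scaling/permutation
        V = W0 @ H0                                  # exactly rank 2
        M = ps.ContextMatrix(pd.DataFrame(V, index=CONTEXT_CLASSES,
                                          columns=[f"s{i}" for i in range(30)]))
        sets, chosen, diag = ps.extract_signatures(M, k_range=[2], restarts=8,
                                                   max_iter=2000, tol=1e-10,
                                                   seed=2)
        ref = pd.DataFrame(W0, index=CONTEXT_CLASSES, columns=["t1", "t2"])
        match = ps.match_reference(sets[2], ref, one_to_one=True)
        assert (match["cosine"] >= 0.99).all()

    def test_objective_trace_monotone(self):
        model = ps.make_signature_model(2, 12, seed=3)
        maf = ps.make_mutation_catalog(model, 80, seed=4)
        M = ps.build_context_matrix(_catalog_from_frame(maf.astype(str)))
        sets, _, _ = ps.extract_signatures(M, k_range=[2, 3], restarts=4, seed=5)
        for s in sets.values():
            d = np.diff(s.objective_trace)
            assert (d <= 1e-6 * np.maximum(np.abs(s.objective_trace[:-1]), 1.0)).all()

    def test_rank1_closed_form_is_row_marginal(self):
        gen = np.random.default_rng(6)
        V = gen.poisson(5.0, size=(96, 10)).astype(float) + 1
        w, h = _rank1_kl(V)
        np.testing.assert_allclose(w[:, 0], V.sum(axis=1) / V.sum())
        np.testing.assert_allclose(h[0], V.sum(axis=0))
        # and through the public API
        M = ps.ContextMatrix(pd.DataFrame(V.astype(int), index=CONTEXT_CLASSES,
                                          columns=[f"s{i}" for i in range(10)]))
        sets, _, _ = ps.extract_signatures(M, k_range=[1], restarts=1, seed=0)
        np.testing.assert_allclose(sets[1].W.to_numpy()[:, 0],
                                   V.astype(int).sum(axis=1) / V.astype(int).sum(),
                                   atol=1e-9)

    def test_restart_determinism(self):
        model = ps.make_signature_model(2, 10, seed=8)
        maf = ps.make_mutation_catalog(model, 60, seed=9)
        M = ps.build_context_matrix(_catalog_from_frame(maf.astype(str)))
        a = ps.extract_signatures(M, k_range=[2], restarts=3, seed=7)[0][2]
        b = ps.extract_signatures(M, k_range=[2], restarts=3, seed=7)[0][2]
        pd.testing.assert_frame_equal(a.W, b.W)
        pd.testing.assert_frame_equal(a.H, b.H)

    def test_zero_count_sample_rejected(self):
        V = np.ones((96, 3))
        V[:, 1] = 0
        M = ps.ContextMatrix(pd.DataFrame(V.astype(int), index=CONTEXT_CLASSES,
                                          columns=list("abc")))
        with pytest.raises(ValueError, match="positive mutation count"):
            ps.extract_signatures(M, k_range=[1], seed=0)


class TestMatchReference:
    @pytest.fixture()
    def ref(self):
        gen = np.random.default_rng(10)
        R = gen.dirichlet(np.full(96, 0.2), size=4).T
        return pd.DataFrame(R, index=CONTEXT_CLASSES,
                            columns=[f"R{i}" for i in range(4)])

    def test_identical_column_similarity_one(self, ref):
        W = ref[["R2"]].rename(columns={"R2": "mine"})
        m = ps.match_reference(W, ref)
        assert m.loc["mine", "best_match"] == "R2"
        assert m.loc["mine", "cosine"] == pytest.approx(1.0)

    def test_orthogonal_point_masses_similarity_zero(self):
        W = pd.DataFrame(0.0, index=CONTEXT_CLASSES, columns=["a"])
        W.iloc[0, 0] = 1.0
        R = pd.DataFrame(0.0, index=CONTEXT_CLASSES, columns=["r"])
        R.iloc[1, 0] = 1.0
        assert ps.match_reference(W, R).loc["a", "cosine"] == pytest.approx(0.0)

    def test_dirichlet_jitter_high_similarity(self, ref):
        gen = np.random.default_rng(11)
        noisy = gen.dirichlet(200 * ref["R0"].to_numpy() + 1e-9)
        W = pd.DataFrame({"noisy": noisy}, index=CONTEXT_CLASSES)
        m = ps.match_reference(W, ref)
        assert m.loc["noisy", "best_match"] == "R0"
        assert m.loc["noisy", "cosine"] >= 0.95

    def test_row_order_mismatch_rejected(self, ref):
        W = ref[["R0"]]
        with pytest.raises(ValueError, match="reindex"):
            ps.match_reference(W, ref.iloc[::-1])


class TestRefitExposures:
    def test_known_mixture_recovered_within_5pct(self):
        model = ps.make_signature_model(3, 20, seed=12)
        maf = ps.make_mutation_catalog(model, 1000, seed=13)
        M = ps.build_context_matrix(_catalog_from_frame(maf.astype(str)))
        refit = ps.refit_exposures(M, model.profiles, n_boot=10, seed=14)
        err = np.abs(refit.point_fraction.to_numpy() - model.exposures.to_numpy())
        assert err.max() <= 0.05
        assert refit.replicates.shape[0] == 10

    def test_single_signature_truth_leaves_competitors_near_zero(self):
        gen = np.random.default_rng(15)
        P = pd.DataFrame(gen.dirichlet(np.full(96, 0.05), size=3).T,
                         index=CONTEXT_CLASSES, columns=["a", "b", "c"])
        H = pd.DataFrame(np.array([[1.0], [0.0], [0.0]]), index=["a", "b", "c"],
                         columns=["s1"])
        maf = ps.make_mutation_catalog(ps.PlantedSignatureModel(P, H), 1000, seed=16)
        M = ps.build_context_matrix(_catalog_from_frame(maf.astype(str)))
        refit = ps.refit_exposures(M, P, n_boot=5, seed=17)
        assert refit.point_fraction.loc[["b", "c"], "s1"].sum() <= 0.02

    def test_zero_mutation_sample_flagged(self):
        P = pd.DataFrame(np.full((96, 1), 1 / 96), index=CONTEXT_CLASSES,
                         columns=["flat"])
        V = pd.DataFrame({"s1": np.ones(96, dtype=int), "s2": 0},
                         index=CONTEXT_CLASSES)
        refit = ps.refit_exposures(ps.ContextMatrix(V), P, n_boot=3, seed=0)
        assert refit.zero_mutation_samples == ["s2"]
        assert (refit.point["s2"] == 0).all()


class TestSignatureExpressionScreen:
    def test_engineered_and_anticorrelated_genes(self, rng):
        n = 60
        H = pd.DataFrame(rng.dirichlet([1, 1], size=n).T, index=["S1", "S2"],
                         columns=[f"s{i}" for i in range(n)])
        expr = pd.DataFrame(rng.normal(size=(5, n)),
                            index=[f"g{i}" for i in range(5)], columns=H.columns)
        expr.loc["g0"] = H.loc["S1"] * 10 + 0.01 * rng.normal(size=n)
        expr.loc["g1"] = -H.loc["S1"] * 10 + 0.01 * rng.normal(size=n)
        res = ps.signature_expression_screen(H, expr)
        g0 = res[(res.gene == "g0") & (res.signature == "S1")].iloc[0]
        g1 = res[(res.gene == "g1") & (res.signature == "S1")].iloc[0]
        assert g0["flagged"] and g0["r"] > 0.99
        assert not g1["flagged"]

    def test_null_rate_matches_simulation_oracle(self):
        """Flag rate of independent genes agrees with a direct simulation of
        the joint r > .2, p < .05 rule at the same n."""
        gen = np.random.default_rng(20)
        n, n_genes = 150, 1500
        H = pd.DataFrame(gen.dirichlet([1, 1, 1], size=n).T[:1],
                         index=["S1"], columns=[f"s{i}" for i in range(n)])
        expr = pd.DataFrame(gen.normal(size=(n_genes, n)),
                            index=[f"g{i}" for i in range(n_genes)],
                            columns=H.columns)
        res = ps.signature_expression_screen(H, expr)
        rate = res["flagged"].mean()
        # independent oracle: simulate null Pearson r directly
        from scipy import stats as sps
        sims = 4000
        x = gen.normal(size=(sims, n))
        y = gen.normal(size=n)
        r = (x - x.mean(1, keepdims=True)) @ ((y - y.mean()) / y.std())
        r = r / (x.std(1) * n)
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * sps.t.sf(np.abs(t), df=n - 2)
        oracle = ((r > 0.2) & (p < 0.05)).mean()
        se = np.sqrt(oracle * (1 - oracle) / sims + rate * (1 - rate) / n_genes)
        assert abs(rate - oracle) <= 3 * se + 1e-3

    def test_constant_gene_skipped(self, rng):
        H = pd.DataFrame(rng.dirichlet([1, 1], size=20).T, index=["S1", "S2"],
                         columns=[f"s{i}" for i in range(20)])
        expr = pd.DataFrame(np.ones((2, 20)), index=["flat", "flat2"],
                            columns=H.columns)
        expr.loc["flat2"] = rng.normal(size=20)
        res = ps.signature_expression_screen(H, expr)
        assert res.attrs["skipped"] == ["flat"]


class TestTmb:
    def test_counts_and_additivity(self):
        rows = ([("s1", "c", i, "C", "T", "SNP", "ACG") for i in range(5)]
                + [("s3", "c", i, "C", "T", "SNP", "ACG") for i in range(7)]
                + [("s3", "c", 99, "CC", "TT", "DNP", "ACC")])
        cat = _catalog_from_frame(maf_frame(rows))
        t = ps.tmb(cat)
        assert t.loc["s1", "total"] == 5
        assert t.loc["s3", "total"] == 8
        assert t.loc["s3", "snv"] == 7
        assert (t["snv"] <= t["total"]).all()
        cat2 = _catalog_from_frame(maf_frame(rows + rows))
        assert (ps.tmb(cat2)["total"] == 2 * t["total"]).all()
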