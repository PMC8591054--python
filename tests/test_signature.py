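import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from iciscore.io import ExpressionMatrix
from iciscore.signature import (ICIModel, assign_gene_types, boruta_select,
                                compare_gene_panels, differential_expression,
                                fit_ici_model, score_samples)


def _expr(values, prefix="G"):
    values = np.asarray(values, dtype=float)
    genes = [f"{prefix}{i}" for i in range(values.shape[0])]
    samples = [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values)


class TestDifferentialExpression:
    def test_equal_group_means_yield_no_calls(self, rng):
        base = rng.normal(5, 1, size=(30, 4))
        X = np.hstack([base, base])  # identical groups
        res = differential_expression(_expr(X), [1] * 4 + [0] * 4)
        assert np.allclose(res.table["log2_fold_change"], 0)
        assert (res.table["direction"] == "ns").all()

    def test_zero_prior_df_recovers_ordinary_t(self, rng):
        X = rng.normal(6, 1, size=(25, 12))
        X[:4, :6] += 1.5
        labels = [1] * 6 + [0] * 6
        res = differential_expression(_expr(X), labels, prior_df=0)
        t_ref, _ = sps.ttest_ind(X[:, :6], X[:, 6:], axis=1, equal_var=True)
        np.testing.assert_allclose(res.table["t"].to_numpy(), t_ref, rtol=1e-10)

    def test_matches_limma_oracle(self, tmp_path, rng):
        """Moderated t, prior fit and p-values agree with the reference
        empirical-Bayes implementation in R."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; limma oracle cannot run")
        X = rng.normal(6, 1, size=(40, 11))
        X[:5, :6] += 2.0
        expr = _expr(X)
        res = differential_expression(expr, [1] * 6 + [0] * 5)
        xfile = tmp_path / "x.tsv"
        ofile = tmp_path / "out.tsv"
        expr.to_frame().to_csv(xfile, sep="\t")
        script = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{xfile}", row.names=1))
        design <- cbind(Intercept=1, Group=c(rep(1,6), rep(0,5)))
        fit <- eBayes(lmFit(x, design))
        out <- data.frame(t=fit$t[,"Group"], p=fit$p.value[,"Group"])
        write.table(out, "{ofile}", sep="\\t", quote=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(ofile, sep="\t")
        np.testing.assert_allclose(res.table["t"].to_numpy(), ref["t"].to_numpy(), rtol=1e-8)
        np.testing.assert_allclose(res.table["p_value"].to_numpy(), ref["p"].to_numpy(),
                                   rtol=1e-6)

    def test_planted_effects_sensitivity_and_fdr(self, rng):
        n_per, n_genes, n_true = 100, 1000, 200
        X = rng.normal(5, 1, size=(n_genes, 2 * n_per))
        X[:n_true, :n_per] += 1.5
        res = differential_expression(_expr(X), [1] * n_per + [0] * n_per)
        called = res.table["direction"] != "ns"
        sensitivity = called[:n_true].mean()
        false_calls = called[n_true:].sum()
        assert sensitivity > 0.9
        assert false_calls / max(called.sum(), 1) < 0.1

    def test_degenerate_groups_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError):
            differential_expression(_expr(X), [1, 0, 0, 0])

    def test_wilcoxon_fallback_runs(self, rng):
        X = rng.normal(5, 1, size=(20, 12))
        X[:3, :6] += 3
        res = differential_expression(_expr(X), [1] * 6 + [0] * 6, method="wilcoxon")
        assert (res.table["p_value"][:3] < 0.05).all()


class TestAssignGeneTypes:
    def _two_block(self):
        # 3 genes high in cluster 1, 3 genes high in cluster 2, plus one flat gene
        labels = np.array([1] * 5 + [2] * 5)
        block1 = np.where(labels == 1, 8.0, 2.0)
        block2 = np.where(labels == 2, 8.0, 2.0)
        flat = np.array([3.0, 5.0, 3.0, 5.0, 4.0, 3.0, 5.0, 3.0, 5.0, 4.0])
        X = np.vstack([block1, block1, block1, block2, block2, block2, flat])
        return _expr(X), labels

    def test_planted_blocks_split_into_a_and_b(self):
        expr, labels = self._two_block()
        res = assign_gene_types(expr, labels)
        assert res.genes_A == ["G0", "G1", "G2"]
        assert set(res.genes_B) == {"G3", "G4", "G5", "G6"}

    def test_bimodal_gene_has_unit_association(self):
        expr, labels = self._two_block()
        res = assign_gene_types(expr, labels)
        assert res.table.loc["G0", "association"] == pytest.approx(1.0)

    def test_flat_gene_lands_in_b(self):
        expr, labels = self._two_block()
        res = assign_gene_types(expr, labels)
        assert res.table.loc["G6", "gene_type"] == "B"

    def test_anchor_orients_reference_cluster(self):
        expr, labels = self._two_block()
        anchor = np.where(labels == 2, 9.0, 1.0)  # cluster 2 is immune-high
        res = assign_gene_types(expr, labels, anchor=anchor)
        assert res.reference_cluster == 2
        assert set(res.genes_A) == {"G3", "G4", "G5"}

    def test_single_cluster_rejected(self):
        expr, _ = self._two_block()
        with pytest.raises(ValueError):
            assign_gene_types(expr, np.ones(10))


class TestBoruta:
    def test_informative_feature_confirmed_noise_mostly_not(self, rng):
        n = 200
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(rng.normal(size=(n, 50)), columns=[f"N{i}" for i in range(50)])
        X["signal"] = y + rng.normal(0, 0.1, n)
        confirmed = boruta_select(X, y, max_iter=25, seed=1)
        assert "signal" in confirmed
        assert len(confirmed) <= 4  # alpha * 51 plus slack

    def test_pure_noise_rarely_confirmed(self, rng):
        n = 150
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(rng.normal(size=(n, 30)))
        confirmed = boruta_select(X, y, max_iter=20, seed=2)
        assert len(confirmed) <= 0.05 * 30 + 1

    def test_zero_variance_feature_never_confirmed(self, rng):
        n = 100
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(rng.normal(size=(n, 6)), columns=[f"F{i}" for i in range(6)])
        X["const"] = 1.0
        assert "const" not in boruta_select(X, y, max_iter=15, seed=3)

    def test_small_max_iter_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 6)))
        with pytest.raises(ValueError):
            boruta_select(X, rng.integers(0, 2, 20), max_iter=5)


class TestICIModel:
    def test_identical_sets_score_identically_zero(self, rng):
        X = rng.normal(5, 1, size=(6, 20))
        expr = _expr(X)
        genes = ["G0", "G1", "G2"]
        model = fit_ici_model(expr, genes, genes)
        scores = score_samples(model, expr)
        np.testing.assert_allclose(scores["ici_score"], 0.0, atol=1e-10)

    def test_rank_one_set_scores_scaled_mean(self):
        g0 = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.vstack([g0, 2 * g0, np.ones(4), 1 - np.arange(4.0)])
        expr = _expr(X)
        model = fit_ici_model(expr, ["G0", "G1"], ["G2", "G3"])
        sA = score_samples(model, expr)["score_A"].to_numpy()
        assert model.explained_var_A == pytest.approx(1.0)
        mean_profile = (X[0] + X[1]) / 2
        corr = np.corrcoef(sA, mean_profile)[0, 1]
        assert corr == pytest.approx(1.0, abs=1e-10)

    def test_loading_matches_eigendecomposition(self, rng):
        X = rng.normal(size=(5, 30))  # 5 genes x 30 samples
        expr = _expr(X)
        model = fit_ici_model(expr, ["G0", "G1", "G2", "G3", "G4"], ["G0", "G1", "G2", "G3", "G4"])
        cov = np.cov(X)  # gene-gene covariance
        w, v = np.linalg.eigh(cov)
        lead = v[:, np.argmax(w)]
        cosine = abs(float(np.dot(lead, model.loading_A)))
        assert cosine == pytest.approx(1.0, abs=1e-10)

    def test_refit_is_identical(self, default_cohort):
        expr = default_cohort.expression
        gA = [g for g in expr.gene_ids if g.startswith("SIGA")][:10]
        gB = [g for g in expr.gene_ids if g.startswith("SIGB")][:10]
        m1 = fit_ici_model(expr, gA, gB)
        m2 = fit_ici_model(expr, gA, gB)
        np.testing.assert_array_equal(m1.loading_A, m2.loading_A)
        np.testing.assert_array_equal(m1.loading_B, m2.loading_B)

    def test_json_roundtrip(self, rng, tmp_path):
        expr = _expr(rng.normal(size=(6, 8)))
        model = fit_ici_model(expr, ["G0", "G1"], ["G2", "G3"])
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ICIModel.from_json(path)
        np.testing.assert_allclose(back.loading_A, model.loading_A)
        scores1 = score_samples(model, expr)
        scores2 = score_samples(back, expr)
        np.testing.assert_allclose(scores1["ici_score"], scores2["ici_score"], atol=1e-12)

    def test_short_gene_list_rejected(self, rng):
        expr = _expr(rng.normal(size=(6, 8)))
        with pytest.raises(ValueError, match="MISSING"):
            fit_ici_model(expr, ["G0", "MISSING"], ["G2", "G3"])


class TestScoreSamples:
    def _fitted(self, rng, n_genes=20, n_samples=15):
        X = rng.normal(5, 1, size=(n_genes, n_samples))
        expr = _expr(X)
        gA = [f"G{i}" for i in range(0, 8)]
        gB = [f"G{i}" for i in range(8, 16)]
        return expr, fit_ici_model(expr, gA, gB)

    def test_training_cohort_rescored_exactly(self, rng):
        expr, model = self._fitted(rng)
        s1 = score_samples(model, expr)
        s2 = score_samples(model, expr)
        np.testing.assert_array_equal(s1.to_numpy(), s2.to_numpy())

    def test_constant_shift_on_a_genes_moves_score_a_linearly(self, rng):
        expr, model = self._fitted(rng)
        base = score_samples(model, expr)
        shifted = expr.values.copy()
        pos = {g: i for i, g in enumerate(expr.gene_ids)}
        c = 2.5
        for g in model.genes_A:
            shifted[pos[g], 0] += c
        s2 = score_samples(model, ExpressionMatrix(expr.gene_ids, expr.sample_ids, shifted))
        expected = base["score_A"].iloc[0] + c * model.loading_A.sum()
        assert s2["score_A"].iloc[0] == pytest.approx(expected, abs=1e-10)
        assert s2["score_B"].iloc[0] == pytest.approx(base["score_B"].iloc[0], abs=1e-12)

    def test_missing_genes_imputed_up_to_threshold(self, rng):
        expr, model = self._fitted(rng)
        keep = [g for g in expr.gene_ids if g != model.genes_A[0]]  # 7/8 = 87.5%
        sub = expr.subset_genes(keep)
        scores = score_samples(model, sub)
        assert np.isfinite(scores["ici_score"]).all()

    def test_low_coverage_rejected(self, rng):
        expr, model = self._fitted(rng)
        keep = [g for g in expr.gene_ids if g not in model.genes_A[:3]]  # 5/8 = 62.5%
        with pytest.raises(ValueError, match="80%"):
            score_samples(model, expr.subset_genes(keep))


class TestComparePanels:
    def test_planted_shift_detected_with_direction(self, rng):
        n = 60
        X = rng.normal(5, 1, size=(10, 2 * n))
        X[0, :n] += 2.0  # panel gene up in the high group
        genes = ["CD274"] + [f"G{i}" for i in range(9)]
        expr = ExpressionMatrix(genes, [f"S{j}" for j in range(2 * n)], X)
        high = np.array([True] * n + [False] * n)
        table, skipped = compare_gene_panels(expr, high, ["CD274", "G0", "ABSENT"])
        assert skipped == ["ABSENT"]
        assert table.loc["CD274", "direction"] == "up_in_high"
        assert table.loc["CD274", "adjusted_p"] < 0.01
        assert table.loc["G0", "direction"] == "ns"
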