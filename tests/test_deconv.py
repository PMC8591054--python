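import numpy as np
import pytest

from iciscore.datasets import load_synthetic_signature
from iciscore.deconv import deconvolve, estimate_scores, ssgsea_score
from iciscore.io import ExpressionMatrix


def _expr_from_linear(sig, columns, names):
    vals = np.log2(np.column_stack(columns))
    return ExpressionMatrix(list(sig.marker_gene_ids), names, vals)


class TestDeconvolve:
    def test_exact_two_component_mixture(self, signature):
        mix = 0.5 * signature.basis[:, 3] + 0.5 * signature.basis[:, 13]
        expr = _expr_from_linear(signature, [mix, signature.basis[:, 0]], ["mix", "other"])
        f = deconvolve(expr, signature, method="nnls").to_frame()
        assert f.loc["mix", "T cells CD8"] == pytest.approx(0.5, abs=1e-6)
        assert f.loc["mix", "Macrophages M0"] == pytest.approx(0.5, abs=1e-6)
        others = f.loc["mix"].drop(["T cells CD8", "Macrophages M0"])
        assert others.abs().max() < 1e-6

    def test_pure_basis_column_recovered(self, signature):
        expr = _expr_from_linear(signature, [signature.basis[:, 7], signature.basis[:, 2]],
                                 ["tfh", "plasma"])
        f = deconvolve(expr, signature, method="nnls").to_frame()
        assert f.loc["tfh", "T cells follicular helper"] == pytest.approx(1.0, abs=1e-6)
        assert f.loc["plasma", "Plasma cells"] == pytest.approx(1.0, abs=1e-6)

    def test_nnls_invariant_to_positive_rescaling(self, signature):
        mix = 0.3 * signature.basis[:, 1] + 0.7 * signature.basis[:, 20]
        a = _expr_from_linear(signature, [mix, mix], ["s", "t"])
        b = ExpressionMatrix(a.gene_ids, a.sample_ids, a.values + np.log2(7.5))
        fa = deconvolve(a, signature).fractions
        fb = deconvolve(b, signature).fractions
        np.testing.assert_allclose(fa, fb, atol=1e-8)

    def test_noisy_mixtures_recovered_within_mae(self, signature, rng):
        n = 100
        fracs = rng.dirichlet(np.ones(22), size=n)
        linear = signature.basis @ fracs.T
        noisy = np.log2(linear) + rng.normal(0, 0.1, size=linear.shape)
        expr = ExpressionMatrix(list(signature.marker_gene_ids),
                                [f"M{i}" for i in range(n)], noisy)
        est = deconvolve(expr, signature, method="nnls").fractions
        assert np.abs(est - fracs).mean() < 0.05

    def test_nusvr_recovers_dominant_types(self, signature):
        mix = 0.6 * signature.basis[:, 3] + 0.4 * signature.basis[:, 13]
        expr = _expr_from_linear(signature, [mix, signature.basis[:, 0]], ["mix", "o"])
        f = deconvolve(expr, signature, method="nusvr").to_frame()
        top2 = set(f.loc["mix"].nlargest(2).index)
        assert top2 == {"T cells CD8", "Macrophages M0"}

    def test_low_marker_overlap_rejected(self, signature):
        keep = signature.marker_gene_ids[:40]  # 36% of markers
        vals = np.log2(signature.basis[:40, :2] + 1)
        expr = ExpressionMatrix(list(keep), ["a", "b"], vals)
        with pytest.raises(ValueError, match="50%"):
            deconvolve(expr, signature)

    def test_negative_n_perm_rejected(self, signature):
        expr = _expr_from_linear(signature, [signature.basis[:, 0], signature.basis[:, 1]],
                                 ["a", "b"])
        with pytest.raises(ValueError):
            deconvolve(expr, signature, n_perm=-1)

    def test_permutation_p_bounds(self, signature):
        mix = 0.5 * signature.basis[:, 3] + 0.5 * signature.basis[:, 13]
        expr = _expr_from_linear(signature, [mix, signature.basis[:, 5]], ["m", "p"])
        cf = deconvolve(expr, signature, n_perm=19, seed=0)
        p = cf.diagnostics["permutation_p"]
        assert (p >= 1 / 20).all() and (p <= 1).all()
        # structured mixtures beat shuffled nulls
        assert (p <= 0.1).all()


class TestSsgsea:
    def _toy(self):
        # 4-gene universe, two samples; sample ordering is hand-enumerable
        vals = np.array([[4.0, 1.0], [3.0, 2.0], [2.0, 3.0], [1.0, 4.0]])
        return ExpressionMatrix(["g1", "g2", "g3", "g4"], ["s1", "s2"], vals)

    def test_matches_hand_computed_weighted_ecdf(self):
        # sample s1 ranks g1>g2>g3>g4; set {g1,g3}; alpha=0.25
        expr = self._toy()
        alpha = 0.25
        w1, w3 = 4**alpha, 2**alpha
        denom = w1 + w3
        p_in = np.array([w1 / denom, w1 / denom, 1.0, 1.0])
        p_out = np.array([0.0, 0.5, 0.5, 1.0])
        expected = float(np.sum(p_in - p_out))
        s = ssgsea_score(expr, ["g1", "g3"], alpha=alpha)
        assert s["s1"] == pytest.approx(expected, abs=1e-12)

    def test_uniform_upshift_raises_score(self, rng):
        n_genes, genes = 30, [f"g{i}" for i in range(30)]
        base = rng.normal(5, 1, size=n_genes)
        vals = np.column_stack([base.copy(), base.copy()])
        in_set = genes[:8]
        vals[:8, 0] += 5.0
        expr = ExpressionMatrix(genes, ["up", "ref"], vals)
        s = ssgsea_score(expr, in_set)
        assert s["up"] > s["ref"]

    def test_full_universe_set_rejected(self):
        expr = self._toy()
        with pytest.raises(ValueError, match="universe"):
            ssgsea_score(expr, ["g1", "g2", "g3", "g4"])

    def test_fewer_than_two_genes_rejected(self):
        with pytest.raises(ValueError):
            ssgsea_score(self._toy(), ["g1", "nope"])


class TestEstimateScores:
    def test_identical_samples_equal_scores(self):
        vals = np.tile(np.arange(1.0, 11.0)[:, None], (1, 3))
        expr = ExpressionMatrix([f"g{i}" for i in range(10)], ["a", "b", "c"], vals)
        sc = estimate_scores(expr, ["g0", "g1"], ["g8", "g9"]).to_frame()
        assert sc["immune_score"].nunique() == 1
        assert sc["stromal_score"].nunique() == 1

    def test_upregulated_subgroup_scores_higher(self, rng):
        genes = [f"g{i}" for i in range(20)]
        vals = rng.normal(5, 1, size=(20, 6))
        vals[:5, :3] += 4.0  # immune set up in samples 0-2
        expr = ExpressionMatrix(genes, [f"s{i}" for i in range(6)], vals)
        sc = estimate_scores(expr, genes[:5], genes[15:]).to_frame()
        assert sc["immune_score"][:3].mean() > sc["immune_score"][3:].mean()

    def test_agrees_with_bruteforce_ssgsea(self, rng):
        genes = [f"g{i}" for i in range(10)]
        vals = rng.normal(size=(10, 2))
        expr = ExpressionMatrix(genes, ["a", "b"], vals)
        gene_set = ["g2", "g5", "g7"]
        alpha = 0.25
        # independent re-implementation by explicit loop
        expected = []
        for j in range(2):
            order = np.argsort(-vals[:, j], kind="stable")
            hits = np.isin(order, [2, 5, 7])
            w = (10 - np.arange(10)) ** alpha
            wh = np.where(hits, w, 0.0)
            pin = np.cumsum(wh) / wh.sum()
            pout = np.cumsum(~hits) / 7
            expected.append(np.sum(pin - pout))
        s = ssgsea_score(expr, gene_set, alpha=alpha)
        np.testing.assert_allclose(s.to_numpy(), expected, atol=1e-12)
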