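"""Unit and oracle tests for the seven inference approaches."""

import numpy as np
import pandas as pd
import pytest

from consensusgrn.datatypes import ExpressionMatrix, TFList, ValidationError
from consensusgrn.inference import infer_network
from consensusgrn.inference.ggm import infer_ggm, shrunk_partial_correlations
from consensusgrn.inference.mi import (
    clr_scores,
    dpi_prune,
    estimate_spearman_mi,
    infer_aracne,
    infer_clr,
)
from consensusgrn.inference.regression import (
    ElasticNetConfig,
    fit_gene_model,
    infer_elasticnet,
    infer_genie3,
)
from consensusgrn.inference.spectral import (
    DeconvolutionConfig,
    deconvolve_matrix,
    silence_matrix,
)


def _em(arr, genes=None, cols=None, medians=True):
    arr = np.asarray(arr, float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cols = cols or [f"c{j}" for j in range(arr.shape[1])]
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    return ExpressionMatrix(pd.DataFrame((arr - mu) / sd, index=genes,
                                         columns=cols),
                            collapsed_to_medians=medians, standardized=True)


class TestGGM:
    def test_chain_partial_correlation_ordering(self):
        # X -> Y -> Z: pcor(X,Z | Y) must fall below both direct links
        rng = np.random.default_rng(0)
        n = 500
        x = rng.normal(size=n)
        y = 0.9 * x + 0.2 * rng.normal(size=n)
        z = 0.9 * y + 0.2 * rng.normal(size=n)
        pcor, lam = shrunk_partial_correlations(np.vstack([x, y, z]))
        assert 0 <= lam <= 1
        assert abs(pcor[0, 2]) < abs(pcor[0, 1])
        assert abs(pcor[0, 2]) < abs(pcor[1, 2])

    def test_shrinkage_contracts_independent_data(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 500))
        pcor, _ = shrunk_partial_correlations(x)
        cor = np.corrcoef(x)
        off = ~np.eye(10, dtype=bool)
        assert np.mean(np.abs(pcor[off])) < np.mean(np.abs(cor[off]))

    def test_two_genes_single_edge_rank_one(self):
        em = _em(np.array([[1.0, 2.0, 4.0], [2.0, 3.0, 9.0]]),
                 genes=["TF1", "g1"])
        net = infer_ggm(em, TFList(("TF1",)))
        assert len(net) == 1
        assert net.edges.iloc[0]["rank"] == 1.0

    def test_rejects_replicate_level_input(self, preset_expression, preset_tfs):
        replicates, _, _ = preset_expression
        with pytest.raises(ValidationError, match="condition-median"):
            infer_ggm(replicates, preset_tfs)


class TestSpearmanMI:
    def test_known_values(self):
        # rho=0 -> MI=0; rho=0.5 -> -0.5*ln(0.75); monotone pair -> clip ceiling
        assert -0.5 * np.log(0.75) == pytest.approx(0.14384103, abs=1e-7)
        rng = np.random.default_rng(2)
        a = rng.normal(size=200)
        em = _em(np.vstack([a, a ** 3]), genes=["x", "y"], medians=False)
        mi = estimate_spearman_mi(em)
        assert mi.loc["x", "y"] == pytest.approx(-0.5 * np.log(1e-12), rel=1e-6)

    def test_matches_formula_on_random_data(self):
        from scipy.stats import spearmanr
        rng = np.random.default_rng(3)
        arr = rng.normal(size=(6, 80))
        em = _em(arr, medians=False)
        mi = estimate_spearman_mi(em)
        rho = spearmanr(em.values.to_numpy(), axis=1).statistic
        expect = -0.5 * np.log(1 - np.minimum(rho ** 2, 1 - 1e-12))
        np.fill_diagonal(expect, 0.0)
        assert np.abs(mi.to_numpy() - expect).max() < 1e-12


class TestCLR:
    def test_flat_mi_gives_empty_network(self):
        mi = pd.DataFrame(np.full((4, 4), 0.3) - 0.3 * np.eye(4),
                          index=list("abcd"), columns=list("abcd"))
        scores = clr_scores(mi)
        assert np.all(scores.to_numpy() == 0)
        net = infer_clr(mi, TFList(("a",)))
        assert len(net) == 0

    def test_elevated_pair_ranks_first_vs_bruteforce(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(0.1, 0.2, size=(5, 5))
        mi = (base + base.T) / 2
        np.fill_diagonal(mi, 0.0)
        mi[0, 3] = mi[3, 0] = 2.0
        names = list("abcde")
        midf = pd.DataFrame(mi, index=names, columns=names)
        # independent brute-force CLR
        expect = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                row_i = np.delete(mi[i], i)
                row_j = np.delete(mi[j], j)
                zi = max(0.0, (mi[i, j] - row_i.mean()) / row_i.std())
                zj = max(0.0, (mi[i, j] - row_j.mean()) / row_j.std())
                expect[i, j] = np.sqrt(zi ** 2 + zj ** 2)
        got = clr_scores(midf).to_numpy()
        assert np.abs(got - expect).max() < 1e-10
        net = infer_clr(midf, TFList(("a",)))
        top = net.edges.iloc[0]
        assert {top["regulator"], top["target"]} == {"a", "d"}

    def test_score_symmetric(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(0, 1, (6, 6))
        mi = (m + m.T) / 2
        np.fill_diagonal(mi, 0)
        s = clr_scores(pd.DataFrame(mi)).to_numpy()
        assert np.abs(s - s.T).max() < 1e-12


def brute_force_dpi(mi: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Independent triangle-enumeration oracle for ARACNE pruning."""
    out = mi.copy().astype(float)
    p = mi.shape[0]
    marked = set()
    import itertools
    for i, j, k in itertools.combinations(range(p), 3):
        trio = [(mi[i, j], (i, j)), (mi[i, k], (i, k)), (mi[j, k], (j, k))]
        if any(v <= 0 for v, _ in trio):
            continue
        trio.sort(key=lambda t: t[0])
        weakest, pair = trio[0]
        if weakest < trio[1][0] - eps and weakest < trio[2][0] - eps:
            marked.add(pair)
    for i, j in marked:
        out[i, j] = out[j, i] = 0.0
    return out


class TestARACNE:
    def test_hand_triangle(self):
        mi = np.zeros((3, 3))
        mi[0, 1] = mi[1, 0] = 0.9  # XY
        mi[1, 2] = mi[2, 1] = 0.8  # YZ
        mi[0, 2] = mi[2, 0] = 0.5  # XZ -> removed by DPI
        pruned = dpi_prune(mi)
        assert pruned[0, 2] == 0.0 and pruned[2, 0] == 0.0
        assert pruned[0, 1] == 0.9 and pruned[1, 2] == 0.8

    def test_triangle_free_matrix_unchanged(self):
        mi = np.zeros((4, 4))
        mi[0, 1] = mi[1, 0] = 0.5
        mi[2, 3] = mi[3, 2] = 0.4
        assert np.array_equal(dpi_prune(mi), mi)

    def test_tied_triangle_removes_nothing(self):
        mi = np.full((3, 3), 0.7)
        np.fill_diagonal(mi, 0.0)
        assert np.array_equal(dpi_prune(mi), mi)

    def test_equals_bruteforce_oracle_on_random_matrices(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            m = rng.uniform(0, 1, (10, 10))
            m[rng.uniform(size=(10, 10)) < 0.3] = 0.0
            mi = np.triu(m, 1)
            mi = mi + mi.T
            assert np.array_equal(dpi_prune(mi), brute_force_dpi(mi))

    def test_subset_of_unpruned_network(self, preset_expression, preset_tfs):
        replicates, _, _ = preset_expression
        mi = estimate_spearman_mi(replicates)
        net = infer_aracne(mi, preset_tfs)
        full = set()
        for tf in preset_tfs:
            for g in mi.columns:
                if g != tf and mi.loc[tf, g] > 0:
                    full.add((tf, g))
        assert set(map(tuple, net.edges[["regulator", "target"]].values)) <= full


class TestElasticNet:
    def test_exact_copy_tf_dominates(self):
        rng = np.random.default_rng(6)
        n, p = 200, 6
        x = rng.normal(size=(p, n))
        y = x[0]  # target == TF0
        em = _em(np.vstack([x, y]), genes=[f"TF{i}" for i in range(p)] + ["tgt"])
        cfg = ElasticNetConfig(seed=0, n_lambda1=15)
        net = infer_elasticnet(em, TFList(tuple(f"TF{i}" for i in range(p))), cfg)
        tgt_edges = net.edges[net.edges["target"] == "tgt"]
        best = tgt_edges.sort_values("score", ascending=False).iloc[0]
        assert best["regulator"] == "TF0"
        assert best["score"] == pytest.approx(1.0)

    def test_beta_normalization_max_is_one(self, preset_expression, preset_tfs):
        _, medians, _ = preset_expression
        cfg = ElasticNetConfig(seed=0, n_lambda1=10,
                               lambda2_grid=(0.0, 0.1, 1.0))
        net = infer_elasticnet(
            ExpressionMatrix(medians.values.iloc[:20],
                             collapsed_to_medians=True, standardized=True),
            preset_tfs, cfg)
        for _, grp in net.edges.groupby("target"):
            assert grp["score"].max() == pytest.approx(1.0)

    def test_noise_targets_never_score_high(self):
        """Pure-noise targets are either discarded (negative CV-R²) or kept
        with a CV-R² far below what a real signal earns."""
        r2s = []
        for seed in range(25):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(20, 5))  # 20 columns, 5 TFs
            y = rng.normal(size=20)
            y = (y - y.mean()) / y.std(ddof=1)
            cfg = ElasticNetConfig(seed=seed, folds=5, n_lambda1=10,
                                   lambda2_grid=(0.0, 0.1, 1.0, 10.0))
            fit = fit_gene_model(y, x, "tgt", cfg)
            if fit is not None:
                r2s.append(fit.r2)
        assert max(r2s, default=0.0) < 0.6
        # a genuine signal is kept with near-perfect CV-R²
        rng = np.random.default_rng(99)
        x = rng.normal(size=(40, 5))
        y = x[:, 0] + 0.1 * rng.normal(size=40)
        y = (y - y.mean()) / y.std(ddof=1)
        fit = fit_gene_model(y, x, "tgt", ElasticNetConfig(
            seed=0, folds=5, n_lambda1=10, lambda2_grid=(0.0, 0.1, 1.0)))
        assert fit is not None and fit.r2 > 0.9

    def test_too_few_columns_rejected(self, preset_tfs):
        em = _em(np.random.default_rng(0).normal(size=(13, 4)),
                 genes=list(preset_tfs) + ["g1"])
        with pytest.raises(ValidationError, match="folds"):
            infer_elasticnet(em, preset_tfs, ElasticNetConfig(folds=6))


class TestGENIE3:
    def test_copied_tf_gets_top_importance(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(5, 60))
            y = x[1] + 0.05 * rng.normal(size=60)
            em = _em(np.vstack([x, y]),
                     genes=[f"TF{i}" for i in range(5)] + ["tgt"])
            net = infer_genie3(em, TFList(tuple(f"TF{i}" for i in range(5))),
                               n_trees=100, seed=seed)
            tgt = net.edges[net.edges["target"] == "tgt"]
            assert tgt.sort_values("score").iloc[-1]["regulator"] == "TF1"

    def test_importances_sum_to_one_per_target(self, preset_expression,
                                               preset_tfs):
        _, medians, _ = preset_expression
        sub = ExpressionMatrix(medians.values.iloc[:25],
                               collapsed_to_medians=True, standardized=True)
        net = infer_genie3(sub, preset_tfs, n_trees=50, seed=0)
        sums = net.edges.groupby("target")["score"].sum()
        assert np.abs(sums - 1.0).max() < 1e-9

    def test_deterministic_under_seed(self, preset_expression, preset_tfs):
        _, medians, _ = preset_expression
        sub = ExpressionMatrix(medians.values.iloc[:15],
                               collapsed_to_medians=True, standardized=True)
        n1 = infer_genie3(sub, preset_tfs, n_trees=30, seed=9)
        n2 = infer_genie3(sub, preset_tfs, n_trees=30, seed=9)
        pd.testing.assert_frame_equal(n1.edges, n2.edges)


class TestDeconvolution:
    def test_recovers_planted_direct_matrix(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            p = int(rng.integers(4, 9))
            a = rng.normal(size=(p, p))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            a *= 0.5 / np.max(np.abs(np.linalg.eigvalsh(a)))
            g_obs = a @ np.linalg.inv(np.eye(p) - a)
            assert np.abs(deconvolve_matrix(g_obs) - a).max() <= 1e-6

    def test_zero_matrix_maps_to_zero(self):
        assert np.all(deconvolve_matrix(np.zeros((5, 5)),
                                        zero_diagonal=True) == 0)

    def test_no_decrement_when_first_pass_valid(self, caplog):
        rng = np.random.default_rng(11)
        a = rng.normal(size=(6, 6))
        g = (a + a.T) / 2
        with caplog.at_level("INFO", logger="consensusgrn"):
            deconvolve_matrix(g / (2 * np.abs(np.linalg.eigvalsh(g)).max()))
        assert "decremented" not in caplog.text

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            DeconvolutionConfig(beta=1.5)


class TestSilencing:
    def test_identity_input_silences_everything(self):
        assert np.abs(silence_matrix(np.eye(6))).max() == 0.0

    def test_chain_indirect_edge_silenced(self):
        r = 0.8
        g = np.array([[1, r, r * r], [r, 1, r], [r * r, r, 1]], float)
        s = silence_matrix(g)
        assert abs(s[0, 2]) < abs(s[0, 1])

    def test_singular_input_finite_via_pseudoinverse(self, caplog):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(3, 30))
        x = np.vstack([x, x[0]])  # duplicated gene column -> singular G
        g = np.corrcoef(x)
        with caplog.at_level("WARNING", logger="consensusgrn"):
            s = silence_matrix(g)
        assert np.all(np.isfinite(s))
        assert "pseudoinverse" in caplog.text


class TestDispatchInvariants:
    @pytest.mark.parametrize("method", ["ggm", "clr", "aracne",
                                        "deconvolution", "silencing"])
    def test_tf_origin_and_no_self_edges(self, method, preset_expression,
                                         preset_tfs):
        replicates, medians, _ = preset_expression
        net = infer_network(method, medians, replicates, preset_tfs, seed=0)
        assert set(net.edges["regulator"]) <= set(preset_tfs)
        assert (net.edges["regulator"] != net.edges["target"]).all()
        # reproducible ranks
        net2 = infer_network(method, medians, replicates, preset_tfs, seed=0)
        pd.testing.assert_frame_equal(net.edges, net2.edges)

    def test_replicate_methods_refuse_median_input(self, preset_expression,
                                                   preset_tfs):
        _, medians, _ = preset_expression
        with pytest.raises(ValidationError, match="replicate-level"):
            estimate_spearman_mi(medians)
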