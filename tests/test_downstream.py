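import numpy as np
import pytest

from mclrp import (GeneratorSpec, ResponseMatrix, build_drug_gene_network,
                   co_mutation_analysis, generate, null_bundle,
                   rank_genes_per_drug, screen_sensitive,
                   stratify_by_mutation, tissue_mean_response)
from mclrp.data import ExpressionMatrix, MutationProfile, TissueMap
from mclrp.downstream import CO_MUTATION_CLASSES
from mclrp.pca import fit_pca
from mclrp.solver import CompletionResult, SolverConfig, lambda_update


def _response_column(values, mask=None, orientation="higher_is_sensitive"):
    values = np.asarray(values, dtype=float)[:, None]
    mask = (np.ones_like(values, bool) if mask is None
            else np.asarray(mask, bool)[:, None])
    vals = np.where(mask, values, np.nan)
    return ResponseMatrix(vals, mask,
                          [f"C{i}" for i in range(len(values))], ["D0"],
                          orientation)


class TestScreenSensitive:
    def test_upper_quantile_when_higher_is_sensitive(self):
        obs = _response_column(np.arange(1.0, 11.0))
        obs.mask[2, 0] = False  # one missing entry
        obs.values[2, 0] = np.nan
        pred = np.arange(1.0, 11.0)[:, None]
        pred[2, 0] = 9.5
        calls = screen_sensitive(obs, pred, quantile=0.30)
        thr = np.quantile(np.delete(np.arange(1.0, 11.0), 2), 0.70)
        assert calls.thresholds["D0"] == pytest.approx(thr)
        assert list(calls.calls["cell_line"]) == ["C2"]
        pred[2, 0] = 5.0
        assert screen_sensitive(obs, pred, quantile=0.30).calls.empty

    def test_orientation_mirrors_threshold(self):
        values = np.arange(1.0, 11.0)
        hi = _response_column(values)
        lo = _response_column(values, orientation="lower_is_sensitive")
        pred = values[:, None]
        t_hi = screen_sensitive(hi, pred, 0.30).thresholds["D0"]
        t_lo = screen_sensitive(lo, pred, 0.30).thresholds["D0"]
        assert t_hi == pytest.approx(np.quantile(values, 0.70))
        assert t_lo == pytest.approx(np.quantile(values, 0.30))

    def test_no_missing_entries_gives_empty_calls(self):
        obs = _response_column(np.arange(1.0, 11.0))
        calls = screen_sensitive(obs, np.full((10, 1), 100.0), 0.30)
        assert calls.calls.empty

    def test_sparse_drug_excluded_with_warning(self):
        obs = _response_column([1.0, 2.0, 3.0, np.nan],
                               mask=[True, True, True, False])
        obs.mask[3, 0] = False
        with pytest.warns(UserWarning, match="excluded"):
            calls = screen_sensitive(obs, np.zeros((4, 1)), 0.30)
        assert calls.excluded_drugs == ["D0"]


class TestStratifyByMutation:
    def test_identical_groups_p_one_fold_one(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        mut = np.array([1, 1, 1, 0, 0, 0])
        cmp_ = stratify_by_mutation(vals, np.ones(6, bool), mut)
        assert cmp_.p_value == pytest.approx(1.0)
        assert cmp_.fold_change == pytest.approx(1.0)

    def test_large_shift_detected(self, rng):
        wt = rng.standard_normal(20)
        mut = rng.standard_normal(20) + 3.0
        vals = np.concatenate([mut, wt])
        calls = np.r_[np.ones(20, int), np.zeros(20, int)]
        cmp_ = stratify_by_mutation(vals, np.ones(40, bool), calls)
        assert cmp_.p_value < 1e-3
        # permutation oracle on the rank-sum statistic
        obs_stat = np.sum(
            np.argsort(np.argsort(vals))[:20] + 1)
        perms = []
        for _ in range(2000):
            p = rng.permutation(40)
            perms.append(np.sum(np.argsort(np.argsort(vals[p]))[:20] + 1))
        p_perm = np.mean(np.abs(np.array(perms) - 410) >= abs(obs_stat - 410))
        assert p_perm < 0.01

    def test_monotone_transform_invariance(self, rng):
        vals = rng.standard_normal(30)
        calls = rng.integers(0, 2, 30)
        calls[:3], calls[-3:] = 1, 0
        a = stratify_by_mutation(vals, np.ones(30, bool), calls)
        b = stratify_by_mutation(np.exp(vals), np.ones(30, bool), calls)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_underpowered_flagged(self):
        vals = np.arange(6.0)
        calls = np.array([1, 1, 0, 0, 0, 0])
        cmp_ = stratify_by_mutation(vals, np.ones(6, bool), calls)
        assert cmp_.underpowered and np.isnan(cmp_.p_value)

    def test_degenerate_stratification_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            stratify_by_mutation(np.arange(4.0), np.ones(4, bool),
                                 np.ones(4, int))

    def test_fold_change_orientation_adjusted(self):
        # lower values = sensitive: mutants (low IC50) are MORE sensitive
        vals = np.array([1.0, 1.5, 2.0, 7.0, 8.0, 9.0])
        calls = np.array([1, 1, 1, 0, 0, 0])
        cmp_ = stratify_by_mutation(vals, np.ones(6, bool), calls,
                                    orientation="lower_is_sensitive")
        assert cmp_.fold_change > 1


class TestCoMutation:
    def test_class_sizes_partition(self, rng):
        vals = rng.standard_normal(30)
        a = rng.integers(0, 2, 30)
        b = rng.integers(0, 2, 30)
        res = co_mutation_analysis(vals, np.ones(30, bool), a, b)
        assert sum(res["class_sizes"].values()) == 30
        assert set(res["class_sizes"]) == set(CO_MUTATION_CLASSES)

    def test_identical_mutation_vectors_empty_single_classes(self, rng):
        vals = rng.standard_normal(20)
        a = rng.integers(0, 2, 20)
        res = co_mutation_analysis(vals, np.ones(20, bool), a, a)
        assert res["class_sizes"]["MUT/WT"] == 0
        assert res["class_sizes"]["WT/MUT"] == 0
        assert "MUT/WT" not in res["comparisons"]

    def test_synergistic_double_mutant_scenario(self):
        # double-mutant shift twice the single shifts
        spec = GeneratorSpec(m=200, n=50, p=4, k_true=2, noise_sd=0.1,
                             missing_fraction=0.0,
                             mutation_effects=[(0, 1, 1.0), (1, 1, 1.0)],
                             co_mutation_effects=[(0, 1, 1, 2.0)],
                             mutation_prevalence=0.4, seed=3)
        b = generate(spec)
        res = co_mutation_analysis(b.response_complete[:, 1],
                                   np.ones(200, bool),
                                   b.mutations.calls[:, 0],
                                   b.mutations.calls[:, 1])
        fc = {k: v.fold_change for k, v in res["comparisons"].items()}
        assert fc["MUT/MUT"] > fc["MUT/WT"]
        assert fc["MUT/MUT"] > fc["WT/MUT"]


class TestDrugGeneNetwork:
    def _completed(self, bundle):
        from mclrp import admm_solve, denormalize, normalize_response

        norm = normalize_response(bundle.response)
        res = admm_solve(norm, fit_pca(bundle.expression), SolverConfig())
        return denormalize(norm, res.M_hat)

    def test_alpha_zero_empty_and_monotone_in_alpha(self):
        b = generate(GeneratorSpec(m=60, n=40, p=5, seed=2))
        pred = self._completed(b)
        genes = b.mutations.gene_ids[:10]
        n0 = build_drug_gene_network(b.response, pred, b.mutations,
                                     alpha=0.0, genes=genes)
        assert n0.edges.empty
        n1 = build_drug_gene_network(b.response, pred, b.mutations,
                                     alpha=0.05, genes=genes)
        n2 = build_drug_gene_network(b.response, pred, b.mutations,
                                     alpha=0.20, genes=genes)
        e1 = set(map(tuple, n1.edges[["drug", "gene"]].to_numpy()))
        e2 = set(map(tuple, n2.edges[["drug", "gene"]].to_numpy()))
        assert e1 <= e2

    def test_null_spurious_rate_bounded(self):
        from scipy.stats import binom

        b = null_bundle(GeneratorSpec(m=60, n=50, p=10,
                                      missing_fraction=0.2, seed=11))
        pred = self._completed(b)
        net = build_drug_gene_network(b.response, pred, b.mutations,
                                      alpha=0.05)
        n_pairs = len(net.all_pairs)
        # both-sources-significant rate under independence is at most ~alpha
        # (sources are correlated, so alpha is the conservative bound)
        bound = binom.ppf(0.999, n_pairs, 0.05)
        assert len(net.edges) <= bound

    def test_planted_effect_recovered(self):
        b = generate(GeneratorSpec(m=60, n=100, p=6, k_true=3,
                                   missing_fraction=0.3,
                                   mutation_effects=[(7, 2, 3.0)], seed=5))
        pred = self._completed(b)
        net = build_drug_gene_network(b.response, pred, b.mutations,
                                      alpha=0.05, genes=["G00007"])
        hit = ((net.edges["drug"] == "D002")
               & (net.edges["gene"] == "G00007"))
        assert hit.any()

    def test_networkx_export(self):
        b = generate(GeneratorSpec(m=60, n=60, p=5,
                                   mutation_effects=[(0, 0, 3.0)], seed=9))
        pred = self._completed(b)
        net = build_drug_gene_network(b.response, pred, b.mutations,
                                      alpha=0.05, genes=["G00000"])
        g = net.to_networkx()
        assert g.number_of_edges() == len(net.edges)


class TestRankGenes:
    def _fit(self, bundle):
        from mclrp import admm_solve, normalize_response

        norm = normalize_response(bundle.response)
        pca = fit_pca(bundle.expression)
        res = admm_solve(norm, pca, SolverConfig())
        return pca, res

    def test_planted_driver_ranks_first(self):
        # one gene linearly drives one drug's response
        rng = np.random.default_rng(5)
        m, n = 100, 30
        X = rng.standard_normal((m, n))
        X[:, 4] *= 6.0  # dominant-variance driver gene
        resp_vals = np.column_stack([X[:, 4] + 0.05 * rng.standard_normal(m),
                                     rng.standard_normal(m)])
        mask = np.ones((m, 2), bool)
        mask[rng.choice(m, 20, replace=False), 0] = False
        raw = np.where(mask, resp_vals, np.nan)
        expr = ExpressionMatrix(X, [f"C{i}" for i in range(m)],
                                [f"G{j:02d}" for j in range(n)])
        rm = ResponseMatrix(raw, mask, expr.row_ids, ["D0", "D1"])
        from mclrp import admm_solve, normalize_response

        norm = normalize_response(rm)
        pca = fit_pca(expr)
        res = admm_solve(norm, pca, SolverConfig())
        for method in ("model_weights", "correlation"):
            ranked = rank_genes_per_drug(pca, res, expr, rm.col_ids,
                                         method=method, top_n=5)
            assert ranked["D0"].iloc[0]["gene"] == "G04"

    def test_zero_lambda_degenerate_lexicographic(self, small_bundle):
        pca, res = self._fit(small_bundle)
        res_zero = CompletionResult(res.M_hat, np.zeros_like(res.Lambda),
                                    True, 1, 0.0, res.config)
        ranked = rank_genes_per_drug(pca, res_zero, small_bundle.expression,
                                     small_bundle.response.col_ids,
                                     method="model_weights", top_n=3)
        df = ranked["D000"]
        assert df.attrs["degenerate"]
        assert list(df["gene"]) == sorted(small_bundle.expression.gene_ids)[:3]

    def test_top_n_full_returns_permutation(self, small_bundle):
        pca, res = self._fit(small_bundle)
        n = len(small_bundle.expression.gene_ids)
        ranked = rank_genes_per_drug(pca, res, small_bundle.expression,
                                     small_bundle.response.col_ids,
                                     top_n=n + 100)
        assert sorted(ranked["D000"]["gene"]) == sorted(
            small_bundle.expression.gene_ids)

    def test_no_pca_falls_back_to_correlation(self, small_bundle):
        from mclrp import admm_solve, normalize_response

        norm = normalize_response(small_bundle.response)
        res = admm_solve(norm, None, SolverConfig(variant="no_pca", beta=0.5))
        with pytest.warns(UserWarning, match="falling back"):
            ranked = rank_genes_per_drug(None, res, small_bundle.expression,
                                         small_bundle.response.col_ids,
                                         top_n=3)
        assert (ranked["D000"]["method"] == "correlation").all()

    def test_invalid_top_n(self, small_bundle):
        pca, res = self._fit(small_bundle)
        with pytest.raises(ValueError):
            rank_genes_per_drug(pca, res, small_bundle.expression,
                                small_bundle.response.col_ids, top_n=0)


class TestTissueMeans:
    def test_single_and_pair_means(self):
        pred = np.array([[2.0, 1.0], [4.0, 3.0], [10.0, 5.0]])
        tm = TissueMap({"A": "lung", "B": "lung", "C": "skin"})
        out = tissue_mean_response(pred, ["A", "B", "C"], ["D0", "D1"], tm)
        assert out.loc["lung", "D0"] == pytest.approx(3.0)
        assert out.loc["skin", "D0"] == pytest.approx(10.0)
        assert out.loc["skin", "n_cell_lines"] == 1

    def test_count_weighted_grand_mean(self, rng):
        pred = rng.standard_normal((20, 3))
        ids = [f"C{i}" for i in range(20)]
        tm = TissueMap({c: f"t{i % 4}" for i, c in enumerate(ids)})
        out = tissue_mean_response(pred, ids, ["D0", "D1", "D2"], tm)
        w = out["n_cell_lines"].to_numpy()
        grand = (out[["D0", "D1", "D2"]].to_numpy() * w[:, None]).sum(0) / w.sum()
        np.testing.assert_allclose(grand, pred.mean(axis=0), atol=1e-10)

    def test_unmapped_rows_excluded(self):
        pred = np.array([[1.0], [100.0]])
        tm = TissueMap({"A": "lung"})
        out = tissue_mean_response(pred, ["A", "B"], ["D0"], tm)
        assert out.loc["lung", "D0"] == 1.0 and len(out) == 1
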