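import numpy as np
import pandas as pd
import pytest

from neurokd.containers import ExpressionMatrix
from neurokd.deconvolution import (
    compute_celltype_residual,
    filter_low_expression,
    marker_robustness_check,
    normalize_counts,
    partition_variance,
)


class TestNormalizeCounts:
    def test_closed_form_log2cpm(self, counts_matrix):
        values = counts_matrix.values.copy()
        values.iloc[:, 0] = 0.0
        values.iloc[0, 0] = 200.0
        values.iloc[1, 0] = 2_000_000.0 - 200.0
        m = ExpressionMatrix(values, unit="counts")
        out = normalize_counts(m)
        assert out.values.iloc[0, 0] == pytest.approx(np.log2(101), abs=1e-9)
        assert out.values.iloc[2, 0] == 0.0  # count 0 -> 0 for any library

    def test_scale_invariance_per_sample(self, counts_matrix):
        doubled = ExpressionMatrix(counts_matrix.values * 2, unit="counts")
        a = normalize_counts(counts_matrix).values
        b = normalize_counts(doubled).values
        assert np.allclose(a, b, atol=1e-12)

    def test_renormalization_refused(self, counts_matrix):
        once = normalize_counts(counts_matrix)
        with pytest.raises(ValueError, match="refused"):
            normalize_counts(once)

    def test_zero_library_names_sample(self, counts_matrix):
        values = counts_matrix.values.copy()
        values["s3"] = 0.0
        with pytest.raises(ValueError, match="s3"):
            normalize_counts(ExpressionMatrix(values, unit="counts"))


class TestLowExpressionFilter:
    def _cpm_matrix(self, cpm_rows):
        # craft counts whose CPM equals the requested values exactly
        cpm = np.asarray(cpm_rows, dtype=float)
        lib = 1e6
        counts = cpm * lib / 1e6
        # add a ballast gene so library size is constant per sample
        ballast = lib - counts.sum(axis=0)
        values = np.vstack([counts, ballast])
        genes = [f"g{i}" for i in range(len(cpm_rows))] + ["ballast"]
        return ExpressionMatrix(
            pd.DataFrame(values, index=genes,
                         columns=[f"s{j}" for j in range(cpm.shape[1])]),
            unit="counts",
        )

    def test_boundary_strictly_over(self):
        m = self._cpm_matrix([[1.0] * 10, [1.01] * 10])
        kept = filter_low_expression(m, min_cpm=1.0, min_fraction=0.30)
        assert "g0" not in kept.gene_ids  # exactly 1 CPM everywhere -> removed
        assert "g1" in kept.gene_ids

    def test_three_of_ten_at_30pct_retained(self):
        m = self._cpm_matrix([[2.0] * 3 + [0.0] * 7])
        kept = filter_low_expression(m, min_cpm=1.0, min_fraction=0.30)
        assert "g0" in kept.gene_ids

    def test_min_cpm_zero_keeps_any_nonzero(self):
        m = self._cpm_matrix([[0.5] + [0.0] * 9, [0.0] * 10])
        kept = filter_low_expression(m, min_cpm=0.0, min_fraction=0.10)
        assert "g0" in kept.gene_ids
        assert "g1" not in kept.gene_ids


class TestVariancePartition:
    def test_pure_batch_gene_attributed_to_batch(self):
        rng = np.random.default_rng(0)
        n = 120
        batch = rng.integers(0, 2, n)
        meta = pd.DataFrame({"batch": [f"b{k}" for k in batch]},
                            index=[f"s{j}" for j in range(n)])
        values = pd.DataFrame(
            {f"s{j}": [3.0 * batch[j]] for j in range(n)}, index=["g0"]
        )
        m = ExpressionMatrix(values, meta, unit="log2cpm")
        vf = partition_variance(m, ["batch"])
        assert vf.fractions.loc["g0", "batch"] > 0.99

    def test_fractions_sum_to_one(self, default_cohort, neuron_residual):
        cfg, bulk, geno, cov, truth = default_cohort
        names = [n for n, _, _ in cfg.covariate_spec]
        vf = partition_variance(bulk, names, truth.marker_genes)
        sums = vf.fractions.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-6)
        assert (vf.fractions.to_numpy() >= -1e-12).all()

    def test_noise_gene_small_fractions(self):
        rng = np.random.default_rng(3)
        n = 400
        meta = pd.DataFrame(
            {"batch": [f"b{k}" for k in rng.integers(0, 3, n)],
             "age": rng.normal(70, 8, n)},
            index=[f"s{j}" for j in range(n)],
        )
        values = pd.DataFrame(rng.normal(0, 1, (20, n)),
                              index=[f"g{i}" for i in range(20)],
                              columns=meta.index)
        vf = partition_variance(ExpressionMatrix(values, meta, unit="log2cpm"),
                                ["batch", "age"])
        assert (vf.fractions[["batch", "age"]] < 0.05).all().all()

    def test_permuted_covariate_fraction_collapses(self):
        rng = np.random.default_rng(4)
        n = 300
        age = rng.normal(0, 1, n)
        meta = pd.DataFrame({"age": age}, index=[f"s{j}" for j in range(n)])
        values = pd.DataFrame([2.0 * age + rng.normal(0, 0.5, n)],
                              index=["g0"], columns=meta.index)
        m = ExpressionMatrix(values, meta, unit="log2cpm")
        before = partition_variance(m, ["age"]).fractions.loc["g0", "age"]
        meta_perm = meta.copy()
        meta_perm["age"] = rng.permutation(age)
        m2 = ExpressionMatrix(values, meta_perm, unit="log2cpm")
        after = partition_variance(m2, ["age"]).fractions.loc["g0", "age"]
        assert before > 0.8
        assert after < 0.05


class TestCellTypeResidual:
    def test_marker_only_design_gives_centered_expression(self):
        rng = np.random.default_rng(5)
        n = 80
        marker = rng.normal(0, 1, n)
        gene = 1.5 + 0.0 * marker + rng.normal(0, 1, n)
        values = pd.DataFrame([gene, marker], index=["g0", "ENO2"],
                              columns=[f"s{j}" for j in range(n)])
        m = ExpressionMatrix(values, unit="log2cpm")
        res = compute_celltype_residual(m, [], {"neuron": "ENO2"}, "neuron")
        # with only the target marker adjusted, the add-back restores
        # everything except the fitted mean
        assert np.allclose(res.values.loc["g0"],
                           gene - gene.mean(), atol=1e-8)

    def test_markers_excluded_from_output(self, neuron_residual, default_cohort):
        *_, truth = default_cohort
        assert not set(truth.marker_genes.values()) & set(neuron_residual.gene_ids)

    def test_residual_orthogonal_to_adjusted_terms(self, default_cohort):
        from neurokd.deconvolution import build_design

        cfg, bulk, geno, cov, truth = default_cohort
        names = [n for n, _, _ in cfg.covariate_spec]
        res = compute_celltype_residual(bulk, names, truth.marker_genes, "neuron")
        X, colnames, blocks = build_design(bulk, names, truth.marker_genes)
        R = res.values.to_numpy()
        target_col = blocks["marker:neuron"].start
        for j, name in enumerate(colnames):
            if j == target_col or name == "intercept":
                continue
            dots = np.abs(R @ X[:, j])
            bound = 1e-6 * np.linalg.norm(R, axis=1) * np.linalg.norm(X[:, j])
            assert (dots <= bound + 1e-9).all(), name

    def test_neuron_residual_matches_neuron_celltype_best(self, default_cohort,
                                                          neuron_residual):
        cfg, bulk, geno, cov, truth = default_cohort
        de = truth.de_genes["neuron"]
        wins = 0
        for g in de:
            cors = {
                ct: np.corrcoef(neuron_residual.values.loc[g],
                                truth.celltype_expression[ct].loc[g])[0, 1]
                for ct in cfg.cell_types
            }
            wins += max(cors, key=cors.get) == "neuron"
        assert wins / len(de) >= 0.90

    def test_planted_batch_effect_removed(self, default_cohort, neuron_residual):
        cfg, bulk, geno, cov, truth = default_cohort
        batch_codes = pd.Categorical(cov["batch"]).codes.astype(float)
        null_genes = [g for g in neuron_residual.gene_ids
                      if g not in set(truth.de_genes["neuron"])][:100]
        n = len(cov)
        ok = 0
        for g in null_genes:
            r = np.corrcoef(neuron_residual.values.loc[g], batch_codes)[0, 1]
            t = r * np.sqrt((n - 2) / max(1e-12, 1 - r**2))
            ok += abs(t) < 2
        assert ok / len(null_genes) >= 0.95

    def test_missing_marker_named(self, default_cohort):
        cfg, bulk, *_ = default_cohort
        with pytest.raises(ValueError, match="NOPE"):
            compute_celltype_residual(bulk, [], {"neuron": "NOPE"}, "neuron")


class TestMarkerRobustness:
    def test_pool_equal_to_marker_gives_unit_correlation(self, default_cohort):
        cfg, bulk, geno, cov, truth = default_cohort
        marker = truth.marker_genes["neuron"]
        out = marker_robustness_check(
            bulk, [n for n, _, _ in cfg.covariate_spec], marker,
            [marker], n_draws=3, subset_size=1, seed=0,
        )
        assert (out["median_r"] > 0.999999).all()

    def test_neuron_program_subsets_correlate(self, default_cohort):
        cfg, bulk, geno, cov, truth = default_cohort
        de = truth.de_genes["neuron"][:40]
        out = marker_robustness_check(
            bulk, [n for n, _, _ in cfg.covariate_spec],
            truth.marker_genes["neuron"], de, n_draws=8, subset_size=5, seed=1,
        )
        assert out["median_r"].median() > 0.5

    def test_n_draws_validation(self, default_cohort):
        cfg, bulk, geno, cov, truth = default_cohort
        with pytest.raises(ValueError):
            marker_robustness_check(bulk, [], truth.marker_genes["neuron"],
                                    ["G0"], n_draws=0, subset_size=1)
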