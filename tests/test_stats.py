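import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.special import comb

from neurokd.stats import (
    bh_fdr,
    differential_expression,
    fisher_overlap,
    map_cis_eqtl,
    overlap_from_counts,
    sampling_enrichment,
    two_stage_fdr,
)
from neurokd.synthetic import simulate_genotypes


def stepup_oracle(p):
    """Hand implementation of the BH step-up from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestBhFdr:
    def test_matches_hand_stepup_on_fixed_vector(self):
        p = np.array([0.01, 0.04, 0.03, 0.05])
        assert np.allclose(bh_fdr(p), [0.04, 0.05, 0.05, 0.05], atol=1e-12)
        assert np.allclose(bh_fdr(p), stepup_oracle(p), atol=1e-12)

    def test_single_p_is_identity(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_equal_ps_unchanged(self):
        assert np.allclose(bh_fdr([0.2] * 5), 0.2)

    def test_out_of_range_rejected_with_index(self):
        with pytest.raises(ValueError, match="index 2"):
            bh_fdr([0.1, 0.2, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_matches_oracle_on_random_vectors(self, ps):
        assert np.allclose(bh_fdr(ps), stepup_oracle(ps), atol=1e-12)

    def test_monotone_adding_larger_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 20)
        q_before = bh_fdr(p)
        q_after = bh_fdr(np.append(p, 0.999))[:-1]
        assert (q_after >= q_before - 1e-12).all()


class TestTwoStageFdr:
    def test_all_ones_stay_one(self):
        assert np.allclose(two_stage_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_is_identity(self):
        assert two_stage_fdr([0.02])[0] == pytest.approx(0.02)

    def test_dominated_by_bh_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            m = rng.integers(2, 40)
            p = rng.uniform(0, 1, m)
            if rng.random() < 0.5:
                p[: m // 2] *= 1e-4  # half near-zero signals
            assert (two_stage_fdr(p) <= bh_fdr(p) + 1e-12).all()


class TestDifferentialExpression:
    def test_degenerate_equal_groups_p_one(self):
        values = pd.DataFrame([[1.0] * 6], index=["g0"],
                              columns=[f"s{j}" for j in range(6)])
        group = pd.Series(["case"] * 3 + ["control"] * 3, index=values.columns)
        out = differential_expression(values, group)
        assert out.loc["g0", "t"] == 0.0
        assert out.loc["g0", "p"] == pytest.approx(1.0)

    def test_power_on_planted_one_sd_shift(self):
        rng = np.random.default_rng(2)
        n = 200
        cols = [f"s{j}" for j in range(2 * n)]
        group = pd.Series(["case"] * n + ["control"] * n, index=cols)
        shift = np.r_[np.ones(n), np.zeros(n)]
        rows = {f"de{i}": shift + rng.normal(0, 1, 2 * n) for i in range(50)}
        rows.update({f"null{i}": rng.normal(0, 1, 2 * n) for i in range(150)})
        out = differential_expression(pd.DataFrame(rows, index=cols).T, group)
        de_flagged = out.loc[[f"de{i}" for i in range(50)], "significant"].mean()
        assert de_flagged >= 0.90

    def test_fdr_calibration_under_null_mix(self):
        # realized FDR among discoveries stays near the nominal level
        rng = np.random.default_rng(3)
        n = 150
        cols = [f"s{j}" for j in range(2 * n)]
        group = pd.Series(["case"] * n + ["control"] * n, index=cols)
        shift = np.r_[np.ones(n), np.zeros(n)]
        fdrs = []
        for _ in range(20):
            rows = {f"de{i}": 1.5 * shift + rng.normal(0, 1, 2 * n) for i in range(40)}
            rows.update({f"null{i}": rng.normal(0, 1, 2 * n) for i in range(160)})
            out = differential_expression(pd.DataFrame(rows, index=cols).T, group)
            hits = out.index[out["significant"]]
            false = sum(1 for g in hits if g.startswith("null"))
            fdrs.append(false / max(1, len(hits)))
        assert np.mean(fdrs) <= 0.05 + 2 * np.std(fdrs) / np.sqrt(len(fdrs)) + 0.02

    def test_small_group_rejected(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g0"],
                              columns=["a", "b", "c"])
        group = pd.Series(["case", "control", "control"], index=values.columns)
        with pytest.raises(ValueError):
            differential_expression(values, group)


class TestFisherOverlap:
    def test_self_overlap_degenerate(self):
        universe = {f"g{i}" for i in range(10)}
        stat = fisher_overlap(universe, universe, universe)
        assert stat.odds_ratio == np.inf
        assert stat.p == pytest.approx(1.0)
        assert stat.pct_a == stat.pct_b == 100.0

    def test_or_17_from_5_5_5_85_table(self):
        universe = {f"g{i}" for i in range(100)}
        genes = sorted(universe)
        A = set(genes[:10])           # a=5 overlap, b=5
        B = set(genes[5:15])          # c=5, d=85
        stat = fisher_overlap(A, B, universe)
        assert stat.odds_ratio == pytest.approx(17.0)
        # exhaustive hypergeometric two-sided oracle
        M, nA, nB = 100, 10, 10
        probs = [comb(nA, k) * comb(M - nA, nB - k) / comb(M, nB)
                 for k in range(0, min(nA, nB) + 1)]
        p_obs = probs[5]
        p_two = sum(p for p in probs if p <= p_obs + 1e-12)
        assert stat.p == pytest.approx(p_two, rel=1e-9)

    def test_published_percentage_arithmetic(self):
        stat = overlap_from_counts(9361, 7530, 4506, 15000)
        assert round(stat.pct_a, 1) == 48.1
        assert round(stat.pct_b, 1) == 59.8

    def test_symmetry_in_a_b(self):
        universe = {f"g{i}" for i in range(50)}
        genes = sorted(universe)
        A, B = set(genes[:20]), set(genes[10:25])
        s1, s2 = fisher_overlap(A, B, universe), fisher_overlap(B, A, universe)
        assert s1.p == pytest.approx(s2.p)
        assert s1.odds_ratio == pytest.approx(s2.odds_ratio)

    def test_containment_enforced(self):
        with pytest.raises(ValueError, match="x"):
            fisher_overlap({"x"}, set(), {"y"})


class TestSamplingEnrichment:
    def test_empty_overlap_large_expectation_p_near_one(self):
        genes = [f"g{i}" for i in range(40)]
        stat = sampling_enrichment(set(genes[:20]), set(genes[20:]), genes,
                                   n_perm=200, seed=0)
        assert stat.p > 0.5

    def test_maximal_overlap_minimal_p(self):
        genes = [f"g{i}" for i in range(30)]
        A = set(genes[:10])
        stat = sampling_enrichment(A, A, genes, n_perm=400, seed=1)
        assert stat.p == pytest.approx(1 / 401)

    def test_agrees_with_hypergeometric_tail(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(200)]
        A = set(rng.choice(genes, 40, replace=False))
        B = set(rng.choice(genes, 50, replace=False))
        n_perm = 2000
        stat = sampling_enrichment(A, B, genes, n_perm=n_perm, seed=2)
        k = len(A & B)
        exact = sps.hypergeom.sf(k - 1, 200, 50, 40)
        mc_err = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(stat.p - exact) <= 3 * mc_err + 1 / n_perm


class TestCisEqtl:
    def _annotated(self, seed=0, n=400):
        geno = simulate_genotypes(20, n, (0.3, 0.3), seed=seed)
        genes = [f"G{i}" for i in range(20)]
        ann = pd.DataFrame(
            {"chrom": "chr1", "tss": [10_000 * (i + 1) + 100 for i in range(20)],
             "strand": "+"},
            index=pd.Index(genes, name="gene"),
        )
        geno.gene_annotation = ann
        return geno, genes

    def test_window_boundary_inclusive(self):
        geno, genes = self._annotated()
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(0, 1, (20, 400)), index=genes,
                            columns=geno.sample_ids)
        tss = geno.gene_annotation.loc["G0", "tss"]  # 10100
        # variant rs1 at 20000: distance 9900; window exactly 9900 -> tested
        res = map_cis_eqtl(expr, geno, window=9900, fdr=0.05)
        tested = res.pairs[(res.pairs["gene"] == "G0") & (res.pairs["variant"] == "rs1")]
        assert len(tested) == 1
        res2 = map_cis_eqtl(expr, geno, window=9899, fdr=0.05)
        tested2 = res2.pairs[(res2.pairs["gene"] == "G0") & (res2.pairs["variant"] == "rs1")]
        assert len(tested2) == 0

    def test_cross_chromosome_pairs_never_tested(self):
        geno, genes = self._annotated()
        geno.gene_annotation.loc["G0", "chrom"] = "chr2"
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(0, 1, (20, 400)), index=genes,
                            columns=geno.sample_ids)
        res = map_cis_eqtl(expr, geno, window=1e9, fdr=0.05)
        assert (res.pairs["gene"] != "G0").all()

    def test_planted_effect_recovered_across_seeds(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            geno, genes = self._annotated(seed=seed)
            rng = np.random.default_rng(seed)
            expr = pd.DataFrame(rng.normal(0, 1, (20, 400)), index=genes,
                                columns=geno.sample_ids)
            expr.loc["G3"] += 0.8 * geno.dosages.loc["rs3"].to_numpy()
            res = map_cis_eqtl(expr, geno, window=1e6, fdr=0.01)
            hits += "G3" in res.eqtl_genes
        assert hits / n_seeds >= 0.95

    def test_permuted_dosage_null_calibrated(self):
        rates = []
        for seed in range(10):
            geno, genes = self._annotated(seed=seed)
            rng = np.random.default_rng(100 + seed)
            expr = pd.DataFrame(rng.normal(0, 1, (20, 400)), index=genes,
                                columns=geno.sample_ids)
            res = map_cis_eqtl(expr, geno, window=1e6, fdr=0.01)
            rates.append(len(res.eqtl_genes) / 20)
        mc_err = np.std(rates) / np.sqrt(len(rates))
        assert np.mean(rates) <= 0.01 + 2 * mc_err + 0.01

    def test_shared_sample_requirement(self):
        geno, genes = self._annotated()
        expr = pd.DataFrame(np.zeros((20, 5)), index=genes,
                            columns=[f"other{j}" for j in range(5)])
        with pytest.raises(ValueError, match="shared samples"):
            map_cis_eqtl(expr, geno)
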