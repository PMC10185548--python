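"""Differential expression, cis-eQTL mapping, FDR procedures, and set-overlap
statistics.

DE is a per-gene Welch two-sample t-test on deconvolved residuals with
Benjamini–Hochberg correction. cis-eQTL mapping regresses each gene's
residual on allele dosage for every variant within a window of the gene's
TSS (1 Mb by default, both bounds inclusive) and corrects across all tested
pairs. Overlap statistics (Fisher's exact and sampling-based enrichment) are
the shared core reused by module selection, pathway enrichment, knockdown
validation and the cross-cohort replication report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._rng import substream
from .containers import CellTypeResidual, GenotypeData

__all__ = [
    "differential_expression",
    "bh_fdr",
    "two_stage_fdr",
    "map_cis_eqtl",
    "fisher_overlap",
    "sampling_enrichment",
    "OverlapStat",
    "EqtlResult",
]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    bad = np.flatnonzero((p < 0) | (p > 1) | ~np.isfinite(p))
    if len(bad):
        raise ValueError(f"p-value outside [0, 1] at index {bad[0]}")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def two_stage_fdr(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Two-stage linear step-up q-values (Benjamini–Krieger–Yekutieli).

    Stage 1 estimates the number of true nulls m0 via a BH pass at level
    alpha/(1+alpha); stage 2 reruns the step-up with m0 in place of m. The
    result is elementwise no larger than the plain BH q-value.
    """
    p = np.asarray(pvalues, dtype=float)
    bad = np.flatnonzero((p < 0) | (p > 1) | ~np.isfinite(p))
    if len(bad):
        raise ValueError(f"p-value outside [0, 1] at index {bad[0]}")
    if p.size == 0:
        return p.copy()
    q = multipletests(p, alpha=alpha, method="fdr_tsbh")[1]
    return np.minimum(q, bh_fdr(p))


def differential_expression(
    residual: CellTypeResidual | pd.DataFrame, group: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Welch two-sample t-test per gene between case and control samples.

    Returns a frame indexed by gene with columns ``effect`` (case − control
    mean), ``t``, ``p``, ``q`` (BH) and ``significant`` (q < 0.05).
    """
    values = residual.values if isinstance(residual, CellTypeResidual) else residual
    group = pd.Series(group)
    group = group.reindex(values.columns)
    cases = values.loc[:, group == "case"].to_numpy(dtype=float)
    controls = values.loc[:, group == "control"].to_numpy(dtype=float)
    if cases.shape[1] < 2 or controls.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    t, p = sps.ttest_ind(cases, controls, axis=1, equal_var=False)
    # degenerate genes (zero variance in both groups, equal means) -> no evidence
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    q = bh_fdr(p)
    return pd.DataFrame(
        {
            "effect": cases.mean(axis=1) - controls.mean(axis=1),
            "t": t,
            "p": p,
            "q": q,
            "significant": q < 0.05,
        },
        index=values.index,
    )


@dataclass
class EqtlResult:
    """cis-eQTL mapping output: all tested pairs and a per-gene summary."""

    pairs: pd.DataFrame       # gene, variant, chrom, pos, slope, t, p, q
    gene_summary: pd.DataFrame  # per gene: best variant, best q, is_eqtl
    window: float
    fdr: float
    n_skipped_genes: int = 0

    @property
    def eqtl_genes(self) -> list:
        return self.gene_summary.index[self.gene_summary["is_eqtl"]].tolist()

    def best_variant(self, gene) -> str | None:
        if gene in self.gene_summary.index:
            v = self.gene_summary.loc[gene, "best_variant"]
            return None if pd.isna(v) else v
        return None


def map_cis_eqtl(
    residual: CellTypeResidual | pd.DataFrame,
    genotypes: GenotypeData,
    window: float = 1_000_000,
    fdr: float = 0.01,
) -> EqtlResult:
    """Additive cis-eQTL scan of residual expression on allele dosage.

    Tests every (gene, variant) pair on the same chromosome with
    |position − TSS| ≤ window (both bounds inclusive); BH correction is
    applied across all tested pairs, and a gene counts as an eQTL gene when
    any of its pairs reaches q < ``fdr``.
    """
    values = residual.values if isinstance(residual, CellTypeResidual) else residual
    shared = values.columns.intersection(genotypes.sample_ids)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared samples between residual and genotypes")
    Y = values.loc[:, shared]
    D = genotypes.dosages.loc[:, shared]
    ann = genotypes.gene_annotation
    if ann is None:
        raise ValueError("genotypes carry no gene annotation")

    genes = [g for g in Y.index if g in ann.index]
    n_skipped = len(Y.index) - len(genes)
    vpos = genotypes.variant_positions
    n = len(shared)

    Ym = Y.loc[genes].to_numpy(dtype=float)
    Ym = Ym - Ym.mean(axis=1, keepdims=True)
    Dm = D.to_numpy(dtype=float)
    Dm = Dm - Dm.mean(axis=1, keepdims=True)
    y_sd = np.sqrt((Ym**2).sum(axis=1))
    d_sd = np.sqrt((Dm**2).sum(axis=1))

    records = []
    vindex = {v: i for i, v in enumerate(D.index)}
    by_chrom: dict = {}
    for v, row in vpos.iterrows():
        if v in vindex:
            by_chrom.setdefault(row["chrom"], []).append((row["pos"], v))
    for chrom in by_chrom:
        by_chrom[chrom].sort()

    for gi, g in enumerate(genes):
        chrom, tss = ann.loc[g, "chrom"], ann.loc[g, "tss"]
        for pos, v in by_chrom.get(chrom, []):
            if abs(pos - tss) <= window:
                records.append((g, gi, v, vindex[v], chrom, pos))

    if not records:
        pairs = pd.DataFrame(columns=["gene", "variant", "chrom", "pos", "slope", "t", "p", "q"])
        summary = pd.DataFrame(
            columns=["best_variant", "best_q", "is_eqtl"], index=pd.Index(genes, name="gene")
        )
        summary["is_eqtl"] = False
        return EqtlResult(pairs, summary, window, fdr, n_skipped)

    gidx = np.array([r[1] for r in records])
    vidx = np.array([r[3] for r in records])
    num = (Ym[gidx] * Dm[vidx]).sum(axis=1)
    denom = y_sd[gidx] * d_sd[vidx]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1e-300, 1.0 - r**2))
    p = 2 * sps.t.sf(np.abs(t), df)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(d_sd[vidx] > 0, num / d_sd[vidx] ** 2, 0.0)
    q = bh_fdr(p)

    pairs = pd.DataFrame(
        {
            "gene": [r_[0] for r_ in records],
            "variant": [r_[2] for r_ in records],
            "chrom": [r_[4] for r_ in records],
            "pos": [r_[5] for r_ in records],
            "slope": slope,
            "t": t,
            "p": p,
            "q": q,
        }
    )
    best = pairs.loc[pairs.groupby("gene")["q"].idxmin()]
    summary = pd.DataFrame(
        {
            "best_variant": best["variant"].to_numpy(),
            "best_q": best["q"].to_numpy(),
            "best_slope": best["slope"].to_numpy(),
        },
        index=pd.Index(best["gene"], name="gene"),
    ).reindex(genes)
    summary["is_eqtl"] = summary["best_q"] < fdr
    summary["is_eqtl"] = summary["is_eqtl"].fillna(False).astype(bool)
    return EqtlResult(pairs, summary, window, fdr, n_skipped)


@dataclass
class OverlapStat:
    """2×2 set-overlap statistic over a finite universe."""

    n_a: int
    n_b: int
    n_overlap: int
    n_universe: int
    pct_a: float
    pct_b: float
    odds_ratio: float
    p: float
    method: str = "fisher"

    def as_dict(self) -> dict:
        return dict(
            n_a=self.n_a, n_b=self.n_b, n_overlap=self.n_overlap,
            n_universe=self.n_universe, pct_a=self.pct_a, pct_b=self.pct_b,
            odds_ratio=self.odds_ratio, p=self.p, method=self.method,
        )


def overlap_from_counts(n_a: int, n_b: int, n_overlap: int, n_universe: int) -> OverlapStat:
    """Overlap statistic from set sizes alone (e.g. published tallies)."""
    if n_overlap > min(n_a, n_b):
        raise ValueError("overlap exceeds one of the set sizes")
    a = n_overlap
    b = n_a - n_overlap
    c = n_b - n_overlap
    d = n_universe - n_a - n_b + n_overlap
    if d < 0:
        raise ValueError("universe smaller than the union of the sets")
    if b * c == 0:
        # degenerate table: perfect containment -> infinite sample OR
        oddsr = np.inf if a > 0 else np.nan
    else:
        oddsr = (a * d) / (b * c)
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    pct_a = 100.0 * a / n_a if n_a else 0.0
    pct_b = 100.0 * a / n_b if n_b else 0.0
    return OverlapStat(n_a, n_b, a, n_universe, pct_a, pct_b, oddsr, p)


def fisher_overlap(setA, setB, universe) -> OverlapStat:
    """Two-sided Fisher's exact test of the overlap between two gene sets."""
    universe = set(universe)
    A, B = set(setA), set(setB)
    offenders = (A | B) - universe
    if offenders:
        raise ValueError(f"sets not contained in universe: {sorted(offenders)[:5]}")
    return overlap_from_counts(len(A), len(B), len(A & B), len(universe))


def sampling_enrichment(
    setA, setB, universe, n_perm: int = 1000, seed: int = 0
) -> OverlapStat:
    """Permutation overlap test: |A|-sized random draws from the universe.

    Empirical p uses +1 smoothing: (1 + #{null ≥ observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    universe_list = sorted(set(universe))
    A, B = set(setA), set(setB)
    offenders = (A | B) - set(universe_list)
    if offenders:
        raise ValueError(f"sets not contained in universe: {sorted(offenders)[:5]}")
    observed = len(A & B)
    rng = substream(seed, "sampling_enrichment")
    uni = np.array(universe_list, dtype=object)
    in_b = np.isin(uni, sorted(B))
    k = len(A)
    null = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        idx = rng.choice(len(uni), size=k, replace=False)
        null[i] = in_b[idx].sum()
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    stat = overlap_from_counts(len(A), len(B), observed, len(universe_list))
    return OverlapStat(
        stat.n_a, stat.n_b, stat.n_overlap, stat.n_universe,
        stat.pct_a, stat.pct_b, stat.odds_ratio, p, method=f"sampling[{n_perm}]",
    )
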