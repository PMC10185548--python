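"""Weighted co-expression networks, module detection, and AD-module selection.

Adjacency is |Pearson correlation| raised to a soft-thresholding power
(6.5 by default), computed on case samples only. Topological overlap turns
the adjacency into a neighbourhood-sharing similarity; modules are detected
by average-linkage hierarchical clustering of 1 − TOM with a static cut and
merging of undersized clusters. Modules enriched for the AD differential
signature or for neuronal markers form the seeding gene set for causal
network learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .stats import bh_fdr, fisher_overlap

__all__ = [
    "adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "module_trait_association",
    "select_ad_modules",
    "ModuleSet",
]

DEFAULT_POWER = 6.5
DEFAULT_MIN_SIZE = 30
DEFAULT_CUT_HEIGHT = 0.995


def adjacency(
    expr: pd.DataFrame, power: float = DEFAULT_POWER, mode: str = "unsigned"
) -> pd.DataFrame:
    """Soft-thresholded co-expression adjacency, genes × genes.

    ``expr`` has genes in rows and (case) samples in columns. Unsigned mode
    uses |cor|^power; signed mode uses ((1+cor)/2)^power.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    vals = expr.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if len(flat):
        raise ValueError(f"constant gene: {expr.index[flat[0]]!r}")
    cor = np.corrcoef(vals)
    if mode == "unsigned":
        a = np.abs(cor) ** power
    elif mode == "signed":
        a = ((1.0 + cor) / 2.0) ** power
    else:
        raise ValueError(f"unknown mode {mode!r}")
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an adjacency matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij), where the
    sum excludes u ∈ {i, j} and k is connectivity (row sum minus diagonal);
    the diagonal is set to 1.
    """
    a = adj.to_numpy(dtype=float)
    n = a.shape[0]
    k = a.sum(axis=1) - np.diag(a)
    shared = a @ a
    # remove u=i and u=j contributions: a_ii*a_ij + a_ij*a_jj
    shared = shared - np.diag(a)[:, None] * a - a * np.diag(a)[None, :]
    num = shared + a
    kmin = np.minimum(k[:, None], k[None, :])
    denom = kmin + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, num / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


@dataclass
class ModuleSet:
    """Gene → module assignment (label 0 = unassigned) with eigengenes."""

    labels: pd.Series
    min_size: int = DEFAULT_MIN_SIZE
    eigengenes: pd.DataFrame = None  # samples × module labels

    @property
    def module_ids(self) -> list:
        return sorted(int(m) for m in self.labels.unique() if m != 0)

    def members(self, module: int) -> list:
        return self.labels.index[self.labels == module].tolist()

    def sizes(self) -> pd.Series:
        return self.labels[self.labels != 0].value_counts().sort_index()


def detect_modules(
    tom: pd.DataFrame,
    min_size: int = DEFAULT_MIN_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    expr: pd.DataFrame | None = None,
) -> ModuleSet:
    """Average-linkage clustering of 1 − TOM with a static cut.

    Clusters below ``min_size`` are merged into the most similar retained
    cluster (by mean inter-cluster TOM, or eigengene correlation when
    ``expr`` is given); if no retained cluster exists they stay unassigned
    (label 0). Deterministic.
    """
    import warnings

    genes = tom.index
    n = len(genes)
    if n < min_size:
        warnings.warn("fewer genes than min_size; all genes unassigned")
        return ModuleSet(pd.Series(0, index=genes), min_size)
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2.0
    Z = linkage(squareform(diss, checks=False), method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")

    clusters = {c: np.flatnonzero(raw == c) for c in np.unique(raw)}
    large = [c for c, idx in sorted(clusters.items()) if len(idx) >= min_size]
    small = [c for c, idx in sorted(clusters.items()) if len(idx) < min_size]

    labels = np.zeros(n, dtype=int)
    remap = {c: i + 1 for i, c in enumerate(large)}
    for c in large:
        labels[clusters[c]] = remap[c]

    if large and small:
        tomv = tom.to_numpy(dtype=float)
        for c in small:
            idx = clusters[c]
            sims = []
            for tgt in large:
                tgt_idx = clusters[tgt]
                sims.append(tomv[np.ix_(idx, tgt_idx)].mean())
            best = large[int(np.argmax(sims))]
            labels[idx] = remap[best]

    series = pd.Series(labels, index=genes, name="module")
    eig = None
    if expr is not None:
        cols = {}
        for m in sorted(set(labels) - {0}):
            members = genes[labels == m]
            cols[m] = module_eigengene(expr, members)
        if cols:
            eig = pd.DataFrame(cols)
    return ModuleSet(series, min_size, eig)


def module_eigengene(expr: pd.DataFrame, members: Sequence[str]) -> pd.Series:
    """First principal component of a module's standardized expression.

    The sign is fixed canonically (largest-magnitude element positive), so
    the eigengene is invariant under flipping every member row; scaled to
    unit variance.
    """
    members = pd.Index(members)
    missing = members.difference(expr.index)
    if len(missing):
        raise ValueError(f"module members absent from matrix: {list(missing[:5])}")
    if len(members) < 2:
        raise ValueError("need at least 2 member genes")
    sub = expr.loc[members].to_numpy(dtype=float)
    sub = sub - sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1)
    sd[sd == 0] = 1.0
    sub = sub / sd[:, None]
    # first right-singular vector = PC1 across samples
    _, _, vt = np.linalg.svd(sub, full_matrices=False)
    pc = vt[0]
    peak = pc[np.abs(pc) >= np.abs(pc).max() - 1e-12]
    if peak.max() < 0:
        pc = -pc
    pc = pc / pc.std()
    return pd.Series(pc, index=expr.columns, name="eigengene")


def module_trait_association(
    eigengene: pd.Series, trait: pd.Series, kind: str = "linear"
) -> float:
    """p-value for association between a module eigengene and a trait.

    ``kind='anova'`` runs a one-way ANOVA F-test across trait levels
    (diagnosis-style categorical traits); ``kind='linear'`` an OLS slope
    t-test (BRAAK/CERAD/MMSE-style numeric traits).
    """
    trait = trait.reindex(eigengene.index)
    if kind == "anova":
        groups = [eigengene[trait == lev].to_numpy() for lev in pd.unique(trait.dropna())]
        groups = [g for g in groups if len(g)]
        if len(groups) < 2:
            raise ValueError("categorical trait has fewer than 2 levels")
        if all(np.allclose(g.mean(), groups[0].mean()) and g.var() == 0 for g in groups):
            return 1.0
        from scipy.stats import f_oneway

        stat, p = f_oneway(*groups)
        return float(p) if np.isfinite(p) else 1.0
    elif kind == "linear":
        x = trait.to_numpy(dtype=float)
        y = eigengene.to_numpy(dtype=float)
        mask = np.isfinite(x) & np.isfinite(y)
        from scipy.stats import linregress

        res = linregress(x[mask], y[mask])
        p = res.pvalue
        return float(max(p, np.finfo(float).tiny))
    raise ValueError(f"unknown kind {kind!r}")


def select_ad_modules(
    modules: ModuleSet,
    de_genes: Sequence[str],
    neuron_markers: Sequence[str],
    universe: Sequence[str],
    other_celltype_markers: Mapping[str, Sequence[str]] | None = None,
    fdr: float = 0.05,
):
    """Select modules enriched for the AD signature or neuronal markers.

    Per module, Fisher enrichment against ``de_genes`` and against
    ``neuron_markers`` is computed over ``universe``; BH correction runs
    across all (module × set) tests, and a module is selected when either
    enrichment reaches q < ``fdr``. Enrichment for other cell types' marker
    sets is reported but never used for selection. Returns
    ``(summary frame, seeding gene set)``.
    """
    import warnings

    universe = set(universe)
    rows = []
    mids = modules.module_ids
    if not mids:
        warnings.warn("no modules to select from; empty seeding set")
        return pd.DataFrame(), set()
    de = set(de_genes) & universe
    nm = set(neuron_markers) & universe
    tests = []
    for m in mids:
        members = set(modules.members(m)) & universe
        s_de = fisher_overlap(members, de, universe)
        s_nm = fisher_overlap(members, nm, universe) if nm else None
        tests.append((m, "de", s_de))
        if s_nm is not None:
            tests.append((m, "neuron_markers", s_nm))
    qvals = bh_fdr([s.p for _, _, s in tests])
    qmap = {(m, tag): q for (m, tag, _), q in zip(tests, qvals)}
    selected = []
    for m in mids:
        members = set(modules.members(m)) & universe
        q_de = qmap.get((m, "de"), np.nan)
        q_nm = qmap.get((m, "neuron_markers"), np.nan)
        sel = (np.isfinite(q_de) and q_de < fdr) or (np.isfinite(q_nm) and q_nm < fdr)
        row = {"module": m, "size": len(members), "q_de": q_de, "q_neuron_markers": q_nm,
               "selected": sel}
        for ct, markers in (other_celltype_markers or {}).items():
            ms = set(markers) & universe
            row[f"p_{ct}"] = fisher_overlap(members, ms, universe).p if ms else np.nan
        rows.append(row)
        if sel:
            selected.append(m)
    summary = pd.DataFrame(rows).set_index("module")
    seeding = set()
    for m in selected:
        seeding |= set(modules.members(m))
    if not seeding:
        warnings.warn("no module enriched; empty seeding set")
    return summary, seeding
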