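"""Cell-type deconvolution of bulk expression by marker-adjusted residuals.

Bulk brain expression is modelled, per gene, as a linear combination of
demographic/technical covariates and one expression marker per CNS cell type
(population-specific expression analysis). The cell-type-specific component
is obtained by adding the fitted effect of the target cell type's marker back
to the regression residual — no cell-fraction estimation is involved.

The add-back uses the component of the marker orthogonal to the remaining
regressors, so the stored residual is exactly orthogonal to every adjusted
covariate and to every other marker; when the marker is uncorrelated with
the covariates this coincides with adding back slope × marker directly.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .containers import CellTypeResidual, ExpressionMatrix, VarianceFractions

__all__ = [
    "normalize_counts",
    "filter_low_expression",
    "partition_variance",
    "compute_celltype_residual",
    "marker_robustness_check",
    "build_design",
]


def normalize_counts(counts: ExpressionMatrix) -> ExpressionMatrix:
    """log2(1 + CPM) normalization of a raw count matrix.

    Refuses input that is already normalized; per-sample library size is the
    column sum and must be positive.
    """
    if counts.unit != "counts":
        raise ValueError(f"expected unit 'counts', got {counts.unit!r}; re-normalization refused")
    vals = counts.values.to_numpy(dtype=float)
    if vals.size and vals.min() < 0:
        raise ValueError("counts must be non-negative")
    libsize = vals.sum(axis=0)
    zero = np.flatnonzero(libsize <= 0)
    if len(zero):
        bad = counts.sample_ids[zero[0]]
        raise ValueError(f"sample {bad!r} has zero library size")
    cpm = 1e6 * vals / libsize[None, :]
    out = pd.DataFrame(np.log2(1.0 + cpm), index=counts.gene_ids, columns=counts.sample_ids)
    return ExpressionMatrix(out, counts.sample_metadata, unit="log2cpm")


def filter_low_expression(
    matrix: ExpressionMatrix, min_cpm: float = 1.0, min_fraction: float = 0.30
) -> ExpressionMatrix:
    """Keep genes with CPM strictly above ``min_cpm`` in at least
    ``min_fraction`` of samples; gene order is preserved."""
    import warnings

    if matrix.unit == "counts":
        vals = matrix.values.to_numpy(dtype=float)
        cpm = 1e6 * vals / vals.sum(axis=0, keepdims=True)
    elif matrix.unit == "log2cpm":
        cpm = 2.0 ** matrix.values.to_numpy(dtype=float) - 1.0
    else:
        raise ValueError(f"cannot apply a CPM filter to unit {matrix.unit!r}")
    keep = (cpm > min_cpm).mean(axis=1) >= min_fraction
    if not keep.any():
        warnings.warn("low-expression filter removed every gene")
    return ExpressionMatrix(
        matrix.values.loc[keep], matrix.sample_metadata, unit=matrix.unit
    )


def _encode_covariate(series: pd.Series) -> np.ndarray:
    """Dummy-code categoricals (drop-first), pass numerics through; columns centered."""
    if series.dtype.kind in "OUSb" or isinstance(series.dtype, pd.CategoricalDtype):
        dummies = pd.get_dummies(series, drop_first=True).to_numpy(dtype=float)
        if dummies.shape[1] == 0:
            raise ValueError(f"categorical covariate {series.name!r} has a single level")
        return dummies - dummies.mean(axis=0, keepdims=True)
    vec = series.to_numpy(dtype=float)[:, None]
    return vec - vec.mean(axis=0, keepdims=True)


def build_design(
    matrix: ExpressionMatrix,
    covariates: Sequence[str],
    marker_genes: Mapping[str, str] | None = None,
    standardize_markers: bool = True,
) -> tuple[np.ndarray, list, dict]:
    """Assemble the (samples × regressors) design matrix.

    Returns ``(X, column_names, column_blocks)`` where ``column_blocks`` maps
    each covariate/marker name to its column slice. An intercept column is
    always first.
    """
    meta = matrix.sample_metadata
    blocks: dict[str, slice] = {}
    cols = [np.ones((matrix.n_samples, 1))]
    names = ["intercept"]
    start = 1
    for name in covariates:
        if name not in meta.columns:
            raise ValueError(f"covariate {name!r} not found in sample metadata")
        enc = _encode_covariate(meta[name])
        cols.append(enc)
        blocks[name] = slice(start, start + enc.shape[1])
        names += [name if enc.shape[1] == 1 else f"{name}[{k}]" for k in range(enc.shape[1])]
        start += enc.shape[1]
    for ct, gene in (marker_genes or {}).items():
        if gene not in matrix.gene_ids:
            raise ValueError(f"marker gene {gene!r} for cell type {ct!r} absent from matrix")
        vec = matrix.values.loc[gene].to_numpy(dtype=float)
        vec = vec - vec.mean()
        if standardize_markers:
            sd = vec.std()
            if sd == 0:
                raise ValueError(f"marker gene {gene!r} is constant")
            vec = vec / sd
        cols.append(vec[:, None])
        blocks[f"marker:{ct}"] = slice(start, start + 1)
        names.append(f"marker:{ct}")
        start += 1
    X = np.hstack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design; covariates are collinear")
    return X, names, blocks


def _r2(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-row R² of regressing each row of Y (genes × samples) on X."""
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    tss = ((Y.T - Y.T.mean(axis=0)) ** 2).sum(axis=0)
    rss = (resid**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - rss / tss
    return np.where(tss > 0, r2, 0.0)


def partition_variance(
    matrix: ExpressionMatrix,
    covariates: Sequence[str],
    marker_genes: Mapping[str, str] | None = None,
) -> VarianceFractions:
    """Fixed-effect variance partition across covariates and markers.

    Per gene, each term's share is its marginal partial R² (full-model R²
    minus the R² of the model with that term removed); the shares plus the
    residual (1 − full R²) are rescaled to sum to one.
    """
    X, names, blocks = build_design(matrix, covariates, marker_genes)
    Y = matrix.values.to_numpy(dtype=float)
    full = _r2(Y, X)
    parts = {}
    for term, sl in blocks.items():
        keep = np.ones(X.shape[1], dtype=bool)
        keep[sl] = False
        parts[term] = np.clip(full - _r2(Y, X[:, keep]), 0.0, None)
    frame = pd.DataFrame(parts, index=matrix.gene_ids)
    frame["residual"] = np.clip(1.0 - full, 0.0, None)
    total = frame.sum(axis=1).to_numpy()
    total[total == 0] = 1.0
    frame = frame.div(total, axis=0)
    return VarianceFractions(frame, method="partial_r2")


def compute_celltype_residual(
    matrix: ExpressionMatrix,
    covariates: Sequence[str],
    marker_genes: Mapping[str, str],
    target_cell_type: str,
    standardize_markers: bool = True,
) -> CellTypeResidual:
    """Deconvolve bulk expression into one cell type's residual component.

    Per gene (marker genes excluded from the output rows): fit OLS of the
    gene on [intercept + covariates + all marker expressions] and add the
    fitted target-marker effect back to the residual. The add-back uses the
    marker component orthogonal to the other regressors (see module
    docstring), so residuals stay orthogonal to all other adjusted terms and
    are centered.
    """
    if target_cell_type not in marker_genes:
        raise ValueError(f"target cell type {target_cell_type!r} has no marker")
    X, names, blocks = build_design(matrix, covariates, marker_genes, standardize_markers)
    target_col = blocks[f"marker:{target_cell_type}"].start

    keep_rows = ~matrix.gene_ids.isin(list(marker_genes.values()))
    Y = matrix.values.loc[keep_rows].to_numpy(dtype=float)

    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # regressors × genes
    resid = Y.T - X @ beta

    # marker component orthogonal to the remaining regressors
    others = np.delete(X, target_col, axis=1)
    m = X[:, target_col]
    coef, *_ = np.linalg.lstsq(others, m, rcond=None)
    m_perp = m - others @ coef

    out = resid + np.outer(m_perp, beta[target_col])
    values = pd.DataFrame(out.T, index=matrix.gene_ids[keep_rows], columns=matrix.sample_ids)
    coefs = pd.DataFrame(beta.T, index=matrix.gene_ids[keep_rows], columns=names)
    return CellTypeResidual(
        values=values,
        cell_type=target_cell_type,
        marker_gene=marker_genes[target_cell_type],
        adjusted_covariates=list(covariates)
        + [f"marker:{ct}" for ct in marker_genes if ct != target_cell_type],
        fit_coefficients=coefs,
    )


def marker_robustness_check(
    matrix: ExpressionMatrix,
    covariates: Sequence[str],
    single_marker: str,
    candidate_marker_pool: Sequence[str],
    n_draws: int = 20,
    subset_size: int = 5,
    seed: int = 0,
    other_markers: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Compare the single-marker residual against pseudo-residuals built from
    random multi-gene marker subsets.

    For each draw, the mean expression of a random ``subset_size`` subset of
    the pool replaces the single marker in the deconvolution; the per-gene
    Pearson correlation between the two residuals is summarized (median and
    IQR) per draw.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    pool = list(candidate_marker_pool)
    if subset_size > len(pool):
        raise ValueError("subset_size exceeds the candidate pool")
    rng = substream(seed, "marker_robustness")

    base_markers = dict(other_markers or {})
    base_markers["__target__"] = single_marker
    ref = compute_celltype_residual(matrix, covariates, base_markers, "__target__")

    rows = []
    for d in range(n_draws):
        subset = list(rng.choice(pool, size=subset_size, replace=False))
        pseudo_vec = matrix.values.loc[subset].mean(axis=0)
        aug = matrix.values.copy()
        pseudo_name = "__pseudo_marker__"
        aug.loc[pseudo_name] = pseudo_vec
        aug_matrix = ExpressionMatrix(aug, matrix.sample_metadata, unit=matrix.unit)
        markers = dict(other_markers or {})
        markers["__target__"] = pseudo_name
        pseudo = compute_celltype_residual(aug_matrix, covariates, markers, "__target__")
        shared = ref.gene_ids.intersection(pseudo.gene_ids).difference(subset)
        a = ref.values.loc[shared].to_numpy()
        b = pseudo.values.loc[shared].to_numpy()
        a = a - a.mean(axis=1, keepdims=True)
        b = b - b.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
        denom[denom == 0] = np.nan
        cors = (a * b).sum(axis=1) / denom
        q1, med, q3 = np.nanpercentile(cors, [25, 50, 75])
        rows.append({"draw": d, "median_r": med, "iqr": q3 - q1, "n_genes": len(shared)})
    return pd.DataFrame(rows)
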