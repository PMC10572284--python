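"""Cell quality control, log-normalization, HVG selection and PCA.

QC conventions: a cell is removed when it has *fewer than* ``min_genes``
expressed genes, *more than* ``max_genes`` expressed genes (likely doublet),
or *more than* ``max_pct_mito`` percent of its counts on mitochondrial genes.
All three removal inequalities are strict, so boundary cells (exactly 500 or
5000 genes, exactly 5% mito) are retained.

Normalization divides each cell's counts by the cell total, multiplies by a
scale factor (default 10,000) and applies the natural log of one plus the
result (log1p).
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import CountMatrix, NormalizedMatrix, PCAEmbedding
from .errors import ConfigurationError, EmptyResultError

DEFAULT_MITO_PREFIX = "MT-"


def compute_qc_metrics(m: CountMatrix, mito_prefix: str = DEFAULT_MITO_PREFIX) -> pd.DataFrame:
    """Per-cell QC metrics: expressed-gene count, total counts, mito percentage.

    pct_mito is 100 x (counts on genes whose symbol starts with ``mito_prefix``)
    / total counts; a zero-count cell gets pct_mito 0 and is flagged for
    removal via ``flagged_zero_counts``.
    """
    csc = m.values.tocsc()
    n_genes_expressed = np.asarray((csc > 0).sum(axis=0)).ravel()
    total_counts = np.asarray(csc.sum(axis=0)).ravel()
    mito_mask = m.genes["symbol"].astype(str).str.startswith(mito_prefix).values
    mito_counts = np.asarray(csc[mito_mask].sum(axis=0)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(total_counts > 0, 100.0 * mito_counts / np.maximum(total_counts, 1), 0.0)
    return pd.DataFrame(
        {
            "n_genes_expressed": n_genes_expressed.astype(int),
            "total_counts": total_counts.astype(int),
            "pct_mito": pct,
            "flagged_zero_counts": total_counts == 0,
        },
        index=m.barcodes,
    )


def filter_cells(
    m: CountMatrix,
    qc: pd.DataFrame,
    min_genes: int = 500,
    max_genes: int = 5000,
    max_pct_mito: float = 5.0,
) -> CountMatrix:
    """Remove low-quality cells; cell order is preserved.

    Retained cells satisfy min_genes <= n_genes_expressed <= max_genes and
    pct_mito <= max_pct_mito (removal is by strict inequality on the stated
    bounds). Raises :class:`EmptyResultError` if nothing survives.
    """
    qc = qc.loc[m.barcodes]
    keep = (
        (qc["n_genes_expressed"] >= min_genes)
        & (qc["n_genes_expressed"] <= max_genes)
        & (qc["pct_mito"] <= max_pct_mito)
        & ~qc["flagged_zero_counts"]
    )
    if not keep.any():
        raise EmptyResultError(
            f"QC removed all {m.n_cells} cells "
            f"(min_genes={min_genes}, max_genes={max_genes}, max_pct_mito={max_pct_mito})"
        )
    return m.subset_cells(m.barcodes[keep.values])


def normalize(m: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """Log-normalize: value[g, c] = ln(1 + count[g, c] / total[c] * scale_factor)."""
    totals = np.asarray(m.values.sum(axis=0)).ravel()
    if (totals <= 0).any():
        bad = list(m.barcodes[totals <= 0][:5])
        raise ConfigurationError(f"cells with zero total counts cannot be normalized: {bad}")
    dense = np.asarray(m.values.todense(), dtype=float)
    values = np.log1p(dense / totals[None, :] * scale_factor)
    return NormalizedMatrix(
        values=values,
        genes=m.genes,
        cell_meta=m.cell_meta,
        scale_factor=scale_factor,
        source=m,
    )


def _vst_statistic(counts: np.ndarray, clip: Optional[float] = None) -> np.ndarray:
    """Variance of clipped standardized counts under a fitted mean-variance trend.

    The trend is a quadratic fit of log10 variance on log10 mean over genes
    with positive variance; standardized values are clipped at sqrt(n_cells)
    by default.
    """
    n_cells = counts.shape[1]
    mean = counts.mean(axis=1)
    var = counts.var(axis=1, ddof=1)
    stat = np.zeros(len(mean))
    fit_mask = (mean > 0) & (var > 0)
    if fit_mask.sum() < 3:
        return var
    # two-pass fit: highly variable genes would inflate the trend at their
    # own means, so the second pass excludes the most overdispersed decile
    use = fit_mask.copy()
    expected_var = np.zeros_like(mean)
    for it in range(2):
        coef = np.polyfit(np.log10(mean[use]), np.log10(var[use]), deg=2)
        expected_var[mean > 0] = 10 ** np.polyval(coef, np.log10(mean[mean > 0]))
        if it == 0:
            ratio = np.where(expected_var > 0, var / np.maximum(expected_var, 1e-12), 0.0)
            trimmed = fit_mask & (ratio < np.quantile(ratio[fit_mask], 0.9))
            if trimmed.sum() >= 3:
                use = trimmed
    clip_val = np.sqrt(n_cells) if clip is None else clip
    for i in np.where(expected_var > 0)[0]:
        z = (counts[i] - mean[i]) / np.sqrt(expected_var[i])
        z = np.clip(z, -clip_val, clip_val)
        stat[i] = z.var(ddof=1)
    return stat


def select_hvg(
    nm: NormalizedMatrix,
    n_top: int = 2000,
    protein_coding_only: bool = True,
    method: str = "vst",
) -> List[str]:
    """Rank genes by expression variability and return the top ``n_top`` ids.

    ``method='vst'`` ranks by the variance of trend-standardized raw counts
    (requires the provenance link to the source CountMatrix);
    ``method='lognorm_variance'`` ranks by the plain variance of the
    log-normalized values. Ties break by gene id; constant genes always rank
    after any gene with positive variability.
    """
    genes = nm.genes
    eligible = np.ones(len(genes), dtype=bool)
    if protein_coding_only:
        if "biotype" not in genes.columns:
            raise ConfigurationError(
                "protein_coding_only=True requires a 'biotype' column in the gene table"
            )
        eligible &= (genes["biotype"] == "protein_coding").values
    if method == "vst":
        if nm.source is None:
            raise ConfigurationError("method='vst' requires the source CountMatrix link")
        counts = np.asarray(nm.source.values.todense(), dtype=float)
        stat = _vst_statistic(counts)
    elif method == "lognorm_variance":
        stat = nm.values.var(axis=1, ddof=1)
    else:
        raise ConfigurationError(f"unknown HVG method: {method!r}")
    order = pd.DataFrame({"stat": stat, "gene_id": genes.index})[eligible]
    order = order.sort_values(["stat", "gene_id"], ascending=[False, True], kind="mergesort")
    return list(order["gene_id"].head(min(n_top, eligible.sum())))


def center_per_chip(nm: NormalizedMatrix) -> NormalizedMatrix:
    """Subtract per-chip gene means (optional surrogate for batch handling)."""
    values = nm.values.copy()
    chips = nm.cell_meta["chip"].values
    for chip in pd.unique(chips):
        cols = chips == chip
        values[:, cols] -= values[:, cols].mean(axis=1, keepdims=True)
    return NormalizedMatrix(
        values=values,
        genes=nm.genes,
        cell_meta=nm.cell_meta,
        scale_factor=nm.scale_factor,
        source=nm.source,
        centered=True,
    )


def pca(
    nm: NormalizedMatrix,
    hvg: Sequence[str],
    n_dims: int = 16,
    scale_clip: float = 10.0,
) -> PCAEmbedding:
    """PCA of cells on centered, unit-scaled (clipped at +-scale_clip) HVG rows.

    Components are sign-fixed so the largest-magnitude gene loading of each
    component is positive, making coordinates reproducible across runs.
    """
    hvg = list(hvg)
    if len(hvg) < n_dims:
        raise ConfigurationError(f"n_dims={n_dims} exceeds the {len(hvg)} HVGs provided")
    n_cells = nm.values.shape[1]
    if n_dims > min(n_cells, len(hvg)):
        raise ConfigurationError(f"n_dims={n_dims} exceeds min(cells, genes)")
    rows = nm.genes.index.get_indexer(hvg)
    if (rows < 0).any():
        raise ConfigurationError("HVG ids absent from the normalized matrix")
    X = nm.values[rows].T.copy()  # cells x genes
    X -= X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    X /= sd
    np.clip(X, -scale_clip, scale_clip, out=X)
    model = PCA(n_components=n_dims, svd_solver="full")
    coords = model.fit_transform(X)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(n_dims):
        i = np.argmax(np.abs(model.components_[j]))
        if model.components_[j, i] < 0:
            coords[:, j] *= -1.0
            model.components_[j] *= -1.0
    if not np.all(np.diff(model.explained_variance_) <= 1e-9):
        warnings.warn("PCA components not ordered by explained variance")
    return PCAEmbedding(
        coordinates=pd.DataFrame(
            coords, index=nm.barcodes, columns=[f"PC{i + 1}" for i in range(n_dims)]
        ),
        explained_variance_ratio=model.explained_variance_ratio_,
        hvg_gene_ids=hvg,
    )
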