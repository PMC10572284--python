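"""Differential expression: Wilcoxon rank-sum and logistic-regression tests.

The default test is the two-sided Wilcoxon rank-sum. When both groups have at
most ``exact_max`` cells the p-value is computed by exact enumeration of the
rank-sum null distribution (correct under ties); otherwise a tie-corrected
normal approximation with continuity correction is used. Fold changes are
log2((mean(expm1(x_in)) + 1) / (mean(expm1(x_out)) + 1)), i.e. computed on
de-logged normalized expression with a pseudocount of one, so swapping the
groups negates the fold change exactly.
"""

from __future__ import annotations

import warnings
from typing import Optional, Set

import numpy as np
import pandas as pd
from scipy import stats

from .containers import NormalizedMatrix
from .errors import ConfigurationError

EXACT_MAX_GROUP = 10


def wilcoxon_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p-value by enumeration of the null distribution.

    Enumerates, by dynamic programming over the pooled (tied) ranks, the
    number of ways to choose len(x) ranks with each possible rank-sum, and
    returns min(1, 2 * min(P(W <= w), P(W >= w))) where W is the rank sum of
    the first sample. Exact under ties; intended for small groups.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks2 = np.round(2 * stats.rankdata(pooled)).astype(int)  # doubled -> integers
    w_obs = int(ranks2[:n1].sum())
    max_sum = int(ranks2.sum())
    # counts[m, s] = number of m-subsets of ranks with doubled-rank-sum s
    counts = np.zeros((n1 + 1, max_sum + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for r in ranks2:
        for m in range(n1, 0, -1):
            counts[m, r:] += counts[m - 1, : max_sum + 1 - r]
    dist = counts[n1]
    total = dist.sum()
    p_le = dist[: w_obs + 1].sum() / total
    p_ge = dist[w_obs:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _wilcoxon_asymptotic_p(values: np.ndarray, n_in: int) -> np.ndarray:
    """Vectorized two-sided tie-corrected normal-approximation rank-sum test.

    ``values`` is genes x cells with the first ``n_in`` columns forming the
    in-group. Applies the standard tie correction to the variance and a 0.5
    continuity correction, matching the conventions of the classical
    rank-sum implementations.
    """
    n = values.shape[1]
    n_out = n - n_in
    ranks = stats.rankdata(values, axis=1)
    w = ranks[:, :n_in].sum(axis=1)
    mu = n_in * (n + 1) / 2.0
    tie_term = np.zeros(values.shape[0])
    for g in range(values.shape[0]):
        _, t = np.unique(values[g], return_counts=True)
        tie_term[g] = (t**3 - t).sum()
    var = n_in * n_out / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (w - mu - np.sign(w - mu) * 0.5) / np.sqrt(var)
    p = 2 * stats.norm.sf(np.abs(z))
    p[var <= 0] = 1.0  # all values tied
    return np.minimum(p, 1.0)


def logistic_lr_p(x_in: np.ndarray, x_out: np.ndarray) -> float:
    """Likelihood-ratio p-value of expression predicting group membership.

    Fits logit(P(in-group)) = b0 + b1 * expression against the
    intercept-only null and refers the deviance difference to chi2(1).
    """
    import statsmodels.api as sm

    y = np.concatenate([np.ones(len(x_in)), np.zeros(len(x_out))])
    x = np.concatenate([x_in, x_out])
    if np.ptp(x) == 0:
        return 1.0
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full = sm.Logit(y, X).fit(disp=0, maxiter=200, method="lbfgs")
            null = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0, maxiter=200)
            lr = 2.0 * (full.llf - null.llf)
        except Exception:
            return 1.0
    return float(stats.chi2.sf(max(lr, 0.0), df=1))


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if method == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    if method in ("bh", "fdr_bh"):
        from statsmodels.stats.multitest import multipletests

        return multipletests(p, method="fdr_bh")[1]
    raise ConfigurationError(f"unknown adjustment method: {method!r}")


def de_test(
    nm: NormalizedMatrix,
    cells_in: Set[str],
    cells_out: Set[str],
    min_pct: float = 0.05,
    method: str = "wilcoxon",
    adjust: str = "bonferroni",
    exact_max: int = EXACT_MAX_GROUP,
) -> pd.DataFrame:
    """Test each gene for differential expression between two cell groups.

    Genes expressed (normalized value > 0) in fewer than ``min_pct`` of cells
    in *both* groups are skipped. Returns a DataFrame with one row per tested
    gene: gene_id, avg_log2FC, p_value, p_adjusted, pct_in, pct_out.
    """
    cells_in, cells_out = set(cells_in), set(cells_out)
    if cells_in & cells_out:
        raise ConfigurationError("cells_in and cells_out overlap")
    if len(cells_in) < 3 or len(cells_out) < 3:
        raise ConfigurationError(
            f"each group needs >= 3 cells (got {len(cells_in)} vs {len(cells_out)})"
        )
    if method not in ("wilcoxon", "logistic_lr"):
        raise ConfigurationError(f"unknown DE method: {method!r}")
    barcodes = nm.barcodes
    in_idx = barcodes.get_indexer(sorted(cells_in))
    out_idx = barcodes.get_indexer(sorted(cells_out))
    if (in_idx < 0).any() or (out_idx < 0).any():
        raise ConfigurationError("group contains barcodes absent from the matrix")
    Xin = nm.values[:, in_idx]
    Xout = nm.values[:, out_idx]
    pct_in = (Xin > 0).mean(axis=1)
    pct_out = (Xout > 0).mean(axis=1)
    tested = (pct_in >= min_pct) | (pct_out >= min_pct)
    if not tested.any():
        warnings.warn("all genes fell below the expression-fraction filter")
        return pd.DataFrame(
            columns=["gene_id", "avg_log2FC", "p_value", "p_adjusted", "pct_in", "pct_out"]
        )
    rows = np.where(tested)[0]
    mean_in = np.expm1(Xin[rows]).mean(axis=1)
    mean_out = np.expm1(Xout[rows]).mean(axis=1)
    log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
    n_in = len(in_idx)
    if method == "wilcoxon":
        if n_in <= exact_max and len(out_idx) <= exact_max:
            p = np.array(
                [wilcoxon_exact_p(Xin[g], Xout[g]) for g in rows]
            )
        else:
            p = _wilcoxon_asymptotic_p(
                np.concatenate([Xin[rows], Xout[rows]], axis=1), n_in
            )
    else:
        p = np.array([logistic_lr_p(Xin[g], Xout[g]) for g in rows])
    return pd.DataFrame(
        {
            "gene_id": nm.gene_ids[rows],
            "avg_log2FC": log2fc,
            "p_value": p,
            "p_adjusted": _adjust(p, adjust),
            "pct_in": pct_in[rows],
            "pct_out": pct_out[rows],
        }
    ).reset_index(drop=True)


def rank_de(results: pd.DataFrame, alpha: float = 1e-5) -> pd.DataFrame:
    """Keep genes with adjusted p strictly below ``alpha``; rank by |log2FC|.

    Ties on the absolute fold change break by gene id.
    """
    if results.empty:
        return results.copy()
    sig = results[results["p_adjusted"] < alpha].copy()
    sig["_abs"] = sig["avg_log2FC"].abs()
    sig = sig.sort_values(["_abs", "gene_id"], ascending=[False, True], kind="mergesort")
    return sig.drop(columns="_abs").reset_index(drop=True)


def cluster_markers(
    nm: NormalizedMatrix,
    assign: pd.Series,
    cluster_id: int,
    **kwargs,
) -> pd.DataFrame:
    """One-vs-rest DE for a cluster (cells in the cluster vs all other cells)."""
    cells_in = set(assign.index[assign == cluster_id])
    cells_out = set(assign.index[assign != cluster_id])
    return de_test(nm, cells_in, cells_out, **kwargs)


def prepost_contrast(
    nm: NormalizedMatrix,
    assign: pd.Series,
    cluster_id: int,
    stimulus: str = "don",
    **kwargs,
) -> Optional[pd.DataFrame]:
    """Post- vs pre-transplant DE within one cluster for one stimulus.

    The in-group is {cluster, stimulus, post}, the out-group {cluster,
    stimulus, pre}, so negative fold changes mean downregulation after
    transplantation. Returns None (with a warning) when either timepoint is
    missing or too small in this cluster.
    """
    meta = nm.cell_meta.loc[assign.index[assign == cluster_id]]
    meta = meta[meta["stimulus"] == stimulus]
    post = set(meta.index[meta["timepoint"] == "post"])
    pre = set(meta.index[meta["timepoint"] == "pre"])
    if len(post) < 3 or len(pre) < 3:
        warnings.warn(
            f"cluster {cluster_id} / stimulus {stimulus}: "
            f"insufficient cells (pre={len(pre)}, post={len(post)}); contrast skipped"
        )
        return None
    return de_test(nm, post, pre, **kwargs)
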