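"""Gene-length-bias-aware GO over-representation analysis.

Long genes accumulate more reads and are more likely to be called
differentially expressed in RNA-seq, so a naive hypergeometric enrichment
test is biased toward categories of long genes. The correction estimates a
probability weighting function (PWF) — a monotone nondecreasing estimate of
P(gene is DE | gene length) — and tests each category against the Wallenius
noncentral hypergeometric distribution whose odds parameter is the ratio of
the mean PWF weight inside the category to the mean weight outside. With
uniform weights this reduces exactly to the central hypergeometric tail.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, nchypergeom_wallenius
from sklearn.isotonic import IsotonicRegression

from .errors import ConfigurationError

_MIN_WEIGHT = 1e-6


def fit_pwf(
    de_flags: pd.Series,
    gene_lengths: pd.Series,
    n_bins: int = 20,
) -> pd.Series:
    """Estimate P(DE | gene length) by binned proportions with isotonic smoothing.

    Genes are sorted by length into ``n_bins`` equal-count bins; the per-bin
    DE proportion at the bin's median length is smoothed by isotonic
    regression (monotone nondecreasing in length) and interpolated back to
    each gene. Genes without a length annotation receive the mean weight.
    Degenerate inputs (all DE or none DE) yield a flat function with a
    warning.
    """
    de_flags = de_flags.astype(bool)
    lengths = gene_lengths.reindex(de_flags.index)
    known = lengths.notna()
    if known.mean() < 0.9:
        raise ConfigurationError(
            f"gene lengths available for only {known.mean():.0%} of tested genes (need >= 90%)"
        )
    n_de = de_flags.sum()
    if n_de == 0 or n_de == len(de_flags):
        warnings.warn("all-DE or none-DE input: probability weighting function is flat")
        return pd.Series(np.full(len(de_flags), max(de_flags.mean(), _MIN_WEIGHT)),
                         index=de_flags.index, name="pwf")
    sub = pd.DataFrame({"length": lengths[known], "de": de_flags[known]})
    sub = sub.sort_values(["length"])
    n_bins = max(1, min(n_bins, len(sub) // 10 or 1))
    bin_ids = np.floor(np.arange(len(sub)) * n_bins / len(sub)).astype(int)
    grouped = sub.groupby(bin_ids)
    bin_len = grouped["length"].median().values
    bin_prop = grouped["de"].mean().values
    bin_n = grouped["de"].size().values
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(bin_len, bin_prop, sample_weight=bin_n)
    weights = pd.Series(np.nan, index=de_flags.index, name="pwf")
    weights[known] = iso.predict(lengths[known].values)
    weights[~known] = weights[known].mean()
    return weights.clip(lower=_MIN_WEIGHT)


def go_test(
    de_flags: pd.Series,
    categories: Dict[str, Iterable[str]],
    weights: Optional[pd.Series] = None,
    direction: str = "up",
    term_names: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Over-representation p-value per category under the Wallenius model.

    ``de_flags`` (gene -> bool) defines both the gene universe (its index)
    and the DE set. For each category of size m containing k DE genes out of
    D total DE genes in a universe of M, the over-represented p-value is
    P(X >= k) where X follows the Wallenius noncentral hypergeometric
    distribution with odds = mean weight inside / mean weight outside the
    category. Uniform weights use the analytic hypergeometric tail. Empty
    categories (no universe genes) are skipped.
    """
    de_flags = de_flags.astype(bool)
    universe = de_flags.index
    M = len(universe)
    D = int(de_flags.sum())
    if weights is None:
        weights = pd.Series(1.0, index=universe)
    weights = weights.reindex(universe).fillna(weights.mean())
    rows = []
    for term, genes in categories.items():
        in_cat = universe.intersection(pd.Index(list(genes)))
        m = len(in_cat)
        if m == 0 or m == M:
            continue
        k = int(de_flags.loc[in_cat].sum())
        if k == 0:
            p = 1.0
        else:
            w_in = weights.loc[in_cat].mean()
            w_out = weights.loc[universe.difference(in_cat)].mean()
            odds = w_in / w_out
            if abs(odds - 1.0) < 1e-12:
                p = float(hypergeom.sf(k - 1, M, m, D))
            else:
                p = float(nchypergeom_wallenius.sf(k - 1, M, m, D, odds))
        rows.append(
            {
                "term_id": term,
                "term_name": (term_names or {}).get(term, term),
                "direction": direction,
                "over_represented_p": min(max(p, 0.0), 1.0),
                "numDEInCat": k,
                "numInCat": m,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "direction",
                 "over_represented_p", "numDEInCat", "numInCat"],
    )
    return out.sort_values(["over_represented_p", "term_id"]).reset_index(drop=True)


def go_analysis(
    de_results: pd.DataFrame,
    categories: Dict[str, Iterable[str]],
    gene_lengths: pd.Series,
    universe: Iterable[str],
    alpha: float = 0.01,
    term_names: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Directional GO enrichment of a DE table against a gene universe.

    Genes with adjusted p below ``alpha`` are flagged DE; up- and
    down-regulated genes (by the sign of avg_log2FC) are tested separately,
    each against a PWF fitted to that direction's DE flags.
    """
    universe = pd.Index(universe)
    frames = []
    for direction, mask in (
        ("up", de_results["avg_log2FC"] > 0),
        ("down", de_results["avg_log2FC"] < 0),
    ):
        hits = set(de_results.loc[(de_results["p_adjusted"] < alpha) & mask, "gene_id"])
        flags = pd.Series([g in hits for g in universe], index=universe)
        if flags.sum() == 0:
            continue
        weights = fit_pwf(flags, gene_lengths)
        frames.append(go_test(flags, categories, weights, direction, term_names))
    if not frames:
        return pd.DataFrame(
            columns=["term_id", "term_name", "direction",
                     "over_represented_p", "numDEInCat", "numInCat"]
        )
    return pd.concat(frames, ignore_index=True)
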