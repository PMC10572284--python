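"""TCR chain filtering, paired-clonotype construction and repertoire diversity.

The chain filter cascade, applied per cell in this order:

1. productivity: keep chains that are productive (in-frame CDR3, length a
   multiple of 3, no stop codon) with at least ``min_reads`` reads
   (inclusive, default 25);
2. primary-chain selection (r = 1): within each (cell, locus), keep the
   highest-read surviving chain (ties broken lexicographically by CDR3
   nucleotide sequence);
3. dominance: the selected chain must carry more than ``top_threshold``
   (default 0.8) of all reads observed for that (cell, locus), counting
   reads of chains removed in step 1 (conservative denominator);
4. locus fraction: among the selected chains of a cell, a locus is kept only
   if its reads exceed ``flocus_threshold`` (default 0.1) of the cell's
   selected-chain reads summed over loci.

Clonotype keys are ``locus:v_call:j_call:junction_nt`` (the D segment is
excluded from the key: TRA has none and D calls are unreliable); a paired
clonotype exists when both a TRA and a TRB chain of the same cell survive.
TRD chains pass the cascade but never enter diversity calculations.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
import re
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .containers import DIVERSITY_LEVELS, CellClonotype, RepertoireDiversity
from .errors import ConfigurationError, EmptyResultError

logger = logging.getLogger(__name__)

_NT_RE = re.compile(r"^[ACGTacgt]+$")


def translate_cdr3(junction_nt: str) -> Optional[str]:
    """Translate an in-frame CDR3 nucleotide sequence; None if not translatable."""
    if not junction_nt or not _NT_RE.match(junction_nt) or len(junction_nt) % 3 != 0:
        return None
    return str(Seq(junction_nt).translate())


def is_productive(junction_nt: str) -> Optional[bool]:
    """In frame (length divisible by 3) and no stop codon in the translation.

    Returns None for sequences that cannot be assessed (empty or non-ACGT).
    """
    if not junction_nt or not _NT_RE.match(junction_nt):
        return None
    if len(junction_nt) % 3 != 0:
        return False
    return "*" not in translate_cdr3(junction_nt)


def productivity_filter(chains: pd.DataFrame, min_reads: int = 25) -> pd.DataFrame:
    """Keep productive chains with reads >= min_reads.

    Productivity uses the record's ``productive`` flag when set; otherwise it
    is computed from the CDR3 nucleotide sequence. Chains whose productivity
    cannot be determined are dropped with a logged reason.
    """
    flags = []
    for _, row in chains.iterrows():
        flag = row.get("productive")
        if flag is None or (isinstance(flag, float) and pd.isna(flag)):
            flag = is_productive(row["junction"])
            if flag is None:
                logger.info(
                    "chain %s/%s dropped: unparseable CDR3 %r and no productive flag",
                    row["cell_id"], row["locus"], row["junction"],
                )
                flag = False
        flags.append(bool(flag))
    keep = np.array(flags) & (chains["consensus_count"].values >= min_reads)
    return chains[keep].copy()


def select_primary_chain(cell_locus_chains: pd.DataFrame) -> pd.Series:
    """Select the highest-read chain of one (cell, locus); ties by CDR3 sequence.

    Returns the selected row with an added ``top`` field = selected reads /
    total reads over all provided chains of this (cell, locus).
    """
    if cell_locus_chains.empty:
        raise ConfigurationError("select_primary_chain called with no chains")
    ordered = cell_locus_chains.sort_values(
        ["consensus_count", "junction"], ascending=[False, True], kind="mergesort"
    )
    selected = ordered.iloc[0].copy()
    selected["top"] = selected["consensus_count"] / cell_locus_chains["consensus_count"].sum()
    return selected


def apply_filter_cascade(
    chains: pd.DataFrame,
    min_reads: int = 25,
    top_threshold: float = 0.8,
    flocus_threshold: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full chain filter cascade.

    Returns ``(selected, trace)``: one selected chain per surviving
    (cell, locus) with ``top`` and ``flocus`` columns, plus a per-(cell,
    locus) trace recording each rule's outcome and the first failure reason.
    """
    trace_rows = []
    selected_rows = []
    for (cell, locus), grp in chains.groupby(["cell_id", "locus"], sort=True):
        total_reads_pre = grp["consensus_count"].sum()  # pre-productivity denominator
        surviving = productivity_filter(grp, min_reads=min_reads)
        rec = {
            "cell_id": cell,
            "locus": locus,
            "n_chains": len(grp),
            "total_reads": total_reads_pre,
            "pass_productive": len(surviving) > 0,
            "top": np.nan,
            "flocus": np.nan,
            "fail_reason": "",
        }
        if surviving.empty:
            rec["fail_reason"] = "no productive chain with sufficient reads"
            trace_rows.append(rec)
            continue
        sel = select_primary_chain(surviving)
        # dominance over all chains of the locus, including unproductive ones
        top = sel["consensus_count"] / total_reads_pre
        rec["top"] = top
        if not top > top_threshold:
            rec["fail_reason"] = f"top {top:.3f} <= {top_threshold}"
            trace_rows.append(rec)
            continue
        sel["top"] = top
        selected_rows.append(sel)
        trace_rows.append(rec)
    trace = pd.DataFrame(trace_rows)
    if not selected_rows:
        return (
            pd.DataFrame(columns=list(chains.columns) + ["top", "flocus"]),
            trace,
        )
    selected = pd.DataFrame(selected_rows).reset_index(drop=True)
    selected = locus_fraction_filter(selected, flocus_threshold, _annotate_only=True)
    if not trace.empty:
        fl = selected.set_index(["cell_id", "locus"])["flocus"]
        trace = trace.set_index(["cell_id", "locus"])
        trace.loc[fl.index, "flocus"] = fl
        trace = trace.reset_index()
    drop = ~(selected["flocus"] > flocus_threshold)
    if drop.any() and not trace.empty:
        failed = selected.loc[drop, ["cell_id", "locus", "flocus"]]
        trace = trace.set_index(["cell_id", "locus"])
        for (cell, locus), flv in failed.set_index(["cell_id", "locus"])["flocus"].items():
            trace.loc[(cell, locus), "fail_reason"] = (
                f"flocus {flv:.3f} <= {flocus_threshold}"
            )
        trace = trace.reset_index()
    selected = selected[~drop].reset_index(drop=True)
    return selected, trace


def locus_fraction_filter(
    cell_chains: pd.DataFrame,
    flocus_threshold: float = 0.1,
    _annotate_only: bool = False,
) -> pd.DataFrame:
    """Keep loci whose read fraction within the cell exceeds the threshold.

    For each cell, flocus(locus) = reads of that locus / total TCR reads of
    the cell over the chains provided (one selected chain per locus after the
    earlier cascade steps); loci with flocus strictly above the threshold are
    retained. With ``_annotate_only`` the flocus column is added but failing
    rows are kept (the cascade drops them after recording the trace).
    """
    out = cell_chains.copy()
    cell_totals = out.groupby("cell_id")["consensus_count"].transform("sum")
    out["flocus"] = out["consensus_count"] / cell_totals
    if _annotate_only:
        return out
    return out[out["flocus"] > flocus_threshold].reset_index(drop=True)


def clonotype_key(locus: str, v_call: str, j_call: str, junction: str) -> str:
    return f"{locus}:{v_call}:{j_call}:{junction}"


def build_clonotypes(selected: pd.DataFrame) -> List[CellClonotype]:
    """One CellClonotype per cell retaining at least one TRA/TRB chain.

    TRD chains never contribute to clonotypes (report them separately).
    """
    out = []
    for cell, grp in selected.groupby("cell_id", sort=True):
        keys = {"TRA": None, "TRB": None}
        for _, row in grp.iterrows():
            if row["locus"] in keys:
                keys[row["locus"]] = clonotype_key(
                    row["locus"], row["v_call"], row["j_call"], row["junction"]
                )
        if keys["TRA"] or keys["TRB"]:
            out.append(CellClonotype(cell_id=cell, tra=keys["TRA"], trb=keys["TRB"]))
    return out


def shannon_diversity(
    cells: Iterable[CellClonotype],
    level: str,
    sample_id: str = "",
) -> RepertoireDiversity:
    """Shannon diversity H = -sum p_i ln p_i and equitability EH = H / ln S.

    p_i = n_i / N over the N cells carrying a clonotype at the requested
    level (``TRA``, ``TRB`` or ``TRA_AND_TRB``). A monoclonal sample (S = 1)
    has EH = 0 by convention; a sample of all-distinct clonotypes has EH = 1.
    """
    if level not in DIVERSITY_LEVELS:
        raise ConfigurationError(f"unknown diversity level: {level!r}")
    keys = [c.key_at(level) for c in cells]
    keys = [k for k in keys if k is not None]
    if not keys:
        raise EmptyResultError(f"no cells with a clonotype at level {level}")
    counts = pd.Series(keys).value_counts()
    N = int(counts.sum())
    p = counts / N
    H = float(-(p * np.log(p)).sum())
    S = len(counts)
    EH = 0.0 if S == 1 else H / math.log(S)
    return RepertoireDiversity(
        sample_id=sample_id, level=level, S=S, N=N, counts=counts, H=H, EH=EH
    )


def diversity_table(
    clonotypes_by_sample: Dict[str, List[CellClonotype]],
    levels: Iterable[str] = DIVERSITY_LEVELS,
) -> pd.DataFrame:
    """Sample x level table of S, N, H and EH (one row per combination)."""
    rows = []
    for sample_id in sorted(clonotypes_by_sample):
        for level in levels:
            try:
                d = shannon_diversity(clonotypes_by_sample[sample_id], level, sample_id)
            except EmptyResultError:
                continue
            rows.append(
                {"sample_id": sample_id, "level": level,
                 "S": d.S, "N": d.N, "H": d.H, "EH": d.EH}
            )
    return pd.DataFrame(rows, columns=["sample_id", "level", "S", "N", "H", "EH"])


def load_segment_order() -> pd.DataFrame:
    """Bundled V/D/J gene-segment table ordered by genomic position."""
    ref = importlib.resources.files("allosc.data").joinpath("tr_segment_order.tsv")
    with ref.open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["rank"] = np.arange(len(df))
    return df


def vdj_table(selected: pd.DataFrame, segment_order: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Per locus, count cells per V(D)J combination and order segments genomically.

    ``selected`` is the post-cascade chain table (one chain per cell/locus).
    Unknown segment names sort after all known ones, with a logged notice.
    Proportions sum to 1 within each locus.
    """
    if segment_order is None:
        segment_order = load_segment_order()
    rank = dict(zip(segment_order["segment"], segment_order["rank"]))
    unknown = set()

    def seg_rank(name: str) -> float:
        if not name:
            return math.inf
        if name not in rank:
            unknown.add(name)
            return math.inf
        return rank[name]

    rows = []
    for locus, grp in selected.groupby("locus", sort=True):
        combos = grp.groupby(["v_call", "d_call", "j_call"]).size()
        total = combos.sum()
        for (v, d, j), n in combos.items():
            rows.append(
                {"locus": locus, "v_call": v, "d_call": d, "j_call": j,
                 "n_cells": int(n), "proportion": n / total,
                 "_vr": seg_rank(v), "_jr": seg_rank(j)}
            )
    if unknown:
        logger.warning("segments absent from the order table placed last: %s",
                       sorted(unknown))
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(
            columns=["locus", "v_call", "d_call", "j_call", "n_cells", "proportion"]
        )
    out = out.sort_values(["locus", "_vr", "_jr", "v_call", "j_call"], kind="mergesort")
    return out.drop(columns=["_vr", "_jr"]).reset_index(drop=True)


def clonotype_overlap(
    clonotypes_by_sample: Dict[str, List[CellClonotype]],
    level: str = "TRA_AND_TRB",
) -> pd.DataFrame:
    """Symmetric matrix of unique clonotype keys shared between sample pairs."""
    keysets = {
        s: {c.key_at(level) for c in cl if c.key_at(level) is not None}
        for s, cl in clonotypes_by_sample.items()
    }
    samples = sorted(keysets)
    mat = pd.DataFrame(0, index=samples, columns=samples, dtype=int)
    for i, a in enumerate(samples):
        for b in samples[i + 1:]:
            shared = len(keysets[a] & keysets[b])
            mat.loc[a, b] = shared
            mat.loc[b, a] = shared
    return mat
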