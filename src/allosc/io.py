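"""Readers and writers for the standard on-disk formats.

Expression matrices travel as Matrix Market (.mtx) plus genes/barcodes/metadata
TSVs; TCR chains as an AIRR-style rearrangement TSV; gene sets as GMT or
two-column TSV. All round trips are lossless for integer counts.
"""

from __future__ import annotations

import os
from typing import Dict, List

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import AIRR_COLUMNS, CELL_META_COLUMNS, CountMatrix
from .errors import ParseError

MATRIX_FILE = "matrix.mtx"
GENES_FILE = "genes.tsv"
BARCODES_FILE = "barcodes.tsv"
METADATA_FILE = "metadata.tsv"


def write_counts(m: CountMatrix, out_dir: str) -> None:
    """Write a CountMatrix as matrix.mtx + genes/barcodes/metadata TSVs."""
    os.makedirs(out_dir, exist_ok=True)
    coo = m.values.tocoo()
    coo.data = coo.data.astype(np.int64)
    scipy.io.mmwrite(os.path.join(out_dir, MATRIX_FILE), coo, field="integer")
    m.genes.to_csv(os.path.join(out_dir, GENES_FILE), sep="\t", index_label="gene_id")
    with open(os.path.join(out_dir, BARCODES_FILE), "w") as fh:
        fh.write("\n".join(m.barcodes) + "\n")
    m.cell_meta.to_csv(os.path.join(out_dir, METADATA_FILE), sep="\t", index_label="barcode")


def read_counts(in_dir: str) -> CountMatrix:
    """Read a CountMatrix written by :func:`write_counts`."""
    mtx_path = os.path.join(in_dir, MATRIX_FILE)
    try:
        values = scipy.io.mmread(mtx_path)
    except Exception as exc:  # mmread raises ValueError on malformed files
        raise ParseError(f"{mtx_path}: {exc}") from exc
    values = sp.csr_matrix(values)
    genes = pd.read_csv(os.path.join(in_dir, GENES_FILE), sep="\t", index_col="gene_id")
    with open(os.path.join(in_dir, BARCODES_FILE)) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    meta = pd.read_csv(os.path.join(in_dir, METADATA_FILE), sep="\t", index_col="barcode")
    missing = [c for c in CELL_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ParseError(f"{METADATA_FILE}: missing metadata columns {missing}")
    if values.shape[0] != len(genes):
        raise ParseError(
            f"{mtx_path}: {values.shape[0]} rows but {len(genes)} genes in {GENES_FILE}"
        )
    if values.shape[1] != len(barcodes):
        raise ParseError(
            f"{mtx_path}: {values.shape[1]} columns but {len(barcodes)} barcodes"
        )
    if list(meta.index) != barcodes:
        raise ParseError(f"{METADATA_FILE}: barcode order differs from {BARCODES_FILE}")
    values.data = values.data.astype(np.int64)
    return CountMatrix(values=values, genes=genes, cell_meta=meta)


def write_chains(chains: pd.DataFrame, path: str) -> None:
    """Write an AIRR-style rearrangement table as TSV."""
    missing = [c for c in AIRR_COLUMNS if c not in chains.columns]
    if missing:
        raise ParseError(f"chain table missing columns {missing}")
    chains.to_csv(path, sep="\t", index=False)


def read_chains(path: str) -> pd.DataFrame:
    """Read an AIRR-style rearrangement TSV; tolerant of extra columns."""
    try:
        chains = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in AIRR_COLUMNS if c not in chains.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    chains["consensus_count"] = pd.to_numeric(chains["consensus_count"], errors="raise")
    if chains["consensus_count"].min() < 0:
        raise ParseError(f"{path}: negative consensus_count")
    # normalize the productive flag to a nullable boolean
    chains["productive"] = chains["productive"].map(
        lambda v: None
        if pd.isna(v) or v == ""
        else str(v).strip().upper() in ("T", "TRUE", "1", "YES")
    )
    chains["junction"] = chains["junction"].fillna("")
    chains["junction_aa"] = chains["junction_aa"].fillna("")
    chains["d_call"] = chains["d_call"].fillna("")
    return chains


def read_gene_sets(path: str) -> Dict[str, List[str]]:
    """Read gene sets from GMT (term<TAB>desc<TAB>genes...) or 2-column TSV."""
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        fields = first.rstrip("\n").split("\t")
        if path.endswith(".gmt") or len(fields) > 3:
            for ln, line in enumerate(fh, 1):
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    raise ParseError(f"{path}:{ln}: GMT line with fewer than 3 fields")
                sets[parts[0]] = [g for g in parts[2:] if g]
        else:
            df = pd.read_csv(fh, sep="\t", header=None, names=["term", "gene"][: len(fields)] or None)
            if df.shape[1] < 2:
                raise ParseError(f"{path}: expected two columns (term, gene)")
            for term, grp in df.groupby(df.columns[0]):
                sets[str(term)] = list(grp[df.columns[1]].astype(str))
    return sets


def write_gene_sets(sets: Dict[str, List[str]], path: str) -> None:
    with open(path, "w") as fh:
        for term, genes in sets.items():
            fh.write(f"{term}\t{term}\t" + "\t".join(genes) + "\n")


def read_gene_lengths(path: str) -> pd.Series:
    """Read a two-column (gene_id, length_bp) TSV into a Series."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected columns gene_id, length")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="length")
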