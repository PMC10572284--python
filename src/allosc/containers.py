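"""In-memory containers for the expression and repertoire data model.

The expression side follows the genes x cells orientation of the raw count
tables this pipeline consumes; cell metadata records the study design
(patient, pre/post transplant timepoint, donor vs third-party stimulus, chip).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError

#: metadata columns expected on every cell
CELL_META_COLUMNS = ("sample_id", "patient", "timepoint", "stimulus", "chip")

TIMEPOINTS = ("pre", "post")
STIMULI = ("don", "thirdP")
LOCI = ("TRA", "TRB", "TRD")

#: required columns of an AIRR-style rearrangement table
AIRR_COLUMNS = (
    "cell_id",
    "locus",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_aa",
    "consensus_count",
    "productive",
)


@dataclass
class CountMatrix:
    """Raw integer gene x cell count matrix with gene and cell annotation.

    Attributes
    ----------
    values
        Sparse CSR matrix of shape (n_genes, n_cells), nonnegative integers.
    genes
        DataFrame indexed by gene_id with at least a ``symbol`` column;
        ``biotype`` and ``length`` are optional annotation columns.
    cell_meta
        DataFrame indexed by cell barcode with the study-design columns
        (sample_id, patient, timepoint, stimulus, chip).
    """

    values: sp.csr_matrix
    genes: pd.DataFrame
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.genes), len(self.cell_meta)):
            raise ConfigurationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cell_meta)} cells"
            )
        if self.genes.index.has_duplicates:
            raise ConfigurationError("duplicate gene_ids in gene table")
        if self.cell_meta.index.has_duplicates:
            raise ConfigurationError("duplicate cell barcodes in metadata")
        if self.values.nnz and self.values.data.min() < 0:
            raise ConfigurationError("negative entries in count matrix")
        if self.values.nnz and not np.allclose(self.values.data, np.round(self.values.data)):
            raise ConfigurationError("non-integral entries in count matrix")

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    @property
    def barcodes(self) -> pd.Index:
        return self.cell_meta.index

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, barcodes) -> "CountMatrix":
        """Return a new CountMatrix restricted to ``barcodes`` (order preserved)."""
        idx = self.cell_meta.index.get_indexer(pd.Index(barcodes))
        if (idx < 0).any():
            missing = pd.Index(barcodes)[idx < 0]
            raise KeyError(f"unknown barcodes: {list(missing[:5])}")
        return CountMatrix(
            values=self.values[:, idx].tocsr(),
            genes=self.genes,
            cell_meta=self.cell_meta.iloc[idx],
        )


@dataclass
class NormalizedMatrix:
    """Log-normalized expression: ln(1 + count / cell_total * scale_factor).

    ``source`` keeps a link to the CountMatrix the normalization was computed
    from, so count-based statistics (e.g. the variance-stabilized HVG ranking)
    stay available downstream.
    """

    values: np.ndarray  # genes x cells, float
    genes: pd.DataFrame
    cell_meta: pd.DataFrame
    scale_factor: float = 10_000.0
    source: Optional[CountMatrix] = None
    centered: bool = False  # True after per-chip centering; values may be negative

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cell_meta)):
            raise ConfigurationError("normalized matrix shape mismatch")
        if not self.centered and self.values.size and self.values.min() < 0:
            raise ConfigurationError("negative values in log-normalized matrix")

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    @property
    def barcodes(self) -> pd.Index:
        return self.cell_meta.index

    def gene_row(self, gene_id: str) -> np.ndarray:
        return self.values[self.genes.index.get_loc(gene_id)]


@dataclass
class PCAEmbedding:
    """Cell embedding from PCA on scaled highly-variable genes."""

    coordinates: pd.DataFrame  # cells x n_dims
    explained_variance_ratio: np.ndarray
    hvg_gene_ids: list = field(default_factory=list)

    @property
    def barcodes(self) -> pd.Index:
        return self.coordinates.index

    @property
    def n_dims(self) -> int:
        return self.coordinates.shape[1]


@dataclass(frozen=True)
class CellClonotype:
    """A cell's retained TRA/TRB clonotype keys after the chain filter cascade.

    A clonotype key is ``locus:v_call:j_call:junction_nt``; the paired key
    exists only when both chains survived filtering in the same cell.
    """

    cell_id: str
    tra: Optional[str] = None
    trb: Optional[str] = None

    @property
    def paired_key(self) -> Optional[str]:
        if self.tra is not None and self.trb is not None:
            return f"{self.tra}|{self.trb}"
        return None

    def key_at(self, level: str) -> Optional[str]:
        if level == "TRA":
            return self.tra
        if level == "TRB":
            return self.trb
        if level == "TRA_AND_TRB":
            return self.paired_key
        raise ValueError(f"unknown clonotype level: {level!r}")


DIVERSITY_LEVELS = ("TRA", "TRB", "TRA_AND_TRB")


@dataclass
class RepertoireDiversity:
    """Shannon diversity of one sample at one clonotype level.

    S unique clonotypes over N cells with counts n_i, proportions
    p_i = n_i / N; H = -sum p_i ln p_i and equitability EH = H / ln S
    (defined as 0 for a monoclonal sample, S = 1).
    """

    sample_id: str
    level: str
    S: int
    N: int
    counts: pd.Series  # clonotype key -> n_i
    H: float
    EH: float
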