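"""Synthetic joint scRNA-seq + scTCR study generator with known ground truth.

Emulates the statistical structure of a sorted alloreactive T-cell study:
a few hundred cells per sample (the scale of a microwell chip deposit of
sorted CD137+ cells), negative-binomial counts with cluster-specific marker
genes, mitochondrial-fraction contamination with a dead-cell upper tail,
doublets formed by summing two cell profiles, and per-sample TRA/TRB chain
tables drawn from a power-law clonotype frequency distribution — highly
polyclonal at the defaults, with tunable clonal expansion.

Every injection (cluster labels, marker genes, doublets, dead cells, planted
pre/post shifts, true clonotype assignments) is recorded in a
:class:`GroundTruth` object so downstream stages can be validated against
known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix
from .errors import ConfigurationError
from .tcr import load_segment_order

MITO_SYMBOLS = [
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
]
IDENTITY_SYMBOLS = ["CD3D", "TNFRSF9", "CD4", "CD8A", "CD8B", "CD14", "CD19", "NCAM1"]

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SAFE_CODONS = [c for c in _CODONS if c not in _STOP_CODONS]


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Counts are negative binomial with per-gene means around ``baseline_mean``
    and dispersion ``nb_dispersion`` (variance mu + dispersion * mu^2).
    Clonotype frequencies follow a power law p_k proportional to
    k^-clonality_alpha over a pool of ``unique_clonotype_fraction * n_cells``
    clonotypes per sample; a fraction of exactly 1 assigns every cell its own
    clonotype.
    """

    # expression
    n_cells_per_sample: int = 200
    n_genes: int = 2000
    n_clusters: int = 4
    marker_genes_per_cluster: int = 20
    marker_log2fc: float = 2.0
    nb_dispersion: float = 0.5
    baseline_mean: float = 0.5
    mito_gene_count: int = 13
    mito_fraction_beta_params: Tuple[float, float] = (2.0, 80.0)
    doublet_rate: float = 0.03
    dead_cell_rate: float = 0.05
    # repertoire
    clonality_alpha: float = 0.5
    unique_clonotype_fraction: float = 0.9
    unproductive_chain_prob: float = 0.05
    secondary_chain_prob: float = 0.10
    reads_per_chain_mean: float = 150.0
    trd_chain_prob: float = 0.0
    rng_seed: int = 0
    # study design
    n_patients: int = 5
    include_thirdparty: bool = True
    contaminant_cluster: bool = True
    prepost_gene_count: int = 5
    prepost_log2fc: float = -0.6
    prepost_cluster: int = 0
    donor_only_shift: bool = True
    shared_clonotypes: int = 0
    chip_shift: float = 0.0

    def validate(self) -> None:
        for name in (
            "doublet_rate", "dead_cell_rate", "unique_clonotype_fraction",
            "unproductive_chain_prob", "secondary_chain_prob", "trd_chain_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_cells_per_sample", "n_genes", "n_clusters",
            "marker_genes_per_cluster", "mito_gene_count", "n_patients",
        ):
            if getattr(self, name) < (0 if name == "mito_gene_count" else 1):
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("nb_dispersion", "baseline_mean", "reads_per_chain_mean"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.clonality_alpha < 0:
            raise ConfigurationError(f"clonality_alpha must be >= 0, got {self.clonality_alpha}")
        a, b = self.mito_fraction_beta_params
        if a <= 0 or b <= 0:
            raise ConfigurationError(
                f"mito_fraction_beta_params must be positive, got {(a, b)}"
            )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class GroundTruth:
    """Everything the generator injected, for downstream validation."""

    cell_clusters: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))
    marker_genes: Dict[int, Dict[str, float]] = field(default_factory=dict)
    cluster_annotations: Dict[int, str] = field(default_factory=dict)
    contaminant_cluster: Optional[int] = None
    doublets: List[str] = field(default_factory=list)
    doublet_parents: Dict[str, Tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    dead_cells: List[str] = field(default_factory=list)
    prepost_genes: List[str] = field(default_factory=list)
    prepost_cluster: Optional[int] = None
    clonotype_freqs: Dict[str, np.ndarray] = field(default_factory=dict)
    cell_clonotypes: Dict[str, Tuple[str, str]] = field(default_factory=dict)
    shared_clonotype_keys: Dict[Tuple[str, str], List[str]] = field(default_factory=dict)


def _sample_design(cfg: SynthConfig) -> pd.DataFrame:
    rows = []
    chip = 0
    for p in range(cfg.n_patients):
        patient = f"P{p}"
        stimuli = ["don"] + (["thirdP"] if cfg.include_thirdparty else [])
        for stimulus in stimuli:
            for timepoint in ("pre", "post"):
                rows.append(
                    {
                        "sample_id": f"{patient}_{timepoint}_{stimulus}",
                        "patient": patient,
                        "timepoint": timepoint,
                        "stimulus": stimulus,
                        "chip": f"chip{chip}",
                    }
                )
                chip += 1
    return pd.DataFrame(rows)


def _gene_table(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    mito = list(MITO_SYMBOLS[: cfg.mito_gene_count])
    mito += [f"MT-SYN{i}" for i in range(len(mito), cfg.mito_gene_count)]
    n_plain = cfg.n_genes - len(mito) - len(IDENTITY_SYMBOLS)
    if n_plain < cfg.n_clusters * cfg.marker_genes_per_cluster + cfg.prepost_gene_count:
        raise ConfigurationError("n_genes too small for the requested marker structure")
    symbols = IDENTITY_SYMBOLS + mito + [f"GENE{i:04d}" for i in range(n_plain)]
    gene_ids = [f"SYNTG{i:06d}" for i in range(cfg.n_genes)]
    biotype = np.array(["protein_coding"] * cfg.n_genes, dtype=object)
    plain_start = len(IDENTITY_SYMBOLS) + len(mito)
    n_nc = int(0.1 * n_plain)
    nc_idx = rng.choice(np.arange(plain_start, cfg.n_genes), size=n_nc, replace=False)
    biotype[nc_idx] = "lncRNA"
    lengths = np.round(rng.lognormal(7.5, 0.8, size=cfg.n_genes)).astype(int) + 100
    return pd.DataFrame(
        {"symbol": symbols, "biotype": biotype, "length": lengths},
        index=pd.Index(gene_ids, name="gene_id"),
    )


def _cluster_proportions(cfg: SynthConfig) -> np.ndarray:
    K = cfg.n_clusters
    if cfg.contaminant_cluster and K >= 2:
        main = np.linspace(1.0, 0.55, K - 1)
        main = main / main.sum() * 0.95
        return np.concatenate([main, [0.05]])
    w = np.linspace(1.0, 0.55, K)
    return w / w.sum()


def simulate_counts(cfg: SynthConfig) -> Tuple[CountMatrix, GroundTruth]:
    """Generate the full study's gene x cell count matrix and its ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    genes = _gene_table(cfg, rng)
    design = _sample_design(cfg)
    truth = GroundTruth()
    K = cfg.n_clusters
    proportions = _cluster_proportions(cfg)
    contaminant = K - 1 if (cfg.contaminant_cluster and K >= 2) else None
    truth.contaminant_cluster = contaminant
    truth.prepost_cluster = cfg.prepost_cluster if cfg.prepost_gene_count else None

    # per-gene baseline means (lognormal around baseline_mean)
    base = rng.lognormal(np.log(cfg.baseline_mean) - 0.5, 1.0, size=cfg.n_genes)
    sym = genes["symbol"]
    idx_of = {s: i for i, s in enumerate(sym)}
    mito_rows = np.array(
        [i for i, s in enumerate(sym) if s.startswith("MT-")], dtype=int
    )
    base[mito_rows] = 0.0  # mito means are set per cell from the target fraction
    mito_weights = rng.dirichlet(np.full(len(mito_rows), 2.0)) if len(mito_rows) else None

    # cluster -> per-gene log2 fold change
    lfc = np.zeros((cfg.n_genes, K))
    plain_pc = [
        i for i in range(len(IDENTITY_SYMBOLS) + len(mito_rows), cfg.n_genes)
        if genes["biotype"].iloc[i] == "protein_coding"
    ]
    # markers and planted shifts go on reasonably expressed genes, as real
    # cluster markers are; near-zero genes would carry no detectable signal
    med = np.median(base[plain_pc])
    well_expressed = [g for g in plain_pc if base[g] > med]
    rng.shuffle(well_expressed)
    plain_pc = well_expressed
    needed = cfg.marker_genes_per_cluster * (K + 2) + cfg.prepost_gene_count
    if len(plain_pc) < needed:
        raise ConfigurationError(
            f"n_genes too small: need {needed} well-expressed protein-coding genes, "
            f"have {len(plain_pc)}"
        )
    cursor = 0
    for k in range(K):
        # the contaminant is a different cell type altogether; give it a
        # broader and stronger program than the T-cell subclusters
        n_mark = cfg.marker_genes_per_cluster * (3 if k == contaminant else 1)
        fc = cfg.marker_log2fc * (1.5 if k == contaminant else 1.0)
        chosen = plain_pc[cursor: cursor + n_mark]
        cursor += n_mark
        lfc[chosen, k] = fc
        truth.marker_genes[k] = {genes.index[g]: fc for g in chosen}
    # identity markers: T-cell program everywhere except the contaminant cluster
    for s in ("CD3D", "TNFRSF9"):
        base[idx_of[s]] = 2.0
    base[idx_of["CD4"]] = 0.4
    base[idx_of["CD8A"]] = base[idx_of["CD8B"]] = 0.3
    for s in ("CD14", "CD19", "NCAM1"):
        base[idx_of[s]] = 0.05
    for k in range(K):
        if k == contaminant:
            lfc[idx_of["CD14"], k] = 6.0
            lfc[idx_of["CD19"], k] = lfc[idx_of["NCAM1"], k] = 3.0
            lfc[idx_of["CD3D"], k] = lfc[idx_of["TNFRSF9"], k] = -4.0
            truth.cluster_annotations[k] = "contaminant"
        elif k == 2 and K >= 3:
            lfc[idx_of["CD8A"], k] = lfc[idx_of["CD8B"], k] = 4.0
            truth.cluster_annotations[k] = "CD8"
        else:
            lfc[idx_of["CD4"], k] = 3.0
            truth.cluster_annotations[k] = "CD4"

    # planted pre/post shift: well-expressed non-marker genes of one cluster
    if cfg.prepost_gene_count:
        # the shift goes on abundant transcripts, as real pre/post hits are
        pp = sorted(plain_pc[cursor:], key=lambda g: -base[g])[: cfg.prepost_gene_count]
        truth.prepost_genes = [genes.index[g] for g in pp]
    else:
        pp = []

    r = 1.0 / cfg.nb_dispersion

    def nb_draw(mu: np.ndarray) -> np.ndarray:
        out = np.zeros_like(mu, dtype=np.int64)
        pos = mu > 0
        out[pos] = rng.negative_binomial(r, r / (r + mu[pos]))
        return out

    def cell_mean(k: int, f_mito: float, shifted: bool, chip_factor: np.ndarray) -> np.ndarray:
        mu = base * (2.0 ** lfc[:, k]) * chip_factor
        if shifted:
            mu[pp] *= 2.0 ** cfg.prepost_log2fc
        nonmito_total = mu.sum()
        if len(mito_rows) and f_mito > 0:
            mu[mito_rows] = f_mito / (1.0 - f_mito) * nonmito_total * mito_weights
        return mu

    a, b = cfg.mito_fraction_beta_params
    columns: List[np.ndarray] = []
    barcodes: List[str] = []
    meta_rows: List[dict] = []
    cluster_map: Dict[str, int] = {}

    for _, srow in design.iterrows():
        n = cfg.n_cells_per_sample
        chip_factor = (
            np.exp(rng.normal(0.0, cfg.chip_shift, size=cfg.n_genes))
            if cfg.chip_shift > 0
            else np.ones(cfg.n_genes)
        )
        clusters = rng.choice(K, size=n, p=proportions)
        n_doub = int(round(cfg.doublet_rate * n))
        n_dead = int(round(cfg.dead_cell_rate * n))
        special = rng.choice(n, size=n_doub + n_dead, replace=False)
        doublet_idx = set(special[:n_doub])
        dead_idx = set(special[n_doub:])
        shifted_sample = bool(pp) and srow["timepoint"] == "post" and (
            not cfg.donor_only_shift or srow["stimulus"] == "don"
        )
        for i in range(n):
            bc = f"{srow['sample_id']}-CELL{i:04d}"
            k = int(clusters[i])
            shifted = shifted_sample and k == cfg.prepost_cluster
            if i in doublet_idx:
                parents = []
                for k_par in rng.choice(K, size=2, p=proportions):
                    f = rng.beta(a, b)
                    parents.append(
                        nb_draw(cell_mean(int(k_par), f, shifted_sample and int(k_par) == cfg.prepost_cluster, chip_factor))
                    )
                col = parents[0] + parents[1]
                truth.doublets.append(bc)
                truth.doublet_parents[bc] = (parents[0], parents[1])
            else:
                if i in dead_idx:
                    f = rng.uniform(0.08, 0.35)
                    truth.dead_cells.append(bc)
                else:
                    f = rng.beta(a, b)
                col = nb_draw(cell_mean(k, f, shifted, chip_factor))
            columns.append(col)
            barcodes.append(bc)
            cluster_map[bc] = k
            meta_rows.append(dict(srow))

    values = sp.csr_matrix(np.column_stack(columns))
    cell_meta = pd.DataFrame(meta_rows, index=pd.Index(barcodes, name="barcode"))
    truth.cell_clusters = pd.Series(cluster_map).loc[barcodes]
    return CountMatrix(values=values, genes=genes, cell_meta=cell_meta), truth


# ---------------------------------------------------------------------------
# repertoire


def _power_law_freqs(K: int, alpha: float) -> np.ndarray:
    p = np.arange(1, K + 1, dtype=float) ** (-alpha)
    return p / p.sum()


class _ChainFactory:
    """Generates unique TRA/TRB/TRD chain identities (V/J calls + CDR3)."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        seg = load_segment_order()
        self.v = {
            loc: [s for s in seg[seg["locus"] == loc]["segment"] if "V" in s]
            for loc in ("TRA", "TRB", "TRD")
        }
        self.j = {
            loc: [s for s in seg[seg["locus"] == loc]["segment"] if s.split("-")[0].rstrip("0123456789").endswith("J")]
            for loc in ("TRA", "TRB", "TRD")
        }
        self.d = {"TRB": ["TRBD1", "TRBD2"], "TRD": ["TRDD1", "TRDD2", "TRDD3"], "TRA": [""]}
        self.seen: set = set()

    def cdr3(self) -> str:
        while True:
            n_aa = int(self.rng.integers(8, 17))
            codons = ["TGT"] + [
                _SAFE_CODONS[i] for i in self.rng.integers(0, len(_SAFE_CODONS), n_aa - 1)
            ]
            s = "".join(codons)
            if s not in self.seen:
                self.seen.add(s)
                return s

    def chain(self, locus: str) -> dict:
        return {
            "locus": locus,
            "v_call": str(self.rng.choice(self.v[locus])),
            "d_call": str(self.rng.choice(self.d[locus])) if locus != "TRA" else "",
            "j_call": str(self.rng.choice(self.j[locus])),
            "junction": self.cdr3(),
        }


def _finish_chain(chain: dict, cell_id: str, reads: int, productive: bool,
                  rng: np.random.Generator) -> dict:
    from .tcr import translate_cdr3

    junction = chain["junction"]
    if not productive:
        if rng.random() < 0.5:
            junction = junction[:-1]  # frameshift: length no longer divisible by 3
            aa = ""
        else:
            k = 3 * int(rng.integers(1, len(junction) // 3))
            junction = junction[:k] + "TGA" + junction[k + 3:]
            aa = translate_cdr3(junction) or ""
    else:
        aa = translate_cdr3(junction) or ""
    return {
        "cell_id": cell_id,
        "locus": chain["locus"],
        "v_call": chain["v_call"],
        "d_call": chain["d_call"],
        "j_call": chain["j_call"],
        "junction": junction,
        "junction_aa": aa,
        "consensus_count": int(reads),
        "productive": bool(productive),
    }


def simulate_repertoire(
    cfg: SynthConfig,
    cells: Sequence[str],
    sample_of: Optional[Dict[str, str]] = None,
    cell_meta: Optional[pd.DataFrame] = None,
    truth: Optional[GroundTruth] = None,
) -> Tuple[pd.DataFrame, GroundTruth]:
    """Generate an AIRR-style chain table for the given cells.

    Each cell receives one true TRA and one true TRB chain whose clonotype
    pair is drawn from a per-sample power-law frequency vector. Optional
    noise: secondary same-locus chains at low read counts, unproductive
    corruption of a chain, and occasional TRD chains. Reads are negative
    binomial around ``reads_per_chain_mean`` truncated at 1.
    """
    if not len(cells):
        raise ConfigurationError("cells must be nonempty")
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed + 1)
    factory = _ChainFactory(rng)
    truth = truth if truth is not None else GroundTruth()
    if sample_of is None:
        if cell_meta is not None:
            sample_of = dict(cell_meta["sample_id"])
        else:
            sample_of = {c: "S0" for c in cells}
    cells_by_sample: Dict[str, List[str]] = {}
    for c in cells:
        cells_by_sample.setdefault(sample_of[c], []).append(c)

    # clonotype pools; pools may be partially shared across timepoints of the
    # same patient + stimulus to create known repertoire overlap
    pools: Dict[str, List[Tuple[dict, dict]]] = {}
    shared_pool: Dict[Tuple[str, str], List[Tuple[dict, dict]]] = {}
    for sample_id in sorted(cells_by_sample):
        n = len(cells_by_sample[sample_id])
        K = max(1, int(round(cfg.unique_clonotype_fraction * n)))
        pool = []
        parts = sample_id.split("_")
        group = (parts[0], parts[2]) if len(parts) == 3 else (sample_id, "")
        if cfg.shared_clonotypes and group not in shared_pool:
            shared_pool[group] = [
                (factory.chain("TRA"), factory.chain("TRB"))
                for _ in range(cfg.shared_clonotypes)
            ]
        n_shared = min(cfg.shared_clonotypes, K) if cfg.shared_clonotypes else 0
        pool.extend(shared_pool[group][:n_shared] if n_shared else [])
        pool.extend(
            (factory.chain("TRA"), factory.chain("TRB")) for _ in range(K - n_shared)
        )
        pools[sample_id] = pool
        truth.clonotype_freqs[sample_id] = _power_law_freqs(K, cfg.clonality_alpha)
        if n_shared:
            from .tcr import clonotype_key

            truth.shared_clonotype_keys[group] = [
                clonotype_key(t["locus"], t["v_call"], t["j_call"], t["junction"])
                + "|"
                + clonotype_key(b["locus"], b["v_call"], b["j_call"], b["junction"])
                for t, b in shared_pool[group][:n_shared]
            ]

    reads_shape = cfg.reads_per_chain_mean  # Fano factor 2: var = 2 * mean

    def draw_reads() -> int:
        mu = cfg.reads_per_chain_mean
        return max(1, int(rng.negative_binomial(reads_shape, reads_shape / (reads_shape + mu))))

    from .tcr import clonotype_key

    records: List[dict] = []
    for sample_id in sorted(cells_by_sample):
        pool = pools[sample_id]
        freqs = truth.clonotype_freqs[sample_id]
        members = cells_by_sample[sample_id]
        if cfg.unique_clonotype_fraction >= 1.0:
            assignment = np.arange(len(members)) % len(pool)
        else:
            assignment = rng.choice(len(pool), size=len(members), p=freqs)
        for cell, cl in zip(members, assignment):
            tra, trb = pool[int(cl)]
            truth.cell_clonotypes[cell] = (
                clonotype_key("TRA", tra["v_call"], tra["j_call"], tra["junction"]),
                clonotype_key("TRB", trb["v_call"], trb["j_call"], trb["junction"]),
            )
            for chain in (tra, trb):
                primary_reads = draw_reads()
                productive = rng.random() >= cfg.unproductive_chain_prob
                records.append(_finish_chain(chain, cell, primary_reads, productive, rng))
                if rng.random() < cfg.secondary_chain_prob:
                    extra = factory.chain(chain["locus"])
                    hi = max(2, int(0.3 * primary_reads))
                    records.append(
                        _finish_chain(extra, cell, int(rng.integers(1, hi + 1)), True, rng)
                    )
            if rng.random() < cfg.trd_chain_prob:
                trd = factory.chain("TRD")
                records.append(_finish_chain(trd, cell, draw_reads(), True, rng))
    chains = pd.DataFrame.from_records(records)
    return chains, truth


@dataclass
class SyntheticStudy:
    counts: CountMatrix
    chains: pd.DataFrame
    truth: GroundTruth
    gene_lengths: pd.Series
    go_categories: Dict[str, List[str]]


def simulate_go_categories(
    cfg: SynthConfig,
    genes: pd.DataFrame,
    truth: GroundTruth,
    n_terms: int = 40,
) -> Dict[str, List[str]]:
    """Random gene-set annotation plus terms seeded with the planted genes."""
    rng = np.random.default_rng(cfg.rng_seed + 2)
    gene_ids = list(genes.index)
    cats: Dict[str, List[str]] = {}
    for t in range(n_terms):
        size = int(rng.integers(10, 150))
        cats[f"SYN:{t:07d}"] = list(rng.choice(gene_ids, size=size, replace=False))
    if truth.prepost_genes:
        filler = list(rng.choice(gene_ids, size=30, replace=False))
        cats["SYN:PREPOST"] = sorted(set(truth.prepost_genes) | set(filler))
    for k, markers in truth.marker_genes.items():
        filler = list(rng.choice(gene_ids, size=40, replace=False))
        cats[f"SYN:CLUSTER{k}"] = sorted(set(markers) | set(filler))
    return cats


def simulate_study(cfg: SynthConfig) -> SyntheticStudy:
    """Generate counts, chains, annotation and ground truth in one call."""
    counts, truth = simulate_counts(cfg)
    chains, truth = simulate_repertoire(
        cfg, list(counts.barcodes), cell_meta=counts.cell_meta, truth=truth
    )
    categories = simulate_go_categories(cfg, counts.genes, truth)
    lengths = pd.Series(counts.genes["length"].values, index=counts.genes.index, name="length")
    return SyntheticStudy(
        counts=counts, chains=chains, truth=truth,
        gene_lengths=lengths, go_categories=categories,
    )
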