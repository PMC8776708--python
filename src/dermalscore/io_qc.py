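"""Count-matrix containers, 10x-convention IO, cell filtering and normalization.

The raw unit throughout is the UMI count. Filtering follows the standard
droplet-QC rule for human skin data: drop cells with fewer than ``min_genes``
or more than ``max_genes`` expressed genes, or with a mitochondrial UMI
fraction above ``max_mito`` (mitochondrial genes are recognized by the
HGNC ``MT-`` symbol prefix). All inequalities are strict, so boundary cells
(exactly 200 genes, exactly 5% mitochondrial) are retained.

Normalization is counts-per-scale with a log1p transform:
``value = ln(1 + count / cell_total * scale)``, scale defaulting to 1e6
(the "TPM" layer for UMI data, where no gene-length term applies).
"""

from __future__ import annotations

import gzip
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "QCConfig",
    "QCReport",
    "read_10x",
    "write_10x",
    "qc_filter",
    "normalize",
]


@dataclass
class CountMatrix:
    """Cells x genes non-negative integer UMI counts.

    ``counts`` is CSR with cells on rows. ``gene_ids`` are accession-style
    identifiers, ``gene_symbols`` the HGNC-style symbols used by all
    downstream gene-list operations.
    """

    cell_ids: np.ndarray  # (n_cells,) str
    gene_ids: np.ndarray  # (n_genes,) str
    gene_symbols: np.ndarray  # (n_genes,) str
    counts: sp.csr_matrix  # cells x genes

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        n_cells, n_genes = self.counts.shape
        if n_cells != len(self.cell_ids):
            raise ValueError(
                f"count matrix has {n_cells} rows but {len(self.cell_ids)} cell ids"
            )
        if n_genes != len(self.gene_ids) or n_genes != len(self.gene_symbols):
            raise ValueError(
                f"count matrix has {n_genes} columns but "
                f"{len(self.gene_ids)} gene ids / {len(self.gene_symbols)} symbols"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        """Number of genes with count > 0, per cell."""
        return np.diff(self.counts.indptr)

    def mito_fraction(self, prefix: str = "MT-") -> np.ndarray:
        """Mitochondrial UMI fraction per cell; 0 for all-zero cells."""
        is_mt = np.array([s.startswith(prefix) for s in self.gene_symbols])
        tot = self.cell_totals()
        if not is_mt.any():
            return np.zeros(self.n_cells)
        mito = np.asarray(self.counts[:, is_mt].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, mito / np.maximum(tot, 1), 0.0)
        return frac

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(
            cell_ids=self.cell_ids[mask],
            gene_ids=self.gene_ids,
            gene_symbols=self.gene_symbols,
            counts=self.counts[mask],
        )

    def to_anndata(self):
        """Convert to an AnnData object (requires the optional anndata package)."""
        import anndata as ad

        return ad.AnnData(
            X=self.counts.copy(),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(
                {"gene_symbol": self.gene_symbols},
                index=pd.Index(self.gene_ids, name="gene_id"),
            ),
        )


@dataclass
class NormalizedMatrix:
    """Per-cell scaled log expression sharing axes with its CountMatrix.

    values(c, g) = ln(1 + count(c, g) / total(c) * scale); zero iff the
    underlying count is zero.
    """

    cell_ids: np.ndarray
    gene_ids: np.ndarray
    gene_symbols: np.ndarray
    values: sp.csr_matrix
    scale: float = 1e6
    log_base: str = "natural"
    pseudocount: float = 1.0

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class QCConfig:
    """Cell-filtering thresholds (strict inequalities on both gene bounds)."""

    min_genes: int = 200
    max_genes: int = 7500
    max_mito: float = 0.05
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes must be <= max_genes")
        if not 0 <= self.max_mito <= 1:
            raise ValueError("max_mito must lie in [0, 1]")


@dataclass
class QCReport:
    n_input: int
    n_kept: int
    n_low_genes: int
    n_high_genes: int
    n_high_mito: int
    config: QCConfig
    removed_per_donor: dict = field(default_factory=dict)
    mito_unit: str = "UMI counts"

    def to_json(self, path: str | os.PathLike) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


# ---------------------------------------------------------------------------
# 10x-convention Matrix Market bundles


def _find(path: str, names: list[str]) -> str:
    for name in names:
        for cand in (name, name + ".gz"):
            p = os.path.join(path, cand)
            if os.path.exists(p):
                return p
    raise FileNotFoundError(
        f"none of {names} (or .gz) found in {path!r}"
    )


def _open_maybe_gz(path: str, mode: str = "rt"):
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_10x(path: str | os.PathLike) -> CountMatrix:
    """Read a 10x-convention bundle (matrix.mtx + features/genes.tsv + barcodes.tsv).

    The on-disk matrix is genes x cells (Cell Ranger orientation); the
    returned matrix is cells x genes. Gzipped files are handled
    transparently. Dimension mismatches raise with the offending file name.
    """
    path = os.fspath(path)
    mtx_path = _find(path, ["matrix.mtx"])
    feat_path = _find(path, ["features.tsv", "genes.tsv"])
    bc_path = _find(path, ["barcodes.tsv"])

    with _open_maybe_gz(mtx_path, "rb") as fh:
        mat = scipy.io.mmread(fh)
    feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    if feats.shape[1] < 2:
        feats[1] = feats[0]
    barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)[0]

    n_genes, n_cells = mat.shape
    if n_genes != len(feats):
        raise ValueError(
            f"{mtx_path} declares {n_genes} genes but {feat_path} has {len(feats)} lines"
        )
    if n_cells != len(barcodes):
        raise ValueError(
            f"{mtx_path} declares {n_cells} cells but {bc_path} has {len(barcodes)} lines"
        )
    counts = sp.csr_matrix(mat.T.astype(np.int64))
    return CountMatrix(
        cell_ids=barcodes.to_numpy(dtype=object),
        gene_ids=feats[0].to_numpy(dtype=object),
        gene_symbols=feats[1].to_numpy(dtype=object),
        counts=counts,
    )


def write_10x(m: CountMatrix, path: str | os.PathLike, gzipped: bool = False) -> None:
    """Write a CountMatrix as a 10x-convention bundle (genes x cells on disk)."""
    path = os.fspath(path)
    os.makedirs(path, exist_ok=True)
    suffix = ".gz" if gzipped else ""

    mtx_path = os.path.join(path, "matrix.mtx" + suffix)
    with _open_maybe_gz(mtx_path, "wb") as fh:
        scipy.io.mmwrite(fh, sp.coo_matrix(m.counts.T), field="integer")
    with _open_maybe_gz(os.path.join(path, "features.tsv" + suffix), "wt") as fh:
        for gid, sym in zip(m.gene_ids, m.gene_symbols):
            fh.write(f"{gid}\t{sym}\tGene Expression\n")
    with _open_maybe_gz(os.path.join(path, "barcodes.tsv" + suffix), "wt") as fh:
        for bc in m.cell_ids:
            fh.write(f"{bc}\n")


def read_cell_meta(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-cell annotation table (cell_id, donor, age_group, cluster)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "cell_id" not in meta.columns:
        raise ValueError(f"{path} lacks a 'cell_id' column")
    return meta


# ---------------------------------------------------------------------------
# QC filtering and normalization


def qc_filter(
    m: CountMatrix,
    cfg: QCConfig | None = None,
    meta: pd.DataFrame | None = None,
) -> tuple[CountMatrix, QCReport]:
    """Remove cells failing any QC criterion; genes are untouched.

    A cell is removed when its number of expressed genes is < ``min_genes``
    or > ``max_genes``, or its mitochondrial fraction is > ``max_mito``
    (all strict). An all-zero cell has mitochondrial fraction 0 by
    definition and is removed by the min_genes rule.
    """
    cfg = cfg or QCConfig()
    if m.n_cells == 0:
        raise ValueError("cannot QC-filter a matrix with zero cells")

    n_expr = m.genes_per_cell()
    mito = m.mito_fraction(cfg.mito_prefix)

    low = n_expr < cfg.min_genes
    high = n_expr > cfg.max_genes
    himito = mito > cfg.max_mito
    keep = ~(low | high | himito)

    removed_per_donor: dict = {}
    if meta is not None and "donor" in meta.columns:
        donor = meta.set_index("cell_id")["donor"].reindex(m.cell_ids).to_numpy()
        for d in pd.unique(donor):
            dm = donor == d
            removed_per_donor[str(d)] = int((dm & ~keep).sum())

    report = QCReport(
        n_input=m.n_cells,
        n_kept=int(keep.sum()),
        n_low_genes=int(low.sum()),
        n_high_genes=int(high.sum()),
        n_high_mito=int(himito.sum()),
        config=cfg,
        removed_per_donor=removed_per_donor,
    )
    return m.subset_cells(keep), report


def normalize(m: CountMatrix, scale: float = 1e6) -> NormalizedMatrix:
    """Counts-per-scale log normalization: ln(1 + count/total * scale).

    Zeros stay zero, so the sparsity pattern is preserved, and per cell
    Σ_g (e^value - 1) = scale exactly.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    totals = m.cell_totals()
    if (totals == 0).any():
        raise ValueError(
            "matrix contains cells with zero total counts; run qc_filter first"
        )
    x = m.counts.tocoo().astype(np.float64)
    x.data = np.log1p(x.data / totals[x.row] * scale)
    return NormalizedMatrix(
        cell_ids=m.cell_ids,
        gene_ids=m.gene_ids,
        gene_symbols=m.gene_symbols,
        values=x.tocsr(),
        scale=scale,
    )
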