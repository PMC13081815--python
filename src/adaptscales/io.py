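"""Reading, quality control and normalization of expression count data.

Single-cell UMI matrices arrive in one of three on-disk layouts:

* ``mtx_dir`` — a 10x-style directory of ``matrix.mtx[.gz]`` (features x
  barcodes Matrix Market triplet), ``barcodes.tsv[.gz]`` and
  ``features.tsv[.gz]``;
* ``h5`` — a 10x-style HDF5 feature-barcode matrix (CSC, features x barcodes,
  under the ``matrix`` group);
* ``dense_tsv`` — a dense tab-separated table with cells as rows and a header
  of gene identifiers.

Regardless of layout, :func:`read_counts` returns the matrix in cells x genes
orientation.  Quality control follows the standard UMI workflow: cells are
retained when their number of expressed genes lies within an inclusive band
and their total UMI count clears a floor; genes seen in too few of the
surviving cells are then dropped.  Normalization rescales every cell to a
common target total (10,000 by default) and applies log1p.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class EmptyAfterQCError(ValueError):
    """Raised when quality-control filtering removes every cell."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QCThresholds:
    """Inclusive quality-control bounds for cells and genes.

    A cell is kept when ``min_genes <= #expressed genes <= max_genes`` and its
    total UMI count is at least ``min_counts``; "expressed" means a strictly
    positive count.  A gene is kept when it is expressed in at least
    ``min_cells_per_gene`` of the retained cells.
    """

    min_genes: int = 200
    max_genes: int = 4000
    min_counts: int = 300
    min_cells_per_gene: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.min_genes <= self.max_genes):
            raise ValueError("require 0 < min_genes <= max_genes")
        if self.min_counts < 0 or self.min_cells_per_gene < 0:
            raise ValueError("min_counts and min_cells_per_gene must be >= 0")


@dataclass
class CountMatrix:
    """Sparse cells x genes UMI count matrix with identifiers and metadata.

    ``cell_meta`` is indexed by barcode and always carries a ``sample_id``
    column; additional columns hold categorical environmental labels.
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise FormatError("duplicate cell barcodes")
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("duplicate gene identifiers")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative counts")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(
                {"sample_id": ["sample0"] * n_cells}, index=self.cell_ids
            )
        if "sample_id" not in self.cell_meta.columns:
            raise FormatError("cell_meta must contain a sample_id column")
        if len(self.cell_meta) != n_cells:
            raise FormatError("cell_meta length does not match cell count")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset(self, cell_mask: np.ndarray, gene_mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts[cell_mask][:, gene_mask].tocsr(),
            cell_ids=self.cell_ids[cell_mask],
            gene_ids=self.gene_ids[gene_mask],
            cell_meta=self.cell_meta.loc[np.asarray(cell_mask)].copy()
            if cell_mask.dtype == bool
            else self.cell_meta.iloc[cell_mask].copy(),
        )


@dataclass
class QCReport:
    """Counts removed at each filtering step, in application order."""

    n_cells_in: int
    n_genes_in: int
    removed_low_genes: int
    removed_high_genes: int
    removed_low_counts: int
    removed_genes: int
    n_cells_out: int
    n_genes_out: int
    thresholds: QCThresholds

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_cells_in", "n_genes_in", "removed_low_genes",
            "removed_high_genes", "removed_low_counts", "removed_genes",
            "n_cells_out", "n_genes_out")}
        d["thresholds"] = {
            "min_genes": self.thresholds.min_genes,
            "max_genes": self.thresholds.max_genes,
            "min_counts": self.thresholds.min_counts,
            "min_cells_per_gene": self.thresholds.min_cells_per_gene,
        }
        return d


@dataclass
class NormalizedMatrix:
    """Dense cells x genes log-normalized expression.

    ``values[i, g] = ln(1 + target_sum * counts[i, g] / total_i)`` so that
    ``exp(values) - 1`` row-sums to ``target_sum`` for every cell.
    """

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    cell_meta: pd.DataFrame
    target_sum: float = 10_000.0
    provenance: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class BulkCounts:
    """Bulk RNA-seq gene x sample counts with a condition design table.

    ``design`` is indexed by sample id; expected factor columns are ``heat``
    and ``salt`` (values "-"/"+"), optionally ``strain`` and ``replicate``.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise FormatError(f"duplicated gene ids: {list(dups[:5])}")
        missing = [s for s in self.counts.columns if s not in self.design.index]
        if missing:
            raise FormatError(
                f"samples absent from design table: {missing}"
            )
        extra = [s for s in self.design.index if s not in self.counts.columns]
        if extra:
            warnings.warn(
                f"design contains samples with no counts (retained in design "
                f"only): {extra}",
                stacklevel=2,
            )
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative bulk counts")


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------


def _find(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"missing {stem}[.gz] in {directory}")


def _read_id_column(path: Path) -> np.ndarray:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return np.asarray(ids, dtype=object)


def read_counts(
    path: str | Path,
    format: str = "mtx_dir",
    cell_meta: pd.DataFrame | None = None,
) -> CountMatrix:
    """Read a UMI count matrix, returning cells x genes orientation.

    Matrix Market and 10x HDF5 store features as rows and barcodes as
    columns; both are transposed on read.  ``dense_tsv`` is read as written
    (cells as rows, header row of gene ids, first column of barcodes).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such path: {path}")
    if format == "mtx_dir":
        mtx = _find(path, "matrix.mtx")
        barcodes = _read_id_column(_find(path, "barcodes.tsv"))
        features = _read_id_column(_find(path, "features.tsv"))
        mat = scipy.io.mmread(str(mtx))
        if not np.issubdtype(np.asarray(mat.data if sp.issparse(mat) else mat).dtype, np.integer):
            data = mat.data if sp.issparse(mat) else np.asarray(mat)
            if not np.allclose(data, np.round(data)):
                raise FormatError(f"non-integer entries in {mtx}")
        mat = sp.csr_matrix(mat, dtype=np.int64).T.tocsr()
        if mat.shape[0] != len(barcodes) or mat.shape[1] != len(features):
            raise FormatError(
                f"matrix declares {mat.shape[1]} features x {mat.shape[0]} "
                f"barcodes but id files list {len(features)} features and "
                f"{len(barcodes)} barcodes"
            )
        counts, cell_ids, gene_ids = mat, barcodes, features
    elif format == "h5":
        import h5py

        with h5py.File(path, "r") as f:
            g = f["matrix"]
            shape = tuple(g["shape"][:])  # (n_features, n_barcodes)
            mat = sp.csc_matrix(
                (g["data"][:], g["indices"][:], g["indptr"][:]), shape=shape
            )
            cell_ids = np.array([b.decode() for b in g["barcodes"][:]], dtype=object)
            feat = g["features"]["id"] if "features" in g else g["genes"]
            gene_ids = np.array([x.decode() for x in feat[:]], dtype=object)
        counts = sp.csr_matrix(mat.T, dtype=np.int64)
    elif format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        vals = df.to_numpy()
        if not np.allclose(vals, np.round(vals)):
            raise FormatError(f"non-integer entries in {path}")
        counts = sp.csr_matrix(vals.astype(np.int64))
        cell_ids = df.index.to_numpy(dtype=object)
        gene_ids = df.columns.to_numpy(dtype=object)
    else:
        raise ValueError(f"unknown format {format!r}")
    if cell_meta is not None:
        cell_meta = cell_meta.loc[cell_ids].copy()
    return CountMatrix(counts, cell_ids, gene_ids, cell_meta)


def write_counts(m: CountMatrix, path: str | Path, format: str = "mtx_dir") -> None:
    """Write ``m`` in one of the three supported formats (inverse of read)."""
    path = Path(path)
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(
            str(path / "matrix.mtx"), sp.coo_matrix(m.counts.T), field="integer"
        )
        (path / "barcodes.tsv").write_text("\n".join(m.cell_ids) + "\n")
        (path / "features.tsv").write_text(
            "\n".join(f"{g}\t{g}\tGene Expression" for g in m.gene_ids) + "\n"
        )
    elif format == "h5":
        import h5py

        csc = sp.csc_matrix(m.counts.T)  # features x barcodes
        with h5py.File(path, "w") as f:
            g = f.create_group("matrix")
            g.create_dataset("data", data=csc.data.astype(np.int64))
            g.create_dataset("indices", data=csc.indices.astype(np.int64))
            g.create_dataset("indptr", data=csc.indptr.astype(np.int64))
            g.create_dataset("shape", data=np.asarray(csc.shape, dtype=np.int64))
            g.create_dataset(
                "barcodes", data=np.array([c.encode() for c in m.cell_ids])
            )
            feat = g.create_group("features")
            feat.create_dataset(
                "id", data=np.array([x.encode() for x in m.gene_ids])
            )
    elif format == "dense_tsv":
        pd.DataFrame(
            m.counts.toarray(), index=m.cell_ids, columns=m.gene_ids
        ).to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_cell_meta(path: str | Path) -> pd.DataFrame:
    """Read a metadata table (TSV/CSV); first column is barcode/sample id."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0, dtype=str)


def read_gene_set(path: str | Path, name: str | None = None) -> "GeneSet":
    from .epistasis import GeneSet

    path = Path(path)
    ids = [l.strip() for l in path.read_text().splitlines() if l.strip()]
    return GeneSet(name or path.stem, tuple(ids))


def read_bulk(path: str | Path, design_path: str | Path) -> BulkCounts:
    """Read a genes x samples count TSV and its sample design TSV."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", index_col=0, dtype=str)
    return BulkCounts(counts, design)


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------


def qc_filter(
    m: CountMatrix,
    t: QCThresholds | None = None,
    per_sample_gene_filter: bool = False,
) -> tuple[CountMatrix, QCReport]:
    """Apply cell then gene quality-control filters.

    Cells first: number of expressed genes in ``[min_genes, max_genes]``
    (inclusive) and total counts ``>= min_counts``.  Genes second, computed on
    the cell-filtered matrix: expressed in ``>= min_cells_per_gene`` cells
    (pooled across samples by default; per-sample requires the threshold to be
    met within every sample when ``per_sample_gene_filter``).
    """
    t = t or QCThresholds()
    X = m.counts
    genes_per_cell = X.getnnz(axis=1)
    counts_per_cell = np.asarray(X.sum(axis=1)).ravel()
    low = genes_per_cell < t.min_genes
    high = genes_per_cell > t.max_genes
    shallow = counts_per_cell < t.min_counts
    cell_mask = ~(low | high | shallow)
    if not cell_mask.any():
        raise EmptyAfterQCError(
            "no cells survive QC thresholds "
            f"(min_genes={t.min_genes}, max_genes={t.max_genes}, "
            f"min_counts={t.min_counts})"
        )
    Xc = X[cell_mask]
    if per_sample_gene_filter:
        samples = m.cell_meta.loc[cell_mask, "sample_id"].to_numpy()
        gene_mask = np.ones(m.n_genes, dtype=bool)
        for s in pd.unique(samples):
            cells_per_gene = Xc[samples == s].getnnz(axis=0)
            gene_mask &= cells_per_gene >= t.min_cells_per_gene
    else:
        cells_per_gene = Xc.getnnz(axis=0)
        gene_mask = cells_per_gene >= t.min_cells_per_gene
    out = m.subset(cell_mask, gene_mask)
    report = QCReport(
        n_cells_in=m.n_cells,
        n_genes_in=m.n_genes,
        removed_low_genes=int(low.sum()),
        removed_high_genes=int(high.sum()),
        removed_low_counts=int((shallow & ~low & ~high).sum()),
        removed_genes=int((~gene_mask).sum()),
        n_cells_out=out.n_cells,
        n_genes_out=out.n_genes,
        thresholds=t,
    )
    return out, report


def normalize_log(m: CountMatrix, target_sum: float = 10_000.0) -> NormalizedMatrix:
    """Rescale each cell to ``target_sum`` total counts and apply log1p.

    Natural log; a zero count maps to exactly 0.  Cells with zero total are a
    contract violation (they cannot pass QC) and raise.
    """
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    totals = np.asarray(m.counts.sum(axis=1), dtype=float).ravel()
    if (totals == 0).any():
        raise ValueError("cell with zero total counts; run qc_filter first")
    X = m.counts.astype(float).multiply(target_sum / totals[:, None]).tocsr()
    values = np.log1p(X.toarray())
    return NormalizedMatrix(
        values=values,
        cell_ids=m.cell_ids.copy(),
        gene_ids=m.gene_ids.copy(),
        cell_meta=m.cell_meta.copy(),
        target_sum=float(target_sum),
        provenance={"normalization": "total-count", "target_sum": float(target_sum),
                    "log": "ln(1+x)"},
    )


def preprocess(
    m: CountMatrix,
    thresholds: QCThresholds | None = None,
    target_sum: float = 10_000.0,
    per_sample_gene_filter: bool = False,
) -> tuple[NormalizedMatrix, QCReport]:
    """QC-filter then log-normalize; the one-call entry to the pipeline."""
    filtered, report = qc_filter(m, thresholds, per_sample_gene_filter)
    norm = normalize_log(filtered, target_sum)
    norm.provenance["qc"] = report.to_dict()
    return norm, report
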