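"""Reading, writing, QC and chunking of single-cell count matrices.

The universal unit of model input is the :class:`CellSet`: a dense K x G
integer count matrix with its gene index and per-cell metadata. Files are
read through the field-standard libraries (anndata for h5ad, scipy.io for
MatrixMarket, pandas for CSV) and converted to this container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "CellSet",
    "GeneIndex",
    "ChunkPlan",
    "read_cell_matrix",
    "write_cell_matrix",
    "qc_filter",
    "build_gene_index",
    "chunk_cell_sets",
    "align_to_gene_index",
]


@dataclass
class CellSet:
    """A set of K cells over G genes from one biological sample.

    ``library_size`` is always the row sum of ``counts``; it is recomputed in
    ``__post_init__`` so the invariant cannot drift.
    """

    counts: np.ndarray
    genes: np.ndarray
    cell_ids: np.ndarray
    sample_id: str = "sample"
    cell_type: np.ndarray | None = None
    condition: np.ndarray | None = None
    library_size: np.ndarray = field(init=False)

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if sparse.issparse(self.counts):
            counts = np.asarray(self.counts.todense())
        if counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x genes)")
        if not np.issubdtype(counts.dtype, np.number):
            raise ValueError(f"counts must be numeric, got dtype {counts.dtype}")
        if counts.size and (np.any(counts < 0) or np.any(counts != np.floor(counts))):
            raise ValueError("counts must be non-negative integers")
        self.counts = counts.astype(np.int64)
        self.genes = np.asarray(self.genes, dtype=object)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        k, g = self.counts.shape
        if len(self.genes) != g or len(self.cell_ids) != k:
            raise ValueError("genes/cell_ids lengths must match counts shape")
        for name in ("cell_type", "condition"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=object)
                if len(val) != k:
                    raise ValueError(f"{name} length must equal number of cells")
                setattr(self, name, val)
        self.library_size = self.counts.sum(axis=1)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset(self, rows) -> "CellSet":
        rows = np.asarray(rows)
        return CellSet(
            counts=self.counts[rows],
            genes=self.genes,
            cell_ids=self.cell_ids[rows],
            sample_id=self.sample_id,
            cell_type=None if self.cell_type is None else self.cell_type[rows],
            condition=None if self.condition is None else self.condition[rows],
        )

    def to_anndata(self):
        import anndata as ad

        obs = pd.DataFrame(index=pd.Index(self.cell_ids.astype(str), name="cell_id"))
        obs["sample_id"] = self.sample_id
        if self.cell_type is not None:
            obs["cell_type"] = self.cell_type.astype(str)
        if self.condition is not None:
            obs["condition"] = self.condition.astype(str)
        var = pd.DataFrame(index=pd.Index(self.genes.astype(str), name="gene"))
        return ad.AnnData(X=self.counts.astype(np.float64), obs=obs, var=var)

    @classmethod
    def from_anndata(cls, adata, sample_id: str | None = None, layer: str | None = None,
                     sample_key: str = "sample_id", type_key: str = "cell_type",
                     condition_key: str = "condition") -> "CellSet":
        x = adata.layers[layer] if layer is not None else adata.X
        if sparse.issparse(x):
            x = np.asarray(x.todense())
        x = np.asarray(x)
        if np.any(x < 0) or np.any(x != np.floor(x)):
            raise ValueError("matrix does not contain non-negative integer counts")
        if sample_id is None:
            if sample_key in adata.obs:
                vals = adata.obs[sample_key].astype(str).unique()
                sample_id = vals[0] if len(vals) == 1 else "mixed"
            else:
                sample_id = "sample"
        return cls(
            counts=x,
            genes=np.asarray(adata.var_names, dtype=object),
            cell_ids=np.asarray(adata.obs_names, dtype=object),
            sample_id=sample_id,
            cell_type=(np.asarray(adata.obs[type_key], dtype=object)
                       if type_key in adata.obs else None),
            condition=(np.asarray(adata.obs[condition_key], dtype=object)
                       if condition_key in adata.obs else None),
        )


@dataclass(frozen=True)
class GeneIndex:
    """Unified gene list: union of per-file top HVGs, truncated to ``cap``."""

    genes: tuple
    per_file_top: int
    cap: int

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("GeneIndex genes must be unique")
        if len(self.genes) > self.cap:
            raise ValueError("GeneIndex exceeds its cap")

    def __len__(self):
        return len(self.genes)


@dataclass(frozen=True)
class ChunkPlan:
    chunk_size: int
    drop_short: bool = True

    def __post_init__(self):
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def read_cell_matrix(path, format: str, sample_id: str | None = None,
                     layer: str | None = None, sample_key: str = "sample_id",
                     type_key: str = "cell_type", condition_key: str = "condition") -> CellSet:
    """Read a count matrix from ``h5ad``, ``mtx`` (directory with sidecars) or ``csv``.

    CSV dialect: comma-separated, header row of gene IDs, first column cell IDs.
    MTX: ``matrix.mtx`` (cells x genes triplets) with ``barcodes.tsv`` /
    ``features.tsv`` sidecars and an optional ``metadata.csv``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        return CellSet.from_anndata(adata, sample_id=sample_id, layer=layer,
                                    sample_key=sample_key, type_key=type_key,
                                    condition_key=condition_key)
    if format == "csv":
        try:
            df = pd.read_csv(path, index_col=0)
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"malformed CSV {path}: {exc}") from exc
        return CellSet(counts=df.to_numpy(), genes=np.asarray(df.columns, dtype=object),
                       cell_ids=np.asarray(df.index, dtype=object),
                       sample_id=sample_id or path.stem)
    if format == "mtx":
        mtx_path = path / "matrix.mtx" if path.is_dir() else path
        base = mtx_path.parent
        try:
            mat = spio.mmread(mtx_path)
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
        counts = np.asarray(sparse.coo_matrix(mat).todense())
        genes = _read_sidecar(base, ("features.tsv", "genes.tsv"))
        cells = _read_sidecar(base, ("barcodes.tsv",))
        if genes is None:
            genes = np.array([f"g{i}" for i in range(counts.shape[1])], dtype=object)
        if cells is None:
            cells = np.array([f"c{i}" for i in range(counts.shape[0])], dtype=object)
        cell_type = condition = None
        meta_path = base / "metadata.csv"
        if meta_path.exists():
            meta = pd.read_csv(meta_path, index_col=0)
            if type_key in meta:
                cell_type = np.asarray(meta[type_key], dtype=object)
            if condition_key in meta:
                condition = np.asarray(meta[condition_key], dtype=object)
        return CellSet(counts=counts, genes=genes, cell_ids=cells,
                       sample_id=sample_id or base.name, cell_type=cell_type,
                       condition=condition)
    raise ValueError(f"unknown format {format!r}")


def _read_sidecar(base: Path, names: Sequence[str]) -> np.ndarray | None:
    for name in names:
        p = base / name
        if p.exists():
            col = pd.read_csv(p, sep="\t", header=None)[0]
            return np.asarray(col, dtype=object)
    return None


def write_cell_matrix(cells: CellSet, path, format: str) -> None:
    path = Path(path)
    if format == "h5ad":
        cells.to_anndata().write_h5ad(path)
    elif format == "csv":
        df = pd.DataFrame(cells.counts, index=cells.cell_ids.astype(str),
                          columns=cells.genes.astype(str))
        df.to_csv(path)
    elif format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(path / "matrix.mtx", sparse.coo_matrix(cells.counts))
        pd.Series(cells.genes.astype(str)).to_csv(path / "features.tsv", sep="\t",
                                                  header=False, index=False)
        pd.Series(cells.cell_ids.astype(str)).to_csv(path / "barcodes.tsv", sep="\t",
                                                     header=False, index=False)
        meta = pd.DataFrame(index=pd.Index(cells.cell_ids.astype(str), name="cell_id"))
        if cells.cell_type is not None:
            meta["cell_type"] = cells.cell_type.astype(str)
        if cells.condition is not None:
            meta["condition"] = cells.condition.astype(str)
        if meta.shape[1]:
            meta.to_csv(path / "metadata.csv")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# QC / gene index / chunking
# ---------------------------------------------------------------------------

def qc_filter(cells: CellSet, min_genes: int = 300, max_genes: int = 7000,
              min_umi: int = 700) -> CellSet:
    """Keep cells with min_genes <= detected genes <= max_genes and
    library size >= min_umi (all bounds inclusive). Order is preserved."""
    if min_genes <= 0 or max_genes <= 0 or min_umi <= 0:
        raise ValueError("QC thresholds must be positive")
    if min_genes > max_genes:
        raise ValueError("min_genes must not exceed max_genes")
    detected = (cells.counts > 0).sum(axis=1)
    keep = (detected >= min_genes) & (detected <= max_genes) & (cells.library_size >= min_umi)
    if not keep.any():
        warnings.warn("qc_filter removed every cell", stacklevel=2)
    return cells.subset(np.flatnonzero(keep))


def build_gene_index(files: Sequence[CellSet], per_file_top: int, cap: int) -> GeneIndex:
    """Union of each file's top HVGs (analytic Pearson residuals), truncated to
    ``cap`` by descending maximum residual-variance score across files."""
    from .losses import pearson_residual_scores

    if not files:
        raise ValueError("build_gene_index needs at least one file")
    if per_file_top < 1 or cap < 1:
        raise ValueError("per_file_top and cap must be >= 1")
    best: dict[str, float] = {}
    first_seen: dict[str, int] = {}
    order = 0
    for cs in files:
        scores = pearson_residual_scores(cs.counts)
        top = np.argsort(-scores, kind="stable")[:per_file_top]
        for gi in top:
            gene = str(cs.genes[gi])
            if gene not in first_seen:
                first_seen[gene] = order
                order += 1
            best[gene] = max(best.get(gene, -np.inf), float(scores[gi]))
    ranked = sorted(best, key=lambda g: (-best[g], first_seen[g]))[:cap]
    return GeneIndex(genes=tuple(ranked), per_file_top=per_file_top, cap=cap)


def align_to_gene_index(cells: CellSet, index: GeneIndex) -> CellSet:
    """Reorder columns to the unified gene index, zero-filling absent genes."""
    pos = {g: i for i, g in enumerate(cells.genes)}
    out = np.zeros((cells.n_cells, len(index)), dtype=np.int64)
    for j, gene in enumerate(index.genes):
        i = pos.get(gene)
        if i is not None:
            out[:, j] = cells.counts[:, i]
    return CellSet(counts=out, genes=np.asarray(index.genes, dtype=object),
                   cell_ids=cells.cell_ids, sample_id=cells.sample_id,
                   cell_type=cells.cell_type, condition=cells.condition)


def chunk_cell_sets(files: Iterable[CellSet], plan: ChunkPlan) -> Iterator[CellSet]:
    """Cut each file into contiguous, non-overlapping chunks of ``chunk_size``
    cells in file-native order; trailing cells shorter than a chunk are
    dropped when ``drop_short`` is set. Chunks never cross file boundaries."""
    for cs in files:
        k = plan.chunk_size
        n_full = cs.n_cells // k
        for i in range(n_full):
            yield cs.subset(np.arange(i * k, (i + 1) * k))
        if not plan.drop_short and cs.n_cells % k:
            yield cs.subset(np.arange(n_full * k, cs.n_cells))
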