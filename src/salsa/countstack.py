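"""Triplet-stack representation of gene x barcode UMI count matrices.

Ultra-sparse single-cell expression matrices are handled throughout the
package as zero-free triplet stacks: only data-positive (gene, barcode)
fields are ever stored, and sparsity/occupancy accounting is computed from
exact integer tallies without materializing a dense matrix.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountStack",
    "SparsityReport",
    "BlockReport",
    "FormatError",
    "read_mtx_triplets",
    "read_mtx_dir",
    "sparsity_profile",
    "block_report",
    "block_arithmetic",
    "write_stack",
    "write_tables",
]


class FormatError(ValueError):
    """Raised when an input matrix or axis table violates the 10X triplet dialect."""


@dataclass
class CountStack:
    """Zero-free stack of deduplicated UMI tallies plus axis dictionaries.

    The canonical in-memory form is a CSR matrix of shape
    ``(n_genes, n_barcodes)`` whose stored values are strictly positive
    integers; axis identity lives in ``gene_ids`` / ``barcode_ids``.
    """

    matrix: sp.csr_matrix
    gene_ids: list[str]
    barcode_ids: list[str]
    gene_symbols: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.matrix.eliminate_zeros()
        self.matrix.sum_duplicates()
        if self.matrix.shape != (len(self.gene_ids), len(self.barcode_ids)):
            raise FormatError(
                f"matrix shape {self.matrix.shape} does not match axis tables "
                f"({len(self.gene_ids)} genes, {len(self.barcode_ids)} barcodes)"
            )
        if self.matrix.nnz and self.matrix.data.min() <= 0:
            raise FormatError("UMI tallies must be strictly positive integers")
        if self.gene_symbols is not None and len(self.gene_symbols) != len(self.gene_ids):
            raise FormatError("gene_symbols length must match gene_ids")

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_barcodes(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_positive(self) -> int:
        return int(self.matrix.nnz)

    @property
    def span(self) -> int:
        return self.n_genes * self.n_barcodes

    @property
    def total_umi(self) -> int:
        return int(self.matrix.data.sum()) if self.matrix.nnz else 0

    def entries(self) -> np.ndarray:
        """Structured view (gene_index, barcode_index, umi), one row per data-positive field."""
        coo = self.matrix.tocoo()
        out = np.empty(coo.nnz, dtype=[("gene", np.int64), ("barcode", np.int64), ("umi", np.int64)])
        out["gene"] = coo.row
        out["barcode"] = coo.col
        out["umi"] = coo.data
        return out

    @classmethod
    def from_entries(
        cls,
        entries: Iterable[tuple[int, int, int]],
        gene_ids: Sequence[str],
        barcode_ids: Sequence[str],
        gene_symbols: Sequence[str] | None = None,
    ) -> "CountStack":
        rows, cols, vals = [], [], []
        for g, b, u in entries:
            rows.append(g)
            cols.append(b)
            vals.append(u)
        mat = sp.coo_matrix(
            (vals, (rows, cols)), shape=(len(gene_ids), len(barcode_ids)), dtype=np.int64
        )
        return cls(mat.tocsr(), list(gene_ids), list(barcode_ids),
                   list(gene_symbols) if gene_symbols is not None else None)

    def subset(self, gene_idx=None, barcode_idx=None) -> "CountStack":
        """Restrict to index subsets, keeping axis order; indices are positional."""
        gi = np.arange(self.n_genes) if gene_idx is None else np.asarray(sorted(gene_idx), dtype=int)
        bi = np.arange(self.n_barcodes) if barcode_idx is None else np.asarray(sorted(barcode_idx), dtype=int)
        mat = self.matrix[gi][:, bi]
        syms = [self.gene_symbols[i] for i in gi] if self.gene_symbols is not None else None
        return CountStack(mat.tocsr(), [self.gene_ids[i] for i in gi],
                          [self.barcode_ids[i] for i in bi], syms)


@dataclass
class SparsityReport:
    span: int
    n_positive: int
    occupancy: float
    total_umi: int
    value_composition: dict
    genes_with_1valued: int
    genes_with_4plus: int


@dataclass
class BlockReport:
    block_label: str
    block_genes: int
    block_barcodes: int
    block_span: int
    n_fields: int
    pct_matrix: float
    pct_stack: float
    pct_block_span: float


def _open_text(path) -> io.TextIOBase:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _resolve(dirname: Path, stem: str) -> Path:
    for cand in (dirname / stem, dirname / (stem + ".gz")):
        if cand.exists():
            return cand
    raise FileNotFoundError(f"neither {stem} nor {stem}.gz found in {dirname}")


def read_mtx_triplets(matrix_path, genes_path, barcodes_path) -> CountStack:
    """Read a 10X-style triplet matrix (MatrixMarket + gene/barcode TSVs).

    1-based MTX coordinates are converted to 0-based indices and duplicate
    coordinate lines are summed. Gzip-compressed inputs are accepted
    transparently.
    """
    with _open_text(matrix_path) as fh:
        try:
            mat = scipy.io.mmread(fh)
        except Exception as exc:  # noqa: BLE001 - scipy raises bare ValueError
            raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.nnz:
        if not np.issubdtype(mat.data.dtype, np.integer) and not np.allclose(mat.data, np.round(mat.data)):
            raise FormatError("matrix values must be integer UMI tallies")
        if mat.data.min() < 0:
            raise FormatError("matrix values must be non-negative")
    mat = sp.coo_matrix((mat.data.astype(np.int64), (mat.row, mat.col)), shape=mat.shape)

    with _open_text(genes_path) as fh:
        genes = pd.read_csv(fh, sep="\t", header=None, dtype=str)
    with _open_text(barcodes_path) as fh:
        barcodes = pd.read_csv(fh, sep="\t", header=None, dtype=str)

    if mat.shape[0] != len(genes):
        raise FormatError(f"matrix has {mat.shape[0]} rows but genes table has {len(genes)}")
    if mat.shape[1] != len(barcodes):
        raise FormatError(f"matrix has {mat.shape[1]} columns but barcode table has {len(barcodes)}")

    gene_ids = genes.iloc[:, 0].tolist()
    symbols = genes.iloc[:, 1].tolist() if genes.shape[1] >= 2 else None
    return CountStack(mat.tocsr(), gene_ids, barcodes.iloc[:, 0].tolist(), symbols)


def read_mtx_dir(matrix_dir) -> CountStack:
    """Read a directory holding matrix.mtx, genes.tsv (or features.tsv) and barcodes.tsv."""
    d = Path(matrix_dir)
    try:
        genes = _resolve(d, "genes.tsv")
    except FileNotFoundError:
        genes = _resolve(d, "features.tsv")
    return read_mtx_triplets(_resolve(d, "matrix.mtx"), genes, _resolve(d, "barcodes.tsv"))


def sparsity_profile(stack: CountStack) -> SparsityReport:
    """Exact sparsity accounting: occupancy, count-value composition, 1-valued/4+ gene reach."""
    data = stack.matrix.data
    npos = stack.n_positive
    comp: dict = {}
    if npos:
        comp = {
            1: float(np.count_nonzero(data == 1)) / npos,
            2: float(np.count_nonzero(data == 2)) / npos,
            3: float(np.count_nonzero(data == 3)) / npos,
            "4+": float(np.count_nonzero(data >= 4)) / npos,
        }
    coo = stack.matrix.tocoo()
    genes_1 = int(np.unique(coo.row[coo.data == 1]).size) if npos else 0
    genes_4 = int(np.unique(coo.row[coo.data >= 4]).size) if npos else 0
    return SparsityReport(
        span=stack.span,
        n_positive=npos,
        occupancy=npos / stack.span if stack.span else 0.0,
        total_umi=stack.total_umi,
        value_composition=comp,
        genes_with_1valued=genes_1,
        genes_with_4plus=genes_4,
    )


def block_report(stack: CountStack, gene_subset, barcode_subset, label: str) -> BlockReport:
    """Occupancy accounting for a gene x barcode block of the stack.

    ``pct_matrix`` and ``pct_stack`` are relative to the *full* stack's span
    and data-positive field count; ``pct_block_span`` is the occupancy
    within the block itself.
    """
    gset = np.asarray(sorted(set(gene_subset)), dtype=int)
    bset = np.asarray(sorted(set(barcode_subset)), dtype=int)
    if gset.size == 0 or bset.size == 0:
        raise ValueError(f"block {label!r} is empty: block occupancy is undefined")
    if gset.min() < 0 or gset.max() >= stack.n_genes or bset.min() < 0 or bset.max() >= stack.n_barcodes:
        raise ValueError("subset indices out of range")
    n_fields = int(stack.matrix[gset][:, bset].nnz)
    block_span = int(gset.size) * int(bset.size)
    return BlockReport(
        block_label=label,
        block_genes=int(gset.size),
        block_barcodes=int(bset.size),
        block_span=block_span,
        n_fields=n_fields,
        pct_matrix=n_fields / stack.span,
        pct_stack=n_fields / stack.n_positive if stack.n_positive else 0.0,
        pct_block_span=n_fields / block_span,
    )


def block_arithmetic(block_genes: int, block_barcodes: int, n_fields: int,
                     full_span: int, full_n_positive: int, label: str = "") -> BlockReport:
    """Block accounting from printed tallies alone (no stack required).

    Applies the same formulas as :func:`block_report` to externally
    reported gene/barcode/field counts, e.g. when checking a published
    sparsity table.
    """
    block_span = int(block_genes) * int(block_barcodes)
    return BlockReport(
        block_label=label,
        block_genes=int(block_genes),
        block_barcodes=int(block_barcodes),
        block_span=block_span,
        n_fields=int(n_fields),
        pct_matrix=n_fields / full_span,
        pct_stack=n_fields / full_n_positive,
        pct_block_span=n_fields / block_span,
    )


def write_stack(stack: CountStack, out_dir) -> dict:
    """Write a stack back to the triplet dialect (matrix.mtx + genes.tsv + barcodes.tsv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "genes": out / "genes.tsv",
        "barcodes": out / "barcodes.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), stack.matrix.tocoo(), field="integer")
    genes = pd.DataFrame({"id": stack.gene_ids})
    if stack.gene_symbols is not None:
        genes["symbol"] = stack.gene_symbols
    genes.to_csv(paths["genes"], sep="\t", header=False, index=False)
    pd.Series(stack.barcode_ids).to_csv(paths["barcodes"], sep="\t", header=False, index=False)
    return {k: str(v) for k, v in paths.items()}


def _report_frame(reports) -> pd.DataFrame:
    rows = []
    for r in reports:
        d = dict(r.__dict__)
        if isinstance(d.get("value_composition"), Mapping):
            comp = d.pop("value_composition")
            for k in (1, 2, 3, "4+"):
                d[f"frac_{k}"] = comp.get(k, float("nan"))
        rows.append(d)
    return pd.DataFrame(rows)


def write_tables(objects, out_dir) -> list[str]:
    """Serialize SparsityReport / BlockReport collections as TSV with one row per report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sparsity = [o for o in objects if isinstance(o, SparsityReport)]
    blocks = [o for o in objects if isinstance(o, BlockReport)]
    written = []
    if sparsity:
        p = out / "sparsity_report.tsv"
        _report_frame(sparsity).to_csv(p, sep="\t", index=False)
        written.append(str(p))
    if blocks:
        p = out / "block_report.tsv"
        _report_frame(blocks).to_csv(p, sep="\t", index=False)
        written.append(str(p))
    return written
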