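"""On-disk formats: Matrix-Market triplet directories (matrix.mtx +
barcodes.tsv + features.tsv), read-record tables and ground-truth tables.

The writer emits coordinate integer Matrix-Market with triplets in
deterministic row-major order, so rewriting the same matrix is
byte-identical. Indices are 1-based on disk per the standard and 0-based in
memory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .demux import Whitelist
from .types import CountMatrix

MTX_HEADER = "%%MatrixMarket matrix coordinate integer general"


def write_mtx_triplet(matrix: CountMatrix, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(matrix.matrix)
    order = np.lexsort((coo.col, coo.row))  # row-major
    lines = [MTX_HEADER, f"{matrix.n_genes} {matrix.n_barcodes} {coo.nnz}"]
    lines += [
        f"{r + 1} {c + 1} {int(v)}"
        for r, c, v in zip(coo.row[order], coo.col[order], coo.data[order])
    ]
    (directory / "matrix.mtx").write_text("\n".join(lines) + "\n")
    (directory / "barcodes.tsv").write_text("".join(b + "\n" for b in matrix.barcodes))
    (directory / "features.tsv").write_text("".join(g + "\n" for g in matrix.genes))


def _read_sidecar(path: Path) -> list[str]:
    return [line.split("\t")[0] for line in path.read_text().splitlines() if line]


def read_mtx_triplet(directory: str | Path) -> CountMatrix:
    directory = Path(directory)
    for name in ("matrix.mtx", "barcodes.tsv", "features.tsv"):
        if not (directory / name).exists():
            raise FileNotFoundError(f"missing {name} in {directory}")
    text = (directory / "matrix.mtx").read_text().splitlines()
    if not text or not text[0].startswith("%%MatrixMarket"):
        raise ValueError("malformed header: missing %%MatrixMarket banner")
    header = text[0].lower()
    if "coordinate" not in header:
        raise ValueError("malformed header: only coordinate format is supported")
    body = [line for line in text[1:] if line and not line.startswith("%")]
    if not body:
        raise ValueError("malformed header: missing dimensions line")
    try:
        n_rows, n_cols, nnz = (int(tok) for tok in body[0].split())
    except ValueError as exc:
        raise ValueError("malformed header: bad dimensions line") from exc
    entries = body[1:]
    if len(entries) != nnz:
        raise ValueError(f"dimension mismatch: header declares {nnz} entries, found {len(entries)}")
    rows = np.empty(nnz, dtype=np.int64)
    cols = np.empty(nnz, dtype=np.int64)
    vals = np.empty(nnz, dtype=np.int64)
    for i, line in enumerate(entries):
        r, c, v = line.split()
        rows[i], cols[i], vals[i] = int(r) - 1, int(c) - 1, int(float(v))
    if nnz and (rows.min() < 0 or cols.min() < 0 or rows.max() >= n_rows or cols.max() >= n_cols):
        raise ValueError("dimension mismatch: entry index outside declared shape")
    genes = _read_sidecar(directory / "features.tsv")
    barcodes = _read_sidecar(directory / "barcodes.tsv")
    if len(genes) != n_rows or len(barcodes) != n_cols:
        raise ValueError(
            f"dimension mismatch: matrix is {n_rows}x{n_cols} but sidecars have "
            f"{len(genes)} features / {len(barcodes)} barcodes"
        )
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in barcodes.tsv")
    mat = sp.coo_matrix((vals, (rows, cols)), shape=(n_rows, n_cols)).tocsr()
    return CountMatrix(mat, genes, barcodes)


READ_COLUMNS = ["barcode", "barcode_quals", "umi", "umi_quals", "gene"]


def write_reads_tsv(reads: pd.DataFrame, path: str | Path) -> None:
    reads[READ_COLUMNS].to_csv(path, sep="\t", index=False)


def read_reads_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in READ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"read table missing columns: {missing}")
    return df[READ_COLUMNS]


def write_whitelist_tsv(whitelist: Whitelist, path: str | Path) -> None:
    with open(path, "w") as fh:
        for bc in sorted(whitelist.counts):
            fh.write(f"{bc}\t{whitelist.counts[bc]}\n")


def read_whitelist_tsv(path: str | Path) -> Whitelist:
    counts: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line:
            continue
        parts = line.split("\t")
        counts[parts[0]] = int(parts[1]) if len(parts) > 1 else 0
    return Whitelist(counts)


def write_truth_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
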