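"""On-disk formats: MTX + row/col TSV for matrices, BED for peaks, TSV gene
annotation, CSV metadata and spatial tables, JSON for gene sets and
provenance, Newick for dendrograms."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .atac import GeneAnnotation, PeakMatrix
from .expression import ExpressionMatrix
from .spatial import SpatialCellMap


def write_matrix(path, matrix, row_ids, col_ids, prefix: str) -> None:
    """Write a matrix as <prefix>.mtx with <prefix>.rows.tsv / .cols.tsv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(path / f"{prefix}.mtx"), sparse.coo_matrix(matrix))
    pd.Series(list(row_ids)).to_csv(path / f"{prefix}.rows.tsv", sep="\t",
                                    index=False, header=False)
    pd.Series(list(col_ids)).to_csv(path / f"{prefix}.cols.tsv", sep="\t",
                                    index=False, header=False)


def read_matrix(path, prefix: str):
    path = Path(path)
    m = spio.mmread(str(path / f"{prefix}.mtx"))
    rows = pd.read_csv(path / f"{prefix}.rows.tsv", sep="\t", header=None)[0]
    cols = pd.read_csv(path / f"{prefix}.cols.tsv", sep="\t", header=None)[0]
    return m, pd.Index(rows), pd.Index(cols)


def write_expression(path, mat: ExpressionMatrix) -> None:
    write_matrix(path, mat.tpm, mat.genes, mat.cells, "tpm")
    mat.cell_meta.to_csv(Path(path) / "cell_meta.csv")
    mat.gene_meta.to_csv(Path(path) / "gene_meta.csv")


def read_expression(path) -> ExpressionMatrix:
    m, genes, cells = read_matrix(path, "tpm")
    meta = pd.read_csv(Path(path) / "cell_meta.csv", index_col=0)
    gm_path = Path(path) / "gene_meta.csv"
    gene_meta = pd.read_csv(gm_path, index_col=0) if gm_path.exists() else None
    tpm = m.toarray() if sparse.issparse(m) else np.asarray(m)
    return ExpressionMatrix(tpm=tpm, genes=genes, cells=cells,
                            cell_meta=meta, gene_meta=gene_meta)


def write_bed(path, peaks: pd.DataFrame) -> None:
    """Write peak intervals as BED (0-based half-open, name = peak id)."""
    out = peaks[["chrom", "start", "end"]].copy()
    out["name"] = peaks.index
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name"])
    return df.set_index("name")[["chrom", "start", "end"]]


def write_peak_matrix(path, mat: PeakMatrix, qc: pd.DataFrame | None = None) -> None:
    path = Path(path)
    write_matrix(path, mat.counts, mat.peaks.index, mat.nuclei, "peaks")
    write_bed(path / "peaks.bed", mat.peaks)
    mat.nucleus_meta.to_csv(path / "nucleus_meta.csv")
    if qc is not None:
        qc.to_csv(path / "nucleus_qc.csv")


def read_peak_matrix(path) -> tuple[PeakMatrix, pd.DataFrame | None]:
    path = Path(path)
    m, peak_ids, nuclei = read_matrix(path, "peaks")
    peaks = read_bed(path / "peaks.bed").loc[peak_ids]
    peaks.index.name = "peak_id"
    meta = pd.read_csv(path / "nucleus_meta.csv", index_col=0)
    qc_path = path / "nucleus_qc.csv"
    qc = pd.read_csv(qc_path, index_col=0) if qc_path.exists() else None
    return PeakMatrix(counts=sparse.csr_matrix(m), peaks=peaks, nuclei=nuclei,
                      nucleus_meta=meta), qc


def write_annotation(path, annotation: GeneAnnotation) -> None:
    annotation.table.to_csv(path, sep="\t")


def read_annotation(path) -> GeneAnnotation:
    return GeneAnnotation(pd.read_csv(path, sep="\t", index_col=0))


def write_spatial(path, cells: SpatialCellMap) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cells.table.to_csv(path / "cells.csv")
    if cells.reads is not None:
        cells.reads.to_csv(path / "reads.csv")


def read_spatial(path) -> SpatialCellMap:
    path = Path(path)
    table = pd.read_csv(path / "cells.csv", index_col=0)
    reads_path = path / "reads.csv"
    reads = pd.read_csv(reads_path, index_col=0) if reads_path.exists() else None
    return SpatialCellMap(table=table, reads=reads)


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=default))


def read_json(path):
    return json.loads(Path(path).read_text())


def write_metaprograms(path, metaprograms) -> None:
    write_json(path, [
        {"name": m.name, "members": list(m.members), "top_genes": list(m.top_genes),
         "mean_weights": [float(w) for w in m.mean_weights]}
        for m in metaprograms
    ])


def linkage_to_newick(Z: np.ndarray, leaf_names: list) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    n = len(leaf_names)

    def build(node: int) -> str:
        if node < n:
            return leaf_names[node], 0.0
        i = node - n
        left, right, height = int(Z[i, 0]), int(Z[i, 1]), float(Z[i, 2])
        ls, lh = build(left)
        rs, rh = build(right)
        return f"({ls}:{height - lh:.6g},{rs}:{height - rh:.6g})", height

    s, _ = build(2 * n - 2)
    return s + ";"
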