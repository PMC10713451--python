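"""Readers and writers for the standard on-disk formats.

Matrix Market count triplets (matrix.mtx + barcodes.tsv + features.tsv),
10x-dialect fragment files (tab-separated chrom/start/end/barcode[/count],
0-based half-open, plain or gzipped), BED peaks with a GC sidecar, and TSV
outputs for assignments, links and activities. Readers validate rather than
silently coerce; writers attach a JSON provenance sidecar (seed, parameters,
package version).
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from . import __version__
from .types import CellMatrix, FragmentSet, MetacellAssignment, PeakSet


def read_counts_mtx(
    matrix_path, barcodes_path, features_path, modality: str = "rna"
) -> CellMatrix:
    """Read a cells x features Matrix Market triplet.

    The matrix may be stored either cells-as-rows or the 10x convention
    features-as-rows; orientation is resolved against the id files, and a
    mismatch in either dimension is an error naming both sizes.
    """
    mat = scipy_io.mmread(str(matrix_path))
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].to_numpy()
    features = pd.read_csv(features_path, sep="\t", header=None)[0].to_numpy()
    n_b, n_f = len(barcodes), len(features)
    if mat.shape == (n_b, n_f):
        pass
    elif mat.shape == (n_f, n_b):
        mat = mat.T
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither {n_b} barcodes x "
            f"{n_f} features nor its transpose"
        )
    mat = sparse.csr_matrix(mat)
    if mat.nnz and np.any(mat.data != np.floor(mat.data)):
        bad = int(np.flatnonzero(mat.data != np.floor(mat.data))[0])
        raise ValueError(f"non-integer entry at stored element {bad}")
    return CellMatrix(
        values=mat, cell_ids=barcodes, feature_ids=features, modality=modality
    )


def write_counts_mtx(cm: CellMatrix, out_dir, prefix: str = "") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy_io.mmwrite(str(out / f"{prefix}matrix.mtx"), cm.values.tocoo())
    pd.Series(cm.cell_ids).to_csv(out / f"{prefix}barcodes.tsv", sep="\t", index=False, header=False)
    pd.Series(cm.feature_ids).to_csv(out / f"{prefix}features.tsv", sep="\t", index=False, header=False)


def read_fragments(path) -> FragmentSet:
    """Read a fragments file (4 or 5 tab-separated columns; the count column
    defaults to 1). Gzip is handled transparently; malformed lines raise
    with their line number."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    rows = []
    with opener(path, "rt") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (4, 5):
                raise ValueError(f"line {ln}: expected 4 or 5 columns, got {len(parts)}")
            chrom, start, end, barcode = parts[:4]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(f"line {ln}: non-numeric coordinates {start!r}/{end!r}")
            if end_i <= start_i:
                raise ValueError(f"line {ln}: end {end_i} <= start {start_i}")
            count = 1
            if len(parts) == 5:
                try:
                    count = int(parts[4])
                except ValueError:
                    raise ValueError(f"line {ln}: non-numeric count {parts[4]!r}")
            rows.append((chrom, start_i, end_i, barcode, count))
    records = pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "count"])
    return FragmentSet(records=records)


def write_fragments(fragments: FragmentSet, path) -> None:
    fragments.records.to_csv(path, sep="\t", header=False, index=False)


def read_peaks(bed_path, gc_path=None) -> PeakSet:
    """Read a BED3(+name) peak atlas plus an optional GC sidecar TSV
    (peak_id, gc_content)."""
    bed = pd.read_csv(bed_path, sep="\t", header=None)
    if bed.shape[1] < 3:
        raise ValueError("peak BED needs at least chrom/start/end")
    bed = bed.iloc[:, :4] if bed.shape[1] >= 4 else bed.assign(name=None)
    bed.columns = ["chrom", "start", "end", "peak_id"][: bed.shape[1]]
    if "peak_id" not in bed or bed["peak_id"].isna().any():
        bed["peak_id"] = [f"peak_{i}" for i in range(len(bed))]
    gc = None
    if gc_path is not None:
        side = pd.read_csv(gc_path, sep="\t")
        if not {"peak_id", "gc_content"}.issubset(side.columns):
            raise ValueError("GC sidecar needs columns peak_id, gc_content")
        gc = side.set_index("peak_id").loc[bed["peak_id"], "gc_content"].to_numpy()
    return PeakSet(intervals=bed, gc_content=gc)


def write_peaks(peaks: PeakSet, bed_path, gc_path=None) -> None:
    peaks.intervals[["chrom", "start", "end", "peak_id"]].to_csv(
        bed_path, sep="\t", header=False, index=False
    )
    if gc_path is not None and peaks.gc_content is not None:
        pd.DataFrame(
            {"peak_id": peaks.peak_ids, "gc_content": peaks.gc_content}
        ).to_csv(gc_path, sep="\t", index=False)


def read_gene_annotations(path) -> pd.DataFrame:
    """Gene body intervals from BED6 or a TSV with columns
    gene/chrom/start/end (strand optional)."""
    df = pd.read_csv(path, sep="\t")
    if {"gene", "chrom", "start", "end"}.issubset(df.columns):
        return df
    raw = pd.read_csv(path, sep="\t", header=None)
    if raw.shape[1] >= 6:  # BED6: chrom start end name score strand
        return pd.DataFrame(
            {
                "gene": raw[3],
                "chrom": raw[0],
                "start": raw[1],
                "end": raw[2],
                "strand": raw[5],
            }
        )
    raise ValueError("gene annotations need gene/chrom/start/end columns or BED6")


def write_assignment(assignment: MetacellAssignment, barcodes, path) -> None:
    pd.DataFrame(
        {
            "barcode": np.asarray(barcodes),
            "metacell_id": assignment.labels,
            "max_weight": assignment.max_weight,
            "n_nontrivial": assignment.n_nontrivial,
        }
    ).to_csv(path, sep="\t", index=False)


def write_sparse_tsv(matrix, path) -> None:
    """3-column sparse TSV (row, col, value)."""
    coo = sparse.coo_matrix(matrix)
    pd.DataFrame({"i": coo.row, "j": coo.col, "value": coo.data}).to_csv(
        path, sep="\t", index=False
    )


def write_provenance(path, seed: int | None, params: dict) -> None:
    """JSON sidecar recording how an output was produced."""
    payload = {
        "tool": "metacellkit",
        "version": __version__,
        "seed": seed,
        "params": {k: _jsonable(v) for k, v in params.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v
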