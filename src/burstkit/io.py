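"""Readers and writers for the pipeline's plain-text formats.

Count matrices are TSV (genes as rows, cells as columns) or MatrixMarket
(with ``<name>.rows`` / ``<name>.cols`` sidecar id files, since MatrixMarket
itself carries no identifiers). Genomic intervals are BED3/BED4 and
compartment tracks bedgraph, all 0-based half-open. Readers validate and
reject malformed input rather than coercing it.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import SpikeInWell, TadSet, UmiCountMatrix

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_bed",
    "read_gene_bed",
    "read_bedgraph",
    "compartment_labels",
    "read_spikein_table",
    "write_spikein_table",
    "write_manifest",
]

PathLike = Union[str, Path]


def _infer_format(path: Path) -> str:
    if path.suffix in {".mtx", ".mm"}:
        return "matrixmarket"
    return "tsv"


def read_count_matrix(
    path: PathLike, fmt: Optional[str] = None, qc_path: Optional[PathLike] = None
) -> UmiCountMatrix:
    """Read a genes x cells UMI count matrix (TSV or MatrixMarket).

    TSV: first column = gene ids, header row = cell ids. MatrixMarket: the
    ``.mtx`` file plus ``<path>.rows`` and ``<path>.cols`` id files. Negative
    or non-integer entries are rejected with their location; duplicate ids
    are rejected. ``qc_path`` optionally attaches a per-cell QC TSV with
    columns ``cell_id, exon_reads, exon_mapping_rate``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif fmt == "matrixmarket":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        rows = Path(f"{path}.rows").read_text().split()
        cols = Path(f"{path}.cols").read_text().split()
        if len(rows) != mat.shape[0] or len(cols) != mat.shape[1]:
            raise ValueError(
                f"id sidecar files do not match matrix shape {mat.shape}"
            )
        df = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        raise ValueError(f"unknown count-matrix format {fmt!r}")
    qc = None
    if qc_path is not None:
        qc = pd.read_csv(qc_path, sep="\t", index_col=0)
    return UmiCountMatrix(df, cell_qc=qc)


def write_count_matrix(
    matrix: UmiCountMatrix, path: PathLike, fmt: Optional[str] = None
) -> None:
    """Write a count matrix as TSV or MatrixMarket (+ id sidecars)."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "tsv":
        matrix.counts.to_csv(path, sep="\t")
    elif fmt == "matrixmarket":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(matrix.counts.to_numpy()))
        Path(f"{path}.rows").write_text("\n".join(map(str, matrix.gene_ids)) + "\n")
        Path(f"{path}.cols").write_text("\n".join(map(str, matrix.cell_ids)) + "\n")
    else:
        raise ValueError(f"unknown count-matrix format {fmt!r}")


def _read_bed_frame(path: PathLike, n_cols: int, names: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < n_cols:
        raise ValueError(f"{path} has {df.shape[1]} columns, expected >= {n_cols}")
    df = df.iloc[:, :n_cols]
    df.columns = list(names)
    for col in ("start", "end"):
        if not np.issubdtype(df[col].dtype, np.integer):
            raise ValueError(f"{path}: non-integer {col} coordinates")
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: invalid interval coordinates")
    return df


def read_bed(path: PathLike) -> TadSet:
    """Read TAD intervals from a 3-column BED file (sorted/non-overlapping
    enforced by :class:`TadSet`; a 4th column, if present, becomes tad_id)."""
    raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    n = min(raw.shape[1], 4)
    names = ["chrom", "start", "end", "tad_id"][:n]
    df = _read_bed_frame(path, n, names)
    return TadSet(df)


def read_gene_bed(path: PathLike) -> pd.DataFrame:
    """Read gene annotations from BED4 (chrom, start, end, gene_id); extra
    columns 5-6 are read as ``location`` and ``feature_id`` when present (the
    simulator writes them)."""
    raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    n = min(raw.shape[1], 6)
    names = ["chrom", "start", "end", "gene_id", "location", "feature_id"][:n]
    df = _read_bed_frame(path, max(n, 4), names[: max(n, 4)])
    if df["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    return df[names]


def read_bedgraph(path: PathLike) -> pd.DataFrame:
    """Read a bedgraph track (chrom, start, end, score)."""
    df = _read_bed_frame(path, 4, ["chrom", "start", "end", "score"])
    df["score"] = df["score"].astype(float)
    return df


def compartment_labels(track: pd.DataFrame, a_positive: bool = True) -> pd.DataFrame:
    """Map a compartment eigenvector bedgraph to A/B interval labels by the
    sign of the score (positive = A when ``a_positive``, the usual eigenvector
    convention; flip if the downloaded track uses the opposite sign).
    Zero-score intervals are unlabelled and dropped."""
    track = track[track["score"] != 0].copy()
    pos_label, neg_label = ("A", "B") if a_positive else ("B", "A")
    track["compartment"] = np.where(track["score"] > 0, pos_label, neg_label)
    return track[["chrom", "start", "end", "compartment"]]


def read_spikein_table(path: PathLike) -> list[SpikeInWell]:
    """Read a spike-in TSV: columns ``species_id, input_copies`` then one
    column of detected UMIs per well."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "species_id" or df.columns[1] != "input_copies":
        raise ValueError(
            "spike-in table must start with columns species_id, input_copies"
        )
    df = df.set_index("species_id")
    inputs = df["input_copies"]
    wells = []
    for well_id in df.columns[1:]:
        wells.append(
            SpikeInWell(
                well_id=str(well_id),
                input_copies=inputs,
                detected_umis=df[well_id],
            )
        )
    if not wells:
        raise ValueError("spike-in table contains no well columns")
    return wells


def write_spikein_table(wells: Sequence[SpikeInWell], path: PathLike) -> None:
    data = {"input_copies": wells[0].input_copies}
    for w in wells:
        data[w.well_id] = w.detected_umis
    df = pd.DataFrame(data)
    df.index.name = "species_id"
    df.to_csv(path, sep="\t")


def write_manifest(path: PathLike, config: dict, seed: Optional[int]) -> None:
    """Write a JSON run manifest: configuration, its hash, the master seed
    and the package version — enough to regenerate the run bit-identically."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "burstkit_version": __version__,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
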