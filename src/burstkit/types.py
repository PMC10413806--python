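"""Core domain containers shared across the pipeline.

All genomic intervals are 0-based half-open (BED convention) and strand is
ignored throughout. Kinetic rates are expressed in units of the mRNA
degradation rate, which is fixed to 1 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "BurstParams",
    "UmiCountMatrix",
    "TadSet",
    "SpikeInWell",
]


@dataclass(frozen=True)
class BurstParams:
    """Two-state (telegraph) promoter model parameters.

    The promoter switches OFF -> ON at rate ``k_on`` and ON -> OFF at rate
    ``k_off``; mRNA is synthesised at rate ``k_syn`` only while ON and degrades
    at ``degradation_rate``. All rates are in units of the degradation rate,
    so ``degradation_rate`` is 1 unless explicitly overridden. At steady state
    the copy-number law is Poisson-Beta: Poisson(k_syn * b) with
    b ~ Beta(k_on, k_off).
    """

    k_on: float
    k_off: float
    k_syn: float
    degradation_rate: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k_on) and self.k_on > 0):
            raise ValueError(f"k_on must be positive and finite, got {self.k_on}")
        if not (np.isfinite(self.k_off) and self.k_off > 0):
            raise ValueError(f"k_off must be positive and finite, got {self.k_off}")
        if not (np.isfinite(self.k_syn) and self.k_syn >= 0):
            raise ValueError(f"k_syn must be non-negative and finite, got {self.k_syn}")
        if not (np.isfinite(self.degradation_rate) and self.degradation_rate > 0):
            raise ValueError(
                f"degradation_rate must be positive, got {self.degradation_rate}"
            )

    @property
    def mean(self) -> float:
        """Stationary mean copy number, k_syn * k_on / (k_on + k_off)."""
        return self.k_syn * self.k_on / (self.k_on + self.k_off)

    @property
    def variance(self) -> float:
        """Stationary variance: mean + k_syn^2 * Var(Beta(k_on, k_off))."""
        s = self.k_on + self.k_off
        return self.mean + self.k_syn**2 * self.k_on * self.k_off / (s**2 * (s + 1))

    @property
    def burst_frequency(self) -> float:
        return self.k_on

    @property
    def burst_size_conventional(self) -> float:
        """Mean transcripts per burst under the conventional definition k_syn/k_off."""
        return self.k_syn / self.k_off

    @property
    def burst_size_alt(self) -> float:
        """Alternative burst-size ratio k_syn/k_on, reported alongside the
        conventional one because both conventions circulate in the literature."""
        return self.k_syn / self.k_on


class UmiCountMatrix:
    """Non-negative integer genes x cells UMI count matrix.

    Parameters
    ----------
    counts
        DataFrame with gene identifiers as the index and cell identifiers as
        columns; entries must be non-negative integers.
    cell_qc
        Optional per-cell QC metrics (index = cell ids) with columns
        ``exon_reads`` and ``exon_mapping_rate``.
    """

    def __init__(self, counts: pd.DataFrame, cell_qc: Optional[pd.DataFrame] = None):
        counts = pd.DataFrame(counts)
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if counts.columns.has_duplicates:
            dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate cell ids: {dupes[:5]}")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                bad = np.argwhere(values != np.round(values))[0]
                raise ValueError(
                    "non-integer count at gene "
                    f"{counts.index[bad[0]]!r}, cell {counts.columns[bad[1]]!r}"
                )
            counts = counts.round().astype(np.int64)
            values = counts.to_numpy()
        if values.size and values.min() < 0:
            bad = np.argwhere(values < 0)[0]
            raise ValueError(
                "negative count at gene "
                f"{counts.index[bad[0]]!r}, cell {counts.columns[bad[1]]!r}"
            )
        self.counts = counts.astype(np.int64)
        if cell_qc is not None:
            cell_qc = pd.DataFrame(cell_qc)
            missing = self.counts.columns.difference(cell_qc.index)
            if len(missing):
                raise ValueError(f"cell_qc missing cells: {list(missing[:5])}")
            cell_qc = cell_qc.loc[self.counts.columns]
        self.cell_qc = cell_qc

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def cell_totals(self) -> pd.Series:
        """Total UMIs per cell."""
        return self.counts.sum(axis=0)

    def subset_cells(self, cell_ids) -> "UmiCountMatrix":
        qc = self.cell_qc.loc[cell_ids] if self.cell_qc is not None else None
        return UmiCountMatrix(self.counts[list(cell_ids)], qc)

    def subset_genes(self, gene_ids) -> "UmiCountMatrix":
        return UmiCountMatrix(self.counts.loc[list(gene_ids)], self.cell_qc)

    def __eq__(self, other) -> bool:
        if not isinstance(other, UmiCountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return f"UmiCountMatrix({self.n_genes} genes x {self.n_cells} cells)"


class TadSet:
    """Ordered, non-overlapping TAD intervals per chromosome (0-based half-open)."""

    COLUMNS = ("chrom", "start", "end")

    def __init__(self, intervals: pd.DataFrame):
        df = pd.DataFrame(intervals).copy()
        for col in self.COLUMNS:
            if col not in df.columns:
                raise ValueError(f"TadSet requires column {col!r}")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(f"empty or inverted TAD interval at {bad.to_dict()}")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        for chrom, grp in df.groupby("chrom", sort=False):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping TADs on chromosome {chrom!r}")
        if "tad_id" not in df.columns:
            df["tad_id"] = [f"tad_{i}" for i in range(len(df))]
        self.intervals = df

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def chroms(self) -> list:
        return list(dict.fromkeys(self.intervals["chrom"]))

    def __repr__(self) -> str:
        return f"TadSet({len(self)} TADs on {len(self.chroms)} chromosome(s))"


@dataclass
class SpikeInWell:
    """One well of a spike-in experiment: known input copies and detected UMIs.

    ``input_copies`` and ``detected_umis`` are per-species Series sharing the
    same index. The simulator never emits detected > input, but the type does
    not enforce it (real UMI collisions/errors can violate it).
    """

    well_id: str
    input_copies: pd.Series
    detected_umis: pd.Series

    def __post_init__(self) -> None:
        self.input_copies = pd.Series(self.input_copies)
        self.detected_umis = pd.Series(self.detected_umis)
        if not self.input_copies.index.equals(self.detected_umis.index):
            raise ValueError("input_copies and detected_umis must share species index")
        if (self.input_copies < 0).any():
            raise ValueError("input copies must be non-negative")
        if (self.detected_umis < 0).any():
            raise ValueError("detected UMIs must be non-negative")
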