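"""Binomial technical-noise model and spike-in calibration statistics.

With a single-molecule capture efficiency p, a gene present at n copies is
observed as X ~ Binomial(n, p). The coefficient of variation of X,
CV = sqrt((1 - p) / (n p)), depends on the data only through the mean observed
level n*p, giving a theoretical technical-noise floor as a function of mean
expression. Spike-in wells with known input copy numbers estimate p directly
(mean detected / input) and yield the per-species detection-rate curve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import SpikeInWell, UmiCountMatrix

__all__ = [
    "technical_cv",
    "gene_noise_profile",
    "capture_efficiency",
    "detection_rate",
    "DetectionRateSeries",
    "input_response_fit",
    "InputResponseFit",
]

logger = logging.getLogger(__name__)


def technical_cv(mean_observed, p: float):
    """Theoretical technical CV of binomial capture at mean observed level np.

    CV = sqrt((1 - p) / mean_observed), where ``mean_observed`` is the average
    detected copy number n*p. Strictly decreasing in both arguments; zero at
    p = 1 (perfect capture). Accepts scalars or arrays.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p}")
    mean_observed = np.asarray(mean_observed, dtype=float)
    if np.any(mean_observed <= 0):
        raise ValueError("technical CV is undefined at zero mean expression")
    out = np.sqrt((1.0 - p) / mean_observed)
    return float(out) if out.ndim == 0 else out


def gene_noise_profile(
    matrix: UmiCountMatrix, p_assumed: float = 0.35, ddof: int = 1
) -> pd.DataFrame:
    """Per-gene expression-noise profile: observed mean, observed CV, and the
    theoretical technical CV at the assumed capture efficiency.

    Genes with zero mean are dropped (logged). The observed CV uses the sample
    standard deviation (ddof=1) by default.
    """
    if matrix.n_genes == 0 or matrix.n_cells == 0:
        raise ValueError("count matrix is empty")
    values = matrix.counts.to_numpy(dtype=float)
    means = values.mean(axis=1)
    keep = means > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("gene_noise_profile: dropped %d zero-mean genes", n_dropped)
    sd = values[keep].std(axis=1, ddof=ddof)
    means_kept = means[keep]
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids[keep],
            "mean": means_kept,
            "cv": sd / means_kept,
            "technical_cv": technical_cv(means_kept, p_assumed),
        }
    ).reset_index(drop=True)


def _well_table(wells: Sequence[SpikeInWell]) -> tuple[pd.Series, pd.DataFrame]:
    """(input copies per species, species x wells detected-UMI table)."""
    if not wells:
        raise ValueError("no spike-in wells provided")
    inputs = wells[0].input_copies
    detected = {}
    for w in wells:
        if not w.input_copies.equals(inputs):
            raise ValueError(f"well {w.well_id!r} has inconsistent input copies")
        detected[w.well_id] = w.detected_umis
    return inputs, pd.DataFrame(detected)


def capture_efficiency(wells: Sequence[SpikeInWell]) -> pd.Series:
    """Per-species capture efficiency: mean detected UMIs across wells divided
    by the known input copy number. Species with zero input are excluded with
    a warning."""
    inputs, detected = _well_table(wells)
    usable = inputs > 0
    if (~usable).any():
        warnings.warn(
            f"excluding {int((~usable).sum())} zero-input species from "
            "capture-efficiency estimation",
            stacklevel=2,
        )
    return detected.loc[usable].mean(axis=1) / inputs[usable]


@dataclass
class DetectionRateSeries:
    """Detection-rate curve over spike-in species ordered by input copies."""

    species: pd.Index
    input_copies: np.ndarray
    rate: np.ndarray  # fraction of wells with >= threshold detected UMIs
    smoothed: np.ndarray  # sliding mean; length = len(rate) - window + 1 at step 1
    window: int
    step: int


def detection_rate(
    wells: Sequence[SpikeInWell],
    window: int = 9,
    step: int = 1,
    detected_threshold: int = 1,
) -> DetectionRateSeries:
    """Per-species detection rate with sliding-mean smoothing.

    A species is "detected" in a well when its UMI count is at least
    ``detected_threshold`` (default 1). Species are ordered by ascending input
    copy number; the smoothed series is the sliding mean of the raw rates with
    the given window and step.
    """
    inputs, detected = _well_table(wells)
    order = np.argsort(inputs.to_numpy(), kind="stable")
    inputs = inputs.iloc[order]
    detected = detected.iloc[order]
    rate = (detected.to_numpy() >= detected_threshold).mean(axis=1)
    n = len(rate)
    if window < 1 or window > n:
        raise ValueError(f"window must be in [1, {n}], got {window}")
    if step < 1:
        raise ValueError("step must be >= 1")
    starts = range(0, n - window + 1, step)
    smoothed = np.array([rate[s : s + window].mean() for s in starts])
    return DetectionRateSeries(
        species=inputs.index,
        input_copies=inputs.to_numpy(dtype=float),
        rate=rate,
        smoothed=smoothed,
        window=window,
        step=step,
    )


@dataclass
class InputResponseFit:
    """OLS fit of detected response vs input copy number (log10-log10 by
    default), as used to assess detection linearity across a spike-in ladder."""

    slope: float
    intercept: float
    r_squared: float
    n_species: int
    log_scale: bool


def input_response_fit(
    wells: Sequence[SpikeInWell], log_scale: bool = True
) -> InputResponseFit:
    """Linear regression of mean detected UMIs on input copies across species.

    On the default log10-log10 scale, species with zero mean detection are
    excluded (no pseudocount); at least 3 usable species are required.
    """
    inputs, detected = _well_table(wells)
    mean_detected = detected.mean(axis=1)
    usable = inputs > 0
    if log_scale:
        usable &= mean_detected > 0
    x = inputs[usable].to_numpy(dtype=float)
    y = mean_detected[usable].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError(
            f"need >= 3 usable species for the input-response fit, got {len(x)}"
        )
    if log_scale:
        x, y = np.log10(x), np.log10(y)
    res = stats.linregress(x, y)
    return InputResponseFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_species=len(x),
        log_scale=log_scale,
    )
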