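"""Synthetic single-cell data generator.

Emulates the statistical structure the downstream analysis assumes:

* per-gene mRNA copy numbers drawn from the stationary Poisson-Beta law of the
  two-state telegraph model (``sample_poisson_beta``), with an exact Gillespie
  simulation of the same model retained purely as a distributional oracle
  (``simulate_gillespie``);
* binomial capture thinning at a fixed single-molecule efficiency
  (``apply_capture``);
* a toy genome of ordered, abutting TADs with genes placed fully inside TAD
  interiors and fully inside 5%-flank boundary regions (``simulate_genome``);
* optional planted effects: within-TAD sharing of the burst frequency k_on
  (lognormal jitter around a TAD-level value) and cross-boundary co-expression
  induced by a shared per-cell lognormal scaling of k_syn;
* spike-in wells with known input copy numbers (``simulate_spikein_wells``).

Every sampler takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import BurstParams, SpikeInWell, TadSet, UmiCountMatrix

__all__ = [
    "sample_poisson_beta",
    "simulate_gillespie",
    "sample_stationary_gillespie",
    "apply_capture",
    "simulate_genome",
    "DatasetConfig",
    "SyntheticTruth",
    "simulate_dataset",
    "simulate_spikein_wells",
]


def sample_poisson_beta(
    params: BurstParams, n_cells: int, seed: Optional[int] = None, rng=None
) -> np.ndarray:
    """Draw stationary mRNA copy numbers from the two-state model.

    Uses the Beta-mixture representation of the stationary law: each cell's
    count is Poisson(k_syn * b) with b ~ Beta(k_on, k_off).

    Parameters
    ----------
    params
        Telegraph-model rates (degradation units).
    n_cells
        Number of independent cells to draw.
    seed, rng
        Either an integer seed or an existing ``numpy.random.Generator``.
    """
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    if params.k_syn == 0:
        return np.zeros(n_cells, dtype=np.int64)
    b = rng.beta(params.k_on, params.k_off, size=n_cells)
    return rng.poisson(params.k_syn * b).astype(np.int64)


def default_burn_in(params: BurstParams) -> float:
    """Ten mean promoter cycles plus ten degradation times; long enough for
    the copy number to forget the (empty) initial condition within test
    tolerance."""
    return 10.0 * (1.0 / params.k_on + 1.0 / params.k_off) + 10.0 / params.degradation_rate


def sample_stationary_gillespie(
    params: BurstParams,
    n_draws: int,
    t_end: Optional[float] = None,
    burn_in: Optional[float] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Exact stochastic simulation of the telegraph model, vectorised across
    independent trajectories; returns the copy number of each at ``t_end``.

    The promoter starts in its stationary state, the mRNA count at zero, so
    ``t_end`` must exceed a burn-in of several dwell and degradation times for
    the returned counts to be (approximately) stationary samples.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if burn_in is None:
        burn_in = default_burn_in(params)
    if t_end is None:
        t_end = 1.25 * burn_in
    if not (t_end > 0):
        raise ValueError(f"t_end must be positive, got {t_end}")
    if not (t_end > burn_in >= 0):
        raise ValueError(f"need t_end > burn_in >= 0, got t_end={t_end}, burn_in={burn_in}")

    rng = np.random.default_rng(seed)
    k_on, k_off, k_syn, d = params.k_on, params.k_off, params.k_syn, params.degradation_rate

    on = rng.random(n_draws) < k_on / (k_on + k_off)
    m = np.zeros(n_draws, dtype=np.int64)
    t = np.zeros(n_draws)
    active = np.ones(n_draws, dtype=bool)

    # Each loop iteration advances every still-running trajectory by one event.
    while active.any():
        r_switch = np.where(on, k_off, k_on)
        r_syn = np.where(on, k_syn, 0.0)
        r_deg = d * m
        total = r_switch + r_syn + r_deg
        dt = rng.exponential(1.0, size=n_draws) / total
        u = rng.random(n_draws) * total

        t_next = t + dt
        fire = active & (t_next <= t_end)
        t = np.where(active, np.minimum(t_next, t_end), t)
        active = active & (t_next <= t_end)

        do_switch = fire & (u < r_switch)
        do_syn = fire & ~do_switch & (u < r_switch + r_syn)
        do_deg = fire & ~do_switch & ~do_syn
        on = np.where(do_switch, ~on, on)
        m = m + do_syn.astype(np.int64) - do_deg.astype(np.int64)
    return m


def simulate_gillespie(
    params: BurstParams,
    t_end: Optional[float] = None,
    burn_in: Optional[float] = None,
    seed: Optional[int] = None,
) -> int:
    """One trajectory of the exact telegraph-model simulation; the mRNA copy
    number at ``t_end``. Repeated calls with different seeds sample the
    stationary distribution (given sufficient burn-in)."""
    return int(
        sample_stationary_gillespie(params, 1, t_end=t_end, burn_in=burn_in, seed=seed)[0]
    )


def apply_capture(counts, p: float, seed: Optional[int] = None, rng=None):
    """Binomial capture thinning: each molecule is detected independently with
    probability ``p``, so an entry n becomes Binomial(n, p).

    Accepts an integer array or DataFrame; returns the same type, entrywise
    bounded by the input.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"capture probability must be in [0, 1], got {p}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    is_frame = isinstance(counts, pd.DataFrame)
    values = counts.to_numpy() if is_frame else np.asarray(counts)
    if values.size and values.min() < 0:
        raise ValueError("counts must be non-negative")
    thinned = rng.binomial(values.astype(np.int64), p)
    if is_frame:
        return pd.DataFrame(thinned, index=counts.index, columns=counts.columns)
    return thinned


# ---------------------------------------------------------------------------
# Toy genome
# ---------------------------------------------------------------------------


def _place_genes(region_start: int, region_end: int, n: int, gene_length: int, rng) -> list:
    """Place n non-overlapping genes of fixed length fully inside a region by
    slotting the region into n equal bins and jittering within each bin."""
    span = region_end - region_start
    if n * gene_length > span:
        raise ValueError(
            f"cannot pack {n} genes of {gene_length} bp into a {span} bp region"
        )
    slot = span / n
    starts = []
    for i in range(n):
        lo = region_start + int(np.floor(i * slot))
        hi = region_start + int(np.floor((i + 1) * slot)) - gene_length
        starts.append(int(rng.integers(lo, max(lo, hi) + 1)))
    return starts


def simulate_genome(
    n_tads: int,
    genes_per_tad: int,
    boundary_genes_per_boundary: int = 0,
    tad_length: int = 200_000,
    gene_length: int = 2_000,
    boundary_fraction: float = 0.05,
    chrom: str = "chrS",
    seed: Optional[int] = None,
):
    """Build a toy single-chromosome genome of abutting TADs.

    Within-TAD genes are placed fully inside the TAD interior (excluding the
    boundary flanks, so TAD and boundary gene sets are disjoint by
    construction); boundary genes are placed fully inside each
    ``boundary_fraction``-flank boundary region between adjacent TADs.

    Returns
    -------
    (TadSet, DataFrame)
        The TAD intervals and a gene annotation table with columns
        ``gene_id, chrom, start, end, location, feature_id`` where location is
        ``tad`` or ``boundary``. Coordinates are 0-based half-open.
    """
    if n_tads < 1 or genes_per_tad < 1 or boundary_genes_per_boundary < 0:
        raise ValueError("n_tads and genes_per_tad must be >= 1; boundary genes >= 0")
    if not (0.0 < boundary_fraction < 0.5):
        raise ValueError(f"boundary_fraction must be in (0, 0.5), got {boundary_fraction}")
    rng = np.random.default_rng(seed)
    flank = int(round(boundary_fraction * tad_length))
    if flank < 1:
        raise ValueError("tad_length too small for the boundary fraction")

    tads = pd.DataFrame(
        {
            "chrom": chrom,
            "start": [i * tad_length for i in range(n_tads)],
            "end": [(i + 1) * tad_length for i in range(n_tads)],
            "tad_id": [f"tad_{i}" for i in range(n_tads)],
        }
    )

    records = []
    for i in range(n_tads):
        interior = (i * tad_length + flank, (i + 1) * tad_length - flank)
        for j, start in enumerate(
            _place_genes(interior[0], interior[1], genes_per_tad, gene_length, rng)
        ):
            records.append(
                {
                    "gene_id": f"g_t{i}_{j}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + gene_length,
                    "location": "tad",
                    "feature_id": f"tad_{i}",
                }
            )
    if boundary_genes_per_boundary > 0:
        for i in range(n_tads - 1):
            breakpoint_ = (i + 1) * tad_length
            region = (breakpoint_ - flank, breakpoint_ + flank)
            for j, start in enumerate(
                _place_genes(
                    region[0], region[1], boundary_genes_per_boundary, gene_length, rng
                )
            ):
                records.append(
                    {
                        "gene_id": f"g_b{i}_{j}",
                        "chrom": chrom,
                        "start": start,
                        "end": start + gene_length,
                        "location": "boundary",
                        "feature_id": f"boundary_{i}",
                    }
                )
    genes = pd.DataFrame.from_records(records)
    genes = genes.sort_values("start", kind="mergesort").reset_index(drop=True)
    return TadSet(tads), genes


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------


@dataclass
class DatasetConfig:
    """Per-gene parameter sampling ranges and planted effects.

    Parameters are drawn log-uniformly from the stated ranges, which span
    published mammalian bursting estimates (burst frequencies well below the
    degradation rate for most genes, k_off typically exceeding k_on).

    ``share_tad_kon`` plants within-TAD burst-frequency sharing: all genes of
    a TAD take a common TAD-level k_on multiplied by lognormal jitter with
    sigma ``kon_jitter_sigma`` (0 => identical k_on within each TAD).
    ``boundary_coexpr_sigma`` plants cross-boundary co-expression: genes in the
    same boundary region share a per-cell lognormal factor (sigma given,
    unit mean) scaling k_syn, which induces positive rank correlation without
    materially changing marginal burst parameters.
    """

    k_on_range: tuple = (0.05, 5.0)
    k_off_range: tuple = (0.5, 20.0)
    k_syn_range: tuple = (5.0, 100.0)
    share_tad_kon: bool = False
    kon_jitter_sigma: float = 0.0
    boundary_coexpr_sigma: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_on_range", "k_off_range", "k_syn_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < low <= high, got ({lo}, {hi})")
        if self.kon_jitter_sigma < 0:
            raise ValueError("kon_jitter_sigma must be >= 0")
        if self.boundary_coexpr_sigma < 0:
            raise ValueError("boundary_coexpr_sigma must be >= 0")
        if not self.share_tad_kon and self.kon_jitter_sigma > 0:
            raise ValueError("kon_jitter_sigma set but share_tad_kon is False")

    @classmethod
    def well_expressed(cls, **overrides) -> "DatasetConfig":
        """Parameter regime emulating the population of genes that survive
        burst-fit filtering in real single-cell data.

        TAD-contextual analyses only ever see genes with reliably estimated
        burst parameters, which in practice means adequately expressed genes:
        lowly expressed genes carry order-of-magnitude uncertainty on k_on
        and are removed by the fit filters, so a genome built to study group
        statistics of *kept* genes should generate expression in the
        identifiable range (a few UMIs per cell after capture). The default
        (wider) ranges remain appropriate for parameter-recovery studies that
        probe the filters themselves.
        """
        defaults = dict(
            k_on_range=(0.2, 2.0), k_off_range=(1.0, 10.0), k_syn_range=(20.0, 100.0)
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SyntheticTruth:
    """Complete ground truth for a simulated dataset: per-gene telegraph
    parameters with genomic membership, the capture efficiency used for
    thinning, the planted-effect configuration, and the master seed (so the
    dataset can be regenerated bit-identically)."""

    params: pd.DataFrame  # gene_id, k_on, k_off, k_syn, location, feature_id
    p_capture: float
    config: DatasetConfig
    seed: Optional[int]

    def to_manifest(self) -> dict:
        return {
            "p_capture": self.p_capture,
            "config": asdict(self.config),
            "seed": self.seed,
            "n_genes": int(len(self.params)),
        }


def _loguniform(rng, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def simulate_dataset(
    genome,
    config: DatasetConfig,
    n_cells: int = 150,
    p_capture: float = 0.35,
    seed: Optional[int] = None,
) -> tuple[UmiCountMatrix, SyntheticTruth]:
    """Simulate a UMI count matrix over a toy genome with full ground truth.

    Parameters
    ----------
    genome
        ``(TadSet, gene table)`` pair as returned by :func:`simulate_genome`.
    config
        Parameter ranges and planted effects; with ``share_tad_kon=False`` and
        ``boundary_coexpr_sigma=0`` the dataset is the exchangeable null.
    n_cells
        Cells to simulate.
    p_capture
        Binomial capture efficiency applied to the true molecule counts.

    Returns the observed (thinned) count matrix and a :class:`SyntheticTruth`.
    """
    if not (0.0 <= p_capture <= 1.0):
        raise ValueError(f"p_capture must be in [0, 1], got {p_capture}")
    _, genes = genome
    rng = np.random.default_rng(seed)
    n_genes = len(genes)

    k_off = _loguniform(rng, *config.k_off_range, size=n_genes)
    k_syn = _loguniform(rng, *config.k_syn_range, size=n_genes)
    if config.share_tad_kon:
        k_on = np.empty(n_genes)
        is_tad = (genes["location"] == "tad").to_numpy()
        # TAD-level k_on in stable feature order, then per-gene jitter.
        for fid in pd.unique(genes.loc[is_tad, "feature_id"]):
            idx = ((genes["feature_id"] == fid) & is_tad).to_numpy()
            tad_kon = _loguniform(rng, *config.k_on_range)
            jitter = (
                rng.lognormal(0.0, config.kon_jitter_sigma, size=idx.sum())
                if config.kon_jitter_sigma > 0
                else np.ones(idx.sum())
            )
            k_on[idx] = tad_kon * jitter
        n_other = int((~is_tad).sum())
        k_on[~is_tad] = _loguniform(rng, *config.k_on_range, size=n_other)
    else:
        k_on = _loguniform(rng, *config.k_on_range, size=n_genes)
    lo, hi = config.k_on_range
    np.clip(k_on, lo / 10, hi * 10, out=k_on)  # keep jittered values in a sane band

    # Shared per-cell lognormal factor per boundary region (unit mean).
    factors = {}
    if config.boundary_coexpr_sigma > 0:
        sig = config.boundary_coexpr_sigma
        for fid in pd.unique(genes.loc[genes["location"] == "boundary", "feature_id"]):
            factors[fid] = rng.lognormal(-0.5 * sig**2, sig, size=n_cells)

    true_counts = np.empty((n_genes, n_cells), dtype=np.int64)
    for i in range(n_genes):
        b = rng.beta(k_on[i], k_off[i], size=n_cells)
        lam = k_syn[i] * b
        fid = genes["feature_id"].iloc[i]
        if fid in factors:
            lam = lam * factors[fid]
        true_counts[i] = rng.poisson(lam)

    observed = apply_capture(true_counts, p_capture, rng=rng)
    counts = pd.DataFrame(
        observed,
        index=pd.Index(genes["gene_id"], name="gene_id"),
        columns=[f"cell_{j}" for j in range(n_cells)],
    )
    params = genes[["gene_id", "location", "feature_id"]].copy()
    params["k_on"] = k_on
    params["k_off"] = k_off
    params["k_syn"] = k_syn
    truth = SyntheticTruth(params=params, p_capture=p_capture, config=config, seed=seed)
    return UmiCountMatrix(counts), truth


def simulate_spikein_wells(
    mix, efficiency: float, n_wells: int, seed: Optional[int] = None
) -> list[SpikeInWell]:
    """Simulate spike-in wells: each species' detected UMI count per well is
    Binomial(input copies, efficiency).

    ``mix`` maps species id -> input copy number (dict or Series).
    """
    if not (0.0 <= efficiency <= 1.0):
        raise ValueError(f"efficiency must be in [0, 1], got {efficiency}")
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    mix = pd.Series(mix)
    if (mix < 0).any():
        raise ValueError("input copies must be non-negative")
    rng = np.random.default_rng(seed)
    inputs = mix.round().astype(np.int64)
    wells = []
    for w in range(n_wells):
        detected = pd.Series(
            rng.binomial(inputs.to_numpy(), efficiency), index=mix.index
        )
        wells.append(
            SpikeInWell(well_id=f"well_{w}", input_copies=inputs, detected_umis=detected)
        )
    return wells
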