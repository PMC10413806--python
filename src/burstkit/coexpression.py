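"""Temporal coordination of transcription between gene pairs.

Per-cell transcript levels are normalised by the cell's total UMI count (to
remove global depth / residual extrinsic variation), genes averaging below 2
raw transcripts per cell are excluded, and Spearman's rank correlation
coefficient (SCC) is computed across cells for every unordered gene pair
within a TAD, within a boundary region, and for a random control drawn from
the whole transcriptome. Context-wise SCC distributions are compared by
two-sided two-sample Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .types import UmiCountMatrix

__all__ = [
    "normalize_by_total",
    "filter_low_expression",
    "enumerate_pairs",
    "pair_scc",
    "compare_scc_distributions",
]

logger = logging.getLogger(__name__)

CONTEXTS = ("same_tad", "same_boundary", "random_control")


def normalize_by_total(matrix: UmiCountMatrix) -> pd.DataFrame:
    """Divide each cell's counts by its total UMI count (fraction scale).

    Column sums of the result are exactly 1. Cells with zero total are an
    error (they carry no expression information and make the fraction
    undefined). Ranks, and hence Spearman correlations, are unaffected by the
    overall scale.
    """
    totals = matrix.cell_totals()
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"cells with zero total UMIs: {list(zero.index[:5])}")
    return matrix.counts / totals


def filter_low_expression(matrix: UmiCountMatrix, threshold: float = 2.0) -> pd.Index:
    """Gene ids whose mean raw count across cells is at least ``threshold``
    (genes strictly below are excluded as too lowly expressed for rank
    correlations to be meaningful). Operates on raw counts, not normalised
    fractions."""
    means = matrix.counts.mean(axis=1)
    kept = matrix.gene_ids[means >= threshold]
    if len(kept) == 0:
        raise ValueError(
            f"no genes reach the mean-expression threshold of {threshold} "
            "transcripts per cell"
        )
    return kept


def _feature_pairs(membership: pd.Series, kept: set) -> list[tuple]:
    pairs = []
    by_feature: dict = {}
    for gene_id, fid in membership.items():
        if fid is None or (isinstance(fid, float) and np.isnan(fid)):
            continue
        if str(gene_id) in kept:
            by_feature.setdefault(fid, []).append(str(gene_id))
    for members in by_feature.values():
        pairs.extend(combinations(sorted(members), 2))
    return pairs


def enumerate_pairs(
    tad_membership: pd.Series,
    boundary_membership: Optional[pd.Series],
    kept_genes: Sequence[str],
    n_random: Union[int, str] = 10_000,
    seed: Optional[int] = None,
    exclude_same_feature_controls: bool = False,
) -> pd.DataFrame:
    """Enumerate unordered gene pairs by genomic context.

    ``same_tad`` and ``same_boundary`` pairs are all pairs of kept genes
    sharing a TAD (respectively boundary region) with at least two kept
    genes. The ``random_control`` context draws ``n_random`` unordered pairs
    uniformly from the kept genes regardless of location (pass
    ``n_random="exhaustive"`` for all pairs); controls landing in the same
    feature are kept unless ``exclude_same_feature_controls`` is set.

    Returns a DataFrame with columns ``gene_a, gene_b, context``.
    """
    kept = set(map(str, kept_genes))
    records = []
    for gene_a, gene_b in _feature_pairs(tad_membership, kept):
        records.append((gene_a, gene_b, "same_tad"))
    if boundary_membership is not None:
        for gene_a, gene_b in _feature_pairs(boundary_membership, kept):
            records.append((gene_a, gene_b, "same_boundary"))
    if not records:
        warnings.warn("no feature contains two or more kept genes", stacklevel=2)

    same_feature = {(a, b) for a, b, _ in records}
    genes_sorted = sorted(kept)
    n = len(genes_sorted)
    all_pairs_n = n * (n - 1) // 2
    if n_random == "exhaustive":
        controls = [
            (a, b)
            for a, b in combinations(genes_sorted, 2)
            if not (exclude_same_feature_controls and (a, b) in same_feature)
        ]
    else:
        if n < 2:
            raise ValueError("need >= 2 kept genes for control pairs")
        rng = np.random.default_rng(seed)
        chosen = set()
        controls = []
        # Rejection sampling of distinct unordered pairs.
        target = min(int(n_random), all_pairs_n)
        while len(controls) < target:
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            a, b = sorted((genes_sorted[i], genes_sorted[j]))
            if (a, b) in chosen:
                continue
            if exclude_same_feature_controls and (a, b) in same_feature:
                continue
            chosen.add((a, b))
            controls.append((a, b))
    records.extend((a, b, "random_control") for a, b in controls)
    return pd.DataFrame(records, columns=["gene_a", "gene_b", "context"])


def pair_scc(normalized: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation across cells for each gene pair.

    ``normalized`` is a genes x cells table (typically from
    :func:`normalize_by_total`). Ties receive midranks. Pairs involving a
    zero-variance gene have no defined rank correlation and are dropped with
    a log record. Returns the pair table with an ``scc`` column.
    """
    genes_needed = pd.Index(pairs["gene_a"]).union(pairs["gene_b"]).unique()
    missing = genes_needed.difference(normalized.index)
    if len(missing):
        raise KeyError(f"genes absent from the matrix: {list(missing[:5])}")
    sub = normalized.loc[genes_needed]
    ranks = np.apply_along_axis(stats.rankdata, 1, sub.to_numpy(dtype=float))
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    pos = {g: i for i, g in enumerate(sub.index)}

    ia = pairs["gene_a"].map(pos).to_numpy()
    ib = pairs["gene_b"].map(pos).to_numpy()
    valid = (norms[ia] > 0) & (norms[ib] > 0)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("pair_scc: dropped %d pairs with a zero-variance gene", n_dropped)
    num = (ranks[ia[valid]] * ranks[ib[valid]]).sum(axis=1)
    scc = num / (norms[ia[valid]] * norms[ib[valid]])
    out = pairs.loc[valid].copy()
    out["scc"] = scc
    return out.reset_index(drop=True)


def compare_scc_distributions(pair_scc_table: pd.DataFrame) -> dict:
    """Two-sided two-sample KS comparisons of SCC distributions between
    contexts: same_tad vs control, same_boundary vs control, and same_tad vs
    same_boundary (those present). Every compared context needs >= 2 values."""
    groups = {
        ctx: grp["scc"].to_numpy()
        for ctx, grp in pair_scc_table.groupby("context", sort=False)
    }
    comparisons = [
        ("same_tad", "random_control"),
        ("same_boundary", "random_control"),
        ("same_tad", "same_boundary"),
    ]
    out = {}
    for a, b in comparisons:
        if a not in groups or b not in groups:
            continue
        if len(groups[a]) < 2 or len(groups[b]) < 2:
            raise ValueError(f"context {a!r} or {b!r} has fewer than 2 SCC values")
        ks = stats.ks_2samp(groups[a], groups[b], alternative="two-sided")
        out[(a, b)] = {
            "statistic": float(ks.statistic),
            "pvalue": float(ks.pvalue),
            "n_a": int(len(groups[a])),
            "n_b": int(len(groups[b])),
        }
    return out
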