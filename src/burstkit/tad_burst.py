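"""TAD-contextual burst-frequency variation analysis.

Genes fully contained in a TAD, in a 5%-flank boundary region between
adjacent TADs, or in an A/B compartment interval are grouped by that feature.
Within each eligible group the coefficient of variation (sample sd / mean) of
the per-gene burst frequencies summarises how similar bursting is inside the
feature; random gene groups of matched size give the exchangeable control.
Classes of group CVs are compared by a two-sided Wilcoxon rank-sum test and
by bootstrap distributions of the median CV; A/B compartment contrasts use
two-sided two-sample Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import TadSet

__all__ = [
    "build_boundaries",
    "assign_genes",
    "feature_memberships",
    "group_cv",
    "select_groups",
    "random_control_groups",
    "bootstrap_median_cv",
    "BootstrapCvResult",
    "compartment_contrast",
    "tad_cv_analysis",
    "TadCvAnalysis",
]


def build_boundaries(tads: TadSet, fraction: float = 0.05) -> pd.DataFrame:
    """Boundary regions from adjacent TAD pairs.

    For neighbours A, B on the same chromosome the boundary spans the last
    ``fraction`` of A through the first ``fraction`` of B:
    [A.end - fraction*len(A), B.start + fraction*len(B)). Non-abutting
    neighbours still define one boundary spanning the gap. A chromosome with
    a single TAD contributes no boundaries.
    """
    if not (0.0 < fraction < 0.5):
        raise ValueError(f"fraction must be in (0, 0.5), got {fraction}")
    records = []
    n = 0
    for chrom, grp in tads.intervals.groupby("chrom", sort=False):
        grp = grp.reset_index(drop=True)
        for i in range(len(grp) - 1):
            a, b = grp.iloc[i], grp.iloc[i + 1]
            start = int(round(a["end"] - fraction * (a["end"] - a["start"])))
            end = int(round(b["start"] + fraction * (b["end"] - b["start"])))
            records.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "left_tad": a["tad_id"],
                    "right_tad": b["tad_id"],
                    "boundary_id": f"boundary_{n}",
                }
            )
            n += 1
    return pd.DataFrame.from_records(
        records,
        columns=["chrom", "start", "end", "left_tad", "right_tad", "boundary_id"],
    )


def assign_genes(
    genes: pd.DataFrame, features: pd.DataFrame, feature_id_col: Optional[str] = None
) -> pd.Series:
    """Assign each gene to the feature interval that fully contains it.

    A gene is assigned only if feature.start <= gene.start and
    gene.end <= feature.end; genes straddling feature edges remain unassigned
    (NaN). Feature intervals must be non-overlapping per chromosome. Both
    inputs use 0-based half-open coordinates; a gene on a chromosome absent
    from the feature set is an error (coordinate-system mismatch guard).

    Returns a Series indexed by gene_id holding the feature id or NaN.
    """
    if isinstance(features, TadSet):
        features = features.intervals
    if feature_id_col is None:
        for cand in ("tad_id", "boundary_id", "feature_id", "compartment"):
            if cand in features.columns:
                feature_id_col = cand
                break
        else:
            raise ValueError("cannot infer the feature id column")
    missing = sorted(set(genes["chrom"]) - set(features["chrom"]))
    if missing:
        raise ValueError(f"gene chromosomes absent from the feature set: {missing}")

    out = pd.Series(
        [None] * len(genes), index=pd.Index(genes["gene_id"], name="gene_id"), dtype=object
    )
    for chrom, feat in features.groupby("chrom", sort=False):
        feat = feat.sort_values("start", kind="mergesort")
        starts = feat["start"].to_numpy()
        ends = feat["end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping feature intervals on {chrom!r}")
        sub = genes[genes["chrom"] == chrom]
        idx = np.searchsorted(starts, sub["start"].to_numpy(), side="right") - 1
        valid = idx >= 0
        contained = valid.copy()
        contained[valid] = sub["end"].to_numpy()[valid] <= ends[idx[valid]]
        ids = feat[feature_id_col].to_numpy()
        assigned = np.where(contained, ids[np.clip(idx, 0, None)], None)
        out.loc[sub["gene_id"].to_numpy()] = assigned
    return out


def feature_memberships(
    genes: pd.DataFrame, tads: TadSet, fraction: float = 0.05
) -> tuple[pd.Series, pd.DataFrame, Optional[pd.Series]]:
    """Gene-to-TAD and gene-to-boundary memberships with boundary priority.

    A gene fully contained in a boundary region is a boundary gene even when
    it also lies wholly inside one TAD's flank; "within-TAD" genes are those
    in the TAD but not in any boundary region. This makes the two classes a
    partition (the contrast between them is the point of the analysis).

    Returns (tad_membership, boundaries, boundary_membership); the last is
    None when the TAD set yields no boundaries.
    """
    tad_membership = assign_genes(genes, tads)
    boundaries = build_boundaries(tads, fraction)
    boundary_membership = None
    if len(boundaries):
        boundary_membership = assign_genes(genes, boundaries)
        tad_membership = tad_membership.copy()
        tad_membership[boundary_membership.apply(lambda v: v is not None)] = None
    return tad_membership, boundaries, boundary_membership


def group_cv(values, unbiased: bool = False) -> float:
    """Coefficient of variation of a group of burst frequencies: sample
    standard deviation (ddof=1) divided by the mean. Requires >= 2 values and
    a positive mean; invariant to rescaling all values by a common factor.

    With ``unbiased=True`` the standard small-sample correction
    CV * (1 + 1/(4n)) is applied. The sample CV is downward-biased, more so
    for small groups, so comparisons across classes whose group sizes differ
    by design (e.g. ~10-gene TADs vs ~5-gene boundaries) should use the
    corrected form.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError(f"group CV needs >= 2 values, got {values.size}")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("group CV undefined for non-positive mean")
    cv = float(values.std(ddof=1) / mean)
    if unbiased:
        cv *= 1.0 + 1.0 / (4.0 * values.size)
    return cv


def select_groups(
    membership: pd.Series,
    kept_genes: Sequence[str],
    min_genes: int,
) -> dict[str, list]:
    """Group kept genes by feature membership and keep only groups with at
    least ``min_genes`` members. ``membership`` maps gene_id -> feature id
    (NaN/None = unassigned)."""
    kept = set(map(str, kept_genes))
    groups: dict[str, list] = {}
    for gene_id, fid in membership.items():
        if fid is None or (isinstance(fid, float) and np.isnan(fid)):
            continue
        if str(gene_id) in kept:
            groups.setdefault(str(fid), []).append(str(gene_id))
    return {fid: members for fid, members in groups.items() if len(members) >= min_genes}


def random_control_groups(
    gene_ids: Sequence[str],
    group_size: int,
    n_groups: int,
    seed: Optional[int] = None,
) -> list[np.ndarray]:
    """Random gene groups as the exchangeable control: ``n_groups`` groups of
    ``group_size`` genes sampled uniformly without replacement within each
    group, independently across groups. The group size conventionally matches
    the median gene count of the eligible TAD (or boundary) groups."""
    gene_ids = np.asarray(list(gene_ids))
    if group_size > len(gene_ids):
        raise ValueError(
            f"group_size {group_size} exceeds the {len(gene_ids)} available genes"
        )
    if group_size < 2 or n_groups < 1:
        raise ValueError("need group_size >= 2 and n_groups >= 1")
    rng = np.random.default_rng(seed)
    return [rng.choice(gene_ids, size=group_size, replace=False) for _ in range(n_groups)]


@dataclass
class BootstrapCvResult:
    """Bootstrap distributions of the median group CV per class, plus
    two-sided Wilcoxon rank-sum comparisons computed both on the bootstrap
    medians and on the raw per-group CVs (the latter respects independence
    of the sampling units)."""

    medians: dict  # class -> np.ndarray of n_boot bootstrap medians
    raw_cvs: dict  # class -> np.ndarray of per-group CVs
    wilcoxon_raw: dict  # (class_a, class_b) -> p-value
    wilcoxon_bootstrap: dict  # (class_a, class_b) -> p-value
    n_boot: int


def bootstrap_median_cv(
    cvs_by_class: dict,
    n_boot: int = 10_000,
    seed: Optional[int] = None,
) -> BootstrapCvResult:
    """Bootstrap the median of the group CVs within each class.

    The resampling unit is the group (the CVs are exchangeable within a
    class): each bootstrap draws groups with replacement and records the
    median CV. Classes are compared pairwise by two-sided Wilcoxon rank-sum
    tests on the raw per-group CVs and, alongside, on the bootstrap medians.
    """
    rng = np.random.default_rng(seed)
    medians: dict = {}
    raw: dict = {}
    for cls, cvs in cvs_by_class.items():
        cvs = np.asarray(cvs, dtype=float)
        if cvs.size < 2:
            raise ValueError(f"class {cls!r} needs >= 2 groups, got {cvs.size}")
        raw[cls] = cvs
        idx = rng.integers(0, cvs.size, size=(n_boot, cvs.size))
        medians[cls] = np.median(cvs[idx], axis=1)
    wilcoxon_raw: dict = {}
    wilcoxon_boot: dict = {}
    classes = list(cvs_by_class)
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            wilcoxon_raw[(a, b)] = float(
                stats.mannwhitneyu(raw[a], raw[b], alternative="two-sided").pvalue
            )
            wilcoxon_boot[(a, b)] = float(
                stats.mannwhitneyu(
                    medians[a], medians[b], alternative="two-sided"
                ).pvalue
            )
    return BootstrapCvResult(
        medians=medians,
        raw_cvs=raw,
        wilcoxon_raw=wilcoxon_raw,
        wilcoxon_bootstrap=wilcoxon_boot,
        n_boot=n_boot,
    )


def compartment_contrast(
    fits: pd.DataFrame, compartments: pd.Series, min_genes: int = 2
) -> dict:
    """Two-sided two-sample KS comparison of burst frequency and burst size
    between genes in A and B compartments.

    ``fits`` is a fit table (see ``fits_to_frame``) with kept flags;
    ``compartments`` maps gene_id -> "A"/"B". Returns KS statistic and
    p-value per quantity plus per-compartment gene counts.
    """
    kept = fits[fits["kept"]].set_index("gene_id")
    labels = compartments.reindex(kept.index)
    a_genes = kept[labels == "A"]
    b_genes = kept[labels == "B"]
    if len(a_genes) < min_genes or len(b_genes) < min_genes:
        raise ValueError(
            f"need >= {min_genes} kept genes per compartment, got "
            f"A={len(a_genes)}, B={len(b_genes)}"
        )
    out = {"n_A": int(len(a_genes)), "n_B": int(len(b_genes))}
    for label, col in [
        ("burst_frequency", "burst_frequency"),
        ("burst_size", "burst_size_conventional"),
    ]:
        ks = stats.ks_2samp(a_genes[col], b_genes[col], alternative="two-sided")
        out[label] = {"statistic": float(ks.statistic), "pvalue": float(ks.pvalue)}
    return out


@dataclass
class TadCvAnalysis:
    """End-to-end TAD CV analysis output."""

    cvs: dict  # class -> per-group CVs ("tad", "boundary", "random_tad", "random_boundary")
    group_sizes: dict  # class -> median group size used / observed
    bootstrap: BootstrapCvResult


def tad_cv_analysis(
    genes: pd.DataFrame,
    tads: TadSet,
    fits: pd.DataFrame,
    min_tad_genes: int = 8,
    min_boundary_genes: int = 4,
    boundary_fraction: float = 0.05,
    n_random_groups: Optional[int] = None,
    n_boot: int = 10_000,
    seed: Optional[int] = None,
) -> TadCvAnalysis:
    """Full burst-frequency CV contrast: within-TAD vs cross-boundary vs
    random gene groups.

    Eligible groups are TADs with >= ``min_tad_genes`` kept genes and
    boundary regions with >= ``min_boundary_genes`` kept genes. Random
    control groups match each class in number (``n_random_groups`` overrides)
    and in size (median gene count of the eligible groups of that class).
    """
    kept_fits = fits[fits["kept"]].set_index("gene_id")
    kept_genes = list(kept_fits.index.astype(str))
    freqs = kept_fits["burst_frequency"]

    tad_membership, boundaries, boundary_membership = feature_memberships(
        genes, tads, boundary_fraction
    )
    cvs: dict = {}
    sizes: dict = {}
    rng = np.random.default_rng(seed)

    specs = [("tad", tad_membership, min_tad_genes)]
    if boundary_membership is not None:
        specs.append(("boundary", boundary_membership, min_boundary_genes))
    for cls, membership, min_genes in specs:
        groups = select_groups(membership, kept_genes, min_genes)
        if len(groups) < 2:
            raise ValueError(
                f"fewer than 2 eligible {cls} groups (min {min_genes} kept genes)"
            )
        cvs[cls] = np.array(
            [group_cv(freqs.loc[members], unbiased=True) for members in groups.values()]
        )
        med_size = int(np.median([len(m) for m in groups.values()]))
        sizes[cls] = med_size
        n_rand = n_random_groups if n_random_groups is not None else len(groups)
        rand_groups = random_control_groups(
            kept_genes, med_size, n_rand, seed=int(rng.integers(2**31))
        )
        cvs[f"random_{cls}"] = np.array(
            [group_cv(freqs.loc[g], unbiased=True) for g in rand_groups]
        )
    boot = bootstrap_median_cv(cvs, n_boot=n_boot, seed=int(rng.integers(2**31)))
    return TadCvAnalysis(cvs=cvs, group_sizes=sizes, bootstrap=boot)
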