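"""TAD geometry, gene-feature assignment, group CVs, bootstrap machinery and
compartment contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import burstkit as bk
from burstkit.types import TadSet


def tadset(rows):
    return TadSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


class TestBuildBoundaries:
    def test_five_percent_flanks_abutting(self):
        tads = tadset([("chr1", 0, 1000), ("chr1", 1000, 3000)])
        b = bk.build_boundaries(tads, 0.05)
        assert len(b) == 1
        assert (b.loc[0, "start"], b.loc[0, "end"]) == (950, 1100)

    def test_gap_between_tads_spanned(self):
        tads = tadset([("chr1", 0, 1000), ("chr1", 1200, 2200)])
        b = bk.build_boundaries(tads, 0.05)
        assert (b.loc[0, "start"], b.loc[0, "end"]) == (950, 1250)

    def test_single_tad_chromosome_yields_no_boundaries(self):
        b = bk.build_boundaries(tadset([("chr1", 0, 1000)]))
        assert len(b) == 0

    def test_half_fraction_rejected(self):
        tads = tadset([("chr1", 0, 1000), ("chr1", 1000, 2000)])
        with pytest.raises(ValueError):
            bk.build_boundaries(tads, 0.5)

    @given(frac=st.floats(0.01, 0.49))
    @settings(max_examples=25, deadline=None)
    def test_boundaries_stay_within_tad_midpoints(self, frac):
        tads = tadset([("chr1", 0, 1000), ("chr1", 1000, 4000), ("chr1", 4000, 5000)])
        b = bk.build_boundaries(tads, frac)
        iv = tads.intervals
        for _, row in b.iterrows():
            left = iv[iv["tad_id"] == row["left_tad"]].iloc[0]
            right = iv[iv["tad_id"] == row["right_tad"]].iloc[0]
            assert row["start"] >= (left["start"] + left["end"]) / 2 - 1
            assert row["end"] <= (right["start"] + right["end"]) / 2 + 1


class TestAssignGenes:
    GENES = pd.DataFrame(
        {
            "gene_id": ["full", "straddle", "in_boundary"],
            "chrom": ["chr1"] * 3,
            "start": [100, 950, 960],
            "end": [200, 1050, 1040],
        }
    )

    def test_containment_rule(self):
        tads = tadset([("chr1", 0, 1000), ("chr1", 1000, 2000)])
        assigned = bk.assign_genes(self.GENES, tads)
        assert assigned["full"] == "tad_0"
        assert assigned["straddle"] is None
        boundaries = bk.build_boundaries(tads, 0.05)  # [950, 1050)
        b_assigned = bk.assign_genes(
            pd.DataFrame(
                {"gene_id": ["g"], "chrom": ["chr1"], "start": [960], "end": [1040]}
            ),
            boundaries,
        )
        assert b_assigned["g"] == "boundary_0"

    def test_chromosome_mismatch_is_error(self):
        tads = tadset([("chr1", 0, 1000)])
        genes = pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["chrX"], "start": [10], "end": [20]}
        )
        with pytest.raises(ValueError, match="chrX"):
            bk.assign_genes(genes, tads)

    def test_tad_and_boundary_memberships_disjoint_on_synthetic_genome(self, toy_genome):
        """Pipeline-level membership partitions the synthetic genome: a gene
        inside a boundary region counts as a boundary gene, never as a
        within-TAD gene."""
        tads, genes = toy_genome
        in_tad, _, in_boundary = bk.feature_memberships(genes, tads, 0.05)
        both = [
            g
            for g in genes["gene_id"]
            if in_tad[g] is not None and in_boundary[g] is not None
        ]
        assert both == []
        # every simulated boundary gene is recovered as such
        planted = set(genes.loc[genes["location"] == "boundary", "gene_id"])
        recovered = {g for g in genes["gene_id"] if in_boundary[g] is not None}
        assert planted == recovered


class TestGroupCv:
    def test_constant_group(self):
        assert bk.group_cv([2, 2, 2]) == 0.0

    def test_hand_computed_value(self):
        assert bk.group_cv([1, 2, 3]) == pytest.approx(0.5)

    @given(
        values=st.lists(st.floats(0.1, 100), min_size=2, max_size=20),
        c=st.floats(0.01, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, values, c):
        assert bk.group_cv(np.array(values) * c) == pytest.approx(
            bk.group_cv(values), rel=1e-9
        )

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            bk.group_cv([1.0])


class TestSelectGroups:
    def test_threshold_application(self):
        membership = pd.Series(
            {f"g{i}": "tad_0" for i in range(7)} | {f"h{i}": "tad_1" for i in range(8)}
        )
        groups = bk.select_groups(membership, membership.index, min_genes=8)
        assert set(groups) == {"tad_1"}

    def test_boundary_minimum(self):
        membership = pd.Series({f"g{i}": "b_0" for i in range(4)})
        groups = bk.select_groups(membership, membership.index, min_genes=4)
        assert len(groups["b_0"]) == 4

    def test_unkept_genes_do_not_count(self):
        membership = pd.Series({f"g{i}": "tad_0" for i in range(10)})
        groups = bk.select_groups(membership, [f"g{i}" for i in range(5)], min_genes=8)
        assert groups == {}


class TestRandomControlGroups:
    def test_deterministic_given_seed(self):
        genes = [f"g{i}" for i in range(30)]
        a = bk.random_control_groups(genes, 5, 10, seed=3)
        b = bk.random_control_groups(genes, 5, 10, seed=3)
        assert all((x == y).all() for x, y in zip(a, b))

    def test_no_replacement_within_group(self):
        groups = bk.random_control_groups([f"g{i}" for i in range(10)], 10, 5, seed=0)
        for g in groups:
            assert len(set(g)) == 10

    def test_oversized_group_rejected(self):
        with pytest.raises(ValueError):
            bk.random_control_groups(["a", "b"], 3, 1, seed=0)

    def test_null_exchangeability_of_mean_cv(self):
        """Random groups drawn from the same pool as TAD groups have matching
        mean CVs under the exchangeable null."""
        rng = np.random.default_rng(4)
        freqs = pd.Series(rng.lognormal(0, 0.5, 400), index=[f"g{i}" for i in range(400)])
        tad_groups = [freqs.index[i * 10 : (i + 1) * 10] for i in range(40)]
        tad_cvs = [bk.group_cv(freqs.loc[g]) for g in tad_groups]
        rand = bk.random_control_groups(freqs.index, 10, 40, seed=5)
        rand_cvs = [bk.group_cv(freqs.loc[g]) for g in rand]
        assert stats.mannwhitneyu(tad_cvs, rand_cvs).pvalue > 0.01


class TestBootstrapMedianCv:
    def test_degenerate_groups_point_mass(self):
        res = bk.bootstrap_median_cv(
            {"a": [0.3] * 10, "b": [0.3] * 8}, n_boot=2000, seed=0
        )
        assert np.all(res.medians["a"] == 0.3)
        assert np.all(res.medians["b"] == 0.3)

    def test_separated_classes_do_not_overlap(self):
        rng = np.random.default_rng(1)
        res = bk.bootstrap_median_cv(
            {"low": rng.normal(0.1, 0.02, 40), "high": rng.normal(0.5, 0.05, 40)},
            n_boot=5000,
            seed=2,
        )
        assert np.quantile(res.medians["low"], 0.995) < np.quantile(
            res.medians["high"], 0.005
        )
        assert res.wilcoxon_raw[("low", "high")] < 1e-6

    def test_single_group_class_rejected(self):
        with pytest.raises(ValueError):
            bk.bootstrap_median_cv({"a": [0.5], "b": [0.4, 0.3]}, n_boot=10, seed=0)

    def test_deterministic(self):
        cvs = {"a": [0.1, 0.2, 0.3], "b": [0.4, 0.5, 0.6]}
        r1 = bk.bootstrap_median_cv(cvs, n_boot=100, seed=9)
        r2 = bk.bootstrap_median_cv(cvs, n_boot=100, seed=9)
        np.testing.assert_array_equal(r1.medians["a"], r2.medians["a"])


class TestCompartmentContrast:
    def _fits(self, kon_a, kon_b):
        rows = []
        for i, k in enumerate(kon_a):
            rows.append(("a%d" % i, k, 10.0, True))
        for i, k in enumerate(kon_b):
            rows.append(("b%d" % i, k, 10.0, True))
        df = pd.DataFrame(rows, columns=["gene_id", "burst_frequency", "burst_size_conventional", "kept"])
        labels = pd.Series(
            {r[0]: ("A" if r[0].startswith("a") else "B") for r in rows}
        )
        return df, labels

    def test_identical_distributions_not_significant(self):
        vals = np.linspace(0.1, 2, 50)
        fits, labels = self._fits(vals, vals)
        res = bk.compartment_contrast(fits, labels)
        assert res["burst_frequency"]["statistic"] == pytest.approx(0.0)
        assert res["burst_frequency"]["pvalue"] > 0.99

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(7)
        base = rng.lognormal(0, 0.5, 500)
        shifted = 2 * rng.lognormal(0, 0.5, 100)
        fits, labels = self._fits(shifted, base)
        res = bk.compartment_contrast(fits, labels)
        assert res["burst_frequency"]["pvalue"] < 0.01

    def test_shuffled_labels_null(self):
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(20):
            vals = rng.lognormal(0, 0.5, 120)
            fits, labels = self._fits(vals[:60], vals[60:])
            shuffled = pd.Series(
                rng.permutation(labels.to_numpy()), index=labels.index
            )
            pvals.append(bk.compartment_contrast(fits, shuffled)["burst_frequency"]["pvalue"])
        assert min(pvals) > 1e-4 and np.mean(np.array(pvals) < 0.5) < 0.9

    def test_empty_compartment_rejected(self):
        fits, labels = self._fits(np.linspace(0.1, 1, 10), [])
        with pytest.raises(ValueError):
            bk.compartment_contrast(fits, labels)
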