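"""Generator correctness: stationary moments, oracle equivalence, thinning
closure, genome geometry, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import burstkit as bk
from burstkit.simulate import DatasetConfig, sample_stationary_gillespie


class TestPoissonBetaSampler:
    def test_zero_synthesis_gives_zero_counts(self):
        params = bk.BurstParams(k_on=1.0, k_off=2.0, k_syn=0.0)
        assert bk.sample_poisson_beta(params, 5, seed=0).tolist() == [0] * 5

    @pytest.mark.parametrize(
        "k_on,k_off,k_syn",
        [(0.3, 1.0, 20.0), (1.0, 1.0, 2.0), (5.0, 5.0, 50.0), (0.1, 8.0, 60.0)],
    )
    def test_stationary_moments(self, k_on, k_off, k_syn):
        """Sample mean and variance match the closed-form Poisson-Beta
        moments within 3 Monte-Carlo standard errors at n = 1e5."""
        params = bk.BurstParams(k_on, k_off, k_syn)
        n = 100_000
        x = bk.sample_poisson_beta(params, n, seed=42)
        se_mean = x.std(ddof=1) / np.sqrt(n)
        assert abs(x.mean() - params.mean) < 3 * se_mean
        m4 = stats.moment(x, 4)
        se_var = np.sqrt((m4 - x.var() ** 2) / n)
        assert abs(x.var(ddof=1) - params.variance) < 3 * se_var

    def test_zero_probability_uniform_mixing(self):
        """For k_on = k_off = 1, k_syn = 2 the zero-probability equals the
        analytic integral (1 - e^-2)/2."""
        params = bk.BurstParams(1.0, 1.0, 2.0)
        x = bk.sample_poisson_beta(params, 200_000, seed=3)
        p0 = (x == 0).mean()
        expected = (1 - np.exp(-2)) / 2
        assert abs(p0 - expected) < 3 * np.sqrt(expected * (1 - expected) / 200_000)

    def test_deterministic_given_seed(self):
        params = bk.BurstParams(0.4, 2.0, 25.0)
        a = bk.sample_poisson_beta(params, 100, seed=9)
        b = bk.sample_poisson_beta(params, 100, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            bk.BurstParams(k_on=0.0, k_off=1.0, k_syn=5.0)
        with pytest.raises(ValueError):
            bk.BurstParams(k_on=1.0, k_off=-1.0, k_syn=5.0)
        with pytest.raises(ValueError):
            bk.sample_poisson_beta(bk.BurstParams(1, 1, 1), 0, seed=0)


class TestGillespieOracle:
    def test_zero_synthesis(self):
        assert bk.simulate_gillespie(bk.BurstParams(1, 1, 0), seed=5) == 0

    def test_matches_poisson_beta_sampler(self):
        """The exact trajectory simulation and the Beta-mixture sampler draw
        from the same stationary law (two-sample KS)."""
        params = bk.BurstParams(1.0, 1.0, 2.0)
        g = sample_stationary_gillespie(params, 3000, seed=10)
        s = bk.sample_poisson_beta(params, 3000, seed=11)
        assert stats.ks_2samp(g, s).pvalue > 0.01

    def test_fast_switching_limit_is_poisson(self):
        """With fast symmetric switching the stationary law approaches
        Poisson(k_syn / 2)."""
        params = bk.BurstParams(200.0, 200.0, 8.0)
        g = sample_stationary_gillespie(params, 3000, seed=12)
        pois = np.random.default_rng(13).poisson(4.0, 3000)
        assert stats.ks_2samp(g, pois).pvalue > 0.01

    def test_invalid_times_rejected(self):
        with pytest.raises(ValueError):
            bk.simulate_gillespie(bk.BurstParams(1, 1, 2), t_end=-1.0, seed=0)
        with pytest.raises(ValueError):
            bk.simulate_gillespie(bk.BurstParams(1, 1, 2), t_end=1.0, burn_in=2.0, seed=0)


class TestApplyCapture:
    def test_identity_and_zero(self):
        counts = np.arange(12).reshape(3, 4)
        np.testing.assert_array_equal(bk.apply_capture(counts, 1.0, seed=0), counts)
        assert bk.apply_capture(counts, 0.0, seed=0).sum() == 0

    def test_binomial_expectation(self):
        out = bk.apply_capture(np.full(20_000, 1000), 0.35, seed=1)
        se = np.sqrt(1000 * 0.35 * 0.65 / 20_000)
        assert abs(out.mean() - 350) < 3 * se

    def test_entrywise_bounded_and_dataframe_roundtrip(self):
        df = pd.DataFrame([[5, 0], [100, 3]], index=["a", "b"], columns=["c1", "c2"])
        out = bk.apply_capture(df, 0.5, seed=2)
        assert isinstance(out, pd.DataFrame)
        assert (out.to_numpy() <= df.to_numpy()).all()

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            bk.apply_capture(np.ones(3, dtype=int), 1.5, seed=0)

    def test_thinning_closure(self):
        """Binomial thinning of Poisson-Beta(k_on, k_off, k_syn) at p has the
        same law as Poisson-Beta(k_on, k_off, p * k_syn)."""
        params = bk.BurstParams(0.5, 2.0, 40.0)
        base = bk.sample_poisson_beta(params, 30_000, seed=21)
        thinned = bk.apply_capture(base, 0.35, seed=22)
        direct = bk.sample_poisson_beta(
            bk.BurstParams(0.5, 2.0, 0.35 * 40.0), 30_000, seed=23
        )
        assert stats.ks_2samp(thinned, direct).pvalue > 0.01


class TestSimulateGenome:
    def test_within_tad_containment(self, toy_genome):
        tads, genes = toy_genome
        tad_iv = tads.intervals.set_index("tad_id")
        for _, g in genes[genes["location"] == "tad"].iterrows():
            tad = tad_iv.loc[g["feature_id"]]
            assert tad["start"] <= g["start"] and g["end"] <= tad["end"]

    def test_boundary_gene_counts(self):
        tads, genes = bk.simulate_genome(2, 3, boundary_genes_per_boundary=2, seed=1)
        assert (genes["location"] == "boundary").sum() == 2
        assert (genes["location"] == "tad").sum() == 6

    def test_deterministic(self):
        a = bk.simulate_genome(3, 4, 2, seed=5)
        b = bk.simulate_genome(3, 4, 2, seed=5)
        pd.testing.assert_frame_equal(a[0].intervals, b[0].intervals)
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_impossible_packing_rejected(self):
        with pytest.raises(ValueError, match="pack"):
            bk.simulate_genome(2, 500, tad_length=10_000, gene_length=1_000, seed=0)

    def test_genes_do_not_overlap(self, toy_genome):
        _, genes = toy_genome
        g = genes.sort_values("start")
        assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()


class TestSimulateDataset:
    def test_zero_jitter_shares_kon_exactly(self, toy_genome):
        cfg = DatasetConfig(share_tad_kon=True, kon_jitter_sigma=0.0)
        _, truth = bk.simulate_dataset(toy_genome, cfg, n_cells=20, seed=3)
        tad_truth = truth.params[truth.params["location"] == "tad"]
        for _, grp in tad_truth.groupby("feature_id"):
            assert grp["k_on"].nunique() == 1

    def test_null_dataset_mean_matches_thinned_mixture(self, toy_genome):
        """Per-gene sample means track p * k_syn * k_on / (k_on + k_off)."""
        cfg = DatasetConfig()
        matrix, truth = bk.simulate_dataset(toy_genome, cfg, n_cells=4000, p_capture=0.35, seed=4)
        t = truth.params.set_index("gene_id")
        expected = 0.35 * t["k_syn"] * t["k_on"] / (t["k_on"] + t["k_off"])
        observed = matrix.counts.mean(axis=1)
        sd = matrix.counts.std(axis=1, ddof=1)
        se = sd / np.sqrt(matrix.n_cells)
        assert (np.abs(observed - expected.loc[observed.index]) < 4 * se + 0.02).all()

    def test_planted_boundary_coexpression_positive_scc(self):
        """The shared per-cell factor induces positive rank correlation for
        boundary gene pairs on average (single pairs are noisy)."""
        genome = bk.simulate_genome(12, 2, boundary_genes_per_boundary=2, seed=5)
        cfg = DatasetConfig.well_expressed(boundary_coexpr_sigma=0.6)
        matrix, truth = bk.simulate_dataset(genome, cfg, n_cells=300, seed=5)
        genes = truth.params
        sccs = []
        for _, grp in genes[genes["location"] == "boundary"].groupby("feature_id"):
            a, b = grp["gene_id"].iloc[:2]
            sccs.append(
                stats.spearmanr(matrix.counts.loc[a], matrix.counts.loc[b]).statistic
            )
        sccs = np.array(sccs)
        assert sccs.mean() > 0.05
        assert (sccs > 0).mean() >= 0.6

    def test_truth_covers_every_gene_and_is_reproducible(self, toy_genome):
        cfg = DatasetConfig()
        m1, t1 = bk.simulate_dataset(toy_genome, cfg, n_cells=30, seed=11)
        m2, t2 = bk.simulate_dataset(toy_genome, cfg, n_cells=30, seed=11)
        assert set(t1.params["gene_id"]) == set(m1.gene_ids)
        pd.testing.assert_frame_equal(m1.counts, m2.counts)
        pd.testing.assert_frame_equal(t1.params, t2.params)

    def test_config_inconsistency_rejected(self):
        with pytest.raises(ValueError):
            DatasetConfig(share_tad_kon=False, kon_jitter_sigma=0.5)


class TestSpikeInWells:
    def test_extreme_efficiencies(self):
        mix = {"s1": 12, "s2": 30}
        wells = bk.simulate_spikein_wells(mix, 0.0, 4, seed=0)
        assert all((w.detected_umis == 0).all() for w in wells)
        wells = bk.simulate_spikein_wells(mix, 1.0, 4, seed=0)
        assert all(w.detected_umis["s1"] == 12 for w in wells)

    def test_binomial_expectation(self):
        wells = bk.simulate_spikein_wells({"s": 20}, 0.35, 1000, seed=1)
        detected = np.array([w.detected_umis["s"] for w in wells])
        se = np.sqrt(20 * 0.35 * 0.65 / 1000)
        assert abs(detected.mean() - 7.0) < 3 * se

    def test_never_exceeds_input(self):
        wells = bk.simulate_spikein_wells({"s": 15, "t": 3}, 0.8, 50, seed=2)
        for w in wells:
            assert (w.detected_umis <= w.input_copies).all()
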