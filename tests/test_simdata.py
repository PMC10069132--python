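"""Simulator contracts: determinism, differentiation targets, planted signals."""

import dataclasses

import numpy as np
import pytest

from popscan.genio import MISSING
from popscan.popdiv import wc_theta, wc_theta_per_locus
from popscan.simdata import (
    AutozygositySpec,
    SimulationConfig,
    SweepSpec,
    TruthSet,
    diploidize_and_emit,
    inject_autozygosity,
    inject_sweep,
    simulate_haplotypes,
    wright_fisher_haplotypes,
)


def small_config(**kw):
    base = dict(seed=11, chromosomes=[("1", 5_000_000)], n_diploids_per_pop=10)
    base.update(kw)
    return SimulationConfig(**base)


def two_pop_labels(haps):
    g1 = haps["pop1"].to_genotypes()
    g2 = haps["pop2"].to_genotypes()
    geno = np.vstack([g1.geno, g2.geno])
    labels = np.r_[np.zeros(g1.n_samples, int), np.ones(g2.n_samples, int)]
    return geno, labels


class TestSimulate:
    def test_determinism_bit_identical(self):
        cfg = small_config()
        h1, t1 = simulate_haplotypes(cfg)
        h2, t2 = simulate_haplotypes(cfg)
        for pop in h1:
            np.testing.assert_array_equal(h1[pop].haps, h2[pop].haps)
        np.testing.assert_array_equal(t1.ancestral_freq, t2.ancestral_freq)

    def test_zero_fst_means_no_differentiation(self):
        # founder sampling adds ~1/n_founders of apparent differentiation, so
        # the Balding-Nichols target is probed with a wide founder pool
        cfg = SimulationConfig(seed=2, chromosomes=[("1", 250_000_000)],
                               n_diploids_per_pop=50, fst_target=0.0,
                               n_founders=500)
        haps, _ = simulate_haplotypes(cfg)
        geno, labels = two_pop_labels(haps)
        assert geno.shape[1] >= 4500
        per_locus = wc_theta_per_locus(geno, labels)
        assert abs(np.nanmean(per_locus)) < 0.01

    def test_balding_nichols_fst_recovered(self):
        cfg = SimulationConfig(seed=3, chromosomes=[("1", 250_000_000)],
                               n_diploids_per_pop=50, fst_target=0.10,
                               n_founders=500)
        haps, _ = simulate_haplotypes(cfg)
        geno, labels = two_pop_labels(haps)
        theta = wc_theta(geno, labels)
        assert 0.08 <= theta <= 0.12

    def test_rejects_degenerate_configs(self):
        with pytest.raises(ValueError):
            simulate_haplotypes(small_config(chromosomes=[("1", 60_000)]))  # < 2 markers
        with pytest.raises(ValueError):
            small_config(fst_target=0.0, n_founders=1)
        with pytest.raises(ValueError):
            small_config(fst_target=1.0)
        with pytest.raises(ValueError):
            small_config(ancestral_maf_range=(0.5, 0.2))

    def test_sample_freq_tracks_population_freq(self):
        cfg = SimulationConfig(seed=5, chromosomes=[("1", 100_000_000)],
                               n_diploids_per_pop=50, n_founders=200)
        haps, truth = simulate_haplotypes(cfg)
        f_obs = haps["pop1"].haps.mean(axis=0)
        f_true = truth.pop_freqs["pop1"]
        # binomial sampling noise at 100 haplotype draws (founder resampling
        # roughly doubles the variance); check aggregate agreement
        resid = f_obs - f_true
        assert abs(resid.mean()) < 0.01
        assert resid.std() < 3 * np.sqrt(0.25 / 100)


class TestSweep:
    def test_full_frequency_forces_identity(self):
        cfg = small_config()
        haps, _ = simulate_haplotypes(cfg)
        spec = SweepSpec(0, "1", 2_500_000, 1_000_000, 1.0)
        swept = inject_sweep(haps["pop1"], spec, seed=1)
        idx = np.flatnonzero(
            (swept.markers.bp >= 1_500_000) & (swept.markers.bp <= 3_500_000))
        win = swept.haps[:, idx]
        assert (win == win[0]).all()

    def test_carrier_count_rounding(self):
        cfg = small_config(n_diploids_per_pop=50)  # 2n = 100
        haps, truth = simulate_haplotypes(cfg)
        spec = SweepSpec(0, "1", 2_500_000, 1_000_000, 0.9)
        swept = inject_sweep(haps["pop1"], spec, seed=1, truth=truth)
        assert truth.sweeps[-1]["n_carriers"] == 90
        idx = np.flatnonzero(
            (swept.markers.bp >= 1_500_000) & (swept.markers.bp <= 3_500_000))
        win = swept.haps[:, idx]
        counts = np.unique([tuple(r) for r in win], axis=0, return_counts=True)[1]
        assert counts.max() >= 90

    def test_markers_outside_window_untouched(self):
        cfg = small_config()
        haps, _ = simulate_haplotypes(cfg)
        spec = SweepSpec(0, "1", 2_500_000, 500_000, 0.8)
        swept = inject_sweep(haps["pop1"], spec, seed=4)
        outside = np.flatnonzero(
            (swept.markers.bp < 2_000_000) | (swept.markers.bp > 3_000_000))
        np.testing.assert_array_equal(swept.haps[:, outside],
                                      haps["pop1"].haps[:, outside])

    def test_small_window_warns(self):
        cfg = small_config()
        haps, _ = simulate_haplotypes(cfg)
        with pytest.warns(UserWarning, match="SNPs"):
            inject_sweep(haps["pop1"], SweepSpec(0, "1", 2_500_000, 100_000, 0.9), seed=1)


class TestAutozygosity:
    def test_full_carrier_fraction_all_homozygous(self):
        cfg = small_config(chromosomes=[("1", 10_000_000)])
        haps, _ = simulate_haplotypes(cfg)
        spec = AutozygositySpec(0, "1", 4_000_000, 6_000_000, 1.0)
        az = inject_autozygosity(haps["pop1"], spec, seed=1)
        idx = np.flatnonzero((az.markers.bp >= 4_000_000) & (az.markers.bp <= 6_000_000))
        assert len(idx) >= 30
        np.testing.assert_array_equal(az.haps[0::2][:, idx], az.haps[1::2][:, idx])

    def test_carrier_count_and_first_haplotype_untouched(self):
        cfg = small_config(n_diploids_per_pop=10)
        haps, truth = simulate_haplotypes(cfg)
        spec = AutozygositySpec(0, "1", 1_000_000, 4_000_000, 0.6)
        az = inject_autozygosity(haps["pop1"], spec, seed=2, truth=truth)
        assert len(truth.autozygosity) == 6
        np.testing.assert_array_equal(az.haps[0::2], haps["pop1"].haps[0::2])

    def test_empty_span_rejected(self):
        cfg = small_config()
        haps, _ = simulate_haplotypes(cfg)
        with pytest.raises(ValueError, match="no SNPs"):
            inject_autozygosity(haps["pop1"], AutozygositySpec(0, "1", 10, 20, 1.0), seed=1)


class TestDiploidize:
    def test_identity_without_noise(self):
        cfg = small_config()
        haps, _ = simulate_haplotypes(cfg)
        g = diploidize_and_emit(haps, seed=9)
        manual = haps["pop1"].haps[0::2] + haps["pop1"].haps[1::2]
        np.testing.assert_array_equal(g.geno[:10], manual)

    def test_het_coding(self):
        cfg = small_config()
        haps, _ = simulate_haplotypes(cfg)
        h = haps["pop1"]
        g = diploidize_and_emit({"pop1": h}, seed=0)
        j = 3
        expected = h.haps[0, j] + h.haps[1, j]
        assert g.geno[0, j] == expected

    def test_missing_rate_realized(self):
        cfg = SimulationConfig(seed=13, chromosomes=[("1", 25_000_000)],
                               n_diploids_per_pop=10)
        haps, _ = simulate_haplotypes(cfg)
        g = diploidize_and_emit(haps, missing_rate=0.05, seed=13)
        frac = (g.geno == MISSING).mean()
        assert g.geno.size >= 10_000
        assert abs(frac - 0.05) < 0.01

    def test_rates_validated(self):
        cfg = small_config()
        haps, _ = simulate_haplotypes(cfg)
        with pytest.raises(ValueError):
            diploidize_and_emit(haps, missing_rate=1.5)

    def test_emits_files_and_truth_round_trip(self, tmp_path):
        cfg = small_config(
            autozygosity_specs=[AutozygositySpec(0, "1", 1_000_000, 3_000_000, 0.5)])
        haps, truth = simulate_haplotypes(cfg)
        diploidize_and_emit(haps, seed=1, out_prefix=tmp_path / "sim", truth=truth)
        assert (tmp_path / "sim.ped").exists()
        assert (tmp_path / "sim.map").exists()
        assert (tmp_path / "sim.pop1.haps.tsv").exists()
        back = TruthSet.read_intervals(tmp_path / "sim.truth_intervals.tsv")
        az = back[back["record"] == "autozygosity"]
        assert len(az) == len(truth.autozygosity)
        assert set(az["individual"]) == {r["individual"] for r in truth.autozygosity}
        assert (az["start_bp"] == 1_000_000).all() and (az["end_bp"] == 3_000_000).all()


def test_wright_fisher_drift_changes_frequencies():
    hs0 = wright_fisher_haplotypes(n_diploids=50, n_snps=200, n_generations=0, seed=7)
    hs = wright_fisher_haplotypes(n_diploids=50, n_snps=200, n_generations=50, seed=7)
    f0, f1 = hs0.haps.mean(axis=0), hs.haps.mean(axis=0)
    # same initial draw, drift moves frequencies; variance of change ~ p(1-p) t/2N
    assert np.std(f1 - f0) > 0.05
    assert hs.haps.shape == (100, 200)
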