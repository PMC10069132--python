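"""EHHS variants vs. pair-counting oracle, iES integration, scan statistics."""

import numpy as np
import pandas as pd
import pytest

from popscan.ehhscan import (
    EHHSCurve,
    CandidateRegion,
    ScanTrack,
    ScanWindow,
    consolidate_regions,
    cross_pop_scan,
    ehhs_curve,
    integrate_ies,
    pscore_from_z,
    significance_windows,
)

from conftest import make_haps
from oracles import ehhs_brute, ies_brute


class TestEHHS:
    def test_four_haplotype_worked_example(self):
        # h1=(0,0), h2=(0,0), h3=(1,1), h4=(1,0); core = marker 0
        hs = make_haps([[0, 0], [0, 0], [1, 1], [1, 0]])
        tang = ehhs_curve(hs, 0, "tang")
        sab = ehhs_curve(hs, 0, "sabeti")
        assert tang.ehhs[0] == 1.0 and sab.ehhs[0] == 1.0
        assert tang.ehhs[1] == pytest.approx(0.5)      # 2*1 / (2*1 + 2*1)
        assert sab.ehhs[1] == pytest.approx(1 / 6)     # C(2,2)/C(4,2)

    def test_identical_haplotypes_everywhere_one(self):
        hs = make_haps(np.zeros((6, 10), dtype=np.int8))
        for variant in ("tang", "sabeti"):
            curve = ehhs_curve(hs, 4, variant)
            if variant == "tang":
                np.testing.assert_allclose(curve.ehhs, 1.0)
            else:
                # off-core markers: all 6 haplotypes identical -> 30/30 pairs
                np.testing.assert_allclose(curve.ehhs, 1.0)

    def test_monomorphic_core_tang_undefined_sabeti_defined(self):
        haps = np.array([[0, 0, 1], [0, 1, 0], [0, 0, 0], [0, 1, 1]])
        hs = make_haps(haps)
        tang = ehhs_curve(hs, 0, "tang")
        sab = ehhs_curve(hs, 0, "sabeti")
        # monomorphic core: every pair is core-homozygous; tang denominator is
        # n(n-1) so the value equals the sabeti off-core value here
        assert np.isfinite(sab.ehhs).all()
        assert np.isfinite(tang.ehhs).all()

    def test_needs_four_haplotypes(self):
        hs = make_haps([[0, 1], [1, 0]])
        with pytest.raises(ValueError):
            ehhs_curve(hs, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9)) * 2
        m = int(rng.integers(3, 21))
        haps = rng.integers(0, 2, size=(n, m)).astype(np.int8)
        hs = make_haps(haps)
        core = int(rng.integers(0, m))
        for variant in ("tang", "sabeti"):
            got = ehhs_curve(hs, core, variant).ehhs
            exp = ehhs_brute(haps, core, variant)
            mask = ~np.isnan(exp)
            np.testing.assert_allclose(got[mask], exp[mask], atol=1e-12)
            assert np.isnan(got[~mask]).all()

    def test_monotone_nonincreasing_from_core(self, rng):
        haps = rng.integers(0, 2, size=(12, 15)).astype(np.int8)
        hs = make_haps(haps)
        for variant in ("tang", "sabeti"):
            c = ehhs_curve(hs, 7, variant)
            core_pos = int(np.flatnonzero(c.indices == 7)[0])
            right = c.ehhs[core_pos + 1:]
            left = c.ehhs[:core_pos][::-1]
            for side in (right, left):
                side = side[~np.isnan(side)]
                assert np.all(np.diff(side) <= 1e-12)

    def test_missing_allele_drops_haplotype(self):
        haps = np.array([[0, 0, 0], [0, -1, 0], [1, 1, 1], [1, 1, 0]])
        hs = make_haps(haps)
        c = ehhs_curve(hs, 0, "sabeti")
        # at marker 1 haplotype 2 leaves: classes among {h1,h3,h4} over [0..1]
        # {00}, {11,11} -> pairs = 1; denominator C(3,2)... with n=3 alive: 3*2/2=3
        assert c.ehhs[1] == pytest.approx(1 / 3)


class TestIntegrateIES:
    def _curve(self, bp, vals, core_idx):
        bp = np.asarray(bp)
        return EHHSCurve(core=core_idx, indices=np.arange(len(bp)), bp=bp,
                         ehhs=np.asarray(vals, dtype=float), variant="tang")

    def test_trapezoid_arithmetic(self):
        curve = self._curve([0, 100_000], [1.0, 0.5], 0)
        got = integrate_ies(curve, cutoff=0.05, discard_at_border=False)
        assert got == pytest.approx(75_000.0)

    def test_truncation_at_first_below_cutoff(self):
        curve = self._curve([0, 100_000, 200_000, 300_000, 400_000],
                            [0.01, 1.0, 0.02, 1.0, 1.0], 1)
        # left: trapezoid to bp 0 (0.01 below cutoff); right: trapezoid to 200k
        got = integrate_ies(curve, cutoff=0.05, discard_at_border=False)
        assert got == pytest.approx(0.5 * (1 + 0.01) * 100_000 + 0.5 * (1 + 0.02) * 100_000)

    def test_border_discard(self):
        curve = self._curve([0, 100_000, 200_000], [1.0, 1.0, 0.9], 0)
        assert np.isnan(integrate_ies(curve, cutoff=0.05, discard_at_border=True))
        assert integrate_ies(curve, cutoff=0.05, discard_at_border=False) > 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_numeric_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(5, 25))
        bp = np.sort(rng.choice(np.arange(1, 10_000_000), size=m, replace=False))
        core = int(rng.integers(0, m))
        vals = rng.uniform(0, 1, size=m)
        vals[core] = 1.0
        curve = self._curve(bp, vals, core)
        for border in (True, False):
            got = integrate_ies(curve, cutoff=0.05, discard_at_border=border)
            exp = ies_brute(bp, vals, core, cutoff=0.05, discard_at_border=border)
            if np.isnan(exp):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(exp, rel=1e-9)


class TestPScore:
    def test_zero_score_zero_pscore(self):
        assert pscore_from_z(np.array([0.0]))[0] == 0.0

    def test_standard_normal_quantile_identity(self):
        got = pscore_from_z(np.array([1.959964]))[0]
        assert got == pytest.approx(-np.log10(0.05), abs=1e-4)


class TestCrossPopScan:
    def _haps_pair(self, seed=0, m=400):
        from popscan.simdata import SimulationConfig, simulate_haplotypes
        cfg = SimulationConfig(seed=seed, chromosomes=[("1", m * 50_000)],
                               n_diploids_per_pop=15)
        haps, _ = simulate_haplotypes(cfg)
        return haps["pop1"], haps["pop2"]

    def test_identical_populations_all_zero(self):
        ha, _ = self._haps_pair()
        track = cross_pop_scan(ha, ha, "rsb")
        t = track.table
        defined = t["raw"].notna()
        assert defined.sum() > 100
        assert np.allclose(t.loc[defined, "raw"], 0.0)
        assert np.allclose(t.loc[defined, "pscore"], 0.0)

    def test_antisymmetry_under_population_swap(self):
        ha, hb = self._haps_pair(seed=3)
        for stat in ("rsb", "xpehh"):
            t1 = cross_pop_scan(ha, hb, stat).table
            t2 = cross_pop_scan(hb, ha, stat).table
            d = t1["raw"].notna() & t2["raw"].notna()
            np.testing.assert_allclose(t1.loc[d, "raw"], -t2.loc[d, "raw"], atol=1e-9)
            np.testing.assert_allclose(t1.loc[d, "score"], -t2.loc[d, "score"], atol=1e-7)
            np.testing.assert_allclose(t1.loc[d, "pscore"], t2.loc[d, "pscore"], atol=1e-6)

    def test_standardization_schemes(self):
        ha, hb = self._haps_pair(seed=5)
        rsb = cross_pop_scan(ha, hb, "rsb").table
        xp = cross_pop_scan(ha, hb, "xpehh").table
        s = rsb["score"].dropna()
        assert np.nanmedian(s) == pytest.approx(0.0, abs=1e-9)
        assert np.nanstd(rsb["raw"] - np.nanmedian(rsb["raw"])) > 0
        assert np.nanmean(xp["score"].dropna()) == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_maps_rejected(self):
        ha, hb = self._haps_pair()
        hb2 = make_haps(hb.haps[:, :-1])
        with pytest.raises(ValueError):
            cross_pop_scan(ha, hb2)


class TestWindows:
    def _track(self, bp, pscore, chrom="1"):
        t = pd.DataFrame({"chrom": chrom, "bp": bp, "snp": [f"s{i}" for i in range(len(bp))],
                          "ies_a": 1.0, "ies_b": 1.0, "raw": 0.0, "score": 0.0,
                          "pscore": pscore})
        return ScanTrack(t, "rsb")

    def test_tiling_arithmetic(self):
        bp = np.linspace(0, 1_000_000, 101).astype(int)
        track = self._track(bp, np.zeros(101))
        wins = significance_windows(track)
        assert [w.start_bp for w in wins] == [0, 240_000, 480_000, 720_000, 960_000]

    def test_three_snp_rule_strict(self):
        bp = [10_000, 20_000, 30_000, 40_000]
        wins = significance_windows(self._track(bp, [4.5, 4.5, 4.5, 0.0]))
        assert wins[0].significant
        wins = significance_windows(self._track(bp, [4.5, 4.5, 4.0, 0.0]))
        assert not wins[0].significant  # p-score must strictly exceed 4

    def test_no_signal_no_windows(self):
        bp = np.arange(0, 2_000_000, 25_000)
        wins = significance_windows(self._track(bp, np.zeros(len(bp))))
        assert not any(w.significant for w in wins)

    def test_overlap_must_be_smaller_than_window(self):
        with pytest.raises(ValueError):
            significance_windows(self._track([0, 1], [0, 0]), window_bp=10_000,
                                 overlap_bp=10_000)


class TestConsolidate:
    def _track(self, bp, pscore):
        t = pd.DataFrame({"chrom": "1", "bp": bp, "snp": [f"s{i}" for i in range(len(bp))],
                          "ies_a": 1.0, "ies_b": 1.0, "raw": 0.0, "score": 0.0,
                          "pscore": pscore})
        return ScanTrack(t, "rsb")

    def test_overlapping_windows_merge_to_one_region(self):
        bp = np.arange(0, 500_001, 10_000)
        ps = np.zeros(len(bp))
        ps[(bp >= 220_000) & (bp <= 260_000)] = 5.0  # straddles the 10-kb overlap
        track = self._track(bp, ps)
        wins = significance_windows(track)
        assert sum(w.significant for w in wins) == 2
        regions = consolidate_regions(wins, None, [], track, None)
        assert len(regions) == 1
        assert regions[0].methods == {"Rsb"}
        assert regions[0].start_bp == 220_000 and regions[0].end_bp == 260_000

    def test_disjoint_methods_stay_separate(self):
        bp = np.arange(0, 2_000_001, 10_000)
        ps_r = np.zeros(len(bp))
        ps_r[(bp >= 100_000) & (bp <= 150_000)] = 5.0
        ps_x = np.zeros(len(bp))
        ps_x[(bp >= 1_500_000) & (bp <= 1_550_000)] = 5.0
        tr_r, tr_x = self._track(bp, ps_r), self._track(bp, ps_x)
        regions = consolidate_regions(significance_windows(tr_r),
                                      significance_windows(tr_x), [], tr_r, tr_x)
        assert len(regions) == 2
        assert regions[0].methods == {"Rsb"}
        assert regions[1].methods == {"XP-EHH"}

    def test_island_joins_overlapping_scan_region(self):
        from popscan.rohscan import ROHIsland
        bp = np.arange(0, 1_000_001, 10_000)
        ps = np.zeros(len(bp))
        ps[(bp >= 300_000) & (bp <= 360_000)] = 5.0
        track = self._track(bp, ps)
        wins = significance_windows(track)
        isl = ROHIsland("g", "1", 350_000, 420_000, 8, 0.5, 0.1)
        regions = consolidate_regions(wins, None, [isl], track, None)
        joint = [r for r in regions if len(r.methods) > 1]
        assert len(joint) == 1
        assert joint[0].methods == {"Rsb", "ROH-island"}
        assert joint[0].start_bp == 300_000 and joint[0].end_bp == 420_000
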