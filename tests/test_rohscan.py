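"""ROH calling vs. exhaustive enumeration, F_ROH arithmetic, island calling."""

import numpy as np
import pandas as pd
import pytest

from popscan.genio import MISSING, GenotypeMatrix, MarkerMap
from popscan.rohscan import (
    L_AUT_DEFAULT,
    ROHParams,
    detect_roh,
    froh,
    nearest_rank_quantile,
    roh_islands,
    snp_incidence,
)

from conftest import make_geno, make_markers
from oracles import _roh_ok, roh_brute


def geno_from_rows(rows, spacing=35_000, start=1):
    return make_geno(np.asarray(rows, dtype=np.int8), spacing=spacing, start=start)


def called_intervals(geno, params):
    """detect_roh output as marker-index interval tuples per individual."""
    pos_of = {(c, b): i for i, (c, b) in
              enumerate(zip(geno.markers.chrom, geno.markers.bp))}
    out = {}
    for s in detect_roh(geno, params):
        a = pos_of[(s.chrom, s.start_bp)]
        b = pos_of[(s.chrom, s.end_bp)]
        out.setdefault(s.individual, []).append((a, b))
    return out


class TestDetectROH:
    def test_clean_run_single_segment(self):
        # 35 homozygous SNPs at uniform 35-kb spacing span 1.19 Mb < 1.2 Mb...
        # use 36 SNPs to exceed 1.2 Mb: span = 35*35kb = 1.225 Mb
        row = [0] * 36
        geno = geno_from_rows([row])
        segs = detect_roh(geno, ROHParams())
        assert len(segs) == 1
        assert segs[0].n_snps == 36
        assert segs[0].length_bp == 35 * 35_000 + 1

    def test_too_few_snps_no_segment(self):
        geno = geno_from_rows([[0] * 29], spacing=50_000)
        assert detect_roh(geno, ROHParams()) == []

    def test_het_budget_respected_matches_oracle(self):
        row = [0] * 40
        row[12] = 1
        row[27] = 1  # two hets: no 40-SNP run, oracle decides the best subintervals
        geno = geno_from_rows([row])
        params = ROHParams()
        got = called_intervals(geno, params).get("ind0", [])
        pos = geno.markers.bp
        het = [g == 1 for g in row]
        mis = [False] * 40
        expected = roh_brute(list(pos), het, mis, params)
        assert sorted(got) == sorted(expected)
        for a, b in got:
            assert sum(het[a:b + 1]) <= 1

    def test_gap_splits_run(self):
        markers = make_markers(60, spacing=35_000)
        t = markers.table.copy()
        t.loc[30:, "bp"] += 600_000  # 635-kb gap above the 500-kb ceiling
        geno = GenotypeMatrix(np.zeros((1, 60), dtype=np.int8), ["i"], ["p"],
                              MarkerMap(t))
        pos = list(MarkerMap(t).bp)
        expected = roh_brute(pos, [False] * 60, [False] * 60, ROHParams())
        got = called_intervals(geno, ROHParams()).get("i", [])
        assert sorted(got) == sorted(expected)
        for a, b in expected:
            assert not (a < 30 <= b)  # nothing bridges the gap

    def test_unsorted_map_rejected(self):
        t = make_markers(40).table.copy()
        t.loc[5, "bp"], t.loc[6, "bp"] = t.loc[6, "bp"], t.loc[5, "bp"]
        with pytest.raises(ValueError):
            MarkerMap(t)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_fixtures_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(30, 51))
        n = int(rng.integers(1, 8))
        spacing = int(rng.integers(20_000, 60_000))
        # homozygous-biased genotypes so runs exist
        g = rng.choice([0, 0, 0, 0, 2, 2, 1, MISSING],
                       size=(n, m), p=[.35, .2, .15, .1, .1, .05, .03, .02])
        geno = make_geno(g.astype(np.int8), spacing=spacing)
        params = ROHParams(min_length_bp=int(0.6 * spacing * m), min_snps=10)
        got = called_intervals(geno, params)
        pos = list(geno.markers.bp)
        for i in range(n):
            het = [geno.geno[i, j] == 1 for j in range(m)]
            mis = [geno.geno[i, j] == MISSING for j in range(m)]
            expected = roh_brute(pos, het, mis, params)
            assert sorted(got.get(f"ind{i}", [])) == sorted(expected), f"ind{i}"

    def test_segments_revalidate(self):
        rng = np.random.default_rng(99)
        g = rng.choice([0, 2, 1], size=(10, 120), p=[.6, .35, .05]).astype(np.int8)
        geno = make_geno(g, spacing=30_000)
        params = ROHParams(min_length_bp=900_000)
        pos = {s: i for i, s in enumerate(geno.markers.snp)}
        for seg in detect_roh(geno, params):
            a = np.flatnonzero(geno.markers.bp == seg.start_bp)[0]
            b = np.flatnonzero(geno.markers.bp == seg.end_bp)[0]
            row = geno.geno[geno.sample_ids.index(seg.individual)]
            het = [x == 1 for x in row]
            mis = [x == MISSING for x in row]
            assert _roh_ok(list(geno.markers.bp), het, mis, a, b, params)


class TestFroh:
    def _one_segment_geno(self):
        return geno_from_rows([[0] * 40])

    def test_froh_arithmetic_with_chip_constant(self):
        from popscan.rohscan import ROHSegment
        seg = ROHSegment("i", "1", 1, 245_206_000, 300, 0, 0)
        geno = self._one_segment_geno()
        geno = GenotypeMatrix(geno.geno, ["i"], ["p"], geno.markers)
        res = froh([seg], geno)
        assert res.per_individual.loc[0, "froh"] == pytest.approx(0.1)

    def test_no_segments_zero(self):
        geno = self._one_segment_geno()
        res = froh([], geno, l_aut_bp=L_AUT_DEFAULT)
        assert res.per_individual.loc[0, "froh"] == 0.0
        assert res.per_individual.loc[0, "n_segments"] == 0

    def test_length_classes_and_mnroh(self):
        from popscan.rohscan import ROHSegment
        segs = [ROHSegment("a", "1", 1, 2_000_000, 40, 0, 0),
                ROHSegment("a", "2", 1, 7_000_000, 140, 0, 0),
                ROHSegment("b", "1", 1, 21_000_000, 500, 0, 0)]
        geno = make_geno(np.zeros((3, 40), dtype=np.int8),
                         ids=["a", "b", "c"], pops=["p", "p", "p"])
        res = froh(segs, geno, l_aut_bp=100_000_000)
        grp = res.per_group.iloc[0]
        assert grp["1-<5Mb"] == 1 and grp["5-<10Mb"] == 1 and grp[">=20Mb"] == 1
        assert grp["mn_roh_all"] == pytest.approx(1.0)          # 3 segs / 3 inds
        assert grp["mn_roh_carriers"] == pytest.approx(1.5)     # 3 segs / 2 carriers

    def test_invalid_laut(self):
        geno = self._one_segment_geno()
        with pytest.raises(ValueError):
            froh([], geno, l_aut_bp=0)


class TestIslands:
    def _geno(self, n=10, m=200):
        return make_geno(np.ones((n, m), dtype=np.int8), spacing=50_000)

    def test_incidence_fraction(self):
        from popscan.rohscan import ROHSegment
        geno = self._geno()
        segs = [ROHSegment(f"ind{i}", "1", 1_000_001, 3_000_001, 40, 0, 0)
                for i in range(6)]
        inc = snp_incidence(segs, geno, [f"ind{i}" for i in range(10)])
        inside = (geno.markers.bp >= 1_000_001) & (geno.markers.bp <= 3_000_001)
        assert np.allclose(inc[inside], 0.6)
        assert np.allclose(inc[~inside], 0.0)

    def test_uniform_incidence_no_island(self):
        from popscan.rohscan import ROHSegment
        geno = self._geno()
        first, last = geno.markers.bp[0], geno.markers.bp[-1]
        segs = [ROHSegment(f"ind{i}", "1", int(first), int(last), 200, 0, 0)
                for i in range(10)]
        assert roh_islands(segs, geno, "pop1") == []

    def test_all_zero_incidence_empty(self):
        geno = self._geno()
        assert roh_islands([], geno, "pop1") == []

    def test_single_peak_detected(self):
        # the planted plateau must hold < 0.1% of markers, otherwise the
        # 99.9th-percentile threshold sits on the plateau itself and the
        # strict ">" rule (correctly) returns nothing
        from popscan.rohscan import ROHSegment
        geno = self._geno(n=10, m=50_000)
        segs = [ROHSegment(f"ind{i}", "1", 10_000_001, 12_000_001, 40, 0, 0)
                for i in range(6)]
        islands = roh_islands(segs, geno, "pop1", percentile=0.999)
        assert len(islands) == 1
        isl = islands[0]
        assert isl.start_bp >= 10_000_001 and isl.end_bp <= 12_000_001
        assert isl.peak_incidence == pytest.approx(0.6)

    def test_invariant_to_individual_order(self):
        from popscan.rohscan import ROHSegment
        geno = self._geno(n=6, m=500)
        segs = [ROHSegment(f"ind{i}", "1", 5_000_001, 7_000_001, 40, 0, 0)
                for i in (0, 2, 4)]
        a = roh_islands(segs, geno, "pop1")
        b = roh_islands(list(reversed(segs)), geno, "pop1")
        assert [(i.start_bp, i.end_bp) for i in a] == [(i.start_bp, i.end_bp) for i in b]

    def test_nearest_rank(self):
        v = np.arange(1, 101)
        assert nearest_rank_quantile(v, 0.999) == 100
        assert nearest_rank_quantile(v, 0.5) == 50
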