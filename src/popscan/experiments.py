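"""Recovery experiments on synthetic data with known truth.

Each function simulates data under fixed study conditions, runs the relevant
pipeline stage, and returns the measured quantity.  These are the package's
calibration/power experiments; the test suite asserts on their outputs and the
acceptance script reports them.

Two background regimes are used deliberately:

* the *haplotype-cluster* regime (default 30 founders per population) carries
  realistic array-scale LD and is what the sweep/EHH experiments run on;
* the *outbred* regime (500 founders) removes the founder bottleneck, which
  otherwise (a) adds ~1/n_founders of apparent differentiation on top of the
  Balding–Nichols target and (b) seeds background autozygosity that would
  contaminate ROH-recovery truth.  F_ST, ROH-island, and F_ROH experiments run
  in this regime so the measured quantity is the planted one.
"""

from __future__ import annotations

import numpy as np

from .ehhscan import consolidate_regions, cross_pop_scan, significance_windows
from .popdiv import ld_ne, wc_theta
from .rohscan import ROHParams, detect_roh, froh, roh_islands
from .simdata import (
    AutozygositySpec,
    SimulationConfig,
    SweepSpec,
    simulate_haplotypes,
    wright_fisher_haplotypes,
)


def _seed_list(base_seed: int, n: int) -> list[int]:
    # keep derived seeds well below 2**31
    return [(int(base_seed) * 1_000 + 17 * k) % (2**31 - 1) for k in range(n)]


# ---------------------------------------------------------------------------
# F_ST recovery (Balding–Nichols target 0.10, 5,000 SNPs, 50 diploids/pop)
# ---------------------------------------------------------------------------

def fst_recovery(base_seed: int = 0, n_seeds: int = 20, fst_target: float = 0.10) -> list[float]:
    """Genome-wide Weir–Cockerham theta per replicate simulation."""
    thetas = []
    for s in _seed_list(base_seed, n_seeds):
        cfg = SimulationConfig(seed=s, chromosomes=[("1", 250_000_000)],
                               n_diploids_per_pop=50, fst_target=fst_target,
                               n_founders=500)
        haps, _ = simulate_haplotypes(cfg)
        g1, g2 = haps["pop1"].to_genotypes(), haps["pop2"].to_genotypes()
        geno = np.vstack([g1.geno, g2.geno])
        labels = np.r_[np.zeros(50, int), np.ones(50, int)]
        thetas.append(wc_theta(geno, labels))
    return thetas


# ---------------------------------------------------------------------------
# Sweep detection power / null calibration
# (40-Mb chromosome, 1 SNP / 25 kb, 50 diploids/pop, freq-0.9 1-Mb sweep)
# ---------------------------------------------------------------------------

SWEEP_CORE_BP = 20_000_000


def _scan_config(seed: int, with_sweep: bool) -> SimulationConfig:
    sweeps = [SweepSpec(0, "1", SWEEP_CORE_BP, 1_000_000, 0.9)] if with_sweep else []
    return SimulationConfig(seed=seed, chromosomes=[("1", 40_000_000)],
                            snp_spacing_bp=25_000, n_diploids_per_pop=50,
                            sweep_specs=sweeps)


def _scan_one(seed: int, with_sweep: bool):
    haps, _ = simulate_haplotypes(_scan_config(seed, with_sweep))
    cache: dict = {}
    tracks, windows = {}, {}
    for stat in ("rsb", "xpehh"):
        tr = cross_pop_scan(haps["pop1"], haps["pop2"], stat, _ies_cache=cache)
        tracks[stat] = tr
        windows[stat] = significance_windows(tr)
    regions = consolidate_regions(windows["rsb"], windows["xpehh"], [],
                                  tracks["rsb"], tracks["xpehh"])
    return tracks, windows, regions


def sweep_power(base_seed: int = 0, n_seeds: int = 20) -> list[bool]:
    """Per replicate: does a region supported by both Rsb and XP-EHH overlap
    the true sweep core?"""
    hits = []
    for s in _seed_list(base_seed, n_seeds):
        _, _, regions = _scan_one(s, with_sweep=True)
        hits.append(any(
            {"Rsb", "XP-EHH"} <= r.methods and r.start_bp <= SWEEP_CORE_BP <= r.end_bp
            for r in regions))
    return hits


def null_calibration(base_seed: int = 0, n_seeds: int = 20) -> dict:
    """No-sweep replicates: outlier-SNP fraction and significant-window counts."""
    n_hot = n_defined = 0
    window_counts = []
    for s in _seed_list(base_seed, n_seeds):
        tracks, windows, _ = _scan_one(s, with_sweep=False)
        for stat in ("rsb", "xpehh"):
            p = tracks[stat].table["pscore"]
            n_hot += int((p > 4.0).sum())
            n_defined += int(p.notna().sum())
            window_counts.append(sum(w.significant for w in windows[stat]))
    return {
        "outlier_fraction": n_hot / n_defined if n_defined else float("nan"),
        "median_significant_windows": float(np.median(window_counts)),
        "window_counts": window_counts,
    }


# ---------------------------------------------------------------------------
# ROH-island recovery (chip-scale outbred genome, one 2-Mb span at 0.6)
# ---------------------------------------------------------------------------

ISLAND_SPAN = (50_000_000, 52_000_000)


def island_recovery(base_seed: int = 0, n_seeds: int = 20) -> list[bool]:
    """Per replicate: does the 99.9th-percentile procedure return exactly one
    island, overlapping the planted 2-Mb span?"""
    chroms = [(str(c), 120_000_000) for c in range(1, 21)]
    hits = []
    for s in _seed_list(base_seed, n_seeds):
        cfg = SimulationConfig(
            seed=s, chromosomes=chroms, snp_spacing_bp=50_000,
            n_diploids_per_pop=25, n_founders=500,
            autozygosity_specs=[AutozygositySpec(0, "1", *ISLAND_SPAN, 0.6)])
        haps, _ = simulate_haplotypes(cfg)
        geno = haps["pop1"].to_genotypes()
        segments = detect_roh(geno, ROHParams())
        islands = roh_islands(segments, geno, "pop1", percentile=0.999)
        ok = (len(islands) == 1
              and islands[0].chrom == "1"
              and islands[0].start_bp <= ISLAND_SPAN[1]
              and islands[0].end_bp >= ISLAND_SPAN[0])
        hits.append(ok)
    return hits


# ---------------------------------------------------------------------------
# F_ROH recovery (planted spans covering 8% of the covered genome)
# ---------------------------------------------------------------------------

def froh_recovery(seed: int = 0) -> float:
    """Mean F_ROH when noise-free autozygosity covers 0.08 of L_AUT."""
    chroms = [(str(c), 100_000_000) for c in range(1, 6)]
    spans = [AutozygositySpec(0, str(c), 10_000_000, 20_000_000, 1.0)
             for c in (1, 2, 3, 4)]  # 4 x 10 Mb = 40 Mb of 500 Mb
    cfg = SimulationConfig(seed=seed, chromosomes=chroms, snp_spacing_bp=50_000,
                           n_diploids_per_pop=25, n_founders=500,
                           autozygosity_specs=spans)
    haps, _ = simulate_haplotypes(cfg)
    geno = haps["pop1"].to_genotypes()
    segments = detect_roh(geno, ROHParams())
    l_aut = sum(length for _, length in chroms)
    res = froh(segments, geno, l_aut_bp=l_aut)
    return float(res.per_individual["froh"].mean())


# ---------------------------------------------------------------------------
# LD-based Ne recovery against the forward Wright–Fisher oracle (N = 100)
# ---------------------------------------------------------------------------

def ne_recovery(base_seed: int = 0, n_seeds: int = 10, true_n: int = 100) -> list[bool]:
    """Per replicate: are all Ne estimates in bins with 10 <= t <= 50 within a
    factor of two of the simulated size?"""
    hits = []
    for s in _seed_list(base_seed, n_seeds):
        hs = wright_fisher_haplotypes(n_diploids=true_n, n_snps=2000,
                                      chrom_length_bp=100_000_000,
                                      n_generations=200, seed=s)
        traj = ld_ne(hs.to_genotypes(), seed=s)["wf"]
        t = traj.table
        sel = t[(t["t"] >= 10) & (t["t"] <= 50) & t["ne"].notna()]
        ok = len(sel) >= 4 and bool(
            ((sel["ne"] >= true_n / 2) & (sel["ne"] <= true_n * 2)).all())
        hits.append(ok)
    return hits
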