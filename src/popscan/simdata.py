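"""Two-population phased-genotype simulator with known truth.

The generator emulates the study design this pipeline targets: two groups of
diploids genotyped on a medium-density SNP array, with background
differentiation at a chosen F_ST, array-scale linkage structure, and planted
signals — hard selective sweeps (a long shared haplotype at high frequency in
one group) and autozygous segments that produce runs of homozygosity.

Model
-----
* Per SNP, an ancestral allele frequency p ~ U(ancestral_maf_range).
* Each population's frequency is Balding–Nichols: Beta(p(1-F)/F, (1-p)(1-F)/F)
  with F = ``fst_target`` (F = 0 degenerates to p itself).
* ``n_founders`` founder haplotypes per population are drawn site-wise from the
  population frequency; every sample haplotype is a recombinant mosaic of
  founders with crossover count ~ Poisson(recomb_rate * chrom_length) and
  uniform crossover positions.  This induces EHH/LD decay on the scale of the
  mean founder-segment length (1/recomb_rate) without coalescent machinery.
* Sweeps overwrite a window of carrier haplotypes with one template haplotype;
  autozygosity copies haplotype 1 onto haplotype 2 over a span.

Every operation derives its RNG stream from (config seed, operation name), so
stages are individually reproducible and mutually decoupled.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import (
    MISSING,
    GenotypeMatrix,
    HaplotypeSet,
    MarkerMap,
    write_hap_tsv,
    write_ped_map,
)


def _rng(seed: int, op: str) -> np.random.Generator:
    """Operation-scoped RNG: one stream per (seed, operation name)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(op.encode())]))


@dataclass
class SweepSpec:
    """A planted hard sweep: one template haplotype copied into carriers.

    ``extent_bp`` is the half-width of the swept window around ``core_bp``;
    ``target_freq`` is the haplotype frequency reached in the target population.
    """

    pop: int
    chrom: str
    core_bp: int
    extent_bp: int
    target_freq: float

    def __post_init__(self) -> None:
        if not 0 < self.target_freq <= 1:
            raise ValueError("target_freq must be in (0, 1]")
        if self.extent_bp <= 0:
            raise ValueError("extent_bp must be positive")


@dataclass
class AutozygositySpec:
    """A planted autozygous span carried by a fraction of one population."""

    pop: int
    chrom: str
    start_bp: int
    end_bp: int
    carrier_fraction: float

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValueError("start_bp must be < end_bp")
        if not 0 < self.carrier_fraction <= 1:
            raise ValueError("carrier_fraction must be in (0, 1]")


@dataclass
class SimulationConfig:
    """All knobs of the two-population simulator; the seed fully determines output."""

    n_diploids_per_pop: int = 30
    chromosomes: list[tuple[str, int]] = field(default_factory=lambda: [("1", 50_000_000)])
    snp_spacing_bp: int = 50_000
    n_founders: int = 30
    recomb_rate: float = 1e-6  # crossovers per bp per mosaic draw (mean segment 1 Mb)
    ancestral_maf_range: tuple[float, float] = (0.1, 0.9)
    fst_target: float = 0.05
    sweep_specs: list[SweepSpec] = field(default_factory=list)
    autozygosity_specs: list[AutozygositySpec] = field(default_factory=list)
    seed: int = 0
    n_pops: int = 2

    def __post_init__(self) -> None:
        lo, hi = self.ancestral_maf_range
        if not 0 < lo < hi < 1:
            raise ValueError("ancestral_maf_range must satisfy 0 < lo < hi < 1")
        if not 0 <= self.fst_target < 1:
            raise ValueError("fst_target must be in [0, 1)")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if self.n_diploids_per_pop <= 0 or self.n_founders <= 0:
            raise ValueError("counts must be positive")
        if self.fst_target == 0 and self.n_founders < 2:
            raise ValueError("fst_target 0 with < 2 founders leaves no diversity source")


@dataclass
class TruthSet:
    """Ground truth of one simulation run, for downstream recovery tests."""

    markers: MarkerMap
    ancestral_freq: np.ndarray
    pop_freqs: dict[str, np.ndarray]
    sweeps: list[dict] = field(default_factory=list)
    autozygosity: list[dict] = field(default_factory=list)

    def write(self, prefix) -> tuple[Path, Path]:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        intervals = Path(f"{prefix}.truth_intervals.tsv")
        rows = []
        for s in self.sweeps:
            rows.append(
                ("sweep", s["pop"], s.get("individual", "."), s["chrom"],
                 s["start_bp"], s["end_bp"], s["n_carriers"])
            )
        for a in self.autozygosity:
            rows.append(
                ("autozygosity", a["pop"], a["individual"], a["chrom"],
                 a["start_bp"], a["end_bp"], 1)
            )
        pd.DataFrame(
            rows, columns=["record", "pop", "individual", "chrom", "start_bp", "end_bp", "value"]
        ).to_csv(intervals, sep="\t", index=False)

        freqs = Path(f"{prefix}.truth_freqs.tsv")
        df = pd.DataFrame({"chrom": self.markers.chrom, "snp": self.markers.snp,
                           "bp": self.markers.bp, "ancestral": self.ancestral_freq})
        for pop, f in self.pop_freqs.items():
            df[pop] = f
        df.to_csv(freqs, sep="\t", index=False, float_format="%.10g")
        return intervals, freqs

    @staticmethod
    def read_intervals(path) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t", dtype={"chrom": str, "pop": str, "individual": str})


def _marker_positions(config: SimulationConfig, rng: np.random.Generator) -> MarkerMap:
    rows = []
    for chrom, length in config.chromosomes:
        m = max(int(round(length / config.snp_spacing_bp)), 0)
        if m < 2:
            raise ValueError(f"chromosome {chrom}: fewer than 2 markers at the requested spacing")
        pos = np.sort(rng.integers(1, length + 1, size=m))
        # enforce strictly increasing positions
        pos = pos + np.arange(m)
        rows.append(pd.DataFrame({"chrom": str(chrom), "snp": [f"snp_{chrom}_{i}" for i in range(m)],
                                  "bp": pos, "a_minor": "A", "a_major": "B"}))
    return MarkerMap(pd.concat(rows, ignore_index=True))


def simulate_haplotypes(config: SimulationConfig) -> tuple[dict[str, HaplotypeSet], TruthSet]:
    """Simulate phased haplotypes for each population plus the truth record.

    Returns ``({pop_label: HaplotypeSet}, TruthSet)``; population labels are
    ``pop1``, ``pop2``.  Planted sweeps/autozygosity from the config are applied
    in order after the neutral background.
    """
    rng = _rng(config.seed, "simulate_haplotypes")
    markers = _marker_positions(config, rng)
    m = markers.n_markers

    lo, hi = config.ancestral_maf_range
    anc = rng.uniform(lo, hi, size=m)
    F = config.fst_target
    pop_freqs: dict[str, np.ndarray] = {}
    haps_by_pop: dict[str, HaplotypeSet] = {}
    chrom_arr = markers.chrom
    bp = markers.bp

    for p in range(config.n_pops):
        label = f"pop{p + 1}"
        if F > 0:
            freq = rng.beta(anc * (1 - F) / F, (1 - anc) * (1 - F) / F)
        else:
            freq = anc.copy()
        pop_freqs[label] = freq
        founders = (rng.random((config.n_founders, m)) < freq).astype(np.int8)

        n_hap = 2 * config.n_diploids_per_pop
        haps = np.empty((n_hap, m), dtype=np.int8)
        for chrom, length in config.chromosomes:
            idx = np.flatnonzero(chrom_arr == str(chrom))
            cpos = bp[idx]
            for h in range(n_hap):
                k = rng.poisson(config.recomb_rate * length)
                breaks = np.sort(rng.integers(1, length + 1, size=k))
                founder_ids = rng.integers(0, config.n_founders, size=k + 1)
                seg = np.searchsorted(breaks, cpos, side="right")
                haps[h, idx] = founders[founder_ids[seg], idx]
        sample_ids = [f"{label}_ind{i}" for i in range(config.n_diploids_per_pop)]
        haps_by_pop[label] = HaplotypeSet(haps, sample_ids, label, markers)

    truth = TruthSet(markers, anc, pop_freqs)
    for si, spec in enumerate(config.sweep_specs):
        label = f"pop{spec.pop + 1}"
        haps_by_pop[label] = inject_sweep(
            haps_by_pop[label], spec, seed=config.seed + 7919 * (si + 1), truth=truth
        )
    for ai, spec in enumerate(config.autozygosity_specs):
        label = f"pop{spec.pop + 1}"
        haps_by_pop[label] = inject_autozygosity(
            haps_by_pop[label], spec, seed=config.seed + 104729 * (ai + 1), truth=truth
        )
    return haps_by_pop, truth


def _span_indices(markers: MarkerMap, chrom: str, start_bp: int, end_bp: int) -> np.ndarray:
    idx = markers.chrom_indices(chrom)
    bp = markers.bp[idx]
    return idx[(bp >= start_bp) & (bp <= end_bp)]


def inject_sweep(haps: HaplotypeSet, spec: SweepSpec, seed: int,
                 truth: TruthSet | None = None) -> HaplotypeSet:
    """Plant a hard sweep: copy one template haplotype into carriers over a window."""
    import warnings

    chrom_lengths = {c: haps.markers.bp[haps.markers.chrom_indices(c)].max()
                     for c in haps.markers.chromosomes()}
    if spec.chrom not in chrom_lengths:
        raise ValueError(f"chromosome {spec.chrom!r} not in marker map")
    start = spec.core_bp - spec.extent_bp
    end = spec.core_bp + spec.extent_bp
    win = _span_indices(haps.markers, spec.chrom, start, end)
    if len(win) < 30:
        warnings.warn(
            f"sweep window holds only {len(win)} SNPs; it may be undetectable "
            "under a >=3-significant-SNP window rule",
            stacklevel=2,
        )
    rng = _rng(seed, "inject_sweep")
    n_hap = haps.n_haplotypes
    n_carriers = int(round(spec.target_freq * n_hap))
    template = int(rng.integers(0, n_hap))
    others = np.setdiff1d(np.arange(n_hap), [template])
    extra = rng.choice(others, size=max(n_carriers - 1, 0), replace=False)
    carriers = np.concatenate([[template], extra])[:n_carriers]
    new = haps.haps.copy()
    new[np.ix_(carriers, win)] = haps.haps[template, win]
    if truth is not None:
        truth.sweeps.append(
            {"pop": haps.population, "chrom": spec.chrom, "core_bp": spec.core_bp,
             "start_bp": start, "end_bp": end, "n_carriers": int(n_carriers)}
        )
    return HaplotypeSet(new, list(haps.sample_ids), haps.population, haps.markers)


def inject_autozygosity(haps: HaplotypeSet, spec: AutozygositySpec, seed: int,
                        truth: TruthSet | None = None) -> HaplotypeSet:
    """Plant exact autozygous runs: haplotype 2 := haplotype 1 over the span."""
    span = _span_indices(haps.markers, spec.chrom, spec.start_bp, spec.end_bp)
    if len(span) == 0:
        raise ValueError("autozygosity span contains no SNPs")
    rng = _rng(seed, "inject_autozygosity")
    n_ind = haps.n_individuals
    n_carriers = int(round(spec.carrier_fraction * n_ind))
    carriers = rng.choice(n_ind, size=n_carriers, replace=False)
    new = haps.haps.copy()
    for i in carriers:
        new[2 * i + 1, span] = new[2 * i, span]
    if truth is not None:
        for i in sorted(carriers):
            truth.autozygosity.append(
                {"pop": haps.population, "individual": haps.sample_ids[i],
                 "chrom": spec.chrom, "start_bp": spec.start_bp, "end_bp": spec.end_bp}
            )
    return HaplotypeSet(new, list(haps.sample_ids), haps.population, haps.markers)


def diploidize_and_emit(haps_by_pop: dict[str, HaplotypeSet], missing_rate: float = 0.0,
                        genotyping_error_rate: float = 0.0, seed: int = 0,
                        out_prefix=None, truth: TruthSet | None = None) -> GenotypeMatrix:
    """Collapse haplotype pairs to genotypes, add call noise, optionally emit files.

    Allele-flip errors are applied at the haplotype-allele level (so the emitted
    phased file and PED stay mutually consistent); missingness is applied to
    genotype calls only.  Emits ``<prefix>.ped/.map``, per-population
    ``<prefix>.<pop>.haps.tsv`` and the truth TSVs when ``out_prefix`` is given.
    """
    if not 0 <= missing_rate <= 1 or not 0 <= genotyping_error_rate <= 1:
        raise ValueError("rates must be in [0, 1]")
    rng = _rng(seed, "diploidize_and_emit")

    noisy: dict[str, HaplotypeSet] = {}
    genos = []
    for pop, hs in haps_by_pop.items():
        h = hs.haps.copy()
        if genotyping_error_rate > 0:
            flips = rng.random(h.shape) < genotyping_error_rate
            h[flips] = 1 - h[flips]
        noisy[pop] = HaplotypeSet(h, list(hs.sample_ids), pop, hs.markers)
        genos.append(noisy[pop].to_genotypes())

    geno = GenotypeMatrix(
        np.vstack([g.geno for g in genos]),
        [s for g in genos for s in g.sample_ids],
        [p for g in genos for p in g.populations],
        genos[0].markers,
    )
    if missing_rate > 0:
        mask = rng.random(geno.geno.shape) < missing_rate
        g = geno.geno.copy()
        g[mask] = MISSING
        geno = GenotypeMatrix(g, geno.sample_ids, geno.populations, geno.markers)

    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        write_ped_map(geno, out_prefix)
        for pop, hs in noisy.items():
            write_hap_tsv(hs, f"{out_prefix}.{pop}.haps.tsv")
        if truth is not None:
            truth.write(out_prefix)
    return geno


# ---------------------------------------------------------------------------
# Forward Wright–Fisher simulator (independent of the founder-mosaic model):
# a random-mating diploid population with per-meiosis recombination, used to
# generate data whose true effective population size is known.
# ---------------------------------------------------------------------------

def wright_fisher_haplotypes(n_diploids: int = 100, n_snps: int = 2000,
                             chrom_length_bp: int = 100_000_000,
                             n_generations: int = 200,
                             recomb_rate_per_bp: float = 1e-8,
                             init_maf_range: tuple[float, float] = (0.1, 0.9),
                             seed: int = 0) -> HaplotypeSet:
    """Simulate a single random-mating population forward in time.

    Each generation, every offspring haplotype is a recombinant gamete of a
    uniformly chosen parent (crossovers Bernoulli per marker interval at
    ``recomb_rate_per_bp`` per bp, i.e. 1 cM/Mb at the default).  Initial
    haplotypes are site-wise Bernoulli draws at U(init_maf_range) frequencies,
    so linkage disequilibrium at drift–recombination equilibrium builds up over
    the simulated generations.
    """
    rng = _rng(seed, "wright_fisher")
    lo, hi = init_maf_range
    pos = np.sort(rng.choice(np.arange(1, chrom_length_bp), size=n_snps, replace=False))
    freq = rng.uniform(lo, hi, size=n_snps)
    n_hap = 2 * n_diploids
    haps = (rng.random((n_hap, n_snps)) < freq).astype(np.int8)

    gap = np.diff(pos).astype(float)
    p_cross = 0.5 * (1.0 - np.exp(-2.0 * recomb_rate_per_bp * gap))  # Haldane per interval

    for _ in range(n_generations):
        parents = rng.integers(0, n_diploids, size=n_hap)
        pa = haps[2 * parents]
        pb = haps[2 * parents + 1]
        crosses = rng.random((n_hap, n_snps - 1)) < p_cross
        start = rng.integers(0, 2, size=(n_hap, 1))
        phase = (start + np.cumsum(crosses, axis=1, dtype=np.int32) % 2) % 2
        phase = np.concatenate([start, phase], axis=1).astype(bool)
        haps = np.where(phase, pb, pa).astype(np.int8)

    markers = MarkerMap(pd.DataFrame({
        "chrom": "1", "snp": [f"wf_{i}" for i in range(n_snps)], "bp": pos,
        "a_minor": "A", "a_major": "B"}))
    ids = [f"wf_ind{i}" for i in range(n_diploids)]
    return HaplotypeSet(haps, ids, "wf", markers)
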