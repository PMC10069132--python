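# Methods

`popscan` reimplements, as a tested pipeline over synthetic data with known
truth, a standard livestock population-genomics workflow: SNP-array quality
control, within- and between-population diversity, runs of homozygosity (ROH)
and the genomic inbreeding coefficient F_ROH, ROH islands, and
cross-population extended-haplotype-homozygosity scans (Rsb and XP-EHH) with
window-consensus candidate-region calling. This note records the models,
conventions, and numerical choices, and what the synthetic experiments do and
do not demonstrate about real data.

## Synthetic data model

Real array genotypes for this kind of study are usually not redistributable,
so every downstream stage is exercised on simulated two-population data in
which the quantities to be recovered are planted.

**Background.** Per SNP, an ancestral allele frequency p is drawn uniformly
on `ancestral_maf_range` (default 0.1–0.9). Each population's frequency
follows the Balding–Nichols model, Beta(p(1−F)/F, (1−p)(1−F)/F), with
F = `fst_target` (default 0.05, a plausible within-breed-group value; F = 0
degenerates to p). Linkage structure comes from a founder-mosaic construction:
`n_founders` founder haplotypes per population are drawn site-wise from the
population frequency, and each sample haplotype is a mosaic of founders with
crossover count ~ Poisson(`recomb_rate` × chromosome length) and uniform
crossover positions.

**Defaults and why.**

| parameter | default | rationale |
|---|---|---|
| `n_diploids_per_pop` | 30 | typical per-breed array study sample size |
| `snp_spacing_bp` | 50 kb | medium-density (≈50K) array on a ≈2.5 Gb genome |
| `n_founders` | 30 | mirrors the ≈30-haplotype-cluster structure that phasing models fit to such data; gives realistic EHH decay over ≈1 Mb |
| `recomb_rate` | 1e−6 /bp | mean founder segment 1 Mb, so background haplotype sharing decays on the Mb scale as on real arrays |
| `fst_target` | 0.05 | modest between-group differentiation |

A deliberate property of the founder-mosaic model: the founder pool is a
bottleneck, so realized between-population differentiation is approximately
`fst_target` + (1 − `fst_target`)/`n_founders`, and pairs of haplotypes within
an individual occasionally share a founder over a long stretch, creating
*background autozygosity*. Experiments whose planted truth would be
contaminated by these effects — F_ST recovery, ROH-island recovery, F_ROH
recovery — therefore run in an "outbred" regime with 500 founders (bottleneck
contribution ≈0.002 to F_ST; background ROH essentially absent), while the
sweep/EHH experiments keep the 30-founder haplotype-cluster regime whose LD is
the signal those statistics consume.

**Planted signals.** A hard sweep copies one template haplotype into
round(`target_freq` × 2n) haplotypes over ±`extent_bp` around the core;
markers outside the window are untouched. Autozygosity copies haplotype 1
onto haplotype 2 over a span for a `carrier_fraction` of individuals, so the
planted run is exactly homozygous. Genotypes are haplotype-pair sums, with
optional symmetric allele-flip error (applied at the haplotype level so the
emitted phased file and PED stay consistent) and per-call missingness (applied
to genotypes only). All randomness derives from (seed, operation name), so
every stage is reproducible in isolation.

The simulator is *not* a demographic model: no mutation, no coalescent
genealogy, no soft sweeps, and no meaningful "true Ne" for the mosaic
background. Passing tests show the estimators recover what was planted under
array-like marker density and LD, not that they are robust to demographic
histories the generator cannot produce. The LD-based Ne estimator is
validated separately against a forward Wright–Fisher simulation (random
mating, N = 100 diploids, Haldane recombination at 1 cM/Mb, 200 generations)
in which the true size is known.

## Quality control

Six filters in the listed order: (1) SNP call rate strictly > 0.90;
(2) markers without a chromosome or physical position; (3) individuals with
missing fraction not strictly < 0.05, judged on the **full input panel** (an
animal's genotyping success rate, the PLINK `--mind` convention — on small
panels a post-filter denominator would make this rule unreachable, because any
marker carrying a missing call already fails the strict call-rate rule);
(4) MAF strictly > 0.01, recomputed after sample removal; (5) autosomes only
(labels 1–26 by default, configurable); (6) greedy first-seen-kept removal of
one member of each sample pair with identity-by-state ≥ 0.99, computed as the
mean shared-allele fraction over mutually non-missing markers on the
post-filter, pre-pruning set. Thresholds are taken literally as strict
inequalities. LD pruning slides a 50-SNP window in 5-SNP steps and removes
markers until no retained within-window pair has genotype-dosage r² > 0.5;
the removal rule (drop the lower-call-rate member of the worst pair, ties to
the higher index) is a deterministic stand-in for undocumented tool-specific
tie-breaking, and full sweeps repeat to a fixed point so the bound holds on
the output by construction.

The LD-pruned set feeds only the diversity/structure branch; ROH and EHH
branches use the unpruned post-QC set.

## Diversity and structure

H_O is the per-marker heterozygote fraction among non-missing calls; H_E is
plain 2p(1−p) (the PLINK convention; the unbiased 2n/(2n−1) version is a
flag). Summaries are mean ± SD over all markers, monomorphic included.

F_ST is the Weir–Cockerham (1984) two-population θ, with per-locus variance
components combined as a ratio of sums over loci. Significance comes from
permuting individuals between the pair, with p = (1 + #{θ* ≥ θ̂})/(n_perm+1);
the default 1,000 permutations keep test runtimes reasonable (production
studies use 10,000). Reynolds distance is the drift-linearized
D = −ln(1 − θ̂) with θ̂ clamped to [0, 1). Note θ̂ is a between-*sample*
differentiation estimator: any bottleneck in how the samples were generated
(founder pools included) is real differentiation to it.

Structure uses classical (Torgerson) MDS of 1 − IBS distances:
double-center −d²/2, eigendecompose, coordinates from the top-k positive
eigenvalues, explained fractions relative to the positive spectrum. For
Euclidean inputs the embedding is exact, which the tests verify to 1e−6.

**LD-based Ne.** Sved's relation E[r²] ≈ 1/(α + 4Nc) is inverted per
recombination-distance bin: syntenic pair distance c = bp × 1e−8 Morgans
(constant 1 cM/Mb map), composite (genotype-dosage) r², bins of width 0.005 M
over 0.005–0.1 M, sample correction r²_adj = r̄² − 1/n, α = 1, and
N_e(bin) = (1/4c̄)(1/r²_adj − α) at t = 1/(2c̄) generations back. Ne13/Ne50
are read from the bins with t nearest 13 and 50. Groups below 20 individuals
are skipped; larger groups are subsampled to 20 (seeded), matching the
study-design convention this follows. Bins with r²_adj ≥ 1/α (within 1e−9)
are reported undefined. Against the Wright–Fisher oracle the estimator lands
within a factor of two of truth for 10 ≤ t ≤ 50; tool-exact parity with any
particular Ne software (mutation adjustments, phasing corrections, adaptive
binning) is out of scope.

## Runs of homozygosity

The caller implements the segment criteria *declaratively* with
exhaustive-maximal semantics rather than a scanning-window heuristic: a
segment is a maximal marker interval per individual and chromosome with
≥ 30 SNPs, span ≥ 1 Mb (first to last SNP, inclusive), ≤ 1 heterozygous and
≤ 1 missing call, mean density ≤ 100 kb/SNP, and no adjacent gap > 500 kb.
Maximality means no qualifying superset exists; overlapping qualifying
intervals merge into their union when the union qualifies, otherwise the
longer (ties leftmost) is kept. Internally, gap violations hard-split each
chromosome; a two-pointer pass finds heterozygosity/missingness-clean maximal
windows; within each window a vectorized interval grid plus cumulative-OR
maximality screen finds candidates. The implementation is verified to equal
exhaustive subinterval enumeration on hundreds of randomized fixtures; a
window-scanning caller agrees only approximately, which is a documented
divergence in the oracle-verified semantics' favour.

F_ROH = L_ROH/L_AUT per individual, with L_AUT defaulting to the ≈2,452.06 Mb
autosomal coverage of the ovine medium-density chip; analyses on simulated
genomes pass the simulated genome length instead. The mean ROH count is
reported with both denominators (all individuals, and carriers of ≥ 1
segment), since the field uses both. Length classes: 1–<5, 5–<10, 10–<15,
15–<20, ≥20 Mb.

**ROH islands.** Per-SNP incidence is the fraction of group members whose ROH
covers the SNP; the threshold is the nearest-rank 99.9th percentile of the
group's genome-wide incidence distribution; islands are maximal runs of
consecutive markers with incidence strictly above it (single-SNP islands
allowed; computed genome-wide per group, not per chromosome). A consequence
worth knowing: on panels where a common autozygous plateau spans ≥ 0.1% of
all markers, the percentile threshold lands *on* the plateau and the strict
comparison returns nothing — island calling is intrinsically a chip-scale
(tens of thousands of markers) procedure, and the recovery experiment
simulates a 2.4 Gb / 48,000 SNP genome accordingly.

## EHH statistics

At core s and marker t, haplotypes partition into classes identical over
[s..t]. Two site-specific EHH variants are implemented, both defined as 1 at
the core:

* **tang** (used for Rsb): Σ_k n_k(n_k−1) / Σ_a n_a(n_a−1), a over core-allele
  classes — the probability that a random ordered pair, homozygous at the
  core, is identical out to t;
* **sabeti** (used for XP-EHH): Σ_k C(n_k,2) / C(n,2) — the fraction of all
  unordered pairs identical over the interval.

A haplotype with a missing allele leaves all classes (numerator and
denominator) from that marker outward; a core monomorphic under tang is
undefined. iES integrates EHHS over physical position by the trapezoid rule,
each side truncated at the first marker with EHHS < 0.05 (that marker
included); a side that reaches the chromosome end still at or above the
cutoff marks the site undefined (border discard, default on). Both choices
match the conventional implementation of these statistics.

Per SNP, raw = ln(iES_A/iES_B); Rsb standardizes with median-centering,
XP-EHH with mean-centering, both by the genome-wide SD (a plain Z-test, no
frequency binning). The two-sided p-score is −log10(1 − 2|Φ(z) − 0.5|),
computed via the normal log-survival function for tail accuracy. Windows of
250 kb tile each chromosome from the first marker position with 10-kb overlap
(terminal windows may be shorter); a window is significant with ≥ 3 SNPs
strictly above −log10 p = 4. Per method, overlapping significant windows
merge into regions bounded by their first/last significant SNP (SNP-edge, not
window-edge, boundaries); regions from different methods (including ROH
islands) overlapping by ≥ 1 bp consolidate into one candidate region with the
union span and the joined method set.

## Calibration and power (what the experiments measure)

`popscan.experiments` fixes the study conditions; the test suite asserts on
them and `scripts/acceptance.py` reports them:

* EHHS and ROH callers equal their brute-force oracles on 200 random
  fixtures each (pair counting ≤ 16 haplotypes × 20 markers; exhaustive
  interval enumeration ≤ 50 SNPs × 20 individuals).
* Balding–Nichols F = 0.10 (5,000 SNPs, 50/pop, outbred regime): genome-wide
  θ̂ within ±0.02 in ≥ 18/20 replicates.
* Sweep power: frequency-0.9, 1-Mb-half-width sweep on a 40-Mb chromosome at
  1 SNP/25 kb, 50/pop — a region supported by both Rsb and XP-EHH overlaps
  the core in ≥ 18/20 replicates; the matched no-sweep simulations yield
  ≤ 0.5% of SNPs above p-score 4 and a median of zero significant windows.
* Island recovery: one 2-Mb span at carrier fraction 0.6 on a 48,000-SNP
  outbred genome — exactly one island, overlapping the span, in ≥ 18/20.
* F_ROH: noise-free spans covering 8% of the covered genome — mean F_ROH
  within 0.08 ± 0.01.
* Ne: within a factor of two of the Wright–Fisher truth (N = 100) for all
  bins with 10 ≤ t ≤ 50 in ≥ 8/10 replicates.

Problem sizes (single 40-Mb chromosomes for scans, 20 replicate seeds,
1,000-permutation default) are the package's chosen balance between
statistical resolution and the few minutes a full verification run takes.

## Known limitations

* PED/MAP and haplotype-TSV parsing is strict by design; malformed records
  raise rather than coerce.
* Strand harmonization in merging drops A/T and C/G ambiguous markers whose
  allele pairs disagree; no frequency-based resolution is attempted.
* The ROH caller's exhaustive-maximal semantics can differ from
  window-scanning tools near segment boundaries.
* Haplotype phasing itself, model-based clustering (Admixture-style), graph
  migration fitting, and gene annotation are out of scope.
* `apply_qc` is idempotent on its own output in the tested regimes, but
  pathological missingness patterns interacting with the full-panel
  missingness rule could in principle require a second pass.
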