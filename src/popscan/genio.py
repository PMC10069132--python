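"""Genotype and haplotype containers plus the text formats the pipeline touches.

The in-memory model is deliberately small: a :class:`MarkerMap` (ordered SNP
annotation), a :class:`GenotypeMatrix` (samples x markers minor-allele dosages
with ``-1`` for missing), and a :class:`HaplotypeSet` (phased binary haplotypes,
two consecutive rows per individual).  Readers reject malformed records rather
than coercing them; ``read . write`` is the identity on the in-memory model.

Supported formats: PLINK text PED/MAP, a phased haplotype matrix as TSV
(rows = haplotypes, columns = markers, header = marker ids), and phased VCF
(via pysam; unphased GT separators are an error).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

#: complementary bases, used when harmonizing allele orientation across files
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: sentinel for an unobserved (monomorphic) minor allele
NO_ALLELE = "0"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class MarkerMap:
    """Ordered marker annotation: chromosome, id, bp position, allele codes.

    ``a_minor`` is the counted (dosage) allele; ``a_major`` the other one.
    Positions are 1-based and strictly increasing within each chromosome.
    """

    table: pd.DataFrame

    REQUIRED = ("chrom", "snp", "bp", "a_minor", "a_major")

    def __post_init__(self) -> None:
        missing_cols = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing_cols:
            raise ValueError(f"MarkerMap missing columns {missing_cols}")
        t = self.table.reset_index(drop=True)
        t["chrom"] = t["chrom"].astype(str)
        t["snp"] = t["snp"].astype(str)
        t["bp"] = t["bp"].astype(np.int64)
        self.table = t
        if t["snp"].duplicated().any():
            dup = t.loc[t["snp"].duplicated(), "snp"].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        for chrom, grp in t.groupby("chrom", sort=False):
            bp = grp["bp"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def snp(self) -> np.ndarray:
        return self.table["snp"].to_numpy()

    @property
    def bp(self) -> np.ndarray:
        return self.table["bp"].to_numpy()

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == str(chrom))

    def subset(self, idx) -> "MarkerMap":
        idx = np.asarray(idx, dtype=np.intp)
        return MarkerMap(self.table.iloc[idx].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls (minor-allele dosage 0/1/2, -1 missing)."""

    geno: np.ndarray
    sample_ids: list[str]
    populations: list[str]
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (samples x markers)")
        n, m = self.geno.shape
        if len(self.sample_ids) != n or len(self.populations) != n:
            raise ValueError("sample id / population label count mismatch")
        if self.markers.n_markers != m:
            raise ValueError("marker map length does not match genotype columns")
        if any(not p for p in self.populations):
            raise ValueError("population labels must be non-empty")

    @property
    def n_samples(self) -> int:
        return self.geno.shape[0]

    @property
    def n_markers(self) -> int:
        return self.geno.shape[1]

    def subset_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeMatrix(
            self.geno[idx],
            [self.sample_ids[i] for i in idx],
            [self.populations[i] for i in idx],
            self.markers,
        )

    def subset_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeMatrix(
            self.geno[:, idx], list(self.sample_ids), list(self.populations), self.markers.subset(idx)
        )

    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls."""
        return (self.geno != MISSING).mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return (self.geno == MISSING).mean(axis=1)

    def allele_freq(self) -> np.ndarray:
        """Per-marker frequency of the counted (minor at load time) allele."""
        g = np.ma.masked_equal(self.geno, MISSING)
        return np.asarray(g.mean(axis=0).filled(np.nan)) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def group_indices(self) -> dict[str, np.ndarray]:
        pops = np.asarray(self.populations)
        return {p: np.flatnonzero(pops == p) for p in dict.fromkeys(self.populations)}


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes for one population.

    Rows ``2i`` and ``2i+1`` are the two haplotypes of individual ``i``.
    Alleles are 0/1 (``-1`` marks a missing allele, tolerated only by the EHH
    statistics' drop-out rule).
    """

    haps: np.ndarray
    sample_ids: list[str]
    population: str
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.haps = np.asarray(self.haps, dtype=np.int8)
        if self.haps.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if self.haps.shape[0] % 2:
            raise ValueError("odd haplotype count: haplotypes must pair per individual")
        if self.haps.shape[0] // 2 != len(self.sample_ids):
            raise ValueError("sample id count must be half the haplotype count")
        if self.markers.n_markers != self.haps.shape[1]:
            raise ValueError("marker map length does not match haplotype columns")
        bad = ~np.isin(self.haps, (0, 1, MISSING))
        if bad.any():
            raise ValueError("haplotype alleles must be 0/1 (or -1 missing)")

    @property
    def n_haplotypes(self) -> int:
        return self.haps.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.haps.shape[0] // 2

    def to_genotypes(self) -> GenotypeMatrix:
        """Collapse haplotype pairs to dosage genotypes (missing if either allele is)."""
        a = self.haps[0::2].astype(np.int16)
        b = self.haps[1::2].astype(np.int16)
        g = a + b
        g[(a == MISSING) | (b == MISSING)] = MISSING
        return GenotypeMatrix(
            g.astype(np.int8),
            list(self.sample_ids),
            [self.population] * len(self.sample_ids),
            self.markers,
        )


# ---------------------------------------------------------------------------
# PED / MAP
# ---------------------------------------------------------------------------

def read_map(map_path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise FormatError(f"{map_path}: line {lineno}: expected 4 MAP columns, got {len(parts)}")
            rows.append((parts[0], parts[1], parts[2], int(parts[3])))
    return pd.DataFrame(rows, columns=["chrom", "snp", "cm", "bp"])


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK text PED/MAP into a minor-allele-dosage genotype matrix.

    Allele coding is resolved at load time: the counted allele is the less
    frequent one over all samples (ties broken toward the lexicographically
    smaller allele), so downstream heterozygosity/MAF are orientation-free.
    ``0 0`` is missing; a third allele at any marker is an error.
    """
    mp = read_map(map_path)
    m = len(mp)
    sample_ids: list[str] = []
    populations: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            populations.append(parts[0])
            sample_ids.append(parts[1])
            allele_rows.append(parts[6:])
    if not allele_rows:
        raise FormatError(f"{ped_path}: no samples")
    alleles = np.array(allele_rows, dtype="U8").reshape(len(allele_rows), m, 2)

    n = alleles.shape[0]
    geno = np.zeros((n, m), dtype=np.int8)
    a_minor: list[str] = []
    a_major: list[str] = []
    for j in range(m):
        col = alleles[:, j, :]
        obs = col[col != NO_ALLELE]
        uniq, counts = np.unique(obs, return_counts=True)
        if len(uniq) > 2:
            raise FormatError(f"marker {mp['snp'].iloc[j]!r} has >2 alleles: {sorted(uniq)}")
        if len(uniq) == 0:
            a_minor.append(NO_ALLELE)
            a_major.append(NO_ALLELE)
            geno[:, j] = MISSING
            continue
        if len(uniq) == 1:
            major, minor = uniq[0], NO_ALLELE
        else:
            # minor = less frequent; tie -> lexicographically smaller
            order = np.lexsort((uniq, counts))
            minor, major = uniq[order[0]], uniq[order[1]]
        missing_mask = (col == NO_ALLELE).any(axis=1)
        half_missing = (col == NO_ALLELE).any(axis=1) & ~(col == NO_ALLELE).all(axis=1)
        if half_missing.any():
            raise FormatError(f"marker {mp['snp'].iloc[j]!r}: half-missing genotype call")
        dosage = (col == minor).sum(axis=1).astype(np.int8)
        dosage[missing_mask] = MISSING
        geno[:, j] = dosage
        a_minor.append(minor)
        a_major.append(major)

    markers = MarkerMap(
        pd.DataFrame(
            {
                "chrom": mp["chrom"],
                "snp": mp["snp"],
                "bp": mp["bp"],
                "a_minor": a_minor,
                "a_major": a_major,
            }
        )
    )
    return GenotypeMatrix(geno, sample_ids, populations, markers)


def write_ped_map(geno: GenotypeMatrix, prefix) -> tuple[Path, Path]:
    """Write PLINK text PED/MAP.

    PED header fields: family id = population label, individual id, parents 0 0,
    sex 0, phenotype -9.  Heterozygotes are written minor allele first.
    """
    if geno.n_samples == 0 or geno.n_markers == 0:
        raise ValueError("refusing to write an empty genotype matrix")
    t = geno.markers.table
    if ((t["a_major"] == NO_ALLELE) & (geno.geno.max(axis=0) >= 0)).any():
        raise ValueError("missing allele codes for one or more markers")
    if (t["a_minor"] == NO_ALLELE).any() and (geno.geno == 1).any(axis=0)[
        (t["a_minor"] == NO_ALLELE).to_numpy()
    ].any():
        raise ValueError("marker without a minor-allele code carries nonzero dosage")

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    with open(map_path, "w") as fh:
        for _, row in t.iterrows():
            fh.write(f"{row.chrom}\t{row.snp}\t0\t{row.bp}\n")

    minor = t["a_minor"].to_numpy()
    major = t["a_major"].to_numpy()
    pair_by_code = {
        0: [f"{ma} {ma}" for ma in major],
        1: [f"{mi} {ma}" for mi, ma in zip(minor, major)],
        2: [f"{mi} {mi}" for mi in minor],
        MISSING: ["0 0"] * geno.n_markers,
    }
    with open(ped_path, "w") as fh:
        for i in range(geno.n_samples):
            fields = [geno.populations[i], geno.sample_ids[i], "0", "0", "0", "-9"]
            row = geno.geno[i]
            fields.extend(pair_by_code[int(g)][j] for j, g in enumerate(row))
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# Phased haplotypes
# ---------------------------------------------------------------------------

def write_hap_tsv(haps: HaplotypeSet, path) -> Path:
    """Haplotype matrix as TSV: header = marker ids, one row per haplotype."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(haps.markers.snp) + "\n")
        for row in haps.haps:
            fh.write("\t".join(str(int(a)) for a in row) + "\n")
    return path


def read_phased(path, fmt: str = "tsv", markers: MarkerMap | None = None,
                population: str = "pop1", sample_ids: list[str] | None = None) -> HaplotypeSet:
    """Read already-phased haplotypes from TSV or phased VCF.

    TSV: rows = haplotypes, columns = markers, header row of marker ids.  A
    ``markers`` map should be supplied to attach positions; without one a
    unit-spaced stub map is synthesized (adequate for format tests only).
    VCF: one ``HaplotypeSet`` over all samples; any unphased GT ("/") or
    non-biallelic site is an error.
    """
    if fmt == "tsv":
        return _read_hap_tsv(path, markers, population, sample_ids)
    if fmt == "vcf":
        return _read_hap_vcf(path, population)
    raise ValueError(f"unsupported phased format {fmt!r}")


def _read_hap_tsv(path, markers, population, sample_ids) -> HaplotypeSet:
    with open(path) as fh:
        header = fh.readline().split()
        rows = []
        for lineno, line in enumerate(fh, 2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != len(header):
                raise FormatError(f"{path}: line {lineno}: ragged haplotype row")
            rows.append(parts)
    if len(rows) % 2:
        raise FormatError(f"{path}: odd haplotype count ({len(rows)})")
    haps = np.array(rows, dtype=np.int8)
    if markers is None:
        markers = MarkerMap(
            pd.DataFrame(
                {
                    "chrom": "1",
                    "snp": header,
                    "bp": np.arange(1, len(header) + 1),
                    "a_minor": "A",
                    "a_major": "B",
                }
            )
        )
    else:
        if list(markers.snp) != header:
            raise FormatError(f"{path}: header marker ids do not match the supplied map")
    if sample_ids is None:
        sample_ids = [f"{population}_{i}" for i in range(len(rows) // 2)]
    return HaplotypeSet(haps, sample_ids, population, markers)


def _read_hap_vcf(path, population) -> HaplotypeSet:
    import pysam

    rows_chrom, rows_id, rows_bp, rows_ref, rows_alt = [], [], [], [], []
    columns = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise FormatError(f"{path}: non-biallelic site at {rec.chrom}:{rec.pos}")
            col = np.empty(2 * len(samples), dtype=np.int8)
            for si, s in enumerate(samples):
                call = rec.samples[s]
                gt = call["GT"]
                if gt is None or len(gt) != 2 or gt[0] is None or gt[1] is None:
                    raise FormatError(f"{path}: missing GT at {rec.chrom}:{rec.pos} sample {s}")
                if not call.phased:
                    raise FormatError(
                        f"{path}: unphased genotype at {rec.chrom}:{rec.pos} sample {s}"
                    )
                col[2 * si] = gt[0]
                col[2 * si + 1] = gt[1]
            columns.append(col)
            rows_chrom.append(rec.chrom)
            rows_id.append(rec.id if rec.id else f"{rec.chrom}:{rec.pos}")
            rows_bp.append(rec.pos)
            rows_ref.append(rec.ref)
            rows_alt.append(rec.alts[0])
    if not columns:
        raise FormatError(f"{path}: no variant records")
    haps = np.stack(columns, axis=1)
    markers = MarkerMap(
        pd.DataFrame(
            {"chrom": rows_chrom, "snp": rows_id, "bp": rows_bp,
             "a_minor": rows_alt, "a_major": rows_ref}
        )
    )
    return HaplotypeSet(haps, samples, population, markers)


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def _is_ambiguous(a1: str, a2: str) -> bool:
    """A/T and C/G pairs cannot be strand-resolved without frequency heuristics."""
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def merge_on_markers(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Merge two datasets on shared markers, harmonizing allele orientation.

    Markers are matched on (id, chromosome, bp); samples are concatenated.
    Where the two files carry the same two alleles in swapped orientation the
    second file's dosages are flipped (2 - g).  Where the allele pairs differ,
    a strand flip (complement) is attempted unless the pair is A/T or C/G
    strand-ambiguous; unresolvable markers are dropped.
    """
    dup = set(a.sample_ids) & set(b.sample_ids)
    if dup:
        raise ValueError(f"duplicated sample ids across datasets: {sorted(dup)[:5]}")

    ta, tb = a.markers.table, b.markers.table
    key_a = {(r.snp, r.chrom, r.bp): i for i, r in enumerate(ta.itertuples())}
    keep_a: list[int] = []
    keep_b: list[int] = []
    flip_b: list[bool] = []
    for jb, r in enumerate(tb.itertuples()):
        ia = key_a.get((r.snp, r.chrom, r.bp))
        if ia is None:
            continue
        ra = ta.iloc[ia]
        pa = (ra["a_minor"], ra["a_major"])
        pb = (r.a_minor, r.a_major)
        decision = _orientation(pa, pb)
        if decision is None:
            continue
        keep_a.append(ia)
        keep_b.append(jb)
        flip_b.append(decision)
    if not keep_a:
        raise ValueError("no shared markers between datasets")

    order = np.argsort(keep_a, kind="stable")
    keep_a = [keep_a[i] for i in order]
    keep_b = [keep_b[i] for i in order]
    flip_b = [flip_b[i] for i in order]

    ga = a.geno[:, keep_a]
    gb = b.geno[:, keep_b].copy()
    flip_mask = np.asarray(flip_b)
    if flip_mask.any():
        cols = gb[:, flip_mask]
        flipped = (2 - cols).astype(np.int8)
        flipped[cols == MISSING] = MISSING
        gb[:, flip_mask] = flipped
    geno = np.vstack([ga, gb])
    markers = a.markers.subset(keep_a)
    return GenotypeMatrix(
        geno,
        list(a.sample_ids) + list(b.sample_ids),
        list(a.populations) + list(b.populations),
        markers,
    )


def _orientation(pa: tuple[str, str], pb: tuple[str, str]) -> bool | None:
    """Return False (keep), True (flip dosage), or None (drop) for one marker."""
    set_a = {x for x in pa if x != NO_ALLELE}
    set_b = {x for x in pb if x != NO_ALLELE}
    if set_b <= set_a or set_a <= set_b:
        if pa[0] != NO_ALLELE and pa[0] == pb[1] and pa[1] == pb[0]:
            return True
        return False
    # attempt strand flip
    if _is_ambiguous(*pa) or _is_ambiguous(*pb):
        return None
    comp_b = {_COMPLEMENT.get(x, "?") for x in set_b}
    if comp_b <= set_a or set_a <= comp_b:
        cb = tuple(_COMPLEMENT.get(x, "?") for x in pb)
        if pa[0] != NO_ALLELE and pa[0] == cb[1] and pa[1] == cb[0]:
            return True
        return False
    return None
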