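"""Runs of homozygosity: segment calling, F_ROH, length classes, ROH islands.

The caller implements segment criteria directly with exhaustive-maximal
semantics: a reported segment is a maximal marker interval (per individual and
chromosome) satisfying all of — minimum SNP count, minimum bp span, bounded
heterozygous and missing calls, bounded mean bp-per-SNP density, and no
adjacent-marker gap above the ceiling.  This is the declarative counterpart of
the common scanning-window heuristic; window-based callers approximate it.

F_ROH = L_ROH / L_AUT with L_AUT defaulting to the autosomal length covered by
the ovine medium-density array (2452.06 Mb).  ROH islands are maximal runs of
consecutive markers whose within-group ROH incidence strictly exceeds a
high nearest-rank percentile of the genome-wide incidence distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

L_AUT_DEFAULT = 2_452_060_000  # bp covered by the array on the autosomes


@dataclass
class ROHParams:
    min_length_bp: int = 1_000_000
    min_snps: int = 30
    max_het: int = 1
    max_missing: int = 1
    max_bp_per_snp: int = 100_000   # minimum density: one SNP per this many bp
    max_gap_bp: int = 500_000

    def __post_init__(self) -> None:
        for name in ("min_length_bp", "min_snps", "max_bp_per_snp", "max_gap_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_het < 0 or self.max_missing < 0:
            raise ValueError("allowances must be non-negative")


@dataclass
class ROHSegment:
    individual: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def _qualifies(pos: np.ndarray, het: np.ndarray, mis: np.ndarray,
               a: int, b: int, params: ROHParams) -> bool:
    """Whether marker interval [a, b] (inclusive indices) satisfies all criteria."""
    n = b - a + 1
    if n < params.min_snps:
        return False
    span = int(pos[b] - pos[a] + 1)
    if span < params.min_length_bp:
        return False
    if span / n > params.max_bp_per_snp:
        return False
    if het[a:b + 1].sum() > params.max_het:
        return False
    if mis[a:b + 1].sum() > params.max_missing:
        return False
    if n > 1 and np.max(np.diff(pos[a:b + 1])) > params.max_gap_bp:
        return False
    return True


def _maximal_in_window(pos: np.ndarray, params: ROHParams) -> list[tuple[int, int]]:
    """Maximal subintervals of a het/missing/gap-clean window that satisfy the
    SNP-count, span, and density criteria.  Returns (a, b) index pairs.

    Vectorized over the k x k interval grid; maximality via cumulative OR over
    supersets (an interval is maximal iff no interval extending it one marker
    left or right — or both — qualifies).
    """
    k = len(pos)
    if k < params.min_snps:
        return []
    a_idx = np.arange(k)
    span = pos[None, :] - pos[:, None] + 1            # span[a, b]
    nsnp = a_idx[None, :] - a_idx[:, None] + 1
    q = (nsnp >= params.min_snps) & (span >= params.min_length_bp) \
        & (span <= nsnp * params.max_bp_per_snp)
    if not q.any():
        return []
    # cum[a, b] = any qualifying interval with a' <= a and b' >= b
    cum = np.logical_or.accumulate(q, axis=0)
    cum = np.logical_or.accumulate(cum[:, ::-1], axis=1)[:, ::-1]
    has_super = np.zeros_like(q)
    has_super[1:, :] |= cum[:-1, :]
    has_super[:, :-1] |= cum[:, 1:]
    maximal = q & ~has_super
    aa, bb = np.nonzero(maximal)
    return list(zip(aa.tolist(), bb.tolist()))


def _merge_segments(cands: list[tuple[int, int]], pos, het, mis,
                    params: ROHParams) -> list[tuple[int, int]]:
    """Resolve overlapping qualifying intervals left-to-right: merge into the
    union when the union itself qualifies, else keep the longer (tie: leftmost)."""
    if not cands:
        return []
    cands = sorted(cands)
    out: list[tuple[int, int]] = []
    cur = cands[0]
    for nxt in cands[1:]:
        if nxt[0] <= cur[1]:  # overlap in marker indices
            union = (min(cur[0], nxt[0]), max(cur[1], nxt[1]))
            if _qualifies(pos, het, mis, union[0], union[1], params):
                cur = union
            else:
                len_cur = pos[cur[1]] - pos[cur[0]]
                len_nxt = pos[nxt[1]] - pos[nxt[0]]
                if len_nxt > len_cur:
                    cur = nxt
        else:
            out.append(cur)
            cur = nxt
    out.append(cur)
    return out


def _detect_one(pos: np.ndarray, het: np.ndarray, mis: np.ndarray,
                params: ROHParams) -> list[tuple[int, int]]:
    """All maximal qualifying intervals for one individual on one chromosome."""
    m = len(pos)
    if m == 0:
        return []
    # hard-split at gaps above the ceiling: no segment may bridge them
    gap_breaks = np.flatnonzero(np.diff(pos) > params.max_gap_bp)
    block_starts = np.r_[0, gap_breaks + 1]
    block_ends = np.r_[gap_breaks, m - 1]

    cands: list[tuple[int, int]] = []
    for blo, bhi in zip(block_starts, block_ends):
        # two-pointer: het/missing-clean maximal windows within the block
        bad = (het[blo:bhi + 1].astype(np.int32), mis[blo:bhi + 1].astype(np.int32))
        k = bhi - blo + 1
        hcum = np.r_[0, np.cumsum(bad[0])]
        mcum = np.r_[0, np.cumsum(bad[1])]
        right = blo - 1
        prev_right = -1
        a = blo
        while a <= bhi:
            # extend right as far as budgets allow
            r = max(right, a - 1)
            while r + 1 <= bhi:
                lo, hi = a - blo, r + 1 - blo
                if (hcum[hi + 1] - hcum[lo] > params.max_het
                        or mcum[hi + 1] - mcum[lo] > params.max_missing):
                    break
                r += 1
            right = r
            if r >= a and r > prev_right:
                window_pos = pos[a:r + 1]
                for wa, wb in _maximal_in_window(window_pos, params):
                    cands.append((a + wa, a + wb))
                prev_right = r
            # next distinct window starts after the first budget-consuming marker
            nxt = a + 1
            while nxt <= bhi and not (het[nxt - 1] or mis[nxt - 1]):
                nxt += 1
            a = nxt

    if not cands:
        return []
    cands = sorted(set(cands))
    # drop intervals strictly contained in another candidate (cross-window maximality)
    keep = []
    for i, (a, b) in enumerate(cands):
        contained = any(
            (c <= a and d >= b and (c, d) != (a, b)) for c, d in cands
        )
        if not contained:
            keep.append((a, b))
    return _merge_segments(keep, pos, het, mis, params)


def detect_roh(geno: GenotypeMatrix, params: ROHParams | None = None) -> list[ROHSegment]:
    """Call ROH segments for every individual on every chromosome.

    Requires markers sorted by (chromosome, position); works on the unpruned
    post-QC marker set.
    """
    params = params or ROHParams()
    segments: list[ROHSegment] = []
    for chrom in geno.markers.chromosomes():
        cidx = geno.markers.chrom_indices(chrom)
        pos = geno.markers.bp[cidx]
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"marker map not sorted on chromosome {chrom}")
        sub = geno.geno[:, cidx]
        for i in range(geno.n_samples):
            row = sub[i]
            het = row == 1
            mis = row == MISSING
            for a, b in _detect_one(pos, het, mis, params):
                segments.append(ROHSegment(
                    individual=geno.sample_ids[i], chrom=str(chrom),
                    start_bp=int(pos[a]), end_bp=int(pos[b]),
                    n_snps=int(b - a + 1),
                    n_het=int(het[a:b + 1].sum()),
                    n_missing=int(mis[a:b + 1].sum()),
                ))
    return segments


def segments_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"individual": s.individual, "chrom": s.chrom, "start_bp": s.start_bp,
          "end_bp": s.end_bp, "length_bp": s.length_bp, "n_snps": s.n_snps,
          "n_het": s.n_het, "n_missing": s.n_missing} for s in segments],
        columns=["individual", "chrom", "start_bp", "end_bp", "length_bp",
                 "n_snps", "n_het", "n_missing"],
    )


# ---------------------------------------------------------------------------
# F_ROH and summaries
# ---------------------------------------------------------------------------

LENGTH_CLASSES = ((1e6, 5e6), (5e6, 10e6), (10e6, 15e6), (15e6, 20e6), (20e6, np.inf))
LENGTH_CLASS_LABELS = ("1-<5Mb", "5-<10Mb", "10-<15Mb", "15-<20Mb", ">=20Mb")


@dataclass
class FrohResult:
    per_individual: pd.DataFrame   # individual, population, l_roh_bp, n_segments, froh
    per_group: pd.DataFrame        # population, mn_roh_all, mn_roh_carriers, al_roh_bp, class counts
    l_aut_bp: int


def froh(segments: list[ROHSegment], geno: GenotypeMatrix,
         l_aut_bp: int = L_AUT_DEFAULT) -> FrohResult:
    """Per-individual F_ROH = L_ROH / L_AUT plus group-level ROH summaries.

    The mean number of ROH is reported with both denominators — all
    individuals, and only those carrying at least one segment.
    """
    if l_aut_bp <= 0:
        raise ValueError("l_aut_bp must be positive")
    seg = segments_frame(segments)
    pop_of = dict(zip(geno.sample_ids, geno.populations))
    rows = []
    for ind in geno.sample_ids:
        s = seg[seg["individual"] == ind] if len(seg) else seg
        l_roh = int(s["length_bp"].sum()) if len(s) else 0
        rows.append({"individual": ind, "population": pop_of[ind],
                     "l_roh_bp": l_roh, "n_segments": len(s),
                     "froh": l_roh / l_aut_bp})
    per_ind = pd.DataFrame(rows)

    grows = []
    for pop, grp in per_ind.groupby("population", sort=False):
        pop_segs = seg[seg["individual"].isin(grp["individual"])] if len(seg) else seg
        carriers = grp[grp["n_segments"] > 0]
        counts = {
            label: int(((pop_segs["length_bp"] >= lo) & (pop_segs["length_bp"] < hi)).sum())
            if len(pop_segs) else 0
            for label, (lo, hi) in zip(LENGTH_CLASS_LABELS, LENGTH_CLASSES)
        }
        grows.append({
            "population": pop,
            "froh_mean": grp["froh"].mean(),
            "mn_roh_all": grp["n_segments"].mean(),
            "mn_roh_carriers": carriers["n_segments"].mean() if len(carriers) else 0.0,
            "al_roh_bp": pop_segs["length_bp"].mean() if len(pop_segs) else np.nan,
            **counts,
        })
    return FrohResult(per_ind, pd.DataFrame(grows), l_aut_bp)


# ---------------------------------------------------------------------------
# ROH islands
# ---------------------------------------------------------------------------

@dataclass
class ROHIsland:
    group: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    peak_incidence: float
    threshold: float


def snp_incidence(segments: list[ROHSegment], geno: GenotypeMatrix,
                  individuals: list[str]) -> np.ndarray:
    """Per-SNP fraction of the listed individuals whose ROH covers the SNP."""
    chrom = geno.markers.chrom
    bp = geno.markers.bp
    count = np.zeros(geno.n_markers, dtype=np.int64)
    members = set(individuals)
    for s in segments:
        if s.individual not in members:
            continue
        mask = (chrom == s.chrom) & (bp >= s.start_bp) & (bp <= s.end_bp)
        count[mask] += 1
    return count / len(individuals)


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: the ceil(q*N)-th smallest value."""
    v = np.sort(np.asarray(values))
    rank = int(np.ceil(q * len(v)))
    rank = min(max(rank, 1), len(v))
    return float(v[rank - 1])


def roh_islands(segments: list[ROHSegment], geno: GenotypeMatrix, group: str,
                percentile: float = 0.999) -> list[ROHIsland]:
    """Group-level ROH islands: maximal runs of consecutive markers whose
    incidence strictly exceeds the nearest-rank ``percentile`` quantile of the
    group's genome-wide per-SNP incidence distribution."""
    members = [s for s, p in zip(geno.sample_ids, geno.populations) if p == group]
    if len(members) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 individuals")
    inc = snp_incidence(segments, geno, members)
    if not inc.any():
        log.warning("roh_islands: all incidences zero in group %s", group)
        return []
    thr = nearest_rank_quantile(inc, percentile)
    above = inc > thr
    islands: list[ROHIsland] = []
    chrom = geno.markers.chrom
    bp = geno.markers.bp
    for c in dict.fromkeys(chrom):
        cidx = np.flatnonzero(chrom == c)
        flags = above[cidx]
        if not flags.any():
            continue
        edges = np.diff(np.r_[0, flags.astype(int), 0])
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1) - 1
        for a, b in zip(starts, ends):
            sel = cidx[a:b + 1]
            islands.append(ROHIsland(
                group=group, chrom=str(c), start_bp=int(bp[sel[0]]),
                end_bp=int(bp[sel[-1]]), n_snps=int(b - a + 1),
                peak_incidence=float(inc[sel].max()), threshold=thr,
            ))
    return islands
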