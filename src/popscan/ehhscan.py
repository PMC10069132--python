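"""Cross-population haplotype scans: EHHS, iES, Rsb, XP-EHH, window consensus.

Site-specific extended haplotype homozygosity (EHHS) at a core marker s,
evaluated at a marker t, partitions haplotypes into classes identical over
[s..t] (class sizes n_k, total n):

* tang variant:   EHHS(t) = sum_k n_k (n_k - 1) / sum_a n_a (n_a - 1),
  where a indexes the core-allele classes — i.e. the fraction of ordered
  haplotype pairs homozygous at the core that remain identical out to t;
* sabeti variant: EHHS(t) = sum_k C(n_k, 2) / C(n, 2) — the fraction of all
  unordered pairs identical over [s..t].

Both are defined to be 1 at the core itself.  iES is the trapezoidal integral
of EHHS over physical position, truncated at the first marker where EHHS drops
below a cutoff; a site whose EHHS never drops below the cutoff before the
chromosome end is discarded (border rule).

The cross-population statistics are the per-SNP log-ratios ln(iES_A/iES_B):
Rsb uses the tang variant and median-centred standardization, XP-EHH the
sabeti variant and mean-centred standardization.  Two-sided p-scores are
-log10(1 - 2|Phi(z) - 0.5|).  Significance windows tile each chromosome
(250 kb, 10 kb overlap) and flag windows holding at least three SNPs with
p-score strictly above 4; per-method windows merge into regions bounded by
their significant SNPs, and regions overlapping across methods consolidate
into candidate regions with the union span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genio import MISSING, HaplotypeSet
from .rohscan import ROHIsland

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# EHHS
# ---------------------------------------------------------------------------

@dataclass
class EHHSCurve:
    core: int                 # marker index within the chromosome slice
    indices: np.ndarray       # marker indices covered (ascending, includes core)
    bp: np.ndarray            # their positions
    ehhs: np.ndarray          # EHHS at each covered marker
    variant: str


def _ehhs_side(haps: np.ndarray, core: int, step: int, variants: tuple[str, ...],
               stop_below: float | None) -> dict[str, list[float]]:
    """EHHS values extending from the core in one direction (core excluded).

    Haplotype classes extend marker by marker; a haplotype with a missing
    allele leaves all classes (dropped from numerator and denominator) from
    that marker outward.  Stops early once every requested variant has dropped
    below ``stop_below`` (values for the crossing marker are included).
    """
    n, m = haps.shape
    alive = haps[:, core] != MISSING
    classes = haps[:, core].astype(np.int64).copy()
    classes[~alive] = -1
    out: dict[str, list[float]] = {v: [] for v in variants}

    t = core + step
    while 0 <= t < m:
        col = haps[:, t]
        alive = alive & (col != MISSING)
        key = classes * 2 + col
        key[~alive] = -1
        _, classes = np.unique(key, return_inverse=True)
        classes = classes.astype(np.int64)
        classes[~alive] = -1

        counts = np.bincount(classes[alive]) if alive.any() else np.array([], dtype=int)
        pairs = (counts * (counts - 1)).sum()
        n_alive = int(alive.sum())
        done = True
        for v in variants:
            if v == "tang":
                core_counts = np.bincount(haps[alive, core].astype(np.int64)) if n_alive else np.array([])
                denom = (core_counts * (core_counts - 1)).sum()
                val = pairs / denom if denom > 0 else np.nan
            elif v == "sabeti":
                denom = n_alive * (n_alive - 1)
                val = pairs / denom if denom > 0 else np.nan
            else:
                raise ValueError(f"unknown EHHS variant {v!r}")
            out[v].append(float(val))
            if stop_below is None or not (val < stop_below) and not np.isnan(val):
                done = False
        if stop_below is not None and done:
            break
        t += step
    return out


def ehhs_curve(haps: HaplotypeSet, core: int, variant: str = "tang") -> EHHSCurve:
    """Full EHHS curve around a core marker (whole chromosome, no truncation).

    The core must lie on a single chromosome slice of the marker map; EHHS is
    evaluated at every marker of that chromosome.  A core monomorphic under the
    tang variant yields NaN values (undefined denominator).
    """
    if haps.n_haplotypes < 4:
        raise ValueError("need at least 4 haplotypes")
    chrom = haps.markers.chrom[core]
    cidx = haps.markers.chrom_indices(chrom)
    local_core = int(np.flatnonzero(cidx == core)[0])
    sub = haps.haps[:, cidx]

    left = _ehhs_side(sub, local_core, -1, (variant,), None)[variant]
    right = _ehhs_side(sub, local_core, +1, (variant,), None)[variant]
    ehhs = np.array(left[::-1] + [1.0] + right)
    indices = cidx[local_core - len(left): local_core + len(right) + 1]
    return EHHSCurve(core=core, indices=indices, bp=haps.markers.bp[indices],
                     ehhs=ehhs, variant=variant)


def integrate_ies(curve: EHHSCurve, cutoff: float = 0.05,
                  discard_at_border: bool = True) -> float:
    """Trapezoidal integral of EHHS over bp, truncated below ``cutoff``.

    Each side integrates outward from the core up to and including the first
    marker whose EHHS is below the cutoff; if a side reaches the chromosome
    end still at or above the cutoff and ``discard_at_border``, the site is
    undefined (NaN).
    """
    core_pos = int(np.flatnonzero(curve.indices == curve.core)[0])
    total = 0.0
    for sl in (slice(core_pos, None, 1), slice(core_pos, None, -1)):
        vals = curve.ehhs[sl]
        bps = curve.bp[sl].astype(float)
        below = np.flatnonzero(vals < cutoff)
        if len(below) == 0:
            # this side ran to the chromosome end still at/above the cutoff
            if discard_at_border:
                return float("nan")
            stop = len(vals) - 1
        else:
            stop = int(below[0])
        if stop >= 1:
            total += float(np.trapezoid(vals[:stop + 1], np.abs(bps[:stop + 1] - bps[0])))
    return total


def _ies_track(haps: HaplotypeSet, variants: tuple[str, ...], cutoff: float,
               discard_at_border: bool) -> dict[str, np.ndarray]:
    """iES at every marker, per requested EHHS variant, with early truncation."""
    m = haps.markers.n_markers
    out = {v: np.full(m, np.nan) for v in variants}
    chrom = haps.markers.chrom
    bp = haps.markers.bp.astype(float)
    for c in haps.markers.chromosomes():
        cidx = haps.markers.chrom_indices(c)
        sub = haps.haps[:, cidx]
        pos = bp[cidx]
        k = len(cidx)
        for local in range(k):
            sides = {v: 0.0 for v in variants}
            ok = {v: True for v in variants}
            for step in (-1, +1):
                vals = _ehhs_side(sub, local, step, variants, cutoff)
                for v in variants:
                    seq = np.array([1.0] + vals[v])
                    below = np.flatnonzero(seq < cutoff)
                    if len(below) == 0:
                        # the side ran to the chromosome end without decaying
                        if discard_at_border:
                            ok[v] = False
                            continue
                        stop = len(seq) - 1
                    else:
                        stop = int(below[0])
                    if stop >= 1:
                        marker_ids = local + step * np.arange(stop + 1)
                        sides[v] += float(np.trapezoid(seq[:stop + 1],
                                                       np.abs(pos[marker_ids] - pos[local])))
            for v in variants:
                if ok[v]:
                    out[v][cidx[local]] = sides[v]
    return out


# ---------------------------------------------------------------------------
# Cross-population scan
# ---------------------------------------------------------------------------

@dataclass
class ScanTrack:
    table: pd.DataFrame   # chrom, bp, snp, ies_a, ies_b, raw, score, pscore
    statistic: str


def pscore_from_z(z: np.ndarray) -> np.ndarray:
    """Two-sided p-score: -log10(1 - 2|Phi(z) - 0.5|) = -log10(2 Phi(-|z|))."""
    z = np.asarray(z, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.log10(2.0) + norm.logsf(np.abs(z)) / np.log(10.0)
    out = -logp
    out[np.isnan(z)] = np.nan
    return np.maximum(out, 0.0)


def cross_pop_scan(haps_a: HaplotypeSet, haps_b: HaplotypeSet, statistic: str = "rsb",
                   cutoff: float = 0.05, discard_at_border: bool = True,
                   _ies_cache: dict | None = None) -> ScanTrack:
    """Per-SNP standardized log-ratio of iES between two populations.

    ``rsb`` uses the tang EHHS variant and median-centred standardization;
    ``xpehh`` the sabeti variant and mean-centred standardization.  Sites where
    either population's iES is undefined or zero are NaN.
    """
    if statistic not in ("rsb", "xpehh"):
        raise ValueError("statistic must be 'rsb' or 'xpehh'")
    if list(haps_a.markers.snp) != list(haps_b.markers.snp):
        raise ValueError("populations must share a marker map")
    variant = "tang" if statistic == "rsb" else "sabeti"

    if _ies_cache is not None and variant in _ies_cache:
        ies_a, ies_b = _ies_cache[variant]
    else:
        both = ("tang", "sabeti") if _ies_cache is not None else (variant,)
        tracks_a = _ies_track(haps_a, both, cutoff, discard_at_border)
        tracks_b = _ies_track(haps_b, both, cutoff, discard_at_border)
        if _ies_cache is not None:
            for v in both:
                _ies_cache[v] = (tracks_a[v], tracks_b[v])
        ies_a, ies_b = tracks_a[variant], tracks_b[variant]

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.log(ies_a / ies_b)
    raw[~np.isfinite(raw)] = np.nan
    defined = ~np.isnan(raw)
    if defined.sum() < 100:
        log.warning("cross_pop_scan: only %d defined sites; standardization may be unstable",
                    int(defined.sum()))
    center = np.nanmedian(raw) if statistic == "rsb" else np.nanmean(raw)
    scale = np.nanstd(raw)
    if scale > 0:
        score = (raw - center) / scale
    else:
        # degenerate spread (e.g. identical populations): no site deviates
        score = np.where(np.isnan(raw), np.nan, 0.0)
    pscore = pscore_from_z(score)

    table = pd.DataFrame({
        "chrom": haps_a.markers.chrom, "bp": haps_a.markers.bp,
        "snp": haps_a.markers.snp, "ies_a": ies_a, "ies_b": ies_b,
        "raw": raw, "score": score, "pscore": pscore,
    })
    return ScanTrack(table, statistic)


# ---------------------------------------------------------------------------
# Windows and candidate regions
# ---------------------------------------------------------------------------

@dataclass
class ScanWindow:
    chrom: str
    start_bp: int
    end_bp: int
    n_significant: int
    significant: bool


def significance_windows(track: ScanTrack, window_bp: int = 250_000,
                         overlap_bp: int = 10_000, min_snps: int = 3,
                         threshold: float = 4.0) -> list[ScanWindow]:
    """Tile each chromosome with sliding windows from the first marker position.

    Step = window - overlap.  A window is significant iff it holds at least
    ``min_snps`` SNPs with p-score strictly above ``threshold``.  The terminal
    window may be shorter; it uses the same SNP-count rule.
    """
    if overlap_bp >= window_bp:
        raise ValueError("overlap must be smaller than the window")
    step = window_bp - overlap_bp
    t = track.table
    out: list[ScanWindow] = []
    for chrom, grp in t.groupby("chrom", sort=False):
        bp = grp["bp"].to_numpy()
        hot = (grp["pscore"].to_numpy() > threshold)
        first, last = int(bp.min()), int(bp.max())
        start = first
        while start <= last:
            end = start + window_bp - 1
            in_win = (bp >= start) & (bp <= end)
            n_sig = int((hot & in_win).sum())
            out.append(ScanWindow(str(chrom), start, min(end, last), n_sig,
                                  n_sig >= min_snps))
            start += step
    return out


@dataclass
class CandidateRegion:
    chrom: str
    start_bp: int
    end_bp: int
    methods: set[str]
    n_significant: int


def _method_regions(windows: list[ScanWindow], track: ScanTrack,
                    threshold: float = 4.0) -> list[tuple[str, int, int, int]]:
    """Merge overlapping/adjacent significant windows; bound each region by the
    first and last significant SNP inside the merged span."""
    sig = [w for w in windows if w.significant]
    merged: list[list] = []
    for w in sorted(sig, key=lambda w: (w.chrom, w.start_bp)):
        if merged and merged[-1][0] == w.chrom and w.start_bp <= merged[-1][2] + 1:
            merged[-1][2] = max(merged[-1][2], w.end_bp)
        else:
            merged.append([w.chrom, w.start_bp, w.end_bp])
    t = track.table
    out = []
    for chrom, lo, hi in merged:
        sel = t[(t["chrom"] == chrom) & (t["bp"] >= lo) & (t["bp"] <= hi)
                & (t["pscore"] > threshold)]
        if len(sel) == 0:
            continue
        out.append((chrom, int(sel["bp"].min()), int(sel["bp"].max()), len(sel)))
    return out


def consolidate_regions(windows_rsb: list[ScanWindow] | None,
                        windows_xpehh: list[ScanWindow] | None,
                        islands: list[ROHIsland] | None,
                        track_rsb: ScanTrack | None = None,
                        track_xpehh: ScanTrack | None = None,
                        threshold: float = 4.0) -> list[CandidateRegion]:
    """Union regions across methods: regions overlapping by >= 1 bp merge into
    one candidate with the union span and the joined supporting-method set."""
    pieces: list[CandidateRegion] = []
    if windows_rsb is not None and track_rsb is not None:
        for chrom, lo, hi, n in _method_regions(windows_rsb, track_rsb, threshold):
            pieces.append(CandidateRegion(chrom, lo, hi, {"Rsb"}, n))
    if windows_xpehh is not None and track_xpehh is not None:
        for chrom, lo, hi, n in _method_regions(windows_xpehh, track_xpehh, threshold):
            pieces.append(CandidateRegion(chrom, lo, hi, {"XP-EHH"}, n))
    for isl in islands or []:
        pieces.append(CandidateRegion(isl.chrom, isl.start_bp, isl.end_bp,
                                      {"ROH-island"}, isl.n_snps))

    pieces.sort(key=lambda r: (r.chrom, r.start_bp, r.end_bp))
    out: list[CandidateRegion] = []
    for r in pieces:
        if out and out[-1].chrom == r.chrom and r.start_bp <= out[-1].end_bp:
            prev = out[-1]
            prev.end_bp = max(prev.end_bp, r.end_bp)
            prev.methods = prev.methods | r.methods
            prev.n_significant += r.n_significant
        else:
            out.append(CandidateRegion(r.chrom, r.start_bp, r.end_bp,
                                       set(r.methods), r.n_significant))
    return out


def regions_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"chrom": r.chrom, "start_bp": r.start_bp, "end_bp": r.end_bp,
          "methods": "+".join(sorted(r.methods)), "n_significant": r.n_significant}
         for r in regions],
        columns=["chrom", "start_bp", "end_bp", "methods", "n_significant"],
    )
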