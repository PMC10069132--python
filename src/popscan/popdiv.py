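"""Per-population diversity, differentiation, structure, and LD-based Ne.

* Heterozygosity: per-marker observed H_O (het fraction among non-missing
  calls) and expected H_E = 2p(1-p) with p the within-group allele frequency
  (plain PLINK convention; an unbiased 2n/(2n-1) correction is switchable).
* F_ST: Weir & Cockerham (1984) theta per locus, combined as the ratio of the
  summed variance components over loci; significance by permuting individuals
  between the pair of groups.  Reynolds distance D = -ln(1 - theta).
* Structure: classical (Torgerson) MDS of 1 - IBS distances.
* Ne: Sved's relation between expected r^2 and effective size —
  E[r^2] ~ 1/(alpha + 4 N c) — inverted per recombination-distance bin, with
  t = 1/(2c) generations back and a 1/n small-sample correction on r^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix
from .qc import _dosage_r2, ibs_matrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------

@dataclass
class DiversitySummary:
    table: pd.DataFrame  # population, n, ho_mean, ho_sd, he_mean, he_sd


def marker_heterozygosity(geno: GenotypeMatrix, idx: np.ndarray,
                          unbiased: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker (H_O, H_E) within the sample subset ``idx``.

    Markers with no non-missing call in the subset come back as NaN.
    """
    g = geno.geno[idx]
    obs = g != MISSING
    n_obs = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n_obs > 0, (g == 1).sum(axis=0) / n_obs, np.nan)
        p = np.where(n_obs > 0, np.where(obs, g, 0).sum(axis=0) / (2 * n_obs), np.nan)
    he = 2 * p * (1 - p)
    if unbiased:
        he = he * (2 * n_obs) / np.maximum(2 * n_obs - 1, 1)
    return ho, he


def heterozygosity(geno: GenotypeMatrix, groups: dict[str, np.ndarray] | None = None,
                   unbiased: bool = False) -> DiversitySummary:
    """Mean +/- SD of H_O and H_E over all markers, per group."""
    groups = groups or geno.group_indices()
    rows = []
    for name, idx in groups.items():
        idx = np.asarray(idx)
        if len(idx) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 individuals")
        ho, he = marker_heterozygosity(geno, idx, unbiased=unbiased)
        skipped = int(np.isnan(ho).sum())
        if skipped:
            log.info("heterozygosity group=%s skipped %d all-missing markers", name, skipped)
        rows.append({"population": name, "n": len(idx),
                     "ho_mean": np.nanmean(ho), "ho_sd": np.nanstd(ho, ddof=1),
                     "he_mean": np.nanmean(he), "he_sd": np.nanstd(he, ddof=1)})
    return DiversitySummary(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Weir–Cockerham F_ST, permutation significance, Reynolds distance
# ---------------------------------------------------------------------------

def _wc_components(geno_pair: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Weir–Cockerham (1984) variance components (a, a+b+c) for two
    groups encoded in ``labels`` (0/1).  Vectorized over loci; loci with fewer
    than 2 observed individuals in either group are NaN."""
    r = 2
    comp_a = []
    n_i = np.empty((2, geno_pair.shape[1]))
    p_i = np.empty((2, geno_pair.shape[1]))
    h_i = np.empty((2, geno_pair.shape[1]))
    for k in (0, 1):
        g = geno_pair[labels == k]
        obs = g != MISSING
        n = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(obs, g, 0).sum(axis=0) / (2 * n)
            h = (g == 1).sum(axis=0) / n
        n_i[k], p_i[k], h_i[k] = n, p, h
    valid = (n_i >= 2).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_i.mean(axis=0)
        nc = (r * nbar - (n_i ** 2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    denom = a + b + c
    a = np.where(valid, a, np.nan)
    denom = np.where(valid, denom, np.nan)
    return a, denom


def wc_theta(geno_pair: np.ndarray, labels: np.ndarray) -> float:
    """Genome-wide Weir–Cockerham theta: ratio of summed components over loci."""
    a, denom = _wc_components(geno_pair, labels)
    num = np.nansum(a)
    den = np.nansum(denom)
    return float(num / den) if den != 0 else np.nan


def wc_theta_per_locus(geno_pair: np.ndarray, labels: np.ndarray) -> np.ndarray:
    a, denom = _wc_components(geno_pair, labels)
    with np.errstate(invalid="ignore", divide="ignore"):
        return a / denom


@dataclass
class DistanceMatrix:
    populations: list[str]
    fst: np.ndarray
    pvalues: np.ndarray
    reynolds: np.ndarray

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            name: pd.DataFrame(getattr(self, name), index=self.populations,
                               columns=self.populations)
            for name in ("fst", "pvalues", "reynolds")
        }


def pairwise_fst(geno: GenotypeMatrix, groups: dict[str, np.ndarray] | None = None,
                 n_perm: int = 1000, seed: int = 0) -> DistanceMatrix:
    """Pairwise Weir–Cockerham theta with permutation p-values and Reynolds D.

    p-value = (1 + #{theta* >= theta_hat}) / (n_perm + 1), permuting individual
    labels between the two groups.  D = -ln(1 - theta) with theta clamped to
    [0, 1).
    """
    groups = groups or geno.group_indices()
    names = list(groups)
    for name, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 individuals")
    k = len(names)
    fst = np.zeros((k, k))
    pvals = np.zeros((k, k))
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            ia, ib = np.asarray(groups[names[i]]), np.asarray(groups[names[j]])
            sub = geno.geno[np.concatenate([ia, ib])]
            labels = np.r_[np.zeros(len(ia), dtype=int), np.ones(len(ib), dtype=int)]
            theta = wc_theta(sub, labels)
            fst[i, j] = fst[j, i] = theta
            if n_perm > 0:
                count = 0
                lab = labels.copy()
                for _ in range(n_perm):
                    rng.shuffle(lab)
                    if wc_theta(sub, lab) >= theta:
                        count += 1
                p = (1 + count) / (n_perm + 1)
            else:
                p = np.nan
            pvals[i, j] = pvals[j, i] = p
    clamped = np.clip(fst, 0.0, 1.0 - 1e-12)
    reynolds = -np.log(1.0 - clamped)
    np.fill_diagonal(reynolds, 0.0)
    return DistanceMatrix(names, fst, pvals, reynolds)


# ---------------------------------------------------------------------------
# IBS-based classical MDS
# ---------------------------------------------------------------------------

@dataclass
class MDSResult:
    coords: np.ndarray           # samples x k
    explained: np.ndarray        # per-dimension fraction of positive-eigenvalue variation
    sample_ids: list[str]


def classical_mds(dist: np.ndarray, k: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson MDS: double-center -d^2/2, eigendecompose, keep top-k positive."""
    d2 = np.asarray(dist, dtype=float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-12
    n_pos = int(pos.sum())
    use = min(k, n_pos)
    coords = vecs[:, :use] * np.sqrt(vals[:use])
    explained = vals[:use] / vals[:n_pos].sum() if n_pos else np.zeros(0)
    return coords, explained


def ibs_mds(geno: GenotypeMatrix, k: int = 3) -> MDSResult:
    """MDS of pairwise (1 - IBS) distances between samples."""
    if geno.n_samples < k + 1:
        raise ValueError("need at least k+1 samples")
    dist = 1.0 - ibs_matrix(geno)
    coords, explained = classical_mds(dist, k=k)
    if coords.shape[1] < k:
        log.warning("ibs_mds: only %d positive eigenvalues; returning fewer dimensions",
                    coords.shape[1])
    return MDSResult(coords, explained, list(geno.sample_ids))


# ---------------------------------------------------------------------------
# LD-based effective population size
# ---------------------------------------------------------------------------

@dataclass
class NeTrajectory:
    table: pd.DataFrame   # bin_lo_c, bin_hi_c, c_mean, t, r2_adj, ne, n_pairs
    ne13: float
    ne50: float


def sved_ne(r2_adj: float, c: float, alpha: float = 1.0) -> float:
    """Invert Sved's E[r^2] = 1/(alpha + 4Nc): N = (1/(4c)) (1/r^2 - alpha)."""
    return (1.0 / (4.0 * c)) * (1.0 / r2_adj - alpha)


def _default_bins() -> np.ndarray:
    # recombination-distance bin edges in Morgans: 0.005 to 0.1 in 0.005 steps,
    # i.e. generations back t = 1/(2c) from ~100 down to ~5
    return np.arange(0.005, 0.1001, 0.005)


def ld_ne(geno: GenotypeMatrix, groups: dict[str, np.ndarray] | None = None,
          bins: np.ndarray | None = None, alpha: float = 1.0,
          sample_correction: bool = True, min_group: int = 20,
          max_sample: int = 20, cm_per_mb: float = 1.0,
          seed: int = 0) -> dict[str, NeTrajectory]:
    """Historical Ne per group from binned syntenic-pair r^2.

    Genetic distance between a marker pair is bp distance times
    ``cm_per_mb`` (constant-rate map, Morgans).  Groups smaller than
    ``min_group`` are skipped (logged); larger groups are subsampled to
    ``max_sample`` individuals (seeded).  ``ne13``/``ne50`` are read from the
    bins whose t = 1/(2c) is nearest 13 and 50 generations.
    """
    groups = groups or geno.group_indices()
    edges = np.asarray(bins if bins is not None else _default_bins())
    rng = np.random.default_rng(seed)
    out: dict[str, NeTrajectory] = {}
    morgan_per_bp = cm_per_mb * 1e-8

    for name, idx in groups.items():
        idx = np.asarray(idx)
        if len(idx) < min_group:
            log.info("ld_ne: group %s has %d (<%d) individuals; skipped", name, len(idx), min_group)
            continue
        if len(idx) > max_sample:
            idx = rng.choice(idx, size=max_sample, replace=False)
        n = len(idx)
        sums = np.zeros(len(edges) - 1)
        csums = np.zeros(len(edges) - 1)
        counts = np.zeros(len(edges) - 1, dtype=np.int64)
        for chrom in geno.markers.chromosomes():
            cidx = geno.markers.chrom_indices(chrom)
            if len(cidx) < 2:
                continue
            sub = geno.geno[np.ix_(idx, cidx)]
            # drop monomorphic columns within the subsample
            p = GenotypeMatrix(sub, [str(i) for i in range(n)], ["g"] * n,
                               geno.markers.subset(cidx)).maf()
            poly = np.flatnonzero(p > 0)
            if len(poly) < 2:
                continue
            sub = sub[:, poly]
            pos = geno.markers.bp[cidx][poly]
            r2 = _dosage_r2(sub)
            iu, ju = np.triu_indices(len(poly), k=1)
            c = np.abs(pos[ju] - pos[iu]) * morgan_per_bp
            which = np.digitize(c, edges) - 1
            ok = (which >= 0) & (which < len(edges) - 1)
            np.add.at(sums, which[ok], r2[iu[ok], ju[ok]])
            np.add.at(csums, which[ok], c[ok])
            np.add.at(counts, which[ok], 1)

        with np.errstate(invalid="ignore", divide="ignore"):
            r2_mean = np.where(counts > 0, sums / counts, np.nan)
            c_mean = np.where(counts > 0, csums / counts, np.nan)
        r2_adj = r2_mean - (1.0 / n if sample_correction else 0.0)
        t = 1.0 / (2.0 * c_mean)
        ne = np.full_like(r2_adj, np.nan)
        defined = (r2_adj > 0) & (r2_adj < 1.0 / alpha - 1e-9) & (counts > 0)
        ne[defined] = (1.0 / (4.0 * c_mean[defined])) * (1.0 / r2_adj[defined] - alpha)
        table = pd.DataFrame({
            "bin_lo_c": edges[:-1], "bin_hi_c": edges[1:], "c_mean": c_mean,
            "t": t, "r2_adj": r2_adj, "ne": ne, "n_pairs": counts,
        })
        valid = table["ne"].notna()
        def _nearest(target: float) -> float:
            if not valid.any():
                return np.nan
            sub = table[valid]
            return float(sub.loc[(sub["t"] - target).abs().idxmin(), "ne"])
        out[name] = NeTrajectory(table, ne13=_nearest(13.0), ne50=_nearest(50.0))
    return out
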