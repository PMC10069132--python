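"""Marker/sample quality control and LD pruning for SNP-array genotypes.

Six filters, applied in their conventional enumeration order:

1. drop SNPs with call rate not higher than the minimum (strict ``>``);
2. drop SNPs without a chromosome or physical position;
3. drop individuals whose missing-genotype fraction is not lower than the
   maximum (strict ``<`` retained);
4. drop SNPs whose minor allele frequency is not higher than the minimum
   (strict ``>``; MAF recomputed after the sample filter);
5. drop non-autosomal SNPs;
6. for each pair of samples with identity-by-state at or above the duplicate
   threshold, drop the later-seen member (greedy, first-seen kept).

LD pruning slides a 50-SNP window in 5-SNP steps and removes markers until no
retained within-window pair has genotype-dosage r^2 above the ceiling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class QCConfig:
    snp_call_rate_min: float = 0.90
    indiv_missing_max: float = 0.05
    maf_min: float = 0.01
    autosomes_only: bool = True
    autosome_labels: tuple[str, ...] | None = None  # default: integer labels 1..26
    ibs_duplicate_threshold: float = 0.99
    ld_window_snps: int = 50
    ld_step_snps: int = 5
    ld_r2_max: float = 0.5

    def __post_init__(self) -> None:
        for name in ("snp_call_rate_min", "indiv_missing_max", "maf_min",
                     "ibs_duplicate_threshold", "ld_r2_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.ld_window_snps > self.ld_step_snps > 0:
            raise ValueError("require ld_window_snps > ld_step_snps > 0")


@dataclass
class QCReport:
    """Per-step before/after counts with the removed item ids; counts telescope."""

    steps: list[dict] = field(default_factory=list)

    def add(self, step: str, kind: str, before: int, after: int, removed: list[str]) -> None:
        self.steps.append({"step": step, "kind": kind, "before": before,
                           "after": after, "removed": list(removed)})

    def removed_ids(self) -> set[str]:
        return {i for s in self.steps for i in s["removed"]}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{**{k: s[k] for k in ("step", "kind", "before", "after")},
              "n_removed": len(s["removed"]),
              "removed": ",".join(s["removed"])} for s in self.steps]
        )


def _default_autosomes() -> set[str]:
    return {str(i) for i in range(1, 27)}


def ibs_matrix(geno: GenotypeMatrix) -> np.ndarray:
    """Pairwise identity-by-state: mean shared-allele fraction over mutually
    non-missing markers (1 - |gi - gj| / 2)."""
    g = geno.geno.astype(np.float64)
    obs = g != MISSING
    g0 = np.where(obs, g, 0.0)
    obs_f = obs.astype(np.float64)
    # sum over mutually observed markers of |gi - gj|, via the identity
    # |a-b| expansion is awkward; do it pairwise but vectorized per row.
    n = geno.n_samples
    out = np.ones((n, n))
    for i in range(n):
        diff = np.abs(g0[i] - g0)                      # (n, m)
        both = obs_f[i] * obs_f                        # (n, m)
        denom = both.sum(axis=1)
        num = (diff * both).sum(axis=1)
        with np.errstate(invalid="ignore"):
            out[i] = 1.0 - 0.5 * num / denom
    np.fill_diagonal(out, 1.0)
    return out


def apply_qc(geno: GenotypeMatrix, cfg: QCConfig | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the six QC filters in order; returns the filtered matrix and report."""
    cfg = cfg or QCConfig()
    if geno.n_samples == 0 or geno.n_markers == 0:
        raise ValueError("empty genotype matrix")
    report = QCReport()
    cur = geno
    # per-individual missingness is judged on the full input panel (the
    # genotyping success rate of the animal), not on the post-filter markers
    sample_missing = geno.sample_missing_rate()

    # (1) SNP call rate strictly higher than the minimum
    keep = cur.call_rate() > cfg.snp_call_rate_min
    report.add("snp_call_rate", "marker", cur.n_markers, int(keep.sum()),
               list(cur.markers.snp[~keep]))
    cur = cur.subset_markers(np.flatnonzero(keep))

    # (2) SNPs lacking a chromosome or physical position
    t = cur.markers.table
    keep = ((t["chrom"] != "0") & (t["chrom"] != "") & (t["bp"] > 0)).to_numpy()
    report.add("position_known", "marker", cur.n_markers, int(keep.sum()),
               list(cur.markers.snp[~keep]))
    cur = cur.subset_markers(np.flatnonzero(keep))

    # (3) individuals with missing fraction strictly lower than the maximum
    keep = sample_missing < cfg.indiv_missing_max
    report.add("sample_missingness", "sample", cur.n_samples, int(keep.sum()),
               [cur.sample_ids[i] for i in np.flatnonzero(~keep)])
    cur = cur.subset_samples(np.flatnonzero(keep))
    if cur.n_samples == 0:
        raise ValueError("empty after QC: all samples removed")

    # (4) MAF strictly higher than the minimum (recomputed after step 3)
    keep = cur.maf() > cfg.maf_min
    report.add("maf", "marker", cur.n_markers, int(keep.sum()),
               list(cur.markers.snp[~keep]))
    cur = cur.subset_markers(np.flatnonzero(keep))

    # (5) autosomes only
    if cfg.autosomes_only:
        autosomes = set(cfg.autosome_labels) if cfg.autosome_labels else _default_autosomes()
        keep = np.isin(cur.markers.chrom, list(autosomes))
        report.add("autosomes", "marker", cur.n_markers, int(keep.sum()),
                   list(cur.markers.snp[~keep]))
        cur = cur.subset_markers(np.flatnonzero(keep))

    # (6) IBS duplicates: greedy, keep first-seen
    ibs = ibs_matrix(cur)
    removed: list[int] = []
    removed_set: set[int] = set()
    n = cur.n_samples
    for i in range(n):
        if i in removed_set:
            continue
        for j in range(i + 1, n):
            if j in removed_set:
                continue
            if ibs[i, j] >= cfg.ibs_duplicate_threshold:
                removed.append(j)
                removed_set.add(j)
    keep_idx = [i for i in range(n) if i not in removed_set]
    report.add("ibs_duplicates", "sample", n, len(keep_idx),
               [cur.sample_ids[j] for j in sorted(removed_set)])
    cur = cur.subset_samples(keep_idx)
    if cur.n_samples == 0:
        raise ValueError("empty after QC: all samples removed")

    for s in report.steps:
        log.info("qc step=%s kind=%s before=%d after=%d removed=%d",
                 s["step"], s["kind"], s["before"], s["after"], len(s["removed"]))
    return cur, report


def _dosage_r2(g: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation of dosage columns.

    Missing calls are mean-imputed per column before correlating (composite
    LD on genotypes; no phase needed).
    """
    x = g.astype(np.float64)
    obs = x != MISSING
    x[~obs] = np.nan
    col_mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_mean, inds[1])
    x -= x.mean(axis=0)
    denom = np.sqrt((x ** 2).sum(axis=0))
    denom[denom == 0] = np.nan
    xn = x / denom
    r = xn.T @ xn
    return np.nan_to_num(r ** 2, nan=0.0)


def ld_prune(geno: GenotypeMatrix, cfg: QCConfig | None = None) -> GenotypeMatrix:
    """Sliding-window LD pruning (window/step in SNP counts, r^2 ceiling).

    Within each window, while some pair exceeds the ceiling, the member of the
    worst (highest-r^2) pair with the lower call rate is removed (tie: higher
    marker index).  Full sweeps repeat until a pass removes nothing, so the
    retained set has no within-window pair above the ceiling by construction.
    """
    cfg = cfg or QCConfig()
    call_rate = geno.call_rate()
    chrom = geno.markers.chrom
    keep_mask = np.ones(geno.n_markers, dtype=bool)

    changed = True
    while changed:
        changed = False
        for c in geno.markers.chromosomes():
            cidx = np.flatnonzero(chrom == c)
            start = 0
            while True:
                alive = cidx[keep_mask[cidx]]
                if start >= len(alive) - 1:
                    break
                win = alive[start:start + cfg.ld_window_snps]
                if len(win) >= 2:
                    r2 = _dosage_r2(geno.geno[:, win])
                    np.fill_diagonal(r2, 0.0)
                    while True:
                        local = np.flatnonzero(np.array([keep_mask[w] for w in win]))
                        if len(local) < 2:
                            break
                        sub = r2[np.ix_(local, local)]
                        mx = sub.max()
                        if mx <= cfg.ld_r2_max:
                            break
                        a, b = np.unravel_index(np.argmax(sub), sub.shape)
                        ga, gb = win[local[a]], win[local[b]]
                        # remove lower call rate; tie -> higher marker index
                        if call_rate[ga] < call_rate[gb]:
                            drop = ga
                        elif call_rate[gb] < call_rate[ga]:
                            drop = gb
                        else:
                            drop = max(ga, gb)
                        keep_mask[drop] = False
                        changed = True
                start += cfg.ld_step_snps
    kept = np.flatnonzero(keep_mask)
    log.info("ld_prune kept %d of %d markers", len(kept), geno.n_markers)
    return geno.subset_markers(kept)
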