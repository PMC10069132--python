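#!/usr/bin/env python
"""Cross-population haplotype scans (Rsb, XP-EHH) between the two groups.

Loads the phased haplotypes emitted by 01_simulate.py, restricts them to the
post-QC markers, computes per-SNP iES in each population, the standardized
log-ratios, and the two-sided -log10 p tracks, then flags 250-kb windows
(10-kb overlap) holding >= 3 SNPs above -log10 p = 4.  Tracks and window
tables under results/scan/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from popscan.ehhscan import cross_pop_scan, significance_windows
from popscan.genio import HaplotypeSet, read_ped_map, read_phased

ROOT = Path(__file__).resolve().parent.parent / "results"


def restrict(haps, markers):
    keep = np.flatnonzero(np.isin(haps.markers.snp, markers.snp))
    return HaplotypeSet(haps.haps[:, keep], list(haps.sample_ids),
                        haps.population, haps.markers.subset(keep))


def main() -> None:
    clean = read_ped_map(ROOT / "qc" / "study_qc.ped", ROOT / "qc" / "study_qc.map")
    sim = ROOT / "sim"
    full_map = read_ped_map(sim / "study.ped", sim / "study.map").markers
    ha = restrict(read_phased(sim / "study.pop1.haps.tsv", "tsv",
                              markers=full_map, population="pop1"), clean.markers)
    hb = restrict(read_phased(sim / "study.pop2.haps.tsv", "tsv",
                              markers=full_map, population="pop2"), clean.markers)
    out = ROOT / "scan"
    out.mkdir(parents=True, exist_ok=True)

    cache: dict = {}
    for stat in ("rsb", "xpehh"):
        track = cross_pop_scan(ha, hb, stat, _ies_cache=cache)
        track.table.to_csv(out / f"{stat}_track.tsv", sep="\t", index=False)
        windows = significance_windows(track)
        pd.DataFrame([{"chrom": w.chrom, "start_bp": w.start_bp, "end_bp": w.end_bp,
                       "n_significant": w.n_significant, "significant": w.significant}
                      for w in windows]).to_csv(out / f"{stat}_windows.tsv",
                                                sep="\t", index=False)
        n_sig = sum(w.significant for w in windows)
        top = track.table.loc[track.table["pscore"].idxmax()]
        print(f"{stat}: {n_sig} significant windows; top SNP {top['snp']} "
              f"at {top['chrom']}:{int(top['bp'])} (-log10 p = {top['pscore']:.2f})")


if __name__ == "__main__":
    main()
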