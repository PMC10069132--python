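#!/usr/bin/env python
"""Diversity and structure on the LD-pruned set: H_O/H_E, F_ST, MDS, Ne.

Reads results/qc/study_qc_pruned.ped/.map.  Reports per-population observed
and expected heterozygosity (mean +/- SD over markers), pairwise
Weir-Cockerham F_ST with 1,000-permutation significance and Reynolds
distances, IBS-MDS coordinates with explained variation, and the LD-based Ne
trajectory (skipped for groups under 20 animals).  Tables under
results/diversity/.
"""

from pathlib import Path

import pandas as pd

from popscan.genio import read_ped_map
from popscan.popdiv import heterozygosity, ibs_mds, ld_ne, pairwise_fst

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 2024


def main() -> None:
    geno = read_ped_map(ROOT / "qc" / "study_qc_pruned.ped",
                        ROOT / "qc" / "study_qc_pruned.map")
    out = ROOT / "diversity"
    out.mkdir(parents=True, exist_ok=True)

    div = heterozygosity(geno)
    div.table.to_csv(out / "heterozygosity.tsv", sep="\t", index=False)
    print(div.table.to_string(index=False))

    dm = pairwise_fst(geno, n_perm=1000, seed=SEED)
    for name, frame in dm.to_frames().items():
        frame.to_csv(out / f"{name}.tsv", sep="\t")
    print(f"F_ST(pop1, pop2) = {dm.fst[0, 1]:.4f} "
          f"(P = {dm.pvalues[0, 1]:.4f}), Reynolds D = {dm.reynolds[0, 1]:.4f}")

    mds = ibs_mds(geno, k=3)
    coords = pd.DataFrame({"sample": mds.sample_ids,
                           **{f"dim{d + 1}": mds.coords[:, d]
                              for d in range(mds.coords.shape[1])}})
    coords.to_csv(out / "mds.tsv", sep="\t", index=False)
    pct = ", ".join(f"{100 * e:.2f}%" for e in mds.explained)
    print(f"MDS explained variation: {pct}")

    ne = ld_ne(geno, seed=SEED)
    for g, traj in ne.items():
        traj.table.to_csv(out / f"ne_{g}.tsv", sep="\t", index=False)
        print(f"{g}: Ne13 = {traj.ne13:.0f}, Ne50 = {traj.ne50:.0f}")
    if not ne:
        print("Ne: all groups below the 20-animal minimum; skipped")


if __name__ == "__main__":
    main()
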