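"""One-command orchestration: simulate/ingest -> QC -> diversity -> ROH -> scans.

Stage order and data routing follow the analysis design the pipeline
reproduces: the LD-pruned genotype set feeds only the diversity/structure
branch (heterozygosity, F_ST/Reynolds, MDS, Ne); the unpruned post-QC set
feeds the ROH branch; phased haplotypes (restricted to post-QC markers) feed
the Rsb/XP-EHH branch.  Candidate regions consolidate the three methods.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ehhscan, popdiv, qc, rohscan, simdata
from .genio import GenotypeMatrix, HaplotypeSet, read_ped_map, read_phased

log = logging.getLogger(__name__)


@dataclass
class ScanSettings:
    cutoff: float = 0.05
    discard_at_border: bool = True
    window_bp: int = 250_000
    overlap_bp: int = 10_000
    min_snps: int = 3
    threshold: float = 4.0
    island_percentile: float = 0.999


@dataclass
class PipelineConfig:
    outdir: str = "popscan_out"
    seed: int = 0
    # either a simulation config ...
    simulation: simdata.SimulationConfig | None = None
    # ... or input files
    ped: str | None = None
    map: str | None = None
    phased: dict[str, str] = field(default_factory=dict)  # scan group -> haplotype TSV/VCF
    scan_groups: list[str] = field(default_factory=list)  # exactly 2 population labels
    qc: qc.QCConfig = field(default_factory=qc.QCConfig)
    roh: rohscan.ROHParams = field(default_factory=rohscan.ROHParams)
    scan: ScanSettings = field(default_factory=ScanSettings)
    l_aut_bp: int | None = None   # None: sum of simulated chromosome lengths, else chip default
    n_perm: int = 1000
    run_ne: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = dict(raw)
        if "simulation" in kw and kw["simulation"] is not None:
            sim = dict(kw["simulation"])
            if "chromosomes" in sim:
                sim["chromosomes"] = [tuple(c) for c in sim["chromosomes"]]
            if "ancestral_maf_range" in sim:
                sim["ancestral_maf_range"] = tuple(sim["ancestral_maf_range"])
            sim["sweep_specs"] = [simdata.SweepSpec(**s) for s in sim.get("sweep_specs", [])]
            sim["autozygosity_specs"] = [
                simdata.AutozygositySpec(**s) for s in sim.get("autozygosity_specs", [])
            ]
            kw["simulation"] = simdata.SimulationConfig(**sim)
        if "qc" in kw:
            kw["qc"] = qc.QCConfig(**kw["qc"])
        if "roh" in kw:
            kw["roh"] = rohscan.ROHParams(**kw["roh"])
        if "scan" in kw:
            kw["scan"] = ScanSettings(**kw["scan"])
        return cls(**kw)


def _restrict_haps(haps: HaplotypeSet, geno: GenotypeMatrix) -> HaplotypeSet:
    """Restrict a haplotype set to the (post-QC) markers of a genotype matrix."""
    keep_ids = set(geno.markers.snp)
    idx = np.flatnonzero(np.isin(haps.markers.snp, list(keep_ids)))
    return HaplotypeSet(haps.haps[:, idx], list(haps.sample_ids), haps.population,
                        haps.markers.subset(idx))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    out = Path(cfg.outdir)
    for sub in ("qc", "diversity", "roh", "scan", "regions"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "artifacts": []}

    def _emit(path: Path, frame) -> None:
        frame.to_csv(path, sep="\t", index=False)
        report["artifacts"].append(str(path))

    # --- ingest or simulate -------------------------------------------------
    try:
        if cfg.simulation is not None:
            sim = dataclasses.replace(cfg.simulation, seed=cfg.seed)
            haps_by_pop, truth = simdata.simulate_haplotypes(sim)
            geno = simdata.diploidize_and_emit(
                haps_by_pop, seed=cfg.seed, out_prefix=out / "sim", truth=truth
            )
            scan_groups = cfg.scan_groups or list(haps_by_pop)
            report["stages"]["simulate"] = {
                "n_samples": geno.n_samples, "n_markers": geno.n_markers,
                "sweeps": truth.sweeps, "autozygous_intervals": len(truth.autozygosity),
            }
        else:
            if not (cfg.ped and cfg.map):
                raise ValueError("either a simulation config or ped/map paths are required")
            geno = read_ped_map(cfg.ped, cfg.map)
            haps_by_pop = {
                g: read_phased(p, fmt="vcf" if str(p).endswith(".vcf") else "tsv",
                               markers=geno.markers, population=g)
                for g, p in cfg.phased.items()
            }
            scan_groups = cfg.scan_groups or list(haps_by_pop)
            report["stages"]["ingest"] = {"n_samples": geno.n_samples,
                                          "n_markers": geno.n_markers}
        if len(scan_groups) != 2:
            raise ValueError("exactly 2 scan groups are required")
    except Exception as exc:
        raise RuntimeError(f"stage ingest/simulate failed: {exc}") from exc

    # --- QC -----------------------------------------------------------------
    try:
        clean, qreport = qc.apply_qc(geno, cfg.qc)
        pruned = qc.ld_prune(clean, cfg.qc)
        _emit(out / "qc" / "qc_report.tsv", qreport.to_frame())
        report["stages"]["qc"] = {
            "markers_in": geno.n_markers, "markers_post_qc": clean.n_markers,
            "markers_post_prune": pruned.n_markers,
            "samples_in": geno.n_samples, "samples_post_qc": clean.n_samples,
        }
    except Exception as exc:
        raise RuntimeError(f"stage qc failed: {exc}") from exc

    # --- diversity / structure (pruned branch) ------------------------------
    try:
        div = popdiv.heterozygosity(pruned)
        _emit(out / "diversity" / "heterozygosity.tsv", div.table)
        dm = popdiv.pairwise_fst(pruned, n_perm=cfg.n_perm, seed=cfg.seed)
        for name, frame in dm.to_frames().items():
            frame.to_csv(out / "diversity" / f"{name}.tsv", sep="\t")
            report["artifacts"].append(str(out / "diversity" / f"{name}.tsv"))
        mds = popdiv.ibs_mds(pruned)
        coords = {"sample": mds.sample_ids}
        coords.update({f"dim{d + 1}": mds.coords[:, d] for d in range(mds.coords.shape[1])})
        import pandas as pd
        _emit(out / "diversity" / "mds.tsv", pd.DataFrame(coords))
        ne = popdiv.ld_ne(pruned, seed=cfg.seed) if cfg.run_ne else {}
        for g, traj in ne.items():
            _emit(out / "diversity" / f"ne_{g}.tsv", traj.table)
        report["stages"]["diversity"] = {
            "fst": {f"{a}~{b}": float(dm.fst[i, j])
                    for i, a in enumerate(dm.populations)
                    for j, b in enumerate(dm.populations) if i < j},
            "mds_explained": [float(x) for x in mds.explained],
            "ne13": {g: t.ne13 for g, t in ne.items()},
            "ne50": {g: t.ne50 for g, t in ne.items()},
        }
    except Exception as exc:
        raise RuntimeError(f"stage diversity failed: {exc}") from exc

    # --- ROH branch (unpruned post-QC set) ----------------------------------
    try:
        segments = rohscan.detect_roh(clean, cfg.roh)
        l_aut = cfg.l_aut_bp
        if l_aut is None:
            if cfg.simulation is not None:
                l_aut = sum(length for _, length in cfg.simulation.chromosomes)
            else:
                l_aut = rohscan.L_AUT_DEFAULT
        fr = rohscan.froh(segments, clean, l_aut_bp=l_aut)
        _emit(out / "roh" / "segments.tsv", rohscan.segments_frame(segments))
        _emit(out / "roh" / "froh.tsv", fr.per_individual)
        _emit(out / "roh" / "froh_groups.tsv", fr.per_group)
        islands = []
        for g in scan_groups:
            islands.extend(rohscan.roh_islands(segments, clean, g,
                                               percentile=cfg.scan.island_percentile))
        import pandas as pd
        isl_frame = pd.DataFrame(
            [{"group": i.group, "chrom": i.chrom,
              "start": i.start_bp - 1, "end": i.end_bp,   # BED half-open
              "n_snps": i.n_snps, "peak": i.peak_incidence, "threshold": i.threshold}
             for i in islands],
            columns=["group", "chrom", "start", "end", "n_snps", "peak", "threshold"])
        _emit(out / "roh" / "islands.bed.tsv", isl_frame)
        report["stages"]["roh"] = {
            "n_segments": len(segments), "n_islands": len(islands),
            "froh_mean": {r["population"]: float(r["froh_mean"])
                          for _, r in fr.per_group.iterrows()},
        }
    except Exception as exc:
        raise RuntimeError(f"stage roh failed: {exc}") from exc

    # --- EHH scans (phased branch) ------------------------------------------
    try:
        ga, gb = scan_groups
        ha = _restrict_haps(haps_by_pop[ga], clean)
        hb = _restrict_haps(haps_by_pop[gb], clean)
        cache: dict = {}
        tracks = {}
        windows = {}
        for stat in ("rsb", "xpehh"):
            tr = ehhscan.cross_pop_scan(ha, hb, stat, cutoff=cfg.scan.cutoff,
                                        discard_at_border=cfg.scan.discard_at_border,
                                        _ies_cache=cache)
            tracks[stat] = tr
            windows[stat] = ehhscan.significance_windows(
                tr, cfg.scan.window_bp, cfg.scan.overlap_bp,
                cfg.scan.min_snps, cfg.scan.threshold)
            _emit(out / "scan" / f"{stat}_track.tsv", tr.table)
        regions = ehhscan.consolidate_regions(
            windows["rsb"], windows["xpehh"], islands,
            tracks["rsb"], tracks["xpehh"], cfg.scan.threshold)
        _emit(out / "regions" / "candidate_regions.tsv", ehhscan.regions_frame(regions))
        report["stages"]["scan"] = {
            "significant_windows": {s: sum(w.significant for w in ws)
                                    for s, ws in windows.items()},
            "n_regions": len(regions),
            "regions": [
                {"chrom": r.chrom, "start_bp": r.start_bp, "end_bp": r.end_bp,
                 "methods": sorted(r.methods)} for r in regions],
        }
    except Exception as exc:
        raise RuntimeError(f"stage scan failed: {exc}") from exc

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    with open(out / "run_report.txt", "w") as fh:
        for stage, info in report["stages"].items():
            fh.write(f"[{stage}] {json.dumps(info, default=str)}\n")
    return report
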