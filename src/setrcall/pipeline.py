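"""End-to-end orchestration: normalize -> CNV -> LOH -> UPD -> QC -> report.

Every sample in the panel is tested against the leave-one-out median
baseline built from the remaining samples; a run writes call tables,
per-sample tracks, and an atomic JSON manifest recording the config,
input checksums, per-stage record counts and all warnings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cnv_caller import CnvCall, CnvParams, call_cnvs, infer_sex
from .depth_normalization import (BaselinePanel, build_baseline,
                                  make_ratio_profile, normalize_by_baseline)
from .io_formats import (CytobandTable, SnpSite, TargetSet, filter_sites_by_af,
                         read_allele_counts, read_depth_table, read_targets,
                         write_calls)
from .loh_upd_caller import (LohCall, LohParams, build_rhet_baseline, call_loh,
                             check_consistency, classify_upd,
                             leave_one_out_rhet_baseline)

logger = logging.getLogger("setrcall")


@dataclass
class RunConfig:
    targets_path: str = ""
    depth_path: str = ""
    allele_counts_path: str = ""
    cytoband_path: str | None = None
    out_dir: str = "setrcall_out"
    depth_dialect: str = "mean-depth"
    p_cnv: float = 0.05
    p_seed2: float = 0.2
    p_loh: float = 0.01
    min_probes: int = 45
    min_cnv_size: int = 1_000_000
    min_loh_size: int = 5_000_000
    max_gap: int = 5
    window: int = 25
    min_depth: int = 10
    min_samples: int = 8
    seed: int = 0

    def __post_init__(self):
        for name in ("p_cnv", "p_seed2", "p_loh"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.min_samples < 3:
            raise ValueError("min_samples has a hard floor of 3")
        if self.min_samples < 8:
            logger.warning("min_samples %d is below the recommended 8-sample "
                           "minimum; baseline medians may not be robust",
                           self.min_samples)

    def cnv_params(self) -> CnvParams:
        return CnvParams(p_probe=self.p_cnv, p_seed2=self.p_seed2,
                         max_gap=self.max_gap, p_region=self.p_cnv,
                         min_probes=self.min_probes,
                         min_size_bp=self.min_cnv_size)

    def loh_params(self) -> LohParams:
        return LohParams(p_loh=self.p_loh, window=self.window,
                         min_depth=self.min_depth,
                         min_size_bp=self.min_loh_size)


@dataclass
class RunResult:
    cnv_calls: list[CnvCall] = field(default_factory=list)
    loh_calls: list[LohCall] = field(default_factory=list)
    karyotypes: dict[str, str] = field(default_factory=dict)
    qc_warnings: list[str] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def analyze_panel(targets: TargetSet, depths: dict, alleles: dict,
                  sites: list[SnpSite], config: RunConfig,
                  cytobands: CytobandTable | None = None) -> RunResult:
    """Run the callers for every sample against leave-one-out baselines.

    `depths` maps sample -> DepthProfile, `alleles` sample ->
    SiteAlleleTable aligned to `sites` (already AF-filtered).
    """
    sample_ids = list(depths)
    if len(sample_ids) < config.min_samples:
        raise ValueError(
            f"panel of {len(sample_ids)} below min_samples={config.min_samples} "
            f"(8-sample minimum rule)")
    profiles = [make_ratio_profile(depths[s], targets) for s in sample_ids]
    allele_tables = [alleles[s] for s in sample_ids] if alleles else []
    result = RunResult()
    cnv_params = config.cnv_params()
    loh_params = config.loh_params()

    R = np.vstack([p.r for p in profiles])
    PRE = np.vstack([p.pre_r for p in profiles])
    for j, sample in enumerate(sample_ids):
        loo = [k for k in range(len(sample_ids)) if k != j]
        med_r = np.median(R[loo], axis=0)
        med_pre = np.median(PRE[loo], axis=0)
        zero_frac = np.mean(PRE[loo] == 0, axis=0)
        mask = (med_r <= 0) | ~np.isfinite(med_r) | (zero_frac > 0.5)
        panel = BaselinePanel(med_r, med_pre, len(loo),
                              [sample_ids[k] for k in loo], mask=mask)
        prof = normalize_by_baseline(profiles[j], panel)
        with np.errstate(divide="ignore", invalid="ignore"):
            panel_r_m = np.where(mask, np.nan, R[loo] / med_r)
            panel_raw = np.where(mask | (med_pre <= 0), np.nan, PRE[loo] / med_pre)
        sample_cnvs = call_cnvs(prof, panel_r_m, targets, cnv_params,
                                panel_raw=panel_raw)
        result.cnv_calls.extend(sample_cnvs)
        sex = infer_sex(prof, targets)
        if cytobands is not None or sex.sex != "unknown":
            from .cnv_caller import format_karyotype
            result.karyotypes[sample] = format_karyotype(sex, sample_cnvs,
                                                         cytobands)
        if allele_tables:
            rhet_base = leave_one_out_rhet_baseline(
                allele_tables, j, min_samples=config.min_samples)
            raw_loh = call_loh(allele_tables[j], rhet_base, sites, loh_params)
            classified = classify_upd(raw_loh, sample_cnvs,
                                      min_size_bp=config.min_loh_size)
            result.loh_calls.extend(classified)
            result.qc_warnings.extend(
                check_consistency(classified, sample_cnvs,
                                  min_size_bp=config.min_loh_size))
    return result


def run_all(config: RunConfig) -> RunResult:
    """Load inputs from disk, analyze the panel, write outputs + manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    targets = read_targets(config.targets_path)
    depths = read_depth_table(config.depth_path, targets,
                              dialect=config.depth_dialect)
    sites_all = []
    alleles: dict = {}
    if config.allele_counts_path:
        from .io_formats import read_snp_sites
        sites_path = Path(config.allele_counts_path).with_name("sites.tsv")
        sites_all = read_snp_sites(sites_path)
        alleles = read_allele_counts(config.allele_counts_path, sites_all,
                                     min_depth=config.min_depth)
        sites_all, _ = filter_sites_by_af(sites_all)
    cytobands = (CytobandTable.read(config.cytoband_path)
                 if config.cytoband_path else None)
    result = analyze_panel(targets, depths, alleles, sites_all, config,
                           cytobands)
    write_calls(result.cnv_calls, out / "cnv_calls.tsv")
    write_calls(result.loh_calls, out / "loh_calls.tsv")
    if result.karyotypes:
        with open(out / "karyotypes.tsv", "w") as fh:
            for s, k in sorted(result.karyotypes.items()):
                fh.write(f"{s}\t{k}\n")
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "inputs": {
            "targets": _sha256(config.targets_path),
            "depth": _sha256(config.depth_path),
            "allele_counts": (_sha256(config.allele_counts_path)
                              if config.allele_counts_path else None),
        },
        "counts": {
            "samples": len(depths),
            "targets": len(targets),
            "sites": len(sites_all),
            "cnv_calls": len(result.cnv_calls),
            "loh_calls": len(result.loh_calls),
        },
        "warnings": result.qc_warnings,
    }
    tmp = out / "manifest.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    os.replace(tmp, out / "manifest.json")
    result.manifest = manifest
    return result
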