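"""End-to-end orchestration: simulate -> dF/F maps -> angular profiles ->
histology -> behavior -> cross-modal statistics -> machine-readable report.

A run is driven by a single :class:`RunConfig` (YAML-loadable). Stages run
in dependency order; disabling an upstream stage makes its consumers fail
with an actionable error. The report embeds the config hash and seed, and
re-running the same config reproduces it bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import calcium, crossmodal, histology, synthetic
from .config import SimConfig, config_hash, odorant_group
from .geometry import bulb_mask

log = logging.getLogger("olfactomap")

DEFAULT_STAGES = ("imaging", "histology", "behavior", "crossmodal")


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    genotypes: tuple[str, ...] = ("WT", "5xFAD")
    stages: tuple[str, ...] = DEFAULT_STAGES
    out_dir: str | None = None
    write_raw: bool = False  # also materialize TIFF/CSV dataset directories

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {"sim", "genotypes", "stages", "out_dir", "write_raw"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        sim = SimConfig.from_dict(raw.get("sim", {}))
        return cls(
            sim=sim,
            genotypes=tuple(raw.get("genotypes", ("WT", "5xFAD"))),
            stages=tuple(raw.get("stages", DEFAULT_STAGES)),
            out_dir=raw.get("out_dir"),
            write_raw=bool(raw.get("write_raw", False)),
        )

    def to_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict(),
            "genotypes": list(self.genotypes),
            "stages": list(self.stages),
            "write_raw": self.write_raw,
        }


def _require(stage: str, stages, artifact: str) -> None:
    if stage not in stages:
        raise RuntimeError(
            f"stage '{stage}' is disabled but its output ({artifact}) is "
            "required; enable it or disable the downstream consumer"
        )


def analyze_genotype_imaging(cfg: SimConfig) -> dict:
    """Per-odorant activity maps and signed dorsoventral profiles for one
    simulated animal (streams one odorant at a time)."""
    mask = bulb_mask(cfg.fov_px)
    out: dict[str, dict] = {}
    for od in cfg.odorants:
        ts, truth = synthetic.simulate_odorant_trials(cfg, od)
        dmap = calcium.average_trials(ts)
        resp_mag = calcium.response_image(dmap, sign="magnitude")
        resp_raw = calcium.response_image(dmap, sign="raw")
        grid_mag = calcium.build_grid(np.where(mask, resp_mag, np.nan), mask)
        grid_raw = calcium.build_grid(np.where(mask, resp_raw, np.nan), mask)
        rois = calcium.detect_activity_rois(resp_mag, cfg.um_per_px)
        out[od] = {
            "grid_magnitude": grid_mag,
            "dv_profile_raw": calcium.grid_dv_profile(grid_raw),
            "peak_dff": float(np.nanmax(grid_mag)),
            "n_rois": len(rois),
            "truth": truth,
        }
        del ts
    return out


def run(config: RunConfig, out_dir=None) -> dict:
    """Execute the enabled stages and return (and optionally write) the
    aggregated report."""
    stages = set(config.stages)
    out = Path(out_dir or config.out_dir) if (out_dir or config.out_dir) else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config.to_dict())
    report: dict = {
        "config_hash": chash,
        "seed": config.sim.seed,
        "genotypes": list(config.genotypes),
        "odorants": {
            od: {"group": odorant_group(od)} for od in config.sim.odorants
        },
    }
    sim_cfgs = {g: config.sim.replace(genotype=g) for g in config.genotypes}

    imaging: dict[str, dict] = {}
    if "imaging" in stages:
        for g, cfg in sim_cfgs.items():
            log.info("imaging stage: genotype %s", g)
            imaging[g] = analyze_genotype_imaging(cfg)
            if config.write_raw and out is not None:
                synthetic.write_dataset(cfg, out / "raw")
        for od in config.sim.odorants:
            report["odorants"][od]["peak_dff"] = {
                g: imaging[g][od]["peak_dff"] for g in config.genotypes
            }

    profiles: dict[str, dict] = {}
    if "histology" in stages:
        for g, cfg in sim_cfgs.items():
            profile, _, truth = synthetic.generate_histology_profile(cfg, "sagittal")
            profiles[g] = {"profile": profile, "truth": truth}
        if {"WT", "5xFAD"} <= set(config.genotypes):
            report["region_ratios"] = histology.region_ratio(
                profiles["WT"]["profile"], profiles["5xFAD"]["profile"]
            )

    if "behavior" in stages:
        for od_i, od in enumerate(config.sim.odorants):
            pis = {}
            for g in config.genotypes:
                test, _ = synthetic.generate_trajectory(
                    detects=synthetic.detects_odorant(g, od),
                    seed=config.sim.seed * 1009 + 2 * od_i + (0 if g == "WT" else 10_000),
                    condition=od,
                )
                ctrl, _ = synthetic.generate_trajectory(
                    detects=False,
                    seed=config.sim.seed * 1009 + 2 * od_i + 1 + (0 if g == "WT" else 10_000),
                    condition="MO",
                )
                pis[g] = beh.session_pi(test, ctrl)
            report["odorants"][od]["pi"] = pis

    if "crossmodal" in stages:
        _require("imaging", stages, "activity maps")
        # odor-map clustering on the wild-type maps
        ref = "WT" if "WT" in imaging else next(iter(imaging))
        maps = {od: imaging[ref][od]["grid_magnitude"] for od in config.sim.odorants}
        corr = crossmodal.odor_map_correlation(maps)
        k = min(2, len(maps))
        cluster = crossmodal.cluster_odorants(corr, k=k)
        report["cluster"] = cluster
        report["odor_map_correlation"] = {
            a: {b: float(corr.loc[a, b]) for b in corr.columns} for a in corr.index
        }
        # angle-matched histology x calcium correlation per genotype
        _require("histology", stages, "A11 angular profiles")
        rows = []
        for g in config.genotypes:
            for od in config.sim.odorants:
                res, _ = crossmodal.angle_matched_correlation(
                    profiles[g]["profile"], imaging[g][od]["dv_profile_raw"]
                )
                report["odorants"][od].setdefault("angle_matched", {})[g] = {
                    "rho": res.rho,
                    "p": res.p_two_tailed,
                    "n_pairs": res.n_pairs,
                    "ci95": list(res.ci95),
                }
                rows.append(
                    {
                        "odorant": od,
                        "genotype": g,
                        "rho": res.rho,
                        "ci_low": res.ci95[0],
                        "ci_high": res.ci95[1],
                        "p": res.p_two_tailed,
                        "n_pairs": res.n_pairs,
                    }
                )
        # genotype x region statistics on the marker count tables
        counts, _ = synthetic.generate_count_tables(config.sim)
        stats_rows = []
        for marker in sorted(counts["marker"].unique()):
            sub = counts[counts["marker"] == marker]
            anova, posthoc = crossmodal.two_way_anova_bonferroni(sub)
            for r in anova + posthoc:
                stats_rows.append(
                    {
                        "marker": marker,
                        "test": r.test,
                        "label": r.label,
                        "statistic": r.statistic,
                        "df": r.df,
                        "p": r.p,
                        "adjustment": r.adjustment,
                    }
                )
        report["count_stats"] = stats_rows
        if out is not None:
            pd.DataFrame(rows).to_csv(out / "correlations.csv", index=False)
            pd.DataFrame(stats_rows).to_csv(out / "stats.csv", index=False)
            (out / "cluster.json").write_text(json.dumps(cluster, indent=2, sort_keys=True))

    if out is not None:
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=float)
        )
    return report
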