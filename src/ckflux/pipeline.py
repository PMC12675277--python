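"""Orchestration of pipeline stages with dependency ordering and run logging."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import dose_response, expression, fitting, io, segmentation, simulate
from .errors import CkfluxError, ConfigurationError
from .model import KineticParams

__all__ = ["run_pipeline", "RunReport", "STAGES"]

#: stages in dependency order
STAGES = ("simulate", "fit", "dose-response", "segment", "rel")

logger = logging.getLogger("ckflux")


@dataclass
class RunReport:
    status: int
    artifacts: Dict[str, str] = field(default_factory=dict)
    errors: List[str] = field(default_factory=list)


def _stage_simulate(cfg: io.PipelineConfig, out: Path) -> Dict[str, str]:
    design = simulate.SimulationDesign(
        time_grid=tuple(np.linspace(0.0, cfg.sim_t_end, cfg.sim_n_points)),
        c0=cfg.sim_c0,
        f=cfg.f,
        noise_sd=cfg.sim_noise_sd,
        seed=cfg.seed,
    )
    truth_sat = dose_response.SaturationParams(v_lim=1.78, ic50=112.21, D=2e-3)
    dataset, truth = simulate.simulate_competition_experiment(
        truth_sat, shared_E=4e-3, shared_K=0.02, design=design, tracer="tZ-like"
    )
    assays_path = out / "assays.csv"
    io.write_assays(dataset, assays_path)
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    return {"assays": str(assays_path), "truth": str(truth_path)}


def _stage_fit(cfg: io.PipelineConfig, out: Path, artifacts: Dict[str, str]) -> Dict[str, str]:
    assays_path = cfg.assays_csv or artifacts.get("assays")
    if not assays_path:
        raise ConfigurationError("fit stage needs assays_csv (or a prior simulate stage)")
    dataset = io.read_assays(assays_path)
    solver = fitting.SolverConfig(ftol=cfg.ftol, xtol=cfg.xtol, max_nfev=cfg.max_nfev)
    if cfg.shared_ek:
        fits = [fitting.fit_dataset_shared(dataset, solver)]
    else:
        fits = [fitting.fit_single_assay(a, dataset.f, solver) for a in dataset.assays]
    for fit in fits:
        logger.info(
            "fit converged=%s residual_norm=%.3g bound_hits=%s",
            fit.converged,
            fit.residual_norm,
            fit.bound_hits,
        )
    params_path = out / "params.csv"
    io.write_fit_results(fits, params_path, shared=cfg.shared_ek)
    return {"params": str(params_path), "_dataset": dataset, "_fits": fits}


def _stage_dose_response(cfg: io.PipelineConfig, out: Path, artifacts) -> Dict[str, str]:
    dataset = artifacts.get("_dataset")
    fits = artifacts.get("_fits")
    if dataset is None or fits is None:
        raise ConfigurationError("dose-response stage needs a prior fit stage")
    rows = []
    for fit in fits:
        for assay in dataset.assays:
            if assay.assay_id not in fit.params:
                continue
            cond = assay.condition
            if "competitor_conc_nM" not in cond:
                continue
            rows.append(
                (
                    str(cond.get("tracer", "")),
                    str(cond.get("competitor", "")),
                    float(cond["competitor_conc_nM"]),
                    fit.params[assay.assay_id].I,
                )
            )
    series_map: Dict[tuple, list] = {}
    for tracer, comp, cK, I in rows:
        series_map.setdefault((tracer, comp), []).append((cK, I))
    sat_fits = {}
    for key, points in series_map.items():
        points.sort()
        series = dose_response.DoseResponseSeries(
            competitor_conc=[p[0] for p in points],
            I_values=[p[1] for p in points],
            tracer=key[0],
            competitor=key[1],
        )
        sat_fits[key] = dose_response.fit_saturation(series)
        logger.info(
            "saturation %s/%s IC50=%.4g nM no_saturation=%s",
            key[0],
            key[1],
            sat_fits[key].params.ic50,
            sat_fits[key].no_saturation,
        )
    sat_path = out / "saturation.csv"
    io.write_saturation_fits(sat_fits, sat_path)
    return {"saturation": str(sat_path)}


def _stage_segment(cfg: io.PipelineConfig, out: Path, artifacts) -> Dict[str, str]:
    if not cfg.image_path:
        raise ConfigurationError("segment stage needs image_path")
    image = io.read_image(cfg.image_path)
    result = segmentation.segment_shoots(image, cfg.segmentation_config())
    logger.info("segmented %d object(s)", result.object_count)
    areas_path = out / "areas.csv"
    segmentation.areas_report(result, dpi=cfg.dpi).to_csv(areas_path, index=False)
    mask_path = out / "label_mask.png"
    io.write_label_mask(result.label_mask, mask_path)
    return {"areas": str(areas_path), "label_mask": str(mask_path)}


def _stage_rel(cfg: io.PipelineConfig, out: Path, artifacts) -> Dict[str, str]:
    if not cfg.qpcr_csv:
        raise ConfigurationError("rel stage needs qpcr_csv")
    df = io.read_qpcr(cfg.qpcr_csv)
    rel = expression.compute_rel_table(df)
    rel_path = out / "rel.csv"
    rel.to_csv(rel_path, index=False)
    produced = {"rel": str(rel_path)}
    if "genotype" in rel.columns and rel["genotype"].nunique() > 1:
        groups = {
            str(g): sub["rel"].tolist() for g, sub in rel.groupby("genotype")
        }
        cmp = expression.group_compare(groups)
        cmp_path = out / "rel_comparison.json"
        cmp_path.write_text(
            json.dumps(
                {"statistic": cmp.statistic, "pvalue": cmp.pvalue, "significance": cmp.significance},
                indent=2,
            )
        )
        produced["rel_comparison"] = str(cmp_path)
    return produced


_RUNNERS = {
    "simulate": lambda cfg, out, art: _stage_simulate(cfg, out),
    "fit": _stage_fit,
    "dose-response": _stage_dose_response,
    "segment": _stage_segment,
    "rel": _stage_rel,
}


def run_pipeline(
    config: io.PipelineConfig, stages: Sequence[str] = ()
) -> RunReport:
    """Execute the selected stages in dependency order.

    An empty stage list is a no-op with status 0.  A stage failure aborts all
    downstream stages and yields a nonzero status.  A run log recording the
    seed and a configuration hash is written to the output directory.
    """
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigurationError(f"unknown stage(s): {unknown}; valid: {list(STAGES)}")
    report = RunReport(status=0)
    if not stages:
        return report
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log_lines = [f"seed={config.seed}", f"config_hash={config.digest()}"]
    artifacts: Dict[str, object] = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        try:
            produced = _RUNNERS[stage](config, out, artifacts)
            artifacts.update(produced)
            log_lines.append(f"stage={stage} status=ok")
        except Exception as exc:
            report.status = 1
            report.errors.append(f"{stage}: {exc}")
            log_lines.append(f"stage={stage} status=failed error={exc}")
            logger.error("stage %s failed: %s", stage, exc)
            break
    report.artifacts = {k: v for k, v in artifacts.items() if not k.startswith("_")}
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
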