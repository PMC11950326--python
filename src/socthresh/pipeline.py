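"""Full analysis pipeline: effect sizes -> model comparison -> threshold
inference -> bias diagnostics, with a reproducible JSON report.

Stage order mirrors the analysis it automates: per-observation effect sizes
and pooling come first; a linear-versus-nonlinear prefit (linear, quadratic,
GAM by AIC) decides whether threshold detection is warranted; the six-family
breakpoint comparison estimates the initial-SOC threshold; the side-contrast
bootstrap and the between-group Q_M quantify the evidence either side of it;
the bias battery closes the run.  Everything stochastic is controlled by the
single seed in the run configuration, and the report contains no wall-clock
content, so a rerun with the same input/config/seed is byte-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import bias as bias_mod
from . import inference, meta, models

logger = logging.getLogger("socthresh")

REPORT_VERSION = "1"


class PipelineStageError(meta.SocthreshError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (echoed verbatim into the report)."""

    input: str
    fraction: str = "POC"
    weighting: str = "inverse-variance"  # or "none"
    pooling: str = "random"  # or "fixed"
    sd_policy: str = "impute"  # or "exclude"
    n_boot: int = 999
    seed: int | None = None
    min_side: int = 5
    refine_grid: bool = False
    out_dir: str | None = None
    dump_bootstrap: bool = False

    def validate(self) -> None:
        if self.seed is None and self.n_boot > 0:
            raise ValueError("seed is required whenever a bootstrap runs")
        if self.weighting not in ("inverse-variance", "none"):
            raise ValueError(f"unknown weighting {self.weighting!r}")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                logger.error("stage %s failed: %s", name, exc)
                raise PipelineStageError(name, exc) from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result

        return wrapped

    return deco


@_stage("schema")
def _load(cfg: RunConfig):
    observations = meta.read_observations(cfg.input)
    if cfg.fraction:
        observations = [o for o in observations if o.fraction == cfg.fraction]
    if len(observations) < 2:
        raise meta.SchemaError(
            f"fewer than 2 observations for fraction {cfg.fraction!r}"
        )
    return observations


@_stage("effect_sizes")
def _effects(cfg: RunConfig, observations):
    return meta.effect_sizes(observations, sd_policy=cfg.sd_policy)


@_stage("pooling")
def _pool(cfg: RunConfig, effects):
    return meta.pool_effects(
        effects, n_boot=cfg.n_boot, seed=cfg.seed, method=cfg.pooling
    )


@_stage("model_comparison")
def _models(cfg: RunConfig, effects):
    import numpy as np

    x = np.array([es.initial_soc for es in effects])
    y = np.array([es.lnrr for es in effects])
    w = (
        np.array([es.weight for es in effects])
        if cfg.weighting == "inverse-variance"
        else None
    )
    prefit, comparison, threshold = models.detect_threshold(
        x, y, w, min_side=cfg.min_side, refine=cfg.refine_grid
    )
    return x, y, w, prefit, comparison, threshold


@_stage("threshold_inference")
def _inference(cfg: RunConfig, effects, x, y, w, threshold):
    import numpy as np

    contrast = inference.bootstrap_side_slopes(
        x, y, w if w is not None else np.ones_like(x),
        threshold=threshold, n_boot=cfg.n_boot, seed=cfg.seed,
        min_side=cfg.min_side,
    )
    qm = inference.threshold_qm(effects, threshold)
    return contrast, qm


@_stage("bias_diagnostics")
def _bias(cfg: RunConfig, effects):
    return bias_mod.bias_battery(effects, method=cfg.pooling)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and return (and optionally write) the report."""
    cfg.validate()
    cfg_dict = asdict(cfg)
    # the destination directory is not part of the analysis: leaving it out
    # keeps reports byte-identical across reruns into different locations
    cfg_dict.pop("out_dir")
    report = {
        "version": REPORT_VERSION,
        "config": cfg_dict,
        "config_hash": meta.config_hash(cfg_dict),
        "seed": cfg.seed,
        "failed_stage": None,
        "warnings": [],
    }
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    try:
        observations = _load(cfg)
        effects = _effects(cfg, observations)
        report["counts"] = {
            "n_obs": len(effects),
            "n_studies": len({es.study_id for es in effects}),
            "n_sd_imputed": sum(es.sd_imputed for es in effects),
            "n_weight_capped": sum(es.weight_capped for es in effects),
        }
        if any(es.sd_imputed for es in effects):
            report["warnings"].append("missing SDs imputed by the mean-CV method")
        if any(es.weight_capped for es in effects):
            report["warnings"].append("zero-variance weights capped at the 99th percentile")

        pooled = _pool(cfg, effects)
        report["pooled"] = {
            "estimate": pooled.estimate, "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high, "tau2": pooled.tau2,
            "pvalue": pooled.pvalue, "method": pooled.method,
            "n_boot": pooled.n_boot,
        }
        report["response_classes_pct"] = pooled.class_counts

        x, y, w, prefit, comparison, threshold = _models(cfg, effects)
        report["prefit"] = {
            "best": prefit.best,
            "nonlinear": prefit.best != "linear",
            "table": prefit.selection_table,
        }
        report["model_comparison"] = {
            "best": comparison.best,
            "aic_bic_disagree": comparison.aic_bic_disagree,
            "table": comparison.selection_table,
        }
        if comparison.aic_bic_disagree:
            report["warnings"].append("AIC and BIC favour different families")

        # a threshold is only defined when the prefit prefers a nonlinear
        # shape AND the six-model comparison picks a breakpoint family
        report["threshold"] = (
            None if threshold is None else round(float(threshold), 1)
        )
        if threshold is not None:
            contrast, qm = _inference(cfg, effects, x, y, w, threshold)
            report["side_contrast"] = contrast.summary()
            report["subgroup_qm"] = {
                "qm": qm.qm, "df": qm.df, "p": qm.p,
                "group_effects": qm.group_effects,
            }
            if contrast.discarded_left or contrast.discarded_right:
                report["warnings"].append("some bootstrap replicates were discarded")
            if out_dir and cfg.dump_bootstrap:
                pd.DataFrame(
                    {
                        "slopes_left": pd.Series(contrast.slopes_left),
                        "slopes_right": pd.Series(contrast.slopes_right),
                        "values_left": pd.Series(contrast.values_left),
                        "values_right": pd.Series(contrast.values_right),
                    }
                ).to_csv(out_dir / "side_contrast_bootstrap.csv", index=False)

        diag = _bias(cfg, effects)
        report["bias"] = {
            "egger_intercept": diag.egger_intercept,
            "egger_p": diag.egger_p,
            "failsafe_n": diag.failsafe_n,
            "failsafe_criterion": diag.failsafe_criterion,
            "failsafe_pass": diag.failsafe_pass,
            "jackknife_robust": diag.jackknife_robust,
            "temporal_beta": diag.temporal_beta,
            "temporal_p": diag.temporal_p,
        }

        if out_dir:
            meta.effects_to_frame(effects).to_csv(out_dir / "effect_sizes.csv", index=False)
            pd.DataFrame(comparison.selection_table).to_csv(
                out_dir / "model_selection.csv", index=False
            )
            pd.DataFrame(diag.jackknife).to_csv(out_dir / "jackknife.csv", index=False)
            pd.DataFrame(
                {
                    "bin_low": diag.notes["histogram"]["bin_edges"][:-1],
                    "bin_high": diag.notes["histogram"]["bin_edges"][1:],
                    "count": diag.notes["histogram"]["counts"],
                }
            ).to_csv(out_dir / "effect_histogram.csv", index=False)
    except PipelineStageError as err:
        report["failed_stage"] = err.stage
        report["error"] = str(err.cause)
        if out_dir:
            meta.write_report(report, out_dir / "report.json")
        raise
    if out_dir:
        meta.write_report(report, out_dir / "report.json")
    return report
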