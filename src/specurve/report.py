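"""End-to-end pipeline and report exports.

``run_pipeline`` chains the stages in the fixed order: (optional) synthetic
generation -> exclusions -> Little's MCAR test (diagnostic) -> EM
imputation -> scale scoring -> standardization -> specification enumeration
and fitting -> per-predictor summaries -> forced-null bootstrap inference.
It writes a per-specification results CSV, a plot-ready curve CSV, a
summary table and a JSON run manifest.

The summary table mirrors per-content-type reporting: median beta with
significance stars from the bootstrap median test, partial r^2 (flagged
when >= 0.01, the effect-size threshold considered large enough to matter
for public attention), and NSRPD as "k/n" with stars from the bootstrap
NSRPD test.  Stars: '*' for p < 0.05, '***' for p < 0.001.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curve import SpecificationCurve, SpecResult, results_to_frame, sort_results
from .inference import InferenceResult, NullBootstrapInference
from .preprocess import EMSettings, em_impute, littles_mcar_test, score_scales, standardize
from .simulate import (
    ALL_SCALE_ITEMS,
    CONTENT_ALIASES,
    CONTENT_COLUMNS,
    COVARIATE_COLUMNS,
    OUTCOME_COLUMNS,
    GeneratorConfig,
    apply_missingness,
    calibrate_effects,
    generate_survey,
    read_survey_csv,
)

__all__ = ["ResultsTable", "run_pipeline", "export_curve", "significance_stars"]

logger = logging.getLogger(__name__)

EFFECT_SIZE_FLAG = 0.01  # partial r^2 at or above this is flagged


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ResultsTable:
    """Per-predictor summary table."""

    frame: pd.DataFrame

    @classmethod
    def build(
        cls,
        summaries: dict,
        inference: dict[str, InferenceResult] | None = None,
    ) -> "ResultsTable":
        rows = []
        for pred, summ in summaries.items():
            inf = inference.get(pred) if inference else None
            p_median = inf.p_median if inf else float("nan")
            p_nsrpd = inf.p_nsrpd if inf else float("nan")
            rows.append(
                {
                    "predictor": pred,
                    "predictor_label": CONTENT_ALIASES.get(pred, pred),
                    "median_beta": summ.median_beta,
                    "median_stars": significance_stars(p_median)
                    if inf
                    else "",
                    "partial_r2": summ.partial_r2_at_median,
                    "partial_r2_flag": bool(
                        summ.partial_r2_at_median >= EFFECT_SIZE_FLAG
                    ),
                    "median_partial_r2": summ.median_partial_r2,
                    "nsrpd": f"{summ.nsrpd}/{summ.n_specs}",
                    "nsrpd_stars": significance_stars(p_nsrpd) if inf else "",
                    "n_sig_pos": summ.n_sig_pos,
                    "n_sig_neg": summ.n_sig_neg,
                    "n_nonsig": summ.n_nonsig,
                    "dominant_sign": summ.dominant_sign,
                    "p_median": p_median,
                    "p_nsrpd": p_nsrpd,
                }
            )
        return cls(pd.DataFrame(rows))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def export_curve(results: list[SpecResult], path, alpha: float = 0.05) -> pd.DataFrame:
    """Write the plot-ready curve: one record per specification, sorted
    ascending by beta (ties broken by specification order), with 95% CI
    bounds, a dot color class and the decision-matrix coordinates."""
    if not results:
        raise ValueError("results must be non-empty")
    frame = results_to_frame(sort_results(results))
    frame.insert(0, "x_index", np.arange(1, len(frame) + 1))
    sig = frame["p_value"] < alpha
    frame["color"] = np.where(
        sig & (frame["beta"] < 0),
        "negative_significant",
        np.where(sig & (frame["beta"] > 0), "positive_significant", "nonsignificant"),
    )
    try:
        frame.to_csv(path, index=False)
    except OSError as err:
        raise OSError(f"cannot write curve export to {path}: {err}") from err
    return frame


# ---------------------------------------------------------------------------
# pipeline


_PIPELINE_KEYS = {
    "generator",
    "data_csv",
    "alpha",
    "n_boot",
    "covariate_sets",
    "seed",
    "em",
    "inference_scope",
    "incomplete_threshold",
}


def _load_pipeline_config(config_path) -> dict:
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    unknown = set(cfg) - _PIPELINE_KEYS
    if unknown:
        raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
    if ("generator" in cfg) == ("data_csv" in cfg):
        raise ValueError("config must name exactly one of 'generator' or 'data_csv'")
    return cfg


def _analysis_columns(data: pd.DataFrame) -> list[str]:
    return [
        c
        for c in CONTENT_COLUMNS + ALL_SCALE_ITEMS + COVARIATE_COLUMNS
        if c in data.columns
    ]


def run_pipeline(
    config_path,
    seed: int | None = None,
    alpha: float | None = None,
    n_boot: int | None = None,
    out_dir=None,
    covariate_sets: list | None = None,
) -> ResultsTable:
    """Run the full analysis from a YAML config; CLI-style arguments
    override config values.  Writes results.csv, curve.csv, table.csv and
    manifest.json under ``out_dir`` (if given) and returns the summary
    table."""
    t0 = time.perf_counter()
    cfg = _load_pipeline_config(config_path)
    seed = int(cfg.get("seed", 0)) if seed is None else int(seed)
    alpha = float(cfg.get("alpha", 0.05)) if alpha is None else float(alpha)
    n_boot = int(cfg.get("n_boot", 500)) if n_boot is None else int(n_boot)
    if covariate_sets is None:
        covariate_sets = cfg.get("covariate_sets")
    if covariate_sets is not None:
        covariate_sets = [tuple(s) for s in covariate_sets]
    em_cfg = cfg.get("em", {}) or {}
    em_settings = EMSettings(
        tol=float(em_cfg.get("tol", 1e-4)), max_iter=int(em_cfg.get("max_iter", 100))
    )

    manifest: dict = {
        "seed": seed,
        "alpha": alpha,
        "n_boot": n_boot,
        "specurve_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "python_version": platform.python_version(),
        "timings_s": {},
    }

    # -- input -------------------------------------------------------------
    if "generator" in cfg:
        gen_cfg = dict(cfg["generator"])
        calibrate = bool(gen_cfg.pop("calibrate", False))
        gcfg = GeneratorConfig.from_dict(gen_cfg)
        if calibrate:
            gcfg = calibrate_effects(gcfg)
        data = generate_survey(gcfg, seed=seed)
        if gcfg.missing_rate > 0:
            data = apply_missingness(data, gcfg.missing_rate, seed=seed + 1)
        manifest["input"] = {"kind": "generator", "n_participants": len(data)}
    else:
        data = read_survey_csv(cfg["data_csv"])
        manifest["input"] = {"kind": "csv", "path": str(cfg["data_csv"]), "n_rows": len(data)}
    manifest["timings_s"]["input"] = round(time.perf_counter() - t0, 3)

    # -- exclusions: ownership first, then completeness --------------------
    n0 = len(data)
    if "owns_smartphone" in data.columns:
        data = data[data["owns_smartphone"] == 1].reset_index(drop=True)
        manifest["excluded_non_owners"] = n0 - len(data)
        logger.info("excluded %d non-owners", n0 - len(data))
    analysis_cols = _analysis_columns(data)
    thresh = float(cfg.get("incomplete_threshold", 0.5))
    frac_missing = data[analysis_cols].isna().mean(axis=1)
    n1 = len(data)
    data = data[frac_missing < thresh].reset_index(drop=True)
    manifest["excluded_incomplete"] = n1 - len(data)
    if n1 - len(data):
        logger.info("excluded %d incomplete responses", n1 - len(data))

    # -- missing-data handling ---------------------------------------------
    t1 = time.perf_counter()
    if data[analysis_cols].isna().any().any():
        mcar = littles_mcar_test(data, analysis_cols)
        manifest["littles_mcar"] = mcar.to_dict()
        logger.info(
            "Little's MCAR test: chi2=%.3f df=%d p=%.4g",
            mcar.chi2,
            mcar.df,
            mcar.p_value,
        )
        data = em_impute(data, analysis_cols, em_settings)
        manifest["em"] = {
            "converged": bool(data.attrs.get("em_converged", True)),
            "n_iter": int(data.attrs.get("em_n_iter", 0)),
        }
    manifest["timings_s"]["missing_data"] = round(time.perf_counter() - t1, 3)

    # -- scoring and standardization ----------------------------------------
    data = score_scales(data)
    data = standardize(data, OUTCOME_COLUMNS + CONTENT_COLUMNS + COVARIATE_COLUMNS)

    # -- curve ---------------------------------------------------------------
    t2 = time.perf_counter()
    curve = SpecificationCurve(covariate_sets=covariate_sets, alpha=alpha).fit(data)
    manifest["n_specifications"] = len(curve.specs_)
    manifest["timings_s"]["curve"] = round(time.perf_counter() - t2, 3)

    # -- inference -----------------------------------------------------------
    t3 = time.perf_counter()
    inference = NullBootstrapInference(
        n_boot=n_boot,
        alpha=alpha,
        scope=str(cfg.get("inference_scope", "predictor")),
        random_state=seed,
    ).fit(data, curve=curve)
    manifest["timings_s"]["inference"] = round(time.perf_counter() - t3, 3)

    table = ResultsTable.build(curve.summaries_, inference.results_)

    sig = np.array([r.p_value for r in curve.results_]) < alpha
    betas = np.array([r.beta for r in curve.results_])
    manifest["sign_counts"] = {
        "significant_negative": int(np.sum(sig & (betas < 0))),
        "significant_positive": int(np.sum(sig & (betas > 0))),
        "nonsignificant": int(np.sum(~sig | (betas == 0))),
    }
    manifest["timings_s"]["total"] = round(time.perf_counter() - t0, 3)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results_to_frame(curve.results_).to_csv(out / "results.csv", index=False)
        export_curve(curve.results_, out / "curve.csv", alpha=alpha)
        table.to_csv(out / "table.csv")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        logger.info("wrote results to %s", out)

    table.manifest = manifest  # type: ignore[attr-defined]
    return table
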