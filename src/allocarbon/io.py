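"""Tabular I/O and the end-to-end analysis pipeline.

The canonical interchange format is the tree CSV described in
:mod:`allocarbon.data`.  ``run_pipeline`` chains the whole analysis:
data (read or simulate) → NSUR fits per requested system → jackknife
validation tables → four-method carbon comparison → RCBD ANOVA with
LSD letters, writing every report plus a machine-readable run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allometry import COMPONENTS, AdditiveParams
from .carbon import (
    bootstrap_rmse_rc,
    conversion_factors_for_method,
    method_error_matrix,
    rmse_rc_table,
)
from .comparison import compare_methods
from .data import validate_tree_table
from .nsur import CompatibleSystemModel
from .simulate import SimulationConfig, simulate_dataset
from .validation import param_summary, ra2_summary, validation_table

__all__ = ["read_tree_table", "write_tree_table", "PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"  # report precision; sidecar JSON keeps full precision


def read_tree_table(path, excel: bool = False) -> pd.DataFrame:
    """Read and validate a canonical tree table.

    CSV by default; set ``excel=True`` to read the first sheet of an
    XLS/XLSX workbook with the same column layout (requires openpyxl
    for xlsx).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_excel(path) if excel else pd.read_csv(path)
    return validate_tree_table(df)


def write_tree_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    validate_tree_table(df)
    df.to_csv(path, index=False)
    return path


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full analysis run.

    Either ``input_path`` (a canonical tree CSV) or ``simulation``
    must be provided; if both are None the default simulation runs.
    """

    input_path: str | None = None
    excel: bool = False
    simulation: SimulationConfig | None = None
    labels: tuple = ("BM1", "BM2", "CM3", "CM4")
    weights: str = "fixed"  # fixed | estimate | unit
    alpha: float = 0.05
    error_mode: str = "absolute"  # absolute | signed
    biomass_weighted_tree_mean: bool = False
    bootstrap_reps: int = 2000
    out_dir: str = "allocarbon_run"
    seed: int = 0

    def __post_init__(self):
        if not self.labels:
            raise ValueError("at least one model label is required")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in ``stage``."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _jsonable(obj):
    if isinstance(obj, AdditiveParams):
        return dict(zip(AdditiveParams.NAMES, obj.as_array().tolist()))
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write all reports to ``out_dir``.

    Returns a dict of the in-memory results (data, fits, jackknifes,
    tables).  Any stage failure raises :class:`PipelineError` naming
    the stage; reports written before the failure are left on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}
    manifest: dict = {
        "package": "allocarbon",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": _jsonable(config),
        "stages": [],
    }
    full_precision: dict = {}

    def stage(name):
        manifest["stages"].append(name)
        logger.info("pipeline stage: %s", name)

    try:
        stage("data")
        if config.input_path is not None:
            data = read_tree_table(config.input_path, excel=config.excel)
        else:
            sim = config.simulation or SimulationConfig(seed=config.seed)
            data = simulate_dataset(sim)
            manifest["simulation"] = _jsonable(sim)
        write_tree_table(data, out / "trees.csv")
        results["data"] = data
    except Exception as e:  # noqa: BLE001
        raise PipelineError("data", e) from e

    results["fits"] = {}
    results["jackknife"] = {}
    for label in config.labels:
        try:
            stage(f"fit+jackknife {label}")
            model = CompatibleSystemModel(data, label, weights=config.weights)
            fit = model.fit()
            jk = fit.jackknife()
            results["fits"][label] = fit
            results["jackknife"][label] = jk
            ps = param_summary(jk)
            ra = ra2_summary(jk)
            vt = validation_table(jk)
            ps.to_csv(out / f"params_summary_{label}.csv", float_format=FLOAT_FORMAT)
            ra.to_csv(out / f"ra2_summary_{label}.csv", float_format=FLOAT_FORMAT)
            vt.to_csv(out / f"validation_{label}.csv", float_format=FLOAT_FORMAT)
            full_precision[label] = {
                "params_summary": ps.to_dict(),
                "ra2_summary": ra.to_dict(),
                "validation": vt.to_dict(),
                "full_fit_params": _jsonable(fit.params),
                "converged": bool(fit.converged),
            }
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"fit+jackknife {label}", e) from e

    if {"BM1", "CM3"} <= set(config.labels):
        try:
            stage("carbon comparison")
            factors = {
                m: conversion_factors_for_method(m, data, config.biomass_weighted_tree_mean)
                for m in (2, 3, 4)
            }
            pd.DataFrame(
                {f"method_{m}": f.as_array() for m, f in factors.items()},
                index=list(COMPONENTS),
            ).to_csv(out / "conversion_factors.csv", float_format=FLOAT_FORMAT)
            matrix = method_error_matrix(
                data,
                results["jackknife"]["BM1"],
                results["jackknife"]["CM3"],
                config.biomass_weighted_tree_mean,
            )
            matrix.to_csv(out / "method_errors.csv", index=False, float_format=FLOAT_FORMAT)
            rc = rmse_rc_table(matrix)
            rc.to_csv(out / "rmse_rc.csv", float_format=FLOAT_FORMAT)
            ci = bootstrap_rmse_rc(matrix, n_boot=config.bootstrap_reps, seed=config.seed)
            (out / "rmse_rc_ci.json").write_text(
                json.dumps(_jsonable(ci.to_dict(orient="records")), indent=1)
            )
            results["method_errors"] = matrix
            results["rmse_rc"] = rc
            results["rmse_rc_ci"] = ci
            full_precision["rmse_rc"] = rc.to_dict()
        except Exception as e:  # noqa: BLE001
            raise PipelineError("carbon comparison", e) from e

        try:
            stage("anova+lsd")
            anovas, letter_rows = {}, []
            for name in COMPONENTS + ("total",):
                anova, grouping = compare_methods(
                    matrix, name, response=config.error_mode, alpha=config.alpha
                )
                anovas[name] = {
                    "table": anova.to_frame().to_dict(),
                    "lsd": grouping.lsd,
                    "means": dict(zip(grouping.treatments, grouping.means)),
                }
                for trt, mean, letters in zip(
                    grouping.treatments, grouping.means, grouping.letters
                ):
                    letter_rows.append((name, trt, mean, letters))
                results.setdefault("anova", {})[name] = (anova, grouping)
            (out / "anova_tables.json").write_text(json.dumps(_jsonable(anovas), indent=1))
            pd.DataFrame(
                letter_rows, columns=["component", "method", "mean_error_kg", "letters"]
            ).to_csv(out / "lsd_letters.csv", index=False, float_format=FLOAT_FORMAT)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("anova+lsd", e) from e

    (out / "report_full.json").write_text(json.dumps(_jsonable(full_precision), indent=1))
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=1))
    results["manifest"] = manifest
    return results
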