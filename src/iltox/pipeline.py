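"""End-to-end orchestration: featurize/generate → split → fit → evaluate.

:func:`run_pipeline` takes a validated :class:`RunConfig`, produces every
artifact of a model-comparison study in one output directory — descriptor
table, stepwise MLR model and trace, ELM neuron sweep and final model,
side-by-side validation reports — and writes a manifest stamping each
artifact with the configuration hash and the seeds used.  Stages run
independently: a failing stage is recorded in the manifest and the remaining
artifacts are still written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import elm as elm_mod
from . import metrics as metrics_mod
from . import mlr as mlr_mod
from .descriptors import TARGET_COLUMN, feature_columns
from .synthetic import QSARGenSpec, gen_qsar_dataset

__all__ = ["RunConfig", "ConfigError", "run_pipeline"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The run configuration failed validation before any computation."""


@dataclass
class RunConfig:
    """Validated parameters for one pipeline run.

    Either ``table`` points at an existing descriptor CSV (rows = samples,
    named descriptor columns plus ``logEC50``) or ``synthetic`` holds keyword
    overrides for :class:`~iltox.synthetic.QSARGenSpec` and a table is
    generated.  Stepwise and ELM settings are plain keyword dictionaries
    forwarded to the respective fit functions.
    """

    out_dir: str | Path
    seed: int = 7
    table: str | Path | None = None
    synthetic: dict = field(default_factory=dict)
    split_fraction: float = 0.8
    stepwise: dict = field(default_factory=dict)
    elm: dict = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        if not (0.0 < self.split_fraction <= 1.0):
            raise ConfigError("split_fraction must be in (0, 1]")
        if self.table is not None and not Path(self.table).exists():
            raise ConfigError(f"descriptor table not found: {self.table}")
        known_sw = {"p_enter", "p_remove", "max_terms"}
        bad = set(self.stepwise) - known_sw
        if bad:
            raise ConfigError(f"unknown stepwise settings: {sorted(bad)}")
        known_elm = {"n_hidden", "counts", "refine_radius", "ridge",
                     "include_output_bias"}
        bad = set(self.elm) - known_elm
        if bad:
            raise ConfigError(f"unknown elm settings: {sorted(bad)}")
        if self.table is not None:
            known_syn = set()
        else:
            known_syn = set(QSARGenSpec.__dataclass_fields__)
        bad = set(self.synthetic) - known_syn
        if bad:
            raise ConfigError(f"unknown synthetic settings: {sorted(bad)}")
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        try:
            cfg = cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None
        return cfg.validate()

    def digest(self) -> str:
        canon = json.dumps(
            {**{k: (str(v) if isinstance(v, Path) else v)
                for k, v in asdict(self).items()}},
            sort_keys=True, ensure_ascii=False)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _comparison_frame(reports: dict[str, dict]) -> pd.DataFrame:
    """Side-by-side model comparison: one row per (model, dataset)."""
    rows = []
    for model_name, rep in reports.items():
        for label in ("train", "test", "total"):
            m = rep["metrics"][label]
            rows.append({"model": model_name, "dataset": label,
                         "n": m["n"], "r2": m["r2"],
                         "aard_pct": m["aard_pct"], "rmse": m["rmse"]})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full study and return the manifest (also written to disk).

    Artifacts: ``descriptors.csv``, ``split.json``, ``mlr_model.json`` +
    ``mlr_trace.csv``, ``elm_sweep.csv`` + ``elm_model.json``,
    ``report_mlr.json`` / ``report_elm.json``, ``comparison.csv``,
    ``manifest.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "schema": "iltox.pipeline_manifest/1",
        "config_hash": config.digest(),
        "seed": config.seed,
        "artifacts": {},
        "failures": {},
        "timings_s": {},
    }

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # keep going; record the failure
                logger.exception("pipeline stage %s failed", name)
                manifest["failures"][name] = f"{type(exc).__name__}: {exc}"
                result = None
            manifest["timings_s"][name] = round(time.perf_counter() - t0, 3)
            return result
        return wrap

    @stage("table")
    def table():
        if config.table is not None:
            df = pd.read_csv(config.table, index_col=0)
        else:
            spec = QSARGenSpec(**{"seed": config.seed, **config.synthetic})
            df, truth = gen_qsar_dataset(spec)
            truth.to_json(out / "true_model.json")
            manifest["artifacts"]["true_model"] = "true_model.json"
        df.to_csv(out / "descriptors.csv")
        manifest["artifacts"]["descriptors"] = "descriptors.csv"
        return df

    if table is None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest

    train, test = metrics_mod.split_train_test(table, config.split_fraction,
                                               seed=config.seed)
    (out / "split.json").write_text(json.dumps(
        {"train": list(map(str, train.index)),
         "test": list(map(str, test.index)),
         "fraction": config.split_fraction, "seed": config.seed}, indent=2))
    manifest["artifacts"]["split"] = "split.json"

    reports: dict[str, dict] = {}
    selected_features: list[str] = []

    @stage("mlr")
    def mlr_report():
        cfg = mlr_mod.StepwiseConfig(**config.stepwise)
        model, trace = mlr_mod.stepwise_select(train, cfg)
        selected_features.extend(model.names)
        model.to_json(out / "mlr_model.json")
        trace.to_csv(out / "mlr_trace.csv", index=False)
        manifest["artifacts"]["mlr_model"] = "mlr_model.json"
        manifest["artifacts"]["mlr_trace"] = "mlr_trace.csv"
        rep = metrics_mod.validation_report(model, train, test)
        (out / "report_mlr.json").write_text(json.dumps(rep, indent=2,
                                                        ensure_ascii=False))
        manifest["artifacts"]["report_mlr"] = "report_mlr.json"
        return rep

    @stage("elm")
    def elm_report():
        # the nonlinear model builds on the stepwise-selected descriptors;
        # fall back to all features if selection produced nothing
        feats = selected_features or feature_columns(train)
        elm_cfg = dict(config.elm)
        fit_kwargs = {k: elm_cfg[k] for k in ("ridge", "include_output_bias")
                      if k in elm_cfg}
        Xtr, ytr = train[feats], train[TARGET_COLUMN]
        Xte, yte = test[feats], test[TARGET_COLUMN]
        if "n_hidden" in elm_cfg:
            best_n = int(elm_cfg["n_hidden"])
        else:
            sweep_kwargs = {}
            if "counts" in elm_cfg:
                sweep_kwargs["coarse"] = [int(k) for k in elm_cfg["counts"]]
            if "refine_radius" in elm_cfg:
                sweep_kwargs["refine_radius"] = int(elm_cfg["refine_radius"])
            sweep = elm_mod.auto_sweep(Xtr, ytr, Xte, yte, seed=config.seed,
                                       **sweep_kwargs, **fit_kwargs)
            sweep.curve.to_csv(out / "elm_sweep.csv", index=False)
            manifest["artifacts"]["elm_sweep"] = "elm_sweep.csv"
            best_n = sweep.best_n
        model = elm_mod.fit_elm(Xtr, ytr, n_hidden=best_n, seed=config.seed,
                                **fit_kwargs)
        model.to_json(out / "elm_model.json")
        manifest["artifacts"]["elm_model"] = "elm_model.json"
        rep = metrics_mod.validation_report(model, train, test)
        (out / "report_elm.json").write_text(json.dumps(rep, indent=2,
                                                        ensure_ascii=False))
        manifest["artifacts"]["report_elm"] = "report_elm.json"
        return rep

    if mlr_report is not None:
        reports["MLR"] = mlr_report
    if elm_report is not None:
        reports["ELM"] = elm_report
    if reports:
        comparison = _comparison_frame(reports)
        comparison.to_csv(out / "comparison.csv", index=False)
        manifest["artifacts"]["comparison"] = "comparison.csv"

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
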