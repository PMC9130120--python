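"""End-to-end orchestration: simulate -> filter -> aggregate -> impute ->
describe -> transform -> fit, with a reloadable run manifest.

A run is a pure function of (input files, config, seed): rerunning with
the same configuration reproduces identical outputs. Stage products are
plain CSV/JSON files in the output directory:

- ``days.csv`` / ``subjects.csv`` / ``truth.json`` (simulated input)
- ``exclusions.csv`` (dropped participants, with reasons)
- ``imputation_log.csv`` (every repaired value: old, new, method)
- ``analysis.csv`` (one closed composition per subject-timepoint)
- ``means.csv``, ``changes.csv``, ``ternary_panels.csv``, ``regions.csv``
- ``table3.csv`` (+ ``table3_sensitivity.csv``), ``fits.json``
- ``manifest.json``
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition import closure
from .descriptives import change_compositions, group_regions, mean_table, ternary_panels
from .imputation import DetectionLimitSpec, impute_below_limit, impute_missing
from .lmm import BalanceLMM, CodingConfig
from .preprocess import (
    PART_COLS,
    aggregate_subject_timepoint,
    filter_participants,
    filter_valid_days,
    load_days,
    load_subjects,
)
from .synthetic import TrialConfig, generate_trial, write_trial

__all__ = ["DEFAULT_CONFIG", "RunManifest", "load_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": True,
    "input": {"days": None, "subjects": None},
    "timepoints": ["baseline", "m6"],
    "min_wear_min": 600.0,
    "min_valid_days": 4,
    "aggregation": "compositional",
    "detection_limit": 0.5,
    "sensitivity": False,
    "region_kind": "mean",
    "region_level": 0.95,
    "time_coding": "months",
    "generator": {},
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge the default config with a YAML file and explicit overrides."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for k, v in user.items():
            if k not in cfg:
                raise KeyError(f"unknown config key {k!r}")
            if isinstance(cfg[k], dict) and isinstance(v, dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    for k, v in (overrides or {}).items():
        if v is not None:
            cfg[k] = v
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class StageRecord:
    name: str
    n_records: int
    outputs: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list[StageRecord] = field(default_factory=list)

    def add(self, name, n_records, outputs=(), notes=()) -> None:
        self.stages.append(StageRecord(name, int(n_records), [str(p) for p in outputs], list(notes)))

    def save(self, path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "stages": [vars(s) for s in self.stages],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            payload = json.load(fh)
        m = cls(payload["config_hash"], payload["seed"], payload["version"])
        m.stages = [StageRecord(**s) for s in payload["stages"]]
        return m


def _impute(analysis: pd.DataFrame, cfg: dict, which: str):
    """Missing-value then detection-limit imputation on the aggregates."""
    logs = []
    part_cols = list(PART_COLS)
    if analysis[part_cols].isna().any().any():
        res = impute_missing(analysis, part_cols)
        analysis, log = res.data, res.log
        logs.append(log)
    spec = DetectionLimitSpec("mvpa_min", float(cfg["detection_limit"]))
    res = impute_below_limit(analysis, part_cols, spec, which=which)
    logs.append(res.log)
    analysis = analysis.copy()
    analysis[part_cols] = closure(analysis[part_cols].to_numpy(dtype=float), 1440.0)
    logs = [lg for lg in logs if not lg.empty]
    log = pd.concat(logs, ignore_index=True) if logs else res.log.iloc[0:0]
    return analysis, log


def run_pipeline(
    cfg: dict,
    out_dir,
    stages: tuple[str, ...] = ("simulate", "preprocess", "describe", "fit"),
) -> RunManifest:
    """Execute the configured stages and write all artifacts to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(_config_hash(cfg), int(cfg["seed"]), __version__)

    days_path, subjects_path = cfg["input"].get("days"), cfg["input"].get("subjects")
    if cfg["simulate"] and "simulate" in stages:
        gen_cfg = TrialConfig(**{**cfg["generator"], "seed": int(cfg["seed"])})
        trial = generate_trial(gen_cfg)
        paths = write_trial(trial, out)
        days_path, subjects_path = paths["days"], paths["subjects"]
        manifest.add("simulate", len(trial.days), paths.values())
    if days_path is None or subjects_path is None:
        raise FileNotFoundError("no input files: enable 'simulate' or set input.days/input.subjects")

    days = load_days(days_path)
    subjects = load_subjects(subjects_path)

    if "preprocess" not in stages:
        manifest.save(out / "manifest.json")
        return manifest

    days, n_removed = filter_valid_days(days, float(cfg["min_wear_min"]))
    days, subjects, exclusions = filter_participants(
        days, subjects, tuple(cfg["timepoints"]), int(cfg["min_valid_days"])
    )
    exclusions.to_csv(out / "exclusions.csv", index=False)
    manifest.add(
        "filter",
        len(days),
        [out / "exclusions.csv"],
        [f"{n_removed} invalid days removed", f"{len(exclusions)} participants excluded"],
    )

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        analysis_raw = aggregate_subject_timepoint(days, cfg["aggregation"])
    notes = sorted({str(w.message) for w in caught})
    analysis, imp_log = _impute(analysis_raw, cfg, which="zeros")
    imp_log.to_csv(out / "imputation_log.csv", index=False)
    analysis.to_csv(out / "analysis.csv", index=False)
    manifest.add(
        "aggregate_impute",
        len(analysis),
        [out / "analysis.csv", out / "imputation_log.csv"],
        notes + [f"{len(imp_log)} values imputed"],
    )

    if "describe" in stages:
        tps = tuple(cfg["timepoints"])
        means = mean_table(analysis, subjects, timepoints=tps)
        means.to_csv(out / "means.csv", index=False)
        changes = change_compositions(analysis, tps[0], tps[-1])
        changes.to_csv(out / "changes.csv", index=False)
        panels = ternary_panels(changes, subjects)
        panels.to_csv(out / "ternary_panels.csv", index=False)
        regions = group_regions(
            changes, subjects, level=float(cfg["region_level"]), kind=cfg["region_kind"]
        )
        regions.to_csv(out / "regions.csv", index=False)
        manifest.add(
            "describe",
            len(changes),
            [out / n for n in ("means.csv", "changes.csv", "ternary_panels.csv", "regions.csv")],
        )

    if "fit" in stages:
        coding = CodingConfig(time_coding=cfg["time_coding"])
        results = BalanceLMM(analysis, subjects, coding=coding).fit()
        results.to_csv(out / "table3.csv")
        with open(out / "fits.json", "w") as fh:
            json.dump(results.variance_components(), fh, indent=1)
        manifest.add("fit", len(analysis), [out / "table3.csv", out / "fits.json"])

        if cfg["sensitivity"]:
            sens, sens_log = _impute(analysis_raw, cfg, which="below")
            sens_log.to_csv(out / "imputation_log_sensitivity.csv", index=False)
            sens_results = BalanceLMM(sens, subjects, coding=coding).fit()
            sens_results.to_csv(out / "table3_sensitivity.csv")
            manifest.add(
                "sensitivity",
                len(sens),
                [out / "table3_sensitivity.csv", out / "imputation_log_sensitivity.csv"],
                [f"{len(sens_log)} values imputed under the {cfg['detection_limit']}-min screen"],
            )

    manifest.save(out / "manifest.json")
    return manifest
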