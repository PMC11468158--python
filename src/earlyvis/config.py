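"""Experiment configuration: YAML schema, validation, and orchestration.

A config plus the code version uniquely determines every output: all
randomness descends from the single ``seed`` via named substreams. Unknown
keys fail fast with the offending key path, so a typo cannot silently fall
back to a default.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import lesions as ls
from . import models as md
from . import protocol as pr
from . import stimuli as st

__all__ = ["ConfigError", "ExperimentConfig", "load_config", "run_experiment",
           "write_report"]


class ConfigError(ValueError):
    pass


def _check_keys(section: dict, allowed: set[str], path: str) -> None:
    for k in section:
        if k not in allowed:
            raise ConfigError(f"unknown config key: {path}{k}")


@dataclass
class ExperimentConfig:
    seed: int = 0
    stimuli: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    conditions: list[dict] = field(default_factory=list)
    train: dict = field(default_factory=dict)
    lesions: list[dict] = field(default_factory=list)
    cache_augmentations: int = 0
    output_dir: str = "results"

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        _check_keys(raw, {"seed", "stimuli", "model", "conditions", "train",
                          "lesions", "cache_augmentations", "output_dir"}, "")
        _check_keys(raw.get("stimuli", {}),
                    {"n_per_class", "n_scenes", "fg_params"}, "stimuli.")
        _check_keys(raw.get("model", {}), {"variant", "input_scale"}, "model.")
        _check_keys(raw.get("train", {}),
                    {"learning_rate", "momentum", "batch_size", "epochs",
                     "max_epochs", "patience", "shuffle"}, "train.")
        for i, c in enumerate(raw.get("conditions", [])):
            _check_keys(c, {"scale_min", "rot_max", "background",
                            "n_train_per_class", "n_test_per_class", "n_runs"},
                        f"conditions[{i}].")
        for i, l in enumerate(raw.get("lesions", [])):
            _check_keys(l, {"mode", "channels", "consistency_threshold", "action"},
                        f"lesions[{i}].")
        variant = raw.get("model", {}).get("variant", "V1S")
        if variant not in md.VARIANTS:
            raise ConfigError(f"unknown model variant: {variant!r}")
        for i, c in enumerate(raw.get("conditions", [])):
            bg = c.get("background", "mid_gray")
            try:
                st.BackgroundKind(bg)
            except ValueError:
                raise ConfigError(f"unknown background kind: {bg!r} "
                                  f"(conditions[{i}].background)") from None
        return cls(**raw)

    def build_condition(self, c: dict) -> pr.Condition:
        c = dict(c)
        if "background" in c:
            c["background"] = st.BackgroundKind(c["background"])
        return pr.Condition(**c)

    def build_model(self) -> md.ModelSpec:
        return md.make_model(self.model.get("variant", "V1S"),
                             input_scale=self.model.get("input_scale", 255.0))

    def build_train_config(self) -> pr.TrainConfig:
        return pr.TrainConfig(**self.train)

    def build_stimset(self) -> pr.StimulusSet:
        s = self.stimuli
        return pr.StimulusSet.synthetic(
            n_per_class=s.get("n_per_class", 100),
            seed=self.seed,
            n_scenes=s.get("n_scenes", 50),
            fg_params=s.get("fg_params"))


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    return ExperimentConfig.from_dict(raw)


def _condition_row(cond: pr.Condition) -> dict:
    return {"scale_min": cond.scale_min, "rot_max": cond.rot_max,
            "background": cond.background.value}


def _results_frame(tag: str, variant: str, res: pr.ConditionResult) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(res.runs):
        rows.append({"stage": tag, "variant": variant, **_condition_row(res.condition),
                     "run": i, "accuracy": r.accuracy, "hit_rate": r.hit_rate,
                     "false_alarm_rate": r.false_alarm_rate, "dprime": r.dprime})
    return pd.DataFrame(rows)


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path | None = None,
                   log_path: str | Path | None = None) -> pd.DataFrame:
    """Execute the configured stages: runs per condition, then lesions.

    Returns the tidy per-run results table and writes ``results.csv`` plus a
    JSON-lines log under the output directory.
    """
    out = Path(out_dir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_file = Path(log_path) if log_path else out / "run_log.jsonl"
    log_entries = []

    def log(stage: str, t0: float, **extra):
        log_entries.append({"stage": stage, "wall_time_s": round(time.time() - t0, 3),
                            "seed": cfg.seed, **extra})

    t0 = time.time()
    stimset = cfg.build_stimset()
    log("stimuli", t0, n_per_class=len(stimset.faces))
    model = cfg.build_model()
    tcfg = cfg.build_train_config()

    frames = []
    base_results: pr.ConditionResult | None = None
    base_pool: pr.FeaturePool | None = None
    base_cond: pr.Condition | None = None
    for c in cfg.conditions:
        cond = cfg.build_condition(c)
        t0 = time.time()
        pool = None
        if cfg.cache_augmentations > 0:
            pool = pr.FeaturePool.build(
                model, stimset, cond,
                seed=int(pr.substream(cfg.seed, "pool-seed").integers(2**31)),
                K=cfg.cache_augmentations)
        res = pr.run_condition(model, cond, stimset, master_seed=cfg.seed,
                               cfg=tcfg, pool=pool)
        frames.append(_results_frame("full", model.variant, res))
        log("condition", t0, **_condition_row(cond),
            median_accuracy=res.median_accuracy)
        if base_results is None:
            base_results, base_pool, base_cond = res, pool, cond

    for spec_raw in cfg.lesions:
        spec = ls.LesionSpec(
            mode=spec_raw["mode"],
            channels=tuple(spec_raw.get("channels", ())),
            consistency_threshold=spec_raw.get("consistency_threshold", 0),
            action=spec_raw.get("action", "keep_only"))
        t0 = time.time()
        if spec.mode == "drop_channels":
            lm = ls.drop_channels(model, spec.channels)
            tag = f"drop_{''.join(f'F{c}' for c in spec.channels)}"
        elif spec.mode == "keep_channels":
            lm = ls.keep_channels(model, spec.channels)
            tag = f"keep_{''.join(f'F{c}' for c in spec.channels)}"
        else:
            if base_results is None:
                raise ConfigError("consistency lesions need at least one condition")
            table = ls.weight_sign_consistency(base_results.runs)
            lm = ls.apply_consistency_subset(model, table,
                                             spec.consistency_threshold, spec.action)
            tag = f"cs{spec.consistency_threshold}_{spec.action}"
        cond = base_cond if base_cond is not None else cfg.build_condition({})
        pool = base_pool.masked(lm.unit_mask) if base_pool is not None else None
        res = pr.run_condition(lm, cond, stimset, master_seed=cfg.seed,
                               cfg=tcfg, pool=pool)
        frames.append(_results_frame(tag, model.variant, res))
        log("lesion", t0, lesion=tag, n_units=lm.n_units,
            median_accuracy=res.median_accuracy)

    if not frames:
        raise ConfigError("config requests no conditions and no lesions")
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(out / "results.csv", index=False, float_format="%.6f")
    with open(log_file, "w") as fh:
        for e in log_entries:
            fh.write(json.dumps(e) + "\n")
    return table


def write_report(results: pd.DataFrame | str | Path, out_dir: str | Path | None = None,
                 ) -> dict[str, pd.DataFrame]:
    """Aggregate a tidy results table into condition-level summaries.

    Produces per-condition medians/IQRs with recomputed d' columns and a
    scale x rotation accuracy pivot per background. Errors on empty input.
    """
    if not isinstance(results, pd.DataFrame):
        results = pd.read_csv(results)
    if results.empty:
        raise ValueError("empty results table")
    keys = ["stage", "variant", "scale_min", "rot_max", "background"]

    def q1(x):
        return float(np.percentile(x, 25))

    def q3(x):
        return float(np.percentile(x, 75))

    summary = (results.groupby(keys, as_index=False)
               .agg(n_runs=("accuracy", "size"),
                    median_accuracy=("accuracy", "median"),
                    accuracy_q1=("accuracy", q1),
                    accuracy_q3=("accuracy", q3),
                    median_hit=("hit_rate", "median"),
                    median_fa=("false_alarm_rate", "median"),
                    median_dprime=("dprime", "median")))
    summary["accuracy_iqr"] = summary["accuracy_q3"] - summary["accuracy_q1"]
    pivot = results.pivot_table(index=["stage", "variant", "background", "scale_min"],
                                columns="rot_max", values="accuracy",
                                aggfunc="median")
    out = {"summary": summary, "grid": pivot}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out_dir / "summary.csv", index=False, float_format="%.6f")
        pivot.to_csv(out_dir / "condition_grid.csv", float_format="%.6f")
    return out
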