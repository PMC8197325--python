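"""End-to-end orchestration: data -> preprocess -> split -> per-classifier
wrapped feature selection -> stacking fusion -> JSON reports.

The pipeline is fully deterministic under its seed and touches the test
partition only in the final scoring stage, after every selection decision
(feature subsets and base-classifier combination) has been made on the
training and validation partitions.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from . import data as dat
from .learners import DEFAULT_ROSTER, LEARNER_TAGS, make_classifier, predict_label_proba
from .metrics import percent
from .search import enumerate_metric_pairs, xgbibs_select
from .stacking import INPUT_MODES, BaseLearnerSpec, FusionConfig, sel_stacking_fit_predict
from .importance import METRICS

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_xgb_stacking", "load_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the config echo."""

    def __init__(self, stage: str, cfg: "RunConfig", cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}\nconfig: {cfg.model_dump()}")
        self.stage = stage
        self.cause = cause


class SyntheticConfig(BaseModel):
    n_samples: int = 2990
    n_informative: int = 8
    n_redundant: int = 10
    n_noise: int = 50
    n_qualitative: int = 32
    effect_size: float = 1.0
    label_balance: float = Field(0.5, gt=0.0, lt=1.0)


class PreprocessConfig(BaseModel):
    enabled: bool = True
    max_missing_frac: float = Field(0.5, ge=0.0, le=1.0)
    outlier_sd: float = Field(5.0, gt=0.0)
    impute: str = "median_mode"


class SplitConfig(BaseModel):
    ratio: tuple[float, float, float] = (6.0, 2.0, 2.0)
    stratified: bool = True


class SelectConfig(BaseModel):
    i1: str = "total_gain"
    i2: str = "cover"
    enumerate_pairs: bool = False
    booster_params: dict[str, Any] = Field(default_factory=dict)

    @field_validator("i1", "i2")
    @classmethod
    def _metric(cls, v: str) -> str:
        if v not in METRICS:
            raise ValueError(f"unknown importance metric {v!r}; choose from {METRICS}")
        return v


class FuseConfig(BaseModel):
    K: int = Field(6, ge=2)
    meta: str = "svm"
    input_mode: str = "label_proba"
    meta_params: dict[str, Any] = Field(default_factory=dict)

    @field_validator("input_mode")
    @classmethod
    def _mode(cls, v: str) -> str:
        if v not in INPUT_MODES:
            raise ValueError(f"input_mode must be one of {INPUT_MODES}")
        return v


class RunConfig(BaseModel):
    """Validated configuration of a full run."""

    csv: Optional[str] = None
    label_column: str = "label"
    synthetic: Optional[SyntheticConfig] = SyntheticConfig()
    preprocess: PreprocessConfig = PreprocessConfig()
    split: SplitConfig = SplitConfig()
    roster: list[str] = Field(default_factory=lambda: list(DEFAULT_ROSTER))
    select: SelectConfig = SelectConfig()
    fuse: FuseConfig = FuseConfig()
    learner_params: dict[str, dict[str, Any]] = Field(default_factory=dict)
    output_dir: Optional[str] = None
    seed: int = 42

    @field_validator("roster")
    @classmethod
    def _tags(cls, v: list[str]) -> list[str]:
        bad = [t for t in v if t not in LEARNER_TAGS]
        if bad:
            raise ValueError(f"unknown classifier tags {bad}; choose from {LEARNER_TAGS}")
        if not v:
            raise ValueError("roster is empty")
        return v


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.model_validate(yaml.safe_load(fh) or {})


def _stage(name: str, cfg: RunConfig):
    class _Ctx:
        def __enter__(self):
            logger.info("stage=%s start", name)

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, cfg, exc) from exc
            logger.info("stage=%s done", name)
            return False

    return _Ctx()


def run_xgb_stacking(cfg: RunConfig) -> dict:
    """Execute the full pipeline and return (and optionally write) the report
    bundle: one selection report per roster classifier plus one fusion report.
    """
    with _stage("data", cfg):
        if cfg.csv:
            ds = dat.load_dataset(cfg.csv, cfg.label_column)
        else:
            spec = dat.SyntheticSpec(seed=cfg.seed, **cfg.synthetic.model_dump())
            ds = dat.generate_synthetic(spec)

    with _stage("preprocess", cfg):
        if cfg.preprocess.enabled:
            ds, prep_report = dat.preprocess(
                ds,
                max_missing_frac=cfg.preprocess.max_missing_frac,
                impute=cfg.preprocess.impute,
                outlier_sd=cfg.preprocess.outlier_sd,
            )
        else:
            prep_report = dat.PreprocessReport()

    with _stage("split", cfg):
        rt, rv, rte = cfg.split.ratio
        split_spec = dat.SplitSpec(rt, rv, rte, seed=cfg.seed, stratified=cfg.split.stratified)
        train, val, test = dat.split_dataset(ds, split_spec)

    selections: dict[str, Any] = {}
    with _stage("feature_selection", cfg):
        for tag in cfg.roster:
            params = cfg.learner_params.get(tag)
            if cfg.select.enumerate_pairs:
                pair, res, _ = enumerate_metric_pairs(
                    train, val, tag, seed=cfg.seed, learner_params=params,
                    booster_params=cfg.select.booster_params or None,
                )
            else:
                pair = (cfg.select.i1, cfg.select.i2)
                res = xgbibs_select(
                    train, val, tag, i1=pair[0], i2=pair[1], seed=cfg.seed,
                    learner_params=params,
                    booster_params=cfg.select.booster_params or None,
                )
            logger.info(
                "stage=select classifier=%s subset_size=%d acc=%.4f",
                tag, len(res.best_subset), res.best_acc,
            )
            selections[tag] = {"pair": pair, "result": res}

    with _stage("fusion", cfg):
        candidates = [
            BaseLearnerSpec(
                tag=tag,
                feature_subset=frozenset(sel["result"].best_subset),
                seed=cfg.seed,
                params=cfg.learner_params.get(tag),
            )
            for tag, sel in selections.items()
        ]
        fusion_cfg = FusionConfig(
            candidates=candidates, K=cfg.fuse.K, meta=cfg.fuse.meta,
            input_mode=cfg.fuse.input_mode, seed=cfg.seed,
            meta_params=cfg.fuse.meta_params or None,
        )
        fusion = sel_stacking_fit_predict(train, val, test, fusion_cfg)

    with _stage("final_scoring", cfg):
        naf = ds.n_features
        per_classifier = {}
        for tag, sel in selections.items():
            res = sel["result"]
            cols = sorted(res.best_subset)
            model = make_classifier(tag, seed=cfg.seed, params=cfg.learner_params.get(tag))
            model.fit(train.frame(cols), train.y)
            label, _ = predict_label_proba(model, test.frame(cols))
            test_acc = float((label == test.y).mean())
            per_classifier[tag] = {
                "subset": cols,
                "NSF": len(cols),
                "NAF": naf,
                "dr": res.dr,
                "dr_pct": percent(res.dr),
                "metric_pair": list(sel["pair"]),
                "full_set_val_acc": res.full_acc,
                "val_acc": res.best_acc,
                "val_acc_pct": percent(res.best_acc),
                "test_acc": test_acc,
                "test_acc_pct": percent(test_acc),
                "n_evaluations": res.n_evaluations,
            }

    bundle = {
        "seed": cfg.seed,
        "n_samples": ds.n_samples,
        "n_features": ds.n_features,
        "partition_sizes": [train.n_samples, val.n_samples, test.n_samples],
        "preprocess": vars(prep_report),
        "per_classifier": per_classifier,
        "fusion": {
            **fusion.to_dict(),
            "val_acc_pct": percent(fusion.val_accuracy),
            "test_acc_pct": percent(fusion.test_accuracy),
        },
    }

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(bundle, sort_keys=True, indent=2))
        traces = {
            tag: sel["result"].to_dict() for tag, sel in selections.items()
        }
        (out / "search_traces.json").write_text(json.dumps(traces, sort_keys=True, indent=2))
    return bundle
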