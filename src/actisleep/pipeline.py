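"""End-to-end orchestration: simulate → score → build dataset → train → evaluate.

Stages communicate only through serialized artifacts (CSV/JSON) inside a run
directory, so each stage is independently runnable and testable. Every run
writes provenance metadata (config, seed, package version) to ``run.json``;
re-running with an identical config and seed reproduces all outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import (
    instances_from_frame,
    instances_to_frame,
    segment_awake_pairs,
    stratified_split,
)
from .evaluation import evaluate_predictions
from .io import MinuteSeries, read_minute_csv, write_minute_csv
from .models import ARCHITECTURES, SleepQualityClassifier
from .scoring import ScoringConfig, periods_to_frame, score_recording
from .simulate import SimConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Validated per-stage configuration with one global seed."""

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    min_awake_min: int = 60
    fixed_length: int = 960
    split_ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    architectures: tuple[str, ...] = ARCHITECTURES
    learning_rate: float = 0.001
    max_epochs: int = 50

    def __post_init__(self) -> None:
        self.sim = dataclasses.replace(self.sim, seed=self.seed)
        unknown = set(self.architectures) - set(ARCHITECTURES)
        if unknown:
            raise ValueError(f"unknown architectures: {sorted(unknown)}")


def load_config(path: str | Path | None, seed: int | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file with per-stage sections."""
    raw = yaml.safe_load(Path(path).read_text()) if path else {}
    if raw is None:
        raw = {}
    sim = SimConfig(**{k: tuple(v) if isinstance(v, list) else v
                       for k, v in raw.get("sim", {}).items()})
    scoring = ScoringConfig(**raw.get("scoring", {}))
    kwargs = {k: v for k, v in raw.items() if k not in ("sim", "scoring")}
    if "split_ratios" in kwargs:
        kwargs["split_ratios"] = tuple(kwargs["split_ratios"])
    if "architectures" in kwargs:
        kwargs["architectures"] = tuple(kwargs["architectures"])
    cfg = PipelineConfig(sim=sim, scoring=scoring, **kwargs)
    if seed is not None:
        cfg.seed = seed
        cfg.sim = dataclasses.replace(cfg.sim, seed=seed)
    return cfg


def _config_digest(cfg: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(type(o))

    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def simulate_stage(cfg: PipelineConfig, out_dir: Path) -> list[MinuteSeries]:
    series, truth = generate_cohort(cfg.sim)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in series:
        write_minute_csv(s, out_dir / f"{s.subject_id}.csv")
    (out_dir / "ground_truth.json").write_text(
        json.dumps(
            {
                "nights": [dataclasses.asdict(n) for n in truth.nights],
                "nonwear": truth.nonwear,
            }
        )
    )
    return series


def score_stage(cfg: PipelineConfig, sim_dir: Path, out_path: Path) -> pd.DataFrame:
    frames = []
    for csv_path in sorted(sim_dir.glob("S*.csv")):
        series = read_minute_csv(csv_path)
        periods = score_recording(series, cfg.scoring)
        frames.append(periods_to_frame(periods, series, cfg.scoring))
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    out_path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_path, index=False)
    return table


def build_dataset_stage(cfg: PipelineConfig, sim_dir: Path, out_dir: Path):
    instances = []
    exclude = cfg.scoring.nonwear_mode == "exclude"
    for csv_path in sorted(sim_dir.glob("S*.csv")):
        series = read_minute_csv(csv_path)
        periods = score_recording(series, cfg.scoring)
        instances.extend(
            segment_awake_pairs(periods, series, cfg.min_awake_min, exclude_nonwear=exclude)
        )
    split = stratified_split(instances, cfg.split_ratios, seed=cfg.seed)
    out_dir.mkdir(parents=True, exist_ok=True)
    instances_to_frame(instances, cfg.fixed_length).to_csv(
        out_dir / "instances.csv", index=False
    )
    (out_dir / "split.json").write_text(
        json.dumps(
            {
                "train": split.train.tolist(),
                "validation": split.validation.tolist(),
                "test": split.test.tolist(),
                "ratios": list(split.ratios),
                "seed": split.seed,
            }
        )
    )
    return instances, split


def _load_dataset(data_dir: Path):
    df = pd.read_csv(data_dir / "instances.csv")
    split = json.loads((data_dir / "split.json").read_text())
    instances = instances_from_frame(df)
    X = [inst.awake_activity for inst in instances]
    y = np.array([inst.label for inst in instances])
    return X, y, split


def train_stage(
    cfg: PipelineConfig, data_dir: Path, architecture: str, out_dir: Path
) -> SleepQualityClassifier:
    X, y, split = _load_dataset(data_dir)
    tr, va = split["train"], split["validation"]
    model = SleepQualityClassifier(
        architecture=architecture,
        learning_rate=cfg.learning_rate,
        max_epochs=cfg.max_epochs,
        fixed_length=cfg.fixed_length,
        random_state=cfg.seed,
    )
    model.fit(
        [X[i] for i in tr], y[tr], validation_data=([X[i] for i in va], y[va])
    )
    out_dir.mkdir(parents=True, exist_ok=True)
    model.save(out_dir / architecture)
    return model


def evaluate_stage(
    model: SleepQualityClassifier, data_dir: Path, out_dir: Path, architecture: str
) -> dict:
    X, y, split = _load_dataset(data_dir)
    te = split["test"]
    conf = model.predict_proba([X[i] for i in te])[:, 1]
    report = evaluate_predictions(y[te], conf)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = report.rounded()
    (out_dir / f"{architecture}_metrics.json").write_text(json.dumps(payload, indent=2))
    pd.DataFrame(report.roc_points, columns=["fpr", "tpr"]).to_csv(
        out_dir / f"{architecture}_roc.csv", index=False
    )
    return payload


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all stages in order inside ``out_dir``; returns the run directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "run.json").write_text(
        json.dumps(
            {
                "config": dataclasses.asdict(cfg),
                "config_digest": _config_digest(cfg),
                "seed": cfg.seed,
                "version": __version__,
            },
            indent=2,
            default=str,
        )
    )
    stage = "simulate"
    try:
        simulate_stage(cfg, out_dir / "sim")
        stage = "score"
        score_stage(cfg, out_dir / "sim", out_dir / "periods.csv")
        stage = "build-dataset"
        build_dataset_stage(cfg, out_dir / "sim", out_dir / "dataset")
        for arch in cfg.architectures:
            stage = f"train[{arch}]"
            model = train_stage(cfg, out_dir / "dataset", arch, out_dir / "models")
            stage = f"evaluate[{arch}]"
            metrics = evaluate_stage(model, out_dir / "dataset", out_dir / "reports", arch)
            logger.info("%s: %s", arch, metrics)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out_dir
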