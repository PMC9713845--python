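"""End-to-end experiment orchestration.

For every participant: estimate the lookback window from the training-phase
play-length series, frame the log as sliding-window supervised samples, and
for every (architecture family x augmentation technique) cell of the grid:
augment the training split, train a personalized classifier, predict the 30
test days, and score. Macro means per cell mirror the study's comparison
grid of families against augmentation techniques.

Determinism: every cell derives its own seed from the global seed, the
participant id, the family and the technique (stable CRC32 hash), so results
do not depend on execution order and an optional parallel runner would agree
with the sequential one.
"""

from __future__ import annotations

import json
import logging
import zlib

import numpy as np
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence, Union

import pandas as pd
import yaml

from .augmentation import TECHNIQUES, AugmentationConfig, augment_dataset
from .cohort import CohortConfig, ParticipantLog, read_cohort, simulate_cohort
from .evaluation import (
    CohortReport,
    aggregate,
    confusion,
    metrics,
)
from .models import (
    FAMILIES,
    TrainingConfig,
    build_model,
    default_spec,
    predict_proba,
    save_model,
    train,
)
from .windowing import (
    LabelRule,
    WindowSizeEstimate,
    estimate_window_size,
    make_supervised,
    TRAIN_DAYS,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentError",
    "run_experiment",
    "estimate_cohort_windows",
    "load_experiment_config",
    "cell_seed",
    "write_report",
    "render_report",
]

logger = logging.getLogger(__name__)

PER_PARTICIPANT_COLUMNS = (
    "participant_id", "precision", "recall", "f1", "auc", "accuracy",
    "n_test", "window_size", "family", "technique",
)


class ExperimentError(ValueError):
    """Invalid experiment configuration."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Full description of one comparison-grid experiment."""

    cohort: Union[str, Path, CohortConfig] = field(default_factory=CohortConfig)
    label_rule: LabelRule = field(default_factory=LabelRule)
    w_max: int = 10
    w_fallback: int = 3
    techniques: tuple[str, ...] = TECHNIQUES
    families: tuple[str, ...] = FAMILIES
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    output_dir: Union[str, Path, None] = None
    save_models: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.families or not self.techniques:
            raise ExperimentError("families and techniques grids must be non-empty")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ExperimentError(f"unknown families: {sorted(unknown)}")
        unknown = set(self.techniques) - set(TECHNIQUES)
        if unknown:
            raise ExperimentError(f"unknown techniques: {sorted(unknown)}")


def cell_seed(global_seed: int, participant_id: str, family: str, technique: str) -> int:
    """Stable per-cell seed below 2^31, independent of execution order."""
    key = f"{global_seed}|{participant_id}|{family}|{technique}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def _load_logs(config: ExperimentConfig) -> list[ParticipantLog]:
    if isinstance(config.cohort, CohortConfig):
        return simulate_cohort(config.cohort)
    path = Path(config.cohort)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    return read_cohort(path)


def estimate_cohort_windows(
    logs: Sequence[ParticipantLog], w_max: int = 10, fallback: int = 3
) -> list[WindowSizeEstimate]:
    """Window-size estimates from each participant's days 1-30 play series."""
    return [
        estimate_window_size(
            log.play_series()[:TRAIN_DAYS], w_max, fallback, log.participant_id
        )
        for log in logs
    ]


def run_experiment(config: ExperimentConfig) -> dict[tuple[str, str], CohortReport]:
    """Run the full grid; returns one :class:`CohortReport` per cell.

    Writes ``per_participant.csv`` and ``macro_grid.json`` under
    ``config.output_dir`` when set. A failure for one participant aborts the
    run with that participant named; nothing is silently skipped.
    """
    logs = _load_logs(config)
    estimates = estimate_cohort_windows(logs, config.w_max, config.w_fallback)
    splits = [
        make_supervised(log, est, config.label_rule)
        for log, est in zip(logs, estimates)
    ]

    grid: dict[tuple[str, str], CohortReport] = {}
    window_sizes = {est.participant_id: est.window_size for est in estimates}
    for family in config.families:
        for technique in config.techniques:
            per_participant = []
            for split in splits:
                seed = cell_seed(config.seed, split.participant_id, family, technique)
                aug_cfg = replace(config.augmentation, technique=technique, seed=seed)
                train_set = augment_dataset(split.train, aug_cfg)
                spec = default_spec(family, split.window_size)
                model = build_model(spec, seed=seed)
                train(model, train_set, replace(config.training, seed=seed))
                X_test = np.stack([s.features for s in split.test])
                scores = np.asarray(predict_proba(model, X_test), dtype=float)
                labels = [s.label for s in split.test]
                preds = (scores >= config.training.decision_threshold).astype(int)
                pm = metrics(
                    confusion(labels, preds), scores, labels,
                    participant_id=split.participant_id,
                )
                logger.info(
                    "cell %s/%s/%s window=%d train=%d final_loss=%.4f "
                    "f1=%.3f acc=%.3f",
                    split.participant_id, family, technique, split.window_size,
                    len(train_set), model.training_history[-1], pm.f1, pm.accuracy,
                )
                per_participant.append(pm)
                if config.save_models and config.output_dir is not None:
                    save_model(
                        model,
                        Path(config.output_dir) / "models"
                        / split.participant_id / family / technique,
                    )
            grid[(family, technique)] = aggregate(per_participant)
    if config.output_dir is not None:
        write_report(grid, config.output_dir, window_sizes)
    return grid


def write_report(
    grid: Mapping[tuple[str, str], CohortReport],
    output_dir: Union[str, Path],
    window_sizes: Mapping[str, int] | None = None,
) -> None:
    """Write the per-participant table (CSV) and the macro grid (JSON)."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    windows = window_sizes or {}
    rows = []
    macro: dict[str, dict] = {}
    for (family, technique), report in sorted(grid.items()):
        for pm in report.per_participant:
            rows.append(
                (
                    pm.participant_id, pm.precision, pm.recall, pm.f1, pm.auc,
                    pm.accuracy, pm.n_test, windows.get(pm.participant_id, -1),
                    family, technique,
                )
            )
        macro.setdefault(family, {})[technique] = {
            "macro": dict(report.macro),
            "n_contributing": dict(report.n_contributing),
            "n_excluded": dict(report.n_excluded),
        }
    pd.DataFrame(rows, columns=list(PER_PARTICIPANT_COLUMNS)).to_csv(
        output_dir / "per_participant.csv", index=False
    )
    (output_dir / "macro_grid.json").write_text(json.dumps(macro, indent=2))


def render_report(runs_dir: Union[str, Path]) -> dict:
    """Re-render the macro grid from a stored per-participant table.

    Recomputes macro means (with the same undefined-exclusion policy) from
    ``per_participant.csv``; rendering a finished run is idempotent.
    """
    runs_dir = Path(runs_dir)
    csv_path = runs_dir / "per_participant.csv"
    if not csv_path.exists():
        raise FileNotFoundError(f"no per-participant table at {csv_path}")
    df = pd.read_csv(csv_path)
    from .evaluation import ParticipantMetrics

    macro: dict[str, dict] = {}
    for (family, technique), grp in df.groupby(["family", "technique"]):
        pms = [
            ParticipantMetrics(
                participant_id=str(r.participant_id),
                precision=r.precision, recall=r.recall, f1=r.f1,
                auc=r.auc, accuracy=r.accuracy, n_test=int(r.n_test),
            )
            for r in grp.itertuples(index=False)
        ]
        report = aggregate(pms)
        macro.setdefault(family, {})[technique] = {
            "macro": dict(report.macro),
            "n_contributing": dict(report.n_contributing),
            "n_excluded": dict(report.n_excluded),
        }
    (runs_dir / "macro_grid.json").write_text(json.dumps(macro, indent=2))
    return macro


# --------------------------------------------------------------------------
# YAML configuration
# --------------------------------------------------------------------------

def load_experiment_config(path: Union[str, Path], **overrides) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a YAML document.

    Blocks: ``cohort`` (a path string or CohortConfig fields), ``label``,
    ``window``, ``augmentation``, ``model``, ``training``, ``output``,
    ``seed``. Every field has a default; keyword overrides win over the file.
    """
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ExperimentError("experiment config must be a mapping")

    kwargs: dict = {}
    cohort = doc.get("cohort")
    if isinstance(cohort, str):
        kwargs["cohort"] = cohort
    elif isinstance(cohort, dict):
        if "adherence_base_rate_params" in cohort:
            cohort["adherence_base_rate_params"] = tuple(
                cohort["adherence_base_rate_params"]
            )
        kwargs["cohort"] = CohortConfig(**cohort)
    if "label" in doc:
        kwargs["label_rule"] = LabelRule(**doc["label"])
    window = doc.get("window", {})
    if "w_max" in window:
        kwargs["w_max"] = int(window["w_max"])
    if "fallback" in window:
        kwargs["w_fallback"] = int(window["fallback"])
    aug = dict(doc.get("augmentation", {}))
    techniques = aug.pop("techniques", None)
    if aug:
        kwargs["augmentation"] = AugmentationConfig(**aug)
    if techniques is not None:
        kwargs["techniques"] = tuple(techniques)
    model = doc.get("model", {})
    if "families" in model:
        kwargs["families"] = tuple(model["families"])
    if "training" in doc:
        kwargs["training"] = TrainingConfig(**doc["training"])
    if "output" in doc:
        kwargs["output_dir"] = doc["output"].get("directory")
        kwargs["save_models"] = bool(doc["output"].get("save_models", False))
    if "seed" in doc:
        kwargs["seed"] = int(doc["seed"])
    kwargs.update(overrides)
    return ExperimentConfig(**kwargs)
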