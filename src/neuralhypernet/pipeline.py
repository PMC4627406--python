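"""End-to-end orchestration: cohort -> discretization -> Q-analysis ->
feature split -> holdout -> hidden-size sweep -> training -> evaluation.

Every stage writes its artifact under the output directory, all randomness
descends from a single seed, and any stage failure is re-raised with the
stage name so partial artifacts remain inspectable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ann as ann_mod
from . import evaluate as eval_mod
from . import qanalysis as qa
from . import synth as synth_mod
from .preprocess import build_incidence, select_variables
from .schema import LABEL_COLUMN, descriptor_name
from .thresholds import load_threshold_map

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

_FEATURE_SETS = ("connected", "unconnected", "union")


@dataclass
class PipelineConfig:
    """Declarative run description; every artifact is re-derivable from it.

    ``input_csv=None`` generates a synthetic cohort from ``synth`` overrides;
    ``feature_set`` picks which side of the backcloth split feeds the
    classifier.  ``sweep_sizes=None`` skips model selection and trains at
    ``hidden_neurons`` directly.
    """

    input_csv: str | None = None
    synth: dict = field(default_factory=dict)
    threshold_path: str | None = None
    invert_po2: bool = False
    feature_set: str = "union"
    anchor: str | None = None
    train_fraction: float = 0.85
    sweep_sizes: list[int] | None = None
    sweep_folds: int = 10
    hidden_neurons: int = 8
    learning_rate: float = 0.5
    momentum: float = 0.9
    max_epochs: int = 200
    decision_threshold: float = 0.5
    seed: int = 0
    outdir: str = "out"

    def __post_init__(self) -> None:
        if self.feature_set not in _FEATURE_SETS:
            raise ValueError(
                f"feature_set must be one of {_FEATURE_SETS}, got {self.feature_set!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    config: PipelineConfig
    report: eval_mod.EvaluationReport
    plateau: qa.PlateauReport
    connected: list[str]
    unconnected: list[str]
    best_hidden: int
    artifacts: dict[str, Path]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


@_stage("synth")
def _load_or_generate(config: PipelineConfig, outdir: Path, artifacts: dict):
    if config.input_csv is not None:
        return synth_mod.read_cohort(config.input_csv)
    scfg = synth_mod.SyntheticConfig(**{"seed": config.seed, **config.synth})
    cohort = synth_mod.generate_cohort(scfg)
    path = outdir / "cohort.csv"
    synth_mod.write_cohort(cohort, path)
    artifacts["cohort"] = path
    return cohort


@_stage("preprocess")
def _preprocess(config: PipelineConfig, cohort, outdir: Path, artifacts: dict):
    tmap = load_threshold_map(config.threshold_path)
    variables = select_variables(cohort)
    inc = build_incidence(
        cohort,
        variables=variables,
        threshold_map=tmap,
        include_diagnosis=True,
        invert_po2=config.invert_po2,
    )
    path = outdir / "incidence.csv"
    inc.to_csv(path)
    artifacts["incidence"] = path
    return inc


@_stage("qanalysis")
def _qanalysis(config: PipelineConfig, inc, outdir: Path, artifacts: dict):
    sfm = qa.shared_face_matrix(inc)
    profile = qa.structure_profile(sfm)
    anchor = config.anchor or descriptor_name(LABEL_COLUMN, 1)
    plateau = qa.find_plateau(profile, anchor)
    connected, unconnected = qa.split_feature_sets(plateau, inc.descriptors)

    sfm.to_csv(outdir / "shared_face.csv")
    profile.to_csv(outdir / "qprofile.csv", anchor=anchor)
    plateau_payload = {
        "q_lo": plateau.q_lo,
        "q_hi": plateau.q_hi,
        "members": sorted(plateau.members),
        "contains_positive_diagnosis": plateau.contains_positive_diagnosis,
    }
    (outdir / "plateau.json").write_text(
        json.dumps(plateau_payload, indent=2, sort_keys=True) + "\n"
    )
    (outdir / "feature_sets.json").write_text(
        json.dumps(
            {"connected": connected, "unconnected": unconnected},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    artifacts.update(
        shared_face=outdir / "shared_face.csv",
        qprofile=outdir / "qprofile.csv",
        plateau=outdir / "plateau.json",
        feature_sets=outdir / "feature_sets.json",
    )
    return sfm, profile, plateau, connected, unconnected


@_stage("train")
def _train(config: PipelineConfig, X, y, outdir: Path, artifacts: dict):
    train_idx, val_idx = ann_mod.holdout_split(
        X, y, train_fraction=config.train_fraction, seed=config.seed + 1
    )
    best_hidden = config.hidden_neurons
    if config.sweep_sizes:
        sweep = ann_mod.sweep_hidden(
            X[train_idx],
            y[train_idx],
            sizes=config.sweep_sizes,
            k=config.sweep_folds,
            seed=config.seed + 2,
            learning_rate=config.learning_rate,
            momentum=config.momentum,
            max_epochs=config.max_epochs,
        )
        sweep.to_csv(outdir / "sweep.csv")
        artifacts["sweep"] = outdir / "sweep.csv"
        best_hidden = sweep.best_hidden
    model = ann_mod.MLPBackpropClassifier(
        hidden_neurons=best_hidden,
        learning_rate=config.learning_rate,
        momentum=config.momentum,
        max_epochs=config.max_epochs,
        decision_threshold=config.decision_threshold,
        random_state=config.seed + 3,
    )
    model.fit(X[train_idx], y[train_idx])
    ann_mod.save_model(model, outdir / "model.txt")
    artifacts["model"] = outdir / "model.txt"
    return model, best_hidden, train_idx, val_idx


@_stage("evaluate")
def _evaluate(config: PipelineConfig, model, X_val, y_val, ids_val, outdir: Path, artifacts: dict):
    scores = model.predict_proba(X_val)[:, 1]
    report = eval_mod.evaluate_classifier(
        y_val, scores, threshold=config.decision_threshold, patient_ids=ids_val
    )
    report.to_json(outdir / "evaluation.json")
    report.roc_to_csv(outdir / "roc.csv")
    artifacts.update(evaluation=outdir / "evaluation.json", roc=outdir / "roc.csv")
    return report


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write all artifacts under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    cohort = _load_or_generate(config, outdir, artifacts)
    inc = _preprocess(config, cohort, outdir, artifacts)
    sfm, profile, plateau, connected, unconnected = _qanalysis(config, inc, outdir, artifacts)

    feats = inc.feature_view()
    if config.feature_set == "connected":
        chosen = connected
    elif config.feature_set == "unconnected":
        chosen = unconnected
    else:
        chosen = feats.descriptors
    if not chosen:
        raise StageError(
            f"stage 'train' failed: the {config.feature_set!r} feature set is empty"
        )
    col_idx = [feats.descriptors.index(d) for d in chosen]
    mask = feats.labeled_mask
    X = feats.matrix[np.ix_(mask, col_idx)].astype(float)
    y = feats.labels[mask].astype(int)
    ids = [p for p, m in zip(feats.patients, mask) if m]

    model, best_hidden, train_idx, val_idx = _train(config, X, y, outdir, artifacts)
    report = _evaluate(
        config,
        model,
        X[val_idx],
        y[val_idx],
        [ids[i] for i in val_idx],
        outdir,
        artifacts,
    )

    log_payload = {
        "config": config.to_dict(),
        "n_patients": len(inc.patients),
        "n_descriptors": len(inc.descriptors),
        "n_features_used": len(chosen),
        "best_hidden": best_hidden,
        "stage_seeds": {
            "synth": config.seed,
            "holdout": config.seed + 1,
            "sweep": config.seed + 2,
            "train": config.seed + 3,
        },
    }
    (outdir / "run_log.json").write_text(
        json.dumps(log_payload, indent=2, sort_keys=True) + "\n"
    )
    artifacts["run_log"] = outdir / "run_log.json"
    logger.info("pipeline complete: AUC=%.3f Jaccard=%.3f", report.auc, report.jaccard)
    return PipelineResult(
        config=config,
        report=report,
        plateau=plateau,
        connected=connected,
        unconnected=unconnected,
        best_hidden=best_hidden,
        artifacts=artifacts,
    )
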