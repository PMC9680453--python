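"""End-to-end experiment orchestration: generate -> curate -> extract ->
train -> evaluate -> compare.

One :class:`ExperimentConfig` drives the whole comparison: a phantom
dataset is generated and curated, frozen-backbone features are extracted
and cached, every requested model variant is trained with its own seed,
and all variants are scored on the held-out test subjects with the full
metric suite.  Every artifact lands under the output directory with the
config echoed, and the run is deterministic for fixed seeds.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import curation, models
from .curation import (
    DEFAULT_FRACTIONS,
    CuratedDataset,
    LabelStore,
    SliceLabel,
    SplitAssignment,
    curate_dataset,
    load_label_store,
    split_subjects,
)
from .evaluation import EvalReport, evaluate
from .features import (
    BackboneSpec,
    FeatureSequence,
    build_sequence,
    cached_stack_features,
    get_backbone_spec,
)
from .models import (
    VARIANTS,
    HeadConfig,
    TrainingConfig,
    TrainingHistory,
    build_variant,
    predict_stack,
    select_epoch,
    sequences_to_arrays,
    train,
)
from .phantoms import PhantomConfig, generate_dataset

__all__ = [
    "ExperimentConfig",
    "VariantResult",
    "ComparisonReport",
    "run_experiment",
    "extract_sequences",
    "render_subject_report",
]

log = logging.getLogger("saxlevel")

CNN_BATCH_SIZE = 32  # per-image batches; sequence models use config.training.batch_size


@dataclass
class ExperimentConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    split_fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    split_seed: int = 0
    backbone: str = "TinyTest"
    backbone_weights: str = "random"
    variants: tuple[str, ...] = VARIANTS
    training: TrainingConfig = field(default_factory=TrainingConfig)

    def __post_init__(self) -> None:
        for v in self.variants:
            if v not in VARIANTS:
                raise ValueError(f"unknown variant {v!r}; known: {VARIANTS}")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        d = yaml.safe_load(text)
        d["phantom"] = PhantomConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d.get("phantom", {}).items()
        })
        d["training"] = TrainingConfig(**d.get("training", {}))
        d["split_fractions"] = tuple(d.get("split_fractions", DEFAULT_FRACTIONS))
        d["variants"] = tuple(d.get("variants", VARIANTS))
        return cls(**d)


@dataclass
class VariantResult:
    variant: str
    report: EvalReport
    history: TrainingHistory
    selected_epoch: int
    param_count: int


@dataclass
class ComparisonReport:
    backbone: str
    results: dict[str, VariantResult]
    config: ExperimentConfig

    def sotd_summary(self) -> dict[str, int]:
        return {v: r.report.sotd for v, r in self.results.items()}

    def format_text(self) -> str:
        lines = [f"### Model comparison — backbone {self.backbone} ###", ""]
        for v, r in self.results.items():
            lines.append(r.report.format_table(name=v))
            lines.append(f"selected epoch: {r.selected_epoch}   trainable params: {r.param_count}")
            lines.append("")
        lines.append(f"SOTD by model (backbone {self.backbone}; lower is better):")
        width = max(self.sotd_summary().values()) or 1
        for v, s in self.sotd_summary().items():
            bar = "#" * max(1, round(40 * s / width)) if s else ""
            lines.append(f"  {v:8s} {s:5d} {bar}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "backbone": self.backbone,
            "results": {
                v: {
                    "report": r.report.to_dict(),
                    "selected_epoch": r.selected_epoch,
                    "param_count": r.param_count,
                    "history": dataclasses.asdict(r.history),
                }
                for v, r in self.results.items()
            },
            "config": dataclasses.asdict(self.config),
        }


def _stage_generate(config: ExperimentConfig, dataset_dir: Path) -> dict:
    manifest_path = dataset_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("config") == dataclasses.asdict(config.phantom):
            log.info("generate: cache hit at %s", dataset_dir)
            return manifest
    log.info("generate: writing %d phantom subjects to %s", config.phantom.n_subjects, dataset_dir)
    return generate_dataset(config.phantom, dataset_dir)


def extract_sequences(
    dataset: CuratedDataset,
    labels: LabelStore,
    spec: BackboneSpec,
    subjects: list[str],
    cache_dir: Path | None = None,
) -> list[FeatureSequence]:
    """Frozen-backbone features for every (subject, phase), as padded sequences."""
    sequences = []
    for subject in subjects:
        for phase in dataset.phases(subject):
            stack = dataset.stack(subject, phase)
            feats = cached_stack_features(stack, spec, cache_dir)
            seq_labels = labels.sequence(subject, phase, stack.indices)
            sequences.append(build_sequence(feats, seq_labels))
    return sequences


def _flatten_for_cnn(sequences: list[FeatureSequence]) -> tuple[np.ndarray, np.ndarray]:
    X = np.concatenate([s.matrix[s.mask] for s in sequences])
    y = np.concatenate([s.label_sequence[s.mask] for s in sequences])
    return X, y


def _audit_no_leakage(split: SplitAssignment, train_ids: set[str], test_ids: set[str]) -> None:
    overlap = train_ids & test_ids
    if overlap:
        raise RuntimeError(f"subject-wise leakage: {sorted(overlap)} in both train and test")


def run_experiment(config: ExperimentConfig, output_dir: Path) -> ComparisonReport:
    """Execute all stages and return (and persist) the model comparison."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    (output_dir / "config.yaml").write_text(config.to_yaml())

    stage = "generate"
    try:
        dataset_dir = output_dir / "dataset"
        _stage_generate(config, dataset_dir)

        stage = "curate"
        dataset = curate_dataset(dataset_dir)
        labels = load_label_store(dataset_dir / "labels.json")
        log.info("curate: retained %d subjects, excluded %d",
                 len(dataset.retained), len(dataset.excluded))

        stage = "split"
        split = split_subjects(dataset.retained, config.split_fractions, config.split_seed)
        (output_dir / "split.json").write_text(json.dumps({
            "fractions": list(split.fractions),
            "seed": split.seed,
            "assignment": dict(split.assignment),
        }, indent=1, sort_keys=True))
        parts = {p: split.members(p) for p in curation.PARTITIONS}
        _audit_no_leakage(split, set(parts["training"]), set(parts["testing"]))
        _audit_no_leakage(split, set(parts["training"]), set(parts["validation"]))

        stage = "extract"
        spec = get_backbone_spec(config.backbone, weights=config.backbone_weights)
        cache_dir = output_dir / "features"
        seqs = {
            p: extract_sequences(dataset, labels, spec, parts[p], cache_dir)
            for p in curation.PARTITIONS
        }
        log.info("extract: %s sequences per partition",
                 {p: len(s) for p, s in seqs.items()})

        stage = "train"
        results: dict[str, VariantResult] = {}
        rnn_arrays = {p: sequences_to_arrays(s) for p, s in seqs.items()}
        cnn_arrays = {p: _flatten_for_cnn(s) for p, s in seqs.items()}
        for vi, variant in enumerate(config.variants):
            vseed = int(config.training.seed + 1000 * (vi + 1))
            model = build_variant(variant, spec.feature_dim, HeadConfig(), seed=vseed)
            tcfg = dataclasses.replace(
                config.training,
                seed=vseed,
                batch_size=CNN_BATCH_SIZE if variant == "cnn" else config.training.batch_size,
            )
            data = cnn_arrays if variant == "cnn" else rnn_arrays
            log.info("train: %s (%d params, %d epochs)",
                     variant, model.param_count(), tcfg.epochs)
            snapshots, history = train(
                model, data["training"], data["validation"], tcfg
            )
            chosen = select_epoch(history)
            model.set_weights(snapshots.best_weights)

            # persist the learning curves and a checkpoint with config echo
            vdir = output_dir / "models" / variant
            vdir.mkdir(parents=True, exist_ok=True)
            with open(vdir / "history.csv", "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["epoch", "train_loss", "val_loss", "train_acc", "val_acc"])
                for e in range(len(history)):
                    w.writerow([e, history.train_loss[e], history.val_loss[e],
                                history.train_acc[e], history.val_acc[e]])
            np.savez(vdir / "checkpoint.npz",
                     *snapshots.best_weights,
                     config=np.array(json.dumps({
                         "backbone": spec.name, "variant": variant,
                         "seed": vseed, "selected_epoch": chosen,
                     })))

            stage_eval = f"evaluate[{variant}]"
            y_true, y_pred, probs = [], [], []
            for fs in seqs["testing"]:
                labels_pred, p = predict_stack(model, fs)
                valid = np.flatnonzero(fs.mask)
                y_true.extend(int(v) for v in fs.label_sequence[valid])
                y_pred.extend(int(v) for v in labels_pred)
                probs.append(p[valid])
            report = evaluate(y_true, y_pred, np.concatenate(probs))
            log.info("%s: accuracy %.3f SOTD %d", stage_eval, report.accuracy, report.sotd)
            results[variant] = VariantResult(
                variant=variant, report=report, history=history,
                selected_epoch=chosen, param_count=model.param_count(),
            )

        stage = "report"
        comparison = ComparisonReport(backbone=spec.name, results=results, config=config)
        rdir = output_dir / "reports"
        rdir.mkdir(exist_ok=True)
        (rdir / "comparison.json").write_text(json.dumps(comparison.to_dict(), indent=1))
        (rdir / "comparison.txt").write_text(comparison.format_text())
        return comparison
    except Exception as e:
        raise RuntimeError(f"experiment stage {stage!r} failed: {e}") from e


def render_subject_report(
    model,
    sequence: FeatureSequence,
    true_labels: list[SliceLabel] | None = None,
) -> str:
    """Per-slice text listing of ground truth vs prediction for one stack.

    Each line shows the slice index, the truth, the prediction in the
    ``(BS) (P = OBS)`` style, and a correctness flag.
    """
    valid = np.flatnonzero(sequence.mask)
    if true_labels is None:
        if np.any(sequence.label_sequence[valid] < 0):
            raise ValueError("subject has unlabeled slices; cannot render report")
        true_labels = [SliceLabel(int(v)) for v in sequence.label_sequence[valid]]
    predictions, _ = predict_stack(model, sequence)
    lines = [f"subject {sequence.subject_id} phase {sequence.phase_id}"]
    n_wrong = 0
    for i, (truth, pred) in enumerate(zip(true_labels, predictions)):
        ok = truth == pred
        n_wrong += not ok
        flag = "correct" if ok else "INCORRECT"
        lines.append(
            f"  slice {i:2d}: ({truth.token.upper()}) (P = {pred.token.upper()})  {flag}"
        )
    lines.append(f"  {len(predictions) - n_wrong}/{len(predictions)} correct")
    return "\n".join(lines)
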