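"""Subject-grouped cross-validation, metrics, and the training harnesses.

The evaluation protocol groups subjects (30 subjects -> 10 groups of 3 by
default); each group serves as the test set once while the remaining groups
are split 7 train : 2 validation, so no subject ever appears on both sides
of a fold.  Reported metrics are the mean over folds of accuracy and
macro-F1, with row-normalised confusion matrices per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from PIL import Image
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
)

from .config import ModelConfig, TrainConfig
from .features import build_stat_vector
from .gadf import encode_window
from .model import HazardFusionClassifier
from .nn import cross_entropy, sgd_momentum_step  # noqa: F401  (re-exported API)
from .synthetic import SyntheticDataset


@dataclass
class FoldPlan:
    """Subject groups and the per-fold train/val/test subject splits."""

    groups: list[list[str]]
    folds: list[dict[str, list[str]]]
    seed: int


def make_fold_plan(
    subject_ids: Sequence[str], seed: int = 0, n_groups: int = 10
) -> FoldPlan:
    """Partition subjects into ``n_groups`` groups and derive the folds.

    Each group is the test set of exactly one fold; the remaining groups
    are randomly split into train and validation in a 7:2 proportion
    (scaled when n_groups differs from 10).
    """
    ids = sorted(set(subject_ids))
    if len(ids) % n_groups != 0:
        raise ValueError(
            f"{len(ids)} subjects cannot be split into {n_groups} equal groups"
        )
    group_size = len(ids) // n_groups
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    groups = [
        [ids[order[g * group_size + k]] for k in range(group_size)]
        for g in range(n_groups)
    ]
    n_val = int(round((n_groups - 1) * 2 / 9))
    folds = []
    for t in range(n_groups):
        rest = [g for g in range(n_groups) if g != t]
        rest = list(rng.permutation(rest))
        val_groups = rest[:n_val]
        train_groups = rest[n_val:]
        folds.append(
            {
                "train": sorted(s for g in train_groups for s in groups[g]),
                "val": sorted(s for g in val_groups for s in groups[g]),
                "test": sorted(groups[t]),
            }
        )
    return FoldPlan(groups=groups, folds=folds, seed=seed)


@dataclass
class EvalReport:
    """Accuracy, macro-F1, per-class metrics and the confusion matrix."""

    accuracy: float
    macro_f1: float
    labels: list
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    confusion: np.ndarray  # raw counts, rows = true class
    confusion_percent: np.ndarray  # row-normalised, in percent

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "labels": [str(c) for c in self.labels],
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "confusion": self.confusion.tolist(),
            "confusion_percent": self.confusion_percent.tolist(),
        }


def evaluate(y_true, y_pred, labels: Sequence | None = None) -> EvalReport:
    """Multi-class accuracy (correct/total), one-vs-rest P/R/F1, macro-F1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("predictions and labels must be equal-length, non-empty")
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    labels = list(labels)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    conf = confusion_matrix(y_true, y_pred, labels=labels)
    row_sums = conf.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(row_sums > 0, 100.0 * conf / row_sums, 0.0)
    return EvalReport(
        accuracy=float(accuracy_score(y_true, y_pred)),
        macro_f1=float(f1.mean()),
        labels=labels,
        precision=prec,
        recall=rec,
        f1=f1,
        confusion=conf,
        confusion_percent=percent,
    )


def preprocess_dataset(
    dataset: SyntheticDataset, config: ModelConfig
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Materialize model inputs for every sample of a dataset.

    Returns (X, y, subjects) where X holds the enabled modalities:
    resized environment images, GADF pseudo-images of the x-y-z reduction,
    and 63-element stat vectors.
    """
    n = len(dataset)
    side_env = config.env_input_side
    X: dict[str, np.ndarray] = {}
    if config.use_env:
        X["env"] = np.empty((n, side_env, side_env, 3), dtype=np.float32)
    if config.use_gadf:
        X["gadf"] = np.empty(
            (n, config.gadf_input_side, config.gadf_input_side, 3), dtype=np.float32
        )
    if config.use_stats:
        X["stats"] = np.empty((n, config.stat_dim_in), dtype=float)
    y = np.empty(n, dtype=object)
    subjects = np.empty(n, dtype=object)
    for i in range(n):
        meta_label = dataset.label_codes[i]
        y[i] = meta_label
        subjects[i] = dataset.subject_ids[i]
        if config.use_env:
            img = dataset.scene_image(i)
            if img.shape[0] != side_env:
                im = Image.fromarray((img * 255).round().astype(np.uint8))
                img = (
                    np.asarray(im.resize((side_env, side_env), Image.BILINEAR), float)
                    / 255.0
                )
            X["env"][i] = img
        if config.use_env or config.use_gadf or config.use_stats:
            window = dataset.accel_window(i)
        if config.use_gadf:
            X["gadf"][i] = encode_window(window, "x-y-z", side=config.gadf_input_side)
        if config.use_stats:
            X["stats"][i] = build_stat_vector(window)
    return X, np.asarray(y, dtype=object), np.asarray(subjects, dtype=object)


def _index(X: dict[str, np.ndarray], mask: np.ndarray) -> dict[str, np.ndarray]:
    return {k: v[mask] for k, v in X.items()}


@dataclass
class CrossValResult:
    fold_reports: list[EvalReport]
    histories: list[list[dict]]
    mean_accuracy: float = field(init=False)
    mean_macro_f1: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_accuracy = float(np.mean([r.accuracy for r in self.fold_reports]))
        self.mean_macro_f1 = float(np.mean([r.macro_f1 for r in self.fold_reports]))


def run_cross_validation(
    X: dict[str, np.ndarray],
    y: np.ndarray,
    subjects: np.ndarray,
    fold_plan: FoldPlan,
    model_config: ModelConfig,
    train_config: TrainConfig,
    folds: Sequence[int] | None = None,
) -> CrossValResult:
    """Train and evaluate one classifier per fold of the plan.

    Subject disjointness between train/val/test is asserted on every fold.
    ``folds`` restricts execution to a subset of fold indices (the mean is
    then over those folds).
    """
    subjects = np.asarray(subjects)
    y = np.asarray(y)
    reports, histories = [], []
    fold_ids = range(len(fold_plan.folds)) if folds is None else folds
    for f in fold_ids:
        split = fold_plan.folds[f]
        tr = set(split["train"])
        va = set(split["val"])
        te = set(split["test"])
        assert not (tr & te) and not (va & te) and not (tr & va), "subject leakage"
        m_tr = np.isin(subjects, list(tr))
        m_va = np.isin(subjects, list(va))
        m_te = np.isin(subjects, list(te))
        if not m_tr.any() or not m_te.any():
            raise ValueError(f"fold {f} has an empty train or test split")
        clf = HazardFusionClassifier(model_config, train_config)
        clf.fit(
            _index(X, m_tr), y[m_tr],
            X_val=_index(X, m_va) if m_va.any() else None,
            y_val=y[m_va] if m_va.any() else None,
        )
        reports.append(evaluate(y[m_te], clf.predict(_index(X, m_te))))
        histories.append(clf.history_)
    return CrossValResult(fold_reports=reports, histories=histories)


#: The seven input combinations of the ablation grid.
ABLATION_GRID: dict[str, dict[str, bool]] = {
    "rgb": {"use_env": True, "use_gadf": False, "use_stats": False},
    "gadf": {"use_env": False, "use_gadf": True, "use_stats": False},
    "stats": {"use_env": False, "use_gadf": False, "use_stats": True},
    "gadf+stats": {"use_env": False, "use_gadf": True, "use_stats": True},
    "rgb+gadf": {"use_env": True, "use_gadf": True, "use_stats": False},
    "rgb+stats": {"use_env": True, "use_gadf": False, "use_stats": True},
    "rgb+gadf+stats": {"use_env": True, "use_gadf": True, "use_stats": True},
}


def ablation_configs(base: ModelConfig) -> dict[str, ModelConfig]:
    """Model configs for the seven ablation rows, derived from a base config."""
    import copy as _copy

    out = {}
    for name, flags in ABLATION_GRID.items():
        cfg = _copy.deepcopy(base)
        for key, val in flags.items():
            setattr(cfg, key, val)
        out[name] = cfg
    return out


def plot_confusion(report: EvalReport, path: str) -> None:
    """Write a row-percentage confusion-matrix heatmap to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(report.confusion_percent, cmap="Blues", vmin=0, vmax=100)
    ax.set_xticks(range(len(report.labels)), report.labels, rotation=45)
    ax.set_yticks(range(len(report.labels)), report.labels)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    for i in range(len(report.labels)):
        for j in range(len(report.labels)):
            v = report.confusion_percent[i, j]
            if v >= 0.5:
                ax.text(j, i, f"{v:.0f}", ha="center", va="center",
                        color="white" if v > 50 else "black", fontsize=7)
    fig.colorbar(im, ax=ax, label="% of true class")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
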