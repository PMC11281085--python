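"""Accelerometer-only camera gate: a decision tree over the 63 statistics.

Running the rear camera continuously is the dominant power cost of the
hazard monitor, so an axis-aligned decision tree classifies each window
from its statistical descriptor alone and the camera (and hence the
multimodal network) is activated only when the user is actually using the
phone: static use, level walking, or stair climbing.  A fourth "other"
class covers streams outside those regimes (e.g. the phone shaken loosely
in a bag) and keeps the camera off.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .config import GateConfig
from .features import STAT_VECTOR_DIM, UndefinedStatisticError, build_stat_vector
from .signals import AccelWindow

#: Activities that switch the camera on.
PHONE_USE_ACTIVITIES = ("static_use", "walking_use", "stairs_use")
ACTIVITY_LABELS = PHONE_USE_ACTIVITIES + ("other",)

#: Map from motion-regime names to gate activity labels.
REGIME_TO_ACTIVITY = {
    "static": "static_use",
    "walking": "walking_use",
    "stairs": "stairs_use",
    "shaking": "other",
}


@dataclass
class GateDecision:
    activity: str
    camera_on: bool
    latency_s: float


class CameraGate(ClassifierMixin, BaseEstimator):
    """Decision-tree activity classifier with the camera-activation rule."""

    def __init__(self, gate_config: GateConfig | None = None):
        self.gate_config = gate_config

    def fit(self, X: np.ndarray, y):
        cfg = self.gate_config or GateConfig()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != STAT_VECTOR_DIM:
            raise ValueError(f"gate features must be (N, {STAT_VECTOR_DIM})")
        if len(np.unique(y)) < 2:
            raise ValueError("gate training needs at least 2 activity classes")
        self.tree_ = DecisionTreeClassifier(
            criterion=cfg.criterion,
            max_depth=cfg.max_depth,
            min_samples_leaf=cfg.min_samples_leaf,
            random_state=cfg.seed,
        ).fit(X, y)
        self.classes_ = self.tree_.classes_
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "tree_")
        return self.tree_.predict(np.asarray(X, dtype=float))

    def decide(self, window: AccelWindow) -> GateDecision:
        """Classify one window and apply the camera rule.

        Degenerate windows (no spread on some axis, so the statistics are
        undefined) are treated as "other" with the camera off.
        """
        check_is_fitted(self, "tree_")
        t0 = time.perf_counter()
        try:
            features = build_stat_vector(window)
        except (UndefinedStatisticError, ValueError) as err:
            warnings.warn(
                f"degenerate window, camera stays off: {err}",
                RuntimeWarning, stacklevel=2,
            )
            return GateDecision("other", False, time.perf_counter() - t0)
        activity = str(self.tree_.predict(features[None, :])[0])
        return GateDecision(
            activity=activity,
            camera_on=activity in PHONE_USE_ACTIVITIES,
            latency_s=time.perf_counter() - t0,
        )

    def export_tree_json(self, path: str | Path) -> None:
        """Write the tree (feature index, threshold, children, leaf class)."""
        check_is_fitted(self, "tree_")
        t = self.tree_.tree_
        nodes = []
        for i in range(t.node_count):
            if t.children_left[i] == -1:
                leaf_class = str(self.classes_[int(np.argmax(t.value[i][0]))])
                nodes.append({"id": i, "leaf": True, "class": leaf_class})
            else:
                nodes.append(
                    {
                        "id": i,
                        "leaf": False,
                        "feature": int(t.feature[i]),
                        "threshold": float(t.threshold[i]),
                        "left": int(t.children_left[i]),
                        "right": int(t.children_right[i]),
                    }
                )
        Path(path).write_text(json.dumps({"nodes": nodes}, indent=1))


def train_gate(features: np.ndarray, labels, config: GateConfig | None = None) -> CameraGate:
    """Fit the decision-tree gate on (N, 63) features and activity labels."""
    return CameraGate(config).fit(features, labels)


def gate_decide(window: AccelWindow, gate: CameraGate) -> GateDecision:
    return gate.decide(window)
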