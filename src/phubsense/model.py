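"""The dual-branch lightweight fusion network and its sklearn-style estimator.

Architecture
------------
Environment branch: a depthwise-separable backbone (5 blocks, 13 ds units,
x32 downsampling) over 192 x 192 RGB scene images (224 reduced by the
resolution factor beta = 6/7); its final 6 x 6 x 1024 map is average-pooled
into a 1024-element descriptor.

Motion branch: the same topology thinned by the width factor alpha = 0.75
(channels rounded to multiples of 8) over GADF pseudo-images, pooled to a
768-element deep feature; in parallel the 63-element statistical vector is
expanded to 256 by a fully connected layer.  Deep and statistical motion
features are concatenated (1024) and modulated by a gated linear unit
GLU(X) = X (*) sigmoid(X W_g + b_g).

Fusion: environment and motion vectors concatenate to 2048, a
squeeze-and-excitation bottleneck reweights the components, and an affine
head + softmax yields the nine hazard-class probabilities.

Any subset of the three inputs (RGB, GADF, stats) can be enabled for
ablation runs; vector lengths shrink accordingly.
"""

from __future__ import annotations

import copy
from typing import Iterable

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .config import ModelConfig, TrainConfig
from .nn import (
    BatchNorm2D,
    Conv2D,
    Dense,
    DepthwiseConv2D,
    GlobalAvgPool,
    ReLU,
    Sequential,
    Sigmoid,
    SGDMomentum,
    cross_entropy,
    softmax,
    softmax_cross_entropy_grad,
)

#: (output channels at alpha=1, stride) for the 13 depthwise-separable units:
#: Block1 tail, Block2, Block3, Block4, and the seven units of Block5.
_DS_PLAN: tuple[tuple[int, int], ...] = (
    (64, 1),
    (128, 2),
    (128, 1), (256, 2),
    (256, 1), (512, 2),
    (512, 1), (512, 1), (512, 1), (512, 1), (512, 1), (1024, 2), (1024, 1),
)


def scaled_channels(c: int, alpha: float) -> int:
    """Apply the width factor: nearest multiple of 8, minimum 8."""
    return max(8, int(round(c * alpha / 8)) * 8)


def build_backbone(alpha: float, rng: np.random.Generator) -> tuple[Sequential, int]:
    """Build the 5-block depthwise-separable backbone; returns (net, channels)."""
    ch = lambda c: scaled_channels(c, alpha)  # noqa: E731
    layers = [
        Conv2D(3, ch(32), k=3, stride=2, rng=rng),
        BatchNorm2D(ch(32)),
        ReLU(),
    ]
    cin = ch(32)
    for cout_base, stride in _DS_PLAN:
        cout = ch(cout_base)
        layers += [
            DepthwiseConv2D(cin, k=3, stride=stride, rng=rng),
            BatchNorm2D(cin),
            ReLU(),
            Conv2D(cin, cout, k=1, rng=rng),
            BatchNorm2D(cout),
            ReLU(),
        ]
        cin = cout
    return Sequential(layers), cin


def build_env_branch(config: ModelConfig, rng: np.random.Generator | None = None):
    """Environment backbone (full width) + its pooled descriptor length."""
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    net, channels = build_backbone(1.0, rng)
    return net, channels


def build_motion_branch(config: ModelConfig, rng: np.random.Generator | None = None):
    """Motion backbone thinned by the width factor alpha."""
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    net, channels = build_backbone(config.alpha, rng)
    return net, channels


class FusionNetwork:
    """Forward/backward graph of the full fusion model (ablation-aware)."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.env_backbone = self.motion_backbone = None
        self.env_dim = self.motion_deep_dim = self.stat_dim = 0
        if config.use_env:
            self.env_backbone, self.env_dim = build_backbone(1.0, rng)
            self.env_pool = GlobalAvgPool()
        if config.use_gadf:
            self.motion_backbone, self.motion_deep_dim = build_backbone(config.alpha, rng)
            self.motion_pool = GlobalAvgPool()
        if config.use_stats:
            self.stat_dim = config.stat_dim_out
            self.stat_fc = Dense(config.stat_dim_in, config.stat_dim_out, rng=rng)
            self.stat_relu = ReLU()

        self.motion_dim = self.motion_deep_dim + self.stat_dim
        if self.motion_dim:
            self.glu_fc = Dense(self.motion_dim, self.motion_dim, rng=rng)
            self.glu_sig = Sigmoid()

        self.joint_dim = self.env_dim + self.motion_dim
        if self.joint_dim % config.se_ratio != 0:
            raise ValueError(
                f"se_ratio {config.se_ratio} does not divide the joint "
                f"vector length {self.joint_dim}"
            )
        hidden = self.joint_dim // config.se_ratio
        self.se_fc1 = Dense(self.joint_dim, hidden, rng=rng)
        self.se_relu = ReLU()
        self.se_fc2 = Dense(hidden, self.joint_dim, rng=rng)
        self.se_sig = Sigmoid()
        self.head = Dense(self.joint_dim, config.num_classes, rng=rng)

    # -- plumbing ---------------------------------------------------------
    def _components(self) -> Iterable:
        for name in (
            "env_backbone", "motion_backbone", "stat_fc", "stat_relu",
            "glu_fc", "glu_sig", "se_fc1", "se_relu", "se_fc2", "se_sig",
            "head",
        ):
            comp = getattr(self, name, None)
            if comp is not None:
                yield comp

    def param_items(self):
        for comp in self._components():
            yield from comp.param_items()

    def n_params(self) -> int:
        return sum(layer.params[key].size for layer, key in self.param_items())

    def _all_layers(self):
        for comp in self._components():
            if isinstance(comp, Sequential):
                yield from comp.layers
            else:
                yield comp

    def state_dict(self) -> list:
        state = []
        for layer in self._all_layers():
            entry = {k: v.copy() for k, v in layer.params.items()}
            if isinstance(layer, BatchNorm2D):
                entry["_rmean"] = layer.running_mean.copy()
                entry["_rvar"] = layer.running_var.copy()
            state.append(entry)
        return state

    def load_state_dict(self, state: list) -> None:
        for layer, entry in zip(self._all_layers(), state, strict=True):
            for k in layer.params:
                layer.params[k] = entry[k].copy()
            if isinstance(layer, BatchNorm2D):
                layer.running_mean = entry["_rmean"].copy()
                layer.running_var = entry["_rvar"].copy()

    # -- forward / backward ----------------------------------------------
    def forward(self, batch: dict[str, np.ndarray], training: bool = False,
                capture: dict | None = None) -> np.ndarray:
        cfg = self.config
        parts_m, parts_j = [], []
        self._have = {"env": False, "gadf": False, "stats": False}
        if cfg.use_env:
            if "env" not in batch:
                raise ValueError("model requires an 'env' image batch")
            fmap = self.env_backbone.forward(batch["env"], training)
            env_desc = self.env_pool.forward(fmap, training)
            parts_j.append(env_desc)
            self._have["env"] = True
            if capture is not None:
                capture["env_map_shape"] = fmap.shape
                capture["env_descriptor"] = env_desc.shape[1]
        if cfg.use_gadf:
            if "gadf" not in batch:
                raise ValueError("model requires a 'gadf' pseudo-image batch")
            fmap = self.motion_backbone.forward(batch["gadf"], training)
            motion_deep = self.motion_pool.forward(fmap, training)
            parts_m.append(motion_deep)
            self._have["gadf"] = True
            if capture is not None:
                capture["motion_deep"] = motion_deep.shape[1]
        if cfg.use_stats:
            if "stats" not in batch:
                raise ValueError("model requires a 'stats' batch")
            if batch["stats"].shape[1] != cfg.stat_dim_in:
                raise ValueError(
                    f"stat vector must have length {cfg.stat_dim_in}, "
                    f"got {batch['stats'].shape[1]}"
                )
            stat_exp = self.stat_relu.forward(
                self.stat_fc.forward(batch["stats"].astype(np.float32), training),
                training,
            )
            parts_m.append(stat_exp)
            self._have["stats"] = True
            if capture is not None:
                capture["stat_vector_in"] = batch["stats"].shape[1]
                capture["stat_expanded"] = stat_exp.shape[1]

        if parts_m:
            x_m = np.concatenate(parts_m, axis=1)
            gate = self.glu_sig.forward(self.glu_fc.forward(x_m, training), training)
            y_m = x_m * gate
            self._glu_x, self._glu_gate = x_m, gate
            parts_j.append(y_m)
            if capture is not None:
                capture["motion_fused"] = y_m.shape[1]

        joint = np.concatenate(parts_j, axis=1)
        hidden = self.se_relu.forward(self.se_fc1.forward(joint, training), training)
        weights = self.se_sig.forward(self.se_fc2.forward(hidden, training), training)
        fused = joint * weights
        self._joint, self._se_weights = joint, weights
        logits = self.head.forward(fused, training)
        if capture is not None:
            capture["joint"] = joint.shape[1]
            capture["classes"] = logits.shape[1]
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.head.backward(dlogits)
        djoint = dfused * self._se_weights
        dweights = dfused * self._joint
        dh = self.se_fc2.backward(self.se_sig.backward(dweights))
        djoint = djoint + self.se_fc1.backward(self.se_relu.backward(dh))

        offset = 0
        if self._have["env"]:
            denv = djoint[:, offset : offset + self.env_dim]
            offset += self.env_dim
            self.env_backbone.backward(self.env_pool.backward(denv))
        if self.motion_dim:
            dy_m = djoint[:, offset:]
            dx_m = dy_m * self._glu_gate
            dgate = dy_m * self._glu_x
            dx_m = dx_m + self.glu_fc.backward(self.glu_sig.backward(dgate))
            moff = 0
            if self._have["gadf"]:
                dmotion = dx_m[:, : self.motion_deep_dim]
                moff = self.motion_deep_dim
                self.motion_backbone.backward(self.motion_pool.backward(dmotion))
            if self._have["stats"]:
                dstat = dx_m[:, moff:]
                self.stat_fc.backward(self.stat_relu.backward(dstat))

    def predict_proba(self, batch: dict[str, np.ndarray]) -> np.ndarray:
        return softmax(self.forward(batch, training=False))


def expand_stats(stat_fc: Dense, stat_vector: np.ndarray) -> np.ndarray:
    """Affine 63 -> 256 expansion with ReLU (functional convenience)."""
    v = np.atleast_2d(np.asarray(stat_vector, dtype=np.float32))
    if v.shape[1] != stat_fc.params["w"].shape[0]:
        raise ValueError(
            f"expected input length {stat_fc.params['w'].shape[0]}, got {v.shape[1]}"
        )
    return np.maximum(stat_fc.forward(v), 0.0)


def glu_modulate(x: np.ndarray, w_g: np.ndarray, b_g: np.ndarray) -> np.ndarray:
    """GLU(X) = X (*) sigmoid(X W_g + b_g), elementwise."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if w_g.shape != (x.shape[1], x.shape[1]) or b_g.shape != (x.shape[1],):
        raise ValueError("gate parameter shapes do not match the input length")
    gate = 1.0 / (1.0 + np.exp(-(x @ w_g + b_g)))
    return x * gate


def count_parameters(model: FusionNetwork | Sequential) -> int:
    """Total trainable scalar parameters (batch-norm gamma/beta included)."""
    return int(model.n_params())


class HazardFusionClassifier(ClassifierMixin, BaseEstimator):
    """Nine-class hazard-state classifier over (image, GADF, stats) inputs.

    Follows the sklearn estimator contract: ``fit(X, y)`` / ``predict`` /
    ``predict_proba`` with ``get_params``-clonable constructor arguments.
    ``X`` is a dict with any subset of the keys enabled in ``config``:

    - ``"env"``:   (N, H, W, 3) float images in [0, 1], H = W = 192 default
    - ``"gadf"``:  (N, S, S, 3) float pseudo-images in [0, 1]
    - ``"stats"``: (N, 63) statistical descriptors

    Training minimises mean cross-entropy with momentum SGD; when a
    validation set is supplied the parameters from the best-validation-
    accuracy epoch are restored after the final epoch.
    """

    def __init__(self, config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None):
        self.config = config
        self.train_config = train_config

    def _tensorize(self, X: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        cfg = self.config_
        batch: dict[str, np.ndarray] = {}
        for key in ("env", "gadf"):
            if getattr(cfg, f"use_{key}"):
                img = np.asarray(X[key], dtype=np.float32)
                if img.ndim != 4 or img.shape[3] != 3:
                    raise ValueError(f"'{key}' must be (N, H, W, 3)")
                # center pixel values; NHWC -> NCHW
                batch[key] = np.ascontiguousarray(
                    img.transpose(0, 3, 1, 2) - np.float32(0.5)
                )
        if cfg.use_stats:
            stats = np.asarray(X["stats"], dtype=np.float64)
            batch["stats"] = ((stats - self.stat_mean_) / self.stat_scale_).astype(
                np.float32
            )
        return batch

    def fit(self, X: dict[str, np.ndarray], y,
            X_val: dict[str, np.ndarray] | None = None, y_val=None):
        self.config_ = copy.deepcopy(self.config) if self.config else ModelConfig()
        self.train_config_ = (
            copy.deepcopy(self.train_config) if self.train_config else TrainConfig()
        )
        self.config_.validate()
        self.train_config_.validate()
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != self.config_.num_classes:
            # allow training on a subset of classes (ablation/small fixtures)
            self.config_.num_classes = len(self.classes_)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        yi = np.array([class_index[c] for c in y])

        if self.config_.use_stats:
            stats = np.asarray(X["stats"], dtype=np.float64)
            self.stat_mean_ = stats.mean(axis=0)
            self.stat_scale_ = np.maximum(stats.std(axis=0), 1e-8)

        self.network_ = FusionNetwork(self.config_)
        tc = self.train_config_
        opt = SGDMomentum(self.network_.param_items(), tc.learning_rate, tc.momentum)
        rng = np.random.default_rng(tc.seed)
        batch_all = self._tensorize(X)
        n = len(yi)
        onehot = np.eye(self.config_.num_classes, dtype=np.float32)[yi]

        self.history_: list[dict[str, float]] = []
        best_val, best_state = -np.inf, None
        for epoch in range(tc.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, tc.batch_size):
                idx = order[start : start + tc.batch_size]
                mini = {k: v[idx] for k, v in batch_all.items()}
                logits = self.network_.forward(mini, training=True)
                probs = softmax(logits)
                loss = cross_entropy(probs, onehot[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch}: loss={loss}"
                    )
                self.network_.backward(softmax_cross_entropy_grad(probs, onehot[idx]))
                opt.step()
                losses.append(loss)
            record = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if X_val is not None and y_val is not None:
                val_acc = float(np.mean(self.predict(X_val) == np.asarray(y_val)))
                record["val_acc"] = val_acc
                if val_acc > best_val:
                    best_val = val_acc
                    best_state = self.network_.state_dict()
            self.history_.append(record)
        if best_state is not None:
            self.network_.load_state_dict(best_state)
        return self

    def predict_proba(self, X: dict[str, np.ndarray]) -> np.ndarray:
        check_is_fitted(self, "network_")
        batch_all = self._tensorize(X)
        n = len(next(iter(batch_all.values())))
        out = []
        step = max(1, self.train_config_.batch_size)
        for start in range(0, n, step):
            mini = {k: v[start : start + step] for k, v in batch_all.items()}
            out.append(self.network_.predict_proba(mini))
        return np.concatenate(out, axis=0)

    def predict(self, X: dict[str, np.ndarray]) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def n_parameters(self) -> int:
        check_is_fitted(self, "network_")
        return count_parameters(self.network_)

    def predict_sample_proba(self, sample) -> np.ndarray:
        """Probabilities for one MultimodalSample (preprocessed on the fly).

        The sample must carry every modality the model was configured with;
        a missing one raises ValueError.
        """
        check_is_fitted(self, "network_")
        from PIL import Image

        from .features import build_stat_vector
        from .gadf import encode_window

        cfg = self.config_
        X: dict[str, np.ndarray] = {}
        if cfg.use_env:
            if getattr(sample, "image", None) is None:
                raise ValueError("sample lacks the scene image modality")
            img = np.asarray(sample.image, dtype=float)
            side = cfg.env_input_side
            if img.shape[0] != side:
                im = Image.fromarray((img * 255).round().astype(np.uint8))
                img = np.asarray(im.resize((side, side), Image.BILINEAR), float) / 255.0
            X["env"] = img[None]
        if cfg.use_gadf or cfg.use_stats:
            if getattr(sample, "window", None) is None:
                raise ValueError("sample lacks the acceleration modality")
        if cfg.use_gadf:
            X["gadf"] = encode_window(
                sample.window, "x-y-z", side=cfg.gadf_input_side
            )[None]
        if cfg.use_stats:
            X["stats"] = build_stat_vector(sample.window)[None]
        return self.predict_proba(X)[0]
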