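"""Synthetic paired acceleration + scene-image data for the nine hazard states.

No public dataset pairs rear-camera frames with phone acceleration for
distracted-walking hazards, so this module procedurally emulates one: three
motion regimes (static phone use, level walking, stair climbing) crossed
with four scene contexts (stairs, zebra crossing, wet surface, darkness)
give the nine valid hazard classes.  Signals are 50 Hz triaxial
acceleration in m/s^2 with gravity (9.81) on the device-vertical X axis;
images are 224 x 224 RGB rasters with the contexts' defining structure
(step edges, high-contrast bands, specular blobs, low luminance).

The generator is fully deterministic given the dataset seed, and applies
per-subject amplitude/frequency jitter so subject-grouped cross-validation
is non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from PIL import Image

from .config import SyntheticDatasetSpec
from .signals import AccelWindow

GRAVITY = 9.81


@dataclass(frozen=True)
class MotionRegime:
    """Oscillation parameters of one phone-use motion state.

    ``vertical_amp`` drives the device-vertical (X) axis; the horizontal
    axes carry an antiphase fraction of the same oscillation (arms swing
    against the torso), which concentrates energy in the X-Y-Z reduction.
    """

    name: str
    dominant_freq: float  # Hz
    vertical_amp: float  # m/s^2
    horizontal_amp: float  # m/s^2
    noise_sd: float  # m/s^2
    harmonic_ratio: float = 0.0  # first-harmonic amplitude / fundamental

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


#: Walking cadence ~1.7 Hz, stairs slower (~1.3 Hz) with a stronger vertical
#: component and a visible first harmonic from the two-phase step cycle.
REGIMES: dict[str, MotionRegime] = {
    "static": MotionRegime("static", 0.0, 0.0, 0.0, 0.05),
    "walking": MotionRegime("walking", 1.7, 1.2, 0.5, 0.15),
    "stairs": MotionRegime("stairs", 1.3, 2.16, 0.7, 0.20, harmonic_ratio=0.45),
}

#: Out-of-regime stream (vigorous shaking, e.g. phone loose in a bag) used
#: only to train the camera gate's "other" class; never a hazard sample.
SHAKING_REGIME = MotionRegime("shaking", 4.5, 3.5, 2.5, 0.8)


@dataclass(frozen=True)
class SceneContext:
    """Photometric parameters of one hazard scene category."""

    name: str
    luminance_mean: float

    def __post_init__(self) -> None:
        if self.name == "darkness" and self.luminance_mean >= 0.15:
            raise ValueError("darkness context must have luminance_mean < 0.15")
        if self.name != "darkness" and self.luminance_mean < 0.3:
            raise ValueError("non-dark contexts must have luminance_mean >= 0.3")


SCENES: dict[str, SceneContext] = {
    "stairs": SceneContext("stairs", 0.50),
    "zebra": SceneContext("zebra", 0.55),
    "wet": SceneContext("wet", 0.38),
    "darkness": SceneContext("darkness", 0.06),
}


@dataclass(frozen=True)
class HazardLabel:
    """One of the nine (motion, scene) hazard classes."""

    code: str
    motion: str
    scene: str


#: The nine valid motion x scene combinations.  C = climbing stairs,
#: W = walking, S = static; STA/DAR/WET/ZEB name the scene.  Static use on
#: plain flat ground is not a hazard and is never emitted.
HAZARD_LABELS: tuple[HazardLabel, ...] = (
    HazardLabel("CSTA", "stairs", "stairs"),
    HazardLabel("CDAR", "stairs", "darkness"),
    HazardLabel("WWET", "walking", "wet"),
    HazardLabel("WDAR", "walking", "darkness"),
    HazardLabel("WZEB", "walking", "zebra"),
    HazardLabel("SSTA", "static", "stairs"),
    HazardLabel("SDAR", "static", "darkness"),
    HazardLabel("SWET", "static", "wet"),
    HazardLabel("SZEB", "static", "zebra"),
)
LABEL_CODES = tuple(lab.code for lab in HAZARD_LABELS)
LABEL_BY_CODE = {lab.code: lab for lab in HAZARD_LABELS}


def gen_accel(
    regime: MotionRegime,
    duration: float,
    rate: float,
    seed: int,
    amp_factor: float = 1.0,
    freq_offset: float = 0.0,
) -> np.ndarray:
    """Generate a (n, 3) triaxial acceleration window for one regime.

    X carries gravity plus the regime oscillation; Y and Z carry antiphase
    fractions (0.40 and 0.25 of horizontal_amp-scaled swing).  Gaussian
    noise of regime.noise_sd is added per axis.  Deterministic given seed.
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    freq = max(regime.dominant_freq + freq_offset, 0.0)
    phase = rng.uniform(0, 2 * np.pi)
    amp_v = regime.vertical_amp * amp_factor
    amp_h = regime.horizontal_amp * amp_factor
    osc = amp_v * np.sin(2 * np.pi * freq * t + phase)
    if regime.harmonic_ratio > 0:
        phase2 = rng.uniform(0, 2 * np.pi)
        osc = osc + regime.harmonic_ratio * amp_v * np.sin(
            4 * np.pi * freq * t + phase2
        )
    sway = np.sin(2 * np.pi * freq * t + phase) if freq > 0 else np.zeros(n)
    ax = GRAVITY + osc + rng.normal(0, regime.noise_sd, n)
    ay = -0.80 * amp_h * sway + rng.normal(0, regime.noise_sd, n)
    az = -0.50 * amp_h * sway + rng.normal(0, regime.noise_sd, n)
    return np.column_stack([ax, ay, az])


def _scene_stairs(size: int, rng: np.random.Generator) -> np.ndarray:
    n_steps = int(rng.integers(5, 9))
    img = np.zeros((size, size))
    edges = np.linspace(0, size, n_steps + 1).astype(int)
    for k in range(n_steps):
        top, bot = edges[k], edges[k + 1]
        base = 0.42 + 0.16 * (k % 2)
        grad = np.linspace(0.06, -0.06, bot - top)[:, None]
        img[top:bot] = base + grad
        img[max(bot - 2, 0) : bot] = 0.15  # shadow line at the step nosing
    img += rng.normal(0, 0.03, img.shape)
    return img


def _scene_zebra(size: int, rng: np.random.Generator) -> np.ndarray:
    period = int(rng.integers(size // 10, size // 6))
    rows = np.arange(size)
    phase = int(rng.integers(0, period))
    stripe = ((rows + phase) // period) % 2
    img = np.where(stripe[:, None] == 0, 0.85, 0.25) * np.ones((size, size))
    img += rng.normal(0, 0.03, img.shape)
    return img


def _scene_wet(size: int, rng: np.random.Generator) -> np.ndarray:
    img = np.full((size, size), 0.32)
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(int(rng.integers(6, 12))):
        cy, cx = rng.uniform(0, size, 2)
        sy = rng.uniform(size / 30, size / 10)
        sx = sy * rng.uniform(1.2, 2.5)  # puddles stretch horizontally
        blob = np.exp(-(((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2))
        img += 0.55 * blob
    img += rng.normal(0, 0.03, img.shape)
    return img


def _scene_darkness(size: int, rng: np.random.Generator) -> np.ndarray:
    img = np.full((size, size), 0.05)
    for _ in range(int(rng.integers(2, 5))):  # faint silhouettes
        y0, x0 = rng.integers(0, size - size // 6, 2)
        h, w = rng.integers(size // 12, size // 6, 2)
        img[y0 : y0 + h, x0 : x0 + w] += 0.05
    img += rng.normal(0, 0.02, img.shape)
    return img


_SCENE_PAINTERS = {
    "stairs": _scene_stairs,
    "zebra": _scene_zebra,
    "wet": _scene_wet,
    "darkness": _scene_darkness,
}

# mild per-context RGB tint so channels are not strictly identical
_SCENE_TINTS = {
    "stairs": (1.0, 0.97, 0.92),
    "zebra": (0.95, 0.95, 1.0),
    "wet": (0.90, 0.96, 1.0),
    "darkness": (0.95, 0.95, 1.05),
}


def gen_scene(context: SceneContext | str, size: int, seed: int) -> np.ndarray:
    """Generate a procedural (size, size, 3) RGB scene image in [0, 1]."""
    name = context if isinstance(context, str) else context.name
    if name not in _SCENE_PAINTERS:
        raise ValueError(f"unknown scene context {name!r}")
    if size < 32:
        raise ValueError("size must be >= 32")
    rng = np.random.default_rng(seed)
    gray = _SCENE_PAINTERS[name](size, rng)
    tint = np.array(_SCENE_TINTS[name])
    img = np.clip(gray[:, :, None] * tint[None, None, :], 0.0, 1.0)
    return img


@dataclass
class MultimodalSample:
    """One (acceleration window, keyframe image, hazard label) triple."""

    sample_id: str
    subject_id: str
    label: HazardLabel
    window: AccelWindow
    image: np.ndarray  # (H, W, 3) float in [0, 1]


class SyntheticDataset:
    """Lazy container over a generated dataset.

    Per-sample metadata (subject, label, derived seeds) is computed up
    front; acceleration windows and images are materialized on demand so
    datasets of thousands of pairs stay cheap to enumerate.
    """

    def __init__(self, spec: SyntheticDatasetSpec):
        spec.validate()
        self.spec = spec
        root = np.random.default_rng(spec.seed)
        n_total = spec.n_subjects * spec.pairs_per_subject
        seeds = root.integers(0, 2**31 - 1, size=(n_total, 2))
        self._meta: list[dict] = []
        self._subject_jitter: dict[str, tuple[float, float]] = {}
        for s in range(spec.n_subjects):
            sid = f"S{s:03d}"
            self._subject_jitter[sid] = (
                float(root.uniform(0.85, 1.15)),
                float(root.uniform(-0.15, 0.15)),
            )
        for g in range(n_total):
            s = g // spec.pairs_per_subject
            label = HAZARD_LABELS[g % len(HAZARD_LABELS)]
            self._meta.append(
                {
                    "sample_id": f"P{g:05d}",
                    "subject_id": f"S{s:03d}",
                    "label_code": label.code,
                    "accel_seed": int(seeds[g, 0]),
                    "image_seed": int(seeds[g, 1]),
                }
            )

    def __len__(self) -> int:
        return len(self._meta)

    @property
    def label_codes(self) -> list[str]:
        return [m["label_code"] for m in self._meta]

    @property
    def subject_ids(self) -> list[str]:
        return [m["subject_id"] for m in self._meta]

    def accel_window(self, i: int) -> AccelWindow:
        m = self._meta[i]
        label = LABEL_BY_CODE[m["label_code"]]
        amp, df = self._subject_jitter[m["subject_id"]]
        samples = gen_accel(
            REGIMES[label.motion], self.spec.window_s, self.spec.sample_rate,
            seed=m["accel_seed"], amp_factor=amp, freq_offset=df,
        )
        return AccelWindow(
            t_start=0.0, t_end=self.spec.window_s, samples=samples,
            rate=self.spec.sample_rate, subject_id=m["subject_id"],
        )

    def scene_image(self, i: int) -> np.ndarray:
        m = self._meta[i]
        label = LABEL_BY_CODE[m["label_code"]]
        return gen_scene(SCENES[label.scene], self.spec.image_side, m["image_seed"])

    def __getitem__(self, i: int) -> MultimodalSample:
        m = self._meta[i]
        return MultimodalSample(
            sample_id=m["sample_id"],
            subject_id=m["subject_id"],
            label=LABEL_BY_CODE[m["label_code"]],
            window=self.accel_window(i),
            image=self.scene_image(i),
        )

    def __iter__(self) -> Iterator[MultimodalSample]:
        for i in range(len(self)):
            yield self[i]

    def manifest(self, accel_dir: str = "accel", image_dir: str = "images") -> pd.DataFrame:
        rows = []
        for m in self._meta:
            rows.append(
                {
                    "sample_id": m["sample_id"],
                    "subject_id": m["subject_id"],
                    "label_code": m["label_code"],
                    "accel_path": f"{accel_dir}/{m['sample_id']}.csv",
                    "image_path": f"{image_dir}/{m['sample_id']}.png",
                    "t_start": 0.0,
                    "t_end": self.spec.window_s,
                }
            )
        return pd.DataFrame(rows)


def gen_dataset(spec: SyntheticDatasetSpec) -> SyntheticDataset:
    """Generate the paired dataset described by ``spec`` (lazy container)."""
    return SyntheticDataset(spec)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> Path:
    """Materialize a dataset to disk: accel CSVs, PNG images, manifest.csv."""
    outdir = Path(outdir)
    (outdir / "accel").mkdir(parents=True, exist_ok=True)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    manifest = dataset.manifest()
    for i, row in manifest.iterrows():
        window = dataset.accel_window(i)
        t = window.t_start + np.arange(window.n) / window.rate
        pd.DataFrame(
            {"t": t, "ax": window.samples[:, 0], "ay": window.samples[:, 1],
             "az": window.samples[:, 2]}
        ).to_csv(outdir / row["accel_path"], index=False)
        img = (dataset.scene_image(i) * 255).round().astype(np.uint8)
        Image.fromarray(img).save(outdir / row["image_path"])
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return outdir / "manifest.csv"


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read a dataset manifest written by :func:`write_dataset`."""
    df = pd.read_csv(path)
    required = {"sample_id", "subject_id", "label_code", "accel_path",
                "image_path", "t_start", "t_end"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    return df
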