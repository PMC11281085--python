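"""Gramian Angular Difference Field encoding of 1-D acceleration series.

A series is min-max rescaled into [-1, 1], mapped to polar phase angles
phi_i = arccos(x~_i), and expanded into the antisymmetric n x n matrix
G_ij = sin(phi_i - phi_j).  The matrix is computed through the algebraic
identity G = sqrt(1 - x~^2) outer x~  -  x~ outer sqrt(1 - x~^2), which
avoids trigonometric calls; the direct sin(phi_i - phi_j) form is kept as
an independent test oracle.  Rendering maps [-1, 1] linearly to [0, 1],
replicates to three channels and bilinearly resizes to the backbone's
input side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from sklearn.base import BaseEstimator, TransformerMixin

from .signals import AccelWindow, ReducedSignal, reduce_window


class DegenerateSeriesError(ValueError):
    """Raised for constant series, whose min-max rescaling is undefined."""


def normalize(series: np.ndarray) -> np.ndarray:
    """Rescale a series into [-1, 1] via ((x - max) + (x - min)) / (max - min).

    The maximum maps to +1 and the minimum to -1.  A constant series has no
    scale and raises DegenerateSeriesError.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("normalize expects a 1-D series of length >= 2")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateSeriesError("constant series cannot be rescaled to [-1, 1]")
    return ((x - hi) + (x - lo)) / (hi - lo)


@dataclass
class PolarEncoding:
    """Phase angles phi_i = arccos(x~_i) with timestamps-as-radii r_i = t_i/N."""

    angles: np.ndarray
    radii: np.ndarray


def to_polar(normalized: np.ndarray, N: int | None = None, tol: float = 1e-9) -> PolarEncoding:
    """Map a [-1, 1] series to polar phase angles (bijective on [-1, 1]).

    Values outside [-1, 1] by more than ``tol`` raise; within tolerance they
    are clamped.  ``N`` is the radius scale constant and defaults to the
    series length, so radii lie in (0, 1]; radii exist only for plotting and
    do not enter the GADF matrix.
    """
    x = np.asarray(normalized, dtype=float)
    if np.any(x > 1 + tol) or np.any(x < -1 - tol):
        raise ValueError("normalized values must lie in [-1, 1]")
    x = np.clip(x, -1.0, 1.0)
    n = x.size
    if N is None:
        N = n
    angles = np.arccos(x)
    radii = np.arange(1, n + 1) / N
    return PolarEncoding(angles=angles, radii=radii)


def gadf(normalized: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """The n x n difference-field matrix G_ij = sin(phi_i - phi_j).

    Computed algebraically as s_i x~_j - x~_i s_j with s = sqrt(1 - x~^2).
    The result has a zero diagonal, is antisymmetric, and all entries lie
    in [-1, 1].
    """
    x = np.asarray(normalized, dtype=float)
    if np.any(np.abs(x) > 1 + tol):
        raise ValueError("gadf expects a normalized series in [-1, 1]")
    x = np.clip(x, -1.0, 1.0)
    s = np.sqrt(1.0 - x**2)
    return np.outer(s, x) - np.outer(x, s)


def render_pseudo_image(G: np.ndarray, side: int = 224) -> np.ndarray:
    """Render a GADF matrix as a (side, side, 3) float raster in [0, 1].

    [-1, 1] maps linearly to [0, 1]; the single channel is replicated to
    three so the raster feeds an RGB-shaped backbone; resizing is bilinear.
    """
    if side < 32:
        raise ValueError("side must be >= 32")
    G = np.asarray(G, dtype=float)
    plane = (G + 1.0) / 2.0
    if plane.shape != (side, side):
        im = Image.fromarray(plane.astype(np.float32), mode="F")
        plane = np.asarray(im.resize((side, side), Image.BILINEAR), dtype=float)
    plane = np.clip(plane, 0.0, 1.0)
    return np.repeat(plane[:, :, None], 3, axis=2)


def encode_window(
    window: AccelWindow, method: str = "x-y-z", side: int = 224
) -> np.ndarray:
    """Reduce a triaxial window, GADF-encode it, and render the pseudo-image."""
    reduced = reduce_window(window, method)
    return render_pseudo_image(gadf(normalize(reduced.values)), side=side)


class GADFImageTransformer(TransformerMixin, BaseEstimator):
    """Stateless transformer: triaxial windows -> GADF pseudo-images.

    Parameters
    ----------
    method : str
        Axis reduction applied before encoding (default the highest-energy
        "x-y-z" combination).
    side : int
        Output raster side in pixels.

    ``transform`` accepts an (N, n, 3) array or a sequence of AccelWindow
    and returns an (N, side, side, 3) float array.
    """

    def __init__(self, method: str = "x-y-z", side: int = 224):
        self.method = method
        self.side = side

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        out = np.empty((len(X), self.side, self.side, 3), dtype=np.float32)
        for i, item in enumerate(X):
            window = (
                item
                if isinstance(item, AccelWindow)
                else AccelWindow(0.0, 0.0, np.asarray(item), rate=1.0)
            )
            out[i] = encode_window(window, method=self.method, side=self.side)
        return out
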