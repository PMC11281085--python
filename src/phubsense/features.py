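"""The 63-element statistical descriptor of a triaxial window.

Nine statistics — mean, population variance, maximum, minimum, median,
bias-adjusted skewness, excess kurtosis, interquartile range, and
coefficient of variation — are computed over seven derived series per
window (the raw X, Y, Z axes, the magnitude V, and the subtractions X-Y,
X-Z, Y-Z), giving 7 x 9 = 63 values in a fixed layout.

Conventions: variance is the population (1/n) form and its square root is
the sigma used inside skewness, kurtosis and Cv; skewness carries the
n/((n-1)(n-2)) adjustment; kurtosis is the excess form with the
-3 (n-1)^2 / ((n-2)(n-3)) correction so a normal sample scores ~0;
quartiles use linear interpolation between order statistics.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .signals import AccelWindow, reduce_window

#: Derived-signal set feeding the statistics (the x-y-z combination is
#: consumed by the GADF branch instead and is excluded here).
STAT_SIGNALS = ("x", "y", "z", "v", "x-y", "x-z", "y-z")
STAT_NAMES = (
    "mean", "variance", "max", "min", "median",
    "skewness", "kurtosis", "iqr", "cv",
)
FEATURE_NAMES = tuple(
    f"{sig.replace('-', '')}_{stat}" for sig in STAT_SIGNALS for stat in STAT_NAMES
)
STAT_VECTOR_DIM = len(FEATURE_NAMES)  # 63


class UndefinedStatisticError(ValueError):
    """A statistic is undefined on this input (zero mean or zero spread)."""


def compute_stats(series: np.ndarray) -> dict[str, float]:
    """Compute the nine statistics of a 1-D series (n >= 4 required)."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("compute_stats expects a 1-D series")
    n = x.size
    if n < 4:
        raise ValueError("compute_stats requires n >= 4 (kurtosis correction)")

    if x.max() == x.min():
        raise UndefinedStatisticError("zero spread: skewness/kurtosis/Cv undefined")
    mu = float(x.mean())
    var = float(np.mean((x - mu) ** 2))  # population form
    sigma = float(np.sqrt(var))
    if abs(mu) < 1e-12:
        raise UndefinedStatisticError("near-zero mean: Cv undefined")

    z = (x - mu) / sigma
    skew = n / ((n - 1) * (n - 2)) * float(np.sum(z**3))
    kurt = (
        n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * float(np.sum(z**4))
        - 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    )
    xs = np.sort(x)
    if n % 2 == 1:
        median = float(xs[(n - 1) // 2])
    else:
        median = float((xs[n // 2 - 1] + xs[n // 2]) / 2.0)
    q1, q3 = np.quantile(x, [0.25, 0.75], method="linear")
    return {
        "mean": mu,
        "variance": var,
        "max": float(x.max()),
        "min": float(x.min()),
        "median": median,
        "skewness": skew,
        "kurtosis": kurt,
        "iqr": float(q3 - q1),
        "cv": sigma / mu,
    }


def build_stat_vector(window: AccelWindow) -> np.ndarray:
    """Assemble the 63-element descriptor of one window (fixed layout)."""
    values = []
    for sig in STAT_SIGNALS:
        series = reduce_window(window, sig).values
        try:
            stats = compute_stats(series)
        except ValueError as err:
            raise type(err)(f"signal {sig!r}: {err}") from err
        values.extend(stats[name] for name in STAT_NAMES)
    return np.asarray(values, dtype=float)


class StatVectorTransformer(TransformerMixin, BaseEstimator):
    """Stateless transformer: triaxial windows -> (N, 63) feature matrix.

    Accepts an (N, n, 3) array or a sequence of AccelWindow.
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        out = np.empty((len(X), STAT_VECTOR_DIM), dtype=float)
        for i, item in enumerate(X):
            window = (
                item
                if isinstance(item, AccelWindow)
                else AccelWindow(0.0, 0.0, np.asarray(item), rate=1.0)
            )
            out[i] = build_stat_vector(window)
        return out

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
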