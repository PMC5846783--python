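"""Natural cubic spline bases with fixed degrees of freedom.

The density models restrict each smooth to a small fixed basis (3 df by
default) instead of penalised smoothness estimation.  The basis is the
classical natural ("restricted") cubic spline: linear tails beyond the
boundary knots, interior knots at equally spaced quantiles of the training
values, and columns centred to zero mean over the training data so the
intercept carries the overall level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineBasis", "build_spline_basis"]


def _raw_natural_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Uncentred natural cubic basis, ``len(knots) - 1`` columns."""
    k = knots
    K = len(k)

    def d(i, xx):
        num = np.maximum(xx - k[i], 0.0) ** 3 - np.maximum(xx - k[K - 1], 0.0) ** 3
        return num / (k[K - 1] - k[i])

    cols = [x]
    for i in range(K - 2):
        cols.append(d(i, x) - d(K - 2, x))
    return np.column_stack(cols)


@dataclass(frozen=True)
class SplineBasis:
    """Frozen basis for one covariate: knots plus training centring."""

    variable: str
    knots: np.ndarray
    center: np.ndarray
    train_min: float
    train_max: float

    @property
    def df(self) -> int:
        return len(self.knots) - 1

    def transform(self, x) -> np.ndarray:
        """Evaluate the centred basis at new values (linear extrapolation)."""
        x = np.asarray(x, dtype=float)
        return _raw_natural_basis(np.atleast_1d(x), self.knots) - self.center


def build_spline_basis(x, df: int = 3, knots=None, variable: str = "x") -> SplineBasis:
    """Build a centred natural cubic basis from training values.

    Knots default to the min/max boundaries plus ``df - 1`` interior knots at
    equally spaced quantiles.  Returns the frozen :class:`SplineBasis`; call
    ``.transform`` for the matrix.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < df + 1:
        raise ValueError("need a 1-d sample with more than df distinct values")
    uniq = np.unique(x)
    if len(uniq) <= df:
        raise ValueError(
            f"covariate {variable!r} has {len(uniq)} distinct values; need > {df}"
        )
    if knots is None:
        probs = np.linspace(0.0, 1.0, df + 1)
        knots = np.quantile(x, probs)
        knots[0], knots[-1] = uniq[0], uniq[-1]
        knots = np.unique(knots)
        if len(knots) != df + 1:
            # heavily tied samples: fall back to evenly spaced knots
            knots = np.linspace(uniq[0], uniq[-1], df + 1)
    else:
        knots = np.sort(np.asarray(knots, dtype=float))
        if len(knots) != df + 1:
            raise ValueError("need df + 1 knots (boundaries included)")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    raw = _raw_natural_basis(x, knots)
    center = raw.mean(axis=0)
    return SplineBasis(
        variable=variable,
        knots=knots,
        center=center,
        train_min=float(x.min()),
        train_max=float(x.max()),
    )
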