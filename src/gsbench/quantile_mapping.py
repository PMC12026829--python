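"""Empirical quantile mapping (QM) for calibrating predictions.

QM corrects distributional bias in model output ``x`` against reference data
``y`` by equating cumulative distribution functions:

    h(x) = CDF_y^{-1}(CDF_x(x)),

so the mapped values share the reference distribution over the calibration
sample.  Here the "model" is the GBLUP fit on the training lines, the
reference is the observed training phenotypes, and h is applied to the test
predictions.  The implementation is non-parametric: h is the monotone
piecewise-linear interpolant between paired empirical quantiles (type-7) at
equally spaced probability points.  Outside the calibrated range the default
``constant_offset`` policy shifts by the boundary offset (QUANT/RQUANT-style
behaviour), avoiding wild linear extrapolation on small folds; ``clamp``
pins to the boundary reference quantile instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError

__all__ = ["TransferFunction", "build_transfer", "apply_transfer", "DEFAULT_MAX_KNOTS"]

DEFAULT_MAX_KNOTS = 100

_POLICIES = ("constant_offset", "clamp")


@dataclass
class TransferFunction:
    """Monotone piecewise-linear map between paired quantile knots."""

    x_quantiles: np.ndarray
    y_quantiles: np.ndarray
    n_knots: int
    extrapolation_policy: str = "constant_offset"

    def __post_init__(self) -> None:
        self.x_quantiles = np.asarray(self.x_quantiles, dtype=float)
        self.y_quantiles = np.asarray(self.y_quantiles, dtype=float)
        if self.n_knots < 2:
            raise ConfigurationError("n_knots must be >= 2")
        if len(self.x_quantiles) != len(self.y_quantiles):
            raise InputError("x_quantiles and y_quantiles must have equal length")
        if len(self.x_quantiles) != self.n_knots:
            raise InputError("knot arrays must have length n_knots")
        if np.any(np.diff(self.x_quantiles) < 0) or np.any(np.diff(self.y_quantiles) < 0):
            raise InputError("quantile knots must be non-decreasing")
        if self.extrapolation_policy not in _POLICIES:
            raise ConfigurationError(
                f"extrapolation_policy must be one of {_POLICIES}"
            )

    def __call__(self, x) -> np.ndarray:
        return apply_transfer(self, x)


def build_transfer(
    observed_train,
    predicted_train,
    n_knots: int | None = None,
    extrapolation_policy: str = "constant_offset",
) -> TransferFunction:
    """Fit h from training (predicted, observed) pairs.

    Knots are empirical quantiles (type-7 / linear interpolation) of each
    sample at ``n_knots`` equally spaced probabilities spanning [0, 1].
    ``n_knots`` defaults to ``min(100, n_train)``; tied values enter the
    quantiles as-is, keeping the fit deterministic.
    """
    observed = np.asarray(observed_train, dtype=float)
    predicted = np.asarray(predicted_train, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise InputError("observed and predicted must be equal-length 1-D vectors")
    if len(observed) < 2:
        raise InputError("need at least 2 calibration pairs")
    if not (np.isfinite(observed).all() and np.isfinite(predicted).all()):
        raise InputError("calibration values must be finite")
    if n_knots is None:
        n_knots = min(DEFAULT_MAX_KNOTS, len(observed))
    if n_knots < 2:
        raise ConfigurationError("n_knots must be >= 2")
    probs = np.linspace(0.0, 1.0, n_knots)
    return TransferFunction(
        x_quantiles=np.quantile(predicted, probs),
        y_quantiles=np.quantile(observed, probs),
        n_knots=int(n_knots),
        extrapolation_policy=extrapolation_policy,
    )


def apply_transfer(tf: TransferFunction, predicted_test) -> np.ndarray:
    """Map values through h; empty input yields empty output."""
    x = np.asarray(predicted_test, dtype=float)
    if x.size == 0:
        return x.copy()
    xq, yq = tf.x_quantiles, tf.y_quantiles
    out = np.interp(x, xq, yq)
    below = x < xq[0]
    above = x > xq[-1]
    if tf.extrapolation_policy == "constant_offset":
        out[below] = x[below] + (yq[0] - xq[0])
        out[above] = x[above] + (yq[-1] - xq[-1])
    else:  # clamp — np.interp already pins to the boundary knots
        pass
    return out
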