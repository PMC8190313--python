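"""Gaussian-kernel locally weighted shape-on-age regression.

The expected face at a target age is the prediction of a locally weighted
regression of the GPA-aligned vertex coordinates on age.  With a single
predictor (age), a one-component partial-least-squares regression is
algebraically identical to per-coordinate weighted least squares, which is
what is implemented: for coordinate j,

    slope_j = sum_i w_i (a_i - a_bar_w)(x_ij - x_bar_wj)
              / sum_i w_i (a_i - a_bar_w)^2

and the expected face at the target age t is ``x_bar_w + slope * (t -
a_bar_w)``.  Weights are Gaussian in age distance, with a variable
bandwidth chosen as the smallest sigma achieving a target effective sample
size, so sparsely sampled ages borrow strength from a wider window while
densely sampled ages stay local.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateDesignError,
    ExtrapolationError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "KernelConfig",
    "KernelSpec",
    "WeightVector",
    "LocalShapeModel",
    "gaussian_weights",
    "effective_sample_size",
    "adaptive_bandwidth",
    "fit_local_model",
    "age_adjusted_residuals",
]


@dataclass(frozen=True)
class KernelConfig:
    """Cohort-level kernel defaults: bandwidth floor and target effective n.

    ``sigma_floor`` (years) prevents the window collapsing where data are
    dense; ``min_effective_n`` is the Kish effective sample size every
    local model must reach, so each age's variation model stays
    representative.
    """

    sigma_floor: float = 1.0
    min_effective_n: float = 200.0

    def __post_init__(self) -> None:
        if not self.sigma_floor > 0:
            raise ValidationError("sigma_floor must be > 0")
        if not self.min_effective_n >= 1:
            raise ValidationError("min_effective_n must be >= 1")


@dataclass(frozen=True)
class KernelSpec:
    """A fully resolved kernel at one target age."""

    target_age: float
    sigma: float  # years; may be math.inf for equal weights
    sigma_floor: float = 1.0
    min_effective_n: float = 1.0

    def __post_init__(self) -> None:
        if not self.sigma_floor > 0:
            raise ValidationError("sigma_floor must be > 0")
        if not self.sigma >= self.sigma_floor:
            raise ValidationError(
                f"sigma ({self.sigma}) must be >= sigma_floor ({self.sigma_floor})"
            )
        if not self.min_effective_n >= 1:
            raise ValidationError("min_effective_n must be >= 1")


@dataclass
class WeightVector:
    """Non-negative kernel weights with their sum and Kish effective n."""

    weights: np.ndarray
    sum_of_weights: float
    effective_n: float


def effective_sample_size(weights: np.ndarray) -> float:
    """Kish effective sample size ``(sum w)^2 / sum w^2``."""
    w = np.asarray(weights, dtype=np.float64)
    denom = float(np.sum(w**2))
    if denom == 0:
        return 0.0
    return float(np.sum(w)) ** 2 / denom


def gaussian_weights(
    training_ages: np.ndarray, target_age: float, sigma: float
) -> WeightVector:
    """Gaussian kernel weights ``w_i = exp(-(a_i - t)^2 / (2 sigma^2))``.

    ``sigma = inf`` gives equal (unit) weights.  A training age equal to the
    target always receives weight exactly 1.
    """
    a = np.asarray(training_ages, dtype=np.float64)
    if not np.isfinite(a).all():
        raise ValidationError("training ages must be finite")
    if not sigma > 0:
        raise ValidationError("sigma must be > 0")
    if math.isinf(sigma):
        w = np.ones_like(a)
    else:
        w = np.exp(-((a - float(target_age)) ** 2) / (2.0 * sigma**2))
    return WeightVector(
        weights=w, sum_of_weights=float(w.sum()), effective_n=effective_sample_size(w)
    )


def adaptive_bandwidth(
    training_ages: np.ndarray,
    target_age: float,
    sigma_floor: float = 1.0,
    min_effective_n: float = 200.0,
    resolution: float = 1e-4,
) -> float:
    """Smallest sigma >= sigma_floor reaching the target effective n.

    The Kish effective sample size is non-decreasing in sigma (weights
    flatten as the window widens), so a doubling search brackets the
    threshold and bisection refines it to ``resolution`` years.
    """
    a = np.asarray(training_ages, dtype=np.float64)
    n = a.size
    if n < min_effective_n:
        raise InsufficientDataError(
            f"{n} training subjects cannot reach effective n "
            f">= {min_effective_n} (deficit {min_effective_n - n:g})"
        )

    def eff(sigma: float) -> float:
        return gaussian_weights(a, target_age, sigma).effective_n

    if eff(sigma_floor) >= min_effective_n:
        return float(sigma_floor)
    lo, hi = sigma_floor, sigma_floor
    while eff(hi) < min_effective_n:
        hi *= 2.0
        if hi > 1e9:
            raise InsufficientDataError(
                f"effective n saturates below {min_effective_n} at target age "
                f"{target_age} (max reachable ~ {eff(1e9):.1f})"
            )
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if eff(mid) >= min_effective_n:
            hi = mid
        else:
            lo = mid
    return float(hi)


@dataclass
class LocalShapeModel:
    """Local linear model of shape on age around one target age.

    ``expected`` is the model's face at ``target_age``; ``slope`` has units
    mm/year per coordinate.  The prediction at the weighted-mean age equals
    the weighted-mean shape by construction.
    """

    target_age: float
    mean_age: float  # weighted mean training age
    mean_shape: np.ndarray  # (k, 3)
    slope: np.ndarray  # (k, 3)
    expected: np.ndarray  # (k, 3)
    weights: WeightVector
    kernel: KernelSpec

    def predict(self, age: float) -> np.ndarray:
        """Expected face at an arbitrary age under the local linear trend."""
        return self.mean_shape + self.slope * (float(age) - self.mean_age)


def fit_local_model(
    aligned_shapes: np.ndarray,
    ages: np.ndarray,
    kernel: KernelSpec,
    allow_extrapolation: bool = False,
) -> LocalShapeModel:
    """Weighted local linear (one-component PLS) fit of shape on age.

    ``aligned_shapes`` is ``(n, k, 3)`` after GPA.  Raises
    :class:`DegenerateDesignError` when the weighted age variance vanishes
    and :class:`ExtrapolationError` when the target age lies outside the
    training range (override with ``allow_extrapolation``).
    """
    X = np.asarray(aligned_shapes, dtype=np.float64)
    a = np.asarray(ages, dtype=np.float64)
    if X.ndim != 3 or X.shape[0] != a.size:
        raise ValidationError(
            f"aligned shapes {X.shape} inconsistent with {a.size} ages"
        )
    t = float(kernel.target_age)
    if not allow_extrapolation and not (a.min() <= t <= a.max()):
        raise ExtrapolationError(
            f"target age {t} outside training range [{a.min():g}, {a.max():g}]; "
            "pass allow_extrapolation=True to override"
        )
    wv = gaussian_weights(a, t, kernel.sigma)
    w = wv.weights
    if wv.sum_of_weights <= 0:
        raise DegenerateDesignError("all kernel weights are zero")
    if np.unique(a[w > 0]).size < 2:
        raise DegenerateDesignError(
            "need >= 2 distinct training ages with nonzero weight"
        )
    mean_age = float(np.sum(w * a) / wv.sum_of_weights)
    mean_shape = np.einsum("n,nkc->kc", w, X) / wv.sum_of_weights
    da = a - mean_age
    var_age = float(np.sum(w * da**2))
    if var_age <= 0:
        raise DegenerateDesignError("weighted age variance is zero")
    slope = np.einsum("n,nkc->kc", w * da, X) / var_age
    expected = mean_shape + slope * (t - mean_age)
    return LocalShapeModel(
        target_age=t,
        mean_age=mean_age,
        mean_shape=mean_shape,
        slope=slope,
        expected=expected,
        weights=wv,
        kernel=kernel,
    )


def age_adjusted_residuals(
    aligned_shapes: np.ndarray,
    ages: np.ndarray,
    model: LocalShapeModel,
) -> tuple[np.ndarray, WeightVector]:
    """Residual displacements from each subject's own-age prediction.

    Returns an ``(n, 3k)`` matrix whose row i is
    ``x_i - (expected + slope * (a_i - target_age))`` flattened, i.e. the
    subject's displacement from the expected face at the subject's own age,
    expressed in the target-age frame — plus the kernel weights used to fit
    the model.  The weighted mean of the residuals is zero per coordinate
    (normal equations).
    """
    X = np.asarray(aligned_shapes, dtype=np.float64)
    a = np.asarray(ages, dtype=np.float64)
    if X.ndim != 3 or X.shape[0] != a.size:
        raise ValidationError(
            f"aligned shapes {X.shape} inconsistent with {a.size} ages"
        )
    n = X.shape[0]
    pred = (
        model.expected[None]
        + model.slope[None] * (a - model.target_age)[:, None, None]
    )
    residuals = (X - pred).reshape(n, -1)
    return residuals, model.weights
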