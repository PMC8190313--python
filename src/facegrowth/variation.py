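"""Age/sex-specific models of normal variation and growth-curve building.

Two complementary parameterizations of the variation around the expected
face are fitted from the same kernel-weighted, age-adjusted residuals:

* **Pointwise standard deviations** — weighted RMS displacement per vertex
  along each anatomical axis, along the expected-surface normal, and in
  total magnitude.  These standardize a patient's displacements into
  z-scores.
* **Statistical shape model (SSM)** — orthonormal modes of variation with
  per-mode variances, obtained from an SVD of sqrt(w_i / sum w)-scaled
  residual rows *without* column centering or standardization, so the
  squared singular values are weighted variances along the modes.  The
  smallest leading set of modes explaining at least ``retained_fraction``
  (default 98%) of the total weighted variance is kept.

``build_growth_curves`` repeats expected face + pointwise SD + SSM over an
age grid (default spacing 0.3 years) for one sex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .align import gpa
from .errors import (
    InsufficientDataError,
    InvalidModelError,
    SingularProjectionError,
    ValidationError,
)
from .mesh import AxisConvention, CorrespondedShape, TriangleTopology, compute_vertex_normals
from .regression import (
    KernelConfig,
    KernelSpec,
    WeightVector,
    adaptive_bandwidth,
    age_adjusted_residuals,
    fit_local_model,
)

__all__ = [
    "PointwiseSD",
    "SSM",
    "ModelEntry",
    "GrowthCurveModel",
    "pointwise_sd",
    "fit_ssm",
    "ssm_project",
    "mahalanobis_sq",
    "default_age_grid",
    "build_growth_curves",
]

logger = logging.getLogger(__name__)

#: Published evaluation grids: every 0.3 years, 0.5-68.9 (female), 0.5-51.8 (male).
DEFAULT_AGE_STEP = 0.3
DEFAULT_AGE_RANGE = {"female": (0.5, 68.9), "male": (0.5, 51.8)}


@dataclass
class PointwiseSD:
    """Per-vertex weighted RMS displacement (mm) by direction.

    The three axis components are an orthonormal decomposition, so
    ``sd_magnitude**2 == sd_ml**2 + sd_si**2 + sd_ap**2`` at every vertex.
    """

    sd_ml: np.ndarray
    sd_si: np.ndarray
    sd_ap: np.ndarray
    sd_normal: np.ndarray
    sd_magnitude: np.ndarray

    def __post_init__(self) -> None:
        arrs = [self.sd_ml, self.sd_si, self.sd_ap, self.sd_normal, self.sd_magnitude]
        k = np.asarray(arrs[0]).shape
        for a in arrs:
            a = np.asarray(a, dtype=np.float64)
            if a.shape != k or (a < 0).any():
                raise ValidationError("pointwise SDs must be matching non-negative arrays")


def pointwise_sd(
    residuals: np.ndarray,
    weights: np.ndarray | WeightVector,
    expected_normals: np.ndarray,
    axis_convention: AxisConvention | None = None,
) -> PointwiseSD:
    """Weighted RMS of per-vertex displacements by direction.

    For each vertex and direction d: ``sd = sqrt(sum_i w_i d_i^2 / sum_i
    w_i)``, reducing to the ordinary (uncentred) SD under equal weights.
    Weights enter only as relative values — rescaling all weights leaves
    every SD unchanged.
    """
    w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights, float)
    R = np.asarray(residuals, dtype=np.float64)
    conv = axis_convention or AxisConvention()
    n = R.shape[0]
    if w.shape != (n,):
        raise ValidationError(f"weights shape {w.shape} does not match n={n}")
    wsum = float(w.sum())
    if wsum <= 0:
        raise ValidationError("empty kernel: sum of weights is zero")
    D = R.reshape(n, -1, 3)
    k = D.shape[1]
    normals = np.asarray(expected_normals, dtype=np.float64)
    if normals.shape != (k, 3):
        raise ValidationError(f"normals shape {normals.shape} != ({k}, 3)")

    var_axis = np.einsum("n,nkc->kc", w, D**2) / wsum  # (k, 3)
    proj = np.einsum("nkc,kc->nk", D, normals)
    var_normal = np.einsum("n,nk->k", w, proj**2) / wsum
    sd_axis = np.sqrt(var_axis)
    return PointwiseSD(
        sd_ml=sd_axis[:, conv.medial_lateral],
        sd_si=sd_axis[:, conv.superior_inferior],
        sd_ap=sd_axis[:, conv.anterior_posterior],
        sd_normal=np.sqrt(var_normal),
        sd_magnitude=np.sqrt(var_axis.sum(axis=1)),
    )


@dataclass
class SSM:
    """Statistical shape model: orthonormal modes with per-mode variances.

    ``modes`` is ``(m, 3k)`` with orthonormal rows; ``mode_variances`` are
    the expected (weighted) variances along each mode, sorted descending.
    ``total_variance`` is the total weighted residual variance of the
    training sample, so ``mode_variances.sum() / total_variance`` is the
    retained fraction actually achieved.
    """

    modes: np.ndarray
    mode_variances: np.ndarray
    retained_fraction: float
    n_effective: float
    total_variance: float

    def __post_init__(self) -> None:
        M = np.asarray(self.modes, dtype=np.float64)
        lam = np.asarray(self.mode_variances, dtype=np.float64)
        if M.ndim != 2 or lam.shape != (M.shape[0],):
            raise ValidationError("modes must be (m, 3k) with m variances")
        if (lam <= 0).any():
            raise InvalidModelError("mode variances must be positive")
        if (np.diff(lam) > 1e-12 * lam[0]).any():
            raise InvalidModelError("mode variances must be sorted descending")
        object.__setattr__(self, "modes", M)
        object.__setattr__(self, "mode_variances", lam)

    @property
    def n_modes(self) -> int:
        return int(self.modes.shape[0])

    def reconstruct(self, coefficients: np.ndarray) -> np.ndarray:
        """Displacement field (3k,) from mode coefficients."""
        return self.modes.T @ np.asarray(coefficients, dtype=np.float64)


def fit_ssm(
    residuals: np.ndarray,
    weights: np.ndarray | WeightVector,
    retained_fraction: float = 0.98,
) -> SSM:
    """Fit an SSM by weighted, uncentred SVD of the residual matrix.

    Rows are scaled by ``sqrt(w_i / sum w)`` before the SVD (no column
    centering or standardization), so each squared singular value is the
    weighted variance along its right singular vector.  The smallest
    leading set of modes whose cumulative variance fraction reaches
    ``retained_fraction`` is kept, additionally capped at
    ``floor(effective_n) - 1`` modes as a small-sample guard.
    """
    if isinstance(weights, WeightVector):
        w = weights.weights
        n_eff = weights.effective_n
    else:
        w = np.asarray(weights, dtype=np.float64)
        n_eff = float(w.sum()) ** 2 / float(np.sum(w**2)) if w.any() else 0.0
    R = np.asarray(residuals, dtype=np.float64)
    if R.ndim != 2 or R.shape[0] != w.size:
        raise ValidationError(f"residuals {R.shape} inconsistent with {w.size} weights")
    pos = w > 0
    if pos.sum() < 2:
        raise InsufficientDataError("need >= 2 subjects with positive weight")
    if not 0 < retained_fraction <= 1:
        raise ValidationError("retained_fraction must be in (0, 1]")

    scaled = R * np.sqrt(w / w.sum())[:, None]
    _, svals, Vt = np.linalg.svd(scaled, full_matrices=False)
    variances = svals**2
    total = float(variances.sum())
    if total <= 0:
        raise InvalidModelError("residuals are identically zero; rank-zero model")
    nonzero = variances > 1e-14 * variances[0]
    variances, Vt = variances[nonzero], Vt[nonzero]
    cum = np.cumsum(variances) / total
    m = int(np.searchsorted(cum, retained_fraction - 1e-12) + 1)
    m = min(m, variances.size)
    cap = max(1, int(np.floor(n_eff)) - 1)
    m = min(m, cap)
    return SSM(
        modes=Vt[:m],
        mode_variances=variances[:m],
        retained_fraction=retained_fraction,
        n_effective=n_eff,
        total_variance=total,
    )


def ssm_project(
    ssm: SSM,
    displacement: np.ndarray,
    vertex_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted least-squares projection of a displacement onto SSM modes.

    Solves ``min_c || W^(1/2) (d - M^T c) ||^2`` where the per-vertex
    weights are replicated to the three coordinates of each vertex.  With
    equal weights this is the plain orthogonal projection ``c = M d``.
    """
    d = np.asarray(displacement, dtype=np.float64).ravel()
    M = ssm.modes
    if d.size != M.shape[1]:
        raise ValidationError(f"displacement length {d.size} != {M.shape[1]}")
    if vertex_weights is None:
        return M @ d
    vw = np.asarray(vertex_weights, dtype=np.float64)
    if vw.size * 3 != d.size:
        raise ValidationError(
            f"{vw.size} vertex weights do not match {d.size // 3} vertices"
        )
    if (vw < 0).any() or not vw.any():
        raise SingularProjectionError("vertex weights must be non-negative, not all zero")
    W = np.repeat(vw / vw.max(), 3)
    if np.ptp(W) == 0:
        return M @ d
    MW = M * W
    G = MW @ M.T
    b = MW @ d
    try:
        c = np.linalg.solve(G, b)
    except np.linalg.LinAlgError as exc:
        raise SingularProjectionError(f"weighted projection is singular: {exc}") from exc
    if not np.isfinite(c).all():
        raise SingularProjectionError("weighted projection produced non-finite coefficients")
    return c


def mahalanobis_sq(ssm: SSM, coefficients: np.ndarray) -> tuple[float, float]:
    """Squared Mahalanobis distance of mode coefficients and its chi-square tail.

    ``D^2 = sum_j c_j^2 / lambda_j``; the tail probability is the upper tail
    of the chi-square distribution with m (number of modes) degrees of
    freedom, i.e. the p-value of the face being as extreme under the model.
    """
    c = np.asarray(coefficients, dtype=np.float64).ravel()
    lam = ssm.mode_variances
    if c.size != lam.size:
        raise ValidationError(f"{c.size} coefficients for {lam.size} modes")
    if (lam <= 0).any():
        raise InvalidModelError("mode variances must be positive")
    d2 = float(np.sum(c**2 / lam))
    return d2, float(stats.chi2.sf(d2, df=lam.size))


# ---------------------------------------------------------------------------
# growth-curve orchestration
# ---------------------------------------------------------------------------


@dataclass
class ModelEntry:
    """Everything the growth curves store at one grid age."""

    age: float
    expected: np.ndarray  # (k, 3)
    normals: np.ndarray  # (k, 3), unit, outward
    sd: PointwiseSD
    ssm: SSM
    sigma: float  # kernel bandwidth actually used (years)
    effective_n: float


@dataclass
class GrowthCurveModel:
    """Per-sex sequence of expected faces and variation models over an age grid."""

    sex: str
    ages: np.ndarray
    entries: list[ModelEntry]
    topology: TriangleTopology
    kernel: KernelConfig
    retained_fraction: float
    allow_scale: bool = False

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=np.float64)
        if ages.ndim != 1 or ages.size != len(self.entries):
            raise ValidationError("age grid and entries are inconsistent")
        if ages.size > 1:
            steps = np.diff(ages)
            if (steps <= 0).any():
                raise ValidationError("age grid must be strictly increasing")
            if np.ptp(steps) > 1e-9:
                raise ValidationError("age grid must have constant spacing")
        self.ages = ages

    @property
    def age_range(self) -> tuple[float, float]:
        return float(self.ages[0]), float(self.ages[-1])

    def at_age(self, age: float) -> ModelEntry:
        """Nearest-grid-age lookup (the choice is logged, not interpolated)."""
        idx = int(np.argmin(np.abs(self.ages - float(age))))
        entry = self.entries[idx]
        logger.info(
            "model lookup: requested age %.3f -> grid age %.3f (%s)",
            float(age), entry.age, self.sex,
        )
        return entry


def default_age_grid(sex: str, step: float = DEFAULT_AGE_STEP) -> np.ndarray:
    """The published evaluation grid for one sex (constant 0.3-year spacing)."""
    if sex not in DEFAULT_AGE_RANGE:
        raise ValidationError(f"sex must be 'male' or 'female', got {sex!r}")
    lo, hi = DEFAULT_AGE_RANGE[sex]
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def build_growth_curves(
    shapes: list[CorrespondedShape],
    topology: TriangleTopology,
    sex: str | None = None,
    age_grid: np.ndarray | None = None,
    kernel: KernelConfig = KernelConfig(),
    retained_fraction: float = 0.98,
    allow_scale: bool = False,
    allow_extrapolation: bool = False,
) -> GrowthCurveModel:
    """Build the full growth-curve model for one sex over an age grid.

    Pipeline per grid age: adaptive bandwidth -> Gaussian weights -> local
    linear fit (expected face) -> age-adjusted residuals -> pointwise SDs
    and SSM.  GPA (pose only by default; see ``allow_scale``) is applied to
    the whole training set once, up front.

    Raises :class:`InsufficientDataError` listing every grid age at which
    the target effective sample size cannot be reached.
    """
    if sex is not None:
        shapes = [s for s in shapes if s.sex == sex]
    else:
        sexes = {s.sex for s in shapes}
        if len(sexes) != 1:
            raise ValidationError(
                "training set mixes sexes; pass sex= to select one"
            )
        sex = next(iter(sexes))
    if not shapes:
        raise InsufficientDataError(f"no training shapes for sex {sex!r}")
    for s in shapes:
        if s.n_vertices != topology.n_vertices:
            raise ValidationError(
                f"subject {s.subject_id!r} has {s.n_vertices} vertices, "
                f"topology {topology.n_vertices}"
            )
        if s.age is None:
            raise ValidationError(f"subject {s.subject_id!r} has no age")
    ages = np.asarray([s.age for s in shapes], dtype=np.float64)
    grid = default_age_grid(sex) if age_grid is None else np.asarray(age_grid, float)

    result = gpa([s.vertices for s in shapes], allow_scale=allow_scale)
    aligned = result.aligned
    logger.info("GPA converged in %d iterations (n=%d, sex=%s)",
                result.iterations, len(shapes), sex)

    failing = []
    sigmas = []
    for t in grid:
        try:
            sigmas.append(
                adaptive_bandwidth(ages, float(t), kernel.sigma_floor,
                                   kernel.min_effective_n)
            )
        except InsufficientDataError:
            failing.append(float(t))
            sigmas.append(np.nan)
    if failing:
        raise InsufficientDataError(
            f"effective n < {kernel.min_effective_n} at grid ages {failing}"
        )

    entries = []
    for t, sigma in zip(grid, sigmas):
        spec = KernelSpec(
            target_age=float(t), sigma=float(sigma),
            sigma_floor=kernel.sigma_floor, min_effective_n=kernel.min_effective_n,
        )
        model = fit_local_model(aligned, ages, spec,
                                allow_extrapolation=allow_extrapolation)
        residuals, wv = age_adjusted_residuals(aligned, ages, model)
        normals = compute_vertex_normals(model.expected, topology)
        sd = pointwise_sd(residuals, wv, normals, topology.axis_convention)
        ssm = fit_ssm(residuals, wv, retained_fraction)
        logger.info(
            "age %.2f: sigma=%.3f yr, effective n=%.1f, %d modes (%.2f%% variance)",
            t, sigma, wv.effective_n, ssm.n_modes,
            100.0 * ssm.mode_variances.sum() / ssm.total_variance,
        )
        entries.append(
            ModelEntry(age=float(t), expected=model.expected, normals=normals,
                       sd=sd, ssm=ssm, sigma=float(sigma),
                       effective_n=wv.effective_n)
        )
    return GrowthCurveModel(
        sex=sex, ages=grid, entries=entries, topology=topology,
        kernel=kernel, retained_fraction=retained_fraction,
        allow_scale=allow_scale,
    )
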