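"""Patient-facing analyses: facial signatures, normal equivalents, morphs.

A patient is compared against the age- and sex-specific model of normal
variation in two ways:

* the **facial signature** standardizes the per-vertex displacement from
  the expected face into z-scores (per anatomical axis, along the surface
  normal with outward positive, and in magnitude);
* the **normal equivalent** reconstructs the patient inside the span of
  normal variation by an iteratively reweighted projection onto the SSM
  modes, bounded by a critical Mahalanobis distance (default p = 0.05), so
  regions that do not fit normal variation are interpolated from those
  that do.  One iteration with equal, never-updated weights is the
  "closest control".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .align import centroid_size, gpa, procrustes_pair
from .errors import FaceGrowthError, ValidationError
from .mesh import CorrespondedShape, TriangleTopology, write_ply
from .variation import GrowthCurveModel, ModelEntry, SSM, mahalanobis_sq, ssm_project

__all__ = [
    "FacialSignature",
    "NormalEquivalent",
    "Morph",
    "align_to_expected",
    "facial_signature",
    "signature_from_entry",
    "normal_equivalent",
    "closest_control",
    "normal_equivalent_for",
    "make_morph",
    "export_signature_colormap",
]

logger = logging.getLogger(__name__)

#: MAD-to-SD factor for the robust residual scale of the weight update.
_MAD_SCALE = 1.4826


@dataclass
class FacialSignature:
    """Per-vertex z-score map of a patient against the expected face.

    Directional z-scores are signed; ``z_normal > 0`` means the point is
    displaced outward (along the expected-surface normal).  ``mask`` marks
    vertices where every SD is positive; where an SD is zero the
    corresponding z is NaN.
    """

    z_ml: np.ndarray
    z_si: np.ndarray
    z_ap: np.ndarray
    z_normal: np.ndarray
    z_magnitude: np.ndarray
    displacement: np.ndarray  # (k, 3) mm, patient minus expected
    expected: np.ndarray  # (k, 3) mm, the expected face used as reference
    mask: np.ndarray  # True where all SDs > 0
    model_age: float  # grid age actually used
    target_age: float  # age requested
    sex: str

    @property
    def patient_vertices(self) -> np.ndarray:
        """The aligned patient geometry (expected + displacement)."""
        return self.expected + self.displacement


def align_to_expected(
    patient_vertices: np.ndarray,
    expected: np.ndarray,
    allow_scale: bool = False,
) -> np.ndarray:
    """Superimpose a patient onto the expected face by ordinary Procrustes.

    Scaling should match how the model was built (pose-only by default) so
    that z-scores are computed in the model's frame and units.
    """
    transform = procrustes_pair(patient_vertices, expected, allow_scale=allow_scale)
    return transform.apply(patient_vertices)


def signature_from_entry(
    aligned_vertices: np.ndarray,
    entry: ModelEntry,
    model: GrowthCurveModel,
    target_age: float,
) -> FacialSignature:
    """Signature of an already-aligned patient against one grid-age entry."""
    d = np.asarray(aligned_vertices, dtype=np.float64) - entry.expected
    conv = model.topology.axis_convention

    def _z(component: np.ndarray, sd: np.ndarray) -> np.ndarray:
        z = np.full_like(component, np.nan)
        ok = sd > 0
        z[ok] = component[ok] / sd[ok]
        return z

    z_ml = _z(d[:, conv.medial_lateral], entry.sd.sd_ml)
    z_si = _z(d[:, conv.superior_inferior], entry.sd.sd_si)
    z_ap = _z(d[:, conv.anterior_posterior], entry.sd.sd_ap)
    z_normal = _z(np.einsum("kc,kc->k", d, entry.normals), entry.sd.sd_normal)
    z_magnitude = _z(np.linalg.norm(d, axis=1), entry.sd.sd_magnitude)
    mask = np.isfinite(z_ml) & np.isfinite(z_si) & np.isfinite(z_ap) \
        & np.isfinite(z_normal) & np.isfinite(z_magnitude)
    if not mask.all():
        logger.warning("signature: %d vertices masked (zero SD)", int((~mask).sum()))
    return FacialSignature(
        z_ml=z_ml, z_si=z_si, z_ap=z_ap, z_normal=z_normal,
        z_magnitude=z_magnitude, displacement=d, expected=entry.expected,
        mask=mask, model_age=entry.age, target_age=float(target_age),
        sex=model.sex,
    )


def facial_signature(
    patient: CorrespondedShape | np.ndarray,
    model: GrowthCurveModel,
    age: float | None = None,
    sex: str | None = None,
    align: bool = True,
) -> FacialSignature:
    """Facial signature of a patient against their age/sex-specific model.

    The nearest grid age is used (and logged).  The patient is superimposed
    onto the expected face first unless ``align=False`` (already aligned).
    """
    if isinstance(patient, CorrespondedShape):
        vertices = patient.vertices
        age = age if age is not None else patient.age
        sex = sex if sex is not None else patient.sex
    else:
        vertices = np.asarray(patient, dtype=np.float64)
    if age is None:
        raise ValidationError("patient age is required")
    if sex is not None and sex != model.sex:
        raise ValidationError(f"patient sex {sex!r} does not match model ({model.sex})")
    entry = model.at_age(age)
    if align:
        vertices = align_to_expected(vertices, entry.expected,
                                     allow_scale=model.allow_scale)
    return signature_from_entry(vertices, entry, model, target_age=float(age))


@dataclass
class NormalEquivalent:
    """Patient reconstruction constrained to the span of normal variation."""

    vertices: np.ndarray  # (k, 3)
    normal_difference: np.ndarray | None  # (k,) mm, patient minus NE along normal
    coefficients: np.ndarray
    mahalanobis_sq: float
    tail_probability: float
    iterations: int
    vertex_weights: np.ndarray


def normal_equivalent(
    patient_vertices: np.ndarray,
    ssm: SSM,
    expected_face: np.ndarray,
    normals: np.ndarray | None = None,
    p_crit: float = 0.05,
    max_iter: int = 10,
    tol: float = 1e-4,
    update_weights: bool = True,
    initial_weights: np.ndarray | None = None,
) -> NormalEquivalent:
    """Iteratively reweighted, Mahalanobis-bounded projection onto SSM modes.

    Per iteration: (1) weighted projection of (patient - expected) onto the
    modes; (2) if the chi-square tail of D^2 falls below ``p_crit``, the
    coefficient vector is radially rescaled (in standardized coordinates)
    onto the critical Mahalanobis sphere; (3) reconstruction; (4) the
    per-vertex residual magnitudes set the next weights through a Gaussian
    kernel with robust scale 1.4826 x median residual, so poorly
    reconstructed regions lose influence.  Stops when the reconstruction
    RMS change drops below ``tol`` mm or after ``max_iter`` iterations.

    The final tail probability is always >= ``p_crit`` and the returned
    reconstruction lies in the span of the modes.
    """
    patient = np.asarray(patient_vertices, dtype=np.float64)
    expected = np.asarray(expected_face, dtype=np.float64)
    if patient.shape != expected.shape:
        raise ValidationError(f"patient {patient.shape} vs expected {expected.shape}")
    if not 0 < p_crit < 1:
        raise ValidationError("p_crit must be in (0, 1)")
    k = patient.shape[0]
    d = (patient - expected).ravel()
    if not np.isfinite(d).all():
        raise FaceGrowthError("non-finite patient displacement")
    m = ssm.n_modes
    d2_crit = float(stats.chi2.ppf(1.0 - p_crit, df=m))

    if initial_weights is None:
        w = np.ones(k)
    else:
        w = np.asarray(initial_weights, dtype=np.float64).copy()
        if w.shape != (k,):
            raise ValidationError(f"initial weights must be ({k},)")

    prev_recon = None
    recon = np.zeros((k, 3))
    c = np.zeros(m)
    d2 = 0.0
    iterations = 0
    for iterations in range(1, max_iter + 1):
        c = ssm_project(ssm, d, vertex_weights=None if np.ptp(w) == 0 else w)
        d2, _ = mahalanobis_sq(ssm, c)
        if d2 > d2_crit:
            c = c * np.sqrt(d2_crit / d2)
            d2 = d2_crit
        recon = ssm.reconstruct(c).reshape(k, 3)
        if prev_recon is not None:
            change = float(np.sqrt(np.mean((recon - prev_recon) ** 2)))
            if change < tol:
                break
        prev_recon = recon
        if update_weights and iterations < max_iter:
            residual = patient - (expected + recon)
            rmag = np.linalg.norm(residual, axis=1)
            if not np.isfinite(rmag).all():
                raise FaceGrowthError("non-finite reconstruction residuals")
            scale = _MAD_SCALE * float(np.median(rmag))
            if scale <= 0:
                w = np.ones(k)
            else:
                w = np.exp(-(rmag**2) / (2.0 * scale**2))
                if not w.any() or w.max() < 1e-300:
                    raise FaceGrowthError("weight update degenerated to all zeros")

    tail = float(stats.chi2.sf(d2, df=m))
    ne_vertices = expected + recon
    normal_difference = None
    if normals is not None:
        normals = np.asarray(normals, dtype=np.float64)
        normal_difference = np.einsum("kc,kc->k", patient - ne_vertices, normals)
    return NormalEquivalent(
        vertices=ne_vertices,
        normal_difference=normal_difference,
        coefficients=c,
        mahalanobis_sq=d2,
        tail_probability=tail,
        iterations=iterations,
        vertex_weights=w,
    )


def closest_control(
    patient_vertices: np.ndarray,
    ssm: SSM,
    expected_face: np.ndarray,
    normals: np.ndarray | None = None,
    p_crit: float = 0.05,
) -> NormalEquivalent:
    """Single-iteration, equal-weights special case of the normal equivalent."""
    return normal_equivalent(
        patient_vertices, ssm, expected_face, normals=normals, p_crit=p_crit,
        max_iter=1, update_weights=False, initial_weights=None,
    )


def normal_equivalent_for(
    patient: CorrespondedShape | np.ndarray,
    model: GrowthCurveModel,
    age: float | None = None,
    p_crit: float = 0.05,
    max_iter: int = 10,
    tol: float = 1e-4,
    align: bool = True,
) -> NormalEquivalent:
    """Normal equivalent against the nearest grid-age entry of a model."""
    if isinstance(patient, CorrespondedShape):
        vertices = patient.vertices
        age = age if age is not None else patient.age
    else:
        vertices = np.asarray(patient, dtype=np.float64)
    if age is None:
        raise ValidationError("patient age is required")
    entry = model.at_age(age)
    if align:
        vertices = align_to_expected(vertices, entry.expected,
                                     allow_scale=model.allow_scale)
    return normal_equivalent(
        vertices, entry.ssm, entry.expected, normals=entry.normals,
        p_crit=p_crit, max_iter=max_iter, tol=tol,
    )


@dataclass
class Morph:
    """Average face of a small set of individuals."""

    vertices: np.ndarray  # (k, 3), rescaled to the members' mean size
    member_ids: list[str]
    age: float  # arithmetic mean of member ages
    size: float  # mean member centroid size (mm)


def make_morph(shapes: list[CorrespondedShape]) -> Morph:
    """Vertex-wise average after unit-size GPA, rescaled to the mean size.

    The members are co-aligned by GPA with unit-size scaling (averaging
    shape independently of size), averaged vertex-wise, and the average is
    scaled back so its centroid size equals the mean of the members'
    original centroid sizes.  The morph's age is the mean member age.
    """
    if len(shapes) < 2:
        raise ValidationError("a morph needs >= 2 member faces")
    ages = [s.age for s in shapes]
    if any(a is None for a in ages):
        raise ValidationError("every morph member needs an age")
    result = gpa([s.vertices for s in shapes], allow_scale=True)
    consensus = result.consensus
    mean_size = float(result.centroid_sizes.mean())
    vertices = consensus * (mean_size / centroid_size(consensus))
    return Morph(
        vertices=vertices,
        member_ids=[s.subject_id for s in shapes],
        age=float(np.mean(ages)),
        size=mean_size,
    )


def export_signature_colormap(
    signature: FacialSignature,
    topology: TriangleTopology,
    path,
    display_range: float = 2.0,
) -> None:
    """Write the aligned patient mesh with ``z_normal`` as a scalar channel.

    The PLY gains a per-vertex double property ``signature`` holding the
    signed normal-direction z-score (outward positive).  ``display_range``
    is recorded as a comment-level convention only: viewers should apply a
    symmetric colour scale of +/- ``display_range`` z (default 2), so
    saturated colours mark points outside the +/- 2 SD band.  Masked
    vertices (zero SD) are written as 0.
    """
    z = np.where(signature.mask, np.nan_to_num(signature.z_normal), 0.0)
    if z.shape[0] != topology.n_vertices:
        raise ValidationError("signature does not match topology vertex count")
    write_ply(
        path,
        signature.patient_vertices,
        topology.triangles,
        binary=False,
        vertex_scalars={"signature": z},
    )
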