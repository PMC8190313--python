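"""Similarity alignment: centroid size, ordinary Procrustes, and GPA.

Superimposition removes the nuisance similarity transform (translation,
rotation, optionally isotropic scale) that a camera or scanner imposes,
leaving only shape — and, when scaling is off, size — to be analysed.
Rotations are constrained to be proper (det +1): faces are chiral, so
reflections are never admissible.

Conventions: shapes are ``(k, 3)`` row-vector arrays; a similarity
transform acts as ``y = s * x @ R + t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, DegenerateGeometryError, ValidationError

__all__ = [
    "SimilarityTransform",
    "ProcrustesResult",
    "centroid_size",
    "procrustes_pair",
    "apply_transform",
    "gpa",
]


@dataclass(frozen=True)
class SimilarityTransform:
    """Proper similarity transform ``y = scale * x @ rotation + translation``."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,), mm
    scale: float = 1.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if R.shape != (3, 3):
            raise ValidationError(f"rotation must be 3x3, got {R.shape}")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-8:
            raise ValidationError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValidationError("rotation must be proper (det +1); no reflections")
        if not self.scale > 0:
            raise ValidationError(f"scale must be positive, got {self.scale}")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, vertices: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(vertices, float) @ self.rotation + self.translation


def apply_transform(transform: SimilarityTransform, vertices: np.ndarray) -> np.ndarray:
    return transform.apply(vertices)


def centroid_size(vertices: np.ndarray) -> float:
    """Centroid size: sqrt of summed squared vertex distances from the centroid.

    The standard geometric-morphometrics size measure: invariant to rigid
    motion, linear in isotropic scaling.  All-coincident vertices give 0
    (degenerate; downstream operations reject such shapes).
    """
    v = np.asarray(vertices, dtype=np.float64)
    if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 1:
        raise ValidationError(f"vertices must be (k, 3) with k >= 1, got {v.shape}")
    centred = v - v.mean(axis=0)
    return float(np.sqrt(np.sum(centred**2)))


def procrustes_pair(
    moving: np.ndarray, target: np.ndarray, allow_scale: bool = False
) -> SimilarityTransform:
    """Ordinary Procrustes superimposition of ``moving`` onto ``target``.

    Returns the proper similarity transform minimising the summed squared
    vertex distances to ``target`` (Kabsch/Umeyama via SVD of the
    cross-covariance).  With ``allow_scale=False`` the scale is fixed at 1.
    """
    A = np.asarray(moving, dtype=np.float64)
    B = np.asarray(target, dtype=np.float64)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValidationError(f"shape mismatch {A.shape} vs {B.shape}")
    mu_a, mu_b = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - mu_a, B - mu_b
    H = Ac.T @ Bc
    U, S, Vt = np.linalg.svd(H)
    if S[0] <= 0 or np.sum(S > 1e-12 * S[0]) < 2:
        raise DegenerateGeometryError(
            "point configuration has rank < 2; rotation/reflection ambiguous"
        )
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.array([1.0, 1.0, d])
    R = (U * D) @ Vt
    if allow_scale:
        denom = float(np.sum(Ac**2))
        if denom <= 0:
            raise DegenerateGeometryError("moving shape is a single point")
        s = float(np.sum(S * D)) / denom
        if s <= 0:
            raise DegenerateGeometryError("non-positive optimal scale")
    else:
        s = 1.0
    t = mu_b - s * mu_a @ R
    return SimilarityTransform(rotation=R, translation=t, scale=s)


@dataclass
class ProcrustesResult:
    """Output of generalized Procrustes analysis."""

    aligned: np.ndarray  # (n, k, 3)
    consensus: np.ndarray  # (k, 3), arithmetic mean of aligned shapes
    transforms: list[SimilarityTransform]
    centroid_sizes: np.ndarray  # (n,), original sizes in mm
    iterations: int
    objective_history: np.ndarray  # summed squared distance to consensus per iter


def _rotations_to_consensus(stack: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Vectorised proper Kabsch rotations of each centred shape onto consensus."""
    H = np.einsum("nka,kb->nab", stack, consensus)
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("nab,nbc->nac", U, Vt))
    U = U.copy()
    U[:, :, 2] *= np.sign(det)[:, None]
    return np.einsum("nab,nbc->nac", U, Vt)


def gpa(
    shapes,
    allow_scale: bool = False,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ProcrustesResult:
    """Generalized Procrustes analysis of ``n >= 2`` corresponded shapes.

    Shapes are centred (and, with ``allow_scale``, scaled to unit centroid
    size) and then iteratively rotated onto the evolving consensus — the
    arithmetic mean of the aligned shapes — until the consensus RMS change
    drops below ``tol`` mm.  The alignment objective (summed squared
    distance of aligned shapes to the consensus) is non-increasing across
    iterations.

    With ``allow_scale=True`` every aligned shape has exactly unit centroid
    size; the consensus is then in unit-size shape space rather than mm.
    """
    X = np.asarray([np.asarray(s, dtype=np.float64) for s in shapes])
    if X.ndim != 3 or X.shape[0] < 2 or X.shape[2] != 3:
        raise ValidationError(f"need >= 2 shapes of common (k, 3), got {X.shape}")
    n = X.shape[0]
    centroids = X.mean(axis=1)
    centred = X - centroids[:, None, :]
    sizes = np.sqrt(np.sum(centred**2, axis=(1, 2)))
    if (sizes <= 0).any():
        raise DegenerateGeometryError("a shape has zero centroid size")
    work = centred / sizes[:, None, None] if allow_scale else centred

    rot_acc = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    consensus = work.mean(axis=0)
    objective = []
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        R = _rotations_to_consensus(work, consensus)
        work = np.einsum("nka,nab->nkb", work, R)
        rot_acc = np.einsum("nab,nbc->nac", rot_acc, R)
        new_consensus = work.mean(axis=0)
        objective.append(float(np.sum((work - new_consensus[None]) ** 2)))
        change = float(np.sqrt(np.mean((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"GPA did not converge in {max_iter} iterations "
            f"(last consensus RMS change {change:.3e} >= tol {tol:.1e})"
        )

    transforms = []
    for i in range(n):
        s = 1.0 / sizes[i] if allow_scale else 1.0
        R = rot_acc[i]
        t = -s * centroids[i] @ R
        transforms.append(SimilarityTransform(rotation=R, translation=t, scale=s))
    return ProcrustesResult(
        aligned=work,
        consensus=consensus,
        transforms=transforms,
        centroid_sizes=sizes,
        iterations=iterations,
        objective_history=np.asarray(objective),
    )
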