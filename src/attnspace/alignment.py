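"""Procrustes alignment of point configurations and the stress error measure.

Two MDS configurations are compared by removing the linear indeterminacy of
MDS — translation, rotation, reflection, and optionally uniform scaling — via
the least-squares Procrustes transform, then quantifying the remaining
mismatch with the normalized stress

    stress = sum_{i<j} (d1_ij - d2_ij)^2 / sum_{i<j} (d1_ij - <d1>)^2

where d1 and d2 are within-configuration Euclidean distances and <d1> is the
mean of the first configuration's distances.  Stress is deliberately
asymmetric: the denominator is computed from the first-named configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import orthogonal_procrustes
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .errors import (
    DegenerateConfigurationError,
    DegenerateHullError,
    DomainError,
    UndefinedStressError,
)


@dataclass
class AlignmentResult:
    aligned_config_2: np.ndarray  # Y mapped into X's frame
    rotation: np.ndarray  # orthogonal k x k matrix (may include reflection)
    translation: np.ndarray
    scale: float  # 1.0 when scaling disabled
    stress: float
    d1: np.ndarray  # unique-pair distances of X
    d2: np.ndarray  # unique-pair distances of aligned Y


def stress(X, Y) -> float:
    """Normalized squared distance mismatch of two corresponding configurations."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0] or X.shape[0] < 3:
        raise DomainError("configurations must share >= 3 corresponding points")
    d1 = pdist(X)
    d2 = pdist(Y)
    denom = float(np.sum((d1 - d1.mean()) ** 2))
    if denom <= 1e-12 * float(d1.mean() ** 2):
        raise UndefinedStressError(
            "all reference distances equal: stress undefined"
        )
    return float(np.sum((d1 - d2) ** 2) / denom)


def procrustes_align(X, Y, allow_scaling: bool = True) -> AlignmentResult:
    """Align Y to X by translation + rotation/reflection (+ optional scaling).

    The transform minimizes the summed squared coordinate differences; the
    result records the transform and the stress of (X, aligned Y).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise DomainError("configurations must have identical shapes")
    if X.shape[0] < 3:
        raise DomainError("need >= 3 points")
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mx, Y - my
    norm_y2 = float(np.sum(Yc ** 2))
    if norm_y2 == 0 or float(np.sum(Xc ** 2)) == 0:
        raise DegenerateConfigurationError("all points coincident")
    R, s = orthogonal_procrustes(Yc, Xc)
    scale = float(s / norm_y2) if allow_scaling else 1.0
    aligned = scale * Yc @ R + mx
    translation = mx - scale * my @ R
    d1 = pdist(X)
    d2 = pdist(aligned)
    denom = float(np.sum((d1 - d1.mean()) ** 2))
    if denom <= 1e-12 * float(d1.mean() ** 2):
        raise UndefinedStressError(
            "all reference distances equal: stress undefined"
        )
    return AlignmentResult(
        aligned_config_2=aligned,
        rotation=R,
        translation=translation,
        scale=scale,
        stress=float(np.sum((d1 - d2) ** 2) / denom),
        d1=d1,
        d2=d2,
    )


def convex_hull_summary(points):
    """(hull area, mean distance of hull vertices from the centroid).

    The centroid is that of the full configuration, so the radius summary is
    comparable across conditions sharing a common center.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise DegenerateHullError("need >= 3 planar points")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateHullError("degenerate (collinear) points") from exc
    centroid = pts.mean(axis=0)
    radii = np.linalg.norm(pts[hull.vertices] - centroid, axis=1)
    return float(hull.volume), float(radii.mean())
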