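"""Classical (Torgerson) metric multidimensional scaling.

Double-center the squared distance matrix, B = -1/2 * J D^2 J with J the
centering projector, eigendecompose B, and take coordinates as eigenvectors
scaled by the square root of the top-k non-negative eigenvalues.  Correlation
distances are generally non-Euclidean, so negative eigenvalues can occur;
they are excluded from both the coordinates and the variance normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .geometry import DistanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # (n, k), centered at the origin
    eigenvalues: np.ndarray  # all n eigenvalues of B, sorted descending
    variance_explained_by_dim: np.ndarray  # fractions, positive spectrum only
    stimulus_labels: list


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-|.| component is positive (deterministic)."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def classical_mds(dm, k: int = 2) -> EmbeddingResult:
    """Embed a distance matrix into k dimensions by classical scaling."""
    if isinstance(dm, DistanceMatrix):
        d = dm.values
        labels = list(dm.stimulus_labels)
    else:
        d = np.asarray(dm, dtype=float)
        labels = list(range(d.shape[0]))
        DistanceMatrix(values=d, stimulus_labels=labels)  # validates shape
    n = d.shape[0]
    if not (1 <= k <= n - 1):
        raise DomainError(f"k must be in [1, {n - 1}]")
    d2 = d ** 2
    row = d2.mean(axis=1, keepdims=True)
    col = d2.mean(axis=0, keepdims=True)
    b = -0.5 * (d2 - row - col + d2.mean())
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    pos = eigvals > max(1e-12 * max(eigvals.max(), 0.0), 0.0)
    n_pos = int(pos.sum())
    if n_pos < k:
        logger.warning(
            "only %d positive eigenvalue(s); trailing embedding dimensions "
            "are zero", n_pos,
        )
    use = min(k, n_pos)
    coords = np.zeros((n, k))
    if use > 0:
        coords[:, :use] = _fix_signs(
            eigvecs[:, :use] * np.sqrt(eigvals[:use])
        )
    neg_mass = float(-eigvals[eigvals < 0].sum())
    pos_mass = float(eigvals[eigvals > 0].sum())
    if pos_mass > 0 and neg_mass > 0.05 * pos_mass:
        logger.info(
            "negative eigenvalue mass is %.1f%% of the positive spectrum",
            100.0 * neg_mass / pos_mass,
        )
    if pos_mass > 0:
        var_by_dim = np.maximum(eigvals[:n_pos], 0.0) / pos_mass
    else:
        var_by_dim = np.zeros(0)
    return EmbeddingResult(
        coordinates=coords,
        eigenvalues=eigvals,
        variance_explained_by_dim=var_by_dim,
        stimulus_labels=labels,
    )


def variance_explained(eigenvalues, k: int) -> float:
    """Fraction of positive-spectrum variance captured by the top k dimensions."""
    w = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    pos = w[w > 0]
    if pos.size == 0:
        raise DomainError("no positive eigenvalue: variance undefined")
    return float(pos[:k].sum() / pos.sum())
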