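"""Statistical inference: shuffle-split bootstrap for stress, rank tests,
and the z-test power analysis.

The bootstrap implements the resampling null for the stress between two
attentional conditions: trials of the two conditions are pooled within each
(cell, stimulus) pair, shuffled, and split back into two pseudo-conditions
with the original per-condition trial counts; the full pipeline (gain
re-estimation -> population matrices -> correlation distances -> classical
MDS -> full Procrustes -> stress) is run on each split, and the p-value is
the fraction of resampled stress values strictly greater than the observed
one.  Gains are re-estimated inside every iteration: the population matrices
are gain-scaled passive vectors, so the shuffle can only reach the geometry
through the gains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist

from .errors import DomainError, NoSolutionError

__all__ = [
    "BootstrapResult",
    "PowerSpec",
    "bootstrap_stress_test",
    "shuffle_split_stress_test",
    "rank_sum_test",
    "sign_rank_test",
    "minimal_detectable_effect",
    "power_of_effect",
]


# -- rank tests ---------------------------------------------------------------


def rank_sum_test(sample_a, sample_b) -> float:
    """Two-sided Wilcoxon-Mann-Whitney rank-sum p-value."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("both samples must be non-empty")
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue
    )


def sign_rank_test(paired_differences) -> float:
    """Two-sided Wilcoxon signed-rank p-value; zero differences are dropped.

    All-zero differences are a degenerate comparison and return p = 1 by
    convention.
    """
    d = np.asarray(paired_differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    return float(
        stats.wilcoxon(d, alternative="two-sided", method="auto").pvalue
    )


# -- power analysis -----------------------------------------------------------


@dataclass
class PowerSpec:
    """Two-sided one-sample z-test power specification."""

    n: int = 28  # number of paired distance comparisons, n(n-1)/2 for n=8
    alpha: float = 0.05
    target_power: float = 0.8
    sd: float = 1.0

    def __post_init__(self):
        if self.n < 2:
            raise DomainError("n must be >= 2")
        if not (0 < self.alpha < 1) or not (0 < self.target_power < 1):
            raise DomainError("alpha and target_power must be in (0, 1)")
        if self.sd <= 0:
            raise DomainError("sd must be > 0")


def minimal_detectable_effect(spec: PowerSpec) -> float:
    """Smallest effect reaching the target power, closed form.

    delta = (z_{1-alpha/2} + z_{power}) * sd / sqrt(n), the standard z-test
    sample-size identity (the far rejection tail is negligible at usual
    alpha/power and is ignored, as in the usual sample-size utilities).
    """
    z_a = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_b = stats.norm.ppf(spec.target_power)
    if z_a + z_b <= 0:
        raise NoSolutionError("requested power unreachable for this alpha")
    return float((z_a + z_b) * spec.sd / np.sqrt(spec.n))


def power_of_effect(delta: float, spec: PowerSpec, both_tails: bool = True) -> float:
    """Power of the two-sided z-test at effect ``delta``.

    With ``both_tails=True`` this is the exact rejection probability (at
    delta = 0 it equals alpha).  With ``both_tails=False`` only the dominant
    tail is counted — the approximation underlying the closed-form
    ``minimal_detectable_effect``, which it round-trips exactly.
    """
    z_a = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    u = abs(delta) * np.sqrt(spec.n) / spec.sd
    p = stats.norm.cdf(u - z_a)
    if both_tails:
        p += stats.norm.cdf(-u - z_a)
    return float(p)


# -- fast pipeline kernels for resampling ------------------------------------


def _mds_coords(d: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical-scaling coordinates, lean path used inside the bootstrap."""
    d2 = d ** 2
    row = d2.mean(axis=1, keepdims=True)
    b = -0.5 * (d2 - row - row.T + d2.mean())
    eigvals, eigvecs = np.linalg.eigh(b)
    idx = np.argsort(eigvals)[::-1][:k]
    w = np.maximum(eigvals[idx], 0.0)
    return eigvecs[:, idx] * np.sqrt(w)


def _corr_dist(m: np.ndarray) -> np.ndarray:
    c = np.corrcoef(m, rowvar=False)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


def _scaled_stress(x: np.ndarray, y: np.ndarray) -> float:
    """Normalized stress of (x, Procrustes-aligned y) with scaling enabled."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    norm_y2 = float(np.sum(yc ** 2))
    if norm_y2 == 0:
        return float("inf")
    s = float(np.linalg.svd(yc.T @ xc, compute_uv=False).sum() / norm_y2)
    d1 = pdist(xc)
    d2 = s * pdist(yc)
    denom = float(np.sum((d1 - d1.mean()) ** 2))
    return float(np.sum((d1 - d2) ** 2) / denom)


def _split_stress(x, p8, mean_a, mean_b, k):
    """Gain fit -> matrices -> distances -> MDS -> Procrustes stress."""
    sxx = np.einsum("ij,ij->i", x, x)
    b_a = np.einsum("ij,ij->i", x, mean_a) / sxx
    b_b = np.einsum("ij,ij->i", x, mean_b) / sxx
    ca = _mds_coords(_corr_dist(b_a[:, None] * p8), k)
    cb = _mds_coords(_corr_dist(b_b[:, None] * p8), k)
    return _scaled_stress(ca, cb)


# -- bootstrap ----------------------------------------------------------------


@dataclass
class BootstrapResult:
    observed_stress: float
    null_stresses: np.ndarray
    p_value: float
    n_boot: int
    seed: Optional[int]

    def to_dict(self) -> dict:
        return {
            "observed_stress": self.observed_stress,
            "p_value": self.p_value,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "null_stresses": self.null_stresses.tolist(),
        }


def shuffle_split_stress_test(
    x: np.ndarray,
    p8: np.ndarray,
    trials_a: np.ndarray,
    trials_b: np.ndarray,
    n_boot: int = 10_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    k: int = 2,
) -> BootstrapResult:
    """Shuffle-split bootstrap on pre-extracted per-cell arrays.

    ``x`` (cells x 3) are matched passive condition means, ``p8`` (cells x 8)
    the passive response vectors, and ``trials_a``/``trials_b`` the matched
    attention-task trial rates with layout (cells x 3 stimuli x repetitions).
    The minimum reportable p is 1/n_boot; ties with the observed stress count
    as non-exceeding.
    """
    x = np.asarray(x, dtype=float)
    p8 = np.asarray(p8, dtype=float)
    ta = np.asarray(trials_a, dtype=float)
    tb = np.asarray(trials_b, dtype=float)
    if n_boot < 1:
        raise DomainError("n_boot must be >= 1")
    if ta.ndim != 3 or tb.ndim != 3 or ta.shape[:2] != tb.shape[:2]:
        raise DomainError("trial tensors must be (cells, stimuli, reps)")
    if np.any(np.einsum("ij,ij->i", x, x) == 0):
        raise DomainError("a cell has an all-zero matched passive vector")
    if rng is None:
        rng = np.random.default_rng(seed)

    observed = _split_stress(x, p8, ta.mean(axis=2), tb.mean(axis=2), k)

    r_a = ta.shape[2]
    pool = np.concatenate([ta, tb], axis=2)
    n_tot = pool.shape[2]
    null = np.empty(n_boot)
    for i in range(n_boot):
        idx = np.argsort(rng.random(pool.shape), axis=2)
        shuffled = np.take_along_axis(pool, idx, axis=2)
        null[i] = _split_stress(
            x, p8,
            shuffled[:, :, :r_a].mean(axis=2),
            shuffled[:, :, r_a:n_tot].mean(axis=2),
            k,
        )
    p = float(np.sum(null > observed) / n_boot)
    return BootstrapResult(
        observed_stress=float(observed),
        null_stresses=null,
        p_value=p,
        n_boot=n_boot,
        seed=seed,
    )


def bootstrap_stress_test(
    table_a,
    table_b=None,
    *,
    task_a: str,
    task_b: str,
    area: str,
    decode_space: str,
    n_boot: int = 10_000,
    seed: Optional[int] = None,
    ecc_band=None,
    k: int = 2,
    min_reps: int = 2,
) -> BootstrapResult:
    """Shuffle-split bootstrap on trial tables.

    ``table_a`` must contain the passive baseline and the ``task_a`` trials;
    ``table_b`` (if given and distinct) contributes the ``task_b`` trials and
    is concatenated row-wise.  Trials of the two attention conditions are
    pooled and shuffled within each (cell, stimulus) pair.
    """
    import pandas as pd

    from .pipeline import prepare_condition  # deferred: avoids import cycle

    table = table_a
    if table_b is not None and table_b is not table_a:
        table = pd.concat([table_a, table_b], ignore_index=True)
    cond = prepare_condition(
        table, area=area, decode_space=decode_space,
        ecc_band=ecc_band, min_reps=min_reps,
    )
    return shuffle_split_stress_test(
        cond.x, cond.p8, cond.trials[task_a], cond.trials[task_b],
        n_boot=n_boot, seed=seed, k=k,
    )
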