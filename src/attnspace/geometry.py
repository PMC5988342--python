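"""Population response vectors, correlation distances, and mean distances.

A population response vector is the ordered list of mean firing rates of all
retained cells to one stimulus.  The distance between two stimuli is the
correlation distance d = 1 - r, where r is the Pearson correlation between
the two vectors' elements across cells — correlations between condition
vectors over the population, not between individual neurons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import ATTENTION_TASKS
from .errors import (
    DomainError,
    EmptyPopulationError,
    UndefinedCorrelationError,
)
from .gainmodel import GainEstimate

logger = logging.getLogger(__name__)


@dataclass
class PopulationMatrix:
    """Cells x stimuli matrix of mean rates for one condition."""

    values: np.ndarray  # (n_cells, n_stimuli)
    cell_ids: List[str]
    stimulus_labels: List
    task: str = ""
    decode_space: str = ""
    area: str = ""
    mean_eccentricity: float = float("nan")

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DomainError("population matrix must be 2-D")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise DomainError("population matrix entries must be finite and >= 0")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[1]


@dataclass
class DistanceMatrix:
    """Symmetric hollow matrix of correlation distances between stimuli."""

    values: np.ndarray
    stimulus_labels: List

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DomainError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DomainError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise DomainError("distance matrix must be hollow")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def unique_distances(self) -> np.ndarray:
        """The n(n-1)/2 upper-triangle distances."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.stimulus_labels, columns=self.stimulus_labels
        )


def correlation_distance(u, v) -> float:
    """d = 1 - Pearson r between two population response vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or u.size < 3:
        raise DomainError("need matched vectors of length >= 3")
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        raise UndefinedCorrelationError("constant vector: correlation undefined")
    r = float(np.corrcoef(u, v)[0, 1])
    return float(np.clip(1.0 - r, 0.0, 2.0))


def distance_matrix(pm: PopulationMatrix) -> DistanceMatrix:
    """All pairwise correlation distances between the stimulus columns."""
    if pm.n_cells < 3:
        raise DomainError("need >= 3 cells to correlate population vectors")
    cols = pm.values
    if np.any(np.ptp(cols, axis=0) == 0):
        raise UndefinedCorrelationError(
            "a stimulus column is constant across cells"
        )
    corr = np.corrcoef(cols, rowvar=False)
    d = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(values=d, stimulus_labels=list(pm.stimulus_labels))


def mean_distance(dm: DistanceMatrix):
    """Mean and standard error of the unique off-diagonal distances."""
    if dm.n < 2:
        raise DomainError("need >= 2 stimuli")
    vals = dm.unique_distances()
    se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return float(vals.mean()), se


def percent_change(a: float, b: float) -> float:
    """100 * (a - b) / b; positive when the first condition is larger."""
    if b == 0:
        raise DomainError("zero baseline mean distance")
    return 100.0 * (a - b) / b


def build_population_matrix(
    passive_means: pd.DataFrame,
    gains: Optional[Sequence[GainEstimate]],
    *,
    task: str,
    decode_space: str,
    area: str = "",
    eccentricities: Optional[pd.Series] = None,
    ecc_band: Optional[tuple] = None,
) -> PopulationMatrix:
    """Assemble the cells x 8 matrix for one condition.

    ``passive_means`` is a cells x stimuli DataFrame of passive condition
    means (index: cell_id, columns: stimulus labels).  For an attention task
    each cell's row is its passive 8-vector scaled by that cell's fitted
    (task, decode-space) gain; for the passive condition gains are implicitly
    one.  Cells outside the (inclusive) eccentricity band, cells without a
    gain estimate, and cells whose row is constant across all stimuli are
    excluded; stimulus eccentricities of retained cells are summarized by
    their mean, mirroring the analysis convention of treating all stimuli as
    if at the population-average eccentricity.
    """
    pm = passive_means.copy()
    if ecc_band is not None:
        if eccentricities is None:
            raise DomainError("ecc_band given without per-cell eccentricities")
        lo, hi = ecc_band
        keep = eccentricities[(eccentricities >= lo) & (eccentricities <= hi)]
        pm = pm.loc[pm.index.intersection(keep.index)]
    if task in ATTENTION_TASKS:
        if gains is None:
            raise DomainError(f"gains required for attention task {task!r}")
        gmap = {
            g.cell_id: g.gain
            for g in gains
            if g.task == task and g.decode_space == decode_space
        }
        pm = pm.loc[[c for c in pm.index if c in gmap]]
        scale = np.array([gmap[c] for c in pm.index])
    else:
        scale = np.ones(len(pm))
    values = pm.to_numpy() * scale[:, None]
    flat = np.ptp(values, axis=1) == 0
    if flat.any():
        logger.warning(
            "dropping %d cell(s) with constant response vectors (%s, %s, %s)",
            int(flat.sum()), area, decode_space, task,
        )
        values = values[~flat]
        pm = pm.loc[~flat]
    if len(pm) == 0:
        raise EmptyPopulationError(
            f"no cells retained for ({area}, {decode_space}, {task})"
        )
    mean_ecc = (
        float(eccentricities.loc[pm.index].mean())
        if eccentricities is not None else float("nan")
    )
    return PopulationMatrix(
        values=values,
        cell_ids=list(pm.index),
        stimulus_labels=list(pm.columns),
        task=task,
        decode_space=decode_space,
        area=area,
        mean_eccentricity=mean_ecc,
    )
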