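"""Attentional gain factors: through-origin regression and rescaling.

A cell's attentional gain factor for a task is the slope of the least-squares
regression, constrained through the origin, of its attention-task responses
on its passive-task responses to the same stimuli:

    b = sum(x_i * y_i) / sum(x_i ** 2)

with ``x`` the passive and ``y`` the attention condition means.  Multiplying
a cell's eight passive responses by the fitted gain yields its estimated
attention-condition responses for stimuli never shown in the attention task.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List

import numpy as np
import pandas as pd

from .config import ATTENTION_TASKS
from .errors import DegenerateFitError, DomainError
from .inference import sign_rank_test


@dataclass(frozen=True)
class GainEstimate:
    cell_id: str
    area: str
    task: str
    decode_space: str
    gain: float
    n_points: int


def fit_gain(attention_responses, passive_responses, *, cell_id="",
             area="", task="", decode_space="") -> GainEstimate:
    """Least-squares slope through the origin of attention on passive rates."""
    y = np.asarray(attention_responses, dtype=float)
    x = np.asarray(passive_responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise DomainError("need matched 1-D response vectors of length >= 2")
    if np.any(x < 0) or np.any(y < 0):
        raise DomainError("firing rates must be non-negative")
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise DegenerateFitError("all-zero passive responses: gain undefined")
    b = float(np.dot(x, y) / sxx)
    return GainEstimate(cell_id=cell_id, area=area, task=task,
                        decode_space=decode_space, gain=b, n_points=x.size)


def apply_gain(passive_8, g: GainEstimate | float) -> np.ndarray:
    """Scale a passive 8-stimulus response vector by a fitted gain."""
    gain = g.gain if isinstance(g, GainEstimate) else float(g)
    return np.asarray(passive_8, dtype=float) * gain


def gain_histogram_summary(estimates: Iterable[GainEstimate]) -> Dict:
    """Per (area, decode-space) gain summaries and the between-task paired test.

    Returns a nested dict: area -> decode_space -> {task: {mean, median, n},
    'paired_p': two-sided Wilcoxon signed-rank p between the two attention
    tasks over cells present in both}.
    """
    rows = [
        (e.area, e.decode_space, e.task, e.cell_id, e.gain) for e in estimates
    ]
    if not rows:
        raise DomainError("no gain estimates to summarize")
    df = pd.DataFrame(
        rows, columns=["area", "decode_space", "task", "cell_id", "gain"]
    )
    out: Dict = {}
    for (area, space), grp in df.groupby(["area", "decode_space"], sort=True):
        entry = {}
        for task, tgrp in grp.groupby("task", sort=True):
            if len(tgrp) < 2:
                raise DomainError(
                    f"need >= 2 estimates for ({area}, {space}, {task})"
                )
            entry[task] = {
                "mean": float(tgrp["gain"].mean()),
                "median": float(tgrp["gain"].median()),
                "n": int(len(tgrp)),
            }
        wide = grp.pivot_table(index="cell_id", columns="task", values="gain")
        if all(t in wide.columns for t in ATTENTION_TASKS):
            paired = wide.dropna()
            diffs = (
                paired[ATTENTION_TASKS[0]] - paired[ATTENTION_TASKS[1]]
            ).to_numpy()
            entry["paired_p"] = sign_rank_test(diffs)
        out.setdefault(area, {})[space] = entry
    return out


def gains_to_frame(estimates: List[GainEstimate]) -> pd.DataFrame:
    """Gains as a flat table (cell_id, area, task, decode_space, gain, n_points)."""
    return pd.DataFrame([e.__dict__ for e in estimates])
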