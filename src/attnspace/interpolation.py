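"""Periodic spline interpolation of location tuning along the stimulus ring.

The passive-location task samples eight polar angles at constant eccentricity;
the attention tasks use three angles that generally fall between those grid
points (matched in eccentricity).  Passive responses at the active angles are
estimated with a cubic spline with periodic boundary conditions — the natural
choice on a circular domain — and clamped at zero from below because firing
rates cannot be negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import DegenerateGridError, DomainError


@dataclass
class AngularTuning:
    """One cell's passive responses around the iso-eccentric ring."""

    polar_angles: np.ndarray  # degrees, canonicalized to [0, 360)
    responses: np.ndarray  # spikes/s, non-negative
    eccentricity: float = 0.0

    def __post_init__(self):
        angles = np.asarray(self.polar_angles, dtype=float) % 360.0
        responses = np.asarray(self.responses, dtype=float)
        if angles.shape != responses.shape or angles.ndim != 1:
            raise DomainError("angles and responses must be matched 1-D arrays")
        if np.any(responses < 0):
            raise DomainError("responses must be non-negative")
        order = np.argsort(angles, kind="stable")
        angles = angles[order]
        if np.any(np.diff(angles) == 0):
            raise DegenerateGridError("duplicate sample angles")
        self.polar_angles = angles
        self.responses = responses[order]


def interpolate_passive(tuning: AngularTuning, target_angles) -> np.ndarray:
    """Periodic cubic-spline estimate of passive rates at the target angles."""
    t = np.asarray(target_angles, dtype=float)
    if not np.all(np.isfinite(t)):
        raise DomainError("target angles must be finite")
    x = np.append(tuning.polar_angles, tuning.polar_angles[0] + 360.0)
    y = np.append(tuning.responses, tuning.responses[0])
    spline = CubicSpline(x, y, bc_type="periodic")
    # map targets into the knot span [x0, x0 + 360)
    t_span = x[0] + (t - x[0]) % 360.0
    return np.maximum(spline(t_span), 0.0)


def nearest_grid_shift(passive_angles, active_angles) -> np.ndarray:
    """Absolute angular distance of each active angle to its nearest grid angle."""
    p = np.asarray(passive_angles, dtype=float) % 360.0
    a = np.asarray(active_angles, dtype=float) % 360.0
    diff = np.abs((a[:, None] - p[None, :] + 180.0) % 360.0 - 180.0)
    return diff.min(axis=1)


def angular_shift_report(
    passive_angles,
    active_angles_by_cell: Mapping[str, np.ndarray],
    area_by_cell: Mapping[str, str],
) -> Dict[str, Dict[str, float]]:
    """Per-area mean/median absolute polar shift incurred by interpolation."""
    if not active_angles_by_cell:
        raise DomainError("at least one cell is required")
    shifts: Dict[str, list] = {}
    for cell_id, angles in active_angles_by_cell.items():
        area = area_by_cell[cell_id]
        shifts.setdefault(area, []).extend(
            nearest_grid_shift(passive_angles, angles).tolist()
        )
    return {
        area: {
            "mean_deg": float(np.mean(vals)),
            "median_deg": float(np.median(vals)),
            "n_angles": len(vals),
        }
        for area, vals in sorted(shifts.items())
    }
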