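"""Synthetic two-area neural populations with attentional gain and warp.

The generator emulates a delayed match-to-sample recording session: every
simulated cell is tested in two attention tasks (attend shape / attend
location; 3 shapes x 3 locations, many repetitions, plus catch trials) and
two passive tasks (8 shapes at the best location; 8 iso-eccentric locations
with the best shape).  Spatial tuning is von Mises in polar angle, shape
tuning is i.i.d. lognormal over the 8 shapes, attention acts as a per-cell
multiplicative engagement gain with optional warping mechanisms (per-stimulus
gain heterogeneity, or attention-dependent tuning shifts), and trial noise is
Poisson on spike counts in a fixed window.

Why engagement gains: an attention trial has a single firing rate, yet each
attention task carries two measurable gain factors — one against each passive
baseline.  The generator therefore draws one engagement factor per task
(passive-shape = 1, passive-location = 1/rho) and the four ground-truth
(task, decode-space) gains per cell are the implied ratios: the shape-decode
gains equal the attention engagements, the location-decode gains equal
engagement x rho.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import (
    ALL_TASKS,
    ATTENTION_TASKS,
    LOCATION,
    LOCATION_ATTENTION,
    PASSIVE_LOCATION,
    PASSIVE_SHAPE,
    SHAPE,
    SHAPE_ATTENTION,
    SimConfig,
)
from .errors import DomainError, LabelError

TRIAL_COLUMNS = [
    "cell_id",
    "area",
    "task",
    "shape_id",
    "polar_angle_deg",
    "eccentricity_deg",
    "rep",
    "rate_hz",
    "is_catch",
]


@dataclass
class CellGroundTruth:
    """Generator-side parameters of one simulated cell."""

    cell_id: str
    area: str
    preferred_angle: float  # degrees in [0, 360)
    location_kappa: float
    eccentricity: float  # degrees of visual angle
    shape_rates: np.ndarray  # baseline rate per shape at the preferred location
    gains: Dict[Tuple[str, str], float]  # (task, decode_space) -> multiplier
    engagement: Dict[str, float]  # task -> engagement factor
    shift: float = 0.0  # attentional tuning displacement, degrees
    shape_blend: float = 0.0  # attention-to-shape blending weight in [0, 1]
    active_shapes: Tuple[int, int, int] = (0, 1, 2)
    active_angles: Tuple[float, float, float] = (0.0, 120.0, 240.0)
    passive_angle: float = 0.0  # single location of the passive-shape task
    best_shape: int = 0  # single shape of the passive-location task
    gain_jitter: Optional[Dict[str, np.ndarray]] = field(default=None)

    def __post_init__(self):
        self.shape_rates = np.asarray(self.shape_rates, dtype=float)
        if np.any(self.shape_rates < 0):
            raise DomainError("shape_rates must be non-negative")
        if any(g <= 0 for g in self.gains.values()):
            raise DomainError("gains must be strictly positive")
        self.preferred_angle = float(self.preferred_angle) % 360.0

    @property
    def peak_rate(self) -> float:
        return float(self.shape_rates.max())

    def gain(self, task: str, decode_space: str) -> float:
        try:
            return self.gains[(task, decode_space)]
        except KeyError as exc:
            raise LabelError(f"no gain for ({task}, {decode_space})") from exc


# -- tuning primitives --------------------------------------------------------


def _wrap_deg(delta):
    """Wrap angular differences to (-180, 180] degrees."""
    return (np.asarray(delta, dtype=float) + 180.0) % 360.0 - 180.0


def _vm_profile(angle_deg, preferred_deg, kappa):
    """Peak-normalized von Mises profile exp(kappa * (cos(delta) - 1))."""
    delta = np.deg2rad(np.asarray(angle_deg, dtype=float) - preferred_deg)
    return np.exp(kappa * (np.cos(delta) - 1.0))


def _shifted_preferred(preferred_deg, attended_deg, shift_deg):
    """Preferred angle moved toward the attended angle by shift_deg, clamped."""
    delta = _wrap_deg(np.asarray(attended_deg, dtype=float) - preferred_deg)
    step = np.sign(delta) * np.minimum(np.abs(delta), shift_deg)
    return preferred_deg + step


def location_tuning(cell: CellGroundTruth, polar_angle, task: str):
    """Mean firing rate of ``cell`` at a polar angle under ``task``.

    The profile is von Mises, normalized so the peak equals the cell's peak
    rate.  During the location-attention task a nonzero ``cell.shift`` moves
    the preferred angle toward the attended (= presented) location.
    """
    if task not in ALL_TASKS:
        raise LabelError(f"unknown task {task!r}")
    polar_angle = np.asarray(polar_angle, dtype=float)
    if not np.all(np.isfinite(polar_angle)):
        raise DomainError("polar angle must be finite")
    pref = cell.preferred_angle
    if task == LOCATION_ATTENTION and cell.shift != 0.0:
        pref = _shifted_preferred(pref, polar_angle, cell.shift)
    return cell.peak_rate * _vm_profile(polar_angle, pref, cell.location_kappa)


def apply_attention(rate, cell: CellGroundTruth, task: str, decode_space: str,
                    condition_index: Optional[int] = None):
    """Scale a passive rate by the cell's (task, decode-space) gain.

    When the cell carries per-stimulus gain jitter (``warp_mode`` including
    gain heterogeneity) and a condition index is given, the jitter drawn once
    at simulation time is applied on top of the scalar gain.
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise DomainError("rate must be >= 0")
    if task not in ALL_TASKS:
        raise LabelError(f"unknown task {task!r}")
    if task in (PASSIVE_SHAPE, PASSIVE_LOCATION):
        return rate
    out = rate * cell.gain(task, decode_space)
    if cell.gain_jitter is not None and condition_index is not None:
        out = out * cell.gain_jitter[task][condition_index]
    return out


def sample_trials(mean_rate: float, n_reps: int, window: float,
                  rng: np.random.Generator):
    """Poisson trial rates: counts ~ Poisson(mean * window), rate = count/window."""
    if mean_rate < 0:
        raise DomainError("mean_rate must be >= 0")
    if window <= 0:
        raise DomainError("window must be > 0")
    counts = rng.poisson(mean_rate * window, size=int(n_reps))
    return counts / window


def select_active_stimuli(passive_shape_rates, passive_location_rates,
                          location_angles=None):
    """Choose the per-cell active subsets the way the experimenter would.

    Shapes: the two strongest responses plus the weakest (ties broken toward
    the lowest index; the weakest is chosen among shapes not already picked,
    so three distinct shapes always result).  Locations: the best passive
    angle plus +/-120 degrees, wrapped to [0, 360).
    """
    f = np.asarray(passive_shape_rates, dtype=float)
    h = np.asarray(passive_location_rates, dtype=float)
    order = np.argsort(-f, kind="stable")
    top2 = sorted(int(i) for i in order[:2])
    remaining = [i for i in range(f.size) if i not in top2]
    weakest = int(min(remaining, key=lambda i: (f[i], i)))
    shapes = tuple(sorted(top2 + [weakest]))
    if location_angles is None:
        location_angles = np.arange(h.size) * (360.0 / h.size)
    best = float(np.asarray(location_angles, dtype=float)[int(np.argmax(h))])
    angles = tuple(sorted(((best + off) % 360.0) for off in (0.0, 120.0, -120.0)))
    return shapes, angles


# -- session simulation -------------------------------------------------------


def _draw_cells(cfg: SimConfig, area: str, rng: np.random.Generator):
    n = cfg.n_cells_per_area[area]
    conc = cfg.preferred_angle_concentration[area]
    if conc > 0:
        center = np.deg2rad(cfg.preferred_angle_center[area])
        pref = np.rad2deg(rng.vonmises(center, conc, n)) % 360.0
    else:
        pref = rng.uniform(0.0, 360.0, n)
    lo, hi = cfg.eccentricity_bands[area]
    ecc = rng.uniform(lo, hi, n)
    shape_rates = cfg.base_rate * np.exp(
        rng.normal(0.0, cfg.shape_lognormal_sigma, (n, cfg.n_shapes))
    )
    gains = {}
    for task in ATTENTION_TASKS:
        mu, sd = cfg.gain_log_mean_sd[area][task]
        gains[task] = np.exp(rng.normal(mu, sd, n))
    if cfg.shared_task_gains:
        gains[ATTENTION_TASKS[1]] = gains[ATTENTION_TASKS[0]].copy()
    mu_r, sd_r = cfg.passive_offset_log_mean_sd[area]
    rho = np.exp(rng.normal(mu_r, sd_r, n))
    mode = cfg.warp_mode[area]
    mag = cfg.warp_magnitude[area]
    jitter = None
    if mode in ("gain_heterogeneity", "both") and mag > 0:
        jitter = {
            task: np.exp(rng.normal(0.0, mag, (n, 9))) for task in ATTENTION_TASKS
        }
    return pref, ecc, shape_rates, gains, rho, jitter


def simulate_population(cfg: SimConfig):
    """Simulate a full session.

    Returns a long-format trial table (one row per trial) covering the two
    attention tasks and the two passive tasks for every cell, plus the list
    of per-cell ground-truth records.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.location_angles
    n_catch_per_cond = int(round(
        cfg.catch_fraction / (1.0 - cfg.catch_fraction) * cfg.reps_attention
    )) if cfg.catch_fraction > 0 else 0

    frames: List[pd.DataFrame] = []
    ground_truth: List[CellGroundTruth] = []

    for area in cfg.areas:
        pref, ecc, shape_rates, g_att, rho, jitter = _draw_cells(cfg, area, rng)
        n = cfg.n_cells_per_area[area]
        kappa = cfg.location_kappa_by_area[area]
        shift_deg = cfg.shift_degrees(area)
        mode = cfg.warp_mode[area]
        blend = (
            min(cfg.warp_magnitude[area], 1.0)
            if mode in ("tuning_shift", "both")
            else 0.0
        )
        cell_ids = np.array([f"{area}_{i:03d}" for i in range(n)])

        # stimulus selection from the noiseless tuning surface
        vm_grid = _vm_profile(grid[None, :], pref[:, None], kappa)  # (n, L)
        best_loc_idx = np.argmax(vm_grid, axis=1)
        theta0 = grid[best_loc_idx]
        active_shapes = np.empty((n, 3), dtype=int)
        active_angles = np.empty((n, 3), dtype=float)
        best_shape = np.empty(n, dtype=int)
        for c in range(n):
            shapes, angles = select_active_stimuli(
                shape_rates[c], vm_grid[c], grid
            )
            active_shapes[c] = shapes
            active_angles[c] = angles
            best_shape[c] = int(np.argmax(shape_rates[c]))

        engagement = {
            SHAPE_ATTENTION: g_att[SHAPE_ATTENTION],
            LOCATION_ATTENTION: g_att[LOCATION_ATTENTION],
            PASSIVE_SHAPE: np.ones(n),
            PASSIVE_LOCATION: 1.0 / rho,
        }

        # --- per-task condition mean rates, (n_cells, n_conditions) ---------
        def attention_means(task):
            f = shape_rates[np.arange(n)[:, None], active_shapes]  # (n, 3)
            if task == SHAPE_ATTENTION and blend > 0:
                fmax = shape_rates.max(axis=1, keepdims=True)
                f = (1.0 - blend) * f + blend * fmax
            if task == LOCATION_ATTENTION and shift_deg > 0:
                pref_eff = _shifted_preferred(
                    pref[:, None], active_angles, shift_deg
                )
                vm = np.exp(
                    kappa
                    * (np.cos(np.deg2rad(active_angles - pref_eff)) - 1.0)
                )
            else:
                vm = _vm_profile(active_angles, pref[:, None], kappa)  # (n, 3)
            means = (
                engagement[task][:, None, None] * f[:, :, None] * vm[:, None, :]
            ).reshape(n, 9)  # shape-major condition order
            if jitter is not None:
                means = means * jitter[task]
            return means

        task_conditions = {}
        for task in ATTENTION_TASKS:
            means = attention_means(task)
            cond_shape = np.repeat(active_shapes, 3, axis=1)  # (n, 9)
            cond_angle = np.tile(active_angles, (1, 3))
            task_conditions[task] = (means, cond_shape, cond_angle,
                                     cfg.reps_attention, n_catch_per_cond)

        ps_means = shape_rates * _vm_profile(theta0, pref, kappa)[:, None]
        task_conditions[PASSIVE_SHAPE] = (
            ps_means,
            np.tile(np.arange(cfg.n_shapes), (n, 1)),
            np.tile(theta0[:, None], (1, cfg.n_shapes)),
            cfg.reps_passive_shape,
            0,
        )
        pl_means = (
            engagement[PASSIVE_LOCATION][:, None]
            * shape_rates[np.arange(n), best_shape][:, None]
            * vm_grid
        )
        task_conditions[PASSIVE_LOCATION] = (
            pl_means,
            np.tile(best_shape[:, None], (1, cfg.n_locations)),
            np.tile(grid, (n, 1)),
            cfg.reps_passive_location,
            0,
        )

        # --- expand to trials, in a fixed task order for determinism --------
        for task in ALL_TASKS:
            means, cond_shape, cond_angle, reps, n_catch = task_conditions[task]
            n_cond = means.shape[1]
            total_reps = reps + n_catch
            if cfg.trial_noise:
                counts = rng.poisson(
                    means[:, :, None] * cfg.window_s, size=(n, n_cond, total_reps)
                )
                rates = counts / cfg.window_s
            else:
                rates = np.broadcast_to(
                    means[:, :, None], (n, n_cond, total_reps)
                ).copy()
            rep_idx = np.broadcast_to(
                np.arange(total_reps), (n, n_cond, total_reps)
            )
            is_catch = rep_idx >= reps
            frames.append(pd.DataFrame({
                "cell_id": np.repeat(cell_ids, n_cond * total_reps),
                "area": area,
                "task": task,
                "shape_id": np.repeat(cond_shape, total_reps).astype(int),
                "polar_angle_deg": np.repeat(cond_angle, total_reps),
                "eccentricity_deg": np.repeat(ecc, n_cond * total_reps),
                "rep": rep_idx.ravel(),
                "rate_hz": rates.ravel(),
                "is_catch": is_catch.ravel(),
            }))

        for c in range(n):
            cell_gains = {
                (SHAPE_ATTENTION, SHAPE): float(g_att[SHAPE_ATTENTION][c]),
                (LOCATION_ATTENTION, SHAPE): float(g_att[LOCATION_ATTENTION][c]),
                (SHAPE_ATTENTION, LOCATION): float(
                    g_att[SHAPE_ATTENTION][c] * rho[c]
                ),
                (LOCATION_ATTENTION, LOCATION): float(
                    g_att[LOCATION_ATTENTION][c] * rho[c]
                ),
            }
            ground_truth.append(CellGroundTruth(
                cell_id=str(cell_ids[c]),
                area=area,
                preferred_angle=float(pref[c]),
                location_kappa=float(kappa),
                eccentricity=float(ecc[c]),
                shape_rates=shape_rates[c].copy(),
                gains=cell_gains,
                engagement={t: float(engagement[t][c]) for t in ALL_TASKS},
                shift=float(shift_deg),
                shape_blend=float(blend),
                active_shapes=tuple(int(s) for s in active_shapes[c]),
                active_angles=tuple(float(a) for a in active_angles[c]),
                passive_angle=float(theta0[c]),
                best_shape=int(best_shape[c]),
                gain_jitter=(
                    {t: jitter[t][c].copy() for t in ATTENTION_TASKS}
                    if jitter is not None else None
                ),
            ))

    table = pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]
    return table, ground_truth


# -- IO -----------------------------------------------------------------------


def write_trial_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"trial table missing columns: {missing}")
    return df


def write_ground_truth(cells: List[CellGroundTruth], path) -> None:
    records = []
    for c in cells:
        records.append({
            "cell_id": c.cell_id,
            "area": c.area,
            "preferred_angle": c.preferred_angle,
            "location_kappa": c.location_kappa,
            "eccentricity": c.eccentricity,
            "shape_rates": c.shape_rates.tolist(),
            "gains": {f"{t}|{s}": g for (t, s), g in c.gains.items()},
            "engagement": c.engagement,
            "shift": c.shift,
            "shape_blend": c.shape_blend,
            "active_shapes": list(c.active_shapes),
            "active_angles": list(c.active_angles),
            "passive_angle": c.passive_angle,
            "best_shape": c.best_shape,
        })
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1, sort_keys=True)


def read_ground_truth(path) -> List[CellGroundTruth]:
    with open(path) as fh:
        records = json.load(fh)
    cells = []
    for r in records:
        gains = {}
        for key, g in r["gains"].items():
            task, space = key.split("|")
            gains[(task, space)] = g
        cells.append(CellGroundTruth(
            cell_id=r["cell_id"],
            area=r["area"],
            preferred_angle=r["preferred_angle"],
            location_kappa=r["location_kappa"],
            eccentricity=r["eccentricity"],
            shape_rates=np.asarray(r["shape_rates"]),
            gains=gains,
            engagement=r["engagement"],
            shift=r["shift"],
            shape_blend=r["shape_blend"],
            active_shapes=tuple(r["active_shapes"]),
            active_angles=tuple(r["active_angles"]),
            passive_angle=r["passive_angle"],
            best_shape=r["best_shape"],
        ))
    return cells
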