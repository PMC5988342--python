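"""End-to-end analysis: trial table -> gains -> geometry -> stress report.

For each brain area and each decode space (shape / location) the pipeline

1. estimates per-cell attentional gain factors for both attention tasks by
   through-origin regression on the three stimuli shared with the passive
   task (for location decode, passive responses at the active angles are
   first estimated by periodic spline interpolation along the ring);
2. scales each cell's eight passive responses by its gain to obtain the
   attention-condition population matrices;
3. computes correlation-distance matrices, mean response distances, and
   percent changes between tasks with rank-sum p-values;
4. embeds each condition by classical MDS, aligns condition pairs by
   Procrustes (with and without scaling), summarizes convex hulls, and
   quantifies residual warping by stress with a shuffle-split bootstrap p;
5. for the location space, compares each MDS map against the physical
   stimulus ring (stress vs physical locations).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .alignment import convex_hull_summary, procrustes_align
from .config import (
    ALL_TASKS,
    ATTENTION_TASKS,
    AnalysisConfig,
    DECODE_SPACES,
    LOCATION,
    PASSIVE_FOR_SPACE,
    SHAPE,
    config_hash,
)
from .embedding import classical_mds, variance_explained
from .errors import (
    DomainError,
    InsufficientTrialsError,
    ValidationError,
)
from .gainmodel import GainEstimate, gain_histogram_summary
from .geometry import (
    build_population_matrix,
    distance_matrix,
    mean_distance,
    percent_change,
)
from .inference import rank_sum_test, shuffle_split_stress_test
from .interpolation import (
    AngularTuning,
    angular_shift_report,
    interpolate_passive,
    nearest_grid_shift,
)
from .syndata import select_active_stimuli  # noqa: F401  (pipeline-level API)

logger = logging.getLogger(__name__)

_PAIRS: Tuple[Tuple[str, str], ...] = (
    ("shape_attention", "location_attention"),
    ("shape_attention", "passive"),
    ("location_attention", "passive"),
)


@dataclass
class ConditionData:
    """Per-(area, decode-space) arrays extracted from a trial table."""

    area: str
    decode_space: str
    passive_task: str
    cell_ids: List[str]
    stimulus_labels: List  # the 8 passive stimuli (shape ids or angles)
    p8: np.ndarray  # (cells, 8) passive condition means
    x: np.ndarray  # (cells, 3) matched passive means (interpolated for location)
    matched_stimuli: np.ndarray  # (cells, 3) matched stimulus labels per cell
    trials: Dict[str, np.ndarray]  # task -> (cells, 3, reps) matched trial rates
    eccentricities: pd.Series
    active_angles_by_cell: Dict[str, np.ndarray] = field(default_factory=dict)
    n_excluded_zero_passive: int = 0
    n_excluded_ecc: int = 0

    @property
    def passive_means(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.p8, index=self.cell_ids, columns=self.stimulus_labels
        )


def _stim_column(decode_space: str) -> str:
    return "shape_id" if decode_space == SHAPE else "polar_angle_deg"


def _trial_tensor(sub: pd.DataFrame, cells: List[str], stim_by_cell: Dict,
                  stim_col: str, min_reps: int) -> np.ndarray:
    """Stack matched trials into (cells, 3, reps), truncating ragged counts."""
    sub = sub.sort_values(["cell_id", stim_col, "rep"], kind="stable")
    counts = sub.groupby(["cell_id", stim_col], sort=True).size()
    if counts.min() < max(min_reps, 1):
        raise InsufficientTrialsError(
            f"fewer than {min_reps} trials in a (cell, stimulus) pair"
        )
    r = int(counts.min())
    if counts.nunique() > 1:
        keep = sub.groupby(["cell_id", stim_col], sort=False).cumcount() < r
        sub = sub[keep]
    tensor = np.full((len(cells), 3, r), np.nan)
    rates = sub["rate_hz"].to_numpy()
    pos = 0
    index = {c: i for i, c in enumerate(cells)}
    for cell, stim in counts.index:
        i = index[cell]
        j = int(np.searchsorted(stim_by_cell[cell], stim))
        tensor[i, j, :] = rates[pos:pos + r]
        pos += r
    if np.isnan(tensor).any():
        raise InsufficientTrialsError("missing (cell, stimulus) trial groups")
    return tensor


def prepare_condition(
    table: pd.DataFrame,
    *,
    area: str,
    decode_space: str,
    ecc_band: Optional[tuple] = None,
    min_reps: int = 2,
) -> ConditionData:
    """Extract the per-cell arrays one decode space needs from a trial table.

    Catch trials are excluded up front.  Cells are dropped (and counted) when
    they fall outside the eccentricity band or their matched passive vector
    is all zero (gain undefined).
    """
    if decode_space not in DECODE_SPACES:
        raise ValidationError(f"unknown decode space {decode_space!r}")
    passive_task = PASSIVE_FOR_SPACE[decode_space]
    df = table[(table["area"] == area) & (~table["is_catch"])]
    if df.empty:
        raise ValidationError(f"no trials for area {area!r}")
    present = set(df["task"].unique())
    if passive_task not in present:
        raise ValidationError(f"missing task {passive_task!r} for area {area!r}")
    att_tasks = [t for t in ATTENTION_TASKS if t in present]
    if not att_tasks:
        raise ValidationError(f"no attention-task trials for area {area!r}")

    stim_col = _stim_column(decode_space)
    passive = df[df["task"] == passive_task]
    p8_frame = (
        passive.groupby(["cell_id", stim_col], sort=True)["rate_hz"]
        .mean().unstack()
    )
    att = df[df["task"].isin(att_tasks)]
    # the held-fixed stimulus of the passive task, per cell
    if decode_space == SHAPE:
        fixed = passive.groupby("cell_id", sort=True)["polar_angle_deg"].first()
        match_col = "polar_angle_deg"
    else:
        fixed = passive.groupby("cell_id", sort=True)["shape_id"].first()
        match_col = "shape_id"

    cells = sorted(set(p8_frame.index) & set(att["cell_id"].unique()))
    ecc = (
        df.groupby("cell_id", sort=True)["eccentricity_deg"].first().loc[cells]
    )
    n_excluded_ecc = 0
    if ecc_band is not None:
        lo, hi = ecc_band
        inside = ecc[(ecc >= lo) & (ecc <= hi)].index
        n_excluded_ecc = len(cells) - len(inside)
        cells = [c for c in cells if c in set(inside)]
    if not cells:
        raise ValidationError(f"no cells retained for ({area}, {decode_space})")

    # matched attention stimuli per cell, sorted ascending
    stim_by_cell: Dict[str, np.ndarray] = {}
    matched_att = []
    for cell, grp in att.groupby("cell_id", sort=True):
        if cell not in set(cells):
            continue
        if decode_space == SHAPE:
            rows = grp[np.isclose(grp["polar_angle_deg"], fixed[cell])]
        else:
            rows = grp[grp["shape_id"] == fixed[cell]]
        stims = np.sort(rows[stim_col].unique())
        if stims.size != 3:
            raise ValidationError(
                f"cell {cell}: expected 3 matched attention stimuli, "
                f"found {stims.size}"
            )
        stim_by_cell[cell] = stims
        matched_att.append(rows)
    matched_att = pd.concat(matched_att, ignore_index=True)

    p8 = p8_frame.loc[cells].to_numpy()
    labels = list(p8_frame.columns)
    matched_stimuli = np.vstack([stim_by_cell[c] for c in cells])

    active_angles_by_cell: Dict[str, np.ndarray] = {}
    if decode_space == SHAPE:
        col_index = {s: j for j, s in enumerate(labels)}
        x = np.vstack([
            p8[i, [col_index[s] for s in stim_by_cell[c]]]
            for i, c in enumerate(cells)
        ])
    else:
        grid = np.asarray(labels, dtype=float)
        x = np.empty((len(cells), 3))
        for i, c in enumerate(cells):
            tuning = AngularTuning(
                polar_angles=grid, responses=p8[i], eccentricity=float(ecc[c])
            )
            x[i] = interpolate_passive(tuning, stim_by_cell[c])
            active_angles_by_cell[c] = stim_by_cell[c]

    # drop cells whose matched passive vector is all zero (gain undefined)
    ok = (x ** 2).sum(axis=1) > 0
    n_zero = int((~ok).sum())
    if n_zero:
        logger.warning(
            "excluding %d cell(s) with all-zero matched passive responses "
            "(%s, %s)", n_zero, area, decode_space,
        )
        cells = [c for c, good in zip(cells, ok) if good]
        p8, x, matched_stimuli = p8[ok], x[ok], matched_stimuli[ok]
        active_angles_by_cell = {
            c: v for c, v in active_angles_by_cell.items() if c in set(cells)
        }

    trials: Dict[str, np.ndarray] = {}
    for task in att_tasks:
        sub = matched_att[matched_att["task"] == task]
        trials[task] = _trial_tensor(sub, cells, stim_by_cell, stim_col, min_reps)

    # matched passive trials (for attention-vs-passive resampling): the
    # passive trials at the grid stimulus nearest each matched stimulus
    if decode_space == SHAPE:
        passive_stim_by_cell = stim_by_cell
        psub = pd.concat([
            passive[(passive["cell_id"] == c)
                    & (passive[stim_col].isin(stim_by_cell[c]))]
            for c in cells
        ], ignore_index=True)
    else:
        grid = np.asarray(labels, dtype=float)
        passive_stim_by_cell = {}
        frames = []
        for c in cells:
            d = np.abs((stim_by_cell[c][:, None] - grid[None, :] + 180.0)
                       % 360.0 - 180.0)
            nearest = grid[np.argmin(d, axis=1)]
            if np.unique(nearest).size != 3:
                raise DomainError(
                    "matched active angles collapse onto fewer than 3 grid "
                    "angles; passive resampling undefined"
                )
            passive_stim_by_cell[c] = np.sort(nearest)
            frames.append(
                passive[(passive["cell_id"] == c)
                        & (passive[stim_col].isin(nearest))]
            )
        psub = pd.concat(frames, ignore_index=True)
    try:
        trials[passive_task] = _trial_tensor(
            psub, cells, passive_stim_by_cell, stim_col, min_reps
        )
    except InsufficientTrialsError:
        logger.warning("too few passive trials for resampling; passive "
                       "bootstrap disabled for (%s, %s)", area, decode_space)

    return ConditionData(
        area=area,
        decode_space=decode_space,
        passive_task=passive_task,
        cell_ids=cells,
        stimulus_labels=labels,
        p8=p8,
        x=x,
        matched_stimuli=matched_stimuli,
        trials=trials,
        eccentricities=ecc.loc[cells],
        active_angles_by_cell=active_angles_by_cell,
        n_excluded_zero_passive=n_zero,
        n_excluded_ecc=n_excluded_ecc,
    )


def estimate_gains(cond: ConditionData) -> List[GainEstimate]:
    """Per-cell through-origin gains for every attention task present."""
    out: List[GainEstimate] = []
    sxx = np.einsum("ij,ij->i", cond.x, cond.x)
    for task in ATTENTION_TASKS:
        if task not in cond.trials:
            continue
        y = cond.trials[task].mean(axis=2)
        b = np.einsum("ij,ij->i", cond.x, y) / sxx
        for cell, gain in zip(cond.cell_ids, b):
            out.append(GainEstimate(
                cell_id=cell, area=cond.area, task=task,
                decode_space=cond.decode_space, gain=float(gain), n_points=3,
            ))
    return out


def physical_ring(angles_deg, eccentricity: float) -> np.ndarray:
    """Planar coordinates of stimuli on the iso-eccentric ring."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return eccentricity * np.column_stack([np.cos(a), np.sin(a)])


def stress_vs_physical(embedding, physical_angles, eccentricity: float) -> float:
    """Stress between an MDS map and the physical stimulus ring.

    Full Procrustes (scaling on), with the MDS configuration as the first
    (reference) configuration of the stress formula.
    """
    coords = getattr(embedding, "coordinates", embedding)
    coords = np.asarray(coords, dtype=float)[:, :2]
    ring = physical_ring(physical_angles, eccentricity)
    return procrustes_align(coords, ring, allow_scaling=True).stress


@dataclass
class RunReport:
    """JSON-serializable end-to-end analysis report."""

    provenance: Dict
    gain_summary: Dict
    interpolation: Dict
    spaces: Dict  # area -> decode_space -> tables/figures-style entries

    def to_dict(self) -> Dict:
        return {
            "provenance": self.provenance,
            "gain_summary": self.gain_summary,
            "interpolation": self.interpolation,
            "spaces": self.spaces,
        }

    def to_json(self, path=None) -> str:
        import json

        payload = json.dumps(self.to_dict(), sort_keys=True, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _validate_table(table: pd.DataFrame) -> List[str]:
    required = {"cell_id", "area", "task", "shape_id", "polar_angle_deg",
                "eccentricity_deg", "rep", "rate_hz", "is_catch"}
    missing_cols = sorted(required - set(table.columns))
    if missing_cols:
        raise ValidationError(f"trial table missing columns: {missing_cols}")
    areas = sorted(table["area"].unique())
    problems = []
    for area in areas:
        present = set(table.loc[table["area"] == area, "task"].unique())
        absent = [t for t in ALL_TASKS if t not in present]
        if absent:
            problems.append(f"area {area}: missing tasks {absent}")
    if problems:
        raise ValidationError("; ".join(problems))
    return areas


def run_full_analysis(table: pd.DataFrame, cfg: Optional[AnalysisConfig] = None
                      ) -> RunReport:
    """Run the whole analysis on a long-format trial table."""
    cfg = cfg or AnalysisConfig()
    areas = _validate_table(table)
    t0 = time.perf_counter()

    all_gains: List[GainEstimate] = []
    spaces: Dict = {}
    interp_report: Dict = {}
    boot_counter = 0

    for area in areas:
        spaces[area] = {}
        for space in DECODE_SPACES:
            stage0 = time.perf_counter()
            band = (
                cfg.eccentricity_bands.get(area) if space == LOCATION else None
            )
            cond = prepare_condition(
                table, area=area, decode_space=space, ecc_band=band,
                min_reps=cfg.min_reps,
            )
            gains = estimate_gains(cond)
            all_gains.extend(gains)

            passive_means = cond.passive_means
            tasks = [t for t in ATTENTION_TASKS if t in cond.trials]
            matrices = {}
            for task in tasks:
                matrices[task] = build_population_matrix(
                    passive_means, gains, task=task, decode_space=space,
                    area=area, eccentricities=cond.eccentricities,
                )
            matrices["passive"] = build_population_matrix(
                passive_means, None, task=cond.passive_task,
                decode_space=space, area=area,
                eccentricities=cond.eccentricities,
            )

            dms = {name: distance_matrix(pm) for name, pm in matrices.items()}
            mean_d = {}
            for name, dm in dms.items():
                m, se = mean_distance(dm)
                mean_d[name] = {"mean": m, "se": se}
            three_task_avg = float(np.mean(
                [mean_d[name]["mean"] for name in mean_d]
            ))

            comparisons = {}
            for a_name, b_name in _PAIRS:
                if a_name not in dms or b_name not in dms:
                    continue
                da = dms[a_name].unique_distances()
                db = dms[b_name].unique_distances()
                comparisons[f"{a_name}_vs_{b_name}"] = {
                    "percent_change": percent_change(
                        float(da.mean()), float(db.mean())
                    ),
                    "rank_sum_p": rank_sum_test(da, db),
                }

            embeddings = {}
            hulls = {}
            for name, dm in dms.items():
                emb = classical_mds(dm, k=cfg.k)
                embeddings[name] = emb
                if cfg.k >= 2:
                    hull_area, hull_radius = convex_hull_summary(
                        emb.coordinates[:, :2]
                    )
                    hulls[name] = {"area": hull_area,
                                   "mean_radius": hull_radius}

            stress_entries = {}
            for a_name, b_name in _PAIRS:
                if a_name not in embeddings or b_name not in embeddings:
                    continue
                ali = procrustes_align(
                    embeddings[a_name].coordinates,
                    embeddings[b_name].coordinates,
                    allow_scaling=True,
                )
                entry = {"stress": ali.stress}
                task_b = (
                    cond.passive_task if b_name == "passive" else b_name
                )
                if cfg.run_bootstrap and task_b in cond.trials:
                    boot_counter += 1
                    res = shuffle_split_stress_test(
                        cond.x, cond.p8,
                        cond.trials[a_name], cond.trials[task_b],
                        n_boot=cfg.n_boot,
                        rng=np.random.default_rng([cfg.seed, boot_counter]),
                        k=cfg.k,
                    )
                    entry["bootstrap_p"] = res.p_value
                    entry["bootstrap_observed_stress"] = res.observed_stress
                    entry["n_boot"] = res.n_boot
                stress_entries[f"{a_name}_vs_{b_name}"] = entry

            entry = {
                "n_cells": len(cond.cell_ids),
                "n_excluded_eccentricity": cond.n_excluded_ecc,
                "n_excluded_zero_passive": cond.n_excluded_zero_passive,
                "mean_distance": mean_d,
                "three_task_average": three_task_avg,
                "distance_comparisons": comparisons,
                "embeddings": {
                    name: {
                        "coordinates": emb.coordinates.tolist(),
                        "stimulus_labels": emb.stimulus_labels,
                        "eigenvalues": emb.eigenvalues.tolist(),
                        "variance_explained": variance_explained(
                            emb.eigenvalues, cfg.k
                        ),
                    }
                    for name, emb in embeddings.items()
                },
                "convex_hulls": hulls,
                "stress_comparisons": stress_entries,
            }

            if space == LOCATION:
                mean_ecc = float(cond.eccentricities.mean())
                entry["stress_vs_physical"] = {
                    name: stress_vs_physical(
                        emb, cond.stimulus_labels, mean_ecc
                    )
                    for name, emb in embeddings.items()
                }
                interp_report.update(angular_shift_report(
                    cond.stimulus_labels,
                    cond.active_angles_by_cell,
                    {c: area for c in cond.active_angles_by_cell},
                ))
            spaces[area][space] = entry
            logger.info(
                "analyzed (%s, %s) in %.2fs", area, space,
                time.perf_counter() - stage0,
            )

    report = RunReport(
        provenance={
            "seed": cfg.seed,
            "config_sha256": config_hash(cfg),
            "package_version": __version__,
            "n_cells_per_area": {
                a: int(table.loc[table["area"] == a, "cell_id"].nunique())
                for a in areas
            },
        },
        gain_summary=gain_histogram_summary(all_gains),
        interpolation=interp_report,
        spaces=spaces,
    )
    logger.info("full analysis in %.2fs", time.perf_counter() - t0)
    return report


__all__ = [
    "ConditionData",
    "RunReport",
    "estimate_gains",
    "nearest_grid_shift",
    "physical_ring",
    "prepare_condition",
    "run_full_analysis",
    "select_active_stimuli",
    "stress_vs_physical",
]
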