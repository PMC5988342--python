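"""Configuration models for the simulator and the analysis pipeline.

Both configs are pydantic models so that JSON configs coming in through the
CLI are schema-validated before any computation starts.
"""

from __future__ import annotations

import hashlib
import json
from typing import Dict, Tuple

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ConfigurationError

# Task labels -----------------------------------------------------------------

SHAPE_ATTENTION = "shape_attention"
LOCATION_ATTENTION = "location_attention"
PASSIVE_SHAPE = "passive_shape"
PASSIVE_LOCATION = "passive_location"

ATTENTION_TASKS = (SHAPE_ATTENTION, LOCATION_ATTENTION)
PASSIVE_TASKS = (PASSIVE_SHAPE, PASSIVE_LOCATION)
ALL_TASKS = ATTENTION_TASKS + PASSIVE_TASKS

SHAPE = "shape"
LOCATION = "location"
DECODE_SPACES = (SHAPE, LOCATION)

AREAS = ("AIT", "LIP")

#: passive baseline task used when decoding each stimulus space
PASSIVE_FOR_SPACE = {SHAPE: PASSIVE_SHAPE, LOCATION: PASSIVE_LOCATION}

WARP_MODES = ("none", "gain_heterogeneity", "tuning_shift", "both")

#: angular displacement (degrees) of a tuning-curve shift at warp_magnitude 1;
#: one passive-grid spacing for the default 8-location ring.
SHIFT_DEG_PER_UNIT_MAGNITUDE = 45.0


class SimConfig(BaseModel):
    """Design parameters of a simulated two-area recording session.

    Defaults reproduce the recording design this generator emulates: two areas
    (an AIT-like ventral population and an LIP-like dorsal one), 8 shapes,
    8 iso-eccentric locations, per-cell active subsets of 3 shapes x 3
    locations, 12 repetitions of each of the 9 sample conditions in each of
    the two attention tasks (216 non-catch matching trials per cell), 20%
    catch trials, and Poisson trial noise on rates counted in a fixed window.
    """

    model_config = ConfigDict(extra="forbid")

    n_cells_per_area: Dict[str, int] = Field(
        default_factory=lambda: {"AIT": 85, "LIP": 53}
    )
    n_shapes: int = 8
    n_locations: int = 8
    eccentricity_bands: Dict[str, Tuple[float, float]] = Field(
        default_factory=lambda: {"AIT": (2.0, 6.0), "LIP": (7.0, 12.0)}
    )
    reps_attention: int = 12
    reps_passive_shape: int = 4
    reps_passive_location: int = 12
    catch_fraction: float = 0.20
    base_rate: float = 20.0  # spikes/s at the preferred shape and location
    window_s: float = 0.5  # spike-count window used to convert rates<->counts
    # AIT-like cells are shape selective with large receptive fields and only
    # shallow polar-angle tuning; LIP-like cells are sharply space selective.
    location_kappa_by_area: Dict[str, float] = Field(
        default_factory=lambda: {"AIT": 0.5, "LIP": 3.0}
    )
    # von Mises concentration of the preferred-angle distribution itself;
    # 0 = uniform coverage of the ring. AIT-like coverage is biased toward
    # a contralateral/foveal cluster, LIP-like coverage tiles the ring.
    preferred_angle_concentration: Dict[str, float] = Field(
        default_factory=lambda: {"AIT": 2.5, "LIP": 0.0}
    )
    preferred_angle_center: Dict[str, float] = Field(
        default_factory=lambda: {"AIT": 0.0, "LIP": 0.0}
    )
    shape_lognormal_sigma: float = 0.8
    # log-space (mu, sd) of the per-cell engagement gain of each attention
    # task; these are identically the shape-decode gain distributions.
    gain_log_mean_sd: Dict[str, Dict[str, Tuple[float, float]]] = Field(
        default_factory=lambda: {
            "AIT": {
                SHAPE_ATTENTION: (0.1398, 0.30),  # ln 1.15
                LOCATION_ATTENTION: (0.0770, 0.30),  # ln 1.08
            },
            "LIP": {
                SHAPE_ATTENTION: (0.3001, 0.40),  # ln 1.35
                LOCATION_ATTENTION: (0.2624, 0.40),  # ln 1.30
            },
        }
    )
    # log-space (mu, sd) of rho = passive_shape/passive_location engagement;
    # location-decode gains are engagement_gain * rho.
    passive_offset_log_mean_sd: Dict[str, Tuple[float, float]] = Field(
        default_factory=lambda: {
            "AIT": (-0.0726, 0.25),  # ln 0.93
            "LIP": (-0.5108, 0.30),  # ln 0.60
        }
    )
    # share one engagement draw between the two attention tasks per cell,
    # making their trials exchangeable (the bootstrap's null scenario)
    shared_task_gains: bool = False
    warp_mode: Dict[str, str] = Field(
        default_factory=lambda: {"AIT": "none", "LIP": "none"}
    )
    warp_magnitude: Dict[str, float] = Field(
        default_factory=lambda: {"AIT": 0.0, "LIP": 0.0}
    )
    trial_noise: bool = True
    seed: int = 0

    # -- validators -----------------------------------------------------------

    @field_validator("warp_mode", "warp_magnitude", "location_kappa_by_area",
                     "preferred_angle_concentration", "preferred_angle_center",
                     mode="before")
    @classmethod
    def _broadcast_area_scalars(cls, v):
        if not isinstance(v, dict):
            return {a: v for a in AREAS}
        return v

    def model_post_init(self, __context) -> None:
        # runs after pydantic's own validation; raises unwrapped so callers
        # see ConfigurationError directly
        for name in ("n_shapes", "n_locations", "reps_attention",
                     "reps_passive_shape", "reps_passive_location"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for area, n in self.n_cells_per_area.items():
            if n < 1:
                raise ConfigurationError(f"n_cells_per_area[{area}] must be >= 1")
        if not (0.0 <= self.catch_fraction < 1.0):
            raise ConfigurationError("catch_fraction must be in [0, 1)")
        if self.base_rate < 0 or self.window_s <= 0:
            raise ConfigurationError("base_rate must be >= 0 and window_s > 0")
        for area in self.areas:
            lo, hi = self.eccentricity_bands[area]
            if not (0 < lo < hi):
                raise ConfigurationError(
                    f"eccentricity band for {area} must satisfy 0 < lo < hi"
                )
            if self.location_kappa_by_area.get(area, 0.0) < 0:
                raise ConfigurationError("location kappa must be >= 0")
            mode = self.warp_mode.get(area, "none")
            if mode not in WARP_MODES:
                raise ConfigurationError(f"unknown warp_mode {mode!r}")
            if self.warp_magnitude.get(area, 0.0) < 0:
                raise ConfigurationError("warp_magnitude must be >= 0")
            if area not in self.gain_log_mean_sd:
                raise ConfigurationError(f"gain_log_mean_sd missing area {area}")
            if area not in self.passive_offset_log_mean_sd:
                raise ConfigurationError(
                    f"passive_offset_log_mean_sd missing area {area}"
                )

    # -- helpers --------------------------------------------------------------

    @property
    def areas(self) -> tuple:
        return tuple(sorted(self.n_cells_per_area))

    @property
    def location_angles(self):
        """Equally spaced polar angles of the passive location ring, degrees."""
        import numpy as np

        return np.arange(self.n_locations) * (360.0 / self.n_locations)

    def shift_degrees(self, area: str) -> float:
        """Tuning-curve displacement implied by this area's warp settings."""
        if self.warp_mode[area] in ("tuning_shift", "both"):
            return self.warp_magnitude[area] * SHIFT_DEG_PER_UNIT_MAGNITUDE
        return 0.0


class AnalysisConfig(BaseModel):
    """Knobs of the end-to-end analysis."""

    model_config = ConfigDict(extra="forbid")

    eccentricity_bands: Dict[str, Tuple[float, float]] = Field(
        default_factory=lambda: {"AIT": (2.0, 6.0), "LIP": (7.0, 12.0)}
    )
    k: int = 2  # embedding dimensionality reported/plotted
    n_boot: int = 10_000
    run_bootstrap: bool = True
    min_reps: int = 2
    seed: int = 0

    def model_post_init(self, __context) -> None:
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if self.n_boot < 1:
            raise ConfigurationError("n_boot must be >= 1")


def config_hash(cfg: BaseModel) -> str:
    """Stable sha256 of a config's canonical JSON, for provenance."""
    payload = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def load_config(path, model):
    """Load and validate a JSON config file against a pydantic model."""
    with open(path) as fh:
        raw = json.load(fh)
    return model.model_validate(raw)
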