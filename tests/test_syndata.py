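"""Generator honors the recording design and its tuning model."""

import numpy as np
import pandas as pd
import pytest

from attnspace import (
    CellGroundTruth,
    LOCATION_ATTENTION,
    PASSIVE_LOCATION,
    PASSIVE_SHAPE,
    SHAPE_ATTENTION,
    apply_attention,
    location_tuning,
    sample_trials,
    select_active_stimuli,
    simulate_population,
)
from attnspace.config import ATTENTION_TASKS
from attnspace.errors import ConfigurationError, DomainError, LabelError
from attnspace.syndata import _vm_profile

from conftest import make_config


def _cell(**kw):
    defaults = dict(
        cell_id="c0", area="AIT", preferred_angle=30.0, location_kappa=2.0,
        eccentricity=4.0, shape_rates=np.array([10, 20, 5, 8, 12, 7, 9, 11.0]),
        gains={(t, s): 1.0 for t in ATTENTION_TASKS for s in ("shape", "location")},
        engagement={},
    )
    defaults.update(kw)
    return CellGroundTruth(**defaults)


class TestLocationTuning:
    def test_flat_when_kappa_zero(self):
        cell = _cell(location_kappa=0.0)
        rates = location_tuning(cell, np.arange(0, 360, 10.0), PASSIVE_LOCATION)
        assert np.allclose(rates, cell.peak_rate)

    def test_peak_at_preference(self):
        cell = _cell()
        grid = np.arange(0.0, 360.0, 1.0)
        rates = location_tuning(cell, grid, PASSIVE_LOCATION)
        assert np.isclose(rates.max(), cell.peak_rate)
        assert np.isclose(grid[np.argmax(rates)], cell.preferred_angle)

    def test_von_mises_falloff_90_degrees(self):
        # kappa=2 at 90 deg from preference: peak * exp(2*(cos90 - 1))
        cell = _cell(location_kappa=2.0)
        rate = location_tuning(cell, cell.preferred_angle + 90.0, PASSIVE_SHAPE)
        assert np.isclose(rate, cell.peak_rate * np.exp(-2.0), rtol=1e-12)

    def test_shift_moves_tuning_toward_attended(self):
        cell = _cell(shift=20.0)
        probe = cell.preferred_angle + 90.0
        shifted = location_tuning(cell, probe, LOCATION_ATTENTION)
        static = location_tuning(cell, probe, PASSIVE_LOCATION)
        assert shifted > static  # attention pulls the curve toward the probe

    def test_unknown_task_rejected(self):
        with pytest.raises(LabelError):
            location_tuning(_cell(), 10.0, "free_viewing")


class TestApplyAttention:
    def test_pure_scaling(self):
        gains = {(t, s): 2.0 for t in ATTENTION_TASKS for s in ("shape", "location")}
        cell = _cell(gains=gains)
        assert apply_attention(10.0, cell, SHAPE_ATTENTION, "shape") == 20.0

    def test_passive_task_unchanged(self):
        assert apply_attention(7.0, _cell(), PASSIVE_SHAPE, "shape") == 7.0

    def test_unknown_task_rejected(self):
        with pytest.raises(LabelError):
            apply_attention(1.0, _cell(), "saccade", "shape")

    def test_negative_rate_rejected(self):
        with pytest.raises(DomainError):
            apply_attention(-1.0, _cell(), SHAPE_ATTENTION, "shape")

    def test_zero_magnitude_heterogeneity_equals_none(self):
        kw = dict(seed=3, n_cells_per_area={"AIT": 4, "LIP": 4})
        t_none, _ = simulate_population(
            make_config(warp_mode="none", warp_magnitude=0.0, **kw))
        t_warp, _ = simulate_population(
            make_config(warp_mode="gain_heterogeneity", warp_magnitude=0.0, **kw))
        pd.testing.assert_frame_equal(t_none, t_warp)


class TestSampleTrials:
    def test_zero_mean_gives_zero_rates(self, rng):
        assert np.all(sample_trials(0.0, 50, 0.5, rng) == 0)

    def test_poisson_mean_recovered(self):
        rates = sample_trials(20.0, 10_000, 0.5, np.random.default_rng(0))
        se = np.sqrt(20.0 / 0.5) / np.sqrt(10_000)
        assert abs(rates.mean() - 20.0) < 3 * se

    def test_seeded_reproducibility(self):
        a = sample_trials(15.0, 100, 0.5, np.random.default_rng(42))
        b = sample_trials(15.0, 100, 0.5, np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_negative_mean_rejected(self, rng):
        with pytest.raises(DomainError):
            sample_trials(-1.0, 10, 0.5, rng)


class TestSelectActiveStimuli:
    def test_two_strongest_plus_weakest(self):
        shapes, _ = select_active_stimuli(
            [9, 8, 1, 2, 3, 4, 5, 6], np.ones(8))
        assert shapes == (0, 1, 2)

    def test_locations_at_120_degree_spacing(self):
        h = _vm_profile(np.arange(8) * 45.0, 10.0, 2.0)
        _, angles = select_active_stimuli(np.arange(8), h,
                                          np.array([10.0 + 45 * i for i in range(8)]))
        assert angles == (10.0, 130.0, 250.0)

    def test_tie_break_lowest_index(self):
        shapes, _ = select_active_stimuli(np.ones(8), np.ones(8))
        assert shapes == (0, 1, 2)


class TestSessionDesign:
    def test_fixed_seed_byte_identical(self):
        cfg = make_config(n_cells_per_area={"AIT": 5, "LIP": 4})
        t1, g1 = simulate_population(cfg)
        t2, g2 = simulate_population(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        assert all(a.gains == b.gains for a, b in zip(g1, g2))

    def test_design_counts(self, small_session):
        cfg, table, truth = small_session
        att = table[table["task"].isin(ATTENTION_TASKS)]
        per_cell = att[~att["is_catch"]].groupby("cell_id").size()
        assert (per_cell == cfg.reps_attention * 9 * 2).all()  # 216 by default
        # catch trials are additional and flagged, at the configured fraction
        frac = att["is_catch"].mean()
        assert abs(frac - cfg.catch_fraction) < 0.02
        for cell in truth[:4]:
            sub = att[(att["cell_id"] == cell.cell_id) & (~att["is_catch"])]
            assert set(sub["shape_id"]) == set(cell.active_shapes)
            assert set(np.round(sub["polar_angle_deg"], 6)) == set(
                np.round(cell.active_angles, 6))
            reps = sub.groupby(["task", "shape_id", "polar_angle_deg"]).size()
            assert (reps >= 5).all() and (reps == cfg.reps_attention).all()

    def test_passive_task_structure(self, small_session):
        cfg, table, _ = small_session
        ps = table[table["task"] == PASSIVE_SHAPE]
        pl = table[table["task"] == PASSIVE_LOCATION]
        for cell, grp in ps.groupby("cell_id"):
            assert set(grp["shape_id"]) == set(range(cfg.n_shapes))
            assert grp["polar_angle_deg"].nunique() == 1
        for cell, grp in pl.groupby("cell_id"):
            assert grp["shape_id"].nunique() == 1
            assert set(grp["polar_angle_deg"]) == set(cfg.location_angles)
        assert not ps["is_catch"].any() and not pl["is_catch"].any()

    def test_eccentricity_bands_respected(self, small_session):
        cfg, table, _ = small_session
        for area, (lo, hi) in cfg.eccentricity_bands.items():
            ecc = table.loc[table["area"] == area, "eccentricity_deg"]
            assert ecc.between(lo, hi).all()

    def test_noiseless_unity_attention_equals_passive_tuning(
            self, noiseless_unity_session):
        _, table, truth = noiseless_unity_session
        by_id = {c.cell_id: c for c in truth}
        att = table[table["task"].isin(ATTENTION_TASKS) & ~table["is_catch"]]
        for (cell_id, shape, angle), grp in att.groupby(
                ["cell_id", "shape_id", "polar_angle_deg"]):
            cell = by_id[cell_id]
            expected = cell.shape_rates[shape] * _vm_profile(
                angle, cell.preferred_angle, cell.location_kappa)
            assert np.allclose(grp["rate_hz"], expected, rtol=1e-10)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            make_config(catch_fraction=1.0)
        with pytest.raises(ConfigurationError):
            make_config(reps_attention=0)
        with pytest.raises(ConfigurationError):
            make_config(warp_mode="sideways")
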