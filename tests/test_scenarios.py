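"""End-to-end scenario behaviour at test resolution."""

import copy

import numpy as np
import pytest

from vancoelute.errors import ValidationError
from vancoelute.release import slab_release_analytic
from vancoelute.scenarios import (
    default_config,
    load_config,
    run_agar,
    run_human_bone_plate,
    run_in_vitro_release,
    run_rat_tibia,
    run_scenario,
    save_config,
)
from vancoelute.units import convert_diffusivity


@pytest.fixture(scope="module")
def in_vitro_result():
    return run_in_vitro_release(default_config("in_vitro_release", "test"))


@pytest.fixture(scope="module")
def agar_result():
    return run_agar(default_config("agar", "test"))


@pytest.fixture(scope="module")
def rat_result():
    return run_rat_tibia(default_config("rat_tibia", "test"))


class TestInVitroRelease:

    def test_starts_at_zero_and_is_monotone(self, in_vitro_result):
        assert in_vitro_result.fraction_released[0] == 0.0
        assert np.all(np.diff(in_vitro_result.fraction_released) >= -1e-12)

    def test_approaches_complete_release(self, in_vitro_result):
        assert in_vitro_result.fraction_released[-1] > 0.9

    def test_matches_analytic_slab_series(self, in_vitro_result):
        cfg = default_config("in_vitro_release", "test")
        D = convert_diffusivity(2.83e-6, "cm^2/s", "mm^2/h")
        L = cfg["geometry"]["slab_length_mm"]
        t = in_vitro_result.times[1:]
        exact = slab_release_analytic(D, L, t)
        x = D * t / L**2
        m = (x >= 0.01) & (x <= 1.0)
        rel = np.abs(in_vitro_result.fraction_released[1:][m] - exact[m]) / exact[m]
        assert rel.max() < 0.02

    def test_doubling_thickness_quadruples_half_release_time(self):
        def t50(length, dx, t_end):
            cfg = default_config("in_vitro_release", "test")
            cfg["geometry"]["slab_length_mm"] = length
            cfg["geometry"]["dx_mm"] = dx
            cfg["run"]["t_end_h"] = t_end
            r = run_in_vitro_release(cfg)
            return np.interp(0.5, r.fraction_released, r.times)

        t1 = t50(1.0, 0.05, 1.0)
        t2 = t50(2.0, 0.1, 4.0)
        assert t2 / t1 == pytest.approx(4.0, rel=0.05)

    def test_clearance_enabled_warns(self):
        cfg = default_config("in_vitro_release", "test")
        cfg["clearance"]["half_life_h"] = 4.0
        with pytest.warns(UserWarning, match="deviates"):
            run_in_vitro_release(cfg)

    def test_mass_ledger_closes(self, in_vitro_result):
        assert in_vitro_result.sim.ledger.closure_error() < 1e-6


class TestAgar:

    def test_inhibition_area_exceeds_substrate_footprint(self, agar_result):
        assert agar_result.inhibition_area_cm2 > 9.0

    def test_mass_ledger_closes(self, agar_result):
        assert agar_result.sim.ledger.closure_error() < 1e-6

    def test_area_monotone_in_released_mass(self, agar_result):
        cfg = default_config("agar", "test")
        cfg["source"]["total_load_ug"] *= 2.0
        bigger = run_agar(cfg)
        assert bigger.inhibition_area_cm2 >= agar_result.inhibition_area_cm2

    def test_mic_front_at_edge_raises(self):
        cfg = default_config("agar", "test")
        cfg["geometry"]["domain_mm"] = 34.0  # barely larger than the source
        with pytest.raises(ValidationError, match="domain edge"):
            run_agar(cfg)


class TestRatTibia:

    def test_zero_dose_gives_zero_series(self):
        cfg = default_config("rat_tibia", "test")
        cfg["source"]["dose_ug"] = 0.0
        cfg["run"]["t_end_h"] = 2.0
        r = run_rat_tibia(cfg)
        assert np.all(r.cortical_avg == 0.0)

    def test_rise_to_peak_then_decay(self, rat_result):
        i = int(np.argmax(rat_result.cortical_avg))
        t_peak = rat_result.times[i]
        assert 0 < t_peak < 12.0  # rises within hours
        assert rat_result.cortical_avg[-1] < rat_result.cortical_avg[i]

    def test_decays_to_under_one_percent_of_peak(self):
        cfg = default_config("rat_tibia", "test")
        cfg["run"]["t_end_h"] = 40.0  # 10 half-lives
        r = run_rat_tibia(cfg)
        assert r.cortical_avg[-1] < 0.01 * r.cortical_avg.max()

    def test_linearity_in_dose(self, rat_result):
        cfg = default_config("rat_tibia", "test")
        cfg["source"]["dose_ug"] *= 2.0
        r2 = run_rat_tibia(cfg)
        np.testing.assert_allclose(r2.cortical_avg, 2.0 * rat_result.cortical_avg, rtol=1e-9)

    def test_missing_dose_rejected(self):
        cfg = default_config("rat_tibia", "test")
        del cfg["source"]["dose_ug"]
        with pytest.raises(ValidationError, match="dose"):
            run_rat_tibia(cfg)

    def test_clearance_ledger_closes(self, rat_result):
        led = rat_result.sim.ledger
        assert led.cleared == pytest.approx(led.initial - led.stored, rel=1e-9)


class TestHumanBonePlate:
    def test_no_clearance_series_non_decreasing(self):
        cfg = default_config("human_bone_plate", "test")
        cfg["clearance"]["half_life_h"] = None
        r = run_human_bone_plate(cfg)
        tol = 1e-9 * r.tissue_avg.max()
        assert np.all(np.diff(r.tissue_avg) >= -tol)

    def test_single_peak_then_decline_with_clearance(self, bone_plate_test_result):
        avg = bone_plate_test_result.tissue_avg
        i = int(np.argmax(avg))
        tol = 1e-9 * avg.max()
        assert 0 < i < avg.size - 1
        assert np.all(np.diff(avg[: i + 1]) >= -tol)
        assert np.all(np.diff(avg[i:]) <= tol)

    def test_longer_half_life_dominates_pointwise(self, bone_plate_test_result):
        cfg = default_config("human_bone_plate", "test")
        cfg["clearance"]["half_life_h"] = 6.0
        r6 = run_human_bone_plate(cfg)
        r4 = bone_plate_test_result
        assert np.all(r6.tissue_avg[1:] >= r4.tissue_avg[1:])

    def test_cortical_concentration_dominates_cancellous(self, bone_plate_test_result):
        """Source-side maximum principle: near cortical ≥ cancellous region."""
        bone = bone_plate_test_result.bone
        cort = bone.grid.layer_cells("cortical_near")
        canc = bone.grid.layer_cells("cancellous")
        for state in bone.states[1:]:
            assert state[cort].mean() >= state[canc].mean()

    def test_ledgers_close(self, bone_plate_test_result):
        for sim in (bone_plate_test_result.tissue, bone_plate_test_result.bone):
            led = sim.ledger
            assert led.cleared == pytest.approx(led.influx - led.stored, rel=1e-6)

    def test_zone_map_partitions_bone(self, bone_plate_test_result):
        zm = bone_plate_test_result.zone_map("bone")
        grid = bone_plate_test_result.bone.grid
        total = grid.n_cells * grid.cell_volume
        assert sum(zm.areas.values()) == pytest.approx(total)


class TestConfigRoundTrip:
    @pytest.mark.parametrize(
        "name", ["in_vitro_release", "agar", "rat_tibia", "human_bone_plate"]
    )
    def test_yaml_round_trip_runs(self, tmp_path, name):
        cfg = default_config(name, "test")
        path = tmp_path / f"{name}.yaml"
        save_config(cfg, path)
        loaded = load_config(path)
        assert loaded == cfg
        run_scenario(loaded)  # must not raise

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValidationError):
            default_config("warp_drive")
        with pytest.raises(ValidationError):
            run_scenario({"scenario": "warp_drive"})
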