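"""White Monte Carlo transport: conservation, scaling, and the diffusion oracle."""

import numpy as np
import pytest

from halftone_sfdi import (
    OpticalProperties,
    TransportConfig,
    WMCTable,
    rd_diffusion,
    rd_frequency,
    simulate_white_mc,
)

# value of the semi-infinite diffusion closed form at (mua=0.01, musp=1.0,
# fx=0, n=1.4), fixed from an independent exact-arithmetic transcription of
# the published formula
DIFFUSION_PIN_FX0 = 0.6148876974487387
DIFFUSION_PIN_FX01 = 0.2508142606734987


class TestSimulation:
    def test_one_record_per_photon_with_physical_ranges(self, mc_table):
        n = mc_table.config.n_photons
        assert mc_table.exit_radius.size == n
        assert np.all(mc_table.exit_radius >= 0)
        assert np.all(mc_table.path_length > 0)
        assert np.all((mc_table.exit_weight > 0) & (mc_table.exit_weight <= 1))

    def test_energy_conservation_without_absorption(self, mc_table):
        # no absorption: every launched photon is eventually remitted
        assert mc_table.exit_weight.sum() / mc_table.config.n_photons == pytest.approx(1.0)

    def test_matched_boundary_exits_on_first_contact(self):
        table = simulate_white_mc(TransportConfig(n_photons=20_000, n_rel=1.0, seed=3))
        assert table.exit_weight.sum() / 20_000 == pytest.approx(1.0)

    def test_seeded_determinism_is_bit_exact(self):
        cfg = TransportConfig(n_photons=20_000, seed=99)
        a = simulate_white_mc(cfg)
        b = simulate_white_mc(cfg)
        assert np.array_equal(a.exit_radius, b.exit_radius)
        assert np.array_equal(a.path_length, b.path_length)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"g": 1.0},
            {"g": -1.5},
            {"n_rel": 0.9},
            {"n_photons": 0},
            {"musp_ref": 0.0},
            {"max_path_mm": -1.0},
        ],
    )
    def test_nonphysical_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TransportConfig(**kwargs)

    def test_save_load_round_trip(self, mc_table, tmp_path):
        path = tmp_path / "table.h5"
        mc_table.save(path)
        loaded = WMCTable.load(path)
        assert np.array_equal(loaded.exit_radius, mc_table.exit_radius)
        assert np.array_equal(loaded.path_length, mc_table.path_length)
        assert loaded.config == mc_table.config
        assert loaded.n_truncated == mc_table.n_truncated


class TestRdFrequency:
    def test_fx_zero_equals_absorption_weighted_total(self, mc_table):
        props = OpticalProperties(0.013, 0.9)
        scale = mc_table.config.musp_ref / props.musp
        expected = (
            np.dot(
                mc_table.exit_weight * np.exp(-props.mua * mc_table.path_length * scale),
                np.ones(mc_table.path_length.size),
            )
            / mc_table.config.n_photons
        )
        assert rd_frequency(mc_table, props, 0.0) == pytest.approx(expected, rel=1e-12)

    def test_rd_strictly_decreases_when_mua_doubles(self, mc_table):
        for fx in (0.0, 0.1):
            lo = rd_frequency(mc_table, OpticalProperties(0.01, 1.0), fx)
            hi = rd_frequency(mc_table, OpticalProperties(0.02, 1.0), fx)
            assert hi < lo

    @pytest.mark.parametrize("mua,musp", [(0.005, 0.3), (0.005, 2.0), (0.04, 0.3), (0.04, 2.0), (0.01, 1.0)])
    def test_rd_nonincreasing_in_fx_over_phantom_range(self, mc_table, mua, musp):
        fx = np.linspace(0.0, 0.5, 11)
        rd = rd_frequency(mc_table, OpticalProperties(mua, musp), fx)
        assert np.all(np.diff(rd) <= 1e-12)
        assert np.all((rd >= 0) & (rd <= 1))

    def test_invalid_inputs_rejected(self, mc_table):
        with pytest.raises(ValueError):
            OpticalProperties(0.01, 0.0)
        with pytest.raises(ValueError):
            rd_frequency(mc_table, OpticalProperties(0.01, 1.0), -0.1)

    def test_absorbing_medium_remits_less_than_unity(self, mc_table):
        assert rd_frequency(mc_table, OpticalProperties(0.02, 1.0), 0.0) < 1.0


class TestDiffusionOracle:
    def test_frozen_transcription_values(self):
        props = OpticalProperties(0.01, 1.0)
        assert rd_diffusion(props, 0.0, 1.4) == pytest.approx(DIFFUSION_PIN_FX0, rel=1e-12)
        assert rd_diffusion(props, 0.1, 1.4) == pytest.approx(DIFFUSION_PIN_FX01, rel=1e-12)

    def test_high_frequency_rolloff_to_zero(self):
        props = OpticalProperties(0.01, 1.0)
        fx = np.linspace(0.0, 15.0, 40)  # up to >10x the transport coefficient
        rd = rd_diffusion(props, fx, 1.4)
        assert np.all(np.diff(rd) < 0)
        assert rd[-1] < 1e-3

    def test_rd0_increases_with_scattering(self):
        rd = [rd_diffusion(OpticalProperties(0.01, m), 0.0, 1.4) for m in (0.5, 1.0, 2.0)]
        assert rd[0] < rd[1] < rd[2]

    def test_mc_matches_diffusion_in_diffusive_regime(self, mc_table):
        """Agreement holds where fx is small against the transport
        coefficient; the high-fx breakdown is exercised separately."""
        cases = [
            (0.01, 1.0, 0.0),
            (0.01, 1.0, 0.05),
            (0.005, 2.0, 0.0),
            (0.005, 2.0, 0.05),
            (0.005, 2.0, 0.1),
        ]
        for mua, musp, fx in cases:
            props = OpticalProperties(mua, musp)
            mc = rd_frequency(mc_table, props, fx)
            df = rd_diffusion(props, fx, 1.4)
            assert abs(mc - df) / df < 0.10, (mua, musp, fx)
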