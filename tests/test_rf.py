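import math

import numpy as np
import pytest

from implantheat.constants import GAMMA_PROTON, REF_PULSE_LENGTH
from implantheat.errors import ValidationError
from implantheat.rf import (
    Limits,
    RFConfiguration,
    calibrate_beta,
    configuration_index,
    pulse_length_sensitivity,
    sar10g_peak,
    temporal_averages,
    whole_body_average,
    xi_threshold,
)
from implantheat.sequence import RFPulse, SequenceModel
from implantheat.voxel import VoxelField


def _config(make, b1_values, sar_values=1.0):
    return RFConfiguration(
        b1_map=make(np.asarray(b1_values, dtype=complex), kind="b1_plus"),
        sar_map=make(sar_values, kind="sar_nominal"),
        density_map=make(1000.0, kind="density"),
        body_mask=make(np.ones((10, 10, 11), dtype=np.int8), kind="mask"),
    )


class TestCalibrateBeta:
    def test_uniform_map_closed_form(self, uniform_grid):
        b = 1e-6
        cfg = _config(uniform_grid, np.full((10, 10, 11), b))
        expected = (math.pi / 2) / (GAMMA_PROTON * b * REF_PULSE_LENGTH)
        assert calibrate_beta(cfg) == pytest.approx(expected, rel=1e-9)

    def test_two_compartment_closed_form(self, uniform_grid):
        b = 1e-6
        b1 = np.full((10, 10, 11), b)
        b1[5:] = 2 * b
        cfg = _config(uniform_grid, b1)
        theta_star = math.acos((-1 + math.sqrt(33)) / 8)
        expected = theta_star / (GAMMA_PROTON * b * REF_PULSE_LENGTH)
        assert calibrate_beta(cfg) == pytest.approx(expected, rel=1e-6)

    def test_antipodal_phases_degenerate(self, uniform_grid, caplog):
        b1 = np.full((10, 10, 11), 1e-6, dtype=complex)
        b1[5:] *= -1.0  # phase pi
        cfg = _config(uniform_grid, b1)
        with caplog.at_level("WARNING"):
            beta = calibrate_beta(cfg)
        assert beta > 0
        assert "degenerate" in caplog.text

    def test_zero_b1_raises(self, uniform_grid):
        cfg = _config(uniform_grid, np.zeros((10, 10, 11)))
        with pytest.raises(ValidationError, match="no signal"):
            calibrate_beta(cfg)

    def test_matches_grid_search_oracle_on_random_smooth_map(self, uniform_grid):
        rng = np.random.default_rng(42)
        x, y, z = np.meshgrid(
            np.linspace(-1, 1, 10), np.linspace(-1, 1, 10), np.linspace(-1, 1, 11),
            indexing="ij",
        )
        mag = 1e-6 * (1.0 + 0.4 * np.sin(2 * x) * np.cos(y) + 0.2 * z)
        phase = 0.5 * x + 0.3 * np.sin(y + z) + rng.normal() * 0.1
        cfg = _config(uniform_grid, mag * np.exp(1j * phase))
        beta = calibrate_beta(cfg)
        # two-stage dense grid-search oracle over the same slab, final step 1e-6
        from implantheat.rf import central_slab_mask

        b1 = np.asarray(cfg.b1_map.values)[central_slab_mask(cfg)]
        mags, phasors = np.abs(b1), b1 / np.abs(b1)

        def f(bgrid):
            return np.abs(
                np.sin(np.multiply.outer(bgrid, mags) * GAMMA_PROTON * REF_PULSE_LENGTH)
                @ phasors
            )

        coarse = np.arange(0.0, 4 * beta, 1e-3 * beta)
        b0 = coarse[np.argmax(f(coarse))]
        fine = np.arange(b0 - 2e-3 * beta, b0 + 2e-3 * beta, 1e-6)
        oracle = fine[np.argmax(f(fine))]
        assert beta == pytest.approx(oracle, rel=1e-5)


class TestConfigurationIndex:
    def test_identity_beta(self, uniform_grid):
        cfg = _config(uniform_grid, np.full((10, 10, 11), 1e-6), sar_values=3.0)
        cfg.beta = 1.0
        np.testing.assert_allclose(configuration_index(cfg).values, 3.0)

    def test_quadratic_scaling(self, uniform_grid):
        cfg = _config(uniform_grid, np.full((10, 10, 11), 1e-6), sar_values=3.0)
        cfg.beta = 2.0
        np.testing.assert_allclose(configuration_index(cfg).values, 12.0)

    def test_hotspot_elementwise(self, uniform_grid):
        sar = np.ones((10, 10, 11))
        sar[4, 4, 5] = 100.0
        cfg = _config(uniform_grid, np.full((10, 10, 11), 1e-6), sar_values=sar)
        cfg.beta = 0.5
        assert configuration_index(cfg).values[4, 4, 5] == pytest.approx(25.0)

    def test_uncalibrated_raises(self, uniform_grid):
        cfg = _config(uniform_grid, np.full((10, 10, 11), 1e-6))
        with pytest.raises(ValidationError, match="calibrat"):
            configuration_index(cfg)


class TestWholeBodyAverage:
    def test_uniform(self, uniform_grid):
        xi = uniform_grid(5.0, kind="xi")
        assert whole_body_average(
            xi, uniform_grid(1000.0, "density"), uniform_grid(np.ones((10, 10, 11), dtype=np.int8), "mask")
        ) == pytest.approx(5.0)

    def test_half_and_half(self, uniform_grid):
        vals = np.zeros((10, 10, 11))
        vals[:5] = 10.0
        vals[5:] = 0.0
        xi = uniform_grid(vals, "xi")
        avg = whole_body_average(
            xi, uniform_grid(1000.0, "density"), uniform_grid(np.ones((10, 10, 11), dtype=np.int8), "mask")
        )
        assert avg == pytest.approx(5.0)

    def test_matches_brute_force_with_nonuniform_density(self, uniform_grid):
        rng = np.random.default_rng(1)
        xi_vals = rng.uniform(0, 10, (10, 10, 11))
        rho_vals = rng.uniform(900, 1100, (10, 10, 11))
        mask_vals = (rng.uniform(size=(10, 10, 11)) > 0.3).astype(np.int8)
        avg = whole_body_average(
            uniform_grid(xi_vals, "xi"),
            uniform_grid(rho_vals, "density"),
            uniform_grid(mask_vals, "mask"),
        )
        m = mask_vals.astype(bool)
        assert avg == pytest.approx((xi_vals * rho_vals)[m].sum() / rho_vals[m].sum())

    def test_empty_mask_raises(self, uniform_grid):
        with pytest.raises(ValidationError):
            whole_body_average(
                uniform_grid(1.0, "xi"),
                uniform_grid(1000.0, "density"),
                uniform_grid(np.zeros((10, 10, 11), dtype=np.int8), "mask"),
            )


def _field(values, spacing, kind):
    return VoxelField(values, (spacing,) * 3, kind=kind)


class TestSar10gPeak:
    def test_uniform_field_preserved(self):
        dims = (25, 25, 25)
        xi = _field(np.full(dims, 7.0), 2e-3, "xi")
        rho = _field(np.full(dims, 1000.0), 2e-3, "density")
        mask = _field(np.ones(dims, dtype=np.int8), 2e-3, "mask")
        assert sar10g_peak(xi, rho, mask) == pytest.approx(7.0)

    def test_single_hot_voxel_cube_count(self):
        # 2 mm voxels at 1000 kg/m^3: 8 mg per voxel; the smallest centred
        # cube reaching 10 g is 11^3 = 1331 voxels
        dims = (31, 31, 31)
        vals = np.zeros(dims)
        vals[15, 15, 15] = 100.0
        xi = _field(vals, 2e-3, "xi")
        rho = _field(np.full(dims, 1000.0), 2e-3, "density")
        mask = _field(np.ones(dims, dtype=np.int8), 2e-3, "mask")
        assert sar10g_peak(xi, rho, mask) == pytest.approx(100.0 / 1331)

    def test_two_hotspots_max_semantics(self):
        dims = (41, 41, 41)
        vals = np.zeros(dims)
        vals[8, 8, 8] = 50.0
        vals[30, 30, 30] = 120.0
        xi = _field(vals, 2e-3, "xi")
        rho = _field(np.full(dims, 1000.0), 2e-3, "density")
        mask = _field(np.ones(dims, dtype=np.int8), 2e-3, "mask")
        assert sar10g_peak(xi, rho, mask) == pytest.approx(120.0 / 1331)

    def test_too_small_object_raises(self):
        dims = (5, 5, 5)
        xi = _field(np.ones(dims), 2e-3, "xi")
        rho = _field(np.full(dims, 1000.0), 2e-3, "density")
        mask = _field(np.ones(dims, dtype=np.int8), 2e-3, "mask")
        with pytest.raises(ValidationError, match="too small"):
            sar10g_peak(xi, rho, mask)

    def test_linearity_and_bounds(self):
        rng = np.random.default_rng(5)
        dims = (21, 21, 21)
        vals = rng.uniform(0, 10, dims)
        xi = _field(vals, 3e-3, "xi")
        rho = _field(np.full(dims, 1000.0), 3e-3, "density")
        mask = _field(np.ones(dims, dtype=np.int8), 3e-3, "mask")
        peak = sar10g_peak(xi, rho, mask)
        assert sar10g_peak(_field(3 * vals, 3e-3, "xi"), rho, mask) == pytest.approx(3 * peak)
        wb = whole_body_average(xi, rho, mask)
        assert 0 <= peak <= vals.max() + 1e-12
        assert peak >= wb - 1e-9  # peak local average dominates the global mean here


class TestTemporalAverages:
    def test_half_window(self):
        tr, iec = temporal_averages(0.1, 10.0, 180.0)
        assert (tr, iec) == (pytest.approx(1.0), pytest.approx(0.5))

    def test_full_window_equal(self):
        tr, iec = temporal_averages(0.1, 10.0, 360.0)
        assert tr == pytest.approx(iec)

    def test_longer_than_window_saturates(self):
        tr, iec = temporal_averages(0.1, 10.0, 900.0)
        assert iec == pytest.approx(tr)

    def test_worked_example(self):
        tr, iec = temporal_averages(0.12, 349.0, 130.0)
        assert tr == pytest.approx(41.88)
        assert iec == pytest.approx(15.123, abs=5e-3)

    def test_consistency_ratio(self):
        limits = Limits()
        for ts in (10.0, 100.0, 359.0, 360.0, 1000.0):
            tr, iec = temporal_averages(0.3, 5.0, ts, limits)
            assert iec / tr == pytest.approx(min(1.0, ts / limits.T_IEC))


class TestXiThreshold:
    def test_short_sequence_independent_of_ts(self):
        assert xi_threshold(0.1, 100.0, 10.0) == pytest.approx(xi_threshold(0.1, 150.0, 10.0))
        assert xi_threshold(0.1, 100.0, 10.0) == pytest.approx(2 * 10.0 / 0.1)

    def test_worked_example(self):
        assert xi_threshold(0.12, 130.0, 10.0) == pytest.approx(166.7, abs=0.05)

    def test_at_full_window(self):
        assert xi_threshold(0.1, 360.0, 10.0) == pytest.approx(100.0)

    def test_zero_psi_raises(self):
        with pytest.raises(ValidationError, match="unbounded"):
            xi_threshold(0.0, 100.0, 10.0)


class TestPulseLengthSensitivity:
    @pytest.fixture
    def seq(self):
        pulses = [
            RFPulse(flip_angle=1.2, duration=1e-3, shape="apodized_sinc", time_bandwidth=4),
            RFPulse(flip_angle=0.6, duration=2e-3, shape="apodized_sinc", time_bandwidth=6),
        ]
        return SequenceModel("s", TR=0.01, duration=60.0, rf_pulses=pulses)

    def test_zero_change(self, seq):
        assert pulse_length_sensitivity(seq, 0.0) == pytest.approx(0.0)

    def test_thirty_percent(self, seq):
        assert pulse_length_sensitivity(seq, 0.30) == pytest.approx(1 / 1.3 - 1, rel=1e-9)

    def test_first_order_slope(self, seq):
        eps = 1e-3
        assert pulse_length_sensitivity(seq, eps) == pytest.approx(-eps, rel=2e-3)

    def test_invalid_change_raises(self, seq):
        with pytest.raises(ValidationError):
            pulse_length_sensitivity(seq, -1.0)
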