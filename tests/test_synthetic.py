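"""Synthetic exam generator: signal placement, protocol, determinism."""
import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cervelast import (CompressionProtocol, ProbeSpec, TissueModel,
                       adaptive_protocol, simulate_exam, simulate_frame)
from cervelast.synthetic import ConfigError, SafetyLimitError

from conftest import REFERENCE_ELASTICITY


class TestProbeAndTissueValidation:
    @pytest.mark.parametrize("kwargs", [
        {"sampling_rate": 8e6},            # Nyquist violation at 5 MHz
        {"pulse_duration": 2e-6},          # above the 1 us limit
        {"max_pressure_kpa": 45.0},        # above the device range
        {"frame_rate": 0.0},
        {"record_depth_mm": -1.0},
    ])
    def test_invalid_probe_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            ProbeSpec(**kwargs)

    @pytest.mark.parametrize("kwargs", [
        {"elasticity_kpa_mm": 0.0},
        {"rest_length_mm": 8.0},           # below the min compressed length
        {"surface_reflectivity": 1.5},
        {"scatterer_amplitude": 1.0},
    ])
    def test_invalid_tissue_rejected(self, kwargs):
        base = dict(elasticity_kpa_mm=1.0, rest_length_mm=40.0)
        base.update(kwargs)
        with pytest.raises(ConfigError):
            TissueModel(**base)

    def test_invalid_protocol_rejected(self):
        with pytest.raises(ConfigError):
            CompressionProtocol(contact_pressure_kpa=5.0, peak_pressure_kpa=2.0)


class TestSimulateFrame:
    def test_sample_count_matches_record_depth(self, quiet_tissue, probe):
        # 2 * 60 mm / 1540 m/s * 50 MHz
        frame = simulate_frame(quiet_tissue, probe, 0.0, 0, snr_db=None,
                               pressure_noise=False)
        assert len(frame.samples) == 3896

    def test_surface_echo_sample_index_at_rest(self, quiet_tissue, probe):
        # round-trip to 43 mm: 55.84 us * 50 MHz = sample 2792
        frame = simulate_frame(quiet_tissue, probe, 0.0, 0, snr_db=None,
                               pressure_noise=False)
        assert abs(int(np.argmax(np.abs(frame.samples))) - 2792) <= 1

    def test_zero_reflectivity_gives_silent_frame(self, probe):
        tissue = TissueModel(elasticity_kpa_mm=1.0, rest_length_mm=40.0,
                             surface_reflectivity=0.0, scatterer_density_per_mm=0.0)
        frame = simulate_frame(tissue, probe, 5.0, 0, snr_db=None, pressure_noise=False)
        assert np.all(frame.samples == 0.0)

    def test_pressure_above_probe_limit_rejected(self, quiet_tissue, probe):
        with pytest.raises(SafetyLimitError):
            simulate_frame(quiet_tissue, probe, 31.0, 0)

    def test_pressure_noise_is_gaussian_30pa(self, quiet_tissue, probe):
        rng = np.random.default_rng(0)
        measured = [simulate_frame(quiet_tissue, probe, 10.0, rng).applied_pressure_kpa
                    for _ in range(400)]
        err_pa = (np.array(measured) - 10.0) * 1000.0
        assert abs(err_pa.mean()) < 6.0             # 3 SE of the 30 Pa noise
        assert 24.0 < err_pa.std() < 36.0


class TestSimulateExam:
    def test_frame_count_from_ramp(self, quiet_tissue, probe):
        rec = simulate_exam(quiet_tissue, probe, CompressionProtocol(), 0, snr_db=None)
        assert len(rec.frames) == 300  # 3 s at 100 frames/s
        rec2 = simulate_exam(quiet_tissue, probe,
                             CompressionProtocol(ramp_duration_s=1.0, hold_frames=10),
                             0, snr_db=None)
        assert len(rec2.frames) == 110

    def test_frame_interval_matches_frame_rate(self, compression_recording, probe):
        dt = np.diff(compression_recording.timestamps_s())
        assert np.allclose(dt, 1.0 / probe.frame_rate)

    def test_protocol_exceeding_probe_limit_rejected(self, quiet_tissue, probe):
        protocol = CompressionProtocol(peak_pressure_kpa=29.0)
        tight = dataclasses.replace(probe, max_pressure_kpa=25.0)
        with pytest.raises(SafetyLimitError):
            simulate_exam(quiet_tissue, tight, protocol, 0)

    def test_same_seed_bit_identical(self, probe):
        tissue = TissueModel(elasticity_kpa_mm=1.2, rest_length_mm=38.0)
        a = simulate_exam(tissue, probe, CompressionProtocol(), 42)
        b = simulate_exam(tissue, probe, CompressionProtocol(), 42)
        assert np.array_equal(a.sample_matrix(), b.sample_matrix())
        assert np.array_equal(a.pressures_kpa(), b.pressures_kpa())

    def test_echo_depth_monotone_under_compression(self, compression_recording):
        # with noise off the peak index must never move deeper as pressure rises
        peaks = np.argmax(np.abs(compression_recording.sample_matrix()), axis=1)
        assert np.all(np.diff(peaks) <= 0)

    def test_constant_pressure_constant_depth(self, quiet_tissue, probe):
        protocol = CompressionProtocol(contact_pressure_kpa=5.0, peak_pressure_kpa=5.0)
        rec = simulate_exam(quiet_tissue, probe, protocol, 0,
                            snr_db=None, pressure_noise=False)
        peaks = np.argmax(np.abs(rec.sample_matrix()), axis=1)
        assert np.ptp(peaks) == 0

    def test_ground_truth_slope_consistency(self, quiet_tissue, probe, compression_recording):
        """(peak - contact) / depth change reproduces the configured elasticity."""
        peaks = np.argmax(np.abs(compression_recording.sample_matrix()), axis=1)
        quantum_mm = quiet_tissue.speed_of_sound / (2 * probe.sampling_rate) * 1000
        depth_drop = (peaks[0] - peaks[-1]) * quantum_mm
        pressures = compression_recording.pressures_kpa()
        recovered = (pressures[-1] - pressures[0]) / depth_drop
        assert recovered == pytest.approx(REFERENCE_ELASTICITY, rel=5e-3)

    def test_reference_compression_endpoint(self, quiet_tissue, probe):
        """43 mm rest length compresses to 25 mm at 21 kPa."""
        frame = simulate_frame(quiet_tissue, probe, 21.0, 0, snr_db=None,
                               pressure_noise=False)
        quantum_mm = quiet_tissue.speed_of_sound / (2 * probe.sampling_rate) * 1000
        depth = np.argmax(np.abs(frame.samples)) * quantum_mm
        assert depth == pytest.approx(25.0, abs=0.05)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(elasticity=st.floats(0.05, 5.0), rest_length=st.floats(15.0, 55.0),
       p1=st.floats(0.0, 30.0), p2=st.floats(0.0, 30.0))
def test_compressed_length_non_increasing_in_pressure(elasticity, rest_length, p1, p2):
    tissue = TissueModel(elasticity_kpa_mm=elasticity, rest_length_mm=rest_length)
    lo, hi = sorted((p1, p2))
    assert tissue.compressed_length_mm(hi) <= tissue.compressed_length_mm(lo)
    assert tissue.compressed_length_mm(hi) >= tissue.min_compressed_length_mm


class TestAdaptiveProtocol:
    def test_stiff_tissue_capped_at_base_peak(self):
        stiff = TissueModel(elasticity_kpa_mm=3.5, rest_length_mm=40.0)
        assert adaptive_protocol(stiff).peak_pressure_kpa == 21.0

    def test_soft_tissue_gets_reduced_peak(self):
        soft = TissueModel(elasticity_kpa_mm=0.44, rest_length_mm=43.0)
        protocol = adaptive_protocol(soft)
        assert protocol.peak_pressure_kpa < 21.0
        # the commanded peak never compresses below the saturation floor
        assert soft.compressed_length_mm(protocol.peak_pressure_kpa) == \
            pytest.approx(0.35 * 43.0)
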