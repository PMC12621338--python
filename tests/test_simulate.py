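import math

import numpy as np
import pytest

from kneeadl.activities import ACTIVITY_LABELS, ActivityProfile, Waveform, default_profiles
from kneeadl.simulate import (
    SimulationConfig,
    flexion_waveform,
    generate_dataset,
    segment_kinematics,
    simulate_recording,
    synthesize_imu,
)
from kneeadl.stream_io import load_manifest


TABLE_ROWS = {
    "walking": (7, 62, 0.94),
    "jogging": (7, 62, 1.4),
    "stair_ascent": (13, 94, 0.56),
    "stair_descent": (14, 98, 0.58),
    "sitting_down": (6, 94, 0.16),
    "standing_up": (6, 94, 0.16),
    "knee_bending": (4, 98, 0.13),
    "standing_still": (7, 13, 0.1),
}


class TestProfiles:
    def test_default_profiles_match_published_kinematics(self, profiles):
        assert set(profiles) == set(ACTIVITY_LABELS)
        for name, (lo, hi, rate) in TABLE_ROWS.items():
            p = profiles[name]
            assert (p.rom_min, p.rom_max, p.rate) == (lo, hi, rate), name

    def test_invalid_rom_rejected(self):
        with pytest.raises(ValueError):
            ActivityProfile("walking", 62, 7, 0.94, Waveform.PERIODIC)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            ActivityProfile("walking", 7, 62, 2.5, Waveform.PERIODIC)


class TestFlexionWaveform:
    def test_walking_cycle_minimum_at_t0(self, profiles):
        assert flexion_waveform(profiles["walking"], 0.0) == pytest.approx(7.0)

    def test_walking_cycle_maximum_at_half_period(self, profiles):
        t_half = 0.5 / 0.94
        assert flexion_waveform(profiles["walking"], t_half) == pytest.approx(62.0)

    def test_standing_still_stays_in_range(self, profiles):
        t = np.linspace(0, 60, 3001)
        theta = flexion_waveform(profiles["standing_still"], t)
        assert theta.min() >= 7.0 and theta.max() <= 13.0

    @pytest.mark.parametrize("name", sorted(TABLE_ROWS))
    def test_output_always_within_rom(self, profiles, name):
        p = profiles[name]
        t = np.linspace(0, 5 * p.period, 2000)
        theta = flexion_waveform(p, t, phase=1.3)
        assert theta.min() >= p.rom_min - 1e-9
        assert theta.max() <= p.rom_max + 1e-9

    def test_negative_t_rejected(self, profiles):
        with pytest.raises(ValueError):
            flexion_waveform(profiles["walking"], -0.1)

    def test_half_cycle_down_ramp_then_constant(self, profiles):
        p = profiles["sitting_down"]
        half = 0.5 / p.rate
        assert flexion_waveform(p, 0.0) == pytest.approx(p.rom_min)
        assert flexion_waveform(p, half) == pytest.approx(p.rom_max)
        assert flexion_waveform(p, half + 5.0) == pytest.approx(p.rom_max)
        t = np.linspace(0, half, 100)
        assert np.all(np.diff(flexion_waveform(p, t)) >= 0)

    def test_half_cycle_up_is_reverse_ramp(self, profiles):
        p = profiles["standing_up"]
        assert flexion_waveform(p, 0.0) == pytest.approx(p.rom_max)
        assert flexion_waveform(p, 10.0) == pytest.approx(p.rom_min)


class TestSegmentKinematics:
    def test_constant_theta_gives_zero_velocity(self, profiles):
        theta = np.full(100, 30.0)
        kin = segment_kinematics(theta, profiles["walking"], 0.02)
        assert np.allclose(kin.femoral_velocity, 0)
        assert np.allclose(kin.tibial_velocity, 0)

    def test_zero_femoral_share_puts_flexion_in_tibia(self):
        p = ActivityProfile("walking", 7, 62, 0.94, Waveform.PERIODIC,
                            femoral_share=0.0)
        theta = flexion_waveform(p, np.arange(200) * 0.02)
        kin = segment_kinematics(theta, p, 0.02)
        assert np.allclose(kin.femoral_orientation, 0)
        assert np.allclose(kin.tibial_orientation, -theta)

    def test_orientation_difference_is_exactly_minus_theta(self, profiles):
        for name in ("walking", "sitting_down", "standing_up"):
            p = profiles[name]
            theta = flexion_waveform(p, np.arange(500) * 0.02)
            kin = segment_kinematics(theta, p, 0.02)
            np.testing.assert_allclose(
                kin.tibial_orientation - kin.femoral_orientation, -theta,
                rtol=0, atol=1e-9)

    def test_walking_spectral_peak_at_cycle_rate(self, profiles):
        p = profiles["walking"]
        dt = 0.02
        theta = flexion_waveform(p, np.arange(3000) * dt)
        kin = segment_kinematics(theta, p, dt)
        spectrum = np.abs(np.fft.rfft(kin.tibial_velocity))
        freqs = np.fft.rfftfreq(3000, dt)
        peak = freqs[1:][np.argmax(spectrum[1:])]  # skip DC
        assert peak == pytest.approx(0.94, abs=0.1)

    def test_empty_series_rejected(self, profiles):
        with pytest.raises(ValueError):
            segment_kinematics(np.array([]), profiles["walking"], 0.02)


class TestSynthesizeImu:
    def test_static_gravity_norm(self, profiles, quiet_config, rng):
        p = profiles["standing_still"]
        theta = flexion_waveform(p, np.arange(500) * 0.02)
        kin = segment_kinematics(theta, p, 0.02)
        stream = synthesize_imu(kin.tibial_orientation, kin.tibial_velocity,
                                quiet_config, "tibial", rng)
        norms = np.linalg.norm(stream.accel, axis=1)
        assert abs(norms.mean() - 9.81) < 0.05

    def test_gravity_norm_with_default_noise(self, profiles, rng):
        config = SimulationConfig(dropout_prob=0.0, start_offset_max=0.0)
        p = profiles["standing_still"]
        theta = flexion_waveform(p, np.arange(2000) * 0.02)
        kin = segment_kinematics(theta, p, 0.02)
        stream = synthesize_imu(kin.tibial_orientation, kin.tibial_velocity,
                                config, "tibial", rng)
        assert 9.6 <= np.linalg.norm(stream.accel, axis=1).mean() <= 10.0

    def test_gyro_integration_recovers_walking_rom(self, profiles, quiet_config):
        # trapezoidal integral of (tibial - femoral) knee-axis gyro over one
        # cycle must recover the 62 - 7 = 55 degree flexion excursion
        fem, tib = simulate_recording(profiles["walking"], quiet_config,
                                      duration_s=4.0,
                                      rng=np.random.Generator(np.random.PCG64(0)))
        diff = tib.gyro[:, 0] - fem.gyro[:, 0]
        t_s = fem.t_ms / 1000.0
        theta_rec = -np.concatenate([[0.0], np.cumsum(
            0.5 * (diff[1:] + diff[:-1]) * np.diff(t_s))])
        excursion = theta_rec.max() - theta_rec.min()
        assert abs(excursion - 55.0) < 2.0

    @pytest.mark.parametrize("name", ["walking", "jogging", "stair_ascent",
                                      "stair_descent"])
    def test_dominant_gyro_frequency_matches_rate(self, profiles, name,
                                                  quiet_config):
        p = profiles[name]
        fem, tib = simulate_recording(p, quiet_config, duration_s=20.0,
                                      rng=np.random.Generator(np.random.PCG64(3)))
        g = tib.gyro[:, 0]
        spectrum = np.abs(np.fft.rfft(g - g.mean()))
        freqs = np.fft.rfftfreq(len(g), 0.02)
        peak = freqs[np.argmax(spectrum)]
        assert peak == pytest.approx(p.rate, abs=0.1)

    def test_same_seed_bit_identical(self, profiles):
        config = SimulationConfig()
        out = []
        for _ in range(2):
            rng = np.random.Generator(np.random.PCG64(7))
            out.append(simulate_recording(profiles["jogging"], config, 5.0, rng))
        (f1, t1), (f2, t2) = out
        assert f1 == f2 and t1 == t2

    def test_start_offsets_within_bound(self, profiles):
        config = SimulationConfig()
        rng = np.random.Generator(np.random.PCG64(11))
        fem, tib = simulate_recording(profiles["walking"], config, 3.0, rng)
        delta = abs(int(fem.t_ms[0]) - int(tib.t_ms[0]))
        assert 0 <= delta <= config.start_offset_max
        assert 0 <= fem.t_ms[0] <= config.start_offset_max
        assert 0 <= tib.t_ms[0] <= config.start_offset_max

    def test_jogging_impacts_add_high_frequency_energy(self, profiles,
                                                       quiet_config):
        rng = np.random.Generator(np.random.PCG64(5))
        fem_j, tib_j = simulate_recording(profiles["jogging"], quiet_config,
                                          5.0, rng)
        no_impact = ActivityProfile("jogging", 7, 62, 1.4, Waveform.PERIODIC,
                                    femoral_share=0.35, impact_amplitude=0.0)
        rng = np.random.Generator(np.random.PCG64(5))
        fem_n, tib_n = simulate_recording(no_impact, quiet_config, 5.0, rng)
        assert tib_j.accel[:, 2].max() > tib_n.accel[:, 2].max() + 1.0

    def test_mismatched_series_lengths_rejected(self, quiet_config, rng):
        with pytest.raises(ValueError):
            synthesize_imu(np.zeros(5), np.zeros(6), quiet_config, "tibial", rng)


class TestGenerateDataset:
    def test_single_rep_gives_eight_recordings_minimum(self, tmp_path):
        config = SimulationConfig(reps_per_class=1, seed=0)
        manifest = generate_dataset(config, output_dir=tmp_path)
        assert len(manifest.recordings) >= 8
        assert {r.activity for r in manifest.recordings} == set(ACTIVITY_LABELS)

    def test_total_reps_meet_quota(self, tmp_path):
        config = SimulationConfig(reps_per_class=5, seed=0)
        manifest = generate_dataset(config, output_dir=tmp_path)
        for label in ACTIVITY_LABELS:
            reps = sum(r.reps for r in manifest.recordings
                       if r.activity == label)
            assert reps >= 5, label

    def test_manifest_round_trips_and_files_exist(self, tmp_path):
        config = SimulationConfig(reps_per_class=1, seed=3)
        generate_dataset(config, output_dir=tmp_path)
        manifest = load_manifest(tmp_path / "manifest.json")
        assert all(manifest.resolve(r.femoral_csv).exists()
                   for r in manifest.recordings)

    def test_byte_identical_under_fixed_seed(self, tmp_path):
        config = SimulationConfig(reps_per_class=2, seed=9)
        dirs = [tmp_path / "a", tmp_path / "b"]
        for d in dirs:
            generate_dataset(config, output_dir=d)
        files_a = sorted(p.name for p in dirs[0].iterdir())
        files_b = sorted(p.name for p in dirs[1].iterdir())
        assert files_a == files_b
        for name in files_a:
            assert (dirs[0] / name).read_bytes() == (dirs[1] / name).read_bytes()

    def test_unwritable_path_raises(self):
        config = SimulationConfig(reps_per_class=1)
        with pytest.raises(OSError):
            generate_dataset(config, output_dir="/proc/nonexistent/dir")
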