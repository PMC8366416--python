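import numpy as np
import pytest
from scipy import signal as sps

from emgdecode.errors import ConfigurationError, DataError
from emgdecode.synthetic import (DEFAULT_PEAK_ANGLE, MOTIONS, DayShiftSpec,
                                 ParadigmSpec, SynergySpec, apply_day_shift,
                                 build_paradigm_angles, default_mixing_matrix,
                                 generate_session, simulate_activations,
                                 synthesize_emg)


class TestParadigmAngles:
    def test_wf_positive_we_negative_on_joint_one_only(self):
        spec = ParadigmSpec(angle_jitter_deg=0.0)
        rec = build_paradigm_angles(spec, seed=0)
        assert rec.samples[:, 0].max() == pytest.approx(DEFAULT_PEAK_ANGLE["WF"], rel=0.01)
        assert rec.samples[:, 0].min() == pytest.approx(DEFAULT_PEAK_ANGLE["WE"], rel=0.01)
        # P/S and HG/HO joints reach their own peaks but joint 0 is flat there
        assert rec.samples[:, 1].max() == pytest.approx(DEFAULT_PEAK_ANGLE["P"], rel=0.01)
        assert rec.samples[:, 2].min() == pytest.approx(DEFAULT_PEAK_ANGLE["HO"], rel=0.01)

    def test_zero_peaks_give_zero_series(self):
        spec = ParadigmSpec(peak_angle={m: 0.0 for m in MOTIONS}, angle_jitter_deg=0.0)
        rec = build_paradigm_angles(spec, seed=1)
        assert np.all(rec.samples == 0.0)

    def test_sample_count_is_duration_times_rate(self):
        # 1 excursion of 2 s + rests of 1 s before/after = 4 s -> 480 samples
        spec = ParadigmSpec(motion_order=("WF",), hold_duration=2.0, rest_duration=1.0)
        rec = build_paradigm_angles(spec, seed=0)
        assert rec.n_samples == int(round(spec.trial_duration * spec.fs_angle))
        assert rec.n_samples == 480

    def test_excursions_start_and_end_at_zero(self):
        spec = ParadigmSpec(angle_jitter_deg=0.0)
        rec = build_paradigm_angles(spec, seed=0)
        n_rest = int(spec.rest_duration * spec.fs_angle)
        assert np.all(rec.samples[:n_rest] == 0.0)
        assert np.all(rec.samples[-n_rest:] == 0.0)

    def test_sign_convention_enforced_in_spec(self):
        with pytest.raises(ConfigurationError):
            ParadigmSpec(peak_angle={**DEFAULT_PEAK_ANGLE, "WE": 30.0})

    def test_sign_conservation_when_both_directions_present(self):
        rec = build_paradigm_angles(ParadigmSpec(), seed=7)
        assert rec.samples[:, 0].max() > 0 and rec.samples[:, 0].min() < 0


class TestActivations:
    def test_constant_zero_angles_give_zero_activations(self):
        spec = ParadigmSpec(peak_angle={m: 0.0 for m in MOTIONS}, angle_jitter_deg=0.0)
        rec = build_paradigm_angles(spec, seed=0)
        acts = simulate_activations(rec)
        assert np.all(acts == 0.0)

    def test_wf_pulse_activates_only_first_primitive(self):
        spec = ParadigmSpec(motion_order=("WF",), angle_jitter_deg=0.0)
        acts = simulate_activations(build_paradigm_angles(spec, seed=0))
        assert acts[:, 0].max() == pytest.approx(1.0)
        assert np.all(acts[:, 1:] == 0.0)

    def test_peak_activation_aligns_with_peak_angle(self):
        spec = ParadigmSpec(motion_order=("P",), angle_jitter_deg=0.0)
        rec = build_paradigm_angles(spec, seed=0)
        acts = simulate_activations(rec)
        assert abs(int(np.argmax(acts[:, 2])) - int(np.argmax(rec.samples[:, 1]))) <= 1

    def test_activations_nonnegative_and_zero_at_rest(self):
        rec = build_paradigm_angles(ParadigmSpec(angle_jitter_deg=0.0), seed=0)
        acts = simulate_activations(rec)
        assert np.all(acts >= 0.0)
        assert np.all(acts[:10] == 0.0)


class TestSynthesizeEmg:
    def test_zero_activation_zero_floor_gives_silence(self):
        spec = SynergySpec(noise_floor=0.0)
        acts = np.zeros((120, 6))
        emg = synthesize_emg(acts, spec, fs_emg=500.0, seed=0)
        assert np.all(emg.samples == 0.0)
        assert emg.n_samples == 500

    def test_envelope_tracks_modulator_on_active_channels(self):
        paradigm = ParadigmSpec(motion_order=("WF", "WE", "P", "S", "HG", "HO"),
                                angle_jitter_deg=0.0)
        spec = SynergySpec()
        rec = build_paradigm_angles(paradigm, seed=3)
        acts = simulate_activations(rec)
        emg = synthesize_emg(acts, spec, fs_emg=500.0, seed=3)
        modulator = acts @ spec.mixing_matrix.T + spec.noise_floor
        t_act = np.arange(len(modulator)) / 120.0
        t_emg = np.arange(emg.n_samples) / 500.0
        sos = sps.butter(4, 5.0, btype="low", fs=500.0, output="sos")
        env = sps.sosfiltfilt(sos, np.abs(emg.samples), axis=0)
        active = np.flatnonzero(spec.mixing_matrix.max(axis=1) >= 1.0)
        for c in active:
            mod_up = np.interp(t_emg, t_act, modulator[:, c])
            r = np.corrcoef(env[:, c], mod_up)[0, 1]
            assert r > 0.8, f"channel {c + 1}: envelope/modulator r={r:.2f}"

    def test_zero_mixing_row_leaves_floor_only(self):
        mix = default_mixing_matrix()
        mix[0, :] = 0.0
        spec = SynergySpec(mixing_matrix=mix, noise_floor=0.1)
        acts = np.ones((240, 6))
        emg = synthesize_emg(acts, spec, fs_emg=500.0, seed=1)
        # rms of floor-only channel is the floor; driven channels are larger
        assert emg.samples[:, 0].std() == pytest.approx(0.1, rel=0.15)
        assert emg.samples[:, 12].std() > 3 * emg.samples[:, 0].std()

    def test_carrier_band_must_respect_nyquist(self):
        spec = SynergySpec(carrier_band=(20.0, 240.0))
        with pytest.raises(ConfigurationError):
            synthesize_emg(np.zeros((10, 6)), spec, fs_emg=400.0, seed=0)

    def test_negative_activations_rejected(self):
        with pytest.raises(DataError):
            synthesize_emg(-np.ones((10, 6)), SynergySpec(), fs_emg=500.0, seed=0)


class TestSession:
    @pytest.mark.parametrize("n_trials", [10, 5])
    def test_trial_counts_for_both_experiment_designs(self, short_paradigm, n_trials):
        session = generate_session(short_paradigm, n_trials=n_trials, seed=0)
        assert session.n_trials == n_trials

    def test_same_seed_reproduces_session(self, short_paradigm):
        a = generate_session(short_paradigm, n_trials=2, seed=5)
        b = generate_session(short_paradigm, n_trials=2, seed=5)
        for (emg_a, ang_a), (emg_b, ang_b) in zip(a.trials, b.trials):
            np.testing.assert_array_equal(emg_a.samples, emg_b.samples)
            np.testing.assert_array_equal(ang_a.samples, ang_b.samples)

    def test_trials_differ_within_session(self, small_session):
        assert not np.array_equal(small_session.trials[0][0].samples,
                                  small_session.trials[1][0].samples)


class TestDayShift:
    def test_identity_shift_is_bitwise_noop(self, small_session):
        shifted = apply_day_shift(small_session, DayShiftSpec())
        for (emg_a, _), (emg_b, _) in zip(small_session.trials, shifted.trials):
            np.testing.assert_array_equal(emg_a.samples, emg_b.samples)

    def test_channel_gain_scales_exactly(self, small_session):
        gains = np.ones(32)
        gains[0] = 2.0
        shifted = apply_day_shift(small_session, DayShiftSpec(channel_gain=gains))
        orig = small_session.trials[0][0].samples
        new = shifted.trials[0][0].samples
        np.testing.assert_array_equal(new[:, 0], orig[:, 0] * 2.0)
        np.testing.assert_array_equal(new[:, 1:], orig[:, 1:])

    def test_layout_shift_permutes_columns(self, small_session):
        from emgdecode.layout import DEFAULT_LAYOUT

        shifted = apply_day_shift(small_session, DayShiftSpec(layout_shift=1))
        orig = small_session.trials[0][0].samples
        new = shifted.trials[0][0].samples
        for ch in range(1, 33):
            side, r, c = DEFAULT_LAYOUT.position(ch)
            src = DEFAULT_LAYOUT.channel_at(side, r, (c - 1) % 4)
            np.testing.assert_array_equal(new[:, ch - 1], orig[:, src - 1])

    def test_angles_unchanged_by_shift(self, small_session):
        shifted = apply_day_shift(small_session, DayShiftSpec.random(9))
        for (_, ang_a), (_, ang_b) in zip(small_session.trials, shifted.trials):
            np.testing.assert_array_equal(ang_a.samples, ang_b.samples)

    def test_invalid_shift_specs_rejected(self):
        with pytest.raises(ConfigurationError):
            DayShiftSpec(layout_shift=4)
        with pytest.raises(ConfigurationError):
            DayShiftSpec(channel_gain=np.zeros(32))
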