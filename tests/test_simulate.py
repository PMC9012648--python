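"""Synthetic-session generator: rendering, projection, noise, acquisition."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.signal import fftconvolve

from abrreref.simulate import (
    ContinuousRecording,
    Dipole,
    NoiseModel,
    Session,
    SessionConfig,
    acquire_against_reference,
    add_background_noise,
    project_to_scalp,
    render_source_timecourse,
    simulate_session,
)
from abrreref.template import StimulusTrain


def _brainstem(template):
    return replace(template, components=tuple(
        c for c in template.components if c.name != "MLR"))


class TestRenderSourceTimecourse:
    def test_single_stimulus_is_bare_kernel(self, template):
        train = StimulusTrain(25.0, 75.0, n_stimuli=1)
        wave, onsets = render_source_timecourse(template, train, 20000.0)
        kernel = template.kernel(25.0, 75.0, 20000.0)
        n = min(len(wave), len(kernel))
        assert np.array_equal(wave[:n], kernel[:n])
        assert list(onsets) == [0]

    def test_matches_fftconvolve_superposition_oracle(self, template):
        # independent construction: impulse train convolved with the kernel
        train = StimulusTrain(100.0, 75.0, n_stimuli=50)
        fs = 20000.0
        wave, onsets = render_source_timecourse(template, train, fs)
        impulses = np.zeros(len(wave))
        impulses[onsets] = 1.0
        oracle = fftconvolve(impulses, template.kernel(100.0, 75.0, fs))[: len(wave)]
        assert np.allclose(wave, oracle, atol=1e-9 * np.max(np.abs(wave)))

    def test_no_overlap_at_25_per_s_with_short_template(self, template):
        # brainstem-only support < 40 ms inter-stimulus interval
        bs = _brainstem(template)
        train = StimulusTrain(25.0, 75.0, n_stimuli=8)
        wave, onsets = render_source_timecourse(bs, train, 20000.0)
        kernel = bs.kernel(25.0, 75.0, 20000.0)
        assert len(kernel) < 800
        for on in onsets[:-1]:
            seg = wave[on:on + len(kernel)]
            assert np.max(np.abs(seg - kernel)) < 1e-12

    def test_mlr_overlaps_following_epochs_at_100_per_s(self, template):
        # 10 ms inter-stimulus interval < MLR support: epochs after the first
        # differ from the isolated-stimulus kernel
        train = StimulusTrain(100.0, 75.0, n_stimuli=20)
        wave, onsets = render_source_timecourse(template, train, 20000.0)
        kernel = template.kernel(100.0, 75.0, 20000.0)
        seg = wave[onsets[10]:onsets[10] + 200]
        assert np.max(np.abs(seg - kernel[:200])) > 0.01 * np.max(np.abs(kernel))

    def test_low_sampling_rate_rejected(self, template):
        with pytest.raises(ValueError, match="4 kHz"):
            render_source_timecourse(template, StimulusTrain(25.0, 75.0, 1), 1000.0)


class TestProjectToScalp:
    def test_zero_wave_gives_zero_scalp(self, recording_leadfield):
        d = Dipole([0.0, 0.0, 0.03], [0.0, 0.0, 1.0])
        rec = project_to_scalp(np.zeros(100), d, recording_leadfield)
        assert not rec.data.any()
        assert rec.reference == "infinity"

    def test_linearity_in_source_amplitude(self, recording_leadfield, rng):
        wave = rng.standard_normal(200)
        d = Dipole([0.0, 0.01, 0.04], [0.5, 0.0, 1.0])
        r1 = project_to_scalp(wave, d, recording_leadfield)
        r2 = project_to_scalp(2 * wave, d, recording_leadfield)
        assert np.allclose(r2.data, 2 * r1.data)

    def test_deep_midline_source_polarity(self, montage, head):
        # superior dipole near the centre: vertex positive, mastoids negative
        from abrreref.forward import dipole_gains

        g = dipole_gains(montage, head, [0.0, 0.02, 0.01], [0.0, 0.2873, 0.9578])[:, 0]
        g_cz = g[montage.names.index("Cz")]
        g_m1 = g[montage.names.index("M1")]
        assert abs(g_cz) > abs(g_m1)
        assert g_cz > 0 > g_m1

    def test_leadfield_without_geometry_rejected(self, recording_leadfield):
        from abrreref.forward import LeadField

        bare = LeadField(recording_leadfield.matrix, recording_leadfield.channel_names,
                         "x")
        with pytest.raises(ValueError, match="geometry"):
            project_to_scalp(np.zeros(10), Dipole([0, 0, 0.03], [0, 0, 1]), bare)


@pytest.fixture(scope="module")
def clean(recording_leadfield):
    data = np.zeros((len(recording_leadfield.channel_names), 40000), np.float32)
    return ContinuousRecording(data, 20000.0, [0], recording_leadfield.channel_names)


class TestBackgroundNoise:
    def test_zero_noise_is_identity(self, clean, recording_leadfield):
        model = NoiseModel(scalp_rms_uV=0.0, sensor_noise_rms_uV=0.0, seed=1)
        assert add_background_noise(clean, model, recording_leadfield) is clean

    def test_same_seed_bit_identical(self, clean, recording_leadfield):
        model = NoiseModel(seed=42)
        a = add_background_noise(clean, model, recording_leadfield)
        b = add_background_noise(clean, model, recording_leadfield)
        assert np.array_equal(a.data, b.data)

    def test_channel_rms_matches_target(self, clean, recording_leadfield):
        model = NoiseModel(scalp_rms_uV=8.0, sensor_noise_rms_uV=0.0, seed=3)
        out = add_background_noise(clean, model, recording_leadfield)
        rms = np.sqrt(np.mean(out.data.astype(np.float64) ** 2, axis=1))
        assert np.mean(rms) == pytest.approx(8.0, rel=0.10)

    def test_missing_seed_rejected(self, clean, recording_leadfield):
        with pytest.raises(ValueError, match="seed"):
            add_background_noise(clean, NoiseModel(), recording_leadfield)


class TestAcquisition:
    def test_subtracts_reference_entrywise(self):
        data = np.array([[1.0, 2.0], [3.0, 5.0], [2.0, 2.0]])
        rec = ContinuousRecording(data, 20000.0, [], ("A", "B", "REF"))
        out = acquire_against_reference(rec, "REF")
        assert out.channel_names == ("A", "B")
        assert np.array_equal(out.data, [[-1.0, 0.0], [1.0, 3.0]])
        assert out.reference == "REF"

    def test_common_mode_removed(self):
        data = np.tile([[1.0, -2.0, 3.0]], (4, 1))
        rec = ContinuousRecording(data, 20000.0, [], ("A", "B", "C", "REF"))
        out = acquire_against_reference(rec, "REF")
        assert not out.data.any()

    def test_second_application_is_noop(self):
        data = np.arange(6.0).reshape(3, 2)
        rec = ContinuousRecording(data, 20000.0, [], ("A", "B", "REF"))
        once = acquire_against_reference(rec, "REF")
        twice = acquire_against_reference(once, "REF")
        assert twice is once

    def test_unknown_reference_rejected(self):
        rec = ContinuousRecording(np.zeros((2, 5)), 20000.0, [], ("A", "B"))
        with pytest.raises(KeyError, match="XX"):
            acquire_against_reference(rec, "XX")


class TestSession:
    def test_trial_duration_and_event_count(self, noiseless_session):
        rec = noiseless_session.simulate_trial(0, 25.0, 75.0)
        assert rec.n_samples == 200 * 20000 // 25  # n_stimuli / rate seconds
        assert len(rec.events) == 200
        assert rec.reference == "REF"
        assert "REF" not in rec.channel_names and len(rec.channel_names) == 32

    def test_identical_seed_bit_identical_recordings(self):
        cfg = SessionConfig(n_subjects=1, conditions=((50.0, 80.0),), n_stimuli=20,
                            n_trials=1, seed=11)
        a = Session(cfg).simulate_trial(0, 50.0, 80.0, 0)
        b = Session(cfg).simulate_trial(0, 50.0, 80.0, 0)
        assert np.array_equal(a.data, b.data)

    def test_trials_share_truth_but_differ_in_noise(self):
        cfg = SessionConfig(n_subjects=1, conditions=((50.0, 80.0),), n_stimuli=20,
                            n_trials=2, seed=11)
        ses = Session(cfg)
        t0 = ses.simulate_trial(0, 50.0, 80.0, 0)
        t1 = ses.simulate_trial(0, 50.0, 80.0, 1)
        assert not np.array_equal(t0.data, t1.data)
        assert len(ses.ground_truth) == 1

    def test_doubling_template_amplitudes_doubles_clean_output(self, template):
        cfg = SessionConfig(n_subjects=1, conditions=((50.0, 80.0),), n_stimuli=5,
                            n_trials=1, seed=2, noise_enabled=False,
                            amplitude_jitter=0, depth_jitter=0,
                            orientation_jitter_deg=0)
        base = Session(cfg, template=template).simulate_trial(0, 50.0, 80.0)
        doubled_t = template.scaled({c.name: 2.0 for c in template.components})
        doubled = Session(cfg, template=doubled_t).simulate_trial(0, 50.0, 80.0)
        assert np.allclose(doubled.data, 2 * base.data, rtol=1e-5, atol=1e-7)

    def test_ground_truth_wave_v_latency_monotone(self):
        rates = ((10.0, 75.0), (25.0, 75.0), (50.0, 75.0), (100.0, 75.0))
        levels = tuple((25.0, l) for l in (80.0, 65.0, 50.0))
        cfg = SessionConfig(n_subjects=1, conditions=rates + levels, n_stimuli=1,
                            n_trials=1, seed=0, noise_enabled=False)
        ses = Session(cfg)
        v_rate = [ses.ground_truth[(0, r, 75.0)].true_latencies_ms["V"]
                  for r, _ in rates]
        assert all(b > a for a, b in zip(v_rate, v_rate[1:]))
        v_level = [ses.ground_truth[(0, 25.0, l)].true_latencies_ms["V"]
                   for _, l in levels]
        assert all(b > a for a, b in zip(v_level, v_level[1:]))

    def test_simulate_session_collect_yields_all_trials(self):
        ses = simulate_session(n_subjects=2, conditions=((50.0, 80.0),),
                               n_stimuli=5, n_trials=2, seed=3,
                               noise_enabled=False)
        trials = ses.collect()
        assert len(trials) == 4
        assert {(t.subject, t.trial) for t in trials} == {(0, 0), (0, 1), (1, 0), (1, 1)}
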