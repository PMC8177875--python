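"""Cleaning chain: filters, artifact event detection, SSP, segment handling."""

import numpy as np
import pytest

from alpharatio.cohortsim import Recording, make_channel_meta
from alpharatio.exceptions import InsufficientDataError, InvalidArgumentError
from alpharatio.preprocess import (
    PreprocessConfig,
    Projector,
    apply_projector,
    bandpass_filter,
    compute_ssp,
    detect_artifact_events,
    drop_bad_segments,
    notch_filter,
    preprocess_recording,
)
from alpharatio.spectral import welch_psd

from conftest import make_recording, tone

FS = 600.0


def psd_at(rec, freq):
    psd = welch_psd(rec)
    return psd.power[:, np.argmin(np.abs(psd.freqs - freq))]


def _ricker_train(duration, fs, period=1.0, a=0.015):
    t = np.arange(int(duration * fs)) / fs
    out = np.zeros_like(t)
    w = np.arange(-0.06, 0.06 + 0.5 / fs, 1 / fs)
    wave = (1 - (w / a) ** 2) * np.exp(-(w**2) / (2 * a**2))
    starts = np.arange(0.5, duration - 0.5, period)
    for s in starts:
        c = int(round(s * fs))
        out[c - len(wave) // 2 : c - len(wave) // 2 + len(wave)] += wave
    return out, starts


class TestNotch:
    def test_tone_attenuated_passband_untouched(self, rng):
        noise = 0.05 * rng.standard_normal((2, int(60 * FS)))
        rec = make_recording(noise + tone(50, 60, FS) + tone(10, 60, FS), FS)
        out = notch_filter(rec, [50.0])
        atten_50 = 10 * np.log10(psd_at(rec, 50) / psd_at(out, 50))
        change_10 = np.abs(10 * np.log10(psd_at(rec, 10) / psd_at(out, 10)))
        assert np.all(atten_50 >= 30)
        assert np.all(change_10 < 1)

    def test_empty_freq_list_is_identity(self, rng):
        rec = make_recording(rng.standard_normal((2, 1000)), FS)
        out = notch_filter(rec, [])
        np.testing.assert_array_equal(out.data, rec.data)

    def test_frequency_at_or_above_nyquist_rejected(self, rng):
        rec = make_recording(rng.standard_normal((2, 1000)), FS)
        with pytest.raises(InvalidArgumentError, match="Nyquist"):
            notch_filter(rec, [300.0])


class TestBandpass:
    def test_drift_removed_tone_kept(self, rng):
        sig = tone(0.2, 60, FS) + tone(10, 60, FS) + 0.01 * rng.standard_normal((2, int(60 * FS)))
        rec = make_recording(sig, FS)
        out = bandpass_filter(rec, 1.0, 200.0)
        atten_drift = 10 * np.log10(psd_at(rec, 0.25) / psd_at(out, 0.25))
        change_10 = np.abs(10 * np.log10(psd_at(rec, 10) / psd_at(out, 10)))
        assert np.all(atten_drift >= 20)
        assert np.all(change_10 < 1)

    def test_band_interior_signal_nearly_unchanged_and_zero_phase(self):
        x = tone(10, 30, FS)
        rec = make_recording(np.vstack([x, x]), FS)
        out = bandpass_filter(rec, 1.0, 200.0)
        core = slice(int(2 * FS), int(28 * FS))  # ignore edge transients
        rms = np.sqrt(np.mean(rec.data[0, core] ** 2))
        assert np.max(np.abs(out.data[0, core] - rec.data[0, core])) < 0.01 * rms
        # zero-phase: cross-correlation peak at zero lag
        xc = np.correlate(out.data[0, core], rec.data[0, core], mode="full")
        lag = np.argmax(xc) - (len(rec.data[0, core]) - 1)
        assert abs(lag) <= 1

    @pytest.mark.parametrize("low,high", [(200.0, 1.0), (0.0, 10.0), (1.0, 400.0)])
    def test_invalid_edges_rejected(self, rng, low, high):
        rec = make_recording(rng.standard_normal((2, 1000)), FS)
        with pytest.raises(InvalidArgumentError):
            bandpass_filter(rec, low, high)

    def test_filters_are_linear(self, rng):
        x = rng.standard_normal((2, int(20 * FS)))
        y = rng.standard_normal((2, int(20 * FS)))
        a, b = 2.5, -1.3

        for filt in (
            lambda r: bandpass_filter(r, 1.0, 200.0),
            lambda r: notch_filter(r, [50.0]),
        ):
            fx = filt(make_recording(x, FS)).data
            fy = filt(make_recording(y, FS)).data
            fxy = filt(make_recording(a * x + b * y, FS)).data
            np.testing.assert_allclose(fxy, a * fx + b * fy, rtol=1e-8, atol=1e-10)


class TestEventDetection:
    def test_cardiac_reference_at_60_bpm(self, rng):
        ref, starts = _ricker_train(60, FS, period=1.0)
        ref = ref + 0.02 * rng.standard_normal(len(ref))
        events = detect_artifact_events(ref, FS, kind="cardiac")
        assert abs(len(events) - len(starts)) <= 2
        gaps = np.diff(events)
        assert abs(np.median(gaps) - 1.0) <= 0.05

    def test_flat_reference_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="flat"):
            events = detect_artifact_events(np.zeros(6000), FS, kind="cardiac")
        assert len(events) == 0

    def test_refractory_merges_close_peaks(self, rng):
        fs = 600.0
        ref = np.zeros(int(10 * fs))
        w = np.arange(-0.06, 0.06 + 0.5 / fs, 1 / fs)
        wave = (1 - (w / 0.015) ** 2) * np.exp(-(w**2) / (2 * 0.015**2))
        for t0 in (5.0, 5.1):  # two peaks inside one 0.3 s refractory window
            c = int(t0 * fs)
            ref[c - len(wave) // 2 : c - len(wave) // 2 + len(wave)] += wave
        ref += 0.01 * rng.standard_normal(len(ref))
        events = detect_artifact_events(ref, fs, kind="cardiac")
        assert len(events) == 1


class TestSSP:
    @pytest.fixture
    def artifact_recording(self, rng):
        """Rank-1 artifact with a known topography plus background noise."""
        n_ch, dur = 16, 120
        train, starts = _ricker_train(dur, FS, period=1.0)
        topo = rng.standard_normal(n_ch)
        topo /= np.linalg.norm(topo)
        data = 0.1 * rng.standard_normal((n_ch, len(train))) + 3.0 * np.outer(topo, train)
        rec = make_recording(data, FS, reference_channels={"cardiac": train.copy()})
        return rec, topo, starts

    def test_first_component_recovers_topography(self, artifact_recording):
        rec, topo, starts = artifact_recording
        proj = compute_ssp(rec, starts, window=(0.2, 0.4), n_components=1)
        cosine = abs(float(proj.basis[:, 0] @ topo))
        assert cosine > 0.99
        assert proj.explained_fraction[0] > 0.9

    def test_projection_removes_event_locked_average(self, artifact_recording):
        rec, _, starts = artifact_recording
        proj = compute_ssp(rec, starts, window=(0.2, 0.4), n_components=1)
        clean = apply_projector(rec, proj)

        def evoked_rms(r):
            epochs = [
                r.data[:, int(t * FS) - 120 : int(t * FS) + 240]
                for t in starts
                if int(t * FS) - 120 >= 0 and int(t * FS) + 240 <= r.n_samples
            ]
            avg = np.mean(epochs, axis=0)
            avg -= avg.mean(axis=1, keepdims=True)
            return float(np.sqrt((avg**2).mean()))

        assert evoked_rms(clean) <= 0.1 * evoked_rms(rec)

    def test_projector_idempotent_and_never_inflates_variance(self, artifact_recording):
        rec, _, starts = artifact_recording
        proj = compute_ssp(rec, starts, window=(0.2, 0.4), n_components=2)
        once = apply_projector(rec, proj)
        twice = apply_projector(once, proj)
        scale = float(np.sqrt(np.mean(once.data**2)))
        assert np.max(np.abs(twice.data - once.data)) < 1e-10 * scale
        assert np.all(once.data.var(axis=1) <= rec.data.var(axis=1) + 1e-12)
        # covariance rank drops by n_components
        ev = np.linalg.eigvalsh(np.cov(once.data))
        assert (ev < 1e-10 * ev.max()).sum() >= proj.n_components

    def test_zero_components_rejected(self, artifact_recording):
        rec, _, starts = artifact_recording
        with pytest.raises(InvalidArgumentError):
            compute_ssp(rec, starts, n_components=0)

    def test_too_few_epochs_named_in_error(self, artifact_recording):
        rec, _, starts = artifact_recording
        with pytest.raises(InsufficientDataError, match="3"):
            compute_ssp(rec, starts[:3], n_components=1)

    def test_pure_noise_epochs_have_low_explained_fraction(self, rng):
        rec = make_recording(rng.standard_normal((16, int(120 * FS))), FS)
        events = np.arange(1.0, 119.0, 1.0)
        proj = compute_ssp(rec, events, window=(0.2, 0.4), n_components=1)
        assert proj.explained_fraction[0] < 0.5

    def test_empty_basis_is_identity(self, rng):
        rec = make_recording(rng.standard_normal((4, 1000)), FS)
        proj = Projector(basis=np.zeros((4, 0)))
        out = apply_projector(rec, proj)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_channel_mismatch_rejected(self, rng):
        rec = make_recording(rng.standard_normal((4, 1000)), FS)
        basis = np.eye(6)[:, :1]
        with pytest.raises(InvalidArgumentError):
            apply_projector(rec, Projector(basis=basis))


class TestSegments:
    def test_no_annotations_returns_full_recording(self, rng):
        rec = make_recording(rng.standard_normal((2, int(60 * FS))), FS)
        segs = drop_bad_segments(rec)
        assert len(segs) == 1
        assert segs[0].n_samples == rec.n_samples

    def test_interval_arithmetic(self, rng):
        rec = make_recording(
            rng.standard_normal((2, int(60 * FS))), FS, annotations=[(10.0, 20.0, "muscle")]
        )
        segs = drop_bad_segments(rec)
        assert [round(s.duration) for s in segs] == [10, 40]

    def test_short_gap_discarded(self, rng, caplog):
        import logging

        rec = make_recording(
            rng.standard_normal((2, int(60 * FS))),
            FS,
            annotations=[(10.0, 20.0, "a"), (22.0, 40.0, "b")],
        )
        with caplog.at_level(logging.INFO, logger="alpharatio.preprocess"):
            segs = drop_bad_segments(rec, min_duration=4.0)
        assert [round(s.duration) for s in segs] == [10, 20]
        assert "discarded 1 segment" in caplog.text

    def test_annotation_outside_recording_rejected(self, rng):
        with pytest.raises(InvalidArgumentError, match="outside"):
            make_recording(
                rng.standard_normal((2, 1000)), FS, annotations=[(1.0, 100.0, "late")]
            )

    def test_overlapping_annotations_merged(self, rng):
        rec = make_recording(
            rng.standard_normal((2, int(60 * FS))),
            FS,
            annotations=[(10.0, 25.0, "a"), (20.0, 30.0, "b")],
        )
        segs = drop_bad_segments(rec)
        assert [round(s.duration) for s in segs] == [10, 30]


class TestFullChain:
    def test_preprocess_log_structure(self):
        from alpharatio.cohortsim import OscillatorSpec, SubjectSpec, simulate_subject

        spec = SubjectSpec(group="control", oscillators=[OscillatorSpec(10.25)], seed=1)
        rec = simulate_subject(spec, duration=60, sampling_rate=600, n_channels=8)
        segments, log = preprocess_recording(rec, PreprocessConfig())
        assert len(segments) >= 1
        assert log["events"]["cardiac"] > 30
        assert "cardiac" in log["projectors"]
        assert log["n_segments"] == len(segments)

    def test_preprocessing_preserves_rate_metadata_duration(self):
        from alpharatio.cohortsim import SubjectSpec, simulate_subject

        rec = simulate_subject(SubjectSpec(group="c", seed=2), duration=30,
                               sampling_rate=600, n_channels=4)
        out = bandpass_filter(notch_filter(rec, [50.0]), 1.0, 200.0)
        assert out.sampling_rate == rec.sampling_rate
        assert out.n_samples == rec.n_samples
        assert out.channel_meta.equals(rec.channel_meta)
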