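"""Baseline correction, elliptic alpha bandpass, ICA rejection, epoching."""

import numpy as np
import pytest
from scipy import signal as sps

from vmibci.preprocess import (
    Recording,
    TrialEpoch,
    bandpass_alpha,
    correct_baseline,
    extract_epochs,
    fit_ica,
    preprocess_session,
    reject_components,
    _design_bandpass,
)
from vmibci.synth import SynthConfig, generate_session

FS = 250.0


def one_channel(x, fs=FS):
    return Recording(
        data=np.atleast_2d(x), fs=fs, channel_labels=["O1"], subject=0
    )


class TestRecordingTypes:
    def test_label_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="channel labels"):
            Recording(np.zeros((3, 10)), FS, ["a", "b"])

    def test_nonfinite_rejected(self):
        data = np.zeros((1, 10))
        data[0, 3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            Recording(data, FS, ["a"])

    def test_epoch_label_sets_closed(self):
        with pytest.raises(ValueError, match="task"):
            TrialEpoch(np.zeros((1, 10)), FS, ["a"], "sideways", "imagine", 0, 0)
        with pytest.raises(ValueError, match="phase"):
            TrialEpoch(np.zeros((1, 10)), FS, ["a"], "forward", "dream", 0, 0)

    def test_channel_lookup_by_label(self):
        rec = Recording(np.arange(20.0).reshape(2, 10), FS, ["O1", "O2"])
        assert np.array_equal(rec.channel("O2"), np.arange(10.0, 20.0))
        with pytest.raises(KeyError):
            rec.channel("Cz")


class TestCorrectBaseline:
    def test_constant_channel_zeroed(self):
        out = correct_baseline(one_channel(np.full(100, 5.0)))
        assert np.allclose(out.data, 0.0, atol=1e-9)

    def test_ramp_zeroed(self):
        out = correct_baseline(one_channel(0.3 * np.arange(200.0)))
        assert np.allclose(out.data, 0.0, atol=1e-9)

    def test_sinusoid_plus_ramp_matches_least_squares(self):
        t = np.arange(500) / FS
        x = np.sin(2 * np.pi * 10 * t) + 2.5 * t + 1.0
        out = correct_baseline(one_channel(x))
        # closed-form: subtract the best-fit line of the full signal
        slope, intercept = np.polyfit(np.arange(500.0), x, 1)
        expected = x - (slope * np.arange(500.0) + intercept)
        assert np.allclose(out.data[0], expected, atol=1e-9)
        assert abs(out.data[0].mean()) < 1e-9


class TestBandpass:
    def test_designed_response_meets_template(self):
        sos = _design_bandpass(8.0, 13.0, FS)
        w, h = sps.sosfreqz(sos, worN=8192, fs=FS)
        mag2 = np.abs(h) ** 2  # net forward-backward magnitude

        def net(freq):
            return mag2[np.argmin(np.abs(w - freq))]

        assert net(10.0) >= 0.89
        assert net(2.0) <= 0.032
        for f_stop in (4.0, 26.0):
            assert net(f_stop) <= 10 ** (-30 / 10)

    def test_inband_tone_preserved_stopband_tone_crushed(self):
        t = np.arange(0, 4, 1 / FS)
        rec = one_channel(np.cos(2 * np.pi * 10 * t))
        out = bandpass_alpha(rec)
        assert out.data[0][200:-200].max() >= 0.89
        low = bandpass_alpha(one_channel(np.cos(2 * np.pi * 2 * t)))
        assert np.abs(low.data[0][200:-200]).max() <= 0.032

    def test_zero_in_zero_out(self):
        out = bandpass_alpha(one_channel(np.zeros(1000)))
        assert np.all(out.data == 0)

    def test_linearity(self, rng):
        x, y = rng.standard_normal((2, 1000))
        fx = bandpass_alpha(one_channel(x)).data
        fy = bandpass_alpha(one_channel(y)).data
        fxy = bandpass_alpha(one_channel(2.0 * x - 3.0 * y)).data
        assert np.allclose(fxy, 2.0 * fx - 3.0 * fy, rtol=1e-9, atol=1e-9)

    def test_zero_phase_no_lag(self):
        t = np.arange(0, 4, 1 / FS)
        x = np.cos(2 * np.pi * 10 * t)
        y = bandpass_alpha(one_channel(x)).data[0]
        xc = np.correlate(y[200:-200], x[200:-200], mode="full")
        lag = np.argmax(xc) - (len(y[200:-200]) - 1)
        assert lag == 0

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_alpha(one_channel(np.zeros(100), fs=20.0))


@pytest.fixture(scope="module")
def blink_session():
    cfg = SynthConfig(n_blocks=3, blink_rate=12.0, seed=3)
    rec, _ = generate_session(cfg, 0)
    clean, _ = generate_session(cfg.with_(blink_rate=0.0), 0)
    model = fit_ica(correct_baseline(rec), seed=0)
    return rec, clean, model


class TestIca:
    def test_blink_component_found_and_scored(self, blink_session):
        _, _, model = blink_session
        assert model.rejected
        assert {"fp2_abs_r", "kurtosis"} <= set(model.rule_scores.columns)
        assert len(model.rule_scores) == 18
        flagged = model.rule_scores.loc[sorted(model.rejected)]
        assert (
            (flagged["fp2_abs_r"] >= 0.7) | (flagged["kurtosis"] >= 10)
        ).all()

    def test_rejection_suppresses_blink_peaks(self, blink_session):
        rec, clean, model = blink_session
        detrended = correct_baseline(rec)
        out = reject_components(model, detrended)
        blink_only = rec.channel("Fp2") - clean.channel("Fp2")
        peaks = np.flatnonzero(blink_only > 60.0)
        assert peaks.size > 0
        before = np.abs(detrended.channel("Fp2")[peaks]).max()
        after = np.abs(out.channel("Fp2")[peaks]).max()
        assert after <= 0.2 * before
        # occipital signal variance is not inflated by the cleanup
        assert out.channel("O1").var() <= 1.01 * detrended.channel("O1").var()

    def test_round_trip_identity_without_rejection(self, blink_session):
        rec, _, model = blink_session
        detrended = correct_baseline(rec)
        model_keep = type(model)(
            unmixing=model.unmixing, mixing=model.mixing, mean=model.mean,
            rejected=set(), rule_scores=model.rule_scores,
            channel_labels=model.channel_labels,
        )
        out = reject_components(model_keep, detrended)
        rel = np.linalg.norm(out.data - detrended.data) / np.linalg.norm(
            detrended.data
        )
        assert rel < 1e-6

    def test_rejecting_everything_zeroes_detrended_recording(
        self, blink_session
    ):
        rec, _, model = blink_session
        detrended = correct_baseline(rec)
        model_all = type(model)(
            unmixing=model.unmixing, mixing=model.mixing, mean=model.mean,
            rejected=set(range(18)), rule_scores=model.rule_scores,
            channel_labels=model.channel_labels,
        )
        out = reject_components(model_all, detrended)
        assert np.abs(out.data).max() < 0.05 * np.abs(detrended.data).max()

    def test_rank_deficient_data_rejected(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((17, 4000))
        data = np.vstack([base, base[0]])  # duplicated channel
        rec = Recording(data, FS, list(SynthConfig().channel_labels))
        with pytest.raises(ValueError, match="rank"):
            fit_ica(rec, seed=0)


class TestExtractEpochs:
    def test_epoch_count_and_shape(self, small_session, alpha_epochs):
        cfg, _, _ = small_session
        assert len(alpha_epochs) == 4 * cfg.n_blocks
        for ep in alpha_epochs:
            assert ep.data.shape == (18, 750)
            assert ep.duration == pytest.approx(3.0)
            assert ep.phase == "imagine"

    def test_task_balance(self, alpha_epochs):
        tasks = [e.task for e in alpha_epochs]
        for t in ("forward", "reverse", "left", "right"):
            assert tasks.count(t) == 10

    def test_window_is_index_exact_and_idempotent(self, small_session):
        _, rec, events = small_session
        a = extract_epochs(rec, events)
        b = extract_epochs(rec, events)
        assert all(np.array_equal(x.data, y.data) for x, y in zip(a, b))
        ev = events[events["phase"] == "imagine"].iloc[0]
        start = int(round((ev.onset + 1.0) * rec.fs))
        assert np.array_equal(a[0].data, rec.data[:, start : start + 750])

    def test_out_of_bounds_event_reported(self, small_session):
        _, rec, events = small_session
        late = events.copy()
        late.loc[late.index[-2], "onset"] = rec.duration - 2.0
        with pytest.raises(ValueError, match="outside"):
            extract_epochs(rec, late)

    def test_event_at_time_zero_is_valid(self):
        rec = Recording(
            np.zeros((1, 2000)), FS, ["O1"], subject=0
        )
        import pandas as pd

        events = pd.DataFrame(
            [dict(onset=0.0, duration=5.0, task="forward", phase="imagine",
                  block=0, subject=0)]
        )
        eps = extract_epochs(rec, events)
        assert len(eps) == 1 and eps[0].data.shape == (1, 750)


class TestPreprocessSession:
    def test_epochs_are_detrended_and_band_limited(self, alpha_epochs):
        ep = alpha_epochs[0]
        assert np.abs(ep.data.mean(axis=1)).max() < 1e-6
        f, p = sps.welch(ep.channel("O1"), fs=ep.fs, nperseg=512)
        inband = p[(f >= 7) & (f <= 14)].sum()
        assert inband / p.sum() > 0.95

    def test_invalid_ica_stage_rejected(self, small_session):
        _, rec, events = small_session
        with pytest.raises(ValueError, match="ica_stage"):
            preprocess_session(rec, events, ica_stage="mid-band")
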