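"""Preprocessing of multi-channel EEG: baseline correction, zero-phase
elliptic alpha-band filtering, ICA artifact rejection, and epoch extraction.

The stage order follows the analysis it serves: drift/baseline removal,
8-13 Hz elliptic bandpass (order 4, 0.5 dB ripple, 40 dB stopband, applied
forward-backward so the net response is eighth order and zero phase), ICA
removal of ocular/myographic components, then extraction of the 1-4 s
window of each 5 s task event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats
from sklearn.decomposition import FastICA

__all__ = [
    "Recording",
    "TrialEpoch",
    "IcaModel",
    "correct_baseline",
    "bandpass_alpha",
    "fit_ica",
    "reject_components",
    "extract_epochs",
    "preprocess_session",
]

TASK_LABELS = ("forward", "reverse", "left", "right")
PHASE_LABELS = ("observe", "imagine")


@dataclass
class Recording:
    """A continuous multi-channel recording in microvolts."""

    data: np.ndarray  # channels x samples
    fs: float
    channel_labels: list[str]
    subject: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            i = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in {self.channel_labels}"
            ) from None
        return self.data[i]

    def copy_with(self, data: np.ndarray) -> "Recording":
        return _dc_replace(self, data=data)


@dataclass
class TrialEpoch:
    """One labelled 3 s analysis segment (channels x samples, microvolts)."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    task: str
    phase: str
    subject: int
    block: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.task not in TASK_LABELS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.phase not in PHASE_LABELS:
            raise ValueError(f"unknown phase {self.phase!r}")

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            i = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in {self.channel_labels}"
            ) from None
        return self.data[i]

    def copy_with(self, data: np.ndarray) -> "TrialEpoch":
        return _dc_replace(self, data=data)


@dataclass
class IcaModel:
    """Fitted ICA decomposition with per-component artifact diagnostics.

    ``rule_scores`` holds, per component, the absolute Pearson correlation of
    its time course with the Fp2 channel (ocular proxy) and its excess
    kurtosis; ``rejected`` is the set flagged by the rule |r| >= 0.7 or
    kurtosis >= 10.
    """

    unmixing: np.ndarray  # components x channels
    mixing: np.ndarray  # channels x components
    mean: np.ndarray  # per-channel mean removed before unmixing
    rejected: set[int]
    rule_scores: pd.DataFrame
    channel_labels: list[str]


# ---------------------------------------------------------------------------


def correct_baseline(x: Recording | TrialEpoch):
    """Remove the per-channel least-squares linear trend (intercept +
    slope). Channel means of the output are zero to numerical precision."""
    detrended = sps.detrend(x.data, axis=-1, type="linear")
    return x.copy_with(detrended)


def _design_bandpass(low: float, high: float, fs: float) -> np.ndarray:
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= fs / 2:
        raise ValueError(
            f"bandpass edge {high} Hz not below Nyquist ({fs / 2} Hz)"
        )
    return sps.ellip(4, 0.5, 40.0, [low, high], btype="bandpass",
                     fs=fs, output="sos")


def bandpass_alpha(x: Recording | TrialEpoch, low: float = 8.0,
                   high: float = 13.0):
    """Zero-phase elliptic bandpass (default 8-13 Hz alpha band), applied
    forward-backward per channel."""
    sos = _design_bandpass(low, high, x.fs)
    filtered = sps.sosfiltfilt(sos, x.data, axis=-1)
    return x.copy_with(filtered)


# ---------------------------------------------------------------------------
# ICA


def _highpass(data: np.ndarray, fs: float, cutoff: float = 0.5) -> np.ndarray:
    sos = sps.butter(4, cutoff, btype="highpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, data, axis=-1)


def fit_ica(
    rec: Recording,
    n_components: int | None = None,
    seed: int = 0,
    r_threshold: float = 0.7,
    kurtosis_threshold: float = 10.0,
) -> IcaModel:
    """Seeded fast fixed-point ICA on the 0.5 Hz high-passed recording.

    Components are scored against the ocular proxy (correlation with Fp2)
    and for impulsiveness (excess kurtosis); those crossing either threshold
    are marked for rejection.
    """
    n_comp = rec.n_channels if n_components is None else int(n_components)
    if rec.n_channels < n_comp:
        raise ValueError("n_components exceeds channel count")
    if rec.n_samples < 10 * n_comp:
        raise ValueError("need >= 10x n_components samples to fit ICA")

    hp = _highpass(rec.data, rec.fs)
    sv = np.linalg.svd(hp - hp.mean(axis=1, keepdims=True),
                       compute_uv=False)
    rank = int(np.sum(sv > sv[0] * 1e-10))
    if rank < n_comp:
        var = hp.var(axis=1)
        flat = [rec.channel_labels[i] for i in np.argsort(var)[: n_comp - rank]]
        raise ValueError(
            f"rank-deficient data (rank {rank} < {n_comp} components); "
            f"lowest-variance channels: {flat}"
        )

    ica = FastICA(
        n_components=n_comp,
        random_state=int(seed),
        whiten="unit-variance",
        max_iter=2000,
        tol=1e-5,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on noise data
        sources = ica.fit_transform(hp.T).T  # components x samples
    unmixing = ica.components_
    mixing = ica.mixing_
    mean = ica.mean_

    fp2 = hp[rec.channel_labels.index("Fp2")]
    scores = []
    rejected: set[int] = set()
    for i, s in enumerate(sources):
        r = abs(float(np.corrcoef(s, fp2)[0, 1])) if s.std() > 0 else 0.0
        k = float(spstats.kurtosis(s))  # excess kurtosis
        if r >= r_threshold or k >= kurtosis_threshold:
            rejected.add(i)
        scores.append({"component": i, "fp2_abs_r": r, "kurtosis": k})
    return IcaModel(
        unmixing=unmixing,
        mixing=mixing,
        mean=mean,
        rejected=rejected,
        rule_scores=pd.DataFrame(scores).set_index("component"),
        channel_labels=list(rec.channel_labels),
    )


def reject_components(model: IcaModel, rec: Recording) -> Recording:
    """Zero the rejected ICA sources and back-project.

    With nothing rejected this is an identity up to numerical tolerance.
    """
    if model.channel_labels != list(rec.channel_labels):
        raise ValueError("ICA model fitted on a different channel set")
    centred = rec.data - model.mean[:, None]
    sources = model.unmixing @ centred
    keep = np.ones(sources.shape[0], dtype=bool)
    if model.rejected:
        keep[sorted(model.rejected)] = False
    cleaned = model.mixing[:, keep] @ sources[keep] + model.mean[:, None]
    return rec.copy_with(cleaned)


# ---------------------------------------------------------------------------
# epoching


def extract_epochs(
    rec: Recording,
    events: pd.DataFrame,
    t_start: float = 1.0,
    t_end: float = 4.0,
    phase: str = "imagine",
) -> list[TrialEpoch]:
    """One epoch per matching event: the half-open sample window
    [onset + t_start, onset + t_end), i.e. round((t_end - t_start) * fs)
    samples starting at round((onset + t_start) * fs)."""
    if phase not in PHASE_LABELS:
        raise ValueError(f"phase must be one of {PHASE_LABELS}")
    n_samp = int(round((t_end - t_start) * rec.fs))
    sel = events[
        events["phase"].eq(phase) & events["task"].isin(TASK_LABELS)
    ]
    bad = []
    epochs: list[TrialEpoch] = []
    for row in sel.itertuples():
        start = int(round((row.onset + t_start) * rec.fs))
        stop = start + n_samp
        if start < 0 or stop > rec.n_samples:
            bad.append((row.onset, row.task, row.block))
            continue
        epochs.append(
            TrialEpoch(
                data=rec.data[:, start:stop].copy(),
                fs=rec.fs,
                channel_labels=list(rec.channel_labels),
                task=row.task,
                phase=phase,
                subject=int(row.subject),
                block=int(row.block),
            )
        )
    if bad:
        raise ValueError(
            f"{len(bad)} event window(s) fall outside the recording: {bad}"
        )
    return epochs


def preprocess_session(
    rec: Recording,
    events: pd.DataFrame,
    band: tuple[float, float] = (8.0, 13.0),
    use_ica: bool = True,
    ica_stage: str = "post-band",
    seed: int = 0,
    t_start: float = 1.0,
    t_end: float = 4.0,
    phase: str = "imagine",
) -> list[TrialEpoch]:
    """Full preprocessing of one session down to detrended analysis epochs.

    ``ica_stage`` selects whether ICA sees the recording before or after the
    alpha bandpass (default: after; blinks carry little alpha-band
    energy, so "pre-band" is offered as well).
    """
    if ica_stage not in ("pre-band", "post-band"):
        raise ValueError("ica_stage must be 'pre-band' or 'post-band'")
    out = correct_baseline(rec)
    if use_ica and ica_stage == "pre-band":
        out = reject_components(fit_ica(out, seed=seed), out)
    out = bandpass_alpha(out, *band)
    if use_ica and ica_stage == "post-band":
        out = reject_components(fit_ica(out, seed=seed), out)
    epochs = extract_epochs(out, events, t_start, t_end, phase)
    return [correct_baseline(e) for e in epochs]
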