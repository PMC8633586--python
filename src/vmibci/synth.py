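"""Synthetic visual-motor-imagery EEG sessions.

The generator emulates the statistical structure the downstream analysis
assumes: 18 channels in a 10-20 montage, a block paradigm (10 s fixation
cross, then for each of four imagined car-movement directions 5 s of
observation followed by 5 s of imagery, closed by 5 s of rest), pink-noise
background on every channel, slow baseline drift, stereotyped ocular
artifacts maximal on Fp2, and -- the decodable effect -- an alpha-band
carrier on the occipital leads O1/O2 whose amplitude envelope during imagery
follows a task-specific stationary AR(6) process.

Setting ``effect_scale=0`` makes the four task-conditional distributions
identical by construction; every draw is a pure function of ``(seed,
subject)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .preprocess import Recording

__all__ = [
    "MONTAGE_18",
    "TASKS",
    "SynthConfig",
    "generate_session",
    "generate_ar_process",
    "generate_tone",
    "resonant_ar6",
    "ar_process_sd",
    "block_events",
]

#: The 18 recording channels of the montage, front to back.
MONTAGE_18 = (
    "Fp2", "F7", "F8", "F3", "F4", "Fc3", "Fc4", "C3", "C4",
    "P3", "P4", "O1", "O2", "Fz", "Fcz", "Cz", "Pz", "Oz",
)

#: The four imagined driving directions.
TASKS = ("forward", "reverse", "left", "right")

# Block timeline (seconds): cross, then per direction observe+imagine, rest.
CROSS_S = 10.0
TASK_S = 5.0
REST_S = 5.0
BLOCK_S = CROSS_S + 4 * 2 * TASK_S + REST_S  # 55 s

#: Fractional depth of the task-conditional envelope modulation at saturation.
MOD_DEPTH = 0.9

# Ocular-artifact spatial pattern: unit weight on Fp2 decaying front-to-back.
_BLINK_WEIGHTS = {
    "Fp2": 1.0,
    "F7": 0.5, "F8": 0.5, "F3": 0.5, "F4": 0.5, "Fz": 0.5,
    "Fc3": 0.3, "Fc4": 0.3, "Fcz": 0.3,
    "C3": 0.2, "C4": 0.2, "Cz": 0.2,
    "P3": 0.1, "P4": 0.1, "Pz": 0.1,
    "O1": 0.05, "O2": 0.05, "Oz": 0.05,
}


def resonant_ar6(freq: float, radius: float, fs: float) -> tuple[float, ...]:
    """Six AR coefficients of a resonator at ``freq`` Hz with pole radius
    ``radius`` (quoted at a 250 Hz reference grid), padded with zeros.

    The radius is rescaled as r**(250/fs) so the continuous-time decay is
    preserved when the sampling rate changes.
    """
    r = float(radius) ** (250.0 / fs)
    w = 2.0 * np.pi * freq / fs
    a1 = 2.0 * r * np.cos(w)
    a2 = -(r * r)
    return (a1, a2, 0.0, 0.0, 0.0, 0.0)


def _default_profiles(fs: float) -> dict[str, tuple[float, ...]]:
    # Envelope dynamics stay below ~2.5 Hz so the AM sidebands of a 10 Hz
    # carrier survive an 8-13 Hz bandpass. Tasks span the slow-to-broadband
    # range; left vs right is the maximally distinct pair.
    return {
        "forward": resonant_ar6(0.3, 0.996, fs),
        "reverse": resonant_ar6(1.2, 0.985, fs),
        "left": resonant_ar6(2.0, 0.95, fs),
        "right": (0.5, 0.0, 0.0, 0.0, 0.0, 0.0),
    }


@dataclass
class SynthConfig:
    """Study-condition parameters for one synthetic session.

    Defaults are the desk-scale test conditions (250 Hz, 10 blocks);
    ``SynthConfig.acquisition_scale()`` gives the acquisition-scale settings
    (1,000 Hz, 50 blocks, 25 subjects).
    """

    n_subjects: int = 3
    n_blocks: int = 10
    fs: float = 250.0
    channel_labels: tuple[str, ...] = MONTAGE_18
    alpha_freq: float = 10.0  # Hz, centre of the 8-13 Hz band
    class_envelope_ar: dict[str, tuple[float, ...]] | None = None
    effect_scale: float = 1.0  # 0 => no class information
    alpha_amp: float = 15.0  # uV, baseline occipital alpha amplitude
    noise_sd: float = 10.0  # uV, pink-noise background RMS
    drift_amp: float = 20.0  # uV, sub-0.5 Hz baseline wander
    blink_rate: float = 6.0  # events/min
    blink_amp: float = 100.0  # uV peak on Fp2
    shared_source_pair: tuple[str, str] | None = None
    shared_source_amp: float = 8.0  # uV, common alpha-band source
    seed: int = 0

    def __post_init__(self) -> None:
        labels = tuple(self.channel_labels)
        if len(labels) != 18 or len(set(labels)) != 18:
            raise ValueError(
                f"channel_labels must be 18 unique names, got {len(labels)}"
            )
        if set(labels) != set(MONTAGE_18):
            raise ValueError("channel_labels must be the 18-channel montage")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not 8.0 <= self.alpha_freq <= 13.0:
            raise ValueError("alpha_freq must lie in the 8-13 Hz band")
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be >= 0")
        self.channel_labels = labels
        if self.class_envelope_ar is None:
            self.class_envelope_ar = _default_profiles(self.fs)
        missing = set(TASKS) - set(self.class_envelope_ar)
        if missing:
            raise ValueError(f"class_envelope_ar missing tasks: {sorted(missing)}")
        for task, coeffs in self.class_envelope_ar.items():
            if len(coeffs) != 6:
                raise ValueError(f"{task}: need 6 AR coefficients")
            _check_stationary(np.asarray(coeffs, float))

    @classmethod
    def acquisition_scale(cls, **overrides) -> "SynthConfig":
        kwargs = dict(n_subjects=25, n_blocks=50, fs=1000.0)
        kwargs.update(overrides)
        return cls(**kwargs)

    def with_(self, **overrides) -> "SynthConfig":
        return replace(self, **overrides)


# ---------------------------------------------------------------------------
# primitive generators


def _check_stationary(coeffs: np.ndarray) -> None:
    # x_t = sum a_k x_{t-k} + e_t  is stationary iff the roots of
    # z^p - a_1 z^{p-1} - ... - a_p lie inside the unit circle.
    poly = np.concatenate(([1.0], -coeffs))
    roots = np.roots(poly)
    bad = roots[np.abs(roots) >= 1.0]
    if bad.size:
        raise ValueError(
            f"non-stationary AR coefficients: characteristic roots with "
            f"|z| >= 1: {np.round(bad, 4)}"
        )


def ar_process_sd(coeffs: np.ndarray | tuple, noise_sd: float = 1.0) -> float:
    """Stationary standard deviation of the AR process x_t = sum a_k x_{t-k}
    + e_t, by solving the Yule-Walker autocovariance system."""
    a = np.asarray(coeffs, dtype=float)
    _check_stationary(a)
    p = a.size
    # unknowns g0..gp: g0 = sum a_k g_k + s2 ; g_j = sum a_k g_{|j-k|}
    A = np.zeros((p + 1, p + 1))
    b = np.zeros(p + 1)
    A[0, 0] = 1.0
    A[0, 1:] -= a
    b[0] = noise_sd**2
    for j in range(1, p + 1):
        A[j, j] = 1.0
        for k in range(1, p + 1):
            A[j, abs(j - k)] -= a[k - 1]
    g = np.linalg.solve(A, b)
    return float(np.sqrt(g[0]))


def generate_ar_process(
    coeffs: np.ndarray | tuple,
    n: int,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
    burn: int = 500,
) -> np.ndarray:
    """``n`` samples of a stationary AR process driven by Gaussian white
    noise with sd ``noise_sd``; convention x_t = sum a_k x_{t-k} + e_t."""
    a = np.asarray(coeffs, dtype=float)
    _check_stationary(a)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    e = rng.normal(0.0, noise_sd, size=n + burn)
    x = lfilter([1.0], np.concatenate(([1.0], -a)), e)
    return x[burn:]


def generate_tone(
    freq: float,
    amp: float,
    fs: float,
    n: int,
    phase: float = 0.0,
) -> np.ndarray:
    """amp * cos(2 pi freq t + phase) sampled at ``fs``."""
    if freq >= fs / 2:
        raise ValueError(f"tone at {freq} Hz aliases at fs={fs} Hz")
    t = np.arange(n) / fs
    return amp * np.cos(2.0 * np.pi * freq * t + phase)


def _alpha_band_noise(
    n: int, sd: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """White noise restricted to the 8-13 Hz band, normalized to sd."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < 8.0) | (f > 13.0)] = 0.0
    x = np.fft.irfft(spec, n)
    s = x.std()
    if s > 0:
        x *= sd / s
    return x


def _pink_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping, normalized to sd."""
    if sd == 0.0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    x *= sd / x.std()
    return x


# ---------------------------------------------------------------------------
# paradigm and session assembly


def block_events(block: int, subject: int, t0: float,
                 order: np.ndarray) -> list[dict]:
    """Event rows for one block starting at ``t0`` seconds."""
    rows = [dict(onset=t0, duration=CROSS_S, task="cross", phase="none",
                 block=block, subject=subject)]
    t = t0 + CROSS_S
    for d in order:
        task = TASKS[d]
        rows.append(dict(onset=t, duration=TASK_S, task=task,
                         phase="observe", block=block, subject=subject))
        t += TASK_S
        rows.append(dict(onset=t, duration=TASK_S, task=task,
                         phase="imagine", block=block, subject=subject))
        t += TASK_S
    rows.append(dict(onset=t, duration=REST_S, task="rest", phase="none",
                     block=block, subject=subject))
    return rows


def _alpha_segment(
    cfg: SynthConfig,
    task: str,
    n: int,
    modulated: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """One channel's alpha-band burst for one 5 s event."""
    phase = rng.uniform(0.0, 2.0 * np.pi)
    carrier = generate_tone(cfg.alpha_freq, 1.0, cfg.fs, n, phase)
    if modulated and cfg.effect_scale > 0:
        coeffs = cfg.class_envelope_ar[task]
        u = generate_ar_process(coeffs, n, 1.0, rng)
        u /= ar_process_sd(coeffs)
        # bounded modulation: strictly positive envelope, linear in the
        # effect for small scales, saturating (never degenerate) for large
        env = cfg.alpha_amp * (
            1.0 + MOD_DEPTH * np.tanh(0.4 * cfg.effect_scale * u)
        )
    else:
        env = np.full(n, cfg.alpha_amp)
    return env * carrier


def generate_session(
    config: SynthConfig, subject: int = 0
) -> tuple[Recording, pd.DataFrame]:
    """One subject's full session: an 18-channel recording plus its event
    table. Deterministic in ``(config.seed, subject)``."""
    cfg = config
    fs = cfg.fs
    n_total = int(round(cfg.n_blocks * BLOCK_S * fs))
    labels = list(cfg.channel_labels)
    ch_index = {name: i for i, name in enumerate(labels)}
    rng = np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, int(subject)])

    data = np.empty((18, n_total))
    for i in range(18):
        data[i] = _pink_noise(n_total, cfg.noise_sd, rng)

    # slow baseline wander: three random sub-0.5 Hz sinusoids per channel
    if cfg.drift_amp > 0:
        t = np.arange(n_total) / fs
        for i in range(18):
            drift = np.zeros(n_total)
            for _ in range(3):
                f = rng.uniform(0.02, 0.4)
                ph = rng.uniform(0, 2 * np.pi)
                drift += np.sin(2 * np.pi * f * t + ph)
            data[i] += cfg.drift_amp / 3.0 * drift

    # event table
    rows: list[dict] = []
    for b in range(cfg.n_blocks):
        order = rng.permutation(4)
        rows.extend(block_events(b, subject, b * BLOCK_S, order))
    events = pd.DataFrame(rows)

    # occipital alpha bursts (constant envelope while observing, task-AR
    # modulated while imagining) and optional shared connectivity source
    n_event = int(round(TASK_S * fs))
    for row in rows:
        if row["phase"] not in ("observe", "imagine"):
            continue
        start = int(round(row["onset"] * fs))
        sl = slice(start, start + n_event)
        modulated = row["phase"] == "imagine"
        for ch in ("O1", "O2"):
            data[ch_index[ch], sl] += _alpha_segment(
                cfg, row["task"], n_event, modulated, rng
            )
        if cfg.shared_source_pair is not None and modulated:
            # band-limited (8-13 Hz) noise: a waveform shared verbatim by
            # the two channels, incoherent with every alpha carrier
            src = _alpha_band_noise(n_event, cfg.shared_source_amp, fs, rng)
            for ch in cfg.shared_source_pair:
                data[ch_index[ch], sl] += src

    # ocular artifacts: Gaussian deflections, fixed spatial decay from Fp2
    if cfg.blink_rate > 0 and cfg.blink_amp > 0:
        n_blinks = rng.poisson(cfg.blink_rate * n_total / fs / 60.0)
        width = 0.1  # s, gaussian sd
        half = int(round(4 * width * fs))
        tt = (np.arange(2 * half + 1) - half) / fs
        shape = np.exp(-0.5 * (tt / width) ** 2)
        weights = np.array([_BLINK_WEIGHTS[ch] for ch in labels])
        for _ in range(n_blinks):
            centre = rng.integers(half, n_total - half)
            amp = cfg.blink_amp * rng.uniform(0.7, 1.3)
            sl = slice(centre - half, centre + half + 1)
            data[:, sl] += amp * np.outer(weights, shape)

    rec = Recording(
        data=data, fs=fs, channel_labels=labels, subject=int(subject)
    )
    return rec, events
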