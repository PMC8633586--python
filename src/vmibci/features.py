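"""Autoregressive features of the Hilbert envelope of occipital EEG.

For each of O1 and O2: decompose the epoch with EMD, sum the first three
IMFs, take the instantaneous-amplitude envelope of that combination via the
analytic signal, and fit a sixth-order AR model with the Burg algorithm.
The concatenated coefficients {O1_AR1..O1_AR6, O2_AR1..O2_AR6} form the
12-dimensional feature vector.

AR sign convention throughout: x_t = sum_k a_k x_{t-k} + e_t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hht import emd, hilbert_envelope
from .preprocess import TrialEpoch

__all__ = [
    "ArFit",
    "FeatureVector",
    "FEATURE_COLUMNS",
    "burg_ar",
    "combine_imfs",
    "extract_features",
    "extract_feature_table",
]

log = logging.getLogger(__name__)

DEFAULT_CHANNELS = ("O1", "O2")
FEATURE_COLUMNS = tuple(
    f"{ch}_AR{k}" for ch in DEFAULT_CHANNELS for k in range(1, 7)
)


@dataclass
class ArFit:
    """Burg AR fit: coefficients a_1..a_p, innovation variance, reflection
    coefficients (all |k| < 1, which guarantees a stable model)."""

    coefficients: np.ndarray
    noise_variance: float
    order: int
    reflection: np.ndarray

    def poles(self) -> np.ndarray:
        """Roots of z^p - a_1 z^{p-1} - ... - a_p (inside the unit circle
        for a stable fit)."""
        return np.roots(np.concatenate(([1.0], -self.coefficients)))


@dataclass
class FeatureVector:
    """Ordered 12-vector {O1_AR1..O1_AR6, O2_AR1..O2_AR6} with its label."""

    values: np.ndarray
    task: str
    subject: int
    block: int
    channels: tuple[str, str] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (12,):
            raise ValueError(f"expected 12 features, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")


def burg_ar(x: np.ndarray, order: int = 6) -> ArFit:
    """Burg's method: order-recursive minimization of the summed forward and
    backward prediction error via reflection coefficients."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= 2 * order:
        raise ValueError(f"need more than {2 * order} samples, got {n}")
    if np.ptp(x) == 0.0:
        raise ValueError("constant input has no AR representation")

    f = x[1:].copy()  # forward prediction errors
    b = x[:-1].copy()  # backward prediction errors
    a_poly = np.array([1.0])  # monic polynomial 1 - a_1 z^-1 - ...
    energy = float(x @ x) / n
    refl = np.zeros(order)
    for m in range(order):
        den = float(f @ f + b @ b)
        if den == 0.0:
            break  # perfectly predicted; remaining reflections are 0
        k = -2.0 * float(b @ f) / den
        refl[m] = k
        a_poly = np.concatenate((a_poly, [0.0])) + k * np.concatenate(
            ([0.0], a_poly[::-1])
        )
        energy *= 1.0 - k * k
        if m < order - 1:
            f, b = f[1:] + k * b[1:], b[:-1] + k * f[:-1]
    coeffs = -a_poly[1:]
    return ArFit(
        coefficients=coeffs,
        noise_variance=energy,
        order=order,
        reflection=refl,
    )


def combine_imfs(dec, k: int = 3) -> np.ndarray:
    """Elementwise sum of the first ``min(k, available)`` IMFs."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if dec.n_imfs == 0:
        raise ValueError("decomposition holds no IMFs")
    if dec.n_imfs < k:
        log.warning(
            "only %d IMFs available, requested first %d", dec.n_imfs, k
        )
    out = dec.imfs[0].copy()
    for c in dec.imfs[1:k]:
        out += c
    return out


def _envelope_ar(
    x: np.ndarray,
    fs: float,
    k_imfs: int,
    order: int,
    ar_target: str,
    edge_trim: float,
) -> np.ndarray:
    dec = emd(x, fs=fs)
    combined = combine_imfs(dec, k_imfs)
    if ar_target == "envelope":
        series = hilbert_envelope(combined, fs).amplitude
    elif ar_target == "combined-imf":
        series = combined
    else:
        raise ValueError("ar_target must be 'envelope' or 'combined-imf'")
    trim = int(round(edge_trim * series.size))
    if trim:
        series = series[trim:-trim]
    series = series - series.mean()  # Burg assumes zero mean
    return burg_ar(series, order).coefficients


def extract_features(
    epoch: TrialEpoch,
    channels: tuple[str, str] = DEFAULT_CHANNELS,
    k_imfs: int = 3,
    order: int = 6,
    ar_target: str = "envelope",
    edge_trim: float = 0.05,
) -> FeatureVector:
    """The 12-dimensional AR feature vector of one epoch.

    Channel lookup is by label, so the storage order of the epoch does not
    matter. The first and last ``edge_trim`` fraction of the envelope are
    discarded before the AR fit to suppress EMD/Hilbert edge artifacts.
    """
    if len(channels) != 2:
        raise ValueError("exactly two channels are expected")
    values = np.concatenate(
        [
            _envelope_ar(
                epoch.channel(ch), epoch.fs, k_imfs, order, ar_target,
                edge_trim,
            )
            for ch in channels
        ]
    )
    return FeatureVector(
        values=values,
        task=epoch.task,
        subject=epoch.subject,
        block=epoch.block,
        channels=tuple(channels),
    )


def extract_feature_table(
    epochs: list[TrialEpoch],
    channels: tuple[str, str] = DEFAULT_CHANNELS,
    **kwargs,
) -> pd.DataFrame:
    """Feature vectors of many epochs as a tidy table with columns
    subject, block, task, <ch>_AR1..<ch>_AR6 for each channel."""
    cols = [f"{ch}_AR{k}" for ch in channels for k in range(1, 7)]
    rows = []
    for ep in epochs:
        fv = extract_features(ep, channels=channels, **kwargs)
        row = {"subject": fv.subject, "block": fv.block, "task": fv.task}
        row.update(dict(zip(cols, fv.values)))
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject", "block", "task", *cols])
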