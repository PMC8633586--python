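"""Hilbert-Huang spectral analysis: empirical mode decomposition and the
analytic-signal envelope.

The decomposition writes a signal ``s(t)`` as a sum of intrinsic mode
functions (IMFs) plus a residual,

    s(t) = sum_i C_i(t) + R(t),

where each IMF is obtained by "sifting": the mean of the cubic-spline upper
and lower envelopes is subtracted repeatedly until the candidate satisfies a
Cauchy-type normalized squared-difference criterion and the IMF counting
condition (numbers of extrema and zero crossings differ by at most one).
Each IMF is then given an instantaneous amplitude/phase via the discrete
analytic signal C + jH[C].

Everything here is deterministic and operates on 1-D float arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert

__all__ = [
    "InextricableError",
    "IMFDecomposition",
    "AnalyticEnvelope",
    "EnergySeries",
    "find_extrema",
    "envelope_mean",
    "sift",
    "emd",
    "hilbert_envelope",
    "instantaneous_energy",
    "count_zero_crossings",
    "is_imf",
]

#: Cauchy-type sifting threshold (canonical range 0.2-0.3).
SD_THRESHOLD = 0.3
#: Hard cap on sifting iterations per IMF.
MAX_SIFT_ITER = 100
#: Hard cap on the number of extracted IMFs, to guarantee termination.
MAX_IMFS = 12


class InextricableError(ValueError):
    """Raised when a series has too few extrema for envelope construction."""


# ---------------------------------------------------------------------------
# decomposition containers


@dataclass
class IMFDecomposition:
    """An EMD of one channel segment: ordered IMFs plus the final residual."""

    source: np.ndarray
    imfs: list[np.ndarray]
    residual: np.ndarray
    sift_counts: list[int]
    fs: float

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        """Sum of all IMFs plus the residual (equals the source exactly,
        up to floating-point accumulation)."""
        out = self.residual.copy()
        for c in self.imfs:
            out += c
        return out


@dataclass
class AnalyticEnvelope:
    """Analytic-signal view of one IMF: X(t) = C(t) + jY(t) = A(t) e^{jP(t)}."""

    real_part: np.ndarray
    quad_part: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray
    analytic: np.ndarray
    fs: float

    def unwrapped_phase(self) -> np.ndarray:
        return np.unwrap(self.phase)

    def instantaneous_frequency(self) -> np.ndarray:
        """d(phase)/dt in Hz, by central differences of the unwrapped phase."""
        return np.gradient(self.unwrapped_phase()) * self.fs / (2.0 * np.pi)


@dataclass
class EnergySeries:
    """Running mean-square energy EC_N of a series, windowed at one second."""

    values: np.ndarray
    window: int
    fs: float


# ---------------------------------------------------------------------------
# extrema and envelopes


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima of ``x``.

    A plateau (run of equal samples) that is a local extremum contributes a
    single index: the midpoint of the run, rounded down for even-length runs.
    Endpoints are never extrema.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)

    # run-length compress so plateaus become single nodes
    change = np.flatnonzero(np.diff(x) != 0.0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [x.size - 1]))  # inclusive
    vals = x[starts]

    if vals.size < 3:
        return np.array([], dtype=int), np.array([], dtype=int)

    left = vals[:-2]
    mid = vals[1:-1]
    right = vals[2:]
    mid_idx = (starts[1:-1] + ends[1:-1]) // 2

    maxima = mid_idx[(mid > left) & (mid > right)]
    minima = mid_idx[(mid < left) & (mid < right)]
    return maxima.astype(int), minima.astype(int)


def count_zero_crossings(x: np.ndarray) -> int:
    """Number of sign changes, counting a touch of zero once."""
    x = np.asarray(x, dtype=float)
    s = np.sign(x)
    s = s[s != 0]  # exact zeros lie between the neighbouring signs
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s) != 0))


def is_imf(x: np.ndarray) -> bool:
    """IMF counting condition: #extrema and #zero-crossings differ by <= 1."""
    mx, mn = find_extrema(x)
    n_ext = mx.size + mn.size
    return abs(n_ext - count_zero_crossings(x)) <= 1


def _mirrored_spline(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Natural cubic spline through the extrema ``idx`` of ``x``, with the two
    nearest extrema mirrored past each end to suppress edge divergence."""
    n = x.size
    t = idx.astype(float)
    v = x[idx]

    k = min(2, t.size)
    left_t = -t[:k][::-1]  # reflect about sample 0
    left_v = v[:k][::-1]
    right_t = 2.0 * (n - 1) - t[-k:][::-1]
    right_v = v[-k:][::-1]

    tt = np.concatenate([left_t, t, right_t])
    vv = np.concatenate([left_v, v, right_v])
    # mirroring can duplicate knots when an extremum sits at an endpoint
    tt, keep = np.unique(tt, return_index=True)
    vv = vv[keep]
    spline = CubicSpline(tt, vv, bc_type="natural")
    return spline(np.arange(n, dtype=float))


def envelope_mean(
    x: np.ndarray, maxima: np.ndarray, minima: np.ndarray
) -> np.ndarray:
    """Mean of the upper and lower cubic-spline envelopes of ``x``.

    Requires at least two maxima and two minima; otherwise the series is
    inextricable and sifting must stop.
    """
    x = np.asarray(x, dtype=float)
    if len(maxima) < 2 or len(minima) < 2:
        raise InextricableError(
            f"need >=2 maxima and >=2 minima to build envelopes "
            f"(got {len(maxima)} maxima, {len(minima)} minima)"
        )
    upper = _mirrored_spline(x, np.sort(np.asarray(maxima)))
    lower = _mirrored_spline(x, np.sort(np.asarray(minima)))
    return 0.5 * (upper + lower)


# ---------------------------------------------------------------------------
# sifting


def sift(
    x: np.ndarray,
    sd_threshold: float = SD_THRESHOLD,
    max_iter: int = MAX_SIFT_ITER,
) -> tuple[np.ndarray, int]:
    """Extract one IMF from ``x`` by iterated envelope-mean subtraction.

    Stops when the normalized squared change between successive candidates,
    SD = sum((h_prev - h)^2) / sum(h_prev^2), drops below ``sd_threshold``
    AND the candidate satisfies the IMF counting condition, or after
    ``max_iter`` iterations. Returns ``(imf, iterations)``.
    """
    h = np.asarray(x, dtype=float).copy()
    mx, mn = find_extrema(h)
    if len(mx) < 2 or len(mn) < 2:
        raise InextricableError("series has too few extrema to sift")

    iterations = 0
    for _ in range(max_iter):
        try:
            m = envelope_mean(h, mx, mn)
        except InextricableError:
            break  # degenerated mid-sift; return what we have
        h_new = h - m
        denom = float(np.dot(h, h))
        sd = float(np.dot(m, m)) / denom if denom > 0 else 0.0
        h = h_new
        iterations += 1
        mx, mn = find_extrema(h)
        if sd < sd_threshold and is_imf(h):
            break
        if len(mx) < 2 or len(mn) < 2:
            break
    return h, iterations


def emd(
    x: np.ndarray,
    fs: float = 1.0,
    max_imfs: int = MAX_IMFS,
    sd_threshold: float = SD_THRESHOLD,
) -> IMFDecomposition:
    """Full empirical mode decomposition of ``x``.

    IMFs are peeled off the running residual until the residual is monotonic
    or has at most one extremum (or ``max_imfs`` is reached). The sum of the
    IMFs plus the residual reconstructs the input exactly by construction.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError(f"series too short for EMD (n={x.size}, need >= 8)")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")

    residual = x.copy()
    imfs: list[np.ndarray] = []
    counts: list[int] = []
    while len(imfs) < max_imfs:
        mx, mn = find_extrema(residual)
        if mx.size + mn.size <= 1 or mx.size < 2 or mn.size < 2:
            break  # monotonic / single-pole residual: stop
        imf, it = sift(residual, sd_threshold=sd_threshold)
        imfs.append(imf)
        counts.append(it)
        residual = residual - imf
    return IMFDecomposition(
        source=x, imfs=imfs, residual=residual, sift_counts=counts, fs=fs
    )


# ---------------------------------------------------------------------------
# Hilbert spectral analysis


def hilbert_envelope(c: np.ndarray, fs: float) -> AnalyticEnvelope:
    """Analytic signal of one IMF via the FFT construction (negative
    frequencies zeroed, positive doubled); amplitude and wrapped phase."""
    c = np.asarray(c, dtype=float)
    if c.size < 8:
        raise ValueError(f"series too short for analytic signal (n={c.size})")
    analytic = hilbert(c)
    return AnalyticEnvelope(
        real_part=c,
        quad_part=analytic.imag,
        amplitude=np.abs(analytic),
        phase=np.angle(analytic),
        analytic=analytic,
        fs=fs,
    )


def instantaneous_energy(
    c: np.ndarray, fs: float, norm: str = "global_n"
) -> EnergySeries:
    """Average instantaneous energy EC_N of a series.

    For N <= Fs (one second of samples) EC_N is the mean square of samples
    1..N. For N > Fs only the trailing Fs samples enter the sum, but with
    ``norm="global_n"`` (default) the prefactor stays 1/N;
    ``norm="window_length"`` uses 1/Fs instead.
    """
    if norm not in ("global_n", "window_length"):
        raise ValueError(f"unknown norm {norm!r}")
    c = np.asarray(c, dtype=float)
    if c.size < 1:
        raise ValueError("empty series")
    window = int(round(fs))
    if window < 1:
        raise ValueError("fs must be >= 1 sample per second window")

    sq = np.concatenate(([0.0], np.cumsum(c * c)))
    n_idx = np.arange(1, c.size + 1)
    lo = np.maximum(n_idx - window, 0)
    sums = sq[n_idx] - sq[lo]
    if norm == "global_n":
        values = sums / n_idx
    else:
        values = sums / np.minimum(n_idx, window)
    return EnergySeries(values=values, window=window, fs=fs)
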