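"""Independent reference implementations used only as test oracles.

Deliberately simple, written without reference to the package internals so
they constitute an independent computational route:

- ``reference_emd``: a textbook sifting loop (argrelextrema-based extrema,
  cubic-spline envelopes with the canonical mirrored-extrema boundary,
  classic Cauchy SD < 0.2 stop, no counting condition).
- ``oneway_anova``: hand-rolled sum-of-squares one-way ANOVA.
- ``bh_adjust``: the Benjamini-Hochberg formula evaluated directly.
- ``nearest_centroid_cv``: a minimal nearest-centroid classifier.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import argrelextrema
from scipy.stats import f as f_dist


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    # reflect the outermost extrema past the signal ends before fitting
    n = len(x)
    k = min(2, len(idx))
    knots = np.concatenate(
        [-idx[:k][::-1], idx, 2 * (n - 1) - idx[-k:][::-1]]
    ).astype(float)
    vals = np.concatenate([x[idx[:k]][::-1], x[idx], x[idx[-k:]][::-1]])
    knots, keep = np.unique(knots, return_index=True)
    return CubicSpline(knots, vals[keep])(np.arange(n))


def reference_emd(x: np.ndarray, max_imfs: int = 12) -> list[np.ndarray]:
    """Plain EMD: sift each mode until SD < 0.2 (or 200 iterations)."""
    x = np.asarray(x, dtype=float)
    imfs = []
    r = x.copy()
    for _ in range(max_imfs):
        maxima = argrelextrema(r, np.greater)[0]
        minima = argrelextrema(r, np.less)[0]
        if len(maxima) < 2 or len(minima) < 2:
            break
        h = r.copy()
        for _ in range(200):
            mx = argrelextrema(h, np.greater)[0]
            mn = argrelextrema(h, np.less)[0]
            if len(mx) < 2 or len(mn) < 2:
                break
            m = 0.5 * (_envelope(h, mx) + _envelope(h, mn))
            h_new = h - m
            sd = float(np.sum((h - h_new) ** 2) / np.sum(h**2))
            h = h_new
            if sd < 0.2:
                break
        imfs.append(h)
        r = r - h
    return imfs


def oneway_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """(F, p) by explicit sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    f_stat = ms_b / ms_w
    p = float(f_dist.sf(f_stat, df_b, df_w))
    return float(f_stat), p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg: p_(i) * m / i, enforced monotone from the top."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adj[i] = running_min
    return adj


def nearest_centroid_cv(
    X: np.ndarray, y: np.ndarray, k: int = 10, seed: int = 0
) -> float:
    """Mean k-fold accuracy (percent) of a nearest-centroid rule on
    z-scored features; an independent lower bound on decodability."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(y))
    folds = np.array_split(idx, k)
    accs = []
    for f in folds:
        test = np.zeros(len(y), dtype=bool)
        test[f] = True
        mu = X[~test].mean(axis=0)
        sd = X[~test].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (X[~test] - mu) / sd
        Xte = (X[test] - mu) / sd
        classes = np.unique(y[~test])
        cents = np.array([Xtr[y[~test] == c].mean(axis=0) for c in classes])
        d = ((Xte[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        pred = classes[np.argmin(d, axis=1)]
        accs.append(100.0 * float(np.mean(pred == y[test])))
    return float(np.mean(accs))
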