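"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written directly from the mathematical definitions with
explicit Python loops, deliberately sharing no code with the package
implementation it checks.
"""

from __future__ import annotations

import numpy as np


def sta1d_brute(f, t, L, k, w=None):
    """Windowed lag product around index ``t``: direct double-guarded loop."""
    f = np.asarray(f, dtype=float)
    h = L // 2
    if w is None:
        w = np.ones(L)
    total = 0.0
    for l in range(-h, h + 1):
        if not (-h <= l + k <= h):
            continue
        a, b = t + l, t + l + k
        if 0 <= a < len(f) and 0 <= b < len(f):
            total += w[l + h] * f[a] * w[l + k + h] * f[b]
    return total


def asta1d_brute(f, L, w=None):
    """Accumulated lag products: triple loop over center, lag and window."""
    f = np.asarray(f, dtype=float)
    h = L // 2
    return np.array([
        sum(sta1d_brute(f, t, L, k, w) for k in range(-h, h + 1))
        for t in range(len(f))
    ])


def weighted_image(temps, weighting="linear", beta=1.0):
    temps = np.asarray(temps, dtype=float)
    if weighting == "unit":
        p = np.ones_like(temps)
    elif weighting == "linear":
        m = temps.max()
        p = np.ones_like(temps) if m == 0 else temps / m
    elif weighting == "softmax":
        p = np.exp(beta * (temps - temps.max()))
    else:
        raise ValueError(weighting)
    return p * temps


def sta2d_brute(q, m, n, L, k1, k2):
    """2-D windowed lag product at pixel (m, n): quadruple-guarded loop over
    the pre-weighted image ``q``."""
    h = L // 2
    rows, cols = q.shape
    total = 0.0
    for l1 in range(-h, h + 1):
        if not (-h <= l1 + k1 <= h):
            continue
        for l2 in range(-h, h + 1):
            if not (-h <= l2 + k2 <= h):
                continue
            a1, a2 = m + l1, n + l2
            b1, b2 = m + l1 + k1, n + l2 + k2
            if (0 <= a1 < rows and 0 <= a2 < cols
                    and 0 <= b1 < rows and 0 <= b2 < cols):
                total += q[a1, a2] * q[b1, b2]
    return total


def nasta_brute(temps, L, weighting="linear", beta=1.0):
    """Full five-level-loop accumulation plus min-max scaling to [0, 255].

    A constant input image is information-free and maps to all zeros (the
    declared degenerate-normalization convention)."""
    temps = np.asarray(temps, dtype=float)
    if np.ptp(temps) == 0.0:
        return np.zeros_like(temps)
    q = weighted_image(temps, weighting, beta)
    h = L // 2
    rows, cols = q.shape
    acc = np.zeros_like(q)
    for m in range(rows):
        for n in range(cols):
            s = 0.0
            for k1 in range(-h, h + 1):
                for k2 in range(-h, h + 1):
                    s += sta2d_brute(q, m, n, L, k1, k2)
            acc[m, n] = s
    lo, hi = acc.min(), acc.max()
    if hi - lo < 1e-12 * max(1.0, abs(hi)):
        return np.zeros_like(acc)
    return 255.0 * (acc - lo) / (hi - lo)


def dense_contour_points(poly, step=0.005):
    """Dense sampling of a closed polygon's boundary (for distance oracles)."""
    poly = np.asarray(poly, dtype=float)
    out = []
    for i in range(len(poly)):
        a, b = poly[i], poly[(i + 1) % len(poly)]
        npts = max(2, int(np.ceil(np.linalg.norm(b - a) / step)))
        t = np.linspace(0.0, 1.0, npts, endpoint=False)
        out.append(a[None, :] + t[:, None] * (b - a)[None, :])
    return np.vstack(out)


def dense_point_to_contour(a, poly, step=0.005):
    """Point-to-polygon distance by dense boundary sampling."""
    pts = dense_contour_points(poly, step)
    return float(np.min(np.linalg.norm(pts - np.asarray(a, float), axis=1)))
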