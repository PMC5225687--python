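"""Short-term autocorrelation features: 1-D STA/ASTA and the 2-D NASTA map.

The short-term autocorrelation (STA) of a real signal ``f`` at center ``t``
and lag ``k`` is the windowed lag product

    R_t(k) = sum_l w(l) f(t+l) w(l+k) f(t+l+k),

with ``w`` a taper of odd length ``L`` (rectangular by default) and the sum
running over window indices for which both samples are in support (windows
are clipped at the signal/image border; no padding is invented).  The
accumulative STA (ASTA) sums ``R_t(k)`` over all integer lags in
``[-L//2, L//2]``.

In 2-D each sample is additionally weighted by a temperature coefficient
``p`` so that hot pixels dominate the accumulation; the per-pixel lag-pair
accumulation, min-max normalized to [0, 255] over the whole image, is the
NASTA feature map used by the core-stage pressure force.  A constant
accumulation map is information-free and normalizes to all zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .thermio import ThermalImage, ValidationError

__all__ = [
    "StaWindowSpec",
    "FeatureImage",
    "short_term_autocorrelation_1d",
    "asta_1d",
    "sta_2d",
    "nasta",
    "temperature_weights",
]


@dataclass
class StaWindowSpec:
    """Window of odd length ``L >= 3`` with an optional taper.

    ``window_fn`` maps an offset array in ``[-L//2, L//2]`` to taper values;
    ``None`` means rectangular (all ones).
    """

    L: int = 5
    window_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.L < 3 or self.L % 2 == 0:
            raise ValidationError(f"window length must be odd >= 3, got {self.L}")

    @property
    def half(self) -> int:
        return self.L // 2

    def taper(self) -> np.ndarray:
        offs = np.arange(-self.half, self.half + 1)
        if self.window_fn is None:
            return np.ones(self.L)
        w = np.asarray(self.window_fn(offs), dtype=float)
        if w.shape != (self.L,):
            raise ValidationError("window_fn must return an array of length L")
        return w


@dataclass
class FeatureImage:
    """A per-pixel scalar feature field aligned with its source image.

    ``kind`` is ``"nasta"`` (values in [0, 255]) or ``"texture"``.
    """

    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("feature values must be 2-D")
        if self.kind not in ("nasta", "texture"):
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if self.kind == "nasta":
            if self.values.size and (self.values.min() < -1e-9
                                     or self.values.max() > 255 + 1e-9):
                raise ValidationError("nasta values must lie in [0, 255]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def short_term_autocorrelation_1d(f: np.ndarray, t: int,
                                  spec: StaWindowSpec, k: int) -> float:
    """STA of a 1-D signal at center ``t`` and integer lag ``k``."""
    f = np.asarray(f, dtype=float)
    h = spec.half
    if abs(k) > h:
        raise ValidationError(f"lag {k} out of range for L={spec.L}")
    w = spec.taper()
    n = len(f)
    total = 0.0
    for l in range(-h, h + 1):
        if not (-h <= l + k <= h):
            continue  # shifted taper index outside the window
        a, b = t + l, t + l + k
        if 0 <= a < n and 0 <= b < n:
            total += w[l + h] * f[a] * w[l + k + h] * f[b]
    return float(total)


def asta_1d(f: np.ndarray, spec: StaWindowSpec) -> np.ndarray:
    """Accumulative STA: per-index sum of STA over all lags in [-L//2, L//2]."""
    f = np.asarray(f, dtype=float)
    if len(f) < spec.L:
        raise ValidationError(
            f"signal length {len(f)} shorter than window L={spec.L}")
    h = spec.half
    out = np.empty(len(f))
    for t in range(len(f)):
        out[t] = sum(short_term_autocorrelation_1d(f, t, spec, k)
                     for k in range(-h, h + 1))
    return out


def temperature_weights(img: ThermalImage, strategy: str = "linear",
                        beta: float = 1.0) -> np.ndarray:
    """Per-pixel temperature weighting ``p``.

    * ``unit`` — no weighting (p = 1).
    * ``linear`` — ``p = T / max(T)``: monotone emphasis of hot pixels,
      scale-free (default).
    * ``softmax`` — ``p = exp(beta * (T - max(T)))``: sharper emphasis.
    """
    T = img.temps
    if strategy == "unit":
        return np.ones_like(T)
    if strategy == "linear":
        m = float(T.max())
        return np.ones_like(T) if m == 0 else T / m
    if strategy == "softmax":
        return np.exp(beta * (T - float(T.max())))
    raise ValidationError(f"unknown temperature weighting {strategy!r}")


def sta_2d(img: ThermalImage, m: int, n: int, spec: StaWindowSpec,
           k1: int, k2: int, weighting: str = "linear",
           beta: float = 1.0) -> float:
    """Temperature-weighted 2-D STA at pixel ``(m, n)`` and lag ``(k1, k2)``.

    Direct (looped) evaluation; :func:`nasta` uses an equivalent vectorized
    accumulation over all lag pairs.
    """
    h = spec.half
    if abs(k1) > h or abs(k2) > h:
        raise ValidationError(f"lag ({k1},{k2}) out of range for L={spec.L}")
    w1 = spec.taper()
    q = temperature_weights(img, weighting, beta) * img.temps
    rows, cols = img.shape
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
                total += (w1[l1 + h] * w1[l2 + h] * q[a1, a2]
                          * w1[l1 + k1 + h] * w1[l2 + k2 + h] * q[b1, b2])
    return float(total)


def _shifted(q: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """``out[i, j] = q[i+dr, j+dc]`` where defined, else 0 (clipped window)."""
    H, W = q.shape
    out = np.zeros_like(q)
    r0, r1 = max(0, -dr), min(H, H - dr)
    c0, c1 = max(0, -dc), min(W, W - dc)
    if r0 < r1 and c0 < c1:
        out[r0:r1, c0:c1] = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    return out


def nasta(img: ThermalImage, spec: StaWindowSpec = StaWindowSpec(),
          weighting: str = "linear", beta: float = 1.0) -> FeatureImage:
    """NASTA feature map: accumulate the 2-D STA over all lag pairs, then
    min-max normalize to [0, 255].

    Degenerate-normalization convention: a constant input image (or a
    constant accumulation map) carries no information and yields all
    zeros.  The constant-image case is short-circuited because border
    clipping alone would otherwise paint spurious structure onto a
    featureless image."""
    rows, cols = img.shape
    if rows < spec.L or cols < spec.L:
        raise ValidationError(
            f"image {img.shape} smaller than STA window L={spec.L}")
    if np.ptp(img.temps) == 0.0:
        return FeatureImage(values=np.zeros(img.shape), kind="nasta")
    h = spec.half
    w = spec.taper()
    q = temperature_weights(img, weighting, beta) * img.temps

    offs = range(-h, h + 1)
    shifts = {(a, b): _shifted(q, a, b) for a in offs for b in offs}
    acc = np.zeros_like(q)
    # Sum over ordered pairs of window offsets (l, l') with per-axis
    # separation <= L//2: each such pair corresponds to exactly one lag
    # (k1, k2) = l' - l, so this equals the sum of STA over all lag pairs.
    for (a1, a2), s_a in shifts.items():
        wa = w[a1 + h] * w[a2 + h]
        for (b1, b2), s_b in shifts.items():
            if abs(b1 - a1) > h or abs(b2 - a2) > h:
                continue
            acc += (wa * w[b1 + h] * w[b2 + h]) * s_a * s_b

    lo, hi = float(acc.min()), float(acc.max())
    if hi - lo < 1e-12 * max(1.0, abs(hi)):
        values = np.zeros_like(acc)
    else:
        values = np.clip(255.0 * (acc - lo) / (hi - lo), 0.0, 255.0)
    return FeatureImage(values=values, kind="nasta")
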