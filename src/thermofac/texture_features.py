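"""Semi-local Beltrami-framework texture descriptor for the edge stage.

Each pixel is mapped to the embedding ``(x, y, I(window around (x, y)))`` of
length ``w**2 + 2``: its spatial position plus the grayscale values of the
``w x w`` window around it.  The induced metric tensor of that embedding is

    g = I_2 + J^T J,

where ``J`` is the ``(w**2) x 2`` Jacobian of the window values with
respect to the spatial coordinates (central differences, reflected
borders).  ``det(g) >= 1`` everywhere, with equality on locally constant
images; large determinants mark textured/edged neighbourhoods.  The
descriptor

    T(x, y) = exp(-det(g_xy) / sigma)

is bounded in ``(0, exp(-1/sigma)]``, smooth, and monotone decreasing in
``det(g)``, with ``sigma > 0`` acting as a scale parameter.  Because it is
derivative-based, the descriptor is invariant to adding a constant to the
image.  Temperatures (grayscale), not RGB, drive the texture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .nasta_features import FeatureImage
from .thermio import ThermalImage, ValidationError

__all__ = ["TextureSpec", "window_embedding", "metric_tensor",
           "texture_descriptor"]


@dataclass
class TextureSpec:
    """Square window side ``w`` (odd >= 3) and scale parameter ``sigma > 0``."""

    w: int = 5
    sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.w < 3 or self.w % 2 == 0:
            raise ValidationError(f"texture window must be odd >= 3, got {self.w}")
        if not self.sigma > 0:
            raise ValidationError(f"sigma must be > 0, got {self.sigma}")


def _central_gradients(temps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference partials with reflected borders."""
    p = np.pad(temps, 1, mode="reflect")
    gx = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0   # d/d(row)
    gy = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0   # d/d(col)
    return gx, gy


def window_embedding(img: ThermalImage, x: int, y: int,
                     spec: TextureSpec) -> np.ndarray:
    """Position-plus-window embedding at pixel ``(x, y)``: the coordinates
    ``(x, y)`` followed by the ``w**2`` window values in row-major order
    (reflected padding at borders)."""
    h = spec.w // 2
    p = np.pad(img.temps, h, mode="reflect")
    win = p[x:x + spec.w, y:y + spec.w]
    return np.concatenate([[float(x), float(y)], win.ravel()])


def metric_tensor(img: ThermalImage, x: int, y: int,
                  spec: TextureSpec) -> np.ndarray:
    """2x2 metric tensor ``g = I + J^T J`` of the window embedding at
    ``(x, y)``; symmetric positive definite with ``det(g) >= 1``."""
    gx, gy = _central_gradients(img.temps)
    h = spec.w // 2
    pgx = np.pad(gx, h, mode="reflect")
    pgy = np.pad(gy, h, mode="reflect")
    wx = pgx[x:x + spec.w, y:y + spec.w].ravel()
    wy = pgy[x:x + spec.w, y:y + spec.w].ravel()
    g = np.array([[1.0 + wx @ wx, wx @ wy],
                  [wx @ wy, 1.0 + wy @ wy]])
    return g


def texture_descriptor(img: ThermalImage,
                       spec: TextureSpec = TextureSpec()) -> FeatureImage:
    """Per-pixel texture map ``T = exp(-det(g)/sigma)`` (vectorized)."""
    gx, gy = _central_gradients(img.temps)
    w2 = float(spec.w * spec.w)
    sxx = uniform_filter(gx * gx, size=spec.w, mode="reflect") * w2
    syy = uniform_filter(gy * gy, size=spec.w, mode="reflect") * w2
    sxy = uniform_filter(gx * gy, size=spec.w, mode="reflect") * w2
    det = (1.0 + sxx) * (1.0 + syy) - sxy * sxy
    return FeatureImage(values=np.exp(-det / spec.sigma), kind="texture")
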