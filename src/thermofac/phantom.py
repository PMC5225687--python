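"""Synthetic thermal phantoms with known core/edge ground truth.

A phantom emulates the layered structure of an abnormal region in a breast
thermogram: a compact hot *core* plateau at ``t_base + delta_t`` surrounded
by concentric annular *edge* layers whose mean temperature drops by
``layer_drop`` per layer, over a cooler baseline, with optional additive
Gaussian noise and an optional radial boundary perturbation (sinusoidal or
chaotic via the logistic map).  Ground-truth contours for the core boundary
and the outermost layer boundary stand in for manual expert traces, so the
whole pipeline can be exercised and scored without clinical data.

Defaults (baseline 32 °C, core elevation 4 °C, 0.5 °C per-layer drop, noise
SD 0.2 °C) are configurable stand-ins for typical breast-thermogram contrast;
the clinical source tables are not available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .thermio import Contour, ThermalImage, ValidationError

__all__ = ["PhantomSpec", "PhantomTruth", "make_phantom", "chaotic_series"]


@dataclass
class PhantomSpec:
    """Parameters of a layered hot-region phantom.

    Invariants: ``delta_t > n_layers * layer_drop > 0`` (layers strictly
    decrease in temperature and stay above baseline), ``r_core >= 3`` px,
    and all layers (plus perturbation amplitude) fit inside the image.
    """

    shape: tuple[int, int] = (128, 128)
    t_base: float = 32.0
    delta_t: float = 4.0
    center: Optional[tuple[float, float]] = None
    r_core: float = 12.0
    n_layers: int = 3
    layer_drop: float = 0.5
    layer_width: float = 6.0
    noise_sd: float = 0.2
    perturbation: str = "none"      # {none, sinusoidal, chaotic}
    perturb_amp: float = 0.0        # radial amplitude at the outer boundary, px
    seed: int = 0
    n_vertices: int = 128           # ground-truth contour discretization

    def __post_init__(self) -> None:
        if self.center is None:
            self.center = (self.shape[0] / 2.0, self.shape[1] / 2.0)
        if not (self.delta_t > self.n_layers * self.layer_drop > 0):
            raise ValidationError(
                "phantom requires delta_t > n_layers*layer_drop > 0, got "
                f"delta_t={self.delta_t}, n_layers={self.n_layers}, "
                f"layer_drop={self.layer_drop}")
        if self.r_core < 3:
            raise ValidationError(f"r_core must be >= 3 px, got {self.r_core}")
        if self.perturbation not in ("none", "sinusoidal", "chaotic"):
            raise ValidationError(
                f"unknown perturbation mode {self.perturbation!r}")
        if self.perturb_amp < 0:
            raise ValidationError("perturb_amp must be >= 0")
        if self.n_vertices < 64:
            raise ValidationError("ground-truth contours need >= 64 vertices")
        r_outer = self.r_core + self.n_layers * self.layer_width
        cr, cc = self.center
        margin = r_outer + self.perturb_amp
        if (cr - margin < 1 or cc - margin < 1
                or cr + margin > self.shape[0] - 2
                or cc + margin > self.shape[1] - 2):
            raise ValidationError(
                f"layers (outer radius {r_outer} + amplitude "
                f"{self.perturb_amp}) do not fit inside image {self.shape}")

    @property
    def r_outer(self) -> float:
        return self.r_core + self.n_layers * self.layer_width


@dataclass
class PhantomTruth:
    """A phantom image with its construction ground truth."""

    image: ThermalImage
    core_contour: Contour
    edge_contour: Contour
    layer_mean_temps: Sequence[float] = field(default_factory=list)
    spec: Optional[PhantomSpec] = None


def _perturbation_profile(spec: PhantomSpec,
                          rng: np.random.Generator) -> np.ndarray:
    """Relative radial perturbation sampled at the ground-truth vertex angles.

    The same relative profile multiplies every boundary radius,
    ``r(theta) = r * (1 + rel(theta))``, which preserves layer nesting.  The
    amplitude is expressed in pixels at the *outer* boundary.  In chaotic
    mode the profile is an affine image of a logistic-map orbit, so the
    boundary radius series is genuinely chaotic.
    """
    n = spec.n_vertices
    rel_amp = spec.perturb_amp / spec.r_outer if spec.perturb_amp > 0 else 0.0
    if spec.perturbation == "none" or rel_amp == 0.0:
        return np.zeros(n)
    if spec.perturbation == "sinusoidal":
        theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        return rel_amp * np.sin(3.0 * theta)
    # chaotic: logistic orbit mapped to [-1, 1]
    x = chaotic_series(max(n, 50), mode="logistic",
                       seed=int(rng.integers(0, 2**31 - 1)))[:n]
    return rel_amp * (2.0 * np.asarray(x) - 1.0)


def _temperature_colormap(temps: np.ndarray) -> np.ndarray:
    """Fixed documented colormap: min-max normalize, then a piecewise-linear
    blue->cyan->yellow->red ramp.  Exists so the RGB ingestion path is
    testable; it is not a radiometric encoding."""
    lo, hi = float(temps.min()), float(temps.max())
    u = np.zeros_like(temps) if hi == lo else (temps - lo) / (hi - lo)
    r = np.clip(2.0 * u - 0.5, 0.0, 1.0)
    g = np.clip(1.5 - np.abs(2.0 * u - 1.0), 0.0, 1.0)
    b = np.clip(1.5 - 2.0 * u, 0.0, 1.0)
    return (np.stack([r, g, b], axis=-1) * 255).round().astype(np.uint8)


def make_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Render a layered phantom and its ground-truth contours.

    The noiseless temperature of a pixel at distance ``d`` from the center
    (measured against the possibly perturbed boundary radius at the pixel's
    polar angle) is ``t_base + delta_t`` inside the core, ``t_base + delta_t
    - k*layer_drop`` inside annular layer ``k``, and ``t_base`` outside.
    Seeded Gaussian noise is then added.  Ground-truth contours are the
    ``n_vertices``-gon discretizations of the core and outermost boundaries.
    """
    rng = np.random.default_rng(spec.seed)
    rel = _perturbation_profile(spec, rng)
    theta_v = np.linspace(0.0, 2.0 * np.pi, spec.n_vertices, endpoint=False)

    rows, cols = spec.shape
    cr, cc = spec.center
    rr, cc_grid = np.mgrid[0:rows, 0:cols]
    dr, dc = rr - cr, cc_grid - cc
    dist = np.hypot(dr, dc)
    theta_p = np.mod(np.arctan2(dc, dr), 2.0 * np.pi)

    # periodic linear interpolation of the relative perturbation
    theta_ext = np.concatenate([theta_v, [2.0 * np.pi]])
    rel_ext = np.concatenate([rel, [rel[0]]])
    rel_p = np.interp(theta_p.ravel(), theta_ext, rel_ext).reshape(theta_p.shape)
    factor = 1.0 + rel_p

    temps = np.full(spec.shape, spec.t_base, dtype=float)
    # paint layers outside-in, core last
    for k in range(spec.n_layers, 0, -1):
        r_k = spec.r_core + k * spec.layer_width
        temps[dist < r_k * factor] = (
            spec.t_base + spec.delta_t - k * spec.layer_drop)
    core_mask = dist < spec.r_core * factor
    temps[core_mask] = spec.t_base + spec.delta_t

    layer_means = [float(temps[core_mask].mean())]
    prev_mask = core_mask
    masks = []
    for k in range(1, spec.n_layers + 1):
        r_k = spec.r_core + k * spec.layer_width
        m = (dist < r_k * factor) & ~prev_mask
        masks.append(m)
        prev_mask = prev_mask | m

    if spec.noise_sd > 0:
        temps = temps + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    for m in masks:
        layer_means.append(float(temps[m].mean()))
    layer_means[0] = float(temps[core_mask].mean())

    def boundary(r_base: float) -> Contour:
        radii = r_base * (1.0 + rel)
        pts = np.stack([cr + radii * np.cos(theta_v),
                        cc + radii * np.sin(theta_v)], axis=1)
        return Contour(points=pts)

    image = ThermalImage(temps=temps, rgb=_temperature_colormap(temps))
    return PhantomTruth(
        image=image,
        core_contour=boundary(spec.r_core),
        edge_contour=boundary(spec.r_outer),
        layer_mean_temps=layer_means,
        spec=spec,
    )


def chaotic_series(n: int, mode: str = "logistic", seed: int = 0,
                   amplitude: float = 1.0) -> np.ndarray:
    """Reference time series for exercising the Lyapunov test.

    * ``logistic`` — iterates of the fully chaotic logistic map
      ``x_{t+1} = 4 x_t (1 - x_t)`` from a seeded start in (0, 1), after a
      discarded transient; all values stay in (0, 1).
    * ``sine`` — one full period of ``amplitude * sin(2*pi*t/n)``.
    * ``constant`` — all values equal to ``amplitude``.
    """
    if n < 50:
        raise ValidationError(f"series length must be >= 50, got {n}")
    if mode == "constant":
        return np.full(n, amplitude, dtype=float)
    if mode == "sine":
        t = np.arange(n)
        return amplitude * np.sin(2.0 * np.pi * t / n)
    if mode == "logistic":
        rng = np.random.default_rng(seed)
        # avoid the fixed points 0 and 3/4 and the boundary
        x = float(rng.uniform(0.1, 0.9))
        if abs(x - 0.75) < 1e-3:
            x = 0.6
        for _ in range(100):  # transient
            x = 4.0 * x * (1.0 - x)
        out = np.empty(n, dtype=float)
        for i in range(n):
            x = 4.0 * x * (1.0 - x)
            out[i] = x
        return out
    raise ValidationError(f"unknown series mode {mode!r}")
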