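"""Parametric active-contour engine for the two-stage segmentation.

Stage 1 (core): the contour starts as a small seed inside the hottest zone
and evolves under the internal stretching/bending force plus a NASTA
pressure (balloon) force applied along the outward normal.  The pressure
sign is set by the gate ``G(v) = clamp(1 - |v - mu| / (k sigma), -1, 1)``
on the NASTA value at each contour point: the contour inflates where the
feature looks like the reference region (``v`` near ``mu``) and deflates
where it does not, so it comes to rest on the thermal-core boundary.

Stage 2 (edge): the converged core contour, dilated outward by one
resampling step, seeds a second snake driven by the internal force, a
Gaussian-smoothed edge-energy force ``gamma * grad(|grad(G_sigma * I)|^2)``,
a texture pressure force (same gate, computed on the Beltrami texture
descriptor), and a spring force pulling each point back toward its anchor
on the core result.  It expands through the thermal-edge layers and locks
onto the outer boundary, where the temperature drops to baseline.

Both loops use gradient descent with step ``rho = 1``.  The external
(image-derived) forces are applied explicitly; the internal
tension/rigidity terms are integrated semi-implicitly,

    (I + rho * (alpha * K2 + beta * K4)) S^{n+1} = S^n + rho * F_ext,

because the explicit update is unstable for order-one weights (the cyclic
fourth-difference operator has eigenvalues up to 16).  On a cyclic,
uniformly indexed contour both difference operators are circulant, so the
implicit solve is an exact division in Fourier space.  Periodic arc-length
resampling keeps the discretization uniform and enforces counter-clockwise
orientation (so the outward normal is unambiguous).  Every ``fuzzy_every``
iterations a fuzzy controller may retune the tension/rigidity weights or
order a stop; otherwise the loop terminates on energy balance (maximum
point displacement below ``tol``, or a stable enclosed area once the
contour only jitters against an opposing force balance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .nasta_features import FeatureImage
from .thermio import (Contour, ContourInversionError, DegenerateContourError,
                      DegenerateStatisticsError, GeometryError, ThermalImage,
                      ValidationError, points_in_contour, polygon_area,
                      polygon_mask, signed_polygon_area)

__all__ = [
    "SnakeParams",
    "RegionStats",
    "SnakeResult",
    "internal_force",
    "pressure_gate",
    "nasta_pressure_force",
    "texture_pressure_force",
    "edge_energy_force",
    "spring_force",
    "evolve_core",
    "evolve_edge",
    "resample_contour",
    "outward_normals",
    "region_stats",
    "initial_contour",
    "segment",
]

ControllerFn = Callable[..., object]


@dataclass
class SnakeParams:
    """Weights and loop controls for both snake stages.

    alpha, beta   : tension and rigidity weights (start at 1; retuned by the
                    fuzzy controller to the defuzzified output in [0, 1])
    q, k          : NASTA pressure weight and gate tolerance (k sigmas of the
                    reference region mark the zero crossing of the gate)
    gamma, sigma_g: edge-energy weight and Gaussian smoothing SD (px)
    q_T, k_T      : texture pressure weight/tolerance (q_T defaults to q)
    lam           : spring constant toward the edge-stage anchor
    rho           : explicit gradient-descent step (1 works well)
    n_points      : contour discretization (>= 16)
    tol           : energy-balance displacement tolerance (px/iteration)
    sigma_floor   : minimum feature SD used for the NASTA gate, as a fraction
                    of the map's dynamic range (guards uniform regions)
    sigma_floor_T : same floor for the texture gate; larger, so that the mild
                    texture dips at interior layer transitions keep a
                    non-negative gate and only strongly anomalous texture
                    (the outer-boundary crater) deflates
    """

    alpha: float = 1.0
    beta: float = 1.0
    q: float = 0.5
    k: float = 1.25
    gamma: float = 45.0
    sigma_g: float = 3.0
    k_T: float = 2.0
    q_T: Optional[float] = 0.3
    lam: float = 0.005
    rho: float = 1.0
    n_points: int = 100
    max_iter: int = 2000
    reparam_every: int = 5
    fuzzy_every: int = 5
    tol: float = 0.05
    sigma_floor: float = 0.02
    sigma_floor_T: float = 0.35
    edge_dilate: float = 4.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.lam < 0 or self.q < 0:
            raise ValidationError("alpha, beta, lam, q must be >= 0")
        for name in ("k", "gamma", "sigma_g", "k_T", "rho"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if self.q_T is None:
            self.q_T = self.q
        if self.n_points < 16:
            raise ValidationError("n_points must be >= 16")
        if self.max_iter < 1 or self.reparam_every < 1 or self.fuzzy_every < 1:
            raise ValidationError("iteration controls must be >= 1")


@dataclass
class RegionStats:
    """Mean and standard deviation of a feature over a reference region."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")


@dataclass
class SnakeResult:
    """Final contour plus convergence bookkeeping."""

    contour: Contour
    converged: bool
    stopped_by: str                 # {fuzzy, balance, max_iter}
    iterations: int
    assessments: list = field(default_factory=list)


# --------------------------------------------------------------------------
# Geometry utilities
# --------------------------------------------------------------------------

def _ensure_ccw(pts: np.ndarray) -> np.ndarray:
    """Counter-clockwise point order (positive signed area), fixing the
    outward-normal convention."""
    return pts[::-1].copy() if signed_polygon_area(pts) < 0 else pts


def resample_contour(contour: Contour, n: int) -> Contour:
    """Uniform arc-length resampling to ``n`` points, CCW enforced."""
    pts = _ensure_ccw(contour.points)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total < 1e-9:
        raise DegenerateContourError("contour has zero perimeter")
    targets = np.linspace(0.0, total, n, endpoint=False)
    new = np.stack([np.interp(targets, s, closed[:, 0]),
                    np.interp(targets, s, closed[:, 1])], axis=1)
    return Contour(points=new)


def outward_normals(pts: np.ndarray) -> np.ndarray:
    """Unit outward normals of a CCW contour (rotate the central-difference
    tangent by -90 degrees)."""
    t = (np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)) / 2.0
    n = np.stack([t[:, 1], -t[:, 0]], axis=1)
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    norms[norms < 1e-12] = 1.0
    return n / norms


def _sample(values: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Bilinear sampling at continuous (row, col) positions; raises if any
    point falls outside the grid."""
    rows, cols = values.shape
    if (pts[:, 0].min() < 0 or pts[:, 0].max() > rows - 1
            or pts[:, 1].min() < 0 or pts[:, 1].max() > cols - 1):
        raise GeometryError("contour point outside the feature map")
    return map_coordinates(values, [pts[:, 0], pts[:, 1]], order=1,
                           mode="nearest")


def region_stats(feature: FeatureImage, contour: Contour,
                 inner: Optional[Contour] = None,
                 robust: bool = False) -> RegionStats:
    """Feature mean/SD over the pixels inside ``contour`` (minus the
    pixels inside ``inner``, if given — the annulus strategy).  Falls back
    to the 1-px boundary band when the region holds no pixel centers.

    With ``robust=True`` the spread is the scaled median absolute
    deviation (1.4826 MAD), which ignores the minority of boundary-band
    pixels whose feature values are already transitional; the core stage
    uses this so its gate band tracks the homogeneous plateau only."""
    mask = polygon_mask(contour.points, feature.shape)
    if inner is not None:
        mask &= ~polygon_mask(inner.points, feature.shape)
    if not mask.any():
        rr = np.clip(np.round(contour.points[:, 0]).astype(int), 0,
                     feature.shape[0] - 1)
        cc = np.clip(np.round(contour.points[:, 1]).astype(int), 0,
                     feature.shape[1] - 1)
        vals = feature.values[rr, cc]
    else:
        vals = feature.values[mask]
    if robust:
        med = float(np.median(vals))
        sigma = 1.4826 * float(np.median(np.abs(vals - med)))
        return RegionStats(mu=med, sigma=sigma)
    return RegionStats(mu=float(vals.mean()), sigma=float(vals.std()))


def _floored(stats: RegionStats, feature: FeatureImage,
             floor_frac: float) -> RegionStats:
    """Apply the sigma floor (fraction of the map's dynamic range) so the
    gate stays usable over perfectly uniform regions."""
    span = float(feature.values.max() - feature.values.min())
    floor = floor_frac * span if span > 0 else 1e-6
    return RegionStats(mu=stats.mu, sigma=max(stats.sigma, floor, 1e-12))


# --------------------------------------------------------------------------
# Forces
# --------------------------------------------------------------------------

def internal_force(contour: Contour, alpha: float, beta: float) -> np.ndarray:
    """Gradient-descent force of the stretching/bending internal energy:
    ``alpha * S'' - beta * S''''`` by cyclic finite differences."""
    p = contour.points
    d2 = np.roll(p, 1, axis=0) - 2.0 * p + np.roll(p, -1, axis=0)
    d4 = (np.roll(p, 2, axis=0) - 4.0 * np.roll(p, 1, axis=0) + 6.0 * p
          - 4.0 * np.roll(p, -1, axis=0) + np.roll(p, -2, axis=0))
    return alpha * d2 - beta * d4


def pressure_gate(value, stats: RegionStats, k: float):
    """Statistical inflate/deflate gate
    ``G(v) = clamp(1 - |v - mu| / (k sigma), -1, 1)``: +1 at ``v = mu``
    (inflate), 0 at ``|v - mu| = k sigma``, -1 beyond ``2 k sigma``
    (deflate)."""
    if not k > 0:
        raise ValidationError("k must be > 0")
    if stats.sigma <= 0:
        raise DegenerateStatisticsError(
            "zero-sigma region statistics make the pressure gate undefined")
    v = np.asarray(value, dtype=float)
    g = np.clip(1.0 - np.abs(v - stats.mu) / (k * stats.sigma), -1.0, 1.0)
    return float(g) if g.ndim == 0 else g


def _feature_pressure(contour: Contour, feature: FeatureImage,
                      stats: RegionStats, q: float, k: float) -> np.ndarray:
    pts = _ensure_ccw(contour.points)
    vals = _sample(feature.values, pts)
    g = pressure_gate(vals, stats, k)
    n_hat = outward_normals(pts)
    force = q * np.asarray(g)[:, None] * n_hat
    if not np.array_equal(pts, contour.points):  # undo orientation flip
        force = force[::-1]
    return force


def nasta_pressure_force(contour: Contour, nasta_map: FeatureImage,
                         stats: RegionStats, q: float, k: float) -> np.ndarray:
    """NASTA balloon force ``q * G(NASTA(S)) * n_hat`` along the outward
    normal (bilinear NASTA sampling)."""
    if nasta_map.kind != "nasta":
        raise ValidationError("nasta_pressure_force needs a NASTA map")
    return _feature_pressure(contour, nasta_map, stats, q, k)


def texture_pressure_force(contour: Contour, texture_map: FeatureImage,
                           stats: RegionStats, k_T: float,
                           q_T: float) -> np.ndarray:
    """Texture balloon force with the same gate structure, computed on the
    Beltrami texture descriptor."""
    if texture_map.kind != "texture":
        raise ValidationError("texture_pressure_force needs a texture map")
    return _feature_pressure(contour, texture_map, stats, q_T, k_T)


def edge_energy_force(img: ThermalImage, contour: Contour, gamma: float,
                      sigma_g: float) -> np.ndarray:
    """Edge attraction ``gamma * grad(|grad(G_sigma * I)|^2)`` sampled at
    the contour points (ascent on smoothed edge magnitude)."""
    fr, fc = _edge_force_field(img.temps, gamma, sigma_g)
    pts = contour.points
    return np.stack([_sample(fr, pts), _sample(fc, pts)], axis=1)


def _edge_force_field(temps: np.ndarray, gamma: float,
                      sigma_g: float) -> tuple[np.ndarray, np.ndarray]:
    sm = gaussian_filter(temps, sigma_g, mode="nearest")
    gr, gc = np.gradient(sm)
    e = gr * gr + gc * gc
    er, ec = np.gradient(e)
    return gamma * er, gamma * ec


def spring_force(contour: Contour, anchor: Contour, lam: float) -> np.ndarray:
    """Hooke restoring force ``-lam * (V_i - S_i)`` toward the
    corresponding anchor point."""
    if len(contour) != len(anchor):
        raise ValidationError(
            f"contour ({len(contour)}) and anchor ({len(anchor)}) must have "
            "the same point count")
    return -lam * (contour.points - anchor.points)


# --------------------------------------------------------------------------
# Evolution loops
# --------------------------------------------------------------------------

def _clip_to_image(pts: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    pts[:, 0] = np.clip(pts[:, 0], 1.0, shape[0] - 2.0)
    pts[:, 1] = np.clip(pts[:, 1], 1.0, shape[1] - 2.0)
    return pts


_MIN_AREA = 4.0          # px^2; below this the contour has collapsed
_AREA_WINDOW = 10        # iterations per area-stability window
_AREA_RTOL = 5e-3        # relative mean-area change marking force balance


def _semi_implicit_step(pts: np.ndarray, f_ext: np.ndarray, alpha: float,
                        beta: float, rho: float, lam_spring: float = 0.0,
                        anchor: Optional[np.ndarray] = None) -> np.ndarray:
    """One evolution step: explicit image force, implicit internal terms.

    ``K2`` and ``K4`` are the cyclic second/fourth difference operators;
    both are circulant on a uniformly indexed closed contour, so the solve
    is a division by their eigenvalues in Fourier space.  The spring term
    (a diagonal operator pulling toward ``anchor``) is folded into the same
    implicit solve, which keeps the step unconditionally stable for any
    ``alpha, beta, lam_spring >= 0`` — including the stiff-spring limit
    where the contour is pinned to its anchor.
    """
    n = len(pts)
    theta = 2.0 * np.pi * np.arange(n) / n
    lam2 = 2.0 - 2.0 * np.cos(theta)
    lam = alpha * lam2 + beta * lam2 * lam2
    rhs_pts = pts + rho * f_ext
    if lam_spring > 0.0 and anchor is not None:
        rhs_pts = rhs_pts + rho * lam_spring * anchor
    rhs = np.fft.fft(rhs_pts, axis=0)
    denom = (1.0 + rho * (lam + lam_spring))[:, None]
    return np.fft.ifft(rhs / denom, axis=0).real


def _evolve(shape: tuple[int, int], init: Contour, params: SnakeParams,
            force_fn, stats_refresh, controller: Optional[ControllerFn],
            lam_spring: float = 0.0, anchor: Optional[Contour] = None
            ) -> SnakeResult:
    """Shared evolution loop for both stages.

    ``force_fn(contour)`` returns the total per-point *external* force
    (the internal terms are handled by the semi-implicit step);
    ``stats_refresh(contour)`` re-estimates the pressure-gate region
    statistics (called at the consultation cadence).
    """
    S = resample_contour(init, params.n_points)
    alpha, beta = params.alpha, params.beta
    stats_refresh(S)
    prev_consult = S
    assessments: list = []
    areas: list[float] = []

    anchor_pts = anchor.points if anchor is not None else None
    for it in range(1, params.max_iter + 1):
        F = force_fn(S)
        new_pts = _clip_to_image(
            _semi_implicit_step(S.points, F, alpha, beta, params.rho,
                                lam_spring, anchor_pts), shape)
        max_disp = float(np.max(np.linalg.norm(new_pts - S.points, axis=1)))
        S = Contour(points=new_pts)

        if it % params.reparam_every == 0:
            S = resample_contour(S, params.n_points)

        area = polygon_area(S.points)
        if area < _MIN_AREA:
            raise DegenerateContourError(
                f"contour collapsed to area {area:.2f} px^2 at iteration {it}")
        areas.append(area)

        if it % params.fuzzy_every == 0:
            if controller is not None:
                assess = controller(S, prev_consult, alpha, beta)
                assessments.append(assess)
                if assess.alpha_new is not None:
                    alpha = float(assess.alpha_new)
                if assess.beta_new is not None:
                    beta = float(assess.beta_new)
                prev_consult = S
                if assess.stop:
                    return SnakeResult(S, True, "fuzzy", it, assessments)
            stats_refresh(S)

        if max_disp < params.tol:
            return SnakeResult(S, True, "balance", it, assessments)
        if len(areas) >= 2 * _AREA_WINDOW:
            recent = float(np.mean(areas[-_AREA_WINDOW:]))
            older = float(np.mean(areas[-2 * _AREA_WINDOW:-_AREA_WINDOW]))
            if abs(recent - older) / max(recent, 1e-9) < _AREA_RTOL:
                return SnakeResult(S, True, "balance", it, assessments)

    return SnakeResult(S, False, "max_iter", params.max_iter, assessments)


def evolve_core(img: ThermalImage, nasta_map: FeatureImage, init: Contour,
                params: SnakeParams = SnakeParams(),
                controller: Optional[ControllerFn] = None) -> SnakeResult:
    """Evolve the core-stage snake: internal force + NASTA pressure.

    The gate statistics (mu, sigma of NASTA) are estimated from the pixels
    inside the current contour and refreshed at the consultation cadence.
    """
    if nasta_map.kind != "nasta":
        raise ValidationError("evolve_core needs a NASTA feature map")
    state = {"stats": None}

    def refresh(contour: Contour) -> None:
        state["stats"] = _floored(region_stats(nasta_map, contour, robust=True),
                                  nasta_map, params.sigma_floor)

    def total_force(contour: Contour) -> np.ndarray:
        if params.q == 0:
            return np.zeros_like(contour.points)
        return nasta_pressure_force(contour, nasta_map, state["stats"],
                                    params.q, params.k)

    return _evolve(img.shape, init, params, total_force, refresh, controller)


def evolve_edge(img: ThermalImage, texture_map: FeatureImage,
                core_contour: Contour,
                params: SnakeParams = SnakeParams(),
                controller: Optional[ControllerFn] = None) -> SnakeResult:
    """Evolve the edge-stage snake from the converged core outward.

    The initial contour is the core result dilated outward by
    ``edge_dilate`` pixels (clearing the texture transition band of the
    core boundary itself); the spring anchor is the (jointly resampled)
    core contour.  Gate statistics are estimated over the annulus between the
    current contour and the anchor.  The result must enclose the core.
    """
    if texture_map.kind != "texture":
        raise ValidationError("evolve_edge needs a texture feature map")
    anchor = resample_contour(core_contour, params.n_points)
    step = max(_perimeter(anchor.points) / params.n_points,
               params.edge_dilate)
    init = Contour(points=_clip_to_image(
        anchor.points + step * outward_normals(anchor.points), img.shape))

    er_ec = _edge_force_field(img.temps, params.gamma, params.sigma_g)
    state = {"stats": None}

    def refresh(contour: Contour) -> None:
        state["stats"] = _floored(region_stats(texture_map, contour),
                                  texture_map, params.sigma_floor_T)

    def total_force(contour: Contour) -> np.ndarray:
        pts = contour.points
        edge_f = np.stack([_sample(er_ec[0], pts), _sample(er_ec[1], pts)],
                          axis=1)
        return edge_f + texture_pressure_force(contour, texture_map,
                                               state["stats"], params.k_T,
                                               params.q_T)

    result = _evolve(img.shape, init, params, total_force, refresh, controller,
                     lam_spring=params.lam, anchor=anchor)

    # enclosure check against a slightly shrunk anchor, so a result that
    # grazes the anchor (stiff-spring limit) is not flagged as inverted
    probe = anchor.points - 0.75 * outward_normals(anchor.points)
    inside = points_in_contour(probe, result.contour)
    if inside.mean() < 0.98:
        raise ContourInversionError(
            f"edge result encloses only {100 * inside.mean():.0f}% of the "
            "core contour")
    return result


def _perimeter(pts: np.ndarray) -> float:
    closed = np.vstack([pts, pts[:1]])
    return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))


# --------------------------------------------------------------------------
# Automatic initialization and the full pipeline
# --------------------------------------------------------------------------

def _circle(center: np.ndarray, radius: float, n: int = 64) -> Contour:
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return Contour(points=np.stack(
        [center[0] + radius * np.cos(theta),
         center[1] + radius * np.sin(theta)], axis=1))


def initial_contour(img: ThermalImage, seed_radius: float = 5.0) -> Contour:
    """Automatic seed placement.

    Canny edges of the (normalized) temperature image are filled; if the
    global temperature maximum lies inside a closed edge component of
    reasonable size, the seed is a small circle at that component's
    centroid.  Otherwise the fallback is a ``seed_radius``-px circle at the
    temperature maximum.
    """
    from scipy.ndimage import binary_fill_holes, label
    from skimage.feature import canny

    temps = img.temps
    span = float(temps.max() - temps.min())
    hot = np.array(np.unravel_index(np.argmax(temps), temps.shape), dtype=float)
    if span > 0:
        norm = (temps - temps.min()) / span
        edges = canny(norm, sigma=2.0)
        filled = binary_fill_holes(edges)
        interior = filled & ~edges
        labels, _ = label(interior)
        lab = labels[int(round(hot[0])), int(round(hot[1]))]
        if lab > 0:
            ys, xs = np.nonzero(labels == lab)
            if len(ys) >= 25:
                # the component places the seed; the seed itself stays
                # small so it starts strictly inside the hot plateau
                center = np.array([ys.mean(), xs.mean()])
                r_eq = np.sqrt(len(ys) / np.pi)
                radius = float(np.clip(0.2 * r_eq, 3.0, seed_radius))
                return _circle(center, radius)
    radius = float(np.clip(seed_radius, 3.0,
                           0.25 * min(img.shape)))
    return _circle(hot, radius)


@dataclass
class SegmentationResult:
    """Output of the full two-stage pipeline."""

    core: SnakeResult
    edge: SnakeResult
    nasta_map: FeatureImage
    texture_map: FeatureImage
    init: Contour


def segment(img: ThermalImage, config=None,
            use_controller: bool = True) -> SegmentationResult:
    """Run the full pipeline: NASTA map, automatic seed, core snake with
    the fuzzy controller, texture map, edge snake."""
    from . import fuzzy_control
    from .nasta_features import StaWindowSpec, nasta
    from .texture_features import TextureSpec, texture_descriptor
    from .thermio import RunConfig

    cfg = config or RunConfig()
    params = cfg.snake_params()
    nasta_map = nasta(img, StaWindowSpec(L=cfg.sta_window),
                      weighting=cfg.sta_weighting, beta=cfg.sta_softmax_beta)
    texture_map = texture_descriptor(
        img, TextureSpec(w=cfg.texture_window, sigma=cfg.texture_sigma))
    init = initial_contour(img)
    controller = None
    if use_controller:
        rulebase = (fuzzy_control.load_rulebase(cfg.rulebase_path)
                    if cfg.rulebase_path else None)
        controller = fuzzy_control.make_controller(
            img, config=fuzzy_control.MembershipConfig.for_image(
                img, chaos_threshold=cfg.chaos_threshold),
            rulebase=rulebase)
    core = evolve_core(img, nasta_map, init, params, controller)
    edge = evolve_edge(img, texture_map, core.contour, params, controller)
    return SegmentationResult(core=core, edge=edge, nasta_map=nasta_map,
                              texture_map=texture_map, init=init)
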