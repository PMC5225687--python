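"""Mamdani fuzzy controller steering the growing contour.

At every consultation the controller reduces the contour's recent history to
three crisp inputs:

1. the mean temperature of the annular *layer* swept since the previous
   consultation (outer contour minus inner contour),
2. the relative area-growth rate ``r = (A_next - A_prev) / A_prev``,
3. the largest Lyapunov exponent of the contour's radius series (is the
   boundary behaving chaotically?).

Each input is fuzzified against three linguistic labels, a rulebase of
if-then rules is evaluated with min-max (Mamdani) inference, and the
aggregated output membership landscape over the four classes — Normal,
Suspicious, Abnormal, HighlyAbnormal — is collapsed by centroid
defuzzification.  The defuzzified scalar ``mu`` in [0, 1] becomes the new
tension/rigidity weights (``alpha = beta = mu``), and the contour is ordered
to stop when the inferred class is Normal: temperature changes are low and
the contour has left the abnormal thermal layers.

Temperature labels are defined relative to the image's own temperature
range (robust 1st/99th percentiles), so the controller adapts to the
baseline and peak of each thermogram; all breakpoints are configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import chaos
from .thermio import (Contour, GeometryError, InsufficientRecurrenceError,
                      ThermalImage, ValidationError, points_in_contour,
                      polygon_area, polygon_mask)

__all__ = [
    "MembershipFunction",
    "FuzzyRule",
    "FuzzyAssessment",
    "MembershipConfig",
    "CLASSES",
    "DEFAULT_RULEBASE",
    "fuzzify",
    "infer",
    "layer_mean_temperature",
    "area_growth_rate",
    "controller_step",
    "make_controller",
    "parse_rulebase",
    "format_rulebase",
    "load_rulebase",
    "save_rulebase",
]

CLASSES = ("Normal", "Suspicious", "Abnormal", "HighlyAbnormal")

TEMPERATURE_LABELS = ("low", "medium", "high")
RATE_LABELS = ("uniform", "moderate", "excessive")
BEHAVIOR_LABELS = ("non_chaotic", "weakly_chaotic", "chaotic")

# Large-but-finite shoulder extent keeping breakpoints strictly ordered.
_FAR = 1.0e6


@dataclass
class MembershipFunction:
    """Triangular or trapezoidal membership shape.

    ``breakpoints`` are strictly increasing abscissae: 3 for a triangle
    (foot, peak, foot), 4 for a trapezoid (foot, shoulder, shoulder, foot).
    Membership is 0 outside the feet and reaches 1 at the peak/plateau.
    """

    label: str
    shape: str
    breakpoints: Sequence[float]

    def __post_init__(self) -> None:
        bp = [float(b) for b in self.breakpoints]
        n = {"triangular": 3, "trapezoidal": 4}.get(self.shape)
        if n is None:
            raise ValidationError(f"unknown membership shape {self.shape!r}")
        if len(bp) != n:
            raise ValidationError(
                f"{self.shape} membership needs {n} breakpoints, got {len(bp)}")
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValidationError(
                f"breakpoints must be strictly increasing, got {bp}")
        self.breakpoints = bp

    def __call__(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        if self.shape == "triangular":
            a, b, c = self.breakpoints
            y = np.where(x <= b,
                         (x - a) / (b - a),
                         (c - x) / (c - b))
        else:
            a, b, c, d = self.breakpoints
            y = np.where(x <= b, (x - a) / (b - a),
                         np.where(x <= c, 1.0, (d - x) / (d - c)))
        out = np.clip(y, 0.0, 1.0)
        return float(out) if out.ndim == 0 else out


@dataclass
class FuzzyRule:
    """One if-then rule: an antecedent label per input variable (``*`` is a
    wildcard) and an output class consequent."""

    temperature: str
    rate: str
    behavior: str
    consequent: str

    def __post_init__(self) -> None:
        for val, labels, name in (
                (self.temperature, TEMPERATURE_LABELS, "temperature"),
                (self.rate, RATE_LABELS, "rate"),
                (self.behavior, BEHAVIOR_LABELS, "behavior")):
            if val != "*" and val not in labels:
                raise ValidationError(
                    f"unknown {name} label {val!r} (expected {labels} or '*')")
        if self.consequent not in CLASSES:
            raise ValidationError(
                f"unknown output class {self.consequent!r}")


@dataclass
class FuzzyAssessment:
    """One controller verdict: crisp inputs, memberships, inferred class,
    updated snake weights and the stop order."""

    inputs: tuple[float, float, float]    # (layer temp °C, growth rate, L)
    memberships: dict
    cls: str
    alpha_new: Optional[float]
    beta_new: Optional[float]
    stop: bool
    mu_out: Optional[float] = None        # defuzzified scalar in [0, 1]


def _scaled(lo: float, hi: float, u: Sequence[float]) -> list[float]:
    return [lo + ui * (hi - lo) for ui in u]


@dataclass
class MembershipConfig:
    """Membership functions for the three inputs and the output classes,
    plus the chaos threshold separating weak from full chaos."""

    temperature: list[MembershipFunction]
    rate: list[MembershipFunction]
    behavior: list[MembershipFunction]
    output: list[MembershipFunction]
    chaos_threshold: float = 0.1

    @classmethod
    def default(cls, t_min: float, t_max: float) -> "MembershipConfig":
        """Default breakpoints.

        Temperature labels are relative to the image's operating range
        ``[t_min, t_max]``: *low* saturates below baseline + 25 % of the
        range, *high* above baseline + 60 %, with the *medium* peak at
        their midpoint (42.5 %).  Growth-rate labels: *uniform* below 0.05,
        *excessive* above 0.30.  Behavior labels follow the Lyapunov sign
        convention: *non_chaotic* below -0.05, *chaotic* above +0.10, with
        *weakly_chaotic* covering the small positive values in between.
        """
        if not t_max > t_min:
            raise ValidationError(
                f"temperature range must be non-degenerate, got "
                f"[{t_min}, {t_max}]")
        s = lambda u: _scaled(t_min, t_max, u)  # noqa: E731
        temperature = [
            MembershipFunction("low", "trapezoidal",
                               s([-1.0, -0.5, 0.25, 0.425])),
            MembershipFunction("medium", "triangular",
                               s([0.25, 0.425, 0.6])),
            MembershipFunction("high", "trapezoidal",
                               s([0.425, 0.6, 1.5, 2.0])),
        ]
        rate = [
            MembershipFunction("uniform", "trapezoidal",
                               [-_FAR, -1.0, 0.05, 0.175]),
            MembershipFunction("moderate", "triangular",
                               [0.05, 0.175, 0.30]),
            MembershipFunction("excessive", "trapezoidal",
                               [0.175, 0.30, _FAR / 2, _FAR]),
        ]
        behavior = [
            MembershipFunction("non_chaotic", "trapezoidal",
                               [-_FAR, -_FAR / 2, -0.05, 0.025]),
            MembershipFunction("weakly_chaotic", "triangular",
                               [-0.05, 0.025, 0.10]),
            MembershipFunction("chaotic", "trapezoidal",
                               [0.025, 0.10, _FAR / 2, _FAR]),
        ]
        third = 1.0 / 3.0
        output = [
            MembershipFunction("Normal", "triangular", [-third, 0.0, third]),
            MembershipFunction("Suspicious", "triangular",
                               [0.0, third, 2 * third]),
            MembershipFunction("Abnormal", "triangular",
                               [third, 2 * third, 1.0]),
            MembershipFunction("HighlyAbnormal", "triangular",
                               [2 * third, 1.0, 1.0 + third]),
        ]
        return cls(temperature=temperature, rate=rate, behavior=behavior,
                   output=output)

    @classmethod
    def for_image(cls, img: ThermalImage,
                  chaos_threshold: float = 0.1) -> "MembershipConfig":
        """Default config with the temperature range taken from the image's
        robust (1st/99th percentile) temperature span."""
        t_min = float(np.percentile(img.temps, 1))
        t_max = float(np.percentile(img.temps, 99))
        if t_max <= t_min:  # constant image
            t_min, t_max = t_min - 0.5, t_min + 0.5
        out = cls.default(t_min, t_max)
        out.chaos_threshold = chaos_threshold
        return out


# --------------------------------------------------------------------------
# Default rulebase: 25 rules over the 3x3x3 antecedent grid, two of them
# wildcard-merged.  Hot layers are abnormal (the more so when growth is
# excessive or the boundary behaves chaotically); cool layers with orderly
# growth are normal, which is the stop condition.
# --------------------------------------------------------------------------

DEFAULT_RULEBASE = """\
# temperature, rate, behavior -> class
high, excessive, * -> HighlyAbnormal
high, *, chaotic -> HighlyAbnormal
high, excessive, chaotic -> HighlyAbnormal
high, uniform, non_chaotic -> Abnormal
high, uniform, weakly_chaotic -> Abnormal
high, moderate, non_chaotic -> Abnormal
high, moderate, weakly_chaotic -> HighlyAbnormal
medium, uniform, non_chaotic -> Suspicious
medium, uniform, weakly_chaotic -> Suspicious
medium, uniform, chaotic -> Abnormal
medium, moderate, non_chaotic -> Suspicious
medium, moderate, weakly_chaotic -> Abnormal
medium, moderate, chaotic -> Abnormal
medium, excessive, non_chaotic -> Abnormal
medium, excessive, weakly_chaotic -> Abnormal
medium, excessive, chaotic -> HighlyAbnormal
low, uniform, non_chaotic -> Normal
low, uniform, weakly_chaotic -> Normal
low, uniform, chaotic -> Suspicious
low, moderate, non_chaotic -> Normal
low, moderate, weakly_chaotic -> Normal
low, moderate, chaotic -> Suspicious
low, excessive, non_chaotic -> Suspicious
low, excessive, weakly_chaotic -> Suspicious
low, excessive, chaotic -> Suspicious
"""


def parse_rulebase(text: str) -> list[FuzzyRule]:
    """Parse rules from the plain-text table format
    ``temperature, rate, behavior -> class`` (one per line, ``#`` comments,
    ``*`` wildcard)."""
    rules: list[FuzzyRule] = []
    for ln, line in enumerate(text.splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "->" not in line:
            raise ValidationError(f"rule line {ln}: missing '->': {line!r}")
        lhs, rhs = line.split("->", 1)
        parts = [p.strip() for p in lhs.split(",")]
        if len(parts) != 3:
            raise ValidationError(
                f"rule line {ln}: expected 3 antecedent labels, "
                f"got {len(parts)}")
        rules.append(FuzzyRule(parts[0], parts[1], parts[2], rhs.strip()))
    if not rules:
        raise ValidationError("rulebase is empty")
    return rules


def format_rulebase(rules: Sequence[FuzzyRule]) -> str:
    lines = ["# temperature, rate, behavior -> class"]
    for r in rules:
        lines.append(f"{r.temperature}, {r.rate}, {r.behavior} -> "
                     f"{r.consequent}")
    return "\n".join(lines) + "\n"


def load_rulebase(path: str | Path) -> list[FuzzyRule]:
    return parse_rulebase(Path(path).read_text())


def save_rulebase(rules: Sequence[FuzzyRule], path: str | Path) -> None:
    Path(path).write_text(format_rulebase(rules))


def default_rulebase() -> list[FuzzyRule]:
    return parse_rulebase(DEFAULT_RULEBASE)


# --------------------------------------------------------------------------
# Crisp inputs
# --------------------------------------------------------------------------

def layer_mean_temperature(img: ThermalImage, outer: Contour,
                           inner: Contour) -> float:
    """Mean temperature of the annulus inside ``outer`` and outside
    ``inner`` (the layer swept by the growing contour).  If the annulus
    contains no pixel centers, falls back to the mean over the 1-px band of
    pixels along the outer contour."""
    inside = points_in_contour(inner.points, outer)
    center_ok = points_in_contour(np.atleast_2d(
        np.asarray(inner.centroid)), outer)[0]
    if not center_ok and inside.mean() < 0.5:
        raise GeometryError("inner contour is not inside outer contour")
    shape = img.shape
    annulus = polygon_mask(outer.points, shape) & ~polygon_mask(
        inner.points, shape)
    if annulus.any():
        return float(img.temps[annulus].mean())
    # degenerate annulus: 1-px band along the outer contour
    rr = np.clip(np.round(outer.points[:, 0]).astype(int), 0, shape[0] - 1)
    cc = np.clip(np.round(outer.points[:, 1]).astype(int), 0, shape[1] - 1)
    return float(img.temps[rr, cc].mean())


def area_growth_rate(area_prev: float, area_next: float) -> float:
    """Relative area growth ``(A_next - A_prev) / A_prev``; areas are
    shoelace polygon areas of the contour (sub-pixel consistent stand-in
    for pixel counting)."""
    if not area_prev > 0:
        raise ValidationError(f"area_prev must be > 0, got {area_prev}")
    return (area_next - area_prev) / area_prev


# --------------------------------------------------------------------------
# Inference
# --------------------------------------------------------------------------

def fuzzify(value: float,
            functions: Sequence[MembershipFunction]) -> dict[str, float]:
    """Degree of each label at ``value`` (degrees need not sum to 1)."""
    return {fn.label: float(fn(value)) for fn in functions}


_DEFUZZ_GRID = np.linspace(0.0, 1.0, 501)


def infer(assess_inputs: tuple[float, float, float],
          rulebase: Sequence[FuzzyRule],
          membership_config: MembershipConfig,
          alpha_prev: float = 1.0,
          beta_prev: float = 1.0) -> FuzzyAssessment:
    """Mamdani min-max inference with centroid defuzzification.

    Rule strength is the min of its antecedent degrees (wildcards count 1);
    per-class strength is the max over rules; the aggregated output
    landscape is the max over classes of the class membership clipped at
    its strength.  ``cls`` is the class dominating the landscape at the
    centroid (ties resolve toward the more abnormal class); ``alpha_new =
    beta_new = mu_out`` (the centroid, in [0, 1]); ``stop`` iff the class
    is Normal.  If no rule fires at all, the declared fallback is class
    Suspicious with the previous weights and no stop.
    """
    temp, rate, lyap = assess_inputs
    cfg = membership_config
    memberships = {
        "temperature": fuzzify(temp, cfg.temperature),
        "rate": fuzzify(rate, cfg.rate),
        "behavior": fuzzify(lyap, cfg.behavior),
    }

    strengths = {c: 0.0 for c in CLASSES}
    for rule in rulebase:
        degs = []
        for var, label in (("temperature", rule.temperature),
                           ("rate", rule.rate),
                           ("behavior", rule.behavior)):
            degs.append(1.0 if label == "*" else memberships[var][label])
        s = min(degs)
        if s > strengths[rule.consequent]:
            strengths[rule.consequent] = s

    if max(strengths.values()) <= 0.0:
        return FuzzyAssessment(
            inputs=(temp, rate, lyap), memberships=memberships,
            cls="Suspicious", alpha_new=alpha_prev, beta_new=beta_prev,
            stop=False, mu_out=None)

    out_fns = {fn.label: fn for fn in cfg.output}
    landscape = np.zeros_like(_DEFUZZ_GRID)
    for c in CLASSES:
        landscape = np.maximum(landscape,
                               np.minimum(strengths[c],
                                          out_fns[c](_DEFUZZ_GRID)))
    mu_out = float(np.trapezoid(landscape * _DEFUZZ_GRID, _DEFUZZ_GRID)
                   / np.trapezoid(landscape, _DEFUZZ_GRID))

    # class dominating the landscape at the centroid, ties -> more abnormal
    best, best_val = "Normal", -1.0
    for c in CLASSES:  # ordered least to most abnormal
        v = min(strengths[c], float(out_fns[c](mu_out)))
        if v >= best_val:
            best, best_val = c, v
    cls = best

    return FuzzyAssessment(
        inputs=(temp, rate, lyap), memberships=memberships, cls=cls,
        alpha_new=mu_out, beta_new=mu_out, stop=(cls == "Normal"),
        mu_out=mu_out)


def controller_step(img: ThermalImage, contour_now: Contour,
                    contour_prev: Contour,
                    center: Optional[np.ndarray] = None,
                    config: Optional[MembershipConfig] = None,
                    rulebase: Optional[Sequence[FuzzyRule]] = None,
                    lyapunov_spec: Optional[chaos.LyapunovSpec] = None,
                    alpha_prev: float = 1.0,
                    beta_prev: float = 1.0) -> FuzzyAssessment:
    """One full controller consultation: compute the three crisp inputs
    from the contour pair, then run the inference.

    A radius series too regular to contain recurrent structure (the
    insufficient-recurrence case, e.g. a near-perfect circle) is treated as
    firmly non-chaotic.
    """
    if config is None:
        config = MembershipConfig.for_image(img)
    if rulebase is None:
        rulebase = default_rulebase()
    temp = layer_mean_temperature(img, outer=contour_now, inner=contour_prev)
    rate = area_growth_rate(polygon_area(contour_prev.points),
                            polygon_area(contour_now.points))
    spec = lyapunov_spec or chaos.LyapunovSpec()
    try:
        series = chaos.radius_series(contour_now)
        lyap = chaos.lyapunov_exponent(
            series, spec, chaos_threshold=config.chaos_threshold).exponent
    except (InsufficientRecurrenceError, ValidationError):
        lyap = -1.0  # firmly non-chaotic
    return infer((temp, rate, lyap), rulebase, config,
                 alpha_prev=alpha_prev, beta_prev=beta_prev)


def make_controller(img: ThermalImage,
                    config: Optional[MembershipConfig] = None,
                    rulebase: Optional[Sequence[FuzzyRule]] = None,
                    lyapunov_spec: Optional[chaos.LyapunovSpec] = None):
    """Bind image and configuration into the callback signature the snake
    evolution loops expect: ``fn(now, prev, alpha, beta) -> FuzzyAssessment``."""
    if config is None:
        config = MembershipConfig.for_image(img)
    if rulebase is None:
        rulebase = default_rulebase()

    def _controller(contour_now: Contour, contour_prev: Contour,
                    alpha_prev: float = 1.0,
                    beta_prev: float = 1.0) -> FuzzyAssessment:
        return controller_step(img, contour_now, contour_prev,
                               config=config, rulebase=rulebase,
                               lyapunov_spec=lyapunov_spec,
                               alpha_prev=alpha_prev, beta_prev=beta_prev)

    return _controller
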