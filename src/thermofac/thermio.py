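"""Thermal-image and contour I/O, core domain types, configuration and logging.

Conventions used throughout the package
---------------------------------------
* Coordinates are ``(row, col)``, 0-based, with pixel centers at integer
  positions.  Continuous (sub-pixel) snake positions are interpolated
  bilinearly from the pixel grid.
* Contours are *closed* ordered point sequences; the segment from the last
  point back to the first is implicit and the closing point is never
  duplicated in storage.
* Physical distances are pixel distances times ``pixel_pitch_mm``.  Clinical
  thermal cameras rarely publish their pixel-to-millimetre calibration, so
  the pitch is a user input defaulting to 1.0 (i.e. distances in pixels).
* Temperatures are degrees Celsius.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "ThermofacError",
    "ThermoIOError",
    "FormatError",
    "ValidationError",
    "GeometryError",
    "DegenerateContourError",
    "ContourInversionError",
    "DegenerateStatisticsError",
    "InsufficientRecurrenceError",
    "UndefinedStatisticError",
    "ThermalImage",
    "Contour",
    "RunConfig",
    "read_thermal_image",
    "write_thermal_csv",
    "read_contour",
    "write_contour",
    "polygon_area",
    "signed_polygon_area",
    "polygon_centroid",
    "polygon_mask",
    "points_in_contour",
    "configure_logging",
]

logger = logging.getLogger("thermofac")


# --------------------------------------------------------------------------
# Exceptions
# --------------------------------------------------------------------------

class ThermofacError(Exception):
    """Base class for all errors raised by this package."""


class ThermoIOError(ThermofacError, OSError):
    """A file could not be read or written."""


class FormatError(ThermofacError, ValueError):
    """A file parsed, but its contents violate the expected layout."""


class ValidationError(ThermofacError, ValueError):
    """An in-memory value violates a declared invariant."""


class GeometryError(ThermofacError, ValueError):
    """A geometric precondition (nesting, non-degeneracy) is violated."""


class DegenerateContourError(ThermofacError, RuntimeError):
    """The evolving contour collapsed below the minimum admissible area."""


class ContourInversionError(ThermofacError, RuntimeError):
    """The edge-stage result does not enclose the core contour."""


class DegenerateStatisticsError(ThermofacError, ValueError):
    """Region statistics are degenerate (zero spread)."""


class InsufficientRecurrenceError(ThermofacError, RuntimeError):
    """Too few close vector pairs to estimate a Lyapunov exponent."""


class UndefinedStatisticError(ThermofacError, ValueError):
    """A confusion-matrix statistic has a zero denominator."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class ThermalImage:
    """A 2-D temperature field in degrees Celsius with an optional RGB rendering.

    Parameters
    ----------
    temps
        ``(rows, cols)`` array of finite temperature values (°C).
    rgb
        Optional ``(rows, cols, 3)`` uint8 rendering with identical spatial
        dimensions, as produced by the camera software or a colormap.
    pixel_pitch_mm
        Physical size of one pixel in millimetres (> 0).
    """

    temps: np.ndarray
    rgb: Optional[np.ndarray] = None
    pixel_pitch_mm: float = 1.0

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        if self.temps.ndim != 2:
            raise ValidationError(
                f"temps must be a 2-D array, got shape {self.temps.shape}")
        if not np.all(np.isfinite(self.temps)):
            raise ValidationError("temps contains non-finite values")
        if self.rgb is not None:
            self.rgb = np.asarray(self.rgb)
            if self.rgb.shape[:2] != self.temps.shape:
                raise ValidationError(
                    f"rgb shape {self.rgb.shape[:2]} does not match "
                    f"temps shape {self.temps.shape}")
        if not self.pixel_pitch_mm > 0:
            raise ValidationError("pixel_pitch_mm must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.temps.shape


@dataclass
class Contour:
    """A closed, ordered sequence of ``(row, col)`` points.

    The point sequence is cyclic: point ``N-1`` connects back to point 0.
    If the input repeats the first point at the end, that closing duplicate
    is dropped on construction.  At least 4 points are required.
    """

    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError(
                f"contour points must be (N, 2), got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("contour contains non-finite coordinates")
        if len(pts) > 1 and np.array_equal(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 4:
            raise ValidationError(
                f"a closed contour needs at least 4 points, got {len(pts)}")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    @property
    def area(self) -> float:
        return polygon_area(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return polygon_centroid(self.points)


# --------------------------------------------------------------------------
# Polygon geometry helpers (shared by snake, fuzzy control and chaos)
# --------------------------------------------------------------------------

def signed_polygon_area(points: np.ndarray) -> float:
    """Shoelace signed area; positive for counter-clockwise order in the
    convention where ``row`` plays the role of *x* and ``col`` of *y*."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(points: np.ndarray) -> float:
    return abs(signed_polygon_area(points))


def polygon_centroid(points: np.ndarray) -> np.ndarray:
    """Area-weighted centroid of a simple polygon (falls back to the vertex
    mean for near-zero-area polygons)."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-12:
        return p.mean(axis=0)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def polygon_mask(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside the polygon."""
    from skimage.draw import polygon as _sk_polygon

    rr, cc = _sk_polygon(points[:, 0], points[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def points_in_contour(query: np.ndarray, contour: Contour) -> np.ndarray:
    """Vectorized point-in-polygon test (boundary counts as inside)."""
    from skimage.measure import points_in_poly

    inside = points_in_poly(np.asarray(query, dtype=float), contour.points)
    return np.asarray(inside, dtype=bool)


# --------------------------------------------------------------------------
# Image and contour I/O
# --------------------------------------------------------------------------

# ITU-R BT.601 luma weights used as the documented grayscale proxy when only
# an RGB rendering (no radiometric data) is available.
_LUMA = np.array([0.299, 0.587, 0.114])

_KINDS = ("temperature_csv", "temperature_tiff", "rgb_image")


def read_thermal_image(path: str | Path, kind: str = "temperature_csv",
                       pixel_pitch_mm: float = 1.0) -> ThermalImage:
    """Read a thermal image.

    ``kind`` selects the parser:

    * ``temperature_csv`` — rectangular CSV of temperatures in °C.
    * ``temperature_tiff`` — single-channel (radiometric) TIFF of temperatures.
    * ``rgb_image`` — PNG/TIFF rendering; temperatures are proxied by the
      BT.601 luma of the RGB channels (0–255 scale), the standard grayscale
      conversion used when no radiometric data accompanies the rendering.
    """
    path = Path(path)
    if kind not in _KINDS:
        raise ValidationError(f"unknown image kind {kind!r}; expected one of {_KINDS}")
    if not path.is_file():
        raise ThermoIOError(f"cannot read thermal image: no such file {path}")

    if kind == "temperature_csv":
        temps = _read_matrix_csv(path)
        return ThermalImage(temps=temps, pixel_pitch_mm=pixel_pitch_mm)

    if kind == "temperature_tiff":
        import tifffile

        try:
            arr = tifffile.imread(str(path))
        except Exception as exc:  # pragma: no cover - backend specific
            raise ThermoIOError(f"cannot read TIFF {path}: {exc}") from exc
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2:
            raise FormatError(
                f"{path}: temperature TIFF must be single-channel 2-D, "
                f"got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"{path}: non-finite temperature values")
        return ThermalImage(temps=arr, pixel_pitch_mm=pixel_pitch_mm)

    # rgb_image
    import imageio.v3 as iio

    try:
        arr = iio.imread(str(path))
    except Exception as exc:
        raise ThermoIOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] >= 3:
        rgb = np.asarray(arr[:, :, :3], dtype=np.uint8)
    elif arr.ndim == 2:
        rgb = np.stack([arr] * 3, axis=-1).astype(np.uint8)
    else:
        raise FormatError(f"{path}: unsupported image shape {arr.shape}")
    temps = rgb.astype(float) @ _LUMA
    return ThermalImage(temps=temps, rgb=rgb, pixel_pitch_mm=pixel_pitch_mm)


def _read_matrix_csv(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    width = None
    with open(path, newline="") as fh:
        for i, line in enumerate(csv.reader(fh)):
            if not line or (len(line) == 1 and not line[0].strip()):
                continue
            try:
                vals = [float(v) for v in line]
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric value in row {i}: {exc}")
            if width is None:
                width = len(vals)
            elif len(vals) != width:
                raise FormatError(
                    f"{path}: row {i} has {len(vals)} values, expected {width}")
            rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: empty temperature CSV")
    temps = np.array(rows, dtype=float)
    if not np.all(np.isfinite(temps)):
        bad = np.argwhere(~np.isfinite(temps))[0]
        raise ValidationError(
            f"{path}: non-finite temperature at row {bad[0]}, col {bad[1]}")
    return temps


def write_thermal_csv(img: ThermalImage, path: str | Path) -> None:
    """Write the temperature matrix as plain CSV (full precision round trip)."""
    path = Path(path)
    try:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            for row in img.temps:
                w.writerow([f"{v:.17g}" for v in row])
    except OSError as exc:
        raise ThermoIOError(f"cannot write temperature CSV {path}: {exc}") from exc


def read_contour(path: str | Path) -> Contour:
    """Read a contour from a two-column ``row,col`` CSV (one-line header
    optional).  A final point duplicating the first is treated as an explicit
    closure and dropped."""
    path = Path(path)
    if not path.is_file():
        raise ThermoIOError(f"cannot read contour: no such file {path}")
    pts: list[list[float]] = []
    with open(path, newline="") as fh:
        for i, line in enumerate(csv.reader(fh)):
            if not line or (len(line) == 1 and not line[0].strip()):
                continue
            if len(line) != 2:
                raise FormatError(
                    f"{path}: row {i} has {len(line)} columns, expected 2")
            try:
                pts.append([float(line[0]), float(line[1])])
            except ValueError:
                if i == 0:  # header line
                    continue
                raise FormatError(f"{path}: non-numeric cell in row {i}")
    arr = np.array(pts, dtype=float) if pts else np.empty((0, 2))
    if len(arr) > 1 and np.array_equal(arr[0], arr[-1]):
        arr = arr[:-1]
    if len(arr) < 4 or len(np.unique(arr, axis=0)) < 4:
        raise ValidationError(
            f"{path}: a contour needs at least 4 distinct points, "
            f"got {len(arr)}")
    return Contour(points=arr)


def write_contour(contour: Contour, path: str | Path) -> None:
    """Write a contour as ``row,col`` CSV with full printed precision."""
    path = Path(path)
    try:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["row", "col"])
            for r, c in contour.points:
                w.writerow([f"{r:.17g}", f"{c:.17g}"])
    except OSError as exc:
        raise ThermoIOError(f"cannot write contour {path}: {exc}") from exc


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Structured configuration for a full segmentation run.

    Feature-window sizes and fuzzy breakpoints have defaults chosen on
    synthetic phantoms; everything here is overridable from a YAML file.
    """

    # NASTA feature
    sta_window: int = 5
    sta_weighting: str = "linear"   # {unit, linear, softmax}
    sta_softmax_beta: float = 1.0
    # texture feature
    texture_window: int = 5
    texture_sigma: float = 2.0
    # snake parameter overrides (keys of snake.SnakeParams)
    snake: dict = field(default_factory=dict)
    # fuzzy controller
    rulebase_path: Optional[str] = None
    chaos_threshold: float = 0.1
    # misc
    seed: int = 0
    pixel_pitch_mm: float = 1.0
    verbosity: str = "info"

    def snake_params(self):
        from .snake import SnakeParams

        return SnakeParams(**self.snake)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        path = Path(path)
        if not path.is_file():
            raise ThermoIOError(f"cannot read config: no such file {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        import yaml
        from dataclasses import asdict

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def configure_logging(verbosity: str = "info") -> None:
    """Set up structured console logging for the package logger."""
    level = getattr(logging, verbosity.upper(), logging.INFO)
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.setLevel(level)
    if not logger.handlers:
        logger.addHandler(handler)
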