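"""Pattern-deviation plot parsing: from a raster image to a category matrix.

A Humphrey pattern-deviation probability plot is a bordered panel showing
one glyph per test locus, drawn from a five-symbol alphabet (not
significant, and depressed at P < 5%, < 2%, < 1%, < 0.5%).  The parser

1. locates the plot panel (:func:`detect_plot_bounds`) — either by finding
   its rectangular frame, or, for frameless crops, from the extent of the
   symbol mass itself;
2. superimposes the canonical 6-degree locus grid of the stated test
   pattern (:func:`map_loci`), mirroring x for left eyes;
3. classifies the glyph at each locus (:func:`classify_symbol`) by its ink
   density — the mean darkness inside a sampling window of 0.8x the
   inter-locus pitch — against a calibration table of reference densities.

The ink-density feature is deliberately one-dimensional and explicitly
coded: the five standard glyphs are monotonically ordered in ink coverage,
so a transparent nearest-reference rule suffices and every decision can be
audited from the per-locus diagnostics.  Mean darkness is (approximately)
conserved by resampling, which is what makes classification robust to
uniform rescaling of the input image.

Numeric printout values (MD, central sensitivities) are never read from
images; they are user-supplied, so no OCR lives here.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from PIL import Image, ImageDraw
from scipy import ndimage
from skimage.filters import threshold_otsu

from .hpa import (
    Eye,
    PatternDeviationMatrix,
    SignificanceCategory,
    TestPattern,
    get_pattern,
)

__all__ = [
    "PlotParseError",
    "NoPlotFoundError",
    "AmbiguousPlotError",
    "GeometryError",
    "PlotGeometry",
    "CellSample",
    "SymbolCalibration",
    "GLYPH_FAMILIES",
    "draw_glyph",
    "derive_calibration",
    "calibration_from_legend",
    "chart_positions",
    "chart_extent",
    "detect_plot_bounds",
    "map_loci",
    "classify_symbol",
    "parse_pattern_plot",
    "parse_plot",
    "ParseResult",
    "render_overlay",
]

# Sampling window side, as a fraction of the 6-degree inter-locus pitch.
# Below 1.0 so neighbouring windows never overlap.
WINDOW_FRACTION = 0.8

# Degrees of panel padding beyond the outermost locus centers on each side
# (half a cell, so loci sit at the centers of a clean 6-degree tiling).
PANEL_PAD_DEG = 3.0


class PlotParseError(Exception):
    """Base class for image-parsing failures."""


class NoPlotFoundError(PlotParseError):
    pass


class AmbiguousPlotError(PlotParseError):
    def __init__(self, candidates):
        self.candidates = list(candidates)
        super().__init__(
            f"{len(self.candidates)} candidate plot panels found: {self.candidates}"
        )


class GeometryError(PlotParseError):
    pass


# ---------------------------------------------------------------------------
# Chart-space layout (visual-field degrees -> chart degrees)
# ---------------------------------------------------------------------------

def chart_positions(pattern: TestPattern, eye: Eye) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Pairs of (canonical locus, chart position in degrees).

    Loci are stored in right-eye convention (x positive temporal); the
    left-eye chart mirrors x, so the two layouts are reflections about the
    vertical midline.  Chart y is superior-positive.
    """
    sign = 1 if eye is Eye.RIGHT else -1
    return [((x, y), (sign * x, y)) for (x, y) in pattern.loci]


def chart_extent(pattern: TestPattern, eye: Eye) -> tuple[float, float, float, float]:
    """Panel extent (gx0, gx1, gy0, gy1) in chart degrees."""
    xs = [cx for _, (cx, _) in chart_positions(pattern, eye)]
    ys = [cy for _, (_, cy) in chart_positions(pattern, eye)]
    return (
        min(xs) - PANEL_PAD_DEG,
        max(xs) + PANEL_PAD_DEG,
        min(ys) - PANEL_PAD_DEG,
        max(ys) + PANEL_PAD_DEG,
    )


# ---------------------------------------------------------------------------
# Geometry containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlotGeometry:
    """Pixel-space location of the plot panel and its degree mapping.

    ``bbox`` is the panel interior (left, top, right, bottom; right/bottom
    exclusive, continuous pixel coordinates).  ``origin_px`` is the pixel
    position of the visual-field origin; ``px_per_degree`` the scale.  The
    pixel y axis points down while chart y points up, so
    ``py = origin_y - cy * sy``.
    """

    bbox: tuple[float, float, float, float]
    origin_px: tuple[float, float]
    px_per_degree: tuple[float, float]
    mode: str = "frame"

    def __post_init__(self) -> None:
        l, t, r, b = self.bbox
        if not (r > l and b > t):
            raise GeometryError(f"degenerate panel bbox {self.bbox}")
        if min(self.px_per_degree) <= 0:
            raise GeometryError(f"non-positive scale {self.px_per_degree}")

    def to_pixel(self, cx: float, cy: float) -> tuple[float, float]:
        ox, oy = self.origin_px
        sx, sy = self.px_per_degree
        return ox + cx * sx, oy - cy * sy

    def to_json(self) -> dict:
        return {
            "bbox": list(self.bbox),
            "origin_px": list(self.origin_px),
            "px_per_degree": list(self.px_per_degree),
            "mode": self.mode,
        }


@dataclass
class CellSample:
    """One locus's sampling window and measured ink density."""

    locus: tuple[int, int]
    center_px: tuple[float, float]
    window_px: tuple[float, float]
    ink_fraction: float | None = None

    def to_json(self) -> dict:
        return {
            "locus": list(self.locus),
            "center_px": list(self.center_px),
            "window_px": list(self.window_px),
            "ink_fraction": self.ink_fraction,
        }


# ---------------------------------------------------------------------------
# Glyph alphabet (shared with the synthetic renderer)
# ---------------------------------------------------------------------------
# Each glyph is a drawing routine over a cell of side `cell` pixels centered
# at (cx, cy); element sizes scale with the cell so ink *density* is roughly
# size-invariant.  Two families exercise the parser's tolerance of styles:
# "block" (squares/stipple, Humphrey-print-like) and "round" (dots/discs).

# Element sizes are quantised once (from the diameter), independently of
# the sub-pixel position, so a glyph's ink area does not flicker with grid
# phase or jitter.

def _rect(draw: ImageDraw.ImageDraw, cx: float, cy: float, hx: float, hy: float, fill) -> None:
    w, h = max(1, round(2 * hx)), max(1, round(2 * hy))
    x0, y0 = round(cx - w / 2), round(cy - h / 2)
    draw.rectangle([x0, y0, x0 + w - 1, y0 + h - 1], fill=fill)


def _disc(draw: ImageDraw.ImageDraw, cx: float, cy: float, r: float, fill) -> None:
    d = max(1, round(2 * r))
    x0, y0 = round(cx - d / 2), round(cy - d / 2)
    draw.ellipse([x0, y0, x0 + d - 1, y0 + d - 1], fill=fill)


def _block_ns(d, cx, cy, c, ink, bg):
    _rect(d, cx, cy, 0.06 * c, 0.06 * c, ink)


def _block_p5(d, cx, cy, c, ink, bg):
    _rect(d, cx - 0.16 * c, cy - 0.16 * c, 0.08 * c, 0.08 * c, ink)
    _rect(d, cx + 0.16 * c, cy + 0.16 * c, 0.08 * c, 0.08 * c, ink)


def _block_p2(d, cx, cy, c, ink, bg):
    for sx in (-1, 1):
        for sy in (-1, 1):
            _rect(d, cx + sx * 0.17 * c, cy + sy * 0.17 * c, 0.09 * c, 0.09 * c, ink)


def _block_p1(d, cx, cy, c, ink, bg):
    _rect(d, cx, cy, 0.28 * c, 0.28 * c, ink)
    for sx in (-1, 1):
        for sy in (-1, 1):
            _rect(d, cx + sx * 0.14 * c, cy + sy * 0.14 * c, 0.06 * c, 0.06 * c, bg)


def _block_p05(d, cx, cy, c, ink, bg):
    _rect(d, cx, cy, 0.36 * c, 0.36 * c, ink)


def _round_ns(d, cx, cy, c, ink, bg):
    _disc(d, cx, cy, 0.07 * c, ink)


def _round_p5(d, cx, cy, c, ink, bg):
    _disc(d, cx - 0.16 * c, cy + 0.16 * c, 0.09 * c, ink)
    _disc(d, cx + 0.16 * c, cy - 0.16 * c, 0.09 * c, ink)


def _round_p2(d, cx, cy, c, ink, bg):
    for sx in (-1, 1):
        for sy in (-1, 1):
            _disc(d, cx + sx * 0.17 * c, cy + sy * 0.17 * c, 0.10 * c, ink)


def _round_p1(d, cx, cy, c, ink, bg):
    _disc(d, cx, cy, 0.30 * c, ink)
    _disc(d, cx, cy, 0.13 * c, bg)


def _round_p05(d, cx, cy, c, ink, bg):
    _disc(d, cx, cy, 0.40 * c, ink)


GLYPH_FAMILIES: dict[str, dict[SignificanceCategory, Callable]] = {
    "block": {
        SignificanceCategory.NS: _block_ns,
        SignificanceCategory.P5: _block_p5,
        SignificanceCategory.P2: _block_p2,
        SignificanceCategory.P1: _block_p1,
        SignificanceCategory.P05: _block_p05,
    },
    "round": {
        SignificanceCategory.NS: _round_ns,
        SignificanceCategory.P5: _round_p5,
        SignificanceCategory.P2: _round_p2,
        SignificanceCategory.P1: _round_p1,
        SignificanceCategory.P05: _round_p05,
    },
}


def draw_glyph(
    draw: ImageDraw.ImageDraw,
    family: str,
    category: SignificanceCategory,
    cx: float,
    cy: float,
    cell_px: float,
    ink: int = 0,
    bg: int = 255,
) -> None:
    try:
        fn = GLYPH_FAMILIES[family][SignificanceCategory(category)]
    except KeyError:
        raise PlotParseError(f"unknown glyph family {family!r}") from None
    fn(draw, cx, cy, cell_px, ink, bg)


# ---------------------------------------------------------------------------
# Image primitives
# ---------------------------------------------------------------------------

def _as_gray(image) -> np.ndarray:
    """Accept a path, PIL image or array; return float grayscale (0..255)."""
    if isinstance(image, np.ndarray):
        arr = image.astype(float)
        if arr.ndim == 3:
            arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
        return arr
    if not isinstance(image, Image.Image):
        image = Image.open(image)
    return np.asarray(image.convert("L"), dtype=float)


def _darkness(gray: np.ndarray) -> np.ndarray:
    """Normalised ink density per pixel: 0 on background, 1 at full ink."""
    bg = float(np.median(gray))
    lo = float(gray.min())
    if bg - lo < 16:
        raise NoPlotFoundError("image has no discernible ink")
    return np.clip((bg - gray) / (bg - lo), 0.0, 1.0)


def _ink_mask(gray: np.ndarray) -> np.ndarray:
    if gray.min() == gray.max():
        raise NoPlotFoundError("blank image: no plot found")
    mask = gray < threshold_otsu(gray)
    if mask.sum() < 10:
        raise NoPlotFoundError("no symbol mass found in image")
    return mask


# ---------------------------------------------------------------------------
# Panel detection
# ---------------------------------------------------------------------------

def _frame_candidates(mask: np.ndarray) -> list[tuple[int, int, int, int]]:
    """Bounding boxes (l, t, r, b exclusive) of frame-like components:
    large, hollow rectangles."""
    labels, n = ndimage.label(mask)
    out = []
    for sl in ndimage.find_objects(labels):
        if sl is None:
            continue
        h = sl[0].stop - sl[0].start
        w = sl[1].stop - sl[1].start
        if h < 32 or w < 32:
            continue
        sub = mask[sl]
        fill = sub.mean()
        # A frame is mostly empty inside its bbox but fully covers the
        # bbox's border rows/columns.
        border = min(sub[0].mean(), sub[-1].mean(), sub[:, 0].mean(), sub[:, -1].mean())
        if fill < 0.35 and border > 0.9:
            out.append((sl[1].start, sl[0].start, sl[1].stop, sl[0].stop))
    return out


def _frame_interior(mask: np.ndarray, bbox: tuple[int, int, int, int]) -> tuple[float, float, float, float]:
    """Strip the frame band off each edge of its bounding box."""
    l, t, r, b = bbox
    sub = mask[t:b, l:r]

    def run(cov: np.ndarray) -> int:
        w = 0
        while w < min(12, len(cov)) and cov[w] > 0.6:
            w += 1
        return max(w, 1)

    wt = run(sub.mean(axis=1))
    wb = run(sub[::-1].mean(axis=1))
    wl = run(sub.mean(axis=0))
    wr = run(sub[:, ::-1].mean(axis=0))
    interior = (float(l + wl), float(t + wt), float(r - wr), float(b - wb))
    if interior[2] - interior[0] < 8 or interior[3] - interior[1] < 8:
        raise GeometryError(f"frame interior degenerate: {interior}")
    return interior


def _grid_cluster_extremes(values: np.ndarray, span_deg: float) -> tuple[float, float]:
    """Means of the first and last 1-D clusters of grid-aligned centroids.

    Gaps above half the 6-degree pitch split clusters; the pitch is
    estimated from the raw extent (a slight overestimate, which only makes
    the split threshold more permissive by a few percent).
    """
    values = np.sort(values)
    pitch_px = 6.0 * (values[-1] - values[0]) / span_deg
    breaks = np.flatnonzero(np.diff(values) > pitch_px / 2)
    starts = np.concatenate([[0], breaks + 1])
    stops = np.concatenate([breaks + 1, [len(values)]])
    return float(values[starts[0]:stops[0]].mean()), float(values[starts[-1]:stops[-1]].mean())


def detect_plot_bounds(
    image,
    pattern: "TestPattern | str" = "24-2",
    eye: "Eye | str" = Eye.RIGHT,
) -> PlotGeometry:
    """Locate the pattern-deviation panel and derive its degree mapping.

    Preferred route: find the panel's rectangular frame and map the frame
    interior onto the pattern's known degree extent.  For frameless crops,
    fall back to the symbol mass: connected-component centroids of the
    outermost symbol rows/columns mark the outermost locus centers.

    Raises :class:`NoPlotFoundError` on blank images and
    :class:`AmbiguousPlotError` when several frame-like panels are present.
    """
    pattern = get_pattern(pattern)
    eye = Eye.from_token(eye)
    gray = _as_gray(image)
    mask = _ink_mask(gray)
    gx0, gx1, gy0, gy1 = chart_extent(pattern, eye)
    wdeg, hdeg = gx1 - gx0, gy1 - gy0

    frames = _frame_candidates(mask)
    if len(frames) > 1:
        raise AmbiguousPlotError(frames)
    if frames:
        l, t, r, b = _frame_interior(mask, frames[0])
        sx = (r - l) / wdeg
        sy = (b - t) / hdeg
        return PlotGeometry(
            bbox=(l, t, r, b),
            origin_px=(l - gx0 * sx, t + gy1 * sy),
            px_per_degree=(sx, sy),
            mode="frame",
        )

    # Frameless: symbol-extent geometry from component centroids.  Glyphs
    # may consist of several connected components (stipple), so centroids
    # are clustered into grid columns/rows; the outermost cluster means
    # mark the outermost locus centers (glyphs are left-right and
    # top-bottom symmetric, so sub-component centroids average back to the
    # locus center).
    labels, n = ndimage.label(mask)
    if n < 4:
        raise NoPlotFoundError("too few symbols to infer plot geometry")
    centroids = ndimage.center_of_mass(mask, labels, range(1, n + 1))
    ys = np.array([c[0] for c in centroids]) + 0.5
    xs = np.array([c[1] for c in centroids]) + 0.5
    cxs = [cx for _, (cx, _) in chart_positions(pattern, eye)]
    cys = [cy for _, (_, cy) in chart_positions(pattern, eye)]
    span_x, span_y = max(cxs) - min(cxs), max(cys) - min(cys)
    x_lo, x_hi = _grid_cluster_extremes(xs, span_x)
    y_lo, y_hi = _grid_cluster_extremes(ys, span_y)
    sx = (x_hi - x_lo) / span_x
    sy = (y_hi - y_lo) / span_y
    if sx <= 0 or sy <= 0:
        raise GeometryError("symbol mass has no spatial extent")
    ox = x_lo - min(cxs) * sx
    oy = y_hi + min(cys) * sy  # lowest chart y is deepest pixel row
    return PlotGeometry(
        bbox=(ox + gx0 * sx, oy - gy1 * sy, ox + gx1 * sx, oy - gy0 * sy),
        origin_px=(ox, oy),
        px_per_degree=(sx, sy),
        mode="symbols",
    )


def map_loci(geom: PlotGeometry, pattern: "TestPattern | str", eye: "Eye | str") -> list[CellSample]:
    """One sampling window per canonical locus, mirrored for left eyes.

    Raises :class:`GeometryError` if any window center would be meaningless
    (the caller checks image bounds when sampling).
    """
    pattern = get_pattern(pattern)
    eye = Eye.from_token(eye)
    sx, sy = geom.px_per_degree
    wx, wy = WINDOW_FRACTION * 6 * sx, WINDOW_FRACTION * 6 * sy
    samples = []
    for locus, (cx, cy) in chart_positions(pattern, eye):
        px, py = geom.to_pixel(cx, cy)
        samples.append(CellSample(locus=locus, center_px=(px, py), window_px=(wx, wy)))
    return samples


# ---------------------------------------------------------------------------
# Symbol classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SymbolCalibration:
    """Reference ink densities per category, for nearest-reference matching.

    ``references`` may hold several entries per category (one per glyph
    family).  A measurement equidistant from two categories resolves to the
    *less* significant one; a near-tie (distance ratio above
    ``tie_margin``) is classified the same way but flagged low-confidence.
    """

    references: tuple[tuple[SignificanceCategory, float], ...]
    tie_margin: float = 0.8

    def classify(self, fraction: float) -> tuple[SignificanceCategory, bool]:
        if not self.references:
            raise PlotParseError("empty calibration table")
        # Sorting by (distance, category) makes exact ties resolve to the
        # less significant category.
        ranked = sorted((abs(fraction - ref), int(cat)) for cat, ref in self.references)
        d_best, cat_best = ranked[0]
        d_other = next((d for d, c in ranked if c != cat_best), None)
        if d_other is None:
            low_conf = False
        elif d_other == 0:
            low_conf = True
        else:
            low_conf = d_best / d_other > self.tie_margin
        return SignificanceCategory(cat_best), low_conf


# Cell size at which reference densities are measured.  Large, so pixel
# rounding of glyph elements is negligible; ink *density* is scale-free and
# conserved by resampling, so one table serves every detected plot scale.
CALIBRATION_CELL_PX = 96


@functools.lru_cache(maxsize=64)
def derive_calibration(cell_px: int = CALIBRATION_CELL_PX,
                       families: tuple[str, ...] = ("block", "round")) -> SymbolCalibration:
    """Measure each glyph family's ink densities from the glyphs themselves.

    Each glyph is rendered alone on a white canvas and measured in the same
    0.8-pitch window the parser uses, so calibration and measurement share
    the same feature definition.
    """
    refs = []
    side = int(2 * cell_px)
    for family in families:
        for cat in SignificanceCategory:
            img = Image.new("L", (side, side), 255)
            draw_glyph(ImageDraw.Draw(img), family, cat, side / 2, side / 2, cell_px)
            dark = _darkness_window(
                np.asarray(img, dtype=float) / 1.0,
                (side / 2, side / 2),
                (WINDOW_FRACTION * cell_px, WINDOW_FRACTION * cell_px),
                bg=255.0,
            )
            refs.append((cat, dark))
    return SymbolCalibration(references=tuple(refs))


def calibration_from_legend(image, categories: Sequence[SignificanceCategory] = tuple(SignificanceCategory)) -> SymbolCalibration:
    """Derive references from a horizontal legend strip of n equal cells,
    ordered least to most significant."""
    gray = _as_gray(image)
    h, w = gray.shape
    n = len(categories)
    cell = w / n
    refs = []
    for i, cat in enumerate(categories):
        center = ((i + 0.5) * cell, h / 2)
        win = (WINDOW_FRACTION * min(cell, h), WINDOW_FRACTION * min(cell, h))
        refs.append((cat, _darkness_window(gray, center, win, bg=float(np.median(gray)))))
    return SymbolCalibration(references=tuple(refs))


def _darkness_window(gray: np.ndarray, center: tuple[float, float], window: tuple[float, float], bg: float) -> float:
    cx, cy = center
    wx, wy = window
    x0, x1 = int(round(cx - wx / 2)), int(round(cx + wx / 2))
    y0, y1 = int(round(cy - wy / 2)), int(round(cy + wy / 2))
    if x0 < 0 or y0 < 0 or x1 > gray.shape[1] or y1 > gray.shape[0] or x1 <= x0 or y1 <= y0:
        raise GeometryError(f"sampling window [{x0}:{x1}]x[{y0}:{y1}] outside image {gray.shape}")
    sub = gray[y0:y1, x0:x1]
    lo = float(gray.min())
    if bg - lo < 16:
        return 0.0
    return float(np.clip((bg - sub) / (bg - lo), 0.0, 1.0).mean())


def classify_symbol(image, sample: CellSample, calibration: SymbolCalibration | None = None) -> SignificanceCategory:
    """Classify one locus's glyph from its ink density."""
    gray = _as_gray(image)
    if calibration is None:
        calibration = derive_calibration()
    frac = _darkness_window(gray, sample.center_px, sample.window_px, bg=float(np.median(gray)))
    sample.ink_fraction = frac
    cat, _ = calibration.classify(frac)
    return cat


# ---------------------------------------------------------------------------
# Full parse
# ---------------------------------------------------------------------------

@dataclass
class ParseResult:
    matrix: PatternDeviationMatrix
    geometry: PlotGeometry
    samples: list[CellSample]
    warnings: list[str] = field(default_factory=list)

    def diagnostics_json(self) -> dict:
        return {
            "schema": "hpagrade.parse_diagnostics.v1",
            "geometry": self.geometry.to_json(),
            "samples": [s.to_json() for s in self.samples],
            "warnings": list(self.warnings),
        }


def parse_plot(
    image,
    pattern: "TestPattern | str",
    eye: "Eye | str",
    calibration: SymbolCalibration | None = None,
) -> ParseResult:
    """Parse a pattern-deviation plot image, keeping diagnostics.

    Composes panel detection, grid superposition and per-locus symbol
    classification.  Low-confidence classifications (ink density near a
    category boundary) are recorded in ``warnings``, never silently
    upgraded: near-ties resolve toward the less significant category.
    """
    pattern = get_pattern(pattern)
    eye = Eye.from_token(eye)
    gray = _as_gray(image)
    geom = detect_plot_bounds(gray, pattern, eye)
    samples = map_loci(geom, pattern, eye)
    if calibration is None:
        calibration = derive_calibration()
    bg = float(np.median(gray))
    cells = {}
    warnings = []
    for sample in samples:
        frac = _darkness_window(gray, sample.center_px, sample.window_px, bg=bg)
        sample.ink_fraction = frac
        cat, low_conf = calibration.classify(frac)
        cells[sample.locus] = cat
        if low_conf:
            warnings.append(
                f"locus {sample.locus}: ink density {frac:.3f} near category boundary; kept {cat.token}"
            )
    return ParseResult(
        matrix=PatternDeviationMatrix(pattern, cells),
        geometry=geom,
        samples=samples,
        warnings=warnings,
    )


def parse_pattern_plot(
    image,
    pattern: "TestPattern | str",
    eye: "Eye | str",
    calibration: SymbolCalibration | None = None,
) -> PatternDeviationMatrix:
    """Image in, :class:`~hpagrade.hpa.PatternDeviationMatrix` out."""
    return parse_plot(image, pattern, eye, calibration).matrix


# ---------------------------------------------------------------------------
# Overlay visualisation
# ---------------------------------------------------------------------------

_OVERLAY_COLORS = {
    SignificanceCategory.NS: (60, 180, 60),
    SignificanceCategory.P5: (240, 200, 40),
    SignificanceCategory.P2: (240, 140, 20),
    SignificanceCategory.P1: (230, 60, 30),
    SignificanceCategory.P05: (160, 20, 120),
}


def render_overlay(image, result: ParseResult) -> Image.Image:
    """Reproduce the superimposed-grid diagnostic view: the detected panel,
    every sampling window, and the classified category at each locus."""
    if isinstance(image, Image.Image):
        img = image.convert("RGB")
    elif isinstance(image, np.ndarray):
        img = Image.fromarray(image.astype(np.uint8)).convert("RGB")
    else:
        img = Image.open(image).convert("RGB")
    draw = ImageDraw.Draw(img)
    l, t, r, b = result.geometry.bbox
    draw.rectangle([l, t, r - 1, b - 1], outline=(30, 90, 220), width=2)
    for sample in result.samples:
        cx, cy = sample.center_px
        wx, wy = sample.window_px
        cat = result.matrix.cells[sample.locus]
        draw.rectangle(
            [cx - wx / 2, cy - wy / 2, cx + wx / 2, cy + wy / 2],
            outline=_OVERLAY_COLORS[cat],
        )
    return img
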