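"""Synthetic perimetry records and Humphrey-style plot renderings.

The generator produces field records with known per-criterion structure and
renders their pattern-deviation plots as raster images, so the image parser
and rule engine can be validated end-to-end against exact ground truth —
the synthetic counterpart of a clinic-collected validation set.

What is emulated: the bordered pattern-deviation panel, the canonical
24-2/30-2 locus grids (left eyes mirrored), five probability glyphs in two
drawing styles, small placement jitter, and a configurable severity-class
mixture defaulting to a glaucoma-clinic skew with no defect-free fields.
What is *not* emulated: realistic spatial correlation of scotomata
(arcuate bundles, nasal steps), reliability indices, grayscale maps, or
full printout pages — category counts suffice to exercise every rule and
every glyph.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image, ImageDraw

from .hpa import (
    DEFAULT_THRESHOLDS,
    CentralPoints,
    Eye,
    FieldRecord,
    GradedField,
    HpaThresholds,
    PatternDeviationMatrix,
    SeverityGrade,
    SignificanceCategory,
    TestPattern,
    get_pattern,
    grade_field,
    grade_pd1,
    grade_pd5,
    record_from_json,
    record_to_json,
    report_to_json,
)
from .vision import PlotGeometry, chart_extent, chart_positions, draw_glyph, GLYPH_FAMILIES

__all__ = [
    "RenderStyle",
    "RenderMetadata",
    "GenerationError",
    "ANY_GRADE",
    "DEFAULT_CLASS_MIX",
    "render_pattern_plot",
    "sample_field",
    "SyntheticRecord",
    "SyntheticDataset",
    "make_validation_set",
    "write_dataset",
    "load_manifest",
    "verify_dataset",
]


class GenerationError(RuntimeError):
    """Raised when rejection sampling cannot satisfy a target grade."""


ANY_GRADE = "any"

# Default severity mixture (none, mild, moderate, severe): a glaucoma-clinic
# skew with no defect-free fields, mirroring a referral population in which
# every recorded field shows some defect.
DEFAULT_CLASS_MIX = (0.0, 0.4, 0.3, 0.3)

_FRAME_PX = 3
_MARGIN_PX = 12


@dataclass(frozen=True)
class RenderStyle:
    """Rendering knobs for the synthetic plot painter.

    ``cell_px`` is the pixel size of one 6-degree grid cell; ``jitter_px``
    the maximum uniform symbol-center offset; ``background`` the paper
    grayscale level; ``glyph_set`` one of the named glyph families;
    ``noise`` a per-pixel probability of dark speckle (off by default).
    """

    cell_px: int = 32
    frame: bool = True
    jitter_px: int = 1
    background: int = 255
    glyph_set: str = "block"
    noise: float = 0.0

    def __post_init__(self) -> None:
        if self.cell_px < 16:
            raise ValueError("cell_px below 16 px cannot distinguish the five glyphs")
        if self.jitter_px > self.cell_px / 8:
            raise ValueError("jitter above cell_px/8 would spill symbols into neighbour windows")
        if self.glyph_set not in GLYPH_FAMILIES:
            raise ValueError(f"unknown glyph family {self.glyph_set!r}")
        if not 160 <= self.background <= 255:
            raise ValueError("background must stay light (160..255) for ink to be separable")
        if not 0.0 <= self.noise < 0.05:
            raise ValueError("noise is a small speckle probability in [0, 0.05)")


DEFAULT_STYLE = RenderStyle()


@dataclass(frozen=True)
class RenderMetadata:
    """Ground truth emitted with every rendering: the oracle for the parser."""

    geometry: PlotGeometry
    categories: Mapping[tuple[int, int], SignificanceCategory]
    pattern: str
    eye: Eye
    style: RenderStyle
    seed: int


def render_pattern_plot(
    pd: PatternDeviationMatrix,
    eye: "Eye | str",
    style: RenderStyle = DEFAULT_STYLE,
    seed: int = 0,
) -> tuple[Image.Image, RenderMetadata]:
    """Paint a pattern-deviation panel; deterministic in (pd, eye, style, seed).

    Returns the image together with :class:`RenderMetadata` recording the
    true geometry and per-locus categories.
    """
    eye = Eye.from_token(eye)
    gx0, gx1, gy0, gy1 = chart_extent(pd.pattern, eye)
    s = style.cell_px / 6.0
    W = int(round((gx1 - gx0) * s))
    H = int(round((gy1 - gy0) * s))
    fw = _FRAME_PX if style.frame else 0
    L, T = _MARGIN_PX + fw, _MARGIN_PX + fw
    img = Image.new("L", (W + 2 * (_MARGIN_PX + fw), H + 2 * (_MARGIN_PX + fw)), style.background)
    draw = ImageDraw.Draw(img)

    ox, oy = L + (0 - gx0) * s, T + gy1 * s
    if style.frame:
        for k in range(fw):
            draw.rectangle(
                [_MARGIN_PX + k, _MARGIN_PX + k,
                 _MARGIN_PX + 2 * fw + W - 1 - k, _MARGIN_PX + 2 * fw + H - 1 - k],
                outline=0,
            )
        # Meridian cross, as on real printouts; drawn only inside framed
        # panels (frameless geometry relies on symbol centroids alone).
        draw.line([(round(ox), T), (round(ox), T + H - 1)], fill=0)
        draw.line([(L, round(oy)), (L + W - 1, round(oy))], fill=0)

    rng = np.random.default_rng(seed)
    for locus, (cx, cy) in chart_positions(pd.pattern, eye):
        jx = jy = 0.0
        if style.jitter_px:
            jx, jy = rng.uniform(-style.jitter_px, style.jitter_px, size=2)
        px = L + (cx - gx0) * s + jx
        py = T + (gy1 - cy) * s + jy
        draw_glyph(draw, style.glyph_set, pd.cells[locus], px, py, style.cell_px,
                   ink=0, bg=style.background)

    if style.noise > 0:
        arr = np.asarray(img).copy()
        speckle = rng.random(arr.shape) < style.noise
        speckle[:T, :] = speckle[T + H:, :] = False
        speckle[:, :L] = speckle[:, L + W:] = False
        arr[speckle] = 0
        img = Image.fromarray(arr)

    geometry = PlotGeometry(
        bbox=(float(L), float(T), float(L + W), float(T + H)),
        origin_px=(ox, oy),
        px_per_degree=(s, s),
        mode="frame" if style.frame else "symbols",
    )
    meta = RenderMetadata(
        geometry=geometry,
        categories=dict(pd.cells),
        pattern=pd.pattern.name,
        eye=eye,
        style=style,
        seed=seed,
    )
    return img, meta


# ---------------------------------------------------------------------------
# Numeric field sampling
# ---------------------------------------------------------------------------

# MD sampling bands per target grade (low inclusive, high exclusive),
# matching the HPA MD floors.
_MD_BANDS = {
    SeverityGrade.NONE: (-1.0, 2.0),
    SeverityGrade.MILD: (-6.0, -1.2),
    SeverityGrade.MODERATE: (-12.0, -6.2),
    SeverityGrade.SEVERE: (-28.0, -12.2),
}

# Which grades each criterion can express (the central criterion has no
# mild band).
_CRITERION_RANGE = (
    {0, 1, 2, 3},  # md
    {0, 2, 3},     # central
    {0, 1, 2, 3},  # pd5
    {0, 1, 2, 3},  # pd1
)


def _band_counts(target: SeverityGrade, total: int, grader, thr: HpaThresholds) -> list[int]:
    return [c for c in range(total + 1) if grader(c, total, thr) is target]


def _sample_central(target: SeverityGrade, rng: np.random.Generator, thr: HpaThresholds) -> CentralPoints:
    def healthy() -> float:
        return round(float(rng.uniform(thr.central_low + 1.0, 33.0)), 1)

    def depressed() -> float:
        return round(float(rng.uniform(thr.central_zero + 1.0, thr.central_low - 0.6)), 1)

    vals = [healthy() for _ in range(4)]  # order: UN, UT, LN, LT
    if target is SeverityGrade.MODERATE:
        hemi = (0, 1) if rng.random() < 0.5 else (2, 3)
        vals[int(rng.choice(hemi))] = depressed()
    elif target is SeverityGrade.SEVERE:
        if rng.random() < 0.5:
            vals[int(rng.integers(4))] = 0.0
        else:
            vals[int(rng.choice((0, 1)))] = depressed()
            vals[int(rng.choice((2, 3)))] = depressed()
    elif target is not SeverityGrade.NONE:
        raise GenerationError(f"central criterion cannot express {target!r}")
    return CentralPoints.from_values(vals)


def _sample_matrix(
    c5: int, c1: int, pattern: TestPattern, rng: np.random.Generator
) -> PatternDeviationMatrix:
    order = rng.permutation(pattern.locus_count)
    cells: dict[tuple[int, int], SignificanceCategory] = {}
    deep = {SignificanceCategory.P1, SignificanceCategory.P05}
    shallow = {SignificanceCategory.P5, SignificanceCategory.P2}
    for rank, idx in enumerate(order):
        locus = pattern.loci[int(idx)]
        if rank < c1:
            cells[locus] = SignificanceCategory(int(rng.choice(sorted(c.value for c in deep))))
        elif rank < c5:
            cells[locus] = SignificanceCategory(int(rng.choice(sorted(c.value for c in shallow))))
        else:
            cells[locus] = SignificanceCategory.NS
    return PatternDeviationMatrix(pattern, cells)


def sample_field(
    seed=None,
    target: "SeverityGrade | str" = ANY_GRADE,
    pattern: "TestPattern | str" = "24-2",
    eye: "Eye | str | None" = None,
    thr: HpaThresholds = DEFAULT_THRESHOLDS,
    max_tries: int = 200,
    rng: np.random.Generator | None = None,
) -> FieldRecord:
    """Draw one field record whose overall HPA grade equals ``target``.

    Per-criterion grades are drawn at or below the target with at least one
    criterion forced to the target, values are realised inside the matching
    numeric bands, and the result is verified with :func:`grade_field`
    (rejection sampling), so the stored ground truth is by construction the
    rule engine's own verdict on the numeric record.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pattern = get_pattern(pattern)
    for _ in range(max_tries):
        if target == ANY_GRADE:
            goal = SeverityGrade(int(rng.integers(4)))
        else:
            goal = SeverityGrade(target) if not isinstance(target, str) else SeverityGrade.from_label(target)
        comps = [
            int(rng.choice(sorted(g for g in rng_set if g <= goal)))
            for rng_set in _CRITERION_RANGE
        ]
        if max(comps) != int(goal):
            pool = [i for i in range(4) if int(goal) in _CRITERION_RANGE[i]]
            comps[int(rng.choice(pool))] = int(goal)
        g_md, g_c, g5, g1 = (SeverityGrade(c) for c in comps)

        lo, hi = _MD_BANDS[g_md]
        md = round(float(rng.uniform(lo, hi)), 1)
        central = _sample_central(g_c, rng, thr)
        r5 = _band_counts(g5, pattern.locus_count, grade_pd5, thr)
        r1 = _band_counts(g1, pattern.locus_count, grade_pd1, thr)
        if not r5 or not r1:
            continue
        c1 = int(rng.choice(r1))
        r5c = [c for c in r5 if c >= c1]
        if not r5c:
            continue
        c5 = int(rng.choice(r5c))
        chosen_eye = Eye.from_token(eye) if eye is not None else Eye(("left", "right")[int(rng.integers(2))])
        rec = FieldRecord(
            eye=chosen_eye,
            md=md,
            central=central,
            pd=_sample_matrix(c5, c1, pattern, rng),
        )
        if grade_field(rec, thr).overall is goal:
            return rec
    raise GenerationError(f"could not realise target grade {target!r} in {max_tries} tries")


# ---------------------------------------------------------------------------
# Validation-set assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticRecord:
    record_id: str
    field_record: FieldRecord
    truth: GradedField
    image: Image.Image
    metadata: RenderMetadata
    seed: int


@dataclass(frozen=True)
class SyntheticDataset:
    records: tuple[SyntheticRecord, ...]
    seed: int
    class_mix: tuple[float, float, float, float]
    style: RenderStyle


def _mix_counts(n: int, mix: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n records over the four grades."""
    mix = [float(m) for m in mix]
    if len(mix) != 4 or any(m < 0 for m in mix) or abs(sum(mix) - 1.0) > 1e-9:
        raise ValueError(f"class mix must be four non-negative proportions summing to 1, got {mix}")
    exact = [m * n for m in mix]
    counts = [int(np.floor(e)) for e in exact]
    remainder = n - sum(counts)
    order = sorted(range(4), key=lambda i: (-(exact[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def make_validation_set(
    n: int,
    class_mix: Sequence[float] = DEFAULT_CLASS_MIX,
    seed: int = 0,
    style: RenderStyle = DEFAULT_STYLE,
    pattern: "TestPattern | str" = "24-2",
    thr: HpaThresholds = DEFAULT_THRESHOLDS,
) -> SyntheticDataset:
    """Generate ``n`` graded fields with rendered plots and exact truth.

    Deterministic in (n, class_mix, seed, style, pattern): record order,
    eyes, numeric values and pixel content are all reproducible.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    pattern = get_pattern(pattern)
    counts = _mix_counts(n, class_mix)
    grades: list[SeverityGrade] = []
    for g, c in zip(SeverityGrade, counts):
        grades.extend([g] * c)
    rng = np.random.default_rng(seed)
    rng.shuffle(grades)  # interleave classes as a clinic sequence would
    records = []
    for i, goal in enumerate(grades):
        rec_seed = int(rng.integers(2**31))
        rec = sample_field(seed=rec_seed, target=goal, pattern=pattern, thr=thr)
        image, meta = render_pattern_plot(rec.pd, rec.eye, style, seed=rec_seed)
        records.append(
            SyntheticRecord(
                record_id=f"rec{i:04d}",
                field_record=rec,
                truth=grade_field(rec, thr),
                image=image,
                metadata=meta,
                seed=rec_seed,
            )
        )
    return SyntheticDataset(
        records=tuple(records),
        seed=seed,
        class_mix=tuple(float(m) for m in class_mix),
        style=style,
    )


_MANIFEST_COLUMNS = ["record_id", "eye", "pattern", "md", "true_grade", "seed"]


def write_dataset(ds: SyntheticDataset, out_dir) -> Path:
    """Write the on-disk layout: one directory per record (plot.png,
    record.json, truth.json) plus a manifest.csv at the root."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANIFEST_COLUMNS)
        for rec in ds.records:
            rec_dir = out / rec.record_id
            rec_dir.mkdir(exist_ok=True)
            rec.image.save(rec_dir / "plot.png")
            with open(rec_dir / "record.json", "w") as jf:
                json.dump(record_to_json(rec.field_record), jf, indent=1)
            with open(rec_dir / "truth.json", "w") as jf:
                json.dump(report_to_json(rec.truth), jf, indent=1)
            writer.writerow(
                [rec.record_id, rec.field_record.eye.value, rec.field_record.pd.pattern.name,
                 rec.field_record.md, rec.truth.overall.label, rec.seed]
            )
    return manifest


def load_manifest(dataset_dir) -> list[dict]:
    path = Path(dataset_dir) / "manifest.csv"
    if not path.exists():
        raise FileNotFoundError(f"no manifest.csv under {dataset_dir}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _MANIFEST_COLUMNS:
            raise ValueError(f"unexpected manifest columns {reader.fieldnames}")
        return list(reader)


def verify_dataset(dataset_dir, thr: HpaThresholds = DEFAULT_THRESHOLDS) -> int:
    """Self-check on load: stored truth must equal the rule engine's verdict
    recomputed from each numeric record.  Returns the number of records."""
    rows = load_manifest(dataset_dir)
    for row in rows:
        rec_dir = Path(dataset_dir) / row["record_id"]
        truth_path = rec_dir / "truth.json"
        if not truth_path.exists():
            raise FileNotFoundError(f"record {row['record_id']}: truth.json missing")
        with open(rec_dir / "record.json") as fh:
            rec = record_from_json(json.load(fh))
        with open(truth_path) as fh:
            stored = json.load(fh)
        recomputed = grade_field(rec, thr)
        if recomputed.overall.label != stored["overall"] or stored["overall"] != row["true_grade"]:
            raise ValueError(
                f"record {row['record_id']}: stored grade {stored['overall']} "
                f"!= recomputed {recomputed.overall.label}"
            )
    return len(rows)
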