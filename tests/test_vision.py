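"""Parser tests: panel detection, grid superposition, symbol classification,
and exact render/parse round trips under translation and rescaling."""

import numpy as np
import pytest
from PIL import Image, ImageDraw

from hpagrade.hpa import Eye, P24_2, P30_2, PatternDeviationMatrix, SignificanceCategory
from hpagrade.synth import RenderStyle, render_pattern_plot
from hpagrade.vision import (
    AmbiguousPlotError,
    CellSample,
    GeometryError,
    NoPlotFoundError,
    SymbolCalibration,
    WINDOW_FRACTION,
    calibration_from_legend,
    classify_symbol,
    derive_calibration,
    detect_plot_bounds,
    draw_glyph,
    map_loci,
    parse_plot,
    parse_pattern_plot,
    render_overlay,
)

S = SignificanceCategory


def random_matrix(pattern, rng) -> PatternDeviationMatrix:
    cats = rng.integers(0, 5, size=pattern.locus_count)
    return PatternDeviationMatrix(
        pattern, {locus: S(int(c)) for locus, c in zip(pattern.loci, cats)}
    )


def pad_image(img: Image.Image, pad: int, bg: int = 255) -> Image.Image:
    out = Image.new("L", (img.width + 2 * pad, img.height + 2 * pad), bg)
    out.paste(img, (pad, pad))
    return out


class TestDetectPlotBounds:
    def test_recovers_rendered_geometry(self):
        rng = np.random.default_rng(0)
        m = random_matrix(P24_2, rng)
        img, meta = render_pattern_plot(m, Eye.RIGHT, RenderStyle(jitter_px=0), seed=0)
        geom = detect_plot_bounds(img, P24_2, Eye.RIGHT)
        assert np.allclose(geom.bbox, meta.geometry.bbox, atol=2.0)
        assert np.allclose(geom.px_per_degree, meta.geometry.px_per_degree, rtol=0.02)

    def test_blank_image_is_no_plot(self):
        with pytest.raises(NoPlotFoundError):
            detect_plot_bounds(Image.new("L", (200, 200), 255))

    def test_near_blank_noise_is_no_plot(self):
        arr = np.full((200, 200), 255, dtype=np.uint8)
        arr[100, 100] = 0
        with pytest.raises(NoPlotFoundError):
            detect_plot_bounds(arr)

    def test_two_panels_are_ambiguous(self):
        rng = np.random.default_rng(1)
        img, _ = render_pattern_plot(random_matrix(P24_2, rng), Eye.RIGHT, RenderStyle(), seed=1)
        double = Image.new("L", (img.width * 2 + 10, img.height), 255)
        double.paste(img, (0, 0))
        double.paste(img, (img.width + 10, 0))
        with pytest.raises(AmbiguousPlotError):
            detect_plot_bounds(double, P24_2, Eye.RIGHT)

    def test_frameless_fallback(self):
        rng = np.random.default_rng(2)
        m = random_matrix(P30_2, rng)
        img, meta = render_pattern_plot(m, Eye.LEFT, RenderStyle(frame=False, jitter_px=0), seed=2)
        geom = detect_plot_bounds(img, P30_2, Eye.LEFT)
        assert geom.mode == "symbols"
        assert np.allclose(geom.px_per_degree, meta.geometry.px_per_degree, rtol=0.03)


class TestMapLoci:
    @pytest.mark.parametrize("pattern, n", [(P24_2, 54), (P30_2, 76)])
    def test_locus_counts(self, pattern, n):
        rng = np.random.default_rng(3)
        img, meta = render_pattern_plot(random_matrix(pattern, rng), Eye.RIGHT, RenderStyle(), seed=3)
        assert len(map_loci(meta.geometry, pattern, Eye.RIGHT)) == n

    def test_left_right_mirror(self):
        """Left-eye centers are the reflection of right-eye centers about
        the panel's vertical midline."""
        rng = np.random.default_rng(4)
        img, meta = render_pattern_plot(random_matrix(P30_2, rng), Eye.RIGHT, RenderStyle(), seed=4)
        geom = meta.geometry
        right = {s.locus: s.center_px for s in map_loci(geom, P30_2, Eye.RIGHT)}
        left = {s.locus: s.center_px for s in map_loci(geom, P30_2, Eye.LEFT)}
        l, _, r, _ = geom.bbox
        mid = (l + r) / 2
        for locus, (rx, ry) in right.items():
            lx, ly = left[locus]
            assert ly == pytest.approx(ry)
            assert lx - mid == pytest.approx(mid - rx, abs=1e-6)

    def test_windows_do_not_overlap(self):
        rng = np.random.default_rng(5)
        img, meta = render_pattern_plot(random_matrix(P24_2, rng), Eye.RIGHT, RenderStyle(), seed=5)
        samples = map_loci(meta.geometry, P24_2, Eye.RIGHT)
        pitch = 6 * meta.geometry.px_per_degree[0]
        for a in samples:
            for b in samples:
                if a.locus == b.locus:
                    continue
                dx = abs(a.center_px[0] - b.center_px[0])
                dy = abs(a.center_px[1] - b.center_px[1])
                assert max(dx, dy) >= pitch * 0.99
                assert max(dx, dy) > a.window_px[0]


class TestClassifySymbol:
    @pytest.mark.parametrize("family", ["block", "round"])
    @pytest.mark.parametrize("cell", [24, 32, 48])
    def test_each_glyph_classifies_as_rendered(self, family, cell):
        for cat in S:
            side = 2 * cell
            img = Image.new("L", (side, side), 255)
            draw_glyph(ImageDraw.Draw(img), family, cat, side / 2, side / 2, cell)
            sample = CellSample(
                locus=(3, 3),
                center_px=(side / 2, side / 2),
                window_px=(WINDOW_FRACTION * cell, WINDOW_FRACTION * cell),
            )
            assert classify_symbol(img, sample) is cat

    def test_ties_resolve_to_less_significant(self):
        cal = SymbolCalibration(references=((S.NS, 0.25), (S.P5, 0.75)))
        cat, low_conf = cal.classify(0.5)
        assert cat is S.NS
        assert low_conf

    def test_clear_measurement_is_confident(self):
        cal = derive_calibration()
        cat, low_conf = cal.classify(0.85)
        assert cat is S.P05
        assert not low_conf

    def test_window_outside_image_rejected(self):
        img = Image.new("L", (40, 40), 255)
        sample = CellSample(locus=(3, 3), center_px=(38.0, 38.0), window_px=(20.0, 20.0))
        with pytest.raises(GeometryError):
            classify_symbol(img, sample)

    def test_legend_calibration(self):
        cell = 32
        strip = Image.new("L", (5 * cell, cell), 255)
        draw = ImageDraw.Draw(strip)
        for i, cat in enumerate(S):
            draw_glyph(draw, "block", cat, (i + 0.5) * cell, cell / 2, cell)
        cal = calibration_from_legend(strip)
        fracs = dict((c, f) for c, f in cal.references)
        assert sorted(fracs, key=lambda c: fracs[c]) == list(S)


class TestParseRoundTrip:
    def test_parse_recovers_rendered_matrix(self):
        rng = np.random.default_rng(17)
        for i in range(20):
            pattern = (P24_2, P30_2)[i % 2]
            eye = (Eye.LEFT, Eye.RIGHT)[(i // 2) % 2]
            m = random_matrix(pattern, rng)
            img, _ = render_pattern_plot(m, eye, RenderStyle(), seed=i)
            assert parse_pattern_plot(img, pattern, eye) == m

    def test_all_ns_plot_has_zero_depressed(self):
        m = PatternDeviationMatrix.uniform(P24_2)
        img, _ = render_pattern_plot(m, Eye.RIGHT, RenderStyle(), seed=0)
        parsed = parse_pattern_plot(img, P24_2, Eye.RIGHT)
        assert all(cat is S.NS for cat in parsed.cells.values())

    def test_margin_padding_invariance(self):
        rng = np.random.default_rng(6)
        m = random_matrix(P24_2, rng)
        img, _ = render_pattern_plot(m, Eye.RIGHT, RenderStyle(), seed=6)
        base = parse_pattern_plot(img, P24_2, Eye.RIGHT)
        for pad in (1, 10, 20):
            assert parse_pattern_plot(pad_image(img, pad), P24_2, Eye.RIGHT) == base

    @pytest.mark.parametrize("factor", [0.75, 0.9, 1.25, 1.5])
    def test_rescale_invariance(self, factor):
        rng = np.random.default_rng(7)
        m = random_matrix(P30_2, rng)
        img, _ = render_pattern_plot(m, Eye.RIGHT, RenderStyle(), seed=7)
        scaled = img.resize(
            (round(img.width * factor), round(img.height * factor)), Image.BILINEAR
        )
        assert parse_pattern_plot(scaled, P30_2, Eye.RIGHT) == m

    def test_rgb_input_accepted(self):
        rng = np.random.default_rng(8)
        m = random_matrix(P24_2, rng)
        img, _ = render_pattern_plot(m, Eye.RIGHT, RenderStyle(), seed=8)
        assert parse_pattern_plot(img.convert("RGB"), P24_2, Eye.RIGHT) == m

    def test_parse_is_idempotent(self):
        rng = np.random.default_rng(9)
        m = random_matrix(P24_2, rng)
        img, _ = render_pattern_plot(m, Eye.LEFT, RenderStyle(), seed=9)
        first = parse_plot(img, P24_2, Eye.LEFT)
        second = parse_plot(img, P24_2, Eye.LEFT)
        assert first.matrix == second.matrix
        assert [s.ink_fraction for s in first.samples] == [s.ink_fraction for s in second.samples]

    def test_diagnostics_and_overlay(self, tmp_path):
        rng = np.random.default_rng(10)
        m = random_matrix(P24_2, rng)
        img, _ = render_pattern_plot(m, Eye.RIGHT, RenderStyle(), seed=10)
        result = parse_plot(img, P24_2, Eye.RIGHT)
        diag = result.diagnostics_json()
        assert len(diag["samples"]) == 54
        assert all(0 <= s["ink_fraction"] <= 1 for s in diag["samples"])
        overlay = render_overlay(img, result)
        assert overlay.size == img.size
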