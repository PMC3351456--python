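"""Cogwheel geometry: realizability, anchors, rendering determinism."""

import dataclasses

import pytest
from PIL import Image

import cogvenn as cv
from cogvenn.edwards_layout import (
    COG_TEETH,
    DisplayMode,
    layout_from_svg,
    membership_grid,
    parse_geometry_config,
    point_signature,
)


class TestMembership:
    def test_center_offset_into_left_top_is_triple_intersection(self, default_layouts):
        lay = default_layouts[3]
        cx, cy = lay.center
        assert point_signature((cx - 1e-6, cy - 1e-6), lay) == 0b111

    def test_tooth_crest_in_cog_but_not_circle(self, default_layouts):
        import math

        lay = default_layouts[4]
        a, m, phi = lay.cog_params(4)
        theta = -phi / m  # crest of the first tooth
        rho = lay.circle_radius * (1 + a) * 0.98
        cx, cy = lay.center
        p = (cx + rho * math.cos(theta), cy + rho * math.sin(theta))
        assert cv.membership(p, 4, lay)
        assert not cv.membership(p, 3, lay)

    def test_set_index_out_of_range(self, default_layouts):
        with pytest.raises(ValueError):
            cv.membership((0.0, 0.0), 3, default_layouts[2])


class TestValidate:
    @pytest.mark.parametrize("n", range(2, 7))
    def test_all_patterns_realized(self, default_layouts, n):
        report = cv.validate_layout(default_layouts[n], resolution=400)
        assert report.passed
        assert len(report.realized_patterns) == 1 << n
        assert report.min_region_sample_count > 0

    def test_degenerate_amplitude_fails(self):
        # zero amplitude collapses a cog onto the circle, so every
        # pattern separating set 4 from set 3 goes missing
        bad = cv.EdwardsLayout(n=6, cog_amplitudes=(0.0, 0.30, 0.17))
        report = cv.validate_layout(bad, resolution=400)
        assert not report.passed
        assert report.missing
        with pytest.raises(cv.LayoutValidationError):
            cv.build_layout(6, cog_amplitudes=(0.0, 0.30, 0.17), resolution=400)

    def test_teeth_double(self):
        assert COG_TEETH[5] == 2 * COG_TEETH[4]
        assert COG_TEETH[6] == 2 * COG_TEETH[5]

    def test_too_coarse_resolution_rejected(self, default_layouts):
        with pytest.raises(ValueError):
            cv.validate_layout(default_layouts[2], resolution=100)


class TestAnchors:
    @pytest.mark.parametrize("n", range(2, 7))
    def test_every_anchor_reproduces_its_signature(self, default_layouts, n):
        lay = default_layouts[n]
        anchors = cv.region_anchors(lay, resolution=400)
        assert set(anchors) == set(range(1, 1 << n))
        for sig, anchor in anchors.items():
            assert point_signature(anchor.point, lay) == sig

    def test_set1_only_anchor_in_left_half(self, default_layouts):
        lay = default_layouts[2]
        anchor = cv.region_anchor(lay, 0b01, resolution=400)
        assert anchor.point[0] < lay.center[0]


class TestRenderSvg:
    def test_counts_mode_disjoint_pair(self, default_layouts, disjoint_pair, tmp_path):
        part = cv.compute_partition(disjoint_pair)
        svg = cv.render_svg(default_layouts[2], part, DisplayMode.COUNTS)
        assert svg.count('class="region"') == 2
        assert svg.count("<title>") == 2

    def test_identical_sets_single_label(self, default_layouts, six_identical):
        part = cv.compute_partition(six_identical)
        svg = cv.render_svg(default_layouts[6], part, DisplayMode.INDEX)
        assert svg.count('class="region"') == 1
        assert 'data-signature="63"' in svg

    def test_tooltip_count_equals_nonempty_regions(self, default_layouts):
        plan = cv.random_plan(5, seed=21)
        _, part = cv.generate_collection(plan)
        svg = cv.render_svg(default_layouts[5], part, DisplayMode.COUNTS)
        nonempty = sum(1 for v in part.regions.values() if v)
        assert svg.count("<title>") == nonempty

    def test_text_mode_truncates_with_ellipsis(self, default_layouts):
        coll = cv.InputCollection.from_lists(
            [("A", [f"m{i:02d}" for i in range(20)]), ("B", ["zz"])]
        )
        part = cv.compute_partition(coll)
        svg = cv.render_svg(default_layouts[2], part, DisplayMode.TEXT)
        assert "(+8 more)" in svg  # 20 members, 12-line budget
        assert "m19" in svg  # full membership still in the tooltip

    def test_rendering_is_deterministic(self, default_layouts, hand_triple):
        part = cv.compute_partition(hand_triple)
        a = cv.render_svg(default_layouts[3], part, DisplayMode.TEXT)
        b = cv.render_svg(default_layouts[3], part, DisplayMode.TEXT)
        assert a == b

    def test_mismatched_n_raises(self, default_layouts, hand_triple):
        part = cv.compute_partition(hand_triple)
        with pytest.raises(ValueError):
            cv.render_svg(default_layouts[4], part)


class TestRaster:
    def test_dimensions_determinism_and_roundtrip(self, default_layouts, disjoint_pair, tmp_path):
        part = cv.compute_partition(disjoint_pair)
        lay = default_layouts[2]
        svg_path = tmp_path / "d.svg"
        cv.render_svg(lay, part, DisplayMode.COUNTS, svg_path)
        assert layout_from_svg(svg_path) == lay
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        w, h = cv.export_raster(svg_path, p1, dpi=150)
        cv.export_raster(svg_path, p2, dpi=150)
        assert abs(w - lay.width * 150 / 96) <= 1
        assert abs(h - lay.height * 150 / 96) <= 1
        assert p1.read_bytes() == p2.read_bytes()
        with Image.open(p1) as img:
            assert img.size == (w, h) and img.format == "PNG"


class TestGeometryConfig:
    def test_overrides_parsed(self, tmp_path):
        cfg = tmp_path / "geom.cfg"
        cfg.write_text("# comment\ncircle_radius = 150\na4=0.45\nphi5 = 0.1\n")
        overrides = parse_geometry_config(cfg)
        assert overrides["circle_radius"] == 150
        assert overrides["cog_amplitudes"] == (0.45, 0.30, 0.17)
        assert overrides["cog_phases"] == (0.0, 0.1, 0.0)

    def test_unknown_key_rejected(self, tmp_path):
        cfg = tmp_path / "geom.cfg"
        cfg.write_text("wobble=3\n")
        with pytest.raises(ValueError):
            parse_geometry_config(cfg)
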