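"""Radial scaling, geometry resolution, SVG composition, formatting, export."""

import math
import xml.etree.ElementTree as ET

import pytest
import yaml

from snailplot import (
    BuscoGene,
    ConfigError,
    PlotConfig,
    bin_assembly,
    export,
    format_number,
    radial_scale,
    render_snail,
    resolve_geometry,
    score_assembly,
    stats_payload,
    summarize_assembly,
    summarize_busco,
)

from conftest import records_from_lengths


def _render(records, config=None, **kwargs):
    summary = summarize_assembly(records)
    config = config or PlotConfig(segments=100)
    ref_summary = kwargs.pop("reference_summary", None)
    geom = resolve_geometry(summary, ref_summary, config)
    bins = bin_assembly(records, config.segments, max_span=geom.max_span)
    return render_snail(summary, bins, config=config, reference_summary=ref_summary, **kwargs)


def _svg(records, config=None, **kwargs):
    return ET.fromstring(_render(records, config, **kwargs))


SVGNS = "{http://www.w3.org/2000/svg}"


class TestRadialScale:
    @pytest.mark.parametrize("function", ["linear", "sqrt", "log"])
    def test_endpoint_identity(self, function):
        assert radial_scale(1000, 1000, function) == 1.0

    def test_sqrt_quarter(self):
        assert radial_scale(250, 1000, "sqrt") == 0.5

    def test_sqrt_dominates_linear(self):
        for frac in [i / 20 for i in range(21)]:
            assert radial_scale(frac * 1e6, 1e6, "sqrt") >= radial_scale(frac * 1e6, 1e6, "linear")

    def test_log_clamps_below_one(self):
        assert radial_scale(0.5, 1000, "log") == 0.0

    @pytest.mark.parametrize("function", ["linear", "sqrt", "log"])
    def test_monotone(self, function):
        values = [radial_scale(l, 1e6, function) for l in (0, 10, 1e3, 1e5, 5e5, 1e6)]
        assert values == sorted(values)


class TestResolveGeometry:
    def test_self_scaling_sweeps_full_circle(self):
        summ = summarize_assembly(records_from_lengths([500, 300, 200]))
        geom = resolve_geometry(summ)
        assert geom.sweep == 360.0
        assert geom.max_span == 1000

    def test_max_span_override_shrinks_sweep(self):
        # published scaling example: 2,560 Mb span on a 2,770,968,735 axis
        summ = summarize_assembly(records_from_lengths([2_560_000_000]))
        geom = resolve_geometry(summ, config=PlotConfig(max_span=2_770_968_735))
        assert geom.sweep == pytest.approx(360.0 * 2_560_000_000 / 2_770_968_735)
        assert round(geom.sweep) == 333

    def test_reference_sets_both_maxima(self):
        summ = summarize_assembly(records_from_lengths([500, 300]))
        ref = summarize_assembly(records_from_lengths([900, 400]))
        geom = resolve_geometry(summ, reference=ref, config=PlotConfig(max_span=1000, max_scaffold=700))
        assert geom.max_span == 1300
        assert geom.max_scaffold == 900

    def test_small_override_warns_and_assembly_wins(self):
        summ = summarize_assembly(records_from_lengths([500, 300]))
        with pytest.warns(UserWarning):
            geom = resolve_geometry(summ, config=PlotConfig(max_span=100))
        assert geom.max_span == 800


class TestPlotConfig:
    def test_badge_forces_linear(self):
        config = PlotConfig(badge=True, scale_function="sqrt")
        assert config.scale_function == "linear"

    def test_invalid_values_rejected(self):
        with pytest.raises(ConfigError):
            PlotConfig(segments=0)
        with pytest.raises(ConfigError):
            PlotConfig(scale_function="cubic")
        with pytest.raises(ConfigError):
            PlotConfig(score_type="super")


class TestRenderSnail:
    def test_deterministic_byte_identical(self):
        recs = records_from_lengths([900, 500, 300, 200, 100], n_fraction=0.05)
        assert _render(recs) == _render(recs)

    def test_badge_mode_has_zero_text_elements(self):
        recs = records_from_lengths([900, 500, 300])
        busco = summarize_busco([BuscoGene("m1", "Complete", "s0"), BuscoGene("m2", "Missing")])
        svg = _svg(recs, PlotConfig(segments=50, badge=True), busco=busco)
        assert len(svg.findall(f".//{SVGNS}text")) == 0

    def test_standard_mode_has_legend_text(self):
        svg = _svg(records_from_lengths([900, 500, 300]))
        assert len(svg.findall(f".//{SVGNS}text")) > 0
        ids = {g.get("id") for g in svg.findall(f".//{SVGNS}g")}
        assert {"count-region", "scaffold-region", "composition", "n50", "n90", "axis", "legend"} <= ids

    def test_single_scaffold_red_overlay_full_circle(self):
        svg = _svg(records_from_lengths([5000]), PlotConfig(segments=50))
        longest = svg.find(f".//{SVGNS}g[@id='longest']")
        assert longest is not None
        assert float(longest.get("data-angle")) == pytest.approx(360.0)

    def test_no_red_overlay_when_first_bin_shared(self):
        # >1 scaffold in the first bin: lengths nearly equal, few segments
        svg = _svg(records_from_lengths([100, 99, 98, 97]), PlotConfig(segments=2))
        assert svg.find(f".//{SVGNS}g[@id='longest']") is None

    def test_fragmented_profile_count_gridlines(self):
        # all scaffolds far below 1% of span, so the first bin holds many
        recs = records_from_lengths([300] * 1500)
        svg = _svg(recs, PlotConfig(segments=100))
        assert svg.find(f".//{SVGNS}g[@id='longest']") is None
        circles = svg.findall(f".//{SVGNS}g[@id='count-gridlines']/{SVGNS}circle")
        assert len(circles) >= 3  # 10, 100, 1000

    def test_nx_overlay_angular_extents(self):
        recs = records_from_lengths([900, 500, 300, 200, 100])
        summary = summarize_assembly(recs)
        config = PlotConfig(segments=100, max_span=4000)
        geom = resolve_geometry(summary, config=config)
        bins = bin_assembly(recs, 100, max_span=geom.max_span)
        svg = ET.fromstring(render_snail(summary, bins, config=config))
        seg_angle = 360.0 / config.segments
        for name, pct in (("n50", 0.5), ("n90", 0.9)):
            overlay = svg.find(f".//{SVGNS}g[@id='{name}']")
            assert abs(float(overlay.get("data-angle")) - pct * geom.sweep) <= seg_angle

    def test_reference_overlay_groups(self):
        recs = records_from_lengths([900, 500, 300])
        ref = records_from_lengths([800, 400])
        ref_summary = summarize_assembly(ref)
        summary = summarize_assembly(recs)
        config = PlotConfig(segments=50)
        geom = resolve_geometry(summary, ref_summary, config)
        bins = bin_assembly(recs, 50, max_span=geom.max_span)
        ref_bins = bin_assembly(ref, 50, max_span=geom.max_span)
        svg = ET.fromstring(
            render_snail(summary, bins, reference_bins=ref_bins,
                         reference_summary=ref_summary, config=config)
        )
        ids = {g.get("id") for g in svg.findall(f".//{SVGNS}g")}
        assert {"reference-fill", "reference-line"} <= ids

    def test_filled_fraction_approximates_relative_aun(self):
        """Linear-scale area ordering: sum of bin min-length fractions ~ auN/Lmax."""
        lengths = list(range(2000, 200, -9))  # 200 distinct lengths
        recs = records_from_lengths(lengths)
        summary = summarize_assembly(recs)
        segments = 200
        bins = bin_assembly(recs, segments)
        filled = sum(b.min_length for b in bins if not b.empty) / (segments * summary.longest)
        assert filled == pytest.approx(summary.aun / summary.longest, abs=2.0 / segments)

    def test_show_score_places_score_text(self):
        recs = records_from_lengths([900, 500, 300])
        scores = score_assembly(summarize_assembly(recs))
        svg = _svg(recs, PlotConfig(segments=50, show_score=True), scores=scores)
        texts = [t.text for t in svg.findall(f".//{SVGNS}g[@id='score']/{SVGNS}text")]
        assert any("snail score" in t for t in texts)


class TestFormatNumber:
    def test_unit_suffix_with_significant_digits(self):
        assert format_number(200_127_270, "absolute") == "200 Mb"

    def test_smaller_units(self):
        assert format_number(2_540_000, "absolute") == "2.54 Mb"
        assert format_number(1_500, "absolute") == "1.5 kb"
        assert format_number(999, "absolute") == "999"

    def test_percentage_rounding(self):
        assert format_number(0.11888, "percentage") == "11.89%"

    def test_truncation_strategy(self):
        config = PlotConfig(rounding="down")
        assert format_number(0.99999, "percentage", config) == "99.99%"

    def test_round_up_strategy(self):
        config = PlotConfig(rounding="up")
        assert format_number(0.11111, "percentage", config) == "11.12%"


class TestExport:
    @pytest.fixture
    def payload(self):
        recs = records_from_lengths([900, 500, 300])
        summary = summarize_assembly(recs)
        return stats_payload(summary, bin_assembly(recs, 10), scores=score_assembly(summary))

    def test_svg_is_well_formed_xml(self, tmp_path):
        dest = tmp_path / "out.svg"
        export(_render(records_from_lengths([900, 500])), dest)
        ET.parse(dest)

    def test_yaml_round_trip(self, tmp_path, payload):
        dest = tmp_path / "out.yaml"
        export(payload, dest)
        assert yaml.safe_load(dest.read_text()) == payload

    def test_json_round_trip(self, tmp_path, payload):
        import json

        dest = tmp_path / "out.json"
        export(payload, dest)
        assert json.loads(dest.read_text()) == payload

    def test_unknown_suffix_names_valid_ones(self, tmp_path):
        with pytest.raises(ConfigError, match="svg, png, json, yaml"):
            export("<svg/>", tmp_path / "out.bmp")
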