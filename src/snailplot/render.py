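"""Layered circular snail plot as SVG, number formatting, and export.

The plot composes, from center outward: a log-scaled cumulative scaffold
count region (light gray, count 1 at the center, white gridline circles at
powers of ten), the size-sorted scaffold length region (dark gray, radial
axis scaled to the longest scaffold via a linear, sqrt or log function),
highlight overlays for the longest scaffold (red, only when the first bin
holds exactly one scaffold), N50 (dark orange, sweeping 50% of the occupied
angle) and N90 (light orange, 90%), an outer base composition track (dark
blue GC outside light blue AT, N proportion as white gaps at the track
edges, GC min-max range as a mid-tone band about the mean boundary), an
optional purple reference-assembly overlay (shading below the target
distribution, line above), and a BUSCO completeness inset.

Angles start at 12 o'clock and proceed clockwise. Badge mode removes every
text element and forces the linear scale function. Rendering is a pure
function of its inputs, so identical inputs produce byte-identical SVG.
"""

from __future__ import annotations

import json
import math
import warnings
import xml.etree.ElementTree as ET
from dataclasses import asdict, dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, ROUND_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .errors import ConfigError
from .snail_score import ScoreSet
from .summary_stats import AssemblySummary, BinSummary, BuscoSummary

SCALE_FUNCTIONS = ("linear", "sqrt", "log")
SCORE_TYPES = ("base", "g", "gs", "ag", "ags")
ROUNDING_STRATEGIES = ("round", "down", "up")
EXPORT_SUFFIXES = ("svg", "png", "json", "yaml")

# Fixed palette; exact hues are presentation plumbing, roles are not.
PALETTE = {
    "background": "#ffffff",
    "count": "#d8d8d8",
    "scaffold": "#686868",
    "longest": "#e31a1c",
    "n50": "#ff7f00",
    "n90": "#fdbf6f",
    "gc": "#1f78b4",
    "at": "#a6cee3",
    "gc_range": "#5b9bd5",
    "reference": "#6a3d9a",
    "busco_complete": "#33a02c",
    "busco_duplicated": "#1a6e1d",
    "busco_fragmented": "#b2df8a",
    "grid": "#ffffff",
    "text": "#303030",
}

_SIZE = 1000.0
_CX = 500.0
_CY = 520.0
_R = 380.0


@dataclass
class PlotConfig:
    """Validated plot configuration (the full customization surface)."""

    segments: int = 1000
    scale_function: str = "linear"
    max_span: Optional[float] = None
    max_scaffold: Optional[float] = None
    badge: bool = False
    show_score: bool = False
    score_type: str = "base"
    significant_digits: int = 3
    decimal_precision: int = 2
    rounding: str = "round"
    show_numbers: bool = False
    busco_numbers: bool = False
    assembly_name: str = ""
    reference_name: str = ""

    def __post_init__(self) -> None:
        if self.badge:
            # badges must be comparable at a glance; force linear scaling
            self.scale_function = "linear"
        if self.scale_function not in SCALE_FUNCTIONS:
            raise ConfigError(f"unknown scale function {self.scale_function!r}; valid: {', '.join(SCALE_FUNCTIONS)}")
        if self.score_type not in SCORE_TYPES:
            raise ConfigError(f"unknown score type {self.score_type!r}; valid: {', '.join(SCORE_TYPES)}")
        if self.rounding not in ROUNDING_STRATEGIES:
            raise ConfigError(f"unknown rounding {self.rounding!r}; valid: {', '.join(ROUNDING_STRATEGIES)}")
        if self.segments < 1:
            raise ConfigError(f"segments must be >= 1, got {self.segments}")
        if self.significant_digits < 1:
            raise ConfigError("significant-digits must be >= 1")
        if self.decimal_precision < 0:
            raise ConfigError("decimal-precision must be >= 0")


@dataclass
class PlotGeometry:
    """Resolved geometry: radii budget, swept angle, axis maxima."""

    center: tuple[float, float]
    radius: float
    count_inner: float
    count_outer: float
    scaffold_inner: float
    scaffold_outer: float
    composition_inner: float
    composition_outer: float
    bin_angle: float
    sweep: float
    max_span: float
    max_scaffold: float


def radial_scale(length: float, max_scaffold: float, function: str = "linear") -> float:
    """Map a scaffold length to a radial fraction in [0, 1].

    linear: L/Lmax; sqrt: sqrt(L/Lmax); log: log10(max(L,1))/log10(max(Lmax,2))
    (lengths below 1 clamp to 0). All functions map Lmax to 1.
    """
    if max_scaffold <= 0:
        raise ConfigError("max_scaffold must be positive")
    length = min(max(length, 0.0), max_scaffold)
    if function == "linear":
        frac = length / max_scaffold
    elif function == "sqrt":
        frac = math.sqrt(length / max_scaffold)
    elif function == "log":
        frac = math.log10(max(length, 1.0)) / math.log10(max(max_scaffold, 2.0))
    else:
        raise ConfigError(f"unknown scale function {function!r}")
    return min(max(frac, 0.0), 1.0)


def resolve_geometry(
    summary: AssemblySummary,
    reference: Optional[AssemblySummary] = None,
    config: Optional[PlotConfig] = None,
) -> PlotGeometry:
    """Resolve axis maxima and swept angle for an assembly (+reference).

    Each axis maximum is the largest of the assembly's own value, the
    reference's (if given), and the configured override (if given). An
    override smaller than the assembly's own value is ignored with a warning.
    """
    config = config or PlotConfig()
    max_span = float(summary.span)
    max_scaffold = float(summary.longest)
    if reference is not None:
        max_span = max(max_span, float(reference.span))
        max_scaffold = max(max_scaffold, float(reference.longest))
    if config.max_span is not None:
        if config.max_span < summary.span:
            warnings.warn(
                f"--max-span {config.max_span:g} is smaller than the assembly span "
                f"{summary.span}; using the assembly span",
                stacklevel=2,
            )
        max_span = max(max_span, float(config.max_span))
    if config.max_scaffold is not None:
        if config.max_scaffold < summary.longest:
            warnings.warn(
                f"--max-scaffold {config.max_scaffold:g} is smaller than the longest scaffold "
                f"{summary.longest}; using the longest scaffold",
                stacklevel=2,
            )
        max_scaffold = max(max_scaffold, float(config.max_scaffold))
    sweep = 360.0 * summary.span / max_span
    return PlotGeometry(
        center=(_CX, _CY),
        radius=_R,
        count_inner=0.0,
        count_outer=0.25,
        scaffold_inner=0.25,
        scaffold_outer=0.85,
        composition_inner=0.85,
        composition_outer=1.0,
        bin_angle=360.0 / config.segments,
        sweep=sweep,
        max_span=max_span,
        max_scaffold=max_scaffold,
    )


# --- number formatting -------------------------------------------------------

_UNITS = ((1e9, "Gb"), (1e6, "Mb"), (1e3, "kb"))

_ROUNDING_MODES = {"round": ROUND_HALF_UP, "down": ROUND_DOWN, "up": ROUND_UP}


def round_value(value: float, ndigits: int, strategy: str = "round") -> float:
    """Round to ``ndigits`` decimals: half away from zero, toward zero, or away."""
    if strategy not in _ROUNDING_MODES:
        raise ConfigError(f"unknown rounding {strategy!r}; valid: {', '.join(ROUNDING_STRATEGIES)}")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=_ROUNDING_MODES[strategy]))


def format_number(value: float, mode: str, config: Optional[PlotConfig] = None) -> str:
    """Format a value for display.

    ``absolute`` applies unit suffixes (kb/Mb/Gb) and significant-digit
    rounding; ``percentage`` multiplies by 100 and shows a fixed number of
    decimal places. The rounding strategy comes from the config.
    """
    config = config or PlotConfig()
    if not math.isfinite(value):
        raise ConfigError(f"cannot format non-finite value {value!r}")
    if mode == "percentage":
        pct = round_value(value * 100.0, config.decimal_precision, config.rounding)
        return f"{pct:.{config.decimal_precision}f}%"
    if mode != "absolute":
        raise ConfigError(f"unknown format mode {mode!r}; expected absolute or percentage")
    unit, suffix = 1.0, ""
    for threshold, name in _UNITS:
        if abs(value) >= threshold:
            unit, suffix = threshold, name
            break
    scaled = value / unit
    if scaled == 0:
        return "0"
    exponent = math.floor(math.log10(abs(scaled)))
    decimals = max(0, config.significant_digits - 1 - exponent)
    rounded = round_value(scaled, decimals, config.rounding)
    text = f"{rounded:.{decimals}f}"
    if "." in text:
        text = text.rstrip("0").rstrip(".")
    return f"{text} {suffix}" if suffix else text


# --- SVG helpers -------------------------------------------------------------


def _pt(r: float, angle_deg: float) -> tuple[float, float]:
    """Polar to canvas: angle measured clockwise from 12 o'clock."""
    a = math.radians(angle_deg)
    return (_CX + r * math.sin(a), _CY - r * math.cos(a))


def _fmt_pts(points: Sequence[tuple[float, float]]) -> str:
    return " L ".join(f"{x:.2f},{y:.2f}" for x, y in points)


def _band_path(
    inner_radii: Sequence[float],
    outer_radii: Sequence[float],
    theta0: float,
    bin_angle: float,
) -> str:
    """Closed path of per-bin constant-radius steps between two radius series."""
    pts: list[tuple[float, float]] = []
    nbins = len(outer_radii)
    for i in range(nbins):
        a0 = theta0 + i * bin_angle
        pts.append(_pt(outer_radii[i], a0))
        pts.append(_pt(outer_radii[i], a0 + bin_angle))
    for i in range(nbins - 1, -1, -1):
        a0 = theta0 + i * bin_angle
        pts.append(_pt(inner_radii[i], a0 + bin_angle))
        pts.append(_pt(inner_radii[i], a0))
    return "M " + _fmt_pts(pts) + " Z"


def _arc_band_path(r_inner: float, r_outer: float, a0: float, a1: float) -> str:
    """Annular sector approximated by <=1 degree polygon steps."""
    steps = max(2, int(math.ceil(abs(a1 - a0))) + 1)
    angles = [a0 + (a1 - a0) * i / (steps - 1) for i in range(steps)]
    pts = [_pt(r_outer, a) for a in angles] + [_pt(r_inner, a) for a in reversed(angles)]
    return "M " + _fmt_pts(pts) + " Z"


def _step_line_path(radii: Sequence[float], theta0: float, bin_angle: float) -> str:
    pts: list[tuple[float, float]] = []
    for i, r in enumerate(radii):
        a0 = theta0 + i * bin_angle
        pts.append(_pt(r, a0))
        pts.append(_pt(r, a0 + bin_angle))
    return "M " + _fmt_pts(pts)


def _non_empty(bins: Sequence[BinSummary]) -> list[BinSummary]:
    return [b for b in bins if not b.empty]


def _text(parent, x: float, y: float, content: str, size: float = 15.0, anchor: str = "start") -> None:
    el = ET.SubElement(
        parent,
        "text",
        {
            "x": f"{x:.2f}",
            "y": f"{y:.2f}",
            "font-size": f"{size:g}",
            "font-family": "sans-serif",
            "fill": PALETTE["text"],
            "text-anchor": anchor,
        },
    )
    el.text = content


# --- main renderer -----------------------------------------------------------


def render_snail(
    summary: AssemblySummary,
    bins: Sequence[BinSummary],
    busco: Optional[BuscoSummary] = None,
    scores: Optional[ScoreSet] = None,
    reference_bins: Optional[Sequence[BinSummary]] = None,
    config: Optional[PlotConfig] = None,
    reference_summary: Optional[AssemblySummary] = None,
) -> str:
    """Compose the full snail plot and return it as an SVG document string.

    ``bins`` must come from ``bin_assembly`` with ``config.segments`` bins
    over the resolved max span; ``reference_bins``, when given, must be
    binned over the same max span so angles line up.
    """
    config = config or PlotConfig()
    geom = resolve_geometry(summary, reference_summary, config)
    rs = lambda length: radial_scale(length, geom.max_scaffold, config.scale_function)

    def scaffold_r(length: float) -> float:
        frac = rs(length)
        return (geom.scaffold_inner + frac * (geom.scaffold_outer - geom.scaffold_inner)) * geom.radius

    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "width": f"{_SIZE:g}",
            "height": f"{_SIZE:g}",
            "viewBox": f"0 0 {_SIZE:g} {_SIZE:g}",
        },
    )
    ET.SubElement(
        svg, "rect",
        {"x": "0", "y": "0", "width": f"{_SIZE:g}", "height": f"{_SIZE:g}", "fill": PALETTE["background"]},
    )

    occupied = _non_empty(bins)
    total = summary.scaffold_count

    # cumulative count region (log axis, count 1 at the center)
    count_pow = max(1, math.ceil(math.log10(total)) if total > 1 else 1)
    count_max = 10.0 ** count_pow
    count_r = [
        geom.count_outer * geom.radius * (math.log10(max(b.cumulative_count, 1)) / count_pow)
        for b in occupied
    ]
    g_count = ET.SubElement(svg, "g", {"id": "count-region"})
    if occupied:
        ET.SubElement(
            g_count, "path",
            {"d": _band_path([0.0] * len(occupied), count_r, 0.0, geom.bin_angle), "fill": PALETTE["count"]},
        )
    g_cgrid = ET.SubElement(svg, "g", {"id": "count-gridlines"})
    power = 10
    while power <= total:
        r = geom.count_outer * geom.radius * (math.log10(power) / count_pow)
        ET.SubElement(
            g_cgrid, "circle",
            {"cx": f"{_CX:.2f}", "cy": f"{_CY:.2f}", "r": f"{r:.2f}",
             "fill": "none", "stroke": PALETTE["grid"], "stroke-width": "1.5"},
        )
        power *= 10

    # reference shading sits below the target scaffold-length distribution
    ref_occupied = _non_empty(reference_bins) if reference_bins else []
    if ref_occupied:
        ref_r = [scaffold_r(b.min_length) for b in ref_occupied]
        g_ref_fill = ET.SubElement(svg, "g", {"id": "reference-fill"})
        ET.SubElement(
            g_ref_fill, "path",
            {"d": _band_path([geom.scaffold_inner * geom.radius] * len(ref_occupied), ref_r, 0.0, geom.bin_angle),
             "fill": PALETTE["reference"], "fill-opacity": "0.3"},
        )

    # scaffold length region: per-bin shortest overlapping scaffold
    g_scaff = ET.SubElement(svg, "g", {"id": "scaffold-region"})
    if occupied:
        radii = [scaffold_r(b.min_length) for b in occupied]
        ET.SubElement(
            g_scaff, "path",
            {"d": _band_path([geom.scaffold_inner * geom.radius] * len(occupied), radii, 0.0, geom.bin_angle),
             "fill": PALETTE["scaffold"]},
        )

    # dashed white radial gridlines through the scaffold region
    g_sgrid = ET.SubElement(svg, "g", {"id": "scaffold-gridlines"})
    for frac in (0.2, 0.4, 0.6, 0.8, 1.0):
        r = scaffold_r(frac * geom.max_scaffold)
        ET.SubElement(
            g_sgrid, "circle",
            {"cx": f"{_CX:.2f}", "cy": f"{_CY:.2f}", "r": f"{r:.2f}",
             "fill": "none", "stroke": PALETTE["grid"], "stroke-width": "1",
             "stroke-dasharray": "4 4"},
        )

    # overlays: longest scaffold (only when alone in the first bin), N50, N90
    if bins and not bins[0].empty and bins[0].cumulative_count == 1:
        angle = 360.0 * summary.longest / geom.max_span
        g_longest = ET.SubElement(svg, "g", {"id": "longest", "data-angle": f"{angle:.4f}"})
        ET.SubElement(
            g_longest, "path",
            {"d": _arc_band_path(geom.scaffold_inner * geom.radius, scaffold_r(summary.longest), 0.0, angle),
             "fill": PALETTE["longest"], "fill-opacity": "0.85"},
        )
    for name, nx_len, pct in (("n50", summary.n50, 0.5), ("n90", summary.n90, 0.9)):
        angle = pct * geom.sweep
        g_nx = ET.SubElement(svg, "g", {"id": name, "data-angle": f"{angle:.4f}"})
        ET.SubElement(
            g_nx, "path",
            {"d": _arc_band_path(geom.scaffold_inner * geom.radius, scaffold_r(nx_len), 0.0, angle),
             "fill": PALETTE[name], "fill-opacity": "0.85"},
        )

    # base composition track: GC dark (outer), AT light (inner), N as white
    # gaps split equally at both track edges, GC range as a mid-tone band
    g_comp = ET.SubElement(svg, "g", {"id": "composition"})
    if occupied:
        r_in = geom.composition_inner * geom.radius
        track_w = (geom.composition_outer - geom.composition_inner) * geom.radius
        at_lo, at_hi, gc_lo, gc_hi, rg_lo, rg_hi = [], [], [], [], [], []
        for b in occupied:
            n_half = b.n_fraction_mean * track_w / 2.0
            w_eff = track_w - 2.0 * n_half
            gc_w = w_eff * b.gc_mean
            at_lo.append(r_in + n_half)
            at_hi.append(r_in + n_half + (w_eff - gc_w))
            gc_lo.append(at_hi[-1])
            gc_hi.append(r_in + n_half + w_eff)
            rg_lo.append(r_in + n_half + w_eff * (1.0 - b.gc_max))
            rg_hi.append(r_in + n_half + w_eff * (1.0 - b.gc_min))
        ET.SubElement(
            g_comp, "path",
            {"d": _band_path(at_lo, at_hi, 0.0, geom.bin_angle), "fill": PALETTE["at"], "id": "composition-at"},
        )
        ET.SubElement(
            g_comp, "path",
            {"d": _band_path(gc_lo, gc_hi, 0.0, geom.bin_angle), "fill": PALETTE["gc"], "id": "composition-gc"},
        )
        ET.SubElement(
            g_comp, "path",
            {"d": _band_path(rg_lo, rg_hi, 0.0, geom.bin_angle), "fill": PALETTE["gc_range"],
             "fill-opacity": "0.6", "id": "composition-gc-range"},
        )

    # reference line sits above everything in the scaffold region, continued
    # across the composition track when the reference ends before the target
    if ref_occupied:
        ref_r = [scaffold_r(b.min_length) for b in ref_occupied]
        g_ref_line = ET.SubElement(svg, "g", {"id": "reference-line"})
        ET.SubElement(
            g_ref_line, "path",
            {"d": _step_line_path(ref_r, 0.0, geom.bin_angle), "fill": "none",
             "stroke": PALETTE["reference"], "stroke-width": "2"},
        )
        if reference_summary is not None and reference_summary.span < summary.span:
            end_angle = 360.0 * reference_summary.span / geom.max_span
            p0 = _pt(geom.composition_inner * geom.radius, end_angle)
            p1 = _pt(geom.composition_outer * geom.radius, end_angle)
            ET.SubElement(
                g_ref_line, "path",
                {"d": f"M {p0[0]:.2f},{p0[1]:.2f} L {p1[0]:.2f},{p1[1]:.2f}",
                 "stroke": PALETTE["reference"], "stroke-width": "2"},
            )

    # circumferential axis: ticks every 5% of the axis maximum
    g_axis = ET.SubElement(svg, "g", {"id": "axis"})
    for k in range(20):
        tick_span = k * 0.05 * geom.max_span
        if tick_span > summary.span:
            break
        angle = 360.0 * tick_span / geom.max_span
        p0 = _pt(geom.radius, angle)
        p1 = _pt(geom.radius + 8, angle)
        ET.SubElement(
            g_axis, "path",
            {"d": f"M {p0[0]:.2f},{p0[1]:.2f} L {p1[0]:.2f},{p1[1]:.2f}",
             "stroke": PALETTE["text"], "stroke-width": "1"},
        )
        if not config.badge:
            if config.show_numbers:
                label = format_number(tick_span, "absolute", config)
            else:
                label = format_number(tick_span / summary.span, "percentage", config)
            lx, ly = _pt(geom.radius + 14, angle)
            _text(g_axis, lx, ly, label, size=12.0, anchor="middle")

    # BUSCO inset (top right)
    if busco is not None:
        g_busco = ET.SubElement(svg, "g", {"id": "busco-inset"})
        bx, by, br = 860.0, 120.0, 70.0

        def busco_arc(frac0: float, frac1: float, color: str, r: float) -> None:
            a0, a1 = 360.0 * frac0, 360.0 * frac1
            if a1 - a0 <= 0:
                return
            steps = max(2, int(math.ceil(a1 - a0)) + 1)
            angles = [a0 + (a1 - a0) * i / (steps - 1) for i in range(steps)]
            pts = [(bx, by)] + [
                (bx + r * math.sin(math.radians(a)), by - r * math.cos(math.radians(a))) for a in angles
            ]
            ET.SubElement(
                g_busco, "path",
                {"d": "M " + _fmt_pts(pts) + " Z", "fill": color},
            )

        ET.SubElement(
            g_busco, "circle",
            {"cx": f"{bx:.2f}", "cy": f"{by:.2f}", "r": f"{br:.2f}",
             "fill": "#f0f0f0", "stroke": PALETTE["text"], "stroke-width": "1"},
        )
        busco_arc(0.0, busco.complete_fraction, PALETTE["busco_complete"], br)
        busco_arc(0.0, busco.duplicated_fraction, PALETTE["busco_duplicated"], br)
        busco_arc(
            busco.complete_fraction,
            busco.complete_fraction + busco.fragmented_fraction,
            PALETTE["busco_fragmented"],
            br,
        )
        if not config.badge:
            if config.busco_numbers:
                c = round(busco.complete_fraction * busco.total)
                s = round(busco.single_fraction * busco.total)
                d = round(busco.duplicated_fraction * busco.total)
                f = round(busco.fragmented_fraction * busco.total)
                m = round(busco.missing_fraction * busco.total)
                line = f"C:{c} [S:{s}, D:{d}], F:{f}, M:{m}, n:{busco.total}"
            else:
                fmt = lambda v: format_number(v, "percentage", config)
                line = (
                    f"C:{fmt(busco.complete_fraction)} [S:{fmt(busco.single_fraction)}, "
                    f"D:{fmt(busco.duplicated_fraction)}], F:{fmt(busco.fragmented_fraction)}, "
                    f"M:{fmt(busco.missing_fraction)}"
                )
            _text(g_busco, bx, by + br + 22, f"BUSCO {busco.lineage}", size=13.0, anchor="middle")
            _text(g_busco, bx, by + br + 40, line, size=12.0, anchor="middle")

    # legend with the core statistics
    if not config.badge:
        g_legend = ET.SubElement(svg, "g", {"id": "legend"})
        fmt_abs = lambda v: format_number(v, "absolute", config)
        fmt_pct = lambda v: format_number(v, "percentage", config)
        lines = []
        if config.assembly_name:
            lines.append(config.assembly_name)
        lines.extend(
            [
                f"Span: {fmt_abs(summary.span)}",
                f"Scaffolds: {summary.scaffold_count:,}",
                f"Longest: {fmt_abs(summary.longest)}",
                f"N50: {fmt_abs(summary.n50)}",
                f"N90: {fmt_abs(summary.n90)}",
                f"GC: {fmt_pct(summary.gc_fraction)}",
                f"N: {fmt_pct(summary.n_fraction)}",
            ]
        )
        if config.reference_name:
            lines.append(f"Reference: {config.reference_name}")
        y = _SIZE - 24.0 * len(lines) - 12.0
        for line in lines:
            _text(g_legend, 16.0, y, line, size=15.0)
            y += 24.0

    if config.show_score and scores is not None and not config.badge:
        value = scores.get(config.score_type)
        g_score = ET.SubElement(svg, "g", {"id": "score"})
        if value is not None:
            _text(g_score, 16.0, 32.0, f"snail score ({config.score_type}): {value:.3f}", size=17.0)
        else:
            _text(g_score, 16.0, 32.0, f"snail score ({config.score_type}): n/a", size=17.0)

    return ET.tostring(svg, encoding="unicode")


# --- statistics payload and export -------------------------------------------


def stats_payload(
    summary: AssemblySummary,
    bins: Sequence[BinSummary],
    busco: Optional[BuscoSummary] = None,
    scores: Optional[ScoreSet] = None,
) -> dict:
    """Plain-type dict of all processed statistics (for JSON/YAML export)."""
    payload = {
        "summary": asdict(summary),
        "bins": [asdict(b) for b in bins],
    }
    if busco is not None:
        payload["busco"] = asdict(busco)
    if scores is not None:
        payload["scores"] = scores.as_dict()
    return payload


def export(document_or_stats, dest) -> None:
    """Write an SVG/PNG image or a JSON/YAML statistics file by suffix.

    ``document_or_stats`` is an SVG document string for .svg/.png and a
    statistics dict (see :func:`stats_payload`) for .json/.yaml.
    """
    dest = Path(dest)
    suffix = dest.suffix.lower().lstrip(".")
    if suffix not in EXPORT_SUFFIXES:
        raise ConfigError(
            f"unsupported output suffix {dest.suffix!r}; valid suffixes: {', '.join(EXPORT_SUFFIXES)}"
        )
    if suffix == "svg":
        dest.write_text(document_or_stats)
    elif suffix == "png":
        try:
            import cairosvg
        except ImportError as exc:
            raise ConfigError(
                "PNG output requires the optional cairosvg package; write .svg instead or install cairosvg"
            ) from exc
        cairosvg.svg2png(bytestring=document_or_stats.encode(), write_to=str(dest))
    elif suffix == "json":
        dest.write_text(json.dumps(document_or_stats, indent=1, sort_keys=True))
    else:
        dest.write_text(yaml.safe_dump(document_or_stats, sort_keys=True))
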