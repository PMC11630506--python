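"""Rule-based chart-type inference and channel phrasing.

In a grammar of graphics a chart has no declared type: a bar chart is just
rectangular marks on a binned genomic x-axis with quantitative heights.
Screen-reader guidelines nevertheless want the familiar chart type up
front, so a small ordered rule table maps mark + channel-type combinations
back to the names people know (scatter plot, heatmap, ideogram, ...).
When no rule matches, the fallback names the mark: "chart with triangles".

Rules are evaluated specificity-first so that, for example, a matrix
(bar mark with genomic intervals on both axes) is never mistaken for a
bar chart, and heatmap vs ideogram turns solely on whether colour encodes
a quantitative or a nominal field.  The rule table and the natural-language
channel/mark maps can be extended from a YAML config file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

from .chart_extraction import ChartUnit
from .colors import color_name, palette_names
from .spec_model import NormalizedTrack

#: chart types counted as "identified" (i.e. a recognisable named chart)
IDENTIFIED_TYPES = frozenset(
    {"Scatter plot", "Line chart", "Bar chart", "Heatmap", "Chromosome Ideogram", "Matrix"}
)

#: plural mark nouns for the fallback "chart with [marks]" form
MARK_PLURAL = {
    "point": "points",
    "line": "lines",
    "bar": "bars",
    "rect": "rectangles",
    "rule": "lines",
    "triangle": "triangles",
    "text": "text",
    "area": "areas",
    "circle": "circles",
}

#: mark phrase used in appearance sentences ("a rectangular mark")
MARK_PHRASE = {
    "point": "point mark",
    "line": "line mark",
    "bar": "bar mark",
    "rect": "rectangular mark",
    "rule": "rule mark (a straight line)",
    "triangle": "triangle mark",
    "text": "text mark",
    "area": "area mark",
    "circle": "circle mark",
}

#: channel names rendered through natural language — raw tokens such as
#: "xe" never reach the reader
CHANNEL_PHRASE = {
    "x": "x-axis",
    "xe": "end of the genomic interval on the x-axis",
    "y": "y-axis",
    "ye": "end of the genomic interval on the y-axis",
    "row": "row (vertical grouping)",
    "color": "color",
    "text": "text label",
}

FIELD_TYPE_PHRASE = {
    "genomic": "genomic",
    "quantitative": "quantitative",
    "nominal": "categorical",
}

CHANNEL_ORDER = ("x", "xe", "y", "ye", "row", "color", "text")


@dataclass(frozen=True)
class ChartTypeRule:
    """One row of the inference table.

    ``requires`` maps channel name to a required field type ("any" for any
    field-bound axis); ``absent`` lists channels that must not be
    field-bound.  Rules are tried in table order; the first match wins.
    """

    name: str
    mark: str
    requires: dict[str, str] = field(default_factory=dict)
    absent: tuple[str, ...] = ()
    inline: str | None = None  # inline (mid-sentence) form when not just lower-cased

    def matches(self, track: NormalizedTrack) -> bool:
        if track.mark != self.mark:
            return False
        for channel, ftype in self.requires.items():
            actual = track.axis_type(channel)
            if actual is None:
                return False
            if ftype != "any" and actual != ftype:
                return False
        for channel in self.absent:
            if track.axis_type(channel) is not None:
                return False
        return True


DEFAULT_RULES: tuple[ChartTypeRule, ...] = (
    ChartTypeRule("Matrix", "bar",
                  {"x": "genomic", "xe": "genomic", "y": "genomic", "ye": "genomic"}),
    ChartTypeRule("Heatmap", "rect", {"x": "genomic", "xe": "genomic", "color": "quantitative"}),
    ChartTypeRule("Chromosome Ideogram", "rect",
                  {"x": "genomic", "xe": "genomic", "color": "nominal"}, inline="ideogram"),
    ChartTypeRule("Scatter plot", "point", {"x": "genomic", "y": "quantitative"}),
    ChartTypeRule("Line chart", "line", {"x": "genomic", "y": "quantitative"}),
    ChartTypeRule("Line chart", "line", {"x": "quantitative", "y": "genomic"}),
    ChartTypeRule("Bar chart", "bar", {"x": "genomic", "y": "quantitative"}),
    ChartTypeRule("Chart with both horizontal and vertical lines", "rule",
                  {"x": "any", "y": "any"}),
    ChartTypeRule("Chart with vertical lines", "rule", {"x": "any"}, absent=("y",)),
    ChartTypeRule("Chart with horizontal lines", "rule", {"y": "any"}, absent=("x",)),
)


@dataclass
class ChartTypeResult:
    """Per-track base types plus the chart-level display name."""

    base_types: list[str]
    display_name: str

    def inline_name(self) -> str:
        return inline_form(self.display_name)


def load_rules(path: str | Path) -> list[ChartTypeRule]:
    """Load extra inference rules from a YAML file.

    Each entry: ``{name, mark, requires: {channel: type}, absent: [...],
    inline}``.  Loaded rules are tried before the built-in table.
    """
    entries = yaml.safe_load(Path(path).read_text()) or []
    rules = []
    for e in entries:
        rules.append(ChartTypeRule(
            name=e["name"], mark=e["mark"],
            requires=dict(e.get("requires", {})),
            absent=tuple(e.get("absent", ())),
            inline=e.get("inline"),
        ))
    return rules


_INLINE_BY_NAME = {r.name: r.inline for r in DEFAULT_RULES if r.inline}


def inline_form(name: str) -> str:
    """Mid-sentence form of a chart-type name ("Chromosome Ideogram" -> "ideogram")."""
    if name in _INLINE_BY_NAME:
        return _INLINE_BY_NAME[name]
    return name[:1].lower() + name[1:] if name else name


def sentence_case(text: str) -> str:
    return text[:1].upper() + text[1:] if text else text


def infer_unit_type(track: NormalizedTrack,
                    rules: Iterable[ChartTypeRule] = DEFAULT_RULES) -> str:
    """Base chart type of one track; the mark-based fallback always applies."""
    for rule in rules:
        if rule.matches(track):
            return rule.name
    noun = MARK_PLURAL.get(track.mark, f"{track.mark} marks")
    return f"Chart with {noun}"


def apply_modifiers(base_types: list[str], layout: str, n_subtracks: int) -> str:
    """Chart-level display name from the per-track base types.

    A circular layout prefixes "Circular".  A two-sub-track overlay with an
    identified type becomes "Annotated [type]" — the annotation reading of
    e.g. a bar chart with threshold lines drawn over it.  Larger overlays
    are enumerated in track order ("chart with text, ..., ideogram and
    chart with vertical lines"): with several sub-tracks no single type
    summarises the canvas, even when one sub-track is identified.
    """
    if not base_types:
        raise ValueError("chart has no base types")

    def circ(name: str) -> str:
        return f"Circular {inline_form(name)}" if layout == "circular" else name

    if n_subtracks <= 1:
        return circ(base_types[0])
    identified = [b for b in base_types if b in IDENTIFIED_TYPES]
    if n_subtracks == 2 and identified:
        return f"Annotated {inline_form(circ(identified[0]))}"
    inlines = [inline_form(circ(b)) for b in base_types]
    if len(inlines) == 1:
        return circ(base_types[0])
    joined = ", ".join(inlines[:-1]) + " and " + inlines[-1]
    return sentence_case(joined)


def infer_chart_type(chart: ChartUnit,
                     rules: Iterable[ChartTypeRule] = DEFAULT_RULES) -> ChartTypeResult:
    """Infer the display name for one chart (overlay-aware)."""
    base = [infer_unit_type(t, rules) for t in chart.member_tracks]
    display = apply_modifiers(base, chart.layout, len(chart.member_tracks))
    return ChartTypeResult(base_types=base, display_name=display)


def _axis_sentence(ch_name: str, binding, marks: list[str] | None = None) -> str:
    phrase = CHANNEL_PHRASE.get(ch_name, f"{ch_name} channel")
    if ch_name == "text":
        return "Text from the data is displayed on the chart; the content of the text is not described."
    if binding.is_axis:
        ftype = FIELD_TYPE_PHRASE.get(binding.field_type, binding.field_type or "data")
        core = f"The {ftype} field '{binding.field}' is shown on the {phrase}"
    else:
        value = binding.value
        if ch_name == "color":
            value = color_name(str(value))
        core = f"The {phrase} is fixed at {value}"
    if marks and len(set(marks)) > 1:
        noun = " and ".join(f"the {MARK_PHRASE.get(m, m)}" for m in dict.fromkeys(marks))
        core += f" for {noun}"
    return core + "."


def describe_encodings(chart: ChartUnit) -> list[str]:
    """Natural-language sentences for the channels of one chart.

    The x- and y-axes come first, remaining channels after.  For overlays
    sharing one data source, identical bindings are merged across marks;
    for different data sources each sub-track keeps its own sentences.
    Text content is reported as present but never echoed.
    """
    sentences: list[str] = []
    if chart.shares_data or not chart.is_overlay:
        merged: dict[str, list[tuple[object, str]]] = {}
        for t in chart.member_tracks:
            for name, binding in t.channels.items():
                merged.setdefault(name, []).append((binding, t.mark))
        for name in _ordered(merged):
            bindings = merged[name]
            distinct = {b for b, _ in bindings}
            if len(distinct) == 1:
                sentences.append(_axis_sentence(name, bindings[0][0],
                                                [m for _, m in bindings]))
            else:
                for binding, mark in bindings:
                    s = _axis_sentence(name, binding)
                    sentences.append(f"For the {MARK_PHRASE.get(mark, mark)}: {s[:1].lower()}{s[1:]}")
    else:
        for i, t in enumerate(chart.member_tracks, start=1):
            for name in _ordered(t.channels):
                sentences.append(
                    f"Sub-track {i} ({MARK_PHRASE.get(t.mark, t.mark)}): "
                    + _axis_sentence(name, t.channels[name])
                )
    return sentences


def _ordered(channel_names: Iterable[str]) -> list[str]:
    names = list(channel_names)
    known = [c for c in CHANNEL_ORDER if c in names]
    rest = [c for c in names if c not in CHANNEL_ORDER]
    return known + rest


def describe_colors(chart: ChartUnit) -> list[str]:
    """Sentences about the colours in use, grouped so readers can skip them."""
    sentences: list[str] = []
    for t in chart.member_tracks:
        ch = t.channel("color")
        if ch is None:
            continue
        if ch.is_axis and ch.field_type == "nominal":
            sentences.append(
                f"The color shows the categories of field '{ch.field}'. "
                f"The default theme colors are used, starting with "
                f"{', '.join(palette_names(3))}."
            )
        elif ch.is_axis and ch.field_type == "quantitative":
            sentences.append(
                f"The color encodes the value of field '{ch.field}' on a continuous scale."
            )
        elif ch.value is not None:
            sentences.append(f"The color used is {color_name(str(ch.value))}.")
    if not sentences:
        sentences.append("No color information is specified; the default theme color is used.")
    return sentences
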