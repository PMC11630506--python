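"""Assembling the description tree and rendering the four outputs.

A figure description is held as a small labelled hierarchy: the root
expands into "title", "composition" and "tracks"; each track (chart) node
expands into its chart type, appearance, axes, colour and data sections.
A screen-reader user walks this tree top-down and only descends where they
want detail.  From the same tree four outputs are rendered:

* **alt text** — one sentence for the ``alt`` attribute: chart type, kind
  of data, title;
* **long description** — flat text for ``longdesc``; for up to two
  single-track charts it equals the full description, otherwise it
  enumerates chart types and titles and refers the reader to the tree;
* **full description** — the depth-first concatenation of every node
  description;
* **HTML** — an ARIA tree widget (``role=tree`` / ``treeitem`` /
  ``group``) plus a separate data-panel region with the statistics, the
  full data table and the diff against the previous snapshot.
"""

from __future__ import annotations

import html as _html
import re
from dataclasses import dataclass, field
from typing import Sequence

from .chart_extraction import ChartUnit, Composition, PositionLabel
from .chart_inference import (ChartTypeResult, MARK_PHRASE, describe_colors,
                              describe_encodings, inline_form, sentence_case)
from .data_stats import DataSnapshot, SnapshotDiff, StatsSummary, stats_sentences
from .genome_coords import AssemblyTable
from .spec_model import NormalizedSpec

NODE_KINDS = ("root", "title", "composition", "tracks", "track", "chart_type",
              "appearance", "axes", "color", "data", "statistics", "table", "diff")


@dataclass
class TreeNode:
    """One node of the navigable description hierarchy."""

    label: str
    description: str = ""
    node_kind: str = "root"
    children: list["TreeNode"] = field(default_factory=list)

    def find(self, kind: str) -> "TreeNode | None":
        if self.node_kind == kind:
            return self
        for child in self.children:
            hit = child.find(kind)
            if hit is not None:
                return hit
        return None

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class DescriptionBundle:
    """The four rendered outputs plus the underlying tree."""

    alt: str
    long: str
    full: str
    tree: TreeNode
    data_panel: TreeNode | None = None


def _track_label(comp: Composition, label: PositionLabel) -> str:
    if comp.n_charts == 1:
        return "track"
    if comp.relation_kind == "grid":
        return f"Track {label.chart_id + 1} ({label.label})"
    return f"track {label.label}"


def _appearance_sentences(chart: ChartUnit) -> str:
    marks = [t.mark for t in chart.member_tracks]
    if len(marks) == 1:
        mark_part = f"The mark is a {MARK_PHRASE.get(marks[0], marks[0])}."
    else:
        noun = ", ".join(MARK_PHRASE.get(m, m) for m in marks[:-1])
        mark_part = (f"This chart overlays {len(marks)} sub-tracks with marks: "
                     f"{noun} and {MARK_PHRASE.get(marks[-1], marks[-1])}.")
    return f"{mark_part} The layout is {chart.layout}."


def build_tree(spec: NormalizedSpec,
               charts: Sequence[ChartUnit],
               composition: Composition,
               labels: Sequence[PositionLabel],
               chart_types: Sequence[ChartTypeResult],
               stats_by_chart: dict[int, StatsSummary] | None = None,
               assembly: AssemblyTable | None = None,
               title: str | None = None) -> TreeNode:
    """Assemble the navigable description hierarchy.

    The root's first-level children are exactly title, composition and
    tracks (title omitted when the figure has none); every chart owns
    exactly one track node, labelled by its position.
    """
    stats_by_chart = stats_by_chart or {}
    title = title if title is not None else spec.global_title
    if title is None and len(charts) == 1:
        title = charts[0].title
    root = TreeNode("visualization", node_kind="root")
    if title:
        root.children.append(TreeNode("title", f"The title is '{title}'.", "title"))
    root.children.append(
        TreeNode("composition", " ".join(composition.sentences), "composition")
    )
    tracks_node = TreeNode("tracks", "", "tracks")
    label_by_chart = {l.chart_id: l for l in labels}
    for chart, ctype in zip(charts, chart_types):
        node = TreeNode(_track_label(composition, label_by_chart[chart.chart_id]),
                        "", "track")
        type_desc = sentence_case(ctype.display_name)
        if not type_desc.endswith("."):
            type_desc += "."
        node.children.append(TreeNode("chart type", type_desc, "chart_type"))
        node.children.append(TreeNode("appearance", _appearance_sentences(chart), "appearance"))
        node.children.append(TreeNode("axes", " ".join(describe_encodings(chart)), "axes"))
        node.children.append(TreeNode("color", " ".join(describe_colors(chart)), "color"))
        data_node = TreeNode("data", "", "data")
        # declared transforms are not executed, but their existence is reported
        if any("dataTransform" in t.extra for t in chart.member_tracks):
            data_node.description = (
                "A data transform (such as a filter) is declared for this track; "
                "the data shown is the already-transformed data."
            )
        stats = stats_by_chart.get(chart.chart_id)
        if stats is not None:
            data_node.children.append(
                TreeNode("statistics", " ".join(stats_sentences(stats, assembly)), "statistics")
            )
            data_node.children.append(
                TreeNode("table", f"The data table has {stats.row_count} rows.", "table")
            )
        elif not data_node.description:
            data_node.description = "No data snapshot is bound to this track."
        node.children.append(data_node)
        tracks_node.children.append(node)
    root.children.append(tracks_node)
    return root


def _data_kind(charts: Sequence[ChartUnit]) -> str:
    types = {
        ch.field_type
        for chart in charts
        for t in chart.member_tracks
        for ch in t.channels.values()
        if ch.is_axis
    }
    if "genomic" in types:
        return "genomic"
    if "quantitative" in types:
        return "quantitative"
    return "tabular"


def render_alt(charts: Sequence[ChartUnit],
               composition: Composition,
               chart_types: Sequence[ChartTypeResult],
               title: str | None = None) -> str:
    """One-sentence alternative text: chart type, kind of data, title."""
    if len(charts) == 1:
        name = sentence_case(chart_types[0].display_name)
        title = title or charts[0].title
        if title:
            return f"{name} showing {_data_kind(charts)} data, titled {title}."
        return f"{name} showing {_data_kind(charts)} data."
    listed = [inline_form(ct.display_name) for ct in chart_types]
    joined = ", ".join(listed[:-1]) + " and " + listed[-1]
    if title:
        return f"Figure with {len(charts)} charts: {joined}, titled {title}."
    return f"Figure with {len(charts)} charts: {joined}."


def render_full(tree: TreeNode) -> str:
    """Depth-first concatenation of every node description (flat text)."""
    parts = [node.description for node in tree.walk() if node.description]
    return "\n".join(parts)


def render_long(charts: Sequence[ChartUnit],
                composition: Composition,
                tree: TreeNode,
                chart_types: Sequence[ChartTypeResult],
                labels: Sequence[PositionLabel]) -> str:
    """Flat text for ``longdesc``.

    Up to two single-track charts: identical to the full description.
    Overlays or more than two charts: composition plus an enumeration of
    chart types and titles, referring the reader to the navigable tree.
    """
    if len(charts) <= 2 and not any(c.is_overlay for c in charts):
        return render_full(tree)
    lines = list(composition.sentences)
    label_by_chart = {l.chart_id: l for l in labels}
    for chart, ctype in zip(charts, chart_types):
        name = _track_label(composition, label_by_chart[chart.chart_id])
        entry = f"{sentence_case(name)}: {inline_form(ctype.display_name)}"
        if chart.title:
            entry += f", titled {chart.title}"
        lines.append(entry + ".")
    lines.append("Refer to the tree-structured description for more information on each chart.")
    return "\n".join(lines)


def render_data_panel(stats: StatsSummary,
                      snapshot: DataSnapshot,
                      diff: SnapshotDiff | None = None,
                      assembly: AssemblyTable | None = None) -> TreeNode:
    """The live data panel: statistics, the full table, and the snapshot diff.

    The diff child exists only once a previous snapshot exists.  Values
    update per snapshot; expansion state is a front-end concern (noted in
    the docs), so the panel itself is stateless.
    """
    panel = TreeNode("data panel", "Most recently shown data.", "data")
    panel.children.append(
        TreeNode("statistics", " ".join(stats_sentences(stats, assembly)), "statistics")
    )
    panel.children.append(
        TreeNode("table",
                 f"The data table has {stats.row_count} rows and "
                 f"{len(snapshot.table.columns)} columns.",
                 "table")
    )
    if diff is not None:
        panel.children.append(
            TreeNode("change from previous data", " ".join(diff.sentences), "diff")
        )
    return panel


def count_sentences(text: str) -> int:
    """Terminator-delimited sentence count ('.', '!', '?')."""
    return len(re.findall(r"[.!?](?:\s|$)", text))


# ---------------------------------------------------------------------------
# HTML emission


def _tree_item_html(node: TreeNode, out: list[str], first: list[bool]) -> None:
    tab = ' tabindex="0"' if first[0] else ' tabindex="-1"'
    first[0] = False
    expandable = bool(node.children)
    aria = ' aria-expanded="false"' if expandable else ""
    out.append(f'<li role="treeitem"{aria}{tab}>')
    out.append(f'<span class="ts-label">{_html.escape(node.label)}</span>')
    if node.description:
        out.append(f'<span class="ts-desc"> {_html.escape(node.description)}</span>')
    if expandable:
        out.append('<ul role="group">')
        for child in node.children:
            _tree_item_html(child, out, first)
        out.append("</ul>")
    out.append("</li>")


def _table_html(snapshot: DataSnapshot) -> str:
    cols = list(snapshot.table.columns)
    out = ['<table class="ts-data-table"><thead><tr>']
    out += [f"<th scope=\"col\">{_html.escape(str(c))}</th>" for c in cols]
    out.append("</tr></thead><tbody>")
    for _, row in snapshot.table.iterrows():
        out.append("<tr>" + "".join(f"<td>{_html.escape(str(v))}</td>" for v in row) + "</tr>")
    out.append("</tbody></table>")
    return "".join(out)


def render_html(tree: TreeNode,
                data_panel: TreeNode | None = None,
                snapshot: DataSnapshot | None = None,
                alt: str = "",
                long_description: str = "") -> str:
    """Emit the two-panel HTML fragment.

    The visualization-information panel is a collapsible ARIA tree
    (``role=tree``; exactly one tabbable item; expandable items carry
    ``aria-expanded``).  The most-recent-data panel is a separate labelled
    region holding the statistics, the diff and the full data table with
    header cells.  The alt text sits in the image ``alt`` attribute and the
    long description is referenced via ``longdesc``.
    """
    out = ['<div class="trackscribe">']
    out.append(
        f'<img src="" alt="{_html.escape(alt, quote=True)}" longdesc="#ts-longdesc"/>'
    )
    out.append(f'<div id="ts-longdesc" class="ts-longdesc" hidden="hidden">'
               f"{_html.escape(long_description)}</div>")
    out.append('<div class="ts-panel" aria-label="Visualization information">')
    out.append('<ul role="tree" aria-label="Description of the visualization">')
    first = [True]
    _tree_item_html(tree, out, first)
    out.append("</ul></div>")
    if data_panel is not None:
        out.append('<div class="ts-panel" role="region" aria-label="Most recent data">')
        out.append("<ul>")
        for child in data_panel.children:
            out.append(f'<li><span class="ts-label">{_html.escape(child.label)}</span>'
                       f'<span class="ts-desc"> {_html.escape(child.description)}</span></li>')
        out.append("</ul>")
        if snapshot is not None:
            out.append(_table_html(snapshot))
        out.append("</div>")
    out.append("</div>")
    return "".join(out)
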