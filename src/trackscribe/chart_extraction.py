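"""Grouping tracks into charts and inferring the figure composition.

Visually there is no difference between a lone track, a single-track view,
and several tracks overlaid on one canvas, so the unit of description is
the *chart*: one individually drawn canvas.  Overlaid tracks form one
chart; every other track is its own chart.  The arrangement tree then
determines how the charts are placed on the page — rows for vertical
(or parallel) arrangements, columns for horizontal (or serial) ones — and
each chart receives a position label ("top", "second row, left", ...)
that descriptions use to refer to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from .spec_model import NormalizedSpec, NormalizedTrack, SpecValidationError

_ORDINALS = ("first", "second", "third", "fourth", "fifth", "sixth", "seventh",
             "eighth", "ninth", "tenth")


@dataclass
class ChartUnit:
    """One drawn canvas: a single track or a set of overlaid tracks."""

    chart_id: int
    member_tracks: list[NormalizedTrack]
    shares_data: bool
    layout: str

    @property
    def is_overlay(self) -> bool:
        return len(self.member_tracks) > 1

    @property
    def title(self) -> str | None:
        for t in self.member_tracks:
            if t.title:
                return t.title
        return None


@dataclass
class Composition:
    """Spatial arrangement of the charts: a row-major grid plus sentences."""

    grid: list[list[int]]
    relation_kind: str  # single | stacked | side_by_side | grid | circular_ring
    sentences: list[str] = field(default_factory=list)

    @property
    def n_charts(self) -> int:
        return sum(len(row) for row in self.grid)


@dataclass(frozen=True)
class PositionLabel:
    chart_id: int
    label: str


def group_overlays(spec: NormalizedSpec) -> list[ChartUnit]:
    """Collapse each overlay group into one chart; other tracks map 1:1.

    Charts are numbered in document order of their first member.  Mixing
    circular and linear layouts inside one overlay is rejected: the
    sub-tracks share a canvas and must share its geometry.
    """
    charts: list[ChartUnit] = []
    seen_groups: dict[int, ChartUnit] = {}
    for track in spec.tracks:
        if track.overlay_group is not None and track.overlay_group in seen_groups:
            chart = seen_groups[track.overlay_group]
            chart.member_tracks.append(track)
            if track.layout != chart.layout:
                raise SpecValidationError(
                    f"overlay group {track.overlay_group} mixes circular and linear layouts"
                )
            continue
        chart = ChartUnit(
            chart_id=len(charts),
            member_tracks=[track],
            shares_data=True,
            layout=track.layout,
        )
        charts.append(chart)
        if track.overlay_group is not None:
            seen_groups[track.overlay_group] = chart
    for chart in charts:
        refs = {t.data_ref for t in chart.member_tracks}
        chart.shares_data = len(refs) == 1
    return charts


def _chart_of_track(charts: list[ChartUnit]) -> dict[int, int]:
    mapping = {}
    for chart in charts:
        for t in chart.member_tracks:
            mapping[t.track_id] = chart.chart_id
    return mapping


def _node_grid(node: dict[str, Any], track_to_chart: dict[int, int]) -> list[list[int]]:
    """Recursively lay a tree node out as a row-major grid of chart ids."""
    if "track" in node:
        return [[track_to_chart[node["track"]]]]
    children = node.get("children", [])
    grids = [_node_grid(c, track_to_chart) for c in children]
    # overlaid members collapse onto the same chart id: drop duplicates
    if not grids:
        return []
    arrangement = node.get("arrangement", "vertical")
    horizontal = arrangement in ("horizontal", "serial")
    if horizontal:
        n_rows = max(len(g) for g in grids)
        merged: list[list[int]] = [[] for _ in range(n_rows)]
        for g in grids:
            for r, row in enumerate(g):
                merged[r].extend(row)
        rows = merged
    else:
        rows = [row for g in grids for row in g]
    # dedupe chart ids (overlay members appear once each) preserving order
    out: list[list[int]] = []
    seen: set[int] = set()
    for row in rows:
        new_row = []
        for c in row:
            if c not in seen:
                seen.add(c)
                new_row.append(c)
        if new_row:
            out.append(new_row)
    return out


def _ring_candidate(tree: dict[str, Any], charts: list[ChartUnit],
                    track_to_chart: dict[int, int]) -> bool:
    """True when the figure is exactly two circular charts in one serial view."""
    if len(charts) != 2 or any(c.layout != "circular" for c in charts):
        return False

    def chart_ids(node: dict[str, Any]) -> set[int]:
        if "track" in node:
            return {track_to_chart[node["track"]]}
        out: set[int] = set()
        for c in node.get("children", []):
            out |= chart_ids(c)
        return out

    def find_serial(node: dict[str, Any]) -> bool:
        if "track" in node:
            return False
        if node.get("arrangement") == "serial" and chart_ids(node) == {0, 1}:
            return True
        return any(find_serial(c) for c in node.get("children", []))

    return find_serial(tree)


def infer_composition(charts: list[ChartUnit], arrangement_tree: dict[str, Any]) -> Composition:
    """Derive the chart grid and the sentences that describe it.

    Vertical / parallel arrangements become rows, horizontal / serial
    arrangements columns; deeper nesting is flattened row-major.  The one
    special case is two circular charts in a serial view, which form a
    single ring rather than sitting side by side.
    """
    track_to_chart = _chart_of_track(charts)
    grid = _node_grid(arrangement_tree, track_to_chart)
    n = len(charts)
    if _ring_candidate(arrangement_tree, charts, track_to_chart):
        return Composition(grid=grid, relation_kind="circular_ring", sentences=[
            "Two circular tracks form one ring together, each forming half of the ring."
        ])
    if n == 1:
        return Composition(grid=grid, relation_kind="single",
                           sentences=["There is one track."])
    sentences = [f"There are {n} tracks."]
    if len(grid) == 1:
        kind = "side_by_side"
        sentences.append("The tracks are placed next to each other.")
    elif all(len(row) == 1 for row in grid):
        kind = "stacked"
        sentences.append("The tracks are placed above each other.")
    else:
        kind = "grid"
        sentences.append(f"There are {len(grid)} rows.")
        widths = {len(row) for row in grid}
        if len(widths) == 1:
            sentences.append(f"Each row has {widths.pop()} tracks next to each other.")
        else:
            for i, row in enumerate(grid):
                noun = "tracks" if len(row) != 1 else "track"
                sentences.append(f"Row {i + 1} has {len(row)} {noun}.")
    return Composition(grid=grid, relation_kind=kind, sentences=sentences)


def _row_name(i: int, n_rows: int) -> str:
    if i == 0:
        return "top row"
    if i == n_rows - 1:
        return "bottom row"
    word = _ORDINALS[i] if i < len(_ORDINALS) else f"{i + 1}th"
    return f"{word} row"


def _col_name(j: int, n_cols: int) -> str:
    if j == 0:
        return "left"
    if j == n_cols - 1:
        return "right"
    if n_cols == 3:
        return "middle"
    return f"column {j + 1}"


def _stack_name(i: int, n: int) -> str:
    if i == 0:
        return "top"
    if i == n - 1:
        return "bottom"
    return _ORDINALS[i] if i < len(_ORDINALS) else f"{i + 1}th"


def position_labels(comp: Composition) -> list[PositionLabel]:
    """Positional names for the charts, unique by construction.

    Multi-column grids use "(row-name, column-name)" labels; single-column
    stacks use top/second/.../bottom; a lone chart is simply "track".
    """
    labels: list[PositionLabel] = []
    grid = comp.grid
    if comp.n_charts == 1:
        return [PositionLabel(grid[0][0], "track")]
    if comp.relation_kind in ("stacked",):
        n = len(grid)
        for i, row in enumerate(grid):
            labels.append(PositionLabel(row[0], _stack_name(i, n)))
        return labels
    if comp.relation_kind in ("side_by_side", "circular_ring"):
        row = grid[0]
        for j, cid in enumerate(row):
            labels.append(PositionLabel(cid, _col_name(j, len(row)) if len(row) > 1 else "track"))
        return labels
    for i, row in enumerate(grid):
        for j, cid in enumerate(row):
            labels.append(PositionLabel(cid, f"{_row_name(i, len(grid))}, {_col_name(j, len(row))}"))
    return labels


def chart_names(comp: Composition, labels: list[PositionLabel]) -> dict[int, str]:
    """Display names used in running text: "Track 1 (top row, left)" etc.

    Numbering follows document order of the charts, not grid order.
    """
    by_chart = {l.chart_id: l.label for l in labels}
    names = {}
    ids = sorted(by_chart)
    for cid in ids:
        if comp.n_charts == 1:
            names[cid] = "Track 1"
        else:
            names[cid] = f"Track {cid + 1} ({by_chart[cid]})"
    return names
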