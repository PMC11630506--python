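"""High-level pipeline: specification in, description bundle out."""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping, Sequence

from .chart_extraction import (ChartUnit, chart_names, group_overlays,
                               infer_composition, position_labels)
from .chart_inference import DEFAULT_RULES, ChartTypeRule, infer_chart_type
from .data_stats import (DataSnapshot, compute_stats, diff_snapshots,
                         load_snapshot)
from .description_render import (DescriptionBundle, build_tree, render_alt,
                                 render_data_panel, render_full, render_html,
                                 render_long)
from .genome_coords import AssemblyTable, build_assembly
from .spec_model import normalize_spec, parse_spec


def track_bindings(chart: ChartUnit) -> dict[str, str]:
    """Column -> field-type bindings implied by a chart's channels."""
    bindings: dict[str, str] = {}
    for t in chart.member_tracks:
        for ch in t.channels.values():
            if ch.is_axis and ch.field_type is not None:
                bindings[ch.field] = ch.field_type
    return bindings


def describe(spec: str | dict[str, Any],
             data: Sequence[str | Path] | Mapping[int, Sequence[str | Path]] | None = None,
             assembly: str | Path | AssemblyTable | None = None,
             rules: Sequence[ChartTypeRule] = DEFAULT_RULES) -> DescriptionBundle:
    """Run the full description pipeline on one specification.

    ``data`` is an ordered sequence of snapshot files (bound to the first
    chart) or a mapping chart-id -> ordered snapshot files; the last
    snapshot per chart feeds the statistics, and the data panel diffs the
    two most recent snapshots.  ``assembly`` overrides the assembly named
    in the spec (bundled name, chrom.sizes path, or a prebuilt table).
    """
    raw = parse_spec(spec)
    nspec = normalize_spec(raw)
    charts = group_overlays(nspec)
    composition = infer_composition(charts, nspec.arrangement_tree)
    labels = position_labels(composition)
    chart_types = [infer_chart_type(c, rules) for c in charts]

    if isinstance(assembly, AssemblyTable):
        table = assembly
    else:
        table = build_assembly(assembly or nspec.tracks[0].assembly)

    snapshots_by_chart: dict[int, list[DataSnapshot]] = {}
    if data is not None:
        mapping = data if isinstance(data, Mapping) else {0: list(data)}
        for cid, paths in mapping.items():
            chart = charts[cid]
            bindings = track_bindings(chart)
            snapshots_by_chart[cid] = [
                load_snapshot(p, bindings, table) for p in paths
            ]

    stats_by_chart = {
        cid: compute_stats(snaps[-1]) for cid, snaps in snapshots_by_chart.items() if snaps
    }
    tree = build_tree(nspec, charts, composition, labels, chart_types,
                      stats_by_chart, table)
    alt = render_alt(charts, composition, chart_types, nspec.global_title)
    full = render_full(tree)
    long_text = render_long(charts, composition, tree, chart_types, labels)

    data_panel = None
    for cid, snaps in snapshots_by_chart.items():
        if not snaps:
            continue
        diff = diff_snapshots(snaps[-2], snaps[-1]) if len(snaps) > 1 else None
        data_panel = render_data_panel(stats_by_chart[cid], snaps[-1], diff, table)
        break
    return DescriptionBundle(alt=alt, long=long_text, full=full, tree=tree,
                             data_panel=data_panel)


def describe_html(spec: str | dict[str, Any], **kwargs: Any) -> str:
    """Convenience wrapper: run :func:`describe` and emit the HTML fragment."""
    data = kwargs.get("data")
    bundle = describe(spec, **kwargs)
    snapshot = None
    if data is not None and bundle.data_panel is not None:
        # reload the most recent snapshot for the table rendering
        raw = parse_spec(spec)
        nspec = normalize_spec(raw)
        charts = group_overlays(nspec)
        mapping = data if isinstance(data, Mapping) else {0: list(data)}
        for cid, paths in mapping.items():
            if paths:
                asm = kwargs.get("assembly")
                table = asm if isinstance(asm, AssemblyTable) else build_assembly(
                    asm or nspec.tracks[0].assembly)
                snapshot = load_snapshot(paths[-1], track_bindings(charts[cid]), table)
                break
    return render_html(bundle.tree, bundle.data_panel, snapshot,
                       alt=bundle.alt, long_description=bundle.long)
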