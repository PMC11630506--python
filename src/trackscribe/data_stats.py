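"""Statistics and diffs over tabular data snapshots.

Interactive genome browsers re-fetch the visible data on every zoom or
pan.  Here that stream is modelled as an ordered sequence of *snapshots*:
small tables (CSV/TSV with a header, or BED3+) whose columns are bound to
visual channels as genomic, quantitative or nominal.  From each snapshot
the descriptions report the genomic and quantitative ranges, where on the
genome the extrema sit, per-category summaries, and — between successive
snapshots — a diff phrased as zooming, panning, row-count and category
changes.

Genomic columns hold absolute (concatenated-genome, 1-based) positions;
BED rows are converted on load.  Spec-declared data transforms are not
executed: a snapshot is taken to be the already-transformed data the
renderer would hand over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from .genome_coords import AssemblyTable, abs_to_rel, describe_range, rel_to_abs


class SnapshotError(ValueError):
    """Malformed snapshot file or binding mismatch."""


@dataclass
class DataSnapshot:
    """One table of visible data with declared column types."""

    snapshot_id: str
    table: pd.DataFrame
    column_types: dict[str, str]  # column -> genomic | quantitative | nominal

    @property
    def n_rows(self) -> int:
        return len(self.table)

    def columns_of(self, kind: str) -> list[str]:
        return [c for c, t in self.column_types.items() if t == kind]


@dataclass
class ExtremumLocation:
    """Value of an extremum, the genomic position of its first attaining row,
    and how many rows attain it."""

    value: float
    genomic_position: int | None
    attained_count: int


@dataclass
class CategoryStats:
    category: str
    genomic_min: int | None
    genomic_max: int | None
    quantitative_min: float | None
    quantitative_max: float | None


@dataclass
class StatsSummary:
    """Everything the statistics section of a description reports."""

    row_count: int
    genomic_min: int | None = None
    genomic_max: int | None = None
    quantitative: dict[str, tuple[ExtremumLocation, ExtremumLocation]] = field(default_factory=dict)
    categories: list[CategoryStats] = field(default_factory=list)
    max_category: str | None = None
    min_category: str | None = None

    @property
    def empty(self) -> bool:
        return self.row_count == 0


def load_snapshot(path: str | Path, bindings: Mapping[str, str],
                  assembly: AssemblyTable | None = None,
                  snapshot_id: str | None = None) -> DataSnapshot:
    """Load a CSV/TSV (header required) or BED3+ file as a typed snapshot.

    ``bindings`` maps column name -> field type for the bound columns.  BED
    intervals (0-based, half-open) are converted to 1-based inclusive
    absolute coordinates via ``assembly`` and exposed as ``position`` /
    ``position_end`` genomic columns alongside any extra BED columns.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".bed":
        if assembly is None:
            raise SnapshotError("an assembly table is required to load BED intervals")
        table = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
        if table.shape[1] < 3:
            raise SnapshotError(f"BED file {path.name} has fewer than 3 columns")
        names = ["chrom", "start", "end"] + [f"col{i}" for i in range(4, table.shape[1] + 1)]
        table.columns = names[: table.shape[1]]
        table["position"] = [
            rel_to_abs(c, int(s) + 1, assembly) for c, s in zip(table["chrom"], table["start"])
        ]
        table["position_end"] = [
            rel_to_abs(c, int(e), assembly) for c, e in zip(table["chrom"], table["end"])
        ]
        types = {"position": "genomic", "position_end": "genomic"}
        for col, ftype in bindings.items():
            if col in table.columns:
                types[col] = ftype
        return DataSnapshot(snapshot_id or path.stem, table, types)

    sep = "\t" if suffix in (".tsv", ".txt") else ","
    table = pd.read_csv(path, sep=sep)
    for col, ftype in bindings.items():
        if col not in table.columns:
            raise SnapshotError(f"bound column {col!r} is missing from {path.name}")
        if ftype in ("genomic", "quantitative") and not pd.api.types.is_numeric_dtype(table[col]):
            raise SnapshotError(f"column {col!r} must be numeric ({ftype}) in {path.name}")
    return DataSnapshot(snapshot_id or path.stem, table, dict(bindings))


def _first_extremum(values: list[float], positions: list[int] | None, best: float) -> ExtremumLocation:
    count = 0
    first_pos = None
    for i, v in enumerate(values):
        if v == best:
            count += 1
            if first_pos is None and positions is not None:
                first_pos = positions[i]
    return ExtremumLocation(best, first_pos, count)


def compute_stats(snapshot: DataSnapshot, bindings: Mapping[str, str] | None = None) -> StatsSummary:
    """Summarise one snapshot.

    Extremum positions use the first attaining row in file order (with the
    attaining count stored), which is the one order-dependent field; ranges
    and counts are permutation-invariant.  Per-category statistics are
    computed only when a nominal column is bound.  An empty snapshot yields
    an empty-stats marker so descriptions can say no data is shown.
    """
    types = dict(bindings) if bindings else snapshot.column_types
    if snapshot.n_rows == 0:
        return StatsSummary(row_count=0)
    table = snapshot.table
    genomic_cols = [c for c, t in types.items() if t == "genomic" and c in table.columns]
    quant_cols = [c for c, t in types.items() if t == "quantitative" and c in table.columns]
    nominal_cols = [c for c, t in types.items() if t == "nominal" and c in table.columns]

    summary = StatsSummary(row_count=snapshot.n_rows)
    if genomic_cols:
        allg = pd.concat([table[c] for c in genomic_cols])
        summary.genomic_min = int(allg.min())
        summary.genomic_max = int(allg.max())
    pos_col = genomic_cols[0] if genomic_cols else None
    positions = [int(v) for v in table[pos_col]] if pos_col else None
    for col in quant_cols:
        values = [float(v) for v in table[col]]
        finite = [v for v in values if not math.isnan(v)]
        if not finite:
            continue
        lo, hi = min(finite), max(finite)
        summary.quantitative[col] = (
            _first_extremum(values, positions, lo),
            _first_extremum(values, positions, hi),
        )

    if nominal_cols and quant_cols:
        cat_col, q_col = nominal_cols[0], quant_cols[0]
        seen: dict[str, CategoryStats] = {}
        for _, row in table.iterrows():
            cat = str(row[cat_col])
            st = seen.get(cat)
            g = int(row[pos_col]) if pos_col else None
            q = float(row[q_col])
            if st is None:
                seen[cat] = CategoryStats(cat, g, g, q, q)
            else:
                if g is not None:
                    st.genomic_min = min(st.genomic_min, g)
                    st.genomic_max = max(st.genomic_max, g)
                st.quantitative_min = min(st.quantitative_min, q)
                st.quantitative_max = max(st.quantitative_max, q)
        summary.categories = list(seen.values())
        # ties broken by first occurrence in row order
        summary.max_category = max(seen.values(), key=lambda s: s.quantitative_max).category
        summary.min_category = min(seen.values(), key=lambda s: s.quantitative_min).category
    elif nominal_cols:
        cat_col = nominal_cols[0]
        seen = {}
        for _, row in table.iterrows():
            cat = str(row[cat_col])
            g = int(row[pos_col]) if pos_col else None
            st = seen.get(cat)
            if st is None:
                seen[cat] = CategoryStats(cat, g, g, None, None)
            elif g is not None:
                st.genomic_min = min(st.genomic_min, g)
                st.genomic_max = max(st.genomic_max, g)
        summary.categories = list(seen.values())
    return summary


@dataclass
class SnapshotDiff:
    """Difference between two successive snapshots of one track."""

    prev_id: str
    curr_id: str
    range_shift: str  # none | zoom_in | zoom_out | pan_left | pan_right | change
    row_delta: int
    extrema_changes: dict[str, tuple[float, float]] = field(default_factory=dict)
    categories_added: list[str] = field(default_factory=list)
    categories_removed: list[str] = field(default_factory=list)
    sentences: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return (self.range_shift == "none" and self.row_delta == 0
                and not self.extrema_changes
                and not self.categories_added and not self.categories_removed)


def _range_shift(prev: StatsSummary, curr: StatsSummary) -> str:
    if prev.genomic_min is None or curr.genomic_min is None:
        return "none"
    p = (prev.genomic_min, prev.genomic_max)
    c = (curr.genomic_min, curr.genomic_max)
    if p == c:
        return "none"
    inside = p[0] <= c[0] and c[1] <= p[1]
    contains = c[0] <= p[0] and p[1] <= c[1]
    if inside and not contains:
        return "zoom_in"
    if contains and not inside:
        return "zoom_out"
    if c[0] > p[0] and c[1] > p[1]:
        return "pan_right"
    if c[0] < p[0] and c[1] < p[1]:
        return "pan_left"
    return "change"


_SHIFT_SENTENCE = {
    "zoom_in": "The genomic range narrowed: the view zoomed in.",
    "zoom_out": "The genomic range widened: the view zoomed out.",
    "pan_right": "The genomic range moved towards the end of the genome: the view panned right.",
    "pan_left": "The genomic range moved towards the start of the genome: the view panned left.",
    "change": "The genomic range changed.",
}


def diff_snapshots(prev: DataSnapshot, curr: DataSnapshot) -> SnapshotDiff:
    """Describe what changed between two snapshots sharing one binding set.

    Identical inputs yield the empty diff with a "no change" sentence.
    Swapping the arguments negates the row-count delta and mirrors the
    zoom/pan direction.
    """
    if set(prev.column_types) != set(curr.column_types):
        raise SnapshotError("snapshots do not share the same column bindings")
    pstats = compute_stats(prev)
    cstats = compute_stats(curr)
    shift = _range_shift(pstats, cstats)
    diff = SnapshotDiff(
        prev_id=prev.snapshot_id,
        curr_id=curr.snapshot_id,
        range_shift=shift,
        row_delta=cstats.row_count - pstats.row_count,
    )
    for col in cstats.quantitative:
        if col in pstats.quantitative:
            pmax = pstats.quantitative[col][1].value
            cmax = cstats.quantitative[col][1].value
            if pmax != cmax:
                diff.extrema_changes[col] = (pmax, cmax)
    pcats = [c.category for c in pstats.categories]
    ccats = [c.category for c in cstats.categories]
    diff.categories_added = [c for c in ccats if c not in pcats]
    diff.categories_removed = [c for c in pcats if c not in ccats]

    if diff.empty:
        diff.sentences = ["There is no change in the data shown."]
        return diff
    if shift != "none":
        diff.sentences.append(_SHIFT_SENTENCE[shift])
    if diff.row_delta:
        more = "more" if diff.row_delta > 0 else "fewer"
        diff.sentences.append(
            f"The table now has {abs(diff.row_delta)} {more} rows "
            f"({pstats.row_count} before, {cstats.row_count} now)."
        )
    for col, (old, new) in diff.extrema_changes.items():
        diff.sentences.append(
            f"The maximum of '{col}' changed from {fmt_num(old)} to {fmt_num(new)}."
        )
    if diff.categories_added:
        diff.sentences.append("Categories added: " + ", ".join(diff.categories_added) + ".")
    if diff.categories_removed:
        diff.sentences.append("Categories removed: " + ", ".join(diff.categories_removed) + ".")
    return diff


def fmt_num(v: float) -> str:
    """Compact number formatting for sentences (ints without decimals)."""
    if isinstance(v, int) or (isinstance(v, float) and v.is_integer()):
        return str(int(v))
    return f"{v:g}"


def stats_sentences(stats: StatsSummary, assembly: AssemblyTable | None = None) -> list[str]:
    """Render a summary as the sentences of the statistics section."""
    if stats.empty:
        return ["No data is shown."]
    sentences = [f"The data consists of {stats.row_count} rows."]
    if stats.genomic_min is not None and assembly is not None:
        sentences.append(describe_range(stats.genomic_min, stats.genomic_max, assembly))
    for col, (lo, hi) in stats.quantitative.items():
        sentences.append(
            f"The values of '{col}' range from {fmt_num(lo.value)} to {fmt_num(hi.value)}."
        )
        for which, ext in (("maximum", hi), ("minimum", lo)):
            if ext.genomic_position is not None and assembly is not None:
                rel = abs_to_rel(ext.genomic_position, assembly)
                where = rel.phrase() if rel.mapped else "an unmapped part of the genome"
                tie = f" ({ext.attained_count} positions reach this value)" if ext.attained_count > 1 else ""
                sentences.append(f"The {which} of {fmt_num(ext.value)} occurs at {where}{tie}.")
    if stats.categories:
        names = ", ".join(c.category for c in stats.categories)
        sentences.append(f"There are {len(stats.categories)} categories: {names}.")
        if stats.max_category is not None:
            sentences.append(f"The category with the highest value is '{stats.max_category}'.")
            sentences.append(f"The category with the lowest value is '{stats.min_category}'.")
        for c in stats.categories:
            if c.quantitative_min is not None:
                sentences.append(
                    f"Category '{c.category}': values range from "
                    f"{fmt_num(c.quantitative_min)} to {fmt_num(c.quantitative_max)}."
                )
    return sentences
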