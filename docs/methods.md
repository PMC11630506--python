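# Methods

## Scope and model

`trackscribe` is a deterministic, rule-based description generator for
grammar-based genomics visualizations. It covers the two lower semantic
levels of chart description — visual encodings (what is drawn and how)
and statistical information (ranges, extrema, categories) — organised in
a navigable hierarchy. Trend detection and cross-chart comparison
(perceptual/cognitive content) are out of scope, as is rendering the
visualization itself: the package consumes the specification and
data snapshots, never pixels or tile servers.

## Grammar subset and normalization

The supported grammar is a closed subset: marks
`point, line, bar, rect, rule, triangle, text, area, circle`; channels
`x, xe, y, ye, row, color, text` with field types
`genomic, quantitative, nominal`; view properties
`layout, arrangement (vertical|horizontal|parallel|serial),
alignment (stack|overlay), assembly, title`. Rarely used channels
(`x1, x1e, y1, stroke, opacity, size`) and unknown properties are parsed,
retained and flagged, never fatal — descriptions simply don't use them.
A JSON-Schema document for the subset ships in
`src/trackscribe/schema/`.

Normalization resolves each inheritable property to its nearest
ancestor-or-self assignment, then fills defaults: `layout=linear`,
`assembly=hg38`, `arrangement=vertical`, `alignment=stack`. These
defaults are the ones genome-visualization grammars conventionally
assume; they are a package choice, configurable per call. Normalization
is idempotent, and a normalized spec can be re-expressed as an explicit
raw spec (`NormalizedSpec.to_raw`), which is how idempotence is both
implemented and tested.

## Charts, composition, labels

Overlaid tracks form one chart; every other track is its own chart, even
when several stacked tracks visually resemble a single figure — with
shared axes the one-vs-many reading is genuinely subjective, and the
per-track reading keeps the mapping from specification to description
predictable. Arrangements are flattened row-major into a grid: vertical
and parallel nest as rows, horizontal and serial as columns; nesting
deeper than two levels flattens by the same rule. Two circular charts in
a serial view are a special case: they form one ring, each half of it,
and are described that way rather than as "side by side".

Position labels: multi-column grids use "(row, column)" names — rows
`top row / second row / … / bottom row`, columns `left / middle / right`
(ordinal `column N` beyond three; the three-column vocabulary is fixed
by this package, as is the treatment of wider grids). Single-column
stacks use `top / second / … / bottom`. Labels are unique by
construction.

## Chart-type inference

The rule table is evaluated specificity-first, so multi-channel rules
cannot be shadowed by their simpler prefixes: Matrix (bar, genomic
intervals on both axes) before Bar chart; Heatmap/Ideogram (rect +
genomic x/xe, split by colour field type) before anything rect-based;
then Scatter/Line/Bar; then the rule-mark line charts; then the fallback
"chart with ⟨plural mark⟩". The table is data (a tuple of
`ChartTypeRule`), and extra rules can be loaded from a YAML file; loaded
rules are tried first.

Display names have a sentence-initial and an inline form
("Chart with text" vs "chart with text"); "Chromosome Ideogram" is
"ideogram" inline. Modifiers: circular layout prefixes "Circular".
An overlay of exactly two sub-tracks with at least one identified
(named, non-fallback) type is an "Annotated ⟨type⟩" — the canonical
bar-chart-with-threshold-line reading. Overlays of three or more
sub-tracks are always enumerated in track order, even when one
sub-track is identified: with many layered primitives no single type
summarises the canvas, and the enumeration (e.g. "Chart with text,
chart with text, chart with rectangles, chart with rectangles, ideogram
and chart with vertical lines") is at least faithful. Ties between
several identified types inside one two-track overlay resolve to the
first in track order.

Channel sentences put the x- then y-axis first and render every channel
through a natural-language map — the raw channel tokens (`xe`, `ye`)
never appear; intervals are called intervals. For overlays sharing one
data source identical bindings are merged across marks; for different
sources each sub-track keeps its own sentences. Text marks are reported
as "text is displayed" without echoing content: the content is data, not
structure, and may be arbitrarily long. Colours are grouped under a
dedicated "color" node so uninterested users can skip it; hex values
resolve to approximate English names by nearest-neighbour over a small
fixed named-colour table, and nominal scales report the bundled default
theme palette (Okabe-Ito-derived, colour-blind safe).

## Coordinates

Both the absolute (concatenated-genome) and relative scales are 1-based
and inclusive; this convention is forced by the reference conversion
pair (absolute 1 191 936 000 ↔ chr6:130 737 676 on hg38) against the
canonical UCSC chromosome lengths. The canonical set is chr1..chr22,
chrX, chrY — no alternates, patches or chrM (chrM's inclusion varies
between tools; excluding it keeps "unmapped tail" semantics clean, and a
user-supplied chrom.sizes table can always add it). Positions past the
canonical total are "unmapped": range phrasing appends "as well as an
unmapped part of the genome at the end" rather than naming an unknown
chromosome. Custom assemblies load from two-column chrom.sizes text.

## Statistics, diffs, degenerate inputs

Statistics are computed per snapshot: genomic min/max over all genomic
columns; per quantitative column min/max with the genomic position of
the *first row in file order* attaining each extremum plus the count of
attaining rows (the explicit tie rule; it is the only order-dependent
field). "The category with the most extreme values" is read as the
category attaining the global maximum (the minimum-attaining category is
also reported); ties again break by first occurrence. An empty snapshot
produces an empty-stats marker and the sentence "No data is shown."
NaN quantitative values are ignored for extrema.

Diffs between successive snapshots classify the genomic-range change by
interval containment: strictly contained → zoom in, strictly containing
→ zoom out, both endpoints shifted the same way → pan left/right,
otherwise a generic change; plus row-count delta, per-column maximum
changes and category set changes. Diffing a snapshot with itself is
empty and says "no change". The classification is antisymmetric by
construction. Spec-declared data transforms are not executed — snapshots
are taken as already transformed, mirroring how a renderer hands over
visible data; interactivity is modelled as an ordered list of snapshot
files rather than live callbacks.

## Description outputs

The tree's root expands into title (omitted when absent), composition
and tracks; each chart owns one track node with children chart type,
appearance, axes, color, data→{statistics, table} — that child order is
a package choice. Alt text is always exactly one sentence
(terminator-delimited counting over `.`/`!`/`?`); figures with two or
more charts enumerate chart types instead of describing one. The long
description equals the full description for up to two single-track
charts; with overlays or more than two charts it enumerates chart types
and titles and refers the reader to the tree, and is therefore shorter
than the full text. The full description is the depth-first
concatenation of all node descriptions. The HTML emitter produces
static two-panel markup: one ARIA tree (single `role=tree`, `treeitem`s
with `aria-expanded` when expandable, exactly one tabbable item) and a
separate data-panel region with the statistics and the full table;
standard tree-widget keyboard behaviour and expansion-state persistence
are front-end concerns, no script is shipped.

## Synthetic data

The gallery generator emits eight small deterministic specifications
(bar chart, line chart, ideogram, heatmap, circular half-ring pair,
annotated bar chart, 3×2 grid, gene-annotation-style overlay plus a
triangle track) with paired CSV snapshots of ≤40 rows spanning hg38 —
the ideogram snapshot deliberately runs past the canonical total to
exercise unmapped-tail phrasing. These stand in, at desk scale, for the
public ChIP-seq / Micro-C / GenBank data such figures normally bind; no
network data is fetched. The random generator draws marks, channel
types, overlay groups, nested arrangements and snapshot tables from
seeded distributions and records bookkeeping (track counts, overlay
sizes) that property tests use as an independent oracle. What the
synthetic inputs do not emulate: real tile-server binning, spec-declared
transforms, million-row tables, or informative free-text labels — so
passing tests demonstrate correctness of the description logic, not
robustness to messy real-world specifications.

## Numerical and sizing choices

Numbers in sentences print compactly (integers without decimals, `%g`
otherwise). Property suites run at 500 random specs, 1000 random
positions per assembly and 1000 random snapshots of ≤40 rows — sizes
chosen to exercise the combinatorics thoroughly while the whole suite
and the acceptance script each complete in seconds. Description-length
statistics reported by the acceptance script are means over this
package's own gallery and characterise only it.

## Known limitations

No trend or cross-chart comparison sentences; no execution of
spec-declared transforms (a declared filter is reported as existing but
never applied to snapshots); fallback naming for every chart type outside the rule table
(arcs, links); description quality is bounded by the informativeness of
the titles and field names the spec author chose.
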