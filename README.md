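# trackscribe

Screen-reader-ready text descriptions for grammar-based genomics data
visualizations.

## The problem

Genomics figures — genome-browser tracks, ideograms, contact-map heatmaps,
multi-view compositions — are usually published without useful alternative
text, which makes them inaccessible to blind and low-vision readers who
rely on screen readers. General alt-text generators handle basic bar and
pie charts but not grammar-based genomics visualizations, where the chart
type is never declared: a specification only says *bar marks on a genomic
x-axis with quantitative heights*, and interaction (zoom/pan) constantly
changes the data on screen.

`trackscribe` takes a JSON visualization specification in a subset of the
[Gosling](http://gosling-lang.org) grammar (views, tracks, marks, visual
channels `x/xe/y/ye/row/color/text`), plus optional tabular snapshots of
the data each track currently shows, and deterministically produces:

* **alt text** — one sentence: chart type, kind of data, title;
* **long description** — flat text for the `longdesc` attribute;
* **full description** — the depth-first concatenation of the whole
  description tree;
* a **navigable description tree** (title / composition / tracks, each
  track expanding into chart type, appearance, axes, color, data) and an
  ARIA-compliant **HTML fragment** (`role=tree`) with a separate **data
  panel** holding statistics, the full data table and a diff against the
  previous snapshot.

## How it works

1. **Normalization** — view-level properties (layout, assembly, data, …)
   are inherited down to every track; grammar defaults
   (`layout=linear`, `assembly=hg38`, `arrangement=vertical`) fill the rest.
2. **Chart extraction** — overlaid tracks become one *chart* (one drawn
   canvas); arrangements map to a row-major grid, giving each chart a
   position label ("top", "second row, left").
3. **Chart-type inference** — an ordered rule table maps mark + channel
   types to familiar names: point+genomic x+quantitative y → *Scatter
   plot*; rect+genomic x/xe+quantitative color → *Heatmap*, nominal color
   → *Chromosome Ideogram*; bar with genomic intervals on both axes →
   *Matrix*; rule marks → vertical/horizontal line charts; otherwise the
   fallback "chart with ⟨marks⟩". Circular layouts prefix "Circular";
   a two-sub-track overlay with an identified type becomes
   "Annotated ⟨type⟩".
4. **Coordinates** — data positions are absolute offsets on the
   concatenated canonical chromosomes (chr1..chr22, chrX, chrY; both
   scales 1-based inclusive). With cumulative offsets o_i, absolute
   position p maps to chromosome i with o_i < p ≤ o_i + L_i at relative
   position p − o_i; positions past the total are "an unmapped part of
   the genome".
5. **Statistics & diffs** — per snapshot: genomic/quantitative ranges,
   extrema and the genomic position of their first attaining row,
   per-category summaries; between snapshots: zoom/pan direction from
   interval containment, row-count delta, category changes.

## Worked example

```python
import trackscribe as ts

hg38 = ts.build_assembly("hg38")
rel = ts.abs_to_rel(1191936000, hg38)
print(rel.chromosome, rel.position)   # chr6 130737676

import tempfile, pathlib
out = pathlib.Path(tempfile.mkdtemp())
ts.generate_fixtures(out, "gallery")  # deterministic example specs + CSVs
bundle = ts.describe((out / "bar_chart.json").read_text(),
                     data=[out / "chipseq.csv"])
print(bundle.alt)
```

prints

```
chr6 130737676
Bar chart showing genomic data, titled Tonsil ChIP-seq in Th1 cells.
```

The first line is the absolute→relative coordinate conversion (position
1 191 936 000 on the concatenated hg38 genome falls 130 737 676 bp into
chromosome 6). The second is the one-sentence alt text for a bar-chart
spec: inferred type, data kind, title. `bundle.long`, `bundle.full`,
`bundle.tree` and `ts.describe_html(...)` give the other outputs; the
`examples/` directory has one short script per capability.

A thin CLI wraps the same functions:

```bash
trackscribe generate --profile gallery --out fixtures/
trackscribe describe fixtures/bar_chart.json --data fixtures/chipseq.csv --format alt
```

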