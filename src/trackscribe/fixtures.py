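"""Synthetic specification and snapshot generators.

Real genomics figures are driven by large remote datasets; everything in
this package is instead exercised on two families of synthetic inputs:

* the **gallery** — a fixed set of small specifications mirroring the
  common figure categories (bar chart, line chart, ideogram, heatmap,
  circular half-ring pair, annotated bar chart, 3x2 multi-view grid,
  gene-annotation-style overlay) with paired CSV snapshots.  The gallery
  is deterministic: regenerating it always produces identical bytes.
  The public accessions typically behind such figures (e.g. ChIP-seq GEO
  samples GSM2048305, GSM1375210, GSM2048292, GSM2048310 and GenBank
  GCA_000001405.15) are documented here for orientation but never
  downloaded; the snapshots are synthetic stand-ins at desk scale.
* **random** draws — seeded random specifications and snapshots used by
  the property suites; the same seed always reproduces the same bytes.
"""

from __future__ import annotations

import json
import random
from pathlib import Path
from typing import Any

import pandas as pd

from .assemblies import HG38_CHROM_SIZES
from .genome_coords import build_assembly
from .spec_model import FIELD_TYPES, LAYOUTS, MARKS, NormalizedSpec

GALLERY_TITLE = "Tonsil ChIP-seq in Th1 cells"

_HG38 = build_assembly("hg38")


def _bar_track(data: str, title: str | None = None, **extra: Any) -> dict[str, Any]:
    track: dict[str, Any] = {
        "mark": "bar",
        "data": data,
        "x": {"field": "position", "type": "genomic"},
        "y": {"field": "peak", "type": "quantitative"},
    }
    if title:
        track["title"] = title
    track.update(extra)
    return track


def gallery_specs() -> dict[str, dict[str, Any]]:
    """The deterministic gallery specifications, keyed by fixture name."""
    specs: dict[str, dict[str, Any]] = {}

    specs["bar_chart"] = {
        "title": GALLERY_TITLE,
        "tracks": [_bar_track("chipseq.csv", GALLERY_TITLE)],
    }
    specs["line_chart"] = {
        "title": "ChIP-seq signal",
        "tracks": [{
            "mark": "line",
            "data": "chipseq.csv",
            "x": {"field": "position", "type": "genomic"},
            "y": {"field": "peak", "type": "quantitative"},
            "title": "ChIP-seq signal",
        }],
    }
    specs["ideogram"] = {
        "title": "Chromosome overview",
        "tracks": [{
            "mark": "rect",
            "data": "cytobands.csv",
            "x": {"field": "position", "type": "genomic"},
            "xe": {"field": "position_end", "type": "genomic"},
            "color": {"field": "stain", "type": "nominal"},
        }],
    }
    specs["heatmap"] = {
        "title": "Contact frequency",
        "tracks": [{
            "mark": "rect",
            "data": "contacts.csv",
            "x": {"field": "position", "type": "genomic"},
            "xe": {"field": "position_end", "type": "genomic"},
            "color": {"field": "count", "type": "quantitative"},
        }],
    }
    specs["circular_ring"] = {
        "arrangement": "serial",
        "layout": "circular",
        "views": [
            {"tracks": [_bar_track("chipseq.csv")]},
            {"tracks": [_bar_track("chipseq.csv")]},
        ],
    }
    specs["annotated_bar_chart"] = {
        "alignment": "overlay",
        "tracks": [
            _bar_track("chipseq.csv", GALLERY_TITLE),
            {
                "mark": "rule",
                "data": "chipseq.csv",
                "y": {"field": "threshold", "type": "quantitative"},
            },
        ],
    }
    bar = lambda i: _bar_track("chipseq.csv", f"Sample {i}")  # noqa: E731
    specs["grid_3x2"] = {
        "arrangement": "horizontal",
        "views": [
            {"arrangement": "vertical", "views": [{"tracks": [bar(i)]} for i in (1, 2, 3)]},
            {"arrangement": "vertical", "views": [{"tracks": [bar(i)]} for i in (4, 5, 6)]},
        ],
    }
    gene = "genes.csv"
    specs["gene_annotation"] = {
        "arrangement": "vertical",
        "views": [
            {
                "alignment": "overlay",
                "tracks": [
                    {"mark": "text", "data": gene,
                     "x": {"field": "position", "type": "genomic"},
                     "text": {"field": "name"}},
                    {"mark": "text", "data": gene,
                     "x": {"field": "position", "type": "genomic"},
                     "text": {"field": "name"}},
                    {"mark": "rect", "data": gene,
                     "x": {"field": "position", "type": "genomic"},
                     "xe": {"field": "position_end", "type": "genomic"}},
                    {"mark": "rect", "data": gene,
                     "x": {"field": "position", "type": "genomic"},
                     "xe": {"field": "position_end", "type": "genomic"}},
                    {"mark": "rect", "data": gene,
                     "x": {"field": "position", "type": "genomic"},
                     "xe": {"field": "position_end", "type": "genomic"},
                     "color": {"field": "strand", "type": "nominal"}},
                    {"mark": "rule", "data": gene,
                     "x": {"field": "position", "type": "genomic"}},
                ],
            },
            {
                "tracks": [{
                    "mark": "triangle",
                    "data": gene,
                    "x": {"field": "position", "type": "genomic"},
                    "xe": {"field": "position_end", "type": "genomic"},
                }],
            },
        ],
    }
    return specs


def gallery_snapshots() -> dict[str, pd.DataFrame]:
    """Deterministic CSV snapshots paired with the gallery specs."""
    rng = random.Random(20240)
    tables: dict[str, pd.DataFrame] = {}

    positions = sorted(rng.sample(range(1, _HG38.total), 40))
    tables["chipseq.csv"] = pd.DataFrame({
        "position": positions,
        "peak": [round(rng.uniform(0.0, 25.0), 3) for _ in positions],
        "threshold": [5.0] * len(positions),
    })

    # one banded row per canonical chromosome, plus an unmapped tail row
    rows = []
    stains = ("gneg", "gpos50", "acen")
    for i, (chrom, length) in enumerate(HG38_CHROM_SIZES.items()):
        offset = _HG38.offset_of(chrom)
        rows.append({"position": offset + 1, "position_end": offset + length,
                     "stain": stains[i % len(stains)]})
    rows.append({"position": _HG38.total + 1,
                 "position_end": _HG38.total + 15000000, "stain": "unmapped"})
    tables["cytobands.csv"] = pd.DataFrame(rows)

    starts = sorted(rng.sample(range(1, _HG38.total - 1000000), 30))
    tables["contacts.csv"] = pd.DataFrame({
        "position": starts,
        "position_end": [s + 1000000 for s in starts],
        "count": [rng.randint(1, 500) for _ in starts],
    })

    gene_starts = sorted(rng.sample(range(1, 248000000), 20))
    tables["genes.csv"] = pd.DataFrame({
        "position": gene_starts,
        "position_end": [s + rng.randint(1000, 100000) for s in gene_starts],
        "name": [f"GENE{i + 1}" for i in range(len(gene_starts))],
        "strand": [rng.choice(["+", "-"]) for _ in gene_starts],
    })
    return tables


#: snapshot file(s) used by each gallery spec, bound to chart 0
GALLERY_DATA = {
    "bar_chart": ["chipseq.csv"],
    "line_chart": ["chipseq.csv"],
    "ideogram": ["cytobands.csv"],
    "heatmap": ["contacts.csv"],
    "circular_ring": ["chipseq.csv"],
    "annotated_bar_chart": ["chipseq.csv"],
    "grid_3x2": ["chipseq.csv"],
    "gene_annotation": ["genes.csv"],
}


class RandomSpecGenerator:
    """Seeded generator of valid random specifications and snapshots.

    Bookkeeping (track counts, overlay group sizes) is recorded with each
    spec so property tests can check conservation laws against the
    generator rather than against the code under test.
    """

    def __init__(self, seed: int):
        self.rng = random.Random(seed)

    def _channels(self, mark: str) -> dict[str, Any]:
        rng = self.rng
        channels: dict[str, Any] = {
            "x": {"field": "position", "type": "genomic"},
        }
        if rng.random() < 0.7:
            channels["y"] = {"field": "peak", "type": "quantitative"}
        if mark == "rect" or rng.random() < 0.2:
            channels["xe"] = {"field": "position_end", "type": "genomic"}
        if rng.random() < 0.4:
            channels["color"] = (
                {"field": "sample", "type": rng.choice(("nominal", "quantitative"))}
                if rng.random() < 0.6 else {"value": "#0072B2"}
            )
        if mark == "text":
            channels["text"] = {"field": "name"}
        return channels

    def _track(self) -> dict[str, Any]:
        rng = self.rng
        mark = rng.choice(MARKS)
        track: dict[str, Any] = {"mark": mark, "data": f"data{rng.randint(0, 3)}.csv"}
        track.update(self._channels(mark))
        if rng.random() < 0.3:
            track["title"] = f"Track {rng.randint(1, 99)}"
        if rng.random() < 0.2:
            track["layout"] = rng.choice(LAYOUTS)
        if rng.random() < 0.15:
            track["assembly"] = rng.choice(("hg38", "hg19"))
        return track

    def spec(self, max_depth: int = 2) -> tuple[dict[str, Any], dict[str, Any]]:
        """One random raw spec plus generator bookkeeping."""
        meta = {"n_tracks": 0, "overlay_sizes": []}

        def view(depth: int) -> dict[str, Any]:
            rng = self.rng
            node: dict[str, Any] = {}
            if rng.random() < 0.5:
                node["arrangement"] = rng.choice(("vertical", "horizontal", "parallel", "serial"))
            if rng.random() < 0.3:
                node["layout"] = rng.choice(LAYOUTS)
            if rng.random() < 0.2:
                node["assembly"] = rng.choice(("hg38", "hg19"))
            kind = rng.random()
            if kind < 0.25 and depth < max_depth:
                node["views"] = [view(depth + 1) for _ in range(rng.randint(1, 3))]
            elif kind < 0.45:
                size = rng.randint(2, 4)
                node["alignment"] = "overlay"
                tracks = [self._track() for _ in range(size)]
                for t in tracks:
                    t.pop("layout", None)  # overlays share the view's layout
                node["tracks"] = tracks
                meta["n_tracks"] += size
                meta["overlay_sizes"].append(size)
            else:
                n = rng.randint(1, 3)
                node["tracks"] = [self._track() for _ in range(n)]
                meta["n_tracks"] += n
            return node

        root = view(0)
        if self.rng.random() < 0.5:
            root["title"] = f"Figure {self.rng.randint(1, 999)}"
        return root, meta

    def snapshot(self, max_rows: int = 200, with_category: bool | None = None) -> pd.DataFrame:
        """One random snapshot table with position/peak (and maybe category)."""
        rng = self.rng
        n = rng.randint(1, max_rows)
        if with_category is None:
            with_category = rng.random() < 0.5
        table = {
            "position": sorted(rng.randint(1, _HG38.total) for _ in range(n)),
            "peak": [round(rng.uniform(-10, 100), 2) for _ in range(n)],
        }
        if with_category:
            cats = ["alpha", "beta", "gamma"][: rng.randint(1, 3)]
            table["sample"] = [rng.choice(cats) for _ in range(n)]
        return pd.DataFrame(table)

    def inject_violations(self, spec: NormalizedSpec, k: int) -> int:
        """Corrupt a normalized spec in place with exactly ``k`` violations.

        Each injection is guaranteed to produce exactly one validation
        issue; the count is returned for use as the test oracle.
        """
        injected = 0
        kinds = ["mark", "layout"]
        candidates = [(t, kind) for t in spec.tracks for kind in kinds]
        self.rng.shuffle(candidates)
        for track, kind in candidates:
            if injected >= k:
                break
            if kind == "mark" and track.mark in MARKS:
                track.mark = "hexagon"
                injected += 1
            elif kind == "layout" and track.layout in LAYOUTS:
                track.layout = "spiral"
                injected += 1
        return injected


def generate_fixtures(out_dir: str | Path, profile: str, seed: int = 0,
                      n_random: int = 5) -> list[Path]:
    """Write fixture files for a profile; same seed, same bytes.

    ``gallery`` writes the deterministic gallery (specs as JSON, snapshots
    as CSV); ``random`` writes ``n_random`` seeded random spec/snapshot
    pairs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if profile == "gallery":
        for name, spec in gallery_specs().items():
            path = out / f"{name}.json"
            path.write_text(json.dumps(spec, indent=2, sort_keys=True) + "\n")
            written.append(path)
        for name, table in gallery_snapshots().items():
            path = out / name
            table.to_csv(path, index=False)
            written.append(path)
    elif profile == "random":
        gen = RandomSpecGenerator(seed)
        for i in range(n_random):
            spec, _ = gen.spec()
            path = out / f"random_{seed}_{i}.json"
            path.write_text(json.dumps(spec, indent=2, sort_keys=True) + "\n")
            written.append(path)
            snap = out / f"random_{seed}_{i}.csv"
            gen.snapshot().to_csv(snap, index=False)
            written.append(snap)
    else:
        raise ValueError(f"unknown fixture profile {profile!r} (gallery or random)")
    return written
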