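"""Snapshot loading, statistics and diffs, checked against brute-force scans."""

import math

import pandas as pd
import pytest

import trackscribe as ts
from trackscribe.data_stats import SnapshotError, fmt_num


def make_snapshot(table, types, sid="s"):
    return ts.DataSnapshot(sid, pd.DataFrame(table), types)


BINDINGS = {"position": "genomic", "peak": "quantitative"}


class TestLoadSnapshot:
    def test_csv_with_header(self, tmp_path, hg38):
        p = tmp_path / "snap.csv"
        p.write_text("position,peak\n1,2.0\n10,4.0\n20,1.0\n30,9.0\n")
        snap = ts.load_snapshot(p, BINDINGS, hg38)
        assert snap.n_rows == 4
        assert snap.column_types["peak"] == "quantitative"

    def test_bed_interval_conversion(self, tmp_path, hg38):
        """BED is 0-based half-open; chr2:0-100 starts at abs len(chr1)+1."""
        p = tmp_path / "snap.bed"
        p.write_text("chr2\t0\t100\n")
        snap = ts.load_snapshot(p, {}, hg38)
        assert snap.table["position"].iloc[0] == hg38.length_of("chr1") + 1
        assert snap.table["position_end"].iloc[0] == hg38.length_of("chr1") + 100

    def test_missing_bound_column_named(self, tmp_path, hg38):
        p = tmp_path / "snap.csv"
        p.write_text("position\n1\n")
        with pytest.raises(SnapshotError, match="peak"):
            ts.load_snapshot(p, BINDINGS, hg38)

    def test_non_numeric_quantitative_rejected(self, tmp_path, hg38):
        p = tmp_path / "snap.csv"
        p.write_text("position,peak\n1,high\n")
        with pytest.raises(SnapshotError, match="numeric"):
            ts.load_snapshot(p, BINDINGS, hg38)


def brute_force_stats(rows, pos_col="position", q_col="peak", cat_col=None):
    """Independent full-scan oracle for StatsSummary fields."""
    out = {
        "n": len(rows),
        "gmin": min(r[pos_col] for r in rows),
        "gmax": max(r[pos_col] for r in rows),
        "qmin": min(r[q_col] for r in rows),
        "qmax": max(r[q_col] for r in rows),
    }
    out["qmin_pos"] = next(r[pos_col] for r in rows if r[q_col] == out["qmin"])
    out["qmax_pos"] = next(r[pos_col] for r in rows if r[q_col] == out["qmax"])
    out["qmin_count"] = sum(r[q_col] == out["qmin"] for r in rows)
    out["qmax_count"] = sum(r[q_col] == out["qmax"] for r in rows)
    if cat_col:
        cats = {}
        for r in rows:
            c = r[cat_col]
            cats.setdefault(c, []).append(r)
        out["cats"] = {
            c: (min(x[pos_col] for x in rs), max(x[pos_col] for x in rs),
                min(x[q_col] for x in rs), max(x[q_col] for x in rs))
            for c, rs in cats.items()
        }
        best = max(cats.values(), key=lambda rs: max(x[q_col] for x in rs))
        # first-occurrence tie break over category insertion order
        out["max_cat"] = next(
            c for c, rs in cats.items()
            if max(x[q_col] for x in rs) == max(x[q_col] for x in best)
        )
    return out


def assert_matches_oracle(stats, oracle):
    assert stats.row_count == oracle["n"]
    assert stats.genomic_min == oracle["gmin"]
    assert stats.genomic_max == oracle["gmax"]
    lo, hi = stats.quantitative["peak"]
    assert (lo.value, lo.genomic_position, lo.attained_count) == (
        oracle["qmin"], oracle["qmin_pos"], oracle["qmin_count"])
    assert (hi.value, hi.genomic_position, hi.attained_count) == (
        oracle["qmax"], oracle["qmax_pos"], oracle["qmax_count"])


class TestComputeStats:
    def test_single_row(self):
        snap = make_snapshot({"position": [42], "peak": [7.0]}, BINDINGS)
        stats = ts.compute_stats(snap)
        lo, hi = stats.quantitative["peak"]
        assert lo.value == hi.value == 7.0
        assert lo.genomic_position == hi.genomic_position == 42

    def test_two_category_fixture_matches_brute_force(self):
        rows = [
            {"position": 10, "peak": 5.0, "sample": "a"},
            {"position": 20, "peak": 9.0, "sample": "b"},
            {"position": 30, "peak": 1.0, "sample": "a"},
            {"position": 40, "peak": 9.0, "sample": "a"},
            {"position": 50, "peak": 3.0, "sample": "b"},
            {"position": 60, "peak": 2.0, "sample": "a"},
        ]
        snap = make_snapshot(pd.DataFrame(rows),
                             dict(BINDINGS, sample="nominal"))
        stats = ts.compute_stats(snap)
        oracle = brute_force_stats(rows, cat_col="sample")
        assert_matches_oracle(stats, oracle)
        assert stats.max_category == oracle["max_cat"]
        by_cat = {c.category: c for c in stats.categories}
        for cat, (gmin, gmax, qmin, qmax) in oracle["cats"].items():
            c = by_cat[cat]
            assert (c.genomic_min, c.genomic_max, c.quantitative_min,
                    c.quantitative_max) == (gmin, gmax, qmin, qmax)

    def test_all_equal_ties_broken_by_first_occurrence(self):
        snap = make_snapshot({"position": [1, 2, 3], "peak": [4.0] * 3,
                              "sample": ["x", "y", "z"]},
                             dict(BINDINGS, sample="nominal"))
        stats = ts.compute_stats(snap)
        lo, hi = stats.quantitative["peak"]
        assert hi.genomic_position == 1 and hi.attained_count == 3
        assert stats.max_category == "x" and stats.min_category == "x"

    def test_empty_snapshot_marker(self):
        snap = make_snapshot({"position": [], "peak": []}, BINDINGS)
        stats = ts.compute_stats(snap)
        assert stats.empty
        assert ts.stats_sentences(stats) == ["No data is shown."]

    def test_random_snapshots_match_brute_force(self):
        gen = ts.RandomSpecGenerator(17)
        for _ in range(60):
            table = gen.snapshot(max_rows=60, with_category=True)
            snap = ts.DataSnapshot("r", table,
                                   dict(BINDINGS, sample="nominal"))
            stats = ts.compute_stats(snap)
            oracle = brute_force_stats(table.to_dict("records"), cat_col="sample")
            assert_matches_oracle(stats, oracle)
            assert stats.max_category == oracle["max_cat"]

    def test_permutation_invariance_of_ranges(self):
        gen = ts.RandomSpecGenerator(29)
        table = gen.snapshot(max_rows=50, with_category=False)
        shuffled = table.sample(frac=1, random_state=1).reset_index(drop=True)
        a = ts.compute_stats(ts.DataSnapshot("a", table, BINDINGS))
        b = ts.compute_stats(ts.DataSnapshot("b", shuffled, BINDINGS))
        assert (a.genomic_min, a.genomic_max) == (b.genomic_min, b.genomic_max)
        assert a.quantitative["peak"][1].value == b.quantitative["peak"][1].value


class TestDiff:
    def snap(self, positions, peaks, sid="s"):
        return make_snapshot({"position": positions, "peak": peaks}, BINDINGS, sid)

    def test_self_diff_is_empty_with_no_change_sentence(self):
        s = self.snap([1, 100], [2.0, 3.0])
        diff = ts.diff_snapshots(s, s)
        assert diff.empty
        assert any("no change" in t for t in diff.sentences)

    def test_contained_range_is_zoom_in(self):
        prev = self.snap([1, 1000], [2.0, 3.0], "p")
        curr = self.snap([100, 500], [2.0, 3.0], "c")
        assert ts.diff_snapshots(prev, curr).range_shift == "zoom_in"

    def test_antisymmetry(self):
        gen = ts.RandomSpecGenerator(41)
        for _ in range(40):
            a = ts.DataSnapshot("a", gen.snapshot(max_rows=40), dict(BINDINGS))
            b = ts.DataSnapshot("b", gen.snapshot(max_rows=40), dict(BINDINGS))
            ab, ba = ts.diff_snapshots(a, b), ts.diff_snapshots(b, a)
            assert ab.row_delta == -ba.row_delta
            mirror = {"zoom_in": "zoom_out", "zoom_out": "zoom_in",
                      "pan_left": "pan_right", "pan_right": "pan_left",
                      "none": "none", "change": "change"}
            assert ba.range_shift == mirror[ab.range_shift]

    def test_row_delta_matches_counting_oracle(self):
        gen = ts.RandomSpecGenerator(43)
        for _ in range(30):
            a = ts.DataSnapshot("a", gen.snapshot(max_rows=80), dict(BINDINGS))
            b = ts.DataSnapshot("b", gen.snapshot(max_rows=80), dict(BINDINGS))
            assert ts.diff_snapshots(a, b).row_delta == len(b.table) - len(a.table)

    def test_binding_mismatch_rejected(self):
        a = self.snap([1], [1.0])
        b = make_snapshot({"position": [1]}, {"position": "genomic"})
        with pytest.raises(SnapshotError, match="bindings"):
            ts.diff_snapshots(a, b)


def test_number_formatting():
    assert fmt_num(5.0) == "5"
    assert fmt_num(5.25) == "5.25"
    assert fmt_num(130737676) == "130737676"
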