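"""Description tree schema, alt/long/full semantics and the HTML emitter."""

import json
import xml.etree.ElementTree as ET

import pandas as pd
import pytest

import trackscribe as ts
from trackscribe.description_render import count_sentences
from conftest import gallery_bundle


BAR = {
    "mark": "bar",
    "data": "d.csv",
    "x": {"field": "position", "type": "genomic"},
    "y": {"field": "peak", "type": "quantitative"},
}


class TestTreeSchema:
    def test_root_children_title_composition_tracks(self, bar_chart_bundle):
        kinds = [c.node_kind for c in bar_chart_bundle.tree.children]
        assert kinds == ["title", "composition", "tracks"]

    def test_title_omitted_when_absent(self):
        bundle = ts.describe(json.dumps({"tracks": [BAR]}))
        assert [c.node_kind for c in bundle.tree.children] == ["composition", "tracks"]

    def test_one_track_node_per_chart(self, gallery_dir):
        bundle = gallery_bundle(gallery_dir, "grid_3x2", with_data=False)
        tracks = bundle.tree.find("tracks")
        assert len(tracks.children) == 6

    def test_stacked_track_labels(self, gallery_dir):
        bundle = gallery_bundle(gallery_dir, "gene_annotation", with_data=False)
        labels = [c.label for c in bundle.tree.find("tracks").children]
        assert labels == ["track top", "track bottom"]

    def test_color_lives_in_dedicated_node(self, bar_chart_bundle):
        color = bar_chart_bundle.tree.find("color")
        assert color is not None and color.label == "color"

    def test_sibling_labels_unique_on_random_specs(self):
        gen = ts.RandomSpecGenerator(53)
        for _ in range(40):
            raw, _ = gen.spec()
            bundle = ts.describe(raw)
            for node in bundle.tree.walk():
                labels = [c.label for c in node.children]
                assert len(labels) == len(set(labels))


class TestAlt:
    def test_bar_chart_golden(self, bar_chart_bundle):
        assert bar_chart_bundle.alt == (
            "Bar chart showing genomic data, titled Tonsil ChIP-seq in Th1 cells."
        )

    def test_untitled_single_chart(self):
        bundle = ts.describe(json.dumps({"tracks": [dict(BAR, mark="point")]}))
        assert bundle.alt == "Scatter plot showing genomic data."

    def test_many_charts_enumerate_types(self, gallery_dir):
        bundle = gallery_bundle(gallery_dir, "grid_3x2", with_data=False)
        assert bundle.alt.startswith("Figure with 6 charts:")
        assert bundle.alt.count("bar chart") == 6

    def test_alt_is_one_sentence_everywhere(self, gallery_dir):
        for name in ts.fixtures.GALLERY_DATA:
            bundle = gallery_bundle(gallery_dir, name, with_data=False)
            assert count_sentences(bundle.alt) == 1
        gen = ts.RandomSpecGenerator(59)
        for _ in range(50):
            raw, _ = gen.spec()
            assert count_sentences(ts.describe(raw).alt) == 1


class TestLongAndFull:
    def test_single_track_long_equals_full(self, bar_chart_bundle):
        assert bar_chart_bundle.long == bar_chart_bundle.full

    def test_two_single_track_charts_long_equals_full(self):
        bundle = ts.describe(json.dumps({"tracks": [dict(BAR), dict(BAR)]}))
        assert bundle.long == bundle.full

    def test_overlay_long_is_shorter_than_full(self, gallery_dir):
        bundle = gallery_bundle(gallery_dir, "annotated_bar_chart")
        assert bundle.long != bundle.full
        assert len(bundle.long) < len(bundle.full)

    def test_many_charts_long_enumerates_and_refers_to_tree(self, gallery_dir):
        bundle = gallery_bundle(gallery_dir, "grid_3x2", with_data=False)
        entries = [l for l in bundle.long.splitlines() if l.startswith("Track ")]
        assert len(entries) == 6
        assert "tree" in bundle.long.splitlines()[-1]
        assert len(bundle.long) < len(bundle.full)

    def test_full_is_depth_first_concatenation(self, bar_chart_bundle):
        descriptions = [n.description for n in bar_chart_bundle.tree.walk()
                        if n.description]
        assert bar_chart_bundle.full == "\n".join(descriptions)


class TestDataPanel:
    def write_csv(self, tmp_path, name, positions, peaks):
        p = tmp_path / name
        pd.DataFrame({"position": positions, "peak": peaks}).to_csv(p, index=False)
        return p

    def test_first_snapshot_has_no_diff_child(self, tmp_path):
        p = self.write_csv(tmp_path, "a.csv", [1, 100], [2.0, 3.0])
        bundle = ts.describe(json.dumps({"tracks": [BAR]}), data=[p])
        kinds = [c.node_kind for c in bundle.data_panel.children]
        assert "diff" not in kinds

    def test_identical_second_snapshot_reports_no_change(self, tmp_path):
        p = self.write_csv(tmp_path, "a.csv", [1, 100], [2.0, 3.0])
        bundle = ts.describe(json.dumps({"tracks": [BAR]}), data=[p, p])
        diff = next(c for c in bundle.data_panel.children if c.node_kind == "diff")
        assert "no change" in diff.description

    def test_zoomed_in_snapshot_reports_narrowed_range(self, tmp_path):
        a = self.write_csv(tmp_path, "a.csv", [1, 1000], [2.0, 3.0])
        b = self.write_csv(tmp_path, "b.csv", [200, 600], [2.0, 3.0])
        bundle = ts.describe(json.dumps({"tracks": [BAR]}), data=[a, b])
        diff = next(c for c in bundle.data_panel.children if c.node_kind == "diff")
        assert "zoomed in" in diff.description

    def test_whole_genome_range_sentence(self, gallery_dir):
        bundle = gallery_bundle(gallery_dir, "ideogram")
        stats = bundle.tree.find("statistics")
        assert (
            "The genomic range is shown from chromosome 1 to chromosome 22 "
            "and the X and Y chromosomes, as well as an unmapped part of the "
            "genome at the end." in stats.description
        )


class TestHtml:
    @pytest.fixture()
    def html_root(self, gallery_dir):
        spec = (gallery_dir / "bar_chart.json").read_text()
        html = ts.describe_html(spec, data=[gallery_dir / "chipseq.csv"])
        return ET.fromstring(html)

    def test_exactly_one_tree_role(self, html_root):
        assert len(html_root.findall(".//*[@role='tree']")) == 1

    def test_expandable_items_carry_aria_expanded(self, html_root):
        for item in html_root.findall(".//*[@role='treeitem']"):
            has_group = item.find("./*[@role='group']") is not None
            assert (item.get("aria-expanded") is not None) == has_group

    def test_exactly_one_tabbable_item(self, html_root):
        tab0 = [e for e in html_root.iter() if e.get("tabindex") == "0"]
        assert len(tab0) == 1

    def test_root_level_options(self, html_root):
        tree = html_root.find(".//*[@role='tree']")
        root_item = tree.find("./*[@role='treeitem']")
        group = root_item.find("./*[@role='group']")
        labels = [li.find("./span").text for li in group.findall("./*[@role='treeitem']")]
        assert labels == ["title", "composition", "tracks"]

    def test_alt_and_longdesc_attributes(self, html_root):
        img = html_root.find(".//img")
        assert img.get("alt").startswith("Bar chart showing genomic data")
        assert img.get("longdesc") == "#ts-longdesc"

    def test_data_table_header_and_rows(self, html_root):
        table = html_root.find(".//table")
        headers = table.findall("./thead/tr/th")
        assert [h.text for h in headers] == ["position", "peak", "threshold"]
        assert len(table.findall("./tbody/tr")) == 40

    def test_two_panel_layout(self, html_root):
        panels = html_root.findall(".//div[@class='ts-panel']")
        assert len(panels) == 2
        assert panels[1].get("role") == "region"


def test_declared_transform_is_echoed_not_executed():
    spec = dict(tracks=[dict(BAR, dataTransform=[{"type": "filter", "field": "peak"}])])
    bundle = ts.describe(json.dumps(spec))
    data = bundle.tree.find("data")
    assert "transform" in data.description
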