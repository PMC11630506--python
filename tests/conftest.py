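import pytest

import trackscribe as ts


@pytest.fixture(scope="session")
def hg38():
    return ts.build_assembly("hg38")


@pytest.fixture(scope="session")
def gallery_dir(tmp_path_factory):
    """The deterministic gallery fixtures, written once per session."""
    out = tmp_path_factory.mktemp("gallery")
    ts.generate_fixtures(out, "gallery")
    return out


def gallery_bundle(gallery_dir, name, with_data=True):
    spec = (gallery_dir / f"{name}.json").read_text()
    data = None
    if with_data:
        data = [gallery_dir / f for f in ts.fixtures.GALLERY_DATA[name]]
    return ts.describe(spec, data=data)


@pytest.fixture(scope="session")
def bar_chart_bundle(gallery_dir):
    return gallery_bundle(gallery_dir, "bar_chart")


def run_pipeline(spec_text):
    """Parse -> normalize -> charts -> composition -> labels -> types."""
    nspec = ts.normalize_spec(ts.parse_spec(spec_text))
    charts = ts.group_overlays(nspec)
    comp = ts.infer_composition(charts, nspec.arrangement_tree)
    labels = ts.position_labels(comp)
    types = [ts.infer_chart_type(c) for c in charts]
    return nspec, charts, comp, labels, types


#: independent oracle for property inheritance: a brute-force walk over the
#: raw JSON tree that records, per track leaf, the nearest ancestor-or-self
#: assignment of each inheritable property.
def inherited_props_oracle(node, inherited=None, out=None):
    inherited = dict(inherited or {})
    out = out if out is not None else []
    for key in ("layout", "assembly", "data", "static", "width", "height"):
        if key in node:
            inherited[key] = node[key]
    if "mark" in node:
        out.append(inherited)
        return out
    for child in node.get("views", []) + node.get("tracks", []):
        inherited_props_oracle(child, inherited, out)
    return out
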