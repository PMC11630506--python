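"""Infer familiar chart types from mark + channel combinations.

A grammar spec never names its chart type; the rule table recovers it from
the visual encodings, with a mark-based fallback when nothing matches.
"""

import json

import trackscribe as ts

G = {"field": "position", "type": "genomic"}
GE = {"field": "position_end", "type": "genomic"}
Q = {"field": "peak", "type": "quantitative"}
N = {"field": "stain", "type": "nominal"}

cases = [
    ("point mark, genomic x, quantitative y", {"mark": "point", "x": G, "y": Q}),
    ("rect mark, genomic x/xe, quantitative color", {"mark": "rect", "x": G, "xe": GE, "color": Q}),
    ("rect mark, genomic x/xe, nominal color", {"mark": "rect", "x": G, "xe": GE, "color": N}),
    ("bar mark, genomic intervals on both axes", {"mark": "bar", "x": G, "xe": GE, "y": G, "ye": GE}),
    ("triangle mark (no rule matches)", {"mark": "triangle", "x": G}),
]

for desc, track in cases:
    track["data"] = "d.csv"
    nspec = ts.normalize_spec(ts.parse_spec(json.dumps({"tracks": [track]})))
    print(f"{desc:48s} -> {ts.infer_unit_type(nspec.tracks[0])}")

print()
print("Overlays: a bar chart with a threshold line over it becomes")
spec = {"alignment": "overlay", "tracks": [
    {"mark": "bar", "data": "d.csv", "x": G, "y": Q},
    {"mark": "rule", "data": "d.csv", "y": Q},
]}
nspec = ts.normalize_spec(ts.parse_spec(json.dumps(spec)))
chart = ts.group_overlays(nspec)[0]
print(" ", ts.infer_chart_type(chart).display_name)
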