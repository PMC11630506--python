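"""Data statistics and the snapshot diff of the live data panel.

Interaction (zoom/pan) is modelled as an ordered sequence of snapshot
files; the data panel always shows the most recent snapshot's statistics
plus a description of what changed since the previous one.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

import trackscribe as ts

tmp = Path(tempfile.mkdtemp())
wide = tmp / "wide.csv"
zoom = tmp / "zoomed.csv"
pd.DataFrame({"position": [1_000_000, 500_000_000, 1_500_000_000],
              "peak": [3.0, 12.5, 7.0]}).to_csv(wide, index=False)
pd.DataFrame({"position": [400_000_000, 600_000_000],
              "peak": [12.5, 9.0]}).to_csv(zoom, index=False)

spec = json.dumps({"tracks": [{
    "mark": "bar", "data": "d.csv",
    "x": {"field": "position", "type": "genomic"},
    "y": {"field": "peak", "type": "quantitative"},
}]})

bundle = ts.describe(spec, data=[wide, zoom])
for child in bundle.data_panel.children:
    print(f"[{child.label}]")
    print(" ", child.description)
print()
print("The diff section reports the narrowed genomic range (a zoom-in)")
print("and the row-count change between the two snapshots.")
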