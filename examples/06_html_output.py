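"""Emit the ARIA tree + data panel HTML fragment for embedding in a page.

The fragment holds: an img carrying the alt text and a longdesc reference,
one keyboard-navigable tree (role=tree/treeitem/group, one tabbable item),
and a separate region with the data statistics and the full table.
"""

import tempfile
from pathlib import Path

import trackscribe as ts

out = Path(tempfile.mkdtemp())
ts.generate_fixtures(out, "gallery")

html = ts.describe_html((out / "bar_chart.json").read_text(),
                        data=[out / "chipseq.csv"])

print(html[:600], "...")
print()
print("structural facts:")
print("  role=tree occurrences:    ", html.count('role="tree"'))
print("  treeitem occurrences:     ", html.count('role="treeitem"'))
print("  tabbable (tabindex=0):    ", html.count('tabindex="0"'))
print("  table body rows:          ", html.count("<td>") // 3, "(3 columns each)")
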