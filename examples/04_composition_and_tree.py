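"""Multi-chart composition sentences and the navigable description tree.

A 3x2 grid of charts (two columns of three stacked tracks) is described
row-wise, and every chart is referred to by its position.
"""

import tempfile
from pathlib import Path

import trackscribe as ts

out = Path(tempfile.mkdtemp())
ts.generate_fixtures(out, "gallery")

bundle = ts.describe((out / "grid_3x2.json").read_text())

comp = bundle.tree.find("composition")
print("Composition:", comp.description)
print()
print("Description tree (a screen reader walks this top-down and expands")
print("only the branches the user cares about):")


def show(node, depth=0):
    text = f" — {node.description}" if node.description else ""
    print("  " * depth + f"{node.label}{text[:70]}")
    for child in node.children:
        show(child, depth + 1)


show(bundle.tree)
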