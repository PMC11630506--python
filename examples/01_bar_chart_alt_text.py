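"""Describe a single bar-chart specification: alt text, long and full text.

Builds a one-track spec (bar mark, genomic x, quantitative y) with a small
CSV snapshot and prints the three flat-text outputs a web page would embed.
"""

import tempfile
from pathlib import Path

import trackscribe as ts

out = Path(tempfile.mkdtemp())
ts.generate_fixtures(out, "gallery")

spec = (out / "bar_chart.json").read_text()
bundle = ts.describe(spec, data=[out / "chipseq.csv"])

print("ALT TEXT (goes in the <img alt> attribute, always one sentence):")
print(" ", bundle.alt)
print()
print("LONG DESCRIPTION (referenced via longdesc; equals the full")
print("description because this figure is a single, non-overlaid chart):")
print(bundle.long)
print()
print("The statistics paragraph above is computed from the 40-row snapshot:")
print("ranges, extrema and their chromosome-relative genomic positions.")
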