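"""Convert absolute genome coordinates to chromosome-relative positions.

Genome browsers address the concatenated canonical chromosomes with one
absolute offset; descriptions phrase positions per chromosome instead.
"""

import trackscribe as ts

hg38 = ts.build_assembly("hg38")

pos = 1191936000
rel = ts.abs_to_rel(pos, hg38)
print(f"absolute {pos} on hg38  ->  {rel.chromosome}, position {rel.position}")
print(f"round trip: {ts.rel_to_abs(rel.chromosome, rel.position, hg38)}")
print()
print("A range spanning the whole genome plus an unmapped tail is phrased as:")
print(" ", ts.describe_range(1, hg38.total + 15_000_000, hg38))
print()
print("A range inside one chromosome:")
start, end = ts.rel_to_abs("chr3", 1000, hg38), ts.rel_to_abs("chr3", 2000, hg38)
print(" ", ts.describe_range(start, end, hg38))
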