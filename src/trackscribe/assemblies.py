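"""Bundled chromosome-length tables for common human reference assemblies.

Lengths are the UCSC Genome Browser canonical chromosome sizes
(chrom.sizes), restricted to the canonical set chr1..chr22, chrX, chrY.
Alternate loci, patches and chrM are intentionally excluded: positions on
the concatenated genome beyond the canonical total are treated as
"unmapped" by the coordinate converter.
"""

# chrom -> length in bp, in canonical order
HG38_CHROM_SIZES: dict[str, int] = {
    "chr1": 248956422,
    "chr2": 242193529,
    "chr3": 198295559,
    "chr4": 190214555,
    "chr5": 181538259,
    "chr6": 170805979,
    "chr7": 159345973,
    "chr8": 145138636,
    "chr9": 138394717,
    "chr10": 133797422,
    "chr11": 135086622,
    "chr12": 133275309,
    "chr13": 114364328,
    "chr14": 107043718,
    "chr15": 101991189,
    "chr16": 90338345,
    "chr17": 83257441,
    "chr18": 80373285,
    "chr19": 58617616,
    "chr20": 64444167,
    "chr21": 46709983,
    "chr22": 50818468,
    "chrX": 156040895,
    "chrY": 57227415,
}

HG19_CHROM_SIZES: dict[str, int] = {
    "chr1": 249250621,
    "chr2": 243199373,
    "chr3": 198022430,
    "chr4": 191154276,
    "chr5": 180915260,
    "chr6": 171115067,
    "chr7": 159138663,
    "chr8": 146364022,
    "chr9": 141213431,
    "chr10": 135534747,
    "chr11": 135006516,
    "chr12": 133851895,
    "chr13": 115169878,
    "chr14": 107349540,
    "chr15": 102531392,
    "chr16": 90354753,
    "chr17": 81195210,
    "chr18": 78077248,
    "chr19": 59128983,
    "chr20": 63025520,
    "chr21": 48129895,
    "chr22": 51304566,
    "chrX": 155270560,
    "chrY": 59373566,
}

BUNDLED_ASSEMBLIES: dict[str, dict[str, int]] = {
    "hg38": HG38_CHROM_SIZES,
    "hg19": HG19_CHROM_SIZES,
}
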