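"""Merge two callers' back-splice junctions and classify them genomically.

Caller A and caller B disagree on support; junctions are unified by exact
coordinates, support is the per-sample max, and anything never reaching two
junction reads is dropped. Classes follow the single-gene/exon rules.
"""

import pandas as pd

from cernaforge.annotation import GeneModel, classify_all, merge_junction_calls

genes = [
    GeneModel("PHOT1", "chr1", "+", 100, 1000, exons=[(100, 300), (500, 700), (900, 1000)]),
    GeneModel("SGR2", "chr1", "+", 2000, 2600, exons=[(2000, 2200), (2400, 2600)]),
]

def rows(recs):
    out = []
    for chrom, s, e, name, strand, d4, d6 in recs:
        out.append(dict(chrom=chrom, start=s, end=e, name=name, score=max(d4, d6),
                        strand=strand, Day4=d4, Day6=d6))
    return pd.DataFrame(out)

caller_a = rows([
    ("chr1", 150, 950, "circ_exonic", "+", 3, 0),    # ends in exons of PHOT1
    ("chr1", 320, 480, "circ_intronic", "+", 0, 4),  # inside PHOT1 intron 1
    ("chr1", 1200, 1700, "circ_desert", "+", 2, 2),  # between the genes
    ("chr1", 150, 2500, "circ_twogene", "+", 5, 1),  # spans PHOT1 and SGR2
    ("chr1", 600, 950, "circ_weak", "+", 1, 1),      # never 2 reads: filtered
])
caller_b = rows([("chr1", 150, 950, "circ_exonic", "+", 1, 2)])

junctions = merge_junction_calls({"find_circ": caller_a, "CIRI2": caller_b}, min_reads=2)
classify_all(junctions, genes)
for j in junctions:
    print(f"{j.name:14s} {j.chrom}:{j.start}-{j.end}  support={int(j.junction_reads.max())} "
          f"callers={sorted(j.callers)}  class={j.circ_class:10s} parents={sorted(j.parent_genes)}")
print("\n'circ_weak' is absent: one junction read is indistinguishable from noise.")
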