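"""Delimit an LD block around a focal marker and find candidate genes in it.

The block is every same-chromosome marker with r^2 >= 0.8 against the
focal trait-associated marker; responsive genes overlapping the block
interval become candidate quantitative trait genes (QTGs).
"""

import numpy as np
import pandas as pd

from macetools.qtg import delimit_block, find_qtg, ld_r2
from macetools.synth import SynthConfig, generate_genotypes

print("pairwise r^2 on 4 inbred lines:")
a = np.array([0, 0, 1, 1.0])
print(f"  identical markers -> {ld_r2(a, a):.2f}; "
      f"complementary coding -> {ld_r2(a, 1 - a):.2f}; "
      f"independent -> {ld_r2(a, np.array([0, 1, 0, 1.0])):.2f}")

config = SynthConfig(seed=42)
marker_map, genotypes, truth = generate_genotypes(config)
block = delimit_block("M0001", marker_map, genotypes, r2_min=0.8)
print(f"\nblock around M0001: {len(block.members)} markers on {block.chrom}, "
      f"{block.start:,}-{block.end:,} ({block.length / 1e3:.0f} kb)")
print(f"generator's true block: {truth.block_members['block01']}")

genes = pd.DataFrame(
    {"chrom": block.chrom,
     "start": [block.start + 5_000, block.end + 50_000],
     "end": [block.start + 8_000, block.end + 53_000]},
    index=pd.Index(["inside_gene", "outside_gene"], name="gene_id"),
)
hits = find_qtg([block], genes)
print(f"\ncandidate QTGs (responsive genes overlapping the block): "
      f"{[h.gene_id for h in hits]}")
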