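"""Gene grammar: build a gene by hand, then mine genes from a random genome.

A gene is a TATA box ("1010"), 5-50 four-digit cis-elements, a reserved
kind word, and a kind-specific payload.  Random 100 kb genomes typically
carry on the order of 150-200 genes discovered by the scanner.
"""

from collections import Counter

import numpy as np

from wgdsim import random_genome, scan_genes

# A hand-made regulatory gene: TATA + 5 cis words + regulatory kind word
# + payload (target cis word "2231" + even sign digit -> activator).
hand_made = "1010" + "22313333222211113210" + "0011" + "22310"
(gene,) = scan_genes(hand_made)
print(f"hand-made gene: kind={gene.kind.value} identity={gene.identity} "
      f"span={gene.span}")
# -> a regulatory activator; its product binds the cis word 2231 in other
#    promoters and raises their expression level.

genome = random_genome(100_000, np.random.default_rng(0))
genes = scan_genes(genome)
print(f"\nrandom 100 kb genome: {len(genes)} genes")
for kind, n in sorted(Counter(g.kind.value for g in genes).items()):
    print(f"  {kind:25s} {n}")
# The per-kind counts are roughly uniform over the 13 reserved kind words;
# regulatory genes split ~50/50 into activators and repressors.
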