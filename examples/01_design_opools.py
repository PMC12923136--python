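"""Design a barcoded NNK oPool library for a short coding sequence.

Builds a Hamming-distance-3 barcode codebook, tiles a 75-codon CDS into
three 25-codon fragments, and assembles one degenerate oligo per codon.
"""

import numpy as np

from barcodedms.design import build_full_design, generate_codebook, validate_design
from barcodedms.simulate import random_cds, random_context

rng = np.random.default_rng(1)
cds = random_cds(75, rng, id="demo_cds")
upstream = random_context(rng, 40)
downstream = random_context(rng, 10)

# 75 codons need 150 distinct barcodes (two fixed 12-mers per codon position)
codebook = generate_codebook(k=12, target_size=200, seed=1)
design = build_full_design(
    cds, codebook, upstream_context=upstream, downstream_context=downstream, seed=1
)
report = validate_design(design)

print(f"CDS: {cds.codon_count} codons -> {len(design)} oPools")
for pool in design:
    print(f"  {pool.pool_id}: {len(pool.oligos)} oligos, "
          f"fragment codons {pool.fragment.codon_start}-{pool.fragment.codon_end}")
oligo = design[0].oligos[0]
print(f"example oligo {oligo.name} ({len(oligo.sequence)} nt, "
      f"{oligo.degenerate_count} degenerate positions):")
print(f"  {oligo.sequence}")
print(f"design validation clean: {report.ok}")
# Each oligo is homology + fragment-with-NNK + anchor + BsaI module +
# 30-nt barcode + PBS_i7; 9 degenerate positions = 3 (NNK) + 6 (spacers).
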