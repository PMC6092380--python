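"""lncRNA discovery filters and strand-aware positional classification.

Candidates must exceed 200 nt, lack a long ORF, and not be sense-adjacent
single-exon fragments; survivors are classified against protein-coding genes
as genic (exonic/intronic, full/partial, sense/antisense) or intergenic,
with a 50-kb neighbor search for the intergenic class.
"""

from collections import Counter

from lncweave.genome_classify import classify_all, filter_putative_lncrnas, find_neighbors
from lncweave.synthetic_data import SimulationConfig, generate_genome

cfg = SimulationConfig(seed=1)
annotation, truth = generate_genome(cfg)

retained, rejected = filter_putative_lncrnas(sorted(truth.lnc_class), annotation)
print(f"candidates: {len(truth.lnc_class)}, retained: {len(retained)}, "
      f"rejected: {dict(Counter(rejected.values()))}")

classes = classify_all(retained, annotation)
print("class counts:", dict(Counter(c.category for c in classes.values())))

intergenic = next(t for t, c in classes.items() if c.category == "intergenic"
                  and c.orientation != "not_applicable")
for nb in find_neighbors(intergenic, annotation)[:2]:
    print(f"{intergenic}: {nb.gene_id} {nb.side} at {nb.distance} nt "
          f"({nb.relative_strand})")
# Distances are edge-to-edge gaps; a neighbor at exactly 50,000 nt is still
# inside the window (inclusive boundary).
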