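"""Generate a synthetic divergent-family study with planted ground truth.

The generator emulates a pooled-family muscle RNA-seq design: 98 phenotyped
full-sib families, 22 sequenced pooled libraries, five traits each with a
4-high vs 4-low family contrast, and planted DE transcripts, co-expressed
lncRNA-mRNA pairs, miRNA sponge sites and promoter TF motifs.
"""

from lncweave.synthetic_data import (
    SimulationConfig,
    generate_expression,
    generate_genome,
    generate_phenotypes,
    generate_regulatory,
)

cfg = SimulationConfig(seed=1)
annotation, truth = generate_genome(cfg)
phenotypes, designs = generate_phenotypes(cfg)
counts = generate_expression(annotation, cfg, truth, designs)
mirnas, pwms = generate_regulatory(annotation, cfg, truth)

print(f"genes: {len(annotation.genes)} "
      f"({sum(g.biotype == 'lncRNA' for g in annotation.genes.values())} lncRNA loci)")
print(f"counts matrix: {counts.values.shape[0]} transcripts x "
      f"{counts.values.shape[1]} pooled family libraries")
print(f"phenotyped fish: {len(phenotypes)} in {phenotypes['family'].nunique()} families")
print(f"planted: {len(truth.de_ids())} DE transcripts, {len(truth.pairs)} co-expressed "
      f"pairs, {len(truth.sponges)} sponge triplets, {len(truth.tf_insertions)} TF motifs")
print("\nWBW contrast:", designs["WBW"])
# Every planted element is logged in `truth`, so each downstream stage can be
# scored against exact ground truth rather than eyeballed.
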