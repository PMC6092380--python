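"""Consensus miRNA target calls, sponge triplets and lncRNA:mRNA pairing.

Four internal predictors (seed class, duplex energy <= -13 kcal/mol,
accessibility, pairing pattern) vote per seed-anchored site; >= 3 votes is a
consensus call. A sponge triplet is a network edge whose lncRNA and mRNA
3'UTR both carry consensus sites for the same miRNA.
"""

from lncweave.coexpression import CoexpressionEdge
from lncweave.rna_interactions import (
    duplex_energy,
    find_sponge_candidates,
    lnctar_ndg,
    predict_targets_consensus,
    reverse_complement_rna,
)

mirna = "UAGGUAGUAGGUUGUAUAGUUU"
lncrna = "GGGAUUU" + reverse_complement_rna(mirna) + "CCAUUGGGAAACCCUUUGGGAAACCC"
utr = "AAAUUU" + reverse_complement_rna(mirna) + "GGGCCCAAAUUUGGGCCCAAA"

dg, trace = duplex_energy(mirna, reverse_complement_rna(mirna))
print(f"perfect duplex: dG = {dg:.2f} kcal/mol over {len(trace)} paired positions")

lnc_calls = predict_targets_consensus(mirna, lncrna, mirna_id="mir-x",
                                      target_id="lnc1", target_region="lncRNA_full")
utr_calls = predict_targets_consensus(mirna, utr, mirna_id="mir-x",
                                      target_id="mrnaA", target_region="mRNA_3UTR")
for c in lnc_calls + utr_calls:
    print(f"  {c.target_id}: {c.site_class} site, dG={c.delta_g:.1f}, "
          f"predictors={sorted(c.predictors)}, consensus={c.consensus}")

edge = CoexpressionEdge("lnc1", "mrnaA", r=0.93)
triplets = find_sponge_candidates([edge], lnc_calls + utr_calls)
print(f"sponge triplets: {[(t.lncrna_id, t.mirna_id, t.mrna_id) for t in triplets]}")

res = lnctar_ndg(lncrna, utr * 3, lncrna_id="lnc1", mrna_id="mrnaA")
print(f"lncRNA:mRNA pairing: best dG {res.best_dg:.1f} over {res.window_length} nt, "
      f"ndG = {res.ndg:.3f} ({'pass' if res.passes else 'fail'} at -0.10)")
# ndG normalizes the best gapless duplex energy per overlap nucleotide.
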