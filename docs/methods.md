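# Methods

This note records the models, procedures, parameter defaults and design
choices behind `lncweave`, and what the synthetic study does and does not
establish about real data.

## Study design being modelled

The pipeline targets a pooled-family divergent design: a phenotyped
population of full-sib families (default 98, ~5 fish each), five muscle
traits (whole-body weight WBW, muscle yield as % of WBW, fillet fat %,
Allo-Kramer shear force, fillet whiteness), and one pooled RNA-seq library
per selected family. For each trait the 4 highest- and 4 lowest-ranked
families form a contrast; because extreme families recur across traits, the
union of all selections (default 22 families) is the sequenced set. There
are no fish-level replicates: each library is one pooled family, so a
contrast is 4 libraries vs 4 libraries.

## Phenotypes

Whiteness is derived from CIELAB readings as
`W = 100 − √((100 − L*)² + a*² + b*²)`; it is bounded above by 100 with
equality only at (L*, a*, b*) = (100, 0, 0). Muscle yield and fat scale
with body size, so they are ranked on OLS residuals after regressing family
means on WBW (optionally with categorical fixed effects such as sex or
harvest group, dummy-coded). WBW, shear force and whiteness are ranked on
raw family means. Selection takes the top-k and bottom-k families
(descending order, ties broken by family id, so selection is invariant to
input order). A full mixed model with random family effects would be the
textbook choice for variance decomposition; fixed-effects OLS on family
means reproduces the selection logic exactly and is what is implemented —
heritability estimation is out of scope.

qPCR support is limited to the ΔΔCt fold change
`2^−[(Ct_target,test − Ct_ref,test) − (Ct_target,ctrl − Ct_ref,ctrl)]`.

## Differential expression

Counts, not TPM, are tested. TPM (`rate_i = count_i / length_i`,
rescaled so each column sums to 10⁶) is computed for reporting and for the
co-expression stage; a per-library scaling to the grand-mean column sum is
applied before correlation (a no-op on exact TPM, kept for generality with
externally supplied matrices).

The two-group test is an exact conditional test on the sum of counts per
group. Group sums are modelled as negative binomial — the sum of n iid
NB(μ, φ) libraries is NB(nμ, φ/n) — with group means proportional to total
library size. Conditioning on the grand total gives a discrete distribution
over the split, evaluated by direct summation over the support; at φ = 0 it
reduces exactly to the conditional binomial with success probability
S_A/(S_A+S_B). The two-sided p doubles the smaller tail (observed point
included) and is capped at 1.

The common dispersion is estimated by the method of moments: within each
contrast group, counts are library-size-normalized and
φ̂_t = (s² − m)/m² is computed per transcript; the common value is the
**median** over all per-transcript estimates, floored at 0.01. The median,
rather than a ratio-of-sums pool, is used because a few genuinely
high-variance transcripts (e.g. strongly co-regulated ones) otherwise
dominate the pooled numerator and destroy power for everything else.
Tagwise shrinkage is out of scope.

Fold changes use the signed convention (ratios < 1 reported as −1/ratio)
with a pseudo-count of 0.5 added to the size-normalized group means only
(never to the test). A transcript is DE at BH q < 0.05 **and** FC ≥ 2 or
≤ −2; both thresholds are inclusive on FC and strict on q. FDR is
controlled per contrast, and transcripts with zero counts in both groups
are excluded from the test and from the BH family size; the choice of
per-contrast FDR is recorded in every output header.

## lncRNA discovery and positional classification

Discovery filters: spliced length > 200 nt; a coding-potential proxy
(longest ATG-initiated ORF over the three forward frames < 100 codons,
configurable — dedicated coding-potential classifiers are cited tools with
unpublished internals, so a transparent proxy is used); removal of
single-exon transcripts lying in sense orientation within 500 nt
(edge-to-edge; overlap counts as 0) of a protein-coding gene, which are
typically assembly fragments. Membership in other noncoding classes
(rRNA/tRNA) is accepted as a user-supplied exclusion list rather than
recomputed, since that requires covariance-model databases.

Classification is against protein-coding **gene spans**, with the exon
union over a gene's transcripts deciding exonic vs intronic: a lncRNA is
`genic_exonic` if ≥ 1 nt overlaps any exon, `genic_intronic` if it overlaps
the gene span but no exon, `intergenic` otherwise. Overlap is `full` when
the lncRNA span lies inside some partner's span. Orientation is sense or
antisense relative to the partner that sets the category (exonic beats
intronic; ties by gene id); intergenic lncRNAs take their orientation from
the nearest coding neighbor within the 50-kb window when one exists, else
`not_applicable`. Neighbor distances are edge-to-edge gaps, the window
boundary is inclusive (a gap of exactly 50,000 nt counts), and touching
spans have distance 0 but are not overlapping. Distances "upstream" and
"downstream" are relative to the lncRNA's strand. All positional logic is
validated against a per-base set-intersection oracle on random genomes.

## Co-expression network

For every (DE lncRNA, protein-coding transcript) pair with computable
correlation, the standard product-moment Pearson r across **all** family
libraries (not just the contrast families) is computed on scaled TPM;
zero-variance transcripts are excluded. Edges keep positive correlations at
R ≥ 0.85 (inclusive). Each edge is typed: `overlapping` if the mRNA's gene
is an overlap partner of the lncRNA, `neighbor_cis` if it is within the
50-kb neighbor list (distance reported), else `trans` (including other
contigs). No p-values or multiplicity control are applied to edges. The
implementation is a standardized matrix product, verified against an
all-pairs `corrcoef` scan.

## miRNA targets, sponges, lncRNA:mRNA pairing

**Duplex energy.** ΔG is minimized over all gapless antiparallel
alignments of the two strands. Adjacent paired positions contribute a
37 °C nearest-neighbor stack energy (Watson–Crick values from the standard
Turner set; G·U wobble entries follow the published wobble parameters),
unpaired positions contribute 0, and the table is embedded as data with a
canonical-lookup symmetry `E(p,q) = E(rev q, rev p)` so strand swapping
cannot change the energy. Bulges and internal loops are deliberately out of
model: gapless duplexes keep an exact enumeration oracle feasible, at the
cost of underestimating affinity for bulged sites — a documented
limitation, acceptable because every threshold in the pipeline is applied
to the same gapless score.

**Seed sites.** The target is scanned for the reverse complement of miRNA
positions 2–7; matches upgrade to 7mer-m8 (position 8 pairs the base 5′ of
the core), 7mer-A1 (an A opposite position 1), or 8mer (both). Coordinates
are 0-based half-open on the target.

**Consensus.** Four internal predictors vote per seed-anchored site: seed
(any seed class), energy (full-site duplex ΔG ≤ −13 kcal/mol, strict),
accessibility (ΔΔG = ΔG − 0.2 kcal/mol/nt × window length ≤ −10 kcal/mol,
the sign convention kept as specified), and pattern (≥ 11 paired positions
with ≤ 1 unpaired seed position in the best trace). A site is a consensus
call with ≥ 3 votes. This preserves the multi-tool voting architecture and
shared energy floor of public consensus servers whose individual tools are
not re-implementable from their descriptions; lncRNAs are scanned over
their full sequence, mRNAs over the 3′UTR only.

**Sponges.** A sponge triplet is emitted for every network edge whose
lncRNA and mRNA both carry a consensus site for the same miRNA; every
emitted triplet is certifiable by re-checking edge membership and both
sites.

**lncRNA:mRNA pairing.** The shorter sequence slides along the longer at
full overlap in 1-nt steps; each offset is scored as a fixed gapless
duplex, and ndG = best ΔG / overlap length with a pass at ndG ≤ −0.10
(inclusive). The `window` argument is a minimum-overlap guard (≥ 20 nt).
Reported reference values for this statistic in the literature are
internally inconsistent (a normalization by 2 rather than by length would
be needed to reproduce them, which contradicts a −0.10 cutoff scale), so
the per-nucleotide normalization is implemented and those two worked
numbers are not reproduced. Note that for long random sequences the
expected gapless ΔG grows linearly with overlap (~9/64 of adjacent
positions form stacked pairs by chance), so long pairs essentially always
pass the −0.10/nt cutoff; the statistic is only discriminative for short
windows.

## Promoter TFBS

A promoter is the 500 nt immediately upstream of the gene's TSS on its
strand (reverse-complemented for − genes), truncated — never padded — at
contig ends; an empty promoter is a warning, not an error. PWMs are built
from count matrices with pseudo-count 1 and log₂-odds weights against an
iid background (uniform by default). Both strands are scanned (exposed as a
flag; the choice is not documented in the source protocol). A hit requires
dissimilarity = 100·(max − score)/(max − min) ≤ 5% **and** RE < 0.05,
where RE is the expected number of windows in this promoter (both strands)
scoring at least as high under the background — computed from the exact
score distribution by dynamic programming with scores binned at 1e−9, not
by simulation. The shipped 26-TF set (myogenin, MyoD, MEF-2C, SRF, …) is
synthetic, for testing only: licensed matrix libraries cannot be
redistributed, so the artifact takes PWMs as input files.

## Enrichment

One-sided hypergeometric over-representation (upper tail at the observed
overlap) per term against a user-supplied term → gene map, intersected
with the universe; the universe defaults to the expressed protein-coding
transcripts of the run (standard practice; the source protocol does not
state its background). BH q-values over all tested terms. Terms with
q < 0.05 become nodes of the enrichment map, joined when the overlap
coefficient |A∩B|/min(|A|,|B|) is ≥ 0.5 (inclusive); no GO-hierarchy
propagation is performed.

## Synthetic data generator

The generator is first-class, tested code and the source of every test
fixture. Defaults are the study conditions: 2 contigs, 120 coding genes
(3–5 exons of 150–400 nt, introns 700–1300 nt, a 150-nt 3′UTR in the
terminal exon), 80 lncRNAs in class proportions 9% exonic / 20% intronic /
71% intergenic (antisense fraction 0.5; 80% of intergenic lncRNAs have a
coding neighbor within 50 kb, the rest sit in a ≥ 60-kb desert), 98
families / 22 sequenced / 5 fish each, NB dispersion φ = 0.1, lognormal
library-size factors (σ = 0.15, ≈ ±30%), 35 planted DE transcripts plus 8
planted co-expressed pairs at fold change 4, 12 miRNAs of 21 nt, 4 sponge
triplets, 26 PWMs with 6 planted promoter insertions.

Layout discipline makes classes exact by construction: each coding gene
owns a 14-kb slot; exonic lncRNAs cross an internal exon (full) or the
terminal exon extending past the gene end (partial); intronic lncRNAs sit
wholly inside an intron; near-intergenic lncRNAs are placed strictly closer
to their host than to the next gene so the truth orientation is
unambiguous. All lncRNAs get two exons, so the single-exon filter never
removes planted structure. ORFs ≥ 100 codons in lncRNAs are broken by
writing TAA into the first free codon (TAA cannot create an ATG, so this
terminates), with planted sites and motifs protected by a reservation
registry.

Phenotypes: WBW is the driver; muscle yield and fat regress on the
unshifted growth potential at configurable R² (defaults 0.56 and 0.50),
shear force and whiteness at 0.18 and 0.01; whiteness is derived row-wise
from generated L*, a*, b*. Designated contrast families receive a ±8
family-SD effect shift (the WBW shift goes only into the recorded WBW
column so it cannot leak into other traits' rankings); this is deliberately
larger than real divergent selection would produce, so that ranking the
generated data recovers the configured contrast sets deterministically.
Setting `trait_shift_sd = 0` gives a pure calibration surface on which the
fitted R² values match the configured ones.

Expression: counts ~ NB(μ, φ) with μ = baseline × library factor; planted
DE multiplies μ by the fold change in the trait's high (or low) families.
Planted co-expressed pairs are made DE in the same trait and direction
(co-regulation, as observed for overlapping DE pairs) and share a lognormal
latent factor exp(σz − σ²/2) with corr(z₁, z₂) = 0.95 and σ = 2.5 — the
value that maximizes the expected raw-scale Pearson transfer in a
Monte-Carlo scan of σ ∈ [0.8, 3.5] (see Limitations).

Sponge sites are the reverse complement of the **full** miRNA (position 1
forced to U, so the seed region is a canonical 8mer with an A opposite
position 1), written inside a single lncRNA exon and into the mRNA 3′UTR;
full-length sites make the energy and pattern predictors pass
deterministically, so triplet recovery does not depend on sequence luck.
TF insertions write the PWM consensus at a logged promoter offset.

Determinism: every stage draws from its own substream
`default_rng([seed, crc32(stage)])`, so adding a stage never perturbs
another stage's draws, and a fixed seed reproduces every output file byte
for byte.

What the generator does **not** emulate: read-level noise and mapping
artifacts, alternative splicing, GC/length biases, batch effects,
population structure among families, realistic motif degeneracy, or
conservation signal. Passing tests therefore establish correctness of the
analysis logic under the stated stochastic model, not performance on real
libraries.

## Numerical choices

- Internal coordinates are 0-based half-open everywhere; GFF3's 1-based
  closed convention is converted exactly once at the file boundary.
- Gene strand "." is rejected — sense/antisense logic requires a strand.
- The conditional NB distribution is computed in log-space and normalized
  before tail summation; totals are conditioned as integers.
- PWM score-distribution DP bins scores at 1e−9; TPM matrices are written
  at 10 significant digits so column sums survive a read round-trip at the
  1e−6 relative tolerance.
- Ties everywhere (ranking, neighbor sort, partner choice) break on
  lexicographic ids, making all outputs order-independent.

## Limitations

- **Raw-scale Pearson recovery of planted pairs is bounded.** With NB
  dispersion φ = 0.1, a latent correlation of 0.95, and 22 libraries, the
  population correlation between two planted counts profiles is capped
  near 0.83 for every latent scale σ (the NB noise contributes unshared
  variance φ·e^{σ²} that grows with the signal, and the lognormal
  transform damps the shared fraction by e^{−(1−ρ)σ²}); even a perfectly
  shared latent caps at 1/(1+φ) ≈ 0.91. In Monte-Carlo, at most ~2/3 of
  planted pairs clear the R ≥ 0.85 edge threshold in any configuration, so
  a typical default run recovers 5–6 of 8 planted pairs and a
  corresponding fraction of sponge triplets. This is a property of
  thresholded raw-scale correlation under multiplicative counting noise,
  not of the implementation; log-scale correlation would transfer ~0.95 of
  pairs but is not what this pipeline (or the protocol it implements)
  computes.
- Gapless duplexes underestimate affinity of bulged miRNA sites; the
  consensus vote partially compensates via the seed and pattern predictors.
- The ndG statistic saturates for long overlaps (see above).
- The coding-potential proxy is cruder than dedicated classifiers; its
  threshold is configurable.
- Family selection assumes complete phenotype tables; missing values are
  an error, not imputed.
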