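"""Synthetic genomes, counts, phenotypes and regulatory elements with ground truth.

The generator emulates the study design every downstream stage expects:
22 pooled full-sib family libraries drawn from a 98-family phenotyped
population, five traits each contrasting 4 high- against 4 low-ranked
families, negative-binomially distributed counts with planted >= 2-fold
differential expression, planted co-expressed lncRNA-mRNA pairs driven by a
shared lognormal latent factor, planted sponge triplets (a perfect-
complement miRNA site written into both the lncRNA and the partner mRNA
3'UTR) and transcription-factor consensus motifs written into selected
500-nt promoters.  Everything planted is logged in :class:`GroundTruth`;
no planted structure exists outside it.  All draws derive from per-stage
substreams of a single seed, so outputs are byte-identical under a fixed
seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_classify import MAX_ORF_CODONS, STOP_CODONS
from .io_formats import ExpressionMatrix, Gene, GenomeAnnotation, Transcript
from .phenotype import whiteness_index
from .tfbs import MUSCLE_TF_NAMES, PWM

TRAITS = ("WBW", "muscle_yield", "fat", "shear_force", "whiteness")
_DNA_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_COMP_TABLE = bytes.maketrans(b"ACGT", b"TGCA")


def _substream(seed: int, stage: str) -> np.random.Generator:
    """Independent per-stage RNG substream (stage-name CRC mixed with the seed)."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stage.encode())])


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the emulated study conditions."""

    seed: int = 0
    # genome
    n_contigs: int = 2
    contig_length: int | None = None  # auto-sized when None
    n_coding: int = 120
    n_lnc: int = 80
    class_proportions: dict = field(
        default_factory=lambda: {"exonic": 0.09, "intronic": 0.20, "intergenic": 0.71}
    )
    antisense_fraction: float = 0.5
    intergenic_near_fraction: float = 0.8  # has a coding neighbor within 50 kb
    # families / traits
    n_families: int = 98  # phenotyped population
    n_sequenced: int = 22  # pooled RNA-seq libraries
    n_fish_per_family: int = 5
    families_per_tail: int = 4
    # expression
    n_de_lnc: int = 20
    n_de_coding: int = 15
    fold_change: float = 4.0
    dispersion: float = 0.1
    libsize_sigma: float = 0.15  # lognormal sd of library-size factors (~+/-30%)
    # co-expression
    n_pairs: int = 8
    latent_rho: float = 0.95
    latent_sigma: float = 2.5
    # regulatory
    n_mirnas: int = 12
    mirna_length: int = 21
    n_sponge: int = 4
    n_tfs: int = 26
    n_tf_pairs: int = 3  # pairs receiving the same TF motif in both promoters
    # phenotype calibration (coefficient of determination vs WBW)
    r2_vs_wbw: dict = field(
        default_factory=lambda: {
            "muscle_yield": 0.56, "fat": 0.50, "shear_force": 0.18, "whiteness": 0.01,
        }
    )
    trait_shift_sd: float = 8.0  # planted family-effect shift, in family-SD units

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.fold_change < 1:
            raise ValueError("fold change must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_de_lnc > self.n_lnc or self.n_de_coding > self.n_coding:
            raise ValueError("planted DE counts exceed transcript totals")
        if self.n_pairs > min(self.n_de_lnc, self.n_coding) and self.n_pairs > 0:
            raise ValueError("planted pair count exceeds available transcripts")
        if self.n_sponge > self.n_pairs or self.n_sponge > self.n_mirnas:
            raise ValueError("planted sponge count exceeds pairs or miRNAs")
        if self.n_sequenced > self.n_families:
            raise ValueError("more sequenced families than phenotyped families")

    def class_counts(self) -> dict[str, int]:
        """Integer class targets; remainder goes to the intergenic class."""
        n_ex = int(round(self.n_lnc * self.class_proportions["exonic"]))
        n_in = int(round(self.n_lnc * self.class_proportions["intronic"]))
        return {"exonic": n_ex, "intronic": n_in, "intergenic": self.n_lnc - n_ex - n_in}


@dataclass
class GroundTruth:
    lnc_class: dict[str, dict] = field(default_factory=dict)  # tid -> class record
    trait_families: dict[str, dict] = field(default_factory=dict)  # trait -> {high, low}
    de: dict[str, dict[str, int]] = field(default_factory=dict)  # trait -> {tid: +1/-1}
    pairs: list[dict] = field(default_factory=list)  # planted co-expressed pairs
    sponges: list[dict] = field(default_factory=list)  # lnc/mirna/mrna + site coords
    tf_insertions: list[dict] = field(default_factory=list)  # tf/gene/promoter offset

    def de_ids(self) -> set[str]:
        return {tid for d in self.de.values() for tid in d}


# -- genome sequence editing ----------------------------------------------


class _GenomeEditor:
    """Mutable view of contig sequences plus a registry of protected intervals."""

    def __init__(self, annotation: GenomeAnnotation):
        self.ann = annotation
        self.buf = {cid: bytearray(seq, "ascii") for cid, seq in annotation.contigs.items()}
        self.reserved: dict[str, list[tuple[int, int]]] = {}

    def flush(self) -> None:
        self.ann.contigs = {cid: b.decode("ascii") for cid, b in self.buf.items()}

    def reserve(self, contig: str, start: int, end: int) -> None:
        self.reserved.setdefault(contig, []).append((start, end))

    def overlaps_reserved(self, contig: str, start: int, end: int) -> bool:
        return any(start < e and end > s for s, e in self.reserved.get(contig, []))

    def tx_positions(self, tid: str) -> np.ndarray:
        """Genome position of every transcript base, in transcript 5'->3' order."""
        t = self.ann.transcripts[tid]
        g = self.ann.genes[t.gene_id]
        pos = np.concatenate([np.arange(s, e) for s, e in t.exons])
        return pos[::-1] if g.strand == "-" else pos

    def tx_seq(self, tid: str) -> str:
        t = self.ann.transcripts[tid]
        g = self.ann.genes[t.gene_id]
        raw = b"".join(bytes(self.buf[g.contig][s:e]) for s, e in t.exons)
        if g.strand == "-":
            raw = raw.translate(_COMP_TABLE)[::-1]
        return raw.decode("ascii")

    def write_tx(self, tid: str, offset: int, subseq: str, reserve: bool = False) -> None:
        """Overwrite genome bases so transcript ``tid`` reads ``subseq`` at ``offset``."""
        t = self.ann.transcripts[tid]
        g = self.ann.genes[t.gene_id]
        positions = self.tx_positions(tid)
        if offset < 0 or offset + len(subseq) > len(positions):
            raise ValueError(f"site longer than target {tid}")
        buf = self.buf[g.contig]
        touched = positions[offset : offset + len(subseq)]
        for p, base in zip(touched, subseq):
            buf[int(p)] = ord(base if g.strand == "+" else _COMP[base])
        if reserve:
            self.reserve(g.contig, int(touched.min()), int(touched.max()) + 1)

    def write_genome(self, contig: str, start: int, seq: str, reserve: bool = False) -> None:
        self.buf[contig][start : start + len(seq)] = seq.encode("ascii")
        if reserve:
            self.reserve(contig, start, start + len(seq))


def _longest_orf_span(seq: str) -> tuple[int, int] | None:
    """(start, codons) of the longest forward-frame ATG-initiated ORF, or None."""
    best: tuple[int, int] | None = None
    for frame in range(3):
        i = frame
        while i + 3 <= len(seq):
            if seq[i : i + 3] == "ATG":
                codons = 0
                j = i
                while j + 3 <= len(seq):
                    if seq[j : j + 3] in STOP_CODONS:
                        break
                    codons += 1
                    j += 3
                if best is None or codons > best[1]:
                    best = (i, codons)
                i = j + 3
            else:
                i += 3
    return best


def _scrub_orfs(editor: _GenomeEditor, lnc_ids: list[str], limit: int = MAX_ORF_CODONS) -> None:
    """Break ORFs >= ``limit`` codons in lncRNA transcripts by writing stop codons.

    The stop codon goes into the first codon of the offending ORF whose
    genome bases are not reserved (planted miRNA sites and TF motifs stay
    intact).  Writing TAA can never create an ATG, so this terminates.
    """
    for tid in sorted(lnc_ids):
        g = editor.ann.genes[editor.ann.transcripts[tid].gene_id]
        positions = editor.tx_positions(tid)
        for _ in range(200):
            orf = _longest_orf_span(editor.tx_seq(tid))
            if orf is None or orf[1] < limit:
                break
            start, codons = orf
            placed = False
            for c in range(1, codons):
                o = start + 3 * c
                gpos = positions[o : o + 3]
                lo, hi = int(gpos.min()), int(gpos.max()) + 1
                if editor.overlaps_reserved(g.contig, lo, hi):
                    continue
                editor.write_tx(tid, o, "TAA")
                placed = True
                break
            if not placed:
                raise ValueError(f"cannot scrub ORF in {tid}: fully reserved")
        else:
            raise ValueError(f"ORF scrubbing did not converge for {tid}")


# -- genome ----------------------------------------------------------------

_SLOT = 14_000  # per-coding-gene slot, leaves room for genic + nearby lncRNAs
_DESERT_MARGIN = 60_000  # gene-free margin before far-intergenic lncRNAs


def _make_coding_gene(rng, gid, tid, contig, start, strand):
    """Multi-exon gene with a 150-nt 3'UTR in the terminal exon."""
    n_exons = int(rng.integers(3, 6))
    exon_lens = rng.integers(150, 401, n_exons)
    intron_lens = rng.integers(700, 1301, n_exons - 1)
    exons = []
    pos = start
    for i in range(n_exons):
        exons.append((pos, pos + int(exon_lens[i])))
        pos += int(exon_lens[i])
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    end = exons[-1][1]
    if strand == "+":
        utr3 = (exons[-1][1] - 150, exons[-1][1])
    else:
        utr3 = (exons[0][0], exons[0][0] + 150)
    return Gene(gid, contig, strand, start, end, "protein_coding"), Transcript(tid, gid, exons, utr3=utr3)


def _two_exon_spans(rng, start, end):
    """Split [start, end) into two exons separated by a small intron."""
    length = end - start
    e1 = int(rng.integers(max(80, length // 4), max(81, length // 2)))
    intron = int(rng.integers(40, 80))
    return [(start, start + e1), (start + e1 + intron, end)]


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def generate_genome(config: SimulationConfig) -> tuple[GenomeAnnotation, GroundTruth]:
    """Place coding genes and lncRNAs so every requested class is realized exactly.

    Raises a sizing error when a fixed ``contig_length`` cannot hold the
    requested features; with the default auto-sizing, contigs are cut to fit.
    """
    rng = _substream(config.seed, "genome")
    counts = config.class_counts()
    n_near = int(round(counts["intergenic"] * config.intergenic_near_fraction))
    n_far = counts["intergenic"] - n_near

    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}
    truth = GroundTruth()

    per_contig = [config.n_coding // config.n_contigs] * config.n_contigs
    for i in range(config.n_coding % config.n_contigs):
        per_contig[i] += 1
    far_per_contig = [n_far // config.n_contigs] * config.n_contigs
    for i in range(n_far % config.n_contigs):
        far_per_contig[i] += 1

    coding: list[tuple[Gene, Transcript]] = []
    contig_cursor: dict[str, int] = {}
    gi = 0
    for ci in range(config.n_contigs):
        contig = f"contig{ci + 1}"
        cursor = int(rng.integers(2_000, 4_000))
        for _ in range(per_contig[ci]):
            gi += 1
            strand = "+" if rng.random() < 0.5 else "-"
            gene, tx = _make_coding_gene(rng, f"pcg{gi:04d}", f"mrna{gi:04d}", contig, cursor, strand)
            genes[gene.gene_id] = gene
            transcripts[tx.transcript_id] = tx
            coding.append((gene, tx))
            cursor = gene.start + _SLOT
        contig_cursor[contig] = cursor

    n_genic_slots = counts["exonic"] + counts["intronic"] + n_near
    if n_genic_slots > len(coding):
        raise ValueError(
            f"{n_genic_slots} host-anchored lncRNAs requested but only "
            f"{len(coding)} coding genes available; increase n_coding"
        )
    host_order = list(rng.permutation(len(coding)))
    host_iter = iter(host_order)

    li = 0

    def add_lnc(contig, strand, spans, category, overlap, orientation, partner=None):
        nonlocal li
        li += 1
        gid, tid = f"lncg{li:04d}", f"lnc{li:04d}"
        genes[gid] = Gene(gid, contig, strand, spans[0][0], spans[-1][1], "lncRNA")
        transcripts[tid] = Transcript(tid, gid, spans)
        truth.lnc_class[tid] = {
            "category": category, "overlap": overlap, "orientation": orientation,
            "partner": partner,
        }
        return tid

    # exonic: alternate fully-contained (crossing an internal exon) and
    # partial (crossing the terminal exon, extending past the gene end)
    for j in range(counts["exonic"]):
        host, htx = coding[next(host_iter)]
        anti = rng.random() < config.antisense_fraction
        strand = _flip(host.strand) if anti else host.strand
        full = j % 2 == 0
        if full:
            ex = htx.exons[1]
            start = max(host.start + 1, ex[0] - int(rng.integers(100, 200)))
            end = min(host.end - 1, ex[1] + int(rng.integers(100, 200)))
        else:
            ex = htx.exons[-1]
            start = ex[0] + int(rng.integers(20, 80))
            end = host.end + int(rng.integers(300, 500))
        add_lnc(
            host.contig, strand, _two_exon_spans(rng, start, end),
            "genic_exonic", "full" if full else "partial",
            "antisense" if anti else "sense", partner=host.gene_id,
        )

    # intronic: wholly inside an intron of the host (always full containment)
    for _ in range(counts["intronic"]):
        host, htx = coding[next(host_iter)]
        introns = [
            (htx.exons[k][1], htx.exons[k + 1][0])
            for k in range(len(htx.exons) - 1)
            if htx.exons[k + 1][0] - htx.exons[k][1] >= 500
        ]
        if not introns:
            raise ValueError(f"no intron of {host.gene_id} can host an intronic lncRNA")
        intron = introns[int(rng.integers(len(introns)))]
        start = intron[0] + int(rng.integers(10, 60))
        end = intron[1] - int(rng.integers(10, 60))
        anti = rng.random() < config.antisense_fraction
        add_lnc(
            host.contig, _flip(host.strand) if anti else host.strand,
            _two_exon_spans(rng, start, end),
            "genic_intronic", "full", "antisense" if anti else "sense",
            partner=host.gene_id,
        )

    # intergenic with a neighbor within 50 kb: in the gap downstream of a
    # slot, strictly closer to its host than to the next slot's gene so the
    # host defines the truth orientation
    for _ in range(n_near):
        host, htx = coding[next(host_iter)]
        length = int(rng.integers(400, 900))
        host_len = host.end - host.start
        gap_cap = (_SLOT - host_len - length) // 2
        gap = int(rng.integers(800, min(2_400, gap_cap)))
        start = host.end + gap
        end = start + length
        anti = rng.random() < config.antisense_fraction
        add_lnc(
            host.contig, _flip(host.strand) if anti else host.strand,
            _two_exon_spans(rng, start, end),
            "intergenic", "none", "antisense" if anti else "sense", partner=None,
        )

    # far intergenic: in a desert >= 60 kb beyond the last gene of the contig
    contig_end: dict[str, int] = dict(contig_cursor)
    for ci in range(config.n_contigs):
        if far_per_contig[ci] == 0:
            continue
        contig = f"contig{ci + 1}"
        pos = contig_cursor[contig] + _DESERT_MARGIN
        for _ in range(far_per_contig[ci]):
            start = pos
            end = start + int(rng.integers(400, 900))
            add_lnc(
                contig, "+" if rng.random() < 0.5 else "-",
                _two_exon_spans(rng, start, end),
                "intergenic", "none", "not_applicable", partner=None,
            )
            pos = end + int(rng.integers(1_000, 2_000))
        contig_end[contig] = pos

    contigs: dict[str, str] = {}
    for ci in range(config.n_contigs):
        contig = f"contig{ci + 1}"
        needed = contig_end[contig] + 10_000
        length = config.contig_length if config.contig_length is not None else needed
        if length < needed:
            raise ValueError(
                f"contig_length {length} too short: {contig} needs {needed} nt "
                "for the requested features"
            )
        contigs[contig] = _DNA_BYTES[rng.integers(0, 4, length)].tobytes().decode("ascii")

    annotation = GenomeAnnotation(contigs=contigs, genes=genes, transcripts=transcripts)
    editor = _GenomeEditor(annotation)
    _scrub_orfs(editor, [t for t in transcripts if t.startswith("lnc")])
    editor.flush()
    return annotation, truth


# -- trait designs ---------------------------------------------------------


def assign_trait_families(config: SimulationConfig) -> tuple[list[str], dict[str, dict]]:
    """Deterministic 4-vs-4 family sets per trait over the sequenced pool.

    Every sequenced family appears in at least one contrast, so the union
    of the per-trait selections is exactly the sequenced set, as in a
    pooled design where shared extreme families are sequenced once.
    """
    families = [f"F{i + 1:02d}" for i in range(config.n_families)]
    rng = _substream(config.seed, "design")
    pool = sorted(rng.choice(config.n_families, size=config.n_sequenced, replace=False))
    pool_ids = [families[i] for i in pool]
    k = config.families_per_tail
    designs: dict[str, dict] = {}
    for t, trait in enumerate(TRAITS):
        slots = [pool_ids[(2 * k * t + j) % len(pool_ids)] for j in range(2 * k)]
        if len(set(slots)) < len(slots):
            raise ValueError("sequenced pool too small for disjoint high/low sets")
        designs[trait] = {"high": slots[:k], "low": slots[k:]}
    return families, designs


# -- phenotypes ------------------------------------------------------------

_TRAIT_BASE = {
    "WBW": (985.0, 140.0, 180.0),  # mean, family SD, fish SD (g)
    "muscle_yield": (47.0, 1.3, 1.2),  # % of WBW
    "fat": (8.0, 0.9, 0.8),  # % of fillet
    "shear_force": (520.0, 45.0, 40.0),  # g/g sample
}
_LAB_BASE = {"L": (45.0, 1.6, 1.4), "a": (3.0, 0.6, 0.5), "b": (10.0, 1.0, 0.9)}


def generate_phenotypes(
    config: SimulationConfig, designs: dict[str, dict] | None = None
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Per-fish phenotype table with planted divergent family effects.

    WBW is the driver: muscle yield and fat regress on it at the configured
    R-squared, shear force and whiteness are nearly independent of it, and
    whiteness is derived row-wise from generated L*, a*, b* readings.  The
    designated contrast families additionally receive a +/- family-effect
    shift (``trait_shift_sd`` family SDs; set 0 for a pure calibration run)
    so that ranking the generated data recovers the configured sets.
    """
    families, auto_designs = assign_trait_families(config)
    designs = designs or auto_designs
    rng = _substream(config.seed, "phenotype")
    nf, npf = config.n_families, config.n_fish_per_family
    idx = {f: i for i, f in enumerate(families)}

    def shift(trait, fam_sd):
        s = np.zeros(nf)
        for f in designs[trait]["high"]:
            s[idx[f]] += config.trait_shift_sd * fam_sd
        for f in designs[trait]["low"]:
            s[idx[f]] -= config.trait_shift_sd * fam_sd
        return s

    # other traits regress on the unshifted growth potential; the recorded
    # WBW column additionally carries the WBW contrast shift, so the WBW
    # contrast cannot leak into the other traits' rankings
    mu_w, fsd_w, isd_w = _TRAIT_BASE["WBW"]
    wbw_fam = mu_w + fsd_w * rng.standard_normal(nf)
    wbw = np.repeat(wbw_fam, npf) + isd_w * rng.standard_normal(nf * npf)
    wbw_sd = np.hypot(fsd_w, isd_w)

    cols: dict[str, np.ndarray] = {
        "family": np.repeat(families, npf),
        "fish": np.array([f"fish{i + 1}" for i in range(nf * npf)]),
        "WBW": np.round(wbw + np.repeat(shift("WBW", fsd_w), npf), 1),
    }

    for trait in ("muscle_yield", "fat", "shear_force"):
        mu, fam_sd, fish_sd = _TRAIT_BASE[trait]
        total_sd = np.hypot(fam_sd, fish_sd)
        r2 = config.r2_vs_wbw[trait]
        slope = np.sqrt(r2) * total_sd / wbw_sd
        resid_sd = np.sqrt(max(1e-12, 1.0 - r2)) * total_sd
        fam_part = np.repeat(
            shift(trait, fam_sd) + (fam_sd / total_sd) * resid_sd * rng.standard_normal(nf), npf
        )
        fish_part = (fish_sd / total_sd) * resid_sd * rng.standard_normal(nf * npf)
        vals = mu + slope * (wbw - wbw.mean()) + fam_part + fish_part
        cols[trait] = np.round(np.clip(vals, 0.1, None), 2)

    # CIELAB channels; whiteness inherits its (small) WBW dependence through L*
    lab: dict[str, np.ndarray] = {}
    for ch, (mu, fam_sd, fish_sd) in _LAB_BASE.items():
        fam = np.repeat(fam_sd * rng.standard_normal(nf), npf)
        lab[ch] = mu + fam + fish_sd * rng.standard_normal(nf * npf)
    r2w = config.r2_vs_wbw["whiteness"]
    lab["L"] = (
        lab["L"]
        + np.sqrt(r2w) * _LAB_BASE["L"][1] / wbw_sd * (wbw - wbw.mean())
        + np.repeat(shift("whiteness", _LAB_BASE["L"][1]), npf)
    )
    for ch in ("L", "a", "b"):
        cols[ch] = np.round(lab[ch], 2)
    cols["whiteness"] = np.round(whiteness_index(cols["L"], cols["a"], cols["b"]), 4)
    return pd.DataFrame(cols), designs


# -- expression ------------------------------------------------------------


def generate_expression(
    annotation: GenomeAnnotation,
    config: SimulationConfig,
    truth: GroundTruth,
    designs: dict[str, dict] | None = None,
) -> ExpressionMatrix:
    """NB counts over the sequenced family libraries, with planted structure.

    Planted DE transcripts get the configured fold change in their trait's
    high (direction +1) or low (direction -1) families.  Planted
    co-expressed pairs are DE in the same trait and direction and share a
    lognormal latent factor with correlation ``latent_rho``.  Updates
    ``truth`` in place and returns the counts matrix.
    """
    _, auto_designs = assign_trait_families(config)
    designs = designs or auto_designs
    truth.trait_families = designs
    all_fams = {f"F{i + 1:02d}" for i in range(config.n_families)}
    for trait, d in designs.items():
        unknown = (set(d["high"]) | set(d["low"])) - all_fams
        if unknown:
            raise ValueError(f"trait {trait} references unknown families: {sorted(unknown)}")

    libraries = sorted({f for d in designs.values() for f in d["high"] + d["low"]})
    rng = _substream(config.seed, "expression")

    biotype_of = {
        tid: annotation.genes[tx.gene_id].biotype for tid, tx in annotation.transcripts.items()
    }
    lnc_ids = sorted(t for t, b in biotype_of.items() if b == "lncRNA")
    cod_ids = sorted(t for t, b in biotype_of.items() if b == "protein_coding")
    ids = cod_ids + lnc_ids
    n, m = len(ids), len(libraries)
    idx = {tid: i for i, tid in enumerate(ids)}

    baseline = rng.lognormal(mean=np.log(40.0), sigma=1.0, size=n)
    libfactor = rng.lognormal(mean=0.0, sigma=config.libsize_sigma, size=m)

    de_lnc = list(rng.choice(lnc_ids, size=config.n_de_lnc, replace=False)) if config.n_de_lnc else []
    de_cod = list(rng.choice(cod_ids, size=config.n_de_coding, replace=False)) if config.n_de_coding else []
    for tid in de_lnc + de_cod:
        baseline[idx[tid]] = rng.uniform(80.0, 300.0)

    truth.de = {t: {} for t in TRAITS}
    for j, tid in enumerate(de_lnc):
        truth.de[TRAITS[j % len(TRAITS)]][tid] = 1 if j % 2 == 0 else -1
    for j, tid in enumerate(de_cod):
        truth.de[TRAITS[j % len(TRAITS)]][tid] = 1 if j % 2 == 0 else -1

    # planted co-expressed pairs: lnc from the DE set; the mRNA partner is
    # made DE in the same trait and direction (co-regulated, as observed for
    # overlapping DE pairs) and both share the latent factor below
    truth.pairs = []
    if config.n_pairs:
        pair_lnc = de_lnc[: config.n_pairs]
        free_cod = [c for c in cod_ids if c not in de_cod]
        pair_mrna = list(rng.choice(free_cod, size=config.n_pairs, replace=False))
        for lnc, mrna in zip(pair_lnc, pair_mrna):
            trait = next(t for t in TRAITS if lnc in truth.de[t])
            direction = truth.de[trait][lnc]
            truth.de[trait][mrna] = direction
            baseline[idx[mrna]] = rng.uniform(80.0, 300.0)
            truth.pairs.append(
                {"lncrna_id": lnc, "mrna_id": mrna, "rho": config.latent_rho, "trait": trait}
            )

    mu = np.outer(baseline, libfactor)

    col_of = {f: j for j, f in enumerate(libraries)}
    for trait, calls in truth.de.items():
        hi = [col_of[f] for f in designs[trait]["high"] if f in col_of]
        lo = [col_of[f] for f in designs[trait]["low"] if f in col_of]
        for tid, direction in calls.items():
            mu[idx[tid], hi if direction > 0 else lo] *= config.fold_change

    sig = config.latent_sigma
    for pair in truth.pairs:
        z1 = rng.standard_normal(m)
        z2 = config.latent_rho * z1 + np.sqrt(1 - config.latent_rho**2) * rng.standard_normal(m)
        mu[idx[pair["lncrna_id"]]] *= np.exp(sig * z1 - sig**2 / 2)
        mu[idx[pair["mrna_id"]]] *= np.exp(sig * z2 - sig**2 / 2)

    if config.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    df = pd.DataFrame(counts, index=ids, columns=libraries)
    return ExpressionMatrix(values=df, unit="counts")


# -- regulatory elements ---------------------------------------------------


def generate_regulatory(
    annotation: GenomeAnnotation, config: SimulationConfig, truth: GroundTruth
) -> tuple[dict[str, str], list[PWM]]:
    """Plant miRNA sites into sponge pairs and TF motifs into promoters.

    For each planted sponge triplet the reverse complement of the full
    miRNA (position 1 forced to U, so the seed region forms a canonical
    8mer with an A opposite position 1) is written into the lncRNA
    transcript and into the partner mRNA's 3'UTR.  TF consensus motifs go
    into the 500-nt promoters of both members of selected pairs.  lncRNA
    ORFs are re-scrubbed afterwards with every planted element protected.
    Mutates the annotation's contig sequences in place; returns (miRNA
    sequences, PWM list).
    """
    rng = _substream(config.seed, "regulatory")

    mirnas: dict[str, str] = {}
    for i in range(config.n_mirnas):
        body = "".join(np.array(list("ACGU"))[rng.integers(0, 4, config.mirna_length - 1)])
        mirnas[f"mir-{i + 1:02d}"] = "U" + body

    if config.n_sponge and not truth.pairs:
        raise ValueError("sponge planting requires planted pairs (run generate_expression first)")

    editor = _GenomeEditor(annotation)
    truth.sponges = []
    mirna_ids = sorted(mirnas)
    for si in range(config.n_sponge):
        pair = truth.pairs[si]
        mid = mirna_ids[si]
        site = _revcomp_dna(mirnas[mid])
        lnc_tid, mrna_tid = pair["lncrna_id"], pair["mrna_id"]

        # keep the site inside one lncRNA exon so it is contiguous on the genome
        t = annotation.transcripts[lnc_tid]
        strand = annotation.genes[t.gene_id].strand
        exon_lens = [e - s for s, e in (t.exons if strand == "+" else reversed(t.exons))]
        off, placed = 0, None
        for el in exon_lens:
            if el >= len(site) + 20:
                placed = off + int(rng.integers(10, el - len(site) - 9))
                break
            off += el
        if placed is None:
            raise ValueError(f"site longer than every exon of {lnc_tid}")
        editor.write_tx(lnc_tid, placed, site, reserve=True)

        utr_off = _plant_in_utr3(editor, mrna_tid, site, rng)
        truth.sponges.append(
            {
                "lncrna_id": lnc_tid, "mirna_id": mid, "mrna_id": mrna_tid,
                "lnc_site_offset": placed, "mrna_utr_offset": utr_off,
                "site_length": len(site),
            }
        )

    # strongly informative synthetic PWMs over the muscle TF names
    pwms: list[PWM] = []
    for name in MUSCLE_TF_NAMES[: config.n_tfs]:
        L = int(rng.integers(8, 13))
        consensus_idx = rng.integers(0, 4, L)
        counts = np.ones((4, L))
        counts[consensus_idx, np.arange(L)] = 20.0
        pwms.append(PWM(name=name, counts=counts))

    truth.tf_insertions = []
    for pi in range(min(config.n_tf_pairs, len(truth.pairs))):
        pair = truth.pairs[pi]
        pwm = pwms[pi % len(pwms)]
        for tid in (pair["lncrna_id"], pair["mrna_id"]):
            gene_id = annotation.transcripts[tid].gene_id
            offset = _plant_promoter_motif(editor, gene_id, pwm.consensus, rng)
            if offset is not None:
                truth.tf_insertions.append(
                    {"tf": pwm.name, "gene_id": gene_id, "transcript_id": tid, "offset": offset}
                )

    lnc_ids = [tid for tid, tx in annotation.transcripts.items()
               if annotation.genes[tx.gene_id].biotype == "lncRNA"]
    _scrub_orfs(editor, lnc_ids)
    editor.flush()
    return mirnas, pwms


def _revcomp_dna(rna: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "U": "A", "T": "A"}
    return "".join(comp[c] for c in reversed(rna))


def _plant_in_utr3(editor: _GenomeEditor, mrna_tid: str, site: str, rng) -> int:
    """Write a site into the 3'UTR; returns the offset within the UTR (5'->3')."""
    t = editor.ann.transcripts[mrna_tid]
    g = editor.ann.genes[t.gene_id]
    if t.utr3 is None:
        raise ValueError(f"mRNA {mrna_tid} has no annotated 3'UTR")
    s, e = t.utr3
    if e - s < len(site):
        raise ValueError(f"site longer than 3'UTR of {mrna_tid}")
    off = int(rng.integers(0, e - s - len(site) + 1))
    if g.strand == "+":
        editor.write_genome(g.contig, s + off, site, reserve=True)
    else:
        # the UTR's 5'->3' direction runs right-to-left on the genome
        rc = site.translate(str.maketrans(_COMP))[::-1]
        editor.write_genome(g.contig, e - off - len(site), rc, reserve=True)
    return off


def _plant_promoter_motif(
    editor: _GenomeEditor, gene_id: str, consensus: str, rng, length: int = 500
) -> int | None:
    """Write a consensus motif into a gene's promoter; returns promoter offset."""
    g = editor.ann.genes[gene_id]
    clen = editor.ann.contig_lengths[g.contig]
    L = len(consensus)
    if g.strand == "+":
        pstart = max(0, g.start - length)
        plen = g.start - pstart
        if plen < L:
            return None
        off = int(rng.integers(0, plen - L + 1))
        editor.write_genome(g.contig, pstart + off, consensus, reserve=True)
    else:
        pend = min(clen, g.end + length)
        plen = pend - g.end
        if plen < L:
            return None
        off = int(rng.integers(0, plen - L + 1))
        rc = consensus.translate(str.maketrans(_COMP))[::-1]
        editor.write_genome(g.contig, pend - off - L, rc, reserve=True)
    return off


def write_truth_tables(truth: GroundTruth, outdir: str, seed: int) -> None:
    """Emit the ground-truth tables alongside the generated data files."""
    import os

    from .io_formats import write_table

    hdr = f"lncweave synthetic truth, seed={seed}"
    write_table(
        [{"transcript_id": tid, **rec} for tid, rec in sorted(truth.lnc_class.items())],
        os.path.join(outdir, "truth_lnc_class.tsv"),
        ["transcript_id", "category", "overlap", "orientation", "partner"],
        header_comment=hdr,
    )
    de_rows = [
        {"trait": trait, "transcript_id": tid, "direction": d}
        for trait, calls in truth.de.items()
        for tid, d in sorted(calls.items())
    ]
    write_table(de_rows, os.path.join(outdir, "truth_de.tsv"),
                ["trait", "transcript_id", "direction"], header_comment=hdr)
    write_table(truth.pairs, os.path.join(outdir, "truth_pairs.tsv"),
                ["lncrna_id", "mrna_id", "rho", "trait"], header_comment=hdr)
    write_table(truth.sponges, os.path.join(outdir, "truth_sponges.tsv"),
                ["lncrna_id", "mirna_id", "mrna_id", "lnc_site_offset",
                 "mrna_utr_offset", "site_length"], header_comment=hdr)
    write_table(truth.tf_insertions, os.path.join(outdir, "truth_tf_insertions.tsv"),
                ["tf", "gene_id", "transcript_id", "offset"], header_comment=hdr)
    design_rows = [
        {"trait": trait, "tail": tail, "family": fam}
        for trait, d in truth.trait_families.items()
        for tail in ("high", "low")
        for fam in d[tail]
    ]
    write_table(design_rows, os.path.join(outdir, "truth_designs.tsv"),
                ["trait", "tail", "family"], header_comment=hdr)
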