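"""lncRNA discovery filters and strand-aware positional classification.

A putative lncRNA must be longer than 200 nt spliced, lack a long open
reading frame (the coding-potential proxy), and single-exon transcripts
sitting in sense orientation within 500 nt of a protein-coding gene are
discarded as likely assembly fragments.  Retained lncRNAs are classified
against protein-coding gene spans as genic (exonic or intronic; full or
partial overlap; sense or antisense) or intergenic, with a 50-kb neighbor
search for the intergenic class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import GenomeAnnotation, Span, Transcript

MIN_LENGTH_NT = 200
MAX_ORF_CODONS = 100
SENSE_ADJACENCY_NT = 500
NEIGHBOR_WINDOW_NT = 50_000

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class LncClassification:
    lncrna_id: str
    category: str  # genic_exonic | genic_intronic | intergenic
    overlap: str  # full | partial | none
    orientation: str  # sense | antisense | not_applicable
    partners: list[str] = field(default_factory=list)
    dist_upstream: int | None = None
    dist_downstream: int | None = None
    window: int = NEIGHBOR_WINDOW_NT


@dataclass
class Neighbor:
    gene_id: str
    side: str  # upstream | downstream, relative to the lncRNA's strand
    distance: int
    relative_strand: str  # sense | antisense


def longest_orf_codons(seq: str) -> int:
    """Longest ATG-initiated ORF, in codons, over the three forward frames.

    An ORF running off the transcript end without a stop still counts; the
    stop codon itself is not counted.
    """
    seq = seq.upper().replace("U", "T")
    best = 0
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
                best = max(best, codons)
                i = j + 3
            else:
                i += 3
    return best


def span_gap(a: Span, b: Span) -> int:
    """Gap between closest edges of two half-open spans; 0 if they touch or overlap."""
    if a[0] < b[1] and b[0] < a[1]:
        return 0
    return max(a[0], b[0]) - min(a[1], b[1])


def spans_overlap(a: Span, b: Span) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def filter_putative_lncrnas(
    candidates: list[str],
    annotation: GenomeAnnotation,
    max_orf_codons: int = MAX_ORF_CODONS,
    min_length: int = MIN_LENGTH_NT,
    adjacency: int = SENSE_ADJACENCY_NT,
    exclusion_ids: set[str] | None = None,
) -> tuple[list[str], dict[str, str]]:
    """Apply the lncRNA discovery filters to candidate transcript ids.

    Returns (retained ids, rejection reason per rejected id).
    ``exclusion_ids`` is an optional user-supplied list of transcripts known
    to belong to other noncoding classes (rRNA/tRNA etc.), removed as-is.
    """
    exclusion_ids = exclusion_ids or set()
    retained: list[str] = []
    rejected: dict[str, str] = {}
    for tid in candidates:
        t = annotation.transcripts[tid]
        g = annotation.genes[t.gene_id]
        if tid in exclusion_ids:
            rejected[tid] = "other noncoding class (user exclusion list)"
            continue
        if t.spliced_length <= min_length:
            rejected[tid] = f"length <= {min_length}"
            continue
        seq = annotation.transcript_sequence(tid)
        if longest_orf_codons(seq) >= max_orf_codons:
            rejected[tid] = f"ORF >= {max_orf_codons} codons"
            continue
        if len(t.exons) == 1:
            near_sense = False
            probe = (max(0, t.start - adjacency), t.end + adjacency)
            for cg in annotation.genes_overlapping(g.contig, probe, "protein_coding"):
                if cg.strand == g.strand and span_gap((t.start, t.end), cg.span) <= adjacency:
                    near_sense = True
                    break
            if near_sense:
                rejected[tid] = "sense-adjacent single-exon"
                continue
        retained.append(tid)
    return retained, rejected


def classify_lncrna_position(
    lncrna: str | Transcript, annotation: GenomeAnnotation, window: int = NEIGHBOR_WINDOW_NT
) -> LncClassification:
    """Positional class of one lncRNA against protein-coding genes.

    Genic overlap is judged against gene spans; the exonic/intronic split
    uses the union of exons over each partner gene's transcripts.  When
    several genes overlap, all are reported as partners and the category is
    the highest-priority relation (exonic beats intronic); the orientation
    is taken from the partner defining the category.
    """
    t = annotation.transcripts[lncrna] if isinstance(lncrna, str) else lncrna
    g = annotation.genes[t.gene_id]
    if g.contig not in annotation.contig_lengths:
        raise ValueError(f"lncRNA {t.transcript_id} on unknown contig {g.contig}")
    span = (t.start, t.end)
    partners = annotation.genes_overlapping(g.contig, span, "protein_coding")

    if not partners:
        cls = LncClassification(t.transcript_id, "intergenic", "none", "not_applicable", window=window)
        neighbors = find_neighbors(t, annotation, window=window)
        for nb in neighbors:
            if nb.side == "upstream" and cls.dist_upstream is None:
                cls.dist_upstream = nb.distance
            if nb.side == "downstream" and cls.dist_downstream is None:
                cls.dist_downstream = nb.distance
        if neighbors:
            cls.orientation = neighbors[0].relative_strand
        return cls

    relations: list[tuple[int, str, str]] = []  # (priority, gene_id, relation)
    for pg in partners:
        exonic = any(spans_overlap(span, ex) for ex in annotation.gene_exon_union(pg.gene_id))
        relations.append((0 if exonic else 1, pg.gene_id, "exonic" if exonic else "intronic"))
    relations.sort()
    _, primary_id, primary_rel = relations[0]
    primary = annotation.genes[primary_id]

    contained = any(pg.start <= span[0] and span[1] <= pg.end for pg in partners)
    return LncClassification(
        lncrna_id=t.transcript_id,
        category="genic_exonic" if primary_rel == "exonic" else "genic_intronic",
        overlap="full" if contained else "partial",
        orientation="sense" if g.strand == primary.strand else "antisense",
        partners=[gid for _, gid, _ in relations],
        window=window,
    )


def find_neighbors(
    lncrna: str | Transcript, annotation: GenomeAnnotation, window: int = NEIGHBOR_WINDOW_NT
) -> list[Neighbor]:
    """Protein-coding genes within ``window`` nt of a non-overlapping lncRNA.

    Distance is the gap between closest span edges (inclusive boundary:
    a gap of exactly ``window`` is kept).  Sides are relative to the
    lncRNA's strand (upstream = its 5' side).  Sorted by distance, ties by
    gene id.  Calling this on an overlapping lncRNA is an error.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    t = annotation.transcripts[lncrna] if isinstance(lncrna, str) else lncrna
    g = annotation.genes[t.gene_id]
    span = (t.start, t.end)
    # probe extended by 1 so a gene ending exactly `window` away still overlaps
    probe = (max(0, span[0] - window - 1), span[1] + window + 1)
    out: list[Neighbor] = []
    for cg in annotation.genes_overlapping(g.contig, probe, "protein_coding"):
        if spans_overlap(span, cg.span):
            raise ValueError(
                f"lncRNA {t.transcript_id} overlaps {cg.gene_id}; "
                "use classify_lncrna_position for genic lncRNAs"
            )
        d = span_gap(span, cg.span)
        if d > window:
            continue
        left_of_lnc = cg.end <= span[0]
        if g.strand == "+":
            side = "upstream" if left_of_lnc else "downstream"
        else:
            side = "downstream" if left_of_lnc else "upstream"
        out.append(
            Neighbor(
                gene_id=cg.gene_id,
                side=side,
                distance=d,
                relative_strand="sense" if cg.strand == g.strand else "antisense",
            )
        )
    out.sort(key=lambda nb: (nb.distance, nb.gene_id))
    return out


def classify_all(
    lnc_ids: list[str], annotation: GenomeAnnotation, window: int = NEIGHBOR_WINDOW_NT
) -> dict[str, LncClassification]:
    return {tid: classify_lncrna_position(tid, annotation, window=window) for tid in lnc_ids}
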