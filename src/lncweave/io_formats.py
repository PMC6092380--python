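"""Standard-format I/O and the shared genome data model.

All coordinates are 0-based half-open internally; GFF3's 1-based closed
convention is converted exactly once, at the file boundary.  Every other
module consumes the containers defined here, so their invariants are
validated eagerly on construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gffutils
from Bio.Seq import reverse_complement
from Bio.SeqIO.FastaIO import SimpleFastaParser
from intervaltree import IntervalTree

Span = tuple[int, int]

VALID_STRANDS = frozenset({"+", "-"})


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


def to_internal(start_1based: int, end_1based: int) -> Span:
    """GFF3 1-based closed -> 0-based half-open."""
    return (start_1based - 1, end_1based)


def to_gff3(span: Span) -> tuple[int, int]:
    """0-based half-open -> GFF3 1-based closed (inverse of :func:`to_internal`)."""
    return (span[0] + 1, span[1])


@dataclass
class Gene:
    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    biotype: str  # "protein_coding" | "lncRNA"

    @property
    def span(self) -> Span:
        return (self.start, self.end)


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    exons: list[Span]
    utr3: Span | None = None

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GenomeAnnotation:
    """Genes, transcripts and (optionally) contig sequences, with interval indexes.

    ``contigs`` maps contig id to uppercase sequence; ``contig_lengths`` is
    kept separately so annotation-only files (with ``##sequence-region``
    directives) can be validated without sequence.
    """

    contigs: dict[str, str] = field(default_factory=dict)
    contig_lengths: dict[str, int] = field(default_factory=dict)
    genes: dict[str, Gene] = field(default_factory=dict)
    transcripts: dict[str, Transcript] = field(default_factory=dict)
    _trees: dict[tuple[str, str], IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            self.contig_lengths.setdefault(cid, len(seq))
        self.validate()
        self._build_indexes()

    def validate(self) -> None:
        for g in self.genes.values():
            if g.strand not in VALID_STRANDS:
                raise FormatError(f"gene {g.gene_id}: strand {g.strand!r} is not +/-")
            if g.contig not in self.contig_lengths:
                raise FormatError(f"gene {g.gene_id}: unknown contig {g.contig!r}")
            if not (0 <= g.start < g.end <= self.contig_lengths[g.contig]):
                raise FormatError(
                    f"gene {g.gene_id}: span ({g.start},{g.end}) outside contig "
                    f"{g.contig} of length {self.contig_lengths[g.contig]}"
                )
        for t in self.transcripts.values():
            if t.gene_id not in self.genes:
                raise FormatError(
                    f"transcript {t.transcript_id}: Parent gene {t.gene_id!r} not found"
                )
            g = self.genes[t.gene_id]
            if not t.exons:
                raise FormatError(f"transcript {t.transcript_id}: no exons")
            prev_end = -1
            for s, e in t.exons:
                if s >= e:
                    raise FormatError(f"transcript {t.transcript_id}: empty exon ({s},{e})")
                if s < prev_end:
                    raise FormatError(
                        f"transcript {t.transcript_id}: exons overlap or are unsorted"
                    )
                prev_end = e
            if t.exons[0][0] < g.start or t.exons[-1][1] > g.end:
                raise FormatError(
                    f"transcript {t.transcript_id}: exons exceed gene span of {g.gene_id}"
                )

    def _build_indexes(self) -> None:
        self._trees = {}
        for g in self.genes.values():
            key = (g.contig, g.biotype)
            tree = self._trees.setdefault(key, IntervalTree())
            tree[g.start:g.end] = g.gene_id

    # -- queries -----------------------------------------------------------

    def genes_overlapping(self, contig: str, span: Span, biotype: str) -> list[Gene]:
        tree = self._trees.get((contig, biotype))
        if tree is None:
            return []
        hits = tree.overlap(span[0], span[1])
        return sorted((self.genes[iv.data] for iv in hits), key=lambda g: g.gene_id)

    def genes_of_biotype(self, biotype: str) -> list[Gene]:
        return sorted(
            (g for g in self.genes.values() if g.biotype == biotype),
            key=lambda g: g.gene_id,
        )

    def transcripts_of_gene(self, gene_id: str) -> list[Transcript]:
        return sorted(
            (t for t in self.transcripts.values() if t.gene_id == gene_id),
            key=lambda t: t.transcript_id,
        )

    def gene_exon_union(self, gene_id: str) -> list[Span]:
        """Union of exon spans over all of a gene's transcripts, merged and sorted."""
        spans = sorted(
            s for t in self.transcripts.values() if t.gene_id == gene_id for s in t.exons
        )
        merged: list[list[int]] = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]

    def transcript_sequence(self, transcript_id: str) -> str:
        """Spliced transcript sequence, 5'->3' on the transcript's strand."""
        t = self.transcripts[transcript_id]
        g = self.genes[t.gene_id]
        if g.contig not in self.contigs:
            raise FormatError(f"no sequence loaded for contig {g.contig}")
        seq = "".join(self.contigs[g.contig][s:e] for s, e in t.exons)
        return reverse_complement(seq) if g.strand == "-" else seq


# -- FASTA -----------------------------------------------------------------


def read_fasta(path: str, *, keep_u: bool = False) -> dict[str, str]:
    """Read FASTA into an insertion-ordered ``{id: uppercase sequence}`` mapping.

    Ids are the first whitespace-delimited header token.  ``U`` is normalized
    to ``T`` for genomic input unless ``keep_u`` is set (miRNA input).
    """
    out: dict[str, str] = {}
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            sid = header.split()[0] if header.split() else ""
            if not sid:
                raise FormatError(f"{path}: record with empty id")
            if sid in out:
                raise FormatError(f"{path}: duplicate sequence id {sid!r}")
            seq = seq.upper()
            if not keep_u:
                seq = seq.replace("U", "T")
            if not seq:
                raise FormatError(f"{path}: empty sequence for {sid!r}")
            bad = set(seq) - set("ACGTUN")
            if bad:
                raise FormatError(f"{path}: invalid characters {sorted(bad)} in {sid!r}")
            out[sid] = seq
    return out


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# -- GFF3 ------------------------------------------------------------------


def read_gff3(path: str, fasta: str | dict[str, str] | None = None) -> GenomeAnnotation:
    """Parse a GFF3 file (gene/transcript/exon/three_prime_UTR dialect).

    Contig lengths come from ``##sequence-region`` directives and/or the
    optional ``fasta`` sequences (path or preloaded mapping).  Raises
    :class:`FormatError` on orphan Parents or features beyond contig bounds.
    """
    contigs: dict[str, str] = {}
    if fasta is not None:
        contigs = read_fasta(fasta) if isinstance(fasta, str) else dict(fasta)

    lengths: dict[str, int] = {cid: len(s) for cid, s in contigs.items()}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    lengths.setdefault(parts[1], int(parts[3]))
            elif not line.startswith("#"):
                break

    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            merge_strategy="error",
            keep_order=True,
            sort_attribute_values=True,
        )
    except Exception as exc:  # gffutils raises several concrete types
        raise FormatError(f"{path}: GFF3 parse failure: {exc}") from exc

    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}
    utr3: dict[str, Span] = {}

    for f in db.features_of_type("gene", order_by=("seqid", "start")):
        if f.strand not in VALID_STRANDS:
            raise FormatError(f"{path}: gene {f.id}: strand {f.strand!r} rejected")
        biotype = f.attributes.get("biotype", ["protein_coding"])[0]
        if f.seqid not in lengths:
            raise FormatError(f"{path}: gene {f.id}: contig {f.seqid!r} has no known length")
        genes[f.id] = Gene(f.id, f.seqid, f.strand, *to_internal(f.start, f.end), biotype)

    for f in db.features_of_type(("transcript", "mRNA", "lnc_RNA"), order_by=("seqid", "start")):
        parent = f.attributes.get("Parent", [None])[0]
        if parent is None or parent not in genes:
            raise FormatError(
                f"{path}: transcript {f.id}: orphan Parent {parent!r} "
                f"(line: {f.seqid} {f.start} {f.end})"
            )
        transcripts[f.id] = Transcript(f.id, parent, exons=[])

    for f in db.features_of_type("exon", order_by=("seqid", "start")):
        parent = f.attributes.get("Parent", [None])[0]
        if parent is None or parent not in transcripts:
            raise FormatError(
                f"{path}: exon at {f.seqid}:{f.start}-{f.end}: orphan Parent {parent!r}"
            )
        transcripts[parent].exons.append(to_internal(f.start, f.end))

    for f in db.features_of_type("three_prime_UTR", order_by=("seqid", "start")):
        parent = f.attributes.get("Parent", [None])[0]
        if parent is None or parent not in transcripts:
            raise FormatError(
                f"{path}: three_prime_UTR at {f.seqid}:{f.start}-{f.end}: "
                f"orphan Parent {parent!r}"
            )
        utr3[parent] = to_internal(f.start, f.end)

    for tid, t in transcripts.items():
        t.exons.sort()
        t.utr3 = utr3.get(tid)

    return GenomeAnnotation(
        contigs=contigs, contig_lengths=lengths, genes=genes, transcripts=transcripts
    )


def write_gff3(annotation: GenomeAnnotation, path: str, header_comment: str | None = None) -> None:
    """Write the annotation back out in the same GFF3 dialect read_gff3 accepts."""
    lines = ["##gff-version 3"]
    if header_comment:
        lines.append(f"# {header_comment}")
    for cid in sorted(annotation.contig_lengths):
        lines.append(f"##sequence-region {cid} 1 {annotation.contig_lengths[cid]}")
    for gid in sorted(annotation.genes):
        g = annotation.genes[gid]
        s, e = to_gff3(g.span)
        lines.append(
            "\t".join(
                [g.contig, "lncweave", "gene", str(s), str(e), ".", g.strand, ".",
                 f"ID={gid};biotype={g.biotype}"]
            )
        )
        for t in annotation.transcripts_of_gene(gid):
            ts, te = to_gff3((t.start, t.end))
            lines.append(
                "\t".join(
                    [g.contig, "lncweave", "transcript", str(ts), str(te), ".",
                     g.strand, ".", f"ID={t.transcript_id};Parent={gid}"]
                )
            )
            for i, ex in enumerate(t.exons, 1):
                xs, xe = to_gff3(ex)
                lines.append(
                    "\t".join(
                        [g.contig, "lncweave", "exon", str(xs), str(xe), ".", g.strand,
                         ".", f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}"]
                    )
                )
            if t.utr3 is not None:
                us, ue = to_gff3(t.utr3)
                lines.append(
                    "\t".join(
                        [g.contig, "lncweave", "three_prime_UTR", str(us), str(ue), ".",
                         g.strand, ".", f"ID={t.transcript_id}.utr3;Parent={t.transcript_id}"]
                    )
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# -- expression matrices ---------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Transcripts x libraries expression values with a unit tag.

    ``values`` is a pandas DataFrame (rows = transcript ids, columns =
    library/family ids).  ``unit`` is one of ``counts``, ``TPM``, ``scaled``.
    """

    values: "pandas.DataFrame"  # noqa: F821 - imported lazily to keep module load light
    unit: str

    def __post_init__(self) -> None:
        import pandas as pd

        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.unit not in {"counts", "TPM", "scaled"}:
            raise FormatError(f"unknown expression unit {self.unit!r}")
        if (self.values.values < 0).any():
            raise FormatError("expression matrix contains negative values")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise FormatError("expression matrix has duplicate row or column ids")
        if self.unit == "TPM":
            sums = self.values.sum(axis=0).to_numpy()
            if not ((abs(sums - 1e6) <= 1e6 * 1e-6).all()):
                raise FormatError("TPM columns must each sum to 1e6 (relative tol 1e-6)")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.values.columns)


def read_expression_tsv(path: str, unit: str = "counts") -> ExpressionMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return ExpressionMatrix(values=df, unit=unit)


def write_expression_tsv(matrix: ExpressionMatrix, path: str, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        # 10 significant digits so TPM column sums survive a read round-trip
        matrix.values.to_csv(fh, sep="\t", index_label="transcript_id", float_format="%.10g")


# -- tables ----------------------------------------------------------------


def _render(v) -> str:
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, float):
        if math.isnan(v):
            return "NA"
        return f"{v:.6g}"
    return str(v)


def write_table(records: list[dict], path: str, schema: list[str], header_comment: str | None = None) -> None:
    """Write uniform records as a TSV with a header row.

    Floats are rendered with 6 significant digits; the caller controls row
    order.  A record missing a schema column is an error naming the column.
    """
    for i, rec in enumerate(records):
        for col in schema:
            if col not in rec:
                raise FormatError(f"record {i} is missing column {col!r}")
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(schema) + "\n")
        for rec in records:
            fh.write("\t".join(_render(rec[col]) for col in schema) + "\n")


def read_table(path: str) -> list[dict]:
    """Read a TSV written by :func:`write_table` (values stay strings)."""
    rows: list[dict] = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise FormatError(f"{path}: row with {len(fields)} fields, expected {len(header)}")
            rows.append(dict(zip(header, fields)))
    if header is None:
        raise FormatError(f"{path}: no header row")
    return rows
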