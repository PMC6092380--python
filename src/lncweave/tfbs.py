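"""Promoter extraction and PWM scanning for muscle transcription factors.

Promoters are the 500 nt immediately upstream of a gene's transcription
start on its own strand.  A position-weight matrix is built from base counts
with a pseudo-count of 1 and log-odds weights against an iid background.
Hits must satisfy both a dissimilarity ceiling (percent of the attainable
score range lost, default 5%) and an expectation ceiling (RE: expected
number of windows in a random promoter scoring at least as high, default
< 0.05, computed from the exact score distribution under the background).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import reverse_complement

from .io_formats import FormatError, GenomeAnnotation

logger = logging.getLogger(__name__)

PROMOTER_LENGTH_NT = 500
MAX_DISSIMILARITY_PCT = 5.0
RE_THRESHOLD = 0.05

#: The 26 muscle-development transcription factors scanned by default.
MUSCLE_TF_NAMES = (
    "myogenin", "MyoD", "NF-AT1", "c-Fos", "c-Jun", "JunB", "FOXO4", "CREB",
    "Elk-1", "E47", "MAZ", "MEF-2C", "GATA-2", "NFI/CTF", "NF-Y", "VDR",
    "Smad3", "Smad4", "PEA3", "SRF", "Sp1", "Sp3", "YY1", "p53", "GR", "AR",
)

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class PWM:
    """Log-odds position-weight matrix built from base counts."""

    name: str
    counts: np.ndarray  # 4 x L, rows A/C/G/T
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, float)
        self.background = np.asarray(self.background, float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 4:
            raise ValueError(f"PWM {self.name}: need a 4 x L matrix with L >= 4")
        if (self.counts < 0).any():
            raise ValueError(f"PWM {self.name}: negative counts")
        if abs(self.background.sum() - 1.0) > 1e-9 or (self.background <= 0).any():
            raise ValueError(f"PWM {self.name}: background must be positive and sum to 1")
        freqs = (self.counts + self.pseudocount) / (
            self.counts.sum(axis=0) + 4 * self.pseudocount
        )
        self.weights = np.log2(freqs / self.background[:, None])
        self.max_score = float(self.weights.max(axis=0).sum())
        self.min_score = float(self.weights.min(axis=0).sum())
        if not self.max_score > self.min_score:
            raise ValueError(f"PWM {self.name}: degenerate matrix (max == min score)")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.weights.argmax(axis=0))

    def score(self, window: str) -> float:
        idx = [_BASE_IDX[c] for c in window]
        return float(self.weights[idx, range(self.length)].sum())

    def dissimilarity(self, score: float) -> float:
        return 100.0 * (self.max_score - score) / (self.max_score - self.min_score)

    def tail_probability(self, score: float, rounding: float = 1e-9) -> float:
        """P(random L-mer under the background scores >= ``score``), exact.

        Dynamic program over the discrete score distribution; scores are
        binned at ``rounding`` resolution so equal-by-construction scores
        merge despite float noise.
        """
        if not hasattr(self, "_dist_cache") or self._dist_cache[0] != rounding:
            dist: dict[int, float] = {0: 1.0}
            for pos in range(self.length):
                nxt: dict[int, float] = {}
                for key, p in dist.items():
                    for b in range(4):
                        k = key + round(self.weights[b, pos] / rounding)
                        nxt[k] = nxt.get(k, 0.0) + p * self.background[b]
                dist = nxt
            keys = np.array(sorted(dist))
            probs = np.array([dist[k] for k in keys])
            suffix = np.cumsum(probs[::-1])[::-1]
            self._dist_cache = (rounding, keys, suffix)
        _, keys, suffix = self._dist_cache
        threshold = round(score / rounding) - 1
        i = int(np.searchsorted(keys, threshold, side="right"))
        return float(suffix[i]) if i < len(keys) else 0.0


@dataclass
class TFBSHit:
    tf_name: str
    sequence_id: str
    offset: int  # 0-based start on the forward sequence
    strand: str  # + | -
    score: float
    dissimilarity: float
    re: float  # expected windows >= score in a random promoter of this length


def extract_promoter(
    gene_id: str, annotation: GenomeAnnotation, length: int = PROMOTER_LENGTH_NT
) -> str:
    """Upstream promoter sequence on the gene's strand, truncated at contig ends."""
    g = annotation.genes[gene_id]
    contig = annotation.contigs.get(g.contig)
    if contig is None:
        raise FormatError(f"no sequence loaded for contig {g.contig}")
    if g.strand == "+":
        start = max(0, g.start - length)
        seq = contig[start : g.start]
    else:
        end = min(len(contig), g.end + length)
        seq = reverse_complement(contig[g.end : end])
    if not seq:
        logger.warning("gene %s: empty promoter (gene at contig edge)", gene_id)
    elif len(seq) < length:
        logger.info("gene %s: promoter truncated to %d nt at contig boundary", gene_id, len(seq))
    return seq


def pwm_scan(
    pwm: PWM,
    sequence: str,
    sequence_id: str = "seq",
    max_dissimilarity: float = MAX_DISSIMILARITY_PCT,
    re_threshold: float = RE_THRESHOLD,
    both_strands: bool = True,
) -> list[TFBSHit]:
    """Scan one sequence with one PWM; windows containing N are skipped.

    RE for a candidate window = tail probability of its score times the
    number of windows scanned in this promoter (both strands when enabled).
    """
    seq = sequence.upper()
    L = pwm.length
    if len(seq) < L:
        return []
    n_windows_per_strand = len(seq) - L + 1
    n_windows = n_windows_per_strand * (2 if both_strands else 1)

    strands = [("+", seq)]
    if both_strands:
        strands.append(("-", reverse_complement(seq)))

    hits: list[TFBSHit] = []
    for strand, s in strands:
        idx = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
        code = np.full(idx.shape, 4, dtype=np.int64)  # 4 = N / unknown
        for b, i in _BASE_IDX.items():
            code[idx == ord(b)] = i
        windows = np.lib.stride_tricks.sliding_window_view(code, L)
        valid = (windows < 4).all(axis=1)
        if not valid.all():
            logger.debug("%s: %d windows skipped (N)", sequence_id, int((~valid).sum()))
        padded = np.vstack([pwm.weights, np.zeros((1, L))])
        scores = padded[windows, np.arange(L)].sum(axis=1)
        diss = 100.0 * (pwm.max_score - scores) / (pwm.max_score - pwm.min_score)
        for i in np.flatnonzero(valid & (diss <= max_dissimilarity)):
            score = float(scores[i])
            re = pwm.tail_probability(score) * n_windows
            if re >= re_threshold:
                continue
            offset = int(i) if strand == "+" else len(seq) - L - int(i)
            hits.append(
                TFBSHit(
                    tf_name=pwm.name,
                    sequence_id=sequence_id,
                    offset=offset,
                    strand=strand,
                    score=score,
                    dissimilarity=float(diss[i]),
                    re=re,
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_promoters(
    pwms: list[PWM], promoters: dict[str, str], **kwargs
) -> list[TFBSHit]:
    hits: list[TFBSHit] = []
    for pid in sorted(promoters):
        for pwm in pwms:
            hits.extend(pwm_scan(pwm, promoters[pid], sequence_id=pid, **kwargs))
    return hits


def shared_tfbs(
    pairs,
    hits: list[TFBSHit],
    promoter_of: dict[str, str] | None = None,
) -> tuple[list[dict], dict[str, dict[str, int]]]:
    """Shared TF sets per co-expressed pair, plus per-TF promoter counts.

    ``promoter_of`` maps transcript ids to promoter sequence ids (identity
    by default).  Pairs where one member has no promoter hits at all are
    flagged.
    """
    promoter_of = promoter_of or {}
    tf_by_seq: dict[str, set[str]] = {}
    for h in hits:
        tf_by_seq.setdefault(h.sequence_id, set()).add(h.tf_name)

    records: list[dict] = []
    for e in pairs:
        lnc_seq = promoter_of.get(e.lncrna_id, e.lncrna_id)
        mrna_seq = promoter_of.get(e.mrna_id, e.mrna_id)
        lnc_tfs = tf_by_seq.get(lnc_seq, set())
        mrna_tfs = tf_by_seq.get(mrna_seq, set())
        shared = sorted(lnc_tfs & mrna_tfs)
        records.append(
            {
                "lncrna_id": e.lncrna_id,
                "mrna_id": e.mrna_id,
                "shared_tfs": "|".join(shared) if shared else "NA",
                "n_shared": len(shared),
                "flagged": not lnc_tfs or not mrna_tfs,
            }
        )

    summary: dict[str, dict[str, int]] = {}
    lnc_ids = {promoter_of.get(e.lncrna_id, e.lncrna_id) for e in pairs}
    mrna_ids = {promoter_of.get(e.mrna_id, e.mrna_id) for e in pairs}
    all_tfs = sorted({h.tf_name for h in hits})
    for tf in all_tfs:
        with_hit = {sid for sid, tfs in tf_by_seq.items() if tf in tfs}
        summary[tf] = {
            "n_lncrna_promoters": len(with_hit & lnc_ids),
            "n_mrna_promoters": len(with_hit & mrna_ids),
        }
    return records, summary


# -- PWM text format -------------------------------------------------------


def write_pwms(pwms: list[PWM], path: str, header_comment: str | None = None) -> None:
    """One block per TF: a '>name' line then four count rows labelled A/C/G/T."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for b, row in zip(_BASES, pwm.counts):
                fh.write(f"{b}: " + " ".join(f"{v:g}" for v in row) + "\n")


def read_pwms(path: str, background: np.ndarray | None = None) -> list[PWM]:
    pwms: list[PWM] = []
    name: str | None = None
    rows: dict[str, list[float]] = {}

    def flush():
        if name is None:
            return
        if set(rows) != set(_BASES):
            raise FormatError(f"PWM {name!r}: need exactly rows A/C/G/T, got {sorted(rows)}")
        counts = np.array([rows[b] for b in _BASES])
        kwargs = {} if background is None else {"background": background}
        pwms.append(PWM(name=name, counts=counts, **kwargs))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].strip()
                rows = {}
            else:
                base, _, rest = line.partition(":")
                base = base.strip().upper()
                if base not in _BASE_IDX:
                    raise FormatError(f"{path}: unexpected PWM row {line!r}")
                rows[base] = [float(x) for x in rest.split()]
    flush()
    return pwms
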