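"""miRNA seed matching, duplex free energy, consensus target calls, sponges.

Duplex free energy is the minimum over all gapless antiparallel alignments
of two RNA strands, scored with an embedded 37 degC nearest-neighbor stack
table (Watson-Crick plus G.U wobble; see docs/methods.md for provenance).
Bulges and internal loops are deliberately out of model: gapless duplexes
keep an exhaustive enumeration oracle feasible and are sufficient for
seed-anchored site scoring.

Consensus target calling mirrors the multi-tool voting architecture used in
practice: four internal predictors (seed class, duplex energy at the
-13 kcal/mol floor, site accessibility, pairing pattern) vote per site and a
site is a consensus call when at least three support it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ENERGY_FLOOR = -13.0  # kcal/mol, shared by the energy predictor
ACCESS_THRESHOLD = -10.0  # kcal/mol on ddG
ACCESS_COST_PER_NT = 0.2  # kcal/mol/nt opening cost over the site window
PATTERN_MIN_PAIRS = 11
PATTERN_MAX_SEED_MISMATCH = 1
CONSENSUS_MIN_SUPPORT = 3
NDG_CUTOFF = -0.10  # kcal/mol/nt for lncRNA:mRNA pairing

_IDX = {"A": 0, "C": 1, "G": 2, "U": 3}
_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}

# Canonical stack entries, keyed ((top_i, bottom_i), (top_i+1, bottom_i+1))
# for the step 5'-top_i top_i+1-3' / 3'-bottom_i bottom_i+1-5'.  kcal/mol at
# 37 degC.  The symmetry E(p,q) = E(reverse q, reverse p) fills the rest.
_CANONICAL_STACKS: dict[tuple[tuple[str, str], tuple[str, str]], float] = {
    # Watson-Crick / Watson-Crick
    (("A", "U"), ("A", "U")): -0.93,
    (("A", "U"), ("U", "A")): -1.10,
    (("U", "A"), ("A", "U")): -1.33,
    (("C", "G"), ("U", "A")): -2.08,
    (("C", "G"), ("A", "U")): -2.11,
    (("G", "C"), ("U", "A")): -2.24,
    (("G", "C"), ("A", "U")): -2.35,
    (("C", "G"), ("G", "C")): -2.36,
    (("G", "C"), ("G", "C")): -3.26,
    (("G", "C"), ("C", "G")): -3.42,
    # steps involving G.U wobble pairs
    (("A", "U"), ("G", "U")): -0.55,
    (("A", "U"), ("U", "G")): -1.36,
    (("C", "G"), ("G", "U")): -1.41,
    (("C", "G"), ("U", "G")): -2.11,
    (("G", "C"), ("G", "U")): -1.53,
    (("G", "C"), ("U", "G")): -2.51,
    (("U", "A"), ("G", "U")): -1.00,
    (("G", "U"), ("A", "U")): -1.27,
    (("G", "U"), ("G", "U")): -0.50,
    (("G", "U"), ("U", "G")): 1.29,
    (("U", "G"), ("G", "U")): 0.30,
}

_VALID_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def _build_tables() -> tuple[np.ndarray, np.ndarray]:
    ok = np.zeros((4, 4), dtype=bool)
    for a, b in _VALID_PAIRS:
        ok[_IDX[a], _IDX[b]] = True
    stack = np.zeros((4, 4, 4, 4))
    filled = np.zeros((4, 4, 4, 4), dtype=bool)

    def put(p, q, e):
        i = (_IDX[p[0]], _IDX[p[1]], _IDX[q[0]], _IDX[q[1]])
        if filled[i] and stack[i] != e:
            raise AssertionError(f"inconsistent stack entry {p}/{q}")
        stack[i] = e
        filled[i] = True

    for (p, q), e in _CANONICAL_STACKS.items():
        put(p, q, e)
        put((q[1], q[0]), (p[1], p[0]), e)  # symmetric image
    for p in _VALID_PAIRS:
        for q in _VALID_PAIRS:
            i = (_IDX[p[0]], _IDX[p[1]], _IDX[q[0]], _IDX[q[1]])
            if not filled[i]:
                raise AssertionError(f"stack table missing entry {p}/{q}")
    return ok, stack


_PAIR_OK, _STACK = _build_tables()


def _encode_rna(seq: str, name: str = "sequence") -> np.ndarray:
    s = seq.upper().replace("T", "U")
    try:
        return np.array([_IDX[c] for c in s], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"{name} contains invalid character {exc.args[0]!r}") from exc


def _alignment_energy(top: np.ndarray, bot: np.ndarray) -> tuple[float, np.ndarray]:
    """Energy of one fixed gapless antiparallel alignment.

    ``bot`` is given 3'->5' (i.e. already reversed); only adjacent valid
    pairs stack, mismatches contribute nothing.
    """
    ok = _PAIR_OK[top, bot]
    if len(top) < 2:
        return 0.0, ok
    e = _STACK[top[:-1], bot[:-1], top[1:], bot[1:]]
    contrib = np.where(ok[:-1] & ok[1:], e, 0.0)
    return float(contrib.sum()), ok


def duplex_energy(strand1: str, strand2: str) -> tuple[float, list[tuple[int, int]]]:
    """Minimum free energy over all gapless antiparallel alignments.

    Returns (dG in kcal/mol, trace) where the trace lists paired positions
    (index in strand1, index in strand2) of the best alignment.  If no
    alignment reaches dG < 0, returns (0.0, []).
    """
    a = _encode_rna(strand1, "strand1")
    b = _encode_rna(strand2, "strand2")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both strands must be at least 2 nt")
    brev = b[::-1]
    n, m = len(a), len(b)
    best = 0.0
    best_trace: list[tuple[int, int]] = []
    for shift in range(-(m - 1), n):
        i0 = max(0, shift)
        i1 = min(n, m + shift)
        if i1 - i0 < 2:
            continue
        top = a[i0:i1]
        bot = brev[i0 - shift : i1 - shift]
        e, ok = _alignment_energy(top, bot)
        if e < best:
            best = e
            # strand2 index: brev position j' maps back to m - 1 - j'
            best_trace = [
                (i0 + k, m - 1 - (i0 - shift + k)) for k in np.flatnonzero(ok)
            ]
    return best, best_trace


def reverse_complement_rna(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    return "".join(_COMPLEMENT[c] for c in reversed(s))


# -- seed matching ---------------------------------------------------------


@dataclass
class SeedSite:
    start: int  # 0-based half-open on the target
    end: int
    site_class: str  # 8mer | 7mer-m8 | 7mer-A1 | 6mer
    seed_start: int  # start of the 6mer core match


def seed_match_sites(mirna: str, target: str) -> list[SeedSite]:
    """Scan a target (5'->3') for seed matches to miRNA positions 2-7.

    The 6mer core is the reverse complement of miRNA positions 2-7; a match
    upgrades to 7mer-m8 when the base 5' of the core pairs position 8, to
    7mer-A1 when the base opposite position 1 is an A, and to 8mer when both
    hold.  Each core match is reported once with its best class.
    """
    mir = mirna.upper().replace("T", "U")
    if len(mir) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    tgt = target.upper().replace("U", "T")
    if len(tgt) < 6:
        return []
    core = reverse_complement_rna(mir[1:7]).replace("U", "T")
    m8_base = _COMPLEMENT[mir[7]].replace("U", "T")
    sites: list[SeedSite] = []
    for s in range(len(tgt) - 5):
        if tgt[s : s + 6] != core:
            continue
        has_m8 = s >= 1 and tgt[s - 1] == m8_base
        has_a1 = s + 6 < len(tgt) and tgt[s + 6] == "A"
        if has_m8 and has_a1:
            sites.append(SeedSite(s - 1, s + 7, "8mer", s))
        elif has_m8:
            sites.append(SeedSite(s - 1, s + 6, "7mer-m8", s))
        elif has_a1:
            sites.append(SeedSite(s, s + 7, "7mer-A1", s))
        else:
            sites.append(SeedSite(s, s + 6, "6mer", s))
    return sites


# -- consensus target calling ---------------------------------------------


@dataclass
class MirnaSiteCall:
    mirna_id: str
    target_id: str
    target_region: str  # lncRNA_full | mRNA_3UTR
    start: int
    end: int
    site_class: str
    delta_g: float
    predictors: frozenset[str] = field(default_factory=frozenset)
    consensus: bool = False


def predict_targets_consensus(
    mirna: str,
    target: str,
    mirna_id: str = "mirna",
    target_id: str = "target",
    target_region: str = "lncRNA_full",
    min_support: int = CONSENSUS_MIN_SUPPORT,
    energy_floor: float = ENERGY_FLOOR,
    access_cost: float = ACCESS_COST_PER_NT,
    access_threshold: float = ACCESS_THRESHOLD,
) -> list[MirnaSiteCall]:
    """Seed-anchored consensus site calls for one miRNA against one target.

    Predictors per site: ``seed`` (any seed-class match), ``energy`` (full
    duplex dG <= -13 kcal/mol over the site window), ``accessibility``
    (dG minus the per-nt opening cost over the window <= -10 kcal/mol) and
    ``pattern`` (>= 11 paired positions with at most 1 unpaired seed
    position in the best duplex trace).  Consensus requires ``min_support``
    of the four.
    """
    if min_support > 4:
        raise ValueError("min_support cannot exceed the 4 internal predictors")
    mir = mirna.upper().replace("T", "U")
    calls: list[MirnaSiteCall] = []
    for site in seed_match_sites(mir, target):
        L = len(mir)
        # miRNA position i pairs target index (seed_start + 6) - (i - 1)
        w_end = min(len(target), site.seed_start + 7)
        w_start = max(0, site.seed_start + 7 - L)
        window = target[w_start:w_end]
        dg, trace = duplex_energy(mir, window)

        supporting = {"seed"}
        if dg <= energy_floor:
            supporting.add("energy")
        ddg = dg - access_cost * len(window)
        if ddg <= access_threshold:
            supporting.add("accessibility")
        paired_mir = {i for i, _ in trace}
        seed_mismatches = sum(1 for i in range(1, 8) if i not in paired_mir)
        if len(trace) >= PATTERN_MIN_PAIRS and seed_mismatches <= PATTERN_MAX_SEED_MISMATCH:
            supporting.add("pattern")

        calls.append(
            MirnaSiteCall(
                mirna_id=mirna_id,
                target_id=target_id,
                target_region=target_region,
                start=site.start,
                end=site.end,
                site_class=site.site_class,
                delta_g=dg,
                predictors=frozenset(supporting),
                consensus=len(supporting) >= min_support,
            )
        )
    return calls


# -- sponge triplets -------------------------------------------------------


@dataclass
class SpongeTriplet:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    r: float
    lnc_sites: list[MirnaSiteCall]
    mrna_sites: list[MirnaSiteCall]


def find_sponge_candidates(edges, site_calls: list[MirnaSiteCall]) -> list[SpongeTriplet]:
    """Co-expression edges whose lncRNA and mRNA share a consensus miRNA.

    lncRNA sites must be over the full lncRNA sequence, mRNA sites over the
    3'UTR, both consensus-flagged.  Deterministic (lnc, miRNA, mRNA) order.
    """
    lnc_sites: dict[tuple[str, str], list[MirnaSiteCall]] = {}
    utr_sites: dict[tuple[str, str], list[MirnaSiteCall]] = {}
    for c in site_calls:
        if not c.consensus:
            continue
        key = (c.target_id, c.mirna_id)
        if c.target_region == "lncRNA_full":
            lnc_sites.setdefault(key, []).append(c)
        elif c.target_region == "mRNA_3UTR":
            utr_sites.setdefault(key, []).append(c)

    lnc_mirnas: dict[str, set[str]] = {}
    for tid, mid in lnc_sites:
        lnc_mirnas.setdefault(tid, set()).add(mid)
    utr_mirnas: dict[str, set[str]] = {}
    for tid, mid in utr_sites:
        utr_mirnas.setdefault(tid, set()).add(mid)

    triplets: list[SpongeTriplet] = []
    for e in edges:
        shared = lnc_mirnas.get(e.lncrna_id, set()) & utr_mirnas.get(e.mrna_id, set())
        for mid in sorted(shared):
            triplets.append(
                SpongeTriplet(
                    lncrna_id=e.lncrna_id,
                    mirna_id=mid,
                    mrna_id=e.mrna_id,
                    r=e.r,
                    lnc_sites=lnc_sites[(e.lncrna_id, mid)],
                    mrna_sites=utr_sites[(e.mrna_id, mid)],
                )
            )
    triplets.sort(key=lambda t: (t.lncrna_id, t.mirna_id, t.mrna_id))
    return triplets


# -- lncRNA:mRNA pairing ---------------------------------------------------


@dataclass
class LncTarResult:
    lncrna_id: str
    mrna_id: str
    best_dg: float
    window_length: int
    ndg: float
    passes: bool


def lnctar_ndg(
    lncrna: str,
    mrna: str,
    window: int = 20,
    lncrna_id: str = "lncrna",
    mrna_id: str = "mrna",
    cutoff: float = NDG_CUTOFF,
) -> LncTarResult:
    """Sliding-window lncRNA:mRNA pairing score normalized per nucleotide.

    The shorter sequence slides along the longer in 1-nt steps at full
    overlap; each offset is scored as a fixed gapless antiparallel duplex.
    ndG = best dG / overlap length; a pair passes at ndG <= -0.10 (inclusive).
    ``window`` is the minimum admissible overlap length (>= 20 nt).
    """
    if window < 20:
        raise ValueError("window must be >= 20 nt")
    if not lncrna or not mrna:
        raise ValueError("empty sequence")
    a = _encode_rna(lncrna, "lncrna")
    b = _encode_rna(mrna, "mrna")
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    overlap = len(short)
    if overlap < window:
        raise ValueError(f"overlap {overlap} nt is below the {window}-nt window")
    best = 0.0
    for off in range(len(long_) - overlap + 1):
        seg = long_[off : off + overlap][::-1]
        e, _ = _alignment_energy(short, seg)
        if e < best:
            best = e
    ndg = best / overlap
    return LncTarResult(
        lncrna_id=lncrna_id,
        mrna_id=mrna_id,
        best_dg=best,
        window_length=overlap,
        ndg=ndg,
        passes=ndg <= cutoff,
    )
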