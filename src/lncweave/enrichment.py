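"""Fisher-exact gene-set over-representation and the enrichment-map graph.

Enrichment runs against a user-supplied term -> gene-set annotation map (no
live database lookups); the universe defaults to the expressed
protein-coding genes of the run.  Terms passing the FDR cutoff are linked
into an undirected graph wherever their gene sets overlap at an overlap
coefficient of at least 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
from scipy.stats import hypergeom

from .diffexpr import bh_fdr

FDR_CUTOFF = 0.05
OVERLAP_CUTOFF = 0.5


@dataclass
class EnrichmentTerm:
    term_id: str
    name: str
    k: int  # query genes in term
    K: int  # universe genes in term
    n: int  # query size
    N: int  # universe size
    fold_enrichment: float
    p_value: float
    q_value: float = 1.0
    genes: frozenset[str] = field(default_factory=frozenset)


def fisher_enrichment(
    query: set[str],
    annotation: dict[str, set[str]],
    universe: set[str],
    names: dict[str, str] | None = None,
) -> list[EnrichmentTerm]:
    """One-sided (over-representation) hypergeometric test per term, BH-corrected.

    Term gene sets are intersected with the universe; terms with no universe
    genes are skipped.  Results are sorted by (p, term id).
    """
    if not query:
        raise ValueError("empty query set")
    stray = sorted(query - universe)
    if stray:
        raise ValueError(f"query genes outside the universe: {stray[:10]}")
    names = names or {}
    N, n = len(universe), len(query)
    terms: list[EnrichmentTerm] = []
    for term_id in sorted(annotation):
        genes = annotation[term_id] & universe
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        terms.append(
            EnrichmentTerm(
                term_id=term_id,
                name=names.get(term_id, term_id),
                k=k, K=K, n=n, N=N,
                fold_enrichment=fold,
                p_value=min(1.0, p),
                genes=frozenset(genes),
            )
        )
    qvals = bh_fdr([t.p_value for t in terms])
    for t, q in zip(terms, qvals):
        t.q_value = float(q)
    terms.sort(key=lambda t: (t.p_value, t.term_id))
    return terms


def overlap_coefficient(a: set[str], b: set[str]) -> float:
    """|A n B| / min(|A|, |B|); errors on an empty set."""
    if not a or not b:
        raise ValueError("overlap coefficient undefined for empty sets")
    return len(a & b) / min(len(a), len(b))


def build_enrichment_map(
    terms: list[EnrichmentTerm],
    fdr_cutoff: float = FDR_CUTOFF,
    oc_cutoff: float = OVERLAP_CUTOFF,
) -> nx.Graph:
    """Graph of FDR-passing terms linked at overlap coefficient >= cutoff."""
    g = nx.Graph()
    passing = [t for t in terms if t.q_value < fdr_cutoff]
    for t in passing:
        g.add_node(
            t.term_id,
            name=t.name, k=t.k, K=t.K,
            fold_enrichment=t.fold_enrichment,
            p=t.p_value, q=t.q_value,
        )
    for i, a in enumerate(passing):
        for b in passing[i + 1 :]:
            if not a.genes or not b.genes:
                continue
            oc = overlap_coefficient(set(a.genes), set(b.genes))
            if oc >= oc_cutoff:
                g.add_edge(a.term_id, b.term_id, overlap_coefficient=oc)
    return g


def enrichment_map_tables(graph: nx.Graph) -> tuple[list[dict], list[dict]]:
    """Node and edge record lists for TSV emission."""
    nodes = [
        {"term_id": tid, **{k: v for k, v in data.items()}}
        for tid, data in sorted(graph.nodes(data=True))
    ]
    edges = [
        {"term_a": a, "term_b": b, "overlap_coefficient": d["overlap_coefficient"]}
        for a, b, d in sorted(graph.edges(data=True))
    ]
    return nodes, edges
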