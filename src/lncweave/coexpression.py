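"""DE-lncRNA / mRNA co-expression network at Pearson R >= 0.85.

Edges are positive correlations only, computed across all family libraries
(not just the contrast families), and typed by genomic relation:
``overlapping`` (the mRNA's gene is an overlap partner of the lncRNA),
``neighbor_cis`` (within the 50-kb neighbor window) or ``trans``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_classify import LncClassification, Neighbor
from .io_formats import ExpressionMatrix

DEFAULT_R_THRESHOLD = 0.85


@dataclass
class CoexpressionEdge:
    lncrna_id: str
    mrna_id: str
    r: float
    relation: str = "trans"  # overlapping | neighbor_cis | trans
    distance: int | None = None
    traits: list[str] | None = None


def pearson_r(x, y) -> float:
    """Product-moment correlation; errors on zero variance or length < 3."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r))


def build_network(
    de_lnc_ids: list[str],
    expr: ExpressionMatrix,
    mrna_ids: list[str],
    threshold: float = DEFAULT_R_THRESHOLD,
) -> list[CoexpressionEdge]:
    """All (DE lncRNA, mRNA) pairs with computable Pearson r >= threshold.

    Zero-variance transcripts are excluded from the pair universe (their
    correlation is undefined).  Output is sorted by (lncRNA id, mRNA id).
    """
    df = expr.values
    missing = [i for i in de_lnc_ids if i not in df.index]
    if missing:
        raise ValueError(f"DE lncRNAs absent from expression matrix: {missing}")
    mrna_ids = [i for i in mrna_ids if i in df.index]

    lnc = df.loc[de_lnc_ids].to_numpy(float)
    mrna = df.loc[mrna_ids].to_numpy(float)
    lnc_ok = lnc.std(axis=1) > 0
    mrna_ok = mrna.std(axis=1) > 0

    def _standardize(m):
        mu = m.mean(axis=1, keepdims=True)
        sd = m.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (m - mu) / sd

    n = lnc.shape[1]
    corr = _standardize(lnc) @ _standardize(mrna).T / n

    edges: list[CoexpressionEdge] = []
    for i, lid in enumerate(de_lnc_ids):
        if not lnc_ok[i]:
            continue
        for j, mid in enumerate(mrna_ids):
            if not mrna_ok[j] or lid == mid:
                continue
            r = float(min(1.0, max(-1.0, corr[i, j])))
            if r >= threshold:
                edges.append(CoexpressionEdge(lncrna_id=lid, mrna_id=mid, r=r))
    edges.sort(key=lambda e: (e.lncrna_id, e.mrna_id))
    return edges


def annotate_edge_relation(
    edge: CoexpressionEdge,
    classification: LncClassification,
    neighbors: list[Neighbor],
    mrna_gene_of: dict[str, str],
) -> CoexpressionEdge:
    """Type one edge as overlapping / neighbor_cis / trans (in place; returned)."""
    gene = mrna_gene_of.get(edge.mrna_id, edge.mrna_id)
    if gene in classification.partners:
        edge.relation = "overlapping"
        edge.distance = 0
        return edge
    for nb in neighbors:
        if nb.gene_id == gene:
            edge.relation = "neighbor_cis"
            edge.distance = nb.distance
            return edge
    edge.relation = "trans"
    edge.distance = None
    return edge


def annotate_network(
    edges: list[CoexpressionEdge],
    classifications: dict[str, LncClassification],
    neighbor_lists: dict[str, list[Neighbor]],
    mrna_gene_of: dict[str, str],
    de_traits: dict[str, list[str]] | None = None,
) -> list[CoexpressionEdge]:
    for e in edges:
        cls = classifications[e.lncrna_id]
        annotate_edge_relation(e, cls, neighbor_lists.get(e.lncrna_id, []), mrna_gene_of)
        if de_traits is not None:
            e.traits = de_traits.get(e.lncrna_id, [])
    return edges


def to_records(edges: list[CoexpressionEdge]) -> list[dict]:
    return [
        {
            "lncrna_id": e.lncrna_id,
            "mrna_id": e.mrna_id,
            "r": e.r,
            "relation": e.relation,
            "distance": e.distance if e.distance is not None else "NA",
            "traits": "|".join(e.traits) if e.traits else "NA",
        }
        for e in edges
    ]
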