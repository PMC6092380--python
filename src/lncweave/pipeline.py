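"""End-to-end orchestration: simulate -> phenotype -> DE -> classify ->
co-express -> targets -> TFBS -> enrich.

Every stage reads its inputs from files in the output directory and writes
its outputs back there, so any downstream stage can be re-run on its own
from the on-disk state and reproduce the full-run files.  Each output file
carries a header comment recording the package version, the seed and the
stage parameters; the run manifest lists per-stage record counts.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .coexpression import annotate_network, build_network, to_records
from .diffexpr import call_de, compute_tpm, normalize_scaling
from .enrichment import build_enrichment_map, enrichment_map_tables, fisher_enrichment
from .genome_classify import classify_all, filter_putative_lncrnas, find_neighbors
from .io_formats import (
    read_expression_tsv,
    read_fasta,
    read_gff3,
    read_table,
    write_expression_tsv,
    write_fasta,
    write_gff3,
    write_table,
)
from .phenotype import ContrastDesign, correct_for_covariate, select_for_trait
from .rna_interactions import (
    find_sponge_candidates,
    lnctar_ndg,
    predict_targets_consensus,
)
from .synthetic_data import (
    SimulationConfig,
    _substream,
    generate_expression,
    generate_genome,
    generate_phenotypes,
    generate_regulatory,
    write_truth_tables,
)
from .tfbs import extract_promoter, read_pwms, scan_promoters, shared_tfbs, write_pwms


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the offending record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """One config drives the whole run; thresholds default to the study values."""

    outdir: str = "lncweave_out"
    seed: int = 0
    simulate: SimulationConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    # stage parameters
    families_per_tail: int = 4
    fdr_cutoff: float = 0.05
    fc_cutoff: float = 2.0
    r_threshold: float = 0.85
    neighbor_window: int = 50_000
    promoter_length: int = 500
    energy_floor: float = -13.0
    consensus_k: int = 3
    ndg_cutoff: float = -0.10
    max_dissimilarity: float = 5.0
    re_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.fdr_cutoff < 1):
            raise ValueError("fdr_cutoff must lie in (0, 1)")
        if self.fc_cutoff < 1:
            raise ValueError("fc_cutoff must be >= 1")
        if not (0 < self.r_threshold <= 1):
            raise ValueError("r_threshold must lie in (0, 1]")
        if self.neighbor_window <= 0 or self.promoter_length <= 0:
            raise ValueError("window lengths must be positive")
        if not 1 <= self.consensus_k <= 4:
            raise ValueError("consensus_k must be 1..4")
        if self.simulate is None:
            required = {"genome", "annotation", "counts", "phenotypes", "mirnas", "pwms"}
            missing = sorted(required - set(self.inputs))
            if missing:
                raise ValueError(
                    f"config needs either a 'simulate' block or input paths; missing: {missing}"
                )

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        params = raw.pop("params", {})
        cfg = cls(simulate=sim, **raw, **params)
        if cfg.simulate is not None:
            cfg.simulate.seed = cfg.seed
        return cfg

    def header(self, stage: str) -> str:
        return (
            f"lncweave {__version__} stage={stage} seed={self.seed} "
            f"fdr={self.fdr_cutoff} fc={self.fc_cutoff} r={self.r_threshold} "
            f"window={self.neighbor_window} promoter={self.promoter_length} "
            f"energy={self.energy_floor} k={self.consensus_k} ndg={self.ndg_cutoff} "
            f"dissim={self.max_dissimilarity} re={self.re_threshold}"
        )

    def path(self, name: str) -> str:
        return os.path.join(self.outdir, name)


def _load_annotation(cfg: PipelineConfig):
    return read_gff3(cfg.path("annotation.gff3"), fasta=cfg.path("genome.fa"))


def _lnc_and_coding(annotation):
    lnc = sorted(
        t for t, tx in annotation.transcripts.items()
        if annotation.genes[tx.gene_id].biotype == "lncRNA"
    )
    cod = sorted(
        t for t, tx in annotation.transcripts.items()
        if annotation.genes[tx.gene_id].biotype == "protein_coding"
    )
    return lnc, cod


# -- stages ----------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig) -> dict:
    sim = cfg.simulate
    if sim is None:
        # external inputs: copy nothing, later stages read cfg.inputs paths
        for key, src in cfg.inputs.items():
            if not os.path.exists(src):
                raise PipelineError("simulate", f"input {key!r} not found at {src}")
        _link_inputs(cfg)
        return {"n_simulated": 0}
    annotation, truth = generate_genome(sim)
    phen, designs = generate_phenotypes(sim)
    counts = generate_expression(annotation, sim, truth, designs)
    mirnas, pwms = generate_regulatory(annotation, sim, truth)

    hdr = cfg.header("simulate")
    write_fasta(annotation.contigs, cfg.path("genome.fa"))
    write_gff3(annotation, cfg.path("annotation.gff3"), header_comment=hdr)
    write_expression_tsv(counts, cfg.path("counts.tsv"), header_comment=hdr)
    with open(cfg.path("phenotypes.tsv"), "w") as fh:
        fh.write(f"# {hdr}\n")
        phen.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    write_fasta(mirnas, cfg.path("mirnas.fa"))
    write_pwms(pwms, cfg.path("pwms.txt"), header_comment=hdr)
    write_truth_tables(truth, cfg.outdir, sim.seed)
    _write_annotation_map(cfg, annotation, truth)
    return {
        "n_genes": len(annotation.genes),
        "n_transcripts": len(annotation.transcripts),
        "n_libraries": len(counts.library_ids),
        "n_planted_de": len(truth.de_ids()),
        "n_planted_pairs": len(truth.pairs),
        "n_planted_sponges": len(truth.sponges),
        "n_planted_tf_insertions": len(truth.tf_insertions),
    }


def _link_inputs(cfg: PipelineConfig) -> None:
    """Materialize external inputs under the run directory names stages expect."""
    import shutil

    names = {
        "genome": "genome.fa", "annotation": "annotation.gff3",
        "counts": "counts.tsv", "phenotypes": "phenotypes.tsv",
        "mirnas": "mirnas.fa", "pwms": "pwms.txt",
        "annotation_map": "annotation_map.tsv",
    }
    for key, src in cfg.inputs.items():
        dst = cfg.path(names.get(key, os.path.basename(src)))
        if os.path.abspath(src) != os.path.abspath(dst):
            shutil.copyfile(src, dst)


def _write_annotation_map(cfg: PipelineConfig, annotation, truth) -> None:
    """Synthetic GO/KEGG-style term map over the coding transcripts.

    One term collects the planted pair mRNAs (so the co-expressed query has
    real signal); the rest are random draws.
    """
    rng = _substream(cfg.seed, "terms")
    _, cod = _lnc_and_coding(annotation)
    rows = []
    pair_mrnas = sorted({p["mrna_id"] for p in truth.pairs})
    members = set(pair_mrnas) | set(rng.choice(cod, size=min(10, len(cod)), replace=False))
    for gid in sorted(members):
        rows.append({"term_id": "T001", "term_name": "muscle lipid process", "gene_id": gid})
    for t in range(2, 13):
        size = int(rng.integers(10, 31))
        for gid in sorted(rng.choice(cod, size=min(size, len(cod)), replace=False)):
            rows.append({"term_id": f"T{t:03d}", "term_name": f"process {t}", "gene_id": gid})
    write_table(rows, cfg.path("annotation_map.tsv"),
                ["term_id", "term_name", "gene_id"], header_comment=cfg.header("simulate"))


def stage_phenotype(cfg: PipelineConfig) -> dict:
    phen = pd.read_csv(cfg.path("phenotypes.tsv"), sep="\t", comment="#")
    counts = read_expression_tsv(cfg.path("counts.tsv"))
    sequenced = set(counts.library_ids)
    traits = [c for c in ("WBW", "muscle_yield", "fat", "shear_force", "whiteness")
              if c in phen.columns]
    fam_means = phen.groupby("family", sort=True).mean(numeric_only=True)

    corrected_rows = []
    for trait in ("muscle_yield", "fat"):
        if trait not in fam_means.columns or "WBW" not in fam_means.columns:
            continue
        resid, r2 = correct_for_covariate(
            fam_means[trait].to_numpy(), {"WBW": fam_means["WBW"]}
        )
        for fam, value in zip(fam_means.index, resid):
            corrected_rows.append(
                {"family": fam, "trait": trait, "corrected_value": float(value), "r2_vs_wbw": r2}
            )
    write_table(corrected_rows, cfg.path("corrected_phenotypes.tsv"),
                ["family", "trait", "corrected_value", "r2_vs_wbw"],
                header_comment=cfg.header("phenotype"))

    design_rows = []
    n_outside = 0
    for trait in traits:
        design = select_for_trait(phen, trait, k=cfg.families_per_tail)
        for tail, fams in (("high", design.high), ("low", design.low)):
            for fam in fams:
                if fam not in sequenced:
                    n_outside += 1
                design_rows.append({"trait": trait, "tail": tail, "family": fam})
    write_table(design_rows, cfg.path("contrast_design.tsv"),
                ["trait", "tail", "family"], header_comment=cfg.header("phenotype"))
    if n_outside:
        raise PipelineError(
            "phenotype",
            f"{n_outside} selected contrast families have no sequenced library",
        )
    return {"n_traits": len(traits), "n_corrected_rows": len(corrected_rows)}


def _read_designs(cfg: PipelineConfig) -> dict[str, ContrastDesign]:
    rows = read_table(cfg.path("contrast_design.tsv"))
    by_trait: dict[str, dict[str, list[str]]] = {}
    for r in rows:
        by_trait.setdefault(r["trait"], {"high": [], "low": []})[r["tail"]].append(r["family"])
    return {
        t: ContrastDesign(trait=t, high=d["high"], low=d["low"])
        for t, d in by_trait.items()
    }


def stage_de(cfg: PipelineConfig) -> dict:
    annotation = _load_annotation(cfg)
    counts = read_expression_tsv(cfg.path("counts.tsv"))
    designs = _read_designs(cfg)
    lengths = {tid: tx.spliced_length for tid, tx in annotation.transcripts.items()}

    tpm = compute_tpm(counts, lengths)
    write_expression_tsv(tpm, cfg.path("tpm.tsv"), header_comment=cfg.header("de"))

    rows = []
    for trait in sorted(designs):
        for r in call_de(counts, designs[trait], fdr_cutoff=cfg.fdr_cutoff,
                         fc_cutoff=cfg.fc_cutoff):
            rows.append(
                {
                    "transcript_id": r.transcript_id, "trait": trait,
                    "fold_change": r.fold_change, "log2_fc": r.log2_fc,
                    "p_value": r.p_value, "q_value": r.q_value, "de": r.is_de,
                }
            )
    rows.sort(key=lambda r: (r["trait"], r["transcript_id"]))
    write_table(rows, cfg.path("de_results.tsv"),
                ["transcript_id", "trait", "fold_change", "log2_fc",
                 "p_value", "q_value", "de"], header_comment=cfg.header("de"))
    n_de = sum(1 for r in rows if r["de"])
    return {"n_tested": len(rows), "n_de_calls": n_de}


def stage_classify(cfg: PipelineConfig) -> dict:
    annotation = _load_annotation(cfg)
    lnc, _ = _lnc_and_coding(annotation)
    retained, rejected = filter_putative_lncrnas(lnc, annotation)
    filter_rows = [{"transcript_id": t, "status": "retained", "reason": "NA"} for t in retained]
    filter_rows += [
        {"transcript_id": t, "status": "rejected", "reason": reason}
        for t, reason in sorted(rejected.items())
    ]
    filter_rows.sort(key=lambda r: r["transcript_id"])
    write_table(filter_rows, cfg.path("lnc_filter.tsv"),
                ["transcript_id", "status", "reason"], header_comment=cfg.header("classify"))

    classes = classify_all(retained, annotation, window=cfg.neighbor_window)
    rows = []
    for tid in sorted(classes):
        c = classes[tid]
        rows.append(
            {
                "transcript_id": tid, "category": c.category, "overlap": c.overlap,
                "orientation": c.orientation,
                "partners": "|".join(c.partners) if c.partners else "NA",
                "dist_upstream": c.dist_upstream if c.dist_upstream is not None else "NA",
                "dist_downstream": c.dist_downstream if c.dist_downstream is not None else "NA",
                "window": c.window,
            }
        )
    write_table(rows, cfg.path("lnc_classification.tsv"),
                ["transcript_id", "category", "overlap", "orientation", "partners",
                 "dist_upstream", "dist_downstream", "window"],
                header_comment=cfg.header("classify"))

    with open(cfg.path("lnc_classes.bed"), "w") as fh:
        for tid in sorted(classes):
            t = annotation.transcripts[tid]
            g = annotation.genes[t.gene_id]
            fh.write(
                f"{g.contig}\t{t.start}\t{t.end}\t{tid}|{classes[tid].category}\t0\t{g.strand}\n"
            )
    return {
        "n_candidates": len(lnc), "n_retained": len(retained),
        "n_rejected": len(rejected),
        "n_genic": sum(1 for c in classes.values() if c.category != "intergenic"),
        "n_intergenic": sum(1 for c in classes.values() if c.category == "intergenic"),
    }


def _de_lnc_traits(cfg: PipelineConfig, annotation) -> dict[str, list[str]]:
    lnc, _ = _lnc_and_coding(annotation)
    lnc_set = set(lnc)
    traits: dict[str, list[str]] = {}
    for r in read_table(cfg.path("de_results.tsv")):
        if r["de"] == "True" and r["transcript_id"] in lnc_set:
            traits.setdefault(r["transcript_id"], []).append(r["trait"])
    return traits


def stage_coexpress(cfg: PipelineConfig) -> dict:
    annotation = _load_annotation(cfg)
    tpm = read_expression_tsv(cfg.path("tpm.tsv"), unit="TPM")
    scaled = normalize_scaling(tpm)
    _, cod = _lnc_and_coding(annotation)

    de_traits = _de_lnc_traits(cfg, annotation)
    retained = {
        r["transcript_id"]
        for r in read_table(cfg.path("lnc_filter.tsv"))
        if r["status"] == "retained"
    }
    de_lnc = sorted(set(de_traits) & retained)

    edges = build_network(de_lnc, scaled, cod, threshold=cfg.r_threshold)
    classes = classify_all(de_lnc, annotation, window=cfg.neighbor_window)
    neighbor_lists = {
        tid: (find_neighbors(tid, annotation, window=cfg.neighbor_window)
              if classes[tid].category == "intergenic" else [])
        for tid in de_lnc
    }
    mrna_gene_of = {tid: annotation.transcripts[tid].gene_id for tid in cod}
    annotate_network(edges, classes, neighbor_lists, mrna_gene_of, de_traits)

    write_table(to_records(edges), cfg.path("network.tsv"),
                ["lncrna_id", "mrna_id", "r", "relation", "distance", "traits"],
                header_comment=cfg.header("coexpress"))
    return {
        "n_de_lnc": len(de_lnc),
        "n_edges": len(edges),
        "n_overlapping": sum(1 for e in edges if e.relation == "overlapping"),
        "n_neighbor_cis": sum(1 for e in edges if e.relation == "neighbor_cis"),
        "n_trans": sum(1 for e in edges if e.relation == "trans"),
    }


def _network_edges(cfg: PipelineConfig):
    rows = read_table(cfg.path("network.tsv"))
    from .coexpression import CoexpressionEdge

    return [
        CoexpressionEdge(
            lncrna_id=r["lncrna_id"], mrna_id=r["mrna_id"], r=float(r["r"]),
            relation=r["relation"],
            distance=None if r["distance"] == "NA" else int(float(r["distance"])),
            traits=None if r["traits"] == "NA" else r["traits"].split("|"),
        )
        for r in rows
    ]


def _utr3_sequence(annotation, tid: str) -> str | None:
    t = annotation.transcripts[tid]
    g = annotation.genes[t.gene_id]
    if t.utr3 is None:
        return None
    s, e = t.utr3
    seq = annotation.contigs[g.contig][s:e]
    if g.strand == "-":
        from Bio.Seq import reverse_complement

        seq = reverse_complement(seq)
    return seq


def stage_targets(cfg: PipelineConfig) -> dict:
    annotation = _load_annotation(cfg)
    edges = _network_edges(cfg)
    mirnas = read_fasta(cfg.path("mirnas.fa"), keep_u=True)

    lnc_ids = sorted({e.lncrna_id for e in edges})
    mrna_ids = sorted({e.mrna_id for e in edges})

    calls = []
    for mid in sorted(mirnas):
        for tid in lnc_ids:
            calls.extend(
                predict_targets_consensus(
                    mirnas[mid], annotation.transcript_sequence(tid),
                    mirna_id=mid, target_id=tid, target_region="lncRNA_full",
                    min_support=cfg.consensus_k, energy_floor=cfg.energy_floor,
                )
            )
        for tid in mrna_ids:
            utr = _utr3_sequence(annotation, tid)
            if utr is None:
                continue
            calls.extend(
                predict_targets_consensus(
                    mirnas[mid], utr,
                    mirna_id=mid, target_id=tid, target_region="mRNA_3UTR",
                    min_support=cfg.consensus_k, energy_floor=cfg.energy_floor,
                )
            )
    site_rows = [
        {
            "mirna_id": c.mirna_id, "target_id": c.target_id, "region": c.target_region,
            "start": c.start, "end": c.end, "site_class": c.site_class,
            "delta_g": c.delta_g, "predictors": "|".join(sorted(c.predictors)),
            "consensus": c.consensus,
        }
        for c in calls
    ]
    site_rows.sort(key=lambda r: (r["mirna_id"], r["target_id"], r["start"]))
    write_table(site_rows, cfg.path("mirna_sites.tsv"),
                ["mirna_id", "target_id", "region", "start", "end", "site_class",
                 "delta_g", "predictors", "consensus"],
                header_comment=cfg.header("targets"))

    triplets = find_sponge_candidates(edges, calls)
    trip_rows = [
        {
            "lncrna_id": t.lncrna_id, "mirna_id": t.mirna_id, "mrna_id": t.mrna_id,
            "r": t.r, "n_lnc_sites": len(t.lnc_sites), "n_mrna_sites": len(t.mrna_sites),
        }
        for t in triplets
    ]
    write_table(trip_rows, cfg.path("sponge_triplets.tsv"),
                ["lncrna_id", "mirna_id", "mrna_id", "r", "n_lnc_sites", "n_mrna_sites"],
                header_comment=cfg.header("targets"))

    lnctar_rows = []
    for e in edges:
        res = lnctar_ndg(
            annotation.transcript_sequence(e.lncrna_id),
            annotation.transcript_sequence(e.mrna_id),
            lncrna_id=e.lncrna_id, mrna_id=e.mrna_id, cutoff=cfg.ndg_cutoff,
        )
        lnctar_rows.append(
            {
                "lncrna_id": res.lncrna_id, "mrna_id": res.mrna_id,
                "best_dg": res.best_dg, "window_length": res.window_length,
                "ndg": res.ndg, "pass": res.passes,
            }
        )
    write_table(lnctar_rows, cfg.path("lnctar_pairs.tsv"),
                ["lncrna_id", "mrna_id", "best_dg", "window_length", "ndg", "pass"],
                header_comment=cfg.header("targets"))
    return {
        "n_site_calls": len(site_rows),
        "n_consensus_sites": sum(1 for r in site_rows if r["consensus"]),
        "n_sponge_triplets": len(trip_rows),
        "n_lnctar_pass": sum(1 for r in lnctar_rows if r["pass"]),
    }


def stage_tfbs(cfg: PipelineConfig) -> dict:
    annotation = _load_annotation(cfg)
    edges = _network_edges(cfg)
    pwms = read_pwms(cfg.path("pwms.txt"))

    members = sorted({e.lncrna_id for e in edges} | {e.mrna_id for e in edges})
    promoter_of = {tid: annotation.transcripts[tid].gene_id for tid in members}
    promoters = {
        promoter_of[tid]: extract_promoter(
            promoter_of[tid], annotation, length=cfg.promoter_length
        )
        for tid in members
    }
    promoters = {pid: seq for pid, seq in promoters.items() if seq}
    write_fasta(promoters, cfg.path("promoters.fa"))

    hits = scan_promoters(
        pwms, promoters,
        max_dissimilarity=cfg.max_dissimilarity, re_threshold=cfg.re_threshold,
    )
    hit_rows = [
        {
            "tf": h.tf_name, "promoter_id": h.sequence_id, "offset": h.offset,
            "strand": h.strand, "score": h.score,
            "dissimilarity": h.dissimilarity, "re": h.re,
        }
        for h in hits
    ]
    hit_rows.sort(key=lambda r: (r["promoter_id"], r["tf"], r["offset"]))
    write_table(hit_rows, cfg.path("tfbs_hits.tsv"),
                ["tf", "promoter_id", "offset", "strand", "score", "dissimilarity", "re"],
                header_comment=cfg.header("tfbs"))

    records, summary = shared_tfbs(edges, hits, promoter_of=promoter_of)
    write_table(records, cfg.path("shared_tfbs.tsv"),
                ["lncrna_id", "mrna_id", "shared_tfs", "n_shared", "flagged"],
                header_comment=cfg.header("tfbs"))
    summary_rows = [
        {"tf": tf, **counts} for tf, counts in sorted(summary.items())
    ]
    write_table(summary_rows, cfg.path("tfbs_summary.tsv"),
                ["tf", "n_lncrna_promoters", "n_mrna_promoters"],
                header_comment=cfg.header("tfbs"))
    return {
        "n_promoters": len(promoters),
        "n_hits": len(hit_rows),
        "n_pairs_sharing": sum(1 for r in records if r["n_shared"] > 0),
    }


def stage_enrich(cfg: PipelineConfig) -> dict:
    annotation = _load_annotation(cfg)
    edges = _network_edges(cfg)
    counts = read_expression_tsv(cfg.path("counts.tsv"))
    _, cod = _lnc_and_coding(annotation)

    expressed = set(counts.values.index[counts.values.sum(axis=1) > 0])
    universe = {t for t in cod if t in expressed}
    query = {e.mrna_id for e in edges} & universe
    if not query:
        write_table([], cfg.path("enrichment.tsv"),
                    ["term_id", "term_name", "k", "K", "n", "N", "fold_enrichment",
                     "p_value", "q_value"], header_comment=cfg.header("enrich"))
        write_table([], cfg.path("enrichment_map_nodes.tsv"),
                    ["term_id", "name", "k", "K", "fold_enrichment", "p", "q"],
                    header_comment=cfg.header("enrich"))
        write_table([], cfg.path("enrichment_map_edges.tsv"),
                    ["term_a", "term_b", "overlap_coefficient"],
                    header_comment=cfg.header("enrich"))
        return {"n_terms_tested": 0, "n_terms_significant": 0, "n_map_edges": 0}

    term_rows = read_table(cfg.path("annotation_map.tsv"))
    term_genes: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    for r in term_rows:
        term_genes.setdefault(r["term_id"], set()).add(r["gene_id"])
        term_names[r["term_id"]] = r.get("term_name", r["term_id"])

    terms = fisher_enrichment(query, term_genes, universe, names=term_names)
    rows = [
        {
            "term_id": t.term_id, "term_name": t.name, "k": t.k, "K": t.K,
            "n": t.n, "N": t.N, "fold_enrichment": t.fold_enrichment,
            "p_value": t.p_value, "q_value": t.q_value,
        }
        for t in terms
    ]
    write_table(rows, cfg.path("enrichment.tsv"),
                ["term_id", "term_name", "k", "K", "n", "N", "fold_enrichment",
                 "p_value", "q_value"], header_comment=cfg.header("enrich"))

    graph = build_enrichment_map(terms, fdr_cutoff=cfg.fdr_cutoff)
    nodes, map_edges = enrichment_map_tables(graph)
    write_table(nodes, cfg.path("enrichment_map_nodes.tsv"),
                ["term_id", "name", "k", "K", "fold_enrichment", "p", "q"],
                header_comment=cfg.header("enrich"))
    write_table(map_edges, cfg.path("enrichment_map_edges.tsv"),
                ["term_a", "term_b", "overlap_coefficient"],
                header_comment=cfg.header("enrich"))
    return {
        "n_terms_tested": len(terms),
        "n_terms_significant": sum(1 for t in terms if t.q_value < cfg.fdr_cutoff),
        "n_map_edges": len(map_edges),
    }


STAGES = [
    ("simulate", stage_simulate),
    ("phenotype", stage_phenotype),
    ("de", stage_de),
    ("classify", stage_classify),
    ("coexpress", stage_coexpress),
    ("targets", stage_targets),
    ("tfbs", stage_tfbs),
    ("enrich", stage_enrich),
]

_STAGE_FILES = {
    "simulate": ["genome.fa", "annotation.gff3", "counts.tsv", "phenotypes.tsv",
                 "mirnas.fa", "pwms.txt", "annotation_map.tsv"],
    "phenotype": ["corrected_phenotypes.tsv", "contrast_design.tsv"],
    "de": ["tpm.tsv", "de_results.tsv"],
    "classify": ["lnc_filter.tsv", "lnc_classification.tsv", "lnc_classes.bed"],
    "coexpress": ["network.tsv"],
    "targets": ["mirna_sites.tsv", "sponge_triplets.tsv", "lnctar_pairs.tsv"],
    "tfbs": ["promoters.fa", "tfbs_hits.tsv", "shared_tfbs.tsv", "tfbs_summary.tsv"],
    "enrich": ["enrichment.tsv", "enrichment_map_nodes.tsv", "enrichment_map_edges.tsv"],
}


def run_stage(cfg: PipelineConfig, name: str) -> dict:
    """Run one stage against the on-disk state of cfg.outdir."""
    fn = dict(STAGES)[name]
    try:
        return fn(cfg)
    except PipelineError:
        _mark_incomplete(cfg, name)
        raise
    except Exception as exc:
        _mark_incomplete(cfg, name)
        raise PipelineError(name, str(exc)) from exc


def _mark_incomplete(cfg: PipelineConfig, stage: str) -> None:
    for fname in _STAGE_FILES.get(stage, []):
        p = cfg.path(fname)
        if os.path.exists(p):
            os.replace(p, p + ".incomplete")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order; returns (and writes) the run manifest."""
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(cfg).items()
            if k not in {"simulate", "inputs", "outdir"}
        },
        "stages": {},
    }
    for name, _fn in STAGES:
        manifest["stages"][name] = run_stage(cfg, name)
    with open(cfg.path("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
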