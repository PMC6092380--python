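import numpy as np
import pytest

from lncweave.io_formats import Gene, GenomeAnnotation, Transcript
from lncweave.pipeline import PipelineConfig, run_pipeline
from lncweave.synthetic_data import SimulationConfig


def small_sim_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A scaled-down study: same structure, faster to generate."""
    base = dict(
        seed=seed,
        n_contigs=2,
        n_coding=40,
        n_lnc=24,
        n_de_lnc=10,
        n_de_coding=6,
        n_pairs=4,
        n_sponge=2,
        n_tf_pairs=2,
        n_mirnas=6,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One deterministic end-to-end run shared by the read-only tests."""
    outdir = tmp_path_factory.mktemp("run") / "out"
    cfg = PipelineConfig(outdir=str(outdir), seed=3, simulate=small_sim_config(seed=3))
    manifest = run_pipeline(cfg)
    return cfg, manifest


def random_toy_annotation(rng: np.random.Generator) -> tuple[GenomeAnnotation, list[str]]:
    """Adversarial random annotation: arbitrary gene/lncRNA placements.

    Coding genes and lncRNAs are thrown onto short contigs with no layout
    discipline, so overlaps of every kind occur; used to exercise the
    positional classifier against the per-base oracle.
    """
    n_contigs = int(rng.integers(1, 3))
    lengths = {f"c{i}": int(rng.integers(30_000, 120_000)) for i in range(n_contigs)}
    genes, transcripts = {}, {}

    def random_tx(gid, tid, contig, start, max_end):
        n_ex = int(rng.integers(1, 4))
        exons, pos = [], start
        for i in range(n_ex):
            elen = int(rng.integers(50, 400))
            if pos + elen > max_end:
                break
            exons.append((pos, pos + elen))
            pos += elen + int(rng.integers(50, 800))
        if not exons:
            exons = [(start, min(start + 60, max_end))]
        return exons

    n_genes = int(rng.integers(3, 12))
    for i in range(n_genes):
        contig = f"c{int(rng.integers(n_contigs))}"
        start = int(rng.integers(0, lengths[contig] - 5_000))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = random_tx(f"g{i}", f"m{i}", contig, start, lengths[contig])
        genes[f"g{i}"] = Gene(f"g{i}", contig, strand, exons[0][0], exons[-1][1], "protein_coding")
        transcripts[f"m{i}"] = Transcript(f"m{i}", f"g{i}", exons)

    lnc_ids = []
    n_lnc = int(rng.integers(3, 15))
    for i in range(n_lnc):
        contig = f"c{int(rng.integers(n_contigs))}"
        start = int(rng.integers(0, lengths[contig] - 3_000))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = random_tx(f"lg{i}", f"l{i}", contig, start, lengths[contig])
        genes[f"lg{i}"] = Gene(f"lg{i}", contig, strand, exons[0][0], exons[-1][1], "lncRNA")
        transcripts[f"l{i}"] = Transcript(f"l{i}", f"lg{i}", exons)
        lnc_ids.append(f"l{i}")

    ann = GenomeAnnotation(contig_lengths=lengths, genes=genes, transcripts=transcripts)
    return ann, lnc_ids
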