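import numpy as np
import pytest

from conftest import small_sim_config
from lncweave.diffexpr import compute_tpm
from lncweave.genome_classify import longest_orf_codons
from lncweave.phenotype import whiteness_index
from lncweave.rna_interactions import reverse_complement_rna
from lncweave.synthetic_data import (
    SimulationConfig,
    assign_trait_families,
    generate_expression,
    generate_genome,
    generate_phenotypes,
    generate_regulatory,
)


class TestConfigValidation:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(class_proportions={"exonic": 0.5, "intronic": 0.2, "intergenic": 0.2})

    def test_fold_change_below_one_rejected(self):
        with pytest.raises(ValueError, match="fold change"):
            SimulationConfig(fold_change=0.5)

    def test_planted_counts_bounded_by_totals(self):
        with pytest.raises(ValueError, match="exceed"):
            SimulationConfig(n_de_lnc=200, n_lnc=10)

    def test_contig_too_short_raises_sizing_error(self):
        with pytest.raises(ValueError, match="too short"):
            generate_genome(small_sim_config(contig_length=10_000))


class TestGenome:
    def test_same_seed_gives_identical_genome(self):
        a_ann, a_truth = generate_genome(small_sim_config(seed=9))
        b_ann, b_truth = generate_genome(small_sim_config(seed=9))
        assert a_ann.contigs == b_ann.contigs
        assert {g: v.span for g, v in a_ann.genes.items()} == {
            g: v.span for g, v in b_ann.genes.items()
        }
        assert a_truth.lnc_class == b_truth.lnc_class

    def test_requested_class_counts_realized_exactly(self):
        cfg = small_sim_config(seed=4)
        _, truth = generate_genome(cfg)
        want = cfg.class_counts()
        got = {"exonic": 0, "intronic": 0, "intergenic": 0}
        for rec in truth.lnc_class.values():
            key = rec["category"].replace("genic_", "")
            got[key] += 1
        assert got == want

    def test_far_intergenic_has_no_neighbor_in_window(self):
        from lncweave.genome_classify import find_neighbors

        cfg = small_sim_config(seed=6)
        ann, truth = generate_genome(cfg)
        far = [
            tid for tid, rec in truth.lnc_class.items()
            if rec["category"] == "intergenic" and rec["orientation"] == "not_applicable"
        ]
        assert far
        for tid in far:
            assert find_neighbors(tid, ann, window=50_000) == []

    def test_lncrna_orfs_scrubbed_below_threshold(self):
        ann, truth = generate_genome(small_sim_config(seed=7))
        for tid in truth.lnc_class:
            assert longest_orf_codons(ann.transcript_sequence(tid)) < 100

    def test_mrnas_carry_3utr(self):
        ann, _ = generate_genome(small_sim_config(seed=8))
        for tid, t in ann.transcripts.items():
            if tid.startswith("mrna"):
                assert t.utr3 is not None
                assert t.utr3[1] - t.utr3[0] == 150


class TestTraitDesigns:
    def test_union_of_contrasts_is_sequenced_pool(self):
        cfg = SimulationConfig(seed=2)
        _, designs = assign_trait_families(cfg)
        union = {f for d in designs.values() for f in d["high"] + d["low"]}
        assert len(union) == cfg.n_sequenced
        for d in designs.values():
            assert len(d["high"]) == len(d["low"]) == 4
            assert set(d["high"]).isdisjoint(d["low"])


class TestPhenotypes:
    def test_whiteness_column_consistent_with_lab(self):
        phen, _ = generate_phenotypes(SimulationConfig(seed=1))
        recomputed = whiteness_index(phen["L"], phen["a"], phen["b"])
        assert np.allclose(phen["whiteness"], np.round(recomputed, 4))

    def test_r2_calibration_without_contrast_shifts(self):
        from lncweave.phenotype import correct_for_covariate

        r2s = []
        for seed in range(6):
            cfg = SimulationConfig(seed=seed, trait_shift_sd=0.0)
            phen, _ = generate_phenotypes(cfg)
            _, r2 = correct_for_covariate(
                phen["muscle_yield"].to_numpy(), {"WBW": phen["WBW"]}
            )
            r2s.append(r2)
        assert np.mean(r2s) == pytest.approx(0.56, abs=0.10)

    def test_whiteness_nearly_independent_of_wbw(self):
        from lncweave.phenotype import correct_for_covariate

        cfg = SimulationConfig(seed=3, trait_shift_sd=0.0)
        phen, _ = generate_phenotypes(cfg)
        _, r2 = correct_for_covariate(phen["whiteness"].to_numpy(), {"WBW": phen["WBW"]})
        assert r2 < 0.08


class TestExpression:
    def test_same_seed_gives_identical_counts(self):
        cfg = small_sim_config(seed=5)
        ann, truth = generate_genome(cfg)
        c1 = generate_expression(ann, cfg, truth)
        ann2, truth2 = generate_genome(cfg)
        c2 = generate_expression(ann2, cfg, truth2)
        assert c1.values.equals(c2.values)

    def test_planted_de_shows_in_group_means(self):
        cfg = small_sim_config(seed=6)
        ann, truth = generate_genome(cfg)
        counts = generate_expression(ann, cfg, truth)
        # pair members carry a deliberately heavy latent factor, so their
        # group means are noisy; direction is asserted on the plain DE set
        pair_ids = {p["lncrna_id"] for p in truth.pairs} | {p["mrna_id"] for p in truth.pairs}
        ok = total = 0
        for trait, calls in truth.de.items():
            d = truth.trait_families[trait]
            for tid, direction in calls.items():
                if tid in pair_ids:
                    continue
                mh = counts.values.loc[tid, d["high"]].mean()
                ml = counts.values.loc[tid, d["low"]].mean()
                total += 1
                ok += (mh > ml) == (direction > 0)
        assert total > 0 and ok / total >= 0.95

    def test_unknown_family_in_design_rejected(self):
        cfg = small_sim_config(seed=6)
        ann, truth = generate_genome(cfg)
        designs = {t: {"high": ["F999"] * 4, "low": ["F01", "F02", "F03", "F04"]}
                   for t in ("WBW", "muscle_yield", "fat", "shear_force", "whiteness")}
        with pytest.raises(ValueError, match="unknown families"):
            generate_expression(ann, cfg, truth, designs)

    def test_planted_pairs_correlate_above_background(self):
        cfg = small_sim_config(seed=7)
        ann, truth = generate_genome(cfg)
        counts = generate_expression(ann, cfg, truth)
        lengths = {tid: tx.spliced_length for tid, tx in ann.transcripts.items()}
        tpm = compute_tpm(counts, lengths).values
        rng = np.random.default_rng(0)
        pair_r = [
            np.corrcoef(tpm.loc[p["lncrna_id"]], tpm.loc[p["mrna_id"]])[0, 1]
            for p in truth.pairs
        ]
        ids = list(tpm.index)
        null_r = []
        for _ in range(50):
            a, b = rng.choice(ids, 2, replace=False)
            null_r.append(np.corrcoef(tpm.loc[a], tpm.loc[b])[0, 1])
        assert np.median(pair_r) > np.quantile(null_r, 0.95)


class TestRegulatory:
    def test_planted_site_is_full_reverse_complement(self):
        cfg = small_sim_config(seed=8)
        ann, truth = generate_genome(cfg)
        generate_expression(ann, cfg, truth)
        mirnas, _ = generate_regulatory(ann, cfg, truth)
        for sp in truth.sponges:
            site = reverse_complement_rna(mirnas[sp["mirna_id"]]).replace("U", "T")
            lseq = ann.transcript_sequence(sp["lncrna_id"])
            off = sp["lnc_site_offset"]
            assert lseq[off : off + sp["site_length"]] == site
            # the 8mer core (reverse complement of positions 1-8) is inside it
            core8 = reverse_complement_rna(mirnas[sp["mirna_id"]][:8]).replace("U", "T")
            assert core8 in lseq

    def test_planted_mirnas_start_with_u(self):
        cfg = small_sim_config(seed=9)
        ann, truth = generate_genome(cfg)
        generate_expression(ann, cfg, truth)
        mirnas, _ = generate_regulatory(ann, cfg, truth)
        assert all(seq.startswith("U") for seq in mirnas.values())

    def test_regulatory_determinism(self):
        outs = []
        for _ in range(2):
            cfg = small_sim_config(seed=10)
            ann, truth = generate_genome(cfg)
            generate_expression(ann, cfg, truth)
            mirnas, pwms = generate_regulatory(ann, cfg, truth)
            outs.append((mirnas, [(p.name, p.counts.tolist()) for p in pwms],
                         truth.sponges, truth.tf_insertions, ann.contigs))
        assert outs[0] == outs[1]

    def test_ground_truth_ids_all_exist(self):
        cfg = small_sim_config(seed=11)
        ann, truth = generate_genome(cfg)
        generate_expression(ann, cfg, truth)
        mirnas, pwms = generate_regulatory(ann, cfg, truth)
        tids = set(ann.transcripts)
        assert set(truth.lnc_class) <= tids
        assert truth.de_ids() <= tids
        for p in truth.pairs:
            assert {p["lncrna_id"], p["mrna_id"]} <= tids
        for s in truth.sponges:
            assert s["mirna_id"] in mirnas
            assert {s["lncrna_id"], s["mrna_id"]} <= tids
        pwm_names = {p.name for p in pwms}
        for ins in truth.tf_insertions:
            assert ins["tf"] in pwm_names
            assert ins["gene_id"] in ann.genes
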