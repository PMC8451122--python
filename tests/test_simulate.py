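"""Synthetic-data generators: determinism, validation, planted truth."""

import numpy as np
import pytest

from phageadapt.io import ValidationError
from phageadapt import simulate as sim
from phageadapt.synteny import HomologyPairing, pair_homologs, call_blocks
from phageadapt.recruitment import rbb_filter
from phageadapt.tetra import count_tetra


class TestMarkovMachinery:
    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        model = sim.random_order3_model(rng)
        assert model.shape == (64, 4)
        np.testing.assert_allclose(model.sum(axis=1), 1.0, atol=1e-12)

    def test_default_mosaic_models_diverge_measurably(self):
        rng = np.random.default_rng(1)
        base, donor = sim.default_mosaic_models(rng)
        d = sim.signature_divergence(base, donor, n_bases=50_000, seed=0)
        assert d >= 0.002

    def test_sampled_chain_reflects_transition_bias(self):
        # a chain that always emits A after any context is all-A past the seed
        model = np.zeros((64, 4))
        model[:, 0] = 1.0
        rng = np.random.default_rng(2)
        seq = sim.sample_order3_chain(model, 100, rng)
        assert set(seq[3:]) == {"A"}


class TestMosaic:
    def test_same_seed_identical(self):
        g1, t1 = sim.make_mosaic_genome(sim.MosaicSpec(seed=9))
        g2, t2 = sim.make_mosaic_genome(sim.MosaicSpec(seed=9))
        assert g1.residues == g2.residues
        assert t1 == t2

    def test_different_seed_differs(self):
        g1, _ = sim.make_mosaic_genome(sim.MosaicSpec(seed=1))
        g2, _ = sim.make_mosaic_genome(sim.MosaicSpec(seed=2))
        assert g1.residues != g2.residues

    def test_zero_insert_length_rejected(self):
        with pytest.raises(ValidationError):
            sim.MosaicSpec(insert_length=0)

    def test_insert_overflowing_background_rejected(self):
        with pytest.raises(ValidationError):
            sim.MosaicSpec(background_length=10_000, insert_length=5_000, insert_position=7_000)

    def test_truth_span_and_total_length(self):
        spec = sim.MosaicSpec(background_length=20_000, insert_length=6_000, insert_position=5_000, seed=3)
        g, truth = sim.make_mosaic_genome(spec)
        assert len(g) == 20_000
        assert truth == {"insert_start": 5_000, "insert_end": 10_999}

    def test_insert_composition_differs_from_background(self):
        g, truth = sim.make_mosaic_genome(sim.MosaicSpec(seed=4))
        ins = g.residues[truth["insert_start"] - 1 : truth["insert_end"]]
        bg = g.residues[: truth["insert_start"] - 1]
        fi = count_tetra(ins).frequencies()
        fb = count_tetra(bg).frequencies()
        assert np.mean(np.abs(fi - fb)) >= 0.002


class TestReplichore:
    def test_same_seed_identical(self):
        g1, _ = sim.make_replichore_genome(sim.ReplichoreSpec(seed=5))
        g2, _ = sim.make_replichore_genome(sim.ReplichoreSpec(seed=5))
        assert g1.residues == g2.residues

    def test_invalid_origin_rejected(self):
        with pytest.raises(ValidationError):
            sim.ReplichoreSpec(length=100, origin_position=200)

    def test_strand_bias_sign_flips_at_origin(self):
        spec = sim.ReplichoreSpec(length=30_000, origin_position=10_000, bias=0.2, seed=6)
        g, truth = sim.make_replichore_genome(spec)
        before = g.residues[: truth["origin_position"] - 1]
        after = g.residues[truth["origin_position"] - 1 :]
        skew_before = (before.count("G") - before.count("C")) / (
            before.count("G") + before.count("C")
        )
        skew_after = (after.count("G") - after.count("C")) / (
            after.count("G") + after.count("C")
        )
        assert skew_before < -0.1 and skew_after > 0.1

    def test_zero_bias_null_case_is_flat_on_average(self):
        g, _ = sim.make_replichore_genome(sim.ReplichoreSpec(bias=0.0, seed=7))
        skew = (g.residues.count("G") - g.residues.count("C")) / (
            g.residues.count("G") + g.residues.count("C")
        )
        assert abs(skew) < 0.05


class TestSyntenyPair:
    def test_planted_block_called_exactly(self):
        genes_a, genes_b, hits, truth = sim.make_synteny_pair(
            30, 30, [(3, 5, "0,0,0,0")], seed=8
        )
        pairing = pair_homologs(hits, genes_a, genes_b)
        blocks = call_blocks(genes_a, genes_b, pairing)
        assert len(blocks) == 1
        tb = truth["blocks"][0]
        assert blocks[0].a_range == tb["a_range"]
        assert blocks[0].b_range == tb["b_range"]
        assert blocks[0].n_syntenic == tb["n_syntenic"]

    def test_no_planted_blocks_calls_nothing(self):
        genes_a, genes_b, hits, _ = sim.make_synteny_pair(20, 20, [], seed=9)
        pairing = pair_homologs(hits, genes_a, genes_b)
        assert call_blocks(genes_a, genes_b, pairing) == []

    def test_gap_of_five_prevents_block(self):
        genes_a, genes_b, hits, _ = sim.make_synteny_pair(
            40, 40, [(2, 5, "0,0,5,0")], seed=10
        )
        pairing = pair_homologs(hits, genes_a, genes_b)
        assert call_blocks(genes_a, genes_b, pairing) == []

    def test_deterministic_under_seed(self):
        out1 = sim.make_synteny_pair(15, 15, [(1, 5, "1,0,2,0")], seed=11)
        out2 = sim.make_synteny_pair(15, 15, [(1, 5, "1,0,2,0")], seed=11)
        assert out1[0] == out2[0] and out1[1] == out2[1] and out1[2] == out2[2]

    def test_bad_gap_pattern_rejected(self):
        with pytest.raises(ValidationError):
            sim.make_synteny_pair(30, 30, [(1, 5, "0,0")], seed=0)


class TestRecruitmentTables:
    def test_zero_noise_rbb_recovers_truth_exactly(self):
        fwd, rev, orfs, truth = sim.make_recruitment_tables(sim.RecruitSpec(seed=12))
        pairs = rbb_filter(fwd, rev)
        got = {o.gene_id: 0 for o in orfs}
        for _r, o in pairs:
            got[o] += 1
        assert got == truth["counts"]

    def test_full_reciprocity_noise_recovers_below_truth(self):
        spec = sim.RecruitSpec(n_orfs=5, reciprocity_noise=1.0, seed=13)
        fwd, rev, orfs, truth = sim.make_recruitment_tables(spec)
        pairs = rbb_filter(fwd, rev)
        assert len(pairs) < truth["total_planted"]

    def test_all_decoys_recruit_nothing(self):
        spec = sim.RecruitSpec(n_orfs=5, decoy_rate=1.0, seed=14)
        fwd, rev, orfs, truth = sim.make_recruitment_tables(spec)
        assert rev == []
        assert rbb_filter(fwd, rev) == set()

    def test_deterministic_under_seed(self):
        a = sim.make_recruitment_tables(sim.RecruitSpec(seed=15))
        b = sim.make_recruitment_tables(sim.RecruitSpec(seed=15))
        assert a[0] == b[0] and a[1] == b[1] and a[3] == b[3]

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            sim.RecruitSpec(decoy_rate=1.5)
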