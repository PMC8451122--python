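"""Tetranucleotide counting, z-scoring, fragment slicing and profiling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phageadapt.io import GenomeSequence
from phageadapt.tetra import (
    TETRAMER_INDEX,
    DegenerateSignatureError,
    count_tetra,
    zscore,
    slice_fragments,
    pearson,
    signature_profile,
    locate_anomaly,
    SignatureProfile,
)

dna = st.text(alphabet="ACGT", min_size=4, max_size=300)
dna_with_n = st.text(alphabet="ACGTN", min_size=4, max_size=300)


class TestCountTetra:
    def test_homopolymer(self):
        tv = count_tetra("AAAAA")
        assert tv.counts[TETRAMER_INDEX["AAAA"]] == 2
        assert tv.counts.sum() == 2
        assert tv.n_windows_counted == 2

    def test_hand_enumerated_windows(self):
        # ACGTACGT windows: ACGT CGTA GTAC TACG ACGT
        tv = count_tetra("ACGTACGT")
        expected = {"ACGT": 2, "CGTA": 1, "GTAC": 1, "TACG": 1}
        for mer, n in expected.items():
            assert tv.counts[TETRAMER_INDEX[mer]] == n
        assert tv.n_windows_counted == 5
        assert tv.counts.sum() == 5

    def test_window_containing_n_skipped(self):
        tv = count_tetra("ACGTN")
        assert tv.counts[TETRAMER_INDEX["ACGT"]] == 1
        assert tv.n_windows_counted == 1
        assert tv.counts.sum() == 1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            count_tetra("ACG")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(dna_with_n)
    def test_matches_naive_recount(self, seq):
        """Vectorized counts agree with direct substring extraction."""
        naive = {}
        n_valid = 0
        for i in range(len(seq) - 3):
            w = seq[i : i + 4]
            if "N" in w:
                continue
            naive[w] = naive.get(w, 0) + 1
            n_valid += 1
        tv = count_tetra(seq)
        assert tv.n_windows_counted == n_valid
        assert int(tv.counts.sum()) == n_valid
        for mer, n in naive.items():
            assert tv.counts[TETRAMER_INDEX[mer]] == n


class TestZscore:
    def test_closed_form_three_values(self):
        out = zscore(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out, [-1.2247449, 0.0, 1.2247449], atol=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateSignatureError):
            zscore(np.full(256, 3.25))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=256).filter(lambda v: len(set(v)) > 1))
    def test_output_mean_zero_sd_one(self, v):
        out = zscore(np.array(v))
        assert abs(out.mean()) < 1e-9
        assert abs(out.std() - 1.0) < 1e-9


class TestSliceFragments:
    def test_phage_sized_genome_yields_34_fragments(self):
        rng = np.random.default_rng(0)
        g = GenomeSequence(
            id="g", residues="".join(rng.choice(list("ACGT"), size=33_786))
        )
        frags = slice_fragments(g, window_bp=10_000, step_bp=1_000)
        assert len(frags) == 34
        assert all(len(f[2]) == 10_000 for f in frags)
        assert [f[0] for f in frags] == list(range(1, 35))

    def test_window_equal_length_gives_rotations(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        g = GenomeSequence(id="g", residues=seq)
        frags = slice_fragments(g, window_bp=10_000, step_bp=1_000)
        assert len(frags) == 10
        doubled = seq + seq
        for _, _, frag in frags:
            assert len(frag) == 10_000
            assert frag in doubled  # every rotation is a substring of seq+seq

    def test_window_longer_than_genome_rejected(self):
        g = GenomeSequence(id="g", residues="ACGT" * 1_250)  # 5 kb
        with pytest.raises(ValueError, match="window"):
            slice_fragments(g, window_bp=10_000, step_bp=1_000)

    def test_wrap_padding_preserves_composition_of_central_fragment(self, toy_genome):
        # a fragment spanning the whole genome is a rotation: same base counts
        frags = slice_fragments(toy_genome, window_bp=40, step_bp=40)
        assert len(frags) == 1
        assert sorted(frags[0][2]) == sorted(toy_genome.residues)


class TestPearson:
    def test_self_correlation_is_one(self):
        v = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson(v, v) == pytest.approx(1.0)

    def test_anticorrelation_is_minus_one(self):
        v = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson(v, -v) == pytest.approx(-1.0)

    def test_closed_form_four_tuple(self):
        r = pearson(np.array([1, 2, 3, 4.0]), np.array([1, 2, 3, 5.0]))
        assert r == pytest.approx(0.9827076, abs=1e-6)

    def test_symmetric(self):
        a = np.array([1, 2.0, 7, 3])
        b = np.array([2, 0.5, 3, 9])
        assert pearson(a, b) == pearson(b, a)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateSignatureError):
            pearson(np.ones(4), np.array([1, 2, 3, 4.0]))


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(42)
    return GenomeSequence(
        id="g", residues="".join(rng.choice(list("ACGT"), size=20_000))
    )


class TestSignatureProfile:
    def test_fragment_count_and_bounds(self, genome):
        prof = signature_profile(genome, window_bp=5_000, step_bp=1_000)
        assert len(prof) == 20
        assert np.all(prof.r_self >= -1) and np.all(prof.r_self <= 1)
        # every z-vector has mean 0 and population sd 1
        np.testing.assert_allclose(prof.zvec.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(prof.zvec.std(axis=1), 1, atol=1e-9)

    def test_host_equal_phage_gives_identical_tracks(self, genome):
        prof = signature_profile(genome, host=genome, window_bp=5_000, step_bp=1_000)
        np.testing.assert_array_equal(prof.r_self, prof.r_host)

    def test_no_host_leaves_r_host_absent(self, genome):
        prof = signature_profile(genome, window_bp=5_000, step_bp=1_000)
        assert prof.r_host is None

    def test_whole_genome_signature_self_correlates_to_one(self, genome):
        tv = count_tetra(genome.residues)
        z = zscore(tv.frequencies())
        assert pearson(z, z) == pytest.approx(1.0)

    def test_strand_both_differs_but_stays_bounded(self, genome):
        prof = signature_profile(genome, window_bp=5_000, step_bp=1_000, strand="both")
        assert np.all(prof.r_self >= -1) and np.all(prof.r_self <= 1)


class TestLocateAnomaly:
    @staticmethod
    def _profile(r_self):
        r = np.asarray(r_self, dtype=float)
        n = len(r)
        return SignatureProfile(
            window_bp=10,
            step_bp=1,
            fragment_index=np.arange(1, n + 1),
            fragment_center_bp=np.arange(1, n + 1),
            zvec=np.zeros((n, 256)),
            r_self=r,
        )

    def test_monotone_track_has_no_dip_span(self):
        out = locate_anomaly(self._profile(np.linspace(0.99, 0.90, 10)))
        assert out["min_fragment_index"] == 10
        assert out["dip_span"] is None

    def test_flat_track_with_three_fragment_dip(self):
        r = [0.95] * 10 + [0.70, 0.65, 0.72] + [0.95] * 10
        out = locate_anomaly(self._profile(r))
        assert out["min_fragment_index"] == 12
        assert out["min_r_self"] == pytest.approx(0.65)
        assert out["dip_span"] == (11, 13)

    def test_tie_broken_to_first_fragment(self):
        r = [0.9, 0.5, 0.9, 0.5, 0.9]
        out = locate_anomaly(self._profile(r))
        assert out["min_fragment_index"] == 2
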