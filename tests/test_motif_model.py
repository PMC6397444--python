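"""Motif model chain: counts, probabilities, background, PSSM, IC."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motifmc import motif_model as mm
from motifmc.genome_io import GenomeRecord
from motifmc.motif_model import (Background, FrequencyMatrix,
                                 ProbabilityMatrix, TrainingSet,
                                 background_from_genome, build_pssm,
                                 counts_from_alignment, information_content,
                                 probabilities, read_matrix,
                                 reduce_training_set, score)


class TestCounts:
    def test_simple_alignment(self):
        f = counts_from_alignment(TrainingSet(["AC", "AC"]))
        assert f.counts[0, 0] == 2 and f.counts[1, 1] == 2
        assert f.counts.sum() == 4

    def test_mixed_columns(self):
        f = counts_from_alignment(TrainingSet(["AA", "TT"]))
        np.testing.assert_array_equal(f.counts[:, 0], [1, 0, 0, 1])
        np.testing.assert_array_equal(f.counts[:, 1], [1, 0, 0, 1])

    def test_column_sums_equal_n_sites(self):
        rng = np.random.default_rng(0)
        sites = ["".join(rng.choice(list("ACGT"), 17)) for _ in range(15)]
        f = counts_from_alignment(TrainingSet(sites))
        np.testing.assert_array_equal(f.counts.sum(axis=0), [15] * 17)
        assert f.n_sites == 15

    def test_ragged_sites_fatal(self):
        with pytest.raises(ValueError):
            TrainingSet(["ACG", "AC"])


class TestProbabilities:
    def test_no_pseudocount(self):
        f = FrequencyMatrix(np.array([[2.0], [0], [0], [0]]))
        np.testing.assert_allclose(probabilities(f, 0.0).p[:, 0],
                                   [1, 0, 0, 0])

    def test_half_pseudocount(self):
        f = FrequencyMatrix(np.array([[2.0], [0], [0], [0]]))
        np.testing.assert_allclose(probabilities(f, 0.5).p[:, 0],
                                   [0.625, 0.125, 0.125, 0.125])

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(1)
        f = FrequencyMatrix(rng.multinomial(20, [0.25] * 4, size=6).T)
        p = probabilities(f, 0.3).p
        np.testing.assert_allclose(p.sum(axis=0), 1.0, atol=1e-12)

    def test_zero_total_with_zero_pseudocount_fatal(self):
        f = FrequencyMatrix(np.zeros((4, 2)))
        with pytest.raises(ValueError):
            probabilities(f, 0.0)


class TestBackground:
    @pytest.mark.parametrize("seq,expect", [
        ("GGCC", [0.0, 0.5, 0.5, 0.0]),
        ("ACGT", [0.25] * 4),
        ("AATT", [0.5, 0.0, 0.0, 0.5]),
    ])
    def test_gc_symmetric(self, seq, expect):
        bg = background_from_genome(GenomeRecord("x", seq))
        np.testing.assert_allclose(bg.q, expect)

    def test_all_n_fatal(self):
        with pytest.raises(ValueError):
            background_from_genome(GenomeRecord("x", "NNNN"))

    def test_strand_symmetry_invariant(self):
        q = background_from_genome(GenomeRecord("x", "ACGGGTTACG")).q
        assert q[0] == q[3] and q[1] == q[2]
        assert abs(q.sum() - 1) < 1e-12


class TestPssm:
    def test_deterministic_column_sentinel(self):
        p = ProbabilityMatrix(np.array([[1.0], [0], [0], [0]]))
        s = build_pssm(p, Background(0.5)).s
        assert s[0, 0] == pytest.approx(2.0)
        assert np.all(np.isneginf(s[1:, 0]))

    def test_p_equals_q_scores_zero(self):
        p = ProbabilityMatrix(np.full((4, 3), 0.25))
        pssm = build_pssm(p, Background(0.5))
        assert np.allclose(pssm.s, 0.0)
        assert pssm.max_score == 0.0

    def test_max_score_arithmetic(self):
        col = np.array([0.625, 0.125, 0.125, 0.125])
        p = ProbabilityMatrix(np.stack([col, col], axis=1))
        pssm = build_pssm(p, Background(0.5))
        assert pssm.max_score == pytest.approx(2 * np.log2(2.5))

    def test_json_roundtrip(self, tmp_path):
        p = ProbabilityMatrix(np.array([[1.0, 0.25], [0, 0.25],
                                        [0, 0.25], [0, 0.25]]))
        pssm = build_pssm(p, Background(0.4), n_sites=7, name="m")
        path = tmp_path / "pssm.json"
        pssm.to_json(path)
        back = mm.Pssm.from_json(path)
        np.testing.assert_allclose(back.s, pssm.s)
        assert back.background.gc == pssm.background.gc


class TestScore:
    def test_consensus_hits_max(self, small_pssm):
        assert score(small_pssm, small_pssm.consensus()) == \
            pytest.approx(small_pssm.max_score)

    def test_window_with_n_is_minus_inf(self, small_pssm):
        lmer = "N" + small_pssm.consensus()[1:]
        assert score(small_pssm, lmer) == float("-inf")

    def test_wrong_length_fatal(self, small_pssm):
        with pytest.raises(ValueError):
            score(small_pssm, "ACGT")

    def test_likelihood_ratio_normalization_small(self):
        """sum over all L-mers of P_bg(x) * 2^S(x) must be exactly 1."""
        rng = np.random.default_rng(5)
        for _ in range(3):
            L = int(rng.integers(2, 5))
            counts = rng.multinomial(12, rng.dirichlet([1.0] * 4), size=L).T
            pssm = build_pssm(probabilities(FrequencyMatrix(counts), 0.5),
                              Background(float(rng.uniform(0.2, 0.8))))
            q = pssm.background.q
            total = 0.0
            for lmer in itertools.product("ACGT", repeat=L):
                w = "".join(lmer)
                pbg = np.prod([q["ACGT".index(c)] for c in w])
                total += pbg * 2.0 ** score(pssm, w)
            assert total == pytest.approx(1.0, abs=1e-9)


class TestInformationContent:
    def test_uniform_is_zero(self):
        assert information_content(
            ProbabilityMatrix(np.full((4, 5), 0.25))) == pytest.approx(0.0)

    def test_deterministic_is_two_per_column(self):
        p = np.zeros((4, 17))
        p[0] = 1.0
        assert information_content(ProbabilityMatrix(p)) == pytest.approx(34.0)

    def test_half_half_columns(self):
        p = np.array([[0.5, 0.5], [0.5, 0.5], [0, 0], [0, 0.0]])
        assert information_content(ProbabilityMatrix(p)) == pytest.approx(2.0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_ic_bounds_and_pseudocount_shrinkage(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(1, 12))
        counts = rng.multinomial(
            int(rng.integers(2, 40)), rng.dirichlet([0.5] * 4), size=L).T
        f = FrequencyMatrix(counts.astype(float))
        ic0 = information_content(probabilities(f, 0.0))
        ic1 = information_content(probabilities(f, 0.7))
        assert -1e-9 <= ic0 <= 2 * L + 1e-9
        assert ic1 <= ic0 + 1e-9

    def test_column_heights_sum_to_ic(self):
        rng = np.random.default_rng(3)
        f = FrequencyMatrix(rng.multinomial(9, [0.4, 0.3, 0.2, 0.1],
                                            size=6).T.astype(float))
        prob = probabilities(f, 0.0)
        assert mm.column_heights(prob).sum() == pytest.approx(
            information_content(prob))


class TestMonotonicity:
    def test_extra_count_never_decreases_score(self):
        rng = np.random.default_rng(7)
        counts = rng.multinomial(10, [0.25] * 4, size=4).T.astype(float)
        base = build_pssm(probabilities(FrequencyMatrix(counts), 0.5),
                          Background(0.5)).s
        for a in range(4):
            for i in range(4):
                bumped = counts.copy()
                bumped[a, i] += 1
                # column sums must stay equal: bump every column's total
                for j in range(4):
                    if j != i:
                        bumped[rng.integers(0, 4), j] += 1
                s2 = build_pssm(
                    probabilities(FrequencyMatrix(bumped), 0.5),
                    Background(0.5)).s
                assert s2[a, i] >= base[a, i] - 1e-12


class TestReduceTrainingSet:
    def test_identity_when_n_equals_size(self):
        ts = TrainingSet(["ACG", "ACT", "ACG"])
        assert reduce_training_set(ts, 3).sites == ts.sites

    def test_majority_sites_kept(self):
        out = reduce_training_set(TrainingSet(["AA", "AA", "AT"]), 2)
        assert out.sites == ["AA", "AA"]

    def test_n1_picks_best_scoring_site(self):
        # brute force: score each site under the full model
        ts = TrainingSet(["AAAA", "AAAT", "TTTT"])
        full = mm.pssm_from_sites(ts, Background(0.5))
        scores = [score(full, s) for s in ts.sites]
        best = ts.sites[int(np.argmax(scores))]
        assert reduce_training_set(ts, 1).sites == [best]

    def test_bad_n_fatal(self):
        with pytest.raises(ValueError):
            reduce_training_set(TrainingSet(["AA"]), 2)


class TestReadMatrix:
    def test_plain4row(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("2 0\n0 2\n0 0\n0 0\n")
        f = read_matrix(p, "plain4row")
        assert f.length == 2 and f.n_sites == 2
        np.testing.assert_array_equal(f.counts[0], [2, 0])

    def test_plain4row_labeled(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("A | 2 0\nC | 0 2\nG | 0 0\nT | 0 0\n")
        f = read_matrix(p, "plain4row")
        assert f.counts[1, 1] == 2

    def test_regulondb_block_selection(self, tmp_path):
        p = tmp_path / "pssmset.txt"
        p.write_text(
            "Transcription Factor Name: AraC\n"
            "A | 15 0\nC | 0 15\nG | 0 0\nT | 0 0\n"
            "\n"
            "Transcription Factor Name: PurR\n"
            "A | 0 21\nC | 21 0\nG | 0 0\nT | 0 0\n")
        f = read_matrix(p, "regulondb", name="purr")
        assert f.n_sites == 21 and f.counts[1, 0] == 21
        first = read_matrix(p, "regulondb")
        assert first.n_sites == 15

    def test_unequal_rows_fatal(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("1 2 3\n1 2\n1 2 3\n1 2 3\n")
        with pytest.raises(ValueError):
            read_matrix(p, "plain4row")

    def test_negative_counts_fatal(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("1 -2\n1 2\n1 2\n1 2\n")
        with pytest.raises(ValueError):
            read_matrix(p, "plain4row")
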