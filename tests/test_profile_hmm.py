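import math

import numpy as np
import pytest

from spretrace._dna import revcomp
from spretrace.profile_hmm import (
    CalibrationError,
    ModelError,
    ProfileHMM,
    build_hmm,
    calibrate,
    e_value,
    forward_local,
    hits_to_alignment,
    score_for_evalue,
    search_sequence,
    viterbi_best_score,
    viterbi_local,
)
from spretrace.seed_search import Alignment

from conftest import enumerate_local_paths, random_profile_hmm


def aln(*rows):
    return Alignment(ids=[f"r{i}" for i in range(len(rows))], rows=list(rows))


class TestBuildHmm:
    def test_identical_rows_no_pseudocount_are_one_hot(self):
        m = build_hmm(aln("ACG", "ACG", "ACG"), pseudocount=0.0)
        expect = np.array([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0]], float)
        assert np.allclose(m.match_emissions, expect)
        assert m.consensus == "ACG"

    def test_majority_gap_column_is_not_a_match_state(self):
        m = build_hmm(aln("A-G", "A-G", "ACG"))  # middle column 2/3 gaps
        assert m.M == 2

    def test_pseudocount_arithmetic(self):
        # column counts A=2, C=1, pseudocount 1, uniform q:
        # P(A) = (2 + 0.25) / (3 + 1) = 0.5625
        m = build_hmm(aln("A", "A", "C"), pseudocount=1.0)
        assert m.match_emissions[0, 0] == pytest.approx(0.5625)

    def test_all_gap_alignment_is_an_error(self):
        with pytest.raises(ModelError):
            build_hmm(aln("--", "--"))

    def test_empty_alignment_is_an_error(self):
        with pytest.raises(ModelError):
            build_hmm(Alignment(ids=[], rows=[]))

    def test_normalization_invariants(self):
        rng = np.random.default_rng(2)
        rows = ["".join("ACGT-"[i] for i in rng.integers(0, 5, 30))
                for _ in range(8)]
        m = build_hmm(Alignment(ids=[str(i) for i in range(8)], rows=rows))
        m.validate()  # emission/transition sums checked inside
        assert m.M >= 1

    def test_n_treated_as_missing(self):
        m0 = build_hmm(aln("A", "A"), pseudocount=0.0)
        mn = build_hmm(aln("A", "A", "N"), pseudocount=0.0)
        assert np.allclose(m0.match_emissions, mn.match_emissions)


class TestViterbi:
    def test_single_state_closed_form(self):
        m = build_hmm(aln("A", "A"), pseudocount=0.0)
        assert viterbi_best_score(m, "A") == pytest.approx(2.0)

    def test_consensus_beats_any_single_substitution(self):
        rows = ["ACGTTGCA"] * 4
        m = build_hmm(aln(*rows))
        ref = viterbi_best_score(m, "ACGTTGCA")
        for i in range(8):
            for b in "ACGT":
                if b == "ACGTTGCA"[i]:
                    continue
                variant = "ACGTTGCA"[:i] + b + "ACGTTGCA"[i + 1 :]
                assert viterbi_best_score(m, variant) < ref

    @pytest.mark.parametrize("trial", range(25))
    def test_equals_enumeration_oracle(self, trial):
        """Viterbi == max over exhaustive path enumeration (M<=3, len<=6)."""
        rng = np.random.default_rng(100 + trial)
        M = int(rng.integers(1, 4))
        hmm = random_profile_hmm(M, rng)
        L = int(rng.integers(1, 7))
        target = "".join("ACGT"[i] for i in rng.integers(0, 4, L))
        paths = enumerate_local_paths(hmm, target)
        assert viterbi_best_score(hmm, target) == pytest.approx(max(paths), abs=1e-6)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(9)
        hmm = random_profile_hmm(3, rng)
        target = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
        fwd_hits = search_sequence(hmm, target, bit_threshold=-5.0)
        rev_hits = search_sequence(hmm, revcomp(target), bit_threshold=-5.0)
        L = len(target)
        mirrored = sorted(
            (L - h.E + 1, L - h.S + 1, "-" if h.strand == "+" else "+",
             round(h.bit_score, 6))
            for h in fwd_hits
        )
        assert sorted(
            (h.S, h.E, h.strand, round(h.bit_score, 6)) for h in rev_hits
        ) == mirrored


class TestForward:
    def test_single_path_model_equals_viterbi(self):
        # one match state, one-hot emission, one legal path: forward == Viterbi
        m1 = build_hmm(aln("A", "A"), pseudocount=0.0)
        assert forward_local(m1, "A") == pytest.approx(
            viterbi_best_score(m1, "A"))

    @pytest.mark.parametrize("trial", range(15))
    def test_equals_enumeration_logsum(self, trial):
        rng = np.random.default_rng(200 + trial)
        M = int(rng.integers(1, 4))
        hmm = random_profile_hmm(M, rng)
        L = int(rng.integers(1, 7))
        target = "".join("ACGT"[i] for i in rng.integers(0, 4, L))
        paths = enumerate_local_paths(hmm, target)
        mx = max(paths)
        logsum = mx + math.log2(sum(2.0 ** (p - mx) for p in paths))
        assert forward_local(hmm, target) == pytest.approx(logsum, abs=1e-6)

    @pytest.mark.parametrize("trial", range(20))
    def test_forward_ge_viterbi(self, trial):
        rng = np.random.default_rng(300 + trial)
        hmm = random_profile_hmm(int(rng.integers(1, 4)), rng)
        target = "".join("ACGT"[i] for i in rng.integers(0, 4, int(rng.integers(1, 30))))
        assert forward_local(hmm, target) >= viterbi_best_score(hmm, target) - 1e-9


class TestCalibration:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        hmm = random_profile_hmm(5, rng)
        a = calibrate(hmm, n_samples=200, seed=11)
        b = calibrate(hmm, n_samples=200, seed=11)
        assert a == b

    def test_small_n_rejected(self):
        rng = np.random.default_rng(1)
        hmm = random_profile_hmm(3, rng)
        with pytest.raises(ValueError):
            calibrate(hmm, n_samples=50)

    def test_lambda_positive_and_finite(self):
        rng = np.random.default_rng(1)
        hmm = random_profile_hmm(6, rng)
        mu, lam = calibrate(hmm, n_samples=400, seed=5)
        assert lam > 0 and math.isfinite(mu)

    def test_calibration_tail_sanity(self, selected_model):
        """Empirical P(score >= s_0.01) within a factor of 3 of 0.01."""
        from spretrace._dna import random_seq, encode
        from spretrace.profile_hmm import _vit_best

        model = selected_model
        # threshold from the fitted Gumbel at P = 0.01 with N_eff = 1
        s_threshold = score_for_evalue(0.01, model.mu, model.lam, 1.0)
        rng = np.random.default_rng(123)
        tables = model._tables()
        n, hits = 2000, 0
        for _ in range(n):
            seq = random_seq(rng, 200, model.background)
            s, _, _ = _vit_best(encode(seq), *tables)
            if s >= s_threshold:
                hits += 1
        frac = hits / n
        assert 0.01 / 3 <= frac <= 0.01 * 3


class TestEValue:
    def test_closed_form_at_mu(self):
        e = e_value(10.0, mu=10.0, lam=0.7, n_eff=100.0)
        assert e == pytest.approx(100.0 * (1 - math.exp(-1)), rel=1e-9)

    def test_limit_at_high_score(self):
        assert e_value(1e4, 10.0, 0.7, 100.0) == pytest.approx(0.0, abs=1e-12)

    def test_strictly_decreasing(self):
        # below ~mu - 5/lambda the tail probability saturates at 1 in float,
        # so strict monotonicity is checked where P < 1
        scores = np.linspace(7.0, 50, 200)
        evs = [e_value(s, 10.0, 0.7, 100.0) for s in scores]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_inverse(self):
        s = score_for_evalue(1e-5, 10.0, 0.7, 100.0)
        assert e_value(s, 10.0, 0.7, 100.0) == pytest.approx(1e-5, rel=1e-6)


class TestHitsToAlignment:
    def test_all_match_path_row_equals_substring(self):
        m = build_hmm(aln("ACGTAC", "ACGTAC", "ACGTAC"))
        hits = viterbi_local(m, "TTTACGTACTTT", bit_threshold=2.0)
        assert len(hits) == 1
        assert hits[0].aligned_row == "ACGTAC"
        assert all(s.startswith("M") for s in hits[0].path)

    def test_deletion_appears_as_gap(self):
        m = build_hmm(aln("AAACCCGGGTTT", "AAACCCGGGTTT", "AAACCCGGGTTT"))
        hits = viterbi_local(m, "GGAAACCCGGTTTGG", bit_threshold=2.0)
        assert len(hits) == 1
        assert hits[0].aligned_row.count("-") == 1

    def test_empty_hit_set_is_an_error(self):
        with pytest.raises(ModelError):
            hits_to_alignment([])

    def test_fixed_point_on_clean_hits(self):
        """Rebuilding from mutation-free hits reproduces the consensus."""
        rows = ["ACGTACGTACGTACGTACGT"] * 5
        m = build_hmm(aln(*rows))
        targets = ["TT" + rows[0] + "GG", "CC" + rows[0] + "AA"]
        hits = []
        for i, t in enumerate(targets):
            hits.extend(viterbi_local(m, t, f"t{i}", bit_threshold=2.0))
        m2 = build_hmm(hits_to_alignment(hits))
        assert m2.consensus == m.consensus


class TestMultiHit:
    def test_two_copies_give_two_hits(self):
        rows = ["ACGTACGTACGTACGTACGT"] * 4
        m = build_hmm(aln(*rows))
        rng = np.random.default_rng(4)
        bg = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        target = bg[:30] + rows[0] + bg[30:80] + rows[0] + bg[80:]
        hits = viterbi_local(m, target, bit_threshold=10.0)
        assert len(hits) == 2
        spans = sorted((h.S, h.E) for h in hits)
        assert spans[0][1] < spans[1][0]  # non-overlapping


class TestSerialization:
    def test_round_trip(self, tmp_path, selected_model):
        p = tmp_path / "m.hmm"
        selected_model.save(p)
        loaded = ProfileHMM.load(p)
        assert loaded.M == selected_model.M
        assert np.allclose(loaded.match_emissions, selected_model.match_emissions)
        assert loaded.mu == pytest.approx(selected_model.mu)
        assert loaded.lam == pytest.approx(selected_model.lam)
        # scores agree through the round trip
        target = "TT" + selected_model.consensus + "AA"
        assert viterbi_best_score(loaded, target) == pytest.approx(
            viterbi_best_score(selected_model, target))

    def test_bad_magic_is_an_error(self, tmp_path):
        p = tmp_path / "bad.hmm"
        p.write_text("HMMER3/f\n")
        with pytest.raises(ModelError):
            ProfileHMM.load(p)
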