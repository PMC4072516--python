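"""Consensus-walking checks: candidate filters, majority extension,
termination, CpG correction, end-to-end recovery and verification."""

import math

import numpy as np
import pytest

from conftest import random_dna
from paleoline._seq import revcomp
from paleoline.align import global_identity
from paleoline.simulate import cpg_site_mask, query_region
from paleoline.walker import (ColumnSupport, WalkConfig, WalkState,
                              correct_cpg, detect_termination, extend_step,
                              find_candidates, reconstruct,
                              verify_reconstruction, walk)


@pytest.fixture(scope="module")
def small_reconstruction(small_sim, small_query):
    _, masters, _, rs = small_sim
    state, support, corrections, uncorrected = reconstruct(
        small_query, rs.reads, WalkConfig())
    return masters[0], state, support, corrections, uncorrected, rs


def noisy(rng, seq, rate):
    out = list(seq)
    for j in np.nonzero(rng.random(len(seq)) < rate)[0]:
        out[j] = rng.choice([b for b in "ACGT" if b != out[j]])
    return "".join(out)


class TestFindCandidates:
    def _setup(self, rng, n_subs, overhang_len):
        seed = random_dna(rng, 400)
        ext = random_dna(rng, overhang_len)
        matched = list(seed[100:])  # read covers the seed's 3' 300 bp
        pos = np.linspace(0, 299, n_subs).astype(int)
        for i in pos:
            matched[i] = {"A": "C", "C": "G", "G": "T",
                          "T": "A"}[matched[i]]
        read = "".join(matched) + ext
        return seed, [("r0", read)], ext

    def test_identity_below_92_excluded(self):
        rng = np.random.default_rng(0)
        # 25/300 evenly spaced substitutions -> 91.67% identity
        seed, reads, _ = self._setup(rng, 25, 150)
        assert find_candidates(seed, reads, WalkConfig(), "3p") == []

    def test_identity_at_92_included(self):
        rng = np.random.default_rng(0)
        seed, reads, ext = self._setup(rng, 24, 150)  # 92.0%
        cands = find_candidates(seed, reads, WalkConfig(), "3p")
        assert len(cands) == 1
        assert cands[0].overhang == ext

    def test_short_overhang_excluded(self):
        rng = np.random.default_rng(1)
        seed, reads, _ = self._setup(rng, 0, 80)  # < 100 bp overhang
        assert find_candidates(seed, reads, WalkConfig(), "3p") == []

    def test_no_reads_gives_empty_list(self):
        rng = np.random.default_rng(2)
        seed = random_dna(rng, 400)
        bg = [("r", random_dna(rng, 700))]
        assert find_candidates(seed, bg, WalkConfig(), "3p") == []

    def test_five_prime_overhang_reads_away_from_frontier(self):
        rng = np.random.default_rng(3)
        upstream = random_dna(rng, 200)
        seed = random_dna(rng, 400)
        read = upstream + seed[:300]
        cands = find_candidates(seed, [("r", read)], WalkConfig(), "5p")
        assert len(cands) == 1
        # overhang reads away from the frontier: reverse complement of
        # the upstream sequence, closest base first
        assert cands[0].overhang == revcomp(upstream)


class TestExtendStep:
    def test_majority_vote_recovers_exact_extension(self):
        rng = np.random.default_rng(4)
        truth = random_dna(rng, 300)
        overhangs = [noisy(rng, truth, 0.02) for _ in range(30)]
        from paleoline.walker import _majority_extension
        ext = _majority_extension(overhangs, WalkConfig())
        assert ext == truth

    def test_step_capped_at_step_max(self):
        rng = np.random.default_rng(5)
        truth = random_dna(rng, 800)
        from paleoline.walker import _majority_extension
        ext = _majority_extension([truth] * 10, WalkConfig())
        assert len(ext) == 500

    def test_zero_extension_closes_direction(self):
        state = WalkState(consensus="ACGT" * 100)
        out = extend_step(state, "3p", [], WalkConfig())
        assert not out.right_open and out.left_open

    def test_low_depth_column_stops_extension(self):
        rng = np.random.default_rng(6)
        truth = random_dna(rng, 300)
        # only 3 overhangs reach past column 120
        overhangs = [truth[:120]] * 10 + [truth] * 3
        from paleoline.walker import _majority_extension
        ext = _majority_extension(overhangs, WalkConfig())
        assert len(ext) == 120


class TestTermination:
    def test_polya_run_closes_three_prime(self):
        state = WalkState(consensus=random_dna(
            np.random.default_rng(7), 500) + "A" * 20)
        out = detect_termination(state, WalkConfig(polya_run_min=10))
        assert not out.right_open

    def test_no_polya_keeps_both_open(self):
        rng = np.random.default_rng(8)
        state = WalkState(consensus="".join(
            rng.choice(list("CGT"), 500)))
        out = detect_termination(state, WalkConfig())
        assert out.right_open and out.left_open

    def test_walk_step_count_bounded(self, small_sim, small_reconstruction):
        params, _, _, _ = small_sim
        _, state, *_ = small_reconstruction
        bound = math.ceil(params.master_length / WalkConfig().step_min) + 2
        for d in ("3p", "5p"):
            assert sum(1 for s in state.step_log if s[0] == d) <= bound


class TestCpgCorrection:
    def _support(self, dinuc_counts, depth=100):
        # two adjacent columns whose members show the given dinucleotides
        counts = np.zeros((2, 5), dtype=np.int64)
        dinuc = np.zeros((1, 16), dtype=np.int64)
        idx = {b: i for i, b in enumerate("ACGT")}
        for d, n in dinuc_counts.items():
            counts[0, idx[d[0]]] += n
            counts[1, idx[d[1]]] += n
            dinuc[0, idx[d[0]] * 4 + idx[d[1]]] += n
        return ColumnSupport(counts, counts[:, :4].sum(axis=1), dinuc, depth)

    def test_decay_fingerprint_restored_to_cg(self):
        support = self._support({"CA": 40, "TG": 35, "CG": 20, "TA": 5})
        corrected, log = correct_cpg("TG", support, WalkConfig())
        assert corrected == "CG"
        assert log == [(0, "TG")]

    def test_monomorphic_pair_untouched(self):
        support = self._support({"TG": 100})
        corrected, log = correct_cpg("TG", support, WalkConfig())
        assert corrected == "TG" and log == []

    def test_non_cpg_variation_untouched(self):
        # variable column but wrong dinucleotide spectrum
        support = self._support({"AG": 50, "TG": 50})
        corrected, log = correct_cpg("AG", support, WalkConfig())
        assert corrected == "AG" and log == []

    def test_correction_restores_decayed_cpg_sites(
            self, small_reconstruction):
        master, state, support, corrections, uncorrected, _ = \
            small_reconstruction
        m = master.sequence
        assert len(state.consensus) == len(uncorrected)
        ident_corr = global_identity(state.consensus, m)
        ident_raw = global_identity(uncorrected, m)
        assert ident_corr > ident_raw  # strictly improves
        # most wrong columns at master CpG sites are repaired
        cpg = cpg_site_mask(m)
        if len(uncorrected) == len(m):
            raw_err = sum(1 for i in range(len(m))
                          if uncorrected[i] != m[i] and cpg[i])
            corr_err = sum(1 for i in range(len(m))
                           if state.consensus[i] != m[i] and cpg[i])
            assert raw_err > 0
            assert corr_err <= 0.2 * raw_err


class TestEndToEnd:
    def test_reconstruction_recovers_master(self, small_reconstruction):
        master, state, *_ = small_reconstruction
        ident = global_identity(state.consensus, master.sequence)
        assert ident >= 99.0
        assert abs(len(state.consensus) - len(master.sequence)) < 60

    def test_verification_rerun_converges(self, small_reconstruction):
        _, state, _, _, _, rs = small_reconstruction
        rep = verify_reconstruction(state.consensus, rs.reads, WalkConfig(),
                                    rng_seed=1)
        assert rep.identity >= 99.5

    def test_seed_equal_to_consensus_verifies_trivially(self):
        rng = np.random.default_rng(9)
        cons = random_dna(rng, 600)
        # a read set that is just the consensus itself in pieces
        reads = [("a", cons[:400]), ("b", cons[150:550]), ("c", cons[200:])]
        state = walk(cons, reads, WalkConfig())
        assert state.consensus.startswith(cons) or cons in state.consensus

    def test_determinism(self, small_sim, small_query):
        _, _, _, rs = small_sim
        a = walk(small_query, rs.reads, WalkConfig())
        b = walk(small_query, rs.reads, WalkConfig())
        assert a.consensus == b.consensus
        assert a.step_log == b.step_log

    def test_seed_shorter_than_100_rejected(self, small_sim):
        _, _, _, rs = small_sim
        with pytest.raises(ValueError):
            walk("ACGT" * 20, rs.reads, WalkConfig())

    def test_stricter_identity_prevents_cross_family_contamination(
            self, two_family_sim):
        _, masters, _, rs = two_family_sim
        seed = query_region(masters[0], 575)
        wrong = masters[1].sequence
        right = masters[0].sequence
        loose = walk(seed, rs.reads, WalkConfig())
        strict = walk(seed, rs.reads,
                      WalkConfig(min_candidate_identity=97.0))
        # both reconstructions stay on the correct master...
        for state in (loose, strict):
            assert global_identity(state.consensus, right) > \
                global_identity(state.consensus, wrong)
        # ...and the stricter filter does not pull the consensus toward
        # the wrong master (0.5 tolerance: the two walks cover different
        # spans, so the aligned regions differ slightly)
        assert global_identity(strict.consensus, wrong) <= \
            global_identity(loose.consensus, wrong) + 0.5
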