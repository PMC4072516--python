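"""Subfamily discovery checks: column tallies, planted co-segregating splits,
size-floor behavior, iterative refinement, determinism."""

import numpy as np
import pytest

from conftest import random_dna
from oracles import cooccurrence_2x2
from paleoline.coseg import (CosegConfig, SubfamilyModel, column_matrix,
                             consensus_from_counts, filter_subfamilies,
                             iterate_discovery, split_by_cosegregation)
from paleoline.scan import ScanConfig, ScanHit
from paleoline.simulate import query_region


def make_fragment(seq, idx=0, query_start=0):
    """A ScanHit standing for a fragment already aligned to the reference."""
    return ScanHit(read_id=f"f{idx}", read_start=0, read_end=len(seq),
                   strand="+", query_id="ref", identity=100.0,
                   coverage=100.0, aligned_fragment=seq,
                   query_start=query_start, projection=seq,
                   mismatch_count=0, insertions=0)


def planted_pool(rng, n_total=600, n_carriers=300, L=575, noise=0.01,
                 sites=((100, "T"), (400, "A"))):
    """Fragments with i.i.d. noise; the first n_carriers carry the planted
    variants; diagnostic columns themselves are noise-free."""
    ref = list(random_dna(rng, L))
    for col, base in sites:
        # plant pure A<->T transversions so the diagnostic variant can
        # never mimic the CpG-decay fingerprint the splitter masks
        ref[col] = "A" if base == "T" else "T"
    ref = "".join(ref)
    frags = []
    protected = {c for c, _ in sites}
    for i in range(n_total):
        s = list(ref)
        for j in np.nonzero(rng.random(L) < noise)[0]:
            if j not in protected:
                s[j] = rng.choice([b for b in "ACGT" if b != s[j]])
        if i < n_carriers:
            for col, base in sites:
                s[col] = base
        frags.append(make_fragment("".join(s), i))
    return ref, frags


class TestColumnMatrix:
    def test_identical_fragments_are_monomorphic(self):
        rng = np.random.default_rng(0)
        ref = random_dna(rng, 100)
        frags = [make_fragment(ref, i) for i in range(10)]
        counts, cov = column_matrix(frags, ref)
        assert (cov == 10).all()
        assert (counts[:, :4].max(axis=1) == 10).all()

    def test_single_substitution_splits_one_column(self):
        rng = np.random.default_rng(1)
        ref = random_dna(rng, 100)
        mutated = "T" + ref[1:] if ref[0] != "T" else "A" + ref[1:]
        frags = [make_fragment(ref, i) for i in range(9)]
        frags.append(make_fragment(mutated, 9))
        counts, _ = column_matrix(frags, ref)
        split_cols = np.nonzero((counts[:, :4] > 0).sum(axis=1) > 1)[0]
        assert list(split_cols) == [0]
        assert sorted(counts[0, :4][counts[0, :4] > 0]) == [1, 9]

    def test_counts_match_brute_force_tally(self):
        rng = np.random.default_rng(2)
        ref = random_dna(rng, 60)
        frags = []
        for i in range(25):
            s = list(ref)
            for j in np.nonzero(rng.random(60) < 0.1)[0]:
                s[j] = rng.choice(list("ACGT"))
            start = int(rng.integers(0, 20))
            frags.append(make_fragment("".join(s)[start:], i,
                                       query_start=start))
        counts, cov = column_matrix(frags, ref)
        for col in range(60):
            tally = {b: 0 for b in "ACGT-"}
            n_cov = 0
            for f in frags:
                if f.query_start <= col < f.query_end:
                    tally[f.projection[col - f.query_start]] += 1
                    n_cov += 1
            assert cov[col] == n_cov
            for row, b in enumerate("ACGT-"):
                assert counts[col, row] == tally[b]

    def test_fragment_without_alignment_rejected(self):
        with pytest.raises(ValueError):
            column_matrix(["ACGT"], "ACGT")


class TestSplitByCosegregation:
    def test_identical_members_do_not_split(self):
        rng = np.random.default_rng(3)
        ref = random_dna(rng, 200)
        frags = [make_fragment(ref, i) for i in range(120)]
        model = SubfamilyModel(0, ref, list(range(120)), [])
        cfg = CosegConfig(min_subfamily_size=25)
        out = split_by_cosegregation(model, frags, cfg)
        assert len(out) == 1

    def test_planted_variants_split_exactly(self):
        rng = np.random.default_rng(4)
        ref, frags = planted_pool(rng)
        cfg = CosegConfig(min_subfamily_size=250)
        model = SubfamilyModel(0, ref, list(range(600)), [])
        out = split_by_cosegregation(model, frags, cfg)
        sizes = sorted(len(m.members) for m in out)
        assert sizes == [300, 300]
        assert any(set(m.members) == set(range(300)) for m in out), \
            "carriers must form one exact subfamily"

    def test_cooccurrence_count_matches_2x2_oracle(self):
        rng = np.random.default_rng(5)
        ref, frags = planted_pool(rng)
        flags_a = [f.projection[100] == "T" for f in frags]
        flags_b = [f.projection[400] == "A" for f in frags]
        n11, n10, n01, n00 = cooccurrence_2x2(flags_a, flags_b)
        assert n11 == 300 and n11 + n10 + n01 + n00 == 600

    def test_candidate_below_size_floor_not_split(self):
        rng = np.random.default_rng(6)
        ref, frags = planted_pool(rng, n_total=600, n_carriers=200)
        cfg = CosegConfig(min_subfamily_size=250)
        model = SubfamilyModel(0, ref, list(range(600)), [])
        out = split_by_cosegregation(model, frags, cfg)
        assert len(out) == 1

    def test_size_floor_boundary_249_vs_250(self):
        cfg = CosegConfig(min_subfamily_size=250)
        for n_carriers, expect in ((249, 1), (250, 2)):
            rng = np.random.default_rng(100 + n_carriers)
            ref, frags = planted_pool(rng, n_total=600,
                                      n_carriers=n_carriers)
            model = SubfamilyModel(0, ref, list(range(600)), [])
            out = split_by_cosegregation(model, frags, cfg)
            assert len(out) == expect

    def test_partition_is_exact(self):
        rng = np.random.default_rng(7)
        ref, frags = planted_pool(rng)
        model = SubfamilyModel(0, ref, list(range(600)), [])
        out = split_by_cosegregation(model, frags,
                                     CosegConfig(min_subfamily_size=50))
        all_members = sorted(i for m in out for i in m.members)
        assert all_members == list(range(600))  # disjoint and exhaustive

    def test_false_split_rate_under_iid_noise(self):
        splits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            ref = random_dna(rng, 300)
            frags = []
            for i in range(400):
                s = list(ref)
                for j in np.nonzero(rng.random(300) < 0.08)[0]:
                    s[j] = rng.choice([b for b in "ACGT" if b != s[j]])
                frags.append(make_fragment("".join(s), i))
            model = SubfamilyModel(0, ref, list(range(400)), [])
            out = split_by_cosegregation(
                model, frags, CosegConfig(min_subfamily_size=25))
            splits += len(out) > 1
        assert splits <= 1  # <= 5% across 20 seeds

    def test_determinism(self):
        rng = np.random.default_rng(8)
        ref, frags = planted_pool(rng)
        cfg = CosegConfig(min_subfamily_size=100)
        outs = []
        for _ in range(2):
            model = SubfamilyModel(0, ref, list(range(600)), [])
            out = split_by_cosegregation(model, frags, cfg)
            outs.append([tuple(m.members) for m in out])
        assert outs[0] == outs[1]


class TestFilterSubfamilies:
    def _models(self, sizes, rng):
        ref = random_dna(rng, 100)
        models, frags = [], []
        at = 0
        for k, n in enumerate(sizes):
            members = []
            for _ in range(n):
                frags.append(make_fragment(ref, at))
                members.append(at)
                at += 1
            models.append(SubfamilyModel(k, ref, members, []))
        return models, frags

    def test_249_removed_250_retained(self):
        rng = np.random.default_rng(9)
        models, frags = self._models([249, 250, 300], rng)
        out = filter_subfamilies(models, 250, frags)
        assert len(out) == 2
        assert sum(len(m.members) for m in out) == 799  # reassigned

    def test_empty_input_gives_empty_output(self):
        assert filter_subfamilies([], 250) == []

    def test_64_subfamilies_with_7_undersized_leaves_57(self):
        rng = np.random.default_rng(10)
        sizes = [300] * 57 + [100] * 7
        models, frags = self._models(sizes, rng)
        out = filter_subfamilies(models, 250, frags)
        assert len(out) == 57

    def test_all_undersized_raises_with_advice(self):
        rng = np.random.default_rng(11)
        models, frags = self._models([10, 12], rng)
        with pytest.raises(ValueError, match="min_subfamily_size"):
            filter_subfamilies(models, 250, frags)


class TestIterateDiscovery:
    def test_rounds_zero_returns_seed_defined_subfamily(self, small_sim,
                                                        small_query):
        _, _, _, rs = small_sim
        models, hits = iterate_discovery(
            rs, small_query, ScanConfig(),
            CosegConfig(min_subfamily_size=25), rounds=0)
        assert len(models) == 1
        assert sorted(models[0].members) == list(range(len(hits)))

    def test_single_family_consensus_matches_master(self, small_sim,
                                                    small_query):
        from paleoline.align import global_identity
        _, masters, _, rs = small_sim
        models, _ = iterate_discovery(
            rs, small_query, ScanConfig(),
            CosegConfig(min_subfamily_size=25), rounds=2)
        best = max(global_identity(m.consensus, small_query)
                   for m in models)
        assert best >= 99.0

    def test_two_families_recovered_with_accurate_assignment(
            self, two_family_sim):
        import bisect
        _, masters, loci, rs = two_family_sim
        q0 = query_region(masters[0], 575)
        models, hits = iterate_discovery(
            rs, q0, ScanConfig(), CosegConfig(min_subfamily_size=25),
            rounds=2)
        assert len(models) == 2
        # map each hit's read back to its source locus for ground truth
        ivs = sorted((v[0], v[1], k) for k, v in rs.locus_coords.items())
        starts = [iv[0] for iv in ivs]
        by_id = {l.locus_id: l for l in loci}

        def true_family(read_id):
            g0, g1, _ = rs.provenance[read_id]
            i = bisect.bisect_right(starts, g0) - 1
            for j in (i, i + 1):
                if 0 <= j < len(ivs):
                    s, e, lid = ivs[j]
                    if s < g1 and g0 < e:
                        return by_id[lid].true_family
            return None
        from collections import Counter
        table = Counter()
        for h in hits:
            tf = true_family(h.read_id)
            if tf:
                table[(tf, h.assigned_subfamily)] += 1
        # best one-to-one mapping between subfamilies and true families
        sf = sorted({k[1] for k in table})
        acc = max(
            sum(table.get(("F0", a), 0) + table.get(("F1", b), 0)
                for a, b in [(x, y)])
            for x in sf for y in sf if x != y) / max(sum(table.values()), 1)
        assert acc >= 0.95
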