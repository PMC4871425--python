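import numpy as np
import pytest

from gibbsmsa.evaluate import PlantedSetSpec, generate_planted_set
from gibbsmsa.phase2 import resample_sequence
from gibbsmsa.strategies import (
    alignment_similarity,
    cluster_sequences,
    consensus_sequence,
    group_by_shared_features,
    pairwise_identity,
    purged_set_realign,
    resample_cluster_via_consensus,
    resample_group_tandem,
    resample_random_subsets,
    resample_worst_scoring,
)
from gibbsmsa.seqio import SequenceRecord, SequenceSet, decode, encode

from conftest import m_from_msa, make_state, make_trap_instance


def seqset(*strings):
    return SequenceSet(
        [SequenceRecord(f"s{i}", "", encode(s)) for i, s in enumerate(strings)]
    )


def gapless_state(dm, bg, *strings):
    seqs = seqset(*strings)
    w = len(strings[0])
    m = np.tile(np.arange(w), (len(strings), 1))
    return make_state(seqs, m, dm, bg)


class TestClustering:
    def test_identical_pair_is_tight(self, dm58, bg):
        state = gapless_state(dm58, bg, "ACDEFGHIKL", "ACDEFGHIKL", "WWWWWWWWWW")
        clusters = cluster_sequences(state)
        kinds = {tuple(c.members): c.kind for c in clusters}
        assert kinds[(0, 1)] == "tight"
        assert kinds[(2,)] in ("tight", "loose")

    def test_dissimilar_all_singletons(self, dm58, bg):
        state = gapless_state(dm58, bg, "AAAAAAAAAA", "CCCCCCCCCC", "DDDDDDDDDD")
        clusters = cluster_sequences(state, loose_threshold=0.4)
        assert sorted(len(c.members) for c in clusters) == [1, 1, 1]

    def test_single_linkage_chain(self, dm58, bg):
        # a~b and b~c at 50% identity but a~c at 0%: one chained cluster
        state = gapless_state(dm58, bg, "AAAACCCC", "CCCCDDDD", "DDDDAAAA")
        # identities: a-b 0, b-c 0 ... construct a proper chain instead
        state = gapless_state(dm58, bg, "AAAACCCC", "AAAADDDD", "EEEEDDDD")
        ident = pairwise_identity(state.column_matrix())
        assert ident[0, 1] == 0.5 and ident[1, 2] == 0.5 and ident[0, 2] == 0.0
        clusters = cluster_sequences(state, loose_threshold=0.5)
        assert [c.members for c in clusters] == [[0, 1, 2]]

    def test_every_sequence_in_exactly_one_cluster(self, rng, dm58, bg):
        spec = PlantedSetSpec(n_sequences=6, duplication=3, flank_mean=5.0,
                              insertion_prob=0.0)
        seqs, truth = generate_planted_set(spec, rng)
        state = make_state(seqs, m_from_msa(truth), dm58, bg)
        clusters = cluster_sequences(state)
        all_members = sorted(k for c in clusters for k in c.members)
        assert all_members == list(range(state.K))


class TestConsensus:
    def test_identical_members(self, dm58, bg):
        state = gapless_state(dm58, bg, "ACDEF", "ACDEF", "WWWWW")
        cl = [c for c in cluster_sequences(state) if c.members == [0, 1]][0]
        cons = consensus_sequence(cl, state)
        assert decode(cons.residues) == "ACDEF"

    def test_majority_rule(self, dm58, bg):
        state = gapless_state(dm58, bg, "AAAAA", "AAAAA", "CCCCC")
        from gibbsmsa.strategies import SequenceCluster

        cl = SequenceCluster(members=[0, 1, 2], kind="tight")
        cons = consensus_sequence(cl, state)
        assert decode(cons.residues) == "AAAAA"

    def test_tie_alphabetical(self, dm58, bg):
        state = gapless_state(dm58, bg, "AC", "CA")
        from gibbsmsa.strategies import SequenceCluster

        cl = SequenceCluster(members=[0, 1], kind="tight")
        cons = consensus_sequence(cl, state)
        assert decode(cons.residues) == "AA"  # A < C at every tied position

    def test_loose_cluster_rejected(self, dm58, bg):
        from gibbsmsa.strategies import SequenceCluster

        state = gapless_state(dm58, bg, "AC", "CA")
        with pytest.raises(ValueError):
            consensus_sequence(SequenceCluster(members=[0, 1], kind="loose"), state)


class TestGroupTandem:
    def test_group_of_one_equals_single_resample(self, rng, dm58, bg):
        spec = PlantedSetSpec(n_sequences=8, flank_mean=8.0, insertion_prob=0.2,
                              insertion_mean=3.0)
        seqs, truth = generate_planted_set(spec, rng)
        s1 = make_state(seqs, m_from_msa(truth), dm58, bg)
        s2 = make_state(seqs, m_from_msa(truth), dm58, bg)
        resample_group_tandem(s1, [3], np.random.default_rng(77), T=1.0)
        resample_sequence(s2, 3, np.random.default_rng(77), T=1.0)
        assert np.array_equal(s1.m, s2.m)

    def test_counts_conserved(self, rng, dm58, bg):
        spec = PlantedSetSpec(n_sequences=8, flank_mean=8.0)
        seqs, truth = generate_planted_set(spec, rng)
        state = make_state(seqs, m_from_msa(truth), dm58, bg)
        resample_group_tandem(state, [1, 4, 6], rng, T=0.5)
        cc = state.col_counts.copy()
        tc = state.tcounts.copy()
        state.refresh_counts()
        assert np.allclose(state.col_counts, cc, atol=1e-6)
        assert state.tcounts.allclose(tc)

    def test_all_sequences_rejected(self, rng, dm58, bg):
        state = gapless_state(dm58, bg, "ACDEF", "ACDEF", "ACDEF")
        with pytest.raises(ValueError):
            resample_group_tandem(state, [0, 1, 2], rng, T=1.0)


class TestSharedFeatures:
    def test_congruent_insertion_group(self, rng, dm58, bg):
        # 4 of 10 sequences share a similar-length insertion at one spot
        spec = PlantedSetSpec(n_sequences=10, block_widths=(6, 6),
                              insertion_prob=0.0, flank_mean=6.0)
        seqs, truth = generate_planted_set(spec, rng)
        m = m_from_msa(truth)
        # graft an insertion: shift the second block of sequences 0..3 by 5
        recs = []
        for k in range(10):
            res = list(seqs[k].residues)
            if k < 4:
                pos = int(m[k, 6])
                ins = rng.choice(20, size=5).tolist()
                res = res[:pos] + ins + res[pos:]
                m[k, 6:] += 5
            recs.append(SequenceRecord(f"s{k}", "", np.array(res, dtype=np.int8)))
        state = make_state(SequenceSet(recs), m, dm58, bg)
        groups = group_by_shared_features(state)
        assert [0, 1, 2, 3] in groups

    def test_no_features_empty(self, dm58, bg):
        state = gapless_state(dm58, bg, "ACDEF", "ACDEF", "ACDEF")
        assert group_by_shared_features(state) == []

    def test_groups_are_sets_of_two_plus(self, rng, dm58, bg):
        spec = PlantedSetSpec(n_sequences=12, insertion_prob=0.4, insertion_mean=4.0,
                              flank_mean=8.0)
        seqs, truth = generate_planted_set(spec, rng)
        state = make_state(seqs, m_from_msa(truth), dm58, bg)
        groups = group_by_shared_features(state)
        seen = set()
        for g in groups:
            assert len(g) >= 2
            key = frozenset(g)
            assert key not in seen
            seen.add(key)


class TestPurgedSet:
    def test_singletons_degenerate(self, rng, dm58, bg):
        spec = PlantedSetSpec(n_sequences=6, flank_mean=8.0, conservation=8.0)
        seqs, truth = generate_planted_set(spec, rng)
        state = make_state(seqs, m_from_msa(truth), dm58, bg)
        before = {str(state.seqs[i]) for i in range(state.K)}
        purged_set_realign(state, rng, T=0.5, tight_threshold=0.99, loose_threshold=0.99)
        msa = state.to_msa()
        assert {msa.degapped(i) for i in range(len(msa))} == before

    def test_membership_unchanged(self, rng, dm58, bg):
        spec = PlantedSetSpec(n_sequences=5, duplication=3, flank_mean=6.0,
                              insertion_prob=0.0)
        seqs, truth = generate_planted_set(spec, rng)
        state = make_state(seqs, m_from_msa(truth), dm58, bg)
        before = cluster_sequences(state)
        purged_set_realign(state, rng, T=0.0)
        after = cluster_sequences(state)
        assert sorted(k for c in before for k in c.members) == sorted(
            k for c in after for k in c.members
        )


class TestWorstScoring:
    def test_fraction_of_one(self, rng, dm58, bg):
        spec = PlantedSetSpec(n_sequences=8, flank_mean=8.0)
        seqs, truth = generate_planted_set(spec, rng)
        state = make_state(seqs, m_from_msa(truth), dm58, bg)
        before = state.joint_score()
        resample_worst_scoring(state, 0.05, rng, T=0.0)  # ceil(0.4) = 1 sequence
        assert state.joint_score() >= before - 1e-6

    def test_invalid_fraction(self, rng, dm58, bg):
        state = gapless_state(dm58, bg, "ACDEF", "ACDEF", "ACDEF")
        with pytest.raises(ValueError):
            resample_worst_scoring(state, 1.5, rng, T=0.0)

    def test_scores_track_emission_decomposition(self, rng, dm58, bg):
        from gibbsmsa.phase2 import build_view, sequence_score

        spec = PlantedSetSpec(n_sequences=6, flank_mean=6.0, insertion_prob=0.0)
        seqs, truth = generate_planted_set(spec, rng)
        state = make_state(seqs, m_from_msa(truth), dm58, bg)
        view = build_view(state.hmm())
        per_seq = sum(sequence_score(state, k, view) for k in range(state.K))
        assert np.isfinite(per_seq)


class TestRandomSubsets:
    def test_zero_rounds_noop(self, rng, dm58, bg):
        state = gapless_state(dm58, bg, "ACDEF", "ACDEF", "WCDEF")
        before = state.m.copy()
        resample_random_subsets(state, 1, 0, rng, T=1.0)
        assert np.array_equal(state.m, before)

    def test_subset_too_large_rejected(self, rng, dm58, bg):
        state = gapless_state(dm58, bg, "ACDEF", "ACDEF", "WCDEF")
        with pytest.raises(ValueError):
            resample_random_subsets(state, 3, 1, rng, T=1.0)

    def test_coverage(self, rng, dm58, bg):
        # coupon collector over subset draws covers every sequence
        spec = PlantedSetSpec(n_sequences=10, flank_mean=6.0)
        seqs, truth = generate_planted_set(spec, np.random.default_rng(0))
        covered = set()
        for _ in range(200):
            covered.update(rng.choice(10, size=2, replace=False).tolist())
        assert covered == set(range(10))


class TestAlignmentSimilarity:
    def test_identical(self, rng):
        m = rng.integers(0, 5, size=(3, 4)).cumsum(axis=1)
        assert alignment_similarity(m, m.copy()) == 1.0

    def test_disjoint(self):
        a = np.array([[0, 1], [0, 1]])
        b = np.array([[0, 1], [2, 3]])
        assert alignment_similarity(a, b) == 0.0

    def test_partial_overlap_two_thirds(self):
        # three sequences aligned in one column: pairs {01, 02, 12}; the
        # test alignment keeps sequences 0,1 together but moves 2
        a = np.array([[0], [0], [0]])
        b = np.array([[0], [0], [-1]])
        sim = alignment_similarity(a, b)
        #  a has 3 pairs, b has 1 pair, shared 1: (1/3 + 1/1)/2 = 2/3
        assert sim == pytest.approx(2 / 3)

    def test_different_sets_error(self):
        with pytest.raises(ValueError):
            alignment_similarity(np.zeros((2, 1), int), np.zeros((3, 1), int))


class TestConsensusTrapEscape:
    def escaped(self, state, truth_m, cluster):
        # fraction of truth match cells recovered across the cluster
        agree = np.mean([(state.m[k] == truth_m[k]).mean() for k in cluster])
        return agree >= 0.8

    def test_consensus_move_escapes(self, dm58, bg):
        wins = 0
        for seed in range(5):
            state, truth_m, cluster = make_trap_instance(seed, dm58, bg)
            rng = np.random.default_rng(seed)
            clusters = cluster_sequences(state)
            tight = [c for c in clusters if c.kind == "tight" and len(c.members) > 1]
            assert tight, "trap instance must contain a tight cluster"
            for cl in tight:
                resample_cluster_via_consensus(state, cl, rng, T=0.0)
            wins += self.escaped(state, truth_m, cluster)
        assert wins >= 4

    def test_plain_sweeps_stay_trapped(self, dm58, bg):
        stuck = 0
        for seed in range(5):
            state, truth_m, cluster = make_trap_instance(seed, dm58, bg)
            rng = np.random.default_rng(seed)
            for _ in range(3):
                for k in range(state.K):
                    resample_sequence(state, k, rng, T=0.0)
            stuck += not self.escaped(state, truth_m, cluster)
        assert stuck >= 4

    def test_residue_conservation_after_escape_move(self, dm58, bg):
        state, _, _ = make_trap_instance(0, dm58, bg)
        rng = np.random.default_rng(0)
        for cl in cluster_sequences(state):
            if cl.kind == "tight" and 1 < len(cl.members) < state.K:
                resample_cluster_via_consensus(state, cl, rng, T=0.0)
        msa = state.to_msa()
        for i in range(len(msa)):
            assert msa.degapped(i) == str(state.seqs[i])
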