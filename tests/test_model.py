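import math

import numpy as np
import pytest

from gibbsmsa.model import (
    AlignmentPath,
    BlockAlignment,
    IllegalPathError,
    TransitionCounts,
    TransitionPriors,
    block_to_hmm,
    count_transitions,
    integrated_block_llr,
    integrated_transition_loglike,
    placement_site_scores,
    predictive_placement_distribution,
    row_transitions,
    sample_block_placement,
    sample_transition_probabilities,
    transition_point_estimates,
    validate_row,
)
from gibbsmsa.priors import Background, DirichletMixture
from gibbsmsa.seqio import SequenceRecord, SequenceSet, encode


def seqset(*strings):
    return SequenceSet(
        [SequenceRecord(f"s{i}", "", encode(s)) for i, s in enumerate(strings)]
    )


def uniform_background():
    t = np.ones(20) / 20
    return Background(theta0=t, alpha=t * 20)


class TestBlockAlignment:
    def test_colinearity_violation(self):
        seqs = seqset("ACDEFG", "ACDEFG")
        aln = BlockAlignment(widths=[2, 2], starts=[[0, 1], [0, 2]])
        with pytest.raises(ValueError):
            aln.validate(seqs.lengths)

    def test_out_of_bounds(self):
        seqs = seqset("ACD")
        aln = BlockAlignment(widths=[3], starts=[[1]])
        with pytest.raises(ValueError):
            aln.validate(seqs.lengths)

    def test_positions(self):
        aln = BlockAlignment(widths=[2, 1], starts=[[1, 5]])
        assert list(aln.positions(0)) == [1, 2, 5]


class TestIntegratedBlockLLR:
    def test_empty_alignment_scores_zero(self, flat_dm, uniform_bg):
        seqs = seqset("ACD", "ACD")
        aln = BlockAlignment(widths=np.zeros(0, int), starts=np.zeros((2, 0), int))
        assert integrated_block_llr(seqs, aln, flat_dm, uniform_bg) == 0.0

    def test_hand_gamma_case(self, flat_dm, uniform_bg):
        # one column, both sequences 'A', flat beta: marginal
        # Gamma(20)Gamma(3)/(Gamma(22)Gamma(1)) = 1/210; theta0_A = 0.05
        seqs = seqset("A", "A")
        aln = BlockAlignment(widths=[1], starts=[[0], [0]])
        llr = integrated_block_llr(seqs, aln, flat_dm, uniform_bg)
        assert llr == pytest.approx(math.log(1 / 210) - 2 * math.log(0.05), abs=1e-12)

    def test_matches_sequential_polya_oracle(self, rng, uniform_bg):
        # random 5x8 instances, unit weights: LLR must equal the product of
        # sequential predictive probabilities over each column's residues
        alpha = rng.gamma(1.0, 1.0, size=(1, 20)) + 0.1
        dm = DirichletMixture(rho=np.ones(1), alpha=alpha)
        for _ in range(10):
            mats = rng.integers(0, 20, size=(5, 8))
            seqs = SequenceSet(
                [SequenceRecord(f"s{i}", "", m.astype(np.int8)) for i, m in enumerate(mats)]
            )
            aln = BlockAlignment(widths=[8], starts=np.zeros((5, 1), int))
            llr = integrated_block_llr(seqs, aln, dm, uniform_bg)
            oracle = 0.0
            for j in range(8):
                used = np.zeros(20)
                for k in range(5):
                    a = mats[k, j]
                    oracle += math.log(
                        (alpha[0, a] + used[a]) / (alpha[0].sum() + used.sum())
                    )
                    oracle -= math.log(uniform_bg.theta0[a])
                    used[a] += 1
            assert llr == pytest.approx(oracle, abs=1e-9)

    def test_sequence_order_invariance(self, rng, dm20, uniform_bg):
        mats = rng.integers(0, 20, size=(6, 5))
        perm = rng.permutation(6)
        s1 = SequenceSet(
            [SequenceRecord(f"s{i}", "", m.astype(np.int8)) for i, m in enumerate(mats)]
        )
        s2 = SequenceSet(
            [SequenceRecord(f"s{i}", "", m.astype(np.int8)) for i, m in enumerate(mats[perm])]
        )
        a1 = BlockAlignment(widths=[5], starts=np.zeros((6, 1), int))
        assert integrated_block_llr(s1, a1, dm20, uniform_bg) == pytest.approx(
            integrated_block_llr(s2, a1, dm20, uniform_bg), abs=1e-9
        )


class TestPredictivePlacement:
    def test_c_dominant_model_prefers_c(self, uniform_bg):
        lo = np.zeros((1, 20))
        lo[0, 1] = 3.0  # strong log-odds for C
        placements, probs = predictive_placement_distribution(
            encode("ACA"), np.array([1]), lo
        )
        assert len(placements) == 3
        assert placements[int(np.argmax(probs))][0] == 1

    def test_flat_model_uniform(self):
        lo = np.zeros((2, 20))
        placements, probs = predictive_placement_distribution(
            encode("ACDEF"), np.array([2]), lo
        )
        assert np.allclose(probs, 1 / len(placements))

    def test_forced_placement(self):
        lo = np.zeros((4, 20))
        placements, probs = predictive_placement_distribution(
            encode("ACDE"), np.array([2, 2]), lo
        )
        assert len(placements) == 1
        assert probs[0] == pytest.approx(1.0)
        assert list(placements[0]) == [0, 2]

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            predictive_placement_distribution(encode("AC"), np.array([3]), np.zeros((3, 20)))

    def test_sampler_matches_enumeration(self, rng):
        lo = rng.normal(0, 1, size=(3, 20))
        res = encode("ACDEFGH")
        placements, probs = predictive_placement_distribution(res, np.array([2, 1]), lo)
        S = placement_site_scores(res, lo)
        freqs = np.zeros(len(placements))
        keys = {tuple(p): i for i, p in enumerate(placements)}
        n = 4000
        for _ in range(n):
            starts, _ = sample_block_placement(S, np.array([2, 1]), rng, T=1.0)
            freqs[keys[tuple(starts)]] += 1
        freqs /= n
        assert np.all(np.abs(freqs - probs) < 4 * np.sqrt(probs * (1 - probs) / n) + 0.01)

    def test_argmax_at_t0(self, rng):
        lo = rng.normal(0, 1, size=(3, 20))
        res = encode("ACDEFGH")
        placements, probs = predictive_placement_distribution(res, np.array([2, 1]), lo)
        S = placement_site_scores(res, lo)
        starts, _ = sample_block_placement(S, np.array([2, 1]), rng, T=0.0)
        assert list(starts) == list(placements[int(np.argmax(probs))])


class TestCountTransitions:
    def test_identical_gapless_paths(self):
        m = np.tile(np.arange(4), (3, 1))
        tc = count_transitions(m, np.full(3, 10), np.full(3, 100))
        assert np.allclose(tc.mm, 3.0)  # start, interior, exit all M->M
        for t in ("mi", "md", "im", "ii", "dm", "dd"):
            assert np.allclose(getattr(tc, t), 0.0)

    def test_insertion_trace(self):
        # one path with a length-2 insertion after column 1 (0-based col 0)
        m = np.array([[0, 3, 4]])
        tc = count_transitions(m, np.array([10]), np.array([100]))
        assert tc.mi[1] == 1.0 and tc.ii[1] == 1.0 and tc.im[1] == 1.0
        assert tc.mm[0] == 1.0 and tc.mm[2] == 1.0 and tc.mm[3] == 1.0

    def test_weights_scale_linearly(self):
        m = np.array([[0, 3, 4]])
        a = count_transitions(m, np.array([10]), np.array([100]))
        b = count_transitions(m, np.array([10]), np.array([50]))
        for t in ("mm", "mi", "ii", "im"):
            assert np.allclose(getattr(a, t) * 0.5, getattr(b, t))

    def test_illegal_path_raises_with_sequence(self):
        # insertion stranded before a deletion run
        m = np.array([[0, 3, -1, 5]])
        with pytest.raises(IllegalPathError, match="sequence 0"):
            count_transitions(m, np.array([10]), np.array([100]))

    def test_deletion_run_consecutive_ok(self):
        m = np.array([[0, -1, -1, 1]])
        tc = count_transitions(m, np.array([5]), np.array([100]))
        assert tc.md[1] == 1.0 and tc.dd[2] == 1.0 and tc.dm[3] == 1.0


class TestPointEstimates:
    def test_zero_counts_prior_means(self):
        tc = TransitionCounts(1)
        pr = TransitionPriors(n_mm=8, n_mi=1, n_md=1)
        est = transition_point_estimates(tc, pr)
        assert np.allclose(est["iota_o"], 0.1)
        assert np.allclose(est["delta_o"], 0.1)

    def test_hand_case(self):
        tc = TransitionCounts(1)
        tc.mi[1], tc.mm[1] = 2.0, 6.0
        pr = TransitionPriors(n_mm=1, n_mi=1, n_md=1)
        est = transition_point_estimates(tc, pr)
        assert est["iota_o"][1] == pytest.approx(3 / 11)
        assert est["delta_o"][1] == pytest.approx(1 / 11)

    def test_large_count_limit(self):
        tc = TransitionCounts(1)
        tc.mm[1], tc.mi[1], tc.md[1] = 7e6, 2e6, 1e6
        est = transition_point_estimates(tc, TransitionPriors())
        assert est["iota_o"][1] == pytest.approx(0.2, abs=1e-4)
        assert est["delta_o"][1] == pytest.approx(0.1, abs=1e-4)

    def test_open_probabilities_bounded(self, rng):
        tc = TransitionCounts(3)
        for t in ("mm", "mi", "md", "im", "ii", "dm", "dd"):
            getattr(tc, t)[:] = rng.random(4) * 5
        est = transition_point_estimates(tc, TransitionPriors())
        assert np.all(est["iota_o"] + est["delta_o"] < 1)
        assert np.all((est["iota_e"] > 0) & (est["iota_e"] < 1))


class TestSampleTransitions:
    def test_beta_mean(self, rng):
        tc = TransitionCounts(0)
        tc.dd[0], tc.dm[0] = 3.0, 5.0
        pr = TransitionPriors(n_dd=1, n_dm=1)
        n = 100_000
        # the sampler's delta_e is exactly Beta(N_dd+n_dd, N_dm+n_dm)
        d = rng.beta(tc.dd[0] + pr.n_dd, tc.dm[0] + pr.n_dm, size=n)
        assert abs(d.mean() - 0.4) < 3 * d.std() / np.sqrt(n)
        one = sample_transition_probabilities(tc, pr, rng)
        assert 0 < one["delta_e"][0] < 1

    def test_zero_counts_matches_prior(self, rng):
        from scipy.stats import beta, kstest

        tc = TransitionCounts(0)
        pr = TransitionPriors()
        draws = np.array(
            [
                sample_transition_probabilities(tc, pr, rng)["iota_e"][0]
                for _ in range(2000)
            ]
        )
        assert kstest(draws, beta(pr.n_ii, pr.n_im).cdf).pvalue > 0.01

    def test_seed_determinism(self):
        tc = TransitionCounts(2)
        pr = TransitionPriors()
        a = sample_transition_probabilities(tc, pr, np.random.default_rng(3))
        b = sample_transition_probabilities(tc, pr, np.random.default_rng(3))
        for key in a:
            assert np.array_equal(a[key], b[key])

    def test_iota_delta_sum_below_one(self, rng):
        tc = TransitionCounts(1)
        est = sample_transition_probabilities(tc, TransitionPriors(), rng)
        assert np.all(est["iota_o"] + est["delta_o"] < 1)


class TestIntegratedTransitionLoglike:
    def test_zero_counts_zero(self):
        assert integrated_transition_loglike(TransitionCounts(4), TransitionPriors()) == 0.0

    def test_hand_gamma_case(self):
        # one position, N_mm=2, N_mi=1, pseudocounts 1: factor = 1/30
        tc = TransitionCounts(0)
        tc.mm[0], tc.mi[0] = 2.0, 1.0
        pr = TransitionPriors(n_mm=1, n_mi=1, n_md=1)
        assert integrated_transition_loglike(tc, pr) == pytest.approx(
            math.log(1 / 30), abs=1e-12
        )

    def test_monte_carlo_oracle(self, rng):
        # tiny counts: integrate h(Lambda | iota, delta) over the prior
        tc = TransitionCounts(0)
        tc.mm[0], tc.mi[0], tc.md[0] = 2.0, 1.0, 1.0
        tc.ii[0], tc.im[0] = 1.0, 1.0
        pr = TransitionPriors(n_mm=2, n_mi=1, n_md=1, n_ii=1, n_im=2)
        n = 200_000
        d = rng.dirichlet([pr.n_mi, pr.n_md, pr.n_mm], size=n)
        io, do, mm = d[:, 0], d[:, 1], d[:, 2]
        ie = rng.beta(pr.n_ii, pr.n_im, size=n)
        like = (
            mm ** tc.mm[0] * io ** tc.mi[0] * do ** tc.md[0]
            * ie ** tc.ii[0] * (1 - ie) ** tc.im[0]
        )
        est = like.mean()
        se = like.std() / np.sqrt(n)
        val = math.exp(integrated_transition_loglike(tc, pr))
        assert abs(val - est) < 3 * se


class TestBlockToHmm:
    def test_interblock_residues_become_insertions(self, dm20, uniform_bg):
        # blocks of widths 3 and 2 with 4 residues between them
        seqs = seqset("ACDEFGHIK", "ACDEFGHIK", "ACDEFGHIK")
        aln = BlockAlignment(
            widths=[3, 2], starts=np.tile([0, 7], (3, 1))
        )
        hmm, m = block_to_hmm(aln, seqs, TransitionPriors(), dm20, uniform_bg)
        assert hmm.w == 5
        assert np.array_equal(m[0], [0, 1, 2, 7, 8])
        path = AlignmentPath(row=m[0], n=9).states()
        kinds = [s[0] for s in path]
        assert kinds == ["M", "M", "M", "I", "I", "I", "I", "M", "M"]
        assert hmm.tcounts.mi[3] == 3.0 and hmm.tcounts.ii[3] == 9.0

    def test_gapless_alignment_pure_m(self, dm20, uniform_bg):
        seqs = seqset("QACDEQ", "WACDEW")
        aln = BlockAlignment(widths=[4], starts=np.tile([1], (2, 1)))
        hmm, m = block_to_hmm(aln, seqs, TransitionPriors(), dm20, uniform_bg)
        states = AlignmentPath(row=m[0], n=6).states()
        assert [s[0] for s in states] == ["N", "M", "M", "M", "M", "C"]

    def test_emitted_residue_conservation(self, rng, dm20, uniform_bg):
        mats = rng.integers(0, 20, size=(4, 30))
        seqs = SequenceSet(
            [SequenceRecord(f"s{i}", "", m.astype(np.int8)) for i, m in enumerate(mats)]
        )
        starts = np.stack([np.array([2, 12]) for _ in range(4)])
        aln = BlockAlignment(widths=[5, 6], starts=starts)
        _, m = block_to_hmm(aln, seqs, TransitionPriors(), dm20, uniform_bg)
        for k in range(4):
            states = AlignmentPath(row=m[k], n=30).states()
            emitted = [s[2] for s in states if s[0] in "NMIC"]
            assert emitted == list(range(30))


class TestValidateRow:
    def test_strictly_increasing(self):
        with pytest.raises(IllegalPathError):
            validate_row(np.array([3, 2]), 10)

    def test_all_deletions_legal(self):
        validate_row(np.full(4, -1), 10)

    def test_leading_trailing_deletions_legal(self):
        validate_row(np.array([-1, 4, 5, -1]), 10)

    def test_row_transitions_roundtrip_weighting(self):
        row = np.array([1, 2, -1, 3, 6])
        arcs = row_transitions(row)
        assert ("md", 2) in arcs and ("dm", 3) in arcs
        assert ("mi", 4) in arcs and ("ii", 4) in arcs and ("im", 4) in arcs
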