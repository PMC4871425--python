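"""Statistical core: block alignments, their integrated likelihood-ratio
score, predictive placement sampling, HMM transition counts / priors /
posteriors, the integrated transition likelihood, and block-to-HMM
conversion.

Alignment state conventions
---------------------------
A phase-2 alignment is stored as a (K, w) int matrix ``m``: ``m[k, j]`` is
the 0-based residue index of sequence k matched at model column j, or -1
for a deletion.  Insertions are implicit: residues strictly between two
consecutively matched columns are insert-state emissions attached to the
left column; residues before the first / after the last matched column are
unaligned flanks.  Because I->D and D->I arcs do not exist, a legal row
must have consecutive residue indices flanking any internal deletion run.

Transition counters are indexed by source position p = 0..w: p = 0 holds
the start-state arcs (Start->M1 / Start->D1), p in 1..w-1 arcs out of
column p, and p = w the exit arcs (M_w->End counted as mm, D_w->End as dm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .priors import (
    Background,
    DirichletMixture,
    batch_bild_scores,
    batch_posterior_mean_emissions,
    batch_sample_emission_vectors,
    bild_score,
)
from .seqio import NRES, SequenceSet

NEG = -1.0e30  # -inf sentinel that survives arithmetic


# ---------------------------------------------------------------------------
# Block alignments (phase 1)


@dataclass
class BlockAlignment:
    """Ungapped co-linear block alignment: the position matrix a_{k,j}.

    ``widths[b]`` is the width of block b; ``starts[k, b]`` the 0-based
    start of block b in sequence k.  Column j of block b sits at
    ``starts[k, b] + j`` in every sequence.
    """

    widths: np.ndarray  # (B,) ints >= 1
    starts: np.ndarray  # (K, B) ints

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=np.int64)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        if self.widths.ndim != 1 or self.starts.ndim != 2:
            raise ValueError("bad block alignment shapes")
        if self.starts.shape[1] != len(self.widths):
            raise ValueError("starts/widths block count mismatch")

    @property
    def n_blocks(self) -> int:
        return len(self.widths)

    @property
    def w(self) -> int:
        return int(self.widths.sum())

    @property
    def K(self) -> int:
        return self.starts.shape[0]

    def validate(self, lengths: np.ndarray) -> None:
        """Check co-linearity, contiguity and bounds; raise on violation."""
        if np.any(self.widths < 1):
            raise ValueError("block widths must be >= 1")
        ends = self.starts + self.widths[None, :]
        if np.any(self.starts < 0) or np.any(ends > np.asarray(lengths)[:, None]):
            raise ValueError("block placement out of sequence bounds")
        if self.n_blocks > 1 and np.any(ends[:, :-1] > self.starts[:, 1:]):
            raise ValueError("blocks overlap or are out of order (co-linearity)")

    def positions(self, k: int) -> np.ndarray:
        """All w column positions a_{k, .} for sequence k, in column order."""
        return np.concatenate(
            [self.starts[k, b] + np.arange(self.widths[b]) for b in range(self.n_blocks)]
        )

    def column_matrix(self, seqs: SequenceSet) -> np.ndarray:
        """(K, w) residue-code matrix of the aligned columns."""
        K, w = self.K, self.w
        out = np.empty((K, w), dtype=np.int64)
        for k in range(K):
            out[k] = seqs[k].residues[self.positions(k)]
        return out

    def to_match_matrix(self, seqs: SequenceSet) -> np.ndarray:
        """(K, w) matrix of matched residue indices (phase-2 ``m`` format)."""
        return np.stack([self.positions(k) for k in range(self.K)])


def weighted_column_counts(columns: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """(w, 20) weighted residue counts; codes outside 0..19 are skipped."""
    K, w = columns.shape
    out = np.zeros((w, NRES))
    wts = np.asarray(weights, dtype=float) / 100.0
    for j in range(w):
        col = columns[:, j]
        valid = (col >= 0) & (col < NRES)
        np.add.at(out[j], col[valid], wts[valid])
    return out


def emission_llr(col_counts: np.ndarray, dm: DirichletMixture, bg: Background) -> float:
    """Sum of column BILD scores: the integrated emission log-odds vs the
    all-background null (the null therefore scores exactly 0)."""
    return float(batch_bild_scores(col_counts, dm, bg).sum())


def integrated_block_llr(
    seqs: SequenceSet,
    aln: BlockAlignment,
    dm: DirichletMixture,
    bg: Background,
    weights: np.ndarray | None = None,
) -> float:
    """Integrated log-likelihood ratio of a block alignment, in nats."""
    if aln.w == 0:
        return 0.0
    aln.validate(seqs.lengths)
    if weights is None:
        weights = seqs.weights
    cols = aln.column_matrix(seqs)
    return emission_llr(weighted_column_counts(cols, weights), dm, bg)


# ---------------------------------------------------------------------------
# Predictive placement of co-linear blocks


def column_log_odds(
    col_counts: np.ndarray, dm: DirichletMixture, bg: Background
) -> np.ndarray:
    """(w, 20) matrix ln(theta_hat_j / theta0) of posterior-mean log-odds."""
    return np.log(batch_posterior_mean_emissions(col_counts, dm)) - bg.log_theta0[None, :]


def placement_site_scores(residues: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """(w, n) matrix S[j, i]: log-odds of placing column j at residue i.

    UNKNOWN residues score 0 (background emission everywhere).
    """
    w = log_odds.shape[0]
    n = len(residues)
    S = np.zeros((w, n))
    std = residues < NRES
    for j in range(w):
        S[j, std] = log_odds[j, residues[std]]
    return S


def _block_scores(S: np.ndarray, widths: np.ndarray) -> list[np.ndarray]:
    """Per-block total score at every feasible offset (sliding sums)."""
    n = S.shape[1]
    out = []
    cum = 0
    for wb in widths:
        wb = int(wb)
        if wb > n:
            raise ValueError("sequence shorter than a block")
        bs = np.zeros(n - wb + 1)
        for t in range(wb):
            bs += S[cum + t, t : t + n - wb + 1]
        out.append(bs)
        cum += wb
    return out


def _suffix_lse(x: np.ndarray) -> np.ndarray:
    """suf[i] = logsumexp(x[i:]) with suf[len] = NEG."""
    suf = np.full(len(x) + 1, NEG)
    run = NEG
    for i in range(len(x) - 1, -1, -1):
        run = np.logaddexp(run, x[i])
        suf[i] = run
    return suf


def _suffix_max(x: np.ndarray) -> np.ndarray:
    suf = np.full(len(x) + 1, NEG)
    if len(x):
        suf[:-1] = np.maximum.accumulate(x[::-1])[::-1]
    return suf


def placement_log_weight(S: np.ndarray, widths: np.ndarray, starts: np.ndarray) -> float:
    """Unnormalized log weight of one concrete co-linear placement."""
    total = 0.0
    cum = 0
    for b, wb in enumerate(widths):
        for t in range(int(wb)):
            total += S[cum + t, starts[b] + t]
        cum += int(wb)
    return total


def sample_block_placement(
    S: np.ndarray,
    widths: np.ndarray,
    rng: np.random.Generator,
    T: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Sample (or, at T=0, maximize) a co-linear placement of all blocks.

    The placement distribution is the normalized predictive-probability
    product tempered to p^(1/T); dynamic programming over block offsets
    makes both the normalizer and exact sampling linear in sequence length.
    Returns (starts, log normalizer of the tempered distribution).
    """
    widths = np.asarray(widths, dtype=np.int64)
    n = S.shape[1]
    if widths.sum() > n:
        raise ValueError("sequence shorter than total block width")
    St = S if T in (0.0, 1.0) else S / T
    bs = _block_scores(St, widths)
    B = len(widths)
    greedy = T == 0.0
    suffix = _suffix_max if greedy else _suffix_lse

    # f[b][i] = best/total log weight of blocks b.. with block b exactly at i
    f: list[np.ndarray] = [np.empty(0)] * B
    suf: list[np.ndarray] = [np.empty(0)] * B
    f[B - 1] = bs[B - 1]
    suf[B - 1] = suffix(f[B - 1])
    for b in range(B - 2, -1, -1):
        wb = int(widths[b])
        nb = len(bs[b])
        fb = np.full(nb, NEG)
        for i in range(nb):
            nxt = suf[b + 1][i + wb] if i + wb < len(suf[b + 1]) else NEG
            fb[i] = bs[b][i] + nxt
        f[b] = fb
        suf[b] = suffix(fb)

    logZ = float(suf[0][0])
    starts = np.empty(B, dtype=np.int64)
    lo = 0
    for b in range(B):
        cand = f[b][lo:]
        if greedy:
            i = lo + int(np.argmax(cand))  # argmax -> leftmost tie
        else:
            logp = cand - _suffix_lse(cand)[0]
            i = lo + int(rng.choice(len(cand), p=np.exp(logp)))
        starts[b] = i
        lo = i + int(widths[b])
    return starts, logZ


def predictive_placement_distribution(
    residues: np.ndarray,
    widths: np.ndarray,
    log_odds: np.ndarray,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Exhaustive placement distribution (for small instances / tests).

    Returns (placements, probabilities) over every feasible co-linear
    placement of the blocks, proportional to the predictive product.
    """
    widths = np.asarray(widths, dtype=np.int64)
    n = len(residues)
    if widths.sum() > n:
        raise ValueError("sequence shorter than total block width")
    S = placement_site_scores(residues, log_odds)
    placements: list[np.ndarray] = []

    def rec(b: int, lo: int, acc: list[int]) -> None:
        if b == len(widths):
            placements.append(np.array(acc, dtype=np.int64))
            return
        room = int(widths[b:].sum())
        for i in range(lo, n - room + 1):
            rec(b + 1, i + int(widths[b]), acc + [i])

    rec(0, 0, [])
    lw = np.array([placement_log_weight(S, widths, p) for p in placements])
    lw -= lw.max()
    prob = np.exp(lw)
    prob /= prob.sum()
    return placements, prob


# ---------------------------------------------------------------------------
# Transition counts, priors, posteriors


@dataclass(frozen=True)
class TransitionPriors:
    """Pseudocounts for the per-position transition Dirichlet/Beta priors."""

    n_mm: float = 18.0
    n_mi: float = 1.0
    n_md: float = 1.0
    n_ii: float = 1.0
    n_im: float = 1.0
    n_dd: float = 1.0
    n_dm: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_mm, self.n_mi, self.n_md, self.n_ii, self.n_im, self.n_dd, self.n_dm) <= 0:
            raise ValueError("transition pseudocounts must be strictly positive")

    @property
    def n_m(self) -> float:
        return self.n_mm + self.n_mi + self.n_md

    @property
    def n_i(self) -> float:
        return self.n_ii + self.n_im

    @property
    def n_d(self) -> float:
        return self.n_dd + self.n_dm


TRANSITION_TYPES = ("mm", "mi", "md", "im", "ii", "dm", "dd")


class TransitionCounts:
    """Weighted per-position transition counters N_xy[p], p = 0..w."""

    def __init__(self, w: int):
        self.w = w
        for t in TRANSITION_TYPES:
            setattr(self, t, np.zeros(w + 1))

    def copy(self) -> "TransitionCounts":
        out = TransitionCounts(self.w)
        for t in TRANSITION_TYPES:
            setattr(out, t, getattr(self, t).copy())
        return out

    def as_dict(self) -> dict[str, np.ndarray]:
        return {t: getattr(self, t) for t in TRANSITION_TYPES}

    def allclose(self, other: "TransitionCounts", atol: float = 1e-6) -> bool:
        return all(
            np.allclose(getattr(self, t), getattr(other, t), atol=atol)
            for t in TRANSITION_TYPES
        )


class IllegalPathError(ValueError):
    pass


def validate_row(row: np.ndarray, n: int) -> None:
    """Check one sequence's match-column row for structural legality."""
    matched = np.flatnonzero(row >= 0)
    vals = row[matched]
    if np.any(vals >= n):
        raise IllegalPathError("matched residue index out of range")
    if len(vals) > 1:
        if np.any(np.diff(vals) <= 0):
            raise IllegalPathError("match positions not strictly increasing")
        # internal deletion runs forbid adjacent insertions (no I->D / D->I)
        gaps = np.diff(matched)
        bad = (gaps > 1) & (np.diff(vals) != 1)
        if np.any(bad):
            raise IllegalPathError(
                "insertions adjacent to an internal deletion run"
            )


def row_transitions(row: np.ndarray) -> list[tuple[str, int]]:
    """Arcs traversed by one row, as (type, source position p) pairs."""
    w = len(row)
    arcs: list[tuple[str, int]] = []
    arcs.append(("mm", 0) if row[0] >= 0 else ("md", 0))
    for c in range(w - 1):
        p = c + 1
        here_m = row[c] >= 0
        next_m = row[c + 1] >= 0
        if here_m and next_m:
            nins = int(row[c + 1] - row[c] - 1)
            if nins > 0:
                arcs.append(("mi", p))
                arcs.extend([("ii", p)] * (nins - 1))
                arcs.append(("im", p))
            else:
                arcs.append(("mm", p))
        elif here_m:
            arcs.append(("md", p))
        elif next_m:
            arcs.append(("dm", p))
        else:
            arcs.append(("dd", p))
    arcs.append(("mm", w) if row[w - 1] >= 0 else ("dm", w))
    return arcs


def count_transitions(
    m: np.ndarray, lengths: np.ndarray, weights: np.ndarray
) -> TransitionCounts:
    """Accumulate weighted transition counts over all rows of ``m``.

    Each traversed arc adds Wt(k)/100; rows are validated first and an
    illegal arc raises :class:`IllegalPathError` naming the sequence.
    """
    K, w = m.shape
    tc = TransitionCounts(w)
    for k in range(K):
        try:
            validate_row(m[k], int(lengths[k]))
        except IllegalPathError as exc:
            raise IllegalPathError(f"sequence {k}: {exc}") from exc
        add_row_transitions(tc, m[k], weights[k] / 100.0)
    return tc


def add_row_transitions(tc: TransitionCounts, row: np.ndarray, wt: float) -> None:
    for t, p in row_transitions(row):
        getattr(tc, t)[p] += wt


def sub_row_transitions(tc: TransitionCounts, row: np.ndarray, wt: float) -> None:
    add_row_transitions(tc, row, -wt)


def transition_point_estimates(
    tc: TransitionCounts, pr: TransitionPriors
) -> dict[str, np.ndarray]:
    """Posterior-mean transition probabilities per position.

    Returns arrays 'iota_o', 'delta_o', 'iota_e', 'delta_e' of length w+1.
    (Posterior means are used where the description says MAP: with
    pseudocounts <= 1 the mode is degenerate.)
    """
    m_tot = tc.mm + tc.mi + tc.md + pr.n_m
    iota_o = (tc.mi + pr.n_mi) / m_tot
    delta_o = (tc.md + pr.n_md) / m_tot
    iota_e = (tc.ii + pr.n_ii) / (tc.ii + tc.im + pr.n_i)
    delta_e = (tc.dd + pr.n_dd) / (tc.dd + tc.dm + pr.n_d)
    return {
        "iota_o": iota_o,
        "delta_o": delta_o,
        "iota_e": iota_e,
        "delta_e": delta_e,
    }


def sample_transition_probabilities(
    tc: TransitionCounts, pr: TransitionPriors, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Factorized posterior draws of the per-position transition parameters:
    delta_o ~ Beta(N_md+n_md, N_mm+N_mi+n_mm+n_mi); iota_o = (1-delta_o) *
    Beta(N_mi+n_mi, N_mm+n_mm); delta_e ~ Beta(N_dd+n_dd, N_dm+n_dm);
    iota_e ~ Beta(N_ii+n_ii, N_im+n_im)."""
    delta_o = rng.beta(tc.md + pr.n_md, tc.mm + tc.mi + pr.n_mm + pr.n_mi)
    iota_star = rng.beta(tc.mi + pr.n_mi, tc.mm + pr.n_mm)
    iota_o = (1.0 - delta_o) * iota_star
    delta_e = rng.beta(tc.dd + pr.n_dd, tc.dm + pr.n_dm)
    iota_e = rng.beta(tc.ii + pr.n_ii, tc.im + pr.n_im)
    return {
        "iota_o": iota_o,
        "delta_o": delta_o,
        "iota_e": iota_e,
        "delta_e": delta_e,
    }


def _row_factor(N: list[np.ndarray], n: list[float]) -> np.ndarray:
    """Integrated Dirichlet-multinomial factor for one transition row."""
    tot_n = sum(n)
    tot_N = sum(N)
    val = gammaln(tot_n) - gammaln(tot_N + tot_n)
    for Ni, ni in zip(N, n):
        val = val + gammaln(Ni + ni) - gammaln(ni)
    return val


def integrated_transition_loglike(tc: TransitionCounts, pr: TransitionPriors) -> float:
    """log h(Lambda): transition parameters integrated against their priors.

    Product over positions p = 0..w of the match-row trinomial factor and
    the insert- and delete-row Beta factors; zero counts give exactly 0.
    """
    match = _row_factor([tc.mm, tc.mi, tc.md], [pr.n_mm, pr.n_mi, pr.n_md])
    ins = _row_factor([tc.ii, tc.im], [pr.n_ii, pr.n_im])
    dele = _row_factor([tc.dd, tc.dm], [pr.n_dd, pr.n_dm])
    return float(np.sum(match + ins + dele))


# ---------------------------------------------------------------------------
# Profile HMM container and block -> HMM conversion


@dataclass
class ProfileHMM:
    """Profile HMM over w match columns: weighted emission counts, transition
    counts, and the priors needed to produce posterior point estimates or
    posterior draws of all parameters."""

    col_counts: np.ndarray  # (w, 20) weighted residue counts
    tcounts: TransitionCounts
    tpriors: TransitionPriors
    dm: DirichletMixture
    bg: Background
    flank_self: float = 0.99  # fixed flank self-transition (not inferred)

    @property
    def w(self) -> int:
        return self.col_counts.shape[0]

    def point_transitions(self) -> dict[str, np.ndarray]:
        return transition_point_estimates(self.tcounts, self.tpriors)

    def mean_emission_log_odds(self) -> np.ndarray:
        return column_log_odds(self.col_counts, self.dm, self.bg)

    def sampled_emission_log_odds(self, rng: np.random.Generator) -> np.ndarray:
        theta = batch_sample_emission_vectors(self.col_counts, self.dm, rng)
        return np.log(theta) - self.bg.log_theta0[None, :]

    def joint_score(self) -> float:
        """g(A, Lambda) up to the constant null: emission LLR + log h."""
        return emission_llr(self.col_counts, self.dm, self.bg) + (
            integrated_transition_loglike(self.tcounts, self.tpriors)
        )

    def dump(self) -> str:
        """Plain-text per-column debug dump."""
        est = self.point_transitions()
        lines = ["col\tcounts_sum\tbild\tiota_o\tdelta_o\tiota_e\tdelta_e"]
        for j in range(self.w):
            b = bild_score(self.col_counts[j], self.dm, self.bg)
            lines.append(
                f"{j + 1}\t{self.col_counts[j].sum():.3f}\t{b:.3f}\t"
                f"{est['iota_o'][j + 1]:.4f}\t{est['delta_o'][j + 1]:.4f}\t"
                f"{est['iota_e'][j + 1]:.4f}\t{est['delta_e'][j + 1]:.4f}"
            )
        return "\n".join(lines)


@dataclass
class AlignmentPath:
    """Explicit state path of one sequence through the HMM (mainly for
    inspection/tests; samplers operate on the compact row encoding)."""

    row: np.ndarray  # length-w match row (residue index or -1)
    n: int  # sequence length

    def states(self) -> list[tuple[str, int, int]]:
        """Ordered (state, column, residue) triples; residue -1 if silent.
        Columns are 1-based; flanks use column 0 / w+1."""
        validate_row(self.row, self.n)
        w = len(self.row)
        matched = np.flatnonzero(self.row >= 0)
        out: list[tuple[str, int, int]] = []
        first_res = int(self.row[matched[0]]) if len(matched) else self.n
        for i in range(first_res):
            out.append(("N", 0, i))
        pos = first_res
        for c in range(w):
            if self.row[c] >= 0:
                out.append(("M", c + 1, int(self.row[c])))
                pos = int(self.row[c]) + 1
                nxt = self.row[c + 1 :]
                nxt_m = np.flatnonzero(nxt >= 0)
                if len(nxt_m):
                    upto = int(nxt[nxt_m[0]])
                    for i in range(pos, upto):
                        out.append(("I", c + 1, i))
            else:
                out.append(("D", c + 1, -1))
        last = int(self.row[matched[-1]]) if len(matched) else first_res
        start_c = last + 1 if len(matched) else first_res
        for i in range(start_c, self.n):
            out.append(("C", w + 1, i))
        return out

    def emitted(self) -> int:
        return self.n


def block_to_hmm(
    aln: BlockAlignment,
    seqs: SequenceSet,
    tpriors: TransitionPriors,
    dm: DirichletMixture,
    bg: Background,
    weights: np.ndarray | None = None,
) -> tuple[ProfileHMM, np.ndarray]:
    """Convert a phase-1 block alignment into a profile HMM plus the initial
    (deletion-free) match matrix: one match state per block column, with
    inter-block residues as insert emissions at the preceding column."""
    aln.validate(seqs.lengths)
    if weights is None:
        weights = seqs.weights
    m = aln.to_match_matrix(seqs)
    cols = aln.column_matrix(seqs)
    col_counts = weighted_column_counts(cols, weights)
    tcounts = count_transitions(m, seqs.lengths, weights)
    return ProfileHMM(col_counts, tcounts, tpriors, dm, bg), m
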