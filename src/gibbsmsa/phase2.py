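"""Phase 2: annealed Gibbs sampling of sequences against a gapped profile
HMM, with BILD-driven column add/remove/shift moves.

The alignment state is the (K, w) match matrix described in
:mod:`gibbsmsa.model`.  Sequences are realigned by dynamic programming over
the M/I/D state graph (with background-emitting flanks, so the model is
local in each sequence but global in the model); at T=0 the maximum-
probability path is taken, at T>0 a stochastic traceback with local choice
probabilities tempered to p^(1/T).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .model import (
    NEG,
    IllegalPathError,
    ProfileHMM,
    TransitionCounts,
    TransitionPriors,
    add_row_transitions,
    count_transitions,
    emission_llr,
    integrated_transition_loglike,
    sub_row_transitions,
    transition_point_estimates,
    validate_row,
)
from .priors import Background, DirichletMixture, bild_score
from .seqio import NRES, GappedMSA, SequenceSet, decode
from .weights import WeightState, update_weights

logger = logging.getLogger(__name__)


@dataclass
class AnnealSchedule:
    """T = 1.0 down to 0.0 in dt steps, a fixed number of sweeps at each."""

    t_start: float = 1.0
    t_end: float = 0.0
    dt: float = 0.1
    sweeps_per_t: int = 2
    patience: int = 10  # extra T=0 sweeps without a new best before stopping
    max_t0_sweeps: int = 40

    def temperatures(self) -> list[float]:
        n = int(round((self.t_start - self.t_end) / self.dt))
        return [round(self.t_start - i * self.dt, 10) for i in range(n + 1)]


@dataclass
class Phase2Config:
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    early_slack: float = 2.0  # nats of BILD slack for keeping columns early on
    strategy_every: int = 2  # sweeps between strategy-move invocations
    min_add_occupancy: float = 0.5
    #: require the joint score to beat the description cost of the alignment
    #: variables (one placement per sequence); otherwise report no alignment
    mdl_alignment_test: bool = True


# ---------------------------------------------------------------------------
# HMM view used by the aligner


@dataclass
class HMMView:
    """Log-space parameters for one DP pass: per-column match log-odds and
    point-estimate transition log probabilities (index p = source position,
    p = 0 the start state)."""

    E: np.ndarray  # (w, 20) match emission log-odds
    lmm: np.ndarray
    lmi: np.ndarray
    lmd: np.ndarray
    lim: np.ndarray
    ldm: np.ndarray
    lii: np.ndarray
    ldd: np.ndarray
    lneta: float  # flank self-transition
    lnxi: float  # flank exit

    @property
    def w(self) -> int:
        return self.E.shape[0]


def build_view(
    hmm: ProfileHMM,
    rng: np.random.Generator | None = None,
    sample_emissions: bool = False,
) -> HMMView:
    est = transition_point_estimates(hmm.tcounts, hmm.tpriors)
    io, do = est["iota_o"], est["delta_o"]
    ie, de = est["iota_e"], est["delta_e"]
    with np.errstate(divide="ignore"):
        lmm = np.log(np.maximum(1.0 - io - do, 1e-300))
        lmi = np.log(io)
        lmd = np.log(do)
        lim = np.log(1.0 - ie)
        lii = np.log(ie)
        ldm = np.log(1.0 - de)
        ldd = np.log(de)
    # start state has no insert arc: renormalize p=0 over {M1, D1}
    tc, pr = hmm.tcounts, hmm.tpriors
    d0 = (tc.md[0] + pr.n_md) / (tc.md[0] + tc.mm[0] + pr.n_md + pr.n_mm)
    lmm[0], lmd[0] = np.log(1.0 - d0), np.log(d0)
    if sample_emissions:
        assert rng is not None
        E = hmm.sampled_emission_log_odds(rng)
    else:
        E = hmm.mean_emission_log_odds()
    return HMMView(
        E=E, lmm=lmm, lmi=lmi, lmd=lmd, lim=lim, ldm=ldm, lii=lii, ldd=ldd,
        lneta=float(np.log(hmm.flank_self)), lnxi=float(np.log(1.0 - hmm.flank_self)),
    )


# ---------------------------------------------------------------------------
# Sequence-to-HMM alignment DP


def _fill(residues: np.ndarray, v: HMMView, viterbi: bool):
    """Fill M/I/D score matrices, shape (w+1, n+1); index [j, i] = column j
    with i residues consumed.  Row 0 is unused."""
    w, n = v.w, len(residues)
    std = residues < NRES
    M = np.full((w + 1, n + 1), NEG)
    I = np.full((w + 1, n + 1), NEG)
    D = np.full((w + 1, n + 1), NEG)
    FN = np.arange(n + 1) * v.lneta + v.lnxi

    def emit(j: int) -> np.ndarray:
        e = np.zeros(n)
        e[std] = v.E[j - 1, residues[std]]
        return e

    lse3 = (
        (lambda a, b, c: np.maximum(np.maximum(a, b), c))
        if viterbi
        else (lambda a, b, c: np.logaddexp(np.logaddexp(a, b), c))
    )
    lse2 = np.maximum if viterbi else np.logaddexp
    acc = np.maximum.accumulate if viterbi else np.logaddexp.accumulate

    M[1, 1:] = FN[:-1] + v.lmm[0] + emit(1)
    D[1, :] = FN + v.lmd[0]
    for j in range(1, w + 1):
        if j > 1:
            prev = lse3(
                M[j - 1, :-1] + v.lmm[j - 1],
                I[j - 1, :-1] + v.lim[j - 1],
                D[j - 1, :-1] + v.ldm[j - 1],
            )
            M[j, 1:] = prev + emit(j)
            D[j, :] = lse2(M[j - 1, :] + v.lmd[j - 1], D[j - 1, :] + v.ldd[j - 1])
        if j < w:
            # insert-run scan: I[j,i] combines M[j,k<i] via (i-1-k) self-loops
            u = M[j, :-1] + v.lmi[j] - np.arange(n) * v.lii[j]
            I[j, 1:] = acc(u) + np.arange(n) * v.lii[j]
    return M, I, D, FN


def _choose(
    vals: np.ndarray, rng: np.random.Generator, T: float, viterbi: bool
) -> int:
    """Pick an index from unnormalized log weights; tempered at T>0, strict
    first-argmax at T=0 (callers order candidates by tie preference)."""
    if viterbi:
        return int(np.argmax(vals))
    x = (vals - vals.max()) / T
    p = np.exp(x)
    p /= p.sum()
    return int(rng.choice(len(vals), p=p))


def align_sequence_to_hmm(
    residues: np.ndarray,
    view: HMMView,
    rng: np.random.Generator,
    T: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Align one sequence to the model; returns (match row, path log score).

    Every model column is consumed by M or D; leading/trailing residues sit
    in background flanks.  T=0: max-probability path, ties preferring
    M > D > I then leftmost.  T>0: stochastic traceback, local choice
    probabilities tempered to p^(1/T).
    """
    w, n = view.w, len(residues)
    if w < 1:
        raise ValueError("model must have at least one column")
    viterbi = T == 0.0
    M, I, D, FN = _fill(residues, view, viterbi)

    # exit: choose consumed-prefix length and exit state (M_w or D_w)
    tail = (n - np.arange(n + 1)) * view.lneta
    exit_m = M[w, :] + tail
    exit_d = D[w, :] + tail
    cand = np.concatenate([exit_m, exit_d])  # M block first: M preferred on ties
    idx = _choose(cand, rng, T, viterbi)
    state, i = ("M", idx) if idx <= n else ("D", idx - n - 1)

    row = np.full(w, -1, dtype=np.int64)
    score = float(cand[idx])
    j = w
    while j >= 1:
        if state == "M":
            row[j - 1] = i - 1
            if j == 1:
                break
            vals = np.array(
                [
                    M[j - 1, i - 1] + view.lmm[j - 1],
                    D[j - 1, i - 1] + view.ldm[j - 1],
                    I[j - 1, i - 1] + view.lim[j - 1],
                ]
            )
            c = _choose(vals, rng, T, viterbi)
            state = "MDI"[c]
            i -= 1
            j -= 1
        elif state == "D":
            if j == 1:
                break
            vals = np.array(
                [M[j - 1, i] + view.lmd[j - 1], D[j - 1, i] + view.ldd[j - 1]]
            )
            c = _choose(vals, rng, T, viterbi)
            state = "MD"[c]
            j -= 1
        else:  # insert state I_j
            vals = np.array([M[j, i - 1] + view.lmi[j], I[j, i - 1] + view.lii[j]])
            c = _choose(vals, rng, T, viterbi)
            state = "MI"[c]
            i -= 1
    return row, score


def enumerate_paths(n: int, w: int) -> list[np.ndarray]:
    """All legal match rows for a length-n sequence and w columns (tests)."""
    out: list[np.ndarray] = []

    def rec(j: int, row: list[int]) -> None:
        if j == w:
            r = np.array(row, dtype=np.int64)
            try:
                validate_row(r, n)
            except IllegalPathError:
                return
            out.append(r)
            return
        rec(j + 1, row + [-1])
        lo = max([x for x in row if x >= 0], default=-1) + 1
        for i in range(lo, n):
            rec(j + 1, row + [i])

    rec(0, [])
    return out


def path_log_score(row: np.ndarray, residues: np.ndarray, view: HMMView) -> float:
    """Score of one explicit path under the same objective as the DP."""
    from .model import row_transitions

    n = len(residues)
    validate_row(row, n)
    arcs = row_transitions(row)
    lut = {
        "mm": view.lmm, "mi": view.lmi, "md": view.lmd,
        "im": view.lim, "ii": view.lii, "dm": view.ldm, "dd": view.ldd,
    }
    score = 0.0
    for t, p in arcs:
        if p == w_end(row):
            continue  # exit arcs are deterministic in the DP
        score += float(lut[t][p])
    for j in range(len(row)):
        if row[j] >= 0 and residues[row[j]] < NRES:
            score += float(view.E[j, residues[row[j]]])
    matched = np.flatnonzero(row >= 0)
    in_model = (
        int(row[matched[-1]] - row[matched[0]] + 1) if len(matched) else 0
    )
    score += (n - in_model) * view.lneta + view.lnxi
    return score


def w_end(row: np.ndarray) -> int:
    return len(row)


# ---------------------------------------------------------------------------
# Mutable alignment state


class MsaState:
    """Evolving gapped alignment plus incrementally maintained counts."""

    def __init__(
        self,
        seqs: SequenceSet,
        m: np.ndarray,
        tpriors: TransitionPriors,
        dm: DirichletMixture,
        bg: Background,
        wstate: WeightState,
        flank_self: float = 0.99,
    ):
        self.seqs = seqs
        self.m = np.asarray(m, dtype=np.int64)
        self.tpriors = tpriors
        self.dm = dm
        self.bg = bg
        self.wstate = wstate
        self.flank_self = flank_self
        self.refresh_counts()

    # -- bookkeeping ------------------------------------------------------

    @property
    def K(self) -> int:
        return self.m.shape[0]

    @property
    def w(self) -> int:
        return self.m.shape[1]

    @property
    def weights(self) -> np.ndarray:
        return self.wstate.integer

    def refresh_counts(self) -> None:
        """Recompute column and transition counts from scratch."""
        self.col_counts = np.zeros((self.w, NRES))
        if self.w == 0:
            self.tcounts = TransitionCounts(0)
            return
        for k in range(self.K):
            self._add_emissions(k, +1.0)
        self.tcounts = count_transitions(self.m, self.seqs.lengths, self.weights)

    def _add_emissions(self, k: int, sign: float) -> None:
        wt = sign * self.weights[k] / 100.0
        row = self.m[k]
        res = self.seqs[k].residues
        for j in np.flatnonzero(row >= 0):
            r = res[row[j]]
            if r < NRES:
                self.col_counts[j, r] += wt

    def remove_seq(self, k: int) -> None:
        self._add_emissions(k, -1.0)
        sub_row_transitions(self.tcounts, self.m[k], self.weights[k] / 100.0)

    def insert_seq(self, k: int, row: np.ndarray) -> None:
        validate_row(row, len(self.seqs[k]))
        self.m[k] = row
        self._add_emissions(k, +1.0)
        add_row_transitions(self.tcounts, row, self.weights[k] / 100.0)

    def hmm(self) -> ProfileHMM:
        return ProfileHMM(
            self.col_counts, self.tcounts, self.tpriors, self.dm, self.bg,
            flank_self=self.flank_self,
        )

    def joint_score(self) -> float:
        """g(A, Lambda) relative to the null: emission LLR + log h(Lambda)."""
        if self.w == 0:
            return 0.0
        return emission_llr(self.col_counts, self.dm, self.bg) + (
            integrated_transition_loglike(self.tcounts, self.tpriors)
        )

    def column_matrix(self) -> np.ndarray:
        """(K, w) residue codes at match cells; -1 where deleted."""
        out = np.full((self.K, self.w), -1, dtype=np.int64)
        for k in range(self.K):
            row = self.m[k]
            idx = np.flatnonzero(row >= 0)
            out[k, idx] = self.seqs[k].residues[row[idx]]
        return out

    def update_weights(self) -> None:
        """Recompute Henikoff weights (no-op when frozen); counts follow."""
        if self.wstate.frozen or self.w == 0:
            return
        new = update_weights(self.wstate, self.column_matrix())
        if not np.array_equal(new.integer, self.wstate.integer):
            self.wstate = new
            self.refresh_counts()
        else:
            self.wstate = new

    def copy_snapshot(self) -> np.ndarray:
        return self.m.copy()

    def restore_snapshot(self, m: np.ndarray) -> None:
        self.m = m.copy()
        self.refresh_counts()

    # -- conversions ------------------------------------------------------

    def to_msa(self) -> GappedMSA:
        rows = []
        for k in range(self.K):
            res = decode(self.seqs[k].residues)
            row = self.m[k]
            matched = np.flatnonzero(row >= 0)
            first = int(row[matched[0]]) if len(matched) else len(res)
            parts = [res[:first].lower()]
            pos = first
            for j in range(self.w):
                if row[j] >= 0:
                    parts.append(res[row[j]].upper())
                    pos = int(row[j]) + 1
                    nxt = row[j + 1 :]
                    nxt_m = nxt[nxt >= 0]
                    upto = int(nxt_m[0]) if len(nxt_m) else pos
                    parts.append(res[pos:upto].lower())
                else:
                    parts.append("-")
            last = int(row[matched[-1]]) + 1 if len(matched) else first
            parts.append(res[last:].lower())
            rows.append("".join(parts))
        return GappedMSA(ids=self.seqs.ids, rows=rows, n_match=self.w)


def state_from_blocks(
    seqs: SequenceSet,
    aln,
    tpriors: TransitionPriors,
    dm: DirichletMixture,
    bg: Background,
    wstate: WeightState,
) -> MsaState:
    """Convert a phase-1 block alignment into the initial phase-2 state
    (one match state per block column; no deletions; inter-block residues
    become insertions)."""
    m = aln.to_match_matrix(seqs)
    return MsaState(seqs, m, tpriors, dm, bg, wstate)


# ---------------------------------------------------------------------------
# Moves


def resample_sequence(
    state: MsaState, k: int, rng: np.random.Generator, T: float
) -> None:
    """Gibbs step for one sequence: remove it, sample emissions from the
    leave-one-out posterior, realign with point-estimate transitions, and
    restore its counts.  At T=0 the move is guarded: if the greedy
    realignment would lower the joint score the old path is kept."""
    if state.K < 3:
        raise ValueError("need K >= 3")
    if state.w == 0:
        return
    old_row = state.m[k].copy()
    old_score = state.joint_score() if T == 0.0 else None
    state.remove_seq(k)
    view = build_view(state.hmm(), rng, sample_emissions=True)
    row, _ = align_sequence_to_hmm(state.seqs[k].residues, view, rng, T)
    state.insert_seq(k, row)
    if T == 0.0 and old_score is not None and not np.array_equal(row, old_row):
        if state.joint_score() < old_score - 1e-9:
            state.remove_seq(k)
            state.insert_seq(k, old_row)


def sequence_score(state: MsaState, k: int, view: HMMView | None = None) -> float:
    """Per-sequence log-odds contribution under the current mean model."""
    if view is None:
        view = build_view(state.hmm())
    return path_log_score(state.m[k], state.seqs[k].residues, view)


def _repair_rows(state: MsaState, rng: np.random.Generator) -> None:
    """Greedily realign rows whose encoding became illegal after a column
    edit (insertions stranded against a deletion run)."""
    bad = []
    for k in range(state.K):
        try:
            validate_row(state.m[k], len(state.seqs[k]))
        except IllegalPathError:
            bad.append(k)
    if not bad:
        return
    for k in bad:
        state.m[k] = -1  # placeholder; rebuilt below
    state.refresh_counts()
    if state.w == 0:
        return
    for k in bad:
        view = build_view(state.hmm())
        row, _ = align_sequence_to_hmm(state.seqs[k].residues, view, rng, 0.0)
        state.insert_seq(k, row)


def column_add_remove(
    state: MsaState,
    rng: np.random.Generator,
    phase: str = "final",
    cfg: Phase2Config | None = None,
) -> int:
    """Threshold columns on their weighted BILD scores.

    Existing match columns scoring below tau(phase) are converted to
    insertions; insert positions where at least half the weighted sequences
    carry residues are promoted to match columns when they score above the
    threshold.  Returns the number of columns changed.
    """
    cfg = cfg or Phase2Config()
    tau = 0.0 if phase == "final" else -cfg.early_slack
    changed = 0

    # removals (right to left so indices stay valid)
    for j in range(state.w - 1, -1, -1):
        if state.w <= 0:
            break
        if bild_score(state.col_counts[j], state.dm, state.bg) <= tau:
            state.m = np.delete(state.m, j, axis=1)
            changed += 1
    if changed:
        _repair_rows(state, rng)
        state.refresh_counts()
    if state.w == 0:
        return changed

    # additions: iterate to a fixpoint so the model can walk outward into
    # conserved flanks and absorb multi-column insert regions
    for _ in range(64):
        added = _add_columns_once(state, tau, cfg)
        changed += added
        if not added:
            break
    if changed:
        state.refresh_counts()
    return changed


def _candidate_bild(state: MsaState, newcol: np.ndarray, wts: np.ndarray) -> float:
    counts = np.zeros(NRES)
    for k in np.flatnonzero(newcol >= 0):
        r = state.seqs[k].residues[newcol[k]]
        if r < NRES:
            counts[r] += wts[k]
    return bild_score(counts, state.dm, state.bg)


def _add_columns_once(state: MsaState, tau: float, cfg: Phase2Config) -> int:
    """One right-to-left pass of column promotion (inserts + both flanks)."""
    added = 0
    wts = state.weights / 100.0
    total_wt = wts.sum()

    # C-flank growth: residues just beyond the last matched column
    last = np.array(
        [
            int(row[np.flatnonzero(row >= 0)[-1]]) if np.any(row >= 0) else -1
            for row in state.m
        ]
    )
    ext = (last >= 0) & (last + 1 < state.seqs.lengths)
    if wts[ext].sum() >= cfg.min_add_occupancy * total_wt:
        newcol = np.full(state.K, -1, dtype=np.int64)
        newcol[ext] = last[ext] + 1
        # only legal when the carrying row's final model column is matched
        ok = ext & (state.m[:, -1] >= 0)
        newcol[~ok] = -1
        if np.any(newcol >= 0) and _candidate_bild(state, newcol, wts) > tau:
            state.m = np.concatenate([state.m, newcol[:, None]], axis=1)
            added += 1

    # interior insert positions
    for j in range(state.w - 2, -1, -1):
        left = state.m[:, j]
        right = state.m[:, j + 1]
        has_ins = (left >= 0) & (right >= 0) & (right - left > 1)
        if wts[has_ins].sum() < cfg.min_add_occupancy * total_wt:
            continue
        newcol = np.full(state.K, -1, dtype=np.int64)
        newcol[has_ins] = left[has_ins] + 1
        if _candidate_bild(state, newcol, wts) > tau:
            state.m = np.insert(state.m, j + 1, newcol, axis=1)
            added += 1

    # N-flank growth: residues just before the first matched column
    first = np.array(
        [
            int(row[np.flatnonzero(row >= 0)[0]]) if np.any(row >= 0) else -1
            for row in state.m
        ]
    )
    ext = first >= 1
    if wts[ext].sum() >= cfg.min_add_occupancy * total_wt:
        newcol = np.full(state.K, -1, dtype=np.int64)
        ok = ext & (state.m[:, 0] >= 0)
        newcol[ok] = first[ok] - 1
        if np.any(newcol >= 0) and _candidate_bild(state, newcol, wts) > tau:
            state.m = np.concatenate([newcol[:, None], state.m], axis=1)
            added += 1

    if added:
        state.refresh_counts()
    return added


def shift_columns_across_insertions(state: MsaState) -> int:
    """Move edge match columns across insert regions when that improves the
    aggregate weighted BILD score; ties keep the current configuration.
    Returns the number of shifts applied."""
    applied = 0
    j = 0
    while j < state.w - 1:
        left = state.m[:, j]
        right = state.m[:, j + 1]
        has_ins = (left >= 0) & (right >= 0) & (right - left > 1)
        if not np.any(has_ins):
            j += 1
            continue
        wts = state.weights / 100.0
        best_delta, best_m = 0.0, None
        for variant, col in (("pull_right_left", j + 1), ("push_left_right", j)):
            cand = state.m.copy()
            if variant == "pull_right_left":
                cand[has_ins, j + 1] = left[has_ins] + 1
            else:
                cand[has_ins, j] = right[has_ins] - 1
            try:
                for k in np.flatnonzero(has_ins):
                    validate_row(cand[k], len(state.seqs[k]))
            except IllegalPathError:
                continue
            old_counts = np.zeros(NRES)
            new_counts = np.zeros(NRES)
            for k in range(state.K):
                for mat, acc in ((state.m, old_counts), (cand, new_counts)):
                    if mat[k, col] >= 0:
                        r = state.seqs[k].residues[mat[k, col]]
                        if r < NRES:
                            acc[r] += wts[k]
            delta = bild_score(new_counts, state.dm, state.bg) - bild_score(
                old_counts, state.dm, state.bg
            )
            if delta > best_delta + 1e-12:
                best_delta, best_m = delta, cand
        if best_m is not None:
            state.m = best_m
            state.refresh_counts()
            applied += 1
        j += 1
    return applied


# ---------------------------------------------------------------------------
# Driver


def anneal(
    state: MsaState,
    cfg: Phase2Config,
    rng: np.random.Generator,
    strategy_fn: Callable[[MsaState, np.random.Generator, float], None] | None = None,
) -> list[tuple[float, float]]:
    """Anneal an existing state in place, leaving it at the best alignment
    found; returns the (temperature, best joint score) trace per sweep.
    The tracked best is non-decreasing by construction."""
    best_m = state.copy_snapshot()
    best = state.joint_score()
    trace: list[tuple[float, float]] = []
    sweep_no = 0

    def track() -> None:
        nonlocal best, best_m
        s = state.joint_score()
        if s > best + 1e-9:
            best, best_m = s, state.copy_snapshot()

    def sweep(T: float) -> None:
        nonlocal sweep_no
        for k in rng.permutation(state.K):
            resample_sequence(state, int(k), rng, T)
        sweep_no += 1
        if strategy_fn is not None and sweep_no % cfg.strategy_every == 0:
            strategy_fn(state, rng, T)
        track()
        trace.append((T, best))

    schedule = cfg.schedule
    for T in schedule.temperatures():
        if state.w == 0:
            break
        if T < 1.0 and not state.wstate.frozen:
            state.wstate = state.wstate.freeze()
        for _ in range(schedule.sweeps_per_t):
            sweep(T)
            if T == 1.0:
                state.update_weights()
        if state.w == 0:
            break
        column_add_remove(state, rng, "early" if T > 0.05 else "final", cfg)
        shift_columns_across_insertions(state)
        track()

    stall = 0
    for _ in range(schedule.max_t0_sweeps):
        if state.w == 0 or stall >= schedule.patience:
            break
        prev = best
        sweep(0.0)
        column_add_remove(state, rng, "final", cfg)
        shift_columns_across_insertions(state)
        track()
        stall = 0 if best > prev + 1e-9 else stall + 1

    state.restore_snapshot(best_m)
    # a final thresholding so no unsupported column survives in output
    column_add_remove(state, rng, "final", cfg)
    if cfg.mdl_alignment_test and state.w > 0:
        cost = placement_description_cost(state)
        if state.joint_score() <= cost:
            logger.info(
                "alignment not statistically supported (joint %.1f <= "
                "description cost %.1f); reporting no aligned columns",
                state.joint_score(), cost,
            )
            state.m = np.zeros((state.K, 0), dtype=np.int64)
            state.refresh_counts()
    return trace


def placement_description_cost(state: MsaState) -> float:
    """Weighted description length (nats) of the alignment variables: one
    placement choice per sequence.  An alignment whose joint score does not
    exceed this cost is better described as unaligned background — the
    selection bias a greedy sampler exerts on random sequences is of
    exactly this size, so thresholding here keeps random inputs unaligned."""
    wts = state.weights / 100.0
    return float(np.sum(wts * np.log(state.seqs.lengths + 1.0)))


def run_phase2(
    seqs: SequenceSet,
    block_aln,
    cfg: Phase2Config,
    tpriors: TransitionPriors,
    dm: DirichletMixture,
    bg: Background,
    rng: np.random.Generator,
    wstate: WeightState | None = None,
    strategy_fn: Callable[[MsaState, np.random.Generator, float], None] | None = None,
) -> tuple[GappedMSA, MsaState, list[tuple[float, float]]]:
    """Convert a phase-1 block alignment into the gapped HMM state and
    anneal it; returns (best MSA, final state, per-sweep trace)."""
    if wstate is None:
        wstate = WeightState.compute(block_aln.column_matrix(seqs))
    state = state_from_blocks(seqs, block_aln, tpriors, dm, bg, wstate)
    trace = anneal(state, cfg, rng, strategy_fn)
    logger.info("phase2 done: w=%d joint=%.2f", state.w, state.joint_score())
    return state.to_msa(), state, trace
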