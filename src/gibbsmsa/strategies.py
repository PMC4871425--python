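"""Correlated-sequence escape moves and the competitive-selection wrapper.

Single-sequence Gibbs steps get stuck when clusters of closely related
sequences keep pulling a resampled member back to a shared misalignment.
The moves here resample such groups in tandem: via a consensus template for
indel-free tight clusters, via group realignment for looser clusters and
for sequences sharing congruent indels or minority residues, via a purged
(representatives-only) realignment, and by resampling the worst-scoring or
random subsets.  Competitive selection races several independent
trajectories and keeps the one most similar to the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .phase1 import Phase1Config, run_phase1
from .phase2 import (
    AnnealSchedule,
    MsaState,
    Phase2Config,
    align_sequence_to_hmm,
    anneal,
    build_view,
    run_phase2,
    sequence_score,
    state_from_blocks,
)
from .model import TransitionPriors
from .priors import Background, DirichletMixture, bild_score
from .seqio import NRES, UNKNOWN, GappedMSA, SequenceRecord, SequenceSet
from .weights import WeightState

logger = logging.getLogger(__name__)


@dataclass
class SequenceCluster:
    members: list[int]
    kind: str  # 'tight' | 'loose'
    consensus: SequenceRecord | None = None


@dataclass
class SamplerConfig:
    """Full pipeline configuration (population defaults per the method)."""

    population: int = 10
    survivors: int = 5
    tight_threshold: float = 0.95
    loose_threshold: float = 0.40
    worst_fraction: float = 0.10
    subset_rounds: int = 5
    phase1: Phase1Config = field(default_factory=Phase1Config)
    phase2: Phase2Config = field(default_factory=Phase2Config)
    tpriors: TransitionPriors = field(default_factory=TransitionPriors)

    def __post_init__(self) -> None:
        if not (self.population >= self.survivors >= 1):
            raise ValueError("need population >= survivors >= 1")


# ---------------------------------------------------------------------------
# Clustering


def pairwise_identity(colmat: np.ndarray) -> np.ndarray:
    """(K, K) percent identity over match columns (-1 cells skipped)."""
    K = colmat.shape[0]
    out = np.zeros((K, K))
    valid = colmat >= 0
    for a in range(K):
        both = valid[a] & valid
        same = (colmat[a] == colmat) & both
        denom = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            row = np.where(denom > 0, same.sum(axis=1) / np.maximum(denom, 1), 0.0)
        out[a] = row
    np.fill_diagonal(out, 1.0)
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.p = list(range(n))

    def find(self, x: int) -> int:
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.p[max(ra, rb)] = min(ra, rb)


def cluster_sequences(
    state: MsaState,
    tight_threshold: float = 0.95,
    loose_threshold: float = 0.40,
) -> list[SequenceCluster]:
    """Single-linkage clusters on match-column percent identity.

    A cluster is 'tight' when all members share one indel-free mutual
    alignment (identical match rows, hence identical gap pattern) and every
    pair reaches the tight threshold; otherwise 'loose'.
    """
    if not (0 < loose_threshold <= tight_threshold <= 1):
        raise ValueError("need 0 < loose <= tight <= 1")
    colmat = state.column_matrix()
    ident = pairwise_identity(colmat)
    K = state.K
    uf = _UnionFind(K)
    for a in range(K):
        for b in range(a + 1, K):
            if ident[a, b] >= loose_threshold:
                uf.union(a, b)
    groups: dict[int, list[int]] = {}
    for k in range(K):
        groups.setdefault(uf.find(k), []).append(k)

    def is_tight(members: list[int]) -> bool:
        rows_equal = all(
            np.array_equal(state.m[members[0]], state.m[k]) for k in members
        )
        same_len = len({len(state.seqs[k]) for k in members}) == 1
        pairs_ok = all(
            ident[a, b] >= tight_threshold
            for i, a in enumerate(members)
            for b in members[i + 1 :]
        )
        return rows_equal and same_len and pairs_ok

    clusters = []
    for members in groups.values():
        members = sorted(members)
        if len(members) >= 2 and is_tight(members):
            clusters.append(SequenceCluster(members=members, kind="tight"))
            continue
        # split out tight sub-clusters (single linkage at the tight
        # threshold, restricted to identical alignment rows)
        uf2 = _UnionFind(len(members))
        for i, a in enumerate(members):
            for jj in range(i + 1, len(members)):
                b = members[jj]
                if ident[a, b] >= tight_threshold and np.array_equal(
                    state.m[a], state.m[b]
                ) and len(state.seqs[a]) == len(state.seqs[b]):
                    uf2.union(i, jj)
        subs: dict[int, list[int]] = {}
        for i, a in enumerate(members):
            subs.setdefault(uf2.find(i), []).append(a)
        rest: list[int] = []
        for sub in subs.values():
            if len(sub) >= 2 and is_tight(sub):
                clusters.append(SequenceCluster(members=sorted(sub), kind="tight"))
            else:
                rest.extend(sub)
        if rest:
            clusters.append(SequenceCluster(members=sorted(rest), kind="loose"))
    return sorted(clusters, key=lambda c: c.members[0])


def consensus_sequence(cluster: SequenceCluster, state: MsaState) -> SequenceRecord:
    """Weighted-majority consensus of a tight cluster, over the full common
    sequence length (ties resolve to the alphabetically first residue)."""
    if cluster.kind != "tight":
        raise ValueError("consensus is only defined for tight clusters")
    members = cluster.members
    n = len(state.seqs[members[0]])
    wts = state.weights[members] / 100.0
    votes = np.zeros((n, NRES))
    for wt, k in zip(wts, members):
        res = state.seqs[k].residues
        std = res < NRES
        votes[np.arange(n)[std], res[std]] += wt
    cons = np.where(votes.sum(axis=1) > 0, np.argmax(votes, axis=1), UNKNOWN)
    return SequenceRecord(
        id=f"consensus[{members[0]}]", description="cluster consensus",
        residues=cons.astype(np.int8),
    )


# ---------------------------------------------------------------------------
# Group moves


def _guarded(state: MsaState, members: list[int], old_score: float | None) -> None:
    """no-op hook kept for symmetry; guard logic lives in callers."""


def resample_cluster_via_consensus(
    state: MsaState,
    cluster: SequenceCluster,
    rng: np.random.Generator,
    T: float,
) -> None:
    """Template move for tight clusters: remove all members, align the
    consensus sequence to the sampled HMM, and give every member the
    consensus path."""
    if cluster.consensus is None:
        cluster.consensus = consensus_sequence(cluster, state)
    if state.w == 0 or len(cluster.members) >= state.K:
        return
    old_rows = state.m[cluster.members].copy()
    old_score = state.joint_score() if T == 0.0 else None
    for k in cluster.members:
        state.remove_seq(k)
    view = build_view(state.hmm(), rng, sample_emissions=True)
    row, _ = align_sequence_to_hmm(cluster.consensus.residues, view, rng, T)
    for k in cluster.members:
        state.insert_seq(k, row)
    if old_score is not None and state.joint_score() < old_score - 1e-9:
        for i, k in enumerate(cluster.members):
            state.remove_seq(k)
            state.insert_seq(k, old_rows[i])


def resample_group_tandem(
    state: MsaState,
    members: list[int],
    rng: np.random.Generator,
    T: float,
) -> None:
    """Remove a whole group from the counts, then realign its sequences one
    at a time (each realignment sees the previous reinsertions)."""
    if len(members) >= state.K:
        raise ValueError("cannot remove every sequence from the model")
    if state.w == 0 or not members:
        return
    old_rows = state.m[members].copy()
    old_score = state.joint_score() if T == 0.0 else None
    for k in members:
        state.remove_seq(k)
    for k in members:
        view = build_view(state.hmm(), rng, sample_emissions=True)
        row, _ = align_sequence_to_hmm(state.seqs[k].residues, view, rng, T)
        state.insert_seq(k, row)
    if old_score is not None and state.joint_score() < old_score - 1e-9:
        for i, k in enumerate(members):
            state.remove_seq(k)
            state.insert_seq(k, old_rows[i])


def group_by_shared_features(
    state: MsaState,
    length_tolerance: float = 0.20,
    minority_freq: float = 0.25,
) -> list[list[int]]:
    """Candidate correlated groups: shared similar-length insertions at a
    position, shared deletion runs, or a shared minority residue in a
    supported (positive-BILD) column.  Groups have >= 2 members."""
    groups: list[list[int]] = []
    seen: set[frozenset[int]] = set()

    def add(members: list[int]) -> None:
        key = frozenset(members)
        if len(members) >= 2 and key not in seen:
            seen.add(key)
            groups.append(sorted(members))

    m = state.m
    # (a) congruent insertions (length within +-tolerance of the smallest)
    for j in range(state.w - 1):
        left, right = m[:, j], m[:, j + 1]
        ins_len = np.where((left >= 0) & (right >= 0), right - left - 1, 0)
        carriers = np.flatnonzero(ins_len > 0)
        if len(carriers) < 2:
            continue
        order = carriers[np.argsort(ins_len[carriers], kind="stable")]
        group: list[int] = []
        base = 0
        for k in order:
            if not group:
                group, base = [int(k)], int(ins_len[k])
            elif ins_len[k] <= base * (1 + length_tolerance):
                group.append(int(k))
            else:
                add(group)
                group, base = [int(k)], int(ins_len[k])
        add(group)
    # (b) congruent deletion runs
    runs: dict[tuple[int, int], list[int]] = {}
    for k in range(state.K):
        row = m[k]
        j = 0
        while j < state.w:
            if row[j] < 0:
                start = j
                while j < state.w and row[j] < 0:
                    j += 1
                runs.setdefault((start, j), []).append(k)
            else:
                j += 1
    for members in runs.values():
        add(members)
    # (c) shared minority residue in a supported column
    colmat = state.column_matrix()
    for j in range(state.w):
        if bild_score(state.col_counts[j], state.dm, state.bg) <= 0:
            continue
        tot = state.col_counts[j].sum()
        if tot <= 0:
            continue
        freqs = state.col_counts[j] / tot
        for a in np.flatnonzero((freqs > 0) & (freqs < minority_freq)):
            add(list(np.flatnonzero(colmat[:, j] == a)))
    return groups


def purged_set_realign(
    state: MsaState,
    rng: np.random.Generator,
    T: float,
    tight_threshold: float = 0.95,
    loose_threshold: float = 0.40,
) -> None:
    """Realign using a purged set: keep one representative per cluster (the
    member closest to the cluster's match-column consensus), realign the
    representatives by sampling, then resample the excluded sequences back."""
    clusters = cluster_sequences(state, tight_threshold, loose_threshold)
    if len(clusters) < 2 or state.w == 0:
        return
    colmat = state.column_matrix()
    wts = state.weights / 100.0
    reps: list[int] = []
    excluded: list[int] = []
    for cl in clusters:
        if len(cl.members) == 1:
            reps.append(cl.members[0])
            continue
        sub = colmat[cl.members]
        votes = np.zeros((state.w, NRES))
        for i, k in enumerate(cl.members):
            std = (sub[i] >= 0) & (sub[i] < NRES)
            votes[np.arange(state.w)[std], sub[i][std]] += wts[k]
        cons = np.argmax(votes, axis=1)
        has_any = votes.sum(axis=1) > 0
        mism = [
            int(np.sum((sub[i] >= 0) & has_any & (sub[i] != cons)))
            for i in range(len(cl.members))
        ]
        reps.append(cl.members[int(np.argmin(mism))])  # tie -> lowest index
        excluded.extend(k for k in cl.members if k != reps[-1])

    old_score = state.joint_score() if T == 0.0 else None
    old_rows = state.m.copy()
    for k in excluded:
        state.remove_seq(k)
    for k in reps:
        resample_sequence_in_place(state, k, rng, T)
    for k in excluded:
        view = build_view(state.hmm(), rng, sample_emissions=True)
        row, _ = align_sequence_to_hmm(state.seqs[k].residues, view, rng, T)
        state.insert_seq(k, row)
    if old_score is not None and state.joint_score() < old_score - 1e-9:
        state.restore_snapshot(old_rows)


def resample_sequence_in_place(
    state: MsaState, k: int, rng: np.random.Generator, T: float
) -> None:
    """Single-sequence Gibbs step without the K>=3 guard (used while part
    of the population is purged out of the counts)."""
    state.remove_seq(k)
    view = build_view(state.hmm(), rng, sample_emissions=True)
    row, _ = align_sequence_to_hmm(state.seqs[k].residues, view, rng, T)
    state.insert_seq(k, row)


def resample_worst_scoring(
    state: MsaState,
    fraction: float,
    rng: np.random.Generator,
    T: float,
) -> None:
    """Tandem-resample the poorest-scoring fraction of sequences."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    if state.w == 0:
        return
    view = build_view(state.hmm())
    scores = np.array([sequence_score(state, k, view) for k in range(state.K)])
    n = max(1, int(np.ceil(fraction * state.K)))
    n = min(n, state.K - 1)
    worst = list(np.argsort(scores, kind="stable")[:n])  # ties -> lowest index
    resample_group_tandem(state, [int(k) for k in worst], rng, T)


def resample_random_subsets(
    state: MsaState,
    subset_size: int,
    rounds: int,
    rng: np.random.Generator,
    T: float,
) -> None:
    """``rounds`` tandem resamplings of uniformly drawn subsets."""
    if subset_size >= state.K:
        raise ValueError("subset_size must be < K")
    for _ in range(rounds):
        members = sorted(rng.choice(state.K, size=subset_size, replace=False))
        resample_group_tandem(state, [int(k) for k in members], rng, T)


# ---------------------------------------------------------------------------
# Alignment similarity (for competitive selection)


def aligned_pairs(m: np.ndarray) -> set[tuple[int, int, int, int]]:
    """All residue pairs co-aligned in a match column of ``m``."""
    K, w = m.shape
    out: set[tuple[int, int, int, int]] = set()
    for j in range(w):
        ks = np.flatnonzero(m[:, j] >= 0)
        for x in range(len(ks)):
            for y in range(x + 1, len(ks)):
                a, b = int(ks[x]), int(ks[y])
                out.add((a, int(m[a, j]), b, int(m[b, j])))
    return out


def alignment_similarity(ma: np.ndarray, mb: np.ndarray) -> float:
    """Symmetric SP agreement of two alignments of the same sequences:
    average of the fraction of a's aligned pairs found in b and vice versa."""
    if ma.shape[0] != mb.shape[0]:
        raise ValueError("alignments cover different sequence sets")
    pa, pb = aligned_pairs(ma), aligned_pairs(mb)
    if not pa and not pb:
        return 1.0
    if not pa or not pb:
        return 0.0
    inter = len(pa & pb)
    return 0.5 * (inter / len(pa) + inter / len(pb))


# ---------------------------------------------------------------------------
# Strategy scheduling + competitive selection


class StrategyScheduler:
    """Round-robin over the five escape strategies, one per invocation."""

    def __init__(self, cfg: SamplerConfig):
        self.cfg = cfg
        self.i = 0

    def __call__(self, state: MsaState, rng: np.random.Generator, T: float) -> None:
        if state.w == 0 or state.K < 3:
            return
        cfg = self.cfg
        which = self.i % 5
        self.i += 1
        if which == 0:
            for cl in cluster_sequences(state, cfg.tight_threshold, cfg.loose_threshold):
                if cl.kind == "tight" and 2 <= len(cl.members) < state.K:
                    resample_cluster_via_consensus(state, cl, rng, T)
        elif which == 1:
            for members in group_by_shared_features(state):
                if len(members) < state.K:
                    resample_group_tandem(state, members, rng, T)
        elif which == 2:
            purged_set_realign(state, rng, T, cfg.tight_threshold, cfg.loose_threshold)
        elif which == 3:
            resample_worst_scoring(state, cfg.worst_fraction, rng, T)
        else:
            size = max(1, int(np.ceil(state.K / 10)))
            resample_random_subsets(state, min(size, state.K - 1), cfg.subset_rounds, rng, T)


def _subset(seqs: SequenceSet, idx: list[int]) -> SequenceSet:
    return SequenceSet([seqs[i] for i in idx])


def competitive_selection(
    seqs: SequenceSet,
    cfg: SamplerConfig,
    dm1: DirichletMixture,
    dm2: DirichletMixture,
    bg: Background,
    rng: np.random.Generator,
) -> tuple[GappedMSA, MsaState]:
    """Race a population of trajectories and refine the most agreeable one.

    (i) rough block alignment -> clusters -> one representative each;
    (ii) independent block alignments of the representatives (population
    size per config); (iii) brief gapped refinement of each; (iv) score by
    mean pairwise similarity; (v) deeper refinement of the survivors, best
    kept by the same criterion; (vi) remaining sequences sampled back in
    and the full alignment refined.
    """
    # (i) rough clustering pass
    rough_cfg = Phase1Config(
        min_width=cfg.phase1.min_width, max_width=cfg.phase1.max_width,
        patience=1, max_cycles=5, greedy_cycles=0,
    )
    rough, ws, _ = run_phase1(seqs, rough_cfg, dm1, bg, rng)
    rough_state = state_from_blocks(seqs, rough, cfg.tpriors, dm1, bg, ws)
    clusters = cluster_sequences(rough_state, cfg.tight_threshold, cfg.loose_threshold)
    reps = [cl.members[0] for cl in clusters]

    if len(reps) < 3 or cfg.population == 1:
        logger.info(
            "competition skipped (%d representatives); single trajectory", len(reps)
        )
        aln, ws1, _ = run_phase1(seqs, cfg.phase1, dm1, bg, rng)
        sched = StrategyScheduler(cfg)
        msa, state, _ = run_phase2(
            seqs, aln, cfg.phase2, cfg.tpriors, dm2, bg, rng,
            wstate=ws1, strategy_fn=sched,
        )
        return msa, state

    rep_set = _subset(seqs, reps)
    brief = Phase2Config(
        schedule=AnnealSchedule(sweeps_per_t=1, patience=3, max_t0_sweeps=6),
        early_slack=cfg.phase2.early_slack,
    )

    # (ii)+(iii) population of briefly refined candidates
    candidates: list[MsaState] = []
    for _ in range(cfg.population):
        aln, wsr, _ = run_phase1(rep_set, cfg.phase1, dm1, bg, rng)
        st = state_from_blocks(rep_set, aln, cfg.tpriors, dm2, bg, wsr)
        anneal(st, brief, rng)
        candidates.append(st)

    # (iv) similarity ranking
    def mean_sim(i: int, pool: list[MsaState]) -> float:
        return float(
            np.mean([
                alignment_similarity(pool[i].m, pool[j].m)
                for j in range(len(pool)) if j != i
            ])
        )

    sims = [mean_sim(i, candidates) for i in range(len(candidates))]
    order = np.argsort(sims, kind="stable")[::-1]
    survivors = [candidates[int(i)] for i in order[: cfg.survivors]]

    # (v) deeper refinement of the survivors
    deeper = Phase2Config(
        schedule=AnnealSchedule(t_start=0.5, sweeps_per_t=1, patience=4, max_t0_sweeps=8),
        early_slack=cfg.phase2.early_slack,
    )
    sched = StrategyScheduler(cfg)
    for st in survivors:
        anneal(st, deeper, rng, strategy_fn=sched)
    sims2 = [mean_sim(i, survivors) for i in range(len(survivors))]
    winner = survivors[int(np.argmax(sims2))]

    # (vi) sample back the remaining sequences and refine the full alignment
    full_m = np.full((len(seqs), winner.w), -1, dtype=np.int64)
    for i, k in enumerate(reps):
        full_m[k] = winner.m[i]
    full_ws = WeightState(
        raw=np.ones(len(seqs)), integer=np.full(len(seqs), 100, dtype=np.int64)
    )
    state = MsaState(seqs, full_m, cfg.tpriors, dm2, bg, full_ws)
    others = [k for k in range(len(seqs)) if k not in set(reps)]
    for k in others:
        resample_sequence_in_place(state, k, rng, T=0.2)
    state.update_weights()
    final = Phase2Config(
        schedule=AnnealSchedule(t_start=0.5, sweeps_per_t=cfg.phase2.schedule.sweeps_per_t,
                                patience=cfg.phase2.schedule.patience,
                                max_t0_sweeps=cfg.phase2.schedule.max_t0_sweeps),
        early_slack=cfg.phase2.early_slack,
        strategy_every=cfg.phase2.strategy_every,
    )
    anneal(state, final, rng, strategy_fn=StrategyScheduler(cfg))
    return state.to_msa(), state
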