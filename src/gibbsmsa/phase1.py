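"""Phase 1: top-down sampling of an ungapped co-linear block alignment.

Random short blocks are placed co-linearly in every sequence, then
sequences, block-edge columns and whole blocks are Gibbs-sampled in and out
of the alignment until the integrated LLR stops improving.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import (
    BlockAlignment,
    column_log_odds,
    integrated_block_llr,
    placement_site_scores,
    sample_block_placement,
    weighted_column_counts,
)
from .priors import Background, DirichletMixture, bild_score
from .seqio import SequenceSet
from .weights import WeightState, update_weights

logger = logging.getLogger(__name__)


@dataclass
class Phase1Config:
    min_width: int = 5
    max_width: int = 15
    patience: int = 3  # sweeps without a new best LLR before stopping
    max_cycles: int = 60
    greedy_cycles: int = 5  # T=0 polish budget after the T=1 plateau

    def __post_init__(self) -> None:
        if not (1 <= self.min_width <= self.max_width):
            raise ValueError("need 1 <= min_width <= max_width")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def _uniform_colinear_starts(
    n: int, widths: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniform draw over all feasible co-linear placements (stars & bars)."""
    B = len(widths)
    slack = n - int(widths.sum())
    if slack < 0:
        raise ValueError("no feasible placement")
    u = np.sort(rng.choice(slack + B, size=B, replace=False))
    cum = np.concatenate([[0], np.cumsum(widths)[:-1]])
    return u - np.arange(B) + cum


def init_random_blocks(
    seqs: SequenceSet,
    cfg: Phase1Config,
    rng: np.random.Generator,
    n_blocks: int | None = None,
) -> BlockAlignment:
    """Draw block count and widths from the prior, truncate to fit the
    shortest sequence, and place blocks uniformly & independently."""
    lengths = seqs.lengths
    lmin = int(lengths.min())
    if lmin < cfg.min_width:
        raise ValueError(
            f"shortest sequence (length {lmin}) is below the minimum block "
            f"width {cfg.min_width}"
        )
    bmax = max(1, lmin // cfg.max_width)
    if n_blocks is None:
        n_blocks = int(rng.integers(1, bmax + 1))
    widths: list[int] = []
    total = 0
    for _ in range(n_blocks):
        wb = int(rng.integers(cfg.min_width, cfg.max_width + 1))
        if total + wb > lmin:
            break
        widths.append(wb)
        total += wb
    if not widths:
        widths = [min(cfg.max_width, lmin)]
    warr = np.array(widths, dtype=np.int64)
    starts = np.empty((len(seqs), len(warr)), dtype=np.int64)
    for k, n in enumerate(lengths):
        try:
            starts[k] = _uniform_colinear_starts(int(n), warr, rng)
        except ValueError as exc:
            raise ValueError(f"sequence {seqs[k].id!r}: {exc}") from exc
    aln = BlockAlignment(widths=warr, starts=starts)
    aln.validate(lengths)
    return aln


def _counts_without(
    seqs: SequenceSet, aln: BlockAlignment, weights: np.ndarray, k: int
) -> np.ndarray:
    cols = aln.column_matrix(seqs)
    mask = np.ones(len(seqs), dtype=bool)
    mask[k] = False
    return weighted_column_counts(cols[mask], weights[mask])


def resample_sequence_blocks(
    seqs: SequenceSet,
    aln: BlockAlignment,
    k: int,
    dm: DirichletMixture,
    bg: Background,
    weights: np.ndarray,
    rng: np.random.Generator,
    T: float = 1.0,
) -> BlockAlignment:
    """Remove sequence k, rebuild the predictive model from the rest, and
    sample new co-linear block locations for k (argmax at T=0)."""
    if len(seqs) < 3:
        raise ValueError("need K >= 3 to resample against an informative model")
    counts = _counts_without(seqs, aln, weights, k)
    lo = column_log_odds(counts, dm, bg)
    S = placement_site_scores(seqs[k].residues, lo)
    new_starts, _ = sample_block_placement(S, aln.widths, rng, T)
    starts = aln.starts.copy()
    starts[k] = new_starts
    out = BlockAlignment(widths=aln.widths.copy(), starts=starts)
    out.validate(seqs.lengths)
    return out


def _accept(delta: float, rng: np.random.Generator, T: float) -> bool:
    """Two-state Gibbs acceptance with probability sigma(delta/T)."""
    if T == 0.0:
        return delta > 0.0
    x = delta / T
    p = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
    return bool(rng.random() < p)


def sample_edge_column(
    seqs: SequenceSet,
    aln: BlockAlignment,
    block: int,
    side: str,
    dm: DirichletMixture,
    bg: Background,
    weights: np.ndarray,
    rng: np.random.Generator,
    T: float = 1.0,
    action: str | None = None,
) -> BlockAlignment:
    """Sample one edge column of a block in or out of the alignment.

    ``action`` forces 'grow' or 'shrink'; by default a feasible action is
    chosen at random.  Acceptance is two-state Gibbs on the BILD change.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    lengths = seqs.lengths
    starts = aln.starts
    wb = int(aln.widths[block])

    if side == "left":
        lo_bound = (
            starts[:, block - 1] + aln.widths[block - 1]
            if block > 0
            else np.zeros(aln.K, dtype=np.int64)
        )
        can_grow = bool(np.all(starts[:, block] - 1 >= lo_bound))
        grow_pos = starts[:, block] - 1
        shrink_pos = starts[:, block]
    else:
        hi_bound = (
            starts[:, block + 1]
            if block + 1 < aln.n_blocks
            else lengths
        )
        can_grow = bool(np.all(starts[:, block] + wb + 1 <= hi_bound))
        grow_pos = starts[:, block] + wb
        shrink_pos = starts[:, block] + wb - 1
    can_shrink = wb > 1

    if action is None:
        feasible = [a for a, ok in (("grow", can_grow), ("shrink", can_shrink)) if ok]
        if not feasible:
            return aln
        action = feasible[int(rng.integers(len(feasible)))]
    elif action == "grow" and not can_grow:
        return aln
    elif action == "shrink" and not can_shrink:
        return aln

    pos = grow_pos if action == "grow" else shrink_pos
    col = np.array([seqs[k].residues[pos[k]] for k in range(aln.K)])
    cts = weighted_column_counts(col[:, None], weights)[0]
    delta = bild_score(cts, dm, bg)
    if action == "shrink":
        delta = -delta
    if not _accept(delta, rng, T):
        return aln

    widths = aln.widths.copy()
    new_starts = starts.copy()
    if action == "grow":
        widths[block] += 1
        if side == "left":
            new_starts[:, block] -= 1
    else:
        widths[block] -= 1
        if side == "left":
            new_starts[:, block] += 1
    out = BlockAlignment(widths=widths, starts=new_starts)
    out.validate(lengths)
    return out


def sample_block_in_out(
    seqs: SequenceSet,
    aln: BlockAlignment,
    cfg: Phase1Config,
    dm: DirichletMixture,
    bg: Background,
    weights: np.ndarray,
    rng: np.random.Generator,
    T: float = 1.0,
    action: str | None = None,
    slot: int | None = None,
) -> BlockAlignment:
    """Sample a whole block out of, or a new minimal-width block into, the
    alignment (two-state Gibbs on the BILD change)."""
    lengths = seqs.lengths
    if action is None:
        action = "remove" if rng.random() < 0.5 else "insert"

    if action == "remove":
        if aln.n_blocks < 2:
            return aln
        b = int(rng.integers(aln.n_blocks))
        cols = aln.column_matrix(seqs)
        cum = np.concatenate([[0], np.cumsum(aln.widths)])
        cts = weighted_column_counts(cols[:, cum[b] : cum[b + 1]], weights)
        delta = -sum(bild_score(c, dm, bg) for c in cts)
        if not _accept(delta, rng, T):
            return aln
        widths = np.delete(aln.widths, b)
        starts = np.delete(aln.starts, b, axis=1)
        out = BlockAlignment(widths=widths, starts=starts)
        out.validate(lengths)
        return out

    # insert a new minimal-width block into an inter-block slot
    wb = cfg.min_width
    if slot is None:
        slot = int(rng.integers(aln.n_blocks + 1))
    lo = (
        aln.starts[:, slot - 1] + aln.widths[slot - 1]
        if slot > 0
        else np.zeros(aln.K, dtype=np.int64)
    )
    hi = aln.starts[:, slot] if slot < aln.n_blocks else lengths
    room = hi - lo - wb
    if np.any(room < 0):
        return aln  # no feasible co-linear slot in some sequence
    pos = np.array([lo[k] + rng.integers(room[k] + 1) for k in range(aln.K)])
    col = np.stack([seqs[k].residues[pos[k] : pos[k] + wb] for k in range(aln.K)])
    cts = weighted_column_counts(col, weights)
    delta = sum(bild_score(c, dm, bg) for c in cts)
    if not _accept(delta, rng, T):
        return aln
    widths = np.insert(aln.widths, slot, wb)
    starts = np.insert(aln.starts, slot, pos, axis=1)
    out = BlockAlignment(widths=widths, starts=starts)
    out.validate(lengths)
    return out


def run_phase1(
    seqs: SequenceSet,
    cfg: Phase1Config,
    dm: DirichletMixture,
    bg: Background,
    rng: np.random.Generator,
    weight_state: WeightState | None = None,
) -> tuple[BlockAlignment, WeightState, list[float]]:
    """Full phase-1 loop; returns the best-scoring block alignment seen, the
    final weight state, and the best-LLR trace (non-decreasing)."""
    aln = init_random_blocks(seqs, cfg, rng)
    if weight_state is None:
        weight_state = WeightState.compute(aln.column_matrix(seqs))
    best = aln
    best_llr = integrated_block_llr(seqs, aln, dm, bg, weight_state.integer)
    trace = [best_llr]

    def cycle(aln: BlockAlignment, ws: WeightState, T: float):
        order = rng.permutation(len(seqs))
        for k in order:
            aln = resample_sequence_blocks(seqs, aln, int(k), dm, bg, ws.integer, rng, T)
        for b in range(aln.n_blocks):
            for side in ("left", "right"):
                # run growth to rejection so conserved flanks are swallowed
                # quickly, then offer one shrink
                for _ in range(16):
                    grown = sample_edge_column(
                        seqs, aln, b, side, dm, bg, ws.integer, rng, T, action="grow"
                    )
                    if grown is aln:
                        break
                    aln = grown
                aln = sample_edge_column(
                    seqs, aln, b, side, dm, bg, ws.integer, rng, T, action="shrink"
                )
        for slot in range(aln.n_blocks, -1, -1):
            aln = sample_block_in_out(
                seqs, aln, cfg, dm, bg, ws.integer, rng, T, action="insert", slot=slot
            )
        aln = sample_block_in_out(seqs, aln, cfg, dm, bg, ws.integer, rng, T, action="remove")
        ws = update_weights(ws, aln.column_matrix(seqs))
        return aln, ws

    for T, budget in ((1.0, cfg.max_cycles), (0.0, cfg.greedy_cycles)):
        stall = 0
        for _ in range(budget):
            aln, weight_state = cycle(aln, weight_state, T)
            llr = integrated_block_llr(seqs, aln, dm, bg, weight_state.integer)
            if llr > best_llr + 1e-9:
                best, best_llr, stall = aln, llr, 0
            else:
                stall += 1
            trace.append(best_llr)
            if stall >= cfg.patience:
                break
    logger.info("phase1 done: w=%d blocks=%d LLR=%.2f", best.w, best.n_blocks, best_llr)
    return best, weight_state, trace
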