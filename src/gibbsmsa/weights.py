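"""Henikoff position-based sequence redundancy weights.

Raw weights are wt(k) = sum_j 1/(Nt_j * Nr_{k,j}) over match columns where
sequence k has a (standard) residue; they are integerized to
Wt(k) = ceil(100 * wt(k) / wt_max), so weights lie in 1..100 with the
least-redundant sequence at 100.  Weighted counts downstream scale residues
by Wt(k)/100.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .seqio import NRES


def henikoff_weights(columns: np.ndarray) -> np.ndarray:
    """Raw Henikoff weights from a (K, w) residue-code matrix.

    Entries outside 0..19 (deletions coded -1, UNKNOWN) are skipped for the
    carrying sequence.  Raises on w = 0 (weights undefined).
    """
    columns = np.asarray(columns)
    if columns.ndim != 2 or columns.shape[1] == 0:
        raise ValueError("henikoff weights undefined for an empty alignment")
    K, w = columns.shape
    wt = np.zeros(K)
    for j in range(w):
        col = columns[:, j]
        valid = (col >= 0) & (col < NRES)
        if not np.any(valid):
            continue
        counts = np.bincount(col[valid], minlength=NRES)
        ntypes = int(np.sum(counts > 0))
        nr = counts[col[valid]]
        wt[valid] += 1.0 / (ntypes * nr)
    return wt


def integerize_weights(raw: np.ndarray) -> np.ndarray:
    """Wt(k) = ceil(100 * wt(k)/wt_max), clamped into 1..100."""
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("raw weights must be nonnegative")
    mx = raw.max()
    if mx <= 0:
        raise ValueError("all raw weights are zero")
    w = np.ceil(100.0 * raw / mx).astype(np.int64)
    return np.clip(w, 1, 100)


@dataclass(frozen=True)
class WeightState:
    raw: np.ndarray
    integer: np.ndarray  # 1..100
    frozen: bool = False

    @classmethod
    def compute(cls, columns: np.ndarray, frozen: bool = False) -> "WeightState":
        raw = henikoff_weights(columns)
        return cls(raw=raw, integer=integerize_weights(raw), frozen=frozen)

    def freeze(self) -> "WeightState":
        return replace(self, frozen=True)


def update_weights(state: WeightState, columns: np.ndarray) -> WeightState:
    """Recompute weights from the current alignment unless frozen."""
    if state.frozen:
        return state
    return WeightState.compute(columns)
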