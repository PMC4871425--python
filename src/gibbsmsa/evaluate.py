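"""SP-score benchmark evaluation, column relative entropy, and the planted
conserved-domain generator used for testing the sampler end to end.

The SP-score here measures *accuracy against a benchmark*: the proportion
of residue pairs aligned in the benchmark MSA that are similarly aligned
(same match column) in a test MSA.  Benchmark-unaligned residues are
ignored entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .priors import Background
from .seqio import ALPHABET, NRES, GappedMSA, SequenceRecord, SequenceSet, decode


@dataclass(frozen=True)
class SPResult:
    score: float
    counted: int
    matched: int


def _column_map(msa: GappedMSA) -> dict[str, dict[int, int]]:
    """Per sequence id: residue index -> match column (match cells only)."""
    out: dict[str, dict[int, int]] = {}
    for i, sid in enumerate(msa.ids):
        cols = msa.match_columns(i)
        out[sid] = {pos: j for j, pos in enumerate(cols) if pos >= 0}
    return out


def sp_score(benchmark: GappedMSA, test: GappedMSA) -> SPResult:
    """Fraction of benchmark-aligned residue pairs recovered by the test MSA.

    Both MSAs must contain the same sequences (ids and degapped residues);
    a pair counts as recovered only when both residues occupy the same
    match column of the test MSA (insert-aligned residues never count).
    """
    if set(benchmark.ids) != set(test.ids):
        raise ValueError("benchmark and test MSAs contain different sequence ids")
    b_rows = {sid: benchmark.degapped(i) for i, sid in enumerate(benchmark.ids)}
    t_rows = {sid: test.degapped(i) for i, sid in enumerate(test.ids)}
    for sid in b_rows:
        if b_rows[sid] != t_rows[sid]:
            raise ValueError(f"sequence {sid!r} differs between benchmark and test")
    tmap = _column_map(test)
    counted = matched = 0
    for j in range(benchmark.n_match):
        carriers = []
        for i, sid in enumerate(benchmark.ids):
            pos = benchmark.match_columns(i)[j]
            if pos >= 0:
                carriers.append((sid, pos))
        for x in range(len(carriers)):
            for y in range(x + 1, len(carriers)):
                counted += 1
                (sa, pa), (sb, pb) = carriers[x], carriers[y]
                ca = tmap[sa].get(pa)
                if ca is not None and ca == tmap[sb].get(pb):
                    matched += 1
    if counted == 0:
        warnings.warn("benchmark MSA has no aligned pairs; SP-score set to 0")
        return SPResult(0.0, 0, 0)
    return SPResult(matched / counted, counted, matched)


def column_relative_entropy(counts: np.ndarray, bg: Background) -> float:
    """Relative entropy (nats) of a column's residue frequencies vs theta0."""
    counts = np.asarray(counts, dtype=float)
    tot = counts.sum()
    if tot <= 0:
        raise ValueError("relative entropy undefined for zero counts")
    f = counts / tot
    nz = f > 0
    return float(np.sum(f[nz] * (np.log(f[nz]) - np.log(bg.theta0[nz]))))


# ---------------------------------------------------------------------------
# Planted-domain generator


@dataclass
class PlantedSetSpec:
    """Recipe for a synthetic set of full-length sequences that share one
    co-linear multi-block domain amid random flanks."""

    n_sequences: int = 50
    block_widths: tuple[int, ...] = (12, 18, 10)
    conservation: float = 20.0  # Dirichlet concentration on the consensus residue
    insertion_prob: float = 0.3  # per hotspot per sequence
    insertion_mean: float = 8.0  # geometric mean length
    deletion_prob: float = 0.0  # per column per sequence
    flank_mean: float = 60.0  # geometric mean flank length
    duplication: int = 1  # tight-cluster copies per base sequence
    theta0: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_sequences < 2 or any(w < 1 for w in self.block_widths):
            raise ValueError("need K >= 2 and block widths >= 1")
        for p in (self.insertion_prob, self.deletion_prob):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0, 1]")


def cdd_like_spec(**overrides) -> PlantedSetSpec:
    """The default desk-scale preset emulating a conserved-domain set."""
    return PlantedSetSpec(**overrides)


def generate_planted_set(
    spec: PlantedSetSpec, rng: np.random.Generator
) -> tuple[SequenceSet, GappedMSA]:
    """Generate sequences with one planted domain; returns (set, truth MSA).

    Per column, a consensus residue is drawn from theta0 and the column's
    emission distribution is Dirichlet(conservation * e_consensus + theta0);
    insertions of geometric length appear between blocks at the configured
    rate; deletions drop match residues.  Deterministic under the rng.
    """
    theta0 = spec.theta0
    if theta0 is None:
        theta0 = np.ones(NRES) / NRES
    theta0 = np.asarray(theta0, dtype=float)
    w = sum(spec.block_widths)
    consensus = rng.choice(NRES, size=w, p=theta0)
    col_dists = np.empty((w, NRES))
    for j in range(w):
        if spec.conservation <= 0:
            col_dists[j] = theta0  # unconserved columns are pure background
        else:
            a = theta0.copy()
            a[consensus[j]] += spec.conservation
            col_dists[j] = rng.dirichlet(a)

    # hotspots: one between each pair of adjacent blocks
    hotspots = set(np.cumsum(spec.block_widths)[:-1] - 1)  # after column j (0-based)

    records: list[SequenceRecord] = []
    rows: list[str] = []
    ids: list[str] = []
    n_base = spec.n_sequences
    for b in range(n_base):
        nflank = rng.geometric(1.0 / max(spec.flank_mean, 1.0)) - 1
        cflank = rng.geometric(1.0 / max(spec.flank_mean, 1.0)) - 1
        flank_n = rng.choice(NRES, size=nflank, p=theta0)
        flank_c = rng.choice(NRES, size=cflank, p=theta0)
        cells: list[str] = []  # per match column: residue letter or '-'
        inserts: list[str] = [""] * w  # lowercase run after column j
        for j in range(w):
            if rng.random() < spec.deletion_prob:
                cells.append("-")
            else:
                r = int(rng.choice(NRES, p=col_dists[j]))
                cells.append(ALPHABET[r])
            if j in hotspots and rng.random() < spec.insertion_prob:
                ln = int(rng.geometric(1.0 / spec.insertion_mean))
                ins = rng.choice(NRES, size=ln, p=theta0)
                inserts[j] = decode(np.asarray(ins)).lower()
        # an insert run flanked by a deletion is an illegal truth path
        # (the I<->D arcs do not exist); drop the insert in that rare case
        for j in hotspots:
            if inserts[j] and (cells[j] == "-" or (j + 1 < w and cells[j + 1] == "-")):
                inserts[j] = ""
        core: list[int] = []
        for j in range(w):
            if cells[j] != "-":
                core.append(ALPHABET.index(cells[j]))
            for ch in inserts[j]:
                core.append(ALPHABET.index(ch.upper()))
        for d in range(spec.duplication):
            sid = f"seq{b:03d}" + (f".{d + 1}" if spec.duplication > 1 else "")
            residues = np.concatenate(
                [
                    np.asarray(flank_n, dtype=np.int8),
                    np.asarray(core, dtype=np.int8),
                    np.asarray(flank_c, dtype=np.int8),
                ]
            )
            records.append(SequenceRecord(sid, "planted", residues))
            ids.append(sid)
            row = decode(flank_n).lower()
            for j in range(w):
                row += cells[j]
                row += inserts[j]
            row += decode(flank_c).lower()
            rows.append(row)
    seqs = SequenceSet(records)
    truth = GappedMSA(ids=ids, rows=rows, n_match=w)
    for i in range(len(truth)):
        if truth.degapped(i) != decode(seqs[i].residues):
            raise AssertionError("generator truth MSA inconsistent with sequences")
    return seqs, truth


def random_background_set(
    K: int, length: int, rng: np.random.Generator, theta0: np.ndarray | None = None
) -> SequenceSet:
    """K i.i.d. background sequences (null instance with nothing planted)."""
    if theta0 is None:
        theta0 = np.ones(NRES) / NRES
    recs = [
        SequenceRecord(
            f"rand{k:03d}", "background",
            rng.choice(NRES, size=length, p=theta0).astype(np.int8),
        )
        for k in range(K)
    ]
    return SequenceSet(recs)
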