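"""Sequence and alignment I/O: FASTA input, A2M / Stockholm output.

Coordinate conventions used throughout the package: internal positions are
0-based half-open; anything logged or reported is 1-based inclusive.

Residues are encoded over the 20-letter amino-acid alphabet in alphabetical
one-letter order (``ACDEFGHIKLMNPQRSTVWY``); ``X`` and any other nonstandard
letter map to the distinguished :data:`UNKNOWN` code, which contributes
nothing to residue counts and scores at background probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical residue order; index in this string is the residue code.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NRES = 20
#: Code for 'X' and any nonstandard letter.
UNKNOWN = 20

_CODE = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i


class FastaParseError(ValueError):
    """Malformed FASTA input; message carries a 1-based line number."""


def encode(seq: str) -> np.ndarray:
    """Encode a residue string to int8 codes; nonstandard letters -> UNKNOWN."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[arr]
    codes = np.where(codes < 0, np.int8(UNKNOWN), codes).astype(np.int8)
    return codes


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; UNKNOWN renders as 'X'."""
    table = ALPHABET + "X"
    return "".join(table[c] for c in codes)


@dataclass(frozen=True)
class SequenceRecord:
    """One input protein: id, free-text description and encoded residues."""

    id: str
    description: str
    residues: np.ndarray  # int8 codes, values 0..19 or UNKNOWN

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} has length 0")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return decode(self.residues)


class SequenceSet:
    """Ordered collection of :class:`SequenceRecord` with optional weights.

    Provides the residue counting function ``h(.)``: a length-20 vector of
    (optionally weighted) counts in which UNKNOWN residues contribute zero.
    """

    def __init__(self, records: Sequence[SequenceRecord]):
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in SequenceSet")
        self.records = list(records)
        self.weights = np.full(len(records), 100, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, k: int) -> SequenceRecord:
        return self.records[k]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(r) for r in self.records], dtype=np.int64)

    def counts(self, residues: Iterable[int]) -> np.ndarray:
        """h(.): length-20 count vector over a residue-code iterable."""
        h = np.zeros(NRES)
        for c in residues:
            if 0 <= c < NRES:
                h[c] += 1.0
        return h


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Duplicate ids are de-duplicated by suffixing ``.2``, ``.3``, ... and
    logged; nonstandard letters are mapped to UNKNOWN and their total count
    logged.  Zero-length records and non-FASTA content raise
    :class:`FastaParseError` naming the offending line.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    cur_id: str | None = None
    cur_desc = ""
    cur_parts: list[str] = []
    cur_line = 0
    n_unknown = 0

    def flush() -> None:
        nonlocal n_unknown
        if cur_id is None:
            return
        seq = "".join(cur_parts)
        if not seq:
            raise FastaParseError(
                f"{path}: zero-length record {cur_id!r} at line {cur_line}"
            )
        the_id = cur_id
        if the_id in seen:
            seen[the_id] += 1
            new_id = f"{the_id}.{seen[the_id]}"
            logger.warning("duplicate id %r renamed to %r", the_id, new_id)
            the_id = new_id
        else:
            seen[the_id] = 1
        codes = encode(seq)
        n_unknown += int(np.sum(codes == UNKNOWN))
        records.append(SequenceRecord(the_id, cur_desc, codes))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split(None, 1)
                if not header:
                    raise FastaParseError(f"{path}: empty header at line {lineno}")
                cur_id = header[0]
                cur_desc = header[1] if len(header) > 1 else ""
                cur_parts = []
                cur_line = lineno
            else:
                if cur_id is None:
                    raise FastaParseError(
                        f"{path}: non-FASTA content at line {lineno}"
                    )
                if not all(c.isalpha() or c == "*" for c in line):
                    raise FastaParseError(
                        f"{path}: illegal sequence characters at line {lineno}"
                    )
                cur_parts.append(line.replace("*", ""))
    flush()
    if not records:
        raise FastaParseError(f"{path}: empty file (no records) at line 1")
    if n_unknown:
        logger.info("%d nonstandard residues mapped to 'X'", n_unknown)
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in seqs:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n{decode(rec.residues)}\n")


# ---------------------------------------------------------------------------
# Gapped alignments


@dataclass
class GappedMSA:
    """A2M-convention alignment: uppercase = match, lowercase = insert/flank,
    '-' = deletion.  Every row has exactly ``n_match`` match cells (uppercase
    residue or '-')."""

    ids: list[str]
    rows: list[str]
    n_match: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.n_match < 0:
            self.n_match = _count_match(self.rows[0]) if self.rows else 0
        self.validate()

    def validate(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in GappedMSA")
        for i, row in enumerate(self.rows):
            nm = _count_match(row)
            if nm != self.n_match:
                raise ValueError(
                    f"row {self.ids[i]!r} has {nm} match cells, expected "
                    f"{self.n_match}"
                )
            for ch in row:
                if not (ch.isalpha() or ch in "-."):
                    raise ValueError(
                        f"illegal character {ch!r} in row {self.ids[i]!r}"
                    )

    def __len__(self) -> int:
        return len(self.rows)

    def degapped(self, i: int) -> str:
        return degap(self.rows[i])

    def match_columns(self, i: int) -> list[int]:
        """Residue positions (0-based, into the degapped sequence) occupying
        each match column of row ``i``; -1 where the row has a deletion."""
        out: list[int] = []
        pos = 0
        for ch in self.rows[i]:
            if ch == "-":
                out.append(-1)
            elif ch == ".":
                continue
            elif ch.isupper():
                out.append(pos)
                pos += 1
            else:
                pos += 1
        return out


def _count_match(row: str) -> int:
    return sum(1 for ch in row if ch.isupper() or ch == "-")


def degap(row: str) -> str:
    """Drop '-'/'.' cells, uppercase and concatenate the residues of a row."""
    out = []
    for ch in row:
        if ch in "-.":
            continue
        if not ch.isalpha():
            raise ValueError(f"illegal character {ch!r} in alignment row")
        out.append(ch.upper())
    return "".join(out)


def write_msa(msa: GappedMSA, fmt: str, path: str | Path) -> None:
    """Write a GappedMSA as A2M aligned-FASTA or Stockholm 1.0.

    Stockholm output pads insert regions with '.' so rows line up and marks
    match columns on a ``#=GC RF`` line ('x' = match, '.' = insert).
    """
    fmt = fmt.lower()
    if fmt == "a2m":
        with open(path, "w") as fh:
            for sid, row in zip(msa.ids, msa.rows):
                fh.write(f">{sid}\n{row.replace('.', '')}\n")
    elif fmt == "stockholm":
        padded, rf = _pad_rows(msa)
        width = max(max(len(s) for s in msa.ids) + 2, len("#=GC RF") + 2)
        with open(path, "w") as fh:
            fh.write("# STOCKHOLM 1.0\n")
            for sid, row in zip(msa.ids, padded):
                fh.write(f"{sid:<{width}}{row}\n")
            fh.write(f"{'#=GC RF':<{width}}{rf}\n")
            fh.write("//\n")
    else:
        raise ValueError(f"unknown MSA format {fmt!r} (expected a2m/stockholm)")


def _pad_rows(msa: GappedMSA) -> tuple[list[str], str]:
    """Pad lowercase insert runs with '.' to a common width per region."""
    # split each row into n_match+1 insert regions around the match cells
    regions: list[list[str]] = []
    matches: list[list[str]] = []
    for row in msa.rows:
        ins: list[str] = [""]
        mat: list[str] = []
        for ch in row:
            if ch == ".":
                continue
            if ch.isupper() or ch == "-":
                mat.append(ch)
                ins.append("")
            else:
                ins[-1] += ch
        regions.append(ins)
        matches.append(mat)
    widths = [max(len(r[i]) for r in regions) for i in range(msa.n_match + 1)]
    padded = []
    for ins, mat in zip(regions, matches):
        parts = []
        for i in range(msa.n_match + 1):
            parts.append(ins[i].ljust(widths[i], "."))
            if i < msa.n_match:
                parts.append(mat[i])
        padded.append("".join(parts))
    rf = "".join(
        "." * widths[i] + ("x" if i < msa.n_match else "")
        for i in range(msa.n_match + 1)
    )
    return padded, rf


def read_a2m(path: str | Path) -> GappedMSA:
    """Read an A2M aligned-FASTA file (also accepts '.'-padded variants)."""
    ids: list[str] = []
    rows: list[str] = []
    cur: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                ids.append(line[1:].split(None, 1)[0])
                cur = []
                rows.append("")
            else:
                if cur is None:
                    raise FastaParseError(
                        f"{path}: non-FASTA content at line {lineno}"
                    )
                rows[-1] += line
    if not ids:
        raise FastaParseError(f"{path}: empty alignment at line 1")
    return GappedMSA(ids=ids, rows=[r.replace(".", "") for r in rows])
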