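"""Readers and writers for the sequence and structure formats the pipeline touches.

Pre-miRNA sequences arrive as FASTA, secondary structures as Vienna
dot-bracket strings (RNAfold output dialect) or mfold/quickfold CT files,
and cleavage-site annotations as a small TSV. Everything is normalised at
the boundary into :class:`PreMiRNA` / :class:`PairTable` /
:class:`CleavageAnnotation` records using 0-based internal coordinates;
CT files and annotation positions are 1-based on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: sentinel partner index for an unpaired position
UNPAIRED = -1

RNA_ALPHABET = frozenset("ACGU")

ARM_5P = "5p"
ARM_3P = "3p"
ARMS = (ARM_5P, ARM_3P)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class PreMiRNA:
    """A pre-miRNA sequence over the RNA alphabet (T is folded into U on read)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-ACGU characters {sorted(bad)} in sequence"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PairTable:
    """Base-pairing partner map for one structure, 0-based.

    ``partner[i] == j`` means positions i and j are paired;
    ``partner[i] == UNPAIRED`` means position i is in a loop or bulge.
    """

    partner: tuple

    def __post_init__(self) -> None:
        n = len(self.partner)
        for i, j in enumerate(self.partner):
            if j == UNPAIRED:
                continue
            if not 0 <= j < n:
                raise FormatError(f"position {i}: partner {j} out of range 0..{n - 1}")
            if j == i:
                raise FormatError(f"position {i} pairs with itself")
            if self.partner[j] != i:
                raise FormatError(
                    f"asymmetric pairing: position {i} -> {j} but {j} -> {self.partner[j]}"
                )

    def __len__(self) -> int:
        return len(self.partner)

    def is_paired(self, i: int) -> bool:
        return self.partner[i] != UNPAIRED

    @classmethod
    def from_dotbracket(cls, structure: str) -> "PairTable":
        """Stack-match '(' with ')'; '.' marks unpaired positions."""
        partner = [UNPAIRED] * len(structure)
        stack: list[int] = []
        for i, c in enumerate(structure):
            if c == "(":
                stack.append(i)
            elif c == ")":
                if not stack:
                    raise FormatError(f"unbalanced ')' at position {i}")
                j = stack.pop()
                partner[i], partner[j] = j, i
            elif c != ".":
                raise FormatError(f"illegal structure character {c!r} at position {i}")
        if stack:
            raise FormatError(f"unbalanced '(' at position {stack[-1]}")
        return cls(tuple(partner))

    def to_dotbracket(self) -> str:
        """Render as dot-bracket; raises on crossing (pseudoknotted) pairs."""
        out = []
        expected_close: list[int] = []
        for i, j in enumerate(self.partner):
            if expected_close and expected_close[-1] == i:
                expected_close.pop()
                out.append(")")
            elif j == UNPAIRED:
                out.append(".")
            elif j > i:
                if expected_close and j > expected_close[-1]:
                    raise FormatError(
                        f"crossing pairs: ({i},{j}) crosses pair closing at {expected_close[-1]}"
                    )
                expected_close.append(j)
                out.append("(")
            else:
                # a closing partner that did not match the innermost open pair
                raise FormatError(f"crossing pairs at position {i} (partner {j})")
        return "".join(out)


@dataclass(frozen=True)
class CleavageAnnotation:
    """Arm and 1-based position of the nucleotide 5' of the scissile bond."""

    premirna_id: str
    arm: str
    cleavage_pos: int

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise FormatError(f"{self.premirna_id}: arm must be one of {ARMS}, got {self.arm!r}")
        if self.cleavage_pos < 1:
            raise FormatError(f"{self.premirna_id}: cleavage_pos must be >= 1")

    def window_fits(self, length: int) -> bool:
        """Whether the 14-nt cleavage window (7 nt each side of the bond) fits."""
        return 7 <= self.cleavage_pos and self.cleavage_pos + 7 <= length


def _normalise_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def read_fasta(path: Union[str, Path]) -> list[PreMiRNA]:
    """Read a (multi-)FASTA file; ids are kept verbatim up to first whitespace."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalise_rna(str(rec.seq))
        try:
            records.append(PreMiRNA(id=rec.id, sequence=seq))
        except FormatError as exc:
            raise FormatError(f"FASTA record {rec.id!r}: {exc}") from exc
    return records


def write_fasta(records: Iterable[PreMiRNA], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_dotbracket(path: Union[str, Path]) -> list[tuple[PreMiRNA, PairTable]]:
    """Read Vienna-style 3-line records: >id / sequence / structure.

    A trailing free energy on the structure line, e.g. ``(((...))) (-12.30)``,
    is tolerated and ignored.
    """
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    if len(lines) % 3 != 0:
        raise FormatError(f"{path}: expected 3-line records, got {len(lines)} lines")
    out = []
    for k in range(0, len(lines), 3):
        header, seq_line, struct_line = lines[k : k + 3]
        if not header.startswith(">"):
            raise FormatError(f"{path}: record {k // 3}: header must start with '>'")
        rid = header[1:].split()[0] if header[1:].split() else ""
        seq = _normalise_rna(seq_line.strip())
        structure = struct_line.split()[0]
        if len(structure) != len(seq):
            raise FormatError(
                f"{path}: record {rid!r}: structure length {len(structure)} "
                f"!= sequence length {len(seq)}"
            )
        try:
            table = PairTable.from_dotbracket(structure)
        except FormatError as exc:
            raise FormatError(f"{path}: record {rid!r}: {exc}") from exc
        out.append((PreMiRNA(id=rid, sequence=seq), table))
    return out


def write_dotbracket(
    records: Iterable[tuple[PreMiRNA, PairTable]], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        for rec, table in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n{table.to_dotbracket()}\n")


def read_ct(path: Union[str, Path]) -> list[tuple[PreMiRNA, PairTable]]:
    """Read a (possibly multi-structure) 6-column CT file, 1-based on disk.

    Columns: index, base, previous, next, pairing partner (0 = unpaired),
    original index. Structures appear back to back, each introduced by a
    header line whose first token is the structure length. Crossing
    (pseudoknotted) pairs are rejected.
    """
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    out = []
    pos = 0
    while pos < len(lines):
        header = lines[pos].split()
        try:
            n = int(header[0])
        except (ValueError, IndexError):
            raise FormatError(f"{path}: line {pos + 1}: expected CT header starting with length")
        title = header[1] if len(header) > 1 and header[1] not in ("dG", "ENERGY") else ""
        if not title:
            # common dialect: "<n> dG = -12.3 <name>" — take the last token
            title = header[-1] if len(header) > 1 else f"structure_{len(out) + 1}"
        rows = lines[pos + 1 : pos + 1 + n]
        if len(rows) < n:
            raise FormatError(f"{path}: structure {title!r}: expected {n} rows, got {len(rows)}")
        seq_chars = []
        partner = [UNPAIRED] * n
        for r, row in enumerate(rows):
            f = row.split()
            if len(f) < 6:
                raise FormatError(f"{path}: line {pos + 2 + r}: expected 6 CT columns")
            idx, base, pair = int(f[0]), f[1], int(f[4])
            if idx != r + 1:
                raise FormatError(f"{path}: line {pos + 2 + r}: index {idx}, expected {r + 1}")
            seq_chars.append(base)
            if pair != 0:
                partner[idx - 1] = pair - 1
        for i, j in enumerate(partner):
            if j != UNPAIRED and partner[j] != i:
                raise FormatError(
                    f"{path}: structure {title!r}: asymmetric pairing between rows "
                    f"{i + 1} and {j + 1} (row {i + 1} pairs {j + 1}, "
                    f"row {j + 1} pairs {partner[j] + 1})"
                )
        table = PairTable(tuple(partner))
        table.to_dotbracket()  # rejects pseudoknots
        seq = _normalise_rna("".join(seq_chars))
        out.append((PreMiRNA(id=title, sequence=seq), table))
        pos += 1 + n
    return out


def write_ct(records: Iterable[tuple[PreMiRNA, PairTable]], path: Union[str, Path]) -> None:
    """Write 6-column CT (1-based), one block per structure."""
    with open(path, "w") as fh:
        for rec, table in records:
            n = rec.length
            fh.write(f"{n} {rec.id}\n")
            for i in range(n):
                j = table.partner[i]
                pair = 0 if j == UNPAIRED else j + 1
                fh.write(
                    f"{i + 1} {rec.sequence[i]} {i} {i + 2 if i + 1 < n else 0} {pair} {i + 1}\n"
                )


def first_structures(
    records: Sequence[tuple[PreMiRNA, PairTable]]
) -> dict[str, tuple[PreMiRNA, PairTable]]:
    """Keep only the first (minimum free energy) structure per id."""
    out: dict[str, tuple[PreMiRNA, PairTable]] = {}
    for rec, table in records:
        out.setdefault(rec.id, (rec, table))
    return out


def read_annotations(
    path: Union[str, Path],
    premirnas: Union[Mapping[str, PreMiRNA], Sequence[PreMiRNA], None] = None,
) -> list[CleavageAnnotation]:
    """Read the cleavage-site TSV (header line, columns id/arm/cleavage_pos).

    If ``premirnas`` is given, each annotation is validated against the
    window-fit invariant of its sequence; failing rows are skipped with a
    logged warning rather than aborting the run.
    """
    by_id: Mapping[str, PreMiRNA] = {}
    if premirnas is not None:
        if not isinstance(premirnas, Mapping):
            by_id = {p.id: p for p in premirnas}
        else:
            by_id = premirnas

    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    out = []
    for lineno, line in enumerate(lines[1:], start=2):  # skip header
        fields = line.split("\t")
        if len(fields) != 3:
            logger.warning("%s: line %d: expected 3 tab-separated fields; skipped", path, lineno)
            continue
        rid, arm, pos_str = (f.strip() for f in fields)
        try:
            ann = CleavageAnnotation(rid, arm, int(pos_str))
        except (ValueError, FormatError) as exc:
            logger.warning("%s: line %d: %s; skipped", path, lineno, exc)
            continue
        if by_id:
            rec = by_id.get(rid)
            if rec is not None and not ann.window_fits(rec.length):
                logger.warning(
                    "%s: line %d: cleavage window does not fit %s "
                    "(pos %d, length %d); skipped",
                    path, lineno, rid, ann.cleavage_pos, rec.length,
                )
                continue
        out.append(ann)
    return out


def write_annotations(annotations: Iterable[CleavageAnnotation], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("id\tarm\tcleavage_pos\n")
        for ann in annotations:
            fh.write(f"{ann.premirna_id}\t{ann.arm}\t{ann.cleavage_pos}\n")
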