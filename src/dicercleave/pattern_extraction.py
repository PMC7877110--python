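"""Extraction of 14-nt cleavage / non-cleavage patterns and their complements.

A *cleavage pattern* is the 14-nt window with the Dicer scissile bond at its
centre: 7 nt on the 5' side of the bond and 7 nt on the 3' side, so the bond
sits between window positions 7 and 8 (1-based). The annotated cleavage
position is the last nucleotide 5' of the bond (window position 7). The
*non-cleavage pattern* is a same-size window whose centre is shifted 6 nt
toward the arm's free terminus (5' terminus for the 5p arm, 3' terminus for
the 3p arm), i.e. away from the hairpin loop.

The *complementary strand* of a window is read position-wise from the
structure: the letter of the pairing partner, or ``O`` for a loop/bulge
(unpaired) position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .structure_io import (
    ARM_5P,
    CleavageAnnotation,
    PairTable,
    PreMiRNA,
    UNPAIRED,
)

logger = logging.getLogger(__name__)

WINDOW_LENGTH = 14
#: non-cleavage window centre sits this many nt from the cleavage centre
NONCLEAVAGE_SHIFT = 6
#: symbol standing in for a loop/bulge (unpaired) partner
LOOP_BULGE = "O"

LABEL_CLEAVAGE = "cleavage"
LABEL_NONCLEAVAGE = "non_cleavage"
LABELS = (LABEL_CLEAVAGE, LABEL_NONCLEAVAGE)


@dataclass(frozen=True)
class Pattern:
    """A 14-nt window, its structure-derived complement, and its class label."""

    premirna_id: str
    arm: str
    label: str
    window: str
    complement: str
    start: int  # 0-based start of the window in the pre-miRNA

    def __post_init__(self) -> None:
        if len(self.window) != WINDOW_LENGTH or len(self.complement) != WINDOW_LENGTH:
            raise ValueError(
                f"{self.premirna_id}: window and complement must be "
                f"{WINDOW_LENGTH} nt, got {len(self.window)}/{len(self.complement)}"
            )


class ExtractionError(ValueError):
    """Raised when a pattern window cannot be placed inside the sequence."""


def cleavage_window_start(annotation: CleavageAnnotation) -> int:
    """0-based start of the cleavage window (bond between offsets 6|7)."""
    return annotation.cleavage_pos - 7


def complement_of_window(start: int, pair_table: PairTable, sequence: str) -> str:
    """Complementary strand over {A,C,G,U,O} for the window at ``start``."""
    if start < 0 or start + WINDOW_LENGTH > len(sequence):
        raise ExtractionError(
            f"window [{start}, {start + WINDOW_LENGTH}) outside sequence of length {len(sequence)}"
        )
    out = []
    for i in range(start, start + WINDOW_LENGTH):
        j = pair_table.partner[i]
        out.append(LOOP_BULGE if j == UNPAIRED else sequence[j])
    return "".join(out)


def _extract(
    premirna: PreMiRNA,
    pair_table: PairTable,
    annotation: CleavageAnnotation,
    start: int,
    label: str,
) -> Pattern:
    if start < 0 or start + WINDOW_LENGTH > premirna.length:
        raise ExtractionError(
            f"{premirna.id} ({annotation.arm}, {label}): window "
            f"[{start}, {start + WINDOW_LENGTH}) overruns sequence of length {premirna.length}"
        )
    window = premirna.sequence[start : start + WINDOW_LENGTH]
    complement = complement_of_window(start, pair_table, premirna.sequence)
    return Pattern(premirna.id, annotation.arm, label, window, complement, start)


def extract_cleavage_pattern(
    premirna: PreMiRNA, pair_table: PairTable, annotation: CleavageAnnotation
) -> Pattern:
    """The 14-nt window centred on the annotated scissile bond."""
    return _extract(
        premirna, pair_table, annotation, cleavage_window_start(annotation), LABEL_CLEAVAGE
    )


def extract_noncleavage_pattern(
    premirna: PreMiRNA, pair_table: PairTable, annotation: CleavageAnnotation
) -> Pattern:
    """The window shifted 6 nt toward the arm's free terminus."""
    shift = -NONCLEAVAGE_SHIFT if annotation.arm == ARM_5P else NONCLEAVAGE_SHIFT
    start = cleavage_window_start(annotation) + shift
    return _extract(premirna, pair_table, annotation, start, LABEL_NONCLEAVAGE)


def build_dataset(
    premirnas: Sequence[PreMiRNA],
    pair_tables: Union[Mapping[str, PairTable], Sequence[PairTable]],
    annotations: Iterable[CleavageAnnotation],
    arm: str | None = None,
) -> list[Pattern]:
    """One cleavage + one non-cleavage pattern per valid annotation.

    Records whose cleavage or shifted non-cleavage window would cross the
    sequence boundary are dropped entirely (both labels), preserving class
    balance; annotations without a matching sequence/structure are skipped
    with a warning. ``arm`` restricts the dataset to one arm.
    """
    seq_by_id = {p.id: p for p in premirnas}
    if isinstance(pair_tables, Mapping):
        pt_by_id = dict(pair_tables)
    else:
        pt_by_id = {p.id: t for p, t in zip(premirnas, pair_tables)}

    patterns: list[Pattern] = []
    for ann in annotations:
        if arm is not None and ann.arm != arm:
            continue
        rec = seq_by_id.get(ann.premirna_id)
        table = pt_by_id.get(ann.premirna_id)
        if rec is None or table is None:
            logger.warning("no sequence/structure for %s; annotation skipped", ann.premirna_id)
            continue
        try:
            cleav = extract_cleavage_pattern(rec, table, ann)
            noncleav = extract_noncleavage_pattern(rec, table, ann)
        except ExtractionError as exc:
            logger.warning("record dropped: %s", exc)
            continue
        patterns.extend((cleav, noncleav))
    return patterns


_COLUMNS = ["premirna_id", "arm", "label", "window", "complement", "start"]


def patterns_to_frame(patterns: Iterable[Pattern]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in patterns], columns=_COLUMNS)


def write_patterns_tsv(patterns: Iterable[Pattern], path: Union[str, Path]) -> None:
    patterns_to_frame(patterns).to_csv(path, sep="\t", index=False)


def read_patterns_tsv(path: Union[str, Path]) -> list[Pattern]:
    df = pd.read_csv(path, sep="\t", dtype={"premirna_id": str})
    return [
        Pattern(
            premirna_id=row.premirna_id,
            arm=row.arm,
            label=row.label,
            window=row.window,
            complement=row.complement,
            start=int(row.start),
        )
        for row in df.itertuples(index=False)
    ]
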