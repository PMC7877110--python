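"""Synthetic structure-annotated hairpins with known cleavage positions.

The generator emulates the shape of a pre-miRNA as consumed by the
pipeline: a 5p arm, a terminal loop, and a 3p arm that is the
reverse-complement of the 5p arm with bulges (unpaired insertions on one
strand) and mismatches (internal loops) injected at configurable rates.
The ground-truth pair table comes from the generative process itself, so
no folding tool is involved. One 5p and one 3p cleavage annotation are
placed at a fixed bond offset from each free terminus, leaving room for
the 6-nt shifted non-cleavage window.

An optional sequence motif can be planted inside the cleavage window of
positives with a given probability, creating a learnable signal at a known
window position for benchmarking the classifier and the
feature-importance analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .structure_io import (
    ARM_3P,
    ARM_5P,
    CleavageAnnotation,
    PairTable,
    PreMiRNA,
    UNPAIRED,
    write_annotations,
    write_dotbracket,
    write_fasta,
)

_NUCS = np.array(list("ACGU"))
_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class HairpinSpec:
    """Geometry and noise model of a generated hairpin.

    ``cleavage_offset`` is the 1-based position (counted from the arm's
    free terminus) of the nucleotide 5' of the scissile bond; the default
    21 reflects the ~21-nt mature miRNA produced by Dicer. ``motif`` is
    planted at cleavage-window offset ``motif_offset`` (0-based; default 5,
    i.e. window positions 6 onward) with probability ``motif_strength``,
    independently per arm.
    """

    stem_length: int = 30
    loop_length: int = 8
    bulge_rate: float = 0.05
    mismatch_rate: float = 0.1
    motif: str | None = None
    motif_strength: float = 0.0
    motif_offset: int = 5
    cleavage_offset: int = 21
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stem_length < 21:
            raise ValueError("stem_length must be >= 21 so both windows fit")
        for name in ("bulge_rate", "mismatch_rate", "motif_strength"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.bulge_rate == 1:
            # every position a bulge leaves no stem to re-pair; reject rather
            # than emit a meaningless alignment
            raise ValueError("bulge_rate=1 is degenerate (no pairable stem remains)")
        if not 14 <= self.cleavage_offset:
            raise ValueError("cleavage_offset must be >= 14 (shifted window must fit)")
        if self.motif is not None and self.motif_offset + len(self.motif) > 14:
            raise ValueError("motif does not fit inside the 14-nt window")

    @property
    def total_length(self) -> int:
        return 2 * self.stem_length + self.loop_length


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(_NUCS, size=n))


def generate_hairpin(
    spec: HairpinSpec, seed: int | None = None, hairpin_id: str = "synth-0001"
) -> tuple[PreMiRNA, PairTable, tuple[CleavageAnnotation, CleavageAnnotation]]:
    """One hairpin: sequence, ground-truth pair table, and both annotations.

    The 5p motif copy (when drawn) is planted before the 3p arm is derived,
    so its base pairs stay Watson-Crick; the 3p copy overwrites the derived
    strand, so pairs under it may become non-canonical — the pair table,
    which is the ground truth the pipeline reads, is unaffected.
    """
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    S, L = spec.stem_length, spec.loop_length
    N = spec.total_length

    five = _random_seq(rng, S)
    plant5 = spec.motif is not None and rng.random() < spec.motif_strength
    w5_start = spec.cleavage_offset - 7  # 0-based cleavage-window start, 5p
    if plant5:
        for k, c in enumerate(spec.motif):
            five[w5_start + spec.motif_offset + k] = c

    # per stem position: bulge on one strand, or an aligned (mis)matched pair
    bulge = rng.random(S) < spec.bulge_rate
    bulge_side_5p = rng.random(S) < 0.5
    b5 = bulge & bulge_side_5p
    b3 = bulge & ~bulge_side_5p
    mismatch = rng.random(S) < spec.mismatch_rate

    five_idx = [k for k in range(S) if not b5[k]]
    three_idx = [k for k in range(S) if not b3[k]]  # offsets from the 3' terminus

    partner = [UNPAIRED] * N
    three = _random_seq(rng, S)  # indexed by offset from the 3' terminus
    for i, m in zip(five_idx, three_idx):
        j = N - 1 - m
        if mismatch[i]:
            non_wc = [c for c in "ACGU" if c != _WC[five[i]]]
            three[m] = non_wc[rng.integers(len(non_wc))]
        else:
            three[m] = _WC[five[i]]
            partner[i], partner[j] = j, i

    plant3 = spec.motif is not None and rng.random() < spec.motif_strength
    if plant3:
        # 3p cleavage window start, expressed as offset from the 3' terminus
        w3_start_full = N - spec.cleavage_offset - 7  # 0-based in the full sequence
        for k, c in enumerate(spec.motif):
            pos = w3_start_full + spec.motif_offset + k
            three[N - 1 - pos] = c

    loop = _random_seq(rng, L)
    sequence = "".join(five) + "".join(loop) + "".join(three[::-1])
    premirna = PreMiRNA(id=hairpin_id, sequence=sequence)
    table = PairTable(tuple(partner))
    ann5 = CleavageAnnotation(hairpin_id, ARM_5P, spec.cleavage_offset)
    ann3 = CleavageAnnotation(hairpin_id, ARM_3P, N - spec.cleavage_offset)
    return premirna, table, (ann5, ann3)


def generate_hairpins(
    n_hairpins: int, spec: HairpinSpec, seed: int | None = None
) -> tuple[list[PreMiRNA], dict, list[CleavageAnnotation]]:
    """n hairpins as in-memory records (sequences, pair tables by id, annotations)."""
    if n_hairpins < 1:
        raise ValueError("n_hairpins must be >= 1")
    root = np.random.SeedSequence(seed if seed is not None else spec.seed)
    children = root.spawn(n_hairpins)
    premirnas, tables, annotations = [], {}, []
    for k, child in enumerate(children):
        rid = f"synth-{k + 1:04d}"
        rec, table, (a5, a3) = generate_hairpin(
            spec, seed=np.random.default_rng(child).integers(2**31 - 1), hairpin_id=rid
        )
        premirnas.append(rec)
        tables[rid] = table
        annotations.extend((a5, a3))
    return premirnas, tables, annotations


def generate_dataset(
    n_hairpins: int,
    spec: HairpinSpec,
    seed: int | None = None,
    out_dir: Union[str, Path, None] = None,
) -> dict:
    """Generate hairpins and (optionally) write FASTA / dot-bracket / annotation TSV.

    Returns a dict with the in-memory records and, when ``out_dir`` is
    given, the paths of the three files (keys ``fasta``, ``dotbracket``,
    ``annotations``), which are exactly the formats the readers consume.
    """
    premirnas, tables, annotations = generate_hairpins(n_hairpins, spec, seed)
    out = {"premirnas": premirnas, "pair_tables": tables, "annotations": annotations}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta = out_dir / "hairpins.fasta"
        db = out_dir / "hairpins.db"
        ann = out_dir / "annotations.tsv"
        write_fasta(premirnas, fasta)
        write_dotbracket([(p, tables[p.id]) for p in premirnas], db)
        write_annotations(annotations, ann)
        out.update({"fasta": fasta, "dotbracket": db, "annotations_path": ann})
    return out
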