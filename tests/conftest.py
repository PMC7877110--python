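"""Shared fixtures: the worked-example hairpin and small synthetic datasets."""

import pytest
from hypothesis import settings

from dicercleave import (
    CleavageAnnotation,
    HairpinSpec,
    PairTable,
    PreMiRNA,
    build_dataset,
    generate_hairpins,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

# Synthetic 34-nt hairpin hand-built so that the 5p cleavage window, its
# complementary strand, and the shifted non-cleavage window reproduce the
# published worked-example strings. Pairs: window offsets 0-6 and 10-12 are
# stacked; offsets 7-9 and 13 are loops/bulges.
FIG2_SEQUENCE = "AGGUUG" + "UAUAGUUUUAGGGU" + "GAAA" + "CCC" + "AACUAUA"
FIG2_DOTBRACKET = "......" + "(((((((" + "..." + "(((" + "....." + ")))" + ")))))))"
FIG2_CLEAVAGE_POS = 13  # 1-based nucleotide 5' of the scissile bond


@pytest.fixture
def fig2():
    pre = PreMiRNA("fig2", FIG2_SEQUENCE)
    table = PairTable.from_dotbracket(FIG2_DOTBRACKET)
    ann = CleavageAnnotation("fig2", "5p", FIG2_CLEAVAGE_POS)
    return pre, table, ann


@pytest.fixture(scope="session")
def perfect_stem_dataset():
    """Noise-free hairpins: every stem position Watson-Crick paired."""
    spec = HairpinSpec(bulge_rate=0.0, mismatch_rate=0.0)
    premirnas, tables, annotations = generate_hairpins(6, spec, seed=11)
    return spec, premirnas, tables, annotations


@pytest.fixture(scope="session")
def noisy_patterns_5p():
    """A realistic 5p-arm pattern set (bulges, mismatches, no motif)."""
    spec = HairpinSpec()
    premirnas, tables, annotations = generate_hairpins(40, spec, seed=23)
    return build_dataset(premirnas, tables, annotations, arm="5p")
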