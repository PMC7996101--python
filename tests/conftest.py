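import random

import pytest

from itsphylo.core_io import PairTable, SequenceRecord, StructuredSequence
from itsphylo.struct_align import AlignedRow, StructuralAlignment


@pytest.fixture
def rng():
    return random.Random(20240917)


def random_nested_structure(rng, n, min_loop=3, p_pair=0.6):
    """Random nested pairing by recursive splitting (structure only)."""
    partner = [None] * n

    def fill(i, j):
        if j - i < min_loop + 1:
            return
        if rng.random() < p_pair:
            k = rng.randint(i + min_loop + 1, j)
            partner[i], partner[k] = k, i
            fill(i + 1, k - 1)
            fill(k + 1, j)
        else:
            fill(i + 1, j)

    fill(0, n - 1)
    return PairTable(partner)


def random_structured_sequence(rng, n, min_loop=3):
    """Random sequence + compatible random nested structure."""
    pt = random_nested_structure(rng, n, min_loop)
    pairs = {"AU", "UA", "GC", "CG", "GU", "UG"}
    seq = [rng.choice("ACGU") for _ in range(n)]
    for i, j in pt.pairs():
        d = rng.choice(sorted(pairs))
        seq[i], seq[j] = d[0], d[1]
    return StructuredSequence(SequenceRecord(f"r{rng.randrange(10**6)}", "".join(seq)), pt)


@pytest.fixture
def toy_alignment():
    """Five equal-width rows with a shared hairpin and one divergent row."""
    rows = [
        AlignedRow("s1", "GGGAAACCCAU", "(((...))).."),
        AlignedRow("s2", "GGGAAACCCAU", "(((...))).."),
        AlignedRow("s3", "GGGAAACCCGU", "(((...))).."),
        AlignedRow("s4", "GGCAAAGCCAU", "(((...))).."),
        AlignedRow("s5", "GG-AAA-CCAU", "((.....)).."),
    ]
    return StructuralAlignment(rows)
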