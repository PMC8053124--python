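import numpy as np
import pytest

from rearescan.genome_io import ChromosomeRecord
from rearescan.motif_engine import IUPAC_CODES, compile_motif


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_genome():
    return [
        ChromosomeRecord("chr1", "ACGTACGTTGACGGGGCATTTT" * 10),
        ChromosomeRecord("chr2", "TTTTACGTACGT" * 5),
    ]


def random_sequence(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))


def brute_force_scan(pattern, sequence, strands="both"):
    """Independent oracle: per-position character-class matching.

    Expands the IUPAC pattern into sets and slides a window in pure
    Python, on the forward pattern and its reverse complement.
    """
    from rearescan.motif_engine import reverse_complement_pattern

    def matches(pat, window):
        for code, base in zip(pat, window):
            if base not in IUPAC_CODES[code] or base == "N":
                return False
        return True

    length = len(pattern)
    hits = []
    rc = reverse_complement_pattern(pattern)
    for start in range(len(sequence) - length + 1):
        window = sequence[start : start + length]
        if matches(pattern, window):
            hits.append((start, start + length, "+"))
        if strands == "both" and matches(rc, window):
            hits.append((start, start + length, "-"))
    return hits


@pytest.fixture
def re_are_motifs():
    return compile_motif("RE", "RRRCWWGYYYRRRCWWGYYY"), compile_motif("ARE", "TGACNNNGC")
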