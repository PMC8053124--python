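"""IUPAC degenerate-consensus motif compilation and genome scanning.

Transcription-factor binding sequences (the p63 response element RE and the
NRF2 antioxidant response element ARE) are expressed as IUPAC consensus
strings and matched *exactly*: a window is a hit iff every base satisfies
the degenerate code at its position.  There is no PWM scoring.  Both strands
are scanned by default; a reverse-strand hit is reported at its
forward-strand coordinates with strand '-'.

N in the genome matches nothing (assembly gaps must not produce hits), even
against an N in the pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import ChromosomeRecord

__all__ = [
    "IUPAC_CODES",
    "IUPACMotif",
    "MotifHit",
    "compile_motif",
    "reverse_complement_pattern",
    "scan_sequence",
    "scan_genome",
]

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

# Genome bases are encoded A=0 C=1 G=2 T=3 N=4; column 4 of every lookup
# table stays False so N never matches.
_BASE_ORDER = "ACGTN"
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASE_ORDER):
    _ENCODE[ord(_b)] = _i


@dataclass(frozen=True)
class IUPACMotif:
    """A named degenerate consensus pattern with a per-position base table."""

    name: str
    pattern: str

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def table(self) -> np.ndarray:
        """Boolean (length x 5) allowed-base table; the N column is False."""
        return _pattern_table(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    """A strand-aware match of one motif on the genome.

    Coordinates are 0-based half-open on the forward strand regardless of
    the matched strand; ``matched_seq`` is the forward-strand substring.
    """

    chrom: str
    start: int
    end: int
    strand: str
    motif_name: str
    matched_seq: str = ""


def compile_motif(name: str, pattern: str) -> IUPACMotif:
    """Validate an IUPAC consensus string and wrap it as a motif.

    Raises ``ValueError`` naming the first illegal position (1-based, as a
    user would count characters in the config file).
    """
    if not pattern:
        raise ValueError(f"motif {name!r}: empty pattern")
    pattern = pattern.upper()
    for i, ch in enumerate(pattern):
        if ch not in IUPAC_CODES:
            raise ValueError(
                f"motif {name!r}: illegal IUPAC code {ch!r} at position {i + 1}"
            )
    return IUPACMotif(name=name, pattern=pattern)


def reverse_complement_pattern(pattern: str) -> str:
    """Reverse-complement an IUPAC pattern (complement each code, reverse)."""
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(pattern.upper()))


def _pattern_table(pattern: str) -> np.ndarray:
    table = np.zeros((len(pattern), 5), dtype=bool)
    for j, code in enumerate(pattern):
        for base in IUPAC_CODES[code]:
            table[j, _BASE_ORDER.index(base)] = True
    return table


def _encode(sequence: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _match_starts(codes: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Start positions of windows where every base satisfies the table.

    Evaluates the most specific pattern position first so later positions
    only test the surviving candidate windows.
    """
    length = table.shape[0]
    n_win = codes.size - length + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.int64)
    order = np.argsort(table.sum(axis=1), kind="stable")
    j0 = int(order[0])
    cand = np.nonzero(table[j0, codes[j0 : j0 + n_win]])[0]
    for j in order[1:]:
        if cand.size == 0:
            break
        j = int(j)
        cand = cand[table[j, codes[cand + j]]]
    return cand.astype(np.int64)


def scan_sequence(
    motif: IUPACMotif,
    chrom: ChromosomeRecord,
    strands: str = "both",
    collapse_palindromes: bool = False,
) -> list[MotifHit]:
    """Scan one chromosome for exact degenerate matches of ``motif``.

    ``strands`` is ``'+'`` (forward only) or ``'both'``.  A window matching
    the pattern forward yields a '+' hit; a window matching the
    reverse-complement pattern yields a '-' hit at the same forward
    coordinates.  Palindromic windows therefore yield two hits unless
    ``collapse_palindromes`` keeps only the '+' one.  Overlapping hits are
    all reported.  Output is sorted by start, then strand ('+' before '-').
    """
    if strands not in ("+", "both"):
        raise ValueError(f"strands must be '+' or 'both', got {strands!r}")
    codes = _encode(chrom.sequence)
    length = motif.length
    hits: list[MotifHit] = []
    fwd = set(_match_starts(codes, motif.table).tolist())
    rev: set[int] = set()
    if strands == "both":
        rc_table = _pattern_table(reverse_complement_pattern(motif.pattern))
        rev = set(_match_starts(codes, rc_table).tolist())
    for s in sorted(fwd | rev):
        seq = chrom.sequence[s : s + length]
        if s in fwd:
            hits.append(MotifHit(chrom.name, s, s + length, "+", motif.name, seq))
        if s in rev and not (collapse_palindromes and s in fwd):
            hits.append(MotifHit(chrom.name, s, s + length, "-", motif.name, seq))
    return hits


def scan_genome(
    motifs: list[IUPACMotif],
    genome: list[ChromosomeRecord],
    strands: str = "both",
    collapse_palindromes: bool = False,
):
    """Scan every chromosome for every motif.

    Returns ``(hits, counts)`` where ``hits`` maps motif name to its
    concatenated hit list (chromosomes in input order) and ``counts`` is a
    pandas DataFrame of per-chromosome hit counts with a ``total`` row.
    """
    import pandas as pd

    if not motifs or not genome:
        raise ValueError("need at least one motif and one chromosome")
    names = [m.name for m in motifs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate motif names: {names}")
    hits: dict[str, list[MotifHit]] = {m.name: [] for m in motifs}
    counts = {m.name: {} for m in motifs}
    for chrom in genome:
        for motif in motifs:
            chrom_hits = scan_sequence(motif, chrom, strands, collapse_palindromes)
            hits[motif.name].extend(chrom_hits)
            counts[motif.name][chrom.name] = len(chrom_hits)
    table = pd.DataFrame(counts)
    table.loc["total"] = table.sum()
    return hits, table
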