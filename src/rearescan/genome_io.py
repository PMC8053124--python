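"""Readers and writers for the formats the pipeline touches.

Every coordinate in this package is 0-based, half-open (BED-native).
Input dialects that use 1-based positions are converted at this boundary
and never leak further in.

The FASTA reader is deliberately strict: sequences are restricted to
{A, C, G, T, N} after case folding (U is mapped to T), and violations are
reported with the offending line number.  Assembly gaps (N) are legal
sequence but never match any motif code downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ChromosomeRecord",
    "TSSRecord",
    "Peak",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "read_tss_table",
    "read_motif_file",
    "write_tables",
]


class FormatError(ValueError):
    """A malformed input file (bad syntax, coordinates, or characters)."""


_VALID_BASES = frozenset("ACGTN")
_FOLD = str.maketrans({"u": "T", "U": "T"})


@dataclass(frozen=True)
class ChromosomeRecord:
    """One chromosome (or contig): an upper-cased sequence over {A,C,G,T,N}."""

    name: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TSSRecord:
    """A transcription start site, used as the anchor for gene association.

    ``source`` distinguishes protein-coding gene TSS from miRNA TSS so the
    two annotation tracks can be compared separately.
    """

    feature_id: str
    chrom: str
    position: int  # 0-based
    strand: str  # '+' or '-'
    source: str = "gene"  # 'gene' or 'mirna'


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak interval with its mark (e.g. H3K27ac, p63) and
    cell-state label (e.g. KS / KP / DK for keratinocyte stem,
    proliferation-competent, and differentiated states)."""

    chrom: str
    start: int
    end: int
    mark: str = "other"
    state: str = "other"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(
                f"peak end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def read_fasta(path: str | Path) -> list[ChromosomeRecord]:
    """Parse a FASTA file into chromosome records.

    Sequences are upper-cased, U is mapped to T, and any character outside
    {A,C,G,T,N} raises :class:`FormatError` naming the line.  Duplicate
    record names and empty files are rejected; record order is preserved.
    """
    path = Path(path)
    records: list[ChromosomeRecord] = []
    seen: set[str] = set()
    name: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if name is None:
            return
        records.append(ChromosomeRecord(name=name, sequence="".join(chunks)))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                if name in seen:
                    raise FormatError(f"{path}: duplicate record name {name!r}")
                seen.add(name)
                chunks = []
            else:
                if name is None:
                    raise FormatError(
                        f"{path}: sequence before first header at line {lineno}"
                    )
                seq = line.translate(_FOLD).upper()
                bad = set(seq) - _VALID_BASES
                if bad:
                    raise FormatError(
                        f"{path}: illegal character(s) {sorted(bad)} at line {lineno}"
                    )
                chunks.append(seq)
    _flush()
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable, path: str | Path, width: int = 60) -> None:
    """Write records with ``.name``/``.sequence`` (or Biopython SeqRecords)
    as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            name = getattr(rec, "name", None) or getattr(rec, "id", "")
            seq = str(getattr(rec, "sequence", None) or getattr(rec, "seq"))
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(
    path: str | Path,
    mark: str = "other",
    state: str = "other",
    labels_from_columns: bool = False,
) -> list[Peak]:
    """Read a BED3+ file of peak intervals (0-based, half-open).

    With ``labels_from_columns`` the 4th and 5th columns are interpreted as
    mark and state; otherwise the supplied labels apply to every line.
    """
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start ({start}, {end})")
            m, s = mark, state
            if labels_from_columns:
                if len(cols) > 3 and cols[3]:
                    m = cols[3]
                if len(cols) > 4 and cols[4]:
                    s = cols[4]
            peaks.append(Peak(chrom=cols[0], start=start, end=end, mark=m, state=s))
    return peaks


def read_tss_table(
    path: str | Path, source: str = "gene", one_based: bool = False
) -> list[TSSRecord]:
    """Read a tab-separated TSS table: feature_id, chrom, position, strand.

    ``one_based`` accepts genome-browser style 1-based positions and
    subtracts 1 so everything downstream stays 0-based.
    """
    path = Path(path)
    out: list[TSSRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 columns")
            try:
                pos = int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer position") from exc
            if one_based:
                pos -= 1
            if pos < 0:
                raise FormatError(f"{path}:{lineno}: negative position {pos}")
            strand = cols[3]
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: bad strand symbol {strand!r}")
            out.append(
                TSSRecord(
                    feature_id=cols[0], chrom=cols[1], position=pos,
                    strand=strand, source=source,
                )
            )
    return out


def read_hits_bed(path: str | Path) -> list:
    """Read a BED6 file of motif hits (name column = motif, column 6 =
    strand) back into MotifHit records.  ``matched_seq`` is not stored in
    BED and comes back empty."""
    from .motif_engine import MotifHit

    path = Path(path)
    hits = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise FormatError(f"{path}:{lineno}: expected BED6 for motif hits")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            hits.append(MotifHit(cols[0], start, end, cols[5], cols[3]))
    return hits


def read_motif_file(path: str | Path) -> list[tuple[str, str]]:
    """Read a motif configuration file of lines ``name<TAB>IUPAC_pattern``."""
    path = Path(path)
    out: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise FormatError(f"{path}:{lineno}: expected name<TAB>pattern")
            out.append((cols[0], cols[1]))
    return out


# ---------------------------------------------------------------------------
# Tabular output.  One writer handles every pipeline record type; rows are
# sorted by (chrom, start, end) so outputs are deterministic and diffable.
# ---------------------------------------------------------------------------

def _row_key(rec) -> tuple:
    chrom = getattr(rec, "chrom", None)
    if chrom is None and hasattr(rec, "re_hit"):
        chrom = rec.re_hit.chrom
    start = getattr(rec, "start", getattr(rec, "span_start", getattr(rec, "position", 0)))
    end = getattr(rec, "end", getattr(rec, "span_end", start))
    return (chrom or "", start, end)


def _bed_fields(rec) -> tuple[str, int, int, str, str, str]:
    """(chrom, start, end, name, score, strand) for BED6 output."""
    tname = type(rec).__name__
    if tname == "MotifHit":
        return (rec.chrom, rec.start, rec.end, rec.motif_name, "0", rec.strand)
    if tname == "REAREPair":
        name = f"pair|n={rec.spacer_n}|{rec.orientation}"
        return (rec.re_hit.chrom, rec.span_start, rec.span_end, name, "0", ".")
    if tname == "Peak":
        return (rec.chrom, rec.start, rec.end, f"{rec.mark}:{rec.state}", "0", ".")
    raise TypeError(f"cannot express {tname} as BED")


_TSV_COLUMNS = {
    "MotifHit": ("chrom", "start", "end", "strand", "motif_name", "matched_seq"),
    "Peak": ("chrom", "start", "end", "mark", "state"),
    "TSSRecord": ("feature_id", "chrom", "position", "strand", "source"),
    "REAREPair": (
        "chrom", "re_start", "re_end", "re_strand", "are_start", "are_end",
        "are_strand", "spacer_n", "orientation", "steric_ok",
    ),
}


def _tsv_row(rec) -> list:
    tname = type(rec).__name__
    if tname == "REAREPair":
        return [
            rec.re_hit.chrom, rec.re_hit.start, rec.re_hit.end, rec.re_hit.strand,
            rec.are_hit.start, rec.are_hit.end, rec.are_hit.strand,
            rec.spacer_n, rec.orientation, rec.steric_ok,
        ]
    return [getattr(rec, c) for c in _TSV_COLUMNS[tname]]


def write_tables(records: Sequence, path: str | Path, fmt: str = "tsv") -> None:
    """Write a homogeneous record list as a TSV report or BED6 file.

    TSV output carries a '#'-prefixed header naming the columns; BED output
    is plain BED6.  An empty list yields a header-only file (TSV) or an
    empty file (BED).  Mixed record types are a usage error.
    """
    records = list(records)
    types = {type(r).__name__ for r in records}
    if len(types) > 1:
        raise TypeError(f"mixed record types in one table: {sorted(types)}")
    if fmt not in ("tsv", "bed"):
        raise ValueError(f"unknown table format {fmt!r}")
    ordered = sorted(records, key=_row_key)
    with open(path, "w") as fh:
        if fmt == "bed":
            for rec in ordered:
                fields = _bed_fields(rec)
                fh.write("\t".join(str(f) for f in fields) + "\n")
            return
        if records:
            tname = types.pop()
            if tname not in _TSV_COLUMNS:
                if dataclasses.is_dataclass(ordered[0]):
                    cols = tuple(f.name for f in dataclasses.fields(ordered[0]))
                    _TSV_COLUMNS[tname] = cols
                else:
                    raise TypeError(f"cannot tabulate records of type {tname}")
            fh.write("#" + "\t".join(_TSV_COLUMNS[tname]) + "\n")
            for rec in ordered:
                fh.write("\t".join(str(v) for v in _tsv_row(rec)) + "\n")
        else:
            fh.write("#empty\n")
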