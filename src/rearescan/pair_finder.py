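"""Nearest-neighbor RE-ARE pairing, spacer lengths, and steric filtering.

Each p63 response element (RE) hit is joined to the nearest NRF2
antioxidant response element (ARE) hit on the same chromosome, where
"distance" is the inner gap between the two motif intervals (the spacer
``n`` between the core sequences), not center-to-center.  The gap is
negative when the motifs overlap.

A composite element is sterically feasible — both factors can occupy their
sites simultaneously — only when the spacer exceeds a threshold (default
7 bp, from structural modeling of the p63 tetramer and the NRF2-small-MAF
dimer on nucleosomal DNA).

Pairing is RE-driven and many-to-one: AREs vastly outnumber REs, so one ARE
may serve several REs.  A strict one-to-one greedy mode is available.
Strand is ignored for pairing; composite elements are functional in either
orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .genome_io import ChromosomeRecord
from .motif_engine import MotifHit

__all__ = [
    "REAREPair",
    "spacer",
    "pair_nearest",
    "flag_steric",
    "export_pair_sequences",
    "STERIC_THRESHOLD_BP",
]

log = logging.getLogger(__name__)

STERIC_THRESHOLD_BP = 7


@dataclass(frozen=True)
class REAREPair:
    """An RE hit joined to its nearest ARE hit.

    ``spacer_n`` is the inner gap in bases (negative when the motifs
    overlap); ``orientation`` records which motif is upstream; the span is
    the 0-based half-open hull of both motifs.
    """

    re_hit: MotifHit
    are_hit: MotifHit
    spacer_n: int
    orientation: str  # 'RE_upstream' | 'ARE_upstream' | 'overlapping'
    steric_ok: bool

    @property
    def chrom(self) -> str:
        return self.re_hit.chrom

    @property
    def span_start(self) -> int:
        return min(self.re_hit.start, self.are_hit.start)

    @property
    def span_end(self) -> int:
        return max(self.re_hit.end, self.are_hit.end)


def _gap_and_orientation(re_hit: MotifHit, are_hit: MotifHit) -> tuple[int, str]:
    gap_re_up = are_hit.start - re_hit.end
    gap_are_up = re_hit.start - are_hit.end
    gap = max(gap_re_up, gap_are_up)
    if gap < 0:
        return gap, "overlapping"
    if gap == gap_re_up:
        return gap, "RE_upstream"
    return gap, "ARE_upstream"


def spacer(re_hit: MotifHit, are_hit: MotifHit) -> int:
    """Inner gap between two motif intervals on the same chromosome.

    Symmetric in its arguments; negative when the intervals overlap.
    """
    if re_hit.chrom != are_hit.chrom:
        raise ValueError(
            f"hits on different chromosomes: {re_hit.chrom} vs {are_hit.chrom}"
        )
    return _gap_and_orientation(re_hit, are_hit)[0]


def _make_pair(re_hit: MotifHit, are_hit: MotifHit, threshold: int) -> REAREPair:
    gap, orient = _gap_and_orientation(re_hit, are_hit)
    return REAREPair(
        re_hit=re_hit, are_hit=are_hit, spacer_n=gap, orientation=orient,
        steric_ok=gap > threshold,
    )


def pair_nearest(
    re_hits: list[MotifHit],
    are_hits: list[MotifHit],
    max_window: int | None = None,
    steric_threshold: int = STERIC_THRESHOLD_BP,
    one_to_one: bool = False,
) -> list[REAREPair]:
    """Join each RE to the ARE on its chromosome minimizing ``|spacer|``.

    Exactly one pair is emitted per RE that has at least one candidate ARE
    (within ``max_window`` of absolute spacer, if given).  Ties go to the
    lower-coordinate ARE.  With ``one_to_one`` each ARE is used at most
    once, assigned greedily in order of increasing ``|spacer|``.
    Pairs are returned sorted by (chromosome, span_start).
    """
    by_chrom: dict[str, list[MotifHit]] = {}
    for h in are_hits:
        by_chrom.setdefault(h.chrom, []).append(h)
    arrays: dict[str, tuple[list[MotifHit], np.ndarray, np.ndarray]] = {}
    for chrom, hits in by_chrom.items():
        hits.sort(key=lambda h: (h.start, h.end))
        arrays[chrom] = (
            hits,
            np.array([h.start for h in hits], dtype=np.int64),
            np.array([h.end for h in hits], dtype=np.int64),
        )

    def best_index(re_hit: MotifHit, exclude: np.ndarray | None = None) -> int | None:
        entry = arrays.get(re_hit.chrom)
        if entry is None:
            return None
        _, starts, ends = entry
        gaps = np.maximum(starts - re_hit.end, re_hit.start - ends)
        dist = np.abs(gaps)
        if max_window is not None:
            dist = np.where(dist <= max_window, dist, np.iinfo(np.int64).max)
        if exclude is not None:
            dist = np.where(exclude, np.iinfo(np.int64).max, dist)
        j = int(np.argmin(dist))
        if dist[j] == np.iinfo(np.int64).max:
            return None
        return j

    pairs: list[REAREPair] = []
    if not one_to_one:
        for re_hit in re_hits:
            j = best_index(re_hit)
            if j is None:
                continue
            pairs.append(_make_pair(re_hit, arrays[re_hit.chrom][0][j], steric_threshold))
    else:
        # Greedy matching by increasing |spacer|: each RE proposes its
        # nearest free ARE; assignments are fixed best-first.
        used = {chrom: np.zeros(len(entry[0]), dtype=bool) for chrom, entry in arrays.items()}
        proposals = []
        for idx, re_hit in enumerate(re_hits):
            j = best_index(re_hit)
            if j is not None:
                gap = _gap_and_orientation(re_hit, arrays[re_hit.chrom][0][j])[0]
                proposals.append((abs(gap), idx, j))
        import heapq

        heapq.heapify(proposals)
        while proposals:
            _, idx, j = heapq.heappop(proposals)
            re_hit = re_hits[idx]
            if used[re_hit.chrom][j]:
                j2 = best_index(re_hit, exclude=used[re_hit.chrom])
                if j2 is None:
                    continue
                gap = _gap_and_orientation(re_hit, arrays[re_hit.chrom][0][j2])[0]
                heapq.heappush(proposals, (abs(gap), idx, j2))
                continue
            used[re_hit.chrom][j] = True
            pairs.append(_make_pair(re_hit, arrays[re_hit.chrom][0][j], steric_threshold))

    pairs.sort(key=lambda p: (p.chrom, p.span_start, p.span_end))
    return pairs


def flag_steric(
    pairs: list[REAREPair], threshold: int = STERIC_THRESHOLD_BP
) -> tuple[list[REAREPair], list[REAREPair]]:
    """Partition pairs into (feasible, infeasible) under ``spacer > threshold``.

    The strict inequality encodes the structural-model conclusion that
    simultaneous binding requires a spacer of more than ``threshold`` bases:
    a spacer of exactly ``threshold`` is infeasible.  Returned pairs carry a
    refreshed ``steric_ok`` flag.
    """
    feasible, infeasible = [], []
    for p in pairs:
        ok = p.spacer_n > threshold
        p2 = replace(p, steric_ok=ok) if ok != p.steric_ok else p
        (feasible if ok else infeasible).append(p2)
    return feasible, infeasible


def read_pairs_table(path) -> list[REAREPair]:
    """Read a pairs TSV as written by :func:`rearescan.genome_io.write_tables`."""
    pairs: list[REAREPair] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            (chrom, re_s, re_e, re_str, are_s, are_e, are_str,
             spacer_n, orientation, steric_ok) = line.split("\t")
            pairs.append(
                REAREPair(
                    re_hit=MotifHit(chrom, int(re_s), int(re_e), re_str, "RE"),
                    are_hit=MotifHit(chrom, int(are_s), int(are_e), are_str, "ARE"),
                    spacer_n=int(spacer_n),
                    orientation=orientation,
                    steric_ok=steric_ok == "True",
                )
            )
    return pairs


def export_pair_sequences(
    pairs: list[REAREPair],
    genome: list[ChromosomeRecord],
    flank: int = 0,
) -> list:
    """Extract the genomic sequence of each pair span (plus flanks) as
    Biopython SeqRecords, ready for FASTA export to motif-discovery tools.

    Spans extending past a chromosome end are clipped with a warning.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    by_name = {c.name: c for c in genome}
    records = []
    for i, p in enumerate(pairs):
        chrom = by_name.get(p.chrom)
        if chrom is None:
            raise KeyError(f"pair on unknown chromosome {p.chrom!r}")
        lo = p.span_start - flank
        hi = p.span_end + flank
        if lo < 0 or hi > chrom.length:
            log.warning(
                "pair %d span %s:%d-%d with flank %d clipped to chromosome bounds",
                i, p.chrom, p.span_start, p.span_end, flank,
            )
            lo, hi = max(lo, 0), min(hi, chrom.length)
        header = (
            f"{p.chrom}:{p.span_start}-{p.span_end}"
            f"|spacer={p.spacer_n}|{p.orientation}|flank={flank}"
        )
        records.append(SeqRecord(Seq(chrom.sequence[lo:hi]), id=header, description=""))
    return records
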