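"""ChIP-seq peak annotation: pair containment, per-state percentages,
cross-state set algebra, TSS distances, and closest-gene association.

A composite RE-ARE pair is "below" a peak iff the start and end of *each*
motif lie fully within the peak's containment interval; a pair straddling a
peak edge does not count.  The containment interval is by default the
reported peak range from the BED file; a fixed window of +/- ``half_width``
(default 300 bp) around the peak center is available as an alternative
mode, mirroring how the H3K27ac peaks were originally defined by read
enrichment within 300 bp of the peak center.

Genes are associated GREAT-style: each RE-ARE-containing peak takes the TSS
closest to its center, if within ``max_dist`` (default 100 kb).  When a
peak contains several pairs, its gene is assigned once per pair
("assigned in duplicate"), so downstream ontology input weights genes by
the number of composite elements driving them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from intervaltree import IntervalTree

from .genome_io import Peak, TSSRecord
from .motif_engine import MotifHit
from .pair_finder import REAREPair
from .spacing_stats import DistanceSample

__all__ = [
    "Peak",
    "AnnotatedPeak",
    "containment_interval",
    "pairs_under_peaks",
    "percentage_with_pairs",
    "peak_set_algebra",
    "PeakSetPartition",
    "distance_to_nearest",
    "associate_genes",
]


@dataclass
class AnnotatedPeak:
    """A peak together with its fully contained pairs, any lone motif hits
    (RE-only or ARE-only), and the gene(s) later assigned to it."""

    peak: Peak
    contained_pairs: list[REAREPair] = field(default_factory=list)
    single_motif_hits: list[MotifHit] = field(default_factory=list)
    genes: list[tuple[str, int]] = field(default_factory=list)

    @property
    def has_pair(self) -> bool:
        return bool(self.contained_pairs)


def containment_interval(
    peak: Peak, mode: str = "reported_range", half_width: int = 300
) -> tuple[int, int]:
    """The half-open interval a motif must fall inside to count as "under"
    the peak: the reported BED range, or center +/- half_width."""
    if mode == "reported_range":
        return peak.start, peak.end
    if mode == "center_window":
        return peak.center - half_width, peak.center + half_width
    raise ValueError(f"unknown containment mode {mode!r}")


def pairs_under_peaks(
    pairs: Sequence[REAREPair],
    peaks: Sequence[Peak],
    mode: str = "reported_range",
    half_width: int = 300,
    hits: Sequence[MotifHit] | None = None,
) -> tuple[list[AnnotatedPeak], dict[str, int]]:
    """Assign RE-ARE pairs (and optionally lone motif hits) to peaks.

    A pair belongs to a peak iff both motif intervals are fully inside the
    peak's containment interval; because the pair span is the hull of both
    motifs, this is equivalent to full containment of the span.  A pair
    under several overlapping peaks is assigned to each (peak-level counts
    may therefore exceed the number of distinct pairs; pair-level counts
    never do).

    Returns annotated peaks that received at least one pair or lone hit,
    plus a counts dict: ``peaks_total``, ``peaks_with_pairs``,
    ``pair_assignments`` (peak-level), ``pairs_under_any_peak``
    (pair-level, distinct), ``peaks_single_motif_only``.
    """
    annotated = [AnnotatedPeak(peak=p) for p in peaks]
    trees: dict[str, IntervalTree] = {}
    for idx, ann in enumerate(annotated):
        lo, hi = containment_interval(ann.peak, mode, half_width)
        trees.setdefault(ann.peak.chrom, IntervalTree()).addi(lo, hi, idx)

    distinct_pairs = 0
    for pair in pairs:
        tree = trees.get(pair.chrom)
        if tree is None:
            continue
        assigned = False
        for iv in tree.overlap(pair.span_start, pair.span_end):
            if iv.begin <= pair.span_start and pair.span_end <= iv.end:
                annotated[iv.data].contained_pairs.append(pair)
                assigned = True
        if assigned:
            distinct_pairs += 1

    if hits is not None:
        for hit in hits:
            tree = trees.get(hit.chrom)
            if tree is None:
                continue
            for iv in tree.overlap(hit.start, hit.end):
                if iv.begin <= hit.start and hit.end <= iv.end:
                    annotated[iv.data].single_motif_hits.append(hit)
        # hits that are one motif of a contained pair are not "lone"
        for ann in annotated:
            in_pairs = {
                (h.start, h.end, h.strand, h.motif_name)
                for p in ann.contained_pairs
                for h in (p.re_hit, p.are_hit)
            }
            ann.single_motif_hits = [
                h for h in ann.single_motif_hits
                if (h.start, h.end, h.strand, h.motif_name) not in in_pairs
            ]

    counts = {
        "peaks_total": len(annotated),
        "peaks_with_pairs": sum(1 for a in annotated if a.has_pair),
        "pair_assignments": sum(len(a.contained_pairs) for a in annotated),
        "pairs_under_any_peak": distinct_pairs,
        "peaks_single_motif_only": sum(
            1 for a in annotated if not a.has_pair and a.single_motif_hits
        ),
    }
    kept = [a for a in annotated if a.has_pair or a.single_motif_hits]
    return kept, counts


def percentage_with_pairs(
    annotated: Sequence[AnnotatedPeak], all_peaks: Sequence[Peak]
) -> dict[tuple[str, str], float]:
    """Percentage of peaks containing at least one RE-ARE pair, per
    (mark, state) group — e.g. the share of all H3K27ac-positive enhancers
    in a cell state that harbor a composite element."""
    if not all_peaks:
        raise ValueError("no peaks to take a percentage of")
    totals: dict[tuple[str, str], int] = {}
    for p in all_peaks:
        totals[(p.mark, p.state)] = totals.get((p.mark, p.state), 0) + 1
    with_pairs: dict[tuple[str, str], int] = {}
    for a in annotated:
        if a.has_pair:
            key = (a.peak.mark, a.peak.state)
            with_pairs[key] = with_pairs.get(key, 0) + 1
    return {key: 100.0 * with_pairs.get(key, 0) / total for key, total in totals.items()}


class PeakSetPartition(NamedTuple):
    unique_a: list[AnnotatedPeak]
    unique_b: list[AnnotatedPeak]
    common_a: list[AnnotatedPeak]
    common_b: list[AnnotatedPeak]

    def counts(self) -> dict[str, int]:
        return {
            "unique_a": len(self.unique_a),
            "unique_b": len(self.unique_b),
            "common_a": len(self.common_a),
            "common_b": len(self.common_b),
        }


def peak_set_algebra(
    peaks_a: Sequence[AnnotatedPeak], peaks_b: Sequence[AnnotatedPeak]
) -> PeakSetPartition:
    """Split the RE-ARE-containing peaks of two cell states into unique and
    common subsets.

    A peak in A is "common" iff it shares at least one base (same
    chromosome) with any RE-ARE-containing peak in B, and symmetrically.
    Half-open intervals: bookended peaks do not overlap.
    """
    a = [p for p in peaks_a if p.has_pair]
    b = [p for p in peaks_b if p.has_pair]

    def build(peaks: list[AnnotatedPeak]) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for ann in peaks:
            trees.setdefault(ann.peak.chrom, IntervalTree()).addi(
                ann.peak.start, ann.peak.end
            )
        return trees

    trees_a, trees_b = build(a), build(b)

    def split(peaks, other_trees):
        unique, common = [], []
        for ann in peaks:
            tree = other_trees.get(ann.peak.chrom)
            hit = tree is not None and bool(tree.overlap(ann.peak.start, ann.peak.end))
            (common if hit else unique).append(ann)
        return unique, common

    ua, ca = split(a, trees_b)
    ub, cb = split(b, trees_a)
    return PeakSetPartition(unique_a=ua, unique_b=ub, common_a=ca, common_b=cb)


def _interval_arrays(pairs: Sequence[REAREPair]):
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in pairs:
        by_chrom.setdefault(p.chrom, []).append((p.span_start, p.span_end))
    out = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        starts = np.array([s for s, _ in spans], dtype=np.int64)
        ends = np.array([e for _, e in spans], dtype=np.int64)
        out[chrom] = (starts, np.maximum.accumulate(ends), ends)
    return out


def _point_to_intervals(point: int, starts, prefix_max_end, ends) -> int:
    """Distance (bp) from a point to the nearest interval: 0 if covered,
    else the gap to the closest covered base."""
    i = int(np.searchsorted(starts, point, side="right"))
    left = None
    if i > 0:
        if prefix_max_end[i - 1] > point:
            return 0
        left = point - (int(prefix_max_end[i - 1]) - 1)
    right = int(starts[i]) - point if i < starts.size else None
    if left is None and right is None:  # unreachable: caller checks chrom
        raise ValueError("no intervals on chromosome")
    return min(d for d in (left, right) if d is not None)


def distance_to_nearest(
    queries: Sequence, targets: Sequence
) -> tuple[DistanceSample, list]:
    """Distance from each query to its nearest same-chromosome target.

    Supports both directions of the TSS/pair comparison: point queries
    (TSS records) against interval targets (pairs), and interval queries
    against point targets.  The distance is 0 when the point falls inside
    the pair span, else the number of bases separating the point from the
    nearest covered base.  Queries with no target on their chromosome are
    returned separately rather than contributing a value.
    """
    if not list(queries) or not list(targets):
        raise ValueError("queries and targets must be non-empty")
    q0, t0 = queries[0], targets[0]
    point_query = isinstance(q0, TSSRecord)
    point_target = isinstance(t0, TSSRecord)
    if point_query == point_target:
        raise TypeError("expected one point-like side (TSS) and one interval side (pairs)")

    values: list[int] = []
    unmatched: list = []
    if point_query:
        arrays = _interval_arrays(targets)
        for tss in queries:
            entry = arrays.get(tss.chrom)
            if entry is None:
                unmatched.append(tss)
                continue
            values.append(_point_to_intervals(tss.position, *entry))
    else:
        by_chrom: dict[str, np.ndarray] = {}
        for tss in targets:
            by_chrom.setdefault(tss.chrom, []).append(tss.position)
        by_chrom = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in by_chrom.items()}
        for pair in queries:
            pos = by_chrom.get(pair.chrom)
            if pos is None:
                unmatched.append(pair)
                continue
            s, e = pair.span_start, pair.span_end
            inside = np.searchsorted(pos, s) < np.searchsorted(pos, e)
            if inside:
                values.append(0)
                continue
            i = int(np.searchsorted(pos, s))
            cands = []
            if i > 0:
                cands.append(s - int(pos[i - 1]))
            if i < pos.size:
                cands.append(int(pos[i]) - (e - 1))
            values.append(min(cands))
    return DistanceSample(np.array(values, dtype=np.int64)), unmatched


def associate_genes(
    annotated_peaks: Sequence[AnnotatedPeak],
    tss: Sequence[TSSRecord],
    max_dist: int = 100_000,
    duplicate_per_pair: bool = True,
):
    """Assign to each RE-ARE-containing peak the TSS closest to its center,
    GREAT-style, if within ``max_dist``.

    Returns a pandas DataFrame with one row per (peak, contained pair) when
    ``duplicate_per_pair`` (a peak holding two pairs lists its gene twice),
    else one row per peak.  ``distance`` is signed (TSS - peak center).
    Peaks with no TSS in range appear with feature_id 'unassigned'.
    The input ``annotated_peaks`` objects get their ``genes`` field filled.
    """
    import pandas as pd

    if not list(tss):
        raise ValueError("TSS list is empty")
    by_chrom: dict[str, list[TSSRecord]] = {}
    for t in tss:
        by_chrom.setdefault(t.chrom, []).append(t)
    pos_arrays = {}
    for chrom, recs in by_chrom.items():
        recs.sort(key=lambda t: t.position)
        pos_arrays[chrom] = (np.array([t.position for t in recs], dtype=np.int64), recs)

    rows = []
    for ann in annotated_peaks:
        if not ann.has_pair:
            continue
        center = ann.peak.center
        entry = pos_arrays.get(ann.peak.chrom)
        feature, signed = "unassigned", None
        if entry is not None:
            positions, recs = entry
            i = int(np.searchsorted(positions, center))
            best = None
            for j in (i - 1, i):
                if 0 <= j < positions.size:
                    d = abs(int(positions[j]) - center)
                    if best is None or d < best[0]:
                        best = (d, j)
            if best is not None and best[0] <= max_dist:
                rec = recs[best[1]]
                feature = rec.feature_id
                signed = rec.position - center
        ann.genes = [(feature, signed)] if feature != "unassigned" else []
        n_rows = len(ann.contained_pairs) if duplicate_per_pair else 1
        for k in range(n_rows):
            rows.append(
                {
                    "chrom": ann.peak.chrom,
                    "peak_start": ann.peak.start,
                    "peak_end": ann.peak.end,
                    "mark": ann.peak.mark,
                    "state": ann.peak.state,
                    "pair_index": k,
                    "feature_id": feature,
                    "distance": signed if signed is not None else pd.NA,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "peak_start", "peak_end", "mark", "state",
            "pair_index", "feature_id", "distance",
        ],
    )
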