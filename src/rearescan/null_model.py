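"""Randomized-genome null model for RE-ARE spacing.

The control for non-random spacing is a hypothetical genome carrying the
same number of RE and ARE motifs as observed in the real genome, with
positions drawn uniformly at random and counts allocated to chromosomes in
proportion to chromosome length.  The null is positional only: no
nucleotide sequence is realized, because only inter-motif distances are
consumed downstream.

All randomness flows from one integer seed through per-chromosome,
per-motif-role substreams, so placements are reproducible and independent
of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motif_engine import MotifHit
from .pair_finder import REAREPair, pair_nearest

__all__ = [
    "NullGenomeSpec",
    "allocate_counts",
    "place_random_motifs",
    "simulate_null_pairs",
]


@dataclass(frozen=True)
class NullGenomeSpec:
    """Everything needed to realize one random placement of RE and ARE
    motifs over a set of chromosome lengths."""

    chrom_lengths: dict[str, int]
    n_re: int
    n_are: int
    re_length: int
    are_length: int
    seed: int = 0
    non_overlap: bool = False

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("need at least one chromosome")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        if self.n_re < 0 or self.n_are < 0:
            raise ValueError("motif counts must be non-negative")


def allocate_counts(chrom_lengths: dict[str, int], total: int) -> dict[str, int]:
    """Allocate ``total`` motifs across chromosomes proportionally to length.

    Largest-remainder rounding guarantees the allocation sums exactly to
    ``total`` (the null must carry the same number of motifs as the real
    genome).  Remainder ties break by input order, deterministically.
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    names = list(chrom_lengths)
    lengths = np.array([chrom_lengths[n] for n in names], dtype=np.float64)
    genome = lengths.sum()
    if genome <= 0:
        raise ValueError("zero-length genome")
    quota = total * lengths / genome
    base = np.floor(quota).astype(np.int64)
    short = total - int(base.sum())
    # stable sort on descending remainder keeps input order within ties
    order = np.argsort(-(quota - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    return {n: int(c) for n, c in zip(names, base)}


def _substream(seed: int, role: int, chrom_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(role, chrom_index))
    )


def place_random_motifs(spec: NullGenomeSpec, motif: str) -> list[MotifHit]:
    """Place the allocated number of abstract motif hits uniformly at random.

    ``motif`` is ``'RE'`` or ``'ARE'``.  Starts are uniform on
    ``[0, L - motif_length]`` per chromosome; strand is '+' and no sequence
    is realized (positional null).  With ``spec.non_overlap``, disjoint
    placements are drawn directly by gap insertion (uniform over all
    non-overlapping configurations); infeasible requests raise.
    """
    role = {"RE": 0, "ARE": 1}.get(motif)
    if role is None:
        raise ValueError(f"motif must be 'RE' or 'ARE', got {motif!r}")
    n_total = spec.n_re if motif == "RE" else spec.n_are
    mlen = spec.re_length if motif == "RE" else spec.are_length
    alloc = allocate_counts(spec.chrom_lengths, n_total)
    hits: list[MotifHit] = []
    for ci, (chrom, length) in enumerate(spec.chrom_lengths.items()):
        count = alloc[chrom]
        if count == 0:
            continue
        hi = length - mlen
        if hi < 0:
            raise ValueError(f"chromosome {chrom!r} shorter than motif length {mlen}")
        if spec.non_overlap and count * mlen > length:
            raise RuntimeError(
                f"cannot place {count} non-overlapping motifs of length {mlen} "
                f"on chromosome {chrom!r} of length {length}"
            )
        rng = _substream(spec.seed, role, ci)
        if spec.non_overlap:
            # gap-insertion construction: sorted draws over the free space,
            # then shift each start by the room its predecessors occupy
            free = length - count * mlen
            cuts = np.sort(rng.integers(0, free + 1, size=count))
            starts = cuts + mlen * np.arange(count)
        else:
            starts = rng.integers(0, hi + 1, size=count)
        for s in np.sort(starts):
            hits.append(MotifHit(chrom, int(s), int(s) + mlen, "+", motif))
    return hits


def simulate_null_pairs(
    spec: NullGenomeSpec,
    max_window: int | None = None,
    steric_threshold: int = 7,
    one_to_one: bool = False,
) -> tuple[list[REAREPair], np.ndarray]:
    """Place RE and ARE hits independently and pair them exactly as the
    real analysis does.  Returns the pairs and their spacer values."""
    re_hits = place_random_motifs(spec, "RE")
    are_hits = place_random_motifs(spec, "ARE")
    pairs = pair_nearest(
        re_hits, are_hits, max_window=max_window,
        steric_threshold=steric_threshold, one_to_one=one_to_one,
    )
    spacers = np.array([p.spacer_n for p in pairs], dtype=np.int64)
    return pairs, spacers
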