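"""Self-contained synthetic test worlds: genomes with planted RE-ARE pairs,
decoy motifs, matching peak files, and TSS tables, all with machine-readable
ground truth.

The generator emulates the inputs of the real analysis (a reference genome,
ChIP-seq peak intervals, TSS annotations) at desk scale so every pipeline
stage can be exercised and verified without downloads.  Planted composite
elements are placed at non-overlapping loci with spacers drawn from a
configurable distribution; decoy single motifs are scattered uniformly;
peaks cover a chosen fraction of the planted pairs; TSS are set at chosen
distances from pairs.

By default the random background sequence is scrubbed of incidental motif
matches (both strands) so the truth table is exact; a "dirty background"
mode leaves them in for realism.  Everything derives from one seed:
identical config -> byte-identical output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import ChromosomeRecord, Peak, TSSRecord, write_fasta
from .motif_engine import IUPACMotif, compile_motif, scan_sequence
from .null_model import allocate_counts

__all__ = [
    "DEFAULT_RE_PATTERN",
    "DEFAULT_ARE_PATTERN",
    "default_motifs",
    "SyntheticWorldConfig",
    "SyntheticWorld",
    "realize_motif_instance",
    "generate_background",
    "plant_world",
]

log = logging.getLogger(__name__)

# Documented placeholder consensus strings.  The RE follows the canonical
# p53-family element (two RRRCWWGYYY decamers); the ARE is the classical
# NRF2 core.  To reproduce published genome-wide totals, supply the exact
# strings from the original study's supplementary material as configuration.
DEFAULT_RE_PATTERN = "RRRCWWGYYYRRRCWWGYYY"
DEFAULT_ARE_PATTERN = "TGACNNNGC"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def default_motifs() -> tuple[IUPACMotif, IUPACMotif]:
    return (
        compile_motif("RE", DEFAULT_RE_PATTERN),
        compile_motif("ARE", DEFAULT_ARE_PATTERN),
    )


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Study conditions for one synthetic world.

    Defaults mirror the planted-signal benchmark this package is validated
    on: a 5-Mb chromosome at human-like GC content carrying 500 composite
    elements with spacers ~ Normal(100, 10) truncated at 0, half of them
    covered by peaks padded 100 bp beyond the pair span.

    ``spacer_distribution`` / ``tss_distance_distribution`` take the forms
    ("fixed", k), ("uniform", a, b) or ("normal", mu, sigma); normal draws
    are truncated at 0 by redrawing.
    """

    chrom_lengths: dict[str, int] = dc_field(
        default_factory=lambda: {"chrS1": 5_000_000}
    )
    gc_content: float = 0.41
    n_planted_pairs: int = 500
    spacer_distribution: tuple = ("normal", 100.0, 10.0)
    n_decoy_re: int = 0
    n_decoy_are: int = 0
    peak_coverage: float = 0.5
    peak_padding: int = 100
    n_background_peaks: int = 0
    n_tss: int = 50
    tss_distance_distribution: tuple = ("uniform", 1_000, 50_000)
    min_locus_gap: int = 2_000
    clean_background: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if not 0.0 <= self.peak_coverage <= 1.0:
            raise ValueError("peak_coverage must be in [0, 1]")


def _draw_distances(dist: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist[0]
    if kind == "fixed":
        return np.full(n, int(dist[1]), dtype=np.int64)
    if kind == "uniform":
        return rng.integers(int(dist[1]), int(dist[2]) + 1, size=n)
    if kind == "normal":
        mu, sigma = float(dist[1]), float(dist[2])
        out = np.rint(rng.normal(mu, sigma, size=n)).astype(np.int64)
        while np.any(out < 0):  # truncate at 0 by redrawing
            bad = out < 0
            out[bad] = np.rint(rng.normal(mu, sigma, size=int(bad.sum()))).astype(np.int64)
        return out
    raise ValueError(f"unknown distribution kind {kind!r}")


def realize_motif_instance(motif: IUPACMotif, rng: np.random.Generator) -> str:
    """A concrete sequence matching the motif: each position drawn
    uniformly from that position's allowed bases."""
    from .motif_engine import IUPAC_CODES

    return "".join(
        sorted(IUPAC_CODES[code])[rng.integers(0, len(IUPAC_CODES[code]))]
        for code in motif.pattern
    )


def generate_background(
    length: int,
    gc_content: float,
    rng: np.random.Generator,
    forbidden_motifs: tuple[IUPACMotif, ...] = (),
    max_rounds: int = 12,
) -> str:
    """Random sequence with expected GC content, optionally scrubbed of any
    window matching a forbidden motif on either strand.

    Scrubbing redraws matching windows and rescans, up to ``max_rounds``;
    if residual matches remain, a warning reports how many.
    """
    if length < 0:
        raise ValueError("length must be non-negative")
    if length == 0:
        return ""
    for m in forbidden_motifs:
        if set(m.pattern) == {"N"}:
            raise ValueError(f"motif {m.name!r} matches everything; cannot exclude")
    at, gc = (1.0 - gc_content) / 2.0, gc_content / 2.0
    probs = np.array([at, gc, gc, at])  # A C G T
    codes = rng.choice(4, size=length, p=probs).astype(np.uint8)
    if not forbidden_motifs:
        return _BASES[codes].tobytes().decode("ascii")
    for _ in range(max_rounds):
        seq = _BASES[codes].tobytes().decode("ascii")
        record = ChromosomeRecord("tmp", seq)
        windows = []
        for m in forbidden_motifs:
            for h in scan_sequence(m, record, strands="both"):
                windows.append((h.start, h.end))
        if not windows:
            return seq
        for s, e in windows:
            codes[s:e] = rng.choice(4, size=e - s, p=probs).astype(np.uint8)
    seq = _BASES[codes].tobytes().decode("ascii")
    record = ChromosomeRecord("tmp", seq)
    residual = sum(
        len(scan_sequence(m, record, strands="both")) for m in forbidden_motifs
    )
    if residual:
        log.warning(
            "background scrub hit retry cap; %d residual motif matches remain", residual
        )
    return seq


def _scrub_junctions(
    seq: np.ndarray,
    motifs: tuple[IUPACMotif, ...],
    motif_intervals: list[tuple[int, int]],
    gc_content: float,
    rng: np.random.Generator,
    max_rounds: int = 8,
) -> None:
    """Redraw background bases inside spurious motif matches in-place.

    A match whose (start, end) equals a planted motif interval is
    legitimate; any other match gets its non-planted bases redrawn.
    Matches lying entirely within planted bases cannot be fixed and are
    reported with a warning (they are vanishingly rare for realistic
    motifs).
    """
    at, gc = (1.0 - gc_content) / 2.0, gc_content / 2.0
    probs = np.array([at, gc, gc, at])
    planted = set(motif_intervals)
    protected = np.zeros(seq.size, dtype=bool)
    for s, e in motif_intervals:
        protected[s:e] = True
    for _ in range(max_rounds):
        record = ChromosomeRecord("tmp", seq.tobytes().decode("ascii"))
        spurious = [
            (h.start, h.end)
            for m in motifs
            for h in scan_sequence(m, record, strands="both")
            if (h.start, h.end) not in planted
        ]
        if not spurious:
            return
        fixed_any = False
        for s, e in spurious:
            bg = ~protected[s:e]
            if bg.any():
                idx = np.arange(s, e)[bg]
                seq[idx] = _BASES[rng.choice(4, size=idx.size, p=probs)]
                fixed_any = True
        if not fixed_any:
            break
    record = ChromosomeRecord("tmp", seq.tobytes().decode("ascii"))
    residual = [
        (h.start, h.end)
        for m in motifs
        for h in scan_sequence(m, record, strands="both")
        if (h.start, h.end) not in planted
    ]
    if residual:
        log.warning("junction scrub left %d spurious motif matches", len(residual))


@dataclass
class SyntheticWorld:
    """A realized world: genome, peaks, TSS, and the exact truth table."""

    config: SyntheticWorldConfig
    genome: list[ChromosomeRecord]
    peaks: list[Peak]
    tss: list[TSSRecord]
    truth: pd.DataFrame  # kind, chrom, start, end, name, spacer, distance

    @property
    def planted_spacers(self) -> np.ndarray:
        rows = self.truth[self.truth["kind"] == "planted_pair"]
        return rows["spacer"].to_numpy(dtype=np.int64)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit genome.fa, peaks.bed, tss.tsv, truth.tsv and config.txt.

        Outputs are deterministic functions of the config (byte-identical
        across runs with the same config and seed).
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "peaks": outdir / "peaks.bed",
            "tss": outdir / "tss.tsv",
            "truth": outdir / "truth.tsv",
            "config": outdir / "config.txt",
        }
        write_fasta(self.genome, paths["genome"])
        with open(paths["peaks"], "w") as fh:
            for p in sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end)):
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.mark}\t{p.state}\n")
        with open(paths["tss"], "w") as fh:
            for t in sorted(self.tss, key=lambda t: (t.chrom, t.position)):
                fh.write(f"{t.feature_id}\t{t.chrom}\t{t.position}\t{t.strand}\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        with open(paths["config"], "w") as fh:
            for key, value in vars(self.config).items():
                fh.write(f"{key} = {value!r}\n")
        return paths


def plant_world(
    config: SyntheticWorldConfig,
    re_motif: IUPACMotif | None = None,
    are_motif: IUPACMotif | None = None,
) -> SyntheticWorld:
    """Generate a genome with planted RE-ARE pairs, decoys, peaks and TSS.

    Planted pairs occupy non-overlapping loci separated by at least
    ``min_locus_gap`` so nearest-neighbor pairing recovers each planted
    partner rather than a neighbor's motif.  RE/ARE order within a locus is
    randomized 50/50 (composite elements occur in both orientations).
    Raises ``RuntimeError`` when the requested elements cannot be packed.
    """
    if re_motif is None or are_motif is None:
        d_re, d_are = default_motifs()
        re_motif = re_motif or d_re
        are_motif = are_motif or d_are
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed))
    forbidden = (re_motif, are_motif) if config.clean_background else ()

    pair_alloc = allocate_counts(config.chrom_lengths, config.n_planted_pairs)
    decoy_re_alloc = allocate_counts(config.chrom_lengths, config.n_decoy_re)
    decoy_are_alloc = allocate_counts(config.chrom_lengths, config.n_decoy_are)

    genome: list[ChromosomeRecord] = []
    truth_rows: list[dict] = []
    pair_spans: list[tuple[str, int, int, int]] = []  # chrom, start, end, spacer

    for chrom, length in config.chrom_lengths.items():
        n_pairs = pair_alloc[chrom]
        spacers = _draw_distances(config.spacer_distribution, n_pairs, rng)
        locus_lens = re_motif.length + are_motif.length + spacers
        occupied = int(locus_lens.sum()) + config.min_locus_gap * max(n_pairs - 1, 0)
        free = length - occupied
        if free < 0:
            raise RuntimeError(
                f"cannot pack {n_pairs} pair loci into chromosome {chrom!r}: "
                f"need {occupied} bp, have {length}"
            )
        seq = np.frombuffer(
            generate_background(length, config.gc_content, rng, forbidden).encode(),
            dtype=np.uint8,
        ).copy()
        motif_intervals: list[tuple[int, int]] = []  # exact planted motif coords

        cuts = np.sort(rng.integers(0, free + 1, size=n_pairs))
        starts = cuts + np.concatenate(([0], np.cumsum(locus_lens[:-1])))
        starts += config.min_locus_gap * np.arange(n_pairs)
        locus_intervals: list[tuple[int, int]] = []
        for i in range(n_pairs):
            s = int(starts[i])
            spacer = int(spacers[i])
            re_seq = realize_motif_instance(re_motif, rng)
            are_seq = realize_motif_instance(are_motif, rng)
            re_first = bool(rng.integers(0, 2))
            first_seq, second_seq = (re_seq, are_seq) if re_first else (are_seq, re_seq)
            mid = s + len(first_seq) + spacer
            end = mid + len(second_seq)
            seq[s : s + len(first_seq)] = np.frombuffer(first_seq.encode(), dtype=np.uint8)
            seq[mid:end] = np.frombuffer(second_seq.encode(), dtype=np.uint8)
            re_iv = (s, s + len(re_seq)) if re_first else (mid, end)
            are_iv = (mid, end) if re_first else (s, s + len(are_seq))
            truth_rows.append(
                {
                    "kind": "planted_pair", "chrom": chrom, "start": s, "end": end,
                    "name": f"pair_{chrom}_{i}", "spacer": spacer, "distance": pd.NA,
                    "re_start": re_iv[0], "re_end": re_iv[1],
                    "are_start": are_iv[0], "are_end": are_iv[1],
                }
            )
            pair_spans.append((chrom, s, end, spacer))
            locus_intervals.append((s, end))
            motif_intervals.extend([re_iv, are_iv])

        def place_decoys(count: int, motif: IUPACMotif, kind: str) -> None:
            placed = 0
            attempts = 0
            while placed < count and attempts < 200 * max(count, 1):
                attempts += 1
                s = int(rng.integers(0, length - motif.length + 1))
                e = s + motif.length
                if any(s < ie and iv_s < e for iv_s, ie in locus_intervals):
                    continue
                inst = realize_motif_instance(motif, rng)
                seq[s:e] = np.frombuffer(inst.encode(), dtype=np.uint8)
                locus_intervals.append((s, e))
                motif_intervals.append((s, e))
                truth_rows.append(
                    {
                        "kind": kind, "chrom": chrom, "start": s, "end": e,
                        "name": f"{kind}_{chrom}_{placed}", "spacer": pd.NA,
                        "distance": pd.NA, "re_start": pd.NA, "re_end": pd.NA,
                        "are_start": pd.NA, "are_end": pd.NA,
                    }
                )
                placed += 1
            if placed < count:
                raise RuntimeError(
                    f"could not place {count} {kind} decoys on {chrom!r} "
                    f"without overlapping planted loci"
                )

        place_decoys(decoy_re_alloc[chrom], re_motif, "decoy_re")
        place_decoys(decoy_are_alloc[chrom], are_motif, "decoy_are")

        if config.clean_background:
            # Planting can create incidental matches that straddle a motif
            # boundary; redraw only the background bases of such windows so
            # the truth table stays exact.
            _scrub_junctions(
                seq, (re_motif, are_motif), motif_intervals, config.gc_content, rng
            )
        genome.append(ChromosomeRecord(chrom, seq.tobytes().decode("ascii")))

    # Peaks over a random subset of planted pairs, plus optional peaks over
    # empty background (these exercise the "no pair under peak" branch).
    n_covered = int(round(config.peak_coverage * len(pair_spans)))
    covered_idx = rng.choice(len(pair_spans), size=n_covered, replace=False) if pair_spans else []
    peaks: list[Peak] = []
    covered_pairs: list[tuple[str, int, int, int]] = []
    for i in sorted(int(j) for j in covered_idx):
        chrom, s, e, spacer = pair_spans[i]
        lo = max(s - config.peak_padding, 0)
        hi = min(e + config.peak_padding, config.chrom_lengths[chrom])
        peaks.append(Peak(chrom, lo, hi, mark="H3K27ac", state="synthetic"))
        covered_pairs.append(pair_spans[i])
        truth_rows.append(
            {
                "kind": "peak", "chrom": chrom, "start": lo, "end": hi,
                "name": f"peak_over_pair_{i}", "spacer": pd.NA, "distance": pd.NA,
                "re_start": pd.NA, "re_end": pd.NA, "are_start": pd.NA, "are_end": pd.NA,
            }
        )
    chroms = list(config.chrom_lengths)
    for k in range(config.n_background_peaks):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        width = 300 + int(rng.integers(0, 700))
        s = int(rng.integers(0, config.chrom_lengths[chrom] - width))
        peaks.append(Peak(chrom, s, s + width, mark="H3K27ac", state="synthetic"))
        truth_rows.append(
            {
                "kind": "background_peak", "chrom": chrom, "start": s, "end": s + width,
                "name": f"bg_peak_{k}", "spacer": pd.NA, "distance": pd.NA,
                "re_start": pd.NA, "re_end": pd.NA, "are_start": pd.NA, "are_end": pd.NA,
            }
        )

    # TSS at configured distances from planted pair spans (cycled), placed
    # up- or downstream at random.
    tss: list[TSSRecord] = []
    if config.n_tss and pair_spans:
        dists = _draw_distances(config.tss_distance_distribution, config.n_tss, rng)
        for k in range(config.n_tss):
            chrom, s, e, _ = pair_spans[k % len(pair_spans)]
            d = int(dists[k])
            upstream = bool(rng.integers(0, 2))
            pos = s - d if upstream else (e - 1) + d
            pos = min(max(pos, 0), config.chrom_lengths[chrom] - 1)
            strand = "+" if rng.integers(0, 2) else "-"
            tss.append(TSSRecord(f"gene{k:04d}", chrom, pos, strand, "gene"))
            truth_rows.append(
                {
                    "kind": "tss", "chrom": chrom, "start": pos, "end": pos + 1,
                    "name": f"gene{k:04d}", "spacer": pd.NA, "distance": d,
                    "re_start": pd.NA, "re_end": pd.NA, "are_start": pd.NA, "are_end": pd.NA,
                }
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "kind", "chrom", "start", "end", "name", "spacer", "distance",
            "re_start", "re_end", "are_start", "are_end",
        ],
    )
    return SyntheticWorld(config=config, genome=genome, peaks=peaks, tss=tss, truth=truth)
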