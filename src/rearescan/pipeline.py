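"""End-to-end orchestration: scan -> pair -> null -> stats -> annotate ->
associate -> export, with a flat key-value config and deterministic outputs.

Every constant of the analysis lives in :class:`AnalysisConfig` — the
steric threshold (7 bp), the enrichment window (2000 bp), the peak
center-window half-width (300 bp), and the gene-association limit
(100 kb) — never as a literal buried in a stage.  All randomness flows from
the single config seed, and a rerun with the same config produces
byte-identical outputs.
"""

from __future__ import annotations

import ast
import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np

from . import __version__
from .chromatin_annotation import (
    associate_genes,
    pairs_under_peaks,
    peak_set_algebra,
    percentage_with_pairs,
)
from .genome_io import (
    read_bed,
    read_fasta,
    read_motif_file,
    read_tss_table,
    write_fasta,
    write_tables,
)
from .motif_engine import compile_motif, scan_genome
from .null_model import NullGenomeSpec, simulate_null_pairs
from .pair_finder import export_pair_sequences, flag_steric, pair_nearest
from .spacing_stats import compare_real_vs_null
from .chromatin_annotation import distance_to_nearest

__all__ = ["AnalysisConfig", "run_full_analysis", "StageError"]

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {detail}")


@dataclass(frozen=True)
class AnalysisConfig:
    genome_path: str = ""
    motif_path: str = ""
    # each entry: (path, mark, state)
    peak_files: tuple[tuple[str, str, str], ...] = ()
    # each entry: (path, source) with source in {gene, mirna}
    tss_files: tuple[tuple[str, str], ...] = ()
    steric_threshold: int = 7
    enrichment_window: int = 2000
    gene_max_dist: int = 100_000
    containment_mode: str = "reported_range"
    peak_half_width: int = 300
    max_pair_window: int | None = None
    pair_one_to_one: bool = False
    export_flank: int = 0
    seed: int = 0
    output_dir: str = "rearescan_out"

    def to_text(self) -> str:
        lines = []
        for f in fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Parse a flat ``key = value`` config file (values in Python
        literal syntax, as written by :meth:`to_text`)."""
        known = {f.name for f in fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                kwargs[key] = ast.literal_eval(value.strip())
        return cls(**kwargs)


def _write_lines(path: Path, lines: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def run_full_analysis(config: AnalysisConfig) -> Path:
    """Run the full analysis and write all outputs under the config's
    output directory.  Returns that directory.

    Output files, in stage order: per-motif hit BEDs and a count summary;
    the pair table; the null pair table; the spacer comparison report (KS
    and window fractions); the TSS-distance comparison report; annotated
    peaks with per-state percentages; the unique/common peak-set report
    when two cell states are given; the gene-assignment table; pair
    sequences as FASTA; and a run log recording version, seed, and every
    parameter.  A stage failure aborts with the stage name.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_log: list[str] = [
        f"rearescan version {__version__}",
        f"seed {config.seed}",
        "parameters:",
    ] + ["  " + line for line in config.to_text().strip().splitlines()]

    def fail(stage: str, exc: Exception):
        raise StageError(stage, str(exc)) from exc

    # -- scan ---------------------------------------------------------------
    try:
        genome = read_fasta(config.genome_path)
        motif_defs = read_motif_file(config.motif_path)
        motifs = [compile_motif(name, pat) for name, pat in motif_defs]
        names = [m.name for m in motifs]
        if "RE" not in names or "ARE" not in names:
            raise ValueError("motif file must define motifs named 'RE' and 'ARE'")
        hits, counts = scan_genome(motifs, genome, strands="both")
    except StageError:
        raise
    except Exception as exc:
        fail("scan", exc)
    for name, hit_list in hits.items():
        write_tables(hit_list, outdir / f"hits_{name}.bed", fmt="bed")
    counts.to_csv(outdir / "hit_counts.tsv", sep="\t")
    run_log.append(f"scan: {', '.join(f'{n}={len(h)}' for n, h in hits.items())}")

    # -- pair ---------------------------------------------------------------
    try:
        pairs = pair_nearest(
            hits["RE"], hits["ARE"],
            max_window=config.max_pair_window,
            steric_threshold=config.steric_threshold,
            one_to_one=config.pair_one_to_one,
        )
        feasible, infeasible = flag_steric(pairs, config.steric_threshold)
    except StageError:
        raise
    except Exception as exc:
        fail("pair", exc)
    write_tables(pairs, outdir / "pairs.tsv", fmt="tsv")
    write_tables(pairs, outdir / "pairs.bed", fmt="bed")
    run_log.append(
        f"pair: {len(pairs)} pairs, steric feasible {len(feasible)}, "
        f"infeasible {len(infeasible)} (threshold {config.steric_threshold})"
    )

    # -- null ---------------------------------------------------------------
    try:
        spec = NullGenomeSpec(
            chrom_lengths={c.name: c.length for c in genome},
            n_re=len(hits["RE"]),
            n_are=len(hits["ARE"]),
            re_length=next(m.length for m in motifs if m.name == "RE"),
            are_length=next(m.length for m in motifs if m.name == "ARE"),
            seed=config.seed,
        )
        null_pairs, null_spacers = simulate_null_pairs(
            spec,
            max_window=config.max_pair_window,
            steric_threshold=config.steric_threshold,
            one_to_one=config.pair_one_to_one,
        )
    except StageError:
        raise
    except Exception as exc:
        fail("null", exc)
    write_tables(null_pairs, outdir / "null_pairs.tsv", fmt="tsv")
    run_log.append(f"null: {len(null_pairs)} pairs ({spec.n_re} RE, {spec.n_are} ARE)")

    # -- stats --------------------------------------------------------------
    try:
        real_spacers = np.array([abs(p.spacer_n) for p in pairs])
        report = compare_real_vs_null(
            real_spacers, np.abs(null_spacers), window=config.enrichment_window
        )
    except StageError:
        raise
    except Exception as exc:
        fail("stats", exc)
    _write_lines(outdir / "spacer_comparison.tsv", report.to_lines())
    report.histogram.to_csv(outdir / "spacer_histogram.tsv", sep="\t", index=False)
    run_log.append(
        f"stats: KS D={report.ks.d_stat:.4f} p={report.ks.display_p()} "
        f"window diff={report.fraction_difference:.4f}"
    )

    # -- TSS distances ------------------------------------------------------
    tss_records = []
    for path, source in config.tss_files:
        try:
            tss_records.extend(read_tss_table(path, source=source))
        except Exception as exc:
            fail("tss_distance", exc)
    if tss_records and pairs and null_pairs:
        try:
            real_d, _ = distance_to_nearest(tss_records, pairs)
            null_d, _ = distance_to_nearest(tss_records, null_pairs)
            tss_report = compare_real_vs_null(
                real_d, null_d, window=config.enrichment_window
            )
        except StageError:
            raise
        except Exception as exc:
            fail("tss_distance", exc)
        _write_lines(outdir / "tss_distance_comparison.tsv", tss_report.to_lines())
        run_log.append(
            f"tss_distance: KS D={tss_report.ks.d_stat:.4f} "
            f"p={tss_report.ks.display_p()}"
        )

    # -- annotate -----------------------------------------------------------
    annotated_by_state: dict[str, list] = {}
    all_hits = hits["RE"] + hits["ARE"]
    pct_lines: list[str] = []
    for path, mark, state in config.peak_files:
        try:
            peaks = read_bed(path, mark=mark, state=state)
            annotated, ann_counts = pairs_under_peaks(
                pairs, peaks,
                mode=config.containment_mode,
                half_width=config.peak_half_width,
                hits=all_hits,
            )
            pct = percentage_with_pairs(annotated, peaks)
        except StageError:
            raise
        except Exception as exc:
            fail("annotate", exc)
        annotated_by_state[state] = annotated
        rows = []
        for ann in annotated:
            rows.append(
                f"{ann.peak.chrom}\t{ann.peak.start}\t{ann.peak.end}\t{ann.peak.mark}"
                f"\t{ann.peak.state}\t{len(ann.contained_pairs)}"
                f"\t{len(ann.single_motif_hits)}"
            )
        _write_lines(
            outdir / f"annotated_peaks_{state}.tsv",
            ["#chrom\tstart\tend\tmark\tstate\tn_pairs\tn_single_hits"] + rows
            if rows else ["#chrom\tstart\tend\tmark\tstate\tn_pairs\tn_single_hits"],
        )
        for (m, s), value in sorted(pct.items()):
            pct_lines.append(f"{m}\t{s}\t{value:.4f}")
        run_log.append(
            f"annotate[{state}]: {ann_counts['peaks_with_pairs']} of "
            f"{ann_counts['peaks_total']} peaks contain pairs; "
            f"{ann_counts['peaks_single_motif_only']} single-motif-only"
        )
    if config.peak_files:
        _write_lines(
            outdir / "peak_percentages.tsv",
            ["#mark\tstate\tpct_peaks_with_pairs"] + pct_lines,
        )

    # -- peak set algebra (exactly two states) ------------------------------
    states = list(annotated_by_state)
    if len(states) == 2:
        try:
            part = peak_set_algebra(
                annotated_by_state[states[0]], annotated_by_state[states[1]]
            )
        except Exception as exc:
            fail("peak_sets", exc)
        c = part.counts()
        _write_lines(
            outdir / "peak_sets.tsv",
            [
                f"#state_a\t{states[0]}",
                f"#state_b\t{states[1]}",
                f"unique_a\t{c['unique_a']}",
                f"unique_b\t{c['unique_b']}",
                f"common_a\t{c['common_a']}",
                f"common_b\t{c['common_b']}",
            ],
        )
        run_log.append(f"peak_sets: {c}")

    # -- associate genes ----------------------------------------------------
    if tss_records and annotated_by_state:
        for state, annotated in annotated_by_state.items():
            try:
                table = associate_genes(
                    annotated, tss_records, max_dist=config.gene_max_dist
                )
            except Exception as exc:
                fail("associate", exc)
            table.to_csv(outdir / f"gene_assignments_{state}.tsv", sep="\t", index=False)
            run_log.append(f"associate[{state}]: {len(table)} assignment rows")

    # -- export pair sequences ----------------------------------------------
    try:
        seqs = export_pair_sequences(pairs, genome, flank=config.export_flank)
    except Exception as exc:
        fail("export", exc)
    write_fasta(seqs, outdir / "pair_sequences.fasta")
    run_log.append(f"export: {len(seqs)} pair sequences (flank {config.export_flank})")

    with open(outdir / "config.resolved.txt", "w") as fh:
        fh.write(config.to_text())
    _write_lines(outdir / "run_log.txt", run_log)
    return outdir
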