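# rearescan

Genome-wide co-occurrence analysis of **p63 response elements (REs)** and
**NRF2 antioxidant response elements (AREs)** — composite "RE-ARE"
regulatory elements through which the two transcription factors can act
together on the same enhancer or promoter.

The package is for regulatory genomicists who have a genome FASTA, IUPAC
consensus strings for two binding sites, and (optionally) ChIP-seq peak
intervals and TSS tables, and who want to know:

1. **Are the two motifs non-randomly close?**  Every RE is joined to its
   nearest ARE by inner-gap ("spacer") distance, and the spacer
   distribution is compared against a randomized genome carrying the same
   number of motifs placed uniformly, allocated to chromosomes by length.
   The comparison reports the fraction of spacers within a window
   (default 2000 bp) and a two-sample Kolmogorov–Smirnov test with exact
   D over the merged support and the asymptotic p-value
   `Q((sqrt(ne)+0.12+0.11/sqrt(ne))·D)`, `ne = n1·n2/(n1+n2)`.
2. **Which composite elements can actually bind both factors?**  A steric
   filter keeps pairs with spacer > 7 bp (the minimum compatible with
   simultaneous occupancy by the p63 tetramer and the NRF2–small-MAF
   dimer on nucleosomal DNA).
3. **Which elements are active, and near which genes?**  Pairs are placed
   under ChIP-seq peaks (both motifs fully contained), per-state
   percentages and unique/common peak sets between two cell states are
   computed, and each RE-ARE-containing peak is associated with the
   closest TSS within 100 kb, GREAT-style, with genes listed once per
   contained pair.

A synthetic-data module generates complete test worlds — genomes with
planted RE-ARE pairs at controlled spacers, decoy motifs, matching peak
and TSS files, and an exact truth table — so the entire pipeline is
exercised and validated without downloading anything.

All coordinates are 0-based, half-open (BED convention) everywhere.

## Worked example

Generate a synthetic world (1-Mb chromosome, 100 planted pairs with
spacers ~ Normal(100, 10), half covered by peaks) and run the full
pipeline on it:

```bash
rearescan simulate --out demo --seed 7 --chrom-length 1000000 \
    --n-pairs 100 --n-tss 20
rearescan run-all --config demo/analysis_config.txt
cat demo/analysis/spacer_comparison.tsv
```

```
n_real	200
n_null	200
window_bp	2000
fraction_real_within_window	1.000000
fraction_null_within_window	0.320000
fraction_difference	0.680000
ks_d	0.985000
ks_p	6.39663e-87
ks_p_display	< 2.2e-16
```

Reading this: all 200 experimental RE-ARE pairs sit within the 2000-bp
window (the planted spacers are ~100 bp), while only 32% of pairs in the
count-matched uniform null do; the KS test rejects identity of the two
spacer distributions at D = 0.985 (p far below the 2.2e-16 display
floor).  There are 200 pairs rather than 100 because the default RE
consensus is its own reverse complement as a pattern, so each planted
instance is reported on both strands (collapsible with
`collapse_palindromes`).

The run directory also contains the per-motif hit BEDs and count table,
the pair table (coordinates, strands, spacer, orientation, steric flag),
the null pair table, the TSS-distance comparison, annotated peaks with
the percentage of peaks containing a pair, the gene-assignment table
(e.g. `gene0003` at signed distance −1635 bp from its peak center,
listed once per contained pair), pair sequences as FASTA for motif
discovery tools, and a run log with the version, seed, and every
parameter.

Each stage is also available as its own subcommand (`scan`, `pair`,
`nullsim`, `stats`, `annotate`, `associate`, `export-seqs`); chaining
them reproduces `run-all`.  To analyse a real genome, point
`--genome`/`--motifs` at your FASTA and a motif file of
`name<TAB>IUPAC_pattern` lines (the shipped RE/ARE strings are documented
placeholders — supply the consensus strings you mean to study), plus
peak BEDs and TSS tables as available.

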