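# satmap — transcript mapping saturation test for de novo RNA-Seq assembly

How many gigabases of paired-end RNA-Seq reads do you need before a de novo
transcriptome assembly stops gaining new gene transcripts?  For non-model
organisms without a reference genome there is rarely a principled answer;
common practice is to borrow ballpark depths from other species.  `satmap`
implements the **transcript mapping saturation test**, an empirical
procedure for answering the question from one deeply sequenced library:

1. **Clean** raw 2×100 nt read pairs: symmetric end-trimming at phred
   Q ≥ 20, removal of reads < 30 bp, removal of reads containing `N`;
   survivors are classified into *paired* reads (both mates survive) and
   *orphans* (one mate survives).  Only clean paired reads feed assembly.
2. **Partition** the randomized clean paired pool into nested base-count
   quanta (e.g. 1, 3, 5, 8, 10, 13, 16 Gb).
3. **Assemble** each quantum across a k-mer sweep and compute the
   transcript **N50** per (datasize, k) cell
   (N50 = length of the shortest transcript such that transcripts of equal
   or greater length sum to ≥ 50% of the total assembly length).
   The N50-vs-k series typically rises and falls; the k at its interior
   maximum is the **optimized k-mer**, and the N50 there the
   **optimized N50**.  Shallow datasizes whose maximum sits on the k-range
   boundary are flagged *non-peaked* and carry no optimum.
4. **Map** each sub-assembly's transcripts against the full-depth assembly
   (BLAST-like top hit per query, e ≤ 10⁻⁵).  The fraction of
   full-transcriptome transcripts hit is that cell's transcript
   representation; arranged as a datasize × k matrix with coverage
   brackets (<80, 80–85, 85–90, 90–95, 95–100 %), it shows where
   representation saturates.
5. **Recommend** a sequencing depth: the smallest datasize whose optimized
   cell is within 1 point of the target coverage (low end), up to the
   smallest datasize that reaches the target outright and beyond which the
   per-base optimized-N50 gain drops below half its preceding rate
   (high end).

The package also provides the validation screens used to qualify the full
assembly — an ORF query-coverage screen (≥ 70% coverage of known
complete-ORF cDNAs), core-eukaryotic-gene completeness by six-frame
translated alignment (e ≤ 10⁻¹⁰), and a transcript-to-genome-scaffold
coverage histogram — plus a synthetic-data module (log-normal transcript
lengths and expression spanning a configurable dynamic range,
tissue-restricted transcripts, 2×100 nt pairs from ~200 bp fragments with
positional quality decay and substitution errors) so the entire pipeline
runs and is testable without downloading any sequencing data.

## Worked example

Run the whole pipeline on a synthetic library:

```bash
satmap run --outdir demo --seed 7
```

which prints (abridged; numbers from this exact command):

```
satmap 1.0.0 run report
========================================

Read cleaning
  Raw reads: 46,000 reads (100.00%), 4,600,000 nt (100.00%)
  Clean reads: 45,552 reads (99.03%), 4,552,736 nt (98.97%)
  Paired reads: 45,110 reads (98.07%), 4,508,563 nt (98.01%)
  Orphan reads (single end): 442 reads (0.96%), 44,173 nt (0.96%)

K-mer sweeps (per datasize)
  1,000,000 nt: no optimum (N50 maximal at boundary k=21, 281 bp)
  2,000,000 nt: no optimum (N50 maximal at boundary k=21, 275 bp)
  4,000,000 nt: no optimum (N50 maximal at boundary k=29, 269 bp)

Saturation matrix (pct of full transcriptome mapped)
  k       1,000,000     2,000,000     4,000,000
  21          47.99         68.90         90.62
  25          47.99         68.36         96.25
  29          47.45         68.36        100.00

Depth recommendation
  matrix needs >= 3 datasizes with peaked sweeps
```

Read the matrix column-wise: at every k, representation of the full-depth
transcriptome rises with read amount — a 1 Mb sub-assembly recovers ~48%
of the transcripts the 4 Mb assembly contains, a 2 Mb sub-assembly ~68%.
The full assembly's own cell is exactly 100% by construction.  Synthetic
transcriptomes are repeat-free, so the N50-vs-k series here declines
almost monotonically and the sweeps are non-peaked — hence no depth
recommendation is issued for this toy run; on real tissue libraries the
N50 series is bell-shaped and the optimized cells drive the
recommendation.

Library-level use mirrors the CLI: `satmap.readqc.clean_library`,
`satmap.readqc.partition_quanta`, `satmap.assembler.sweep_kmers`,
`satmap.metrics.find_optimized_kmer`, `satmap.saturation.build_matrix`,
`satmap.saturation.recommend_depth`, and
`satmap.simdata.synthetic_saturation_study` for the end-to-end synthetic
run.

The package ships the published rubber-tree (*Hevea brasiliensis*) N50
sweep tables in `satmap.hevea` as reference fixtures; for example the
16 Gb bark series peaks at k = 73 with an optimized N50 of 2,068 bp:

```python
>>> from satmap import hevea, find_optimized_kmer
>>> find_optimized_kmer(hevea.series(hevea.BARK_N50, 16))
(73, 2068, True)
```

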