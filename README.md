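# strlnr

Targeted short-tandem-repeat (STR) genotyping from noisy long reads, using
paired-seed multisampling and length–number–rank (LNR) statistics, together
with a nanopore-style read simulator for controlled evaluation.

## The problem

STR loci — tracts of a 1–6 bp motif repeated in tandem — are the workhorse
markers of forensic identification, paternity testing, and repeat-expansion
disease diagnostics. Long-read (nanopore) sequencing reads span entire STR
tracts plus unique flanks, but its high indel-rich error rate makes naive
length measurement unreliable: a single spurious 1-bp indel inside the tract
shifts the apparent allele length. `strlnr` genotypes *target* STR loci
(given as intervals with motif and reference repeat count) directly from
FASTQ reads, without genome-wide alignment.

## The method

For a locus with tract boundaries `P_start`/`P_end` on the reference and an
extension step size `d` (default 10 bp), round `i = 1..N` (default `N = 10`)
uses the paired seeds

```
left_i  = ref[P_start − d·i, P_start)      right_i = ref[P_end, P_end + d·i)
```

1. **dataset1 (exact-seed harvest).** Reads containing both seeds of round
   `i` exactly (either orientation) contribute the length of the segment
   enclosed between the seed matches. Per round, distinct lengths are
   tallied, sorted by descending supported-read number, and ranked 1..K —
   the LNR summary.
2. **dataset2 (alignment spans).** Each harvested segment (with its matched
   seeds) is locally aligned against the tract ±500 bp of reference; hits
   with ≥3 substitutions are discarded, and subject-side span lengths are
   summarized as a second LNR table.
3. **Rank intersection.** A dataset1 length survives when its minimum rank
   difference to any dataset2 entry is <3 — alignment evidence bounds how
   many length classes are credible. Per round, the top length is kept alone
   if its support exceeds 3× the runner-up's, otherwise the top two are kept.
4. **Mode combination.** The most frequent allele set across the N rounds
   wins; the call is homozygous when the pooled support ratio of its two top
   alleles is ≥3, heterozygous otherwise. A secondary correction demotes a
   minor allele supported an order of magnitude (≥10×) below the major one.
   Allele lengths are converted to repeat counts by rounding
   `(length − ref_tract)/|motif|` onto the motif ladder (off-ladder lengths
   are flagged).

The simulator builds per-locus references with screened random flanks,
derives the two allele haplotypes (`data1` homozygous, `data2` +4 repeat
units, `data3` −4 units), and corrupts amplicon-style reads with
mismatch/insertion/deletion rates given per 100 bp.

## Worked example

`python examples/simulate_and_genotype.py` simulates four loci (2,000 reads
each, 2 mismatches / 1 insertion / 1 deletion per 100 bp) and genotypes
them:

```
L01: lengths=[36] repeats=[12] homozygous support=[1309] rounds_agreeing=8
L02: lengths=[44, 60] repeats=[11, 15] heterozygous support=[549, 414] rounds_agreeing=9
L03: lengths=[27, 39] repeats=[9, 13] heterozygous support=[698, 646] rounds_agreeing=8
L04: lengths=[36] repeats=[12] homozygous support=[1263] rounds_agreeing=6
...
overall concordance: 100.00%
```

Per locus: the called allele tract length(s) in bp, the repeat counts they
map to, the zygosity, the pooled read support per allele, and how many of
the 10 sampling rounds voted for the winning allele set. Concordance is the
fraction of loci whose called repeat-count set matches the simulator truth
exactly. `examples/lnr_walkthrough.py` prints the per-round LNR tables
behind one call; `examples/error_sweep.py` shows accuracy degrading with
error rate, expanded heterozygotes first.

The same pipeline is available from the shell:

```
strlnr simulate --out sim --n-loci 4 --n-reads 2000 --mismatch-rate 2 \
                --insertion-rate 1 --deletion-rate 1 --seed 42
strlnr genotype --reads sim/reads.fastq --reference sim/reference.fasta \
                --loci sim/loci.tsv --out calls
strlnr evaluate --calls calls/calls.tsv --truth sim/truth.tsv
```

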