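# Methods

## Model and procedure

`strlnr` treats targeted STR genotyping as a length-estimation problem over
repeated subsampling. A diploid locus carries one or two allele tract
lengths; every read that spans the tract plus its flanks carries a noisy
measurement of one allele's length. The method never aligns reads to the
genome; instead it anchors measurements with exact flanking seeds and lets
two independent summaries of the same reads vote on which length classes
are real.

**Multisampling with paired seeds.** Round `i` uses the `d·i`-bp reference
sequences immediately upstream/downstream of the tract as a seed pair.
Requiring an *exact* match of both seeds (forward or reverse-complement; a
read is counted once per round, using the leftmost left-seed occurrence and
the nearest right-seed occurrence after it) selects, per round, a different
subset of reads whose anchors were sequenced perfectly. Larger `i` means
stronger anchoring but exponentially fewer surviving reads at high error
rates, so the N rounds trade depth against specificity; rounds with no
surviving evidence abstain. The enclosed-segment lengths of each round are
summarized as length–number–rank (LNR) tables: distinct lengths, their
supported read numbers, dense ranks by descending count (ties broken toward
the shorter length).

**Alignment cross-check (dataset2).** Each harvested segment, including its
matched seeds, is locally aligned (infix alignment, unit costs) against the
tract ±`flank_len` of reference. Hits with ≥ `max_mismatches` substitutions
are discarded; gap columns are counted separately, mirroring BLAST tabular
(m8) semantics in which per-gap lengths are not itemized. Subject-side span
lengths form a second LNR table per round.

**Why the intersection is rank-based.** Local alignment bridges indels with
gaps, so the subject span of essentially every read — whether its tract
carries a sequencing indel or a genuine ±4-unit allele difference — collapses
onto the reference scale (seed context + reference tract). Dataset2 span
*values* therefore carry little allele information, but the *number and rank
structure* of credible span classes is a robust, mismatch-filtered view of
how many length classes the data supports. The default intersection hence
keeps a dataset1 length when its minimum rank difference to any dataset2
entry is `< max_rank_diff`; dataset1 (exact-match evidence) supplies lengths
and counts, dataset2 bounds the accepted rank depth. A stricter
`intersect_mode="length"` variant — same normalized length in both datasets
with a small rank difference — is implemented and unit-tested, but because
of the span collapse it suppresses genuine non-reference alleles (an
expanded allele's spans project onto the reference tract length) and is kept
for comparison only. This was the one genuinely open design point; the
rank-based reading is the only one under which error-free heterozygous
panels genotype perfectly while noisy homozygous panels remain stable, which
is the behavior the method is designed around.

**Calling.** Per round, the top joint length is kept alone when its support
exceeds `support_ratio`× the runner-up's (exclusive), else the top two are
kept. Across rounds, the most frequent allele set wins (ties: larger pooled
support, then lexicographically smaller set). Zygosity: homozygous when the
pooled support ratio of the top two alleles over mode-agreeing rounds is
≥ `mode_ratio` (an alternative reading — ratio of round-vote counts — is
selectable via `mode_ratio_source="votes"`). The secondary correction
demotes a minor allele whose support is ≥ `magnitude_gap`× below the
major's, treating it as background noise. Finally
`repeats = ref_repeats + round((length − ref_tract)/|motif|)` (ties to
even); off-ladder lengths are rounded to the nearest rung and flagged, and a
negative computed repeat count voids the call. Concordance against truth is
scored on repeat-count sets: a heterozygous-looking call whose two lengths
round to the same repeat count (e.g. a true length plus its 1-bp-deletion
shadow) still scores as the correct single-allele genotype — this rounding,
not any count threshold, is what keeps homozygous accuracy flat as error
rates grow.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `step_size` (d) | 10 | bp | per-round seed extension |
| `rounds` (N) | 10 | – | sampling rounds; max seed 100 bp at d=10. No canonical value exists; ~30–100 bp seeds balance uniqueness against exact-match survival |
| `flank_len` | 500 | bp | one-sided alignment reference flank |
| `max_mismatches` | 3 | count | exclusive substitution bound on alignment hits |
| `max_rank_diff` | 3 | rank | exclusive bound on the minimum rank difference |
| `support_ratio` | 3 | ratio | exclusive within-round single-allele threshold |
| `mode_ratio` | 3 | ratio | inclusive homozygosity threshold at combination |
| `magnitude_gap` | 10 | ratio | secondary-correction demotion factor |

Simulator: error rates are error *bases* per 100 template bp per type
(an inserted run of 2 bp counts 2); indel run lengths are geometric with
mean 1.4 capped at 5, reflecting the dominance of 1–2 bp erroneous segments
in nanopore data; insertion/deletion event probabilities are scaled by the
mean run length so realized per-base rates match the request (self-audited
to ±10% over ≥100 kb). Flanks are uniform random A/C/G/T, regenerated until
they contain no triple motif occurrence and do not extend the tract at its
boundary — keeping truth allele lengths unambiguous. Reads are fixed-length
slices randomly positioned so that every read spans the tract plus the
120-bp seed window (amplicon/panel-style coverage), reverse-complemented
with probability 0.5. Designs: `data1` homozygous-reference, `data2` +4
repeat units on one allele, `data3` −4 units.

## What the simulations do and do not show

The generator reproduces the error *content* of long noisy reads
(i.i.d. mismatches and short indels at controlled rates) but not nanopore's
context dependence (homopolymer bias, non-random indel placement), learned
read-length distributions, basecaller quality profiles, or impure/compound
repeat structures. Passing the simulated panels therefore demonstrates the
statistical machinery — anchored harvesting, rank filtering, mode
combination — under controlled error load; it does not certify accuracy on
real sequencing runs, where locus-specific reference mismatches (e.g. an
impure tract inflating the substitution count past `max_mismatches`) and
coverage imbalance add failure modes of their own.

## Numerical and degenerate-input choices

- Dense ranking with ties broken toward the shorter length makes every LNR
  table, and hence every downstream call, deterministic; outputs are
  byte-identical across runs and independent of the worker count.
- Empty rounds abstain and are excluded from the mode; a locus needs ≥1
  informative round, otherwise it is a no-call with reason.
- The internal aligner aligns the full query (infix mode) on both strands,
  taking the lower edit distance (forward on ties) and the first co-optimal
  location; its `bit_score`/`e_value` fields are surrogates (matches −
  mismatches − gap bases; 0.0) used only for best-hit selection. The
  external `blastn` backend (`-task blastn -dust no`) populates all m8
  fields natively; parsed hits re-serialize byte-identically.
- Seeds containing ambiguity codes drop that round only; a truncated
  alignment flank or an extension running off the contig is a per-locus
  error, not a silent clip.
- `round()` half-to-even is used on the repeat ladder; a length exactly
  between rungs (only possible for even motif lengths) resolves
  deterministically and is flagged off-ladder either way.

## Problem sizes

The shipped experiments use 2,000 reads per locus and 1-kb synthetic
flanks: 4 mixed-design loci error-free; 10 homozygous loci at sweep points
(0,0,0) → (3,2,2) per 100 bp × 3 seeds; 10 mixed loci at (2.6,1.5,1.7) × 5
seeds; 12 loci × 5 seeds for the design-difficulty ordering. These sizes
give stable concordance estimates while keeping a full run in tens of
seconds on one core.

## Known limitations

- At the top of the error sweep, round votes can fragment across a true
  length's off-ladder shadows (±1–2 bp classes); very rarely a shadow one
  full motif unit short wins the tie-break and surfaces as a spurious extra
  allele (~1% of homozygous locus-runs at 3/2/2 per 100 bp). Expanded
  heterozygotes (`data2`) degrade first as rates rise — the longer tract
  offers more room for errors, so its length class fragments faster —
  followed by contracted heterozygotes (`data3`), with homozygous loci the
  most robust.
- Compound/impure repeat structures ([A]n[B]nNn[C]n[D]n-style) are out of
  scope, as are stutter modeling, phasing, and genome-wide STR discovery:
  the method is built for *target* loci with declared motifs.
- The substitution filter can starve a locus whose reference copy differs
  from the sample by many substitutions; the threshold is configurable but
  a single value cannot fit all loci.
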