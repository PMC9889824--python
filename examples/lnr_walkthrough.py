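"""Follow one heterozygous locus through the genotyping stages.

Simulates a single +4-repeat-unit heterozygous locus, then shows what each
stage produces for one sampling round: the exact-seed LNR table (dataset1),
the alignment-span LNR table (dataset2), the rank-intersection survivors,
and the per-round genotype — and finally the combined call.  In dataset1 the
two tallest length classes are the two true alleles; dataset2 spans sit on
the reference scale (seed context plus the reference tract), and their rank
depth bounds which dataset1 classes are accepted as real.
"""

from strlnr import (AlignConfig, ErrorProfile, GenotyperConfig, ReadRecord,
                    SeedConfig, SimLocusSpec, align_round, build_lnr,
                    build_reference, call_round, combine_rounds, harvest_round,
                    hits_to_lengths, intersect_round, lengths_to_repeats,
                    make_paired_seeds, secondary_correction, simulate_reads)

spec = SimLocusSpec.from_design("DEMO", "AGAT", 11, "data2", flank_len=1000)
ref, locus = build_reference(spec, seed=7)
sim_reads, truth, _ = simulate_reads(ref, locus, spec,
                                     ErrorProfile(1.0, 0.5, 0.5), 1000, seed=8)
reads = [ReadRecord(r.read_id, r.sequence) for r in sim_reads]
print(f"truth: alleles {sorted(truth.repeat_set)} repeats "
      f"({truth.allele_lengths[0]} bp / {truth.allele_lengths[1]} bp), "
      f"{truth.reads_per_allele} reads per allele")

seed_cfg, align_cfg, gt_cfg = SeedConfig(), AlignConfig(), GenotyperConfig()
align_ref = ref[locus.start - 500:locus.end + 500]

round_genotypes = []
for seed in make_paired_seeds(locus, seed_cfg, {locus.chrom: ref}):
    hits = harvest_round(reads, seed)
    d1 = build_lnr([(h.read_id, h.target_length) for h in hits],
                   locus.name, seed.round_index, "seed-match")
    aln = align_round([(h.read_id, h.query) for h in hits], align_ref, align_cfg)
    d2 = build_lnr(hits_to_lengths(aln, align_cfg),
                   locus.name, seed.round_index, "alignment")
    joint = intersect_round(d1, d2, gt_cfg, seed_context=2 * seed.seed_len)
    rg = call_round(joint, locus.name, seed.round_index, gt_cfg)
    round_genotypes.append(rg)
    if seed.round_index == 1:
        print(f"\nround 1 (seed length {seed.seed_len} bp, {len(hits)} reads harvested)")
        print(" dataset1 (length, count, rank):",
              [(e.length, e.count, e.rank) for e in d1.entries[:5]], "...")
        print(" dataset2 (span, count, rank):  ",
              [(e.length, e.count, e.rank) for e in d2.entries[:5]], "...")
        print(" joint survivors:", [(j.length, j.count) for j in joint])
        print(" round genotype:", rg.alleles)

call = combine_rounds(round_genotypes, gt_cfg)
call = secondary_correction(call, gt_cfg)
call = lengths_to_repeats(call, locus)
print(f"\nfinal call: lengths {call.allele_lengths} -> repeats "
      f"{call.allele_repeats}, {call.zygosity}, "
      f"{call.rounds_agreeing}/{call.rounds_informative} rounds agreeing")
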