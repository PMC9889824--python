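"""End-to-end runs: simulate a dataset bundle, genotype it, evaluate calls.

`run_genotype` wires the stages per locus — paired seeds, exact-seed
harvesting, flank alignment, rank intersection, mode combination — and
writes a calls TSV plus a provenance JSON holding every per-round LNR table,
sufficient to re-derive each call offline.  Loci are independent; one locus
failing does not abort the others.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml
from joblib import Parallel, delayed

from .align import AlignConfig, align_round, hits_to_lengths
from .errors import ConfigurationError, LocusError
from .genotyper import GenotypeCall, GenotyperConfig, genotype_rounds
from .harvest import ReadRecord, harvest_round, read_fastq
from .lnr import build_lnr
from .loci import (SeedConfig, StrLocus, load_loci, make_alignment_reference,
                   make_paired_seeds, read_fasta)
from .simulate import (ErrorProfile, SimLocusSpec, build_reference, make_panel,
                       read_truth_tsv, score_concordance, sha256_of,
                       simulate_reads, write_fasta, write_fastq, write_loci_tsv,
                       write_truth_tsv)

log = logging.getLogger(__name__)

CALL_COLUMNS = ["locus", "allele_lengths", "allele_repeats", "zygosity",
                "supports", "rounds_agreeing", "rounds_informative",
                "corrected", "flags", "reason"]


@dataclass
class RunConfig:
    """Effective configuration of a genotyping run."""

    reads: Optional[str] = None
    reference: Optional[str] = None
    loci: Optional[str] = None
    outdir: str = "strlnr_out"
    seed_cfg: SeedConfig = field(default_factory=SeedConfig)
    align_cfg: AlignConfig = field(default_factory=AlignConfig)
    genotyper_cfg: GenotyperConfig = field(default_factory=GenotyperConfig)
    threads: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(
            reads=data.get("reads"), reference=data.get("reference"),
            loci=data.get("loci"), outdir=data.get("outdir", "strlnr_out"),
            seed_cfg=SeedConfig(**data.get("seed", {})),
            align_cfg=AlignConfig(**data.get("align", {})),
            genotyper_cfg=GenotyperConfig(**data.get("genotyper", {})),
            threads=int(data.get("threads", 1)), seed=int(data.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        return {
            "reads": self.reads, "reference": self.reference, "loci": self.loci,
            "outdir": self.outdir, "seed": self.seed, "threads": self.threads,
            "seed_cfg": asdict(self.seed_cfg), "align_cfg": asdict(self.align_cfg),
            "genotyper_cfg": asdict(self.genotyper_cfg),
        }


def genotype_locus(reads: Sequence[ReadRecord], locus: StrLocus,
                   reference: Dict[str, str], seed_cfg: SeedConfig,
                   align_cfg: AlignConfig,
                   gt_cfg: GenotyperConfig) -> Tuple[GenotypeCall, dict]:
    """Genotype one locus from an in-memory read set; returns (call, provenance)."""
    seeds = make_paired_seeds(locus, seed_cfg, reference)
    if not seeds:
        raise LocusError(f"locus {locus.name}: no usable seed rounds")
    align_ref = make_alignment_reference(locus, seed_cfg, reference)

    d1_rounds, d2_rounds, contexts, prov_rounds = [], [], [], []
    for seed in seeds:
        hits = harvest_round(reads, seed)
        d1 = build_lnr([(h.read_id, h.target_length) for h in hits],
                       locus.name, seed.round_index, "seed-match")
        aln = align_round([(h.read_id, h.query) for h in hits], align_ref, align_cfg)
        d2 = build_lnr(hits_to_lengths(aln, align_cfg),
                       locus.name, seed.round_index, "alignment")
        ctx = 2 * seed.seed_len
        d1_rounds.append(d1)
        d2_rounds.append(d2)
        contexts.append(ctx)
        prov_rounds.append({
            "round": seed.round_index,
            "seed_len": seed.seed_len,
            "harvested_reads": len(hits),
            "aligned_reads": len(aln),
            "dataset1": [[e.length, e.count, e.rank] for e in d1.entries],
            "dataset2": [[e.length, e.count, e.rank] for e in d2.entries],
        })

    call, round_calls = genotype_rounds(d1_rounds, d2_rounds, contexts, locus, gt_cfg)
    for prov, rc in zip(prov_rounds, round_calls):
        prov["round_genotype"] = None if rc is None else [list(a) for a in rc.alleles]
    provenance = {
        "locus": locus.name,
        "rounds": prov_rounds,
        "call": _call_row(call),
    }
    return call, provenance


def _call_row(call: GenotypeCall) -> dict:
    return {
        "locus": call.locus_name,
        "allele_lengths": ",".join(map(str, call.allele_lengths)) or ".",
        "allele_repeats": (",".join(map(str, call.allele_repeats))
                           if call.allele_repeats else "."),
        "zygosity": call.zygosity,
        "supports": ",".join(map(str, call.support)) or ".",
        "rounds_agreeing": call.rounds_agreeing,
        "rounds_informative": call.rounds_informative,
        "corrected": int(call.corrected),
        "flags": ";".join(call.flags) or ".",
        "reason": call.reason or ".",
    }


def write_calls_tsv(calls: Sequence[GenotypeCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for call in calls:
            row = _call_row(call)
            fh.write("\t".join(str(row[c]) for c in CALL_COLUMNS) + "\n")


def read_calls_tsv(path) -> List[GenotypeCall]:
    calls = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            lengths = ([] if row["allele_lengths"] == "." else
                       [int(x) for x in row["allele_lengths"].split(",")])
            repeats = (None if row["allele_repeats"] == "." else
                       [int(x) for x in row["allele_repeats"].split(",")])
            supports = ([] if row["supports"] == "." else
                        [int(x) for x in row["supports"].split(",")])
            calls.append(GenotypeCall(
                locus_name=row["locus"], allele_lengths=lengths,
                zygosity=row["zygosity"], support=supports,
                rounds_agreeing=int(row["rounds_agreeing"]),
                rounds_informative=int(row["rounds_informative"]),
                allele_repeats=repeats, corrected=bool(int(row["corrected"])),
                flags=[] if row["flags"] == "." else row["flags"].split(";"),
                reason=None if row["reason"] == "." else row["reason"],
            ))
    return calls


def run_genotype(cfg: RunConfig) -> List[GenotypeCall]:
    """Genotype every locus in the configured inputs and write report files."""
    for label, p in (("reads", cfg.reads), ("reference", cfg.reference),
                     ("loci", cfg.loci)):
        if p is None or not Path(p).exists():
            raise ConfigurationError(f"{label} path missing or not found: {p}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("effective config: %s", json.dumps(cfg.to_dict(), sort_keys=True))

    reference = read_fasta(cfg.reference)
    loci = load_loci(cfg.loci, reference=reference, strict=False)
    reads = list(read_fastq(cfg.reads))
    log.info("loaded %d loci, %d reads", len(loci), len(reads))

    def _one(locus: StrLocus):
        try:
            return genotype_locus(reads, locus, reference, cfg.seed_cfg,
                                  cfg.align_cfg, cfg.genotyper_cfg)
        except LocusError as exc:
            log.error("locus %s failed: %s", locus.name, exc)
            return (GenotypeCall(locus.name, [], "no-call", [], reason=str(exc)),
                    {"locus": locus.name, "error": str(exc)})

    results = Parallel(n_jobs=cfg.threads, backend="threading")(
        delayed(_one)(locus) for locus in loci)
    calls = [r[0] for r in results]
    provenance = [r[1] for r in results]

    write_calls_tsv(calls, outdir / "calls.tsv")
    with open(outdir / "provenance.json", "w") as fh:
        json.dump({"config": cfg.to_dict(), "loci": provenance}, fh, indent=1,
                  sort_keys=True)
    failed = sum(1 for c in calls if c.zygosity == "no-call" and c.reason)
    if failed:
        log.warning("%d of %d loci produced no call", failed, len(calls))
    return calls


@dataclass
class SimulateConfig:
    outdir: str = "strlnr_sim"
    n_loci: int = 4
    designs: Tuple[str, ...] = ("data1", "data2", "data3")
    n_reads: int = 2000
    flank_len: int = 1000
    profile: ErrorProfile = field(default_factory=ErrorProfile)
    seed: int = 0


def run_simulate(cfg: SimulateConfig,
                 specs: Optional[Sequence[SimLocusSpec]] = None) -> dict:
    """Emit a genotyping-ready bundle: FASTQ, FASTA, loci TSV, truth TSV, manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if specs is None:
        specs = make_panel(cfg.n_loci, cfg.designs, seed=cfg.seed,
                           flank_len=cfg.flank_len)
    sequences, loci, truths, all_reads = {}, [], [], []
    for k, spec in enumerate(specs):
        ref_seq, locus = build_reference(spec, seed=cfg.seed + 1000 + k)
        locus = StrLocus(f"ctg_{spec.name}", locus.start, locus.end, spec.name,
                         locus.motif, locus.ref_repeats)
        reads, truth, _ = simulate_reads(ref_seq, locus, spec, cfg.profile,
                                         cfg.n_reads, seed=cfg.seed + 2000 + k)
        sequences[locus.chrom] = ref_seq
        loci.append(locus)
        truths.append(truth)
        all_reads.extend(reads)

    paths = {
        "reads": outdir / "reads.fastq",
        "reference": outdir / "reference.fasta",
        "loci": outdir / "loci.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fastq(all_reads, paths["reads"])
    write_fasta(sequences, paths["reference"])
    write_loci_tsv(loci, paths["loci"])
    write_truth_tsv(truths, paths["truth"])
    manifest = {name: {"path": str(p), "sha256": sha256_of(p)}
                for name, p in paths.items()}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def run_evaluate(calls_path, truth_path):
    """Score a calls TSV against a truth TSV; returns a ConcordanceReport."""
    calls = read_calls_tsv(calls_path)
    truths = read_truth_tsv(truth_path)
    return score_concordance(calls, truths)


def simulate_and_genotype(specs: Sequence[SimLocusSpec], profile: ErrorProfile,
                          n_reads: int, seed: int,
                          seed_cfg: Optional[SeedConfig] = None,
                          align_cfg: Optional[AlignConfig] = None,
                          gt_cfg: Optional[GenotyperConfig] = None):
    """In-memory simulate → genotype → score loop for one locus panel.

    The workhorse of the simulation experiments: per locus it builds a
    screened synthetic reference, draws reads at the given error profile,
    runs the full genotyping stack, and scores the calls against truth.
    Returns a ConcordanceReport.
    """
    seed_cfg = seed_cfg or SeedConfig()
    align_cfg = align_cfg or AlignConfig()
    gt_cfg = gt_cfg or GenotyperConfig()
    calls, truths = [], []
    for k, spec in enumerate(specs):
        ref_seq, locus = build_reference(spec, seed=seed + 1000 + k)
        sim_reads, truth, _ = simulate_reads(ref_seq, locus, spec, profile,
                                             n_reads, seed=seed + 2000 + k)
        reads = [ReadRecord(r.read_id, r.sequence) for r in sim_reads]
        call, _ = genotype_locus(reads, locus, {locus.chrom: ref_seq},
                                 seed_cfg, align_cfg, gt_cfg)
        calls.append(call)
        truths.append(truth)
    return score_concordance(calls, truths)
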