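"""Synthetic nanopore-style STR read simulator with controllable error rates.

Generates per-locus references with random screened flanks, diploid
haplotypes from a locus/allele truth specification, and amplicon-style reads
corrupted base-by-base with mismatches, insertions, and deletions at
configurable per-100-bp rates — the error axis on which genotyping accuracy
is evaluated.  Three standard designs mirror the evaluation layouts:

* ``data1`` — homozygous, both alleles equal to the reference;
* ``data2`` — heterozygous, second allele expanded by 4 repeat units;
* ``data3`` — heterozygous, second allele contracted by 4 repeat units.

What the generator emulates and what it does not: errors are i.i.d. per base
with geometric indel lengths (mean ~1.4, capped at 5, matching the observed
dominance of 1-2 bp erroneous segments in nanopore data); real nanopore
error processes are context-dependent (homopolymers) and read lengths follow
a learned distribution, neither of which is modeled.  Reads are uniform
slices guaranteed to span the seed window, as in amplicon/panel sequencing.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .genotyper import GenotypeCall
from .harvest import revcomp
from .loci import StrLocus

DESIGN_OFFSETS = {"data1": 0, "data2": +4, "data3": -4}

#: Curated 3-4 bp repeat units (forensic-core-like, no homopolymer motifs).
DEFAULT_MOTIFS = ["ATC", "CTT", "TAG", "GCA", "AGAT", "TCTA", "GATA", "CTAT"]


@dataclass(frozen=True)
class SimLocusSpec:
    """Truth specification for one simulated locus."""

    name: str
    motif: str
    ref_repeats: int
    allele_a_repeats: int
    allele_b_repeats: int
    design: str = "custom"
    flank_len: int = 1000

    def __post_init__(self) -> None:
        if min(self.allele_a_repeats, self.allele_b_repeats, self.ref_repeats) < 1:
            raise ValidationError(f"locus {self.name}: repeat counts must be >= 1")
        if self.flank_len < 200:
            raise ConfigurationError(f"locus {self.name}: flank_len must be >= 200 bp")

    @classmethod
    def from_design(cls, name: str, motif: str, ref_repeats: int, design: str,
                    flank_len: int = 1000) -> "SimLocusSpec":
        if design not in DESIGN_OFFSETS:
            raise ConfigurationError(f"unknown design {design!r}")
        return cls(name, motif, ref_repeats, ref_repeats,
                   ref_repeats + DESIGN_OFFSETS[design], design, flank_len)

    @property
    def is_homozygous(self) -> bool:
        return self.allele_a_repeats == self.allele_b_repeats

    @property
    def truth_repeats(self) -> frozenset:
        return frozenset({self.allele_a_repeats, self.allele_b_repeats})


@dataclass(frozen=True)
class ErrorProfile:
    """Per-100-bp error rates, counting error *bases* (a 2-bp insertion is 2).

    Indel lengths are geometric with mean ``indel_mean`` capped at
    ``indel_cap``; event probabilities are scaled by the mean so the realized
    per-base error rate matches the requested one.
    """

    mismatch_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    indel_mean: float = 1.4
    indel_cap: int = 5

    def __post_init__(self) -> None:
        if min(self.mismatch_rate, self.insertion_rate, self.deletion_rate) < 0:
            raise ConfigurationError("error rates must be >= 0")


@dataclass
class ErrorAudit:
    """Self-audit of injected error operations (the simulator's event log)."""

    template_bases: int = 0
    mismatch_bases: int = 0
    inserted_bases: int = 0
    deleted_bases: int = 0

    def realized_rates(self) -> Tuple[float, float, float]:
        """Realized (mismatch, insertion, deletion) error bases per 100 bp."""
        if self.template_bases == 0:
            return (0.0, 0.0, 0.0)
        f = 100.0 / self.template_bases
        return (self.mismatch_bases * f, self.inserted_bases * f, self.deleted_bases * f)


@dataclass(frozen=True)
class SimTruth:
    locus_name: str
    design: str
    motif: str
    ref_repeats: int
    allele_repeats: Tuple[int, int]
    allele_lengths: Tuple[int, int]
    reads_per_allele: Tuple[int, int]

    @property
    def repeat_set(self) -> frozenset:
        return frozenset(self.allele_repeats)


@dataclass(frozen=True)
class FastqRead:
    read_id: str
    sequence: str

    def to_fastq(self) -> str:
        return f"@{self.read_id}\n{self.sequence}\n+\n{'I' * len(self.sequence)}\n"


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def build_reference(spec: SimLocusSpec, flank_len: Optional[int] = None,
                    seed: int = 0, rng: Optional[np.random.Generator] = None,
                    max_retries: int = 200) -> Tuple[str, StrLocus]:
    """Reference sequence (flank + motif x ref_repeats + flank) and its StrLocus.

    Flanks are i.i.d. uniform A/C/G/T, regenerated (bounded retries) until
    they contain no triple occurrence of the motif and do not extend the
    tract at its boundaries — this keeps the tract boundaries and hence the
    truth allele lengths unambiguous.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    fl = spec.flank_len if flank_len is None else flank_len
    if fl < 200:
        raise ConfigurationError("flank_len must be >= 200 bp")
    motif3 = spec.motif * 3
    left = right = None
    for _ in range(max_retries):
        cand = _random_seq(rng, fl)
        if left is None and motif3 not in cand and cand[-1] != spec.motif[-1]:
            left = cand
        elif right is None and motif3 not in cand and cand[0] != spec.motif[0]:
            right = cand
        if left is not None and right is not None:
            break
    else:
        raise ConfigurationError(
            f"locus {spec.name}: could not generate motif-free flanks in {max_retries} tries")
    tract = spec.motif * spec.ref_repeats
    locus = StrLocus(spec.name, fl, fl + len(tract), spec.name, spec.motif,
                     spec.ref_repeats)
    return left + tract + right, locus


def _corrupt(seq: str, profile: ErrorProfile, rng: np.random.Generator,
             audit: ErrorAudit) -> str:
    """Inject errors into one read template and log every operation."""
    n = len(seq)
    audit.template_bases += n
    p_mm = profile.mismatch_rate / 100.0
    p_ins = profile.insertion_rate / 100.0 / profile.indel_mean
    p_del = profile.deletion_rate / 100.0 / profile.indel_mean

    def _geom() -> int:
        return min(int(rng.geometric(1.0 / profile.indel_mean)), profile.indel_cap)

    # deletions: each event removes a geometric-length segment
    if p_del > 0:
        starts = np.flatnonzero(rng.random(n) < p_del)
        parts, pos = [], 0
        for s in starts:
            if s < pos:
                continue
            g = min(_geom(), n - s)
            parts.append(seq[pos:s])
            pos = s + g
            audit.deleted_bases += g
        parts.append(seq[pos:])
        seq = "".join(parts)

    # mismatches: substitute with one of the three other bases
    if p_mm > 0 and seq:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        pos = np.flatnonzero(rng.random(len(arr)) < p_mm)
        if pos.size:
            idx = np.searchsorted(_BASES, arr[pos])
            arr[pos] = _BASES[(idx + rng.integers(1, 4, pos.size)) % 4]
            audit.mismatch_bases += int(pos.size)
            seq = arr.tobytes().decode()

    # insertions: random bases inserted before flagged positions
    if p_ins > 0 and seq:
        pos = np.flatnonzero(rng.random(len(seq)) < p_ins)
        if pos.size:
            parts, prev = [], 0
            for s in pos:
                g = _geom()
                parts.append(seq[prev:s])
                parts.append(_random_seq(rng, g))
                audit.inserted_bases += g
                prev = s
            parts.append(seq[prev:])
            seq = "".join(parts)
    return seq


def simulate_reads(reference: str, locus: StrLocus, spec: SimLocusSpec,
                   profile: ErrorProfile, n_reads: int,
                   read_span: Optional[int] = None, seed: int = 0,
                   seed_window: int = 120) -> Tuple[List[FastqRead], SimTruth, ErrorAudit]:
    """Simulate reads from the two allele haplotypes of a locus.

    Each read is a contiguous slice of a haplotype chosen with equal
    probability, positioned so the slice spans the tract plus ``seed_window``
    flank on each side (amplicon-style coverage of the target), reverse
    complemented with probability 0.5, then corrupted per the error profile.
    """
    if n_reads <= 0:
        raise ConfigurationError("n_reads must be > 0")
    rng = np.random.default_rng(seed)
    motif_len = len(locus.motif)
    haps = []
    for reps in (spec.allele_a_repeats, spec.allele_b_repeats):
        haps.append(reference[:locus.start] + locus.motif * reps + reference[locus.end:])
    hap_tracts = [spec.allele_a_repeats * motif_len, spec.allele_b_repeats * motif_len]

    if read_span is None:
        read_span = max(hap_tracts) + 2 * seed_window + 160
    if read_span < max(hap_tracts) + 2 * seed_window:
        raise ConfigurationError("read_span too short to span the tract plus seed window")
    if read_span > min(len(h) for h in haps):
        raise ConfigurationError("read_span exceeds the haplotype length; "
                                 "use longer flanks or a shorter read_span")

    audit = ErrorAudit()
    reads: List[FastqRead] = []
    counts = [0, 0]
    alleles = rng.integers(0, 2, n_reads)
    flips = rng.random(n_reads) < 0.5
    for i in range(n_reads):
        a = int(alleles[i])
        counts[a] += 1
        hap = haps[a]
        t_end = locus.start + hap_tracts[a]
        lo = max(0, t_end + seed_window - read_span)
        hi = min(len(hap) - read_span, locus.start - seed_window)
        start = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        template = hap[start:start + read_span]
        seq = _corrupt(template, profile, rng, audit)
        if flips[i]:
            seq = revcomp(seq)
        reads.append(FastqRead(f"sim_{spec.name}_{i:05d}", seq))

    truth = SimTruth(
        locus_name=spec.name, design=spec.design, motif=spec.motif,
        ref_repeats=spec.ref_repeats,
        allele_repeats=(spec.allele_a_repeats, spec.allele_b_repeats),
        allele_lengths=(hap_tracts[0], hap_tracts[1]),
        reads_per_allele=(counts[0], counts[1]),
    )
    return reads, truth, audit


def make_panel(n_loci: int, designs: Sequence[str], seed: int = 0,
               flank_len: int = 1000, motifs: Sequence[str] = tuple(DEFAULT_MOTIFS),
               repeat_range: Tuple[int, int] = (9, 13)) -> List[SimLocusSpec]:
    """Build a panel of locus specs cycling through the given designs."""
    if n_loci < 1:
        raise ConfigurationError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    specs = []
    for k in range(n_loci):
        design = designs[k % len(designs)]
        motif = motifs[int(rng.integers(0, len(motifs)))]
        reps = int(rng.integers(repeat_range[0], repeat_range[1] + 1))
        if design == "data3" and reps <= 4:
            reps = 5
        specs.append(SimLocusSpec.from_design(f"L{k + 1:02d}", motif, reps, design,
                                              flank_len))
    return specs


@dataclass
class ConcordanceReport:
    """Per-locus and aggregate genotype concordance against simulator truth."""

    frame: pd.DataFrame
    overall: float
    per_design: Dict[str, float]

    def __str__(self) -> str:
        parts = [f"overall concordance: {self.overall:.2f}%"]
        parts += [f"  {d}: {v:.2f}%" for d, v in sorted(self.per_design.items())]
        return "\n".join(parts)


def score_concordance(calls: Sequence[GenotypeCall],
                      truths: Sequence[SimTruth]) -> ConcordanceReport:
    """Fraction of loci whose called allele set (as repeat counts) matches
    truth exactly.  Missing or no-call loci count as discordant; a call for a
    locus absent from the truth is an error."""
    truth_by_name = {t.locus_name: t for t in truths}
    calls_by_name: Dict[str, GenotypeCall] = {}
    for c in calls:
        if c.locus_name not in truth_by_name:
            raise ValidationError(f"call for unknown locus {c.locus_name!r}")
        calls_by_name[c.locus_name] = c

    rows = []
    for t in truths:
        call = calls_by_name.get(t.locus_name)
        truth_set = t.repeat_set
        if call is None or call.zygosity == "no-call" or call.repeat_set() is None:
            rows.append((t.locus_name, t.design, sorted(truth_set), None, False, "no-call"))
            continue
        call_set = call.repeat_set()
        if call_set == truth_set:
            reason = ""
        elif call_set < truth_set:
            reason = "missed allele"
        elif call_set > truth_set:
            reason = "extra allele"
        else:
            reason = "wrong allele"
        rows.append((t.locus_name, t.design, sorted(truth_set), sorted(call_set),
                     call_set == truth_set, reason))
    frame = pd.DataFrame(rows, columns=["locus", "design", "truth_repeats",
                                        "called_repeats", "concordant", "reason"])
    overall = 100.0 * frame["concordant"].mean() if len(frame) else 0.0
    per_design = {
        str(d): 100.0 * g["concordant"].mean()
        for d, g in frame.groupby("design")
    }
    return ConcordanceReport(frame, float(overall), per_design)


# ---------------------------------------------------------------------------
# plain-text writers

def write_fastq(reads: Sequence[FastqRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(r.to_fastq())


def write_fasta(sequences: Dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def write_loci_tsv(loci: Sequence[StrLocus], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tmotif\tref_repeats\n")
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.name}\t{l.motif}\t{l.ref_repeats}\n")


def write_truth_tsv(truths: Sequence[SimTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tdesign\tmotif\tref_repeats\tallele_a_repeats\t"
                 "allele_b_repeats\treads_a\treads_b\n")
        for t in truths:
            fh.write(f"{t.locus_name}\t{t.design}\t{t.motif}\t{t.ref_repeats}\t"
                     f"{t.allele_repeats[0]}\t{t.allele_repeats[1]}\t"
                     f"{t.reads_per_allele[0]}\t{t.reads_per_allele[1]}\n")


def read_truth_tsv(path) -> List[SimTruth]:
    truths = []
    df = pd.read_csv(path, sep="\t")
    for _, row in df.iterrows():
        mlen = len(str(row["motif"]))
        truths.append(SimTruth(
            locus_name=str(row["locus"]), design=str(row["design"]),
            motif=str(row["motif"]), ref_repeats=int(row["ref_repeats"]),
            allele_repeats=(int(row["allele_a_repeats"]), int(row["allele_b_repeats"])),
            allele_lengths=(int(row["allele_a_repeats"]) * mlen,
                            int(row["allele_b_repeats"]) * mlen),
            reads_per_allele=(int(row["reads_a"]), int(row["reads_b"])),
        ))
    return truths


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
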