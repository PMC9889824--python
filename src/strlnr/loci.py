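"""Target locus definitions, paired-seed construction, and alignment references.

A short tandem repeat (STR) locus is a tract of a 1-6 bp motif repeated in
tandem on the reference genome.  Genotyping starts from the tract boundaries
``P_start``/``P_end`` (0-based half-open internally) and extends outward in
steps of ``d`` bases: the *i*-th extension round uses the pair of flanking
anchor sequences of length ``d*i`` immediately upstream of ``P_start`` and
downstream of ``P_end`` — the *paired seeds*.  Reads that contain both seeds
exactly pin down the STR-containing segment without any genome-wide alignment.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping

from Bio import SeqIO

from .errors import ConfigurationError, LocusError, ValidationError

log = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class StrLocus:
    """A target STR interval on the reference.

    Coordinates are 0-based half-open; ``end - start`` is the reference
    tract length.  ``motif`` is the repeat unit (1-6 bp, A/C/G/T only) and
    ``ref_repeats`` the repeat count of the reference allele.
    """

    chrom: str
    start: int
    end: int
    name: str
    motif: str
    ref_repeats: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"locus {self.name}: end ({self.end}) must exceed start ({self.start})"
            )
        if not 1 <= len(self.motif) <= 6:
            raise ValidationError(
                f"locus {self.name}: motif length must be 1-6 bp, got {len(self.motif)}"
            )
        if not set(self.motif) <= _VALID_BASES:
            raise ValidationError(
                f"locus {self.name}: motif {self.motif!r} contains non-ACGT characters"
            )
        if self.ref_repeats < 1:
            raise ValidationError(f"locus {self.name}: ref_repeats must be >= 1")

    @property
    def tract_length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SeedConfig:
    """Seed-extension parameters.

    ``step_size`` (d) is the per-round extension in bp, ``rounds`` (N) the
    number of extension rounds, ``flank_len`` the one-sided flank used to
    build the per-locus alignment reference.
    """

    step_size: int = 10
    rounds: int = 10
    flank_len: int = 500

    def __post_init__(self) -> None:
        if self.step_size < 1:
            raise ConfigurationError("step_size must be >= 1")
        if self.rounds < 1:
            raise ConfigurationError("rounds must be >= 1")
        if self.flank_len < self.step_size * self.rounds:
            raise ConfigurationError(
                f"flank_len ({self.flank_len}) must be >= step_size*rounds "
                f"({self.step_size * self.rounds})"
            )


@dataclass(frozen=True)
class PairedSeed:
    """The *i*-th pair of flanking anchors for a locus.

    ``left_seed`` covers ``[P_start - d*i, P_start)`` on the reference and
    ``right_seed`` covers ``[P_end, P_end + d*i)``; both have length ``d*i``.
    """

    locus_name: str
    round_index: int
    left_seed: str
    right_seed: str
    left_span: tuple = field(default=(0, 0))
    right_span: tuple = field(default=(0, 0))

    @property
    def seed_len(self) -> int:
        return len(self.left_seed)


def read_fasta(path) -> Dict[str, str]:
    """Load a (optionally gzip-compressed) FASTA into an uppercased dict."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"FASTA file not found: {path}")
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def load_loci(bed_path, fasta_path=None, *, reference: Mapping[str, str] | None = None,
              strict: bool = True) -> List[StrLocus]:
    """Parse the 6-column loci TSV (chrom, start, end, name, motif, ref_repeats).

    Coordinates in the file are 0-based half-open.  ``#`` lines are comments.
    When a reference is supplied (``fasta_path`` or a pre-loaded ``reference``
    mapping), every chrom must exist and coordinates must fall inside it.
    With ``strict=False``, malformed rows are skipped with a warning instead
    of raising, so one bad row does not abort a run.
    """
    bed_path = Path(bed_path)
    if not bed_path.exists():
        raise ConfigurationError(f"loci file not found: {bed_path}")
    if reference is None and fasta_path is not None:
        reference = read_fasta(fasta_path)

    loci: List[StrLocus] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                loci.append(_parse_row(line, lineno, reference))
            except (ValidationError, ConfigurationError):
                if strict:
                    raise
                log.warning("skipping bad loci row %d in %s", lineno, bed_path)
    if not loci:
        log.warning("no loci parsed from %s", bed_path)
    return loci


def _parse_row(line: str, lineno: int, reference: Mapping[str, str] | None) -> StrLocus:
    fields = line.split("\t") if "\t" in line else line.split()
    if len(fields) < 6:
        raise ValidationError(f"line {lineno}: expected 6 columns, got {len(fields)}")
    chrom, start_s, end_s, name, motif, reps_s = fields[:6]
    try:
        start, end, reps = int(start_s), int(end_s), int(reps_s)
    except ValueError as exc:
        raise ValidationError(f"line {lineno}: non-integer coordinate or repeat count") from exc
    locus = StrLocus(chrom, start, end, name, motif.upper(), reps)
    if reference is not None:
        if chrom not in reference:
            raise ConfigurationError(
                f"line {lineno}: chrom {chrom!r} not present in the reference FASTA"
            )
        if end > len(reference[chrom]):
            raise ValidationError(
                f"line {lineno}: locus {name} extends past the end of {chrom} "
                f"({end} > {len(reference[chrom])})"
            )
    return locus


def make_paired_seeds(locus: StrLocus, cfg: SeedConfig,
                      reference: Mapping[str, str]) -> List[PairedSeed]:
    """Generate the N paired seeds for a locus.

    Round *i* (1-based) yields ``left_seed = ref[P_start - d*i, P_start)`` and
    ``right_seed = ref[P_end, P_end + d*i)``.  Rounds whose seeds contain
    ambiguity codes (N etc.) are dropped with a warning, since exact matching
    against ambiguous bases is meaningless.
    """
    if locus.chrom not in reference:
        raise LocusError(f"locus {locus.name}: chrom {locus.chrom!r} missing from reference")
    seq = reference[locus.chrom].upper()
    d, n = cfg.step_size, cfg.rounds
    if locus.start - d * n < 0 or locus.end + d * n > len(seq):
        raise LocusError(
            f"locus {locus.name}: {n} extension rounds of {d} bp run off the contig "
            f"(contig length {len(seq)})"
        )
    seeds: List[PairedSeed] = []
    for i in range(1, n + 1):
        ls, le = locus.start - d * i, locus.start
        rs, re = locus.end, locus.end + d * i
        left, right = seq[ls:le], seq[rs:re]
        if not (set(left) <= _VALID_BASES and set(right) <= _VALID_BASES):
            log.warning("locus %s round %d: seed contains ambiguous bases; round dropped",
                        locus.name, i)
            continue
        seeds.append(PairedSeed(locus.name, i, left, right, (ls, le), (rs, re)))
    return seeds


def make_alignment_reference(locus: StrLocus, cfg: SeedConfig,
                             reference: Mapping[str, str]) -> str:
    """Extract ``ref[P_start - flank_len, P_end + flank_len)`` for alignment.

    A flank that would be truncated at a contig boundary is an error, not a
    silent clip, because downstream span arithmetic assumes full flanks.
    """
    if locus.chrom not in reference:
        raise LocusError(f"locus {locus.name}: chrom {locus.chrom!r} missing from reference")
    seq = reference[locus.chrom].upper()
    lo, hi = locus.start - cfg.flank_len, locus.end + cfg.flank_len
    if lo < 0 or hi > len(seq):
        raise LocusError(
            f"locus {locus.name}: {cfg.flank_len} bp flanks do not fit on contig "
            f"{locus.chrom} (length {len(seq)})"
        )
    return seq[lo:hi]
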