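"""Exact-seed read harvesting (dataset1).

For each paired seed, scan every read for an exact occurrence of both seeds
in consistent order and measure the target segment enclosed between them.
"Complete matching" is exact substring matching — no mismatches — which is
what makes the harvested lengths trustworthy at high per-base error rates:
a read only contributes when its flanking anchors are sequenced perfectly.

Both orientations of a read are searched; the forward orientation is tried
first and, if it yields a consistent seed pair, the reverse complement is
not also counted (one contribution per read per round).  When a seed occurs
more than once, the leftmost left-seed occurrence is paired with the nearest
right-seed occurrence after it — deterministic, and robust to chimeric or
concatemer reads.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, List, Optional

from .errors import ValidationError
from .loci import PairedSeed

log = logging.getLogger(__name__)

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read.  Quality is informational only; it is never filtered on."""

    read_id: str
    sequence: str
    mean_quality: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"read {self.read_id}: empty sequence")


@dataclass(frozen=True)
class HarvestHit:
    """One harvested target: the segment strictly between the two seed matches.

    ``query`` is the matched segment including both seeds
    (left_seed + target + right_seed) as spelled in the read orientation in
    which the seeds were found; it is what gets aligned for dataset2.
    """

    read_id: str
    target_length: int
    query: str


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream a FASTQ or FASTQ.gz file as ReadRecords (description text tolerated)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip().upper()
            fh.readline()  # '+'
            fh.readline()  # quality
            if not header.startswith("@"):
                raise ValidationError(f"{path}: malformed FASTQ record near {header!r}")
            yield ReadRecord(header[1:].split()[0], seq)


def _find_pair(seq: str, left: str, right: str):
    """Leftmost left-seed occurrence, then nearest right-seed occurrence after it.

    Returns (left_pos, right_pos) or None.  Any right occurrence before or
    overlapping the left match end (negative gap) is never considered because
    the search starts at the left match end.
    """
    p = seq.find(left)
    if p == -1:
        return None
    q = seq.find(right, p + len(left))
    if q == -1:
        return None
    return p, q


def harvest_round(reads: Iterable[ReadRecord], seed: PairedSeed) -> List[HarvestHit]:
    """Extract one target length per read that completely matches both seeds."""
    if not (seed.left_seed and seed.right_seed):
        raise ValidationError("paired seed has an empty side")
    hits: List[HarvestHit] = []
    multi = 0
    llen = len(seed.left_seed)
    for read in reads:
        seq = read.sequence
        pair = _find_pair(seq, seed.left_seed, seed.right_seed)
        if pair is None:
            seq = revcomp(seq)
            pair = _find_pair(seq, seed.left_seed, seed.right_seed)
            if pair is None:
                continue
        p, q = pair
        if seq.find(seed.left_seed, p + 1) != -1 or seq.find(seed.right_seed, q + 1) != -1:
            multi += 1
        hits.append(HarvestHit(read.read_id, q - (p + llen),
                               seq[p:q + len(seed.right_seed)]))
    if multi:
        log.debug("round %d: %d reads had multiple seed occurrences (first pairing used)",
                  seed.round_index, multi)
    return hits
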