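"""Rank-intersection filtering and mode-based diploid genotype calling.

Per sampling round, the exact-seed length distribution (dataset1) is
cross-checked against the alignment-span distribution (dataset2); surviving
lengths are reduced to a one- or two-allele round genotype by supported-read
ratio; the N round genotypes are then combined by mode, zygosity is decided
by a support-ratio threshold, and an order-of-magnitude secondary correction
demotes minor alleles that look like background noise.  Finally allele
lengths are converted to repeat counts on the locus motif ladder.

Intersection semantics.  Because local alignment bridges allele-length
differences with gaps, subject spans are pulled toward the reference span:
dataset2 measures how many *credible* length classes the data supports far
better than it measures their exact values.  The default ``"rank"`` mode
therefore keeps a dataset1 length when the minimum rank difference to any
dataset2 entry is below the threshold — dataset2 bounds the rank depth of
dataset1 classes accepted as real, while dataset1 (exact-match evidence)
supplies the lengths and counts.  The alternative ``"length"`` mode requires
the same length (after removing the seed context from spans) in both
datasets with a small rank difference; it is stricter and collapses
non-reference alleles whenever alignment absorbs their indels, so it is kept
only for comparison.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import ConfigurationError
from .lnr import LNRDataset
from .loci import StrLocus


@dataclass(frozen=True)
class GenotyperConfig:
    """Thresholds for steps 3-4 of the algorithm.

    * ``max_rank_diff`` — exclusive bound on the (minimum) rank difference in
      the dataset1/dataset2 intersection (default 3).
    * ``support_ratio`` — within a round, keep only the top length when
      top_count/second_count exceeds this (default 3, exclusive).
    * ``mode_ratio`` — at the combination step, call homozygous when the
      support ratio of the two top alleles is at least this (default 3,
      inclusive).
    * ``magnitude_gap`` — secondary correction factor: a minor allele whose
      support is this many times below the major allele's is demoted as
      background noise (default 10, one order of magnitude).
    """

    max_rank_diff: int = 3
    support_ratio: float = 3.0
    mode_ratio: float = 3.0
    magnitude_gap: float = 10.0
    intersect_mode: str = "rank"
    mode_ratio_source: str = "support"

    def __post_init__(self) -> None:
        for name in ("max_rank_diff", "support_ratio", "mode_ratio", "magnitude_gap"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.intersect_mode not in ("rank", "length"):
            raise ConfigurationError(f"unknown intersect_mode {self.intersect_mode!r}")
        if self.mode_ratio_source not in ("support", "votes"):
            raise ConfigurationError(f"unknown mode_ratio_source {self.mode_ratio_source!r}")


@dataclass(frozen=True)
class JointEntry:
    """A dataset1 length that survived the intersection, with its dataset1
    count (exact-match evidence) and the ranks it held in both datasets."""

    length: int
    count: int
    rank_d1: int
    rank_d2: int
    d2_count: Optional[int] = None


@dataclass
class RoundGenotype:
    locus_name: str
    round_index: int
    alleles: List[Tuple[int, int]]  # (length, count), sorted by length
    joint_entries: List[JointEntry] = field(default_factory=list)

    @property
    def key(self) -> Tuple[int, ...]:
        return tuple(length for length, _ in self.alleles)


@dataclass
class GenotypeCall:
    """Final one- or two-allele call for a locus."""

    locus_name: str
    allele_lengths: List[int]
    zygosity: str  # homozygous | heterozygous | no-call
    support: List[int]
    rounds_agreeing: int = 0
    rounds_informative: int = 0
    allele_repeats: Optional[List[int]] = None
    corrected: bool = False
    flags: List[str] = field(default_factory=list)
    reason: Optional[str] = None

    def repeat_set(self) -> Optional[frozenset]:
        if self.allele_repeats is None:
            return None
        return frozenset(self.allele_repeats)


def intersect_round(d1: LNRDataset, d2: LNRDataset, cfg: GenotyperConfig,
                    seed_context: int = 0) -> List[JointEntry]:
    """Intersect one round's dataset1 with dataset2.

    ``seed_context`` is the total seed length included in the alignment
    queries (2*d*i) and is subtracted from dataset2 spans so both datasets
    measure the bare target region.  Either dataset being empty yields an
    empty joint set (the round abstains).
    """
    if not d1 or not d2:
        return []
    d2_by_length = {e.length - seed_context: e for e in d2.entries}
    d2_ranks = [e.rank for e in d2.entries]
    joint: List[JointEntry] = []
    for e1 in d1.entries:
        if cfg.intersect_mode == "length":
            e2 = d2_by_length.get(e1.length)
            if e2 is not None and abs(e1.rank - e2.rank) < cfg.max_rank_diff:
                joint.append(JointEntry(e1.length, e1.count, e1.rank, e2.rank, e2.count))
        else:  # "rank": minimum rank difference over all dataset2 entries
            nearest = min(d2_ranks, key=lambda r2: (abs(e1.rank - r2), r2))
            if abs(e1.rank - nearest) < cfg.max_rank_diff:
                e2 = d2_by_length.get(e1.length)
                joint.append(JointEntry(e1.length, e1.count, e1.rank, nearest,
                                        e2.count if e2 else None))
    return joint


def call_round(joint: Sequence[JointEntry], locus_name: str, round_index: int,
               cfg: GenotyperConfig) -> Optional[RoundGenotype]:
    """One- or two-allele genotype for a single round; None when the round abstains.

    The top length by supported read number is kept alone when its count
    exceeds ``support_ratio`` times the runner-up's (exclusive) or when it is
    the only entry; otherwise the top two lengths are kept.
    """
    if not joint:
        return None
    ordered = sorted(joint, key=lambda e: (-e.count, e.length))
    top = ordered[0]
    if len(ordered) == 1 or top.count > cfg.support_ratio * ordered[1].count:
        alleles = [(top.length, top.count)]
    else:
        second = ordered[1]
        alleles = sorted([(top.length, top.count), (second.length, second.count)])
    return RoundGenotype(locus_name, round_index, alleles, list(joint))


def combine_rounds(rounds: Sequence[Optional[RoundGenotype]],
                   cfg: GenotyperConfig) -> GenotypeCall:
    """Combine the N round genotypes by mode and decide zygosity.

    The most frequent allele set across informative rounds wins (ties broken
    by larger pooled supported-read count, then by the lexicographically
    smaller allele set).  Zygosity of a two-allele mode: homozygous when the
    pooled support of the top allele over mode-agreeing rounds is at least
    ``mode_ratio`` times the second allele's (with ``mode_ratio_source=
    "votes"``, the round-vote counts of the best and second-best allele sets
    are compared instead).
    """
    informative = [r for r in rounds if r is not None]
    if not informative:
        return GenotypeCall("", [], "no-call", [], reason="insufficient evidence")
    locus_name = informative[0].locus_name

    votes: Counter = Counter(r.key for r in informative)
    pooled: Dict[Tuple[int, ...], Dict[int, int]] = defaultdict(lambda: defaultdict(int))
    for r in informative:
        for length, count in r.alleles:
            pooled[r.key][length] += count
    ranked = sorted(votes, key=lambda k: (-votes[k], -sum(pooled[k].values()), k))
    mode_key = ranked[0]
    support_by_len = pooled[mode_key]

    lengths = list(mode_key)
    supports = [support_by_len[l] for l in lengths]
    if len(lengths) == 1:
        zygosity = "homozygous"
    else:
        by_support = sorted(lengths, key=lambda l: -support_by_len[l])
        major, minor = by_support[0], by_support[1]
        if cfg.mode_ratio_source == "votes":
            second_votes = votes[ranked[1]] if len(ranked) > 1 else 0
            ratio = votes[mode_key] / second_votes if second_votes else float("inf")
        else:
            ratio = (support_by_len[major] / support_by_len[minor]
                     if support_by_len[minor] else float("inf"))
        if ratio >= cfg.mode_ratio:
            zygosity = "homozygous"
            lengths, supports = [major], [support_by_len[major]]
        else:
            zygosity = "heterozygous"
    return GenotypeCall(locus_name, lengths, zygosity, supports,
                        rounds_agreeing=votes[mode_key],
                        rounds_informative=len(informative))


def secondary_correction(call: GenotypeCall, cfg: GenotyperConfig) -> GenotypeCall:
    """Demote a minor allele whose support is an order of magnitude below the
    major allele's; such classes are background noise, not a second allele."""
    if len(call.allele_lengths) != 2:
        return call
    (l1, s1), (l2, s2) = zip(call.allele_lengths, call.support)
    major, minor = ((l1, s1), (l2, s2)) if s1 >= s2 else ((l2, s2), (l1, s1))
    if minor[1] == 0 or major[1] / minor[1] >= cfg.magnitude_gap:
        return replace(call, allele_lengths=[major[0]], support=[major[1]],
                       zygosity="homozygous", corrected=True)
    return call


def lengths_to_repeats(call: GenotypeCall, locus: StrLocus) -> GenotypeCall:
    """Convert allele lengths (bp) to repeat counts on the locus motif ladder.

    ``repeats = ref_repeats + round((length - ref_tract_length)/motif_length)``;
    a length off the motif ladder is rounded to the nearest rung (ties to
    even) and flagged ``off-ladder``.  A negative computed repeat count voids
    the call.
    """
    if call.zygosity == "no-call" or not call.allele_lengths:
        return call
    mlen = len(locus.motif)
    repeats: List[int] = []
    flags = list(call.flags)
    for length in call.allele_lengths:
        delta = length - locus.tract_length
        rep = locus.ref_repeats + round(delta / mlen)
        if delta % mlen != 0:
            flags.append(f"off-ladder:{length}")
        if rep < 0:
            return replace(call, zygosity="no-call", allele_repeats=None,
                           reason=f"negative repeat count for length {length}",
                           flags=flags)
        repeats.append(rep)
    return replace(call, allele_repeats=repeats, flags=flags)


def genotype_rounds(d1_rounds: Sequence[LNRDataset], d2_rounds: Sequence[LNRDataset],
                    seed_contexts: Sequence[int], locus: StrLocus,
                    cfg: GenotyperConfig) -> Tuple[GenotypeCall, List[Optional[RoundGenotype]]]:
    """Run steps 3-4 over paired per-round LNR datasets and finalize the call."""
    round_calls: List[Optional[RoundGenotype]] = []
    for d1, d2, ctx in zip(d1_rounds, d2_rounds, seed_contexts):
        joint = intersect_round(d1, d2, cfg, seed_context=ctx)
        round_calls.append(call_round(joint, locus.name, d1.round_index, cfg))
    call = combine_rounds(round_calls, cfg)
    if call.zygosity != "no-call":
        call.locus_name = locus.name
    else:
        call = replace(call, locus_name=locus.name)
    call = secondary_correction(call, cfg)
    call = lengths_to_repeats(call, locus)
    return call, round_calls
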