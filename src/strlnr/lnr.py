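"""Length-number-rank (LNR) summaries.

The central statistic of the genotyper: for one sampling round, the distinct
target-sequence lengths observed, each with its supporting read count
("supported read number"), ranked by descending count.  Ranks are consecutive
integers starting at 1; ties in count are broken by ascending length, so the
ranking is deterministic (dense "1,2,3" ranking, never competition-style
"1,2,2,4").
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import pandas as pd


@dataclass(frozen=True)
class LNREntry:
    length: int
    count: int
    rank: int


@dataclass
class LNRDataset:
    """All LNR entries for one locus and one sampling round.

    ``source`` is ``"seed-match"`` for exact-seed harvesting (dataset1) and
    ``"alignment"`` for alignment subject spans (dataset2).
    """

    locus_name: str
    round_index: int
    source: str
    entries: List[LNREntry] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(e.count for e in self.entries)

    @property
    def lengths(self) -> List[int]:
        return [e.length for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __bool__(self) -> bool:
        return bool(self.entries)


def build_lnr(pairs: Iterable[Tuple[str, int]], locus_name: str, round_index: int,
              source: str) -> LNRDataset:
    """Summarize harvested ``(read_id, length)`` pairs into an LNR dataset.

    Lengths are tallied, sorted by descending count (ties: ascending length),
    and ranked 1..K.  An empty input yields an empty dataset, which downstream
    logic treats as an abstaining round.
    """
    counts = Counter(length for _, length in pairs)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    entries = [LNREntry(length, count, rank)
               for rank, (length, count) in enumerate(ordered, start=1)]
    return LNRDataset(locus_name, round_index, source, entries)


def lnr_frame(datasets: Sequence[LNRDataset]) -> pd.DataFrame:
    """Flatten LNR datasets into a tidy table (locus, source, round, length, count, rank)."""
    rows = [
        {"locus": ds.locus_name, "source": ds.source, "round": ds.round_index,
         "length": e.length, "count": e.count, "rank": e.rank}
        for ds in datasets for e in ds.entries
    ]
    return pd.DataFrame(rows, columns=["locus", "source", "round", "length", "count", "rank"])


def write_lnr_tsv(datasets: Sequence[LNRDataset], path) -> None:
    lnr_frame(datasets).to_csv(path, sep="\t", index=False)
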