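"""Flank alignment (dataset2).

Each harvested query (matched seeds plus enclosed target) is locally aligned
against the locus reference — the STR tract extended by ``flank_len`` on each
side — and the subject-side span of the best alignment becomes the read's
alignment-based length estimate.  Hits are filtered by substitution count
(mismatches strictly below a threshold; gap columns are counted separately,
matching BLAST tabular semantics where gap lengths are not itemized).

Two backends produce the same 12-field tabular ("m8") records:

* ``internal`` — edlib in infix (HW) mode: the whole query is aligned at its
  best location inside the reference under unit edit costs, on both strands.
  ``bit_score`` is a simple surrogate (matches − mismatches − gap bases) and
  ``e_value`` is reported as 0.0; both are only used for best-hit selection.
* ``external-blast`` — a BLAST+ ``blastn`` executable (``-task blastn
  -dust no -outfmt 6``); low-complexity filtering is disabled because bare
  repeat tracts are by construction low-complexity.

Only the single best hit per query is kept (highest bit score, then longest
alignment, then smallest subject start), since LNR counting needs exactly one
span per read.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import edlib

from .errors import BackendError, ConfigurationError
from .harvest import revcomp

M8_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_openings", "query_start", "query_end",
    "subject_start", "subject_end", "e_value", "bit_score",
]


@dataclass(frozen=True)
class AlignmentHit:
    """One BLAST-m8-equivalent alignment record (1-based inclusive coordinates).

    Coordinates are strand-normalized so ``subject_start <= subject_end``.
    ``raw`` preserves the original tabular fields when the hit was parsed from
    backend output, so re-serialization is byte-faithful.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_openings: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    e_value: float
    bit_score: float
    raw: Optional[Tuple[str, ...]] = field(default=None, compare=False)

    @property
    def subject_span(self) -> int:
        return self.subject_end - self.subject_start + 1


@dataclass(frozen=True)
class AlignConfig:
    """Alignment filtering and backend selection.

    ``max_mismatches`` is an exclusive bound: hits are kept when
    ``mismatches < max_mismatches`` (default 3, i.e. 0-2 substitutions).
    """

    max_mismatches: int = 3
    backend: str = "internal"
    blast_exe: str = "blastn"

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ConfigurationError("max_mismatches must be >= 0")
        if self.backend not in ("internal", "external-blast"):
            raise ConfigurationError(f"unknown aligner backend {self.backend!r}")


def _cigar_stats(cigar: str) -> Tuple[int, int, int, int, int]:
    """(matches, mismatches, gap_openings, gap_bases, alignment_length) from an
    extended cigar (=, X, I, D)."""
    matches = mismatches = gap_open = gap_bases = aln_len = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        aln_len += n
        if ch == "=":
            matches += n
        elif ch == "X":
            mismatches += n
        else:  # I or D
            gap_open += 1
            gap_bases += n
    return matches, mismatches, gap_open, gap_bases, aln_len


def _align_one_internal(query: str, reference: str, query_id: str,
                        subject_id: str) -> Optional[AlignmentHit]:
    """Best infix alignment of the full query on either strand of the reference."""
    best = None
    for oriented in (query, revcomp(query)):
        res = edlib.align(oriented, reference, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        if best is None or res["editDistance"] < best[0]["editDistance"]:
            best = (res, oriented)
    if best is None:
        return None
    res, oriented = best
    start, end = res["locations"][0]
    matches, mismatches, gap_open, gap_bases, aln_len = _cigar_stats(res["cigar"])
    score = float(matches - mismatches - gap_bases)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        percent_identity=round(100.0 * matches / aln_len, 3) if aln_len else 0.0,
        alignment_length=aln_len,
        mismatches=mismatches,
        gap_openings=gap_open,
        query_start=1,
        query_end=len(query),
        subject_start=start + 1,
        subject_end=end + 1,
        e_value=0.0,
        bit_score=score,
    )


def _best_hits(hits: Sequence[AlignmentHit]) -> Dict[str, AlignmentHit]:
    """Single best hit per query: bit score, then alignment length, then
    smallest subject start for determinism."""
    best: Dict[str, AlignmentHit] = {}
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None or (hit.bit_score, hit.alignment_length, -hit.subject_start) > (
                cur.bit_score, cur.alignment_length, -cur.subject_start):
            best[hit.query_id] = hit
    return best


def _run_blast(queries: Sequence[Tuple[str, str]], reference: str,
               cfg: AlignConfig) -> List[AlignmentHit]:
    with tempfile.TemporaryDirectory(prefix="strlnr_blast_") as tmp:
        qpath = Path(tmp) / "queries.fa"
        spath = Path(tmp) / "subject.fa"
        qpath.write_text("".join(f">{qid}\n{seq}\n" for qid, seq in queries))
        spath.write_text(f">ref\n{reference}\n")
        cmd = [cfg.blast_exe, "-task", "blastn", "-dust", "no",
               "-query", str(qpath), "-subject", str(spath), "-outfmt", "6"]
        try:
            proc = subprocess.run(cmd, capture_output=True, text=True, check=True)
        except FileNotFoundError as exc:
            raise BackendError(f"BLAST executable not found: {cfg.blast_exe}") from exc
        except subprocess.CalledProcessError as exc:
            raise BackendError(f"blastn failed: {exc.stderr.strip()}") from exc
    return parse_m8(proc.stdout)


def parse_m8(text: str) -> List[AlignmentHit]:
    """Parse BLAST tabular (outfmt 6 / m8) output, normalizing minus-strand
    hits so subject_start < subject_end, and retaining raw fields."""
    hits: List[AlignmentHit] = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = tuple(line.rstrip("\n").split("\t"))
        if len(f) != 12:
            raise BackendError(f"malformed m8 line ({len(f)} fields): {line!r}")
        sstart, send = int(f[8]), int(f[9])
        if sstart > send:
            sstart, send = send, sstart
        hits.append(AlignmentHit(
            query_id=f[0], subject_id=f[1], percent_identity=float(f[2]),
            alignment_length=int(f[3]), mismatches=int(f[4]), gap_openings=int(f[5]),
            query_start=int(f[6]), query_end=int(f[7]),
            subject_start=sstart, subject_end=send,
            e_value=float(f[10]), bit_score=float(f[11]), raw=f,
        ))
    return hits


def write_m8(hits: Sequence[AlignmentHit]) -> str:
    """Serialize hits as 12-column tabular text; parsed hits round-trip their
    original printed precision via ``raw``."""
    lines = []
    for h in hits:
        if h.raw is not None:
            lines.append("\t".join(h.raw))
        else:
            lines.append("\t".join(str(v) for v in (
                h.query_id, h.subject_id, f"{h.percent_identity:.3f}",
                h.alignment_length, h.mismatches, h.gap_openings,
                h.query_start, h.query_end, h.subject_start, h.subject_end,
                f"{h.e_value:g}", f"{h.bit_score:g}")))
    return "\n".join(lines) + ("\n" if lines else "")


def align_round(targets: Sequence[Tuple[str, str]], reference: str,
                cfg: AlignConfig) -> List[AlignmentHit]:
    """Align each (read_id, query) against the locus reference; one best hit per query.

    Identical query sequences are aligned once and the hit replicated per
    read, which is a large saving on low-error data.
    """
    if not targets:
        return []
    if cfg.backend == "internal":
        cache: Dict[str, Optional[AlignmentHit]] = {}
        out: List[AlignmentHit] = []
        for read_id, seq in targets:
            if seq not in cache:
                cache[seq] = _align_one_internal(seq, reference, "q", "ref")
            proto = cache[seq]
            if proto is not None:
                out.append(AlignmentHit(**{**proto.__dict__, "query_id": read_id}))
        return out

    # external-blast: dedupe sequences, one representative query each
    seq_to_qid: Dict[str, str] = {}
    for _, seq in targets:
        if seq not in seq_to_qid:
            seq_to_qid[seq] = f"q{len(seq_to_qid)}"
    raw_hits = _run_blast([(qid, seq) for seq, qid in seq_to_qid.items()], reference, cfg)
    best = _best_hits(raw_hits)
    out = []
    for read_id, seq in targets:
        proto = best.get(seq_to_qid[seq])
        if proto is not None:
            out.append(AlignmentHit(**{**proto.__dict__, "query_id": read_id, "raw": None}))
    return out


def hits_to_lengths(hits: Sequence[AlignmentHit],
                    cfg: AlignConfig) -> List[Tuple[str, int]]:
    """Subject-span lengths of hits passing the substitution filter.

    ``span = subject_end - subject_start + 1`` under the 1-based inclusive m8
    convention; hits with ``mismatches >= max_mismatches`` are discarded (the
    bound is exclusive: with the default 3, a 2-mismatch hit is kept and a
    3-mismatch hit is not).
    """
    return [(h.query_id, h.subject_span) for h in hits
            if h.mismatches < cfg.max_mismatches]
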