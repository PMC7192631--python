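"""Sequence I/O, adapter trimming and local alignment with soft clips.

Trimming follows tagmentation-library semantics: the longest read suffix
matching a prefix of the adapter (allowing a bounded mismatch fraction) is
removed, and reads that end up shorter than a minimum length are discarded.

Alignment is best-score local (Smith-Waterman, affine gaps) of a read
against a single amplicon, with unaligned read ends reported as soft clips.
The scoring defaults mirror a local short-read mapper (match +2, mismatch
-6, gap open -5, gap extend -3) with a floor below which a read counts as
unaligned. Ties are broken deterministically: leftmost reference start,
then fewest gap openings. Pre-aligned records can also be ingested from
SAM, so an external mapper may replace the internal aligner.
"""

from __future__ import annotations

import functools
import gzip
import re
from dataclasses import dataclass
from itertools import islice
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam
from Bio import Align

from .guide_model import TargetRegion, revcomp

DEFAULT_ADAPTER = "CTGTCTCTTATACACATCTCTGAGCGGGCTGGCAAGGCAGACCG"

_CIGAR_RE = re.compile(r"(\d+)([MIDNSH])")
_QUERY_OPS = frozenset("MIS")
_REF_OPS = frozenset("MDN")


@dataclass(frozen=True)
class TrimConfig:
    adapter: str = DEFAULT_ADAPTER
    min_overlap: int = 7
    min_length: int = 30
    max_error_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.min_length < 0:
            raise ValueError("min_length must be >= 0")


@dataclass(frozen=True)
class TrimResult:
    sequence: str
    quality: str | None
    removed_bp: int
    discarded: bool


def trim_adapter(sequence: str, quality: str | None = None,
                 config: TrimConfig | None = None) -> TrimResult:
    """Remove the longest adapter-prefix suffix of a read.

    A suffix of at least ``min_overlap`` bases is removed when its mismatch
    fraction against the adapter prefix is at most ``max_error_rate``
    (mismatch budget rounded down). Reads shorter than ``min_length`` after
    trimming are flagged discarded.
    """
    config = config or TrimConfig()
    if not sequence:
        raise ValueError("empty read")
    adapter = config.adapter
    removed = 0
    for k in range(min(len(sequence), len(adapter)), config.min_overlap - 1, -1):
        suffix = sequence[-k:]
        budget = int(k * config.max_error_rate)
        mismatches = sum(a != b for a, b in zip(suffix, adapter))
        if mismatches <= budget:
            removed = k
            break
    trimmed = sequence[:-removed] if removed else sequence
    qual = quality[:len(trimmed)] if quality is not None else None
    return TrimResult(sequence=trimmed, quality=qual, removed_bp=removed,
                      discarded=len(trimmed) < config.min_length)


@dataclass(frozen=True)
class Scoring:
    """Affine local-alignment scoring with an alignment-score floor.

    ``min_anchor`` guards against alignment creep at large-gap junctions:
    a terminal match segment shorter than this that hangs off a gap is
    folded back into the soft clip (short coincidental matches past a
    junction otherwise out-score a clean clip).
    """

    match: int = 2
    mismatch: int = -6
    gap_open: int = -5
    gap_extend: int = -3
    min_score: int = 20
    min_anchor: int = 12


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if not ops or "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


def cigar_query_length(ops: Iterable[tuple[int, str]]) -> int:
    """Read bases consumed by a CIGAR (M, I, S; hard clips excluded)."""
    return sum(n for n, op in ops if op in _QUERY_OPS)


def cigar_reference_span(ops: Iterable[tuple[int, str]]) -> int:
    """Reference bases spanned by a CIGAR (M, D, N)."""
    return sum(n for n, op in ops if op in _REF_OPS)


@dataclass(frozen=True)
class AlignmentRecord:
    """A local alignment of one read against one amplicon."""

    read_id: str
    region: str
    pos: int
    strand: str
    cigar: str
    seq: str
    qual: str | None = None
    score: float = 0.0

    def __post_init__(self) -> None:
        if cigar_query_length(self.ops) != len(self.seq):
            raise ValueError(f"inconsistent record {self.read_id}: "
                             f"CIGAR {self.cigar} does not consume the read")

    @functools.cached_property
    def ops(self) -> list[tuple[int, str]]:
        return parse_cigar(self.cigar)

    @property
    def ref_span(self) -> int:
        return cigar_reference_span(self.ops)

    @property
    def clip5(self) -> str:
        n, op = self.ops[0]
        return self.seq[:n] if op == "S" else ""

    @property
    def clip3(self) -> str:
        n, op = self.ops[-1]
        return self.seq[len(self.seq) - n:] if op == "S" else ""


@functools.lru_cache(maxsize=8)
def _get_aligner(match: int, mismatch: int, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _blocks_to_cigar(target_blocks, query_blocks, read_length: int) -> tuple[str, int, int]:
    """CIGAR with soft clips from aligned coordinate blocks.

    Returns (cigar, reference_start, gap_openings).
    """
    parts: list[str] = []
    gaps = 0
    lead = int(query_blocks[0][0])
    if lead:
        parts.append(f"{lead}S")
    for i, (tb, qb) in enumerate(zip(target_blocks, query_blocks)):
        if i:
            d_ref = int(tb[0]) - int(target_blocks[i - 1][1])
            d_query = int(qb[0]) - int(query_blocks[i - 1][1])
            if d_ref:
                parts.append(f"{d_ref}D")
                gaps += 1
            if d_query:
                parts.append(f"{d_query}I")
                gaps += 1
        parts.append(f"{int(tb[1]) - int(tb[0])}M")
    tail = read_length - int(query_blocks[-1][1])
    if tail:
        parts.append(f"{tail}S")
    return "".join(parts), int(target_blocks[0][0]), gaps


def trim_weak_anchors(ops: list[tuple[int, str]], ref_start: int,
                      min_anchor: int) -> tuple[list[tuple[int, str]], int]:
    """Fold sub-anchor terminal match segments (and their gaps) into soft clips.

    A terminal M run shorter than ``min_anchor`` separated from the
    alignment body by an I/D is converted to S, iteratively from both
    ends, provided matched sequence remains. Query consumption is
    preserved; the returned reference start reflects leading trims.
    """
    ops = list(ops)
    changed = True
    while changed:
        changed = False
        lead = ops[0][0] if ops and ops[0][1] == "S" else 0
        i = 1 if lead else 0
        if (i + 1 < len(ops) and ops[i][1] == "M" and ops[i][0] < min_anchor
                and ops[i + 1][1] in "DI"
                and any(op == "M" for _, op in ops[i + 2:])):
            m = ops[i][0]
            gap_n, gap_op = ops[i + 1]
            ref_start += m + (gap_n if gap_op == "D" else 0)
            new_s = lead + m + (gap_n if gap_op == "I" else 0)
            ops = [(new_s, "S")] + ops[i + 2:]
            changed = True
            continue
        tail = ops[-1][0] if ops and ops[-1][1] == "S" else 0
        j = len(ops) - 2 if tail else len(ops) - 1
        if (j - 1 >= 0 and ops[j][1] == "M" and ops[j][0] < min_anchor
                and ops[j - 1][1] in "DI"
                and any(op == "M" for _, op in ops[:j - 1])):
            m = ops[j][0]
            gap_n, gap_op = ops[j - 1]
            new_s = tail + m + (gap_n if gap_op == "I" else 0)
            ops = ops[:j - 1] + [(new_s, "S")]
            changed = True
    return ops, ref_start


def best_local_alignment(query: str, target: str, scoring: Scoring,
                         max_alternatives: int = 16):
    """Best local alignment of ``query`` in ``target``.

    Returns ``(score, cigar, reference_start, query_start, query_end,
    n_distinct_placements)`` or None when no alignment reaches the score
    floor. Among co-optimal alignments the leftmost reference start wins,
    then the fewest gap openings; ``n_distinct_placements`` counts distinct
    (reference start, reference end) placements among the alternatives
    examined, for ambiguity detection.
    """
    aligner = _get_aligner(scoring.match, scoring.mismatch,
                           scoring.gap_open, scoring.gap_extend)
    alignments = aligner.align(target, query)
    try:
        score = alignments.score
    except (ValueError, IndexError, AttributeError):
        return None
    if score < scoring.min_score:
        return None
    best = None
    placements = set()
    for aln in islice(alignments, max_alternatives):
        target_blocks, query_blocks = aln.aligned
        if len(target_blocks) == 0:
            continue
        cigar, ref_start, _ = _blocks_to_cigar(target_blocks, query_blocks, len(query))
        ops, ref_start = trim_weak_anchors(parse_cigar(cigar), ref_start,
                                           scoring.min_anchor)
        if not any(op == "M" for _, op in ops):
            continue
        cigar = "".join(f"{n}{op}" for n, op in ops)
        gaps = sum(1 for _, op in ops if op in "DI")
        query_start = ops[0][0] if ops[0][1] == "S" else 0
        query_end = len(query) - (ops[-1][0] if ops[-1][1] == "S" else 0)
        ref_end = ref_start + cigar_reference_span(ops)
        placements.add((ref_start, ref_end))
        key = (ref_start, gaps, cigar)
        if best is None or key < best[0]:
            best = (key, cigar, ref_start, query_start, query_end)
    if best is None:
        return None
    return (score, best[1], best[2], best[3], best[4], len(placements))


def align_local(seq: str, region: TargetRegion, scoring: Scoring | None = None,
                read_id: str = "read", qual: str | None = None,
                try_reverse: bool = True,
                max_alternatives: int = 16) -> AlignmentRecord | None:
    """Align one read locally against one amplicon; None when unaligned."""
    scoring = scoring or Scoring()
    if not seq:
        raise ValueError("empty read")
    # fast path: unique exact substring match
    idx = region.sequence.find(seq)
    if idx >= 0 and region.sequence.find(seq, idx + 1) < 0 \
            and region.sequence.find(revcomp(seq)) < 0:
        score = scoring.match * len(seq)
        if score >= scoring.min_score:
            return AlignmentRecord(read_id=read_id, region=region.name, pos=idx,
                                   strand="+", cigar=f"{len(seq)}M", seq=seq,
                                   qual=qual, score=score)
        return None
    fwd = best_local_alignment(seq, region.sequence, scoring, max_alternatives)
    rev = None
    if try_reverse:
        rev = best_local_alignment(revcomp(seq), region.sequence, scoring, max_alternatives)
    if fwd is None and rev is None:
        return None
    if rev is not None and (fwd is None or rev[0] > fwd[0]):
        chosen, strand = rev, "-"
        oriented_seq = revcomp(seq)
        oriented_qual = qual[::-1] if qual is not None else None
    else:
        chosen, strand = fwd, "+"
        oriented_seq, oriented_qual = seq, qual
    score, cigar, ref_start, _, _, _ = chosen
    return AlignmentRecord(read_id=read_id, region=region.name, pos=ref_start,
                           strand=strand, cigar=cigar, seq=oriented_seq,
                           qual=oriented_qual, score=score)


# ---------------------------------------------------------------------------
# FASTQ / SAM

def _open_text(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read id, sequence, quality string) from a FASTQ file."""
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            yield header.strip()[1:].split()[0], seq, qual


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def write_sam(records: Iterable[AlignmentRecord], path: str | Path,
              regions: Mapping[str, TargetRegion]) -> None:
    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": r.name, "LN": len(r)} for r in regions.values()]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.read_id
            seg.flag = 16 if rec.strand == "-" else 0
            seg.reference_id = out.get_tid(rec.region)
            seg.reference_start = rec.pos
            seg.mapping_quality = 60
            seg.cigarstring = rec.cigar
            seg.query_sequence = rec.seq
            if rec.qual is not None:
                seg.query_qualities = pysam.qualitystring_to_array(rec.qual)
            seg.set_tag("AS", int(rec.score))
            out.write(seg)


def read_sam(path: str | Path) -> tuple[list[AlignmentRecord], dict]:
    """Parse mapped SAM records into AlignmentRecords.

    Unmapped records are skipped and counted; records our model cannot
    represent are collected as (read id, message) pairs in ``info['errors']``.
    """
    records: list[AlignmentRecord] = []
    info = {"unmapped_skipped": 0, "errors": []}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.cigarstring is None or seg.query_sequence is None:
                info["unmapped_skipped"] += 1
                continue
            try:
                qual = None
                if seg.query_qualities is not None:
                    qual = pysam.array_to_qualitystring(seg.query_qualities)
                score = float(seg.get_tag("AS")) if seg.has_tag("AS") else 0.0
                records.append(AlignmentRecord(
                    read_id=seg.query_name, region=seg.reference_name,
                    pos=seg.reference_start,
                    strand="-" if seg.is_reverse else "+",
                    cigar=seg.cigarstring, seq=seg.query_sequence,
                    qual=qual, score=score))
            except ValueError as exc:
                info["errors"].append((seg.query_name, str(exc)))
    return records, info
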