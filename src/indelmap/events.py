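"""Indel event primitives shared by the simulator, caller and statistics layers.

An event is a deletion (kind ``D``), an insertion (kind ``I``) or a large
gap (kind ``L``, a deletion that either spans at least ``LARGE_GAP_MIN_BP``
reference bases or carries embedded inserted sequence at the junction).
Coordinates are 0-based half-open intervals on the forward strand of the
amplicon named by ``region``; insertions have ``start == end`` at the
insertion point.

Because the same physical edit admits several equivalent alignment
representations (a deletion flanked by repeats can shift, inserted bases
that match the reference can be absorbed into flanking matches), every
event is stored in a canonical form: matching bases are stripped from the
inserted sequence against both edges of the deleted interval, and the
remaining pure deletion or insertion is left-aligned. Both the simulator's
ground truth and the caller's output pass through :func:`canonicalize_indel`,
so representation-equivalent calls compare equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

#: pure deletions at least this long are reported as large gaps (kind L)
LARGE_GAP_MIN_BP = 40

_VALID_KINDS = frozenset("DIL")


@dataclass(frozen=True)
class IndelEvent:
    """A called or simulated mutation on one amplicon."""

    kind: str
    region: str
    start: int
    end: int
    inserted_seq: str = ""
    sample: str | None = None
    support: int = 1

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.kind == "I":
            if self.start != self.end:
                raise ValueError("insertion must have start == end")
            if not self.inserted_seq:
                raise ValueError("insertion must carry inserted_seq")
        else:
            if self.end <= self.start:
                raise ValueError(f"{self.kind} event must delete at least one base")
        if self.support < 1:
            raise ValueError("support must be >= 1")

    @property
    def size(self) -> int:
        """Number of deleted reference bases (0 for insertions)."""
        return self.end - self.start

    @property
    def net_change(self) -> int:
        """Net length change of the allele: inserted minus deleted bases."""
        return len(self.inserted_seq) - (self.end - self.start)

    def key(self) -> tuple:
        """Identity used for aggregation and truth comparison."""
        return (self.kind, self.region, self.start, self.end, self.inserted_seq)

    def with_support(self, support: int) -> "IndelEvent":
        return replace(self, support=support)


def sort_key(event: IndelEvent) -> tuple:
    return (event.region, event.start, event.end, event.kind, event.inserted_seq)


def classify_kind(start: int, end: int, inserted_seq: str,
                  large_gap_min_bp: int = LARGE_GAP_MIN_BP) -> str:
    """Kind of a canonical edit: I (pure insert), D (small deletion) or L."""
    if end == start:
        return "I"
    if inserted_seq:
        return "L"
    return "L" if end - start >= large_gap_min_bp else "D"


def canonicalize_indel(start: int, end: int, inserted_seq: str,
                       ref: str) -> tuple[int, int, str]:
    """Reduce an edit to its canonical (minimal, left-aligned) representation.

    Strips bases of ``inserted_seq`` that match the deleted reference at
    either edge, then left-aligns the remaining pure deletion or insertion
    against ``ref``. Representation-equivalent edits map to the same triple.
    """
    if start < 0 or end > len(ref) or end < start:
        raise ValueError("interval outside reference")
    deleted = ref[start:end]
    ins = inserted_seq
    # strip inserted bases matching the deleted interval's edges
    while deleted and ins and deleted[0] == ins[0]:
        start += 1
        deleted = deleted[1:]
        ins = ins[1:]
    while deleted and ins and deleted[-1] == ins[-1]:
        end -= 1
        deleted = deleted[:-1]
        ins = ins[:-1]
    if deleted and ins:
        return start, end, ins  # complex indel: no further shift defined
    if deleted:  # pure deletion: left-align across flanking repeats
        while start > 0 and ref[start - 1] == ref[end - 1]:
            start -= 1
            end -= 1
        return start, end, ""
    if ins:  # pure insertion: left-align by rotating matching bases
        while start > 0 and ins[-1] == ref[start - 1]:
            ins = ref[start - 1] + ins[:-1]
            start -= 1
        return start, start, ins
    return start, start, ""  # degenerate no-op


def make_event(region: str, start: int, end: int, inserted_seq: str = "",
               ref: str | None = None, sample: str | None = None,
               support: int = 1,
               large_gap_min_bp: int = LARGE_GAP_MIN_BP) -> IndelEvent | None:
    """Build a canonical event; returns None if the edit cancels out."""
    if ref is not None:
        start, end, inserted_seq = canonicalize_indel(start, end, inserted_seq, ref)
    if start == end and not inserted_seq:
        return None
    kind = classify_kind(start, end, inserted_seq, large_gap_min_bp)
    return IndelEvent(kind=kind, region=region, start=start, end=end,
                      inserted_seq=inserted_seq, sample=sample, support=support)


def allele_key(events: Iterable[IndelEvent]) -> str:
    """Canonical string identity of an event set (one allele)."""
    parts = [f"{e.region}:{e.kind}:{e.start}-{e.end}:{e.inserted_seq}"
             for e in sorted(events, key=sort_key)]
    return ";".join(parts)


def apply_events(sequence: str, events: Sequence[IndelEvent]) -> str:
    """Apply non-overlapping events on one region to a reference sequence."""
    ordered = sorted(events, key=lambda e: (e.start, e.end))
    prev_end = 0
    for e in ordered:
        if e.end > len(sequence):
            raise ValueError("inconsistent genotype: event outside region")
        if e.start < prev_end:
            raise ValueError("inconsistent genotype: overlapping events")
        prev_end = e.end
    out = sequence
    for e in reversed(ordered):
        out = out[:e.start] + e.inserted_seq + out[e.end:]
    return out


_FRAME_COLUMNS = ["sample", "region", "kind", "start", "end", "size",
                  "inserted_seq", "support"]


def events_to_frame(events: Iterable[IndelEvent]) -> pd.DataFrame:
    rows = [(e.sample, e.region, e.kind, e.start, e.end, e.size,
             e.inserted_seq, e.support) for e in events]
    return pd.DataFrame(rows, columns=_FRAME_COLUMNS)


def frame_to_events(frame: pd.DataFrame) -> list[IndelEvent]:
    events = []
    for row in frame.itertuples(index=False):
        ins = "" if pd.isna(row.inserted_seq) else str(row.inserted_seq)
        events.append(IndelEvent(kind=row.kind, region=row.region,
                                 start=int(row.start), end=int(row.end),
                                 inserted_seq=ins,
                                 sample=None if pd.isna(row.sample) else str(row.sample),
                                 support=int(row.support)))
    return events
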