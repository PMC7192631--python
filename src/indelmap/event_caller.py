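"""Amplicon deletion/insertion calling from local alignments.

The caller walks each alignment's CIGAR and emits one deletion event per
D (or N) run and one insertion event per I run. Runs of adjacent gap
operations are folded into a single junction event, and mismatched
alignment columns immediately flanking a deletion are folded back into
the event as inserted sequence, so the call is invariant to how the
aligner chose to represent the junction. Soft-clipped read ends at least
``min_clip_length`` long are rescued by re-aligning the clipped substring
to the reference (the same amplicon, or an extended reference covering
several amplicons); a clip that lands colinearly beyond the primary
mapping closes a large gap (kind L), whose unmatched middle bases become
the embedded inserted sequence. Identical events are aggregated across a
sample's reads and events supported by fewer than ``min_support`` reads
are discarded (support 10 survives a threshold of 10).
"""

from __future__ import annotations

import collections
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import events as ev
from .guide_model import TargetRegion, revcomp
from .read_prep import (AlignmentRecord, Scoring, TrimConfig, align_local,
                        best_local_alignment, cigar_reference_span,
                        parse_cigar, trim_adapter)


@dataclass(frozen=True)
class CallerConfig:
    min_support: int = 10
    second_pass_reference: str = "same_region"  # or "extended_reference"
    min_clip_length: int = 15
    require_colinear: bool = True
    max_events_reported: int | None = None
    large_gap_min_bp: int = ev.LARGE_GAP_MIN_BP

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.min_clip_length < 1:
            raise ValueError("min_clip_length must be >= 1")
        if self.second_pass_reference not in ("same_region", "extended_reference"):
            raise ValueError("second_pass_reference must be same_region or extended_reference")


def extract_cigar_events(record: AlignmentRecord, region_seq: str | None = None,
                         sample: str | None = None,
                         large_gap_min_bp: int = ev.LARGE_GAP_MIN_BP) -> list[ev.IndelEvent]:
    """Per-read indel events from a CIGAR walk (support 1 each).

    N runs are treated as deletions. Adjacent gap runs are merged into one
    junction event. When ``region_seq`` is given, mismatched read bases
    directly flanking a deletion are folded into the event and the result
    is canonicalized, making the call independent of the aligner's gap
    placement.
    """
    ref = record.pos
    query = 0
    tokens: list[tuple] = []  # (op, ref_start, query_start, length)
    for length, op in record.ops:
        if op == "M":
            tokens.append(("M", ref, query, length))
            ref += length
            query += length
        elif op == "I":
            tokens.append(("I", ref, query, length))
            query += length
        elif op in ("D", "N"):
            tokens.append(("D", ref, query, length))
            ref += length
        elif op == "S":
            tokens.append(("S", ref, query, length))
            query += length
        # H consumes neither read nor reference
    if query != len(record.seq):
        raise ValueError(f"inconsistent record {record.read_id}")

    # group maximal runs of adjacent gap tokens into junction events
    groups: list[dict] = []
    i = 0
    while i < len(tokens):
        op = tokens[i][0]
        if op in ("D", "I"):
            j = i
            del_start = del_end = tokens[i][1]
            inserted = []
            while j < len(tokens) and tokens[j][0] in ("D", "I"):
                _, t_ref, t_query, t_len = tokens[j]
                if tokens[j][0] == "D":
                    del_end = t_ref + t_len
                else:
                    inserted.append(record.seq[t_query:t_query + t_len])
                j += 1
            groups.append({"start": del_start, "end": del_end,
                           "ins": "".join(inserted),
                           "left": tokens[i - 1] if i else None,
                           "right": tokens[j] if j < len(tokens) else None})
            i = j
        else:
            i += 1

    out: list[ev.IndelEvent] = []
    for g in groups:
        start, end, ins = g["start"], g["end"], g["ins"]
        if region_seq is not None and end > start:
            # fold mismatched flanking columns back into the junction
            left = g["left"]
            if left is not None and left[0] == "M":
                _, l_ref, l_query, l_len = left
                k = 0
                while k < l_len and record.seq[l_query + l_len - 1 - k] != region_seq[l_ref + l_len - 1 - k]:
                    k += 1
                if k:
                    ins = record.seq[l_query + l_len - k:l_query + l_len] + ins
                    start -= k
            right = g["right"]
            if right is not None and right[0] == "M":
                _, r_ref, r_query, r_len = right
                k = 0
                while k < r_len and record.seq[r_query + k] != region_seq[r_ref + k]:
                    k += 1
                if k:
                    ins = ins + record.seq[r_query:r_query + k]
                    end += k
        event = ev.make_event(record.region, start, end, ins,
                              ref=region_seq, sample=sample,
                              large_gap_min_bp=large_gap_min_bp)
        if event is not None:
            out.append(event)
    out.sort(key=ev.sort_key)
    return out


def rescue_soft_clips(record: AlignmentRecord, reference: TargetRegion,
                      config: CallerConfig | None = None,
                      scoring: Scoring | None = None,
                      sample: str | None = None,
                      stats: collections.Counter | None = None,
                      offset: int = 0) -> list[ev.IndelEvent]:
    """Recover large gaps from soft-clipped read ends.

    Each clip of at least ``min_clip_length`` bases is locally aligned to
    ``reference``; a unique, same-strand, colinear placement (strictly
    beyond the primary mapping on the clipped side) closes an L event
    spanning the unmapped reference interval, with any read bases between
    the two mapped blocks as embedded insertion. ``offset`` shifts the
    primary mapping into the reference's coordinates when the second pass
    uses an extended reference. Ambiguous, inverted or non-colinear clips
    yield no event and are tallied in ``stats``.
    """
    config = config or CallerConfig()
    scoring = scoring or Scoring()
    stats = stats if stats is not None else collections.Counter()
    primary_start = record.pos + offset
    primary_end = primary_start + record.ref_span
    out: list[ev.IndelEvent] = []
    for side, clip in (("5", record.clip5), ("3", record.clip3)):
        if len(clip) < config.min_clip_length:
            continue
        hit = best_local_alignment(clip, reference.sequence, scoring)
        rev_hit = best_local_alignment(revcomp(clip), reference.sequence, scoring)
        if rev_hit is not None and (hit is None or rev_hit[0] > hit[0]):
            stats["clip_inverted"] += 1
            continue
        if hit is None:
            stats["clip_unmapped"] += 1
            continue
        score, _, ref_start, query_start, query_end, n_placements = hit
        if n_placements > 1:
            stats["clip_ambiguous"] += 1
            continue
        # reference span of the clip's own placement
        ref_end = ref_start + cigar_reference_span(parse_cigar(hit[1]))
        if side == "3":
            colinear = ref_start > primary_end
            start, end = primary_end, ref_start
            inserted = clip[:query_start]
        else:
            colinear = ref_end < primary_start
            start, end = ref_end, primary_start
            inserted = clip[query_end:]
        if config.require_colinear and not colinear:
            stats["clip_noncolinear"] += 1
            continue
        if end <= start:
            stats["clip_noncolinear"] += 1
            continue
        event = ev.make_event(reference.name, start, end, inserted,
                              ref=reference.sequence, sample=sample,
                              large_gap_min_bp=config.large_gap_min_bp)
        if event is not None:
            stats["clip_rescued"] += 1
            out.append(event)
    return out


def aggregate_and_filter(events: Iterable[ev.IndelEvent],
                         config: CallerConfig | None = None) -> pd.DataFrame:
    """Merge identical events per sample and drop weakly supported ones.

    Events identical in (sample, kind, region, interval, inserted
    sequence) are merged with summed support; events with support below
    ``min_support`` are discarded (strictly-less-than comparison).
    """
    config = config or CallerConfig()
    frame = ev.events_to_frame(events)
    if frame.empty:
        return frame
    grouped = (frame.groupby(["sample", "region", "kind", "start", "end", "inserted_seq"],
                             dropna=False, as_index=False)["support"].sum())
    grouped["size"] = grouped["end"] - grouped["start"]
    grouped = grouped[grouped["support"] >= config.min_support]
    if config.max_events_reported is not None:
        grouped = (grouped.sort_values(["sample", "support"], ascending=[True, False])
                   .groupby("sample", dropna=False)
                   .head(config.max_events_reported))
    grouped = grouped.sort_values(["sample", "region", "start", "end", "kind"],
                                  kind="mergesort").reset_index(drop=True)
    return grouped[["sample", "region", "kind", "start", "end", "size",
                    "inserted_seq", "support"]]


def _select_region(seq: str, regions: Mapping[str, TargetRegion],
                   scoring: Scoring, read_id: str,
                   qual: str | None) -> AlignmentRecord | None:
    best = None
    for name in sorted(regions):
        rec = align_local(seq, regions[name], scoring, read_id=read_id, qual=qual)
        if rec is not None and (best is None or rec.score > best.score):
            best = rec
    return best


def _process_record(record: AlignmentRecord, regions: Mapping[str, TargetRegion],
                    config: CallerConfig, scoring: Scoring, sample: str,
                    extended_reference: TargetRegion | None,
                    stats: collections.Counter) -> list[ev.IndelEvent]:
    region = regions[record.region]
    read_events = extract_cigar_events(record, region.sequence, sample=sample,
                                       large_gap_min_bp=config.large_gap_min_bp)
    use_extended = (config.second_pass_reference == "extended_reference"
                    and extended_reference is not None)
    if use_extended:
        offset = extended_reference.sequence.find(region.sequence)
        if offset < 0:
            raise ValueError(f"region {region.name} is not contained in "
                             f"extended reference {extended_reference.name}")
        # report all events in extended-reference coordinates
        read_events = [ev.IndelEvent(kind=e.kind, region=extended_reference.name,
                                     start=e.start + offset, end=e.end + offset,
                                     inserted_seq=e.inserted_seq, sample=e.sample,
                                     support=e.support) for e in read_events]
        reference, rescue_offset = extended_reference, offset
    else:
        reference, rescue_offset = region, 0
    if record.clip5 or record.clip3:
        read_events.extend(rescue_soft_clips(record, reference, config, scoring,
                                             sample=sample, stats=stats,
                                             offset=rescue_offset))
    if not read_events:
        stats["unedited_reads"] += 1
    return read_events


def call_sample(reads: Iterable[tuple[str, str, str]],
                regions: Mapping[str, TargetRegion],
                trim: TrimConfig | None = None,
                scoring: Scoring | None = None,
                config: CallerConfig | None = None,
                sample: str = "sample",
                extended_reference: TargetRegion | None = None) -> tuple[pd.DataFrame, dict]:
    """Trim, align and call one sample's reads end to end.

    ``reads`` yields (read id, sequence, quality) tuples. Returns the
    filtered per-sample event table and a run summary with per-stage read
    counts.
    """
    trim = trim or TrimConfig()
    scoring = scoring or Scoring()
    config = config or CallerConfig()
    stats: collections.Counter = collections.Counter()
    all_events: list[ev.IndelEvent] = []
    for read_id, seq, qual in reads:
        stats["reads_in"] += 1
        trimmed = trim_adapter(seq, qual, trim)
        if trimmed.removed_bp:
            stats["reads_trimmed"] += 1
        if trimmed.discarded:
            stats["reads_discarded_short"] += 1
            continue
        record = _select_region(trimmed.sequence, regions, scoring, read_id,
                                trimmed.quality)
        if record is None:
            stats["reads_unaligned"] += 1
            continue
        stats["reads_aligned"] += 1
        all_events.extend(_process_record(record, regions, config, scoring,
                                          sample, extended_reference, stats))
    table = aggregate_and_filter(all_events, config)
    stats["events_prefilter"] = len({e.key() for e in all_events})
    stats["events_reported"] = len(table)
    return table, dict(stats)


def call_cohort(reads: Iterable[tuple[str, str, str]],
                regions: Mapping[str, TargetRegion],
                trim: TrimConfig | None = None,
                scoring: Scoring | None = None,
                config: CallerConfig | None = None,
                sample_delimiter: str = "|",
                extended_reference: TargetRegion | None = None) -> tuple[pd.DataFrame, dict]:
    """Call many samples multiplexed in one read stream.

    The sample id is the read-id prefix before ``sample_delimiter``
    (de-multiplexed amplicon sequencing convention).
    """
    trim = trim or TrimConfig()
    scoring = scoring or Scoring()
    config = config or CallerConfig()
    stats: collections.Counter = collections.Counter()
    all_events: list[ev.IndelEvent] = []
    for read_id, seq, qual in reads:
        sample = read_id.split(sample_delimiter, 1)[0]
        stats["reads_in"] += 1
        trimmed = trim_adapter(seq, qual, trim)
        if trimmed.removed_bp:
            stats["reads_trimmed"] += 1
        if trimmed.discarded:
            stats["reads_discarded_short"] += 1
            continue
        record = _select_region(trimmed.sequence, regions, scoring, read_id,
                                trimmed.quality)
        if record is None:
            stats["reads_unaligned"] += 1
            continue
        stats["reads_aligned"] += 1
        all_events.extend(_process_record(record, regions, config, scoring,
                                          sample, extended_reference, stats))
    table = aggregate_and_filter(all_events, config)
    stats["events_prefilter"] = len({(e.sample,) + e.key() for e in all_events})
    stats["events_reported"] = len(table)
    return table, dict(stats)
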