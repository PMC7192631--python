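"""gRNA arrays, target amplicons and defined-deletion design.

An arrayed-mutagenesis experiment targets one or more amplicons
("regions") with small sets of SpCas9 guides. One guide per array copy is
stochastically activated in each germline stem cell, so two array copies
yield either indels at one or two cut sites or a single deletion spanning
two distinct cut sites (a "defined", inter-target deletion). This module
places guides on their amplicons, computes cut sites, enumerates the
defined deletions a pair of arrays can produce, reports inter-cut spacing,
and does the barcode-pooling arithmetic used when multiplexing amplicons
from different targets into shared sample indices.

Coordinates are 0-based, half-open, on the forward strand of each
amplicon. The SpCas9 double-strand break is taken to be blunt, 3 bp 5' of
the NGG PAM, i.e. between protospacer positions 17 and 18.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

_DNA_RE = re.compile(r"^[ACGTN]+$")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SPACER_LENGTH = 20
#: blunt SpCas9 cut: between protospacer positions 17 and 18 (3 bp 5' of PAM)
CUT_OFFSET = 17


def revcomp(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


class TargetNotFoundError(ValueError):
    """The spacer does not occur in the region ("target not found")."""


class AmbiguousTargetError(ValueError):
    """The spacer occurs more than once in the region ("ambiguous target")."""


class PamNotFoundError(ValueError):
    """The unique spacer match lacks an NGG PAM ("no PAM")."""


class EmptyArrayError(ValueError):
    """A guide array with no guides was supplied ("empty array")."""


@dataclass(frozen=True)
class TargetRegion:
    """One amplicon: a named stretch of forward-strand DNA."""

    name: str
    sequence: str
    exon_label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not _DNA_RE.match(self.sequence):
            raise ValueError(f"region {self.name}: sequence must be A/C/G/T/N")

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GuideRNA:
    """A placed guide: spacer, strand, protospacer offset and cut site."""

    id: str
    spacer: str
    strand: str
    region: str
    protospacer_start: int
    cut_site: int
    weight: float = 1.0
    on_score: float | None = None
    off_score: float | None = None

    def __post_init__(self) -> None:
        if len(self.spacer) != SPACER_LENGTH:
            raise ValueError(f"guide {self.id}: spacer must be {SPACER_LENGTH} nt")
        if self.strand not in "+-":
            raise ValueError(f"guide {self.id}: strand must be + or -")
        if self.weight < 0:
            raise ValueError(f"guide {self.id}: weight must be >= 0")


@dataclass(frozen=True)
class GuideArray:
    """An ordered gRNA set from which one guide is activated per array copy."""

    id: str
    guides: tuple[str, ...]
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "guides", tuple(self.guides))
        if not self.guides:
            raise ValueError(f"array {self.id}: at least one guide is required")
        if self.weights is not None:
            object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
            if len(self.weights) != len(self.guides):
                raise ValueError(f"array {self.id}: weights must align with guides")
            if any(w < 0 for w in self.weights):
                raise ValueError(f"array {self.id}: weights must be >= 0")
        if len(set(self.guides)) != len(self.guides):
            raise ValueError(f"array {self.id}: guide ids must be distinct")

    def resolved_weights(self, guides: Mapping[str, GuideRNA]) -> list[float]:
        if self.weights is not None:
            return list(self.weights)
        return [guides[g].weight for g in self.guides]


@dataclass(frozen=True)
class DefinedDeletion:
    """The deletion produced by simultaneous cuts at two distinct sites."""

    guide_a: str
    guide_b: str
    region: str
    start: int
    end: int

    @property
    def size_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PoolingPlan:
    """Barcode arithmetic for pooling one amplicon per group into mixtures."""

    pooled_groups: tuple[tuple[str, int], ...]
    singleton_count: int
    mixtures: int
    barcodes_required: int
    total_samples: int


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i >= 0:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def locate_guide(region: TargetRegion, spacer: str, guide_id: str | None = None,
                 weight: float = 1.0, on_score: float | None = None,
                 off_score: float | None = None) -> GuideRNA:
    """Place a 20-nt spacer on a region and compute its cut site.

    The spacer (or its reverse complement) must occur exactly once, with an
    NGG PAM immediately 3' of the protospacer on the matching strand.
    """
    spacer = spacer.upper()
    if len(spacer) != SPACER_LENGTH:
        raise ValueError(f"spacer must be {SPACER_LENGTH} nt, got {len(spacer)}")
    seq = region.sequence
    fwd = _find_all(seq, spacer)
    rev = _find_all(seq, revcomp(spacer))
    n_hits = len(fwd) + len(rev)
    if n_hits == 0:
        raise TargetNotFoundError(f"target not found: {spacer} in {region.name}")
    if n_hits > 1:
        raise AmbiguousTargetError(f"ambiguous target: {spacer} occurs {n_hits} times in {region.name}")
    if fwd:
        start = fwd[0]
        pam = seq[start + SPACER_LENGTH:start + SPACER_LENGTH + 3]
        if len(pam) < 3 or pam[1:3] != "GG":
            raise PamNotFoundError(f"no PAM 3' of + strand protospacer at {start} in {region.name}")
        strand, cut = "+", start + CUT_OFFSET
    else:
        start = rev[0]
        pam = seq[start - 3:start]
        if start < 3 or pam[0:2] != "CC":
            raise PamNotFoundError(f"no PAM 3' of - strand protospacer at {start} in {region.name}")
        strand, cut = "-", start + (SPACER_LENGTH - CUT_OFFSET)
    return GuideRNA(id=guide_id or f"{region.name}:{start}{strand}", spacer=spacer,
                    strand=strand, region=region.name, protospacer_start=start,
                    cut_site=cut, weight=weight, on_score=on_score, off_score=off_score)


def enumerate_defined_deletions(array_1: GuideArray, array_2: GuideArray,
                                guides: Mapping[str, GuideRNA]) -> list[DefinedDeletion]:
    """Every deletion obtainable by pairing one guide from each array.

    Pairs must be distinct guides on the same region with distinct cut
    sites; unordered duplicates (which arise when the two arrays are
    identical) are collapsed. Sorted by (region, start, end).
    """
    if not array_1.guides or not array_2.guides:
        raise EmptyArrayError("empty array")
    seen: set[tuple] = set()
    out: list[DefinedDeletion] = []
    for a in array_1.guides:
        for b in array_2.guides:
            if a == b:
                continue
            ga, gb = guides[a], guides[b]
            if ga.region != gb.region or ga.cut_site == gb.cut_site:
                continue
            key = (ga.region,) + tuple(sorted((a, b)))
            if key in seen:
                continue
            seen.add(key)
            if ga.cut_site > gb.cut_site:
                ga, gb = gb, ga
            out.append(DefinedDeletion(guide_a=ga.id, guide_b=gb.id, region=ga.region,
                                       start=ga.cut_site, end=gb.cut_site))
    out.sort(key=lambda d: (d.region, d.start, d.end, d.guide_a, d.guide_b))
    return out


def pooling_plan(pooled_group_sizes: Sequence[int], singleton_count: int,
                 labels: Sequence[str] | None = None) -> PoolingPlan:
    """Barcode/mixture arithmetic when pooling one sample per group.

    ``mixtures`` is the largest group (each mixture takes one sample from
    every group that still has one); every mixture and every singleton
    needs its own barcode.
    """
    sizes = [int(s) for s in pooled_group_sizes]
    if singleton_count < 0 or any(s < 0 for s in sizes):
        raise ValueError("invalid count: group sizes and singletons must be >= 0")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(sizes))]
    mixtures = max(sizes, default=0)
    return PoolingPlan(pooled_groups=tuple(zip(labels, sizes)),
                       singleton_count=int(singleton_count),
                       mixtures=mixtures,
                       barcodes_required=mixtures + int(singleton_count),
                       total_samples=sum(sizes) + int(singleton_count))


def spacing_report(region: TargetRegion, guides: Sequence[GuideRNA],
                   gap_threshold: int = 200) -> pd.DataFrame:
    """Inter-cut distances on a region, amplicon ends included.

    Returns one row per untargeted segment between consecutive cut sites
    (and between each amplicon end and its nearest cut), flagging segments
    longer than ``gap_threshold``.
    """
    on_region = [g for g in guides if g.region == region.name]
    if not on_region:
        raise ValueError(f"no guides on region {region.name}")
    cuts = sorted({g.cut_site for g in on_region})
    bounds = [0] + cuts + [len(region)]
    rows = [
        {"region": region.name, "start": bounds[i], "end": bounds[i + 1],
         "gap_bp": bounds[i + 1] - bounds[i],
         "flagged": (bounds[i + 1] - bounds[i]) > gap_threshold}
        for i in range(len(bounds) - 1)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file formats

def read_regions_fasta(path: str | Path) -> dict[str, TargetRegion]:
    regions: dict[str, TargetRegion] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in regions:
            raise ValueError(f"duplicate region name {rec.id}")
        regions[rec.id] = TargetRegion(name=rec.id, sequence=str(rec.seq))
    return regions


def write_regions_fasta(regions: Mapping[str, TargetRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions.values():
            fh.write(f">{r.name}\n{r.sequence}\n")


def read_guides_tsv(path: str | Path,
                    regions: Mapping[str, TargetRegion]) -> dict[str, GuideRNA]:
    """Load guides from TSV (id, region, spacer[, weight, on_score, off_score])."""
    table = pd.read_csv(path, sep="\t")
    required = {"id", "region", "spacer"}
    if not required.issubset(table.columns):
        raise ValueError(f"guides TSV needs columns {sorted(required)}")
    guides: dict[str, GuideRNA] = {}
    for row in table.itertuples(index=False):
        kwargs = {}
        for opt in ("weight", "on_score", "off_score"):
            if opt in table.columns and not pd.isna(getattr(row, opt)):
                kwargs[opt] = float(getattr(row, opt))
        guide = locate_guide(regions[row.region], row.spacer, guide_id=str(row.id), **kwargs)
        if guide.id in guides:
            raise ValueError(f"duplicate guide id {guide.id}")
        guides[guide.id] = guide
    return guides


def write_guides_tsv(guides: Mapping[str, GuideRNA], path: str | Path) -> None:
    rows = [asdict(g) for g in guides.values()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_defined_deletions_tsv(deletions: Iterable[DefinedDeletion],
                                path: str | Path) -> None:
    rows = [{**asdict(d), "size_bp": d.size_bp} for d in deletions]
    columns = ["region", "start", "end", "size_bp", "guide_a", "guide_b"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def write_pooling_plan_json(plan: PoolingPlan, path: str | Path) -> None:
    payload = asdict(plan)
    payload["pooled_groups"] = [list(g) for g in plan.pooled_groups]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
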