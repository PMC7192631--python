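"""Cohort-level classification and statistics for arrayed mutagenesis.

Per offspring, the filtered event set is classified into one of four
categories: no edit, single-site (events at one cut site), double-site
(independent indels at two cut sites) or inter-target (one deletion
spanning two distinct cut sites). On top of the classification the module
builds the symmetric guide-use matrix, the deletion-size and reading-frame
distributions (with a chi-square goodness-of-fit test against equal
thirds), the unique-allele fraction, and the per-base deletion-coverage
profile with its zero-coverage gap report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import events as ev
from .guide_model import GuideRNA, TargetRegion

CATEGORIES = ("no_edit", "single_site", "double_site", "inter_target")


@dataclass(frozen=True)
class OffspringGenotype:
    """One offspring's classified event set."""

    sample: str | None
    founder: str | None
    events: tuple[ev.IndelEvent, ...]
    category: str
    implicated_guides: frozenset[str]
    unassigned_events: tuple[ev.IndelEvent, ...] = ()
    ambiguous: bool = False

    @property
    def edited(self) -> bool:
        return self.category != "no_edit"

    @property
    def allele_key(self) -> str:
        return ev.allele_key(self.events)


def _interval_distance(event: ev.IndelEvent, cut_site: int) -> int:
    return max(event.start - cut_site, cut_site - event.end, 0)


def _nearest_guide(event: ev.IndelEvent, cuts: Sequence[tuple[str, str, int]],
                   window_bp: int) -> str | None:
    best: tuple[int, str] | None = None
    for guide_id, region, cut in cuts:
        if region != event.region:
            continue
        d = _interval_distance(event, cut)
        if d <= window_bp and (best is None or (d, guide_id) < best):
            best = (d, guide_id)
    return best[1] if best else None


def classify_genotype(events: Iterable[ev.IndelEvent],
                      guides: Mapping[str, GuideRNA],
                      window_bp: int = 20,
                      sample: str | None = None,
                      founder: str | None = None) -> OffspringGenotype:
    """Classify one offspring's events against the guide cut sites.

    A deletion whose two endpoints each lie within ``window_bp`` of two
    distinct cut sites marks the offspring inter-target. Otherwise events
    are assigned to the nearest cut within the window: one implicated
    guide means single-site, two means double-site. Events near no cut are
    kept but flagged unassigned; offspring whose events implicate no guide
    are single-site when the events form one spatial cluster and flagged
    ambiguous otherwise.
    """
    event_list = tuple(sorted(events, key=ev.sort_key))
    if not event_list:
        return OffspringGenotype(sample, founder, (), "no_edit", frozenset())
    cuts = sorted((g.id, g.region, g.cut_site) for g in guides.values())
    # inter-target scan: a single deletion bridging two distinct cuts
    for e in event_list:
        if e.end <= e.start:
            continue
        left = _nearest_point(e.start, e.region, cuts, window_bp)
        right = _nearest_point(e.end, e.region, cuts, window_bp)
        if left and right and left != right:
            implicated = frozenset((left, right))
            return OffspringGenotype(sample, founder, event_list, "inter_target",
                                     implicated)
    implicated: set[str] = set()
    unassigned: list[ev.IndelEvent] = []
    for e in event_list:
        guide = _nearest_guide(e, cuts, window_bp)
        if guide is None:
            unassigned.append(e)
        else:
            implicated.add(guide)
    if implicated:
        category = "single_site" if len(implicated) == 1 else "double_site"
        ambiguous = len(implicated) > 2
    else:
        clusters = _cluster_events(unassigned, 2 * window_bp)
        category = "single_site"
        ambiguous = clusters > 1
    return OffspringGenotype(sample, founder, event_list, category,
                             frozenset(implicated), tuple(unassigned), ambiguous)


def _nearest_point(position: int, region: str,
                   cuts: Sequence[tuple[str, str, int]],
                   window_bp: int) -> str | None:
    best: tuple[int, str] | None = None
    for guide_id, cut_region, cut in cuts:
        if cut_region != region:
            continue
        d = abs(position - cut)
        if d <= window_bp and (best is None or (d, guide_id) < best):
            best = (d, guide_id)
    return best[1] if best else None


def _cluster_events(events: Sequence[ev.IndelEvent], max_span: int) -> int:
    if not events:
        return 0
    ordered = sorted(events, key=ev.sort_key)
    clusters = 1
    prev_end = ordered[0].end
    prev_region = ordered[0].region
    for e in ordered[1:]:
        if e.region != prev_region or e.start - prev_end > max_span:
            clusters += 1
        prev_end = max(prev_end, e.end)
        prev_region = e.region
    return clusters


def classify_cohort(events_by_sample: Mapping[str, Sequence[ev.IndelEvent]],
                    guides: Mapping[str, GuideRNA], window_bp: int = 20,
                    founder_of: Mapping[str, str] | None = None) -> list[OffspringGenotype]:
    out = []
    for sample in sorted(events_by_sample):
        founder = founder_of.get(sample) if founder_of else None
        out.append(classify_genotype(events_by_sample[sample], guides,
                                     window_bp, sample=sample, founder=founder))
    return out


def category_counts(genotypes: Iterable[OffspringGenotype]) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    for g in genotypes:
        if not g.ambiguous:
            counts[g.category] += 1
    return counts


def category_proportions(genotypes: Sequence[OffspringGenotype],
                         edited_only: bool = True) -> dict[str, float]:
    """Category proportions; by default among edited offspring only."""
    counts = category_counts(genotypes)
    if edited_only:
        counts.pop("no_edit")
    total = sum(counts.values())
    if total == 0:
        return {c: float("nan") for c in counts}
    return {c: n / total for c, n in counts.items()}


def use_matrix(genotypes: Iterable[OffspringGenotype],
               guide_order: Sequence[str]) -> pd.DataFrame:
    """Symmetric guide-by-guide table of deduced gRNA choices.

    Single-site offspring increment the diagonal; double-site and
    inter-target offspring increment both (a, b) and (b, a). Ambiguous
    offspring and offspring without implicated guides are excluded.
    """
    order = list(guide_order)
    matrix = pd.DataFrame(0, index=order, columns=order, dtype=int)
    for g in genotypes:
        if g.ambiguous or not g.implicated_guides:
            continue
        picked = sorted(g.implicated_guides, key=order.index)
        if len(picked) == 1 and g.category == "single_site":
            matrix.loc[picked[0], picked[0]] += 1
        elif len(picked) == 2 and g.category in ("double_site", "inter_target"):
            a, b = picked
            matrix.loc[a, b] += 1
            matrix.loc[b, a] += 1
    return matrix


@dataclass(frozen=True)
class FrameResult:
    """Reading-frame spectrum of per-offspring net length changes."""

    counts: tuple[int, int, int]  # frames 0 (in-frame), 1, 2
    chi2: float
    p_value: float


def frame_chi_square(counts: Sequence[int]) -> tuple[float, float]:
    """Pearson chi-square of observed frame counts against equal thirds."""
    observed = np.asarray(counts, dtype=float)
    statistic, p_value = sstats.chisquare(observed)
    return float(statistic), float(p_value)


def frame_analysis(genotypes: Sequence[OffspringGenotype]) -> FrameResult:
    """Reading-frame distribution over edited offspring.

    The per-offspring net length change (inserted minus deleted bases,
    summed over events) is reduced modulo 3; frame 0 collects in-frame
    alleles. Tested against an equal-thirds expectation with 2 degrees of
    freedom.
    """
    edited = [g for g in genotypes if g.edited]
    if not edited:
        raise ValueError("empty cohort")
    counts = [0, 0, 0]
    for g in edited:
        net = sum(e.net_change for e in g.events)
        counts[net % 3] += 1
    chi2, p_value = frame_chi_square(counts)
    return FrameResult(counts=tuple(counts), chi2=chi2, p_value=p_value)


def uniqueness_fraction(genotypes: Sequence[OffspringGenotype],
                        by_founder: bool = False) -> tuple[float | None, pd.DataFrame]:
    """Fraction of edited offspring whose allele occurs exactly once.

    Alleles are compared by their canonical event-set key. With
    ``by_founder`` the occurrence count is taken within each founder's
    offspring. Returns None (and an empty table) when nothing is edited.
    """
    edited = [g for g in genotypes if g.edited]
    per_founder = pd.DataFrame(columns=["founder", "n_edited", "unique_fraction"])
    if not edited:
        return None, per_founder
    scope = (lambda g: (g.founder, g.allele_key)) if by_founder else (lambda g: g.allele_key)
    counts: dict = {}
    for g in edited:
        counts[scope(g)] = counts.get(scope(g), 0) + 1
    fraction = sum(counts[scope(g)] == 1 for g in edited) / len(edited)
    rows = []
    for founder in sorted({g.founder for g in edited}, key=str):
        group = [g for g in edited if g.founder == founder]
        local: dict = {}
        for g in group:
            local[g.allele_key] = local.get(g.allele_key, 0) + 1
        rows.append({"founder": founder, "n_edited": len(group),
                     "unique_fraction": sum(local[g.allele_key] == 1 for g in group) / len(group)})
    return fraction, pd.DataFrame(rows)


@dataclass(frozen=True)
class CoverageResult:
    """Per-base deletion coverage and zero-coverage gap report."""

    region: str
    coverage: np.ndarray
    gaps: tuple[dict, ...]  # {"start", "end", "cut_sites": (guide ids)}


def coverage_matrix(genotypes: Iterable[OffspringGenotype], region: TargetRegion,
                    guides: Mapping[str, GuideRNA] | None = None) -> CoverageResult:
    """Count, per reference base, the offspring whose deletions cover it.

    Each offspring contributes at most one count per position (its
    deletion intervals are unioned first). Maximal zero-coverage intervals
    are reported together with any guide cut sites they contain.
    """
    length = len(region)
    diff = np.zeros(length + 1, dtype=int)
    for g in genotypes:
        covered: list[tuple[int, int]] = []
        for e in g.events:
            if e.end > e.start and e.region == region.name:
                covered.append((max(0, e.start), min(length, e.end)))
        for start, end in _union_intervals(covered):
            diff[start] += 1
            diff[end] -= 1
    coverage = np.cumsum(diff[:-1])
    cuts = []
    if guides:
        cuts = sorted((g.cut_site, g.id) for g in guides.values()
                      if g.region == region.name)
    gaps = []
    zero = coverage == 0
    i = 0
    while i < length:
        if zero[i]:
            j = i
            while j < length and zero[j]:
                j += 1
            inside = tuple(gid for cut, gid in cuts if i <= cut < j)
            gaps.append({"start": i, "end": j, "cut_sites": inside})
            i = j
        else:
            i += 1
    return CoverageResult(region=region.name, coverage=coverage, gaps=tuple(gaps))


def _union_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class CohortSummary:
    """All cohort-level statistics in one bundle."""

    n_offspring: int
    n_ambiguous: int
    category_counts: dict[str, int]
    edited_proportions: dict[str, float]
    use_matrix: pd.DataFrame
    deletion_sizes: list[int]
    size_histogram: tuple[np.ndarray, np.ndarray]  # (counts, bin edges)
    frame: FrameResult | None
    uniqueness: float | None
    per_founder_uniqueness: pd.DataFrame
    coverage: dict[str, CoverageResult] = field(default_factory=dict)


def summarize_cohort(genotypes: Sequence[OffspringGenotype],
                     guides: Mapping[str, GuideRNA],
                     regions: Mapping[str, TargetRegion],
                     size_bin_bp: int = 5) -> CohortSummary:
    counts = category_counts(genotypes)
    sizes = sorted(e.size for g in genotypes for e in g.events if e.size > 0)
    top = (max(sizes) // size_bin_bp + 1) * size_bin_bp if sizes else size_bin_bp
    histogram = np.histogram(sizes, bins=np.arange(0, top + size_bin_bp, size_bin_bp))
    try:
        frame = frame_analysis(genotypes)
    except ValueError:
        frame = None
    uniqueness, per_founder = uniqueness_fraction(genotypes, by_founder=True)
    coverage = {name: coverage_matrix(genotypes, region, guides)
                for name, region in sorted(regions.items())}
    return CohortSummary(
        n_offspring=len(genotypes),
        n_ambiguous=sum(g.ambiguous for g in genotypes),
        category_counts=counts,
        edited_proportions=category_proportions(genotypes, edited_only=True),
        use_matrix=use_matrix(genotypes, sorted(guides)),
        deletion_sizes=sizes,
        size_histogram=histogram,
        frame=frame,
        uniqueness=uniqueness,
        per_founder_uniqueness=per_founder,
        coverage=coverage,
    )


def summary_to_json_dict(summary: CohortSummary) -> dict:
    """JSON-serializable view of a cohort summary."""
    payload = {
        "n_offspring": summary.n_offspring,
        "n_ambiguous": summary.n_ambiguous,
        "category_counts": summary.category_counts,
        "edited_proportions": summary.edited_proportions,
        "use_matrix": {"guides": list(summary.use_matrix.index),
                       "counts": summary.use_matrix.values.tolist()},
        "deletion_size_histogram": {
            "counts": summary.size_histogram[0].tolist(),
            "bin_edges": summary.size_histogram[1].tolist()},
        "frame": None,
        "uniqueness_fraction": summary.uniqueness,
        "per_founder_uniqueness": summary.per_founder_uniqueness.to_dict("records"),
        "coverage": {
            name: {"max_depth": int(cov.coverage.max(initial=0)),
                   "covered_bp": int((cov.coverage > 0).sum()),
                   "gaps": [dict(g, cut_sites=list(g["cut_sites"])) for g in cov.gaps]}
            for name, cov in summary.coverage.items()},
    }
    if summary.frame is not None:
        payload["frame"] = {"counts": list(summary.frame.counts),
                            "chi2": summary.frame.chi2,
                            "p_value": summary.frame.p_value}
    return payload
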