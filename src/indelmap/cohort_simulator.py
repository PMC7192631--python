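"""Synthetic cohorts of germline arrayed-mutagenesis offspring.

The generator emulates the genetics of a conditional gRNA-array cross:
each founder male carries 12-24 germline stem cells (GSCs); in every GSC
each array copy irreversibly recombines to commit one guide, drawn with
probability proportional to its weight. Offspring derive from GSCs.
With Cas9 restricted to post-GSC germ cells ("independent" mode) every
offspring draws a fresh mutational outcome; with Cas9 active in GSCs
("clonal" mode) each GSC draws one outcome that all of its offspring
inherit. An offspring is edited at all with probability
``edit_rate_ceiling`` (the empirical ~35% saturation of germline Cas9
activity, independent of the number of array copies). Given an edit and
two distinct committed guides, the outcome is an inter-target deletion
spanning the two cut sites (suppressed when the cuts are closer than
``dual_cut_min_separation``, mimicking steric interference), independent
indels at both sites, or an indel at a single site, with configurable
category probabilities. Single-site deletions are centred on the cut with
independently drawn left/right extents; insertions place random bases at
the cut.

Ground-truth events are stored in the same canonical representation the
caller emits, and every genotype's category is the one the cohort
classifier assigns to its events, so truth and downstream calls are
directly comparable. Reads are single-end amplicon fragments sampled
uniformly along the mutant allele, with geometric fragment lengths,
uniform substitution errors and the library adapter filling short
fragments out to the read length.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import events as ev
from .cohort_stats import OffspringGenotype, classify_genotype
from .guide_model import GuideArray, GuideRNA, TargetRegion, locate_guide
from .read_prep import DEFAULT_ADAPTER

_BASES = "ACGT"


class DegenerateWeightsError(ValueError):
    """All guide weights are zero ("degenerate weights")."""


@dataclass(frozen=True)
class IndelSizeModel:
    """Size distributions of repair outcomes around a cut site.

    Deletion left/right extents are i.i.d. geometric (on 0, 1, 2, ...)
    with mean ``deletion_mean_bp / 2`` each; totals are redrawn outside
    [1, deletion_max_bp]. Insertion lengths are geometric (on 1, 2, ...)
    with mean ``insertion_mean_bp``. ``insertion_prob`` is the chance a
    single-site outcome is an insertion rather than a deletion;
    ``l_insertion_prob`` is the chance an inter-target junction carries
    embedded inserted bases.
    """

    deletion_mean_bp: float = 8.0
    deletion_max_bp: int = 100
    insertion_mean_bp: float = 2.0
    insertion_prob: float = 0.2
    l_insertion_prob: float = 0.3


@dataclass(frozen=True)
class SimulationConfig:
    germline_mode: str = "independent"  # or "clonal"
    gsc_count_range: tuple[int, int] = (12, 24)
    arrays: tuple[str, ...] = ()
    edit_rate_ceiling: float = 0.35
    per_guide_cut_prob: Mapping[str, float] = field(default_factory=dict)
    indel_size_model: IndelSizeModel = field(default_factory=IndelSizeModel)
    insertion_alphabet: str = _BASES
    dual_cut_min_separation: int = 40
    founder_count: int = 16
    offspring_count: int = 30  # per founder
    inter_target_prob: float = 0.082
    double_site_prob: float = 0.154
    classify_window_bp: int = 20
    reads_per_amplicon: int = 500
    read_length: int = 150
    fragment_mean_bp: int = 300
    base_error_rate: float = 0.001
    adapter: str = DEFAULT_ADAPTER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.germline_mode not in ("independent", "clonal"):
            raise ValueError("germline_mode must be independent or clonal")
        if not 1 <= len(self.arrays) <= 2:
            raise ValueError("one or two gRNA arrays are required")
        for p in (self.edit_rate_ceiling, self.base_error_rate,
                  self.inter_target_prob, self.double_site_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        low, high = self.gsc_count_range
        if low < 1 or high < low:
            raise ValueError("gsc_count_range must be a positive interval")
        if self.offspring_count < 0 or self.founder_count < 1:
            raise ValueError("bad cohort size")


@dataclass(frozen=True)
class TrueGenotype:
    """Ground truth for one offspring."""

    offspring_id: str
    founder_id: str
    gsc_id: str
    chosen_guides: tuple[str, ...]
    events: tuple[ev.IndelEvent, ...]
    category: str
    classified: OffspringGenotype

    # duck-type compatibility with OffspringGenotype for the statistics layer
    @property
    def sample(self) -> str:
        return self.offspring_id

    @property
    def founder(self) -> str:
        return self.founder_id

    @property
    def edited(self) -> bool:
        return self.category != "no_edit"

    @property
    def allele_key(self) -> str:
        return ev.allele_key(self.events)

    @property
    def implicated_guides(self) -> frozenset[str]:
        return self.classified.implicated_guides

    @property
    def ambiguous(self) -> bool:
        return self.classified.ambiguous


def recombine_array(array: GuideArray, rng: np.random.Generator,
                    guides: Mapping[str, GuideRNA] | None = None) -> str:
    """Stochastically commit one guide of an array (weight-proportional)."""
    if array.weights is not None:
        weights = np.asarray(array.weights, dtype=float)
    elif guides is not None:
        weights = np.asarray(array.resolved_weights(guides), dtype=float)
    else:
        weights = np.ones(len(array.guides))
    total = weights.sum()
    if total <= 0:
        raise DegenerateWeightsError(f"degenerate weights in array {array.id}")
    index = rng.choice(len(array.guides), p=weights / total)
    return array.guides[int(index)]


class _OutcomeDrawer:
    """Draws one mutational outcome for a germ cell with committed guides."""

    def __init__(self, config: SimulationConfig, regions: Mapping[str, TargetRegion],
                 guides: Mapping[str, GuideRNA]):
        self.config = config
        self.regions = regions
        self.guides = guides
        model = config.indel_size_model
        self._p_side = 1.0 / (1.0 + model.deletion_mean_bp / 2.0)
        self._p_ins = 1.0 / max(model.insertion_mean_bp, 1.0)

    def _cut_prob(self, guide_id: str) -> float:
        return float(self.config.per_guide_cut_prob.get(guide_id, 1.0))

    def _random_bases(self, n: int, rng: np.random.Generator) -> str:
        alphabet = self.config.insertion_alphabet
        return "".join(alphabet[int(i)] for i in rng.integers(0, len(alphabet), n))

    def _single_site_edit(self, guide: GuideRNA, rng: np.random.Generator) -> tuple[int, int, str]:
        model = self.config.indel_size_model
        region = self.regions[guide.region]
        cut = guide.cut_site
        if rng.random() < model.insertion_prob:
            length = int(rng.geometric(self._p_ins))
            return cut, cut, self._random_bases(length, rng)
        for _ in range(100):
            left = int(rng.geometric(self._p_side)) - 1
            right = int(rng.geometric(self._p_side)) - 1
            total = left + right
            if 1 <= total <= model.deletion_max_bp:
                break
        start = max(0, cut - left)
        end = min(len(region), cut + right)
        if end <= start:  # extent entirely clipped off the amplicon edge
            start, end = max(0, cut - 1), min(len(region), cut + 1)
        return start, end, ""

    def draw(self, committed: Sequence[str], rng: np.random.Generator) -> list[ev.IndelEvent]:
        """Events for one germ-cell outcome (empty list: no edit)."""
        config = self.config
        if rng.random() >= config.edit_rate_ceiling:
            return []
        distinct = sorted(set(committed))
        active = [g for g in distinct if self._cut_prob(g) > 0]
        if not active:
            return []
        intent = "single"
        if len(active) == 2:
            draw = rng.random()
            if draw < config.inter_target_prob:
                intent = "inter"
            elif draw < config.inter_target_prob + config.double_site_prob:
                intent = "double"
            ga, gb = (self.guides[g] for g in active)
            if intent == "inter":
                separation = abs(ga.cut_site - gb.cut_site)
                if ga.region != gb.region or separation < config.dual_cut_min_separation:
                    intent = "single"  # steric suppression / different amplicons
        expected = {"single": "single_site", "double": "double_site",
                    "inter": "inter_target"}[intent]
        for _ in range(100):
            raw = self._draw_intent(intent, active, rng)
            events = []
            ok = True
            for region_name, start, end, ins in raw:
                region = self.regions[region_name]
                event = ev.make_event(region_name, start, end, ins, ref=region.sequence)
                if event is None:
                    ok = False
                    break
                events.append(event)
            if not ok:
                continue
            events.sort(key=ev.sort_key)
            if _overlapping(events):
                continue
            genotype = classify_genotype(events, self.guides, config.classify_window_bp)
            if genotype.category == expected and not genotype.ambiguous:
                return events
        raise RuntimeError("could not draw a consistent outcome in 100 attempts")

    def _draw_intent(self, intent: str, active: list[str],
                     rng: np.random.Generator) -> list[tuple[int, int, str]]:
        config = self.config
        model = config.indel_size_model
        if intent == "inter":
            ga, gb = (self.guides[g] for g in active)
            start, end = sorted((ga.cut_site, gb.cut_site))
            ins = ""
            if rng.random() < model.l_insertion_prob:
                ins = self._random_bases(int(rng.geometric(self._p_ins)), rng)
            return [(ga.region, start, end, ins)]
        if intent == "double":
            return [(self.guides[g].region, *self._single_site_edit(self.guides[g], rng))
                    for g in active]
        probs = np.array([self._cut_prob(g) for g in active], dtype=float)
        guide = self.guides[active[int(rng.choice(len(active), p=probs / probs.sum()))]]
        return [(guide.region, *self._single_site_edit(guide, rng))]


def _overlapping(events: Sequence[ev.IndelEvent]) -> bool:
    by_region: dict[str, list[ev.IndelEvent]] = {}
    for e in events:
        by_region.setdefault(e.region, []).append(e)
    for group in by_region.values():
        ordered = sorted(group, key=lambda e: (e.start, e.end))
        for prev, nxt in zip(ordered, ordered[1:]):
            if nxt.start <= prev.end:  # touching counts: keep junctions separable
                return True
    return False


def simulate_offspring(config: SimulationConfig,
                       regions: Mapping[str, TargetRegion],
                       arrays: Mapping[str, GuideArray],
                       guides: Mapping[str, GuideRNA],
                       rng: np.random.Generator | None = None) -> list[TrueGenotype]:
    """Simulate a cohort of offspring genotypes (no reads).

    Per founder, the GSC count is uniform on ``gsc_count_range`` and each
    GSC commits one guide per array copy. Independent mode draws a fresh
    outcome per offspring (each assigned a uniformly random GSC); clonal
    mode draws one outcome per GSC and replicates it over a
    Poisson-distributed number of offspring per GSC.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chosen_arrays = [arrays[a] for a in config.arrays]
    drawer = _OutcomeDrawer(config, regions, guides)
    cohort: list[TrueGenotype] = []
    low, high = config.gsc_count_range
    for f in range(config.founder_count):
        founder_id = f"F{f:03d}"
        gsc_count = int(rng.integers(low, high + 1))
        committed = [tuple(recombine_array(a, rng, guides) for a in chosen_arrays)
                     for _ in range(gsc_count)]
        births: list[tuple[int, list[ev.IndelEvent]]] = []
        if config.germline_mode == "independent":
            for _ in range(config.offspring_count):
                gsc = int(rng.integers(gsc_count))
                births.append((gsc, drawer.draw(committed[gsc], rng)))
        else:
            per_gsc = rng.poisson(config.offspring_count / gsc_count, gsc_count)
            for gsc in range(gsc_count):
                outcome = drawer.draw(committed[gsc], rng)
                births.extend((gsc, outcome) for _ in range(int(per_gsc[gsc])))
        for i, (gsc, outcome) in enumerate(births):
            offspring_id = f"{founder_id}O{i:04d}"
            classified = classify_genotype(outcome, guides, config.classify_window_bp,
                                           sample=offspring_id, founder=founder_id)
            cohort.append(TrueGenotype(
                offspring_id=offspring_id, founder_id=founder_id,
                gsc_id=f"{founder_id}G{gsc:02d}",
                chosen_guides=committed[gsc], events=tuple(outcome),
                category=classified.category, classified=classified))
    return cohort


def generate_reads(genotype: TrueGenotype, regions: Mapping[str, TargetRegion],
                   guides: Mapping[str, GuideRNA], config: SimulationConfig,
                   rng: np.random.Generator) -> list[tuple[str, str, str]]:
    """Single-end amplicon reads over a genotype's targeted regions.

    Per amplicon, ``reads_per_amplicon`` fragments start uniformly along
    the mutant allele with geometric lengths (mean ``fragment_mean_bp``);
    each read is the first ``read_length`` bases of its fragment, padded
    with the library adapter when the fragment is shorter. Substitution
    errors occur uniformly at ``base_error_rate``.
    """
    targeted = sorted({guides[g].region for g in genotype.chosen_guides})
    reads: list[tuple[str, str, str]] = []
    for region_name in targeted:
        region = regions[region_name]
        on_region = [e for e in genotype.events if e.region == region_name]
        allele = ev.apply_events(region.sequence, on_region)
        reads.extend(_reads_for_allele(genotype.offspring_id, region_name,
                                       allele, config, rng))
    return reads


def _with_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    hits = np.flatnonzero(rng.random(len(read)) < rate)
    if hits.size == 0:
        return read
    chars = list(read)
    for pos in hits:
        current = chars[pos]
        options = [b for b in _BASES if b != current]
        chars[pos] = options[int(rng.integers(0, len(options)))]
    return "".join(chars)


@dataclass
class CohortResult:
    """A simulated cohort: truth genotypes plus sequencing reads."""

    config: SimulationConfig
    genotypes: list[TrueGenotype]
    reads: list[tuple[str, str, str]]


def simulate_cohort(config: SimulationConfig,
                    regions: Mapping[str, TargetRegion],
                    arrays: Mapping[str, GuideArray],
                    guides: Mapping[str, GuideRNA],
                    with_reads: bool = True) -> CohortResult:
    """Simulate genotypes and (optionally) their amplicon reads.

    A single seeded generator drives guide commitment, outcomes and reads,
    so identical configs give byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    genotypes = simulate_offspring(config, regions, arrays, guides, rng)
    reads: list[tuple[str, str, str]] = []
    if with_reads:
        for genotype in genotypes:
            reads.extend(generate_reads(genotype, regions, guides, config, rng))
    return CohortResult(config=config, genotypes=genotypes, reads=reads)


def _reads_for_allele(offspring_id: str, region_name: str, allele: str,
                      config: SimulationConfig,
                      rng: np.random.Generator) -> list[tuple[str, str, str]]:
    length = len(allele)
    reads = []
    for i in range(config.reads_per_amplicon):
        start = int(rng.integers(0, length))
        frag_len = int(rng.geometric(1.0 / config.fragment_mean_bp))
        fragment = allele[start:start + frag_len]
        read = fragment[:config.read_length]
        if len(read) < config.read_length:
            read += config.adapter[:config.read_length - len(read)]
        if config.base_error_rate > 0:
            read = _with_errors(read, config.base_error_rate, rng)
        reads.append((f"{offspring_id}|{region_name}|{i}", read, "I" * len(read)))
    return reads


# ---------------------------------------------------------------------------
# truth tables and fixtures

def genotypes_to_frame(genotypes: Sequence[TrueGenotype]) -> pd.DataFrame:
    rows = [{"offspring": g.offspring_id, "founder": g.founder_id, "gsc": g.gsc_id,
             "chosen_guides": ",".join(g.chosen_guides), "category": g.category,
             "allele_key": g.allele_key} for g in genotypes]
    return pd.DataFrame(rows)


def truth_events_to_frame(genotypes: Sequence[TrueGenotype]) -> pd.DataFrame:
    rows = [{"sample": g.offspring_id, "region": e.region, "kind": e.kind,
             "start": e.start, "end": e.end, "size": e.size,
             "inserted_seq": e.inserted_seq, "support": e.support}
            for g in genotypes for e in g.events]
    return pd.DataFrame(rows, columns=["sample", "region", "kind", "start", "end",
                                       "size", "inserted_seq", "support"])


def config_to_json(config: SimulationConfig, path: str | Path) -> None:
    payload = dataclasses.asdict(config)
    payload["per_guide_cut_prob"] = dict(config.per_guide_cut_prob)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=list)
        fh.write("\n")


def synthetic_region_with_guides(name: str = "amplicon1", length: int = 455,
                                 protospacer_starts: Sequence[int] = (50, 146, 244, 344),
                                 seed: int = 0, exon_label: str | None = None,
                                 guide_prefix: str = "g",
                                 ) -> tuple[TargetRegion, dict[str, GuideRNA]]:
    """A random amplicon with uniquely placed forward-strand guides.

    Draws uniform random sequence, writes an NGG PAM 3' of each requested
    protospacer, and redraws until every spacer occurs exactly once (and
    never on the reverse strand). Cut sites land 17 bp into each
    protospacer.
    """
    starts = sorted(int(s) for s in protospacer_starts)
    if starts and (starts[0] < 0 or starts[-1] + 23 > length):
        raise ValueError("protospacers (plus PAM) must fit inside the region")
    for s, t in zip(starts, starts[1:]):
        if t - s < 23:
            raise ValueError("protospacers must not overlap each other's PAM")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        seq = list("ACGT"[int(i)] for i in rng.integers(0, 4, length))
        for s in starts:
            seq[s + 21] = "G"
            seq[s + 22] = "G"
        sequence = "".join(seq)
        region = TargetRegion(name=name, sequence=sequence, exon_label=exon_label)
        try:
            guides = {}
            for i, s in enumerate(starts):
                guide = locate_guide(region, sequence[s:s + 20],
                                     guide_id=f"{guide_prefix}{i + 1}")
                if guide.protospacer_start != s:
                    raise ValueError("misplaced")
                guides[guide.id] = guide
            return region, guides
        except ValueError:
            continue
    raise RuntimeError("could not draw an unambiguous synthetic region")
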