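import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from indelmap import cohort_simulator as sim
from indelmap import event_caller as ec
from indelmap import events as ev
from indelmap import guide_model as gm
from indelmap import read_prep as rp

from conftest import called_event_sets


def _random_seq(length, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def _record(pos, cigar, seq, region="amp"):
    return rp.AlignmentRecord(read_id="r", region=region, pos=pos, strand="+",
                              cigar=cigar, seq=seq)


class TestExtractCigarEvents:
    def test_single_deletion_run(self):
        record = _record(10, "20M5D20M", "A" * 40)
        events = ec.extract_cigar_events(record)
        assert [(e.kind, e.start, e.end) for e in events] == [("D", 30, 35)]

    def test_single_insertion_run(self):
        seq = "C" * 15 + "ACG" + "T" * 15
        record = _record(0, "15M3I15M", seq)
        events = ec.extract_cigar_events(record)
        assert [(e.kind, e.start, e.end, e.inserted_seq) for e in events] == \
            [("I", 15, 15, "ACG")]

    def test_mixed_deletion_and_insertion(self):
        record = _record(5, "10M2D5M1I5M", "G" * 21)
        events = ec.extract_cigar_events(record)
        assert [(e.kind, e.start, e.end) for e in events] == [("D", 15, 17), ("I", 22, 22)]

    def test_n_run_treated_as_deletion(self):
        record = _record(0, "10M8N10M", "A" * 20)
        events = ec.extract_cigar_events(record)
        assert [(e.kind, e.start, e.end) for e in events] == [("D", 10, 18)]

    def test_adjacent_insertion_deletion_merge_to_one_junction(self):
        """A D run directly followed by I is one complex junction event."""
        ref = _random_seq(100, 1)
        # read: ref[0:20] + 'XX' + ref[70:90]; represented as 20M 2I 50D 20M
        insert = "AA" if ref[20] != "A" and ref[69] != "A" else "CC"
        read = ref[0:20] + insert + ref[70:90]
        record = _record(0, "20M2I50D20M", read)
        events = ec.extract_cigar_events(record, ref)
        assert len(events) == 1
        event = events[0]
        assert event.kind == "L" and (event.start, event.end) == (20, 70)
        assert event.inserted_seq == insert

    def test_mismatch_columns_adjacent_to_deletion_are_folded_in(self):
        """Aligner-absorbed junction bases are recovered as inserted sequence."""
        ref = _random_seq(100, 2)
        # true edit: delete [20, 70) and insert 'q' where q[0] mismatches ref[20]
        q = "A" if ref[20] != "A" else "C"
        # aligner representation: the inserted base consumed as a mismatched M column
        read = ref[0:20] + q + ref[70:90]
        record = _record(0, "21M49D20M", read)  # M column 21 is the mismatch
        events = ec.extract_cigar_events(record, ref)
        assert len(events) == 1
        start, end, ins = ev.canonicalize_indel(20, 70, q, ref)
        assert (events[0].start, events[0].end, events[0].inserted_seq) == (start, end, ins)

    def test_inconsistent_record_raises(self):
        with pytest.raises(ValueError, match="inconsistent record"):
            record = rp.AlignmentRecord.__new__(rp.AlignmentRecord)
            object.__setattr__(record, "read_id", "r")
            object.__setattr__(record, "region", "amp")
            object.__setattr__(record, "pos", 0)
            object.__setattr__(record, "strand", "+")
            object.__setattr__(record, "cigar", "10M")
            object.__setattr__(record, "seq", "A" * 12)
            ec.extract_cigar_events(record)


class TestRescueSoftClips:
    def test_three_prime_clip_closes_large_gap(self):
        region = gm.TargetRegion(name="amp", sequence=_random_seq(300, 11))
        read = region.sequence[0:40] + region.sequence[240:280]
        record = rp.align_local(read, region)
        events = ec.rescue_soft_clips(record, region)
        start, end, ins = ev.canonicalize_indel(40, 240, "", region.sequence)
        assert [(e.kind, e.start, e.end, e.inserted_seq) for e in events] == \
            [("L", start, end, ins)]

    def test_novel_bases_between_blocks_become_inserted_seq(self):
        region = gm.TargetRegion(name="amp", sequence=_random_seq(300, 13))
        novel = "TTAACG"
        read = region.sequence[0:40] + novel + region.sequence[240:280]
        record = rp.align_local(read, region)
        events = ec.rescue_soft_clips(record, region)
        assert len(events) == 1
        start, end, ins = ev.canonicalize_indel(40, 240, novel, region.sequence)
        assert (events[0].kind, events[0].start, events[0].end) == ("L", start, end)
        assert events[0].inserted_seq == ins

    def test_short_clip_below_threshold_yields_nothing(self):
        region = gm.TargetRegion(name="amp", sequence=_random_seq(300, 14))
        read = region.sequence[0:40] + region.sequence[240:248]
        record = rp.align_local(read, region)
        assert record.clip3 == region.sequence[240:248] or len(record.clip3) < 15
        assert ec.rescue_soft_clips(record, region) == []

    def test_inverted_clip_is_logged_not_called(self):
        import collections
        region = gm.TargetRegion(name="amp", sequence=_random_seq(300, 15))
        read = region.sequence[0:40] + gm.revcomp(region.sequence[240:280])
        record = rp.align_local(read, region, try_reverse=False)
        stats = collections.Counter()
        assert ec.rescue_soft_clips(record, region, stats=stats) == []
        assert stats["clip_inverted"] == 1


def _events(n, sample="s", start=30, end=35):
    return [ev.IndelEvent(kind="D", region="amp", start=start, end=end, sample=sample)
            for _ in range(n)]


class TestAggregateAndFilter:
    def test_support_ten_kept_nine_dropped(self):
        table = ec.aggregate_and_filter(_events(10) + _events(9, start=50, end=60))
        assert table["support"].tolist() == [10]
        assert table.iloc[0]["start"] == 30

    def test_empty_input_gives_empty_table(self):
        assert ec.aggregate_and_filter([]).empty

    def test_identical_events_merge_across_reads(self):
        table = ec.aggregate_and_filter(_events(3) + _events(7),
                                        ec.CallerConfig(min_support=1))
        assert len(table) == 1 and table.iloc[0]["support"] == 10

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(counts=st.lists(st.integers(1, 30), min_size=1, max_size=6),
           threshold=st.integers(1, 25))
    def test_raising_min_support_never_adds_events(self, counts, threshold):
        events = [e for i, n in enumerate(counts)
                  for e in _events(n, start=10 * i + 1, end=10 * i + 5)]
        low = ec.aggregate_and_filter(events, ec.CallerConfig(min_support=1))
        high = ec.aggregate_and_filter(events, ec.CallerConfig(min_support=threshold))
        low_keys = set(map(tuple, low[["start", "end"]].values))
        high_keys = set(map(tuple, high[["start", "end"]].values))
        assert high_keys <= low_keys


class TestCallSample:
    def test_unedited_genotype_yields_empty_table(self, fixture4):
        region, _ = fixture4
        rng = np.random.default_rng(0)
        config = sim.SimulationConfig(arrays=("A",), reads_per_amplicon=60,
                                      base_error_rate=0.0)
        reads = sim._reads_for_allele("s0", region.name, region.sequence, config, rng)
        table, summary = ec.call_sample(iter(reads), {region.name: region})
        assert table.empty
        assert summary["reads_aligned"] > 0

    def test_known_deletion_support_counts_covering_reads(self, fixture4):
        """A single 5-bp deletion is called once, with plausible support."""
        region, guides = fixture4
        cut = guides["g2"].cut_site
        allele = region.sequence[:cut - 2] + region.sequence[cut + 3:]
        rng = np.random.default_rng(1)
        config = sim.SimulationConfig(arrays=("A",), reads_per_amplicon=200,
                                      base_error_rate=0.0)
        reads = sim._reads_for_allele("s0", region.name, allele, config, rng)
        table, _ = ec.call_sample(iter(reads), {region.name: region}, sample="s0")
        start, end, _ = ev.canonicalize_indel(cut - 2, cut + 3, "", region.sequence)
        assert len(table) == 1
        row = table.iloc[0]
        assert (row["kind"], row["start"], row["end"]) == ("D", start, end)
        assert 10 <= row["support"] <= 200

    def test_called_events_equal_truth_on_error_free_cohort(self, cohort_error_free,
                                                            called_error_free):
        """Error-free reads reproduce the simulator's exact event sets."""
        table, _ = called_error_free
        called = called_event_sets(table)
        for genotype in cohort_error_free.genotypes:
            truth = {e.key() for e in genotype.events}
            assert called.get(genotype.offspring_id, set()) == truth

    def test_inter_target_deletions_called_as_L(self, cohort_error_free,
                                                called_error_free):
        table, _ = called_error_free
        inter = [g for g in cohort_error_free.genotypes if g.category == "inter_target"]
        assert inter, "fixture cohort should contain inter-target offspring"
        called = called_event_sets(table)
        for genotype in inter:
            kinds = {k for (k, *_rest) in called[genotype.offspring_id]}
            assert "L" in kinds

    def test_read_counts_reconcile(self, called_error_free):
        _, summary = called_error_free
        assert summary["reads_in"] == (summary["reads_aligned"]
                                       + summary["reads_discarded_short"]
                                       + summary.get("reads_unaligned", 0))


class TestErrorRobustness:
    def test_recall_and_precision_at_sequencing_error_rate(self, fixture4, array4):
        """At a 1e-3 substitution rate, true events are recalled and no
        spurious event reaches the support threshold."""
        region, guides = fixture4
        config = sim.SimulationConfig(arrays=("A", "A"), founder_count=3,
                                      offspring_count=35, reads_per_amplicon=400,
                                      base_error_rate=0.001, seed=2)
        cohort = sim.simulate_cohort(config, {region.name: region},
                                     {"A": array4}, guides)
        table, _ = ec.call_cohort(iter(cohort.reads), {region.name: region})
        called = called_event_sets(table)
        n_true = recalled = false_calls = 0
        for g in cohort.genotypes:
            truth = {e.key() for e in g.events}
            got = called.get(g.offspring_id, set())
            n_true += len(truth)
            recalled += len(truth & got)
            false_calls += len(got - truth)
        assert n_true > 20
        assert recalled / n_true >= 0.95
        assert false_calls == 0


class TestSamIngestion:
    def test_sam_records_give_same_events_as_fastq_path(self, tmp_path, fixture4):
        region, guides = fixture4
        cut = guides["g3"].cut_site
        allele = region.sequence[:cut - 4] + region.sequence[cut + 4:]
        rng = np.random.default_rng(3)
        config = sim.SimulationConfig(arrays=("A",), reads_per_amplicon=80,
                                      base_error_rate=0.0)
        reads = sim._reads_for_allele("s0", region.name, allele, config, rng)
        records = []
        kept = []
        for rid, seq, qual in reads:
            trimmed = rp.trim_adapter(seq, qual)
            if trimmed.discarded:
                continue
            record = rp.align_local(trimmed.sequence, region, read_id=rid,
                                    qual=trimmed.quality)
            if record:
                records.append(record)
                kept.append((rid, trimmed.sequence, trimmed.quality))
        path = tmp_path / "aln.sam"
        rp.write_sam(records, path, {region.name: region})
        back, _ = rp.read_sam(path)
        direct = [e for r in records for e in ec.extract_cigar_events(r, region.sequence)]
        via_sam = [e for r in back for e in ec.extract_cigar_events(r, region.sequence)]
        assert sorted(direct, key=ev.sort_key) == sorted(via_sam, key=ev.sort_key)


class TestExtendedReference:
    def test_cross_amplicon_deletion_needs_extended_second_pass(self):
        """A deletion joining two amplicons is recovered on the joined reference."""
        joined_seq = _random_seq(600, 21)
        joined = gm.TargetRegion(name="joined", sequence=joined_seq)
        region_a = gm.TargetRegion(name="ampA", sequence=joined_seq[:300])
        region_b = gm.TargetRegion(name="ampB", sequence=joined_seq[300:])
        allele = joined_seq[:140] + joined_seq[400:]
        rng = np.random.default_rng(5)
        config = sim.SimulationConfig(arrays=("A",), reads_per_amplicon=150,
                                      base_error_rate=0.0)
        reads = sim._reads_for_allele("s0", "x", allele, config, rng)
        caller_config = ec.CallerConfig(second_pass_reference="extended_reference")
        table, _ = ec.call_sample(iter(reads), {"ampA": region_a, "ampB": region_b},
                                  config=caller_config, sample="s0",
                                  extended_reference=joined)
        deletions = table[table["kind"] == "L"]
        assert len(deletions) == 1
        start, end, _ = ev.canonicalize_indel(140, 400, "", joined_seq)
        row = deletions.iloc[0]
        assert (row["region"], row["start"], row["end"]) == ("joined", start, end)
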