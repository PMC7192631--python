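import pytest

from indelmap import cohort_simulator as sim
from indelmap import event_caller as ec
from indelmap import guide_model as gm


@pytest.fixture(scope="session")
def fixture4():
    """A 455-bp amplicon with four uniquely placed guides (cuts ~100 bp apart)."""
    region, guides = sim.synthetic_region_with_guides(seed=3)
    return region, guides


@pytest.fixture(scope="session")
def array4(fixture4):
    _, guides = fixture4
    return gm.GuideArray(id="A", guides=tuple(sorted(guides)))


@pytest.fixture(scope="session")
def cohort_error_free(fixture4, array4):
    """Error-free dual-array cohort (120 offspring) with reads and truth."""
    region, guides = fixture4
    config = sim.SimulationConfig(arrays=("A", "A"), founder_count=3,
                                  offspring_count=40, reads_per_amplicon=300,
                                  base_error_rate=0.0, seed=7)
    return sim.simulate_cohort(config, {region.name: region}, {"A": array4}, guides)


@pytest.fixture(scope="session")
def called_error_free(cohort_error_free, fixture4):
    """Event table called from the shared error-free cohort's reads."""
    region, _ = fixture4
    table, summary = ec.call_cohort(iter(cohort_error_free.reads),
                                    {region.name: region})
    return table, summary


def called_event_sets(table):
    """Per-sample called (kind, region, start, end, inserted_seq) sets."""
    out = {}
    for row in table.itertuples(index=False):
        ins = row.inserted_seq if isinstance(row.inserted_seq, str) else ""
        out.setdefault(row.sample, set()).add(
            (row.kind, row.region, int(row.start), int(row.end), ins))
    return out
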