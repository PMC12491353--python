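import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ystr_popkit.haplotype_io import (
    HaplotypeTable,
    LocusPanel,
    STRProfile,
    YFILER_PANEL,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def single_locus_panel():
    return LocusPanel(loci=("DYS19",), multi_copy=frozenset(), derived_encoding={})


def make_single_locus_table(values_by_pop, panel=None):
    """Build a table with one single-copy locus from {pop: [values]}."""
    panel = panel or LocusPanel(loci=("DYS19",), multi_copy=frozenset(),
                                derived_encoding={})
    profiles = []
    i = 0
    for pop, values in values_by_pop.items():
        for v in values:
            profiles.append(STRProfile.build(f"s{i}", pop, {"DYS19": v}, panel))
            i += 1
    return HaplotypeTable(panel=panel, profiles=tuple(profiles))


def table_from_multiplicities(multiplicities, n_micro_carriers=0,
                              population="Yemen"):
    """Full-panel table whose haplotype spectrum has the given multiplicities.

    Distinct haplotypes differ at DYS19; the first ``n_micro_carriers``
    individuals carry the 17.2 microvariant at DYS458.
    """
    profiles = []
    idx = 0
    base = {
        "DYS19": 14, "DYS389I": 13, "DYS389II": 29, "DYS390": 23, "DYS391": 11,
        "DYS392": 11, "DYS393": 12, "DYS385": (13, 17), "DYS438": 10,
        "DYS439": 11, "DYS437": 14, "DYS448": 20, "DYS456": 15, "DYS458": 17,
        "DYS635": 21, "YGATAH4": 11,
    }
    for h, mult in enumerate(multiplicities):
        for _ in range(mult):
            values = dict(base)
            values["DYS19"] = 10 + h
            if idx < n_micro_carriers:
                values["DYS458"] = 17.2
            else:
                # keep the haplotype key distinct from carrier copies
                values["DYS458"] = 17
            profiles.append(
                STRProfile.build(f"Y{idx:03d}", population, values, YFILER_PANEL)
            )
            idx += 1
    return HaplotypeTable(panel=YFILER_PANEL, profiles=tuple(profiles))


@pytest.fixture(scope="session")
def study_table():
    from ystr_popkit.synthetic_data import simulate_table, study_config

    table, truth = simulate_table(study_config(seed=11))
    return table, truth
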