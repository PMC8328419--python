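"""Hierarchical individual selection and replicate-table construction."""

import numpy as np
import pandas as pd
import pytest

from deepfd.errors import UnresolvableOccurrenceError
from deepfd.resampling import (
    IndividualPools, average_metrics, build_replicates, select_individual,
)
from deepfd.traits import TRAITS


def _individual(iid, species, depth, loc, source="bruv", lat=40.0):
    row = {"individual_id": iid, "species": species, "depth_m": depth,
           "location": loc, "latitude_s": lat, "source": source}
    rng = np.random.default_rng(abs(hash(iid)) % 2**31)
    row.update({t: rng.uniform(0.5, 2.0) for t in TRAITS})
    return row


@pytest.fixture
def pools_df():
    return pd.DataFrame([
        _individual("a1", "sp1", 100, "L1"),
        _individual("a2", "sp1", 100, "L1"),
        _individual("b1", "sp1", 100, "L2"),
        _individual("c1", "sp1", 500, "L3"),
        _individual("d1", "sp1", np.nan, "", source="museum"),
        _individual("d2", "sp2", np.nan, "", source="museum"),
    ])


def test_hierarchy_levels(pools_df, rng):
    pools = IndividualPools(pools_df)
    # two in-cell conspecifics -> level a, one of the two
    ridx, level = select_individual("sp1", (100, "L1"), pools, rng)
    assert level == "a" and pools_df.loc[ridx, "individual_id"] in {"a1", "a2"}
    # none in cell, one at same depth elsewhere -> level b
    ridx, level = select_individual("sp1", (100, "L9"), pools, rng)
    assert level == "b" and pools_df.loc[ridx, "individual_id"] in {"a1", "a2", "b1"}
    # none at that depth -> any bruv record, level c
    ridx, level = select_individual("sp1", (900, "L9"), pools, rng)
    assert level == "c"
    # only museum -> level d
    ridx, level = select_individual("sp2", (100, "L1"), pools, rng)
    assert level == "d" and pools_df.loc[ridx, "individual_id"] == "d2"


def test_unresolvable_species_raises(pools_df, rng):
    pools = IndividualPools(pools_df)
    with pytest.raises(UnresolvableOccurrenceError):
        select_individual("sp404", (100, "L1"), pools, rng)


def test_singleton_pools_make_identical_tables():
    individuals = pd.DataFrame([
        _individual(f"i{k}", f"sp{k}", 100, "L1") for k in range(6)
    ])
    occurrences = pd.DataFrame(
        {"species": [f"sp{k}" for k in range(6)], "depth_m": 100,
         "location": "L1", "latitude_s": 40.0}
    )
    tables = build_replicates(occurrences, individuals, n_rep=10, seed=0)
    for t in tables[1:]:
        pd.testing.assert_frame_equal(t, tables[0])
    assert (tables[0]["level"] == "a").all()


def test_equal_probability_within_pool(pools_df):
    occurrences = pd.DataFrame(
        [{"species": "sp1", "depth_m": 100, "location": "L1", "latitude_s": 40.0},
         {"species": "sp2", "depth_m": 100, "location": "L1", "latitude_s": 40.0}]
    )
    # add more species so normalization has variance
    extra = pd.DataFrame([_individual(f"x{k}", f"sp{k+3}", 100, "L1")
                          for k in range(4)])
    individuals = pd.concat([pools_df, extra], ignore_index=True)
    occ_extra = pd.DataFrame(
        {"species": [f"sp{k+3}" for k in range(4)], "depth_m": 100,
         "location": "L1", "latitude_s": 40.0}
    )
    occurrences = pd.concat([occurrences, occ_extra], ignore_index=True)
    tables = build_replicates(occurrences, individuals, n_rep=100, seed=3)
    picks = [t.loc[t["species"] == "sp1", "individual_id"].iloc[0] for t in tables]
    n_a1 = picks.count("a1")
    assert picks.count("a1") + picks.count("a2") == 100
    # binomial(100, 1/2): 4 sigma band
    assert abs(n_a1 - 50) <= 4 * np.sqrt(100 * 0.25)


def test_replicates_are_normalized_and_seed_deterministic(small_community):
    sim = small_community
    tables = build_replicates(sim.occurrences, sim.individuals, n_rep=3, seed=9)
    again = build_replicates(sim.occurrences, sim.individuals, n_rep=3, seed=9)
    for t, u in zip(tables, again):
        pd.testing.assert_frame_equal(t, u)
    for t in tables:
        assert len(t) == len(sim.occurrences)
        for trait in TRAITS:
            assert abs(t[trait].mean()) < 1e-10
            assert t[trait].std(ddof=1) == pytest.approx(1.0, abs=1e-10)


def test_average_metrics_means_sds_and_exclusions():
    df = pd.DataFrame({
        "replicate": [0, 1, 2, 0, 1, 2],
        "depth_m": [100] * 3 + [500] * 3,
        "location": ["L1"] * 6,
        "M": [1.0, 2.0, 3.0, 5.0, np.nan, 7.0],
    })
    out = average_metrics(df, ["M"])
    row100 = out[out["depth_m"] == 100].iloc[0]
    assert row100["M"] == pytest.approx(2.0)
    assert row100["M_n"] == 3
    row500 = out[out["depth_m"] == 500].iloc[0]
    assert row500["M"] == pytest.approx(6.0)  # undefined replicate excluded
    assert row500["M_n"] == 2
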