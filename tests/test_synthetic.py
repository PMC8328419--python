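"""Generator contracts: determinism, variance calibration, round trips,
missingness, and design realism."""

import numpy as np
import pandas as pd
import pytest

from deepfd.errors import GenerationError, ParameterError
from deepfd.synthetic import (
    SimulationParams, StudyDesign, knockout_missing, simulate_balanced_cells,
    simulate_measurements, simulate_traits,
)
from deepfd.traits import MEASUREMENTS, TRAITS, derive_trait_table


def test_default_design_has_47_cells():
    d = StudyDesign()
    assert len(d.occupied_cells) == 47
    assert list(d.depth_strata) == [50, 100, 300, 500, 700, 900, 1200]
    lats = [lat for _, lat in d.locations]
    assert lats[0] == pytest.approx(29.0) and lats[-1] == pytest.approx(51.0)


def test_negative_variance_rejected():
    with pytest.raises(ParameterError):
        SimulationParams(sigma2_I=-1.0)


def test_determinism_identical_seed(small_community):
    again = simulate_traits(
        StudyDesign(),
        SimulationParams(n_species=15, mean_occ_richness=6,
                         measured_fraction=0.5, seed=11),
    )
    pd.testing.assert_frame_equal(again.individuals, small_community.individuals)
    pd.testing.assert_frame_equal(again.occurrences, small_community.occurrences)


def test_zero_within_variance_gives_identical_conspecifics():
    sim = simulate_traits(
        StudyDesign(),
        SimulationParams(n_species=10, sigma2_I=0.0, measured_fraction=0.8, seed=3),
    )
    for _, grp in sim.individuals.groupby("species"):
        assert np.allclose(grp[TRAITS].to_numpy().std(axis=0), 0.0)


def test_variance_calibration_balanced_cells():
    """Empirical within/between variances converge to the set values."""
    df = simulate_balanced_cells(
        n_cells=500, n_species=6, n_per_species=5,
        sigma2_I=1.0, sigma2_S=4.0, n_traits=2, seed=7,
    )
    within = df.groupby(["cell", "species"])["trait_1"].var(ddof=1)
    est = within.mean()
    se = within.std(ddof=1) / np.sqrt(len(within))
    assert abs(est - 1.0) < 3 * se
    # null between-species effect: species-mean variance matches sigma2_S + sigma2_I/n
    means = df.groupby(["cell", "species"])["trait_2"].mean()
    between = means.groupby(level="cell").var(ddof=1)
    expect = 4.0 + 1.0 / 5
    assert abs(between.mean() - expect) / expect < 0.1


def test_null_between_species_component():
    df = simulate_balanced_cells(200, 5, 5, sigma2_I=1.0, sigma2_S=0.0,
                                 n_traits=1, seed=9)
    means = df.groupby(["cell", "species"])["trait_1"].mean()
    between = means.groupby(level="cell").var(ddof=1)
    # species means only differ through sampling noise sigma2_I/n
    assert between.mean() == pytest.approx(1.0 / 5, rel=0.15)


def test_measurement_roundtrip_exact(small_community, small_morpho):
    derived = derive_trait_table(small_morpho)
    a = derived[TRAITS].to_numpy()
    b = small_community.individuals[TRAITS].to_numpy()
    assert np.abs(a - b).max() < 1e-12


def test_ratio_inversion_example():
    traits = pd.DataFrame([{
        "total_length": 300.0, "eye_size": 0.5, "oral_gape_position": 0.5,
        "jaw_length": 0.4, "elongation": 5.0, "eye_position": 0.6,
        "caudal_peduncle_throttling": 1.5, "pectoral_fin_position": 1.0,
    }])
    m = simulate_measurements(traits, seed=0)
    assert m["Ed"].iloc[0] == pytest.approx(0.5 * m["Hd"].iloc[0])


def test_nonpositive_trait_rejected():
    traits = pd.DataFrame([{t: 1.0 for t in TRAITS}])
    traits.loc[0, "eye_size"] = -0.1
    with pytest.raises(GenerationError, match="eye_size"):
        simulate_measurements(traits)


def test_knockout_rates_and_labels(small_morpho):
    ko = knockout_missing(small_morpho, 0.1, max_missing_per_individual=3, seed=5)
    frac = ko[MEASUREMENTS].isna().to_numpy().mean()
    n = ko[MEASUREMENTS].size
    # binomial oracle: 3 sigma around the nominal rate
    assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / n)
    flagged = ko[ko["exceeds_max_missing"]]
    assert (flagged["n_missing"] > 3).all()
    unflagged = ko[~ko["exceeds_max_missing"]]
    assert (unflagged["n_missing"] <= 3).all()


def test_knockout_rate_zero_and_one(small_morpho):
    ko0 = knockout_missing(small_morpho, 0.0, seed=1)
    assert not ko0[MEASUREMENTS].isna().any().any()
    ko1 = knockout_missing(small_morpho, 1.0, seed=1)
    assert ko1[MEASUREMENTS].isna().all().all()
    assert ko1["exceeds_max_missing"].all()


def test_design_realism_defaults():
    """Measured richness and individuals per species match the field design."""
    sim = simulate_traits(StudyDesign(), SimulationParams(seed=0))
    bruv = sim.individuals[sim.individuals["source"] == "bruv"]
    sp_per_cell = bruv.groupby(["depth_m", "location"])["species"].nunique()
    assert 1 <= sp_per_cell.mean() <= 10
    inds = bruv.groupby(["depth_m", "location", "species"]).size()
    assert 2 <= inds.mean() <= 15
    assert inds.min() >= 2 and inds.max() <= 15
    # occurrence table scale mirrors the study design
    assert 350 <= len(sim.occurrences) <= 650
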