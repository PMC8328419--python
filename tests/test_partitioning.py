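"""PERMANOVA variance partition vs classical ANOVA oracles."""

import numpy as np
import pandas as pd
import pytest

from deepfd.errors import UndefinedMetricError
from deepfd.partitioning import (
    mpfd_i, n0, partition_cell, partition_cells, permanova_one_way,
    variance_components,
)


def classical_anova_ss(values, labels):
    """Textbook one-way ANOVA sums of squares (univariate oracle)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    grand = values.mean()
    ss_between = sum(
        (values[labels == g].mean() - grand) ** 2 * (labels == g).sum()
        for g in np.unique(labels)
    )
    ss_within = sum(
        ((values[labels == g] - values[labels == g].mean()) ** 2).sum()
        for g in np.unique(labels)
    )
    return ss_between, ss_within


def test_worked_univariate_example():
    X = np.array([[0.0], [2.0], [4.0], [6.0]])
    labels = ["A", "A", "B", "B"]
    ss_sp, ss_res, df_sp, df_res = permanova_one_way(X, labels)
    assert ss_sp == pytest.approx(16.0, abs=1e-12)
    assert ss_res == pytest.approx(4.0, abs=1e-12)
    assert (df_sp, df_res) == (1, 2)
    s2i, s2s, prop = variance_components(ss_sp / df_sp, ss_res / df_res, n0([2, 2]))
    assert s2i == pytest.approx(2.0)
    assert s2s == pytest.approx(7.0)
    assert prop == pytest.approx(2 / 9)


def test_all_identical_individuals_zero_ss():
    X = np.ones((6, 3))
    ss_sp, ss_res, _, _ = permanova_one_way(X, ["A"] * 3 + ["B"] * 3)
    assert ss_sp == pytest.approx(0.0, abs=1e-12)
    assert ss_res == pytest.approx(0.0, abs=1e-12)


def test_distance_partition_matches_classical_anova(rng):
    for _ in range(10):
        labels = np.repeat([f"g{i}" for i in range(4)], rng.integers(2, 6, size=4))
        values = rng.normal(size=len(labels))
        ss_sp, ss_res, _, _ = permanova_one_way(values[:, None], labels)
        ssb, ssw = classical_anova_ss(values, labels)
        assert ss_sp == pytest.approx(ssb, abs=1e-10)
        assert ss_res == pytest.approx(ssw, abs=1e-10)


def test_coordinate_additivity(rng):
    """Multivariate SS equal the sum of per-trait univariate SS."""
    labels = np.repeat(["a", "b", "c"], [3, 5, 4])
    X = rng.normal(size=(len(labels), 8))
    ss_sp, ss_res, _, _ = permanova_one_way(X, labels)
    per_trait = [classical_anova_ss(X[:, j], labels) for j in range(8)]
    assert ss_sp == pytest.approx(sum(b for b, _ in per_trait), abs=1e-10)
    assert ss_res == pytest.approx(sum(w for _, w in per_trait), abs=1e-10)


@pytest.mark.parametrize(
    "counts, expected",
    [((5, 5, 5), 5.0), ((2, 4), 8 / 3), ((1, 1, 10), 7 / 4), ((3, 3), 3.0)],
)
def test_n0_formula_values(counts, expected):
    # hand evaluation of (1/(a-1)) [sum n - sum n^2 / sum n]
    assert n0(counts) == pytest.approx(expected, abs=1e-12)


def test_n0_bound_and_balance(rng):
    for _ in range(20):
        counts = rng.integers(1, 12, size=rng.integers(2, 8))
        v = n0(counts)
        assert v <= counts.max() + 1e-12
        assert v > 0
    with pytest.raises(UndefinedMetricError):
        n0([4])


def test_negative_sigma2_s_reported_raw_and_clamped_in_prop():
    s2i, s2s, prop = variance_components(1.0, 2.0, 2.0)
    assert s2s == pytest.approx(-0.5)
    assert prop == pytest.approx(1.0)
    s2i, s2s, prop = variance_components(2.0, 2.0, 2.0)
    assert s2s == pytest.approx(0.0) and prop == pytest.approx(1.0)


def test_mpfd_i_enumeration():
    X = np.array([[0.0], [2.0], [4.0], [6.0]])
    labels = ["A", "A", "B", "B"]
    assert mpfd_i(X, labels) == pytest.approx(2.0)
    assert mpfd_i(np.array([[0.0], [2.0]]), ["A", "A"]) == pytest.approx(2.0)
    with pytest.raises(UndefinedMetricError):
        mpfd_i(np.array([[0.0], [2.0]]), ["A", "B"])
    # per-species averaging variant
    X2 = np.array([[0.0], [2.0], [0.0], [6.0]])
    assert mpfd_i(X2, ["A", "A", "B", "B"]) == pytest.approx(4.0)
    assert mpfd_i(X2, ["A", "A", "B", "B"], per_species_mean=True) == \
        pytest.approx(4.0)


def test_partition_cell_singletons_retained_and_flags():
    X = np.array([[0.0], [2.0], [5.0]])
    res = partition_cell(X, ["A", "A", "B"])
    assert res.a == 2 and res.N == 3
    # singleton informs between-species SS; df_res = 1
    assert np.isfinite(res.sigma2_I)
    res2 = partition_cell(np.array([[0.0], [5.0]]), ["A", "B"])
    assert "df_res" in res2.flags or np.isnan(res2.sigma2_I)


def test_partition_cells_table(small_community):
    bruv = small_community.individuals.query("source == 'bruv'")
    from deepfd.traits import TRAITS, normalize_traits
    norm, _ = normalize_traits(bruv)
    out = partition_cells(norm, trait_cols=TRAITS)
    ok = out.dropna(subset=["Prop_I"])
    assert len(ok) > 0
    assert ((ok["Prop_I"] > 0) & (ok["Prop_I"] <= 1)).all()
    # SS additivity invariant within each cell
    close = np.isclose(ok["MS_species"] * (ok["a"] - 1) + ok["MS_res"] * (ok["N"] - ok["a"]),
                       ok["SS_species"] + ok["SS_res"], atol=1e-8)
    assert close.all()


def test_correlation_of_components_with_direct_distances(rng):
    """sigma2_I tracks MPFD.I and sigma2_S tracks MPFD across heterogeneous cells."""
    from scipy.stats import spearmanr
    from deepfd.synthetic import simulate_balanced_cells
    rows = []
    for k in range(40):
        s2i = rng.uniform(0.2, 3.0)
        s2s = rng.uniform(0.5, 6.0)
        df = simulate_balanced_cells(1, 6, 5, s2i, s2s, n_traits=8, seed=1000 + k)
        X = df[[c for c in df.columns if c.startswith("trait_")]].to_numpy()
        res = partition_cell(X, df["species"].to_numpy())
        means = df.groupby("species").mean(numeric_only=True).to_numpy()
        from deepfd.fd_metrics import distance_matrix, mpfd
        rows.append({"s2i": res.sigma2_I, "mpfd_i": res.mpfd_I,
                     "s2s": res.sigma2_S_raw, "mpfd": mpfd(distance_matrix(means))})
    df = pd.DataFrame(rows)
    assert spearmanr(df["s2i"], df["mpfd_i"]).statistic > 0.8
    assert spearmanr(df["s2s"], df["mpfd"]).statistic > 0.8
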