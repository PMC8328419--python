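"""Distance-based diversity indices, PCA scoring, and the KDE hypervolume."""

import numpy as np
import pandas as pd
import pytest

from deepfd.errors import DegenerateGeometryError, UndefinedMetricError
from deepfd.fd_metrics import (
    compute_cell_metrics, distance_matrix, fhv, mnnd, mpfd, pca_scores,
    vnnd, vpfd,
)
from deepfd.traits import TRAITS


def brute_mpfd(X):
    n = len(X)
    d = [np.linalg.norm(X[i] - X[j]) for i in range(n) for j in range(i + 1, n)]
    return np.mean(d)


def brute_mnnd(X):
    n = len(X)
    nnd = [min(np.linalg.norm(X[i] - X[j]) for j in range(n) if j != i)
           for i in range(n)]
    return np.mean(nnd)


def brute_vpfd(X):
    n = len(X)
    d = [np.linalg.norm(X[i] - X[j]) for i in range(n) for j in range(i + 1, n)]
    return np.var(d, ddof=1)


def brute_vnnd(X):
    n = len(X)
    nnd = [min(np.linalg.norm(X[i] - X[j]) for j in range(n) if j != i)
           for i in range(n)]
    return np.var(nnd, ddof=1)


def test_two_species_single_pair():
    D = distance_matrix(np.array([[0.0], [3.0]]))
    assert mpfd(D) == pytest.approx(3.0)
    assert mnnd(D) == pytest.approx(3.0)


def test_equilateral_triangle():
    pts = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
    D = distance_matrix(pts)
    assert mpfd(D) == pytest.approx(1.0)
    assert vpfd(D) == pytest.approx(0.0, abs=1e-12)
    assert vnnd(D) == pytest.approx(0.0, abs=1e-12)


def test_collinear_nearest_neighbour_values():
    D = distance_matrix(np.array([[0.0], [1.0], [10.0]]))
    assert mnnd(D) == pytest.approx(11 / 3)
    assert vnnd(D) == pytest.approx(64 / 3)


def test_pairwise_distance_variance_hand_value():
    # pairwise distances {1, 1, 4}: collinear points 0, 1, and d with
    # distances chosen directly via a custom matrix
    D = np.array([[0, 1, 4], [1, 0, 1], [4, 1, 0]], dtype=float)
    assert vpfd(D) == pytest.approx(3.0)


def test_undefined_below_minimum_species():
    D1 = distance_matrix(np.array([[0.0]]))
    for metric in (mpfd, mnnd):
        with pytest.raises(UndefinedMetricError):
            metric(D1)
    D2 = distance_matrix(np.array([[0.0], [1.0]]))
    for metric in (vpfd, vnnd):
        with pytest.raises(UndefinedMetricError):
            metric(D2)


def test_metrics_match_bruteforce_and_mnnd_bound(rng):
    for _ in range(20):
        X = rng.normal(size=(rng.integers(3, 15), 8))
        D = distance_matrix(X)
        assert mpfd(D) == pytest.approx(brute_mpfd(X), abs=1e-12)
        assert mnnd(D) == pytest.approx(brute_mnnd(X), abs=1e-12)
        assert vpfd(D) == pytest.approx(brute_vpfd(X), abs=1e-12)
        assert vnnd(D) == pytest.approx(brute_vnnd(X), abs=1e-12)
        assert mnnd(D) <= mpfd(D) + 1e-12
        assert vpfd(D) >= 0 and vnnd(D) >= 0


def test_pca_variance_fractions_and_isotropy(rng):
    df = pd.DataFrame(rng.standard_normal((2000, 8)), columns=TRAITS)
    scores, vexp = pca_scores(df)
    assert np.all(np.diff(vexp) <= 1e-12)
    assert vexp.sum() <= 1 + 1e-12
    # isotropic data: each of 8 PCs explains ~1/8 of the variance
    assert np.allclose(vexp, 0.125, atol=0.02)
    assert list(scores.columns[-4:]) == ["PC1", "PC2", "PC3", "PC4"]


def test_pca_sign_convention_deterministic(rng):
    df = pd.DataFrame(rng.standard_normal((60, 8)), columns=TRAITS)
    s1, _ = pca_scores(df)
    s2, _ = pca_scores(df.copy())
    pd.testing.assert_frame_equal(s1, s2)


def test_fhv_translation_and_scale_equivariance(rng):
    pts = rng.standard_normal((60, 4))
    base = fhv(pts, seed=4, n_mc_samples=60_000)
    shifted = fhv(pts + np.array([5.0, -3.0, 2.0, 100.0]), seed=4,
                  n_mc_samples=60_000)
    tol = 3 * np.hypot(base.se, shifted.se)
    assert abs(shifted.volume - base.volume) < tol
    scaled = fhv(2.0 * pts, seed=4, n_mc_samples=60_000)
    tol = 3 * np.hypot(16 * base.se, scaled.se)
    assert abs(scaled.volume - 16 * base.volume) < tol


def test_fhv_guards():
    with pytest.raises(UndefinedMetricError):
        fhv(np.zeros((4, 4)))
    with pytest.raises(DegenerateGeometryError):
        fhv(np.tile([[1.0, 2.0, 3.0, 4.0]], (6, 1)))


def test_compute_cell_metrics_flags_and_bruteforce(rng):
    rows = []
    for cell, s in [("A", 1), ("B", 2), ("C", 8)]:
        for k in range(s):
            rows.append({"depth_m": 100, "location": cell, "species": f"sp{cell}{k}",
                         **{t: rng.normal() for t in TRAITS}})
    df = pd.DataFrame(rows)
    out = compute_cell_metrics(df, fhv_samples_per_point=500, seed=1)
    a = out[out["location"] == "A"].iloc[0]
    assert a["S"] == 1 and np.isnan(a["MPFD"]) and "pairwise_undefined" in a["flags"]
    b = out[out["location"] == "B"].iloc[0]
    assert np.isfinite(b["MPFD"]) and np.isnan(b["VPFD"])
    c = out[out["location"] == "C"].iloc[0]
    X = df[df["location"] == "C"][TRAITS].to_numpy()
    assert c["MPFD"] == pytest.approx(brute_mpfd(X), abs=1e-10)
    assert np.isfinite(c["FHV"])
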