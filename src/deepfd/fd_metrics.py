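"""Species-level functional diversity indices in normalized trait space.

Five complementary indices are computed per depth-by-location cell from
Euclidean distances among the cell's species in z-scored 8-trait space:

* **MPFD** — mean pairwise distance: functional dispersion, independent of
  species richness.
* **MNND** — mean nearest-neighbour distance: species packing/originality.
* **VPFD** — variance of pairwise distances: regularity of the spread.
* **VNND** — variance of nearest-neighbour distances: regularity of packing.
* **FHV** — functional hypervolume: volume of the region of the first four
  principal-component axes where a Gaussian kernel density built on the
  cell's species exceeds the threshold retaining 95% of total probability
  mass ("loose wrap"), with per-axis Silverman bandwidths.

Variances use the unbiased n-1 denominator. Metrics that need at least
2 (MPFD, MNND) or 3 (VPFD, VNND) species, or 5 points (FHV), signal
undefined rather than returning a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .errors import DegenerateGeometryError, UndefinedMetricError
from .traits import TRAITS

__all__ = [
    "distance_matrix", "mpfd", "mnnd", "vpfd", "vnnd",
    "pca_scores", "fhv", "FHVResult", "compute_cell_metrics",
]

METRIC_COLUMNS = ["S", "FHV", "MPFD", "MNND", "VPFD", "VNND"]


def distance_matrix(X: np.ndarray) -> np.ndarray:
    """Square Euclidean distance matrix among the rows of X."""
    return squareform(pdist(np.asarray(X, dtype=float)))


def _check_square(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    return D


def mpfd(D: np.ndarray) -> float:
    """Mean of the S(S-1)/2 pairwise distances."""
    D = _check_square(D)
    s = D.shape[0]
    if s < 2:
        raise UndefinedMetricError("MPFD needs at least 2 species")
    iu = np.triu_indices(s, k=1)
    return float(D[iu].mean())


def _nnd(D: np.ndarray) -> np.ndarray:
    """Per-species distance to its nearest neighbour."""
    s = D.shape[0]
    masked = D + np.diag(np.full(s, np.inf))
    return masked.min(axis=1)


def mnnd(D: np.ndarray) -> float:
    """Mean over species of the distance to the functionally closest species."""
    D = _check_square(D)
    if D.shape[0] < 2:
        raise UndefinedMetricError("MNND needs at least 2 species")
    return float(_nnd(D).mean())


def vpfd(D: np.ndarray) -> float:
    """Sample variance (n-1) of the pairwise distances."""
    D = _check_square(D)
    s = D.shape[0]
    if s < 3:
        raise UndefinedMetricError("VPFD needs at least 3 species")
    iu = np.triu_indices(s, k=1)
    return float(D[iu].var(ddof=1))


def vnnd(D: np.ndarray) -> float:
    """Sample variance (n-1) of the per-species nearest-neighbour distances."""
    D = _check_square(D)
    if D.shape[0] < 3:
        raise UndefinedMetricError("VNND needs at least 3 species")
    return float(_nnd(D).var(ddof=1))


def pca_scores(
    table: pd.DataFrame, n_components: int = 4, columns: list[str] | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component scores of a normalized trait table.

    The PCA is fit on the table's trait columns (centred; covariance-based,
    which coincides with correlation-based after z-scoring). The sign of
    each component is fixed so its largest-magnitude loading is positive.

    Returns ``(scores, variance_explained)`` where ``scores`` carries the
    table's non-trait columns plus ``PC1..PCk``.
    """
    cols = columns or [c for c in TRAITS if c in table.columns]
    X = table[cols].to_numpy(dtype=float)
    if len(X) < n_components + 1:
        raise UndefinedMetricError(
            f"PCA needs at least {n_components + 1} rows, got {len(X)}"
        )
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    if pca.explained_variance_[-1] <= 1e-12:
        raise UndefinedMetricError(f"trait table has rank < {n_components}")
    # deterministic sign convention
    for k in range(n_components):
        j = int(np.argmax(np.abs(pca.components_[k])))
        if pca.components_[k, j] < 0:
            pca.components_[k] *= -1
            scores[:, k] *= -1
    out = table.drop(columns=cols).copy()
    for k in range(n_components):
        out[f"PC{k+1}"] = scores[:, k]
    return out, pca.explained_variance_ratio_.copy()


@dataclass(frozen=True)
class FHVResult:
    """Monte-Carlo hypervolume estimate with its standard error."""

    volume: float
    se: float
    threshold: float
    bandwidth: np.ndarray


def _silverman_bandwidth(points: np.ndarray) -> np.ndarray:
    """Per-dimension Silverman rule-of-thumb bandwidth vector."""
    n, d = points.shape
    sd = points.std(axis=0, ddof=1)
    return sd * (4.0 / (n * (d + 2.0))) ** (1.0 / (d + 4.0))


def _kde_density(points: np.ndarray, bw: np.ndarray, x: np.ndarray,
                 chunk: int = 4096) -> np.ndarray:
    """Gaussian product-kernel density of ``points`` evaluated at ``x``."""
    n, d = points.shape
    norm = 1.0 / (n * np.prod(bw) * (2.0 * np.pi) ** (d / 2.0))
    out = np.empty(len(x))
    for start in range(0, len(x), chunk):
        xx = x[start:start + chunk]
        z = (xx[:, None, :] - points[None, :, :]) / bw
        out[start:start + chunk] = np.exp(-0.5 * (z**2).sum(axis=2)).sum(axis=1) * norm
    return out


def _kde_sample(points: np.ndarray, bw: np.ndarray, n_samples: int,
                rng: np.random.Generator) -> np.ndarray:
    idx = rng.integers(len(points), size=n_samples)
    return points[idx] + bw * rng.standard_normal((n_samples, points.shape[1]))


def fhv(
    points: np.ndarray,
    quantile: float = 0.05,
    n_mc_samples: int | None = None,
    seed: int = 0,
    samples_per_point: int = 10_000,
) -> FHVResult:
    """Gaussian-KDE hypervolume of a point cloud.

    The density threshold is the ``quantile`` quantile of the kernel
    density over draws from the density itself, so the retained region
    encloses 1 - quantile (default 95%) of total probability mass. The
    volume of that region is then estimated by importance sampling from
    the same density: for Y ~ f, E[1{f(Y) >= t} / f(Y)] equals the volume
    of {f >= t}. Seeded and reproducible; the Monte-Carlo standard error
    is reported alongside the estimate.

    Parameters
    ----------
    points
        (n, d) array, n >= 5, typically the cell's 4-D principal-component
        scores.
    n_mc_samples
        Monte-Carlo draws for both the threshold and the volume stage;
        defaults to ``samples_per_point * n``.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) < 5:
        raise UndefinedMetricError("FHV needs at least 5 points")
    bw = _silverman_bandwidth(points)
    if not np.all(bw > 0):
        raise DegenerateGeometryError(
            "coincident points: zero spread in at least one dimension"
        )
    n_mc = n_mc_samples if n_mc_samples is not None else samples_per_point * len(points)
    rng = np.random.default_rng(seed)

    # stage 1: density threshold retaining 1-quantile of probability mass
    y = _kde_sample(points, bw, n_mc, rng)
    t = float(np.quantile(_kde_density(points, bw, y), quantile))

    # stage 2: importance-sampling volume of the superlevel set
    y = _kde_sample(points, bw, n_mc, rng)
    f = _kde_density(points, bw, y)
    w = np.where(f >= t, 1.0 / f, 0.0)
    return FHVResult(
        volume=float(w.mean()),
        se=float(w.std(ddof=1) / np.sqrt(n_mc)),
        threshold=t,
        bandwidth=bw,
    )


def compute_cell_metrics(
    table: pd.DataFrame,
    min_s_fhv: int = 5,
    fhv_samples_per_point: int = 10_000,
    seed: int = 0,
    cell_cols: tuple[str, ...] = ("depth_m", "location"),
) -> pd.DataFrame:
    """All species-level metrics for every cell of one replicate table.

    The 4-D principal-component space is fit once on the full table; each
    cell's species are scored in that common space for FHV. Undefined
    metrics are reported as missing with the reason in ``flags``, never as
    silent zeros.
    """
    scores, _ = pca_scores(table)
    trait_mat = table[[c for c in TRAITS if c in table.columns]].to_numpy(dtype=float)
    pc_cols = ["PC1", "PC2", "PC3", "PC4"]
    rows = []
    rng = np.random.default_rng(seed)
    for key, idx in table.groupby(list(cell_cols), sort=True).groups.items():
        loc_idx = table.index.get_indexer(idx)
        D = distance_matrix(trait_mat[loc_idx])
        s = len(loc_idx)
        row = dict(zip(cell_cols, key if isinstance(key, tuple) else (key,)))
        if "latitude_s" in table.columns:
            row["latitude_s"] = table.loc[idx[0], "latitude_s"]
        row["S"] = s
        flags = []
        row["MPFD"] = mpfd(D) if s >= 2 else np.nan
        row["MNND"] = mnnd(D) if s >= 2 else np.nan
        row["VPFD"] = vpfd(D) if s >= 3 else np.nan
        row["VNND"] = vnnd(D) if s >= 3 else np.nan
        if s < 2:
            flags.append("pairwise_undefined")
        elif s < 3:
            flags.append("variance_undefined")
        if s >= min_s_fhv:
            try:
                res = fhv(
                    scores.loc[idx, pc_cols].to_numpy(),
                    samples_per_point=fhv_samples_per_point,
                    seed=int(rng.integers(2**31 - 1)),
                )
                row["FHV"] = res.volume
                row["FHV_se"] = res.se
            except DegenerateGeometryError:
                row["FHV"] = np.nan
                flags.append("fhv_degenerate")
        else:
            row["FHV"] = np.nan
            flags.append("fhv_too_few_species")
        row["flags"] = ";".join(flags)
        rows.append(row)
    return pd.DataFrame(rows)
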