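"""Intraspecific vs interspecific partitioning of multivariate trait variance.

Within each depth-by-location cell, trait variation among all measured
individuals is split into a within-species (individual-level) and a
between-species component with a one-way PERMANOVA on Euclidean
distances: species is the factor, individuals are replicates. Only the
sums-of-squares partition is used — no permutation testing. From the
mean squares, the multivariate analogues of the classical unbiased
one-way ANOVA variance components are

    sigma2_I = MS_res
    sigma2_S = (MS_species - MS_res) / n0
    Prop.I   = sigma2_I / (max(sigma2_S, 0) + sigma2_I)

with n0 = (1/(a-1)) * [sum(n_i) - sum(n_i^2)/sum(n_i)] the unbalanced-
design divisor (equal to the common n under balance). sigma2_S is
reported raw (possibly negative) and clamped at zero only inside Prop.I.

Because squared Euclidean distances add over coordinates, these
multivariate components equal the sum over traits of the univariate
ANOVA components — the key identity the tests exploit.

MPFD.I, the mean pairwise distance between conspecific individuals
(pooled over species within the cell), is computed directly alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import UndefinedMetricError

__all__ = [
    "permanova_one_way", "n0", "variance_components", "mpfd_i",
    "PartitionResult", "partition_cell", "partition_cells",
]


def _group_indices(labels) -> dict:
    labels = np.asarray(labels)
    return {g: np.flatnonzero(labels == g) for g in pd.unique(labels)}


def permanova_one_way(
    X: np.ndarray, labels
) -> tuple[float, float, int, int]:
    """Distance-based one-way sums of squares.

    Uses the standard identities on the Euclidean distance matrix:
    ``SS_total = (1/N) * sum_{i<j} d_ij^2`` and
    ``SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2``;
    ``SS_species = SS_total - SS_within``.

    Returns ``(SS_species, SS_res, df_species, df_res)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    groups = _group_indices(labels)
    a = len(groups)
    n = X.shape[0]
    if n < 3 or a < 2:
        raise UndefinedMetricError("need N >= 3 individuals and a >= 2 species")
    if all(len(idx) < 2 for idx in groups.values()):
        raise UndefinedMetricError("no species has 2+ individuals: df_res = 0")
    d2 = squareform(pdist(X)) ** 2
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for idx in groups.values():
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_species = ss_total - ss_within
    return float(ss_species), float(ss_within), a - 1, n - a


def n0(counts) -> float:
    """Unbalanced-design divisor for the between-groups variance component.

    ``n0 = (1/(a-1)) * [sum(n_i) - sum(n_i^2)/sum(n_i)]``; equals the
    common n when the design is balanced.
    """
    counts = np.asarray(counts, dtype=float)
    a = len(counts)
    if a < 2:
        raise UndefinedMetricError("n0 needs at least 2 groups")
    if (counts < 1).any():
        raise ValueError("all group sizes must be >= 1")
    total = counts.sum()
    return float((total - (counts**2).sum() / total) / (a - 1))


def variance_components(
    ms_species: float, ms_res: float, n0_value: float
) -> tuple[float, float, float]:
    """(sigma2_I, raw sigma2_S, Prop.I) from the mean squares.

    sigma2_S is returned raw (may be negative when MS_species < MS_res);
    Prop.I clamps it at zero, so Prop.I is in (0, 1].
    """
    sigma2_i = ms_res
    sigma2_s = (ms_species - ms_res) / n0_value
    prop_i = sigma2_i / (max(sigma2_s, 0.0) + sigma2_i) if sigma2_i > 0 else np.nan
    if sigma2_i == 0 and max(sigma2_s, 0.0) == 0:
        prop_i = np.nan
    return float(sigma2_i), float(sigma2_s), float(prop_i)


def mpfd_i(X: np.ndarray, labels, per_species_mean: bool = False) -> float:
    """Mean pairwise Euclidean distance between conspecific individuals.

    Pairs are pooled across species within the cell by default; with
    ``per_species_mean`` each species' mean pairwise distance is computed
    first and the species means averaged.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    groups = _group_indices(labels)
    dists = []
    species_means = []
    for idx in groups.values():
        if len(idx) < 2:
            continue
        d = pdist(X[idx])
        dists.append(d)
        species_means.append(d.mean())
    if not dists:
        raise UndefinedMetricError("no species has a conspecific pair")
    if per_species_mean:
        return float(np.mean(species_means))
    return float(np.concatenate(dists).mean())


@dataclass
class PartitionResult:
    """Variance partition of one cell."""

    cell: tuple
    a: int
    counts: dict = field(repr=False)
    N: int = 0
    ss_species: float = np.nan
    ss_res: float = np.nan
    ms_species: float = np.nan
    ms_res: float = np.nan
    n0: float = np.nan
    sigma2_I: float = np.nan
    sigma2_S_raw: float = np.nan
    prop_I: float = np.nan
    mpfd_I: float = np.nan
    flags: str = ""


def partition_cell(X: np.ndarray, labels, cell=("",)) -> PartitionResult:
    """Full variance partition of one cell's individuals."""
    labels = np.asarray(labels)
    counts = {g: int((labels == g).sum()) for g in pd.unique(labels)}
    a = len(counts)
    res = PartitionResult(cell=cell, a=a, counts=counts, N=int(len(labels)))
    flags = []
    try:
        res.mpfd_I = mpfd_i(X, labels)
    except UndefinedMetricError:
        flags.append("no_conspecific_pair")
    try:
        ss_sp, ss_res_, df_sp, df_res = permanova_one_way(X, labels)
        res.ss_species, res.ss_res = ss_sp, ss_res_
        res.ms_species = ss_sp / df_sp
        res.ms_res = ss_res_ / df_res
        res.n0 = n0(list(counts.values()))
        res.sigma2_I, res.sigma2_S_raw, res.prop_I = variance_components(
            res.ms_species, res.ms_res, res.n0
        )
    except UndefinedMetricError as exc:
        flags.append(str(exc))
    res.flags = ";".join(flags)
    return res


def partition_cells(
    individuals: pd.DataFrame,
    trait_cols: list[str],
    cell_cols: tuple[str, ...] = ("depth_m", "location"),
) -> pd.DataFrame:
    """Partition every cell of a long individual-level trait table.

    Returns one row per cell with the PERMANOVA sums of squares, mean
    squares, n0, variance components, Prop.I and MPFD.I; cells where a
    component is undefined carry the reason in ``flags``.
    """
    rows = []
    for key, grp in individuals.groupby(list(cell_cols), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        X = grp[trait_cols].to_numpy(dtype=float)
        res = partition_cell(X, grp["species"].to_numpy(), cell=key)
        row = dict(zip(cell_cols, key))
        if "latitude_s" in grp.columns:
            row["latitude_s"] = grp["latitude_s"].iloc[0]
        row.update(
            a=res.a, N=res.N, n0=res.n0,
            SS_species=res.ss_species, SS_res=res.ss_res,
            MS_species=res.ms_species, MS_res=res.ms_res,
            sigma2_I=res.sigma2_I, sigma2_S_raw=res.sigma2_S_raw,
            Prop_I=res.prop_I, MPFD_I=res.mpfd_I, flags=res.flags,
        )
        rows.append(row)
    return pd.DataFrame(rows)
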