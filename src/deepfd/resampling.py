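"""Replicate species-by-cell trait tables via hierarchical resampling.

Species-level diversity metrics need one trait vector per species per
cell, but individuals were not measured in every cell a species occupies.
Each species-by-cell occurrence is therefore represented by one randomly
drawn complete individual, chosen from the highest-priority non-empty
pool:

    (a) conspecifics measured within that depth-by-location cell,
    (b) conspecifics at the same depth stratum (any location),
    (c) conspecifics anywhere in the in-situ video dataset,
    (d) museum specimens of the species.

Drawing is repeated independently to build (by default) 100 replicate
tables; metrics are computed per replicate and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UnresolvableOccurrenceError
from .traits import TRAITS, normalize_traits

LEVELS = ("a", "b", "c", "d")


@dataclass
class IndividualPools:
    """Complete-trait individuals indexed for hierarchical lookup."""

    individuals: pd.DataFrame

    def __post_init__(self):
        df = self.individuals
        self._by_species = {sp: g for sp, g in df.groupby("species", sort=False)}

    def candidate_ids(self, species: str, depth_m, location: str) -> tuple[pd.Index, str]:
        """Ids of the highest-priority non-empty pool and its level."""
        g = self._by_species.get(species)
        if g is None:
            raise UnresolvableOccurrenceError(
                f"species {species!r} has no measurable individual anywhere"
            )
        bruv = g[g["source"] == "bruv"]
        in_cell = bruv[(bruv["depth_m"] == depth_m) & (bruv["location"] == location)]
        if len(in_cell):
            return in_cell.index, "a"
        at_depth = bruv[bruv["depth_m"] == depth_m]
        if len(at_depth):
            return at_depth.index, "b"
        if len(bruv):
            return bruv.index, "c"
        museum = g[g["source"] == "museum"]
        if len(museum):
            return museum.index, "d"
        raise UnresolvableOccurrenceError(
            f"species {species!r} has no measurable individual anywhere"
        )


def select_individual(
    species: str,
    cell: tuple,
    pools: IndividualPools,
    rng: np.random.Generator,
) -> tuple[object, str]:
    """Draw one individual for a (species, cell) occurrence.

    Returns ``(row index into the pools table, selection level)``; the
    draw is uniform within the highest-priority non-empty pool.
    """
    depth_m, location = cell
    idx, level = pools.candidate_ids(species, depth_m, location)
    return idx[int(rng.integers(len(idx)))], level


def build_replicates(
    occurrences: pd.DataFrame,
    individuals: pd.DataFrame,
    n_rep: int = 100,
    seed: int = 0,
    on_unresolvable: str = "error",
) -> list[pd.DataFrame]:
    """Build ``n_rep`` independently drawn, table-wide-normalized replicate tables.

    Parameters
    ----------
    occurrences
        Unique (species, depth_m, location) rows; ``latitude_s`` carried
        through if present.
    individuals
        Complete-trait individuals with identifier columns and the 8
        trait columns.
    on_unresolvable
        ``"error"`` (default, strict) aborts on an occurrence with no
        conspecific individual at any level; ``"drop"`` silently drops it.
    """
    if on_unresolvable not in ("error", "drop"):
        raise ValueError("on_unresolvable must be 'error' or 'drop'")
    pools = IndividualPools(individuals)
    rng = np.random.default_rng(seed)
    carry = [c for c in ("species", "depth_m", "location", "latitude_s")
             if c in occurrences.columns]
    tables = []
    for _ in range(n_rep):
        rows = []
        for occ in occurrences.itertuples(index=False):
            try:
                ridx, level = select_individual(
                    occ.species, (occ.depth_m, occ.location), pools, rng
                )
            except UnresolvableOccurrenceError:
                if on_unresolvable == "drop":
                    continue
                raise
            ind = individuals.loc[ridx]
            row = {c: getattr(occ, c) for c in carry}
            row["individual_id"] = ind.get("individual_id", ridx)
            row["level"] = level
            for t in TRAITS:
                row[t] = ind[t]
            rows.append(row)
        table = pd.DataFrame(rows)
        table, _ = normalize_traits(table)
        tables.append(table)
    return tables


def average_metrics(
    metrics: pd.DataFrame,
    metric_cols: list[str],
    cell_cols: tuple[str, ...] = ("depth_m", "location"),
) -> pd.DataFrame:
    """Average per-replicate cell metrics across replicates.

    ``metrics`` holds one row per (replicate, cell). For each metric the
    per-cell arithmetic mean is taken over the replicates in which the
    metric is defined (non-missing); the replicate standard deviation and
    the count of contributing replicates are retained as ``<m>_sd`` and
    ``<m>_n`` columns.
    """
    grouped = metrics.groupby(list(cell_cols), dropna=False)
    pieces = {}
    for m in metric_cols:
        pieces[m] = grouped[m].mean()
        pieces[f"{m}_sd"] = grouped[m].std(ddof=1)
        pieces[f"{m}_n"] = grouped[m].count()
    return pd.DataFrame(pieces).reset_index()
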