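"""Derivation of the eight functional traits from raw morphometrics.

Each measured fish carries up to 15 raw length measurements (mm). Eight
functional traits are derived from 13 of them; all but total length are
dimensionless ratios, so they are invariant to the absolute scale of the
individual:

========================  =================  =========================
trait                     formula            ecological meaning
========================  =================  =========================
total_length              TL                 body size / trophic proxy
eye_size                  Ed / Hd            prey detection
oral_gape_position        Mo / Hd            feeding position in column
jaw_length                (Uj + Lj) / (2 Hl) size of potential prey
elongation                TL / mBd           body shape, steady swimming
eye_position              Eh / Hd            vertical position
caudal_peduncle_throttling CFd / CPd         caudal propulsion efficiency
pectoral_fin_position     PFi / PFb          manoeuvrability
========================  =================  =========================

Distance-based analyses operate on z-scored ("normalized") trait columns;
:func:`normalize_traits` returns the scaling constants so that cell-level
subsets are always expressed on the table-wide scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NormalizationError, TraitDerivationError

#: The 15 raw measurement column names, in canonical CSV order.
MEASUREMENTS = [
    "TL", "Ed", "Eh", "Hd", "Hl", "Lj", "Uj", "mBd",
    "Mo", "CFd", "CPd", "PFi", "PFb", "M14", "M15",
]

#: Measurements actually consumed by the trait formulas (13 of 15).
REQUIRED_MEASUREMENTS = [
    "TL", "Ed", "Eh", "Hd", "Hl", "Lj", "Uj", "mBd",
    "Mo", "CFd", "CPd", "PFi", "PFb",
]

#: The 8 derived trait column names, in canonical CSV order.
TRAITS = [
    "total_length", "eye_size", "oral_gape_position", "jaw_length",
    "elongation", "eye_position", "caudal_peduncle_throttling",
    "pectoral_fin_position",
]

#: Identifier columns carried alongside measurements / traits.
ID_COLUMNS = ["individual_id", "species", "depth_m", "location", "latitude_s", "source"]


def derive_traits(record: dict | pd.Series) -> dict:
    """Derive the 8 functional traits of one individual.

    Parameters
    ----------
    record
        Mapping with the 13 required measurement keys, each a positive
        length in mm. Missing (None/NaN) or non-positive values raise
        :class:`TraitDerivationError` naming the offending measurement.

    Returns
    -------
    dict
        The 8 traits keyed by :data:`TRAITS` names.
    """
    m = {}
    for name in REQUIRED_MEASUREMENTS:
        value = record.get(name) if isinstance(record, dict) else record[name]
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise TraitDerivationError(name, "is missing")
        value = float(value)
        if value <= 0:
            raise TraitDerivationError(name, f"is non-positive ({value})")
        m[name] = value
    return {
        "total_length": m["TL"],
        "eye_size": m["Ed"] / m["Hd"],
        "oral_gape_position": m["Mo"] / m["Hd"],
        "jaw_length": 0.5 * (m["Uj"] + m["Lj"]) / m["Hl"],
        "elongation": m["TL"] / m["mBd"],
        "eye_position": m["Eh"] / m["Hd"],
        "caudal_peduncle_throttling": m["CFd"] / m["CPd"],
        "pectoral_fin_position": m["PFi"] / m["PFb"],
    }


def derive_trait_table(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorized trait derivation for a table of complete records.

    ``records`` must hold the 13 required measurement columns with no
    missing or non-positive values; identifier columns present in the
    input are carried through unchanged.
    """
    for name in REQUIRED_MEASUREMENTS:
        if name not in records.columns:
            raise TraitDerivationError(name, "column is absent")
        col = records[name].to_numpy(dtype=float)
        if np.isnan(col).any():
            raise TraitDerivationError(name, "has missing values")
        if (col <= 0).any():
            raise TraitDerivationError(name, "has non-positive values")
    m = {k: records[k].to_numpy(dtype=float) for k in REQUIRED_MEASUREMENTS}
    out = pd.DataFrame(
        {
            "total_length": m["TL"],
            "eye_size": m["Ed"] / m["Hd"],
            "oral_gape_position": m["Mo"] / m["Hd"],
            "jaw_length": 0.5 * (m["Uj"] + m["Lj"]) / m["Hl"],
            "elongation": m["TL"] / m["mBd"],
            "eye_position": m["Eh"] / m["Hd"],
            "caudal_peduncle_throttling": m["CFd"] / m["CPd"],
            "pectoral_fin_position": m["PFi"] / m["PFb"],
        },
        index=records.index,
    )
    carry = [c for c in ID_COLUMNS if c in records.columns]
    return pd.concat([records[carry], out], axis=1)


@dataclass(frozen=True)
class Normalization:
    """Column means and sample (n-1) standard deviations of a trait table."""

    means: pd.Series
    sds: pd.Series

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        """z-score ``table``'s trait columns with these constants."""
        out = table.copy()
        for col in self.means.index:
            out[col] = (out[col] - self.means[col]) / self.sds[col]
        return out


def normalize_traits(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    log_total_length: bool = False,
) -> tuple[pd.DataFrame, Normalization]:
    """z-score trait columns across the rows of ``table``.

    Each trait column is centred and scaled to unit sample standard
    deviation (n-1 denominator) across *all* rows of the given table, so
    that per-cell subsets remain on a common table-wide scale.

    Parameters
    ----------
    table
        Trait table (identifier columns are carried through untouched).
    columns
        Trait columns to scale; defaults to :data:`TRAITS` (restricted to
        those present).
    log_total_length
        If True, ``total_length`` is log10-transformed before scaling.
        Off by default: body size enters untransformed.

    Returns
    -------
    (normalized table, Normalization)
    """
    cols = columns if columns is not None else [c for c in TRAITS if c in table.columns]
    if len(table) < 2:
        raise NormalizationError("need at least 2 rows to normalize")
    out = table.copy()
    if log_total_length and "total_length" in cols:
        out["total_length"] = np.log10(out["total_length"].to_numpy(dtype=float))
    means = {}
    sds = {}
    for col in cols:
        x = out[col].to_numpy(dtype=float)
        mu = x.mean()
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise NormalizationError(f"trait column {col!r} has zero variance")
        out[col] = (x - mu) / sd
        means[col] = mu
        sds[col] = sd
    norm = Normalization(means=pd.Series(means), sds=pd.Series(sds))
    return out, norm
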