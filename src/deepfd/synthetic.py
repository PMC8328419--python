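"""Synthetic morphometric datasets with the study's statistical structure.

The sampling design this generator emulates is a stratified grid of
deep-sea baited-video deployments: seven depth strata (50–1200 m) crossed
with seven locations spanning 29–51 °S, of which 47 depth-by-location
cells are occupied. Species occupy cells according to a depth-niche model;
species trait means are multivariate normal around a community centroid
with between-species variance sigma2_S per trait, and individuals scatter
around their species mean with within-species variance sigma2_I, both in
units of a per-trait scale. Optional linear gradients let sigma2_I grow
with depth and between-species dispersion shrink with latitude, which is
how the trend-recovery scenarios are generated.

Everything downstream of the raw data table — trait derivation,
imputation, resampling, diversity metrics, variance partitioning and
gradient models — can therefore be tested against known truth without the
original field data.

Two layers are generated:

* a *trait* layer (:func:`simulate_traits`): individuals with known 8-trait
  vectors and recorded true species means and per-cell variances;
* a *measurement* layer (:func:`simulate_measurements`): 15 raw length
  measurements (mm) per individual that invert the trait formulas exactly,
  with head/body lengths following a smooth log-scale allometry so that
  random-forest imputation has signal to learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GenerationError, ParameterError
from .traits import MEASUREMENTS, TRAITS

__all__ = [
    "StudyDesign",
    "SimulationParams",
    "AllometryParams",
    "SimulatedData",
    "simulate_traits",
    "simulate_balanced_cells",
    "simulate_measurements",
    "knockout_missing",
]

_DEFAULT_DEPTHS = (50, 100, 300, 500, 700, 900, 1200)
# Three-letter location codes, north to south; latitudes evenly spaced 29-51 S.
_DEFAULT_LOCATIONS = (
    ("KER", 29.0), ("GBI", 32.6667), ("MAH", 36.3333), ("CHA", 40.0),
    ("OTA", 43.6667), ("SNA", 47.3333), ("AUC", 51.0),
)
# Two cells left unoccupied so the default design has 47 of 49 cells: the
# shallowest stratum at the two southernmost locations.
_DEFAULT_UNOCCUPIED = ((50, "SNA"), (50, "AUC"))


@dataclass(frozen=True)
class StudyDesign:
    """Depth-by-location sampling grid."""

    depth_strata: tuple[int, ...] = _DEFAULT_DEPTHS
    locations: tuple[tuple[str, float], ...] = _DEFAULT_LOCATIONS
    occupied_cells: frozenset[tuple[int, str]] | None = None
    deployments_per_cell: tuple[int, int] = (5, 7)

    def __post_init__(self):
        depths = list(self.depth_strata)
        if depths != sorted(depths) or len(set(depths)) != len(depths):
            raise ParameterError("depth strata must be strictly increasing")
        lats = [lat for _, lat in self.locations]
        if lats != sorted(lats) or len(set(lats)) != len(lats):
            raise ParameterError("latitudes must be strictly increasing (degrees S)")
        if self.occupied_cells is None:
            cells = {
                (d, name)
                for d in self.depth_strata
                for name, _ in self.locations
            } - set(_DEFAULT_UNOCCUPIED)
            object.__setattr__(self, "occupied_cells", frozenset(cells))
        if len(self.occupied_cells) > len(self.depth_strata) * len(self.locations):
            raise ParameterError("more occupied cells than grid cells")

    @property
    def latitude_of(self) -> dict[str, float]:
        return dict(self.locations)

    def cells(self) -> list[tuple[int, str]]:
        """Occupied cells ordered by depth then latitude."""
        lat = self.latitude_of
        return sorted(self.occupied_cells, key=lambda c: (c[0], lat[c[1]]))

    def normalized_depth(self, depth_m: float) -> float:
        """Depth z-scored over the design's strata."""
        d = np.asarray(self.depth_strata, dtype=float)
        return float((depth_m - d.mean()) / d.std(ddof=1))

    def normalized_latitude(self, latitude_s: float) -> float:
        lats = np.asarray([lat for _, lat in self.locations], dtype=float)
        return float((latitude_s - lats.mean()) / lats.std(ddof=1))


# Community-centroid trait values on the raw (ratio / mm) scale, and the
# per-trait scale unit in which sigma2_S and sigma2_I are expressed. A
# variance of 1 means "one squared scale unit"; scales default to a few
# percent of the centroid so measurements stay positive.
_DEFAULT_TRAIT_MEANS = {
    "total_length": 350.0, "eye_size": 0.35, "oral_gape_position": 0.55,
    "jaw_length": 0.45, "elongation": 4.5, "eye_position": 0.65,
    "caudal_peduncle_throttling": 1.8, "pectoral_fin_position": 1.2,
}
_DEFAULT_TRAIT_SCALES = {
    "total_length": 25.0, "eye_size": 0.03, "oral_gape_position": 0.045,
    "jaw_length": 0.035, "elongation": 0.35, "eye_position": 0.05,
    "caudal_peduncle_throttling": 0.15, "pectoral_fin_position": 0.10,
}


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the synthetic community.

    Variances are per trait, in squared trait-scale units. The defaults
    give Prop.I = sigma2_I/(sigma2_I+sigma2_S) = 1/3, i.e. individuals
    contribute about a third of within-cell trait variance, in the range
    reported for deep-sea fish assemblages.
    """

    n_species: int = 144
    sigma2_S: float = 2.0
    sigma2_I: float = 1.0
    #: additive change in sigma2_I per unit of normalized depth
    sigma2_I_depth_slope: float = 0.0
    #: additive change in sigma2_S per unit of normalized latitude
    sigma2_S_lat_slope: float = 0.0
    #: relative change in expected occurrence richness per normalized depth unit
    richness_depth_slope: float = -0.25
    #: expected number of species-by-cell occurrences per cell
    mean_occ_richness: float = 10.8
    #: width (in stratum index units) of species depth niches
    depth_niche_width: float = 1.6
    #: probability that an occurrence has in-situ measured individuals
    measured_fraction: float = 0.31
    #: individuals per measured species-by-cell occurrence: 2 + Poisson(mean-2),
    #: capped at the stated maximum
    inds_per_species_mean: float = 4.32
    inds_per_species_max: int = 15
    #: preserved museum specimens per species (guaranteed fallback pool)
    museum_per_species: int = 2
    missing_rate: float = 0.0
    trait_means: dict = field(default_factory=lambda: dict(_DEFAULT_TRAIT_MEANS))
    trait_scales: dict = field(default_factory=lambda: dict(_DEFAULT_TRAIT_SCALES))
    #: optional 8x8 between-species trait correlation matrix (None = diagonal)
    species_corr: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.sigma2_S < 0 or self.sigma2_I < 0:
            raise ParameterError("variances must be non-negative")
        if not 0 <= self.missing_rate <= 1:
            raise ParameterError("missing_rate must be in [0, 1]")
        if not 0 <= self.measured_fraction <= 1:
            raise ParameterError("measured_fraction must be in [0, 1]")
        if self.inds_per_species_mean < 2:
            raise ParameterError("inds_per_species_mean must be >= 2")

    def sigma2_I_at(self, design: StudyDesign, depth_m: float) -> float:
        v = self.sigma2_I + self.sigma2_I_depth_slope * design.normalized_depth(depth_m)
        if v < 0:
            raise ParameterError(
                f"sigma2_I becomes negative ({v:.3g}) at depth {depth_m} m"
            )
        return v

    def sigma2_S_at(self, design: StudyDesign, latitude_s: float) -> float:
        v = self.sigma2_S + self.sigma2_S_lat_slope * design.normalized_latitude(latitude_s)
        if v < 0:
            raise ParameterError(
                f"sigma2_S becomes negative ({v:.3g}) at latitude {latitude_s} S"
            )
        return v


@dataclass
class SimulatedData:
    """Output bundle of :func:`simulate_traits`.

    Attributes
    ----------
    individuals : DataFrame
        One row per individual: identifiers, cell, source, 8 trait values.
    occurrences : DataFrame
        Unique (species, depth_m, location) presences from the video layer.
    species_means : DataFrame
        True global trait mean per species (ground truth).
    cell_truth : DataFrame
        Per-cell true sigma2_I and sigma2_S actually used (ground truth).
    design : StudyDesign
    params : SimulationParams
    """

    individuals: pd.DataFrame
    occurrences: pd.DataFrame
    species_means: pd.DataFrame
    cell_truth: pd.DataFrame
    design: StudyDesign
    params: SimulationParams


def _species_mean_matrix(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Species-by-trait matrix of true means on the raw trait scale."""
    k = len(TRAITS)
    scales = np.array([params.trait_scales[t] for t in TRAITS])
    mu = np.array([params.trait_means[t] for t in TRAITS])
    if params.species_corr is not None:
        corr = np.asarray(params.species_corr, dtype=float)
        if corr.shape != (k, k):
            raise ParameterError("species_corr must be 8x8")
        chol = np.linalg.cholesky(corr)
        z = rng.standard_normal((params.n_species, k)) @ chol.T
    else:
        z = rng.standard_normal((params.n_species, k))
    return mu + np.sqrt(params.sigma2_S) * scales * z


def simulate_traits(
    design: StudyDesign | None = None,
    params: SimulationParams | None = None,
) -> SimulatedData:
    """Generate a full synthetic community at the trait level.

    Species are placed in cells by a Gaussian depth-niche occupancy model
    with expected richness declining along the depth gradient; a fraction
    of occurrences carries in-situ measured individuals (2-15 per
    occurrence), and every species carries museum specimens so that all
    occurrences are resolvable by the hierarchical selection rule.
    Identical seeds give identical output.
    """
    design = design or StudyDesign()
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)

    species = [f"sp{i:03d}" for i in range(params.n_species)]
    means = _species_mean_matrix(params, rng)
    scales = np.array([params.trait_scales[t] for t in TRAITS])
    mu = np.array([params.trait_means[t] for t in TRAITS])
    lat_of = design.latitude_of
    n_strata = len(design.depth_strata)
    stratum_idx = {d: i for i, d in enumerate(design.depth_strata)}

    # depth-niche centres in stratum-index units
    niche_centre = rng.uniform(-0.5, n_strata - 0.5, size=params.n_species)

    occ_rows = []
    ind_rows = []
    cell_rows = []
    counter = 0
    for depth, loc in design.cells():
        zd = design.normalized_depth(depth)
        lat = lat_of[loc]
        lam = params.mean_occ_richness * max(0.05, 1.0 + params.richness_depth_slope * zd)
        s_c = int(np.clip(rng.poisson(lam), 1, params.n_species))
        affinity = np.exp(
            -0.5 * ((stratum_idx[depth] - niche_centre) / params.depth_niche_width) ** 2
        )
        p = affinity / affinity.sum()
        occupants = rng.choice(params.n_species, size=s_c, replace=False, p=p)

        s2i_c = params.sigma2_I_at(design, depth)
        s2s_c = params.sigma2_S_at(design, lat)
        # scale species-mean deviations so the cell's between-species
        # dispersion matches its latitude-dependent target
        g = np.sqrt(s2s_c / params.sigma2_S) if params.sigma2_S > 0 else 1.0
        cell_rows.append(
            {"depth_m": depth, "location": loc, "latitude_s": lat,
             "sigma2_I_true": s2i_c, "sigma2_S_true": s2s_c, "S_occ": s_c}
        )
        for s in occupants:
            occ_rows.append({"species": species[s], "depth_m": depth, "location": loc,
                             "latitude_s": lat})
            if rng.uniform() >= params.measured_fraction:
                continue
            n_i = int(min(2 + rng.poisson(params.inds_per_species_mean - 2),
                          params.inds_per_species_max))
            local_mean = mu + g * (means[s] - mu)
            eps = rng.standard_normal((n_i, len(TRAITS)))
            vals = local_mean + np.sqrt(s2i_c) * scales * eps
            for row in vals:
                ind_rows.append(
                    {"individual_id": f"ind{counter:05d}", "species": species[s],
                     "depth_m": depth, "location": loc, "latitude_s": lat,
                     "source": "bruv", **dict(zip(TRAITS, row))}
                )
                counter += 1

    # museum fallback pool: specimens around the global species mean
    for s in range(params.n_species):
        for _ in range(params.museum_per_species):
            eps = rng.standard_normal(len(TRAITS))
            vals = means[s] + np.sqrt(params.sigma2_I) * scales * eps
            ind_rows.append(
                {"individual_id": f"ind{counter:05d}", "species": species[s],
                 "depth_m": np.nan, "location": "", "latitude_s": np.nan,
                 "source": "museum", **dict(zip(TRAITS, vals))}
            )
            counter += 1

    individuals = pd.DataFrame(ind_rows)
    occurrences = pd.DataFrame(occ_rows).drop_duplicates(ignore_index=True)
    species_means = pd.DataFrame(means, columns=TRAITS)
    species_means.insert(0, "species", species)
    cell_truth = pd.DataFrame(cell_rows)
    return SimulatedData(individuals, occurrences, species_means, cell_truth,
                         design, params)


def simulate_balanced_cells(
    n_cells: int,
    n_species: int,
    n_per_species: int,
    sigma2_I: float,
    sigma2_S: float,
    n_traits: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Balanced abstract-trait-space communities for calibration studies.

    Each cell holds ``n_species`` species with ``n_per_species``
    individuals each; species means ~ N(0, sigma2_S) and individuals
    ~ N(mean, sigma2_I), independently per trait (unit scale, zero
    centroid). Returns a long table with columns cell, species,
    individual_id and trait_1..trait_k.
    """
    if sigma2_I < 0 or sigma2_S < 0:
        raise ParameterError("variances must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    cols = [f"trait_{j+1}" for j in range(n_traits)]
    for c in range(n_cells):
        means = np.sqrt(sigma2_S) * rng.standard_normal((n_species, n_traits))
        for s in range(n_species):
            vals = means[s] + np.sqrt(sigma2_I) * rng.standard_normal(
                (n_per_species, n_traits)
            )
            for i, row in enumerate(vals):
                rows.append({"cell": f"cell{c:04d}", "species": f"sp{s:03d}",
                             "individual_id": f"c{c:04d}s{s:03d}i{i:02d}",
                             **dict(zip(cols, row))})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AllometryParams:
    """Log-scale allometry of the anchor and filler measurements.

    Each entry maps a measurement to (log-intercept, slope on log TL,
    log-scale noise sd): ``log X = a + b log TL + eps``. The remaining
    measurements are solved exactly from the trait ratios, so applying
    the trait formulas to the generated measurements reproduces the trait
    vector to floating-point accuracy.
    """

    anchors: dict = field(default_factory=lambda: {
        "Hd": (np.log(0.20), 1.0, 0.02),
        "Hl": (np.log(0.26), 1.0, 0.02),
        "CPd": (np.log(0.08), 1.0, 0.02),
        "PFb": (np.log(0.18), 1.0, 0.02),
        "M14": (np.log(0.30), 1.0, 0.02),
        "M15": (np.log(0.12), 1.0, 0.02),
    })
    #: mean fraction of the combined jaw length carried by the upper jaw
    upper_jaw_fraction: float = 0.55
    upper_jaw_fraction_sd: float = 0.02


def simulate_measurements(
    trait_data: pd.DataFrame,
    allometry: AllometryParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Invert the trait formulas into 15 raw measurements per individual.

    ``trait_data`` must carry the 8 trait columns on the raw ratio/mm
    scale; all ratio traits must be strictly positive. Head depth, head
    length, caudal-peduncle depth, pectoral base depth and the two filler
    measurements follow the log-scale allometry; every other measurement
    is solved from the trait ratios so that trait derivation recovers the
    input exactly.
    """
    allometry = allometry or AllometryParams()
    rng = np.random.default_rng(seed)
    t = {c: trait_data[c].to_numpy(dtype=float) for c in TRAITS}
    for c in TRAITS:
        if (t[c] <= 0).any() or not np.isfinite(t[c]).all():
            bad = int(np.argmax(~((t[c] > 0) & np.isfinite(t[c]))))
            raise GenerationError(
                f"trait {c!r} non-positive or non-finite at row {bad}"
            )
    n = len(trait_data)
    tl = t["total_length"]
    m = {"TL": tl}
    for name, (a, b, sd) in allometry.anchors.items():
        m[name] = np.exp(a + b * np.log(tl) + sd * rng.standard_normal(n))
    m["mBd"] = tl / t["elongation"]
    m["Ed"] = t["eye_size"] * m["Hd"]
    m["Mo"] = t["oral_gape_position"] * m["Hd"]
    m["Eh"] = t["eye_position"] * m["Hd"]
    jaw_sum = 2.0 * t["jaw_length"] * m["Hl"]
    frac = np.clip(
        allometry.upper_jaw_fraction
        + allometry.upper_jaw_fraction_sd * rng.standard_normal(n),
        0.05, 0.95,
    )
    m["Uj"] = frac * jaw_sum
    m["Lj"] = jaw_sum - m["Uj"]
    m["CFd"] = t["caudal_peduncle_throttling"] * m["CPd"]
    m["PFi"] = t["pectoral_fin_position"] * m["PFb"]

    out = pd.DataFrame({k: m[k] for k in MEASUREMENTS}, index=trait_data.index)
    carry = [c for c in trait_data.columns if c not in TRAITS]
    return pd.concat([trait_data[carry], out], axis=1)


def knockout_missing(
    records: pd.DataFrame,
    missing_rate: float,
    max_missing_per_individual: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Mask measurement values completely at random (MCAR).

    Each of the 15 measurement cells is masked independently with
    probability ``missing_rate``. Two bookkeeping columns are added:
    ``n_missing`` and ``exceeds_max_missing`` (True when more than
    ``max_missing_per_individual`` values were masked, i.e. the record is
    ineligible for imputation by construction).
    """
    if not 0 <= missing_rate <= 1:
        raise ParameterError("missing_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = records.copy()
    mask = rng.uniform(size=(len(out), len(MEASUREMENTS))) < missing_rate
    vals = out[MEASUREMENTS].to_numpy(dtype=float)
    vals[mask] = np.nan
    out[MEASUREMENTS] = vals
    out["n_missing"] = mask.sum(axis=1)
    out["exceeds_max_missing"] = out["n_missing"] > max_missing_per_individual
    return out
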