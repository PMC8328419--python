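"""Generate the synthetic community and its raw measurement layer.

Emulates the study design — 7 depth strata (50-1200 m) x 7 locations
(29-51 S), 47 occupied cells, ~144 species — with known within-species
(sigma2_I = 1) and between-species (sigma2_S = 2) trait variance, then
inverts the trait formulas into 15 raw length measurements per individual
and knocks out 4% of the video-derived measurement values at random.

Writes results/data/: morpho_records.csv, occurrences.csv and the
ground-truth sidecars.
"""

import sys
from pathlib import Path

import pandas as pd

from deepfd.synthetic import (
    SimulationParams, StudyDesign, knockout_missing, simulate_measurements,
    simulate_traits,
)
from deepfd.traits import MEASUREMENTS

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)

design = StudyDesign()
params = SimulationParams(seed=SEED)
sim = simulate_traits(design, params)
morpho = simulate_measurements(sim.individuals, seed=SEED + 1)

bruv_mask = morpho["source"] == "bruv"
knocked = knockout_missing(morpho[bruv_mask], 0.04, seed=SEED + 2)
museum = morpho[~bruv_mask].copy()
museum["n_missing"] = 0
museum["exceeds_max_missing"] = False
morpho = pd.concat([knocked, museum]).sort_index()

morpho.to_csv(OUT / "morpho_records.csv", index=False)
sim.occurrences.to_csv(OUT / "occurrences.csv", index=False)
sim.species_means.to_csv(OUT / "truth_species_means.csv", index=False)
sim.cell_truth.to_csv(OUT / "truth_cells.csv", index=False)

bruv = sim.individuals.query("source == 'bruv'")
sp_per_cell = bruv.groupby(["depth_m", "location"])["species"].nunique()
inds = bruv.groupby(["depth_m", "location", "species"]).size()
n_missing = morpho[MEASUREMENTS].isna().to_numpy().sum()
print(f"simulated {len(morpho)} individuals "
      f"({bruv_mask.sum()} video, {(~bruv_mask).sum()} museum), "
      f"{len(sim.occurrences)} species-by-cell occurrences")
print(f"measured richness {sp_per_cell.mean():.2f} species/cell, "
      f"{inds.mean():.2f} individuals/species/cell")
print(f"{n_missing} measurement values masked "
      f"({n_missing / morpho[MEASUREMENTS].size:.1%})")
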