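"""Random-forest imputation of missing raw measurements.

Individuals measured from video frequently lack a few of the 15 raw
lengths (an obscured fin, a closed mouth). A record is *eligible* for
imputation when it misses at most 3 of the 15 measurements and its
species has at least 5 records with complete information in the pooled
(in-situ + museum) dataset; everything else is either already complete or
ineligible.

Imputation follows the missForest scheme, trained per species on the
complete conspecific records: missing entries are initialised with column
means, then each incomplete column is iteratively regressed (random
forest, 300 trees by default) on the other 14 until the normalized
difference between successive imputations first increases, or 20
iterations elapse. Twenty independent runs are averaged into a single
imputed value; an out-of-bag error estimate accompanies each imputed
measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .errors import ParameterError
from .traits import MEASUREMENTS


@dataclass(frozen=True)
class EligibilityRule:
    """Thresholds of the eligibility rule."""

    max_missing: int = 3
    min_complete_conspecifics: int = 5

    def __post_init__(self):
        if self.max_missing < 1 or self.min_complete_conspecifics < 1:
            raise ParameterError("eligibility thresholds must be positive integers")


@dataclass
class EligibilityPartition:
    """Exhaustive, disjoint split of a record table.

    ``complete``: no missing measurement. ``eligible``: 1..max_missing
    missing and enough complete conspecifics. ``ineligible``: the rest.
    """

    complete: pd.DataFrame
    eligible: pd.DataFrame
    ineligible: pd.DataFrame


def find_eligible(
    records: pd.DataFrame, rule: EligibilityRule | None = None
) -> EligibilityPartition:
    """Partition records into (complete, eligible, ineligible)."""
    rule = rule or EligibilityRule()
    miss = records[MEASUREMENTS].isna().sum(axis=1)
    complete_mask = miss == 0
    n_complete = records.loc[complete_mask, "species"].value_counts()
    enough = records["species"].map(n_complete).fillna(0) >= rule.min_complete_conspecifics
    eligible_mask = (miss >= 1) & (miss <= rule.max_missing) & enough
    ineligible_mask = ~complete_mask & ~eligible_mask
    return EligibilityPartition(
        complete=records.loc[complete_mask],
        eligible=records.loc[eligible_mask],
        ineligible=records.loc[ineligible_mask],
    )


def _missforest_run(
    X: np.ndarray, miss_mask: np.ndarray, n_trees: int, max_iter: int, seed: int
) -> np.ndarray:
    """One missForest run on matrix X (rows x 15), NaN marked by miss_mask.

    Returns the imputed matrix. Columns are revisited in order of
    increasing missingness; iteration stops the first time the normalized
    squared difference between successive imputations increases.
    """
    X = X.copy()
    col_order = np.argsort(miss_mask.sum(axis=0))
    col_means = np.nanmean(np.where(miss_mask, np.nan, X), axis=0)
    for j in range(X.shape[1]):
        X[miss_mask[:, j], j] = col_means[j]

    prev = X.copy()
    prev_diff = np.inf
    rng = np.random.default_rng(seed)
    for _ in range(max_iter):
        for j in col_order:
            rows_miss = miss_mask[:, j]
            if not rows_miss.any():
                continue
            rows_obs = ~rows_miss
            other = np.delete(np.arange(X.shape[1]), j)
            rf = RandomForestRegressor(
                n_estimators=n_trees,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            rf.fit(X[rows_obs][:, other], X[rows_obs, j])
            X[rows_miss, j] = rf.predict(X[rows_miss][:, other])
        num = float(((X - prev)[miss_mask] ** 2).sum())
        den = float((X[miss_mask] ** 2).sum())
        diff = num / den if den > 0 else 0.0
        if diff >= prev_diff:
            return prev  # stopping rule: keep the previous sweep's result
        if diff == 0.0:
            break
        prev = X.copy()
        prev_diff = diff
    return X


def _oob_rmse(train: np.ndarray, col: int, n_trees: int, seed: int) -> float:
    """Out-of-bag RMSE of predicting one measurement from the other 14."""
    other = np.delete(np.arange(train.shape[1]), col)
    rf = RandomForestRegressor(
        n_estimators=n_trees, oob_score=True, bootstrap=True,
        random_state=seed, n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rf.fit(train[:, other], train[:, col])
        pred = rf.oob_prediction_
    resid = pred - train[:, col]
    resid = resid[np.isfinite(resid) & (pred != 0)] if np.isnan(resid).any() else resid
    return float(np.sqrt(np.mean(resid**2))) if resid.size else float("nan")


def impute(
    records: pd.DataFrame,
    n_runs: int = 20,
    n_trees: int = 300,
    max_iter: int = 20,
    seed: int = 0,
    rule: EligibilityRule | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing measurements of eligible records.

    Returns ``(filled, audit)``. ``filled`` is a copy of ``records`` in
    which every eligible record's missing values are replaced by the mean
    over ``n_runs`` independent missForest runs trained on its complete
    conspecifics; complete and ineligible records are untouched. ``audit``
    has one row per imputed value: individual_id, measurement,
    imputed_value, run_sd, error_estimate (out-of-bag RMSE of that
    measurement's forest on the training pool), and a ``nonpositive``
    flag (such values are rejected back to missing rather than clamped).
    """
    rule = rule or EligibilityRule()
    part = find_eligible(records, rule)
    out = records.copy()
    audit_rows: list[dict] = []
    if part.eligible.empty:
        return out, pd.DataFrame(
            columns=["individual_id", "measurement", "imputed_value",
                     "run_sd", "error_estimate", "nonpositive"]
        )
    ss = np.random.SeedSequence(seed)
    species_list = sorted(part.eligible["species"].unique())
    species_seeds = {sp: s for sp, s in zip(species_list, ss.spawn(len(species_list)))}

    for sp in species_list:
        sp_seed = species_seeds[sp]
        train_df = part.complete[part.complete["species"] == sp]
        elig_df = part.eligible[part.eligible["species"] == sp]
        train = train_df[MEASUREMENTS].to_numpy(dtype=float)
        elig = elig_df[MEASUREMENTS].to_numpy(dtype=float)
        X = np.vstack([train, elig])
        miss = np.isnan(X)
        run_seeds = sp_seed.spawn(n_runs + 1)
        stack = np.empty((n_runs, *X.shape))
        for r in range(n_runs):
            stack[r] = _missforest_run(
                X, miss, n_trees, max_iter,
                int(run_seeds[r].generate_state(1)[0] % (2**31 - 1)),
            )
        mean_imp = stack.mean(axis=0)
        sd_imp = stack.std(axis=0, ddof=1) if n_runs > 1 else np.zeros_like(mean_imp)

        err_seed = int(run_seeds[-1].generate_state(1)[0] % (2**31 - 1))
        oob_cache: dict[int, float] = {}
        n_train = len(train)
        for local_i, (ridx, _) in enumerate(elig_df.iterrows()):
            row = n_train + local_i
            for j, meas in enumerate(MEASUREMENTS):
                if not miss[row, j]:
                    continue
                value = float(mean_imp[row, j])
                nonpos = value <= 0
                if not nonpos:
                    out.at[ridx, meas] = value
                if j not in oob_cache:
                    oob_cache[j] = _oob_rmse(train, j, n_trees, err_seed)
                audit_rows.append({
                    "individual_id": records.at[ridx, "individual_id"]
                    if "individual_id" in records.columns else ridx,
                    "measurement": meas,
                    "imputed_value": value,
                    "run_sd": float(sd_imp[row, j]),
                    "error_estimate": oob_cache[j],
                    "nonpositive": nonpos,
                })
    return out, pd.DataFrame(audit_rows)
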