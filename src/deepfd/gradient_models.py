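"""Trends of diversity metrics along the depth and latitude gradients.

Each cell-level metric is modelled twice: once with depth as the fixed
gradient and location (latitude) as a random intercept, and once with
latitude fixed and depth stratum random. The fixed gradient enters
through orthogonal polynomial terms (degree 1-3) built on the
standardized gradient; candidate degrees are compared by AIC on
maximum-likelihood fits and the winner is refit by REML. Variance
explained is decomposed into

    marginal  R2 = s2_f / (s2_f + s2_r + s2_e)
    conditional R2 = (s2_f + s2_r) / (s2_f + s2_r + s2_e)

where s2_f is the variance of the fixed-effect predictions, s2_r the
random-intercept variance and s2_e the residual variance.

The depth-by-latitude interaction is tested with a fixed-effects model:
a simple product term when both selected marginal models are linear,
otherwise a tensor-product polynomial surface whose interaction block is
capped at 3 degrees of freedom and tested jointly by an F-test.

VPFD and VNND are log10-transformed before modelling to improve
normality; the regularity indices are strongly right-skewed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DesignError

__all__ = [
    "TrendSpec", "TrendFit", "InteractionReport",
    "polynomial_design", "fit_mixed_trend", "interaction_test",
    "LOG10_METRICS",
]

#: metrics transformed to log10 before modelling
LOG10_METRICS = ("VPFD", "VNND")


@dataclass(frozen=True)
class TrendSpec:
    """What to model and how."""

    response: str
    fixed_gradient: str  # "depth" or "latitude"
    max_degree: int = 3
    transform: str = "none"  # "none" or "log10"

    def __post_init__(self):
        if self.max_degree not in (1, 2, 3):
            raise ValueError("max_degree must be 1, 2 or 3")
        if self.fixed_gradient not in ("depth", "latitude"):
            raise ValueError("fixed_gradient must be 'depth' or 'latitude'")
        if self.transform not in ("none", "log10"):
            raise ValueError("transform must be 'none' or 'log10'")


def polynomial_design(values, max_degree: int) -> np.ndarray:
    """Orthogonal polynomial basis on standardized gradient values.

    The gradient is z-scored, a Vandermonde matrix up to ``max_degree``
    is built, and the polynomial columns are orthogonalized against the
    intercept and each other (QR), then scaled to unit norm — so the
    linear coefficient is invariant to whether higher-order terms are
    included. Requires more distinct values than the degree.
    """
    x = np.asarray(values, dtype=float)
    n_distinct = len(np.unique(x))
    if n_distinct <= max_degree:
        raise DesignError(
            f"need > {max_degree} distinct gradient values, got {n_distinct}"
        )
    z = (x - x.mean()) / x.std(ddof=1)
    V = np.vander(z, N=max_degree + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    Q = Q * np.sign(np.diag(R))  # align with the raw powers
    basis = Q[:, 1:]
    # columns are exactly orthogonal to the intercept (mean 0); scale to
    # unit sample sd so coefficients read per-sd of the gradient term
    return basis / basis.std(axis=0, ddof=1)


@dataclass
class TrendFit:
    """Selected mixed-model fit for one metric and one fixed gradient."""

    spec: TrendSpec
    degree: int
    coefficients: pd.Series
    std_errors: pd.Series
    pvalues: pd.Series
    sigma2_f: float
    sigma2_r: float
    sigma2_e: float
    r2_marginal: float
    r2_conditional: float
    aic_by_degree: dict = field(default_factory=dict)
    flag: str = ""

    @staticmethod
    def r2_from_components(s2f: float, s2r: float, s2e: float) -> tuple[float, float]:
        tot = s2f + s2r + s2e
        return s2f / tot, (s2f + s2r) / tot


def _prepare_response(df: pd.DataFrame, spec: TrendSpec) -> np.ndarray:
    y = df[spec.response].to_numpy(dtype=float)
    if spec.transform == "log10":
        if (y <= 0).any():
            raise ValueError(
                f"log10 transform of {spec.response} requires positive values"
            )
        y = np.log10(y)
    return y


def _gradient_and_groups(df: pd.DataFrame, spec: TrendSpec):
    if spec.fixed_gradient == "depth":
        return df["depth_m"].to_numpy(dtype=float), df["location"].to_numpy()
    return df["latitude_s"].to_numpy(dtype=float), df["depth_m"].to_numpy()


def fit_mixed_trend(cell_metrics: pd.DataFrame, spec: TrendSpec) -> TrendFit:
    """Fit and select the polynomial mixed-effects trend of one metric.

    Rows with a missing response are dropped. Candidate degrees 1 to
    ``spec.max_degree`` are fit with a random intercept per level of the
    random gradient (ML), compared by AIC, and the winner refit by REML.
    A singular or failed mixed fit degrades to a fixed-effects-only OLS
    fit with ``flag='ols_fallback'``.
    """
    df = cell_metrics.dropna(subset=[spec.response])
    if len(df) < 10:
        raise DesignError(f"need >= 10 cells, got {len(df)}")
    y = _prepare_response(df, spec)
    grad, groups = _gradient_and_groups(df, spec)
    if len(np.unique(groups)) < 3:
        raise DesignError("random grouping needs >= 3 levels")
    basis = polynomial_design(grad, spec.max_degree)

    def exog_for(degree):
        X = np.column_stack([np.ones(len(y)), basis[:, :degree]])
        names = ["intercept"] + [f"{spec.fixed_gradient}^{k}" for k in
                                 range(1, degree + 1)]
        return X, names

    aics = {}
    fits = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for degree in range(1, spec.max_degree + 1):
            X, names = exog_for(degree)
            try:
                fit = sm.MixedLM(y, X, groups=groups).fit(reml=False)
                aics[degree] = float(fit.aic)
                fits[degree] = fit
            except Exception:
                continue
    flag = ""
    if aics:
        best = min(aics, key=aics.get)
        X, names = exog_for(best)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.MixedLM(y, X, groups=groups).fit(reml=True)
                params = np.asarray(fit.fe_params)
                bse = np.asarray(fit.bse_fe)
                pvals = np.asarray(fit.pvalues)[: len(params)]
                s2r = float(np.asarray(fit.cov_re)[0, 0])
                s2e = float(fit.scale)
                if not np.isfinite(s2r):
                    raise ValueError("singular random-effects covariance")
            except Exception:
                flag = "ols_fallback"
    else:
        best = 1
        flag = "ols_fallback"
    if flag == "ols_fallback":
        X, names = exog_for(best)
        ols = sm.OLS(y, X).fit()
        params = np.asarray(ols.params)
        bse = np.asarray(ols.bse)
        pvals = np.asarray(ols.pvalues)
        s2r = 0.0
        s2e = float(ols.scale)
    s2f = float(np.var(X @ params))
    r2m, r2c = TrendFit.r2_from_components(s2f, s2r, s2e)
    return TrendFit(
        spec=spec, degree=best,
        coefficients=pd.Series(params, index=names),
        std_errors=pd.Series(bse, index=names),
        pvalues=pd.Series(pvals, index=names),
        sigma2_f=s2f, sigma2_r=s2r, sigma2_e=s2e,
        r2_marginal=r2m, r2_conditional=r2c,
        aic_by_degree=aics, flag=flag,
    )


@dataclass
class InteractionReport:
    """Depth-by-latitude interaction test for one metric."""

    branch: str  # "linear" or "tensor"
    statistic: float
    pvalue: float
    coefficient: float | None = None  # product-term coefficient (linear branch)
    edf: int = 1
    flag: str = ""


def interaction_test(
    cell_metrics: pd.DataFrame,
    response: str,
    depth_degree: int,
    latitude_degree: int,
    transform: str = "none",
) -> InteractionReport:
    """Test the depth-by-latitude interaction with both gradients fixed.

    When both selected marginal models are linear, a fixed-effects linear
    model with a depth-by-latitude product term is fit and the product
    coefficient reported (t-test). Otherwise a tensor-product polynomial
    surface is fit: orthogonal main-effect terms up to each selected
    degree plus an interaction block of at most 3 product columns (3
    degrees of freedom), tested jointly by an F-test against the
    main-effects model. Fewer than 20 cells forces the linear branch with
    a flag.
    """
    spec = TrendSpec(response=response, fixed_gradient="depth", transform=transform)
    df = cell_metrics.dropna(subset=[response])
    y = _prepare_response(df, spec)
    zd = df["depth_m"].to_numpy(dtype=float)
    zl = df["latitude_s"].to_numpy(dtype=float)
    zd = (zd - zd.mean()) / zd.std(ddof=1)
    zl = (zl - zl.mean()) / zl.std(ddof=1)

    linear_branch = depth_degree == 1 and latitude_degree == 1
    flag = ""
    if not linear_branch and len(df) < 20:
        linear_branch = True
        flag = "too_few_cells_for_smooth"

    if linear_branch:
        X = np.column_stack([np.ones(len(y)), zd, zl, zd * zl])
        fit = sm.OLS(y, X).fit()
        return InteractionReport(
            branch="linear",
            statistic=float(fit.tvalues[3]),
            pvalue=float(fit.pvalues[3]),
            coefficient=float(fit.params[3]),
            edf=1, flag=flag,
        )

    dd = polynomial_design(zd, depth_degree)
    ll = polynomial_design(zl, latitude_degree)
    main = np.column_stack([np.ones(len(y)), dd, ll])
    # tensor-product interaction block, capped at 3 columns (3 df)
    prods = [dd[:, 0] * ll[:, 0]]
    if depth_degree >= 2:
        prods.append(dd[:, 1] * ll[:, 0])
    if latitude_degree >= 2:
        prods.append(dd[:, 0] * ll[:, 1])
    inter = np.column_stack(prods[:3])
    full = np.column_stack([main, inter])
    fit_main = sm.OLS(y, main).fit()
    fit_full = sm.OLS(y, full).fit()
    comparison = fit_full.compare_f_test(fit_main)
    return InteractionReport(
        branch="tensor",
        statistic=float(comparison[0]),
        pvalue=float(comparison[1]),
        coefficient=None,
        edf=inter.shape[1],
        flag=flag,
    )
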