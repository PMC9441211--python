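"""Result surfaces: stratified CHP rate tables, provider-rate distributions,
volume-completeness association, and univariate logistic regressions.

Rates are kept at full precision internally; presentation rounds
half-away-from-zero to three decimals (0.6105… prints as 0.611).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .types import ClassifiedCase, SpsProfile, record_fields

__all__ = [
    "cases_to_frame", "rate_table", "rate_table_from_counts",
    "present_rate_table", "round_half_away",
    "fit_univariate_logistic", "RegressionResult",
    "volume_association", "distribution_summary", "DistributionSummary",
]

#: Stratifiers treated as categorical in regressions unless overridden.
CATEGORICAL_PREDICTORS = {"site", "tissue_group", "intent", "sps_code",
                          "case_type", "status"}


def cases_to_frame(cases: Sequence[ClassifiedCase]) -> pd.DataFrame:
    """Classified cases as a DataFrame with an ``is_chp`` indicator column."""
    cols = record_fields(ClassifiedCase)
    df = pd.DataFrame([[getattr(c, f) for f in cols] for c in cases],
                      columns=cols)
    df["is_chp"] = df["status"] == "CHP" if len(df) else pd.Series(dtype=bool)
    return df


# ---------------------------------------------------------------------------
# Rate tables

def round_half_away(x: float, decimals: int = 3) -> float:
    """Round half away from zero (0.6105 -> 0.611), unlike banker's
    rounding."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def rate_table(cases: pd.DataFrame | Sequence[ClassifiedCase],
               stratifiers: Sequence[str]) -> pd.DataFrame:
    """CHP volume/count/rate per stratum combination.

    Returns one row per observed combination of the stratifier values, with
    columns ``volume``, ``chp``, ``rate`` and ``fraction_of_total`` at full
    precision; use :func:`present_rate_table` for display rounding.
    """
    df = cases if isinstance(cases, pd.DataFrame) else cases_to_frame(cases)
    missing = [s for s in stratifiers if s not in df.columns]
    if missing:
        raise KeyError(f"unknown stratifier(s): {missing}")
    if df.empty:
        return pd.DataFrame(columns=[*stratifiers, "volume", "chp", "rate",
                                     "fraction_of_total"])
    grouped = (
        df.groupby(list(stratifiers), sort=True, observed=True)["is_chp"]
        .agg(volume="size", chp="sum")
        .reset_index()
    )
    grouped["chp"] = grouped["chp"].astype(int)
    grouped["rate"] = grouped["chp"] / grouped["volume"]
    grouped["fraction_of_total"] = grouped["volume"] / grouped["volume"].sum()
    return grouped


def rate_table_from_counts(labels: Sequence, volumes: Sequence[int],
                           chps: Sequence[int],
                           stratifier: str = "stratum",
                           include_total: bool = False,
                           total_label: str = "Whole cohort") -> pd.DataFrame:
    """Build a rate table directly from per-stratum (volume, CHP) counts."""
    if not (len(labels) == len(volumes) == len(chps)):
        raise ValueError("labels, volumes and chps must have equal length")
    df = pd.DataFrame({stratifier: list(labels),
                       "volume": list(volumes), "chp": list(chps)})
    total_volume = int(df["volume"].sum())
    total_chp = int(df["chp"].sum())
    df["rate"] = df["chp"] / df["volume"]
    df["fraction_of_total"] = df["volume"] / total_volume
    if include_total:
        total = pd.DataFrame({
            stratifier: [total_label], "volume": [total_volume],
            "chp": [total_chp], "rate": [total_chp / total_volume],
            "fraction_of_total": [1.0],
        })
        df = pd.concat([df, total], ignore_index=True)
    return df


def present_rate_table(table: pd.DataFrame, decimals: int = 3) -> pd.DataFrame:
    """Presentation copy of a rate table: rates and fractions rounded
    half-away-from-zero to ``decimals`` places."""
    out = table.copy()
    for col in ("rate", "fraction_of_total"):
        if col in out.columns:
            out[col] = [round_half_away(v, decimals) for v in out[col]]
    return out


# ---------------------------------------------------------------------------
# Logistic regression

@dataclass
class RegressionResult:
    """One univariate logistic fit of CHP on a predictor.

    ``p_value`` is from the likelihood-ratio test against the
    intercept-only model.
    """

    predictor: str
    coding: str  # "continuous" or "categorical"
    reference_level: str | None
    params: dict[str, float]
    bse: dict[str, float]
    llf: float
    llf_null: float
    p_value: float
    n: int
    converged: bool = True
    separation: bool = False

    @property
    def lrt_statistic(self) -> float:
        return 2.0 * (self.llf - self.llf_null)


def fit_univariate_logistic(
    cases: pd.DataFrame | Sequence[ClassifiedCase],
    predictor: str,
    categorical: bool | None = None,
) -> RegressionResult:
    """Fit logistic(CHP) ~ predictor by maximum likelihood (IRLS).

    Categorical predictors are dummy-coded against their most frequent
    level; ``year`` and the complexity covariates enter as continuous by
    default.  Convergence: log-likelihood change < 1e-8 or 100 iterations.
    Perfect separation is flagged, with coefficients reported at the
    iteration cap.
    """
    df = cases if isinstance(cases, pd.DataFrame) else cases_to_frame(cases)
    if predictor not in df.columns:
        raise KeyError(f"unknown predictor {predictor!r}")
    y = (df["status"] == "CHP").to_numpy(dtype=float)
    x = df[predictor]
    if categorical is None:
        categorical = predictor in CATEGORICAL_PREDICTORS or x.dtype == object
    if x.nunique() < 2:
        raise ValueError(f"degenerate predictor {predictor!r}: a single level")

    reference = None
    if categorical:
        levels = x.value_counts()
        reference = str(levels.index[0])  # most frequent level
        dummies = pd.get_dummies(x.astype(str), prefix=predictor, dtype=float)
        dummies = dummies.drop(columns=f"{predictor}_{reference}")
        X = sm.add_constant(dummies, has_constant="add")
    else:
        X = sm.add_constant(
            pd.DataFrame({predictor: x.to_numpy(dtype=float)}),
            has_constant="add",
        )

    res, separation = _fit_glm(y, X)
    null = sm.GLM(y, np.ones((len(y), 1)),
                  family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
    df_diff = X.shape[1] - 1
    lrt = 2.0 * (res.llf - null.llf)
    p = float(stats.chi2.sf(max(lrt, 0.0), df_diff))
    p = max(p, np.finfo(float).tiny)  # keep within (0, 1]
    return RegressionResult(
        predictor=predictor,
        coding="categorical" if categorical else "continuous",
        reference_level=reference,
        params={k: float(v) for k, v in res.params.items()},
        bse={k: float(v) for k, v in res.bse.items()},
        llf=float(res.llf),
        llf_null=float(null.llf),
        p_value=p,
        n=len(y),
        converged=bool(getattr(res, "converged", True)),
        separation=separation,
    )


def _fit_glm(y: np.ndarray, X: pd.DataFrame):
    """IRLS fit; falls back to a capped BFGS Logit fit under perfect
    separation so coefficients are still reported."""
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-8)
        except PerfectSeparationError:
            separation = True
            res = sm.Logit(y, X).fit(method="bfgs", maxiter=100, disp=0)
    for w in caught:
        if "separation" in str(w.message).lower():
            separation = True
    slopes = [v for k, v in res.params.items() if k != "const"]
    if not separation and slopes and np.abs(slopes).max() > 15:
        separation = True
    if separation:
        warnings.warn("perfect or near-perfect separation: coefficients "
                      "reported at the iteration cap", stacklevel=3)
    return res, separation


# ---------------------------------------------------------------------------
# Provider-rate distribution & volume association

def volume_association(profiles: Sequence[SpsProfile]) -> tuple[float, float]:
    """Spearman rank correlation between per-SPS volume and CHP rate.

    Spearman is used because provider rates are bounded and heavily skewed
    toward 1; rank correlation is insensitive to both.
    """
    if len(profiles) < 3:
        raise ValueError("volume_association requires at least 3 profiles")
    volumes = [p.n_cases for p in profiles]
    rates = [p.chp_rate for p in profiles]
    rho, p = stats.spearmanr(volumes, rates)
    return float(rho), float(p)


@dataclass
class DistributionSummary:
    """Histogram plus truncated/renormalised Gaussian KDE of per-SPS CHP
    rate on [0, 1]."""

    bin_edges: np.ndarray
    counts: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def density_integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def distribution_summary(profiles: Sequence[SpsProfile], bins: int = 20,
                         bandwidth: float | str | None = None,
                         grid_points: int = 512) -> DistributionSummary:
    """Histogram (default 20 equal bins over [0,1]) and kernel density
    (Gaussian, Silverman's rule by default) of per-SPS CHP rates.

    The KDE is evaluated on a grid over [0,1] and renormalised so its
    trapezoid integral is 1, compensating for mass the unbounded kernel
    places outside the unit interval.
    """
    if not profiles:
        raise ValueError("distribution_summary requires at least one profile")
    rates = np.array([p.chp_rate for p in profiles], dtype=float)
    counts, edges = np.histogram(rates, bins=bins, range=(0.0, 1.0))
    grid = np.linspace(0.0, 1.0, grid_points)
    if np.ptp(rates) > 0 and len(rates) > 1:
        kde = stats.gaussian_kde(rates, bw_method=bandwidth or "silverman")
        density = kde(grid)
        bw = float(kde.factor * rates.std(ddof=1))
    else:
        # degenerate (all rates equal): narrow Gaussian bump at the point
        bw = 0.01
        density = stats.norm.pdf(grid, loc=rates[0], scale=bw)
    integral = np.trapezoid(density, grid)
    if integral > 0:
        density = density / integral
    return DistributionSummary(bin_edges=edges, counts=counts, grid=grid,
                               density=density, bandwidth=bw)
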