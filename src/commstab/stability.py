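"""Temporal stability partition of multispecies abundance time series.

The coefficient of variation (CV) of total community abundance factors
exactly into a population-synchrony term and an abundance-weighted mean
population CV:

    CV = CV_w * sqrt(phi)

with

    CV_w = sum_i (mu_i / mu) * (sigma_i / mu_i) = sum_i sigma_i / mu
    phi  = sigma^2 / (sum_i sigma_i)^2

where ``sigma^2`` is the temporal variance of the community total,
``sigma_i`` and ``mu_i`` the temporal standard deviation and mean of
population *i*, and ``mu`` the temporal mean of the community total.
``phi`` is the Loreau–de Mazancourt synchrony index, ranging from 0
(maximum asynchrony, fluctuations cancel) to 1 (perfect synchrony).

On the negative natural-log scale the partition becomes additive:

    community_stability = 1/2 * population_asynchrony
                          + weighted_mean_population_stability

with community_stability = -log CV, population_asynchrony = -log phi and
weighted_mean_population_stability = -log CV_w.

All variances and covariances use the sample (n-1) convention; both
identities hold under either convention as long as it is consistent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .errors import (
    DegenerateCommunityError,
    InvalidArgumentError,
    UndefinedStatisticError,
)

logger = logging.getLogger(__name__)

#: ddof used for every variance / standard deviation in this module.
VARIANCE_DDOF = 1

LONG_COLUMNS = ("site_id", "species_id", "year", "abundance")


@dataclass
class CommunityMatrix:
    """Species x year abundance matrix for one site.

    Absent species-year combinations are zeros; a year absent from the
    site's records altogether should simply not appear in ``years``
    (complete-column analysis, no imputation).
    """

    site_id: str
    species: list[str]
    years: list[int]
    abundance: np.ndarray  # shape (n_species, n_years)

    def __post_init__(self):
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.ndim != 2:
            raise InvalidArgumentError("abundance must be a 2-D matrix")
        if self.abundance.shape != (len(self.species), len(self.years)):
            raise InvalidArgumentError(
                f"abundance shape {self.abundance.shape} does not match "
                f"{len(self.species)} species x {len(self.years)} years"
            )
        if len(self.years) < 2:
            raise InvalidArgumentError("need at least 2 years")
        if len(set(self.species)) != len(self.species):
            raise InvalidArgumentError("duplicate species identifiers")
        if np.any(self.abundance < 0):
            raise InvalidArgumentError("negative abundances")
        if not np.any(self.abundance.sum(axis=1) > 0):
            raise InvalidArgumentError("no species with nonzero total abundance")

    @property
    def totals(self) -> np.ndarray:
        """Total community abundance per year."""
        return self.abundance.sum(axis=0)

    def drop_absent_species(self) -> "CommunityMatrix":
        """Return a copy without species never observed at this site."""
        keep = self.abundance.sum(axis=1) > 0
        return CommunityMatrix(
            site_id=self.site_id,
            species=[s for s, k in zip(self.species, keep) if k],
            years=list(self.years),
            abundance=self.abundance[keep],
        )


@dataclass
class StabilityPartition:
    """Exact CV partition for one community, on both scales."""

    cv_community: float
    cv_w: float
    phi: float
    community_stability: float
    population_asynchrony: float
    weighted_mean_population_stability: float

    def as_dict(self) -> dict:
        return {
            "cv_community": self.cv_community,
            "cv_w": self.cv_w,
            "phi": self.phi,
            "community_stability": self.community_stability,
            "population_asynchrony": self.population_asynchrony,
            "weighted_mean_population_stability": self.weighted_mean_population_stability,
        }


@dataclass
class TaylorFit:
    """Mean-variance (Taylor's law) scaling fit on the log-log scale."""

    slope_b: float
    slope_se: float
    intercept: float
    n_populations: int
    fit_variant: str
    converged: bool = True


def matrices_from_long(
    df: pd.DataFrame, min_years: int | None = None
) -> list[CommunityMatrix]:
    """Pivot a long-format abundance table into per-site matrices.

    Duplicate (site, species, year) rows are summed with a warning.
    """
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"abundance table lacks columns: {sorted(missing)}")
    dup = df.duplicated(subset=["site_id", "species_id", "year"])
    if dup.any():
        logger.warning("summing %d duplicate (site, species, year) rows", dup.sum())
    out = []
    for site_id, g in df.groupby("site_id", sort=True):
        wide = g.pivot_table(
            index="species_id", columns="year", values="abundance",
            aggfunc="sum", fill_value=0.0,
        ).sort_index()
        if min_years is not None and wide.shape[1] < min_years:
            continue
        out.append(
            CommunityMatrix(
                site_id=str(site_id),
                species=[str(s) for s in wide.index],
                years=[int(y) for y in wide.columns],
                abundance=wide.to_numpy(dtype=float),
            )
        )
    return out


def community_cv(m: CommunityMatrix) -> float:
    """CV of total community abundance: sd(total) / mean(total)."""
    totals = m.totals
    mean = totals.mean()
    if mean <= 0:
        raise UndefinedStatisticError("community mean abundance is zero")
    return float(totals.std(ddof=VARIANCE_DDOF) / mean)


def weighted_mean_population_cv(m: CommunityMatrix) -> float:
    """Abundance-weighted mean population CV: sum_i sigma_i / mu.

    Species never observed at the site are dropped first; species with
    zeros in some years contribute those zeros.
    """
    m = m.drop_absent_species()
    mu = m.totals.mean()
    if mu <= 0:
        raise UndefinedStatisticError("no species with positive mean abundance")
    sigma_i = m.abundance.std(axis=1, ddof=VARIANCE_DDOF)
    return float(sigma_i.sum() / mu)


def synchrony_phi(m: CommunityMatrix) -> float:
    """Loreau–de Mazancourt synchrony: var(total) / (sum_i sd_i)^2."""
    sigma_i = m.abundance.std(axis=1, ddof=VARIANCE_DDOF)
    denom = sigma_i.sum()
    if denom == 0:
        raise UndefinedStatisticError("all populations are constant")
    phi = float(np.var(m.totals, ddof=VARIANCE_DDOF) / denom**2)
    # Cauchy-Schwarz bounds phi by 1; anything beyond is rounding error.
    if phi > 1.0:
        if phi > 1.0 + 1e-9:
            raise UndefinedStatisticError(f"synchrony {phi} exceeds 1 beyond rounding")
        phi = 1.0
    return max(phi, 0.0)


def stability_partition(m: CommunityMatrix) -> StabilityPartition:
    """Compute the full CV partition; raises if a log diverges."""
    cv = community_cv(m)
    phi = synchrony_phi(m)
    cv_w = weighted_mean_population_cv(m)
    if cv == 0:
        raise DegenerateCommunityError("cv_community", m.site_id)
    if phi == 0:
        raise DegenerateCommunityError("phi", m.site_id)
    return StabilityPartition(
        cv_community=cv,
        cv_w=cv_w,
        phi=phi,
        community_stability=-math.log(cv) + 0.0,
        population_asynchrony=-math.log(phi) + 0.0,
        weighted_mean_population_stability=-math.log(cv_w) + 0.0,
    )


def partition_table(
    matrices: Iterable[CommunityMatrix],
) -> tuple[pd.DataFrame, list[dict]]:
    """Per-site partition table; degenerate sites go to the exclusion log."""
    rows, excluded = [], []
    for m in matrices:
        try:
            part = stability_partition(m)
        except (DegenerateCommunityError, UndefinedStatisticError) as err:
            logger.warning("excluding site %s: %s", m.site_id, err)
            excluded.append({"site_id": m.site_id, "reason": str(err)})
            continue
        rows.append({"site_id": m.site_id, "n_years": len(m.years), **part.as_dict()})
    return pd.DataFrame(rows), excluded


def _population_frame(tables: Sequence[CommunityMatrix]) -> pd.DataFrame:
    recs = []
    for m in tables:
        mu_i = m.abundance.mean(axis=1)
        var_i = m.abundance.var(axis=1, ddof=VARIANCE_DDOF)
        for sp, mu, var in zip(m.species, mu_i, var_i):
            if mu > 0 and var > 0:
                recs.append(
                    {"site": m.site_id, "species": sp,
                     "log_mean": math.log(mu), "log_var": math.log(var)}
                )
    return pd.DataFrame(recs)


def mean_variance_scaling(
    tables: Sequence[CommunityMatrix], variant: str = "fixed"
) -> TaylorFit:
    """Fit Taylor's law sigma_i^2 = c * mu_i^b across populations.

    Regresses log sample variance on log sample mean of every population
    (site x species) with positive mean and variance.

    Parameters
    ----------
    variant:
        ``"fixed"`` — ordinary least squares; ``"mixed"`` — random
        intercepts for both species and site (crossed), fit by ML.
    """
    if variant not in ("fixed", "mixed"):
        raise InvalidArgumentError(f"unknown variant {variant!r}")
    df = _population_frame(tables)
    if len(df) < 3:
        raise InvalidArgumentError(
            f"need >= 3 populations with positive mean and variance, got {len(df)}"
        )
    if variant == "fixed":
        X = sm.add_constant(df["log_mean"])
        res = sm.OLS(df["log_var"], X).fit()
        return TaylorFit(
            slope_b=float(res.params["log_mean"]),
            slope_se=float(res.bse["log_mean"]),
            intercept=float(res.params["const"]),
            n_populations=len(df),
            fit_variant="fixed-effects",
        )
    df = df.copy()
    df["one"] = 1
    model = sm.MixedLM.from_formula(
        "log_var ~ log_mean",
        groups="one",
        vc_formula={"species": "0 + C(species)", "site": "0 + C(site)"},
        re_formula="0",
        data=df,
    )
    res = model.fit(reml=False)
    return TaylorFit(
        slope_b=float(res.fe_params["log_mean"]),
        slope_se=float(res.bse["log_mean"]),
        intercept=float(res.fe_params["Intercept"]),
        n_populations=len(df),
        fit_variant="species-and-site-random-intercepts",
        converged=bool(res.converged),
    )


class TaylorScaling(BaseEstimator):
    """Estimator wrapper around :func:`mean_variance_scaling`.

    Parameters
    ----------
    variant : str
        ``"fixed"`` or ``"mixed"`` (crossed species/site random intercepts).

    Attributes
    ----------
    slope_ : float
        Estimated Taylor exponent b.
    slope_se_ : float
    intercept_ : float
        Estimated log c.
    n_populations_ : int
    """

    def __init__(self, variant: str = "fixed"):
        self.variant = variant

    def fit(self, X: Sequence[CommunityMatrix], y=None):
        fit = mean_variance_scaling(X, variant=self.variant)
        self.slope_ = fit.slope_b
        self.slope_se_ = fit.slope_se
        self.intercept_ = fit.intercept
        self.n_populations_ = fit.n_populations
        self.fit_ = fit
        return self
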