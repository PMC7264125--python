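"""Habitat-degradation gradients from eight landscape variables.

A correlation-matrix PCA of the eight per-site landscape descriptors
(urban %, cropland %, heterogeneous agriculture %, woodland %,
seminatural open %, sealed soil, agricultural inputs, landscape Shannon
complexity), followed by a varimax rotation of the first two components,
yields two interpretable, near-independent axes: an urban gradient
(urban / sealed-soil sites vs. seminatural ones) and an agricultural
intensity gradient (cropland / high-input sites vs. heterogeneous,
wooded landscapes). Axis identity and sign are fixed deterministically
from the loadings so downstream models never see PCA sign flips; the
urban scores are then log-transformed as ln(score - min + 1) to reduce
skew.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.multivariate.factor_rotation import rotate_factors

from .errors import DegenerateInputError, InvalidArgumentError, NumericalError

logger = logging.getLogger(__name__)

LANDSCAPE_VARIABLES = [
    "urban",
    "cropland",
    "heterogeneous_agriculture",
    "woodland",
    "seminatural_open",
    "sealed_soil",
    "agricultural_inputs",
    "landscape_complexity",
]

URBAN_MARKERS = ("urban", "sealed_soil")
AGRI_MARKER = "cropland"


def landscape_shannon(category_areas) -> float:
    """Shannon diversity -sum p_i ln p_i over land-use category areas."""
    areas = np.asarray(list(category_areas), dtype=float)
    if np.any(areas < 0):
        raise InvalidArgumentError("negative category areas")
    areas = areas[areas > 0]
    if areas.size == 0:
        raise InvalidArgumentError("all category areas are zero")
    p = areas / areas.sum()
    return float(-(p * np.log(p)).sum())


def agricultural_inputs_index(expenses_keur, agricultural_area) -> float:
    """Yearly expenses (k-euro) per unit agricultural area, averaged over years.

    ``expenses_keur`` may be a scalar or a sequence of yearly values; NaN
    entries (years without data) are skipped in the mean.
    """
    if agricultural_area is None or agricultural_area <= 0:
        raise InvalidArgumentError("agricultural area must be positive")
    expenses = np.atleast_1d(np.asarray(expenses_keur, dtype=float))
    expenses = expenses[~np.isnan(expenses)]
    if expenses.size == 0:
        raise InvalidArgumentError("no expense values available")
    return float(expenses.mean() / agricultural_area)


def _varimax_kaiser(loadings: np.ndarray, tol: float, max_iter: int):
    """Kaiser-normalized varimax; returns rotated loadings and rotation T."""
    h = np.sqrt((loadings**2).sum(axis=1))
    if np.any(h == 0):
        raise NumericalError("zero communality row in loadings")
    normed = loadings / h[:, None]
    try:
        rotated_n, T = rotate_factors(
            normed, "varimax", tol=tol, max_tries=max_iter
        )
    except Exception as err:  # non-convergence surfaces as package error
        raise NumericalError(f"varimax rotation failed: {err}") from err
    return rotated_n * h[:, None], T


@dataclass
class LandscapeGradients:
    """Rotated loadings, per-site scores and axis bookkeeping."""

    loadings: pd.DataFrame  # 8 x 2, columns urban_gradient / agri_gradient
    scores: pd.DataFrame  # per-site urban_gradient (log), agri_gradient, raw
    variance_explained: dict
    axis_assignment: dict
    metadata: dict = field(default_factory=dict)


class GradientPCA(BaseEstimator, TransformerMixin):
    """Varimax-rotated two-component PCA of the landscape variables.

    Parameters
    ----------
    variables : list of str, optional
        Column names to use; defaults to :data:`LANDSCAPE_VARIABLES`.
    rotation_tol : float
        Convergence tolerance of the varimax iteration.
    max_iter : int
        Iteration cap for the rotation; exceeding it raises NumericalError.

    Attributes
    ----------
    loadings_ : DataFrame (n_variables x 2)
        Varimax-rotated loadings, columns ``urban_gradient`` and
        ``agri_gradient``, signed so urban / cropland load positively.
    explained_variance_ratio_ : ndarray of shape (2,)
        Share of total (standardized) variance per rotated axis.
    communalities_ : Series
        Per-variable communality of the retained pair (rotation-invariant).
    scores_ : DataFrame
        Scores of the fitted sites, including the log-transformed urban
        gradient.
    """

    def __init__(self, variables=None, rotation_tol: float = 1e-8, max_iter: int = 1000):
        self.variables = variables
        self.rotation_tol = rotation_tol
        self.max_iter = max_iter

    def _check_table(self, X: pd.DataFrame) -> pd.DataFrame:
        variables = self.variables or LANDSCAPE_VARIABLES
        missing = set(variables) - set(X.columns)
        if missing:
            raise InvalidArgumentError(f"landscape table lacks columns: {sorted(missing)}")
        return X[variables].astype(float)

    def fit(self, X: pd.DataFrame, y=None):
        table = self._check_table(X)
        n, p = table.shape
        if n <= p:
            raise InvalidArgumentError(
                f"need more sites ({n}) than variables ({p}) for the PCA"
            )
        for col in table.columns:
            if table[col].nunique() <= 1:
                raise DegenerateInputError(f"constant landscape column: {col}")
        self.mean_ = table.mean(axis=0)
        self.scale_ = table.std(axis=0, ddof=1)
        Z = (table - self.mean_) / self.scale_
        corr = np.asarray(Z.corr())
        eigval, eigvec = np.linalg.eigh(corr)
        order = np.argsort(eigval)[::-1][:2]
        lam = eigval[order]
        V = eigvec[:, order]
        loadings = V * np.sqrt(lam)
        rotated, T = _varimax_kaiser(loadings, self.rotation_tol, self.max_iter)

        # axis identity: the rotated axis loading hardest on the urban
        # markers is the urban gradient
        cols = list(table.columns)
        marker_rows = [cols.index(v) for v in URBAN_MARKERS if v in cols]
        urban_weight = np.abs(rotated[marker_rows, :]).sum(axis=0)
        urban_axis = int(np.argmax(urban_weight))
        agri_axis = 1 - urban_axis

        # sign convention: urban loads positively on the urban axis,
        # cropland on the agricultural one
        signs = np.ones(2)
        if "urban" in cols and rotated[cols.index("urban"), urban_axis] < 0:
            signs[urban_axis] = -1.0
        if AGRI_MARKER in cols and rotated[cols.index(AGRI_MARKER), agri_axis] < 0:
            signs[agri_axis] = -1.0
        rotated = rotated * signs

        # standardized PC scores, rotated by the same orthogonal T
        pc_scores = Z.to_numpy() @ V
        std = pc_scores.std(axis=0, ddof=1)
        U = pc_scores / std
        F = (U @ T) * signs
        scores = pd.DataFrame(
            F[:, [urban_axis, agri_axis]],
            index=X.index,
            columns=["urban_gradient_raw", "agri_gradient"],
        )
        self.urban_log_shift_ = float(scores["urban_gradient_raw"].min())
        scores["urban_gradient"] = np.log(
            scores["urban_gradient_raw"] - self.urban_log_shift_ + 1.0
        )

        self.loadings_ = pd.DataFrame(
            rotated[:, [urban_axis, agri_axis]],
            index=cols,
            columns=["urban_gradient", "agri_gradient"],
        )
        self.rotation_ = T
        self.signs_ = signs
        self.axis_order_ = (urban_axis, agri_axis)
        self.eigenvalues_ = lam
        self.explained_variance_ratio_ = (rotated**2).sum(axis=0)[
            [urban_axis, agri_axis]
        ] / p
        self.communalities_ = pd.Series((rotated**2).sum(axis=1), index=cols)
        # projection for new data: Z -> rotated standardized scores
        self.projection_ = (V / std) @ T * signs
        self.scores_ = scores[["urban_gradient", "agri_gradient", "urban_gradient_raw"]]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "loadings_"):
            raise InvalidArgumentError("GradientPCA is not fitted")
        table = self._check_table(X)
        Z = ((table - self.mean_) / self.scale_).to_numpy()
        F = Z @ self.projection_
        urban_axis, agri_axis = self.axis_order_
        scores = pd.DataFrame(
            F[:, [urban_axis, agri_axis]],
            index=X.index,
            columns=["urban_gradient_raw", "agri_gradient"],
        )
        scores["urban_gradient"] = np.log(
            scores["urban_gradient_raw"] - self.urban_log_shift_ + 1.0
        )
        return scores[["urban_gradient", "agri_gradient", "urban_gradient_raw"]]


def gradient_pca(table: pd.DataFrame, **kwargs) -> LandscapeGradients:
    """Fit :class:`GradientPCA` on a per-site landscape table."""
    est = GradientPCA(**kwargs).fit(table)
    return LandscapeGradients(
        loadings=est.loadings_,
        scores=est.scores_,
        variance_explained={
            "urban_gradient": float(est.explained_variance_ratio_[0]),
            "agri_gradient": float(est.explained_variance_ratio_[1]),
        },
        axis_assignment={
            "urban_gradient": int(est.axis_order_[0]),
            "agri_gradient": int(est.axis_order_[1]),
            "signs": est.signs_.tolist(),
        },
        metadata={
            "rotation": "varimax (Kaiser-normalized)",
            "urban_log_transform": "ln(score - min + 1)",
            "urban_log_shift": est.urban_log_shift_,
            "n_components": 2,
        },
    )
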