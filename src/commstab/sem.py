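"""Piecewise structural equation model with d-separation fit test.

The causal structure is a DAG over per-site summaries: two exogenous
habitat-degradation gradients, two diversity nodes, the two stability
components, and community stability. Each endogenous node is fit by its
own regression on its parents (all variables z-scored first, so slopes
are standardized). Global fit is assessed with Shipley's d-separation
test: every conditional-independence claim the DAG implies but the model
set does not estimate is tested by regression, and the claim p-values are
combined into Fisher's C = -2 sum log p_i, compared with a chi-squared
distribution on 2k degrees of freedom.

Path effects are the products of significant standardized coefficients
along directed paths; total effects sum the paths linking two variables.

Supported error structures per regression: iid OLS, generalized least
squares with an exponential or gaussian spatial correlation (range
profiled by maximum likelihood), and a one-factor random intercept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from .errors import (
    CollinearityError,
    InvalidArgumentError,
    NumericalError,
)

logger = logging.getLogger(__name__)

PVALUE_FLOOR = 1e-16

STABILITY_NODES = dict(
    gradients=("urban_gradient", "agri_gradient"),
    diversity=("species_diversity", "phylo_diversity"),
    components=("population_stability", "population_asynchrony"),
    outcome="community_stability",
)


@dataclass(frozen=True)
class DagSpec:
    """Directed acyclic graph of the model set."""

    nodes: tuple
    edges: tuple  # of (parent, child)

    def __post_init__(self):
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise InvalidArgumentError("the model structure must be acyclic")
        unknown = {u for e in self.edges for u in e} - set(self.nodes)
        if unknown:
            raise InvalidArgumentError(f"edges reference unknown nodes: {sorted(unknown)}")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node) -> tuple:
        return tuple(sorted(p for p, c in self.edges if c == node))

    @property
    def exogenous(self) -> tuple:
        children = {c for _, c in self.edges}
        return tuple(sorted(set(self.nodes) - children))

    @property
    def endogenous(self) -> tuple:
        children = {c for _, c in self.edges}
        return tuple(sorted(children))

    @classmethod
    def stability_dag(cls) -> "DagSpec":
        """The five-model structure: gradients -> diversities ->
        stability components -> community stability."""
        urban, agri = STABILITY_NODES["gradients"]
        div, phy = STABILITY_NODES["diversity"]
        pop, asy = STABILITY_NODES["components"]
        out = STABILITY_NODES["outcome"]
        edges = (
            (urban, div), (agri, div),
            (urban, phy), (agri, phy),
            (urban, pop), (agri, pop), (div, pop), (phy, pop),
            (urban, asy), (agri, asy), (div, asy), (phy, asy),
            (pop, out), (asy, out),
        )
        nodes = (urban, agri, div, phy, pop, asy, out)
        return cls(nodes=nodes, edges=edges)


@dataclass
class FitOptions:
    """How each component regression is fit."""

    error_structure: str = "iid"  # iid | exponential | gaussian | random-intercept
    alpha: float = 0.05
    coordinate_columns: tuple = ("x", "y")
    group_column: str | None = None
    range_grid_size: int = 25

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise InvalidArgumentError("alpha must lie in (0, 1)")
        valid = ("iid", "exponential", "gaussian", "random-intercept")
        if self.error_structure not in valid:
            raise InvalidArgumentError(
                f"error_structure must be one of {valid}, got {self.error_structure!r}"
            )


@dataclass
class ResponseFit:
    """One standardized component regression."""

    response: str
    predictors: tuple
    coef: pd.Series
    se: pd.Series
    pvalues: pd.Series
    aic: float
    n: int
    extra: dict = field(default_factory=dict)


@dataclass
class SemResult:
    """Fitted piecewise SEM."""

    dag: DagSpec
    fits: dict  # response -> ResponseFit
    coefficients: pd.DataFrame  # response, predictor, coef, se, pvalue
    fisher_c: float
    dsep_df: int
    dsep_p: float
    aic: float
    claims: list  # (x, y, conditioning set, p-value)
    options: FitOptions

    def coefficient(self, parent, child) -> tuple[float, float]:
        fit = self.fits[child]
        return float(fit.coef[parent]), float(fit.pvalues[parent])


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise InvalidArgumentError(f"zero-variance variables: {bad}")
    return (df - df.mean()) / sd


def _spatial_corr(dists: np.ndarray, rng_param: float, kind: str) -> np.ndarray:
    if kind == "exponential":
        return np.exp(-dists / rng_param)
    return np.exp(-((dists / rng_param) ** 2))


def _gls_profile(y, X, dists, kind, grid_size):
    """Profile the spatial range by ML; return beta, se, pvalues, aic, r."""
    n, p = X.shape

    def negloglik(log_r):
        corr = _spatial_corr(dists, math.exp(log_r), kind)
        try:
            L = cholesky(corr + 1e-10 * np.eye(n), lower=True)
        except np.linalg.LinAlgError:
            return np.inf
        yw = solve_triangular(L, y, lower=True)
        Xw = solve_triangular(L, X, lower=True)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        sigma2 = resid @ resid / n
        if sigma2 <= 0:
            return np.inf
        logdet = 2.0 * np.log(np.diag(L)).sum()
        return 0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)

    positive = dists[dists > 0]
    if positive.size == 0:
        raise InvalidArgumentError("all sites share identical coordinates")
    lo = math.log(max(np.quantile(positive, 0.05), 1e-6))
    hi = math.log(positive.max() * 4.0)
    grid = np.linspace(lo, hi, grid_size)
    values = [negloglik(g) for g in grid]
    k = int(np.argmin(values))
    span = grid[1] - grid[0]
    res = optimize.minimize_scalar(
        negloglik, bounds=(grid[k] - span, grid[k] + span), method="bounded"
    )
    if not np.isfinite(res.fun):
        raise NumericalError("non-finite likelihood in spatial GLS")
    r_hat = math.exp(res.x)
    corr = _spatial_corr(dists, r_hat, kind)
    c, low = cho_factor(corr + 1e-10 * np.eye(n), lower=True)
    XtSi = cho_solve((c, low), X)
    XtSiX = X.T @ XtSi
    try:
        cov_unscaled = np.linalg.inv(XtSiX)
    except np.linalg.LinAlgError as err:
        raise CollinearityError("singular design in spatial GLS") from err
    beta = cov_unscaled @ (XtSi.T @ y)
    resid = y - X @ beta
    sigma2 = resid @ cho_solve((c, low), resid) / (n - p)
    se = np.sqrt(np.diag(cov_unscaled) * sigma2)
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)
    loglik = -res.fun
    aic = -2.0 * loglik + 2.0 * (p + 2)  # + sigma^2 + range
    return beta, se, pvals, aic, r_hat


def fit_response(
    data: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    options: FitOptions | None = None,
) -> ResponseFit:
    """Fit one standardized regression with the configured error structure."""
    options = options or FitOptions()
    predictors = list(predictors)
    if not predictors:
        raise InvalidArgumentError("at least one predictor required")
    cols = [response] + predictors
    missing = set(cols) - set(data.columns)
    if missing:
        raise InvalidArgumentError(f"data lacks variables: {sorted(missing)}")
    n = len(data)
    if n <= len(predictors) + 2:
        raise InvalidArgumentError("too few observations for the design")
    if not np.isfinite(data[cols].to_numpy()).all():
        raise InvalidArgumentError("non-finite values in model variables")
    Z = _zscore(data[cols])
    y = Z[response].to_numpy()
    X = np.column_stack([np.ones(n), Z[predictors].to_numpy()])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(f"singular design for response {response!r}")
    names = ["const"] + predictors

    if options.error_structure == "iid":
        res = sm.OLS(y, X).fit()
        coef, se, pvals, aic = res.params, res.bse, res.pvalues, res.aic
        extra = {}
    elif options.error_structure in ("exponential", "gaussian"):
        cc = list(options.coordinate_columns)
        if set(cc) - set(data.columns):
            raise InvalidArgumentError(f"spatial fit needs coordinate columns {cc}")
        dists = squareform(pdist(data[cc].to_numpy()))
        coef, se, pvals, aic, r_hat = _gls_profile(
            y, X, dists, options.error_structure, options.range_grid_size
        )
        extra = {"spatial_range": r_hat}
    else:  # random-intercept
        if not options.group_column or options.group_column not in data.columns:
            raise InvalidArgumentError("random-intercept fit needs a group column")
        res = sm.MixedLM(y, X, groups=data[options.group_column].to_numpy()).fit(
            reml=False
        )
        coef = res.fe_params
        se = res.bse[: X.shape[1]]
        pvals = res.pvalues[: X.shape[1]]
        aic = -2.0 * res.llf + 2.0 * (X.shape[1] + 2)
        extra = {"group_var": float(np.asarray(res.cov_re)[0, 0])}

    idx = pd.Index(names)
    coef = pd.Series(np.asarray(coef)[: len(names)], index=idx)
    se = pd.Series(np.asarray(se)[: len(names)], index=idx)
    pvals = pd.Series(np.asarray(pvals)[: len(names)], index=idx)
    return ResponseFit(
        response=response,
        predictors=tuple(predictors),
        coef=coef[predictors],
        se=se[predictors],
        pvalues=pvals[predictors],
        aic=float(aic),
        n=n,
        extra=extra,
    )


def dsep_basis_set(dag: DagSpec) -> list[tuple[str, str, tuple]]:
    """Independence claims implied by the DAG but untested by the model set.

    Each claim is (x, y, conditioning set) with the conditioning set the
    union of the parents of both variables. Pairs are non-adjacent; pairs
    whose members share an identical parent set are excluded — that covers
    pairs of exogenous drivers (whose association the model leaves free)
    and sibling responses of the same saturated regression, neither of
    which the causal ordering constrains. Claims are ordered
    lexicographically and oriented so the topologically later variable is
    the regression response.
    """
    g = dag.graph()
    order = {node: i for i, node in enumerate(nx.topological_sort(g))}
    claims = []
    nodes = sorted(dag.nodes)
    for i, x in enumerate(nodes):
        for y in nodes[i + 1 :]:
            if g.has_edge(x, y) or g.has_edge(y, x):
                continue
            px, py = set(dag.parents(x)), set(dag.parents(y))
            if px == py:
                continue
            first, second = (x, y) if order[x] <= order[y] else (y, x)
            cond = tuple(sorted(px | py))
            claims.append((first, second, cond))
    claims.sort(key=lambda c: (c[0], c[1]))
    return claims


def fisher_c(claim_pvalues: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's C statistic: C = -2 sum log p_i ~ chi^2 on 2k df."""
    ps = list(claim_pvalues)
    if not ps:
        return 0.0, 0, 1.0
    clamped = []
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise InvalidArgumentError(f"p-value {p} outside [0, 1]")
        if p < PVALUE_FLOOR:
            logger.info("clamping claim p-value %.3g at %.0e", p, PVALUE_FLOOR)
            p = PVALUE_FLOOR
        clamped.append(p)
    c = max(-2.0 * sum(math.log(p) for p in clamped), 0.0)
    df = 2 * len(clamped)
    return float(c), df, float(stats.chi2.sf(c, df))


#: a claim regression whose conditioning set leaves less than this share
#: of the response variance unexplained is treated as deterministic
_DETERMINISTIC_RESIDUAL_TOL = 1e-9


def _claim_pvalue(data, x, y, cond, options) -> float:
    """p-value of x in the regression of y on x plus the conditioning set.

    When the conditioning set already determines y (residual variance
    numerically zero — e.g. community stability, which is an exact linear
    identity of its two parent components), the independence claim holds
    trivially and the p-value is 1: any test statistic computed from pure
    rounding noise would be meaningless.
    """
    if cond:
        Zc = _zscore(data[[y] + list(cond)])
        yy = Zc[y].to_numpy()
        Xc = np.column_stack([np.ones(len(yy)), Zc[list(cond)].to_numpy()])
        beta, *_ = np.linalg.lstsq(Xc, yy, rcond=None)
        resid = yy - Xc @ beta
        if resid @ resid < _DETERMINISTIC_RESIDUAL_TOL * (yy @ yy):
            logger.info(
                "claim (%s, %s | %s): response determined by the "
                "conditioning set; independence holds trivially", x, y, cond
            )
            return 1.0
    fit = fit_response(data, y, [x] + list(cond), options)
    return float(fit.pvalues[x])


def fit_piecewise_sem(
    data: pd.DataFrame, dag: DagSpec | None = None, options: FitOptions | None = None
) -> SemResult:
    """Fit every component regression, test d-separation, aggregate AIC."""
    dag = dag or DagSpec.stability_dag()
    options = options or FitOptions()
    missing = set(dag.nodes) - set(data.columns)
    if missing:
        raise InvalidArgumentError(f"data lacks model variables: {sorted(missing)}")
    keep = [c for c in data.columns if c in dag.nodes
            or c in options.coordinate_columns or c == options.group_column]
    data = data[keep].dropna()
    fits, coef_rows = {}, []
    for response in dag.endogenous:
        fit = fit_response(data, response, dag.parents(response), options)
        fits[response] = fit
        for pred in fit.predictors:
            coef_rows.append(
                {
                    "response": response,
                    "predictor": pred,
                    "coef": float(fit.coef[pred]),
                    "se": float(fit.se[pred]),
                    "pvalue": float(fit.pvalues[pred]),
                }
            )
    claims, claim_ps = [], []
    for x, y, cond in dsep_basis_set(dag):
        p = _claim_pvalue(data, x, y, cond, options)
        claims.append((x, y, cond, p))
        claim_ps.append(p)
    c, df, p = fisher_c(claim_ps)
    return SemResult(
        dag=dag,
        fits=fits,
        coefficients=pd.DataFrame(coef_rows),
        fisher_c=c,
        dsep_df=df,
        dsep_p=p,
        aic=float(sum(f.aic for f in fits.values())),
        claims=claims,
        options=options,
    )


# ---------------------------------------------------------------------------
# path-effect decomposition


@dataclass
class PathDecomposition:
    """Total and mediated standardized effects on community stability.

    ``rows`` maps a row label to a float or to None (rendered "NS" when
    every contributing path contains a nonsignificant edge).
    """

    rows: dict
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "effect_on_community_stability": [
                    "NS" if v is None else v for v in self.rows.values()
                ]
            },
            index=list(self.rows.keys()),
        )


def _significant_edge_weights(result: SemResult, alpha: float) -> dict:
    weights = {}
    for _, row in result.coefficients.iterrows():
        coef = row["coef"] if row["pvalue"] < alpha else 0.0
        weights[(row["predictor"], row["response"])] = float(coef)
    return weights


def _paths(dag: DagSpec, source: str, target: str) -> list[list[str]]:
    return [list(p) for p in nx.all_simple_paths(dag.graph(), source, target)]


def _group_value(paths: list[list[str]], weights: Mapping) -> float | None:
    """Sum of path products; None (NS) when every path has a zeroed edge."""
    if not paths:
        return None
    total, any_live = 0.0, False
    for path in paths:
        prod = 1.0
        live = True
        for edge in zip(path[:-1], path[1:]):
            w = weights[edge]
            prod *= w
            if w == 0.0:
                live = False
        if live:
            any_live = True
        total += prod
    return total if any_live else None


def total_path_effect(
    result: SemResult, source: str, target: str, alpha: float | None = None
) -> float | None:
    """Sum of path strengths over every directed path source -> target.

    A path's strength is the product of its standardized coefficients with
    nonsignificant ones (p >= alpha) zeroed; None when every path contains
    a zeroed edge.
    """
    alpha = result.options.alpha if alpha is None else alpha
    weights = _significant_edge_weights(result, alpha)
    return _group_value(_paths(result.dag, source, target), weights)


def path_effects(
    result: SemResult, dag: DagSpec | None = None, alpha: float | None = None
) -> PathDecomposition:
    """Decompose effects on community stability into the standard ledger.

    Path strength is the product of standardized coefficients along the
    path with any coefficient at p >= alpha zeroed; effects "via" a
    variable group paths by their first mediating node, and totals are the
    sums over the grouped paths (exact by construction).
    """
    dag = dag or result.dag
    alpha = result.options.alpha if alpha is None else alpha
    weights = _significant_edge_weights(result, alpha)
    urban, agri = STABILITY_NODES["gradients"]
    div, phy = STABILITY_NODES["diversity"]
    pop, asy = STABILITY_NODES["components"]
    out = STABILITY_NODES["outcome"]

    def grouped(sources, mediators):
        sel = []
        for s in sources:
            for path in _paths(dag, s, out):
                if path[1] in mediators:
                    sel.append(path)
        return sel

    rows = {
        "Diversity: total effects": grouped((div, phy), (pop, asy)),
        "Diversity: diversity effects": grouped((div,), (pop, asy)),
        "Diversity: phylogenetic diversity effects": grouped((phy,), (pop, asy)),
        "Diversity: effects via population stability": grouped((div, phy), (pop,)),
        "Diversity: effects via population asynchrony": grouped((div, phy), (asy,)),
        "Habitat degradation: total effects": grouped((urban, agri), (div, phy, pop, asy)),
        "Habitat degradation: urban effects": grouped((urban,), (div, phy, pop, asy)),
        "Habitat degradation: agricultural intensity effects": grouped(
            (agri,), (div, phy, pop, asy)
        ),
        "Habitat degradation: effects via diversity and phylogenetic diversity": grouped(
            (urban, agri), (div, phy)
        ),
        "Habitat degradation: effects via population stability": grouped(
            (urban, agri), (pop,)
        ),
        "Habitat degradation: effects via population asynchrony": grouped(
            (urban, agri), (asy,)
        ),
    }
    return PathDecomposition(
        rows={label: _group_value(paths, weights) for label, paths in rows.items()},
        alpha=alpha,
    )


class PiecewiseSEM(BaseEstimator):
    """Estimator interface over :func:`fit_piecewise_sem`.

    Parameters
    ----------
    dag : DagSpec, optional
        Causal structure; defaults to the gradients -> diversity ->
        stability-components -> community-stability DAG.
    error_structure : str
        ``"iid"``, ``"exponential"``, ``"gaussian"`` or
        ``"random-intercept"``.
    alpha : float
        Significance level used to zero edges in the path algebra.
    group : str, optional
        Grouping column for the random-intercept structure.

    Attributes
    ----------
    coefficients_ : DataFrame
        Standardized coefficient, SE and p-value per edge.
    fisher_c_, dsep_df_, dsep_p_ : float, int, float
        Shipley's d-separation test of global fit.
    aic_ : float
        Sum of the component-model AICs.
    """

    def __init__(self, dag: DagSpec | None = None, error_structure: str = "iid",
                 alpha: float = 0.05, group: str | None = None):
        self.dag = dag
        self.error_structure = error_structure
        self.alpha = alpha
        self.group = group

    def fit(self, X: pd.DataFrame, y=None):
        options = FitOptions(
            error_structure=self.error_structure,
            alpha=self.alpha,
            group_column=self.group,
        )
        result = fit_piecewise_sem(X, dag=self.dag, options=options)
        self.result_ = result
        self.coefficients_ = result.coefficients
        self.fisher_c_ = result.fisher_c
        self.dsep_df_ = result.dsep_df
        self.dsep_p_ = result.dsep_p
        self.aic_ = result.aic
        return self

    def path_effects(self, alpha: float | None = None) -> PathDecomposition:
        if not hasattr(self, "result_"):
            raise InvalidArgumentError("PiecewiseSEM is not fitted")
        return path_effects(self.result_, alpha=alpha)


def simulate_sem_data(
    dag: DagSpec,
    coefficients: Mapping,
    n: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Linear-Gaussian data from a DAG with known standardized coefficients.

    ``coefficients`` maps (parent, child) edges to path coefficients.
    Exogenous nodes are independent standard normals; every endogenous
    node's residual variance is set so all variables have unit variance,
    which makes the planted coefficients the true standardized slopes.
    Raises when the requested coefficients imply variance > 1.
    """
    g = dag.graph()
    order = list(nx.topological_sort(g))
    cov = pd.DataFrame(np.eye(len(order)), index=order, columns=order) * 0.0
    data = {}
    for node in order:
        parents = dag.parents(node)
        if not parents:
            data[node] = rng.standard_normal(n)
            cov.loc[node, node] = 1.0
            continue
        beta = np.array([float(coefficients.get((p, node), 0.0)) for p in parents])
        sig_pp = cov.loc[list(parents), list(parents)].to_numpy()
        explained = float(beta @ sig_pp @ beta)
        if explained >= 1.0:
            raise InvalidArgumentError(
                f"coefficients into {node!r} imply variance {explained:.3f} >= 1"
            )
        resid_sd = math.sqrt(1.0 - explained)
        value = sum(b * data[p] for b, p in zip(beta, parents))
        data[node] = value + resid_sd * rng.standard_normal(n)
        # propagate analytic covariances so later nodes stay standardized
        for other in order:
            if other == node:
                continue
            cov.loc[node, other] = cov.loc[other, node] = float(
                beta @ cov.loc[list(parents), other].to_numpy()
            )
        cov.loc[node, node] = 1.0
    return pd.DataFrame(data)


def select_buffer(
    datasets: Mapping[str, pd.DataFrame],
    dag: DagSpec | None = None,
    options: FitOptions | None = None,
) -> tuple[str, dict]:
    """Fit the SEM per buffer variant and pick the lowest summed AIC.

    AICs are only compared within one error-structure family.
    """
    if not datasets:
        raise InvalidArgumentError("no buffer datasets supplied")
    results = {tag: fit_piecewise_sem(df, dag=dag, options=options)
               for tag, df in datasets.items()}
    best = min(sorted(results), key=lambda t: results[t].aic)
    return best, results
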