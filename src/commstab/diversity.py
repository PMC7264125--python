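"""Abundance-weighted taxonomic and phylogenetic diversity per site.

Species diversity is the exponential Shannon index (Hill number of order
1, the effective number of equally abundant species), computed from
abundances summed across all years. Phylogenetic diversity is the mean
pairwise patristic distance (MPD) with pairs weighted by products of
relative abundances. Because weighted MPD correlates with species
diversity, downstream analyses use the residuals of an OLS fit of MPD on
diversity within each dataset ("residual MPD"). Chao1 (bias-corrected)
estimates richness under imperfect detection from singleton/doubleton
counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    DegenerateRegressionError,
    InvalidArgumentError,
    MissingTaxonError,
    UndefinedStatisticError,
)

logger = logging.getLogger(__name__)


@dataclass
class CommunityDiversity:
    """Per-site diversity summary."""

    species_diversity: float
    richness: int
    chao: float
    mpd_weighted: float
    mpd_residual: float | None = None


def load_tree(source) -> dendropy.Tree:
    """Load an ultrametric tree from a path, newick string or Tree."""
    if isinstance(source, dendropy.Tree):
        return source
    source = str(source)
    from dendropy.dataio.newickreader import NewickReader

    try:
        if source.lstrip().startswith("("):
            return dendropy.Tree.get(data=source, schema="newick")
        return dendropy.Tree.get(path=source, schema="newick")
    except NewickReader.NewickReaderDuplicateTaxonError as err:
        raise InvalidArgumentError(f"duplicate tip labels in tree: {err}") from err


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    """True when all root-to-tip distances agree within rel_tol * depth."""
    tree = tree.clone(depth=1)
    tree.calc_node_root_distances(return_leaf_distances_only=True)
    depths = np.array([leaf.root_distance for leaf in tree.leaf_node_iter()])
    depth = depths.max()
    if depth == 0:
        return True
    return bool(np.ptp(depths) <= rel_tol * depth)


def effective_diversity(abundance_totals) -> float:
    """Exponential Shannon index exp(-sum p_i ln p_i); zero totals ignored."""
    totals = np.asarray(list(abundance_totals.values())
                        if isinstance(abundance_totals, Mapping)
                        else abundance_totals, dtype=float)
    if np.any(totals < 0):
        raise InvalidArgumentError("negative abundance totals")
    totals = totals[totals > 0]
    if totals.size == 0:
        raise InvalidArgumentError("all abundance totals are zero")
    p = totals / totals.sum()
    return float(np.exp(-(p * np.log(p)).sum()))


def chao_richness(abundance_totals) -> float:
    """Bias-corrected Chao1: S_obs + F1 (F1 - 1) / (2 (F2 + 1)).

    F1 / F2 are the numbers of species observed exactly once / twice.
    Defined on integer counts only.
    """
    totals = np.asarray(list(abundance_totals.values())
                        if isinstance(abundance_totals, Mapping)
                        else abundance_totals, dtype=float)
    if np.any(totals < 0):
        raise InvalidArgumentError("negative abundance totals")
    if not np.allclose(totals, np.round(totals), atol=1e-9):
        raise InvalidArgumentError("Chao1 requires integer counts")
    totals = np.round(totals).astype(int)
    totals = totals[totals > 0]
    if totals.size == 0:
        raise InvalidArgumentError("all abundance totals are zero")
    s_obs = totals.size
    f1 = int((totals == 1).sum())
    f2 = int((totals == 2).sum())
    return float(s_obs + f1 * (f1 - 1) / (2 * (f2 + 1)))


def patristic_distances(tree) -> pd.DataFrame:
    """Tip-to-tip path-length (patristic) distance matrix as a DataFrame."""
    tree = load_tree(tree)
    labels = [t.label for t in tree.taxon_namespace]
    if len(set(labels)) != len(labels):
        raise InvalidArgumentError("duplicate tip labels in tree")
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    taxa = {t.label: t for t in tree.taxon_namespace}
    mat = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[a], taxa[labels[j]])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


def weighted_mpd(dist: pd.DataFrame, abundance_totals: Mapping, weighted: bool = True) -> float:
    """Mean pairwise distance over distinct pairs, abundance-weighted.

    sum_{i != j} p_i p_j d(i, j) / sum_{i != j} p_i p_j with p the relative
    abundances; with ``weighted=False`` every present species gets equal
    weight (plain mean over unordered pairs).
    """
    present = [s for s, a in abundance_totals.items() if a > 0]
    if len(present) < 2:
        raise UndefinedStatisticError("weighted MPD needs >= 2 species present")
    missing = set(present) - set(dist.index)
    if missing:
        raise MissingTaxonError(missing)
    d = dist.loc[present, present].to_numpy(dtype=float)
    if weighted:
        w = np.array([abundance_totals[s] for s in present], dtype=float)
        p = w / w.sum()
    else:
        p = np.full(len(present), 1.0 / len(present))
    pair_w = np.outer(p, p)
    np.fill_diagonal(pair_w, 0.0)
    return float((pair_w * d).sum() / pair_w.sum())


def residual_mpd(mpd_values, diversity_values) -> np.ndarray:
    """Residuals of an OLS fit (with intercept) of MPD on diversity.

    Fit within one dataset (one taxon) at a time; never pool datasets with
    different correlation structure.
    """
    y = np.asarray(mpd_values, dtype=float)
    x = np.asarray(diversity_values, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise InvalidArgumentError("mpd and diversity must be equal-length vectors")
    if y.size < 3:
        raise InvalidArgumentError("need >= 3 sites to residualize MPD")
    if np.ptp(x) == 0:
        raise DegenerateRegressionError("diversity has zero variance")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def site_diversity_table(
    abundance: pd.DataFrame, tree, weighted_mpd_flag: bool = True
) -> pd.DataFrame:
    """Per-site diversity table from a long abundance table and a tree.

    Chao1 is reported only when summed abundances are integer counts
    (NaN otherwise, with a log note).
    """
    dist = patristic_distances(tree)
    rows = []
    chao_ok = True
    for site_id, g in abundance.groupby("site_id", sort=True):
        totals = g.groupby("species_id")["abundance"].sum()
        totals = totals[totals > 0]
        try:
            chao = chao_richness(totals.to_dict())
        except InvalidArgumentError:
            chao = np.nan
            chao_ok = False
        rows.append(
            {
                "site_id": str(site_id),
                "species_diversity": effective_diversity(totals.to_dict()),
                "richness": int(totals.size),
                "chao": chao,
                "mpd_weighted": weighted_mpd(
                    dist, totals.to_dict(), weighted=weighted_mpd_flag
                )
                if totals.size >= 2
                else np.nan,
            }
        )
    if not chao_ok:
        logger.info("non-integer abundances: Chao1 left as NaN for some sites")
    out = pd.DataFrame(rows)
    usable = out["mpd_weighted"].notna()
    if usable.sum() >= 3 and out.loc[usable, "species_diversity"].nunique() > 1:
        out.loc[usable, "mpd_residual"] = residual_mpd(
            out.loc[usable, "mpd_weighted"], out.loc[usable, "species_diversity"]
        )
    else:
        out["mpd_residual"] = np.nan
    return out
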