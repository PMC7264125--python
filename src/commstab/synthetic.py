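"""Synthetic site x species x year communities with known ground truth.

The generator exists so every downstream stage (stability partition,
diversity metrics, gradient PCA, piecewise SEM) can be tested against a
known causal structure without external monitoring data. It emulates:

* two independent standard-normal latent landscape gradients per site
  (urban, agricultural intensity), observed through eight noisy landscape
  variables with the loading structure the gradient PCA is meant to
  recover;
* gradient-dependent species occupancy and mean abundance, creating the
  gradient -> diversity and gradient -> abundance links;
* lognormal abundance dynamics with a single shared site-level
  environmental factor. For species *i* in year *t*:

      N_it = mu_i * exp(s_i * (a * e_t + sqrt(1 - a^2) * eta_it) - s_i^2 / 2)

  with ``e_t`` a site-level standard-normal year effect shared by all
  species, ``a`` the synchrony loading, ``eta_it`` independent noise and
  ``s_i^2 = log(1 + c * mu_i^(b-2))`` chosen so that exactly
  ``E[N_it] = mu_i`` and ``Var[N_it] = c * mu_i^b`` (Taylor's law with
  exponent b and intercept c). The log-scale correlation between any two
  species is a^2, giving continuous control of the synchrony index;
* a pure-birth ultrametric phylogeny over the species pool, scaled to
  unit depth.

A single global seed feeds a hierarchical stream (tree / landscape /
communities), so each sub-stage is reproducible in isolation.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath

from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)

GRADIENTS = ("urban", "agri")
CHANNELS = ("diversity", "mean_abundance", "population_cv")

#: default causal slopes: habitat degradation lowers diversity and mean
#: abundance and raises population-level variability
DEFAULT_GRADIENT_EFFECTS = {
    ("urban", "diversity"): -0.4,
    ("agri", "diversity"): -0.4,
    ("urban", "mean_abundance"): -0.25,
    ("agri", "mean_abundance"): -0.25,
    ("urban", "population_cv"): 0.15,
    ("agri", "population_cv"): 0.15,
}

#: loading of each landscape variable on (urban latent, agri latent);
#: urban and sealed soil mark the urban axis, cropland and agricultural
#: inputs the agricultural one, with wooded / seminatural / heterogeneous
#: / complex landscapes opposing them
LANDSCAPE_STRUCTURE = {
    "urban": (1.0, 0.0),
    "cropland": (0.0, 1.0),
    "heterogeneous_agriculture": (-0.2, -0.45),
    "woodland": (-0.45, -0.2),
    "seminatural_open": (-0.15, -0.45),
    "sealed_soil": (0.9, 0.0),
    "agricultural_inputs": (0.0, 0.9),
    "landscape_complexity": (-0.3, -0.3),
}

# affine placement keeping percentage variables comfortably inside [0, 100]
_CENTER_SCALE = {
    "urban": (30.0, 5.0),
    "cropland": (30.0, 5.0),
    "heterogeneous_agriculture": (30.0, 5.0),
    "woodland": (30.0, 5.0),
    "seminatural_open": (30.0, 5.0),
    "sealed_soil": (30.0, 5.0),
    "agricultural_inputs": (2.0, 0.3),
    "landscape_complexity": (1.2, 0.15),
}

_PERCENT_VARS = (
    "urban",
    "cropland",
    "heterogeneous_agriculture",
    "woodland",
    "seminatural_open",
    "sealed_soil",
)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror a mid-sized monitoring scheme: ~200 sites, a pool of
    30 species, 11-year series, intermediate synchrony, and the Taylor
    exponent estimated for the most variance-scaled of the three taxa
    (b = 1.61).
    """

    n_sites: int = 200
    n_species_pool: int = 30
    years_per_site: int | list[int] = 11
    synchrony_loading: float = 0.5
    taylor_exponent_b: float = 1.61
    taylor_intercept_c: float = 1.0
    gradient_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_GRADIENT_EFFECTS)
    )
    mean_abundance_range: tuple[float, float] = (5.0, 200.0)
    occupancy_logit_base: float = 1.0
    occupancy_species_sd: float = 0.5
    landscape_noise_sd: float = 0.3
    poisson_observations: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1 or self.n_species_pool < 1:
            raise InvalidArgumentError("counts must be >= 1")
        years = (
            self.years_per_site
            if isinstance(self.years_per_site, int)
            else min(self.years_per_site)
        )
        if years < 3:
            raise InvalidArgumentError("years_per_site must be >= 3")
        if not 0.0 <= self.synchrony_loading <= 1.0:
            raise InvalidArgumentError("synchrony_loading must lie in [0, 1]")
        if self.taylor_exponent_b <= 0 or self.taylor_intercept_c <= 0:
            raise InvalidArgumentError("Taylor parameters must be positive")
        lo, hi = self.mean_abundance_range
        if not (0 < lo <= hi):
            raise InvalidArgumentError("mean_abundance_range must be positive")
        for key in self.gradient_effects:
            g, ch = key
            if g not in GRADIENTS or ch not in CHANNELS:
                raise InvalidArgumentError(f"unknown gradient effect {key!r}")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    latent: pd.DataFrame  # site_id, urban, agri, x, y
    site_species: dict  # site_id -> list of species ids
    site_mu: dict  # site_id -> ndarray of per-species mu_i
    site_sigma2: dict  # site_id -> ndarray of c_site * mu_i^b
    site_c: dict  # site_id -> Taylor intercept after gradient modulation
    synchrony_loading: float
    taylor_exponent_b: float
    expected_phi: dict  # site_id -> analytic synchrony expectation

    def to_json(self, path):
        payload = {
            "synchrony_loading": self.synchrony_loading,
            "taylor_exponent_b": self.taylor_exponent_b,
            "latent": self.latent.to_dict(orient="list"),
            "site_species": self.site_species,
            "site_mu": {k: list(map(float, v)) for k, v in self.site_mu.items()},
            "site_sigma2": {k: list(map(float, v)) for k, v in self.site_sigma2.items()},
            "site_c": self.site_c,
            "expected_phi": self.expected_phi,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _child_seed(seed: int, stream: int) -> int:
    ss = np.random.SeedSequence(seed).spawn(8)[stream]
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def simulate_tree(n_species_pool: int, seed: int) -> dendropy.Tree:
    """Pure-birth ultrametric tree over sp1..spN, scaled to unit depth."""
    if n_species_pool < 2:
        raise InvalidArgumentError("need at least 2 species for a tree")
    rng = random.Random(seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species_pool,
        rng=rng,
    )
    # the process stops exactly at the n-th speciation, leaving zero-length
    # tip edges; extend all tips by a fresh exponential waiting time
    extra = rng.expovariate(n_species_pool)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    # deterministic tip labels sp1..spN
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i}"
    # scale to unit depth and force exact ultrametry on the tip edges
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depth = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += 1.0 - leaf.root_distance
    return tree


def simulate_landscape(
    n_sites: int, seed: int, noise_sd: float = 0.3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Landscape table plus the latent gradient scores that produced it.

    Returns ``(table, latent)``: the table has the eight landscape
    variables and site coordinates, the latent frame the two independent
    standard-normal gradients per site.
    """
    if n_sites < 3:
        raise InvalidArgumentError("need at least 3 sites")
    rng = np.random.default_rng(seed)
    site_ids = [f"site{i + 1}" for i in range(n_sites)]
    urban = rng.standard_normal(n_sites)
    agri = rng.standard_normal(n_sites)
    coords = rng.uniform(0.0, 10.0, size=(n_sites, 2))
    table = {}
    for var, (lu, la) in LANDSCAPE_STRUCTURE.items():
        center, scale = _CENTER_SCALE[var]
        raw = lu * urban + la * agri + noise_sd * rng.standard_normal(n_sites)
        vals = center + scale * raw
        if var in _PERCENT_VARS:
            vals = np.clip(vals, 0.0, 100.0)
        else:
            vals = np.clip(vals, 0.0, None)
        table[var] = vals
    out = pd.DataFrame({"site_id": site_ids, **table})
    out["x"] = coords[:, 0]
    out["y"] = coords[:, 1]
    latent = pd.DataFrame(
        {"site_id": site_ids, "urban": urban, "agri": agri,
         "x": coords[:, 0], "y": coords[:, 1]}
    )
    return out, latent


def expected_synchrony(mu: np.ndarray, c: float, b: float, loading: float) -> float:
    """Closed-form synchrony implied by the lognormal factor model.

    For the generator above, Var(N_i) = c mu_i^b and
    Cov(N_i, N_j) = mu_i mu_j (exp(a^2 s_i s_j) - 1) with
    s_i^2 = log(1 + c mu_i^(b-2)); the synchrony index is
    Var(sum N_i) / (sum sd N_i)^2.
    """
    mu = np.asarray(mu, dtype=float)
    s2 = np.log1p(c * mu ** (b - 2.0))
    s = np.sqrt(s2)
    var_i = c * mu**b
    cov = np.outer(mu, mu) * (np.expm1(loading**2 * np.outer(s, s)))
    np.fill_diagonal(cov, var_i)
    return float(cov.sum() / np.sqrt(var_i).sum() ** 2)


def simulate_communities(
    config: SimulationConfig,
    tree: dendropy.Tree | None = None,
    latent: pd.DataFrame | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the long abundance table and its ground truth.

    ``latent`` is the latent-gradient frame from :func:`simulate_landscape`
    (regenerated if omitted); ``tree`` is only consulted to check the
    species pool is covered.
    """
    seed = config.seed if seed is None else seed
    if latent is None:
        _, latent = simulate_landscape(config.n_sites, _child_seed(seed, 1))
    if tree is not None:
        tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        pool = {f"sp{i + 1}" for i in range(config.n_species_pool)}
        if not pool <= tips:
            raise InvalidArgumentError("tree tips do not cover the species pool")
    rng = np.random.default_rng(_child_seed(seed, 2))
    eff = {**{k: 0.0 for k in DEFAULT_GRADIENT_EFFECTS}, **config.gradient_effects}
    pool = [f"sp{i + 1}" for i in range(config.n_species_pool)]
    lo, hi = config.mean_abundance_range
    # species-level propensities, shared across sites
    species_occ = rng.normal(0.0, config.occupancy_species_sd, len(pool))
    species_logmu = rng.uniform(np.log(lo), np.log(hi), len(pool))
    a = config.synchrony_loading
    b = config.taylor_exponent_b

    records = []
    site_species, site_mu, site_sigma2, site_c, expected_phi = {}, {}, {}, {}, {}
    for site_index, row in enumerate(latent.itertuples(index=False)):
        site, u, g = row.site_id, row.urban, row.agri
        logit = (
            config.occupancy_logit_base
            + eff[("urban", "diversity")] * u
            + eff[("agri", "diversity")] * g
            + species_occ
        )
        p_incl = 1.0 / (1.0 + np.exp(-logit))
        present = rng.random(len(pool)) < p_incl
        if not present.any():
            logger.warning("site %s drew an empty community; dropped", site)
            continue
        sp = [s for s, keep in zip(pool, present) if keep]
        mu = np.exp(
            species_logmu[present]
            + eff[("urban", "mean_abundance")] * u
            + eff[("agri", "mean_abundance")] * g
        )
        c_site = config.taylor_intercept_c * np.exp(
            eff[("urban", "population_cv")] * u
            + eff[("agri", "population_cv")] * g
        )
        s2 = np.log1p(c_site * mu ** (b - 2.0))
        s = np.sqrt(s2)
        n_years = (
            config.years_per_site
            if isinstance(config.years_per_site, int)
            else int(config.years_per_site[site_index % len(config.years_per_site)])
        )
        years = np.arange(1, n_years + 1)
        e_t = rng.standard_normal(n_years)
        eta = rng.standard_normal((len(sp), n_years))
        z = a * e_t[None, :] + np.sqrt(max(0.0, 1.0 - a * a)) * eta
        abundance = mu[:, None] * np.exp(s[:, None] * z - s2[:, None] / 2.0)
        if config.poisson_observations:
            abundance = rng.poisson(abundance).astype(float)
        abundance = np.maximum(abundance, 0.0)
        for i, species in enumerate(sp):
            for j, year in enumerate(years):
                records.append((site, species, int(year), abundance[i, j]))
        site_species[site] = sp
        site_mu[site] = mu
        site_sigma2[site] = c_site * mu**b
        site_c[site] = float(c_site)
        expected_phi[site] = expected_synchrony(mu, c_site, b, a)

    abundance_df = pd.DataFrame(records, columns=["site_id", "species_id", "year", "abundance"])
    truth = GroundTruth(
        latent=latent,
        site_species=site_species,
        site_mu=site_mu,
        site_sigma2=site_sigma2,
        site_c=site_c,
        synchrony_loading=a,
        taylor_exponent_b=b,
        expected_phi=expected_phi,
    )
    return abundance_df, truth


def simulate_dataset(config: SimulationConfig):
    """Full synthetic bundle: tree, landscape table, abundances, truth."""
    tree = simulate_tree(config.n_species_pool, _child_seed(config.seed, 0))
    table, latent = simulate_landscape(
        config.n_sites, _child_seed(config.seed, 1), noise_sd=config.landscape_noise_sd
    )
    abundance, truth = simulate_communities(config, tree=tree, latent=latent)
    return tree, table, abundance, truth


def write_dataset(config: SimulationConfig, out_dir) -> dict:
    """Write abundance TSV, newick tree, landscape CSV and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree, table, abundance, truth = simulate_dataset(config)
    paths = {
        "abundance": out / "abundance.tsv",
        "tree": out / "tree.nwk",
        "landscape": out / "landscape.csv",
        "ground_truth": out / "ground_truth.json",
    }
    abundance.to_csv(paths["abundance"], sep="\t", index=False)
    tree.write(path=str(paths["tree"]), schema="newick", suppress_rooting=True)
    table.to_csv(paths["landscape"], index=False)
    truth.to_json(paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}
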