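# commstab

Tools for asking *why* some animal or plant communities keep a steady
total abundance over the years while others fluctuate wildly, and how
land use and biodiversity shape that stability. The package is aimed at
community ecologists working with multi-site, multi-year monitoring
data (e.g. citizen-science bird, bat or butterfly schemes) together
with a species phylogeny and per-site landscape descriptors.

## What it computes

**Stability partition.** For each site, the coefficient of variation of
total community abundance factors exactly into population synchrony and
abundance-weighted population variability:

```
CV = CV_w · √φ          CV   = sd(Σᵢ Nᵢₜ) / mean(Σᵢ Nᵢₜ)
                        CV_w = Σᵢ (μᵢ/μ)(σᵢ/μᵢ) = Σᵢ σᵢ / μ
                        φ    = σ² / (Σᵢ σᵢ)²        (Loreau–de Mazancourt)
```

and on the negative natural-log scale the partition is additive:

```
community stability = ½ · population asynchrony + weighted mean population stability
```

**Diversity.** Exponential Shannon diversity (Hill number of order 1),
species richness, bias-corrected Chao1, abundance-weighted mean pairwise
phylogenetic distance (MPD) from an ultrametric newick tree, and
residual MPD (MPD residualized on species diversity within a dataset).

**Landscape gradients.** A correlation-matrix PCA of eight landscape
variables followed by a Kaiser-normalized varimax rotation yields an
urban gradient and an agricultural-intensity gradient with
deterministic axis labels and signs; urban scores are log-transformed
as `ln(score − min + 1)`.

**Piecewise SEM.** Five standardized regressions (gradients →
diversities → stability components → community stability), Shipley's
d-separation test of global fit via Fisher's C, AIC-based selection
among buffer variants, and an exact path-effect decomposition (total
effects, effects via diversity, via population stability, via
asynchrony; nonsignificant path groups reported as `NS`). Error
structures: iid, exponential or gaussian spatial GLS, or a random
intercept. Taylor's law (σ² ∝ μ^b) is fit across populations by OLS or
with crossed species/site random intercepts.

**Synthetic data.** A generator with known ground truth — lognormal
abundance dynamics driven by one shared site-level environmental factor
(synchrony loading `a`), exact Taylor scaling `Var(N) = c·μ^b`, species
occupancy and mean abundance tied to two independent latent landscape
gradients, and a pure-birth ultrametric phylogeny — so the whole chain
is testable without external data.

## Worked example

```python
import numpy as np
from commstab import CommunityMatrix, stability_partition

m = CommunityMatrix(
    site_id="meadow-12",
    species=["A", "B", "C"],
    years=[2011, 2012, 2013, 2014, 2015],
    abundance=np.array([
        [12.0,  9.0, 15.0, 11.0, 13.0],
        [ 4.0,  6.0,  3.0,  5.0,  2.0],
        [20.0, 24.0, 18.0, 22.0, 26.0],
    ]),
)
for k, v in stability_partition(m).as_dict().items():
    print(f"{k:36s} {v:.4f}")
```

prints

```
cv_community                         0.0558
cv_w                                 0.1837
phi                                  0.0924
community_stability                  2.8855
population_asynchrony                2.3819
weighted_mean_population_stability   1.6946
```

The community total is far steadier (CV 0.056) than its populations
(weighted mean CV 0.184) because the three species fluctuate nearly out
of phase (φ = 0.09; φ = 1 would mean perfectly parallel dynamics), and
2.8855 = ½ · 2.3819 + 1.6946 exactly.

An end-to-end run on synthetic data (or on your own abundance TSV,
newick tree and landscape CSV via a YAML config):

```
commstab pipeline --simulate --out run --seed 42
```

writes `site_summary.tsv`, gradient loadings, bivariate regression and
SEM coefficient tables, a d-separation report and the path-effect
decomposition, e.g.

```
Habitat degradation: total effects                       -0.778
Habitat degradation: effects via population stability    -0.778
Habitat degradation: effects via population asynchrony       NS
```

meaning that in this simulation the planted destabilizing effect of the
two gradients on community stability travels through lowered population
stability rather than through synchrony. On simulated input the bundle
also contains `ground_truth_report.json` comparing recovered synchrony,
Taylor exponent and gradient scores against what the generator planted.

Other CLI entry points: `commstab simulate`, `commstab metrics
stability`, `commstab metrics diversity`, `commstab gradients`,
`commstab sem` (see `--help`).

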