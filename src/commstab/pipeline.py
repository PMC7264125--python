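"""End-to-end orchestration: filter, metrics, gradients, regressions, SEM.

Stages run in a fixed order: site filtering by series length, stability
partition (degenerate communities excluded with a reason), diversity
metrics, gradient PCA on the retained sites only, bivariate stability
regressions, the piecewise SEM and its path-effect decomposition. Every
stage's table is written to the output directory so a run can be resumed
or audited from its artifacts; a fixed seed yields a byte-identical
bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as div
from . import landscape as lsc
from . import sem as sem_mod
from . import stability as stab
from . import synthetic
from .errors import InvalidArgumentError, PipelineError

logger = logging.getLogger(__name__)

SEM_COLUMNS = [
    "urban_gradient",
    "agri_gradient",
    "species_diversity",
    "phylo_diversity",
    "population_stability",
    "population_asynchrony",
    "community_stability",
]


@dataclass
class PipelineConfig:
    """Inputs and knobs for one pipeline run."""

    abundance_path: str | None = None
    tree_path: str | None = None
    landscape_path: str | None = None
    simulate: synthetic.SimulationConfig | None = None
    min_years: int = 3
    alpha: float = 0.05
    error_structure: str = "iid"
    group_column: str | None = None
    weighted_mpd: bool = True
    taylor_variant: str = "fixed"
    out_dir: str = "commstab_run"
    seed: int = 0

    def __post_init__(self):
        if self.min_years < 3:
            raise InvalidArgumentError("min_years must be >= 3")
        if self.simulate is None:
            for name in ("abundance_path", "tree_path", "landscape_path"):
                path = getattr(self, name)
                if path is None:
                    raise InvalidArgumentError(
                        f"{name} is required when no simulate block is given"
                    )
                if not Path(path).exists():
                    raise InvalidArgumentError(f"{name} does not exist: {path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            effects = sim.pop("gradient_effects", None)
            if effects is not None:
                sim["gradient_effects"] = {
                    tuple(k.split(".")): float(v) for k, v in effects.items()
                }
            sim = synthetic.SimulationConfig(**sim)
        return cls(simulate=sim, **raw)


def filter_sites(
    abundance: pd.DataFrame, min_years: int
) -> tuple[pd.DataFrame, list[dict]]:
    """Keep sites with >= min_years distinct surveyed years; log the rest."""
    if min_years < 3:
        raise InvalidArgumentError("min_years must be >= 3")
    years_per_site = abundance.groupby("site_id")["year"].nunique()
    retained = years_per_site[years_per_site >= min_years].index
    exclusions = [
        {"site_id": str(site), "n_years": int(n), "reason": f"fewer than {min_years} years"}
        for site, n in years_per_site.items()
        if site not in set(retained)
    ]
    for e in exclusions:
        logger.info("excluding site %(site_id)s: %(n_years)d years", e)
    out = abundance[abundance["site_id"].isin(retained)].copy()
    if out.empty:
        raise PipelineError("site filtering removed every site")
    return out, exclusions


def bivariate_stability_models(
    summary: pd.DataFrame, options: sem_mod.FitOptions | None = None
) -> pd.DataFrame:
    """Community stability on the gradients, and on the diversity pair."""
    if len(summary) < 10:
        raise InvalidArgumentError("need >= 10 sites for the bivariate models")
    options = options or sem_mod.FitOptions()
    rows = []
    for label, predictors in (
        ("gradients", ["urban_gradient", "agri_gradient"]),
        ("diversity", ["species_diversity", "phylo_diversity"]),
    ):
        fit = sem_mod.fit_response(summary, "community_stability", predictors, options)
        for pred in predictors:
            rows.append(
                {
                    "model": label,
                    "predictor": pred,
                    "coef": float(fit.coef[pred]),
                    "se": float(fit.se[pred]),
                    "pvalue": float(fit.pvalues[pred]),
                    "n": fit.n,
                }
            )
    return pd.DataFrame(rows)


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        sim = config.simulate
        tree, landscape, abundance, truth = synthetic.simulate_dataset(sim)
        return abundance, tree, landscape, truth
    abundance = pd.read_csv(config.abundance_path, sep="\t")
    tree = div.load_tree(config.tree_path)
    landscape = pd.read_csv(config.landscape_path)
    return abundance, tree, landscape, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns it in memory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        abundance, tree, landscape, truth = _load_inputs(config)

        stage = "filter_sites"
        abundance, exclusions = filter_sites(abundance, config.min_years)

        stage = "stability"
        matrices = stab.matrices_from_long(abundance)
        partition, degenerate = stab.partition_table(matrices)
        exclusions += degenerate
        if partition.empty:
            raise PipelineError("no non-degenerate communities left")
        taylor = stab.mean_variance_scaling(matrices, variant=config.taylor_variant)

        stage = "diversity"
        diversity = div.site_diversity_table(
            abundance, tree, weighted_mpd_flag=config.weighted_mpd
        )

        stage = "gradients"
        retained = sorted(partition["site_id"])
        # a "buffer" column marks alternative landscape extractions; the
        # SEM is fit per buffer and the lowest summed AIC wins
        buffers = (
            sorted(landscape["buffer"].astype(str).unique())
            if "buffer" in landscape.columns
            else [None]
        )
        options = sem_mod.FitOptions(
            error_structure=config.error_structure,
            alpha=config.alpha,
            group_column=config.group_column,
        )
        variants = {}
        for tag in buffers:
            land = landscape if tag is None else landscape[
                landscape["buffer"].astype(str) == tag
            ]
            land = land[land["site_id"].isin(retained)].set_index("site_id")
            gradients = lsc.gradient_pca(land.drop(columns="buffer", errors="ignore"))
            scores = gradients.scores.reset_index().rename(columns={"index": "site_id"})

            summary = (
                partition.merge(diversity, on="site_id", how="inner")
                .merge(scores, on="site_id", how="inner")
                .merge(land.reset_index()[["site_id", "x", "y"]], on="site_id", how="inner")
            )
            summary = summary.rename(
                columns={
                    "mpd_residual": "phylo_diversity",
                    "weighted_mean_population_stability": "population_stability",
                }
            )
            summary = summary.sort_values("site_id").reset_index(drop=True)
            sem_ready = summary.dropna(subset=SEM_COLUMNS)
            if len(sem_ready) < len(summary):
                logger.warning(
                    "dropping %d sites with missing SEM variables",
                    len(summary) - len(sem_ready),
                )
            stage = "sem"
            result = sem_mod.fit_piecewise_sem(sem_ready, options=options)
            variants[tag] = (gradients, summary, sem_ready, result)
            stage = "gradients"

        stage = "sem"
        buffer_aics = {str(tag): var[3].aic for tag, var in variants.items()}
        best = min(sorted(variants, key=str), key=lambda t: variants[t][3].aic)
        gradients, summary, sem_ready, result = variants[best]
        decomposition = sem_mod.path_effects(result)

        stage = "bivariate"
        bivariate = bivariate_stability_models(sem_ready, options)

        stage = "report"
        partition.to_csv(out / "stability_partition.tsv", sep="\t", index=False)
        diversity.to_csv(out / "diversity.tsv", sep="\t", index=False)
        gradients.loadings.to_csv(out / "gradient_loadings.tsv", sep="\t")
        summary.to_csv(out / "site_summary.tsv", sep="\t", index=False)
        bivariate.to_csv(out / "bivariate_models.tsv", sep="\t", index=False)
        result.coefficients.to_csv(out / "sem_coefficients.tsv", sep="\t", index=False)
        decomposition.to_frame().to_csv(out / "path_decomposition.tsv", sep="\t")
        (out / "dsep_report.json").write_text(
            json.dumps(
                {
                    "fisher_c": result.fisher_c,
                    "df": result.dsep_df,
                    "p": result.dsep_p,
                    "aic": result.aic,
                    "claims": [
                        {"x": x, "y": y, "conditioning": list(cond), "p": p}
                        for x, y, cond, p in result.claims
                    ],
                },
                indent=1,
                sort_keys=True,
            )
        )
        run_meta = {
            "seed": config.seed,
            "alpha": config.alpha,
            "error_structure": config.error_structure,
            "min_years": config.min_years,
            "variance_convention": "sample (n-1)",
            "log_base": "natural",
            "rotation": "varimax (Kaiser-normalized)",
            "shannon_log_base": "natural",
            "weighted_mpd": config.weighted_mpd,
            "taylor": {
                "slope_b": taylor.slope_b,
                "slope_se": taylor.slope_se,
                "variant": taylor.fit_variant,
                "n_populations": taylor.n_populations,
            },
            "n_sites_retained": int(len(summary)),
            "buffer_aics": buffer_aics,
            "selected_buffer": str(best),
            "exclusions": exclusions,
        }
        (out / "run_metadata.json").write_text(json.dumps(run_meta, indent=1, sort_keys=True))

        truth_report = None
        if truth is not None:
            measured_phi = partition.set_index("site_id")["phi"]
            expected = pd.Series(truth.expected_phi)
            common = measured_phi.index.intersection(expected.index)
            merged_latent = truth.latent.set_index("site_id").loc[
                [s for s in sem_ready["site_id"]]
            ]
            grad_cor = {
                "urban": float(
                    np.corrcoef(
                        sem_ready["urban_gradient_raw"], merged_latent["urban"]
                    )[0, 1]
                ),
                "agri": float(
                    np.corrcoef(sem_ready["agri_gradient"], merged_latent["agri"])[0, 1]
                ),
            }
            truth_report = {
                "mean_measured_phi": float(measured_phi.loc[common].mean()),
                "mean_expected_phi": float(expected.loc[common].mean()),
                "taylor_slope_true": truth.taylor_exponent_b,
                "taylor_slope_estimated": taylor.slope_b,
                "gradient_score_correlations": grad_cor,
            }
            (out / "ground_truth_report.json").write_text(
                json.dumps(truth_report, indent=1, sort_keys=True)
            )
    except Exception as err:
        raise PipelineError(f"stage {stage!r} failed: {err}") from err

    return {
        "summary": summary,
        "partition": partition,
        "diversity": diversity,
        "gradients": gradients,
        "bivariate": bivariate,
        "sem": result,
        "decomposition": decomposition,
        "taylor": taylor,
        "exclusions": exclusions,
        "truth_report": truth_report,
        "out_dir": str(out),
    }
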