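import itertools
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from commstab import (
    DagSpec,
    FitOptions,
    PiecewiseSEM,
    dsep_basis_set,
    fisher_c,
    fit_piecewise_sem,
    fit_response,
    path_effects,
    simulate_sem_data,
)
from commstab.errors import CollinearityError, InvalidArgumentError
from commstab.sem import total_path_effect

STABILITY_COEFS = {
    ("urban_gradient", "species_diversity"): -0.4,
    ("agri_gradient", "species_diversity"): -0.3,
    ("urban_gradient", "phylo_diversity"): 0.2,
    ("agri_gradient", "phylo_diversity"): -0.2,
    ("urban_gradient", "population_stability"): -0.25,
    ("agri_gradient", "population_stability"): -0.3,
    ("species_diversity", "population_stability"): 0.15,
    ("phylo_diversity", "population_stability"): 0.1,
    ("urban_gradient", "population_asynchrony"): -0.05,
    ("agri_gradient", "population_asynchrony"): -0.1,
    ("species_diversity", "population_asynchrony"): 0.35,
    ("phylo_diversity", "population_asynchrony"): 0.25,
    ("population_stability", "community_stability"): 0.6,
    ("population_asynchrony", "community_stability"): 0.45,
}


def brute_force_paths(edges, source, target):
    """Independent path enumeration by depth-first search over an edge list."""
    children = {}
    for a, b in edges:
        children.setdefault(a, []).append(b)
    paths, stack = [], [[source]]
    while stack:
        path = stack.pop()
        if path[-1] == target:
            paths.append(path)
            continue
        for nxt in children.get(path[-1], []):
            stack.append(path + [nxt])
    return paths


class TestDagSpec:
    def test_cycle_rejected(self):
        with pytest.raises(InvalidArgumentError):
            DagSpec(nodes=("a", "b"), edges=(("a", "b"), ("b", "a")))

    def test_stability_dag_structure(self):
        dag = DagSpec.stability_dag()
        assert dag.exogenous == ("agri_gradient", "urban_gradient")
        assert dag.parents("community_stability") == (
            "population_asynchrony",
            "population_stability",
        )
        assert len(dag.edges) == 14


class TestBasisSet:
    def test_fully_connected_dag_has_empty_basis(self):
        nodes = ("a", "b", "c")
        edges = tuple(itertools.combinations(nodes, 2))
        assert dsep_basis_set(DagSpec(nodes=nodes, edges=edges)) == []

    def test_chain_yields_single_claim(self):
        dag = DagSpec(nodes=("x", "m", "y"), edges=(("x", "m"), ("m", "y")))
        assert dsep_basis_set(dag) == [("x", "y", ("m",))]

    def test_stability_dag_claims(self):
        claims = dsep_basis_set(DagSpec.stability_dag())
        pairs = {(x, y) for x, y, _ in claims}
        assert pairs == {
            ("agri_gradient", "community_stability"),
            ("urban_gradient", "community_stability"),
            ("species_diversity", "community_stability"),
            ("phylo_diversity", "community_stability"),
        }
        cond = dict(((x, y), c) for x, y, c in claims)
        assert cond[("urban_gradient", "community_stability")] == (
            "population_asynchrony",
            "population_stability",
        )
        assert cond[("species_diversity", "community_stability")] == (
            "agri_gradient",
            "population_asynchrony",
            "population_stability",
            "urban_gradient",
        )


class TestFisherC:
    def test_empty_basis_set(self):
        assert fisher_c([]) == (0.0, 0, 1.0)

    def test_two_half_pvalues(self):
        c, df, p = fisher_c([0.5, 0.5])
        assert c == pytest.approx(2.772589, abs=1e-6)
        assert df == 4

    def test_underflow_clamped(self):
        c, df, p = fisher_c([0.0, 1.0])
        assert math.isfinite(c)
        assert c == pytest.approx(-2 * math.log(1e-16), rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fisher_c([1.5])


class TestFitResponse:
    def test_exact_line_gives_unit_standardized_slope(self, rng):
        x = rng.standard_normal(50)
        df = pd.DataFrame({"x": x, "y": 3.0 * x + 5.0})
        fit = fit_response(df, "y", ["x"])
        assert fit.coef["x"] == pytest.approx(1.0, abs=1e-10)
        assert fit.pvalues["x"] < 1e-12

    def test_iid_option_matches_plain_ols(self, rng):
        x = rng.standard_normal(80)
        y = 0.4 * x + rng.standard_normal(80)
        df = pd.DataFrame({"x": x, "y": y})
        fit = fit_response(df, "y", ["x"])
        zx = (x - x.mean()) / x.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        ref = sm.OLS(zy, sm.add_constant(zx)).fit()
        assert fit.coef["x"] == pytest.approx(ref.params[1], abs=1e-12)
        assert fit.pvalues["x"] == pytest.approx(ref.pvalues[1], abs=1e-12)

    def test_type_one_error_near_nominal(self):
        rejections = 0
        reps = 1000
        for i in range(reps):
            r = np.random.default_rng(40_000 + i)
            df = pd.DataFrame(
                {"x": r.standard_normal(60), "y": r.standard_normal(60)}
            )
            rejections += fit_response(df, "y", ["x"]).pvalues["x"] < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.02)

    def test_spatial_gls_recovers_range_and_slope(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(2)
        n, r_true, b_true = 200, 1.0, 0.5
        coords = rng.uniform(0, 5, (n, 2))
        corr = np.exp(-squareform(pdist(coords)) / r_true)
        noise = np.linalg.cholesky(corr) @ rng.standard_normal(n)
        x = rng.standard_normal(n)
        df = pd.DataFrame(
            {"y": b_true * x + 0.8 * noise, "x": x,
             "cx": coords[:, 0], "cy": coords[:, 1]}
        )
        fit = fit_response(
            df, "y", ["x"],
            FitOptions(error_structure="exponential", coordinate_columns=("cx", "cy")),
        )
        # standardized truth: b * sd(x) / sd(y)
        b_std = b_true * df["x"].std() / df["y"].std()
        assert abs(fit.coef["x"] - b_std) < 0.1
        assert 0.5 <= fit.extra["spatial_range"] <= 2.0

    def test_random_intercept_recovers_group_shift(self, rng):
        groups = np.repeat(["g1", "g2"], 50)
        x = rng.standard_normal(100)
        y = 0.5 * x + np.where(groups == "g1", 1.0, -1.0) + 0.3 * rng.standard_normal(100)
        df = pd.DataFrame({"x": x, "y": y, "region": groups})
        fit = fit_response(
            df, "y", ["x"],
            FitOptions(error_structure="random-intercept", group_column="region"),
        )
        assert fit.extra["group_var"] > 0.1
        assert fit.pvalues["x"] < 1e-6

    def test_collinear_design_rejected(self, rng):
        x = rng.standard_normal(30)
        df = pd.DataFrame({"x1": x, "x2": 2 * x, "y": x + rng.standard_normal(30)})
        with pytest.raises(CollinearityError):
            fit_response(df, "y", ["x1", "x2"])


@pytest.fixture(scope="module")
def fitted_sem():
    dag = DagSpec.stability_dag()
    data = simulate_sem_data(dag, STABILITY_COEFS, 269, np.random.default_rng(0))
    return fit_piecewise_sem(data), data


class TestPiecewiseSEM:
    def test_simulated_variables_are_standardized(self):
        dag = DagSpec.stability_dag()
        data = simulate_sem_data(dag, STABILITY_COEFS, 20_000, np.random.default_rng(5))
        assert np.allclose(data.std(ddof=1), 1.0, atol=0.05)

    def test_coefficients_recovered(self, fitted_sem):
        result, _ = fitted_sem
        for (parent, child), truth in STABILITY_COEFS.items():
            est, _ = result.coefficient(parent, child)
            assert abs(est - truth) < 0.15

    def test_dsep_accepts_true_dag(self, fitted_sem):
        result, _ = fitted_sem
        assert result.dsep_df == 8
        assert result.dsep_p > 0.05

    def test_aic_is_sum_of_component_aics(self, fitted_sem):
        result, _ = fitted_sem
        assert result.aic == pytest.approx(sum(f.aic for f in result.fits.values()))

    def test_row_shuffle_invariance(self, fitted_sem):
        result, data = fitted_sem
        shuffled = fit_piecewise_sem(data.sample(frac=1.0, random_state=3))
        assert np.allclose(
            result.coefficients["coef"], shuffled.coefficients["coef"], atol=1e-10
        )
        assert shuffled.fisher_c == pytest.approx(result.fisher_c, abs=1e-10)

    def test_rescaling_raw_variable_changes_nothing(self, fitted_sem):
        result, data = fitted_sem
        scaled = data.copy()
        scaled["species_diversity"] *= 1234.5
        other = fit_piecewise_sem(scaled)
        assert np.allclose(
            result.coefficients["coef"], other.coefficients["coef"], atol=1e-10
        )
        assert other.fisher_c == pytest.approx(result.fisher_c, abs=1e-8)
        a = path_effects(result).rows
        b = path_effects(other).rows
        assert all(
            (a[k] is None and b[k] is None) or abs(a[k] - b[k]) < 1e-10 for k in a
        )

    def test_estimator_interface(self, fitted_sem):
        _, data = fitted_sem
        est = PiecewiseSEM().fit(data)
        assert est.dsep_df_ == 8
        assert {"response", "predictor", "coef", "se", "pvalue"} <= set(
            est.coefficients_.columns
        )
        assert est.get_params()["alpha"] == 0.05
        assert est.path_effects().rows


class TestPathEffects:
    @staticmethod
    def make_result(nodes, edges, coefs, pvalues=None):
        """Assemble a SemResult-like object from exact coefficients."""
        from commstab.sem import ResponseFit, SemResult

        dag = DagSpec(nodes=tuple(nodes), edges=tuple(edges))
        rows = []
        for (a, b), v in coefs.items():
            rows.append(
                {"response": b, "predictor": a, "coef": v, "se": 0.0,
                 "pvalue": (pvalues or {}).get((a, b), 0.001)}
            )
        return SemResult(
            dag=dag, fits={}, coefficients=pd.DataFrame(rows),
            fisher_c=0.0, dsep_df=0, dsep_p=1.0, aic=0.0, claims=[],
            options=FitOptions(),
        )

    def test_chain_effect_is_product(self):
        res = self.make_result(
            ("g", "p", "c"), (("g", "p"), ("p", "c")),
            {("g", "p"): 0.5, ("p", "c"): 0.4},
        )
        assert total_path_effect(res, "g", "c") == pytest.approx(0.2)

    def test_direct_plus_indirect(self):
        res = self.make_result(
            ("g", "p", "c"), (("g", "p"), ("p", "c"), ("g", "c")),
            {("g", "p"): 0.5, ("p", "c"): 0.4, ("g", "c"): 0.1},
        )
        assert total_path_effect(res, "g", "c") == pytest.approx(0.3)

    def test_nonsignificant_edge_zeroes_its_paths(self):
        res = self.make_result(
            ("g", "p", "c"), (("g", "p"), ("p", "c"), ("g", "c")),
            {("g", "p"): 0.5, ("p", "c"): 0.4, ("g", "c"): 0.1},
            pvalues={("p", "c"): 0.5},
        )
        assert total_path_effect(res, "g", "c") == pytest.approx(0.1)

    def test_all_paths_blocked_reports_ns(self):
        res = self.make_result(
            ("g", "p", "c"), (("g", "p"), ("p", "c")),
            {("g", "p"): 0.5, ("p", "c"): 0.4},
            pvalues={("p", "c"): 0.9},
        )
        assert total_path_effect(res, "g", "c") is None

    def test_decomposition_matches_brute_force_enumeration(self, fitted_sem):
        result, _ = fitted_sem
        dag = result.dag
        alpha = 0.05
        sig = {
            (r["predictor"], r["response"]): (r["coef"] if r["pvalue"] < alpha else 0.0)
            for _, r in result.coefficients.iterrows()
        }
        dec = path_effects(result).rows

        def oracle(sources, mediators):
            total = 0.0
            for s in sources:
                for path in brute_force_paths(dag.edges, s, "community_stability"):
                    if path[1] not in mediators:
                        continue
                    total += math.prod(
                        sig[e] for e in zip(path[:-1], path[1:])
                    )
            return total

        div = ("species_diversity", "phylo_diversity")
        grads = ("urban_gradient", "agri_gradient")
        comps = ("population_stability", "population_asynchrony")
        expectations = {
            "Diversity: total effects": oracle(div, comps),
            "Diversity: diversity effects": oracle(div[:1], comps),
            "Diversity: phylogenetic diversity effects": oracle(div[1:], comps),
            "Diversity: effects via population stability": oracle(div, comps[:1]),
            "Diversity: effects via population asynchrony": oracle(div, comps[1:]),
            "Habitat degradation: total effects": oracle(grads, div + comps),
            "Habitat degradation: urban effects": oracle(grads[:1], div + comps),
            "Habitat degradation: agricultural intensity effects": oracle(
                grads[1:], div + comps
            ),
            "Habitat degradation: effects via diversity and phylogenetic diversity": oracle(
                grads, div
            ),
            "Habitat degradation: effects via population stability": oracle(
                grads, comps[:1]
            ),
            "Habitat degradation: effects via population asynchrony": oracle(
                grads, comps[1:]
            ),
        }
        for label, expected in expectations.items():
            got = dec[label]
            if got is None:
                assert expected == pytest.approx(0.0, abs=1e-12)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_totals_equal_sum_of_via_rows_exactly(self, fitted_sem):
        result, _ = fitted_sem
        rows = path_effects(result).rows

        def val(key):
            v = rows[key]
            return 0.0 if v is None else v

        assert val("Diversity: total effects") == pytest.approx(
            val("Diversity: effects via population stability")
            + val("Diversity: effects via population asynchrony"),
            abs=1e-12,
        )
        assert val("Diversity: total effects") == pytest.approx(
            val("Diversity: diversity effects")
            + val("Diversity: phylogenetic diversity effects"),
            abs=1e-12,
        )
        assert val("Habitat degradation: total effects") == pytest.approx(
            val("Habitat degradation: effects via diversity and phylogenetic diversity")
            + val("Habitat degradation: effects via population stability")
            + val("Habitat degradation: effects via population asynchrony"),
            abs=1e-12,
        )
        assert val("Habitat degradation: total effects") == pytest.approx(
            val("Habitat degradation: urban effects")
            + val("Habitat degradation: agricultural intensity effects"),
            abs=1e-12,
        )


class TestBufferSelection:
    def test_signal_buffer_wins_by_aic(self):
        from commstab.sem import select_buffer

        dag = DagSpec.stability_dag()
        wins = 0
        reps = 30
        for i in range(reps):
            rng = np.random.default_rng(7000 + i)
            signal = simulate_sem_data(dag, STABILITY_COEFS, 150, rng)
            datasets = {"b500": signal}
            for tag in ("b250", "b1000"):
                noisy = signal.copy()
                # degrade the gradients: replace with pure noise
                noisy["urban_gradient"] = rng.standard_normal(len(signal))
                noisy["agri_gradient"] = rng.standard_normal(len(signal))
                datasets[tag] = noisy
            best, _ = select_buffer(datasets, dag=dag)
            wins += best == "b500"
        assert wins / reps >= 0.8
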