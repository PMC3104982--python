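import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from arrayvar import (
    ArrayDesign,
    DesignMatrixBundle,
    RemlProblem,
    SimulationConfig,
    build_design_matrices,
    build_paper_design,
    fit_all,
    fit_gene,
    fits_frame,
    lps_response_variance,
    simulate_expression,
    subtraction_estimate,
)
from arrayvar.varcomp import test_lps_effect as lps_effect_test
from arrayvar.design import COMPONENTS
from arrayvar.simdata import study_condition_sds

PAPER_SD = study_condition_sds()


def one_way_bundle(n_groups: int, reps: int) -> DesignMatrixBundle:
    """Balanced one-way random-effects layout: intercept + group + residual."""
    n = n_groups * reps
    return DesignMatrixBundle(
        array_ids=[f"a{i}" for i in range(n)],
        X=np.ones((n, 1)),
        fixed_names=["intercept"],
        groupings={
            "subject": np.repeat(np.arange(n_groups), reps),
            "residual": np.arange(n),
        },
        n_levels={"subject": n_groups, "residual": n},
    )


def small_design():
    """Two subjects x two days, 12 arrays, no extra replicates."""
    return build_paper_design(2, 0)


class TestFitGene:
    def test_constant_response_gives_all_zero_components(self, paper_bundle):
        y = np.full(paper_bundle.n_arrays, 1.7)
        fit = fit_gene(y, paper_bundle, gene_id="const")
        assert all(v == 0.0 for v in fit.sigma2.values())
        assert fit.beta["intercept"] == pytest.approx(1.7)
        assert fit.converged

    def test_grid_search_oracle_two_component_instance(self):
        # brute-force maximization of the explicitly coded REML criterion
        # over a dense variance grid cannot beat the optimizer
        design = small_design()  # 12 arrays, no technical replication
        bundle = build_design_matrices(design)
        problem = RemlProblem(bundle, ("day", "residual"))
        cfg = SimulationConfig(
            n_genes=3,
            true_sd={"day": 0.3, "residual": 0.25},
            baseline_sd=0.5, seed=21,
        )
        matrix, _ = simulate_expression(design, cfg)
        grid = np.arange(0.0, 0.41, 0.01)
        for i in range(3):
            y = matrix.M.iloc[i].to_numpy()
            fit = fit_gene(y, bundle, problem=problem)
            theta_hat = np.array([fit.sigma2[c] for c in problem.free])
            f_hat = problem.neg2reml(theta_hat, y, gradient=False)
            best = min(
                problem.neg2reml(np.array(t), y, gradient=False)
                for t in itertools.product(grid, repeat=len(problem.free))
            )
            assert f_hat <= best + 1e-6

    def test_grid_search_oracle_three_component_instance(self):
        # 9-array fully replicated single-subject design separates the
        # three technical components; same grid oracle, step 0.01
        design = build_paper_design(1, 1)
        assert len(design) <= 12
        with pytest.warns(UserWarning, match="aliased"):
            bundle = build_design_matrices(design)
        problem = RemlProblem(bundle, ("stim", "amp", "residual"))
        assert problem.free == ("stim", "amp", "residual")
        cfg = SimulationConfig(
            n_genes=2,
            true_sd={"stim": 0.25, "amp": 0.2, "residual": 0.15},
            baseline_sd=0.5, seed=41,
        )
        matrix, _ = simulate_expression(design, cfg)
        grid = np.arange(0.0, 0.31, 0.01)
        for i in range(2):
            y = matrix.M.iloc[i].to_numpy()
            fit = fit_gene(y, bundle, problem=problem)
            theta_hat = np.array([fit.sigma2[c] for c in problem.free])
            f_hat = problem.neg2reml(theta_hat, y, gradient=False)
            best = min(
                problem.neg2reml(np.array(t), y, gradient=False)
                for t in itertools.product(grid, repeat=3)
            )
            assert f_hat <= best + 1e-6

    def test_balanced_design_matches_anova_estimators(self):
        # classical equivalence: in a balanced one-way layout REML equals
        # the method-of-moments ANOVA estimators when those are positive
        rng = np.random.default_rng(31)
        bundle = one_way_bundle(6, 4)
        for _ in range(5):
            groups = rng.normal(0, 0.6, 6)
            y = np.repeat(groups, 4) + rng.normal(0, 0.3, 24)
            fit = fit_gene(y, bundle, components=("subject", "residual"))
            means = y.reshape(6, 4).mean(axis=1)
            msa = 4 * np.var(means, ddof=1)
            mse = np.mean(np.var(y.reshape(6, 4), axis=1, ddof=1))
            sa = (msa - mse) / 4
            if sa > 0:
                assert fit.sigma2["subject"] == pytest.approx(sa, rel=1e-4, abs=1e-8)
                assert fit.sigma2["residual"] == pytest.approx(mse, rel=1e-4, abs=1e-8)

    def test_reml_optimum_is_local_maximum(self, paper_bundle):
        cfg = SimulationConfig(n_genes=2, true_sd=PAPER_SD, lps_effect_sd=1.0,
                               lps_effect_nonzero_fraction=1.0, seed=22)
        matrix, _ = simulate_expression(build_paper_design(5, 2), cfg)
        problem = RemlProblem(paper_bundle)
        for i in range(2):
            y = matrix.M.iloc[i].to_numpy()
            fit = fit_gene(y, paper_bundle, problem=problem)
            theta = np.array([fit.sigma2[c] for c in problem.free])
            f0 = problem.neg2reml(theta, y, gradient=False)
            delta = 1e-4
            for k in range(len(theta)):
                for sign in (+1, -1):
                    pert = theta.copy()
                    pert[k] += sign * delta
                    if pert[k] < 0:
                        continue
                    assert problem.neg2reml(pert, y, gradient=False) >= f0 - 1e-7

    def test_shift_invariance(self, paper_bundle):
        cfg = SimulationConfig(n_genes=1, true_sd=PAPER_SD, seed=23)
        matrix, _ = simulate_expression(build_paper_design(5, 2), cfg)
        y = matrix.M.iloc[0].to_numpy()
        f1 = fit_gene(y, paper_bundle)
        f2 = fit_gene(y + 2.5, paper_bundle)
        for c in COMPONENTS:
            assert f2.sigma2[c] == pytest.approx(f1.sigma2[c], abs=1e-6)
        assert f2.beta["intercept"] - f1.beta["intercept"] == pytest.approx(2.5, abs=1e-6)
        assert f2.beta["lps"] == pytest.approx(f1.beta["lps"], abs=1e-6)

    def test_analytic_gradient_matches_finite_differences(self, paper_bundle):
        rng = np.random.default_rng(24)
        problem = RemlProblem(paper_bundle)
        y = rng.normal(0, 0.3, paper_bundle.n_arrays)
        theta = rng.uniform(0.01, 0.1, len(problem.free))
        f0, g = problem.neg2reml(theta, y)
        eps = 1e-6
        for k in range(len(theta)):
            pert = theta.copy()
            pert[k] += eps
            fd = (problem.neg2reml(pert, y, gradient=False) - f0) / eps
            assert fd == pytest.approx(g[k], rel=5e-3, abs=1e-4)

    def test_unidentifiable_components_fixed_at_zero(self):
        mk = lambda aid, lps, tube, hyb: ArrayDesign(aid, "A", 1, lps, tube, 1, hyb, "M")
        design = [
            mk("u", 0, None, 1),
            mk("s1", 1, 1, 1), mk("s1b", 1, 1, 2),
            mk("s2", 1, 2, 1), mk("s2b", 1, 2, 2),
        ]
        with pytest.warns(UserWarning):
            bundle = build_design_matrices(design)
        assert {"subject", "day"} <= bundle.unidentifiable
        y = np.array([0.1, 0.5, 0.6, 0.4, 0.3])
        fit = fit_gene(y, bundle)
        assert fit.sigma2["subject"] == 0.0
        assert "subject" in fit.unidentifiable

    def test_non_finite_input_rejected(self, paper_bundle):
        y = np.zeros(paper_bundle.n_arrays)
        y[0] = np.nan
        with pytest.raises(ValueError):
            fit_gene(y, paper_bundle)


class TestFitAll:
    def test_empty_matrix_gives_empty_result(self, paper_bundle):
        M = pd.DataFrame(columns=paper_bundle.array_ids)
        assert fit_all(M, paper_bundle) == []

    def test_single_gene_matches_fit_gene(self, paper_bundle):
        cfg = SimulationConfig(n_genes=1, true_sd=PAPER_SD, seed=25)
        matrix, _ = simulate_expression(build_paper_design(5, 2), cfg)
        fits = fit_all(matrix, paper_bundle)
        solo = fit_gene(matrix.M.iloc[0].to_numpy(), paper_bundle,
                        gene_id=matrix.M.index[0])
        assert len(fits) == 1
        assert fits[0].sigma2 == solo.sigma2
        assert fits[0].gene_id == solo.gene_id

    def test_frame_export_has_all_columns(self, paper_bundle):
        cfg = SimulationConfig(n_genes=3, true_sd=PAPER_SD, seed=26)
        matrix, _ = simulate_expression(build_paper_design(5, 2), cfg)
        frame = fits_frame(fit_all(matrix, paper_bundle))
        for c in COMPONENTS:
            assert f"sigma2_{c}" in frame.columns
            assert f"sd_{c}" in frame.columns
        assert {"beta_lps", "se_lps", "converged"} <= set(frame.columns)


class TestSubtractionEstimate:
    def test_paper_identity(self):
        comps, floored = subtraction_estimate({"hyb": 0.01, "amp": 0.0125})
        assert comps["amp"] == pytest.approx(0.0025)
        assert comps["hyb"] == pytest.approx(0.01)
        assert not floored

    def test_equal_adjacent_levels_give_zero_component(self):
        comps, _ = subtraction_estimate({"hyb": 0.02, "amp": 0.02, "stim": 0.05})
        assert comps["amp"] == 0.0
        assert comps["stim"] == pytest.approx(0.03)

    def test_negative_difference_floored_and_reported(self):
        comps, floored = subtraction_estimate({"hyb": 0.03, "amp": 0.02})
        assert comps["amp"] == 0.0
        assert floored["amp"] == pytest.approx(0.01)

    def test_errors(self):
        with pytest.raises(ValueError):
            subtraction_estimate({})
        with pytest.raises(ValueError):
            subtraction_estimate({"hyb": -0.1})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 5, allow_nan=False), min_size=1, max_size=6))
    def test_components_reconstruct_totals(self, totals):
        totals_map = {f"L{i}": t for i, t in enumerate(totals)}
        comps, floored = subtraction_estimate(totals_map)
        assert all(v >= 0 for v in comps.values())
        # cumulative sums of components reproduce totals up to flooring
        run = 0.0
        for lvl in totals_map:
            run += comps[lvl]
            assert run >= totals_map[lvl] - 1e-9 or lvl in floored or run == pytest.approx(
                max(totals_map[lvl], run), rel=1e-9
            )

    def test_agrees_with_reml_on_balanced_simulation(self, paper_design, paper_bundle):
        # pooled replicate-contrast variances, peeled by subtraction, agree
        # with the across-gene mean REML components for the technical
        # levels when the fitted model matches the generating one
        sd = {"stim": 0.3, "amp": 0.25, "residual": 0.2}
        ng = 800
        cfg = SimulationConfig(n_genes=ng, true_sd=sd, baseline_sd=0.0, seed=27)
        matrix, _ = simulate_expression(paper_design, cfg, bundle=paper_bundle)
        M = matrix.M
        totals = {
            "residual": float(np.var((M["Ad1L1t1a1h1"] - M["Ad1L1t1a1h2"]) / np.sqrt(2), ddof=1)),
            "amp": float(np.var((M["Ad1L1t1a1h1"] - M["Ad1L1t1a2h1"]) / np.sqrt(2), ddof=1)),
            "stim": float(np.var((M["Ad1L1t1a1h1"] - M["Ad1L1t2a1h1"]) / np.sqrt(2), ddof=1)),
        }
        comps, _ = subtraction_estimate(totals)
        fits = fit_all(matrix, paper_bundle, components=("stim", "amp", "residual"))
        # each pooled contrast variance has MC SE ~ total * sqrt(2/(ng-1));
        # the peeled component inherits the SEs of two adjacent totals
        true_totals = {
            "residual": sd["residual"] ** 2,
            "amp": sd["residual"] ** 2 + sd["amp"] ** 2,
            "stim": sd["residual"] ** 2 + sd["amp"] ** 2 + sd["stim"] ** 2,
        }
        mc = np.sqrt(2.0 / (ng - 1))
        prev = 0.0
        for level in ("residual", "amp", "stim"):
            tol = 3 * mc * (true_totals[level] + prev)
            prev = true_totals[level]
            reml_mean = float(np.mean([f.sigma2[level] for f in fits]))
            assert comps[level] == pytest.approx(sd[level] ** 2, abs=tol)
            assert reml_mean == pytest.approx(comps[level], abs=tol)


class TestLpsResponseVariance:
    def make_fit(self, values):
        from arrayvar.varcomp import VarCompFit
        return VarCompFit("g", dict(zip(COMPONENTS, values)), {}, {}, 0.0, True)

    def test_zero_components_sum_to_zero(self):
        assert lps_response_variance(self.make_fit([0.0] * 7)) == 0.0

    def test_additivity_over_all_components(self):
        assert lps_response_variance(self.make_fit([0.01] * 7)) == pytest.approx(0.07)

    def test_biological_technical_partition(self):
        fit = self.make_fit([0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07])
        bio = lps_response_variance(fit, include=("subject", "day"))
        tech = lps_response_variance(fit, include=("stim", "amp", "residual"))
        inter = lps_response_variance(fit, include=("subject_lps", "day_lps"))
        assert bio + tech + inter == pytest.approx(lps_response_variance(fit))

    def test_unknown_component_rejected(self):
        with pytest.raises(ValueError):
            lps_response_variance(self.make_fit([0.0] * 7), include=("bogus",))


class TestLpsEffectTest:
    def test_single_huge_effect_flagged(self, paper_design, paper_bundle):
        ng = 60
        eff = np.zeros(ng)
        cfg = SimulationConfig(n_genes=ng, true_sd={"residual": 0.05},
                               baseline_sd=0.0, seed=28)
        matrix, _ = simulate_expression(paper_design, cfg, bundle=paper_bundle)
        stim_cols = [a.array_id for a in paper_design if a.lps == 1]
        matrix.M.iloc[0, [matrix.M.columns.get_loc(c) for c in stim_cols]] += 3.0
        fits = fit_all(matrix, paper_bundle)
        table = lps_effect_test(fits, fdr=0.05)
        assert bool(table.loc[table.gene_id == matrix.M.index[0], "significant"].iloc[0])
        # the spiked gene dominates; at most stray false positives appear
        assert int(table["significant"].sum()) <= 3
        top = table.sort_values("p").iloc[0]
        assert top["gene_id"] == matrix.M.index[0]

    def test_null_simulation_controls_false_discoveries(self, paper_design, paper_bundle):
        cfg = SimulationConfig(n_genes=400, true_sd=PAPER_SD, lps_effect_sd=0.0,
                               baseline_sd=1.0, seed=29)
        matrix, _ = simulate_expression(paper_design, cfg, bundle=paper_bundle)
        table = lps_effect_test(fit_all(matrix, paper_bundle), fdr=0.05)
        # under the complete null any rejection is false; BH keeps the
        # family-wise rate near the nominal level
        assert table["significant"].mean() <= 0.02

    def test_monotone_in_z(self, paper_design, paper_bundle):
        cfg = SimulationConfig(n_genes=80, true_sd=PAPER_SD, lps_effect_sd=1.0,
                               lps_effect_nonzero_fraction=0.5, seed=30)
        matrix, _ = simulate_expression(paper_design, cfg, bundle=paper_bundle)
        table = lps_effect_test(fit_all(matrix, paper_bundle))
        ordered = table.sort_values("p")
        absz = ordered["z"].abs().to_numpy()
        p = ordered["p"].to_numpy()
        # |z| decreases wherever p strictly increases (p underflows tie at 0)
        ok = (np.diff(absz) <= 1e-9) | (np.diff(p) == 0)
        assert ok.all()

    def test_invalid_fdr_rejected(self):
        with pytest.raises(ValueError):
            lps_effect_test([], fdr=1.5)
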