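"""Analysis-center model fitting: Gram assembly, normal-equations OLS,
distributed IRLS, convergence classification, and oracle comparison."""

import numpy as np
import pandas as pd
import pytest

from vdra import (
    BlockPlan,
    CohortSpec,
    ConvergenceSpec,
    Covariate,
    GramBlock,
    IterationState,
    PartitionPlan,
    RegressionResult,
    SitePartition,
    assemble_global_gram,
    blocked_cross_product,
    compare_results,
    convergence_check,
    fit_linear_distributed,
    fit_logistic_distributed,
    generate_cohort,
    gram_self,
    partition_vertical,
    pooled_oracle_fit,
    secure_cross_product,
)
from vdra.errors import (
    CollinearityError,
    ComparisonError,
    DomainError,
    IncompleteBlocksError,
)
from vdra.secure import pair_seed

from conftest import random_partition_pair


def gram_from_partitions(parts, plan, seed=0, block_plan=None):
    """GlobalGram for a linear model via the secure protocol (the same path
    the networked workflow takes, minus the file fabric)."""
    from vdra import build_linear_gram

    return build_linear_gram(
        parts, (plan.outcome_site, plan.outcome_column), seed=seed, block_plan=block_plan)


class TestAssembleGlobalGram:
    def test_two_site_scenario_dimensions(self, bmi_partitions, bmi_plan):
        gram = gram_from_partitions(bmi_partitions, bmi_plan)
        assert gram.G.shape == (4, 4)  # intercept + surgery/sex/race
        assert gram.column_order[0] == "(Intercept)"
        assert gram.G[0, 0] == bmi_partitions[0].n

    def test_assembled_gram_matches_pooled_design(self, bmi_table, bmi_partitions, bmi_plan):
        gram = gram_from_partitions(bmi_partitions, bmi_plan)
        X = np.column_stack([np.ones(bmi_table.n), bmi_table.matrix(["surgery", "sex", "race"])])
        y = bmi_table.matrix(["bmi"]).ravel()
        np.testing.assert_allclose(gram.G, X.T @ X, atol=1e-9)
        np.testing.assert_allclose(gram.Xty, X.T @ y, atol=1e-9)
        assert gram.yty == pytest.approx(float(y @ y))

    def test_missing_off_diagonal_block_names_the_pair(self):
        a, b = random_partition_pair(20, 2, 1, seed=1)
        blocks = [gram_self(a), gram_self(b)]
        with pytest.raises(IncompleteBlocksError, match="site_a.*site_b"):
            assemble_global_gram(
                blocks,
                [("site_a", a.columns), ("site_b", b.columns)],
                n=20,
                column_sums={"site_a": a.matrix().sum(0), "site_b": b.matrix().sum(0)},
                y_blocks={"site_a": np.zeros(2), "site_b": np.zeros(1)},
                y_sum=0.0,
                yty=0.0,
            )


class TestFitLinearDistributed:
    def test_noiseless_cohort_recovers_exact_coefficients(self):
        spec = CohortSpec(
            n_patients=60,
            covariates=(Covariate("x", "continuous"),),
            outcome_model="linear",
            true_beta=(0.0, 2.0),
            noise_sd=0.0,
            seed=21,
        )
        table = generate_cohort(spec)
        plan = PartitionPlan(("s1", "s2"), {"x": "s1", "y": "s2"}, "s2")
        gram = gram_from_partitions(partition_vertical(table, plan), plan)
        res = fit_linear_distributed(gram)
        np.testing.assert_allclose(res.beta, [0.0, 2.0], atol=1e-10)
        assert res.fit["sigma2"] == pytest.approx(0.0, abs=1e-10)

    def test_duplicated_covariate_across_sites_raises_collinearity(self):
        rng = np.random.default_rng(0)
        n = 30
        x = rng.standard_normal(n)
        ids = np.arange(1, n + 1)
        a = SitePartition("s1", pd.DataFrame({"patient_id": ids, "x": x}))
        b = SitePartition("s2", pd.DataFrame({"patient_id": ids, "x_copy": x, "y": x + 1}))
        plan = PartitionPlan(("s1", "s2"), {"x": "s1", "x_copy": "s2", "y": "s2"}, "s2")
        gram = gram_from_partitions([a, b], plan)
        with pytest.raises(CollinearityError):
            fit_linear_distributed(gram)

    def test_matches_pooled_ols_at_printed_precision(self, bmi_table, bmi_partitions, bmi_plan):
        gram = gram_from_partitions(bmi_partitions, bmi_plan)
        res = fit_linear_distributed(gram)
        oracle = pooled_oracle_fit(bmi_table, "linear", ["surgery", "sex", "race"], "bmi")
        report = compare_results(res, oracle, tol=1e-12)
        assert report.passed

    def test_permutation_invariance(self, bmi_table, bmi_plan):
        # identically permuting rows at all sites leaves the fit unchanged
        perm = np.random.default_rng(3).permutation(bmi_table.n)
        permuted_table = type(bmi_table)(bmi_table.data.iloc[perm].reset_index(drop=True))
        base = fit_linear_distributed(
            gram_from_partitions(partition_vertical(bmi_table, bmi_plan), bmi_plan))
        perm_res = fit_linear_distributed(
            gram_from_partitions(partition_vertical(permuted_table, bmi_plan), bmi_plan))
        assert np.max(np.abs(base.beta - perm_res.beta)) <= 1e-12
        assert np.max(np.abs(base.se - perm_res.se)) <= 1e-12

    def test_block_invariance(self, bmi_partitions, bmi_plan):
        n = bmi_partitions[0].n
        unblocked = fit_linear_distributed(gram_from_partitions(bmi_partitions, bmi_plan))
        blocked = fit_linear_distributed(
            gram_from_partitions(bmi_partitions, bmi_plan, block_plan=BlockPlan.even(n, 4)))
        assert np.max(np.abs(unblocked.beta - blocked.beta)) <= 1e-12
        assert np.max(np.abs(unblocked.se - blocked.se)) <= 1e-12

    def test_equivalence_over_seeded_cohort_suite(self):
        # linear distributed fits match the pooled oracle at 1e-12 across
        # cohort sizes, covariate counts and site splits
        for n, p, n_sites, seed in [(500, 3, 2, 1), (500, 10, 3, 2), (800, 10, 2, 3)]:
            covs = tuple(Covariate(f"x{i}", "continuous") for i in range(p))
            beta = (0.5,) + tuple(((-1) ** i) * 0.3 for i in range(p))
            spec = CohortSpec(n, covs, "linear", beta, 1.0, seed)
            table = generate_cohort(spec)
            sites = tuple(f"s{k}" for k in range(n_sites))
            assignment = {f"x{i}": sites[i % (n_sites - 1)] for i in range(p)}
            assignment["y"] = sites[-1]
            plan = PartitionPlan(sites, assignment, sites[-1])
            gram = gram_from_partitions(partition_vertical(table, plan), plan, seed=seed)
            res = fit_linear_distributed(gram)
            # pooled fit in the distributed (site-grouped) column order
            ordered = [c for c in gram.column_order if c != "(Intercept)"]
            oracle = pooled_oracle_fit(table, "linear", ordered, "y")
            report = compare_results(res, oracle, tol=1e-12)
            assert report.passed, (n, p, n_sites, report.max_abs_diff_beta)


class TestFitLogisticDistributed:
    def test_matches_pooled_irls_oracle(self, logistic_table, logistic_partitions):
        res = fit_logistic_distributed(logistic_partitions, ("site2", "y"), seed=5)
        oracle = pooled_oracle_fit(
            logistic_table, "logistic", [f"x{i}" for i in range(1, 6)], "y")
        report = compare_results(res, oracle, tol=1e-8)
        assert report.passed
        assert res.converged

    def test_deviance_non_increasing_across_iterations(self, logistic_partitions):
        # IRLS monotonicity on a well-separated-free problem
        trace = []
        fit_logistic_distributed(
            logistic_partitions, ("site2", "y"), seed=5, deviance_trace=trace)
        assert len(trace) >= 2
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_warm_start_at_converged_solution_is_a_fixed_point(self, logistic_partitions):
        res = fit_logistic_distributed(logistic_partitions, ("site2", "y"), seed=5)
        again = fit_logistic_distributed(
            logistic_partitions, ("site2", "y"), seed=5, beta_init=res.beta)
        assert again.converged and again.n_iter <= 2
        assert np.max(np.abs(again.beta - res.beta)) <= 1e-8

    def test_max_iter_one_reports_max_iter_reached(self, logistic_partitions):
        res = fit_logistic_distributed(
            logistic_partitions, ("site2", "y"),
            conv=ConvergenceSpec(tol=1e-300, max_iter=1), seed=5)
        assert not res.converged
        assert res.termination_reason == "max-iter-reached"
        assert res.n_iter == 1

    def test_non_binary_outcome_rejected(self, bmi_partitions):
        with pytest.raises(DomainError):
            fit_logistic_distributed(bmi_partitions, ("site2", "bmi"), seed=0)

    def test_weights_lie_in_unit_quarter_interval(self, logistic_partitions):
        # IRLS weights mu(1-mu) are bounded by 1/4 and strictly positive
        from vdra.secure import InMemoryChannel

        channel = InMemoryChannel()
        fit_logistic_distributed(logistic_partitions, ("site2", "y"), seed=5, channel=channel)
        weight_msgs = [s for _f, _t, lbl, s in channel.transcript if lbl == "irls-weights"]
        assert weight_msgs  # the center broadcast weights each iteration


class TestConvergenceCheck:
    def make_states(self, delta, it=1):
        prev = IterationState(it - 1, np.zeros(2))
        new = IterationState(it, np.full(2, delta))
        return prev, new

    def test_small_delta_converges(self):
        prev, new = self.make_states(1e-9)
        assert convergence_check(prev, new, ConvergenceSpec(tol=1e-8, max_iter=10)) == "converged"

    def test_large_delta_at_max_iter(self):
        prev, new = self.make_states(1e-3, it=10)
        status = convergence_check(prev, new, ConvergenceSpec(tol=1e-8, max_iter=10))
        assert status == "max-iter-reached"

    def test_delta_equal_to_tol_continues(self):
        # strict inequality at the boundary
        prev, new = self.make_states(1e-8)
        assert convergence_check(prev, new, ConvergenceSpec(tol=1e-8, max_iter=10)) == "continue"

    def test_relative_deviance_criterion(self):
        prev = IterationState(1, np.zeros(2), deviance=100.0)
        new = IterationState(2, np.ones(2), deviance=100.0 + 1e-9)
        conv = ConvergenceSpec(tol=1e-8, max_iter=10, criterion="relative-deviance-change")
        assert convergence_check(prev, new, conv) == "converged"


class TestOracleAndComparison:
    def test_oracle_r2_in_unit_interval(self, bmi_table):
        res = pooled_oracle_fit(bmi_table, "linear", ["surgery", "sex", "race"], "bmi")
        assert 0.0 <= res.fit["R2"] <= 1.0

    def test_identical_results_pass_with_zero_difference(self, bmi_table):
        res = pooled_oracle_fit(bmi_table, "linear", ["surgery", "sex", "race"], "bmi")
        report = compare_results(res, res, tol=1e-12)
        assert report.passed
        assert report.max_abs_diff_beta == 0.0

    def test_small_difference_fails_tight_tolerance_and_names_term(self, bmi_table):
        res = pooled_oracle_fit(bmi_table, "linear", ["surgery", "sex", "race"], "bmi")
        other = RegressionResult(
            model=res.model, column_order=res.column_order,
            beta=res.beta + np.array([0, 1e-6, 0, 0]), se=res.se,
            cov_beta=res.cov_beta, fit=res.fit, n=res.n, p=res.p)
        report = compare_results(res, other, tol=1e-12)
        assert not report.passed
        assert report.worst_term == "surgery"

    def test_mismatched_column_order_rejected(self, bmi_table):
        res = pooled_oracle_fit(bmi_table, "linear", ["surgery", "sex", "race"], "bmi")
        other = pooled_oracle_fit(bmi_table, "linear", ["race", "sex", "surgery"], "bmi")
        with pytest.raises(ComparisonError):
            compare_results(res, other)

    def test_result_json_round_trip(self, bmi_table, tmp_path):
        res = pooled_oracle_fit(bmi_table, "linear", ["surgery", "sex", "race"], "bmi")
        path = tmp_path / "res.json"
        res.to_json(path)
        again = RegressionResult.from_json(path)
        np.testing.assert_allclose(again.beta, res.beta)
        np.testing.assert_allclose(again.se, res.se)
        assert again.column_order == res.column_order
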