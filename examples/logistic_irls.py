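"""Distributed logistic regression by iteratively reweighted least squares.

Five standardized covariates are split across two sites; the binary outcome
lives at site 2.  Each IRLS iteration the sites report partial linear
predictors, the center broadcasts weights and the working response, and the
cross-site weighted Gram blocks run the secure protocol.  The deviance trace
shows the monotone convergence of the loop.
"""

from vdra import ConvergenceSpec, compare_results, fit_logistic_distributed, pooled_oracle_fit
from vdra.cohort import generate_cohort, partition_vertical
from vdra.studies import standardized_cohort_spec, two_site_plan

spec = standardized_cohort_spec(n=2000, p=5, seed=1, model="logistic")
table = generate_cohort(spec)
plan = two_site_plan(5)
partitions = partition_vertical(table, plan)

trace: list[float] = []
result = fit_logistic_distributed(
    partitions, ("site2", "y"),
    conv=ConvergenceSpec(tol=1e-8, max_iter=25),
    seed=1, deviance_trace=trace,
)
print(result.summary())
print("deviance by iteration:", " -> ".join(f"{d:.4f}" for d in trace))

ordered = [c for c in result.column_order if c != "(Intercept)"]
pooled = pooled_oracle_fit(table, "logistic", ordered, "y")
report = compare_results(result, pooled, tol=1e-8)
print(f"max |beta| difference vs pooled ML fit: {report.max_abs_diff_beta:.3e}")
# Convergence typically takes ~6 iterations; the distributed estimates agree
# with the pooled maximum-likelihood fit far below the 1e-8 tolerance.
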