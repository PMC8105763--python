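# vdra — distributed regression for vertically partitioned patient data

In many clinical studies the variables live in different places: one health
system holds the exposures and demographics, another holds the outcome.
Pooling the patient-level rows is often impossible — privacy, governance,
proprietary interest — yet the study needs one multivariable-adjusted
regression over the combined columns.  **vdra** fits linear and logistic
regressions over such *vertically partitioned* data: the data-contributing
sites exchange only summary-level intermediate statistics through a
simulated, trust-governed file-transfer network, and the results reproduce
the pooled patient-level analysis to within 1e−12 (linear) / 1e−8
(iterative logistic).

It is aimed at biostatisticians and research-network engineers who want a
working, testable model of vertical distributed regression: the sufficient
statistics, the secure cross-site matrix products, the iterative fitting
loop, and the transfer-governance machinery around them.

## The method in brief

With the pooled design `A = [1 X]` split column-wise across sites, the
linear fit needs only the global Gram matrix `G = AᵀA`, `Aᵀy`, `yᵀy`, `n`:

    β̂ = G⁻¹Aᵀy,   σ̂² = (yᵀy − 2β̂ᵀAᵀy + β̂ᵀGβ̂)/(n − p − 1),   cov(β̂) = σ̂²G⁻¹.

Each site computes its own diagonal block `XₖᵀXₖ` locally.  A cross-site
block `XᵢᵀXⱼ` runs a two-message sequential protocol: site A sends an
orthonormal basis `Z` of a random subspace of the orthogonal complement of
its column space; site B returns `X_b − Z(ZᵀX_b)`; A's multiplication
cancels the mask exactly since `ZᵀXₐ = 0`.  Neither side ever sees the
other's raw columns.  Logistic regression iterates this machinery inside
IRLS: sites report partial linear predictors `η_k = X_k β_k`, the analysis
center forms weights `w = μ(1−μ)` and the working response `z`, and the
weighted normal equations are solved from (securely computed) weighted
blocks until `max|Δβ| < 10⁻⁸`.

Every inter-party byte moves through a simulated file-transfer fabric with
per-party mailboxes, checksummed atomic multi-file manifests, a logical
clock, an append-only audit log, and an analysis-center-owned trust matrix
(deny-by-default between sites; a forbidden transfer terminates the run).
Routing is either direct site-to-site or hub-and-spoke relay through the
center — identical results, exactly countable extra transfer legs.

See `docs/methods.md` for the full account.

## Worked example

Two sites, one 200-patient cohort: site 1 holds three binary covariates
(surgery, sex, race), site 2 holds the continuous outcome (BMI).

```python
from vdra import build_linear_gram, compare_results, fit_linear_distributed, pooled_oracle_fit
from vdra.studies import two_site_linear_fixture

table, plan, partitions = two_site_linear_fixture(seed=7, n=200)
gram = build_linear_gram(partitions, ("site2", "bmi"), seed=1)
distributed = fit_linear_distributed(gram)
print(distributed.summary())

pooled = pooled_oracle_fit(table, "linear", ["surgery", "sex", "race"], "bmi")
report = compare_results(distributed, pooled, tol=1e-12)
print(f"max |beta_dra - beta_pooled| = {report.max_abs_diff_beta:.3e}")
```

prints

```
linear regression  (n = 200, p = 3)
term                  estimate    std. error
(Intercept)            24.9285      0.246602
surgery               -1.36327      0.296245
sex                    0.68592      0.293481
race                   0.12203      0.329029
fit: sigma2 = 4.16644, R2 = 0.100511, adj_R2 = 0.0867434
convergence: converged after 1 iteration(s)
max |beta_dra - beta_pooled| = 8.632e-15
```

The coefficient estimates and standard errors are what a pooled OLS fit of
BMI on surgery/sex/race reports — recovered here from summary statistics
alone, with the cross-site blocks computed through the masking protocol —
and the final line shows the distributed and pooled fits agreeing two
orders of magnitude below the 1e−12 working standard.

The `examples/` directory has one short script per capability: the linear
and logistic fits, the secure protocol and its leakage check, trust-matrix
governance, routing-mode accounting, and divide-and-conquer blocking.  A
CLI wraps the same machinery for shell use:

```sh
vdra simulate --spec cohort.json --plan partition.json --out parts/
vdra fit --network net.json --model model.json --partitions parts/ --mode direct --seed 1
vdra compare --dra result.json --oracle oracle.json --tol 1e-12
vdra run --config config.json    # end to end, with oracle comparison
```

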