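"""Reference verification studies: seeded, end-to-end experiments that
measure how faithfully the distributed machinery reproduces pooled
patient-level analysis and honors the transfer-governance contracts.

Each function builds its own synthetic inputs, runs the distributed method,
and returns the measured quantities.  The study sizes are the package's
benchmark conditions: the linear equivalence study uses a cohort of 5452
patients with 10 standardized covariates split across two sites; the
logistic study uses 2000 patients and 5 covariates; the governance, routing
and blocking studies use a small two-site cohort because they measure exact
counts and bit-level invariances, not statistical behavior.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .cohort import (
    BlockPlan,
    CohortSpec,
    Covariate,
    PartitionPlan,
    generate_cohort,
    partition_vertical,
)
from .errors import TrustViolationError
from .models import (
    build_linear_gram,
    compare_results,
    fit_linear_distributed,
    fit_logistic_distributed,
    pooled_oracle_fit,
)
from .network import (
    ModelSpec,
    NetworkConfig,
    create_network,
    make_manifest,
    run_vdra_workflow,
    set_trust,
    transfer,
)
from .secure import secure_cross_product

__all__ = [
    "standardized_cohort_spec",
    "two_site_plan",
    "linear_equivalence_study",
    "logistic_equivalence_study",
    "secure_product_study",
    "governance_study",
    "routing_study",
    "blocking_study",
    "two_site_linear_fixture",
]

CENTER = "analysis_center"


def standardized_cohort_spec(n: int, p: int, seed: int, model: str = "linear") -> CohortSpec:
    covs = tuple(Covariate(f"x{i:02d}", "continuous", {"mu": 0.0, "sigma": 1.0})
                 for i in range(1, p + 1))
    beta = (0.5,) + tuple(((-1) ** i) * (0.6 - 0.05 * i) for i in range(p))
    return CohortSpec(n_patients=n, covariates=covs, outcome_model=model,
                      true_beta=beta, noise_sd=1.0, seed=seed)


def two_site_plan(p: int, split: int | None = None) -> PartitionPlan:
    split = split if split is not None else p // 2
    assign = {f"x{i:02d}": ("site1" if i <= split else "site2") for i in range(1, p + 1)}
    assign["y"] = "site2"
    return PartitionPlan(("site1", "site2"), assign, "site2")


def two_site_linear_fixture(seed: int = 7, n: int = 200):
    """The canonical small two-site scenario: three binary covariates
    (surgery, sex, race) at site 1, the continuous outcome (BMI) at
    site 2."""
    spec = CohortSpec(
        n_patients=n,
        covariates=(
            Covariate("surgery", "binary", {"p": 0.4}),
            Covariate("sex", "binary", {"p": 0.5}),
            Covariate("race", "binary", {"p": 0.3}),
        ),
        outcome_model="linear",
        true_beta=(25.0, -1.2, 0.8, 0.5),
        noise_sd=2.0,
        seed=seed,
        outcome_name="bmi",
    )
    table = generate_cohort(spec)
    plan = PartitionPlan(
        ("site1", "site2"),
        {"surgery": "site1", "sex": "site1", "race": "site1", "bmi": "site2"},
        "site2", "bmi",
    )
    return table, plan, partition_vertical(table, plan)


def linear_equivalence_study(seed: int = 1, n: int = 5452, p: int = 10):
    """Distributed linear fit vs pooled OLS on a two-site cohort.

    Returns the comparison report (max-abs coefficient and standard-error
    differences); the distributed path runs the full secure protocol for
    the cross-site blocks.
    """
    spec = standardized_cohort_spec(n, p, seed)
    table = generate_cohort(spec)
    plan = two_site_plan(p)
    partitions = partition_vertical(table, plan)
    gram = build_linear_gram(partitions, (plan.outcome_site, plan.outcome_column), seed=seed)
    result = fit_linear_distributed(gram)
    ordered = [c for c in gram.column_order if c != "(Intercept)"]
    oracle = pooled_oracle_fit(table, "linear", ordered, "y")
    return compare_results(result, oracle, tol=1e-12), result, oracle


def logistic_equivalence_study(seed: int = 1, n: int = 2000, p: int = 5):
    """Distributed IRLS vs pooled maximum-likelihood logistic fit."""
    spec = standardized_cohort_spec(n, p, seed, model="logistic")
    table = generate_cohort(spec)
    plan = two_site_plan(p)
    partitions = partition_vertical(table, plan)
    result = fit_logistic_distributed(partitions, ("site2", "y"), seed=seed)
    ordered = [c for c in result.column_order if c != "(Intercept)"]
    oracle = pooled_oracle_fit(table, "logistic", ordered, "y")
    return compare_results(result, oracle, tol=1e-8), result, oracle


def secure_product_study(seed: int = 1, n_instances: int = 100):
    """Secure cross products vs direct matrix products on random instances.

    Returns the worst element-wise protocol error and the smallest max
    |payload - raw| over instances (positive means the mask always altered
    the transferred columns).
    """
    import pandas as pd

    from .cohort import SitePartition

    rng = np.random.default_rng(seed)
    worst_err = 0.0
    min_payload_diff = np.inf
    for trial in range(n_instances):
        n = int(rng.integers(10, 101))
        p_a = int(rng.integers(1, 6))
        p_b = int(rng.integers(1, 6))
        ids = np.arange(1, n + 1)
        Xa = rng.standard_normal((n, p_a))
        Xb = rng.standard_normal((n, p_b))
        a = SitePartition("a", pd.DataFrame(
            {"patient_id": ids, **{f"a{j}": Xa[:, j] for j in range(p_a)}}))
        b = SitePartition("b", pd.DataFrame(
            {"patient_id": ids, **{f"b{j}": Xb[:, j] for j in range(p_b)}}))

        class _Capture:
            def __init__(self):
                self.payload = None

            def send(self, frm, to, label, arr):
                if label == "masked-columns":
                    self.payload = arr
                return arr

        cap = _Capture()
        blk = secure_cross_product(a, b, seed=seed * 1000 + trial, channel=cap)
        worst_err = max(worst_err, float(np.max(np.abs(blk.block - Xa.T @ Xb))))
        min_payload_diff = min(min_payload_diff, float(np.max(np.abs(cap.payload - Xb))))
    return {"max_abs_error": worst_err, "min_payload_alteration": min_payload_diff,
            "n_instances": n_instances}


def governance_study(root: str | Path, seed: int = 1):
    """Attempt a forbidden site-to-site transfer and count what happens.

    Returns whether the run terminated and how many manifests were
    delivered after the violation (the contract requires zero)."""
    config = NetworkConfig(CENTER, ("site1", "site2"), str(root), routing_mode="direct")
    net = create_network(config)
    outbox = net.mailbox("site1", "outbox")
    (outbox / "stats.csv").write_text("1.0,2.0\n")
    terminated = False
    try:
        transfer(net, make_manifest(net, "site1", "site2", ["stats.csv"]))
    except TrustViolationError:
        terminated = True
    violation_tick = net.clock
    # any later attempt, even a center-bound one, must be refused
    (net.mailbox("site2", "outbox") / "late.csv").write_text("3.0\n")
    try:
        transfer(net, make_manifest(net, "site2", CENTER, ["late.csv"]))
    except Exception:
        pass
    return {
        "terminated": terminated and net.terminated,
        "post_violation_deliveries": net.audit.delivered_after(violation_tick),
        "terminated_events": net.audit.count("terminated"),
    }


def _run_workflow_in_mode(root: Path, partitions, model_spec, mode: str, seed: int,
                          conv=None, block_plan=None):
    config = NetworkConfig(CENTER, ("site1", "site2"), str(root), routing_mode=mode)
    net = create_network(config)
    if mode == "direct":
        for a in ("site1", "site2"):
            for b in ("site1", "site2"):
                if a != b:
                    set_trust(net, a, b, True, actor=CENTER)
    return run_vdra_workflow(net, partitions, model_spec, seed=seed, conv=conv,
                             block_plan=block_plan)


def routing_study(root: str | Path, seed: int = 1):
    """Identical fixture through direct and hub-and-spoke routing.

    Returns leg counts, the site-to-site exchange count, and the max-abs
    difference between the two modes' regression results (expected 0: only
    the transfer accounting changes)."""
    root = Path(root)
    _table, _plan, partitions = two_site_linear_fixture(seed=seed)
    spec = ModelSpec("linear", "site2", "bmi")
    res_d, met_d, _ = _run_workflow_in_mode(root / "direct", partitions, spec, "direct", seed)
    res_h, met_h, _ = _run_workflow_in_mode(root / "hub", partitions, spec, "hub_and_spoke", seed)
    report = compare_results(res_d, res_h, tol=1e-12)
    return {
        "direct_legs": met_d.n_legs,
        "hub_legs": met_h.n_legs,
        "site_site_exchanges": met_d.n_site_site_exchanges,
        "leg_law_holds": met_h.n_legs == met_d.n_legs + met_d.n_site_site_exchanges,
        "max_abs_result_diff": max(report.max_abs_diff_beta, report.max_abs_diff_se),
    }


def blocking_study(seed: int = 1, n: int = 600, p: int = 6, n_blocks_list=(2, 4, 7)):
    """Divide-and-conquer invariance: fits under several row-block plans
    against the unblocked fit; returns the worst max-abs difference."""
    spec = standardized_cohort_spec(n, p, seed)
    table = generate_cohort(spec)
    plan = two_site_plan(p)
    partitions = partition_vertical(table, plan)
    base = fit_linear_distributed(
        build_linear_gram(partitions, (plan.outcome_site, plan.outcome_column), seed=seed))
    worst = 0.0
    for n_blocks in n_blocks_list:
        blocked = fit_linear_distributed(
            build_linear_gram(partitions, (plan.outcome_site, plan.outcome_column),
                              seed=seed, block_plan=BlockPlan.even(n, n_blocks)))
        worst = max(
            worst,
            float(np.max(np.abs(base.beta - blocked.beta))),
            float(np.max(np.abs(base.se - blocked.se))),
        )
    return {"max_abs_diff": worst, "n_blocks_tested": list(n_blocks_list)}
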