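"""Shared fixtures: small synthetic cohorts and their vertical partitions.

The canonical two-site scenario mirrors a surgery-outcomes study: site 1
holds three binary exposure/demographic covariates (surgery, sex, race),
site 2 holds the continuous outcome (BMI).
"""

import numpy as np
import pytest

from vdra import (
    CohortSpec,
    Covariate,
    PartitionPlan,
    generate_cohort,
    partition_vertical,
)


@pytest.fixture(scope="session")
def bmi_spec():
    return CohortSpec(
        n_patients=200,
        covariates=(
            Covariate("surgery", "binary", {"p": 0.4}),
            Covariate("sex", "binary", {"p": 0.5}),
            Covariate("race", "binary", {"p": 0.3}),
        ),
        outcome_model="linear",
        true_beta=(25.0, -1.2, 0.8, 0.5),
        noise_sd=2.0,
        seed=7,
        outcome_name="bmi",
    )


@pytest.fixture(scope="session")
def bmi_plan():
    return PartitionPlan(
        site_ids=("site1", "site2"),
        column_assignment={"surgery": "site1", "sex": "site1", "race": "site1", "bmi": "site2"},
        outcome_site="site2",
        outcome_column="bmi",
    )


@pytest.fixture(scope="session")
def bmi_table(bmi_spec):
    return generate_cohort(bmi_spec)


@pytest.fixture(scope="session")
def bmi_partitions(bmi_table, bmi_plan):
    return partition_vertical(bmi_table, bmi_plan)


@pytest.fixture(scope="session")
def logistic_spec():
    covs = tuple(
        Covariate(f"x{i}", "continuous", {"mu": 0.0, "sigma": 1.0}) for i in range(1, 6)
    )
    return CohortSpec(
        n_patients=400,
        covariates=covs,
        outcome_model="logistic",
        true_beta=(0.3, 0.5, -0.4, 0.25, 0.0, -0.6),
        seed=11,
    )


@pytest.fixture(scope="session")
def logistic_table(logistic_spec):
    return generate_cohort(logistic_spec)


@pytest.fixture(scope="session")
def logistic_plan():
    return PartitionPlan(
        site_ids=("site1", "site2"),
        column_assignment={
            "x1": "site1", "x2": "site1", "x3": "site1",
            "x4": "site2", "x5": "site2", "y": "site2",
        },
        outcome_site="site2",
    )


@pytest.fixture(scope="session")
def logistic_partitions(logistic_table, logistic_plan):
    return partition_vertical(logistic_table, logistic_plan)


def random_partition_pair(n, p_a, p_b, seed):
    """Two row-aligned site partitions with standard-normal columns."""
    import pandas as pd

    from vdra import SitePartition

    rng = np.random.default_rng(seed)
    ids = np.arange(1, n + 1)
    a = pd.DataFrame({"patient_id": ids})
    for j in range(p_a):
        a[f"a{j}"] = rng.standard_normal(n)
    b = pd.DataFrame({"patient_id": ids})
    for j in range(p_b):
        b[f"b{j}"] = rng.standard_normal(n)
    return SitePartition("site_a", a), SitePartition("site_b", b)
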