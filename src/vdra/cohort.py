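"""Synthetic patient cohorts and their vertical / horizontal partitioning.

This module plays the role of the data-contributing sites' source systems in
a distributed-regression study.  It generates a pooled patient-level table
with a known regression structure (the ground truth the distributed fit must
recover), splits it *vertically* — by column — across two or more sites that
share one linked cohort of patients, and optionally splits each site's slice
*horizontally* — by row — into blocks for divide-and-conquer matrix
computations.

Alignment model: patients carry synthetic integer IDs and every site holds
the same ID multiset in the same canonical (sorted-by-ID) order, emulating a
pre-linked cohort.  Each covariate is drawn from its own seeded random
stream keyed by the covariate's name, so adding a covariate to a spec never
perturbs the values of the existing ones.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import FormatError, PlanError, SpecificationError

ID_COLUMN = "patient_id"

__all__ = [
    "ID_COLUMN",
    "Covariate",
    "CohortSpec",
    "PatientTable",
    "PartitionPlan",
    "SitePartition",
    "BlockPlan",
    "generate_cohort",
    "partition_vertical",
    "partition_blocks",
    "write_partition",
    "read_partition",
    "align_partition",
]


def _column_seed(global_seed: int, name: str) -> np.random.SeedSequence:
    # crc32 keys the stream by column name so streams are order-independent
    return np.random.SeedSequence(
        [int(global_seed) & 0xFFFFFFFF, zlib.crc32(name.encode("utf-8"))]
    )


@dataclass(frozen=True)
class Covariate:
    """One covariate of the data-generating model.

    ``kind`` is ``"continuous"`` (Normal(mu, sigma)) or ``"binary"``
    (Bernoulli(p)); ``params`` holds the distribution parameters
    (``{"mu": ..., "sigma": ...}`` or ``{"p": ...}``).
    """

    name: str
    kind: Literal["continuous", "binary"] = "continuous"
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.kind == "continuous":
            sigma = self.params.get("sigma", 1.0)
            if sigma < 0:
                raise SpecificationError(
                    f"covariate {self.name!r}: sigma must be >= 0, got {sigma}"
                )
        elif self.kind == "binary":
            p = self.params.get("p", 0.5)
            if not 0.0 <= p <= 1.0:
                raise SpecificationError(
                    f"covariate {self.name!r}: Bernoulli p must lie in [0, 1], got {p}"
                )
        else:
            raise SpecificationError(
                f"covariate {self.name!r}: unknown kind {self.kind!r}"
            )

    def sample(self, n: int, seed: np.random.SeedSequence) -> np.ndarray:
        rng = np.random.default_rng(seed)
        if self.kind == "continuous":
            mu = self.params.get("mu", 0.0)
            sigma = self.params.get("sigma", 1.0)
            return rng.normal(mu, sigma, size=n)
        p = self.params.get("p", 0.5)
        return rng.binomial(1, p, size=n).astype(float)


@dataclass(frozen=True)
class CohortSpec:
    """Data-generating specification for one synthetic cohort.

    ``true_beta`` includes the intercept as its first element, so
    ``len(true_beta) == 1 + len(covariates)``.  For a linear outcome,
    ``y = beta0 + X beta + Normal(0, noise_sd^2)``; for a logistic outcome,
    ``y ~ Bernoulli(expit(beta0 + X beta))`` and ``noise_sd`` is ignored.
    """

    n_patients: int
    covariates: tuple[Covariate, ...]
    outcome_model: Literal["linear", "logistic"] = "linear"
    true_beta: tuple[float, ...] = ()
    noise_sd: float = 1.0
    seed: int = 0
    outcome_name: str = "y"

    def validate(self) -> None:
        if len(self.true_beta) != 1 + len(self.covariates):
            raise SpecificationError(
                "true_beta must have length 1 + n_covariates "
                f"({1 + len(self.covariates)}), got {len(self.true_beta)}"
            )
        if self.noise_sd < 0:
            raise SpecificationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_patients < len(self.true_beta) + 2:
            raise SpecificationError(
                f"n_patients must be >= len(true_beta) + 2 = {len(self.true_beta) + 2}"
            )
        if self.outcome_model not in ("linear", "logistic"):
            raise SpecificationError(
                f"outcome_model must be 'linear' or 'logistic', got {self.outcome_model!r}"
            )
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise SpecificationError("covariate names must be unique")
        if self.outcome_name in names or self.outcome_name == ID_COLUMN:
            raise SpecificationError(
                f"outcome name {self.outcome_name!r} collides with another column"
            )
        for cov in self.covariates:
            cov.validate()

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        covs = tuple(
            Covariate(c["name"], c.get("kind", "continuous"), c.get("params", {}))
            for c in d["covariates"]
        )
        return cls(
            n_patients=int(d["n_patients"]),
            covariates=covs,
            outcome_model=d.get("outcome_model", "linear"),
            true_beta=tuple(float(b) for b in d["true_beta"]),
            noise_sd=float(d.get("noise_sd", 1.0)),
            seed=int(d.get("seed", 0)),
            outcome_name=d.get("outcome_name", "y"),
        )


class PatientTable:
    """The pooled patient-level table (exists only inside the simulator and
    the test oracle — in a real study it is never physically assembled).

    Wraps a :class:`pandas.DataFrame` whose first column is the unique
    integer ``patient_id``; all other columns are numeric with no missing
    values.
    """

    def __init__(self, data: pd.DataFrame):
        if ID_COLUMN not in data.columns:
            raise FormatError(f"table must contain a {ID_COLUMN!r} column")
        if data[ID_COLUMN].duplicated().any():
            raise FormatError("patient_id values must be unique")
        if data.isna().any().any():
            raise FormatError("table must not contain missing values")
        cols = [ID_COLUMN] + [c for c in data.columns if c != ID_COLUMN]
        self.data = data.loc[:, cols].reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        """Non-ID column names, in order."""
        return [c for c in self.data.columns if c != ID_COLUMN]

    def matrix(self, columns: Sequence[str]) -> np.ndarray:
        return self.data.loc[:, list(columns)].to_numpy(dtype=float)

    def __eq__(self, other) -> bool:
        return isinstance(other, PatientTable) and self.data.equals(other.data)


@dataclass(frozen=True)
class PartitionPlan:
    """Assignment of every non-ID column to exactly one site."""

    site_ids: tuple[str, ...]
    column_assignment: dict  # column name -> site id
    outcome_site: str
    outcome_column: str = "y"

    def validate(self, table: PatientTable | None = None) -> None:
        if len(self.site_ids) < 2:
            raise PlanError("a vertical partition needs at least 2 sites")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise PlanError("site ids must be unique")
        if self.outcome_site not in self.site_ids:
            raise PlanError(f"outcome_site {self.outcome_site!r} is not a site")
        assigned_sites = set(self.column_assignment.values())
        unknown = assigned_sites - set(self.site_ids)
        if unknown:
            raise PlanError(f"columns assigned to unknown sites: {sorted(unknown)}")
        if self.column_assignment.get(self.outcome_column) != self.outcome_site:
            raise PlanError(
                f"outcome column {self.outcome_column!r} must be assigned to "
                f"outcome_site {self.outcome_site!r}"
            )
        for site in self.site_ids:
            if site not in assigned_sites:
                raise PlanError(f"site {site!r} holds no columns")
        if table is not None:
            missing = set(self.column_assignment) - set(table.columns)
            if missing:
                raise PlanError(f"plan references nonexistent columns: {sorted(missing)}")
            unassigned = set(table.columns) - set(self.column_assignment)
            if unassigned:
                raise PlanError(f"columns not assigned to any site: {sorted(unassigned)}")

    def columns_for(self, site_id: str) -> list[str]:
        return [c for c, s in self.column_assignment.items() if s == site_id]

    @classmethod
    def from_dict(cls, d: dict) -> "PartitionPlan":
        return cls(
            site_ids=tuple(d["site_ids"]),
            column_assignment=dict(d["column_assignment"]),
            outcome_site=d["outcome_site"],
            outcome_column=d.get("outcome_column", "y"),
        )


class SitePartition:
    """One site's column slice of the shared cohort, row-aligned by ID.

    ``row_order`` is a digest of the patient-ID sequence; two partitions with
    equal tokens are guaranteed to list the same patients in the same order.
    """

    def __init__(self, site_id: str, data: pd.DataFrame):
        if ID_COLUMN not in data.columns:
            raise FormatError(f"partition must contain a {ID_COLUMN!r} column")
        if data[ID_COLUMN].duplicated().any():
            raise FormatError("duplicate patient_id in partition")
        if data.isna().any().any():
            raise FormatError("partition must not contain missing values")
        self.site_id = site_id
        cols = [ID_COLUMN] + [c for c in data.columns if c != ID_COLUMN]
        self.data = data.loc[:, cols].reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return [c for c in self.data.columns if c != ID_COLUMN]

    @property
    def patient_ids(self) -> np.ndarray:
        return self.data[ID_COLUMN].to_numpy()

    @property
    def row_order(self) -> str:
        ids = ",".join(str(i) for i in self.patient_ids)
        return hashlib.sha1(ids.encode()).hexdigest()

    def matrix(self, columns: Sequence[str] | None = None) -> np.ndarray:
        cols = list(columns) if columns is not None else self.columns
        missing = set(cols) - set(self.columns)
        if missing:
            raise PlanError(f"site {self.site_id!r} does not hold columns {sorted(missing)}")
        return self.data.loc[:, cols].to_numpy(dtype=float)

    def aligned_with(self, other: "SitePartition") -> bool:
        return self.row_order == other.row_order

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SitePartition)
            and self.site_id == other.site_id
            and self.data.equals(other.data)
        )


@dataclass(frozen=True)
class BlockPlan:
    """Half-open, 0-based row ranges for divide-and-conquer blocking."""

    block_boundaries: tuple[tuple[int, int], ...]

    def validate(self, n_rows: int) -> None:
        if not self.block_boundaries:
            raise PlanError("block plan must contain at least one range")
        prev_end = 0
        for start, end in self.block_boundaries:
            if start != prev_end:
                raise PlanError(
                    f"block ranges must be contiguous: expected start {prev_end}, got {start}"
                )
            if end <= start:
                raise PlanError(f"empty or inverted block range [{start}, {end})")
            prev_end = end
        if prev_end != n_rows:
            raise PlanError(f"block ranges cover [0, {prev_end}) but table has {n_rows} rows")

    @classmethod
    def even(cls, n_rows: int, n_blocks: int) -> "BlockPlan":
        """Split ``n_rows`` into ``n_blocks`` near-equal contiguous ranges."""
        edges = np.linspace(0, n_rows, n_blocks + 1).astype(int)
        return cls(tuple((int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])))

    @classmethod
    def from_dict(cls, d: dict) -> "BlockPlan":
        return cls(tuple((int(a), int(b)) for a, b in d["block_boundaries"]))


def generate_cohort(spec: CohortSpec) -> PatientTable:
    """Generate the pooled patient-level table for ``spec``.

    Deterministic given ``spec.seed``.  Covariate columns are generated
    first, then the outcome: linear outcomes add Normal(0, noise_sd^2) noise
    to the linear predictor, logistic outcomes draw Bernoulli(expit(eta)).
    """
    spec.validate()
    n = spec.n_patients
    frame = {ID_COLUMN: np.arange(1, n + 1, dtype=int)}
    X = np.empty((n, len(spec.covariates)))
    for j, cov in enumerate(spec.covariates):
        X[:, j] = cov.sample(n, _column_seed(spec.seed, cov.name))
        frame[cov.name] = X[:, j]
    beta = np.asarray(spec.true_beta, dtype=float)
    eta = beta[0] + X @ beta[1:]
    if spec.outcome_model == "linear":
        noise_rng = np.random.default_rng(_column_seed(spec.seed, "\x00noise"))
        y = eta + spec.noise_sd * noise_rng.standard_normal(n)
    else:
        out_rng = np.random.default_rng(_column_seed(spec.seed, "\x00outcome"))
        y = out_rng.binomial(1, expit(eta)).astype(float)
    frame[spec.outcome_name] = y
    return PatientTable(pd.DataFrame(frame))


def partition_vertical(table: PatientTable, plan: PartitionPlan) -> list[SitePartition]:
    """Split ``table`` column-wise per ``plan`` into row-aligned site slices.

    Joining the returned partitions back on ``patient_id`` reproduces the
    input table exactly; column sets are pairwise disjoint.
    """
    plan.validate(table)
    return [
        SitePartition(site, table.data.loc[:, [ID_COLUMN] + plan.columns_for(site)])
        for site in plan.site_ids
    ]


def partition_blocks(partition: SitePartition, plan: BlockPlan) -> list[SitePartition]:
    """Slice a site partition row-wise into the blocks of ``plan``.

    Every site of a cohort must use the identical plan so blocks stay
    row-aligned; concatenating the blocks restores the partition.
    """
    plan.validate(partition.n)
    return [
        SitePartition(partition.site_id, partition.data.iloc[start:end])
        for start, end in plan.block_boundaries
    ]


def write_partition(partition: SitePartition, path: str | Path) -> Path:
    """Write a partition as RFC-4180 CSV (header row, patient_id first).

    Floats are printed at full ``repr`` precision so the round trip through
    :func:`read_partition` is lossless.
    """
    path = Path(path)
    partition.data.to_csv(path, index=False)
    return path


def read_partition(path: str | Path, site_id: str | None = None) -> SitePartition:
    """Read a partition CSV; rejects duplicate IDs and missing values."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if ID_COLUMN not in df.columns:
        raise FormatError(f"{path} lacks the {ID_COLUMN!r} column")
    return SitePartition(site_id or path.stem, df)


def align_partition(partition: SitePartition) -> SitePartition:
    """Restore the canonical sorted-by-ID row order."""
    return SitePartition(
        partition.site_id, partition.data.sort_values(ID_COLUMN, kind="mergesort")
    )
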