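"""End-to-end orchestration: seeded, reproducible runs from a JSON config.

A run config names a cohort specification, a vertical partition plan, the
model, the routing mode and the convergence rule; :func:`run_end_to_end`
generates the cohort, partitions it, stands up the transfer network,
executes the distributed regression, fits the pooled oracle, compares the
two at the requested tolerance and writes all artifacts (result, oracle,
comparison, metrics, audit) under the output directory.  Identical config
and seed produce identical artifacts — all timestamps are logical-clock
ticks.

Logging is party-tagged and never includes patient-level values (only
shapes, column names and summary diagnostics).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .cohort import (
    BlockPlan,
    CohortSpec,
    PartitionPlan,
    generate_cohort,
    partition_vertical,
)
from .errors import ConfigError, TrustViolationError, VdraError
from .models import ConvergenceSpec, compare_results, pooled_oracle_fit
from .network import (
    ModelSpec,
    NetworkConfig,
    create_network,
    run_vdra_workflow,
    set_trust,
)

log = logging.getLogger("vdra")

__all__ = ["RunConfig", "validate_config", "run_end_to_end"]

DEFAULT_TOL = {"linear": 1e-12, "logistic": 1e-8}


@dataclass
class RunConfig:
    """Everything one reproducible end-to-end run needs."""

    cohort_spec: CohortSpec
    partition_plan: PartitionPlan
    model: ModelSpec
    routing_mode: str = "direct"
    convergence: ConvergenceSpec = field(default_factory=ConvergenceSpec)
    block_plan: BlockPlan | None = None
    trust: tuple[tuple[str, str, bool], ...] | None = None
    seed: int = 0
    out_dir: str = "vdra-run"
    comparison_tol: float | None = None

    @classmethod
    def from_dict(cls, d: dict, base_dir: Path | None = None) -> "RunConfig":
        def resolve(section):
            # a section may be inline or a path to a JSON file
            if isinstance(section, str):
                path = Path(section)
                if base_dir is not None and not path.is_absolute():
                    path = base_dir / path
                with open(path) as fh:
                    return json.load(fh)
            return section

        return cls(
            cohort_spec=CohortSpec.from_dict(resolve(d["cohort_spec"])),
            partition_plan=PartitionPlan.from_dict(resolve(d["partition_plan"])),
            model=ModelSpec.from_dict(resolve(d["model"])),
            routing_mode=d.get("routing_mode", "direct"),
            convergence=ConvergenceSpec.from_dict(d.get("convergence", {})),
            block_plan=(
                BlockPlan.from_dict(resolve(d["block_plan"])) if d.get("block_plan") else None
            ),
            trust=(
                tuple((f, t, bool(v)) for f, t, v in d["trust"]) if d.get("trust") else None
            ),
            seed=int(d.get("seed", 0)),
            out_dir=d.get("out_dir", "vdra-run"),
            comparison_tol=(
                float(d["comparison_tol"]) if d.get("comparison_tol") is not None else None
            ),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            return cls.from_dict(json.load(fh), base_dir=path.parent)


def validate_config(path: str | Path) -> list[str]:
    """Schema and cross-reference checks on a run-config file; returns the
    list of violations (empty when valid)."""
    violations: list[str] = []
    path = Path(path)
    try:
        with open(path) as fh:
            raw = json.load(fh)
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        return [f"invalid JSON: {exc}"]

    for key in ("cohort_spec", "partition_plan", "model"):
        if key not in raw:
            violations.append(f"missing required section {key!r}")
    if violations:
        return violations

    try:
        config = RunConfig.from_dict(raw, base_dir=path.parent)
    except (KeyError, TypeError, ValueError, VdraError) as exc:
        return [f"config does not parse: {exc}"]

    spec, plan = config.cohort_spec, config.partition_plan
    try:
        spec.validate()
    except VdraError as exc:
        violations.append(f"cohort_spec: {exc}")
    try:
        plan.validate()
    except VdraError as exc:
        violations.append(f"partition_plan: {exc}")

    # cross references between sections
    spec_columns = {c.name for c in spec.covariates} | {spec.outcome_name}
    planned = set(plan.column_assignment)
    for col in sorted(spec_columns - planned):
        violations.append(f"column {col!r} generated but not assigned to any site")
    for col in sorted(planned - spec_columns):
        violations.append(f"plan assigns unknown column {col!r}")
    outcome_claims = [
        s for c, s in plan.column_assignment.items() if c == plan.outcome_column
    ]
    if len(outcome_claims) > 1:
        violations.append("outcome column assigned to more than one site")
    if config.model.outcome_site not in plan.site_ids:
        violations.append(
            f"model outcome_site {config.model.outcome_site!r} is not a planned site"
        )
    elif config.model.outcome_site != plan.outcome_site:
        violations.append(
            f"model outcome_site {config.model.outcome_site!r} disagrees with the "
            f"partition plan's outcome_site {plan.outcome_site!r}"
        )
    if config.model.outcome_column != plan.outcome_column:
        violations.append("model outcome_column disagrees with partition plan")
    if config.convergence.tol <= 0:
        violations.append(f"convergence tol must be > 0, got {config.convergence.tol}")
    if config.routing_mode not in ("direct", "hub_and_spoke"):
        violations.append(f"unknown routing_mode {config.routing_mode!r}")
    if config.block_plan is not None:
        try:
            config.block_plan.validate(spec.n_patients)
        except VdraError as exc:
            violations.append(f"block_plan: {exc}")
    return violations


def run_end_to_end(config: RunConfig) -> int:
    """Execute one seeded run; returns the exit status (0 = comparison
    passed, 1 = comparison failed, 2 = run terminated by trust violation).

    Artifacts written under ``config.out_dir``: ``result.json``,
    ``oracle.json``, ``comparison.json``, ``metrics.json`` and the network
    run directory with its ``audit.jsonl``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec, plan = config.cohort_spec, config.partition_plan
    spec.validate()
    log.info("[simulator] generating cohort: n=%d, %d covariates", spec.n_patients,
             len(spec.covariates))
    table = generate_cohort(spec)
    partitions = partition_vertical(table, plan)
    for part in partitions:
        log.info("[%s] holds columns %s (%d rows)", part.site_id, part.columns, part.n)

    net_config = NetworkConfig(
        analysis_center="analysis_center",
        sites=tuple(plan.site_ids),
        root_path=str(out_dir / "network"),
        routing_mode=config.routing_mode,  # type: ignore[arg-type]
    )
    network = create_network(net_config)
    center = net_config.analysis_center
    if config.trust is not None:
        for frm, to, allowed in config.trust:
            set_trust(network, frm, to, allowed, actor=center)
    elif config.routing_mode == "direct":
        # the center pre-approves the site pairs the protocol needs
        for a in plan.site_ids:
            for b in plan.site_ids:
                if a != b:
                    set_trust(network, a, b, True, actor=center)

    model_spec = config.model
    try:
        result, metrics, audit = run_vdra_workflow(
            network,
            partitions,
            model_spec,
            conv=config.convergence,
            seed=config.seed,
            block_plan=config.block_plan,
        )
    except TrustViolationError as exc:
        log.error("[%s] %s", center, exc)
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump(network.metrics.to_dict(), fh, indent=2)
        return 2

    covariates = [c.name for c in spec.covariates]
    oracle = pooled_oracle_fit(table, model_spec.model, covariates, model_spec.outcome_column)
    tol = config.comparison_tol or DEFAULT_TOL[model_spec.model]
    report = compare_results(result, oracle, tol=tol)
    log.info(
        "[%s] distributed vs pooled: max |d beta| = %.3e, max |d se| = %.3e (tol %g)",
        center, report.max_abs_diff_beta, report.max_abs_diff_se, tol,
    )

    result.to_json(out_dir / "result.json")
    oracle.to_json(out_dir / "oracle.json")
    with open(out_dir / "comparison.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(metrics.to_dict(), fh, indent=2)
    return 0 if report.passed else 1
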