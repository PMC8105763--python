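"""Analysis-center computations: Gram assembly, normal-equations OLS, and
distributed IRLS for logistic regression.

The analysis center never touches patient-level covariates.  For linear
regression the sufficient statistics are the augmented Gram matrix
G = [1 X]'[1 X], the cross-product vector [1 X]'y, the outcome sum of
squares y'y and the cohort size n; coefficients come from the normal
equations ``G beta = X'y`` and the error variance from

    sigma^2 = (y'y - 2 beta'X'y + beta'G beta) / (n - p - 1),

both computable from summaries alone.  For logistic regression the center
drives iteratively reweighted least squares: sites report their partial
linear predictors eta_k = X_k beta_k, the center forms the mean mu, IRLS
weights w = mu(1 - mu) and the working response z, the sites compute
weighted Gram blocks (cross-site blocks via the secure protocol), and the
center solves the weighted normal equations until the coefficient step
falls below tolerance.

The pooled patient-level fit (the oracle every distributed result is
verified against) is delegated to statsmodels and lives in
:func:`pooled_oracle_fit`; it is the only function here that accepts a
pooled :class:`~vdra.cohort.PatientTable`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import scipy.linalg
from scipy.special import expit

from .cohort import PatientTable, SitePartition
from .errors import (
    AssemblyError,
    CollinearityError,
    ComparisonError,
    DomainError,
    IncompleteBlocksError,
    SeparationError,
    SpecificationError,
)
from .secure import (
    GramBlock,
    InMemoryChannel,
    blocked_cross_product,
    pair_seed,
    secure_cross_product,
    secure_cross_product_weighted,
)

INTERCEPT = "(Intercept)"
CONDITION_LIMIT = 1e12
CENTER_ID = "analysis_center"

__all__ = [
    "INTERCEPT",
    "GlobalGram",
    "ConvergenceSpec",
    "IterationState",
    "RegressionResult",
    "ComparisonReport",
    "assemble_global_gram",
    "build_linear_gram",
    "fit_linear_distributed",
    "fit_logistic_distributed",
    "convergence_check",
    "pooled_oracle_fit",
    "compare_results",
]


@dataclass
class GlobalGram:
    """Sufficient statistics for a linear model on the virtual pooled data:
    intercept-augmented Gram matrix, cross products with y, y'y, and n."""

    column_order: tuple[str, ...]  # intercept first, then sites in site order
    G: np.ndarray  # (p+1) x (p+1)
    Xty: np.ndarray  # (p+1,)
    yty: float
    n: int

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        self.Xty = np.asarray(self.Xty, dtype=float)
        p1 = len(self.column_order)
        if self.G.shape != (p1, p1) or self.Xty.shape != (p1,):
            raise AssemblyError(
                f"Gram dimensions {self.G.shape}/{self.Xty.shape} inconsistent "
                f"with {p1} columns"
            )
        if not np.allclose(self.G, self.G.T, atol=1e-8):
            raise AssemblyError("global Gram matrix must be symmetric")

    @property
    def p(self) -> int:
        """Number of covariates, excluding the intercept."""
        return len(self.column_order) - 1


@dataclass(frozen=True)
class ConvergenceSpec:
    """Prespecified stopping rule for iterative fits: stop when the
    criterion value falls strictly below ``tol``, or after ``max_iter``
    iterations, whichever comes first."""

    tol: float = 1e-8
    max_iter: int = 25
    criterion: Literal["max-abs-delta-beta", "relative-deviance-change"] = "max-abs-delta-beta"

    def __post_init__(self):
        if self.tol <= 0:
            raise SpecificationError(f"tol must be > 0, got {self.tol}")
        if self.max_iter < 1:
            raise SpecificationError(f"max_iter must be >= 1, got {self.max_iter}")

    @classmethod
    def from_dict(cls, d: dict) -> "ConvergenceSpec":
        return cls(
            tol=float(d.get("tol", 1e-8)),
            max_iter=int(d.get("max_iter", 25)),
            criterion=d.get("criterion", "max-abs-delta-beta"),
        )


@dataclass
class IterationState:
    """One IRLS iterate as seen by the analysis center."""

    iter_index: int
    beta: np.ndarray
    partial_linear_predictors: dict = field(default_factory=dict)  # site -> eta_k
    weights: np.ndarray | None = None
    deviance: float = np.nan


@dataclass
class RegressionResult:
    """Coefficients, standard errors, covariance, fit statistics and the
    convergence record of one fitted model."""

    model: Literal["linear", "logistic"]
    column_order: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    fit: dict
    n: int
    p: int
    converged: bool = True
    n_iter: int = 1
    termination_reason: Literal["converged", "max-iter-reached"] = "converged"

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.cov_beta = np.asarray(self.cov_beta, dtype=float)

    def to_dict(self) -> dict:
        stat_label = "t" if self.model == "linear" else "z"
        coef_table = [
            {
                "name": name,
                "estimate": float(b),
                "se": float(s),
                stat_label: float(b / s) if s > 0 else float("nan"),
            }
            for name, b, s in zip(self.column_order, self.beta, self.se)
        ]
        return {
            "model": self.model,
            "n": self.n,
            "p": self.p,
            "coefficients": coef_table,
            "cov_beta": self.cov_beta.tolist(),
            "fit": {k: float(v) for k, v in self.fit.items()},
            "convergence": {
                "converged": self.converged,
                "n_iter": self.n_iter,
                "termination_reason": self.termination_reason,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionResult":
        names = tuple(c["name"] for c in d["coefficients"])
        beta = np.array([c["estimate"] for c in d["coefficients"]])
        se = np.array([c["se"] for c in d["coefficients"]])
        conv = d.get("convergence", {})
        return cls(
            model=d["model"],
            column_order=names,
            beta=beta,
            se=se,
            cov_beta=np.asarray(d.get("cov_beta", np.diag(se**2))),
            fit=d.get("fit", {}),
            n=int(d["n"]),
            p=int(d["p"]),
            converged=bool(conv.get("converged", True)),
            n_iter=int(conv.get("n_iter", 1)),
            termination_reason=conv.get("termination_reason", "converged"),
        )

    @classmethod
    def from_json(cls, path) -> "RegressionResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def summary(self) -> str:
        lines = [
            f"{self.model} regression  (n = {self.n}, p = {self.p})",
            f"{'term':<16}{'estimate':>14}{'std. error':>14}",
        ]
        for name, b, s in zip(self.column_order, self.beta, self.se):
            lines.append(f"{name:<16}{b:>14.6g}{s:>14.6g}")
        lines.append("fit: " + ", ".join(f"{k} = {v:.6g}" for k, v in self.fit.items()))
        lines.append(
            f"convergence: {self.termination_reason} after {self.n_iter} iteration(s)"
        )
        return "\n".join(lines)


def _block_lookup(blocks: Sequence[GramBlock]) -> dict:
    table = {}
    for blk in blocks:
        table[(blk.site_i, blk.site_j)] = blk
    return table


def assemble_global_gram(
    blocks: Sequence[GramBlock],
    site_columns: Sequence[tuple[str, Sequence[str]]],
    n: int,
    column_sums: Mapping[str, np.ndarray],
    y_blocks: Mapping[str, np.ndarray],
    y_sum: float,
    yty: float,
    intercept_self: float | None = None,
) -> GlobalGram:
    """Assemble the intercept-augmented global Gram matrix from site blocks.

    ``site_columns`` fixes the global column order (sites in plan order,
    each site's columns in declared order; the intercept is synthesized at
    the center from ``n`` and the per-site ``column_sums``).  Diagonal
    blocks X_k'X_k and one orientation of each off-diagonal block X_i'X_j
    must be present in ``blocks``; ``y_blocks`` maps each site to its
    X_k'y vector.  ``intercept_self`` overrides the [0, 0] entry (1'W1 in a
    weighted assembly; defaults to n, the unweighted value).
    """
    order = [INTERCEPT]
    offsets: dict[str, slice] = {}
    pos = 1
    for site, cols in site_columns:
        cols = list(cols)
        offsets[site] = slice(pos, pos + len(cols))
        order.extend(cols)
        pos += len(cols)
    p1 = pos
    G = np.zeros((p1, p1))
    Xty = np.zeros(p1)
    G[0, 0] = float(n) if intercept_self is None else float(intercept_self)
    Xty[0] = float(y_sum)

    lookup = _block_lookup(blocks)
    for site, cols in site_columns:
        cols = list(cols)
        sl = offsets[site]
        if site not in column_sums:
            raise IncompleteBlocksError(f"missing column sums for site {site!r}")
        cs = np.asarray(column_sums[site], dtype=float).ravel()
        if cs.shape[0] != len(cols):
            raise AssemblyError(
                f"column sums for site {site!r} have length {cs.shape[0]}, "
                f"expected {len(cols)}"
            )
        G[0, sl] = cs
        G[sl, 0] = cs
        diag = lookup.get((site, site))
        if diag is None:
            raise IncompleteBlocksError(f"missing diagonal Gram block ({site!r}, {site!r})")
        if diag.shape != (len(cols), len(cols)):
            raise AssemblyError(
                f"diagonal block for {site!r} has shape {diag.shape}, "
                f"expected {(len(cols), len(cols))}"
            )
        G[sl, sl] = diag.block
        if site not in y_blocks:
            raise IncompleteBlocksError(f"missing X'y block for site {site!r}")
        yb = np.asarray(y_blocks[site], dtype=float).ravel()
        if yb.shape[0] != len(cols):
            raise AssemblyError(
                f"X'y block for site {site!r} has length {yb.shape[0]}, expected {len(cols)}"
            )
        Xty[sl] = yb

    site_ids = [s for s, _ in site_columns]
    for a_idx in range(len(site_ids)):
        for b_idx in range(a_idx + 1, len(site_ids)):
            si, sj = site_ids[a_idx], site_ids[b_idx]
            blk = lookup.get((si, sj))
            transpose = False
            if blk is None:
                blk = lookup.get((sj, si))
                transpose = True
            if blk is None:
                raise IncompleteBlocksError(
                    f"missing off-diagonal Gram block for site pair ({si!r}, {sj!r})"
                )
            M = blk.block.T if transpose else blk.block
            sl_i, sl_j = offsets[si], offsets[sj]
            want = (sl_i.stop - sl_i.start, sl_j.stop - sl_j.start)
            if M.shape != want:
                raise AssemblyError(
                    f"off-diagonal block ({si!r}, {sj!r}) has shape {M.shape}, expected {want}"
                )
            G[sl_i, sl_j] = M
            G[sl_j, sl_i] = M.T

    return GlobalGram(column_order=tuple(order), G=G, Xty=Xty, yty=float(yty), n=int(n))


def build_linear_gram(
    partitions: Sequence[SitePartition],
    outcome: tuple[str, str],
    seed: int = 0,
    g: int | None = None,
    channel=None,
    block_plan=None,
    center: str | None = None,
) -> GlobalGram:
    """Compute the sufficient statistics for a distributed linear model.

    Each site contributes its diagonal Gram block, column sums and (at the
    outcome site) the outcome statistics locally; every cross-site block —
    including X_k'y for sites that do not hold y, which rides along with the
    outcome owner's columns — runs the sequential secure protocol over
    ``channel``.  With ``block_plan`` the cross products are computed
    block-wise and summed (divide-and-conquer).  When ``center`` is given,
    each site also uploads its finished summary statistics to that party
    through the channel, mirroring the real transfer workflow.
    """
    outcome_site, outcome_col = outcome
    parts = {p.site_id: p for p in partitions}
    if outcome_site not in parts or outcome_col not in parts[outcome_site].columns:
        raise DomainError(f"outcome column {outcome_col!r} not found at site {outcome_site!r}")
    site_cols = [
        (p.site_id, [c for c in p.columns if not (p.site_id == outcome_site and c == outcome_col)])
        for p in partitions
    ]
    n = partitions[0].n
    blocks: list[GramBlock] = []
    column_sums: dict[str, np.ndarray] = {}
    y_blocks: dict[str, np.ndarray] = {}
    y = parts[outcome_site].matrix([outcome_col]).ravel()
    y_sum, yty = float(y.sum()), float(y @ y)
    for s, cols in site_cols:
        X = parts[s].matrix(cols)
        blocks.append(GramBlock(s, s, X.T @ X, n, tuple(cols), tuple(cols)))
        column_sums[s] = X.sum(axis=0)
        if s == outcome_site:
            y_blocks[s] = X.T @ y
        if channel is not None and center is not None:
            stats = np.vstack([X.T @ X, X.sum(axis=0)])
            if s == outcome_site:
                stats = np.column_stack(
                    [stats, np.concatenate([y_blocks[s], [y_sum]])])
                channel.send(s, center, f"site-stats-{s}-yty", np.array([[yty]]))
            if stats.size:
                channel.send(s, center, f"site-stats-{s}", stats)
    for a in range(len(site_cols)):
        for b in range(a + 1, len(site_cols)):
            sa, ca = site_cols[a]
            sb, cb = site_cols[b]
            cols_a = ca + ([outcome_col] if sa == outcome_site else [])
            cols_b = cb + ([outcome_col] if sb == outcome_site else [])
            if block_plan is not None:
                blk = blocked_cross_product(
                    parts[sa], parts[sb], block_plan, g=g, seed=seed,
                    channel=channel, columns_a=cols_a, columns_b=cols_b)
            else:
                blk = secure_cross_product(
                    parts[sa], parts[sb], g=g, seed=pair_seed(seed, sa, sb),
                    channel=channel, columns_a=cols_a, columns_b=cols_b)
            M = blk.block
            if sa == outcome_site:
                y_blocks[sb] = M[-1, : len(cb)].copy()
                M = M[: len(ca), :]
            if sb == outcome_site:
                y_blocks[sa] = M[: len(ca), -1].copy()
                M = M[:, : len(cb)]
            blocks.append(GramBlock(sa, sb, M.reshape(len(ca), len(cb)), n,
                                    tuple(ca), tuple(cb)))
            if channel is not None and center is not None and M.size:
                # the computing site uploads the finished block to the center
                channel.send(sa, center, f"gram-{sa}-{sb}", M)
    return assemble_global_gram(
        blocks, site_cols, n=n, column_sums=column_sums, y_blocks=y_blocks,
        y_sum=y_sum, yty=yty)


def _solve_spd(G: np.ndarray, rhs: np.ndarray, condition_limit: float = CONDITION_LIMIT):
    """Solve G x = rhs for symmetric positive-definite G via Cholesky,
    guarding against near-singularity; also returns G^{-1}."""
    cond = np.linalg.cond(G)
    if not np.isfinite(cond) or cond > condition_limit:
        raise CollinearityError(
            f"global Gram matrix is numerically singular (condition number {cond:.3e})"
        )
    try:
        cho = scipy.linalg.cho_factor(G, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - cond check fires first
        raise CollinearityError(str(exc)) from exc
    x = scipy.linalg.cho_solve(cho, rhs)
    Ginv = scipy.linalg.cho_solve(cho, np.eye(G.shape[0]))
    return x, Ginv


def fit_linear_distributed(
    gram: GlobalGram, condition_limit: float = CONDITION_LIMIT, df_resid: int | None = None
) -> RegressionResult:
    """Weighted-sum-free OLS from the global Gram statistics alone.

    ``df_resid`` defaults to n - p - 1 (the residual degrees of freedom with
    an intercept); the error variance convention is configurable because
    different production systems disagree on the denominator.
    """
    beta, Ginv = _solve_spd(gram.G, gram.Xty, condition_limit)
    n, p = gram.n, gram.p
    if df_resid is None:
        df_resid = n - p - 1
    sse = float(gram.yty - 2 * beta @ gram.Xty + beta @ gram.G @ beta)
    sse = max(sse, 0.0)
    sigma2 = sse / df_resid
    cov = sigma2 * Ginv
    se = np.sqrt(np.diag(cov))
    ybar = gram.Xty[0] / n
    sst = float(gram.yty - n * ybar**2)
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_resid if sst > 0 else float("nan")
    return RegressionResult(
        model="linear",
        column_order=gram.column_order,
        beta=beta,
        se=se,
        cov_beta=cov,
        fit={"sigma2": sigma2, "R2": r2, "adj_R2": adj_r2},
        n=n,
        p=p,
    )


def convergence_check(
    state_prev: IterationState, state_new: IterationState, conv: ConvergenceSpec
) -> str:
    """Classify an IRLS step as ``continue``, ``converged`` (criterion value
    strictly below tol) or ``max-iter-reached``."""
    if conv.criterion == "max-abs-delta-beta":
        value = float(np.max(np.abs(state_new.beta - state_prev.beta)))
    elif conv.criterion == "relative-deviance-change":
        denom = max(abs(state_prev.deviance), 1e-12)
        value = abs(state_new.deviance - state_prev.deviance) / denom
    else:  # pragma: no cover - ConvergenceSpec validates
        raise SpecificationError(f"unknown criterion {conv.criterion!r}")
    if value < conv.tol:
        return "converged"
    if state_new.iter_index >= conv.max_iter:
        return "max-iter-reached"
    return "continue"


def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def _weighted_gram(
    sites: Sequence[SitePartition],
    site_cols: list[tuple[str, list[str]]],
    w: np.ndarray,
    z: np.ndarray,
    channel,
    seed: int,
    g: int | None,
    iteration: int,
):
    """One round of weighted sufficient statistics: [1 X]'W[1 X] and
    [1 X]'Wz.  Diagonal blocks and X_k'Wz are local to each site (w and z
    are broadcast by the center); cross-site blocks run the secure
    protocol."""
    blocks: list[GramBlock] = []
    column_sums = {}
    y_blocks = {}
    for idx, (site, cols) in enumerate(site_cols):
        X = sites[idx].matrix(cols)
        blocks.append(
            GramBlock(site, site, (X * w[:, None]).T @ X, sites[idx].n, tuple(cols), tuple(cols))
        )
        column_sums[site] = X.T @ w
        y_blocks[site] = X.T @ (w * z)
    for a in range(len(site_cols)):
        for b in range(a + 1, len(site_cols)):
            sa, ca = site_cols[a]
            sb, cb = site_cols[b]
            blocks.append(
                secure_cross_product_weighted(
                    sites[a],
                    sites[b],
                    w,
                    g=g,
                    seed=pair_seed(seed, sa, sb, iteration),
                    channel=channel,
                    columns_a=ca,
                    columns_b=cb,
                )
            )
    return assemble_global_gram(
        blocks,
        site_cols,
        n=sites[0].n,
        column_sums=column_sums,
        y_blocks=y_blocks,
        y_sum=float(w @ z),
        yty=float(z @ (w * z)),
        intercept_self=float(w.sum()),
    )


def fit_logistic_distributed(
    sites: Sequence[SitePartition],
    outcome: tuple[str, str],
    conv: ConvergenceSpec | None = None,
    channel=None,
    seed: int = 0,
    g: int | None = None,
    center: str = CENTER_ID,
    condition_limit: float = CONDITION_LIMIT,
    beta_init: np.ndarray | None = None,
    deviance_trace: list | None = None,
) -> RegressionResult:
    """Distributed IRLS for logistic regression.

    ``outcome = (site_id, column)`` names the binary outcome and the site
    holding it; the remaining columns of every site enter as covariates in
    site order.  Per iteration each site sends its partial linear predictor
    eta_k = X_k beta_k to the center; the center forms mu = expit(eta),
    weights w = mu(1 - mu) and the working response z = eta + (y - mu)/w and
    broadcasts (w, z); the sites then produce the weighted Gram blocks
    (cross-site blocks via the secure protocol) and the center solves the
    weighted normal equations.  Iteration stops per ``conv``; the final
    covariance is (X'WX)^{-1} at the converged coefficients.

    ``beta_init`` warm-starts the loop (default: all zeros); a caller-owned
    ``deviance_trace`` list collects the per-iteration deviance.
    """
    conv = conv or ConvergenceSpec()
    channel = channel if channel is not None else InMemoryChannel()
    outcome_site, outcome_col = outcome
    site_cols: list[tuple[str, list[str]]] = []
    outcome_partition = None
    for part in sites:
        cols = [c for c in part.columns if not (part.site_id == outcome_site and c == outcome_col)]
        site_cols.append((part.site_id, cols))
        if part.site_id == outcome_site:
            outcome_partition = part
    if outcome_partition is None or outcome_col not in outcome_partition.columns:
        raise DomainError(f"outcome column {outcome_col!r} not found at site {outcome_site!r}")
    for part in sites[1:]:
        if not sites[0].aligned_with(part):
            raise DomainError("site partitions are not row-aligned")
    y = outcome_partition.matrix([outcome_col]).ravel()
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise DomainError("logistic regression requires a binary (0/1) outcome")
    # the outcome site shares y with the semitrusted center once, so the
    # center can form the working response each iteration
    y = channel.send(outcome_site, center, "outcome-vector", y.reshape(-1, 1)).ravel()

    n = sites[0].n
    p1 = 1 + sum(len(c) for _, c in site_cols)
    offsets: dict[str, slice] = {}
    pos = 1
    for site, cols in site_cols:
        offsets[site] = slice(pos, pos + len(cols))
        pos += len(cols)

    def linear_predictor(beta: np.ndarray) -> tuple[np.ndarray, dict]:
        partial = {}
        eta = np.full(n, beta[0])
        for idx, (site, cols) in enumerate(site_cols):
            if not cols:
                continue
            eta_k = sites[idx].matrix(cols) @ beta[offsets[site]]
            eta_k = channel.send(site, center, "partial-linear-predictor", eta_k.reshape(-1, 1))
            partial[site] = eta_k.ravel()
            eta = eta + partial[site]
        return eta, partial

    def broadcast_weights(w: np.ndarray, z: np.ndarray) -> None:
        payload = np.column_stack([w, z])
        for site, _cols in site_cols:
            channel.send(center, site, "irls-weights", payload)

    if beta_init is not None:
        beta = np.asarray(beta_init, dtype=float).copy()
        if beta.shape != (p1,):
            raise SpecificationError(f"beta_init must have length {p1}")
    else:
        beta = np.zeros(p1)
    state = IterationState(iter_index=0, beta=beta.copy())
    status = "continue"
    n_iter = 0
    for it in range(1, conv.max_iter + 1):
        n_iter = it
        eta, partial = linear_predictor(beta)
        mu = expit(eta)
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        broadcast_weights(w, z)
        gram = _weighted_gram(sites, site_cols, w, z, channel, seed, g, it)
        beta_new, _ = _solve_spd(gram.G, gram.Xty, condition_limit)
        if not np.all(np.isfinite(beta_new)) or np.max(np.abs(beta_new)) > 1e10:
            raise SeparationError(
                "IRLS diverged: coefficients are unbounded (complete separation?)"
            )
        new_state = IterationState(
            iter_index=it,
            beta=beta_new,
            partial_linear_predictors=partial,
            weights=w,
            deviance=_binomial_deviance(y, mu),
        )
        if deviance_trace is not None:
            deviance_trace.append(new_state.deviance)
        status = convergence_check(state, new_state, conv)
        state = new_state
        beta = beta_new
        if status in ("converged", "max-iter-reached"):
            break

    # final pass at the converged coefficients: deviance and (X'WX)^{-1}
    eta, _ = linear_predictor(beta)
    mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
    w = mu * (1 - mu)
    z = eta + (y - mu) / w
    broadcast_weights(w, z)
    gram = _weighted_gram(sites, site_cols, w, z, channel, seed, g, conv.max_iter + 1)
    _, Ginv = _solve_spd(gram.G, gram.Xty, condition_limit)
    deviance = _binomial_deviance(y, mu)
    aic = deviance + 2 * p1
    se = np.sqrt(np.diag(Ginv))
    converged = status == "converged"
    return RegressionResult(
        model="logistic",
        column_order=gram.column_order,
        beta=beta,
        se=se,
        cov_beta=Ginv,
        fit={"deviance": deviance, "AIC": aic},
        n=n,
        p=p1 - 1,
        converged=converged,
        n_iter=n_iter,
        termination_reason="converged" if converged else "max-iter-reached",
    )


def pooled_oracle_fit(
    table: PatientTable,
    model: Literal["linear", "logistic"],
    covariate_columns: Sequence[str],
    outcome_column: str,
) -> RegressionResult:
    """Standard pooled patient-level fit (statsmodels), used as the oracle
    the distributed results must reproduce.  Test/verification path only:
    this is the single operation in the module that sees patient-level
    data."""
    import statsmodels.api as sm

    cols = list(covariate_columns)
    X = np.column_stack([np.ones(table.n), table.matrix(cols)])
    y = table.matrix([outcome_column]).ravel()
    order = (INTERCEPT, *cols)
    if model == "linear":
        res = sm.OLS(y, X).fit()
        fit = {
            "sigma2": float(res.scale),
            "R2": float(res.rsquared),
            "adj_R2": float(res.rsquared_adj),
        }
        n_iter = 1
        converged = True
    elif model == "logistic":
        # tight tolerance so the oracle's information matrix is evaluated at
        # the ML optimum, not one deviance-rule step short of it
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=1e-12, maxiter=200)
        fit = {"deviance": float(res.deviance), "AIC": float(res.aic)}
        n_iter = len(res.fit_history["deviance"]) - 1
        converged = bool(res.converged)
    else:
        raise SpecificationError(f"unknown model {model!r}")
    return RegressionResult(
        model=model,
        column_order=order,
        beta=np.asarray(res.params),
        se=np.asarray(res.bse),
        cov_beta=np.asarray(res.cov_params()),
        fit=fit,
        n=table.n,
        p=len(cols),
        converged=converged,
        n_iter=n_iter,
        termination_reason="converged" if converged else "max-iter-reached",
    )


@dataclass
class ComparisonReport:
    """Element-wise agreement between two regression results."""

    max_abs_diff_beta: float
    max_abs_diff_se: float
    fit_diffs: dict
    tol: float
    passed: bool
    worst_term: str

    def to_dict(self) -> dict:
        return {
            "max_abs_diff_beta": self.max_abs_diff_beta,
            "max_abs_diff_se": self.max_abs_diff_se,
            "fit_diffs": self.fit_diffs,
            "tol": self.tol,
            "passed": self.passed,
            "worst_term": self.worst_term,
        }


def compare_results(a: RegressionResult, b: RegressionResult, tol: float = 1e-12) -> ComparisonReport:
    """Compare coefficients, standard errors and shared fit statistics of
    two results fitted on the same columns; ``passed`` requires both the
    beta and se max-abs differences to be <= tol."""
    if a.model != b.model:
        raise ComparisonError(f"cannot compare {a.model} with {b.model} results")
    if tuple(a.column_order) != tuple(b.column_order):
        raise ComparisonError(
            f"column orders differ: {a.column_order} vs {b.column_order}"
        )
    d_beta = np.abs(a.beta - b.beta)
    d_se = np.abs(a.se - b.se)
    worst_idx = int(np.argmax(np.maximum(d_beta, d_se)))
    fit_diffs = {
        k: abs(float(a.fit[k]) - float(b.fit[k])) for k in set(a.fit) & set(b.fit)
    }
    max_beta = float(np.max(d_beta))
    max_se = float(np.max(d_se))
    return ComparisonReport(
        max_abs_diff_beta=max_beta,
        max_abs_diff_se=max_se,
        fit_diffs=fit_diffs,
        tol=tol,
        passed=bool(max_beta <= tol and max_se <= tol),
        worst_term=a.column_order[worst_idx],
    )
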