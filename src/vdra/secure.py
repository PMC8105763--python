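"""Site-side intermediate statistics: Gram blocks and the sequential secure
cross-product protocol.

The global covariance matrix X'X of the virtual pooled design is assembled
from site-specific blocks X_k'X_k (computed locally) and off-diagonal
blocks X_a'X_b that span two sites.  The off-diagonal blocks are computed by
a two-message, sequential projection-masking protocol in which neither site
ever receives the other's patient-level columns:

1. Site A draws Z, an n x g matrix with orthonormal columns spanning a
   random g-dimensional subspace of the orthogonal complement of A's column
   space (so Z'X_a = 0), and sends Z to site B.
2. Site B replies with the masked payload M = X_b - Z (Z'X_b) — its columns
   with their components along Z removed.
3. Site A computes X_a' M = X_a'X_b - (X_a'Z)(Z'X_b) = X_a'X_b.

The payload has n rows (it scales with cohort size, not covariate count),
which is exactly why vertically partitioned regression moves far larger
files than the horizontal setting, where only p x p summaries travel.  The
full n x n masking operator I - ZZ' is never materialized: B applies it as
X_b - Z(Z'X_b).  A ``materialize_full_operator`` option reproduces the n x n
payload for transfer-metrics experiments.

All randomness is seeded; per-block seeds derive from (seed, site pair,
block index).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import BlockPlan, SitePartition, partition_blocks
from .errors import AlignmentError, DimensionError, DomainError, SpecificationError

__all__ = [
    "GramBlock",
    "MaskBasis",
    "MaskedPayload",
    "InMemoryChannel",
    "gram_self",
    "make_mask_basis",
    "secure_cross_product",
    "secure_cross_product_weighted",
    "blocked_cross_product",
    "leakage_check",
    "default_mask_dim",
    "pair_seed",
]


@dataclass
class GramBlock:
    """A cross-product block X_i' X_j between the columns of two sites."""

    site_i: str
    site_j: str
    block: np.ndarray  # p_i x p_j
    n_rows: int
    row_names: tuple[str, ...] = ()
    col_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.block = np.atleast_2d(np.asarray(self.block, dtype=float))

    @property
    def shape(self) -> tuple[int, int]:
        return self.block.shape


@dataclass
class MaskBasis:
    """Orthonormal basis Z of a random subspace orthogonal to the owner's
    column space; the first protocol message."""

    owner_site: str
    Z: np.ndarray  # n x g, Z'Z = I, Z'X_owner = 0
    g: int


@dataclass
class MaskedPayload:
    """The second protocol message: another site's columns with their
    components along the mask basis removed.  Has n rows."""

    producer_site: str
    matrix: np.ndarray  # n x p_j
    provenance: dict = field(default_factory=dict)


class InMemoryChannel:
    """Loopback message channel recording a protocol transcript.

    Used when the secure protocol runs without the file-transfer fabric
    (unit tests, single-process fits).  ``transcript`` entries are
    ``(from_party, to_party, label, shape)`` tuples, in send order.
    """

    def __init__(self):
        self.transcript: list[tuple[str, str, str, tuple[int, ...]]] = []

    def send(self, from_party: str, to_party: str, label: str, array: np.ndarray) -> np.ndarray:
        self.transcript.append((from_party, to_party, label, tuple(array.shape)))
        return array


def default_mask_dim(n: int, p_owner: int) -> int:
    """Default mask dimension g = floor((n - p)/2): half the dimensions the
    rank bound allows, balancing information hidden against payload size."""
    return max((n - p_owner) // 2, 0)


def pair_seed(seed: int, site_a: str, site_b: str, block_index: int = 0) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        [
            int(seed) & 0xFFFFFFFF,
            zlib.crc32(site_a.encode()),
            zlib.crc32(site_b.encode()),
            int(block_index),
        ]
    )


def gram_self(partition: SitePartition, columns: Sequence[str] | None = None) -> GramBlock:
    """Site-specific covariance block X_k'X_k for the named local columns."""
    cols = list(columns) if columns is not None else partition.columns
    if not cols:
        raise SpecificationError("gram_self needs at least one column")
    X = partition.matrix(cols)
    return GramBlock(
        site_i=partition.site_id,
        site_j=partition.site_id,
        block=X.T @ X,
        n_rows=partition.n,
        row_names=tuple(cols),
        col_names=tuple(cols),
    )


def _orthonormal_complement_basis(X: np.ndarray, g: int, rng: np.random.Generator) -> np.ndarray:
    """Orthonormal n x g basis of a random subspace of the orthogonal
    complement of span(X), with Z'X driven to machine precision by repeated
    re-orthogonalization ("twice is enough")."""
    n = X.shape[0]
    if g == 0:
        return np.zeros((n, 0))
    Q, _ = np.linalg.qr(X)
    G = rng.standard_normal((n, g))
    R = G - Q @ (Q.T @ G)
    R -= Q @ (Q.T @ R)
    Z, _ = np.linalg.qr(R)
    Z -= Q @ (Q.T @ Z)
    Z, _ = np.linalg.qr(Z)
    Z -= Q @ (Q.T @ Z)
    return Z


def make_mask_basis(
    partition: SitePartition,
    g: int | None = None,
    seed: int | np.random.SeedSequence = 0,
    columns: Sequence[str] | None = None,
    X: np.ndarray | None = None,
) -> MaskBasis:
    """Construct the mask basis Z for a site's local design matrix.

    ``g`` defaults to floor((n - p)/2) and must satisfy g <= n - p; the
    basis is deterministic given ``seed``.  ``X`` overrides the partition's
    columns (used by the weighted protocol, which masks sqrt(w)-scaled
    columns).
    """
    if X is None:
        X = partition.matrix(columns)
    n, p = X.shape
    if g is None:
        g = default_mask_dim(n, p)
    if g < 0 or g > n - p:
        raise DimensionError(f"mask dimension g={g} outside [0, n - p] = [0, {n - p}]")
    rng = np.random.default_rng(seed)
    Z = _orthonormal_complement_basis(X, g, rng)
    return MaskBasis(owner_site=partition.site_id, Z=Z, g=g)


def _check_alignment(site_a: SitePartition, site_b: SitePartition) -> None:
    if site_a.n != site_b.n or not site_a.aligned_with(site_b):
        raise AlignmentError(
            f"partitions {site_a.site_id!r} and {site_b.site_id!r} are not row-aligned"
        )


def secure_cross_product(
    site_a: SitePartition,
    site_b: SitePartition,
    g: int | None = None,
    seed: int | np.random.SeedSequence = 0,
    channel=None,
    columns_a: Sequence[str] | None = None,
    columns_b: Sequence[str] | None = None,
    weights: np.ndarray | None = None,
    materialize_full_operator: bool = False,
) -> GramBlock:
    """Run the sequential secure protocol and return X_a' X_b.

    Messages pass through ``channel`` (an in-memory loopback by default, or
    the file-transfer fabric inside a network run) in the fixed order
    A -> B (mask basis), B -> A (masked payload).  Site A never sees raw
    X_b; site B never sees raw X_a.  With ``weights`` the protocol runs on
    sqrt(w)-scaled columns and returns X_a' diag(w) X_b.
    """
    _check_alignment(site_a, site_b)
    if channel is None:
        channel = InMemoryChannel()
    cols_a = list(columns_a) if columns_a is not None else site_a.columns
    cols_b = list(columns_b) if columns_b is not None else site_b.columns
    Xa = site_a.matrix(cols_a)
    Xb = site_b.matrix(cols_b)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != (site_a.n,):
            raise DomainError(f"weights must be a length-{site_a.n} vector")
        if np.any(w < 0):
            raise DomainError("weights must be nonnegative")
        sw = np.sqrt(w)[:, None]
        Xa = Xa * sw
        Xb = Xb * sw

    # -- at site A: draw the mask and send it (message 1, A -> B)
    basis = make_mask_basis(site_a, g=g, seed=seed, X=Xa)
    if materialize_full_operator:
        # n x n operator, for transfer-metrics experiments only
        op = np.eye(site_a.n) - basis.Z @ basis.Z.T
        received_op = channel.send(site_a.site_id, site_b.site_id, "mask-operator", op)
        masked = received_op @ Xb
    else:
        Z = channel.send(site_a.site_id, site_b.site_id, "mask-basis", basis.Z)
        # -- at site B: apply I - ZZ' without materializing it
        masked = Xb - Z @ (Z.T @ Xb)
    payload = MaskedPayload(
        producer_site=site_b.site_id,
        matrix=masked,
        provenance={
            "masked_by": site_a.site_id,
            "g": basis.g,
            "columns": list(cols_b),
            "weighted": weights is not None,
        },
    )
    # -- message 2, B -> A: the masked columns
    received = channel.send(site_b.site_id, site_a.site_id, "masked-columns", payload.matrix)
    # -- at site A: Z'X_a = 0, so X_a'(I - ZZ')X_b = X_a'X_b
    block = Xa.T @ received
    return GramBlock(
        site_i=site_a.site_id,
        site_j=site_b.site_id,
        block=block,
        n_rows=site_a.n,
        row_names=tuple(cols_a),
        col_names=tuple(cols_b),
    )


def secure_cross_product_weighted(
    site_a: SitePartition,
    site_b: SitePartition,
    w: np.ndarray,
    g: int | None = None,
    seed: int | np.random.SeedSequence = 0,
    channel=None,
    columns_a: Sequence[str] | None = None,
    columns_b: Sequence[str] | None = None,
) -> GramBlock:
    """X_a' diag(w) X_b via the secure protocol on sqrt(w)-scaled columns.

    Needed by the iterative (IRLS) fits, whose normal equations reweight
    every cross-product block at each iteration.
    """
    return secure_cross_product(
        site_a,
        site_b,
        g=g,
        seed=seed,
        channel=channel,
        columns_a=columns_a,
        columns_b=columns_b,
        weights=np.asarray(w, dtype=float),
    )


def blocked_cross_product(
    site_a: SitePartition,
    site_b: SitePartition,
    block_plan: BlockPlan,
    g: int | None = None,
    seed: int = 0,
    channel=None,
    columns_a: Sequence[str] | None = None,
    columns_b: Sequence[str] | None = None,
    weights: np.ndarray | None = None,
) -> GramBlock:
    """Divide-and-conquer cross product: run the secure protocol within each
    row block of ``block_plan`` and sum the per-block results.

    Cross products are additive over disjoint row blocks, so the sum equals
    the unblocked X_a'X_b; each block uses a mask drawn from its own derived
    seed and a mask dimension bounded by that block's row count.
    """
    _check_alignment(site_a, site_b)
    blocks_a = partition_blocks(site_a, block_plan)
    blocks_b = partition_blocks(site_b, block_plan)
    total: np.ndarray | None = None
    result: GramBlock | None = None
    for idx, (ba, bb) in enumerate(zip(blocks_a, blocks_b)):
        start, end = block_plan.block_boundaries[idx]
        wk = None if weights is None else np.asarray(weights, dtype=float)[start:end]
        gk = g
        if gk is not None:
            p_a = len(columns_a) if columns_a is not None else len(site_a.columns)
            gk = min(gk, max(ba.n - p_a, 0))
        result = secure_cross_product(
            ba,
            bb,
            g=gk,
            seed=pair_seed(seed, site_a.site_id, site_b.site_id, idx),
            channel=channel,
            columns_a=columns_a,
            columns_b=columns_b,
            weights=wk,
        )
        total = result.block if total is None else total + result.block
    assert result is not None and total is not None
    return GramBlock(
        site_i=site_a.site_id,
        site_j=site_b.site_id,
        block=total,
        n_rows=site_a.n,
        row_names=result.row_names,
        col_names=result.col_names,
    )


@dataclass
class LeakageReport:
    """What a masked payload reveals about the raw columns it derives from."""

    masking_active: bool
    max_abs_corr: float
    max_abs_diff: float
    flags: tuple[str, ...]

    @property
    def payload_equals_raw(self) -> bool:
        return self.max_abs_diff == 0.0


def leakage_check(payload: MaskedPayload, raw: np.ndarray) -> LeakageReport:
    """Compare a protocol payload against the raw columns it masks.

    Reports the maximum column-wise |correlation| between payload and raw
    columns and the element-wise max difference; flags ``NO-MASKING`` when
    the degenerate g = 0 mask was used (payload equals raw).
    """
    raw = np.asarray(raw, dtype=float)
    M = np.asarray(payload.matrix, dtype=float)
    flags = []
    g = int(payload.provenance.get("g", -1))
    if g == 0:
        flags.append("NO-MASKING")
    max_abs_diff = float(np.max(np.abs(M - raw))) if raw.size else 0.0
    max_corr = 0.0
    for i in range(M.shape[1]):
        for j in range(raw.shape[1]):
            a, b = M[:, i], raw[:, j]
            sa, sb = a.std(), b.std()
            if sa > 0 and sb > 0:
                c = abs(float(np.corrcoef(a, b)[0, 1]))
                max_corr = max(max_corr, c)
    if max_abs_diff == 0.0 and g != 0:
        flags.append("PAYLOAD-EQUALS-RAW")
    return LeakageReport(
        masking_active=g >= 1,
        max_abs_corr=max_corr,
        max_abs_diff=max_abs_diff,
        flags=tuple(flags),
    )
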