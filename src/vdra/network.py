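"""File-based simulation of a governed multi-party transfer fabric.

Models the workflow of a distributed-data-network file-transfer portal: each
party (one analysis center plus two or more data-contributing sites) owns an
``inbox/`` and ``outbox/`` directory under a versioned run directory; files
move only inside audited, checksummed, atomically delivered manifests; a
trust matrix owned by the analysis center governs which directed
site-to-site transfers are permitted (deny-by-default, mirroring the legacy
behavior where sites could talk only to the center); any transfer that
violates the trust matrix terminates the entire analysis run.

Routing is either ``hub_and_spoke`` — a site-to-site exchange is relayed
through the center as two legs — or ``direct`` — one leg, the enhancement
that halves transfer legs for the sequential cross-site protocol.  Time is a
deterministic logical clock (integer ticks), and every event is appended to
a JSON-lines audit log.

:func:`run_vdra_workflow` executes the full distributed regression over this
fabric: every inter-party matrix or vector is serialized as CSV with a JSON
sidecar, placed in the sender's outbox, and delivered through
:func:`transfer`.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .cohort import BlockPlan, SitePartition
from .errors import (
    ConfigError,
    IntegrityError,
    ManifestError,
    RoutingError,
    RunTerminatedError,
    TrustPermissionError,
    TrustViolationError,
    WorkflowError,
)
from .models import (
    CENTER_ID,
    ConvergenceSpec,
    RegressionResult,
    build_linear_gram,
    fit_linear_distributed,
    fit_logistic_distributed,
)

__all__ = [
    "NetworkConfig",
    "TrustMatrix",
    "TransferManifest",
    "AuditLog",
    "TransferMetrics",
    "Network",
    "NetworkChannel",
    "ModelSpec",
    "create_network",
    "set_trust",
    "transfer",
    "route",
    "send_files",
    "run_vdra_workflow",
    "report_metrics",
    "write_matrix",
    "read_matrix",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Topology of one simulated network run."""

    analysis_center: str
    sites: tuple[str, ...]
    root_path: str
    routing_mode: Literal["hub_and_spoke", "direct"] = "direct"
    batch_transfers: bool = True

    def validate(self) -> None:
        parties = (self.analysis_center, *self.sites)
        if len(set(parties)) != len(parties):
            raise ConfigError("duplicate party ids in network config")
        if len(self.sites) < 2:
            raise ConfigError("a vertical DRA network needs at least 2 sites")
        if self.routing_mode not in ("hub_and_spoke", "direct"):
            raise ConfigError(f"unknown routing mode {self.routing_mode!r}")

    @property
    def party_ids(self) -> tuple[str, ...]:
        return (self.analysis_center, *self.sites)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(
            analysis_center=d.get("analysis_center", CENTER_ID),
            sites=tuple(d["sites"]),
            root_path=d["root_path"],
            routing_mode=d.get("routing_mode", "direct"),
            batch_transfers=bool(d.get("batch_transfers", True)),
        )


@dataclass
class TrustMatrix:
    """Directed site-to-site transfer permissions, owned by the center.

    Transfers to or from the analysis center are always allowed; every
    site-to-site pair is forbidden until the center explicitly enables it.
    """

    owner: str
    allowed: dict = field(default_factory=dict)  # (from, to) -> bool
    version: int = 0

    def permits(self, from_party: str, to_party: str) -> bool:
        if self.owner in (from_party, to_party):
            return True
        return bool(self.allowed.get((from_party, to_party), False))

    def to_dict(self) -> dict:
        return {
            "owner": self.owner,
            "version": self.version,
            "allowed": [[f, t, bool(v)] for (f, t), v in sorted(self.allowed.items())],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrustMatrix":
        return cls(
            owner=d["owner"],
            allowed={(f, t): bool(v) for f, t, v in d.get("allowed", [])},
            version=int(d.get("version", 0)),
        )


@dataclass
class TransferManifest:
    """One batch of files moving between two parties in one delivery event."""

    request_id: str
    from_party: str
    to_party: str
    files: tuple[tuple[str, int, str], ...]  # (name, byte_size, sha256)
    created_at: int

    def __post_init__(self):
        if not self.files:
            raise ManifestError("a transfer manifest must list at least one file")

    def to_dict(self) -> dict:
        return {
            "request_id": self.request_id,
            "from": self.from_party,
            "to": self.to_party,
            "files": [list(f) for f in self.files],
            "created_at": self.created_at,
        }


class AuditLog:
    """Append-only, logically-clocked record of every transfer event."""

    EVENTS = ("submitted", "delivered", "rejected", "terminated")

    def __init__(self, path: Path):
        self.path = path
        self.entries: list[dict] = []

    def append(self, tick: int, event: str, manifest: TransferManifest | None, reason: str = ""):
        assert event in self.EVENTS
        entry = {
            "tick": tick,
            "event": event,
            "request_id": manifest.request_id if manifest else None,
            "from": manifest.from_party if manifest else None,
            "to": manifest.to_party if manifest else None,
            "reason": reason,
        }
        self.entries.append(entry)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry) + "\n")

    def count(self, event: str) -> int:
        return sum(1 for e in self.entries if e["event"] == event)

    def delivered_after(self, tick: int) -> int:
        return sum(1 for e in self.entries if e["event"] == "delivered" and e["tick"] > tick)


@dataclass
class TransferMetrics:
    """Per-run accounting of transfer volume.

    ``n_legs`` counts delivered manifests (one manifest = one leg);
    ``n_site_site_exchanges`` counts logical site-to-site exchanges before
    routing expansion, so in hub mode legs = direct legs + exchanges.
    """

    n_manifests: int = 0
    n_legs: int = 0
    n_site_site_exchanges: int = 0
    total_bytes: int = 0
    per_party_bytes: dict = field(default_factory=dict)
    max_payload_rows: int = 0
    max_payload_cols: int = 0

    def record_leg(self, manifest: TransferManifest) -> None:
        self.n_legs += 1
        nbytes = sum(size for _, size, _ in manifest.files)
        self.total_bytes += nbytes
        for party in (manifest.from_party, manifest.to_party):
            self.per_party_bytes[party] = self.per_party_bytes.get(party, 0) + nbytes

    def record_payload_dim(self, rows: int, cols: int) -> None:
        self.max_payload_rows = max(self.max_payload_rows, rows)
        self.max_payload_cols = max(self.max_payload_cols, cols)

    def to_dict(self) -> dict:
        return {
            "n_manifests": self.n_manifests,
            "n_legs": self.n_legs,
            "n_site_site_exchanges": self.n_site_site_exchanges,
            "total_bytes": self.total_bytes,
            "per_party_bytes": dict(self.per_party_bytes),
            "max_payload_rows": self.max_payload_rows,
            "max_payload_cols": self.max_payload_cols,
        }


class Network:
    """Live state of one simulated run: mailboxes, clock, trust, audit."""

    def __init__(self, config: NetworkConfig, trust: TrustMatrix, run_dir: Path):
        self.config = config
        self.trust = trust
        self.run_dir = run_dir
        self.clock = 0
        self.terminated = False
        self.metrics = TransferMetrics()
        self.audit = AuditLog(run_dir / "audit.jsonl")
        self._request_counter = 0

    def tick(self) -> int:
        self.clock += 1
        return self.clock

    def next_request_id(self) -> str:
        self._request_counter += 1
        return f"req-{self._request_counter:05d}"

    def mailbox(self, party: str, box: Literal["inbox", "outbox"]) -> Path:
        if party not in self.config.party_ids:
            raise RoutingError(f"unknown party {party!r}")
        return self.run_dir / party / box

    def save_trust(self) -> None:
        with open(self.run_dir / "trust.json", "w") as fh:
            json.dump(self.trust.to_dict(), fh, indent=2)


def create_network(config: NetworkConfig, trust: TrustMatrix | None = None) -> Network:
    """Create a fresh, versioned run directory with one mailbox pair per
    party.  Re-creating over an existing root starts run-0002, run-0003, …
    and leaves prior runs (and their audit logs) untouched."""
    config.validate()
    root = Path(config.root_path)
    root.mkdir(parents=True, exist_ok=True)
    version = 1
    while (root / f"run-{version:04d}").exists():
        version += 1
    run_dir = root / f"run-{version:04d}"
    for party in config.party_ids:
        for box in ("inbox", "outbox"):
            (run_dir / party / box).mkdir(parents=True)
    trust = trust or TrustMatrix(owner=config.analysis_center)
    if trust.owner != config.analysis_center:
        raise ConfigError("trust matrix must be owned by the analysis center")
    net = Network(config, trust, run_dir)
    net.save_trust()
    return net


def set_trust(network: Network, from_party: str, to_party: str, allowed: bool, actor: str) -> TrustMatrix:
    """Mutate one directed permission; only the analysis center may do so."""
    if actor != network.trust.owner:
        network.audit.append(
            network.tick(), "rejected", None,
            reason=f"trust mutation by non-owner {actor!r} refused",
        )
        raise TrustPermissionError(
            f"only the analysis center ({network.trust.owner!r}) may modify the trust matrix"
        )
    for party in (from_party, to_party):
        if party not in network.config.party_ids:
            raise RoutingError(f"unknown party {party!r}")
    network.trust.allowed[(from_party, to_party)] = bool(allowed)
    network.trust.version += 1
    network.save_trust()
    return network.trust


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def make_manifest(network: Network, from_party: str, to_party: str, filenames: Sequence[str]) -> TransferManifest:
    """Build a manifest for files sitting in the sender's outbox."""
    outbox = network.mailbox(from_party, "outbox")
    files = []
    for name in filenames:
        path = outbox / name
        if not path.exists():
            raise ManifestError(f"file {name!r} not found in {from_party!r}'s outbox")
        files.append((name, path.stat().st_size, _sha256(path)))
    return TransferManifest(
        request_id=network.next_request_id(),
        from_party=from_party,
        to_party=to_party,
        files=tuple(files),
        created_at=network.tick(),
    )


def transfer(network: Network, manifest: TransferManifest) -> dict:
    """Execute one manifest: trust check, checksum verification, atomic
    multi-file delivery into the receiver's inbox.

    A trust violation terminates the whole analysis run (audit ``rejected``
    then ``terminated``); a checksum mismatch merely rejects the manifest.
    Returns a delivery receipt.
    """
    if network.terminated:
        raise RunTerminatedError(
            f"run is terminated; manifest {manifest.request_id} refused"
        )
    network.audit.append(network.tick(), "submitted", manifest)
    network.metrics.n_manifests += 1
    if not network.trust.permits(manifest.from_party, manifest.to_party):
        network.audit.append(
            network.tick(), "rejected", manifest,
            reason=f"trust matrix forbids {manifest.from_party} -> {manifest.to_party}",
        )
        network.terminated = True
        network.audit.append(network.tick(), "terminated", manifest, reason="trust violation")
        raise TrustViolationError(
            f"transfer {manifest.from_party} -> {manifest.to_party} violates the "
            "trust matrix; analysis terminated"
        )
    outbox = network.mailbox(manifest.from_party, "outbox")
    inbox = network.mailbox(manifest.to_party, "inbox")
    # verify every file before moving any, so the batch lands atomically
    for name, _size, checksum in manifest.files:
        src = outbox / name
        if not src.exists():
            network.audit.append(network.tick(), "rejected", manifest, reason=f"missing file {name}")
            raise IntegrityError(f"file {name!r} vanished from sender outbox")
        if _sha256(src) != checksum:
            network.audit.append(
                network.tick(), "rejected", manifest, reason=f"checksum mismatch on {name}"
            )
            raise IntegrityError(f"checksum mismatch on {name!r}; manifest rejected")
    for name, _size, _checksum in manifest.files:
        shutil.copy2(outbox / name, inbox / name)
    tick = network.tick()
    network.audit.append(tick, "delivered", manifest)
    network.metrics.record_leg(manifest)
    return {
        "request_id": manifest.request_id,
        "delivered_at": tick,
        "n_files": len(manifest.files),
    }


def route(network: Network, from_party: str, to_party: str, filenames: Sequence[str]) -> list[TransferManifest]:
    """Expand one logical exchange into per-leg manifests.

    Hub-and-spoke relays site-to-site exchanges through the center (two
    legs); direct mode and any center-involved exchange use one leg.  Note
    the second hub leg's manifest is built only after the first is
    delivered (see :func:`send_files`); here both are described for
    planning by returning the leg endpoints.
    """
    for party in (from_party, to_party):
        if party not in network.config.party_ids:
            raise RoutingError(f"unknown party {party!r}")
    center = network.config.analysis_center
    hub = (
        network.config.routing_mode == "hub_and_spoke"
        and center not in (from_party, to_party)
    )
    if hub:
        first = make_manifest(network, from_party, center, filenames)
        second = TransferManifest(
            request_id=network.next_request_id(),
            from_party=center,
            to_party=to_party,
            files=first.files,
            created_at=network.tick(),
        )
        return [first, second]
    return [make_manifest(network, from_party, to_party, filenames)]


def send_files(network: Network, from_party: str, to_party: str, filenames: Sequence[str]) -> list[dict]:
    """Route and execute one logical exchange, relaying through the center's
    mailboxes in hub mode.  Counts one site-to-site exchange in the metrics
    when neither endpoint is the center."""
    center = network.config.analysis_center
    if center not in (from_party, to_party):
        network.metrics.n_site_site_exchanges += 1
    legs = route(network, from_party, to_party, filenames)
    receipts = [transfer(network, legs[0])]
    if len(legs) == 2:
        # the center relays: delivered files move from its inbox to its outbox
        inbox = network.mailbox(center, "inbox")
        outbox = network.mailbox(center, "outbox")
        for name in filenames:
            shutil.copy2(inbox / name, outbox / name)
        receipts.append(transfer(network, legs[1]))
    return receipts


# ---------------------------------------------------------------------------
# matrix payload serialization: CSV + JSON sidecar


def write_matrix(directory: Path, stem: str, M: np.ndarray, producer: str, provenance: str) -> list[str]:
    """Write a matrix payload as ``<stem>.csv`` plus a ``<stem>.json``
    sidecar (dimensions, producer, provenance, checksum); returns the two
    file names.  %.17g formatting makes the round trip bit-exact for
    doubles."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    csv_path = directory / f"{stem}.csv"
    np.savetxt(csv_path, M, delimiter=",", fmt="%.17g")
    sidecar = {
        "rows": int(M.shape[0]),
        "cols": int(M.shape[1]),
        "producer": producer,
        "provenance": provenance,
        "checksum": _sha256(csv_path),
    }
    with open(directory / f"{stem}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return [f"{stem}.csv", f"{stem}.json"]


def read_matrix(directory: Path, stem: str) -> np.ndarray:
    M = np.loadtxt(directory / f"{stem}.csv", delimiter=",", ndmin=2)
    with open(directory / f"{stem}.json") as fh:
        sidecar = json.load(fh)
    if M.shape != (sidecar["rows"], sidecar["cols"]):
        raise IntegrityError(f"payload {stem!r} dimensions disagree with sidecar")
    return M


class NetworkChannel:
    """Protocol message channel that moves every array through the transfer
    fabric as a CSV + sidecar batch, honoring routing mode and trust."""

    def __init__(self, network: Network):
        self.network = network
        self.center = network.config.analysis_center
        self.transcript: list[tuple[str, str, str, tuple[int, ...]]] = []
        self._counter = 0

    def send(self, from_party: str, to_party: str, label: str, array: np.ndarray) -> np.ndarray:
        array = np.atleast_2d(np.asarray(array, dtype=float))
        self._counter += 1
        stem = f"{self._counter:05d}-{label}"
        outbox = self.network.mailbox(from_party, "outbox")
        names = write_matrix(outbox, stem, array, from_party, label)
        if self.network.config.batch_transfers:
            send_files(self.network, from_party, to_party, names)
        else:
            for name in names:
                send_files(self.network, from_party, to_party, [name])
        self.network.metrics.record_payload_dim(*array.shape)
        self.transcript.append((from_party, to_party, label, tuple(array.shape)))
        return read_matrix(self.network.mailbox(to_party, "inbox"), stem)


@dataclass(frozen=True)
class ModelSpec:
    """Which model to fit and where the outcome lives."""

    model: Literal["linear", "logistic"]
    outcome_site: str
    outcome_column: str = "y"

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            model=d["model"],
            outcome_site=d["outcome_site"],
            outcome_column=d.get("outcome_column", "y"),
        )


def run_vdra_workflow(
    network: Network,
    partitions: Sequence[SitePartition],
    model_spec: ModelSpec,
    conv: ConvergenceSpec | None = None,
    seed: int = 0,
    g: int | None = None,
    block_plan: BlockPlan | None = None,
) -> tuple[RegressionResult, TransferMetrics, AuditLog]:
    """Execute the full distributed regression over the transfer fabric.

    Sites first compute their site-specific Gram blocks and column sums and
    upload them to the center; the off-diagonal blocks (and cross products
    with the outcome) then run the sequential secure protocol, with every
    message routed per the network's mode; finally the center assembles the
    global Gram matrix and solves the model (iterating for logistic).  Any
    trust violation terminates the run and propagates.
    """
    channel = NetworkChannel(network)
    outcome_site, outcome_col = model_spec.outcome_site, model_spec.outcome_column
    parts = {p.site_id: p for p in partitions}
    if set(parts) != set(network.config.sites):
        raise WorkflowError("partitions do not match the configured sites")
    site_order = [s for s in network.config.sites]
    try:
        if model_spec.model == "logistic":
            result = fit_logistic_distributed(
                [parts[s] for s in site_order],
                (outcome_site, outcome_col),
                conv=conv,
                channel=channel,
                seed=seed,
                g=g,
                center=network.config.analysis_center,
            )
            return result, network.metrics, network.audit

        gram = build_linear_gram(
            [parts[s] for s in site_order],
            (outcome_site, outcome_col),
            seed=seed,
            g=g,
            channel=channel,
            block_plan=block_plan,
            center=network.config.analysis_center,
        )
        result = fit_linear_distributed(gram)
        return result, network.metrics, network.audit
    finally:
        network.save_trust()


def report_metrics(metrics_a: TransferMetrics, metrics_b: TransferMetrics,
                   label_a: str = "direct", label_b: str = "hub_and_spoke") -> dict:
    """Side-by-side transfer accounting for two runs of the same fixture.

    Marks which quantities grow with cohort size n (the masked payloads, n
    rows each) versus covariate count p (the finished Gram blocks,
    p_i x p_j)."""
    table = {
        label_a: metrics_a.to_dict(),
        label_b: metrics_b.to_dict(),
        "leg_difference": metrics_b.n_legs - metrics_a.n_legs,
        "scaling": {
            "masked_payload_rows": "n (cohort size)",
            "gram_block_dims": "p_i x p_j (covariate counts)",
        },
    }
    return table
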