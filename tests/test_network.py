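"""Transfer-fabric governance: mailboxes, trust matrix, atomic batched
manifests, routing modes, termination semantics, and the full networked
workflow."""

import json

import numpy as np
import pytest

from vdra import (
    ConvergenceSpec,
    ModelSpec,
    NetworkConfig,
    compare_results,
    create_network,
    pooled_oracle_fit,
    report_metrics,
    route,
    run_vdra_workflow,
    send_files,
    set_trust,
    transfer,
)
from vdra.errors import (
    ConfigError,
    IntegrityError,
    ManifestError,
    RoutingError,
    RunTerminatedError,
    TrustPermissionError,
    TrustViolationError,
)
from vdra.network import TransferManifest, make_manifest

CENTER = "analysis_center"
SITES = ("site1", "site2")


@pytest.fixture()
def network(tmp_path):
    config = NetworkConfig(CENTER, SITES, str(tmp_path / "net"), routing_mode="direct")
    return create_network(config)


def drop_file(network, party, name, content="0.1,0.2\n"):
    path = network.mailbox(party, "outbox") / name
    path.write_text(content)
    return path


class TestCreateNetwork:
    def test_mailboxes_created_for_every_party(self, network):
        for party in (CENTER, *SITES):
            assert network.mailbox(party, "inbox").is_dir()
            assert network.mailbox(party, "outbox").is_dir()

    def test_zero_sites_rejected(self, tmp_path):
        with pytest.raises(ConfigError):
            create_network(NetworkConfig(CENTER, (), str(tmp_path)))

    def test_duplicate_party_ids_rejected(self, tmp_path):
        with pytest.raises(ConfigError):
            create_network(NetworkConfig(CENTER, (CENTER, "s"), str(tmp_path)))

    def test_recreate_versions_run_directory_and_preserves_audit(self, tmp_path):
        config = NetworkConfig(CENTER, SITES, str(tmp_path / "net"))
        first = create_network(config)
        drop_file(first, "site1", "f.csv")
        transfer(first, make_manifest(first, "site1", CENTER, ["f.csv"]))
        second = create_network(config)
        assert first.run_dir.name == "run-0001"
        assert second.run_dir.name == "run-0002"
        assert (first.run_dir / "audit.jsonl").exists()
        assert first.audit.count("delivered") == 1


class TestTrustMatrix:
    def test_center_can_permit_site_to_site(self, network):
        v0 = network.trust.version
        trust = set_trust(network, "site1", "site2", True, actor=CENTER)
        assert trust.permits("site1", "site2")
        assert trust.version == v0 + 1

    def test_site_cannot_self_authorize(self, network):
        with pytest.raises(TrustPermissionError):
            set_trust(network, "site1", "site2", True, actor="site1")
        assert not network.trust.permits("site1", "site2")

    def test_center_transfers_always_permitted(self, network):
        assert network.trust.permits("site1", CENTER)
        assert network.trust.permits(CENTER, "site2")

    def test_idempotent_reset_still_bumps_version(self, network):
        set_trust(network, "site1", "site2", True, actor=CENTER)
        v1 = network.trust.version
        set_trust(network, "site1", "site2", True, actor=CENTER)
        assert network.trust.version == v1 + 1
        assert network.trust.permits("site1", "site2")

    def test_deny_by_default_between_sites(self, network):
        assert not network.trust.permits("site1", "site2")
        assert not network.trust.permits("site2", "site1")


class TestTransfer:
    def test_batched_manifest_delivers_all_files(self, network):
        names = ["a.csv", "b.csv", "c.csv"]
        for name in names:
            drop_file(network, "site1", name, content=f"{name}\n")
        manifest = make_manifest(network, "site1", CENTER, names)
        receipt = transfer(network, manifest)
        assert receipt["n_files"] == 3
        inbox = network.mailbox(CENTER, "inbox")
        assert all((inbox / n).exists() for n in names)
        assert network.audit.count("delivered") == 1  # one manifest, one leg

    def test_forbidden_site_to_site_terminates_run(self, network):
        drop_file(network, "site1", "f.csv")
        manifest = make_manifest(network, "site1", "site2", ["f.csv"])
        with pytest.raises(TrustViolationError):
            transfer(network, manifest)
        assert network.terminated
        events = [e["event"] for e in network.audit.entries]
        assert events[-2:] == ["rejected", "terminated"]

    def test_no_deliveries_after_termination(self, network):
        drop_file(network, "site1", "f.csv")
        with pytest.raises(TrustViolationError):
            transfer(network, make_manifest(network, "site1", "site2", ["f.csv"]))
        tick = network.clock
        drop_file(network, "site2", "ok.csv")
        with pytest.raises(RunTerminatedError):
            transfer(network, make_manifest(network, "site2", CENTER, ["ok.csv"]))
        assert network.audit.delivered_after(tick) == 0
        assert not (network.mailbox(CENTER, "inbox") / "ok.csv").exists()

    def test_checksum_mismatch_rejects_without_terminating(self, network):
        path = drop_file(network, "site1", "f.csv")
        manifest = make_manifest(network, "site1", CENTER, ["f.csv"])
        path.write_text("tampered\n")
        with pytest.raises(IntegrityError):
            transfer(network, manifest)
        assert not network.terminated
        # an honest retry still works
        fresh = make_manifest(network, "site1", CENTER, ["f.csv"])
        assert transfer(network, fresh)["n_files"] == 1

    def test_empty_manifest_rejected(self, network):
        with pytest.raises(ManifestError):
            TransferManifest("req-x", "site1", CENTER, (), created_at=0)

    def test_every_inbox_file_has_a_delivered_manifest(self, network):
        # governance: nothing appears in an inbox without an audited delivery
        set_trust(network, "site1", "site2", True, actor=CENTER)
        for name in ("a.csv", "b.csv"):
            drop_file(network, "site1", name)
        send_files(network, "site1", CENTER, ["a.csv"])
        send_files(network, "site1", "site2", ["b.csv"])
        delivered = {
            (e["to"], name)
            for e in network.audit.entries if e["event"] == "delivered"
            for name in ("a.csv", "b.csv")
        }
        for party in (CENTER, *SITES):
            for f in network.mailbox(party, "inbox").iterdir():
                assert (party, f.name) in delivered


class TestRouting:
    def test_hub_mode_expands_site_to_site_into_two_legs(self, tmp_path):
        config = NetworkConfig(CENTER, SITES, str(tmp_path), routing_mode="hub_and_spoke")
        net = create_network(config)
        drop_file(net, "site1", "f.csv")
        legs = route(net, "site1", "site2", ["f.csv"])
        assert [(m.from_party, m.to_party) for m in legs] == [
            ("site1", CENTER), (CENTER, "site2")]

    def test_direct_mode_single_leg(self, network):
        drop_file(network, "site1", "f.csv")
        legs = route(network, "site1", "site2", ["f.csv"])
        assert [(m.from_party, m.to_party) for m in legs] == [("site1", "site2")]

    def test_center_bound_transfer_is_one_leg_in_either_mode(self, tmp_path):
        for mode in ("direct", "hub_and_spoke"):
            net = create_network(
                NetworkConfig(CENTER, SITES, str(tmp_path / mode), routing_mode=mode))
            drop_file(net, "site1", "f.csv")
            assert len(route(net, "site1", CENTER, ["f.csv"])) == 1

    def test_unknown_party_rejected(self, network):
        with pytest.raises(RoutingError):
            route(network, "site1", "nowhere", ["f.csv"])

    def test_hub_relay_actually_delivers(self, tmp_path):
        config = NetworkConfig(CENTER, SITES, str(tmp_path), routing_mode="hub_and_spoke")
        net = create_network(config)
        drop_file(net, "site1", "f.csv")
        send_files(net, "site1", "site2", ["f.csv"])
        assert (net.mailbox("site2", "inbox") / "f.csv").exists()
        assert net.metrics.n_legs == 2
        assert net.metrics.n_site_site_exchanges == 1


def run_workflow(tmp_path, partitions, model_spec, mode, seed=1, conv=None, block_plan=None):
    config = NetworkConfig(CENTER, SITES, str(tmp_path / mode), routing_mode=mode)
    net = create_network(config)
    if mode == "direct":
        for a in SITES:
            for b in SITES:
                if a != b:
                    set_trust(net, a, b, True, actor=CENTER)
    return run_vdra_workflow(
        net, partitions, model_spec, seed=seed, conv=conv, block_plan=block_plan)


class TestWorkflow:
    def test_linear_direct_matches_pooled_oracle(self, tmp_path, bmi_table, bmi_partitions):
        result, _metrics, _audit = run_workflow(
            tmp_path, bmi_partitions, ModelSpec("linear", "site2", "bmi"), "direct")
        oracle = pooled_oracle_fit(bmi_table, "linear", ["surgery", "sex", "race"], "bmi")
        assert compare_results(result, oracle, tol=1e-12).passed

    def test_hub_and_direct_agree_and_hub_costs_exactly_the_exchanges(
            self, tmp_path, bmi_partitions):
        spec = ModelSpec("linear", "site2", "bmi")
        res_d, met_d, _ = run_workflow(tmp_path, bmi_partitions, spec, "direct")
        res_h, met_h, _ = run_workflow(tmp_path, bmi_partitions, spec, "hub_and_spoke")
        assert compare_results(res_d, res_h, tol=1e-12).passed
        assert met_h.n_legs == met_d.n_legs + met_d.n_site_site_exchanges
        assert met_h.n_legs > met_d.n_legs

    def test_logistic_workflow_converges_over_the_network(
            self, tmp_path, logistic_table, logistic_partitions):
        result, metrics, _ = run_workflow(
            tmp_path, logistic_partitions, ModelSpec("logistic", "site2", "y"),
            "direct", conv=ConvergenceSpec(tol=1e-8, max_iter=25))
        assert result.converged and result.n_iter <= 25
        oracle = pooled_oracle_fit(
            logistic_table, "logistic", [f"x{i}" for i in range(1, 6)], "y")
        assert compare_results(result, oracle, tol=1e-8).passed
        assert metrics.max_payload_rows == logistic_partitions[0].n

    def test_workflow_without_trust_terminates_in_direct_mode(self, tmp_path, bmi_partitions):
        config = NetworkConfig(CENTER, SITES, str(tmp_path), routing_mode="direct")
        net = create_network(config)  # deny-by-default: no site pair enabled
        with pytest.raises(TrustViolationError):
            run_vdra_workflow(net, bmi_partitions, ModelSpec("linear", "site2", "bmi"), seed=1)
        assert net.terminated
        assert net.audit.count("terminated") == 1

    def test_blocked_workflow_equals_unblocked(self, tmp_path, bmi_partitions):
        from vdra import BlockPlan

        spec = ModelSpec("linear", "site2", "bmi")
        n = bmi_partitions[0].n
        res_u, _, _ = run_workflow(tmp_path / "u", bmi_partitions, spec, "direct")
        res_b, _, _ = run_workflow(
            tmp_path / "b", bmi_partitions, spec, "direct",
            block_plan=BlockPlan.even(n, 4))
        assert np.max(np.abs(res_u.beta - res_b.beta)) <= 1e-12
        assert np.max(np.abs(res_u.se - res_b.se)) <= 1e-12

    def test_gram_block_payloads_are_p_by_p_and_masks_n_rows(self, tmp_path, bmi_partitions):
        _result, metrics, _ = run_workflow(
            tmp_path, bmi_partitions, ModelSpec("linear", "site2", "bmi"), "direct")
        # masked payload row count equals the cohort size n
        assert metrics.max_payload_rows == bmi_partitions[0].n
        table = report_metrics(metrics, metrics)
        assert "n (cohort size)" in table["scaling"]["masked_payload_rows"]


class TestAuditIntegrity:
    def test_audit_is_append_only_jsonl(self, network):
        drop_file(network, "site1", "f.csv")
        transfer(network, make_manifest(network, "site1", CENTER, ["f.csv"]))
        lines = (network.run_dir / "audit.jsonl").read_text().strip().splitlines()
        events = [json.loads(line)["event"] for line in lines]
        assert events == ["submitted", "delivered"]
        ticks = [json.loads(line)["tick"] for line in lines]
        assert ticks == sorted(ticks)
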