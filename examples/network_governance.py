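"""Trust-matrix governance of the file-transfer fabric.

The analysis center owns a deny-by-default trust matrix over directed
site-to-site transfers.  A permitted batch is delivered atomically and
audited; a forbidden transfer terminates the entire analysis run, and no
manifest is delivered afterwards.
"""

import tempfile

from vdra import NetworkConfig, create_network, set_trust, transfer
from vdra.errors import RunTerminatedError, TrustPermissionError, TrustViolationError
from vdra.network import make_manifest

with tempfile.TemporaryDirectory() as root:
    net = create_network(NetworkConfig("analysis_center", ("site1", "site2"), root))

    # only the center may change permissions
    try:
        set_trust(net, "site1", "site2", True, actor="site1")
    except TrustPermissionError as exc:
        print(f"site1 self-authorization refused: {exc}")

    # a center-bound batch of several files is one audited manifest
    for name in ("gram.csv", "gram.json", "sums.csv"):
        (net.mailbox("site1", "outbox") / name).write_text("1,2,3\n")
    receipt = transfer(net, make_manifest(net, "site1", "analysis_center",
                                          ["gram.csv", "gram.json", "sums.csv"]))
    print(f"batch delivered: {receipt['n_files']} files in one manifest")

    # a forbidden site-to-site transfer terminates the run
    (net.mailbox("site1", "outbox") / "leak.csv").write_text("4,5,6\n")
    try:
        transfer(net, make_manifest(net, "site1", "site2", ["leak.csv"]))
    except TrustViolationError as exc:
        print(f"violation: {exc}")
    (net.mailbox("site2", "outbox") / "late.csv").write_text("7,8,9\n")
    try:
        transfer(net, make_manifest(net, "site2", "analysis_center", ["late.csv"]))
    except RunTerminatedError as exc:
        print(f"post-termination transfer refused: {exc}")

    print("audit trail:")
    for entry in net.audit.entries:
        print(f"  tick {entry['tick']:>2}  {entry['event']:<10} "
              f"{entry['from']} -> {entry['to']}  {entry['reason']}")
# The audit log shows submitted/delivered for the honest batch, then
# rejected + terminated for the violation, with zero deliveries after it.
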