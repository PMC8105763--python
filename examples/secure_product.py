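"""The sequential secure cross-product protocol, step by step.

Site A wants X_a'X_b without seeing site B's columns (and vice versa).  A
sends an orthonormal mask basis Z drawn from the orthogonal complement of
its own column space; B returns its columns with their Z-components removed;
A's multiplication cancels the mask exactly because Z'X_a = 0.
"""

import numpy as np

from vdra import InMemoryChannel, leakage_check, make_mask_basis, secure_cross_product
from vdra.secure import MaskedPayload
from vdra.studies import two_site_linear_fixture

_table, _plan, (site1, site2) = two_site_linear_fixture(seed=7, n=200)

channel = InMemoryChannel()
block = secure_cross_product(site1, site2, seed=3, channel=channel)

direct = site1.matrix().T @ site2.matrix()
print("protocol transcript (from, to, message, shape):")
for msg in channel.transcript:
    print("  ", msg)
print(f"max |secure - direct| = {np.max(np.abs(block.block - direct)):.3e}")

# what did site A actually learn about site B's raw column?
basis = make_mask_basis(site1, seed=3)
raw = site2.matrix()
masked = raw - basis.Z @ (basis.Z.T @ raw)
report = leakage_check(MaskedPayload("site2", masked, {"g": basis.g}), raw)
print(f"mask dimension g = {basis.g} of n = {site1.n} rows")
print(f"payload vs raw: max |difference| = {report.max_abs_diff:.3f}, "
      f"max |correlation| = {report.max_abs_corr:.3f}")
# The cross product is exact to ~1e-13 while the transferred payload differs
# from the raw outcome column in every masked direction.
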