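"""Divide-and-conquer blocking of the cross-site matrix computations.

Cross products are additive over disjoint row blocks, so the vertically
partitioned cohort can be sliced horizontally into blocks, each block's
cross products computed (and masked) independently, and the results summed.
The fitted model is identical to the unblocked fit while every single
matrix operation involves only block-sized payloads.
"""

from vdra.studies import blocking_study

stats = blocking_study(seed=1, n=600, p=6, n_blocks_list=(2, 4, 7))
print(f"block counts tested: {stats['n_blocks_tested']}")
print(f"max |blocked - unblocked| over beta and se: {stats['max_abs_diff']:.3e}")
# Agreement at ~1e-16 means blocking is free of statistical cost; it only
# bounds the size of any one masked payload.
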