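"""Dynamic channel masking and the distance-based electrode graph.

Masking draws a rate from {10%, 20%, 30%} per mini-batch and zeroes whole
channels; the spatial branch's adjacency decays with squared electrode
distance, clamped to [0.1, 1].
"""

import numpy as np

from dspmcf import MaskSampler, apply_mask, standard_62_channel_coords
from dspmcf.graph import ElectrodeGraph, SEED_62_CHANNELS

rng = np.random.default_rng(0)
x = rng.normal(size=(8, 62, 5))  # one (T, C, B) window

sampler = MaskSampler(C=62, grid=(0.1, 0.2, 0.3), mode="dynamic", seed=3)
spec = sampler()
xm = apply_mask(x, spec)
print(f"sampled rate {spec.rate:.0%} -> {len(spec.channels)} of 62 channels zeroed")
print(f"masked channels: {spec.channels}")
print(f"energy on masked channels after masking: {np.abs(xm[:, list(spec.channels)]).sum():.1f}")

graph = ElectrodeGraph.standard_62()
A = graph.adjacency
off = ~np.eye(62, dtype=bool)
print(f"\nadjacency range off-diagonal: [{A[off].min():.3f}, {A[off].max():.3f}]")
print(f"fraction of pairs at the 0.1 floor: {(A[off] == 0.1).mean():.2f}")
i = SEED_62_CHANNELS.index("CZ")
strongest = np.argsort(A[i])[::-1][1:4]
print(f"strongest neighbours of CZ: {[SEED_62_CHANNELS[j] for j in strongest]}")
# ^ nearest scalp neighbours get weights above the floor; distant pairs are
#   pruned to 0.1, keeping the graph effectively sparse.
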