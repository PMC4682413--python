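"""Pyramid geometry and storage overhead on a large chromosome.

Builds the multi-resolution max pyramid over a synthetic 10 Mb chromosome
and prints how many bins each level holds, which level serves which viewing
range, and the total storage overhead relative to the base level.
"""

import numpy as np

import basecov as bc

length = 10_000_000
rng = np.random.default_rng(0)
pos = rng.integers(0, 30, length).astype("<u4")
neg = rng.integers(0, 30, length).astype("<u4")
tracks = bc.BaseTrackSet(
    "chr10M", length, (pos + neg).astype("<u4"), pos, neg,
    np.zeros(length, dtype="<u4"),
)
pyr = bc.build_pyramid(tracks)

print(f"{pyr.n_levels} levels over a {length:,} bp chromosome:")
served = 20000
for lvl in pyr.levels:
    print(
        f"  level {lvl.level}: bin width {lvl.bin_width:>5} bp, "
        f"{lvl.n_bins:>10,} bins, serves ranges up to {served:,} bp"
    )
    served *= 20
print(f"storage overhead vs base level: {bc.storage_ratio(pyr):.4f}")

# Each level keeps the per-window MAXIMUM of the level below, so any bin at
# any zoom equals the max base-level depth over its span; the geometric
# series 1 + 1/20 + 1/400 + ... keeps total storage at ~1.05x the base level.
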