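"""Voxel-wise fractal parameter mapping on a synthetic two-region BOLD
phantom.

A 6x6 grid holds an anticorrelated 'background' (H' = 0.4, stationary fGn)
and a non-stationary 'cortex' (H' = 1.3, fBm); the pipeline maps the
spectral index beta, the extended Hurst exponent H', and the signal class
per voxel, then summarizes H' as a histogram.
"""

import numpy as np

from fractkit import (
    PhantomSpec,
    RegionParams,
    generate_phantom,
    map_histogram,
    map_parameters,
)
from fractkit.volume import CLASS_CODES

region_map = np.zeros((6, 6, 1), dtype=int)
region_map[2:5, 2:5, :] = 1  # 'cortex' block in the middle
spec = PhantomSpec(
    region_map,
    regions={0: RegionParams(hurst_prime=0.4), 1: RegionParams(hurst_prime=1.3)},
    n_timepoints=512,
    dt=1.0,
    noise_sd=0.1,
)
vol = generate_phantom(spec, seed=7)

maps = map_parameters(vol, params=("beta", "hprime", "class"))
hp = maps["hprime"].data
print(f"background H': {hp[region_map == 0].mean():.2f} (true 0.4)")
print(f"cortex     H': {hp[region_map == 1].mean():.2f} (true 1.3)")

truth = np.where(region_map == 0, CLASS_CODES["fGn"], CLASS_CODES["fBm"])
agreement = (maps["class"].data == truth).mean()
print(f"class map agreement with the phantom: {agreement:.0%}")

table, n_null = map_histogram(maps["hprime"], bins=np.linspace(0, 2, 11))
print("\nH' histogram (bin -> count):")
for _, row in table[table["count"] > 0].iterrows():
    print(f"  [{row.bin_left:.1f}, {row.bin_right:.1f})  {int(row['count'])}")
print("The two modes reproduce the phantom's two prescribed regions.")
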