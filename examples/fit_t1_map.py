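"""Pixel-wise T1 mapping of an inversion-recovery series.

Builds a two-compartment phantom (800 vs 2000 ms) sampled at the
8-point TI schedule, fits |M0 - (M0 - M(0)) exp(-t/T1)| per pixel and
prints the regional T1 means.
"""

import numpy as np

from rtbimr import fit_t1_map, regional_t1
from rtbimr.synthetic import IRStackSpec, generate_ir_stack

t1_map = np.full((12, 12), 800.0)
t1_map[:, 6:] = 2000.0
spec = IRStackSpec(true_t1_map=t1_map, true_m0_map=np.full((12, 12), 100.0),
                   noise_sd=1.0)  # 1% of M0
series = generate_ir_stack(spec, seed=0)
result = fit_t1_map(series)

left = np.zeros((12, 12), bool); left[:, :6] = True
for name, mask, truth in [("left (true 800 ms)", left, 800.0),
                          ("right (true 2000 ms)", ~left, 2000.0)]:
    r = regional_t1(result, mask)
    print(f"{name}: mean T1 = {r['mean_t1_ms']:.1f} ms "
          f"({r['n_converged']}/{r['n_pixels']} pixels converged)")
print()
print(f"{result.n_converged}/{result.n_fitted} pixels converged overall;")
print("regional means should recover the generating T1 within the noise.")
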