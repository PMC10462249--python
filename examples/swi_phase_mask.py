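"""SWI processing of a phantom slice with one susceptibility source.

Generates a wrapped-phase slice with a single positive-phase bump,
runs unwrap -> high-pass -> positive phase mask -> fourfold mask
multiplication and reports how the source footprint is darkened.
"""

import numpy as np

from rtbimr import process_swi
from rtbimr.synthetic import SWIPhantomSpec, generate_swi_phantom

spec = SWIPhantomSpec(magnitude=np.ones((96, 96)),
                      phase_sources=[((48, 48), 5.0, 4.0)],  # peak 4 rad, wraps
                      wrap=True)
image = generate_swi_phantom(spec, seed=0)
swi, mask = process_swi(image)

yy, xx = np.mgrid[0:96, 0:96]
r = np.hypot(yy - 48, xx - 48)
print(f"phase range emitted (wrapped): [{image.phase.min():.2f}, "
      f"{image.phase.max():.2f}] rad")
print(f"mask range: [{mask.mask.min():.3f}, {mask.mask.max():.3f}] "
      f"(phi_max = {mask.phi_max:.3f} rad)")
print(f"SWI at source core (r<3):  {swi[r < 3].mean():.3f}")
print(f"SWI in far field (r>40):   {swi[r > 40].mean():.3f}")
print()
print("The positive-phase source is darkened toward 0 while phase-free")
print("tissue keeps its magnitude (1.0) - the SWI contrast mechanism.")
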