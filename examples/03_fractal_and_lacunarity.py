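"""Box-counting fractal dimension and gliding-box lacunarity on known shapes.

FD measures space-filling complexity (2 for a filled plane, 1 for a curve,
log8/log3 ~ 1.893 for the Sierpinski carpet); lacunarity measures
gappiness (1 for a perfectly even cover, larger for clustered patterns).
"""

import numpy as np

from octaquant.metrics import fractal_dimension_boxcount, lacunarity_glidingbox
from octaquant.types import AcquisitionMeta, BinaryVesselMap


def vm(mask):
    return BinaryVesselMap(mask, "DVC", AcquisitionMeta("S", "OD", "DVC", 1, 1))


full = np.ones((1024, 1024), bool)
line = np.zeros((1024, 1024), bool)
line[512, :] = True

carpet = np.ones((1, 1), bool)
for _ in range(5):
    z = np.zeros_like(carpet)
    carpet = np.block([[carpet, carpet, carpet], [carpet, z, carpet], [carpet, carpet, carpet]])

print(f"FD filled square : {fractal_dimension_boxcount(vm(full), full):.3f}  (theory 2)")
print(f"FD straight line : {fractal_dimension_boxcount(vm(line), np.ones_like(line)):.3f}  (theory 1)")
fd = fractal_dimension_boxcount(vm(carpet), np.ones_like(carpet), box_sizes=(4, 8, 16, 32, 64))
print(f"FD Sierpinski    : {fd:.3f}  (theory {np.log(8)/np.log(3):.3f})")

region = np.ones((128, 128), bool)
clustered = np.zeros((128, 128), bool)
clustered[:32, :64] = True
uniform = np.zeros((128, 128), bool)
uniform[::4, ::2] = True  # same pixel count, spread out
print(f"lacunarity clustered: {lacunarity_glidingbox(vm(clustered), region, 16):.2f}")
print(f"lacunarity uniform  : {lacunarity_glidingbox(vm(uniform), region, 16):.2f}")
print("equal density, different heterogeneity -> lacunarity separates them")
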