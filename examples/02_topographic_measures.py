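"""Reference-free topographic measures: GFP, spatial correlation, DISS.

GFP measures the momentary strength of a scalp field; DISS compares two
fields' configurations independent of strength, from 0 (identical) to 2
(polarity-inverted), and is tied to the spatial correlation r by
DISS² = 2·(1 − r).
"""

import numpy as np

import erptopo as et

rng = np.random.default_rng(0)
montage = et.make_montage(64, seed=0)
u, v = et.make_templates(2, montage, rng=rng)

print(f"GFP(u)        = {et.gfp(u):.3f} μV (templates are unit-GFP)")
print(f"GFP(3u)       = {et.gfp(3 * u):.3f} μV (homogeneous in strength)")
print(f"DISS(u, u)    = {et.dissimilarity(u, u):.3f}  (identical fields)")
print(f"DISS(u, 3u)   = {et.dissimilarity(u, 3 * u):.3f}  (strength-independent)")
print(f"DISS(u, -u)   = {et.dissimilarity(u, -u):.3f}  (polarity inversion)")
r = et.spatial_correlation(u, v)
d = et.dissimilarity(u, v)
print(f"r(u, v)       = {r:+.3f};  DISS² = {d**2:.3f} = 2(1-r) = {2 * (1 - r):.3f}")
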