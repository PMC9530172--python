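"""Render one synthetic leaf field and quantify its starch content.

Builds a wild-type scene at mid-day (ZT8), renders the paired TPF/SHG
photon-count images, and applies the threshold-gated ratio statistic:
I_SHG (summed SHG counts above background 2) over Cnt_TPF (TPF pixels above
threshold 50).  The ratio is a relative measure of starch per unit
chloroplast area; the colocalization fraction confirms that every
SHG-positive pixel falls inside the chloroplast region delineated from the
TPF channel.
"""

import numpy as np

import starchshg as s

scene = s.SceneConfig(rng_seed=0)
optics = s.OpticsConfig()
diel = s.DielModel.col0()

zt = 8.0
mass = s.starch_mass_at(diel, zt)
truth = s.make_ground_truth(scene, mass, zt, np.random.default_rng(0))
tpf, shg = s.render_scene(scene, optics, truth, np.random.default_rng(1))

quant = s.starch_ratio(tpf, shg)
coloc = s.colocalization(tpf, shg)

print(f"true starch mass at ZT{zt:g}: {mass:.2f} (granule area {truth.granule_area_px} px)")
print(f"I_SHG = {quant.i_shg} counts, Cnt_TPF = {quant.cnt_tpf} px")
print(f"ratio = {quant.ratio:.3f}  (starch per unit chloroplast area)")
print(f"SHG inside chloroplasts: {coloc.inside_fraction:.3f}")
# The ratio rises and falls with the diel starch kinetics; the inside
# fraction near 1 shows the SHG signal originates within chloroplasts.
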