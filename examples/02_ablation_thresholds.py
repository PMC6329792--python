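"""Tissue optics from laser-ablation experiments.

Generates noiseless damage-vs-energy curves at four cortical depths from the
Beer-Lambert threshold model, runs the two-stage fit (erf threshold per
depth, then log-linear regression of threshold on depth), and prints the
recovered extinction length and threshold fluence together with the
depth-extrapolated surface thresholds.
"""

from threephoton import synth
from threephoton import tissue_optics as to

optics = synth.SyntheticOpticsSpec()  # l_ext 270.3 µm, F_th 1.04 J/cm^2
curves = synth.make_damage_dataset(optics, depths=(150.0, 300.0, 450.0, 600.0))

thresholds = []
for curve in curves:
    fit = to.fit_damage_threshold(curve)
    thresholds.append((curve.depth, fit.e_th_surface))
    print(f"depth {curve.depth:5.0f} µm: E_th,surf = {fit.e_th_surface:7.2f} nJ")

model = to.fit_attenuation(thresholds, w0=optics.w0)
print(f"\nextinction length = {model.extinction_length:.1f} µm "
      f"(stderr {model.stderr_extinction:.2g})")
print(f"threshold fluence = {model.threshold_fluence:.3f} J/cm^2 "
      f"(stderr {model.stderr_fluence:.2g})")
print(f"focal-plane threshold energy = {to.threshold_energy_at_depth(model, 0):.1f} nJ")
# The threshold energy the tissue surface must receive grows as exp(z/l_ext);
# the intercept of the log-linear fit is the fluence at which 50% of
# ablation attempts damage tissue, ~1 J/cm^2, i.e. ~14 nJ over the focal spot.
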