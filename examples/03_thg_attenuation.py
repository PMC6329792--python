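"""Extinction lengths from a third-harmonic-generation depth profile.

Builds a synthetic THG signal-vs-depth profile with two tissue segments
(cortex, then white matter below 600 µm) and the stepwise power schedule
used during deep imaging (surface power doubled every 150 µm), then fits
ln(S/P^3) per segment to recover each segment's extinction length.
"""

from threephoton import synth
from threephoton import tissue_optics as to

optics = synth.SyntheticOpticsSpec(
    extinction_lengths=(242.0, 107.0),  # cortex, white matter (µm)
    segment_breaks=(600.0,),
    power_doubling_period=150.0,
)
profile = synth.make_thg_profile(optics, z_max=800.0, z_step=25.0)

for fit in to.fit_thg_attenuation(profile, photon_order=3):
    print(
        f"segment {fit.z_start:5.0f}-{fit.z_stop:5.0f} µm: "
        f"l_ext = {fit.extinction_length:6.1f} µm (stderr {fit.stderr:.2g})"
    )
# The THG signal falls as exp(-3 z / l_ext) once the cube of the delivered
# power is divided out, so each segment's slope gives its extinction length:
# light is attenuated ~2.3x faster in myelinated white matter than in cortex.
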