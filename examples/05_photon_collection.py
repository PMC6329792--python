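"""Monte Carlo emission-photon collection from 1 mm depth.

Launches photons isotropically from a focal plane 1 mm deep in brain-like
tissue (green-emission optical properties: 75 µm scattering length, 1 mm
absorption length, Henyey-Greenstein g = 0.93) and compares the number of
photons collected by 1-inch versus 2-inch collection optics.
"""

from threephoton import transport as tp

medium = tp.BRAIN_MEDIA[520]  # green (GCaMP) emission band
one_inch = tp.CollectionGeometry(aperture_radius=12.7, aperture_distance_above_surface=30.0)
two_inch = tp.CollectionGeometry(aperture_radius=25.4, aperture_distance_above_surface=30.0)

n = 200_000
small = tp.simulate_collection(n, depth=1000.0, medium=medium, geometry=one_inch, seed=123)
large = tp.simulate_collection(n, depth=1000.0, medium=medium, geometry=two_inch, seed=123)

for name, res in (("1-inch", small), ("2-inch", large)):
    print(
        f"{name}: launched {res.n_launched}, collected {res.n_collected} "
        f"({100 * res.collected_fraction:.2f}%), absorbed {res.n_absorbed}, "
        f"escaped uncollected {res.n_escaped_uncollected}"
    )
print(f"fold change (2-inch / 1-inch): {tp.aperture_comparison(small, large):.2f}")
# Multiple scattering spreads the emission over a wide halo at the surface,
# so doubling the aperture diameter captures a substantially larger share of
# the exiting photons — the rationale for 2-inch collection optics.
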