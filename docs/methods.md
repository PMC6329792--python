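# Methods

This note records the models implemented in `threephoton`, the numerical
conventions chosen where a convention was genuinely open, what the synthetic
generators do and do not emulate, and known limitations.

## Photophysics (`threephoton.photophysics`)

The per-pulse three-photon excitation probability is
`Pr_pulse = δE³/τ² · (NA²/(2hcλ))³`. Cross-sections are published in
cm-based units, so all internal arithmetic is CGS (erg, cm, s) with SI
conversion at the API boundary; this removes the easiest way to be wrong by
10¹². The result is not clamped to [0, 1]: values above 1 are unphysical
and signal saturation, which the caller should interpret (the
`saturation_flag` helper classifies against the 0.1 limit, counting the
boundary value itself as saturating — the conservative reading of a strict
`< 0.1` requirement). The time-averaged absorption rate is defined as
`Pr_pulse · R`, which makes the per-pulse and per-second quantities exactly
consistent and realises the `P³δ/(τR)²` proportionality when `E = P/R`.

Safety envelope. Three pulse-energy curves are tabulated against
repetition rate: the heating-limited energy `P_bound/R` (bounds 150 mW
conservative, 300 mW upper, treated as average-power constants — no
thermal-diffusion model), the optical-breakdown energy (constant in R,
scaled across pulse widths as τ^0.4, valid below 1 ps; a warning is issued
above), and the energy required for imaging, anchored at a known working
point (default 10 nJ at 800 kHz, 40 fs) and scaled linearly in τ. How the
imaging energy varies with R is convention-bound, so two modes are
provided and neither is asserted as measured: `constant_pulse_signal`
(default; E independent of R, reproducing the flat 10 nJ anchor) and
`constant_frame_signal` (E³R held fixed, E ∝ R^(−1/3)). The dominant damage
mechanism at each R is the curve with the lower threshold; heating and
breakdown cross at exactly `R = P_bound/E_breakdown`.

The NA entering the excitation formula is the *effective* aperture of the
beam (0.9 by default), not the objective's nominal 1.05; the two are kept
as plain parameters rather than derived from each other.

## Tissue optics (`threephoton.tissue_optics`)

Units: depth µm below the pia (0 = surface), energy nJ, fluence J/cm²,
`w0` µm; in this system `E[nJ] = 10·F·π·w0²`. The focal radius is derived
from a measured three-photon lateral FWHM by un-narrowing the cubed
Gaussian (×√3 on the width) and converting FWHM to the 1/e² radius
(÷√(2 ln 2)).

Erf damage fit. `Damage(%) = 50·[1 + erf((E−E_th)/(1.05·ΔE))]` is fitted
by nonlinear least squares. The 1.05 constant is kept verbatim as the erf
scale with ΔE free; E_th is initialised at the linear interpolation of the
first 50% crossing and ΔE at 20% of the median energy, both bounded
positive. Curves that never cross 50% raise a non-identifiability error
rather than extrapolating. By construction the fitted model is exactly 50%
at E = E_th.

Attenuation regression. OLS of `ln E_th,surf` on depth; slope = 1/l_ext,
intercept = ln(F_th π w0²). Standard errors of the derived parameters come
from the regression by the delta method (`se(1/b) = se(b)/b²`;
`se(e^a c) = e^a c·se(a)`); two-point fits have zero residual degrees of
freedom and report zero/NaN-free stderr via suppressed division.

THG slope fit. Per segment between configured break depths, OLS of
`ln(S/P^order)` on depth with `l_ext = −order/slope`. The default
`photon_order = 3` treats the detected signal as proportional to the cube
of delivered power and ignores attenuation of the emitted harmonic on its
way out; the order is exposed because the convention is not universal. A
numerically flat segment (|slope| < 1e-12 µm⁻¹) reports +inf. Segments are
fitted independently; a sample exactly on a break contributes to both
segments.

## Ablation damage statistic (`threephoton.ablation`)

The 2×2 median filter anchors the window at each pixel (itself plus right,
lower, lower-right neighbours) with nearest-edge padding, and uses the
mean-of-middle-two convention for the even-count median — chosen over
scipy's upper-middle-element convention so a {0,1} checkerboard smooths to
0.5. Otsu's threshold uses a 256-bin histogram per image; thresholding each
image independently makes the damage statistic exactly invariant to a
global affine intensity rescale. Damage is the increase in below-threshold
pixels *within the target mask*, as a percentage of the mask area, clamped
to [0, 100]; mask-restricted counting keeps the statistic bounded (counting
over the whole frame is the other defensible reading of the procedure and
is documented here rather than asserted).

## Photon transport (`threephoton.transport`)

Geometry: z down, surface at z = 0, photons launched at the focal depth
with isotropic (or pinned) initial direction. Steps are exponential with
mean `scattering_length`; absorption is a per-step Russian-roulette
survival test `exp(−step/absorption_length)` (integer photon bookkeeping,
no weights); deflections sample the Henyey–Greenstein inverse CDF. A
surface-crossing photon exits at the exact intersection (absorption applied
over the partial step) and travels in a straight line — refraction at the
tissue/air interface is not modelled. The bottom of the slab is a
terminator; photons ending there are booked as uncollected escapes, not
tissue absorption, so switching absorption off yields exactly zero
absorbed. Collection requires the straight-line continuation to pass within
the aperture radius at the aperture plane *and* an exit angle within the
acceptance half-angle.

The walk is stepped synchronously over the whole batch with a single
counter-based Philox stream, so a run is exactly reproducible given
`(seed, n_photons)` and fast enough for 10⁶-photon runs in seconds. The
per-photon-stream alternative (reproducible under any execution order) was
rejected as orders of magnitude slower in pure Python; determinism is
guaranteed at the run level instead, and asserted by test.

The simplified aperture geometry is deliberately not a model of any
specific collection optics: comparisons between geometries (e.g. 1-inch vs
2-inch apertures) are meaningful in direction and rough magnitude only.
Brain-like presets (`BRAIN_MEDIA`) carry the emission-band optical
properties used throughout: scattering lengths 64/75/90 µm and g =
0.94/0.93/0.92 at 433/520/600 nm with 1 mm water absorption; these are
consumed as fixed inputs, not derived from a scatterer model.

## Calcium pipeline (`threephoton.calcium`)

Registration is integer-pixel: each frame is shifted by the argmax of its
FFT cross-correlation with the pixel-wise mean image, searched within a
shift cap of 10% of the frame size; vacated pixels are filled with the
frame median. No subpixel refinement.

ΔF/F uses F0 = mode of the raw trace's histogram, Freedman–Diaconis bin
width with ties resolved toward the lowest-intensity bin; when the IQR is
zero (heavily quantised traces) the bin count falls back to the square-root
rule so the mode is still localised.

Epoch statistics pool the pre- and post-drift static periods of each
presentation (the pooled reading of "static periods"; pre-only is the
alternative). Responsiveness is a per-direction two-tailed paired t test at
α = 0.05 with no multiple-comparison correction, responsive if any
direction is significant. Zero-variance differences are handled explicitly
(p = 1 if all differences are zero, else p = 0). Note the union rule's
family-wise false-positive rate on pure-noise neurons is
1 − (1 − α)¹² ≈ 0.46 by construction; the *per-direction* test is
calibrated at α, and that calibration is what the test suite asserts.

The tuning model places the second Gaussian lobe at θp + 180 with a shared
width σ — the standard bimodal form the Rp/Rn parameter naming implies
(the printed source form with two identical exponents is taken as a typo).
Fitting is multi-start nonlinear least squares over all 12 presented
directions as initial θp; the solution is canonicalised so the larger lobe
is preferred (swapping lobes rotates θp by 180°) and θp ∈ [0, 360). A flat
curve has undefined R² (NaN) and is never orientation selective; the OS
criterion is strictly R² > 0.6.

Indices are computed on direction means (drift − pooled-static, averaged
over trials) rectified at zero. gOSI uses the doubled-angle vector average
of the rectified means. R_pref is the fitted curve at θp; R_ortho/R_oppo
are the rectified measured responses at the directions nearest θp±90 /
θp+180 (fitted preferred + measured reference — the raw-vs-fitted choice is
not determined by the source procedure). With θp at the curve peak all
three indices lie in [0, 1]; degenerate fits of unresponsive cells can
produce negative OSI/DSI, which is harmless because such cells fail the
responsive/OS filters. A zero response vector yields NaN sentinels.

Layer assignment uses nominal adult mouse V1 boundaries (µm): L1 0–100,
L2/3 100–350, L4 350–450, L5 450–600, L6 600–750, subplate/WM beyond 750;
a depth exactly on a boundary belongs to the deeper layer. Real experiments
locate layers per animal (e.g. by marker lesions), so the table is fully
overridable.

## Synthetic data (`threephoton.synth`)

What is emulated: bimodal-Gaussian direction tuning with uniform parameter
ranges (σ 15–40°, Rp 0.5–1.5 ΔF/F, Rn up to Rp, baseline offsets ≤ 0.05);
GCaMP6s-like kinetics as a difference-of-exponentials kernel (0.2 s rise,
1.8 s decay — plausible values, the indicator's true kinetics are not
fitted); per-frame Gaussian ΔF/F noise (default sd 0.1, i.e. single-trial
amplitude SNR 5–15 before trial averaging); integer translational jitter;
disk ROIs over a uniform background. Not emulated: neuropil contamination,
photobleaching, spike-to-calcium nonlinearity, correlated noise, ROI
overlap, slow drift. Passing tests therefore demonstrate correctness of the
estimators under the assumed noise model, not robustness to every artefact
of real recordings.

The optics generators invert the exact forward models their consumers fit
(erf + Beer–Lambert; piecewise-exponential THG with a stepped power
schedule that the fit divides out), so noiseless closed loops recover
generative parameters to numerical precision — that is the point: they
verify the fitting machinery, not the physics. Trial noise is available
(binomial damaged-site counts; log-normal THG noise). The ablation-pair
generator darkens a concentric disk covering the requested fraction of the
target mask inside bright textured tissue with a dark surround, which is
what makes Otsu's threshold land between lesion and tissue.

Every generator is deterministic given its seed; derived streams offset the
seed by fixed small constants so the sub-generators are decorrelated.

## Problem sizes

Default test and example sizes are chosen to exercise every code path at
desk scale: populations of 24–80 neurons at the full 120-presentation
protocol, 10⁵–10⁶ photons for transport runs, 36-point damage datasets,
33-point THG profiles. All statistical assertions use fixed seeds.

## Interfaces

The package is primarily a library (import `threephoton.*`; see
`examples/`). The click CLI exposes the shell-shaped operations (safety
table, CSV fits, TIFF damage statistic, transport runs, synthetic-data
emitters, and the `run` pipeline driver with a YAML/JSON config that
rejects unknown keys and writes a manifest of every output file).
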