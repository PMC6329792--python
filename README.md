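# threephoton

Analysis toolkit for deep-brain three-photon microscopy: the photophysics
and laser-safety calculations that set usable pulse parameters, inference of
cortical tissue optics from laser-ablation and third-harmonic-generation
(THG) measurements, Monte Carlo transport of emission photons to the
collection optics, and a calcium-imaging pipeline that turns fluorescence
movies into per-neuron visual-tuning physiology. A synthetic-data module
generates every input the pipelines consume — tuned GCaMP6s-like movies,
damage-vs-energy curves, THG depth profiles, ablation image pairs — with
known ground truth, so the whole package is testable end to end without any
recordings.

It is written for microscopists planning damage-free deep imaging (what
pulse energy, width and repetition rate are safe at a given depth?) and for
systems neuroscientists analysing drifting-grating experiments across
cortical layers.

## The models at the core

**Excitation photophysics.** The probability that one pulse excites a
fluorophore by three-photon absorption is

    Pr_pulse = (δ E³ / τ²) · (NA² / (2 h c λ))³

with cross-section δ (cm⁶ (s/photon)²), pulse energy E, pulse width τ.
`Pr_pulse < 0.1` avoids saturation; the time-averaged absorption rate is
`Pr_pulse · R`. Damage thresholds are compared per repetition rate R: bulk
heating caps the average power (150–300 mW), while optical breakdown caps
the pulse energy and grows only as τ^0.4 below 1 ps.

**Tissue optics.** Surface pulse energy reaching a focus at depth z follows
Beer–Lambert, so the surface energy that produces the 50%-damage fluence
F_th at the focus is

    E_th,surf(z) = F_th · π w0² · exp(z / l_ext)

Per depth, E_th,surf is estimated by fitting percent damage with
`50·[1 + erf((E − E_th)/(1.05 ΔE))]`; regressing ln E_th,surf on z gives
the extinction length l_ext (inverse slope) and F_th (intercept). The THG
route fits the slope of ln(S/P³) versus depth per tissue segment.

**Photon transport.** Emission photons random-walk with exponential free
paths, Henyey–Greenstein scattering (mean cosine g) and per-step
Russian-roulette absorption; a surface-exiting photon is collected if its
straight-line continuation passes the aperture within the acceptance angle.

**Visual tuning.** Movies are registered by 2-D cross-correlation to the
mean image; ΔF/F uses the mode of the raw intensity histogram as F0;
responsiveness is a per-direction paired t test (drift vs static epochs);
tuning curves are fit with a bimodal Gaussian
`R(θ) = R0 + Rp·exp(−⟨θ−θp⟩²/2σ²) + Rn·exp(−⟨θ−θp−180⟩²/2σ²)`
(orientation selective if R² > 0.6), and selectivity is summarised by
gOSI = |Σ R(θj) e^{i2θj}| / Σ R(θj), OSI = (Rpref−Rortho)/(Rpref+Rortho)
and DSI = (Rpref−Roppo)/(Rpref+Roppo).

## Worked example

```bash
python examples/02_ablation_thresholds.py
```

```
depth   150 µm: E_th,surf =   24.94 nJ
depth   300 µm: E_th,surf =   43.44 nJ
depth   450 µm: E_th,surf =   75.66 nJ
depth   600 µm: E_th,surf =  131.80 nJ

extinction length = 270.3 µm (stderr 6.7e-13)
threshold fluence = 1.040 J/cm^2 (stderr 3.9e-15)
focal-plane threshold energy = 14.3 nJ
```

Each line is the fitted surface pulse energy giving 50% ablation damage at
that depth; the regression across depths recovers the cortical extinction
length (how far 1300 nm light penetrates before e-fold attenuation) and the
breakdown threshold fluence, which over the focal spot corresponds to
~14 nJ at the focal plane. The other examples cover the safety envelope,
THG attenuation, damage quantification from image pairs, photon collection
(1-inch vs 2-inch optics), and the tuning pipeline on a synthetic
population.

A thin CLI wraps the same functions
(`threephoton safety|ablation-fit|thg-fit|damage|transport|tuning|synth|run`).

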