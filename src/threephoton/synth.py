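"""Synthetic-data generators for every pipeline input.

The generators produce, with known ground truth and full determinism given a
seed:

- direction-tuned GCaMP6s-like dF/F traces (bimodal-Gaussian tuning, a
  difference-of-exponentials indicator kernel, additive Gaussian noise) and
  movies rendering those traces as disk ROIs with translational jitter;
- damage-vs-energy curves from the Beer-Lambert threshold model plus the
  erf damage law, optionally with binomial trial noise;
- two-segment THG depth profiles with a stepwise surface-power schedule;
- before/after ablation image pairs with a darkened lesion disk covering a
  prescribed fraction of the target area.

Defaults mirror the experimental conditions the analysis modules assume:
12 directions, 12 s trials (3 s static / 6 s drift / 3 s static), 10 trials,
4 Hz frames; attenuation model l_ext = 270.3 µm, F_th = 1.04 J/cm^2, w0 from
a 0.45 µm three-photon FWHM; THG segments 242 µm (cortex) / 107 µm (white
matter) with surface power doubling every 150 µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from threephoton import tissue_optics
from threephoton.ablation import AblationImagePair
from threephoton.calcium import (
    DEFAULT_DIRECTIONS,
    RoiTrace,
    StimulusProtocol,
    tuning_model,
    wrap_angle,
)
from threephoton.tissue_optics import (
    AttenuationModel,
    DamageCurve,
    ThgProfile,
    damage_model,
    threshold_energy_at_depth,
    w0_from_three_photon_fwhm,
)


@dataclass(frozen=True)
class SyntheticPopulationSpec:
    """Population model for tuned-trace generation.

    Per-neuron tuning parameters are drawn uniformly from the stated ranges;
    ``noise_sd`` is in dF/F units per frame. The indicator kernel is a
    difference of exponentials with GCaMP6s-like 0.2 s rise and 1.8 s decay.
    """

    n_neurons: int = 80
    fraction_responsive: float = 0.5
    theta_p_range: tuple = (0.0, 360.0)
    sigma_range: tuple = (15.0, 40.0)
    r0_range: tuple = (0.0, 0.05)
    rp_range: tuple = (0.5, 1.5)
    rn_frac_range: tuple = (0.0, 1.0)  # rn as a fraction of rp
    noise_sd: float = 0.1
    rise_tau: float = 0.2  # s
    decay_tau: float = 1.8  # s
    baseline_fluorescence: float = 100.0
    jitter_amplitude: int = 0  # pixels
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_responsive <= 1.0:
            raise ValueError("fraction_responsive must lie in [0, 1]")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("indicator kinetics must be positive")
        if self.noise_sd < 0 or self.n_neurons < 1:
            raise ValueError("invalid population spec")


@dataclass(frozen=True)
class SyntheticOpticsSpec:
    """Generative tissue-optics parameters."""

    extinction_lengths: tuple = (242.0, 107.0)  # µm per segment (cortex, WM)
    segment_breaks: tuple = (600.0,)  # µm
    ablation_extinction_length: float = 270.3  # µm, single-layer cortex model
    threshold_fluence: float = 1.04  # J/cm^2
    fwhm_3p: float = 0.45  # µm, three-photon lateral FWHM
    delta_e_frac: float = 0.15  # erf width as a fraction of E_th
    power_doubling_period: float = 150.0  # µm
    base_power: float = 1.0  # mW at the surface
    thg_noise_sd: float = 0.0  # log-normal sigma on the signal
    seed: int = 0

    @property
    def w0(self) -> float:
        return w0_from_three_photon_fwhm(self.fwhm_3p)

    def attenuation_model(self) -> AttenuationModel:
        return AttenuationModel(
            extinction_length=self.ablation_extinction_length,
            threshold_fluence=self.threshold_fluence,
            w0=self.w0,
        )


def indicator_kernel(rise_tau: float, decay_tau: float, frame_rate: float) -> np.ndarray:
    """Difference-of-exponentials calcium-indicator kernel, peak-normalised."""
    t = np.arange(0.0, 5.0 * decay_tau, 1.0 / frame_rate)
    k = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate indicator kernel")
    return k / peak


def make_tuned_traces(
    spec: SyntheticPopulationSpec, protocol: StimulusProtocol
) -> tuple[list[RoiTrace], pd.DataFrame]:
    """Tuned raw-fluorescence traces plus their ground-truth table.

    Responders respond during each drift epoch with the bimodal-Gaussian
    amplitude at the presented direction, convolved with the indicator
    kernel; non-responders emit baseline + noise only. The ground-truth
    table carries the generative parameters, the noiseless per-direction
    amplitudes, and index values computed directly from those amplitudes.
    """
    rng = np.random.default_rng(spec.seed)
    n_resp = int(round(spec.fraction_responsive * spec.n_neurons))
    responder = np.zeros(spec.n_neurons, dtype=bool)
    responder[:n_resp] = True
    kernel = indicator_kernel(spec.rise_tau, spec.decay_tau, protocol.frame_rate)
    fpt = protocol.frames_per_trial
    pre_f = int(round(protocol.static_pre * protocol.frame_rate))
    drift_f = int(round(protocol.drift * protocol.frame_rate))
    n_frames = protocol.n_frames
    directions = np.asarray(protocol.directions, dtype=float)

    traces: list[RoiTrace] = []
    truth_rows = []
    for i in range(spec.n_neurons):
        theta_p = rng.uniform(*spec.theta_p_range)
        sigma = rng.uniform(*spec.sigma_range)
        r0 = rng.uniform(*spec.r0_range)
        rp = rng.uniform(*spec.rp_range)
        rn = rp * rng.uniform(*spec.rn_frac_range)
        depth = rng.uniform(100.0, 900.0)
        signal = np.zeros(n_frames)
        if responder[i]:
            for k, d_idx in enumerate(protocol.order):
                amp = tuning_model(directions[d_idx], theta_p, sigma, r0, rp, rn)
                drive = np.zeros(fpt)
                drive[pre_f : pre_f + drift_f] = amp
                resp = np.convolve(drive, kernel)[:fpt]
                signal[k * fpt : (k + 1) * fpt] += resp
        dff_noisy = signal + rng.normal(0.0, spec.noise_sd, n_frames)
        raw = spec.baseline_fluorescence * (1.0 + dff_noisy)
        traces.append(RoiTrace(roi_id=i, depth=depth, raw_fluorescence=raw))

        amps = tuning_model(directions, theta_p, sigma, r0, rp, rn) if responder[i] else np.zeros_like(directions)
        gosi, osi, dsi = _indices_from_amplitudes(amps, directions, theta_p)
        truth_rows.append(
            {
                "roi_id": i,
                "responsive": bool(responder[i]),
                "theta_p": theta_p % 360.0,
                "sigma": sigma,
                "r0": r0,
                "rp": rp,
                "rn": rn,
                "depth": depth,
                "gOSI": gosi,
                "OSI": osi,
                "DSI": dsi,
            }
        )
    return traces, pd.DataFrame(truth_rows)


def _indices_from_amplitudes(amps: np.ndarray, directions: np.ndarray, theta_p: float):
    """Ground-truth gOSI/OSI/DSI from noiseless per-direction amplitudes."""
    r = np.clip(amps, 0.0, None)
    total = r.sum()
    if total == 0:
        return float("nan"), float("nan"), float("nan")
    gosi = float(np.abs(np.sum(r * np.exp(1j * np.deg2rad(2.0 * directions)))) / total)
    pref = r[np.argmin(np.abs(wrap_angle(directions - theta_p)))]
    ortho = 0.5 * (
        r[np.argmin(np.abs(wrap_angle(directions - theta_p - 90.0)))]
        + r[np.argmin(np.abs(wrap_angle(directions - theta_p + 90.0)))]
    )
    oppo = r[np.argmin(np.abs(wrap_angle(directions - theta_p - 180.0)))]
    osi = (pref - ortho) / (pref + ortho) if pref + ortho > 0 else float("nan")
    dsi = (pref - oppo) / (pref + oppo) if pref + oppo > 0 else float("nan")
    return gosi, float(osi), float(dsi)


def make_movie(
    traces: list[RoiTrace],
    spec: SyntheticPopulationSpec,
    frame_shape: tuple[int, int] = (64, 64),
    roi_radius: int = 3,
    background: float = 20.0,
    read_noise_sd: float = 0.0,
):
    """Render traces into a jittered movie.

    ROIs are disks on a grid; each frame is translated by an integer jitter
    drawn uniformly from [-amplitude, amplitude] (recorded and returned).
    Returns ``(movie, roi_labels, jitter)``; ``roi_labels`` is a labelled
    integer mask image on the unjittered canvas (label = roi_id + 1).
    """
    if not traces:
        raise ValueError("need at least one trace")
    rng = np.random.default_rng(spec.seed + 1)
    ny, nx = frame_shape
    n_frames = traces[0].raw_fluorescence.size
    labels = np.zeros((ny, nx), dtype=np.int32)
    yy, xx = np.mgrid[0:ny, 0:nx]
    margin = roi_radius + abs(spec.jitter_amplitude) + 1
    n = len(traces)
    grid = int(np.ceil(np.sqrt(n)))
    cy = np.linspace(margin, ny - margin, grid)
    cx = np.linspace(margin, nx - margin, grid)
    centers = [(cy[i // grid], cx[i % grid]) for i in range(n)]
    for tr, (y0, x0) in zip(traces, centers):
        disk = (yy - y0) ** 2 + (xx - x0) ** 2 <= roi_radius**2
        if labels[disk].any():
            raise ValueError("ROIs overlap; reduce radius or neuron count")
        labels[disk] = tr.roi_id + 1
    base = np.full((ny, nx), background)
    movie = np.empty((n_frames, ny, nx))
    jitter = rng.integers(-spec.jitter_amplitude, spec.jitter_amplitude + 1, size=(n_frames, 2)) if spec.jitter_amplitude else np.zeros((n_frames, 2), dtype=int)
    for t in range(n_frames):
        frame = base.copy()
        for tr in traces:
            frame[labels == tr.roi_id + 1] = tr.raw_fluorescence[t]
        frame = np.roll(frame, tuple(jitter[t]), axis=(0, 1))
        if read_noise_sd > 0:
            frame = frame + rng.normal(0.0, read_noise_sd, frame.shape)
        movie[t] = frame
    return movie, labels, jitter


def make_damage_dataset(
    optics_spec: SyntheticOpticsSpec,
    depths=(150.0, 300.0, 450.0, 600.0),
    energies_per_depth: int = 9,
    energy_span: tuple = (0.4, 2.5),
    n_sites: int | None = None,
) -> list[DamageCurve]:
    """Damage-vs-energy curves from the Beer-Lambert + erf generative model.

    Per depth, the surface threshold comes from the attenuation model and
    damage percentages from the erf law over energies spanning
    ``energy_span`` times the threshold. With ``n_sites`` set, each point is
    replaced by a binomial fraction of damaged sites (trial noise).
    """
    model = optics_spec.attenuation_model()
    rng = np.random.default_rng(optics_spec.seed + 2)
    curves = []
    for z in depths:
        e_th = threshold_energy_at_depth(model, z)
        energies = np.linspace(energy_span[0] * e_th, energy_span[1] * e_th, energies_per_depth)
        damage = damage_model(energies, e_th, optics_spec.delta_e_frac * e_th)
        if n_sites is not None:
            damage = 100.0 * rng.binomial(n_sites, damage / 100.0) / n_sites
        curves.append(DamageCurve(depth=z, energies=tuple(energies), damage_percent=tuple(damage)))
    return curves


def make_thg_profile(
    optics_spec: SyntheticOpticsSpec,
    z_max: float = 800.0,
    z_step: float = 25.0,
    signal_scale: float = 1.0e4,
) -> ThgProfile:
    """Piecewise-exponential THG depth profile with a stepped power schedule.

    ``S(z) = C * P(z)^3 * exp(-3 * z_eff)`` where ``z_eff`` accumulates
    ``dz / l_ext(segment)`` across segments (continuous at the breaks); the
    surface power doubles every ``power_doubling_period`` µm. Optional
    multiplicative log-normal noise.
    """
    rng = np.random.default_rng(optics_spec.seed + 3)
    depths = np.arange(0.0, z_max + 0.5 * z_step, z_step)
    breaks = [b for b in optics_spec.segment_breaks if 0.0 < b < z_max]
    edges = np.array([0.0] + breaks + [np.inf])
    z_eff = np.zeros_like(depths)
    for i, z in enumerate(depths):
        acc, z0 = 0.0, 0.0
        for seg, l_ext in enumerate(optics_spec.extinction_lengths):
            hi = min(z, edges[seg + 1])
            if hi > z0:
                acc += (hi - z0) / l_ext
                z0 = hi
            if z0 >= z:
                break
        z_eff[i] = acc
    powers = optics_spec.base_power * 2.0 ** np.floor(depths / optics_spec.power_doubling_period)
    signals = signal_scale * powers**3 * np.exp(-3.0 * z_eff)
    if optics_spec.thg_noise_sd > 0:
        signals = signals * rng.lognormal(0.0, optics_spec.thg_noise_sd, signals.size)
    return ThgProfile(
        depths=tuple(depths),
        signals=tuple(signals),
        powers=tuple(powers),
        segment_breaks=tuple(breaks),
    )


def make_ablation_pair(
    damage_target: float,
    frame_shape: tuple[int, int] = (128, 128),
    target_radius: int = 20,
    seed: int = 0,
    tissue_level: float = 180.0,
    lesion_level: float = 12.0,
    background_level: float = 18.0,
    texture_sd: float = 6.0,
) -> AblationImagePair:
    """Before/after image pair with a lesion covering ``damage_target``%.

    The before image is bright tissue texture over a dark border frame (so
    Otsu separates tissue from background); the target mask is a centred
    disk; the after image darkens a concentric disk whose area is the
    requested fraction of the mask.
    """
    if not 0.0 <= damage_target <= 100.0:
        raise ValueError("damage_target must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    ny, nx = frame_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    r2 = (yy - ny / 2.0) ** 2 + (xx - nx / 2.0) ** 2
    tissue = r2 <= (min(ny, nx) * 0.42) ** 2
    before = np.where(tissue, tissue_level, background_level) + rng.normal(0.0, texture_sd, frame_shape)
    mask = r2 <= target_radius**2
    lesion_radius = target_radius * np.sqrt(damage_target / 100.0)
    lesion = r2 <= lesion_radius**2
    after = before.copy()
    after[lesion] = lesion_level + rng.normal(0.0, texture_sd * 0.3, int(lesion.sum()))
    return AblationImagePair(before=before, after=after, target_mask=mask)
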