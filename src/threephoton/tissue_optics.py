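"""Tissue-optics inference from laser-ablation and THG depth profiles.

Two label-free routes to the effective attenuation (extinction) length of
cortex at the excitation wavelength are implemented.

Ablation route. Surface pulse energy reaching a focus at depth ``z`` is
attenuated by Beer-Lambert's law, so the surface energy producing the
threshold fluence ``F_th`` at the focus is

    E_th,surf(z) = F_th * pi * w0^2 * exp(z / l_ext)

with ``w0`` the one-photon 1/e^2 focal radius. Per depth, ``E_th,surf`` is
estimated by fitting the measured percent-damage curve with

    Damage(%) = 50 * [1 + erf((E - E_th) / (1.05 dE))]

and the set of per-depth thresholds is then regressed as
``ln E_th,surf = ln(F_th pi w0^2) + z / l_ext`` to recover both the
extinction length (inverse slope) and the threshold fluence (intercept).

THG route. The detected third-harmonic signal from depth ``z`` scales as the
cube of focal power, so ``ln(S / P^3)`` falls linearly with depth with slope
``-3 / l_ext``; piecewise fits give per-tissue-segment extinction lengths
(cortex vs white matter).

Unit conventions: depths in µm below the pial surface (0 = surface),
energies in nJ, fluence in J/cm^2, ``w0`` in µm. With those units
``E[nJ] = 10 * F[J/cm^2] * pi * w0[µm]^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize, special

#: nJ per (J/cm^2 * µm^2): 1 J/cm^2 * 1 µm^2 = 1e-8 cm^2 * 1 J/cm^2 = 10 nJ
FLUENCE_UM2_TO_NJ = 10.0

#: the erf scale in the damage model is 1.05 * dE
ERF_SCALE = 1.05


class NonIdentifiableError(ValueError):
    """The data cannot pin down the requested model parameters."""


def w0_from_three_photon_fwhm(fwhm_3p: float) -> float:
    """One-photon 1/e^2 focal radius from a measured three-photon FWHM (µm).

    The three-photon point-spread function is the cube of the one-photon
    Gaussian profile, which narrows its FWHM by sqrt(3); converting FWHM to
    the 1/e^2 radius multiplies by 1/sqrt(2 ln 2). Hence
    ``w0 = sqrt(3) * fwhm_3p / sqrt(2 ln 2)``.
    """
    if not fwhm_3p > 0:
        raise ValueError(f"FWHM must be strictly positive, got {fwhm_3p!r}")
    return math.sqrt(3.0) * fwhm_3p / math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class DamageCurve:
    """Percent ablation damage versus surface pulse energy at one depth."""

    depth: float  # µm
    energies: tuple  # nJ, strictly increasing
    damage_percent: tuple  # 0-100

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        d = np.asarray(self.damage_percent, dtype=float)
        if e.size < 4:
            raise ValueError("a damage curve needs at least 4 energy points")
        if e.size != d.size:
            raise ValueError("energies and damage_percent must have equal length")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing")
        if np.any((d < 0) | (d > 100)):
            raise ValueError("damage values must lie in [0, 100]")
        object.__setattr__(self, "energies", tuple(e))
        object.__setattr__(self, "damage_percent", tuple(d))


@dataclass(frozen=True)
class ThresholdFitResult:
    """Erf-model fit of one damage curve."""

    e_th_surface: float  # nJ, energy giving 50% damage
    delta_e: float  # nJ, transition width parameter
    residual_norm: float

    def __post_init__(self) -> None:
        if not (self.e_th_surface > 0 and self.delta_e > 0):
            raise ValueError("fitted threshold and width must be positive")


@dataclass(frozen=True)
class AttenuationModel:
    """Beer-Lambert threshold model of the cortex."""

    extinction_length: float  # µm
    threshold_fluence: float  # J/cm^2
    w0: float  # µm
    stderr_extinction: float = 0.0
    stderr_fluence: float = 0.0

    def __post_init__(self) -> None:
        if not (self.extinction_length > 0 and self.threshold_fluence > 0 and self.w0 > 0):
            raise ValueError("model parameters must be strictly positive")


@dataclass(frozen=True)
class ThgProfile:
    """THG signal-vs-depth profile with the surface-power schedule used."""

    depths: tuple  # µm, strictly increasing
    signals: tuple  # PMT signal, arbitrary units
    powers: tuple  # surface power, mW
    segment_breaks: tuple = ()  # µm, interior boundaries (e.g. cortex/WM)

    def __post_init__(self) -> None:
        z = np.asarray(self.depths, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        p = np.asarray(self.powers, dtype=float)
        if not (z.size == s.size == p.size):
            raise ValueError("depths, signals and powers must have equal length")
        if np.any(np.diff(z) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(s <= 0) or np.any(p <= 0):
            raise ValueError("signals and powers must be strictly positive")
        object.__setattr__(self, "depths", tuple(z))
        object.__setattr__(self, "signals", tuple(s))
        object.__setattr__(self, "powers", tuple(p))
        object.__setattr__(self, "segment_breaks", tuple(float(b) for b in self.segment_breaks))


@dataclass(frozen=True)
class ThgSegmentFit:
    """Per-segment extinction length from the THG slope."""

    z_start: float
    z_stop: float
    extinction_length: float  # µm, +inf for a flat segment
    stderr: float


def damage_model(energy, e_th: float, delta_e: float):
    """Erf damage model: 50 * [1 + erf((E - E_th) / (1.05 dE))], percent."""
    e = np.asarray(energy, dtype=float)
    return 50.0 * (1.0 + special.erf((e - e_th) / (ERF_SCALE * delta_e)))


def fit_damage_threshold(curve: DamageCurve) -> ThresholdFitResult:
    """Least-squares fit of the erf damage model to one depth's curve.

    E_th is initialised at the energy whose damage is nearest 50% (linear
    interpolation where the curve crosses 50), dE at 20% of the median
    energy; both are bounded positive. By construction the fitted model
    evaluates to exactly 50% at E = E_th.
    """
    e = np.asarray(curve.energies, dtype=float)
    d = np.asarray(curve.damage_percent, dtype=float)
    if d.min() >= 50.0 or d.max() <= 50.0:
        raise NonIdentifiableError(
            "damage curve must span both sides of 50% to identify the threshold"
        )
    # initial E_th: linear interpolation of the first upward 50% crossing
    above = np.nonzero(d >= 50.0)[0]
    i = above[0]
    if i == 0 or d[i] == 50.0:
        e_th0 = e[i]
    else:
        f = (50.0 - d[i - 1]) / (d[i] - d[i - 1])
        e_th0 = e[i - 1] + f * (e[i] - e[i - 1])
    de0 = 0.2 * float(np.median(e))
    popt, _ = optimize.curve_fit(
        damage_model,
        e,
        d,
        p0=[e_th0, de0],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        maxfev=20000,
    )
    resid = d - damage_model(e, *popt)
    return ThresholdFitResult(
        e_th_surface=float(popt[0]),
        delta_e=float(popt[1]),
        residual_norm=float(np.linalg.norm(resid)),
    )


def fit_attenuation(thresholds, w0: float) -> AttenuationModel:
    """Log-linear regression of surface threshold energies on depth.

    ``thresholds`` is a sequence of ``(depth_um, e_th_surface_nj)`` pairs.
    OLS of ``ln E_th`` on ``z`` yields slope ``1/l_ext`` and intercept
    ``ln(10 F_th pi w0^2)`` (nJ/µm unit system). Standard errors of the
    derived quantities follow from the regression by the delta method.
    """
    arr = np.asarray(thresholds, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (depth, threshold) pairs")
    z, e_th = arr[:, 0], arr[:, 1]
    if np.unique(z).size < 2:
        raise NonIdentifiableError("thresholds at a single depth cannot constrain the slope")
    if np.any(e_th <= 0):
        raise ValueError("threshold energies must be strictly positive")
    with np.errstate(divide="ignore", invalid="ignore"):  # 2-point fits have df_resid = 0
        res = sm.OLS(np.log(e_th), sm.add_constant(z)).fit()
        intercept, slope = res.params
        se_intercept, se_slope = res.bse
    if slope <= 0:
        raise NonIdentifiableError("thresholds must increase with depth (positive slope)")
    l_ext = 1.0 / slope
    f_th = math.exp(intercept) / (FLUENCE_UM2_TO_NJ * math.pi * w0**2)
    # delta method: se(1/b) = se(b)/b^2; se(exp(a)·c) = exp(a)·c·se(a)
    se_l = float(se_slope) / slope**2 if np.isfinite(se_slope) else 0.0
    se_f = f_th * float(se_intercept) if np.isfinite(se_intercept) else 0.0
    return AttenuationModel(
        extinction_length=float(l_ext),
        threshold_fluence=float(f_th),
        w0=float(w0),
        stderr_extinction=se_l,
        stderr_fluence=se_f,
    )


def threshold_energy_at_depth(model: AttenuationModel, depth: float) -> float:
    """Surface pulse energy (nJ) whose focal fluence at ``depth`` is F_th."""
    if depth < 0:
        raise ValueError("depth must be non-negative")
    return (
        FLUENCE_UM2_TO_NJ
        * model.threshold_fluence
        * math.pi
        * model.w0**2
        * math.exp(depth / model.extinction_length)
    )


def fluence_at_focus(surface_energy: float, depth: float, model: AttenuationModel) -> float:
    """Focal-plane fluence (J/cm^2) of a surface pulse after attenuation."""
    if surface_energy <= 0:
        raise ValueError("surface energy must be strictly positive")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    return (
        surface_energy
        * math.exp(-depth / model.extinction_length)
        / (FLUENCE_UM2_TO_NJ * math.pi * model.w0**2)
    )


def fit_thg_attenuation(profile: ThgProfile, photon_order: int = 3) -> list[ThgSegmentFit]:
    """Per-segment extinction lengths from ln(S / P^order) depth slopes.

    Each segment between consecutive ``segment_breaks`` is fitted
    independently by OLS; ``l_ext = -photon_order / slope``. A zero slope
    (depth-constant normalised signal) is reported as +inf. Attenuation of
    the emitted harmonic on its way out is not modelled; ``photon_order``
    is exposed so the convention can be changed.
    """
    z = np.asarray(profile.depths, dtype=float)
    s = np.asarray(profile.signals, dtype=float)
    p = np.asarray(profile.powers, dtype=float)
    y = np.log(s / p**photon_order)
    edges = [z[0]] + [b for b in profile.segment_breaks if z[0] < b < z[-1]] + [z[-1]]
    fits: list[ThgSegmentFit] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (z >= lo) & (z <= hi)
        if mask.sum() < 3:
            raise ValueError(f"segment [{lo}, {hi}] µm has fewer than 3 samples")
        res = sm.OLS(y[mask], sm.add_constant(z[mask])).fit()
        slope = res.params[1]
        se_slope = res.bse[1] if np.isfinite(res.bse[1]) else 0.0
        if abs(slope) < 1e-12:  # flat segment within numerical precision
            l_ext, se_l = math.inf, math.inf
        else:
            l_ext = -photon_order / slope
            se_l = photon_order * float(se_slope) / slope**2
        fits.append(
            ThgSegmentFit(
                z_start=float(lo), z_stop=float(hi), extinction_length=float(l_ext), stderr=se_l
            )
        )
    return fits
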