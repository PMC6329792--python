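"""Three-photon excitation photophysics and the laser-damage safety envelope.

The fluorophore excitation probability per pulse for three-photon absorption
is

    Pr_pulse = (delta * E^3 / tau^2) * (NA^2 / (2 h c lambda))^3

where ``delta`` is the three-photon cross-section (cm^6 (s/photon)^2), ``E``
the pulse energy, ``tau`` the pulse width, ``NA`` the effective numerical
aperture and ``lambda`` the excitation wavelength. The time-averaged number
of photons absorbed per fluorophore is ``Pr_pulse * R`` with ``R`` the
repetition rate, which realises the familiar ``n ~ P^3 delta / (tau R)^2``
proportionality exactly when ``E = P / R``.

Because published three-photon cross-sections are cm-based, all internal
arithmetic here is carried out in CGS units; the public API accepts SI and
converts at the boundary. This avoids the silent 1e12 error that mixing
metre- and centimetre-based quantities invites.

The safety-envelope helpers compare, as a function of repetition rate, the
pulse energy at which bulk heating (an average-power bound), optical
breakdown (a fluence-derived energy that grows only as ``tau^0.4`` below
1 ps) and routine imaging each occur.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# CGS physical constants
_H_ERG_S = 6.62607015e-27  # Planck constant, erg s
_C_CM_S = 2.99792458e10  # speed of light, cm/s

_J_TO_ERG = 1.0e7
_M_TO_CM = 1.0e2

#: water-immersion limit for the numerical aperture
_NA_MAX = 1.33

SAFE = "safe"
SATURATING = "saturating"
#: excitation probability above which saturation / PSF broadening sets in
SATURATION_LIMIT = 0.1


class InvalidParameterError(ValueError):
    """A physical parameter is missing, non-positive, or inconsistent."""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value) or value <= 0:
            raise InvalidParameterError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class LaserParams:
    """Pulsed-laser excitation parameters, SI units.

    ``pulse_energy`` and ``average_power`` are linked by ``E = P / R``; either
    may be omitted and is filled in from the other. Supplying both is allowed
    only if they agree to a relative 1e-9.
    """

    average_power: float | None = None  # W
    pulse_energy: float | None = None  # J
    pulse_width: float = 40e-15  # s
    repetition_rate: float = 800e3  # Hz
    wavelength: float = 1300e-9  # m
    numerical_aperture: float = 0.9

    def __post_init__(self) -> None:
        if self.average_power is None and self.pulse_energy is None:
            raise InvalidParameterError("one of average_power or pulse_energy is required")
        if self.pulse_energy is None:
            object.__setattr__(self, "pulse_energy", self.average_power / self.repetition_rate)
        if self.average_power is None:
            object.__setattr__(self, "average_power", self.pulse_energy * self.repetition_rate)
        _require_positive(
            average_power=self.average_power,
            pulse_energy=self.pulse_energy,
            pulse_width=self.pulse_width,
            repetition_rate=self.repetition_rate,
            wavelength=self.wavelength,
            numerical_aperture=self.numerical_aperture,
        )
        if self.numerical_aperture > _NA_MAX:
            raise InvalidParameterError(
                f"numerical_aperture {self.numerical_aperture} exceeds water-immersion limit {_NA_MAX}"
            )
        expected = self.average_power / self.repetition_rate
        if abs(self.pulse_energy - expected) > 1e-9 * max(self.pulse_energy, expected):
            raise InvalidParameterError(
                f"pulse_energy {self.pulse_energy} inconsistent with "
                f"average_power/repetition_rate = {expected}"
            )


@dataclass(frozen=True)
class FluorophoreSpec:
    """Fluorophore nonlinear-absorption properties.

    ``three_photon_cross_section`` is in the units cross-sections are
    published in: cm^6 (s/photon)^2. GCaMP6s is of order 1e-82.
    """

    three_photon_cross_section: float

    def __post_init__(self) -> None:
        _require_positive(three_photon_cross_section=self.three_photon_cross_section)


#: GCaMP6s-like cross-section bracket, cm^6 (s/photon)^2
GCAMP6S_CROSS_SECTION_RANGE = (1e-82, 2e-82)


@dataclass(frozen=True)
class SafetyEnvelope:
    """Bounds delimiting damage-free three-photon imaging.

    heating_power_bound
        Average-power bound above which bulk heating damages tissue; the
        literature brackets it between 150 mW (conservative) and 300 mW.
    breakdown_energy_at_surface
        Surface pulse energy at which optical breakdown occurs at the target
        depth (depth-specific; comes from the attenuation model).
    breakdown_pulse_width_exponent
        Breakdown threshold grows as ``tau**exponent`` for sub-picosecond
        pulses (0.4).
    imaging_anchor
        ``(pulse_energy J, repetition_rate Hz, pulse_width s)`` at which
        imaging at the target depth is known to work.
    """

    heating_power_bound: float  # W
    breakdown_energy_at_surface: float  # J
    imaging_anchor: tuple[float, float, float] = (10e-9, 800e3, 40e-15)
    breakdown_pulse_width_exponent: float = 0.4

    def __post_init__(self) -> None:
        _require_positive(
            heating_power_bound=self.heating_power_bound,
            breakdown_energy_at_surface=self.breakdown_energy_at_surface,
        )
        if not 0 < self.breakdown_pulse_width_exponent < 1:
            raise InvalidParameterError("breakdown_pulse_width_exponent must be in (0, 1)")
        _require_positive(
            anchor_energy=self.imaging_anchor[0],
            anchor_rate=self.imaging_anchor[1],
            anchor_width=self.imaging_anchor[2],
        )


def excitation_probability_per_pulse(laser: LaserParams, fluor: FluorophoreSpec) -> float:
    """Probability that one laser pulse excites a fluorophore in the focus.

    Evaluates ``delta E^3 / tau^2 * (NA^2/(2 h c lambda))^3`` in CGS. The
    result is not clamped: values above 1 signal unphysical saturation and
    are left to the caller to interpret.
    """
    e_erg = laser.pulse_energy * _J_TO_ERG
    lam_cm = laser.wavelength * _M_TO_CM
    focus_factor = laser.numerical_aperture**2 / (2.0 * _H_ERG_S * _C_CM_S * lam_cm)
    return (
        fluor.three_photon_cross_section
        * e_erg**3
        / laser.pulse_width**2
        * focus_factor**3
    )


def photons_absorbed_per_second(laser: LaserParams, fluor: FluorophoreSpec) -> float:
    """Time-averaged three-photon absorption rate per fluorophore (1/s).

    ``Pr_pulse * R``; at fixed average power this scales as
    ``P^3 delta / (tau R)^2``.
    """
    return excitation_probability_per_pulse(laser, fluor) * laser.repetition_rate


def saturation_flag(pr: float) -> str:
    """Classify an excitation probability against the 0.1 saturation limit.

    The boundary value 0.1 itself is classified ``saturating`` (conservative
    reading of the strict ``Pr_pulse < 0.1`` requirement).
    """
    if pr < 0:
        raise InvalidParameterError(f"probability must be non-negative, got {pr}")
    return SAFE if pr < SATURATION_LIMIT else SATURATING


def heating_limited_energy(repetition_rate: float, power_bound: float) -> float:
    """Pulse energy (J) at which average power reaches the heating bound."""
    _require_positive(repetition_rate=repetition_rate, power_bound=power_bound)
    return power_bound / repetition_rate


def breakdown_energy_scaled(
    base_energy: float,
    base_pulse_width: float,
    pulse_width: float,
    exponent: float = 0.4,
) -> float:
    """Rescale a breakdown threshold energy to a different pulse width.

    The optical-breakdown threshold rises only slowly with pulse width,
    ``E_bd ~ tau**0.4``, a scaling valid for pulses shorter than ~1 ps.
    """
    _require_positive(
        base_energy=base_energy, base_pulse_width=base_pulse_width, pulse_width=pulse_width
    )
    if pulse_width >= 1e-12:
        warnings.warn(
            "tau^0.4 breakdown scaling is only established for pulse widths < 1 ps",
            stacklevel=2,
        )
    return base_energy * (pulse_width / base_pulse_width) ** exponent

CONSTANT_PULSE_SIGNAL = "constant_pulse_signal"
CONSTANT_FRAME_SIGNAL = "constant_frame_signal"


def imaging_energy_required(
    repetition_rate: float,
    pulse_width: float,
    envelope: SafetyEnvelope,
    mode: str = CONSTANT_PULSE_SIGNAL,
) -> float:
    """Pulse energy (J) needed for imaging at other laser settings.

    Scales the anchor energy linearly in pulse width (peak intensity sets the
    per-pulse signal). Two repetition-rate conventions are offered because
    the R-dependence of "energy required for imaging" is convention-bound:

    - ``constant_pulse_signal``: per-pulse signal held fixed; E independent
      of R.
    - ``constant_frame_signal``: photons per frame held fixed by keeping
      ``E^3 R`` constant, so ``E ~ R^(-1/3)``.
    """
    _require_positive(repetition_rate=repetition_rate, pulse_width=pulse_width)
    e0, r0, tau0 = envelope.imaging_anchor
    e = e0 * (pulse_width / tau0)
    if mode == CONSTANT_PULSE_SIGNAL:
        return e
    if mode == CONSTANT_FRAME_SIGNAL:
        return e * (repetition_rate / r0) ** (-1.0 / 3.0)
    raise InvalidParameterError(f"unknown imaging-energy mode {mode!r}")


HEATING = "heating"
BREAKDOWN = "breakdown"


def safety_envelope_curves(
    r_grid,
    envelope: SafetyEnvelope,
    mode: str = CONSTANT_PULSE_SIGNAL,
    pulse_width: float | None = None,
) -> pd.DataFrame:
    """Damage and imaging energy curves over a repetition-rate grid.

    Returns one row per repetition rate with the heating-limited energy
    (``power_bound / R``), the breakdown energy (constant in R for a fixed
    pulse width), the imaging energy, and which damage mechanism has the
    lower threshold there. Heating and breakdown cross at exactly
    ``R = power_bound / E_breakdown``: breakdown dominates below, heating
    above.
    """
    r = np.asarray(r_grid, dtype=float)
    if r.size == 0:
        raise InvalidParameterError("repetition-rate grid must be non-empty")
    if np.any(r <= 0):
        raise InvalidParameterError("repetition rates must be strictly positive")
    if np.any(np.diff(r) <= 0):
        raise InvalidParameterError("repetition-rate grid must be sorted strictly ascending")
    tau = envelope.imaging_anchor[2] if pulse_width is None else pulse_width
    e_heat = envelope.heating_power_bound / r
    e_break = breakdown_energy_scaled(
        envelope.breakdown_energy_at_surface,
        envelope.imaging_anchor[2],
        tau,
        envelope.breakdown_pulse_width_exponent,
    )
    e_img = np.array([imaging_energy_required(ri, tau, envelope, mode) for ri in r])
    regime = np.where(e_break < e_heat, BREAKDOWN, HEATING)
    return pd.DataFrame(
        {
            "repetition_rate_hz": r,
            "e_heating_j": e_heat,
            "e_breakdown_j": np.full_like(r, e_break),
            "e_imaging_j": e_img,
            "dominant_damage_mechanism": regime,
        }
    )
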