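"""Monte Carlo transport of emission photons through scattering tissue.

Photons are launched at a focal depth inside a tissue slab and random-walk
with exponentially distributed free paths (mean = scattering length),
Henyey-Greenstein (HG) angular deflections with anisotropy ``g``, and
per-step Russian-roulette absorption with survival probability
``exp(-step / absorption_length)``. A photon terminates by absorption, by
crossing the bottom of the slab (absorbing terminator), or by crossing the
top surface, where it exits in a straight line (refraction at the
tissue/air interface is not modelled). An exiting photon is *collected* iff
its straight-line continuation passes within the aperture radius at the
aperture plane and its exit angle from the vertical is within the
acceptance half-angle.

The walk is stepped synchronously over the whole photon batch with a single
counter-based (Philox) random stream, so a run is exactly reproducible
given ``(seed, n_photons)``.

Geometry: ``z`` increases downward, the surface is ``z = 0``; positions in
µm inside the tissue, collection geometry in mm above the surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_MAX_STEPS = 100_000

ABSORBED = "absorbed"
EXIT = "exit"


@dataclass(frozen=True)
class OpticalMedium:
    """Homogeneous slab: scattering/absorption lengths (µm), HG anisotropy.

    Either length may be ``inf`` to switch the process off. The effective
    extinction length combines both: ``1/l_ext = 1/l_s + 1/l_a``.
    """

    scattering_length: float  # µm
    absorption_length: float  # µm
    anisotropy_g: float
    thickness: float  # µm

    def __post_init__(self) -> None:
        if not (self.scattering_length > 0 and self.absorption_length > 0):
            raise ValueError("scattering and absorption lengths must be positive")
        if not -1.0 < self.anisotropy_g < 1.0:
            raise ValueError(f"anisotropy g must lie in (-1, 1), got {self.anisotropy_g}")
        if not self.thickness > 0:
            raise ValueError("slab thickness must be positive")

    @property
    def extinction_length(self) -> float:
        inv = 1.0 / self.scattering_length + 1.0 / self.absorption_length
        return math.inf if inv == 0 else 1.0 / inv


#: brain-like media at the three emission bands (THG 433 nm, green 520 nm,
#: red 600 nm): scattering lengths 64/75/90 µm, g = 0.94/0.93/0.92,
#: absorption length 1 mm (water).
BRAIN_MEDIA = {
    433: OpticalMedium(64.0, 1000.0, 0.94, 1200.0),
    520: OpticalMedium(75.0, 1000.0, 0.93, 1200.0),
    600: OpticalMedium(90.0, 1000.0, 0.92, 1200.0),
}


@dataclass(frozen=True)
class CollectionGeometry:
    """Simplified collection optics: a circular aperture above the surface."""

    aperture_radius: float  # mm
    aperture_distance_above_surface: float  # mm
    acceptance_half_angle: float = 90.0  # degrees from vertical

    def __post_init__(self) -> None:
        if self.aperture_radius < 0:
            raise ValueError("aperture radius must be non-negative")
        if not self.aperture_distance_above_surface > 0:
            raise ValueError("aperture distance must be positive")
        if not 0.0 < self.acceptance_half_angle <= 90.0:
            raise ValueError("acceptance half-angle must lie in (0, 90] degrees")


@dataclass(frozen=True)
class TransportResult:
    """Photon bookkeeping of one simulation run."""

    n_launched: int
    n_collected: int
    n_absorbed: int
    n_escaped_uncollected: int
    seed: int

    def __post_init__(self) -> None:
        total = self.n_collected + self.n_absorbed + self.n_escaped_uncollected
        if total != self.n_launched:
            raise ValueError(
                f"count conservation violated: {total} outcomes for {self.n_launched} launched"
            )

    @property
    def collected_fraction(self) -> float:
        return self.n_collected / self.n_launched


def sample_hg_cosine(g: float, u):
    """Inverse-CDF sample of the HG scattering cosine from uniform ``u``.

    For ``g = 0`` the distribution is isotropic (``cos = 2u - 1``); the mean
    cosine of the distribution equals ``g``.
    """
    if not -1.0 < g < 1.0:
        raise ValueError(f"anisotropy g must lie in (-1, 1), got {g}")
    u = np.asarray(u, dtype=float)
    if g == 0.0:
        cos = 2.0 * u - 1.0
    else:
        frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        cos = (1.0 + g * g - frac * frac) / (2.0 * g)
    return np.clip(cos, -1.0, 1.0)


def _isotropic_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    cos = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin = np.sqrt(1.0 - cos * cos)
    return np.column_stack([sin * np.cos(phi), sin * np.sin(phi), cos])


def _scatter(dirs: np.ndarray, cos_t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate unit vectors by polar angle acos(cos_t) and azimuth phi."""
    sin_t = np.sqrt(np.clip(1.0 - cos_t * cos_t, 0.0, 1.0))
    ux, uy, uz = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    out = np.empty_like(dirs)
    near_pole = np.abs(uz) > 1.0 - 1e-10
    # general rotation
    denom = np.sqrt(np.clip(1.0 - uz * uz, 1e-30, None))
    cp, sp = np.cos(phi), np.sin(phi)
    out[:, 0] = sin_t * (ux * uz * cp - uy * sp) / denom + ux * cos_t
    out[:, 1] = sin_t * (uy * uz * cp + ux * sp) / denom + uy * cos_t
    out[:, 2] = -sin_t * cp * denom + uz * cos_t
    # vertical propagation: rotate about an arbitrary horizontal axis
    if near_pole.any():
        sign = np.sign(uz[near_pole])
        out[near_pole, 0] = (sin_t * cp)[near_pole]
        out[near_pole, 1] = (sin_t * sp)[near_pole]
        out[near_pole, 2] = sign * cos_t[near_pole]
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    return out / norms


def _propagate_batch(
    n: int,
    depth: float,
    medium: OpticalMedium,
    rng: np.random.Generator,
    initial_direction=None,
):
    """Walk ``n`` photons to termination.

    Returns ``(exit_xy, exit_dirs, n_absorbed, n_bottom)`` where the exit
    arrays hold one row per surface-exiting photon (position µm, unit
    direction with negative z-component) and ``n_bottom`` counts photons
    terminated at the absorbing bottom boundary (booked as uncollected
    escapes, not tissue absorption, so switching absorption off really does
    zero the absorbed count).
    """
    if not 0.0 < depth <= medium.thickness:
        raise ValueError(f"start depth must lie in (0, thickness], got {depth}")
    pos = np.zeros((n, 3))
    pos[:, 2] = depth
    if initial_direction is None:
        dirs = _isotropic_directions(rng, n)
    else:
        d = np.asarray(initial_direction, dtype=float)
        d = d / np.linalg.norm(d)
        dirs = np.tile(d, (n, 1))
    exit_xy, exit_dirs = [], []
    n_absorbed = 0
    n_bottom = 0
    l_s, l_a = medium.scattering_length, medium.absorption_length
    for _ in range(_MAX_STEPS):
        m = pos.shape[0]
        if m == 0:
            break
        if math.isinf(l_s):
            step = np.full(m, np.inf)
        else:
            step = rng.exponential(l_s, m)
        dz = dirs[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            t_top = np.where(dz < 0, -pos[:, 2] / dz, np.inf)
            t_bot = np.where(dz > 0, (medium.thickness - pos[:, 2]) / dz, np.inf)
        t_bound = np.minimum(t_top, t_bot)
        travel = np.minimum(step, t_bound)
        # photons moving exactly horizontally in a non-scattering medium
        stuck = ~np.isfinite(travel)
        if stuck.any():
            n_absorbed += int(stuck.sum())
            keep = ~stuck
            pos, dirs = pos[keep], dirs[keep]
            step, t_top, t_bound, travel = step[keep], t_top[keep], t_bound[keep], travel[keep]
            m = pos.shape[0]
            if m == 0:
                break
        if math.isinf(l_a):
            survives = np.ones(m, dtype=bool)
        else:
            survives = rng.random(m) < np.exp(-travel / l_a)
        exits_top = survives & (travel == t_top)
        hits_bottom = survives & ~exits_top & (travel == t_bound)
        scatters = survives & ~exits_top & ~hits_bottom
        n_absorbed += int(np.count_nonzero(~survives))
        n_bottom += int(np.count_nonzero(hits_bottom))
        if exits_top.any():
            p = pos[exits_top] + travel[exits_top, None] * dirs[exits_top]
            p[:, 2] = 0.0
            exit_xy.append(p[:, :2])
            exit_dirs.append(dirs[exits_top])
        if not scatters.any():
            pos = pos[:0]
            continue
        pos = pos[scatters] + travel[scatters, None] * dirs[scatters]
        d_s = dirs[scatters]
        cos_t = sample_hg_cosine(medium.anisotropy_g, rng.random(d_s.shape[0]))
        phi = rng.uniform(0.0, 2.0 * np.pi, d_s.shape[0])
        dirs = _scatter(d_s, np.asarray(cos_t), phi)
    else:
        # pathological non-terminating photons are booked as absorbed
        n_absorbed += pos.shape[0]
    if exit_xy:
        return np.concatenate(exit_xy), np.concatenate(exit_dirs), n_absorbed, n_bottom
    return np.empty((0, 2)), np.empty((0, 3)), n_absorbed, n_bottom


def propagate_photon(
    start_depth: float,
    medium: OpticalMedium,
    rng: np.random.Generator,
    direction=None,
):
    """Walk a single photon; returns ``(ABSORBED, None, None)`` or
    ``(EXIT, position_xy_um, unit_direction)``."""
    xy, d, n_abs, n_bottom = _propagate_batch(
        1, start_depth, medium, rng, initial_direction=direction
    )
    if n_abs or n_bottom:
        return ABSORBED, None, None
    return EXIT, xy[0], d[0]


def _collected_mask(
    exit_xy: np.ndarray, exit_dirs: np.ndarray, geometry: CollectionGeometry
) -> np.ndarray:
    if exit_xy.shape[0] == 0:
        return np.zeros(0, dtype=bool)
    dz = exit_dirs[:, 2]  # negative: moving up
    cos_exit = -dz
    angle_ok = cos_exit >= math.cos(math.radians(geometry.acceptance_half_angle))
    h_um = geometry.aperture_distance_above_surface * 1000.0
    with np.errstate(divide="ignore"):
        t = h_um / np.where(cos_exit > 0, cos_exit, np.inf)
    x = exit_xy[:, 0] + t * exit_dirs[:, 0]
    y = exit_xy[:, 1] + t * exit_dirs[:, 1]
    r_ok = np.hypot(x, y) <= geometry.aperture_radius * 1000.0
    return angle_ok & r_ok


def simulate_collection(
    n_photons: int,
    depth: float,
    medium: OpticalMedium,
    geometry: CollectionGeometry,
    seed: int,
    initial_direction=None,
) -> TransportResult:
    """Launch photons from the focus and count the collected fraction.

    Initial directions are isotropic unless ``initial_direction`` pins them
    (useful for ballistic-limit checks). Deterministic given
    ``(seed, n_photons)``.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be at least 1")
    rng = np.random.Generator(np.random.Philox(seed))
    exit_xy, exit_dirs, n_absorbed, n_bottom = _propagate_batch(
        n_photons, depth, medium, rng, initial_direction=initial_direction
    )
    collected = _collected_mask(exit_xy, exit_dirs, geometry)
    n_col = int(collected.sum())
    n_exit = exit_xy.shape[0]
    return TransportResult(
        n_launched=n_photons,
        n_collected=n_col,
        n_absorbed=n_absorbed,
        n_escaped_uncollected=n_exit - n_col + n_bottom,
        seed=seed,
    )


def aperture_comparison(result_small: TransportResult, result_large: TransportResult) -> float:
    """Fold change in collected photons between two collection geometries."""
    if result_small.n_launched != result_large.n_launched:
        raise ValueError("results must come from runs with equal n_launched")
    if result_small.n_collected == 0:
        raise ZeroDivisionError("small-aperture run collected no photons")
    return result_large.n_collected / result_small.n_collected
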