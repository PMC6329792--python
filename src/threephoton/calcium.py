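"""Calcium-imaging visual-physiology pipeline.

From a fluorescence movie and a drifting-grating stimulus protocol to
per-neuron response features:

1. rigid registration of every frame to the pixel-wise mean image by the
   argmax of the 2-D cross-correlation (integer shifts);
2. dF/F with the baseline F0 taken as the mode of the raw trace's intensity
   distribution;
3. per-presentation epoch means (static vs drifting grating) grouped by
   direction;
4. responsiveness: a neuron is visually responsive if, for at least one
   direction, the paired t test between its drift-epoch and static-epoch
   means across trials is significant;
5. a bimodal Gaussian (von-Mises-like, wrapped) tuning fit

       R(theta) = R0 + Rp exp(-<theta-theta_p>^2 / 2 sigma^2)
                     + Rn exp(-<theta-theta_p-180>^2 / 2 sigma^2)

   with <.> wrapping angles to (-180, 180]; a neuron is orientation
   selective if the fit's R^2 exceeds 0.6;
6. selectivity indices: gOSI (vector average on doubled angles), OSI
   (preferred vs orthogonal) and DSI (preferred vs opposite), computed on
   responses rectified at zero;
7. nominal cortical-layer assignment from imaging depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

DEFAULT_DIRECTIONS = tuple(range(0, 360, 30))

#: nominal mouse V1 laminar boundaries, µm below the pia; a boundary depth
#: belongs to the deeper layer
DEFAULT_LAYER_BOUNDARIES = (
    (100.0, "L1"),
    (350.0, "L2/3"),
    (450.0, "L4"),
    (600.0, "L5"),
    (750.0, "L6"),
)
SUBPLATE_LABEL = "subplate/WM"

#: R^2 above which a tuning fit counts as orientation selective
OS_R2_THRESHOLD = 0.6


@dataclass(frozen=True)
class StimulusProtocol:
    """Drifting-grating protocol: per-trial pseudorandom direction order.

    Each presentation lasts ``trial_length`` seconds: a static grating for
    the first ``static_pre`` and last ``static_post`` seconds and drift for
    the ``drift`` seconds between. ``order`` holds direction *indices*, one
    per presentation, concatenated trial by trial; within a trial each
    direction appears exactly once.
    """

    directions: tuple = DEFAULT_DIRECTIONS
    trial_length: float = 12.0
    static_pre: float = 3.0
    drift: float = 6.0
    static_post: float = 3.0
    n_trials: int = 10
    frame_rate: float = 4.0
    order: tuple = ()

    def __post_init__(self) -> None:
        if abs(self.static_pre + self.drift + self.static_post - self.trial_length) > 1e-9:
            raise ValueError("static_pre + drift + static_post must equal trial_length")
        if self.n_trials < 1 or self.frame_rate <= 0:
            raise ValueError("n_trials and frame_rate must be positive")
        if not self.order:
            object.__setattr__(
                self,
                "order",
                tuple(np.tile(np.arange(len(self.directions)), self.n_trials)),
            )
        counts = np.bincount(np.asarray(self.order), minlength=len(self.directions))
        if not np.all(counts == self.n_trials):
            raise ValueError("each direction must appear exactly n_trials times in order")

    @classmethod
    def generate(cls, seed: int, **kwargs) -> "StimulusProtocol":
        """Protocol with an independent seeded permutation per trial."""
        rng = np.random.default_rng(seed)
        n_dir = len(kwargs.get("directions", DEFAULT_DIRECTIONS))
        n_trials = kwargs.get("n_trials", 10)
        order = np.concatenate([rng.permutation(n_dir) for _ in range(n_trials)])
        return cls(order=tuple(int(i) for i in order), **kwargs)

    @property
    def n_directions(self) -> int:
        return len(self.directions)

    @property
    def n_presentations(self) -> int:
        return self.n_directions * self.n_trials

    @property
    def frames_per_trial(self) -> int:
        return int(round(self.trial_length * self.frame_rate))

    @property
    def n_frames(self) -> int:
        return self.frames_per_trial * self.n_presentations


@dataclass
class RoiTrace:
    """Per-neuron fluorescence trace and its derived quantities."""

    roi_id: int
    depth: float  # µm
    raw_fluorescence: np.ndarray
    dff: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw_fluorescence = np.asarray(self.raw_fluorescence, dtype=float)
        if self.raw_fluorescence.ndim != 1:
            raise ValueError("raw fluorescence must be a 1-D time series")


@dataclass(frozen=True)
class TuningFitResult:
    theta_p: float  # degrees, [0, 360)
    sigma: float  # degrees
    r0: float
    rp: float
    rn: float
    r_squared: float  # NaN for a flat (degenerate) tuning curve

    def curve(self, theta) -> np.ndarray:
        return tuning_model(theta, self.theta_p, self.sigma, self.r0, self.rp, self.rn)


@dataclass(frozen=True)
class SelectivityIndices:
    gosi: float
    osi: float
    dsi: float


# ---------------------------------------------------------------------------
# movie registration


def register_translation(movie: np.ndarray, max_shift_frac: float = 0.1):
    """Rigid translation correction against the mean image.

    The reference is the pixel-wise mean of all frames; each frame is
    shifted by the integer argmax of its 2-D cross-correlation with the
    reference (computed via FFT), capped at ``max_shift_frac`` of the frame
    size. Pixels rolled in from outside are filled with the frame median.

    Returns ``(registered_movie, shifts)`` with ``shifts[t] = (dy, dx)``
    the applied correction.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError("movie must be (time, y, x)")
    n_frames, ny, nx = movie.shape
    if n_frames < 2:
        warnings.warn("single-frame movie: registration is the identity", stacklevel=2)
        return movie.copy(), np.zeros((n_frames, 2), dtype=int)
    reference = movie.mean(axis=0)
    cap_y = max(1, int(round(max_shift_frac * ny)))
    cap_x = max(1, int(round(max_shift_frac * nx)))
    ref_f = np.fft.rfft2(reference - reference.mean())
    registered = np.empty_like(movie)
    shifts = np.zeros((n_frames, 2), dtype=int)
    for t in range(n_frames):
        frame = movie[t]
        xcorr = np.fft.irfft2(ref_f * np.conj(np.fft.rfft2(frame - frame.mean())), s=(ny, nx))
        # restrict the search to the shift cap (wrapped quadrants)
        dy_candidates = np.r_[np.arange(0, cap_y + 1), np.arange(ny - cap_y, ny)]
        dx_candidates = np.r_[np.arange(0, cap_x + 1), np.arange(nx - cap_x, nx)]
        sub = xcorr[np.ix_(dy_candidates, dx_candidates)]
        iy, ix = np.unravel_index(np.argmax(sub), sub.shape)
        dy = int(dy_candidates[iy])
        dx = int(dx_candidates[ix])
        if dy > ny // 2:
            dy -= ny
        if dx > nx // 2:
            dx -= nx
        shifts[t] = (dy, dx)
        registered[t] = _shift_fill(frame, dy, dx)
    return registered, shifts


def _shift_fill(frame: np.ndarray, dy: int, dx: int) -> np.ndarray:
    out = np.roll(frame, (dy, dx), axis=(0, 1))
    fill = float(np.median(frame))
    if dy > 0:
        out[:dy, :] = fill
    elif dy < 0:
        out[dy:, :] = fill
    if dx > 0:
        out[:, :dx] = fill
    elif dx < 0:
        out[:, dx:] = fill
    return out


def extract_traces(movie: np.ndarray, roi_labels: np.ndarray) -> dict[int, np.ndarray]:
    """Mean intensity per labelled ROI per frame (labels > 0)."""
    movie = np.asarray(movie, dtype=float)
    labels = np.asarray(roi_labels)
    if labels.shape != movie.shape[1:]:
        raise ValueError("ROI label image must match the movie frame shape")
    out = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        mask = labels == lab
        out[int(lab)] = movie[:, mask].mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# dF/F


def compute_dff(raw: np.ndarray) -> np.ndarray:
    """dF/F with F0 = mode of the raw intensity distribution.

    The mode is the centre of the tallest bin of a Freedman-Diaconis
    histogram of the trace (ties resolved toward the lowest-intensity bin).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size == 0:
        raise ValueError("raw trace must be a non-empty 1-D series")
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw trace contains non-finite values")
    f0 = _histogram_mode(raw)
    if f0 <= 0:
        raise ValueError(f"baseline F0 must be positive, got {f0}")
    return (raw - f0) / f0


def _histogram_mode(x: np.ndarray) -> float:
    span = np.ptp(x)
    if span == 0:
        return float(x[0])
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    width = 2.0 * iqr / x.size ** (1.0 / 3.0)
    if width > 0:
        bins = max(int(np.ceil(span / width)), 1)
    else:
        # degenerate IQR (heavily quantised trace): square-root rule
        bins = max(int(np.ceil(np.sqrt(x.size))), 1)
    counts, edges = np.histogram(x, bins=bins)
    i = int(np.argmax(counts))  # argmax takes the first (lowest) max bin
    return float(0.5 * (edges[i] + edges[i + 1]))


# ---------------------------------------------------------------------------
# epoch means and responsiveness


def epoch_responses(dff: np.ndarray, protocol: StimulusProtocol):
    """Static- and drift-epoch dF/F means per direction and trial.

    The two static epochs of each presentation (pre and post drift) are
    pooled. Returns ``(static_means, drift_means)``, each shaped
    ``(n_directions, n_trials)``, trials ordered by occurrence.
    """
    dff = np.asarray(dff, dtype=float)
    fpt = protocol.frames_per_trial
    needed = protocol.n_presentations * fpt
    if dff.size < needed:
        raise ValueError(f"trace has {dff.size} frames but protocol needs {needed}")
    fr = protocol.frame_rate
    pre_f = int(round(protocol.static_pre * fr))
    drift_f = int(round(protocol.drift * fr))
    static = np.zeros((protocol.n_directions, protocol.n_trials))
    drift = np.zeros_like(static)
    seen = np.zeros(protocol.n_directions, dtype=int)
    for k, d_idx in enumerate(protocol.order):
        seg = dff[k * fpt : (k + 1) * fpt]
        static_samples = np.r_[seg[:pre_f], seg[pre_f + drift_f :]]
        t = seen[d_idx]
        static[d_idx, t] = static_samples.mean()
        drift[d_idx, t] = seg[pre_f : pre_f + drift_f].mean()
        seen[d_idx] += 1
    return static, drift


def classify_visually_responsive(static: np.ndarray, drift: np.ndarray, alpha: float = 0.05):
    """Paired t test per direction; responsive iff any direction p < alpha.

    Zero-variance differences are handled explicitly: p = 1 when all
    differences vanish, p = 0 when they are constant but non-zero.
    Returns ``(responsive, p_values)``.
    """
    static = np.atleast_2d(static)
    drift = np.atleast_2d(drift)
    if static.shape != drift.shape or static.shape[1] < 2:
        raise ValueError("need matched static/drift arrays with >= 2 trials")
    pvals = np.ones(static.shape[0])
    for j in range(static.shape[0]):
        diff = drift[j] - static[j]
        if np.allclose(diff.std(), 0.0):
            pvals[j] = 1.0 if np.allclose(diff, 0.0) else 0.0
        else:
            pvals[j] = stats.ttest_rel(drift[j], static[j]).pvalue
    return bool(np.any(pvals < alpha)), pvals


# ---------------------------------------------------------------------------
# tuning fit


def wrap_angle(theta):
    """Wrap angles (degrees) to (-180, 180]."""
    wrapped = -((-np.asarray(theta, dtype=float) + 180.0) % 360.0 - 180.0)
    return wrapped


def tuning_model(theta, theta_p, sigma, r0, rp, rn):
    """Bimodal Gaussian tuning curve, lobes at theta_p and theta_p + 180."""
    theta = np.asarray(theta, dtype=float)
    d1 = wrap_angle(theta - theta_p)
    d2 = wrap_angle(theta - theta_p - 180.0)
    return (
        r0
        + rp * np.exp(-(d1**2) / (2.0 * sigma**2))
        + rn * np.exp(-(d2**2) / (2.0 * sigma**2))
    )


def fit_tuning(direction_means, directions=DEFAULT_DIRECTIONS) -> TuningFitResult:
    """Least-squares bimodal Gaussian fit of a 12-point tuning curve.

    Multi-start over every presented direction as the initial preferred
    direction; the best (lowest SSR) solution is kept and canonicalised so
    the larger lobe is the preferred one and theta_p lies in [0, 360).
    A flat curve (zero total sum of squares) yields ``r_squared = NaN``.
    """
    y = np.asarray(direction_means, dtype=float)
    theta = np.asarray(directions, dtype=float)
    if y.shape != theta.shape:
        raise ValueError("one mean response per direction is required")
    if not np.all(np.isfinite(y)):
        raise ValueError("direction means must be finite")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 1e-20 * max(1.0, float(np.sum(y**2))):
        return TuningFitResult(
            theta_p=float(theta[0]), sigma=30.0, r0=float(y[0]), rp=0.0, rn=0.0,
            r_squared=float("nan"),
        )
    span = float(y.max() - y.min())
    best, best_ssr = None, np.inf
    for theta0 in theta:
        p0 = [theta0, 30.0, float(y.min()), span, 0.5 * span]
        try:
            popt, _ = optimize.curve_fit(
                tuning_model,
                theta,
                y,
                p0=p0,
                bounds=(
                    [-360.0, 1.0, -np.inf, 0.0, 0.0],
                    [720.0, 180.0, np.inf, np.inf, np.inf],
                ),
                maxfev=5000,
            )
        except RuntimeError:
            continue
        ssr = float(np.sum((y - tuning_model(theta, *popt)) ** 2))
        if ssr < best_ssr:
            best, best_ssr = popt, ssr
    if best is None:
        raise RuntimeError("tuning fit failed to converge from every start")
    theta_p, sigma, r0, rp, rn = best
    if rn > rp:
        theta_p, rp, rn = theta_p + 180.0, rn, rp
    theta_p = float(theta_p % 360.0)
    r2 = 1.0 - best_ssr / ss_tot
    return TuningFitResult(
        theta_p=theta_p, sigma=float(abs(sigma)), r0=float(r0), rp=float(rp), rn=float(rn),
        r_squared=float(r2),
    )


def classify_orientation_selective(fit: TuningFitResult) -> bool:
    """Orientation selective iff the tuning fit's R^2 strictly exceeds 0.6."""
    if not np.isfinite(fit.r_squared):
        return False
    return fit.r_squared > OS_R2_THRESHOLD


# ---------------------------------------------------------------------------
# selectivity indices


def selectivity_indices(
    direction_means,
    fit: TuningFitResult,
    directions=DEFAULT_DIRECTIONS,
) -> SelectivityIndices:
    """gOSI, OSI and DSI from direction-mean responses and the tuning fit.

    Responses are rectified at zero first so every index lies in [0, 1].
    gOSI = |sum_j R_j exp(2 i theta_j)| / sum_j R_j. The preferred response
    for OSI/DSI is the fitted curve evaluated at theta_p; the orthogonal
    (opposite) response is the mean of the rectified measured responses at
    the two directions nearest theta_p +/- 90 (theta_p + 180).
    """
    r = np.clip(np.asarray(direction_means, dtype=float), 0.0, None)
    theta = np.asarray(directions, dtype=float)
    total = r.sum()
    if total == 0:
        return SelectivityIndices(float("nan"), float("nan"), float("nan"))
    ang = np.deg2rad(2.0 * theta)
    gosi = float(np.abs(np.sum(r * np.exp(1j * ang))) / total)

    r_pref = max(float(fit.curve(fit.theta_p)), 0.0)
    r_ortho = 0.5 * (
        _response_nearest(r, theta, fit.theta_p + 90.0)
        + _response_nearest(r, theta, fit.theta_p - 90.0)
    )
    r_oppo = _response_nearest(r, theta, fit.theta_p + 180.0)
    osi = _contrast(r_pref, r_ortho)
    dsi = _contrast(r_pref, r_oppo)
    return SelectivityIndices(gosi=gosi, osi=osi, dsi=dsi)


def _response_nearest(r: np.ndarray, theta: np.ndarray, target: float) -> float:
    d = np.abs(wrap_angle(theta - target))
    return float(r[np.argmin(d)])


def _contrast(a: float, b: float) -> float:
    return float((a - b) / (a + b)) if (a + b) > 0 else float("nan")


# ---------------------------------------------------------------------------
# layers


def assign_layer(depth: float, boundaries=DEFAULT_LAYER_BOUNDARIES) -> str:
    """Cortical layer label for an imaging depth (µm below the pia).

    ``boundaries`` is a sequence of ``(upper_edge_um, label)`` sorted by
    depth; a depth exactly on an edge belongs to the deeper layer.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    for edge, label in boundaries:
        if depth < edge:
            return label
    return SUBPLATE_LABEL


# ---------------------------------------------------------------------------
# end-to-end per-ROI analysis


def analyze_traces(
    traces: list[RoiTrace],
    protocol: StimulusProtocol,
    alpha: float = 0.05,
    layer_boundaries=DEFAULT_LAYER_BOUNDARIES,
) -> pd.DataFrame:
    """Full per-neuron feature table from raw traces.

    Columns: roi_id, depth, layer, responsive, p_min, theta_p, sigma,
    r_squared, is_OS, gOSI, OSI, DSI.
    """
    rows = []
    directions = np.asarray(protocol.directions, dtype=float)
    for tr in traces:
        tr.dff = compute_dff(tr.raw_fluorescence)
        static, drift = epoch_responses(tr.dff, protocol)
        responsive, pvals = classify_visually_responsive(static, drift, alpha=alpha)
        means = drift.mean(axis=1) - static.mean(axis=1)
        fit = fit_tuning(means, directions)
        is_os = classify_orientation_selective(fit)
        idx = selectivity_indices(means, fit, directions)
        rows.append(
            {
                "roi_id": tr.roi_id,
                "depth": tr.depth,
                "layer": assign_layer(tr.depth, layer_boundaries),
                "responsive": responsive,
                "p_min": float(pvals.min()),
                "theta_p": fit.theta_p,
                "sigma": fit.sigma,
                "r_squared": fit.r_squared,
                "is_OS": is_os,
                "gOSI": idx.gosi,
                "OSI": idx.osi,
                "DSI": idx.dsi,
            }
        )
    return pd.DataFrame(rows)
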