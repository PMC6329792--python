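"""Percent-damage quantification from before/after ablation image pairs.

Both images are smoothed with a 2x2 median filter, binarised with Otsu's
threshold (each image thresholded independently, so a global intensity
rescale cancels), and the damage statistic is the increase in
below-threshold pixel count inside the targeted ablation region, expressed
as a percentage of the target area:

    damage% = 100 * (N_below_after - N_below_before) / N_target

clamped to [0, 100] (noise can push the raw ratio slightly negative).
Counting is restricted to the target mask so the statistic is bounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu


@dataclass(frozen=True)
class AblationImagePair:
    """Before/after fluorescence images with the intended ablation mask."""

    before: np.ndarray
    after: np.ndarray
    target_mask: np.ndarray

    def __post_init__(self) -> None:
        before = np.asarray(self.before)
        after = np.asarray(self.after)
        mask = np.asarray(self.target_mask, dtype=bool)
        if before.ndim != 2:
            raise ValueError("images must be 2-D")
        if before.shape != after.shape or before.shape != mask.shape:
            raise ValueError("before, after and target_mask must share one shape")
        if not mask.any():
            raise ValueError("target mask must be non-empty")
        object.__setattr__(self, "before", before)
        object.__setattr__(self, "after", after)
        object.__setattr__(self, "target_mask", mask)


def smooth_median_2x2(image: np.ndarray) -> np.ndarray:
    """2x2 median filter with nearest-edge padding.

    Each output pixel is the median of the window anchored at that pixel
    (the pixel itself plus its right, lower and lower-right neighbours);
    the even-count median is the mean of the two middle values, so the
    output is float. Constant images are fixed points.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got {img.ndim}-D")
    padded = np.pad(img, ((0, 1), (0, 1)), mode="edge")
    stack = np.stack(
        [
            padded[:-1, :-1],
            padded[:-1, 1:],
            padded[1:, :-1],
            padded[1:, 1:],
        ]
    )
    stack.sort(axis=0)
    return 0.5 * (stack[1] + stack[2])


def otsu_threshold(image: np.ndarray) -> float:
    """Otsu's threshold over a 256-bin histogram of the image."""
    img = np.asarray(image, dtype=float)
    if np.unique(img).size < 2:
        raise ValueError("Otsu threshold is undefined for a constant image")
    return float(threshold_otsu(img, nbins=256))


def damage_percent(pair: AblationImagePair) -> float:
    """Percent of the targeted ablation area newly dark after ablation."""
    n_target = int(pair.target_mask.sum())
    counts = []
    for img in (pair.before, pair.after):
        smoothed = smooth_median_2x2(img)
        thr = otsu_threshold(smoothed)
        counts.append(int(np.count_nonzero(smoothed[pair.target_mask] < thr)))
    raw = 100.0 * (counts[1] - counts[0]) / n_target
    return float(np.clip(raw, 0.0, 100.0))
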