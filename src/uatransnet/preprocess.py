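"""Classical suspected-region extraction for bright-lesion images.

The pipeline converts a raw grayscale image into a binary "suspected
tumor" mask in five stages:

1. ROI detection — an intensity-percentile bounding box around the bright
   pixels (a deliberately simple stand-in for a learned detector).
2. Contrast adjustment — two-tailed cumulative-histogram clipping: the
   lowest and highest 5% of mass map to 0 and 1.
3. Denoising/enhancement inside the ROI — median filter (impulse noise),
   mean filter (false contours), Laplacian sharpening (edges), all with a
   window set to 5% of the larger ROI side, rounded up to odd.
4. Size estimation — an Otsu split of the ROI histogram; the lesion is
   assumed larger than the smaller class and smaller than the larger one,
   and the Otsu level seeds the growth threshold.
5. Seeded region growing — breadth-first expansion from the brightest
   central pixels; a candidate joins when its intensity I satisfies
   I > theta and mu - I < theta, where mu is the running mean of the
   accepted region.  If the grown region is smaller than the estimated
   lower bound, theta is lowered and growth continues.

All coordinates are 0-based (row, col); boxes are half-open.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = ["ROIBox", "SizeEstimate", "RegionGrowConfig", "detect_roi",
           "clip_histogram", "roi_window_size", "median_filter_roi",
           "mean_filter_roi", "laplacian_enhance", "otsu_threshold",
           "estimate_tumor_size", "select_seeds", "region_grow",
           "segment_suspected_region"]


@dataclass(frozen=True)
class ROIBox:
    """Half-open box [row0,row1) x [col0,col1), 0-based."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self):
        if not (self.row0 < self.row1 and self.col0 < self.col1):
            raise ValueError(f"degenerate ROI box {self}")

    @property
    def height(self) -> int:
        return self.row1 - self.row0

    @property
    def width(self) -> int:
        return self.col1 - self.col0

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)


@dataclass(frozen=True)
class SizeEstimate:
    lower_px: int
    upper_px: int
    otsu_level: float

    def __post_init__(self):
        if not (0 <= self.lower_px <= self.upper_px):
            raise ValueError("need 0 <= lower_px <= upper_px")


@dataclass(frozen=True)
class RegionGrowConfig:
    """Adaptive-threshold growth knobs.

    theta_step defaults to 5% of the unit intensity range; connectivity 4.
    """

    theta_init: float | None = None   # None: take the Otsu level
    theta_step: float = 0.05
    max_rounds: int = 20
    connectivity: int = 4

    def __post_init__(self):
        if self.theta_step <= 0:
            raise ValueError("theta_step must be > 0")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a nonempty 2-D grayscale image")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    return image


def detect_roi(image: np.ndarray, bright_percentile: float = 0.95,
               margin: int = 2) -> ROIBox:
    """Bounding box (plus margin, clipped to the frame) of the brightest pixels.

    Pixels strictly above the `bright_percentile` intensity quantile count as
    suspicious.  Raises on constant images, where nothing stands out.
    """
    image = _check_image(image)
    if image.max() == image.min():
        raise ValueError("no suspicious region: image is constant")
    level = float(np.quantile(image, bright_percentile))
    rows, cols = np.nonzero(image > level)
    if rows.size == 0:   # quantile equals max; fall back to the max set
        rows, cols = np.nonzero(image >= image.max())
    h, w = image.shape
    return ROIBox(max(int(rows.min()) - margin, 0), max(int(cols.min()) - margin, 0),
                  min(int(rows.max()) + 1 + margin, h), min(int(cols.max()) + 1 + margin, w))


def clip_histogram(image: np.ndarray, tail_weight: float = 0.05) -> np.ndarray:
    """Two-tailed contrast clipping: `tail_weight` of cumulative histogram
    mass at each end maps to 0 and 1, the interior rescales linearly."""
    if not 0 < tail_weight < 0.5:
        raise ValueError("tail_weight must lie in (0, 0.5)")
    image = _check_image(image)
    lo = float(np.quantile(image, tail_weight))
    hi = float(np.quantile(image, 1.0 - tail_weight))
    if hi <= lo:   # degenerate histogram: leave untouched
        return image.copy()
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def roi_window_size(roi: ROIBox) -> int:
    """Filter window: 5% of the larger ROI side, rounded up to odd, >= 3."""
    win = math.ceil(0.05 * max(roi.height, roi.width))
    if win < 3:
        return 3
    return win if win % 2 == 1 else win + 1


def _filter_roi(image, roi, window, fn):
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if window > min(roi.height, roi.width):
        raise ValueError(f"window {window} larger than ROI {roi.height}x{roi.width}")
    out = _check_image(image).copy()
    sl = roi.slices()
    out[sl] = fn(out[sl])
    return out


def median_filter_roi(image: np.ndarray, roi: ROIBox, window: int) -> np.ndarray:
    """Median filter applied inside the ROI only (impulse-noise removal)."""
    return _filter_roi(image, roi, window,
                       lambda p: ndimage.median_filter(p, size=window, mode="nearest"))


def mean_filter_roi(image: np.ndarray, roi: ROIBox, window: int) -> np.ndarray:
    """Mean filter inside the ROI (suppresses median-induced false contours)."""
    return _filter_roi(image, roi, window,
                       lambda p: ndimage.uniform_filter(p, size=window, mode="nearest"))


def laplacian_enhance(image: np.ndarray, roi: ROIBox, window: int,
                      strength: float = 0.5) -> np.ndarray:
    """Edge enhancement inside the ROI: image + strength * (-Laplacian),
    smoothed at the window scale, clipped to [0,1].  The discrete 5-point
    Laplacian is exactly zero on constants, so flat regions are untouched."""
    def enhance(patch):
        smoothed = ndimage.gaussian_filter(patch, sigma=window / 6.0, mode="nearest")
        lap = ndimage.laplace(smoothed, mode="nearest")
        return np.clip(patch - strength * lap, 0.0, 1.0)
    return _filter_roi(image, roi, window, enhance)


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Threshold maximizing between-class variance over a fixed histogram.

    The histogram has `n_bins` uniform bins over the observed intensity
    range; ties break toward the lowest maximizing bin.  The returned level
    is the upper edge of the chosen bin, so "foreground" means value > level.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise ValueError("Otsu undefined: input has a single intensity value")
    hist, edges = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    p = hist / hist.sum()
    omega = np.cumsum(p)                       # class-0 mass up to bin t
    mu = np.cumsum(p * (np.arange(n_bins) + 0.5))
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    t = int(np.argmax(sigma_b))                # argmax takes the lowest tie
    return float(edges[t + 1])


def estimate_tumor_size(image: np.ndarray, roi: ROIBox) -> SizeEstimate:
    """Otsu split of the ROI histogram: the lesion is bounded below by the
    smaller class's pixel count and above by the larger's."""
    patch = _check_image(image)[roi.slices()]
    level = otsu_threshold(patch)
    n_fg = int((patch > level).sum())
    n_bg = patch.size - n_fg
    return SizeEstimate(lower_px=min(n_fg, n_bg), upper_px=max(n_fg, n_bg),
                        otsu_level=level)


def select_seeds(image: np.ndarray, roi: ROIBox, k: int = 5) -> list[tuple[int, int]]:
    """The k brightest pixels in the central third of the ROI (both axes),
    ties broken row-major.  k is capped at the central-region size."""
    if k < 1:
        raise ValueError("k must be >= 1")
    image = _check_image(image)
    r0 = roi.row0 + roi.height // 3
    r1 = roi.row0 + max(2 * roi.height // 3, roi.height // 3 + 1)
    c0 = roi.col0 + roi.width // 3
    c1 = roi.col0 + max(2 * roi.width // 3, roi.width // 3 + 1)
    central = image[r0:r1, c0:c1]
    if k > central.size:
        warnings.warn(f"k={k} exceeds central region size {central.size}; capped")
        k = central.size
    order = np.argsort(-central, axis=None, kind="stable")[:k]
    rows, cols = np.unravel_index(order, central.shape)
    return [(int(r + r0), int(c + c0)) for r, c in zip(rows, cols)]


_NEIGHBORS = {4: ((-1, 0), (1, 0), (0, -1), (0, 1)),
              8: ((-1, 0), (1, 0), (0, -1), (0, 1),
                  (-1, -1), (-1, 1), (1, -1), (1, 1))}


def region_grow(image: np.ndarray, seeds: list[tuple[int, int]], theta: float,
                connectivity: int = 4, initial_mask: np.ndarray | None = None,
                freeze_mu: float | None = None,
                allowed: np.ndarray | None = None) -> np.ndarray:
    """Breadth-first seeded region growing.

    A frontier pixel with intensity I joins the region iff ``I > theta`` and
    ``mu - I < theta`` where mu is the running mean intensity of the region
    accepted so far (recomputed after every accepted pixel).  Seeds always
    belong.  `initial_mask` continues growth from an existing region;
    `freeze_mu` fixes mu (used for monotonicity analysis); `allowed`
    restricts growth to a boolean support (e.g. the ROI box).
    """
    image = _check_image(image)
    if not seeds:
        raise ValueError("need at least one seed")
    h, w = image.shape
    for r, c in seeds:
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"seed {(r, c)} outside image {h}x{w}")
    mask = np.zeros((h, w), dtype=bool)
    if initial_mask is not None:
        mask |= initial_mask.astype(bool)
    for r, c in seeds:
        mask[r, c] = True
    total = float(image[mask].sum())
    count = int(mask.sum())
    offsets = _NEIGHBORS[connectivity]
    queue = deque(zip(*np.nonzero(mask)))
    queued = mask.copy()
    while queue:
        r, c = queue.popleft()
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < h and 0 <= cc < w) or mask[rr, cc] or queued[rr, cc]:
                continue
            if allowed is not None and not allowed[rr, cc]:
                continue
            queued[rr, cc] = True
            val = image[rr, cc]
            mu = freeze_mu if freeze_mu is not None else total / count
            if val > theta and mu - val < theta:
                mask[rr, cc] = True
                total += val
                count += 1
                queue.append((rr, cc))
    return mask.astype(np.uint8)


def segment_suspected_region(image: np.ndarray, config: RegionGrowConfig = RegionGrowConfig(),
                             bright_percentile: float = 0.95, n_seeds: int = 5,
                             return_info: bool = False):
    """Full pipeline: ROI -> contrast clip -> filters -> size estimate ->
    seeded growth with size-adaptive threshold.  Returns a full-frame mask.

    After each growth pass, if the region is smaller than the estimated
    lower bound the threshold drops by ``theta_step`` and growth continues
    from the current region; growth stops once the size enters the estimated
    band, exceeds it, or ``max_rounds`` passes are exhausted (then the best
    mask so far is returned with a logged warning).
    """
    image = _check_image(image)
    roi = detect_roi(image, bright_percentile)
    work = clip_histogram(image)
    window = roi_window_size(roi)
    window = min(window, min(roi.height, roi.width) | 1)  # never exceed ROI, keep odd
    if window >= 3 and window <= min(roi.height, roi.width):
        work = median_filter_roi(work, roi, window)
        work = mean_filter_roi(work, roi, window)
        work = laplacian_enhance(work, roi, window)
    try:
        est = estimate_tumor_size(work, roi)
    except ValueError:
        # near-constant ROI: fall back to full-ROI bounds
        est = SizeEstimate(lower_px=0, upper_px=roi.height * roi.width,
                           otsu_level=float(work[roi.slices()].mean()))
    seeds = select_seeds(work, roi, n_seeds)
    theta = config.theta_init if config.theta_init is not None else est.otsu_level
    thetas, mask = [], None
    roi_mask = np.zeros_like(work, dtype=bool)
    roi_mask[roi.slices()] = True
    for _ in range(config.max_rounds):
        thetas.append(theta)
        mask = region_grow(work, seeds, theta, config.connectivity,
                           initial_mask=mask, allowed=roi_mask)
        size = int(mask.sum())
        if size >= est.lower_px or size > est.upper_px:
            break
        theta -= config.theta_step
    else:
        logger.warning("max_rounds=%d exhausted at region size %d < lower bound %d",
                       config.max_rounds, int(mask.sum()), est.lower_px)
    if return_info:
        return mask, {"roi": roi, "estimate": est, "seeds": seeds,
                      "theta_trajectory": thetas, "window": window}
    return mask
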