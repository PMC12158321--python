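"""Image-timing-feature extensions of the mixture background model.

The plain per-pixel mixture model absorbs slowly or intermittently moving
targets into the background (the "stay-hole" failure: interiors of dwelling
flocks turn into false-negative holes).  Two temporal features counteract
this:

1. **SSIM-scheduled learning rate.**  The global structural similarity
   between consecutive crops of a fixed region of interest (ROI) measures
   how fast the scene is changing; the mixture learning rate is set to
   ``alpha = (1 - SSIM) / 80`` inside the ROI, so a quasi-static scene
   (SSIM near 1) almost freezes the model and dwelling targets are not
   absorbed.

2. **Histogram-peak component counts.**  Each ROI pixel keeps a rolling
   grayscale histogram of its recent values; the number of merged histogram
   peaks (peaks closer than a merge distance collapse into the taller one)
   sets the number of Gaussian modes for that pixel.  Outside the ROI the
   count is fixed at 2.

The ROI itself is the bounding box of all foreground detected by the plain
model over a warm-up phase, and stays fixed afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError
from .gmm import GmmParams, MixtureModelState, init_model, step_frame

logger = logging.getLogger(__name__)

__all__ = [
    "RegionOfInterest",
    "SsimParams",
    "TemporalHistogram",
    "PeakRule",
    "ItfGmmConfig",
    "ItfGmmResult",
    "global_ssim",
    "learning_rate_from_ssim",
    "build_roi",
    "count_histogram_peaks",
    "adapt_component_count",
    "itf_gmm_run",
]


@dataclass(frozen=True)
class RegionOfInterest:
    """Axis-aligned rectangle in half-open pixel coordinates."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise InvalidArgumentError("ROI must be nonempty")
        if self.row_start < 0 or self.col_start < 0:
            raise InvalidArgumentError("ROI must lie inside the frame")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_stop - self.row_start, self.col_stop - self.col_start)

    def crop(self, frame: np.ndarray) -> np.ndarray:
        return frame[self.row_start:self.row_stop, self.col_start:self.col_stop]

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.row_start:self.row_stop, self.col_start:self.col_stop] = True
        return m


@dataclass(frozen=True)
class SsimParams:
    """Stabilisation constants of the global SSIM formula."""

    dynamic_range: float = 255.0
    k1: float = 0.01
    k2: float = 0.03

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2


def global_ssim(img_a: np.ndarray, img_b: np.ndarray,
                params: SsimParams = SsimParams()) -> float:
    """Single-window structural similarity of two equally shaped images.

    Means, variances and the covariance are taken over the whole region
    (no sliding window); the result lies in [-1, 1] and equals 1 for
    identical images.
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidArgumentError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise InvalidArgumentError("empty images")
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = float(((a - mu_a) * (b - mu_b)).mean())
    c1, c2 = params.c1, params.c2
    num = (2.0 * mu_a * mu_b + c1) * (2.0 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    return float(num / den)


def learning_rate_from_ssim(ssim: float) -> float:
    """Learning rate ``(1 - SSIM) / 80`` clipped to [0, 1].

    Monotone non-increasing in SSIM: identical consecutive frames give 0
    (a frozen model), a completely dissimilar pair gives 1/40.
    """
    s = float(np.clip(ssim, -1.0, 1.0))
    return float(np.clip((1.0 - s) / 80.0, 0.0, 1.0))


def build_roi(early_masks: list[np.ndarray], margin: int = 0) -> RegionOfInterest:
    """Fixed ROI: tight bounding box of all early foreground, plus a margin.

    If no pixel was detected in any warm-up mask the whole frame becomes
    the ROI (a degenerate but safe fallback, logged as a warning).
    """
    if not early_masks:
        raise InvalidArgumentError("need at least one mask")
    shape = early_masks[0].shape
    union = np.zeros(shape, dtype=bool)
    for m in early_masks:
        if m.shape != shape:
            raise InvalidArgumentError("masks must share one shape")
        union |= m.astype(bool)
    rows = np.flatnonzero(union.any(axis=1))
    cols = np.flatnonzero(union.any(axis=0))
    if rows.size == 0:
        logger.warning("no foreground in warm-up masks; falling back to whole-frame ROI")
        return RegionOfInterest(0, shape[0], 0, shape[1])
    return RegionOfInterest(
        max(int(rows[0]) - margin, 0),
        min(int(rows[-1]) + 1 + margin, shape[0]),
        max(int(cols[0]) - margin, 0),
        min(int(cols[-1]) + 1 + margin, shape[1]),
    )


# ---------------------------------------------------------------------------
# temporal histograms and peak counting
# ---------------------------------------------------------------------------

class TemporalHistogram:
    """Rolling 256-bin grayscale histogram per pixel over a window of frames."""

    def __init__(self, shape: tuple[int, int], window: int) -> None:
        if window < 1:
            raise InvalidArgumentError("window must be >= 1")
        self.window = window
        self.shape = shape
        self.counts = np.zeros((shape[0] * shape[1], 256), dtype=np.int32)
        self._ring = np.zeros((window, shape[0] * shape[1]), dtype=np.uint8)
        self.frames_seen = 0

    def push(self, frame: np.ndarray) -> None:
        if frame.shape != self.shape:
            raise InvalidArgumentError("frame shape does not match histogram grid")
        vals = np.clip(np.asarray(frame), 0, 255).astype(np.uint8).ravel()
        idx = np.arange(vals.size)
        slot = self.frames_seen % self.window
        if self.frames_seen >= self.window:
            old = self._ring[slot]
            np.subtract.at(self.counts, (idx, old.astype(np.intp)), 1)
        np.add.at(self.counts, (idx, vals.astype(np.intp)), 1)
        self._ring[slot] = vals
        self.frames_seen += 1

    def pixel(self, row: int, col: int) -> np.ndarray:
        return self.counts[row * self.shape[1] + col]


@dataclass(frozen=True)
class PeakRule:
    """Histogram-peak filtering rule and component-count clamps."""

    merge_distance: int = 30
    k_min: int = 1
    k_max: int = 5

    def __post_init__(self) -> None:
        if self.merge_distance < 1:
            raise InvalidArgumentError("merge_distance must be >= 1")
        if not 1 <= self.k_min <= self.k_max:
            raise InvalidArgumentError("need 1 <= k_min <= k_max")


def _local_maxima(counts: np.ndarray) -> np.ndarray:
    """Plateau-aware local maxima of (P, 256) histograms.

    A bin is a peak if it is the first bin of a maximal run of equal counts
    that is entered by a strict rise and left by a strict fall.  Histogram
    ends behave as strictly lower neighbours, so a mode at bin 0 or 255
    still counts.
    """
    c = np.asarray(counts, dtype=np.int64)
    if c.ndim == 1:
        c = c[None, :]
    p, n = c.shape
    pad = np.full((p, 1), -1, dtype=np.int64)
    h = np.concatenate([pad, c, pad], axis=1)          # (P, 258)
    diff = np.sign(np.diff(h, axis=1))                 # (P, 257)
    # resolve zero slopes by the next nonzero slope to the right
    resolved = diff.copy()
    for j in range(n - 1, -1, -1):
        z = resolved[:, j] == 0
        resolved[z, j] = resolved[z, j + 1]
    rises = diff[:, :-1] > 0                           # strict rise into bin j
    falls = resolved[:, 1:] < 0                        # eventual strict fall after it
    return rises & falls                               # (P, 256)


def _merge_peaks(positions: np.ndarray, heights: np.ndarray, merge_distance: int) -> int:
    """Greedy left-to-right merge of peaks closer than ``merge_distance``."""
    kept_pos = kept_h = None
    count = 0
    for pos, hgt in zip(positions, heights):
        if kept_pos is not None and pos - kept_pos < merge_distance:
            if hgt > kept_h:      # keep the taller of the merged pair
                kept_pos, kept_h = pos, hgt
        else:
            count += 1
            kept_pos, kept_h = pos, hgt
    return count


def count_histogram_peaks(hist: np.ndarray, rule: PeakRule = PeakRule()) -> int:
    """Merged-peak count of one 256-bin histogram, clamped to [k_min, k_max].

    Invariant to uniform scaling of the counts; an all-zero histogram
    returns ``k_min``.
    """
    h = np.asarray(hist)
    if h.ndim != 1 or h.shape[0] != 256:
        raise InvalidArgumentError("expected a 256-bin histogram")
    if np.any(h < 0):
        raise InvalidArgumentError("bin counts must be nonnegative")
    if not np.any(h > 0):
        return rule.k_min
    is_peak = _local_maxima(h)[0]
    pos = np.flatnonzero(is_peak)
    count = _merge_peaks(pos, h[pos], rule.merge_distance)
    return int(np.clip(count, rule.k_min, rule.k_max))


def _peak_counts_and_positions(
    counts: np.ndarray, rule: PeakRule
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Vectorised merged-peak counts for (P, 256) histograms.

    Returns the clamped counts and, per pixel, the raw (unmerged) peak bin
    positions, used to seed the means of newly grown components.
    """
    is_peak = _local_maxima(counts)
    n_raw = is_peak.sum(axis=1)
    out = np.full(counts.shape[0], rule.k_min, dtype=np.int64)
    positions: list[np.ndarray] = [np.empty(0, dtype=np.int64)] * counts.shape[0]
    single = n_raw == 1
    out[single] = np.clip(1, rule.k_min, rule.k_max)
    rows = np.flatnonzero(n_raw >= 1)
    for r in rows:
        pos = np.flatnonzero(is_peak[r])
        positions[r] = pos
        if pos.size > 1:
            c = _merge_peaks(pos, counts[r, pos], rule.merge_distance)
            out[r] = int(np.clip(c, rule.k_min, rule.k_max))
    return out, positions


# ---------------------------------------------------------------------------
# component-count adaptation
# ---------------------------------------------------------------------------

def adapt_component_count(
    mixture, target_k: int, params: GmmParams | None = None,
    peak_intensities: np.ndarray | None = None,
):
    """Resize a pixel mixture to ``target_k`` components.

    Shrinking drops the lowest-ranked components; growing appends wide,
    low-weight components whose means are taken from histogram peaks not
    yet covered by the mixture (falling back to the existing top mean).
    Weights are renormalised either way.  ``target_k`` below 1 is clamped
    to 1.
    """
    from .gmm import GaussianComponent, PixelMixture  # local import, avoids cycle

    if not isinstance(mixture, PixelMixture):
        raise InvalidArgumentError("expected a PixelMixture")
    params = params or GmmParams()
    target_k = max(int(target_k), 1)
    comps = mixture.components
    if len(comps) > target_k:
        del comps[target_k:]
    elif len(comps) < target_k:
        means = [float(np.ravel(np.asarray(c.mean, dtype=float))[0]) for c in comps]
        pool = list(np.asarray(peak_intensities, dtype=float)) if peak_intensities is not None else []
        while len(comps) < target_k:
            if pool:
                # least-covered peak: farthest from every existing mean
                j = int(np.argmax([min(abs(pk - m) for m in means) for pk in pool]))
                mu = pool.pop(j)
            else:
                mu = means[0]
            comps.append(GaussianComponent(params.replacement_weight, mu, params.init_variance))
            means.append(mu)
    mixture.normalize()
    mixture.sort()
    return mixture


def _adapt_counts_vectorised(
    state: MixtureModelState,
    target: np.ndarray,
    peak_positions: list[np.ndarray] | None,
    region: RegionOfInterest | None,
) -> None:
    """Apply per-pixel component-count targets to the vectorised state.

    ``target`` is (H, W); pixels whose current count equals the target are
    untouched.  Growth seeds new means from uncovered histogram peaks when
    ``peak_positions`` (ROI-local, row-major) are available.
    """
    cap = state.capacity
    target = np.minimum(np.maximum(target, 1), cap)
    cur = state.n_active

    shrink = target < cur
    if shrink.any():
        state.n_active = np.where(shrink, target, state.n_active)
        # zero out dropped slots so renormalize/active_mask stay consistent
        act = state.active_mask()
        state.weight = np.where(act, state.weight, 0.0)

    grow = target > cur
    if grow.any():
        rows, cols = np.nonzero(grow)
        w_roi = region.col_stop - region.col_start if region is not None else None
        for r, c in zip(rows, cols):
            k_now, k_new = int(cur[r, c]), int(target[r, c])
            peaks = None
            if peak_positions is not None and region is not None:
                rr, cc = r - region.row_start, c - region.col_start
                if 0 <= rr < region.shape[0] and 0 <= cc < region.shape[1]:
                    peaks = peak_positions[rr * w_roi + cc]
            means_now = [float(np.ravel(state.mean[r, c, i])[0]) for i in range(k_now)]
            pool = list(map(float, peaks)) if peaks is not None and peaks.size else []
            for i in range(k_now, k_new):
                if pool:
                    j = int(np.argmax([min(abs(pk - m) for m in means_now) for pk in pool]))
                    mu = pool.pop(j)
                else:
                    mu = means_now[0]
                state.weight[r, c, i] = state.params.replacement_weight
                state.mean[r, c, i] = mu
                state.variance[r, c, i] = state.params.init_variance
                means_now.append(mu)
            state.n_active[r, c] = k_new

    if shrink.any() or grow.any():
        state.renormalize()
        state.resort()


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

@dataclass
class ItfGmmConfig:
    """Configuration of the adaptive background-subtraction run.

    ``adapt_lr`` / ``adapt_k`` toggle the two temporal features; with both
    off the run is identical to the plain mixture model (the first ablation
    arm).
    """

    warmup_frames: int = 100
    roi_margin: int = 5
    hist_window: int = 100
    peak_rule: PeakRule = field(default_factory=PeakRule)
    k_init: int = 3
    outside_roi_k: int = 2
    params: GmmParams = field(default_factory=GmmParams)
    ssim: SsimParams = field(default_factory=SsimParams)
    adapt_lr: bool = True
    adapt_k: bool = True
    rho_mode: str = "alpha"


@dataclass
class ItfGmmResult:
    """Masks plus run diagnostics of :func:`itf_gmm_run`."""

    masks: list[np.ndarray]
    warmup_frames: int
    roi: RegionOfInterest | None
    alpha_history: list[float]
    state: MixtureModelState

    def post_warmup_masks(self) -> list[np.ndarray]:
        return self.masks[self.warmup_frames:]


def itf_gmm_run(frames, config: ItfGmmConfig = ItfGmmConfig()) -> ItfGmmResult:
    """Run the adaptive mixture background model over a frame sequence.

    Phase 1 runs the plain model on the first ``warmup_frames`` frames and
    builds the fixed ROI from their detections.  Phase 2 then, per frame:
    pushes the ROI crop into the per-pixel temporal histograms, computes
    the global SSIM between consecutive ROI crops to set the in-ROI
    learning rate, sets per-pixel component counts (merged histogram peaks
    inside the ROI, a fixed count outside), and steps the mixture model.
    One boolean mask per input frame is returned, warm-up masks included.
    """
    frames = [np.asarray(f) for f in frames]
    cfg = config
    if len(frames) < cfg.warmup_frames + 1:
        raise InvalidArgumentError(
            f"need at least {cfg.warmup_frames + 1} frames, got {len(frames)}"
        )
    capacity = max(cfg.peak_rule.k_max, cfg.k_init, cfg.outside_roi_k)
    state = init_model(frames[0], cfg.k_init, cfg.params, capacity=capacity)
    masks: list[np.ndarray] = [np.zeros(frames[0].shape[:2], dtype=bool)]
    alphas: list[float] = []

    for f in frames[1:cfg.warmup_frames]:
        mask, state = step_frame(f, state, rho_mode=cfg.rho_mode)
        masks.append(mask)

    roi = build_roi(masks, cfg.roi_margin) if (cfg.adapt_lr or cfg.adapt_k) else None
    hist = TemporalHistogram(roi.shape, cfg.hist_window) if (roi and cfg.adapt_k) else None
    roi_mask = roi.mask(frames[0].shape[:2]) if roi is not None else None
    prev_crop = roi.crop(frames[cfg.warmup_frames - 1]) if roi is not None else None

    h, w = frames[0].shape[:2]
    for f in frames[cfg.warmup_frames:]:
        alpha = np.full((h, w), cfg.params.alpha)
        if roi is not None and cfg.adapt_lr:
            crop = roi.crop(f)
            a_roi = learning_rate_from_ssim(global_ssim(crop, prev_crop, cfg.ssim))
            alpha[roi_mask] = a_roi
            alphas.append(a_roi)
        if roi is not None:
            prev_crop = roi.crop(f)
        if hist is not None:
            hist.push(roi.crop(f))
            counts, peak_pos = _peak_counts_and_positions(hist.counts, cfg.peak_rule)
            target = np.full((h, w), cfg.outside_roi_k, dtype=np.int64)
            target[roi.row_start:roi.row_stop, roi.col_start:roi.col_stop] = counts.reshape(roi.shape)
            _adapt_counts_vectorised(state, target, peak_pos, roi)
        mask, state = step_frame(f, state, alpha=alpha, rho_mode=cfg.rho_mode)
        masks.append(mask)

    return ItfGmmResult(masks, cfg.warmup_frames, roi, alphas, state)
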