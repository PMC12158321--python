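"""Per-pixel Gaussian-mixture background modelling.

Each pixel of a video is modelled as a small weighted mixture of Gaussian
intensity modes.  Modes that are seen often and have settled to a small
variance are background; a new value that matches no mode (or only a
low-ranked one) is foreground.  The model is updated online with an
exponential learning rate ``alpha``:

* matched mode:   ``w <- (1-a) w + a``, ``mu <- (1-rho) mu + rho x``,
  ``s2 <- (1-rho) s2 + rho (x - mu_old)^2``
* unmatched mode: ``w <- (1-a) w`` (mean and variance untouched)
* no mode matches: the lowest-ranked mode is replaced by a wide new mode
  centred on the observed value.

After every update the weights are renormalised to sum to one and the modes
are re-sorted by ``w / s2`` (descending, stable), so that heavy, tight modes
rank first.  The background is the shortest prefix of ranked modes whose
cumulative weight reaches the background proportion ``T``.

Two surfaces are provided: scalar per-pixel operations
(:func:`match_component`, :func:`update_mixture`, :func:`select_background`)
that act on :class:`PixelMixture` objects, and the vectorised
:class:`MixtureModelState` / :func:`step_frame` path used on whole frames.
Both implement the same arithmetic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError, InvalidStateError

__all__ = [
    "GaussianComponent",
    "PixelMixture",
    "GmmParams",
    "MixtureModelState",
    "init_model",
    "match_component",
    "update_mixture",
    "select_background",
    "step_frame",
    "NO_MATCH",
]

#: Sentinel returned by :func:`match_component` when no component matches.
NO_MATCH: int = -1

_WEIGHT_TOL = 1e-9


@dataclass
class GaussianComponent:
    """One Gaussian intensity mode of a pixel mixture.

    ``mean`` is a scalar in single-channel mode or a length-C vector in
    multi-channel mode; the variance is shared across channels (isotropic
    covariance ``s2 * I``).
    """

    weight: float
    mean: float | np.ndarray
    variance: float

    def sort_key(self) -> float:
        return self.weight / self.variance


@dataclass
class PixelMixture:
    """Ordered list of Gaussian modes for one pixel (descending ``w/s2``)."""

    components: list[GaussianComponent]

    def __post_init__(self) -> None:
        if not self.components:
            raise InvalidStateError("a pixel mixture needs at least one component")

    def __len__(self) -> int:
        return len(self.components)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components], dtype=float)

    def is_sorted(self) -> bool:
        keys = [c.sort_key() for c in self.components]
        return all(a >= b - 1e-12 for a, b in zip(keys, keys[1:]))

    def normalize(self) -> None:
        total = float(sum(c.weight for c in self.components))
        if total <= 0:
            raise InvalidStateError("total mixture weight is not positive")
        for c in self.components:
            c.weight /= total

    def sort(self) -> None:
        # stable: ties in w/s2 keep their current relative order
        self.components.sort(key=lambda c: -c.sort_key())


@dataclass
class GmmParams:
    """Global parameters of the mixture background model.

    alpha
        Default learning rate (dimensionless, > 0).  A config value of -1
        (the conventional "auto" flag) maps to this default.
    background_ratio
        Minimum cumulative weight ``T`` of the ranked prefix regarded as
        background, restricted to [0.5, 1.0].
    match_multiplier
        Match window half-width in standard deviations (classically 2.5).
    init_variance
        Variance assigned to freshly created modes (intensity^2).
    replacement_weight
        Weight of the mode that replaces the weakest one on a no-match.
    variance_floor
        Lower bound kept on every variance, avoids degenerate sigma -> 0.
    channels
        1 for grayscale, 3 for colour with shared per-mode variance.
    """

    alpha: float = 0.005
    background_ratio: float = 0.75
    match_multiplier: float = 2.5
    init_variance: float = 225.0
    replacement_weight: float = 0.05
    variance_floor: float = 1.0
    channels: int = 1

    def __post_init__(self) -> None:
        if not 0.5 <= self.background_ratio <= 1.0:
            raise InvalidArgumentError(
                f"background_ratio must lie in [0.5, 1.0], got {self.background_ratio}"
            )
        if self.match_multiplier <= 0:
            raise InvalidArgumentError("match_multiplier must be positive")
        if self.alpha == -1:
            self.alpha = 0.005
        if self.alpha < 0:
            raise InvalidArgumentError("alpha must be positive (or -1 for the default)")
        if self.variance_floor <= 0:
            raise InvalidArgumentError("variance_floor must be positive")
        if self.channels not in (1, 3):
            raise InvalidArgumentError("channels must be 1 or 3")


class MixtureModelState:
    """Vectorised H x W grid of pixel mixtures.

    Components are stored in fixed-capacity arrays sorted by ``w/s2``;
    ``n_active[r, c]`` gives the live component count K of a pixel.
    """

    def __init__(
        self,
        weight: np.ndarray,
        mean: np.ndarray,
        variance: np.ndarray,
        n_active: np.ndarray,
        params: GmmParams,
        frame_count: int = 0,
    ) -> None:
        self.weight = weight        # (H, W, Kcap)
        self.mean = mean            # (H, W, Kcap) or (H, W, Kcap, C)
        self.variance = variance    # (H, W, Kcap)
        self.n_active = n_active    # (H, W) int
        self.params = params
        self.frame_count = frame_count

    # -- introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.weight.shape[:2]

    @property
    def capacity(self) -> int:
        return self.weight.shape[2]

    def active_mask(self) -> np.ndarray:
        """(H, W, Kcap) boolean mask of live component slots."""
        return np.arange(self.capacity)[None, None, :] < self.n_active[..., None]

    def mixture_at(self, row: int, col: int) -> PixelMixture:
        k = int(self.n_active[row, col])
        comps = []
        for i in range(k):
            mu = self.mean[row, col, i]
            comps.append(
                GaussianComponent(
                    weight=float(self.weight[row, col, i]),
                    mean=float(mu) if np.ndim(mu) == 0 else np.asarray(mu, dtype=float).copy(),
                    variance=float(self.variance[row, col, i]),
                )
            )
        return PixelMixture(comps)

    def copy(self) -> "MixtureModelState":
        return MixtureModelState(
            self.weight.copy(),
            self.mean.copy(),
            self.variance.copy(),
            self.n_active.copy(),
            dataclasses.replace(self.params),
            self.frame_count,
        )

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        np.savez_compressed(
            path,
            weight=self.weight,
            mean=self.mean,
            variance=self.variance,
            n_active=self.n_active,
            frame_count=self.frame_count,
            params=np.array(
                [
                    self.params.alpha,
                    self.params.background_ratio,
                    self.params.match_multiplier,
                    self.params.init_variance,
                    self.params.replacement_weight,
                    self.params.variance_floor,
                    float(self.params.channels),
                ]
            ),
        )

    @classmethod
    def load(cls, path) -> "MixtureModelState":
        with np.load(path) as data:
            p = data["params"]
            params = GmmParams(
                alpha=float(p[0]),
                background_ratio=float(p[1]),
                match_multiplier=float(p[2]),
                init_variance=float(p[3]),
                replacement_weight=float(p[4]),
                variance_floor=float(p[5]),
                channels=int(p[6]),
            )
            return cls(
                data["weight"].copy(),
                data["mean"].copy(),
                data["variance"].copy(),
                data["n_active"].copy(),
                params,
                int(data["frame_count"]),
            )

    # -- maintenance used by step_frame and component adaptation -------
    def renormalize(self) -> None:
        act = self.active_mask()
        w = np.where(act, self.weight, 0.0)
        total = w.sum(axis=2, keepdims=True)
        self.weight = np.where(act, w / total, 0.0)

    def resort(self) -> None:
        act = self.active_mask()
        key = np.where(act, self.weight / self.variance, -np.inf)
        order = np.argsort(-key, axis=2, kind="stable")
        self.weight = np.take_along_axis(self.weight, order, axis=2)
        self.variance = np.take_along_axis(self.variance, order, axis=2)
        if self.mean.ndim == 4:
            self.mean = np.take_along_axis(self.mean, order[..., None], axis=2)
        else:
            self.mean = np.take_along_axis(self.mean, order, axis=2)


def _check_frame(frame: np.ndarray, channels: int) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if channels == 1 and frame.ndim != 2:
        raise InvalidArgumentError(f"expected a 2-D grayscale frame, got shape {frame.shape}")
    if channels == 3 and (frame.ndim != 3 or frame.shape[2] != 3):
        raise InvalidArgumentError(f"expected an H x W x 3 frame, got shape {frame.shape}")
    if frame.size == 0:
        raise InvalidArgumentError("empty frame")
    if frame.min() < 0 or frame.max() > 255:
        raise InvalidArgumentError("frame intensities must lie in [0, 255]")
    return frame


def init_model(first_frame: np.ndarray, k_init: int, params: GmmParams,
               capacity: int | None = None) -> MixtureModelState:
    """Initialise the per-pixel mixtures from the first frame.

    Every pixel receives ``k_init`` modes of equal weight ``1/k_init`` and
    variance ``params.init_variance``; the first mode is centred on the
    observed pixel value, the remaining slots on the same value (they are
    placeholders that the no-match replacement rule will quickly claim).
    """
    if k_init < 1:
        raise InvalidArgumentError(f"k_init must be >= 1, got {k_init}")
    frame = _check_frame(first_frame, params.channels)
    h, w = frame.shape[:2]
    cap = max(capacity or 0, k_init)
    weight = np.zeros((h, w, cap), dtype=float)
    weight[:, :, :k_init] = 1.0 / k_init
    variance = np.full((h, w, cap), params.init_variance, dtype=float)
    if params.channels == 1:
        mean = np.repeat(frame[:, :, None], cap, axis=2)
    else:
        mean = np.repeat(frame[:, :, None, :], cap, axis=2)
    n_active = np.full((h, w), k_init, dtype=np.int64)
    return MixtureModelState(weight, mean, variance, n_active, params, frame_count=0)


# ---------------------------------------------------------------------------
# scalar per-pixel operations
# ---------------------------------------------------------------------------

def match_component(pixel_value, mixture: PixelMixture, multiplier: float) -> int:
    """Index of the first ranked component within ``multiplier`` standard
    deviations of ``pixel_value``, or :data:`NO_MATCH`.

    In multi-channel mode every channel must satisfy the bound.
    """
    if multiplier <= 0:
        raise InvalidArgumentError("multiplier must be positive")
    if len(mixture) == 0:  # pragma: no cover - PixelMixture forbids this
        raise InvalidStateError("empty mixture")
    value = np.asarray(pixel_value, dtype=float)
    for i, comp in enumerate(mixture.components):
        bound = multiplier * np.sqrt(comp.variance)
        if np.all(np.abs(value - np.asarray(comp.mean, dtype=float)) <= bound):
            return i
    return NO_MATCH


def _rho(alpha: float, value, comp: GaussianComponent, mode: str) -> float:
    if mode == "alpha":
        return alpha
    if mode == "scaled_pdf":
        value = np.asarray(value, dtype=float)
        mu = np.asarray(comp.mean, dtype=float)
        d2 = float(np.sum((value - mu) ** 2))
        dim = value.size
        norm = (2.0 * np.pi * comp.variance) ** (dim / 2.0)
        return alpha * float(np.exp(-0.5 * d2 / comp.variance) / norm)
    raise InvalidArgumentError(f"unknown rho mode {mode!r}")


def update_mixture(
    mixture: PixelMixture,
    matched: int,
    pixel_value,
    alpha: float,
    params: GmmParams | None = None,
    rho_mode: str = "alpha",
) -> PixelMixture:
    """Apply one online update to a pixel mixture.

    ``matched`` is the component index returned by :func:`match_component`
    (or :data:`NO_MATCH`).  Weights are renormalised and the components
    re-sorted before returning.  The update is in place; the mixture is
    also returned for convenience.
    """
    if not 0.0 <= alpha <= 1.0:
        raise InvalidArgumentError(f"alpha must lie in [0, 1], got {alpha}")
    params = params or GmmParams()
    value = np.asarray(pixel_value, dtype=float)

    if matched == NO_MATCH:
        for c in mixture.components:
            c.weight *= 1.0 - alpha
        if alpha > 0.0:
            worst = mixture.components[-1]
            worst.weight = params.replacement_weight
            worst.mean = float(value) if value.ndim == 0 else value.copy()
            worst.variance = params.init_variance
    else:
        if not 0 <= matched < len(mixture):
            raise InvalidArgumentError(f"matched index {matched} out of range")
        for i, c in enumerate(mixture.components):
            if i == matched:
                rho = _rho(alpha, value, c, rho_mode)
                c.weight = (1.0 - alpha) * c.weight + alpha
                old_mean = np.asarray(c.mean, dtype=float)
                new_mean = (1.0 - rho) * old_mean + rho * value
                c.mean = float(new_mean) if new_mean.ndim == 0 else new_mean
                d2 = float(np.sum((value - old_mean) ** 2))
                c.variance = max((1.0 - rho) * c.variance + rho * d2, params.variance_floor)
            else:
                c.weight *= 1.0 - alpha
    mixture.normalize()
    mixture.sort()
    return mixture


def select_background(mixture: PixelMixture, T: float) -> int:
    """Number ``B`` of ranked components regarded as background.

    Smallest prefix length whose cumulative weight reaches ``T``.
    """
    if not 0.5 <= T <= 1.0:
        raise InvalidArgumentError(f"T must lie in [0.5, 1.0], got {T}")
    if not mixture.is_sorted():
        raise InvalidStateError("mixture must be sorted by w/s2 before background selection")
    cum = 0.0
    for b, comp in enumerate(mixture.components, start=1):
        cum += comp.weight
        if cum >= T - _WEIGHT_TOL:
            return b
    return len(mixture)


# ---------------------------------------------------------------------------
# vectorised frame step
# ---------------------------------------------------------------------------

def step_frame(
    frame: np.ndarray,
    state: MixtureModelState,
    alpha: float | np.ndarray | None = None,
    rho_mode: str = "alpha",
) -> tuple[np.ndarray, MixtureModelState]:
    """Classify one frame and update the model in place.

    ``alpha`` may be a scalar or a per-pixel (H, W) array; ``None`` uses the
    model default.  Returns ``(mask, state)`` where ``mask`` is boolean with
    True = foreground.  Pixels whose effective alpha is exactly 0 are fully
    frozen (no weight decay and no no-match replacement).
    """
    p = state.params
    frame = _check_frame(frame, p.channels)
    if frame.shape[:2] != state.shape:
        raise InvalidArgumentError(
            f"frame shape {frame.shape[:2]} does not match model grid {state.shape}"
        )
    a = p.alpha if alpha is None else alpha
    a = np.broadcast_to(np.asarray(a, dtype=float), state.shape)
    if a.min() < 0 or a.max() > 1:
        raise InvalidArgumentError("alpha must lie in [0, 1]")

    act = state.active_mask()                               # (H, W, K)
    sigma = np.sqrt(state.variance)
    if p.channels == 1:
        dev = np.abs(frame[:, :, None] - state.mean)
        within = dev <= p.match_multiplier * sigma
    else:
        dev = np.abs(frame[:, :, None, :] - state.mean)
        within = np.all(dev <= (p.match_multiplier * sigma)[..., None], axis=3)
    within &= act

    has_match = within.any(axis=2)
    first = np.argmax(within, axis=2)                       # 0 where no match

    # background prefix length B per pixel (components stored ranked)
    cum = np.cumsum(np.where(act, state.weight, 0.0), axis=2)
    b = np.sum(cum < p.background_ratio - _WEIGHT_TOL, axis=2) + 1
    b = np.minimum(b, state.n_active)

    foreground = ~has_match | (first >= b)

    # --- updates -----------------------------------------------------------
    a3 = a[..., None]
    matched_slot = act & (np.arange(state.capacity)[None, None, :] == first[..., None])
    matched_slot &= has_match[..., None]

    state.weight = np.where(act, (1.0 - a3) * state.weight, state.weight)
    state.weight = np.where(matched_slot, state.weight + a3, state.weight)

    if rho_mode == "alpha":
        rho = a3
    elif rho_mode == "scaled_pdf":
        if p.channels == 1:
            d2 = (frame[:, :, None] - state.mean) ** 2
            dim = 1.0
        else:
            d2 = np.sum((frame[:, :, None, :] - state.mean) ** 2, axis=3)
            dim = 3.0
        pdf = np.exp(-0.5 * d2 / state.variance) / (2.0 * np.pi * state.variance) ** (dim / 2.0)
        rho = a3 * pdf
    else:
        raise InvalidArgumentError(f"unknown rho mode {rho_mode!r}")

    if p.channels == 1:
        old_mean = state.mean
        state.mean = np.where(matched_slot, (1.0 - rho) * old_mean + rho * frame[:, :, None], old_mean)
        d2_old = (frame[:, :, None] - old_mean) ** 2
    else:
        old_mean = state.mean
        m4 = matched_slot[..., None]
        state.mean = np.where(m4, (1.0 - rho[..., None]) * old_mean + rho[..., None] * frame[:, :, None, :], old_mean)
        d2_old = np.sum((frame[:, :, None, :] - old_mean) ** 2, axis=3)
    new_var = (1.0 - rho) * state.variance + rho * d2_old
    state.variance = np.where(matched_slot, np.maximum(new_var, p.variance_floor), state.variance)

    # no-match replacement of the weakest (last ranked) slot, unless frozen
    replace_px = ~has_match & (a > 0.0)
    if replace_px.any():
        last = state.n_active - 1
        slot = np.arange(state.capacity)[None, None, :] == last[..., None]
        rep = slot & replace_px[..., None]
        state.weight = np.where(rep, p.replacement_weight, state.weight)
        state.variance = np.where(rep, p.init_variance, state.variance)
        if p.channels == 1:
            state.mean = np.where(rep, frame[:, :, None], state.mean)
        else:
            state.mean = np.where(rep[..., None], frame[:, :, None, :], state.mean)

    frozen = a == 0.0
    w_pre = state.weight.copy() if frozen.any() else None
    state.renormalize()
    state.resort()
    if w_pre is not None:
        # alpha = 0 is a bit-exact freeze: renormalising an already
        # normalised mixture may still move weights by one ulp, so restore
        state.weight[frozen] = w_pre[frozen]
    state.frame_count += 1
    return foreground, state
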