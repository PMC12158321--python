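"""The strided-convolution UNet (Con-UNet) and its training loop.

A classic UNet encoder–decoder for per-pixel binary classification, with
two departures from the textbook network: the 2x2 max-pooling subsampling
blocks are replaced by 3x3 stride-2 convolutions (so the subsampling step
itself learns features instead of discarding them), and all 3x3
convolutions use reflect padding.  Upsampling is nearest-neighbour x2
followed by a convolution (hole-free); a pure 2x2 transposed-convolution
mode is available as a config switch.  The output layer is a sigmoid over
one foreground class.

Everything runs on NumPy: forward, backward and Adam are implemented in
this package, sized for the small training sets this tool targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.transform import resize

from ..errors import InvalidArgumentError, InvalidStateError
from .layers import Conv2d, MaxPool2, NearestUpsample2, ReLU

__all__ = [
    "ConUNetSpec",
    "TrainingConfig",
    "ConUNet",
    "build_conunet",
    "train_conunet",
    "predict_mask",
    "save_checkpoint",
    "load_checkpoint",
]

SUBSAMPLE_MODES = ("stride2_conv", "maxpool2")
UPSAMPLE_MODES = ("nearest_conv3", "deconv2")


@dataclass(frozen=True)
class ConUNetSpec:
    """Architecture hyperparameters.

    ``base_width`` doubles at every subsampling stage; ``bottleneck_width``
    defaults to the width of the deepest encoder stage.  ``input_size`` is
    the square side the network is trained and evaluated at; any input
    whose sides are divisible by ``2**depth`` is admissible.
    """

    in_channels: int = 1
    depth: int = 4
    base_width: int = 64
    subsample: str = "stride2_conv"
    upsample: str = "nearest_conv3"
    bottleneck_width: int | None = None
    input_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise InvalidArgumentError("depth must be >= 1")
        if self.subsample not in SUBSAMPLE_MODES:
            raise InvalidArgumentError(f"subsample must be one of {SUBSAMPLE_MODES}")
        if self.upsample not in UPSAMPLE_MODES:
            raise InvalidArgumentError(f"upsample must be one of {UPSAMPLE_MODES}")
        if self.input_size % (2 ** self.depth):
            raise InvalidArgumentError("input_size must be divisible by 2**depth")

    @property
    def widths(self) -> list[int]:
        return [self.base_width * 2 ** s for s in range(self.depth)]

    @property
    def bottleneck(self) -> int:
        return self.bottleneck_width or self.widths[-1]


class _Deconv2:
    """2x2 stride-2 transposed convolution (learned x2 upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        std = np.sqrt(2.0 / (cin * 4))
        self.weight = rng.normal(0.0, std, (cout, cin, 2, 2))
        self.bias = np.zeros(cout)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        out = np.einsum("nchw,ocuv->nohuwv", x, self.weight, optimize=True)
        n, o, h, _, w, _ = out.shape
        return out.reshape(n, o, 2 * h, 2 * w) + self.bias[None, :, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, o, h2, w2 = g.shape
        g6 = g.reshape(n, o, h2 // 2, 2, w2 // 2, 2)
        self.grad_weight = np.einsum("nohuwv,nchw->ocuv", g6, self._x, optimize=True)
        self.grad_bias = g.sum(axis=(0, 2, 3))
        return np.einsum("nohuwv,ocuv->nchw", g6, self.weight, optimize=True)


class ConUNet:
    """Encoder–decoder network built from a :class:`ConUNetSpec`."""

    def __init__(self, spec: ConUNetSpec) -> None:
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        w = spec.widths
        conv = lambda ci, co, k=3, s=1, p=1: Conv2d(ci, co, k, s, p, "reflect", rng)

        self.encoder = []
        cin = spec.in_channels
        for s in range(spec.depth):
            stage = {
                "conv1": conv(cin, w[s]), "relu1": ReLU(),
                "conv2": conv(w[s], w[s]), "relu2": ReLU(),
            }
            if spec.subsample == "stride2_conv":
                stage["sub"] = conv(w[s], w[s], 3, 2, 1)
                stage["subrelu"] = ReLU()
            else:
                stage["sub"] = MaxPool2()
                stage["subrelu"] = None
            self.encoder.append(stage)
            cin = w[s]

        wb = spec.bottleneck
        self.bottleneck = {
            "conv1": conv(cin, wb), "relu1": ReLU(),
            "conv2": conv(wb, wb), "relu2": ReLU(),
        }

        self.decoder = []
        cin = wb
        for s in reversed(range(spec.depth)):
            stage: dict = {}
            if spec.upsample == "nearest_conv3":
                stage["up"] = NearestUpsample2()
                stage["upconv"] = conv(cin, w[s])
            else:
                stage["up"] = None
                stage["upconv"] = _Deconv2(cin, w[s], rng)
            stage["uprelu"] = ReLU()
            stage["conv1"] = conv(2 * w[s], w[s])
            stage["relu1"] = ReLU()
            stage["conv2"] = conv(w[s], w[s])
            stage["relu2"] = ReLU()
            self.decoder.append(stage)
            cin = w[s]
        self.head = conv(w[0], 1, 1, 1, 0)

    # -- plumbing ------------------------------------------------------
    def _layers(self):
        for stage in self.encoder:
            yield from (stage["conv1"], stage["conv2"], stage["sub"])
        yield from (self.bottleneck["conv1"], self.bottleneck["conv2"])
        for stage in self.decoder:
            yield from (stage["upconv"], stage["conv1"], stage["conv2"])
        yield self.head

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            out.extend(getattr(layer, "params", []))
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            if getattr(layer, "params", []):
                out.extend([layer.grad_weight, layer.grad_bias])
        return out

    def has_pooling(self) -> bool:
        return any(isinstance(stage["sub"], MaxPool2) for stage in self.encoder)

    # -- passes --------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a (N, C, H, W) batch; H and W divisible by 2**depth."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise InvalidArgumentError(
                f"expected (N, {self.spec.in_channels}, H, W) input, got {x.shape}"
            )
        if x.shape[2] % 2 ** self.spec.depth or x.shape[3] % 2 ** self.spec.depth:
            raise InvalidArgumentError(
                f"spatial size {x.shape[2:]} not divisible by 2**depth={2 ** self.spec.depth}"
            )
        skips = []
        self._feature_shapes = []
        for stage in self.encoder:
            x = stage["relu1"].forward(stage["conv1"].forward(x, train), train)
            x = stage["relu2"].forward(stage["conv2"].forward(x, train), train)
            skips.append(x)
            x = stage["sub"].forward(x, train)
            if stage["subrelu"] is not None:
                x = stage["subrelu"].forward(x, train)
            self._feature_shapes.append(x.shape)
        x = self.bottleneck["relu1"].forward(self.bottleneck["conv1"].forward(x, train), train)
        x = self.bottleneck["relu2"].forward(self.bottleneck["conv2"].forward(x, train), train)
        for stage, skip in zip(self.decoder, reversed(skips)):
            if stage["up"] is not None:
                x = stage["up"].forward(x, train)
            x = stage["uprelu"].forward(stage["upconv"].forward(x, train), train)
            x = np.concatenate([skip, x], axis=1)
            x = stage["relu1"].forward(stage["conv1"].forward(x, train), train)
            x = stage["relu2"].forward(stage["conv2"].forward(x, train), train)
        return self.head.forward(x, train)

    def backward(self, g: np.ndarray) -> None:
        g = self.head.backward(g)
        skip_grads = []
        for stage in reversed(self.decoder):
            g = stage["conv2"].backward(stage["relu2"].backward(g))
            g = stage["conv1"].backward(stage["relu1"].backward(g))
            w = g.shape[1] // 2
            skip_grads.append(g[:, :w])
            g = g[:, w:]
            g = stage["upconv"].backward(stage["uprelu"].backward(g))
            if stage["up"] is not None:
                g = stage["up"].backward(g)
        g = self.bottleneck["conv1"].backward(self.bottleneck["relu1"].backward(
            self.bottleneck["conv2"].backward(self.bottleneck["relu2"].backward(g))))
        # skip_grads were collected shallow-to-deep; encoder unwinds deep-to-shallow
        for stage, sg in zip(reversed(self.encoder), reversed(skip_grads)):
            if stage["subrelu"] is not None:
                g = stage["subrelu"].backward(g)
            g = stage["sub"].backward(g)
            g = g + sg
            g = stage["conv1"].backward(stage["relu1"].backward(
                stage["conv2"].backward(stage["relu2"].backward(g))))

    def sigmoid(self, logits: np.ndarray) -> np.ndarray:
        out = np.empty_like(logits)
        pos = logits >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-logits[pos]))
        ez = np.exp(logits[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out


def build_conunet(spec: ConUNetSpec) -> ConUNet:
    """Instantiate the network described by ``spec`` with seeded weights."""
    return ConUNet(spec)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    """Optimisation protocol.

    The full-scale protocol is 1000 epochs at batch size 2 with Adam and a
    binary cross-entropy loss on the sigmoid output, inputs resized to
    256x256 and an 8:2 train/validation split; all of it is overridable
    for scaled-down runs.
    """

    epochs: int = 1000
    batch_size: int = 2
    learning_rate: float = 1e-4
    #: None: use the network spec's square size; an int resizes to a square;
    #: an (H, W) tuple trains at that geometry (must divide by 2**depth).
    input_size: int | tuple[int, int] | None = None
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise InvalidArgumentError("epochs and batch_size must be >= 1")
        if not 0.0 <= self.val_fraction < 1.0:
            raise InvalidArgumentError("val_fraction must lie in [0, 1)")


def _resize_image(img: np.ndarray, size: int | tuple[int, int]) -> np.ndarray:
    shape = (size, size) if isinstance(size, int) else tuple(size)
    img = np.asarray(img, dtype=float)
    if img.shape == shape:
        return img
    return resize(img, shape, order=1, preserve_range=True, anti_aliasing=False)


def _standardize(img: np.ndarray) -> np.ndarray:
    """Per-image standardisation to zero mean, unit variance.

    Low-contrast thermal frames are nearly constant; feeding the raw scale
    would bury the few-intensity-level target contrast under the common
    mode, so inputs are standardised rather than merely divided by 255.
    """
    m, s = img.mean(), img.std()
    return (img - m) / (s + 1e-6)


def _resize_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    return resize(np.asarray(mask, dtype=float), shape, order=0,
                  preserve_range=True, anti_aliasing=False) > 0.5


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _bce_with_logits(logits: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    z, y = logits, target
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
    return float(loss.mean()), (p - y) / z.size


def train_conunet(
    network: ConUNet,
    images: list[np.ndarray],
    masks: list[np.ndarray],
    config: TrainingConfig = TrainingConfig(),
) -> tuple[ConUNet, list[float]]:
    """Train the network on image/mask pairs; returns it with the per-epoch
    training-loss history.

    Images are resized (bilinear) to the square input size and scaled to
    [0, 1]; masks are resized with nearest neighbour to stay binary.  The
    pairs are split 8:2 into train/validation with a seeded shuffle; the
    optimiser only sees the training split.  With a fixed seed the loss
    history is reproducible run to run on one platform.
    """
    if len(images) == 0 or len(images) != len(masks):
        raise InvalidArgumentError("need equally many images and masks, at least one pair")
    size = config.input_size or network.spec.input_size
    shape = (size, size) if isinstance(size, int) else tuple(size)
    div = 2 ** network.spec.depth
    if shape[0] % div or shape[1] % div:
        raise InvalidArgumentError("input size must be divisible by 2**depth")
    xs, ys = [], []
    for img, msk in zip(images, masks):
        m = np.asarray(msk)
        if not np.isin(np.unique(m), (0, 1, 255, True, False)).all():
            raise InvalidArgumentError("masks must be binary")
        xs.append(_standardize(_resize_image(img, shape))[None, :, :])
        ys.append(_resize_mask(m, shape).astype(float)[None, :, :])
    x = np.stack(xs)
    y = np.stack(ys)

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(x))
    n_val = int(round(config.val_fraction * len(x)))
    n_val = min(n_val, len(x) - 1)
    train_idx = order[n_val:]

    opt = _Adam(network.parameters(), config.learning_rate)
    history: list[float] = []
    for _ in range(config.epochs):
        perm = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(perm), config.batch_size):
            sel = perm[start:start + config.batch_size]
            logits = network.forward(x[sel], train=True)
            loss, g = _bce_with_logits(logits, y[sel])
            network.backward(g)
            opt.step(network.gradients())
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return network, history


def predict_mask(
    network: ConUNet | None,
    frame: np.ndarray,
    threshold: float = 0.5,
    input_size: int | None = None,
) -> np.ndarray:
    """Binary mask for one grayscale frame, in the frame's own geometry.

    The frame is resized to the network input size, pushed through the
    network, the sigmoid map thresholded, and the mask resized back with
    nearest neighbour so it aligns with background-subtraction masks.
    """
    if network is None:
        raise InvalidStateError("no network: train one or load a checkpoint first")
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise InvalidArgumentError("expected a 2-D grayscale frame")
    div = 2 ** network.spec.depth
    if input_size is not None:
        size = input_size
    elif frame.shape[0] % div == 0 and frame.shape[1] % div == 0:
        size = frame.shape          # fully convolutional: run natively
    else:
        size = network.spec.input_size
    x = _standardize(_resize_image(frame, size))[None, None, :, :]
    prob = network.sigmoid(network.forward(x))[0, 0]
    mask = prob >= threshold
    if mask.shape != frame.shape:
        mask = _resize_mask(mask, frame.shape)
    return mask


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(network: ConUNet, path) -> None:
    arrays = {f"param_{i}": p for i, p in enumerate(network.parameters())}
    meta = asdict(network.spec)
    meta_keys = sorted(meta)
    np.savez_compressed(
        path,
        spec_keys=np.array(meta_keys),
        spec_vals=np.array([str(meta[k]) for k in meta_keys]),
        **arrays,
    )


def load_checkpoint(path) -> ConUNet:
    with np.load(path, allow_pickle=False) as data:
        meta = dict(zip(data["spec_keys"].tolist(), data["spec_vals"].tolist()))
        spec = ConUNetSpec(
            in_channels=int(meta["in_channels"]),
            depth=int(meta["depth"]),
            base_width=int(meta["base_width"]),
            subsample=meta["subsample"],
            upsample=meta["upsample"],
            bottleneck_width=None if meta["bottleneck_width"] == "None" else int(meta["bottleneck_width"]),
            input_size=int(meta["input_size"]),
            seed=int(meta["seed"]),
        )
        net = ConUNet(spec)
        for i, p in enumerate(net.parameters()):
            p[...] = data[f"param_{i}"]
    return net
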