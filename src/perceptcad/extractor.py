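"""Stage 1 — perceptive-feature extractor.

A VGG16-layout convolutional network (13 conv layers in five max-pooled
blocks, then three fully connected layers whose last has 128 units) is
trained to *regress* the five quantified BI-RADS descriptor codes from a
two-channel input: the grayscale lesion patch and its binary ROI mask.
Training the network against radiologists' quantified descriptions — rather
than against the biopsy label — bakes human perception into the weights;
after training, the 5-unit output head is discarded and the frozen
128-unit penultimate layer is exposed as the "perceptive features" consumed
by the Stage-2 classifier.

Both views of a case are fed through the same network and share the case's
descriptor target.  The loss is mean squared error over the five codes,
optimized with Adam under a piecewise-constant learning-rate schedule
(1e-4, decaying by 0.1 at configured epochs).

The network is implemented directly on numpy: convolutions are im2col +
BLAS matrix multiplies, with analytic backward passes, inverted dropout and
2x2 max pooling.  A width multiplier and configurable input side allow a
CPU-trainable downsized profile (64 px, 1/8 width) that preserves the
128-feature contract of the full 288-px network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .phantom import Case, LesionPatch

__all__ = [
    "ExtractorConfig",
    "PerceptiveFeatures",
    "TrainedExtractor",
    "DivergenceError",
    "FrozenStateError",
    "build_input",
    "train",
    "extract",
    "extract_batch",
    "predict_descriptors",
    "learning_rate_at",
]

#: VGG16 convolution widths; max-pool follows the last layer of each block.
VGG16_WIDTHS = (64, 64, 128, 128, 256, 256, 256, 512, 512, 512, 512, 512, 512)
VGG16_BLOCK_ENDS = frozenset({1, 3, 6, 9, 12})  # 0-based conv indices followed by a pool

N_FEATURES = 128


class DivergenceError(FloatingPointError):
    """Training loss became non-finite."""


class FrozenStateError(RuntimeError):
    """Operation requires the opposite freeze state."""


@dataclass(frozen=True)
class ExtractorConfig:
    """Architecture and training schedule of the feature extractor.

    The default profile matches the full-scale network (288-px input,
    full VGG16 widths, lr 1e-4 decaying x0.1 at epochs 30 and 60, 70
    epochs).  ``downsized()`` returns the desk-scale test profile: 64-px
    input, 1/8 conv widths, slimmer fully connected stack — the 128-unit
    feature layer is preserved — and a proportionally compressed schedule.

    ``init_scheme``: "scaled" (default) is variance-scaled He initialization;
    "paper_normal" draws every weight from a standard normal, which is kept
    available but destabilizes deep stacks and is not recommended.
    """

    input_side: int = 288
    width_multiplier: float = 1.0
    fc_sizes: tuple[int, int, int] = (4096, 4096, N_FEATURES)
    dropout_rate: float = 0.5
    output_dim: int = 5
    lr_init: float = 1e-4
    lr_decay_gamma: float = 0.1
    lr_decay_epochs: tuple[int, ...] = (30, 60)
    max_epochs: int = 70
    batch_size: int = 16
    init_scheme: str = "scaled"
    center_input: bool = True  # shift [0,1] channels to zero mean at the net entry
    freeze_policy: str = "final"  # "final": last epoch; "best_val": min validation MSE
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fc_sizes) != 3 or self.fc_sizes[-1] != N_FEATURES:
            raise ValueError(f"fc_sizes must be three widths ending in {N_FEATURES}")
        if self.output_dim != 5:
            raise ValueError("output_dim must be 5 (the descriptor codes)")
        if self.input_side % 32 != 0:
            raise ValueError("input_side must be divisible by 32 (five pooling halvings)")
        if not all(1 <= e <= self.max_epochs for e in self.lr_decay_epochs):
            raise ValueError("lr_decay_epochs must lie within [1, max_epochs]")
        if self.init_scheme not in ("scaled", "paper_normal"):
            raise ValueError("init_scheme must be 'scaled' or 'paper_normal'")
        if self.freeze_policy not in ("final", "best_val"):
            raise ValueError("freeze_policy must be 'final' or 'best_val'")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")

    @classmethod
    def downsized(cls, max_epochs: int = 20, seed: int = 0) -> "ExtractorConfig":
        """CPU-trainable profile: 64 px, 1/8 widths, compressed LR schedule.

        Small-batch Adam at 1e-3 with lighter dropout replaces the
        full-scale schedule: at desk scale the step budget, not the data
        volume, limits optimization.
        """
        d1 = max(2, int(round(max_epochs * 0.7)))
        d2 = max(d1 + 1, int(round(max_epochs * 0.9)))
        return cls(
            input_side=64,
            width_multiplier=1 / 8,
            fc_sizes=(512, 256, N_FEATURES),
            dropout_rate=0.2,
            max_epochs=max_epochs,
            lr_decay_epochs=(d1, min(d2, max_epochs)),
            lr_init=1e-3,
            batch_size=8,
            seed=seed,
        )

    @property
    def conv_widths(self) -> tuple[int, ...]:
        return tuple(max(1, int(round(w * self.width_multiplier))) for w in VGG16_WIDTHS)


def learning_rate_at(config: ExtractorConfig, epoch: int) -> float:
    """Piecewise-constant LR: decays by ``lr_decay_gamma`` at each decay epoch.

    Epochs are 1-based; with the default schedule the rate is 1e-4 through
    epoch 29, 1e-5 from 30, and 1e-6 from 60.
    """
    n_decays = sum(epoch >= d for d in config.lr_decay_epochs)
    return config.lr_init * config.lr_decay_gamma**n_decays


@dataclass
class PerceptiveFeatures:
    """The 128 penultimate-layer activations for one lesion view."""

    values: np.ndarray
    case_id: str = ""
    view: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite feature values")


# ---------------------------------------------------------------------------
# layers (float32 forward/backward on numpy + BLAS)
# ---------------------------------------------------------------------------


class _Conv3x3:
    """3x3 same-padding convolution via im2col and a single GEMM."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, scheme: str):
        fan_in = c_in * 9
        std = np.sqrt(2.0 / fan_in) if scheme == "scaled" else 1.0
        self.w = rng.normal(0.0, std, (fan_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)

    @property
    def params(self):
        return [self.w, self.b]

    def _im2col(self, xp: np.ndarray, h: int, w: int) -> np.ndarray:
        n, c = xp.shape[:2]
        cols = np.empty((n, h, w, c, 9), dtype=np.float32)
        for ky in range(3):
            for kx in range(3):
                cols[..., ky * 3 + kx] = xp[:, :, ky : ky + h, kx : kx + w].transpose(0, 2, 3, 1)
        return cols.reshape(n * h * w, c * 9)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = self._im2col(xp, h, w)
        out = cols @ self.w + self.b
        self._cache = (cols, x.shape)
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray):
        cols, (n, c, h, w) = self._cache
        g2 = grad.transpose(0, 2, 3, 1).reshape(n * h * w, -1)
        self.dw = cols.T @ g2
        self.db = g2.sum(axis=0)
        dcols = (g2 @ self.w.T).reshape(n, h, w, c, 9)
        dxp = np.zeros((n, c, h + 2, w + 2), dtype=np.float32)
        for ky in range(3):
            for kx in range(3):
                dxp[:, :, ky : ky + h, kx : kx + w] += dcols[..., ky * 3 + kx].transpose(0, 3, 1, 2)
        self._cache = None
        return dxp[:, :, 1:-1, 1:-1]

    @property
    def grads(self):
        return [self.dw, self.db]


class _ReLU:
    params: list = []
    grads: list = []

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        g = grad * self._mask
        self._mask = None
        return g


class _MaxPool2:
    """2x2 max pooling, stride 2."""

    params: list = []
    grads: list = []

    def forward(self, x, train):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, grad):
        n, c, h, w = self._shape
        g = self._mask * grad[:, :, :, None, :, None]
        self._mask = None
        return g.reshape(n, c, h, w).astype(np.float32)


class _Flatten:
    params: list = []
    grads: list = []

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, scheme: str):
        std = np.sqrt(2.0 / d_in) if scheme == "scaled" else 1.0
        self.w = rng.normal(0.0, std, (d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        g = grad @ self.w.T
        self._x = None
        return g

    @property
    def grads(self):
        return [self.dw, self.db]


class _Dropout:
    """Inverted dropout; identity at inference."""

    params: list = []
    grads: list = []

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        g = grad * self._mask
        self._mask = None
        return g


def _build_network(config: ExtractorConfig, rng: np.random.Generator) -> list:
    """Conv blocks + FC stack; ``layers[-1]`` is the 5-unit linear head."""
    layers: list = []
    c_in = 2
    for i, c_out in enumerate(config.conv_widths):
        layers.append(_Conv3x3(c_in, c_out, rng, config.init_scheme))
        layers.append(_ReLU())
        if i in VGG16_BLOCK_ENDS:
            layers.append(_MaxPool2())
        c_in = c_out
    layers.append(_Flatten())
    side = config.input_side // 32
    d_in = c_in * side * side
    for j, d_out in enumerate(config.fc_sizes):
        layers.append(_Dense(d_in, d_out, rng, config.init_scheme))
        layers.append(_ReLU())
        if j < 2 and config.dropout_rate > 0:  # dropout after the first two FC layers
            layers.append(_Dropout(config.dropout_rate, rng))
        d_in = d_out
    layers.append(_Dense(d_in, config.output_dim, rng, config.init_scheme))
    return layers


def _forward(layers: Sequence, x: np.ndarray, train: bool, upto: int | None = None) -> np.ndarray:
    for layer in layers[:upto]:
        x = layer.forward(x, train)
    return x


class _Adam:
    def __init__(self, params: list, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads: list, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mh = m / (1 - b1**self.t)
            vh = v / (1 - b2**self.t)
            p -= (lr * mh / (np.sqrt(vh) + self.eps)).astype(p.dtype)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def build_input(patch: LesionPatch, input_side: int) -> np.ndarray:
    """Stack a patch into the (2, side, side) network input.

    Channel 0 is the image min-max normalized to [0, 1]; channel 1 is the
    binary ROI mask.  Patches whose side differs from ``input_side`` are
    resampled — bilinear for the image, nearest-neighbour for the mask so it
    stays binary.
    """
    patch.validate()
    image = patch.image.astype(np.float32)
    lo, hi = float(image.min()), float(image.max())
    if hi > lo:
        image = (image - lo) / (hi - lo)
    else:
        image = np.zeros_like(image)
    mask = patch.mask.astype(np.float32)
    if image.shape != (input_side, input_side):
        from skimage.transform import resize

        image = resize(image, (input_side, input_side), order=1, anti_aliasing=True).astype(
            np.float32
        )
        mask = resize(mask, (input_side, input_side), order=0, anti_aliasing=False).astype(
            np.float32
        )
    out = np.stack([image, mask])
    if out.shape != (2, input_side, input_side):
        raise ValueError(f"bad input shape {out.shape} after resample")
    return out


@dataclass
class TrainedExtractor:
    """A trained (optionally frozen) feature-extractor network."""

    layers: list
    config: ExtractorConfig
    history: pd.DataFrame
    frozen: bool = False

    def freeze(self) -> None:
        """Make all weights immutable; required before feature extraction."""
        for layer in self.layers:
            for p in layer.params:
                p.flags.writeable = False
        self.frozen = True

    @property
    def n_feature_layers(self) -> int:
        # everything except the 5-unit output head
        return len(self.layers) - 1


def _stack_training_samples(
    cases: Sequence[Case], input_side: int
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for case in cases:
        target = case.descriptors.as_array().astype(np.float32)
        for view in sorted(case.patches):
            xs.append(build_input(case.patches[view], input_side))
            ys.append(target)
    return np.stack(xs), np.stack(ys)


def _prep(x: np.ndarray, config: ExtractorConfig) -> np.ndarray:
    # zero-centering the [0,1] channels at the network entry speeds He-init
    # ReLU training; it is an internal numerical choice, not an input contract
    return x - np.float32(0.5) if config.center_input else x


def _epoch_mse(layers, x, y, config: ExtractorConfig) -> float:
    se = 0.0
    for i in range(0, len(x), config.batch_size):
        pred = _forward(layers, _prep(x[i : i + config.batch_size], config), train=False)
        se += float(((pred - y[i : i + config.batch_size]) ** 2).sum())
    return se / y.size


def evaluate_mse(model: TrainedExtractor, cases: Sequence[Case]) -> float:
    """Mean squared descriptor-regression error of a model over cases."""
    x, y = _stack_training_samples(cases, model.config.input_side)
    return _epoch_mse(model.layers, x, y, model.config)


def train(
    cases: Sequence[Case],
    config: ExtractorConfig,
    val_cases: Sequence[Case] | None = None,
) -> TrainedExtractor:
    """Train the descriptor-regression network on two-view cases.

    Every view contributes one sample carrying the case's shared 5-code
    target.  Minimizes MSE with Adam under the step LR schedule; per-epoch
    train (and validation, when given) MSE is recorded in ``history``.

    With ``freeze_policy="best_val"`` (and validation cases given) the
    returned weights are those of the epoch with the lowest validation
    MSE — the plateau-based freeze-point selection; the chosen epoch is
    recorded in ``history.attrs``-style column ``chosen``.

    Raises :class:`DivergenceError` if the loss becomes non-finite.
    """
    if len(cases) < 2:
        raise ValueError("need at least 2 training cases")
    rng = np.random.default_rng(config.seed)
    layers = _build_network(config, rng)
    x, y = _stack_training_samples(cases, config.input_side)
    xv = yv = None
    if val_cases:
        xv, yv = _stack_training_samples(val_cases, config.input_side)

    params = [p for layer in layers for p in layer.params]
    opt = _Adam(params)
    records = []
    n = len(x)
    track_best = config.freeze_policy == "best_val" and xv is not None
    best_val, best_epoch, best_params = np.inf, None, None
    for epoch in range(1, config.max_epochs + 1):
        lr = learning_rate_at(config, epoch)
        order = rng.permutation(n)
        train_se = 0.0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = _prep(x[idx], config), y[idx]
            pred = _forward(layers, xb, train=True)
            err = pred - yb
            loss = float((err**2).mean())
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            train_se += float((err**2).sum())
            grad = (2.0 / err.size) * err.astype(np.float32)
            for layer in reversed(layers):
                grad = layer.backward(grad)
            opt.step([g for layer in layers for g in layer.grads], lr)
        rec = {"epoch": epoch, "lr": lr, "train_mse": train_se / y.size}
        if xv is not None:
            rec["val_mse"] = _epoch_mse(layers, xv, yv, config)
            if track_best and rec["val_mse"] < best_val:
                best_val, best_epoch = rec["val_mse"], epoch
                best_params = [p.copy() for p in params]
        records.append(rec)
    history = pd.DataFrame(records)
    if track_best and best_params is not None:
        for p, bp in zip(params, best_params):
            p[...] = bp
        history["chosen"] = history["epoch"] == best_epoch
    return TrainedExtractor(layers=layers, config=config, history=history)


def extract_batch(model: TrainedExtractor, patches: Sequence[LesionPatch]) -> np.ndarray:
    """Feature matrix (n_patches x 128) from the frozen network."""
    if not model.frozen:
        raise FrozenStateError("extractor must be frozen before feature extraction")
    x = np.stack([build_input(p, model.config.input_side) for p in patches])
    feats = []
    bs = model.config.batch_size
    for i in range(0, len(x), bs):
        xb = _prep(x[i : i + bs], model.config)
        feats.append(_forward(model.layers, xb, train=False, upto=model.n_feature_layers))
    return np.concatenate(feats).astype(np.float64)


def extract(
    model: TrainedExtractor, patch: LesionPatch, case_id: str = "", view: str | None = None
) -> PerceptiveFeatures:
    """Perceptive features: post-ReLU activations of the 128-unit FC layer.

    Deterministic — dropout is disabled at inference — and requires a frozen
    model (the output head is bypassed).
    """
    values = extract_batch(model, [patch])[0]
    return PerceptiveFeatures(values=values, case_id=case_id, view=view or patch.view)


def predict_descriptors(model: TrainedExtractor, patch: LesionPatch) -> np.ndarray:
    """The 5-unit head output: predicted quantified descriptor codes.

    Retained for diagnostics; Stage 2 consumes only the 128 features.
    """
    x = _prep(build_input(patch, model.config.input_side)[None], model.config)
    return _forward(model.layers, x, train=False)[0].astype(np.float64)
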