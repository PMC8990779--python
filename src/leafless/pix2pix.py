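"""Conditional GAN translating occluded patches to the non-occluded domain.

The translator follows the Pix2Pix recipe: an encoder–decoder generator
with skip connections maps a stacked grayscale+mask input (channel mode
``"GB"``, or the mask alone in mode ``"B"``) to its non-occluded
counterpart, while a patch-based discriminator judges local regions of
(input, output) stacks as real or generated.  Both adversarial terms are
least-squares losses against 0/1 labels; the generator additionally
carries an L1 reconstruction term weighted by ``lambda_l1 = 100``, which
dominates training and keeps outputs sharp.

Training runs for ``epochs`` epochs with Adam; the learning rate is held
constant at ``lr0`` for the first ``constant_epochs`` epochs and then
decays linearly toward zero.  Per-epoch augmentation resizes the patch
pair with nearest-neighbour interpolation, applies one shared random
crop and flip to input and target, and maps intensities affinely from
[0, 255] to [-1, 1]; at test time only the affine scaling is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import masks, nn


@dataclass(frozen=True)
class TrainConfig:
    """Training schedule and augmentation settings (full-scale defaults)."""

    epochs: int = 600
    lr0: float = 4e-4
    constant_epochs: int = 300
    lambda_l1: float = 100.0
    batch_size: int = 1
    channels: str = "GB"
    seed: int = 0
    resize: int = 286
    crop: int = 256
    flip_prob: float = 0.5
    flip_axis: str = "lr"

    def __post_init__(self):
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be non-negative")
        if self.crop > self.resize:
            raise ValueError("crop size cannot exceed resize size")
        if self.channels not in ("GB", "B"):
            raise ValueError("channels must be 'GB' or 'B'")
        if self.flip_axis not in ("lr", "ud"):
            raise ValueError("flip_axis must be 'lr' or 'ud'")
        if not 0 < self.constant_epochs <= self.epochs:
            raise ValueError("need 0 < constant_epochs <= epochs")


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Constant ``lr0`` for the first ``constant_epochs`` epochs, then a
    linear ramp that hits zero at epoch ``epochs``."""
    if not 0 <= epoch < config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    if epoch < config.constant_epochs:
        return config.lr0
    return config.lr0 * (config.epochs - epoch) / (config.epochs - config.constant_epochs)


def discriminator_loss(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """l_D = (l_Dfake + l_Dreal) / 2 with MSE against labels 0 (fake), 1 (real)."""
    return 0.5 * (nn.mse_to_label(np.asarray(d_fake, float), 0.0)
                  + nn.mse_to_label(np.asarray(d_real, float), 1.0))


def generator_loss(d_on_fake: np.ndarray, x_non: np.ndarray, x_gen: np.ndarray,
                   lambda_l1: float = 100.0) -> float:
    """l_G = MSE of discriminator scores on generated output against the real
    label, plus ``lambda_l1`` times the mean absolute reconstruction error."""
    adv = nn.mse_to_label(np.asarray(d_on_fake, float), 1.0)
    return adv + lambda_l1 * nn.l1_loss(np.asarray(x_non, float),
                                        np.asarray(x_gen, float))


def to_unit_range(x) -> np.ndarray:
    """Affine map [0, 255] -> [-1, 1], float32."""
    return (np.asarray(x, dtype=np.float32) / 127.5) - 1.0


def from_unit_range(x) -> np.ndarray:
    """Affine map [-1, 1] -> [0, 255], rounded uint8."""
    return np.clip(np.round((np.asarray(x, dtype=np.float32) + 1.0) * 127.5),
                   0, 255).astype(np.uint8)


def stack_channels(gray, mask, channels: str = "GB") -> np.ndarray:
    """Build a (C, H, W) uint8 stack; channel order is (gray, mask)."""
    m = masks.as_mask(mask)
    if channels == "B":
        return m[None]
    g = masks.as_gray(gray)
    if g.shape != m.shape:
        raise ValueError("gray and mask shapes differ")
    return np.stack([g, m])


def _resize_nearest(stack: np.ndarray, size: int) -> np.ndarray:
    c, h, w = stack.shape
    rows = np.minimum((np.arange(size) * h) // size, h - 1)
    cols = np.minimum((np.arange(size) * w) // size, w - 1)
    return stack[:, rows[:, None], cols[None, :]]


def augment(input_stack, target_stack, rng, config: TrainConfig,
            train: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Shared-geometry augmentation of an aligned pair.

    Both stacks are resized with nearest-neighbour interpolation, receive
    the *same* random crop window and flip, and are scaled to [-1, 1].
    In test mode (``train=False``) only the scaling is applied.
    """
    a = np.asarray(input_stack)
    b = np.asarray(target_stack)
    if a.shape != b.shape:
        raise ValueError("input and target stacks differ in shape")
    if not train:
        return to_unit_range(a), to_unit_range(b)
    a = _resize_nearest(a, config.resize)
    b = _resize_nearest(b, config.resize)
    margin = config.resize - config.crop
    r0 = int(rng.integers(0, margin + 1))
    c0 = int(rng.integers(0, margin + 1))
    a = a[:, r0: r0 + config.crop, c0: c0 + config.crop]
    b = b[:, r0: r0 + config.crop, c0: c0 + config.crop]
    if config.flip_prob > 0 and rng.random() < config.flip_prob:
        ax = 2 if config.flip_axis == "lr" else 1
        a = np.flip(a, axis=ax)
        b = np.flip(b, axis=ax)
    return to_unit_range(a), to_unit_range(b)


class UNetGenerator:
    """Encoder–decoder with skip connections and a tanh output head.

    ``depth`` strided 4x4 convolutions halve the resolution on the way
    down (plus one bottleneck conv), mirrored by transposed convolutions
    on the way up; each decoder stage concatenates the same-resolution
    encoder features.  ``bilinear_decoder=True`` swaps every transposed
    convolution for bilinear upsampling followed by a 3x3 convolution,
    the standard remedy for checkerboard artifacts.
    """

    def __init__(self, in_channels: int, rng, base: int = 16, depth: int = 3,
                 bilinear_decoder: bool = False):
        self.in_channels = in_channels
        self.depth = depth
        widths = [min(base * 2 ** i, base * 8) for i in range(depth)]
        self.widths = widths

        def up(cin, cout):
            if bilinear_decoder:
                return [nn.Upsample2x("bilinear"),
                        nn.Conv2d(cin, cout, rng, k=3, stride=1, pad=1)]
            return [nn.ConvTranspose2d(cin, cout, rng)]

        self.enc = [nn.Sequential(nn.Conv2d(in_channels, widths[0], rng),
                                  nn.LeakyReLU(0.2))]
        for i in range(1, depth):
            self.enc.append(nn.Sequential(nn.Conv2d(widths[i - 1], widths[i], rng),
                                          nn.InstanceNorm(widths[i]),
                                          nn.LeakyReLU(0.2)))
        self.bottleneck = nn.Sequential(nn.Conv2d(widths[-1], widths[-1], rng),
                                        nn.ReLU())
        self.dec = [nn.Sequential(*up(widths[-1], widths[-1]),
                                  nn.InstanceNorm(widths[-1]), nn.ReLU())]
        for j in range(1, depth):
            cin = 2 * widths[depth - j]
            cout = widths[depth - j - 1]
            self.dec.append(nn.Sequential(*up(cin, cout),
                                          nn.InstanceNorm(cout), nn.ReLU()))
        self.final = nn.Sequential(*up(2 * widths[0], in_channels), nn.Tanh())

    def params(self):
        out = []
        for blk in self.enc + [self.bottleneck] + self.dec + [self.final]:
            out.extend(blk.params())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        feats = []
        h = x
        for blk in self.enc:
            h = blk.forward(h)
            feats.append(h)
        h = self.bottleneck.forward(h)
        for j, blk in enumerate(self.dec):
            h = blk.forward(h)
            skip = feats[self.depth - 1 - j]
            h = np.concatenate([h, skip], axis=1)
        self._feats = feats
        return self.final.forward(h)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        skip_grads = [None] * self.depth
        d = self.final.backward(dout)
        for j in reversed(range(self.depth)):
            blk = self.dec[j]
            w = d.shape[1] // 2
            d_dec, d_skip = d[:, :w], d[:, w:]
            skip_grads[self.depth - 1 - j] = d_skip
            d = blk.backward(d_dec)
        d = self.bottleneck.backward(d)
        for i in reversed(range(self.depth)):
            d = d + skip_grads[i] if skip_grads[i] is not None else d
            d = self.enc[i].backward(d)
        return d


class PatchDiscriminator(nn.Sequential):
    """Patch-based real/fake classifier over local receptive fields.

    Judges overlapping patches of the (conditioning input, candidate
    output) stack and emits a score map rather than one scalar.
    """

    def __init__(self, in_channels: int, rng, base: int = 16):
        super().__init__(
            nn.Conv2d(in_channels, base, rng), nn.LeakyReLU(0.2),
            nn.Conv2d(base, 2 * base, rng), nn.InstanceNorm(2 * base),
            nn.LeakyReLU(0.2),
            nn.Conv2d(2 * base, 1, rng, k=4, stride=1, pad=1),
        )


class Pix2PixTranslator:
    """Estimator-style occluded-to-non-occluded translator.

    ``fit`` trains generator and discriminator adversarially on aligned
    (occluded, non-occluded) channel stacks; ``predict`` translates new
    occluded stacks and returns uint8 stacks in [0, 255] with the mask
    channel snapped onto the legal class values.  Fitted attributes:
    ``generator_``, ``discriminator_``, ``history_`` (per-epoch mean
    l_D / l_G / l1).  Fully deterministic given ``seed``.
    """

    def __init__(self, channels: str = "GB", epochs: int = 600, lr0: float = 4e-4,
                 constant_epochs: int = 300, lambda_l1: float = 100.0,
                 batch_size: int = 1, base_width: int = 16, depth: int = 3,
                 resize: int = 286, crop: int = 256, flip_prob: float = 0.5,
                 flip_axis: str = "lr", beta1: float = 0.5, beta2: float = 0.999,
                 bilinear_decoder: bool = False, seed: int = 0):
        self.channels = channels
        self.epochs = epochs
        self.lr0 = lr0
        self.constant_epochs = constant_epochs
        self.lambda_l1 = lambda_l1
        self.batch_size = batch_size
        self.base_width = base_width
        self.depth = depth
        self.resize = resize
        self.crop = crop
        self.flip_prob = flip_prob
        self.flip_axis = flip_axis
        self.beta1 = beta1
        self.beta2 = beta2
        self.bilinear_decoder = bilinear_decoder
        self.seed = seed

    @classmethod
    def toy(cls, seed: int = 0, epochs: int = 30, **overrides) -> "Pix2PixTranslator":
        """Reduced settings sized for 64x64 toy scenes on one CPU."""
        kw = dict(epochs=epochs, constant_epochs=max(1, epochs // 2),
                  batch_size=4, base_width=16, depth=3, resize=72, crop=64,
                  seed=seed)
        kw.update(overrides)
        return cls(**kw)

    # -- sklearn plumbing ---------------------------------------------------
    _param_names = ("channels", "epochs", "lr0", "constant_epochs", "lambda_l1",
                    "batch_size", "base_width", "depth", "resize", "crop",
                    "flip_prob", "flip_axis", "beta1", "beta2",
                    "bilinear_decoder", "seed")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "Pix2PixTranslator":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @property
    def train_config(self) -> TrainConfig:
        return TrainConfig(epochs=self.epochs, lr0=self.lr0,
                           constant_epochs=self.constant_epochs,
                           lambda_l1=self.lambda_l1, batch_size=self.batch_size,
                           channels=self.channels, seed=self.seed,
                           resize=self.resize, crop=self.crop,
                           flip_prob=self.flip_prob, flip_axis=self.flip_axis)

    @property
    def n_channels(self) -> int:
        return 2 if self.channels == "GB" else 1

    # -- training -----------------------------------------------------------
    def fit(self, X, y=None) -> "Pix2PixTranslator":
        """Train on aligned pairs.

        ``X`` is a sequence of ``(input_stack, target_stack)`` uint8
        arrays of shape (C, H, W), or a sequence of input stacks with
        targets passed separately in ``y``.
        """
        if y is not None:
            pairs = list(zip(X, y))
        else:
            pairs = list(X)
        if not pairs:
            raise ValueError("training set is empty")
        config = self.train_config
        for a, b in pairs:
            if np.shape(a)[0] != self.n_channels or np.shape(b)[0] != self.n_channels:
                raise ValueError(
                    f"channel mode {self.channels!r} expects {self.n_channels}-channel stacks")
        rng = np.random.default_rng(self.seed)
        self.generator_ = UNetGenerator(self.n_channels, rng, base=self.base_width,
                                        depth=self.depth,
                                        bilinear_decoder=self.bilinear_decoder)
        self.discriminator_ = PatchDiscriminator(2 * self.n_channels, rng,
                                                 base=self.base_width)
        opt_g = nn.Adam(self.generator_.params(), lr=self.lr0,
                        beta1=self.beta1, beta2=self.beta2)
        opt_d = nn.Adam(self.discriminator_.params(), lr=self.lr0,
                        beta1=self.beta1, beta2=self.beta2)
        self.history_ = []
        n = len(pairs)
        for epoch in range(self.epochs):
            lr = lr_schedule(epoch, config)
            opt_g.lr = opt_d.lr = lr
            order = rng.permutation(n)
            sums = {"l_D": 0.0, "l_G": 0.0, "l1": 0.0}
            n_batches = 0
            for start in range(0, n, self.batch_size):
                idx = order[start: start + self.batch_size]
                xs, ys = [], []
                for i in idx:
                    a, b = augment(pairs[i][0], pairs[i][1], rng, config)
                    xs.append(a)
                    ys.append(b)
                x = np.stack(xs)
                t = np.stack(ys)
                stats = self._train_step(x, t, opt_g, opt_d)
                for k in sums:
                    sums[k] += stats[k]
                n_batches += 1
            self.history_.append({k: v / n_batches for k, v in sums.items()}
                                 | {"epoch": epoch, "lr": lr})
        return self

    def _train_step(self, x, t, opt_g, opt_d):
        g, d = self.generator_, self.discriminator_
        fake = g.forward(x)

        # discriminator update: real pairs toward 1, generated pairs toward 0
        opt_d.zero_grad()
        d_real = d.forward(np.concatenate([x, t], axis=1))
        d.backward(0.5 * nn.mse_to_label_grad(d_real, 1.0))
        d_fake = d.forward(np.concatenate([x, fake], axis=1))
        d.backward(0.5 * nn.mse_to_label_grad(d_fake, 0.0))
        l_d = discriminator_loss(d_real, d_fake)
        opt_d.step()

        # generator update: fool the discriminator + weighted L1 to the target
        opt_g.zero_grad()
        opt_d.zero_grad()
        scores = d.forward(np.concatenate([x, fake], axis=1))
        d_input_grad = d.backward(nn.mse_to_label_grad(scores, 1.0))
        d_fake_grad = d_input_grad[:, self.n_channels:]
        l1 = nn.l1_loss(t, fake)
        g.backward(d_fake_grad + self.lambda_l1 * nn.l1_loss_grad(fake, t))
        opt_g.step()
        opt_d.zero_grad()  # discriminator grads from the generator pass are discarded
        return {"l_D": l_d, "l_G": nn.mse_to_label(scores, 1.0) + self.lambda_l1 * l1,
                "l1": l1}

    # -- inference ----------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "generator_"):
            raise RuntimeError("Pix2PixTranslator is not fitted yet")

    def predict_raw(self, input_stack) -> np.ndarray:
        """Raw generator output in [-1, 1] for one (C, H, W) uint8 stack."""
        self._check_fitted()
        a = np.asarray(input_stack)
        if a.ndim != 3 or a.shape[0] != self.n_channels:
            raise ValueError(
                f"expected a ({self.n_channels}, H, W) stack, got {a.shape}")
        x = to_unit_range(a)[None]
        return self.generator_.forward(x)[0]

    def translate(self, input_stack) -> tuple[np.ndarray | None, np.ndarray]:
        """Translate one occluded stack; returns ``(gray, mask)``.

        The output is rescaled to [0, 255]; the mask channel is snapped
        onto {0, 127, 255} so it can be counted directly, the gray
        channel (``None`` in mask-only mode) is emitted as-is.
        """
        out = from_unit_range(self.predict_raw(input_stack))
        mask = masks.postprocess_mask(out[-1])
        gray = out[0] if self.channels == "GB" else None
        return gray, mask

    def predict(self, X) -> list[np.ndarray]:
        """Translate a sequence of stacks; mask channels are post-processed."""
        out = []
        for stack in X:
            gray, mask = self.translate(stack)
            out.append(mask[None] if gray is None else np.stack([gray, mask]))
        return out

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint parameters together with the full configuration."""
        self._check_fitted()
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"g{i}": p.value for i, p in enumerate(self.generator_.params())}
        arrays |= {f"d{i}": p.value for i, p in enumerate(self.discriminator_.params())}
        arrays["config_json"] = np.frombuffer(
            json.dumps(self.get_params()).encode(), dtype=np.uint8)
        arrays["history_json"] = np.frombuffer(
            json.dumps(self.history_).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "Pix2PixTranslator":
        data = np.load(path)
        params = json.loads(bytes(data["config_json"]).decode())
        model = cls(**params)
        rng = np.random.default_rng(model.seed)
        model.generator_ = UNetGenerator(model.n_channels, rng,
                                         base=model.base_width, depth=model.depth,
                                         bilinear_decoder=model.bilinear_decoder)
        model.discriminator_ = PatchDiscriminator(2 * model.n_channels, rng,
                                                  base=model.base_width)
        for i, p in enumerate(model.generator_.params()):
            p.value = data[f"g{i}"]
        for i, p in enumerate(model.discriminator_.params()):
            p.value = data[f"d{i}"]
        model.history_ = json.loads(bytes(data["history_json"]).decode())
        return model


def train(pairs, config: TrainConfig, **model_overrides) -> tuple[Pix2PixTranslator, list[dict]]:
    """Functional wrapper: train a translator from a config, return (model, history)."""
    model = Pix2PixTranslator(channels=config.channels, epochs=config.epochs,
                              lr0=config.lr0, constant_epochs=config.constant_epochs,
                              lambda_l1=config.lambda_l1, batch_size=config.batch_size,
                              resize=config.resize, crop=config.crop,
                              flip_prob=config.flip_prob, flip_axis=config.flip_axis,
                              seed=config.seed, **model_overrides)
    model.fit(pairs)
    return model, model.history_
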