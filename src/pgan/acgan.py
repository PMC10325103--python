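"""Auxiliary-classifier GAN: architecture specs, loss, training, generation.

The generator G maps a concatenated input [z, c] — a 100-dimensional
standard-Gaussian noise z and a length-3 region condition c, reshaped to
(103, 1, 1) — through a stack of transposed convolutions to a multi-slice
image in [-1, 1] (tanh output). The discriminator D shares a convolutional
trunk between two heads: a sigmoid real/fake head and a softmax head
predicting the region; D never receives c as an input, the class is
predicted, not given.

The training objective (discriminator view) is

    L = L_D + alpha * L_C,
    L_D = E[log P(real | X_real)] + E[log P(fake | X_fake)],
    L_C = E[log P(chat = c | X)],

ascended for D; the generator follows the non-saturating heuristic,
maximizing log P(real | X_fake) + alpha * log P(chat = c | X_fake). Both
nets use Adam (lr 1e-4, betas (0.5, 0.999)); the classification weight
defaults to alpha = 1.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .conditioning import ConditionVector, MorphSchedule, one_hot
from .datasets import LabeledImageSet
from .nn import functional as F

LayerSpec = tuple[int, int, int, int]  # (out_channels, kernel, stride, padding)

REFERENCE_DECONV_LAYERS: tuple[LayerSpec, ...] = (
    (512, 4, 1, 0), (256, 4, 2, 1), (128, 4, 2, 1), (64, 4, 2, 1), (9, 4, 2, 1))
REFERENCE_CONV_LAYERS: tuple[LayerSpec, ...] = (
    (64, 4, 2, 1), (128, 4, 2, 1), (256, 4, 2, 1), (512, 4, 2, 1), (64, 4, 1, 0))


class TrainingDivergedError(RuntimeError):
    """A non-finite loss was encountered during training."""


@dataclass(frozen=True)
class GeneratorSpec:
    """Transposed-convolution generator architecture."""

    noise_dim: int = 100
    condition_dim: int = 3
    deconv_layers: tuple[LayerSpec, ...] = REFERENCE_DECONV_LAYERS

    @property
    def n_slices(self) -> int:
        return self.deconv_layers[-1][0]

    @classmethod
    def desk(cls, size: int = 32, n_slices: int = 9, base_channels: int = 64,
             noise_dim: int = 100) -> "GeneratorSpec":
        """Truncated stack producing size x size images (size a power of 2, >= 8)."""
        n_doubling = int(np.log2(size)) - 2
        if 2 ** (n_doubling + 2) != size or n_doubling < 1:
            raise ValueError("size must be a power of two >= 8")
        layers = [(base_channels * 2 ** (n_doubling - 1), 4, 1, 0)]
        for j in range(n_doubling - 1, 0, -1):
            layers.append((base_channels * 2 ** (j - 1), 4, 2, 1))
        layers.append((n_slices, 4, 2, 1))
        return cls(noise_dim=noise_dim, deconv_layers=tuple(layers))


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Convolutional trunk + two fully connected heads (real/fake, class)."""

    conv_layers: tuple[LayerSpec, ...] = REFERENCE_CONV_LAYERS
    leaky_slope: float = 0.2
    n_classes: int = 3

    @classmethod
    def desk(cls, size: int = 32, base_channels: int = 64,
             trunk_features: int = 64) -> "DiscriminatorSpec":
        n_halving = int(np.log2(size)) - 2
        if 2 ** (n_halving + 2) != size or n_halving < 1:
            raise ValueError("size must be a power of two >= 8")
        layers = [(base_channels * 2 ** j, 4, 2, 1) for j in range(n_halving)]
        layers.append((trunk_features, 4, 1, 0))
        return cls(conv_layers=tuple(layers))


def generator_output_shape(spec: GeneratorSpec) -> tuple[int, int, int]:
    """(channels, height, width) from a 1x1 input through the deconv stack."""
    size = 1
    channels = spec.noise_dim + spec.condition_dim
    for (c, k, s, p) in spec.deconv_layers:
        size = nn.deconv_out_size(size, k, s, p)
        if size <= 0:
            raise ValueError(
                f"deconv layer ({c},{k},{s},{p}) yields non-positive size {size}")
        channels = c
    return (channels, size, size)


def discriminator_output_shape(spec: DiscriminatorSpec,
                               input_shape: tuple[int, int, int]) -> tuple[int, int, int]:
    """Trunk feature shape for an input of (channels, height, width)."""
    _, h, w = input_shape
    channels = input_shape[0]
    for (c, k, s, p) in spec.conv_layers:
        if h + 2 * p < k or w + 2 * p < k:
            raise ValueError(
                f"conv layer ({c},{k},{s},{p}) kernel exceeds its {h}x{w} input")
        h = nn.conv_out_size(h, k, s, p)
        w = nn.conv_out_size(w, k, s, p)
        if h <= 0 or w <= 0:
            raise ValueError(
                f"conv layer ({c},{k},{s},{p}) yields non-positive size")
        channels = c
    return (channels, h, w)


def acgan_loss(d_real, d_fake, class_post, true_labels,
               alpha: float = 1.0) -> tuple[float, float, float]:
    """Evaluate (L, L_D, L_C) from discriminator posteriors.

    ``d_real``/``d_fake`` are P(real | X_real) and P(fake | X_fake);
    ``class_post`` holds rows of class posteriors with 1-based
    ``true_labels``. Posteriors are clamped before logs.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    d_real = F.clamp_prob(np.atleast_1d(np.asarray(d_real, dtype=float)))
    d_fake = F.clamp_prob(np.atleast_1d(np.asarray(d_fake, dtype=float)))
    post = np.atleast_2d(np.asarray(class_post, dtype=float))
    labels = np.atleast_1d(np.asarray(true_labels)).astype(int)
    if labels.min() < 1 or labels.max() > post.shape[1]:
        raise ValueError("labels must be 1-based class indices")
    l_d = float(np.log(d_real).mean() + np.log(d_fake).mean())
    pc = F.clamp_prob(post[np.arange(len(labels)), labels - 1])
    l_c = float(np.log(pc).mean())
    return l_d + alpha * l_c, l_d, l_c


@dataclass
class GanTrainingConfig:
    """Optimization settings for the adversarial training loop."""

    alpha: float = 1.0
    lr_g: float = 1e-4
    lr_d: float = 1e-4
    epochs: int = 10
    batch_size: int = 32
    seed: int = 0

    def validate(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.lr_g <= 0 or self.lr_d <= 0:
            raise ValueError("learning rates must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


def _build_generator(spec: GeneratorSpec, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    c_in = spec.noise_dim + spec.condition_dim
    n = len(spec.deconv_layers)
    for idx, (c, k, s, p) in enumerate(spec.deconv_layers):
        layers.append(nn.ConvTranspose2d(c_in, c, k, s, p, rng))
        if idx < n - 1:
            layers.append(nn.BatchNorm2d(c))
            layers.append(nn.ReLU())
        else:
            layers.append(nn.Tanh())
        c_in = c
    return nn.Sequential(*layers)


class _Discriminator:
    """Shared convolutional trunk with real/fake and class heads."""

    def __init__(self, spec: DiscriminatorSpec, input_shape: tuple[int, int, int],
                 rng: np.random.Generator):
        self.spec = spec
        trunk_shape = discriminator_output_shape(spec, input_shape)
        layers: list[nn.Layer] = []
        c_in = input_shape[0]
        n = len(spec.conv_layers)
        for idx, (c, k, s, p) in enumerate(spec.conv_layers):
            layers.append(nn.Conv2d(c_in, c, k, s, p, rng))
            # batchnorm only on interior layers: none on the pixel inputs,
            # and none on the trunk output — real and fake are forwarded as
            # separate batches, and per-batch normalization of the final
            # features would erase the batch-level real/fake signal
            if 0 < idx < n - 1:
                layers.append(nn.BatchNorm2d(c))
            layers.append(nn.LeakyReLU(spec.leaky_slope))
            c_in = c
        layers.append(nn.Flatten())
        self.trunk = nn.Sequential(*layers)
        n_feat = int(np.prod(trunk_shape))
        self.adv_head = nn.Linear(n_feat, 1, rng)
        self.cls_head = nn.Linear(n_feat, spec.n_classes, rng)

    def parameters(self) -> list[nn.Parameter]:
        return (self.trunk.parameters() + self.adv_head.parameters()
                + self.cls_head.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def forward(self, x: np.ndarray, train: bool = True):
        feat = self.trunk.forward(x, train=train)
        return self.adv_head.forward(feat, train=train), \
            self.cls_head.forward(feat, train=train)

    def backward(self, d_adv: np.ndarray, d_cls: np.ndarray) -> np.ndarray:
        dfeat = self.adv_head.backward(d_adv) + self.cls_head.backward(d_cls)
        return self.trunk.backward(dfeat)

    def state(self) -> list[np.ndarray]:
        return (self.trunk.state()
                + [p.data.copy() for p in self.adv_head.parameters()]
                + [p.data.copy() for p in self.cls_head.parameters()])

    def load_state(self, state: list[np.ndarray]) -> None:
        n_trunk = len(self.trunk.state())
        self.trunk.load_state(state[:n_trunk])
        rest = state[n_trunk:]
        for p, s in zip(self.adv_head.parameters() + self.cls_head.parameters(),
                        rest):
            p.data[...] = s


class ACGAN:
    """Auxiliary-classifier GAN model bound to a training dataset.

    Parameters
    ----------
    data : LabeledImageSet
        Training images are taken from the ``train`` split (or the whole set
        if no sample is tagged ``train``).
    gen_spec, disc_spec : architecture specifications; defaults are the
        reference 64x64 stacks.
    config : GanTrainingConfig
    """

    def __init__(self, data: LabeledImageSet, gen_spec: GeneratorSpec | None = None,
                 disc_spec: DiscriminatorSpec | None = None,
                 config: GanTrainingConfig | None = None):
        self.gen_spec = gen_spec or GeneratorSpec()
        self.disc_spec = disc_spec or DiscriminatorSpec()
        self.config = config or GanTrainingConfig()
        self.config.validate()
        train = data.split_view("train")
        self.train_data = train if len(train) else data
        if len(self.train_data) < 1:
            raise ValueError("no training samples")
        expected = generator_output_shape(self.gen_spec)
        if tuple(self.train_data.image_shape) != tuple(expected):
            raise ValueError(
                f"data shape {self.train_data.image_shape} does not match the "
                f"generator output {expected}")
        counts = np.array([(self.train_data.labels == k).sum() for k in (1, 2, 3)],
                          dtype=float)
        self.label_probs = counts / counts.sum()

    def fit(self, verbose: bool = False) -> "ACGANResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        gen = _build_generator(self.gen_spec, rng)
        disc = _Discriminator(self.disc_spec, self.train_data.image_shape, rng)
        opt_g = nn.Adam(gen.parameters(), lr=cfg.lr_g)
        opt_d = nn.Adam(disc.parameters(), lr=cfg.lr_d)
        noise_dim = self.gen_spec.noise_dim
        n = len(self.train_data)
        bs = min(cfg.batch_size, n)
        history: list[dict] = []
        it = 0
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n - bs + 1, bs):
                idx = order[start:start + bs]
                x_real = self.train_data.images[idx].astype(np.float64)
                y_real = self.train_data.labels[idx].astype(int) - 1
                m = len(idx)

                # ---- discriminator step ----
                y_fake = rng.choice(3, size=m, p=self.label_probs)
                z = rng.standard_normal((m, noise_dim))
                g_in = self._pack(z, y_fake)
                x_fake = gen.forward(g_in, train=True)

                disc.zero_grad()
                adv_r, cls_r = disc.forward(x_real, train=True)
                l_adv_r, d_adv_r = F.bce_with_logits(adv_r, 1.0)
                l_cls_r, d_cls_r = F.cross_entropy_with_logits(cls_r, y_real)
                disc.backward(d_adv_r, cfg.alpha * d_cls_r)
                adv_f, cls_f = disc.forward(x_fake, train=True)
                l_adv_f, d_adv_f = F.bce_with_logits(adv_f, 0.0)
                l_cls_f, d_cls_f = F.cross_entropy_with_logits(cls_f, y_fake)
                disc.backward(d_adv_f, cfg.alpha * d_cls_f)
                opt_d.step()

                # ---- generator step (non-saturating) ----
                y_fake_g = rng.choice(3, size=m, p=self.label_probs)
                z = rng.standard_normal((m, noise_dim))
                g_in = self._pack(z, y_fake_g)
                gen.zero_grad()
                x_fake = gen.forward(g_in, train=True)
                disc.zero_grad()
                adv_g, cls_g = disc.forward(x_fake, train=True)
                l_adv_g, d_adv_g = F.bce_with_logits(adv_g, 1.0)
                l_cls_g, d_cls_g = F.cross_entropy_with_logits(cls_g, y_fake_g)
                dx_fake = disc.backward(d_adv_g, cfg.alpha * d_cls_g)
                gen.backward(dx_fake)
                opt_g.step()
                disc.zero_grad()

                # objective-form log-probability components for the history
                p_real = F.clamp_prob(F.sigmoid(adv_r))
                p_fake = F.clamp_prob(1.0 - F.sigmoid(adv_f))
                l_d = float(np.log(p_real).mean() + np.log(p_fake).mean())
                l_c = float(-(l_cls_r + l_cls_f) / 2.0)
                row = dict(iteration=it, epoch=epoch, d_adv=l_d, d_class=l_c,
                           g_adv=-l_adv_g, g_class=-l_cls_g,
                           d_loss=l_adv_r + l_adv_f + cfg.alpha * (l_cls_r + l_cls_f),
                           g_loss=l_adv_g + cfg.alpha * l_cls_g)
                if not all(np.isfinite(v) for v in row.values()):
                    raise TrainingDivergedError(
                        f"non-finite loss at iteration {it} (epoch {epoch}): {row}")
                history.append(row)
                it += 1
            if verbose:
                print(f"epoch {epoch}: D {history[-1]['d_loss']:.3f} "
                      f"G {history[-1]['g_loss']:.3f}")
        return ACGANResults(gen, disc, self.gen_spec, self.disc_spec, cfg,
                            pd.DataFrame(history), self.label_probs)

    def _pack(self, z: np.ndarray, labels0: np.ndarray) -> np.ndarray:
        cond = np.zeros((len(labels0), 3))
        cond[np.arange(len(labels0)), labels0] = 1.0
        g_in = np.concatenate([z, cond], axis=1)
        return g_in[:, :, None, None]


class ACGANResults:
    """A fitted ac-GAN: both networks, training history, and samplers."""

    def __init__(self, generator: nn.Sequential, discriminator: _Discriminator,
                 gen_spec: GeneratorSpec, disc_spec: DiscriminatorSpec,
                 config: GanTrainingConfig, history: pd.DataFrame,
                 label_probs: np.ndarray):
        self.generator = generator
        self.discriminator = discriminator
        self.gen_spec = gen_spec
        self.disc_spec = disc_spec
        self.config = config
        self.history = history
        self.label_probs = np.asarray(label_probs, dtype=float)

    # -- sampling ----------------------------------------------------------

    def generate(self, conditions, seed: int | None = None,
                 z: np.ndarray | None = None) -> np.ndarray:
        """Generate one image per condition vector.

        ``conditions`` is a sequence of :class:`ConditionVector` (or an
        (n, 3) array). ``z`` may be passed explicitly for morphing with a
        frozen latent; otherwise it is drawn N(0, I) from ``seed``.
        """
        cond = np.array([np.asarray(c, dtype=float) for c in conditions])
        if cond.ndim != 2 or cond.shape[1] != self.gen_spec.condition_dim:
            raise ValueError(
                f"conditions must be (n, {self.gen_spec.condition_dim})")
        n = cond.shape[0]
        if z is None:
            rng = np.random.default_rng(seed)
            z = rng.standard_normal((n, self.gen_spec.noise_dim))
        z = np.asarray(z, dtype=float)
        if z.shape != (n, self.gen_spec.noise_dim):
            raise ValueError("z has the wrong shape")
        g_in = np.concatenate([z, cond], axis=1)[:, :, None, None]
        out = self.generator.forward(g_in, train=False)
        return out.astype(np.float32)

    def morph(self, source: int, target: int, n_steps: int,
              seed: int | None = None, z: np.ndarray | None = None) -> np.ndarray:
        """Morph one latent z from class ``source`` to ``target`` in n steps.

        Returns an (n_steps + 1, slices, h, w) stack whose endpoints equal
        the one-hot-conditioned generations for the same z.
        """
        schedule = MorphSchedule(source, target, n_steps)
        if z is None:
            rng = np.random.default_rng(seed)
            z = rng.standard_normal((1, self.gen_spec.noise_dim))
        z_rep = np.repeat(np.asarray(z, dtype=float), len(schedule), axis=0)
        return self.generate(list(schedule), z=z_rep)

    def classify(self, images: np.ndarray) -> np.ndarray:
        """Class posteriors from the discriminator's auxiliary head."""
        _, cls_logits = self.discriminator.forward(
            np.asarray(images, dtype=np.float64), train=False)
        return F.softmax(cls_logits)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        last = self.history.iloc[-1] if len(self.history) else None
        lines = [
            "Auxiliary-classifier GAN",
            "=" * 40,
            f"generator layers:     {list(self.gen_spec.deconv_layers)}",
            f"discriminator layers: {list(self.disc_spec.conv_layers)}",
            f"noise dim: {self.gen_spec.noise_dim}   "
            f"condition dim: {self.gen_spec.condition_dim}",
            f"alpha: {self.config.alpha}   lr_g: {self.config.lr_g}   "
            f"lr_d: {self.config.lr_d}",
            f"epochs: {self.config.epochs}   batch size: {self.config.batch_size}",
            f"iterations run: {len(self.history)}",
        ]
        if last is not None:
            lines.append(
                f"final L_D: {last['d_adv']:+.4f}   final L_C: {last['d_class']:+.4f}")
            lines.append(
                f"final D loss: {last['d_loss']:.4f}   final G loss: {last['g_loss']:.4f}")
        return "\n".join(lines)

    def export_history_csv(self, path: str | Path) -> None:
        self.history.to_csv(path, index=False)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: JSON header + both networks' arrays."""
        header = {
            "gen_spec": {"noise_dim": self.gen_spec.noise_dim,
                         "condition_dim": self.gen_spec.condition_dim,
                         "deconv_layers": [list(l) for l in self.gen_spec.deconv_layers]},
            "disc_spec": {"conv_layers": [list(l) for l in self.disc_spec.conv_layers],
                          "leaky_slope": self.disc_spec.leaky_slope,
                          "n_classes": self.disc_spec.n_classes},
            "config": vars(self.config),
            "label_probs": self.label_probs.tolist(),
        }
        gstate = self.generator.state()
        dstate = self.discriminator.state()
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("header.json", json.dumps(header, indent=1))
            zf.writestr("history.csv", self.history.to_csv(index=False))
            for name, state in (("generator", gstate), ("discriminator", dstate)):
                buf = io.BytesIO()
                np.savez(buf, *state)
                zf.writestr(f"{name}.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "ACGANResults":
        with zipfile.ZipFile(path, "r") as zf:
            header = json.loads(zf.read("header.json"))
            history = pd.read_csv(io.BytesIO(zf.read("history.csv")))
            states = {}
            for name in ("generator", "discriminator"):
                with np.load(io.BytesIO(zf.read(f"{name}.npz"))) as npz:
                    states[name] = [npz[k] for k in npz.files]
        gen_spec = GeneratorSpec(
            noise_dim=header["gen_spec"]["noise_dim"],
            condition_dim=header["gen_spec"]["condition_dim"],
            deconv_layers=tuple(tuple(l) for l in header["gen_spec"]["deconv_layers"]))
        disc_spec = DiscriminatorSpec(
            conv_layers=tuple(tuple(l) for l in header["disc_spec"]["conv_layers"]),
            leaky_slope=header["disc_spec"]["leaky_slope"],
            n_classes=header["disc_spec"]["n_classes"])
        config = GanTrainingConfig(**header["config"])
        rng = np.random.default_rng(0)
        gen = _build_generator(gen_spec, rng)
        img_shape = generator_output_shape(gen_spec)
        disc = _Discriminator(disc_spec, img_shape, rng)
        gen.load_state(states["generator"])
        disc.load_state(states["discriminator"])
        return cls(gen, disc, gen_spec, disc_spec, config, history,
                   np.asarray(header["label_probs"]))
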