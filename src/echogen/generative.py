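"""Conditional-GAN translators mapping normalized B-mode images to RF frames.

Three generator variants share one patch discriminator:

* ``pix2pix`` — U-Net: stride-2 4x4 conv encoder (filters doubling from the
  base up to a cap), mirrored transposed-conv decoder with skip connections,
  dropout on the early decoder stages, sigmoid head;
* ``vit_shallow`` — 16x16 patch embedding + learned positional embeddings,
  two transformer encoder blocks, reshape to a low-resolution feature map,
  four transposed-conv upsampling stages;
* ``vit_deep`` — same embedding with five transformer blocks and
  reshape/upsample skip paths from earlier blocks into the decoder.

All geometry is parametric: the full-scale 2048 x 512 instantiation and the
desk-scale 256 x 64 one share the same code. Training follows the cGAN
objective: binary cross-entropy adversarial loss on the patch probability
map (with label smoothing on real labels), plus L1 and L2 reconstruction
losses weighted 1000 and 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor
from .types import NormalizationParams

__all__ = [
    "GeneratorSpec", "DiscriminatorSpec", "LossWeights", "TrainConfig",
    "TrainingLog", "TrainedTranslator", "patch_count", "build_generator",
    "build_discriminator", "generator_loss", "discriminator_loss",
    "train_cgan", "synthesize_rf", "desk_generator_spec",
    "desk_discriminator_spec",
]

VARIANTS = ("pix2pix", "vit_shallow", "vit_deep")


def patch_count(rows: int, cols: int, patch_size: int = 16) -> int:
    """Number of non-overlapping ViT patches in a frame."""
    if rows % patch_size or cols % patch_size:
        raise ValueError("frame dimensions must divide by the patch size")
    return (rows // patch_size) * (cols // patch_size)


@dataclass(frozen=True)
class GeneratorSpec:
    variant: str
    rows: int = 2048
    cols: int = 512
    patch_size: int = 16
    embed_dim: int = 256
    n_heads: int = 8
    mlp_ratio: int = 4
    base_filters: int = 64
    filter_cap: int = 512
    depth: Optional[int] = None      # U-Net levels; None -> min(7, geometry)
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "pix2pix":
            d = self.resolved_depth
            if self.rows % (2 ** d) or self.cols % (2 ** d):
                raise ValueError("rows and cols must divide by 2^depth")
        else:
            patch_count(self.rows, self.cols, self.patch_size)

    @property
    def n_blocks(self) -> int:
        return {"vit_shallow": 2, "vit_deep": 5}.get(self.variant, 0)

    @property
    def resolved_depth(self) -> int:
        if self.depth is not None:
            return self.depth
        geo = int(np.floor(np.log2(min(self.rows, self.cols))))
        return min(7, geo)


@dataclass(frozen=True)
class DiscriminatorSpec:
    rows: int = 2048
    cols: int = 512
    down_filters: tuple[int, int, int] = (64, 128, 256)
    head_filters: tuple[int, int] = (512, 1)
    kernel: int = 3

    def __post_init__(self) -> None:
        if self.rows % 8 or self.cols % 8:
            raise ValueError("input must divide by 8 (three stride-2 blocks)")
        if self.head_filters[-1] != 1:
            raise ValueError("final head must emit a single channel")

    @property
    def output_shape(self) -> tuple[int, int]:
        return (self.rows // 8, self.cols // 8)


@dataclass(frozen=True)
class LossWeights:
    adversarial: float = 1.0
    l1: float = 1000.0
    l2: float = 100.0
    label_smoothing: float = 0.1

    def __post_init__(self) -> None:
        if min(self.adversarial, self.l1, self.l2) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class TrainConfig:
    lr_generator: float = 1e-4
    lr_discriminator: float = 1e-5
    beta1: float = 0.5
    beta2: float = 0.999
    weight_decay: float = 1e-4
    batch_size: int = 1
    epochs_main: int = 150
    epochs_select: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs_main < 1 or self.epochs_select < 0:
            raise ValueError("epochs must be positive")
        if min(self.lr_generator, self.lr_discriminator) <= 0:
            raise ValueError("learning rates must be positive")


@dataclass
class TrainingLog:
    g_loss: list = field(default_factory=list)
    d_loss: list = field(default_factory=list)
    val_recon: list = field(default_factory=list)
    selected_epoch: Optional[int] = None


@dataclass
class TrainedTranslator:
    generator: nn.Module
    spec: GeneratorSpec
    log: TrainingLog
    norm_params: Optional[NormalizationParams] = None


def desk_generator_spec(variant: str, rows: int = 256,
                        cols: int = 64) -> GeneratorSpec:
    """Desk-scale preset sharing code with the full-size configuration."""
    return GeneratorSpec(variant=variant, rows=rows, cols=cols,
                         base_filters=16, filter_cap=128,
                         embed_dim=64, n_heads=4)


def desk_discriminator_spec(rows: int = 256, cols: int = 64) -> DiscriminatorSpec:
    return DiscriminatorSpec(rows=rows, cols=cols,
                             down_filters=(16, 32, 64), head_filters=(128, 1))


# ---------------------------------------------------------------------------
# generators

class _Pix2PixGenerator(nn.Module):
    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        d = spec.resolved_depth
        filters = [min(spec.base_filters * 2 ** i, spec.filter_cap)
                   for i in range(d)]
        self.enc_convs, self.enc_bns = [], []
        c_in = 1
        for i, f in enumerate(filters):
            self.enc_convs.append(nn.Conv2d(c_in, f, 4, 2, 1, rng))
            self.enc_bns.append(nn.BatchNorm2d(f))
            c_in = f
        self.dec_convs, self.dec_bns, self.dec_drops = [], [], []
        for j, i in enumerate(range(d - 2, -1, -1)):
            c_dec_in = filters[d - 1] if j == 0 else filters[i + 1] * 2
            self.dec_convs.append(nn.ConvTranspose2d(c_dec_in, filters[i],
                                                     4, 2, 1, rng))
            self.dec_bns.append(nn.BatchNorm2d(filters[i]))
            p = spec.dropout if j < 3 else 0.0
            self.dec_drops.append(nn.Dropout(p, rng))
        self.head = nn.ConvTranspose2d(filters[0] * 2, 1, 4, 2, 1, rng)

    def forward(self, x):
        skips = []
        h = x
        for conv, bn in zip(self.enc_convs, self.enc_bns):
            h = ag.leaky_relu(bn(conv(h)), 0.2)
            skips.append(h)
        h = skips[-1]
        for j, (conv, bn, drop) in enumerate(
                zip(self.dec_convs, self.dec_bns, self.dec_drops)):
            h = ag.relu(drop(bn(conv(h))))
            h = ag.concat([h, skips[-2 - j]], axis=1)
        return ag.sigmoid(self.head(h))


class _PatchEmbed(nn.Module):
    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        super().__init__()
        p = spec.patch_size
        self.p = p
        self.h = spec.rows // p
        self.w = spec.cols // p
        self.proj = nn.Linear(p * p, spec.embed_dim, rng)
        self.pos = nn.Parameter(
            rng.normal(0.0, 0.02, (1, self.h * self.w, spec.embed_dim)))

    def forward(self, x):
        n = x.shape[0]
        t = ag.reshape(x, (n, self.h, self.p, self.w, self.p))
        t = ag.transpose(t, (0, 1, 3, 2, 4))
        t = ag.reshape(t, (n, self.h * self.w, self.p * self.p))
        return ag.add(self.proj(t), self.pos)


def _tokens_to_map(tokens, n, h, w, e):
    m = ag.reshape(tokens, (n, h, w, e))
    return ag.transpose(m, (0, 3, 1, 2))


class _ViTGenerator(nn.Module):
    """Shallow (2-block) and deep (5-block, skip-connected) ViT generators."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        e = spec.embed_dim
        self.embed = _PatchEmbed(spec, rng)
        self.blocks = [nn.TransformerBlock(e, spec.n_heads, spec.mlp_ratio, rng)
                       for _ in range(spec.n_blocks)]
        chans = [e, e // 2, e // 4, e // 8]
        self.dec_convs = [nn.ConvTranspose2d(chans[i], chans[i + 1], 4, 2, 1,
                                             rng, init="kaiming")
                          for i in range(3)]
        self.dec_bns = [nn.BatchNorm2d(chans[i + 1]) for i in range(3)]
        self.head = nn.ConvTranspose2d(chans[3], 1, 4, 2, 1, rng)
        self.deep = spec.variant == "vit_deep"
        if self.deep:
            # skip taps: blocks 1 and 3 (1-based) feed decoder stages 2 and 1
            self.skip_conv1 = nn.Conv2d(e, e // 2, 1, 1, 0, rng,
                                        init="kaiming")  # block 3
            self.skip_conv2 = nn.Conv2d(e, e // 4, 1, 1, 0, rng,
                                        init="kaiming")  # block 1

    def forward(self, x):
        n = x.shape[0]
        e = self.spec.embed_dim
        h, w = self.embed.h, self.embed.w
        t = self.embed(x)
        taps = {}
        for i, blk in enumerate(self.blocks):
            t = blk(t)
            taps[i + 1] = t
        m = _tokens_to_map(t, n, h, w, e)
        out = m
        for i, (conv, bn) in enumerate(zip(self.dec_convs, self.dec_bns)):
            out = conv(out)
            if self.deep and i == 0:
                skip = _tokens_to_map(taps[3], n, h, w, e)
                out = ag.add(out, self.skip_conv1(ag.upsample_nearest(skip, 2)))
            elif self.deep and i == 1:
                skip = _tokens_to_map(taps[1], n, h, w, e)
                out = ag.add(out, self.skip_conv2(ag.upsample_nearest(skip, 4)))
            out = ag.leaky_relu(bn(out), 0.2)
        return ag.sigmoid(self.head(out))


def build_generator(spec: GeneratorSpec, seed: int = 0) -> nn.Module:
    """Instantiate a generator: [0,1] B-mode (rows x cols) -> [0,1] RF."""
    rng = np.random.default_rng(seed)
    if spec.variant == "pix2pix":
        return _Pix2PixGenerator(spec, rng)
    return _ViTGenerator(spec, rng)


class _PatchDiscriminator(nn.Module):
    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        k = spec.kernel
        self.downs, self.norms = [], []
        c_in = 2
        for f in spec.down_filters:
            self.downs.append(nn.Conv2d(c_in, f, k, 2, 1, rng))
            self.norms.append(nn.LayerNormChannel(f))
            c_in = f
        f512, f1 = spec.head_filters
        self.head1 = nn.Conv2d(c_in, f512, k, 1, 1, rng)
        self.head1_norm = nn.LayerNormChannel(f512)
        self.head2 = nn.Conv2d(f512, f1, k, 1, 1, rng)

    def forward(self, bmode, rf):
        if bmode.shape != rf.shape:
            raise ValueError("B-mode and RF inputs must share shape")
        h = ag.concat([bmode, rf], axis=1)
        for conv, norm in zip(self.downs, self.norms):
            h = ag.leaky_relu(norm(conv(h)), 0.2)
        h = ag.leaky_relu(self.head1_norm(self.head1(h)), 0.2)
        return ag.sigmoid(self.head2(h))


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> nn.Module:
    """Patch discriminator: (B-mode, RF) -> probability map (rows/8, cols/8)."""
    return _PatchDiscriminator(spec, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# losses

_BCE_EPS = 1e-7


def _bce(pred: Tensor, target: float) -> Tensor:
    p = ag.clip(pred, _BCE_EPS, 1.0 - _BCE_EPS)
    return ag.mul(ag.add(ag.mul(ag.log(p), -target),
                         ag.mul(ag.log(ag.add(ag.mul(p, -1.0), 1.0)),
                                -(1.0 - target))).mean(), 1.0)


def generator_loss(synthetic: Tensor, target: np.ndarray,
                   disc_map_on_fake: Tensor,
                   weights: LossWeights = LossWeights()):
    """Adversarial BCE toward real labels plus weighted L1/L2 reconstruction.

    Returns ``(total, components)`` with components logged separately.
    """
    if synthetic.shape != np.asarray(target).shape:
        raise ValueError("synthetic and target shapes differ")
    if not (np.all(np.isfinite(synthetic.data))
            and np.all(np.isfinite(disc_map_on_fake.data))):
        raise FloatingPointError("non-finite values in generator loss inputs")
    diff = ag.add(synthetic, Tensor(-np.asarray(target)))
    l1 = ag.absval(diff).mean()
    l2 = ag.mul(diff, diff).mean()
    adv = _bce(disc_map_on_fake, 1.0)
    total = ag.add(ag.add(ag.mul(adv, weights.adversarial),
                          ag.mul(l1, weights.l1)),
                   ag.mul(l2, weights.l2))
    comps = {"adversarial": float(adv.data), "l1": float(l1.data),
             "l2": float(l2.data),
             "reconstruction": float(weights.l1 * l1.data
                                     + weights.l2 * l2.data)}
    return total, comps


def discriminator_loss(map_real: Tensor, map_fake: Tensor,
                       label_smoothing: float = 0.1) -> Tensor:
    """BCE(map_real, 1 - eps) + BCE(map_fake, 0), averaged over patches.
    Label smoothing is applied to the real labels only."""
    return ag.add(_bce(map_real, 1.0 - label_smoothing), _bce(map_fake, 0.0))


# ---------------------------------------------------------------------------
# training and inference

def _recon_loss(a: np.ndarray, b: np.ndarray, weights: LossWeights) -> float:
    d = a - b
    return float(weights.l1 * np.abs(d).mean() + weights.l2 * (d ** 2).mean())


def _as_batch(img: np.ndarray) -> Tensor:
    return Tensor(np.asarray(img, dtype=np.float64)[None, None])


def train_cgan(train_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
               val_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
               gen_spec: GeneratorSpec,
               disc_spec: Optional[DiscriminatorSpec] = None,
               weights: LossWeights = LossWeights(),
               config: TrainConfig = TrainConfig(),
               norm_params: Optional[NormalizationParams] = None):
    """Alternating discriminator/generator optimization with Adam.

    Trains for ``epochs_main`` epochs, then ``epochs_select`` more during
    which the checkpoint with the lowest validation reconstruction
    (weighted L1 + L2) loss is selected. Deterministic given ``config.seed``.
    """
    if not train_pairs:
        raise ValueError("empty training set")
    if disc_spec is None:
        disc_spec = DiscriminatorSpec(rows=gen_spec.rows, cols=gen_spec.cols,
                                      down_filters=(16, 32, 64),
                                      head_filters=(128, 1))
    rng = np.random.default_rng(config.seed)
    gen = build_generator(gen_spec, seed=int(rng.integers(2 ** 31)))
    disc = build_discriminator(disc_spec, seed=int(rng.integers(2 ** 31)))
    opt_g = nn.Adam(gen.parameters(), lr=config.lr_generator,
                    betas=(config.beta1, config.beta2),
                    weight_decay=config.weight_decay)
    opt_d = nn.Adam(disc.parameters(), lr=config.lr_discriminator,
                    betas=(config.beta1, config.beta2),
                    weight_decay=config.weight_decay)

    log = TrainingLog()
    best = (None, None)  # (val loss, state dict)
    n_epochs = config.epochs_main + config.epochs_select
    for epoch in range(n_epochs):
        order = rng.permutation(len(train_pairs))
        g_losses, d_losses = [], []
        gen.train(), disc.train()
        for idx in order:
            x, y = train_pairs[idx]
            xb, yb = _as_batch(x), _as_batch(y)

            with ag.no_grad():
                gen.eval()
                fake = gen(xb)
                gen.train()
            d_loss = discriminator_loss(disc(xb, yb),
                                        disc(xb, Tensor(fake.data)),
                                        weights.label_smoothing)
            if not np.isfinite(d_loss.data):
                raise RuntimeError(f"discriminator loss diverged at epoch {epoch}")
            opt_d.zero_grad(), opt_g.zero_grad()
            d_loss.backward()
            opt_d.step()

            fake = gen(xb)
            g_loss, comps = generator_loss(fake, yb.data, disc(xb, fake),
                                           weights)
            if not np.isfinite(g_loss.data):
                raise RuntimeError(f"generator loss diverged at epoch {epoch}")
            opt_d.zero_grad(), opt_g.zero_grad()
            g_loss.backward()
            opt_g.step()

            g_losses.append(float(g_loss.data))
            d_losses.append(float(d_loss.data))

        gen.eval()
        with ag.no_grad():
            val = float(np.mean([
                _recon_loss(gen(_as_batch(x)).data[0, 0], y, weights)
                for x, y in val_pairs])) if val_pairs else float(
                    np.mean(g_losses))
        log.g_loss.append(float(np.mean(g_losses)))
        log.d_loss.append(float(np.mean(d_losses)))
        log.val_recon.append(val)
        if epoch >= config.epochs_main or config.epochs_select == 0:
            if best[0] is None or val < best[0]:
                best = (val, gen.state_dict())
                log.selected_epoch = epoch

    if best[1] is not None:
        gen.load_state_dict(best[1])
    gen.eval()
    return TrainedTranslator(generator=gen, spec=gen_spec, log=log,
                             norm_params=norm_params), log


def synthesize_rf(translator, bmode: np.ndarray) -> np.ndarray:
    """Run a trained generator on one normalized B-mode image."""
    gen = translator.generator if isinstance(translator, TrainedTranslator) \
        else translator
    b = np.asarray(bmode, dtype=np.float64)
    if b.min() < -1e-9 or b.max() > 1 + 1e-9:
        raise ValueError("B-mode input must be normalized to [0, 1]")
    spec = getattr(translator, "spec", None)
    if spec is not None and b.shape != (spec.rows, spec.cols):
        raise ValueError("input shape does not match the generator geometry")
    gen.eval()
    with ag.no_grad():
        out = gen(_as_batch(b))
    return out.data[0, 0]
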