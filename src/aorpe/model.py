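"""The parallel-discriminator GAN (P-GAN) for speckle-obscured cell recovery.

Three networks are trained jointly on co-registered (speckled, averaged) patch
pairs:

* a generator ``G`` — an encoder–decoder CNN with skip connections mapping a
  single speckled patch to a cell-mosaic estimate in [0, 1];
* a CNN discriminator ``D2`` — a patch-level real/fake critic that pulls the
  generator's output distribution toward that of the averaged images;
* a twin (Siamese) discriminator ``D1`` — two weight-shared CNN branches whose
  multi-depth features are pooled and fused by a weighted feature fusion (WFF)
  block; the L1 distance between the two fused vectors feeds a learned
  similarity head.  ``D1`` is trained to call two averaged renditions of the
  same tissue "similar" and a (generated, averaged) pair "dissimilar", so the
  generator is pushed to reproduce local cellular features, not merely the
  global distribution.

The ablation family (conventional GAN ``G+D2``, twin-only ``G+D1``, both
discriminators without WFF, and the full model) is expressed purely through
:class:`LossConfig` / :class:`TwinDiscriminatorSpec` configuration — there are
no code forks between variants.  After training the discriminators are
discarded; inference is a single generator pass, tiled with cosine-window
blending for images larger than the training patch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from pathlib import Path

import numpy as np

from .nn import DTYPE, Adam, Conv2d, Linear, Module, Tensor, concat, crop2d, upsample2x

__all__ = [
    "GeneratorSpec", "TwinDiscriminatorSpec", "CNNDiscriminatorSpec",
    "LossConfig", "TrainConfig", "AblationVariant",
    "Generator", "TwinDiscriminator", "CNNDiscriminator",
    "wff_fuse", "twin_similarity", "pgan_step", "train_pgan", "recover",
    "save_generator", "load_generator", "PGANRecovery",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorSpec:
    """Encoder–decoder generator layout.

    ``depth`` strided-conv encoder levels halve resolution each; the decoder
    mirrors them with nearest-neighbour upsampling and (optionally) skip
    connections.  The output is squashed to [0, 1] by a sigmoid.
    """

    depth: int = 4
    base_channels: int = 16
    skip_connections: bool = True

    def __post_init__(self):
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")


@dataclass(frozen=True)
class TwinDiscriminatorSpec:
    """Weight-shared twin trunk with WFF taps.

    ``tap_levels`` are the (0-based) trunk levels whose pooled features enter
    the fusion together with the last level; ``wff_weights`` are the fusion
    weights (mid1, mid2, last) — intermediate weights 0.2 with the last layer
    at 1.0 by default; (0, 0, 1) reproduces the no-WFF ablation, which pools
    the last convolutional layer only.
    """

    depth: int = 4
    base_channels: int = 16
    tap_levels: tuple[int, int] = (1, 2)
    wff_weights: tuple[float, float, float] = (0.2, 0.2, 1.0)

    def __post_init__(self):
        if any(w < 0 for w in self.wff_weights):
            raise ValueError("wff_weights must be >= 0")
        if self.wff_weights[2] <= 0:
            raise ValueError("last-layer fusion weight must be > 0")
        if len(self.tap_levels) != 2 or max(self.tap_levels) >= self.depth - 1:
            raise ValueError("tap_levels must name two intermediate trunk levels")


@dataclass(frozen=True)
class CNNDiscriminatorSpec:
    depth: int = 3
    base_channels: int = 16


class AblationVariant(str, Enum):
    """The configurable model family."""

    G_D2 = "G_D2"                      # conventional GAN
    G_D1 = "G_D1"                      # twin discriminator only
    G_D2_D1_noWFF = "G_D2_D1_noWFF"    # both, last-layer pooling instead of WFF
    PGAN = "PGAN"                      # full model


@dataclass(frozen=True)
class LossConfig:
    """Weights of the generator objective's three terms."""

    adv_d2_weight: float = 1.0
    adv_d1_weight: float = 1.0
    content_weight: float = 100.0
    content_norm: str = "L1"  # or "L2"

    def __post_init__(self):
        if min(self.adv_d2_weight, self.adv_d1_weight, self.content_weight) < 0:
            raise ValueError("loss weights must be >= 0")
        if max(self.adv_d2_weight, self.adv_d1_weight, self.content_weight) == 0:
            raise ValueError("at least one loss weight must be > 0")
        if self.content_norm not in ("L1", "L2"):
            raise ValueError("content_norm must be 'L1' or 'L2'")

    @staticmethod
    def for_variant(variant: AblationVariant, content_weight: float = 100.0) -> "LossConfig":
        v = AblationVariant(variant)
        if v is AblationVariant.G_D2:
            return LossConfig(1.0, 0.0, content_weight)
        if v is AblationVariant.G_D1:
            return LossConfig(0.0, 1.0, content_weight)
        return LossConfig(1.0, 1.0, content_weight)


def twin_spec_for_variant(
    variant: AblationVariant, base: TwinDiscriminatorSpec | None = None
) -> TwinDiscriminatorSpec:
    base = base or TwinDiscriminatorSpec()
    if AblationVariant(variant) is AblationVariant.G_D2_D1_noWFF:
        return replace(base, wff_weights=(0.0, 0.0, 1.0))
    return base


@dataclass(frozen=True)
class TrainConfig:
    """Adversarial training recipe (Adam, lr 2e-4, betas (0.5, 0.9))."""

    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.9
    seed: int = 0
    divergence_threshold: float = 1e6

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")


# --------------------------------------------------------------------------
# networks
# --------------------------------------------------------------------------

def _chans(base: int, level: int, cap: int = 128) -> int:
    return min(base * (2**level), cap)


class Generator(Module):
    """Encoder–decoder CNN with skip connections and sigmoid output."""

    def __init__(self, spec: GeneratorSpec = GeneratorSpec(), rng=None):
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        d, b = spec.depth, spec.base_channels
        self.enc = [
            Conv2d(1 if k == 0 else _chans(b, k - 1), _chans(b, k), 3, stride=2, rng=rng)
            for k in range(d)
        ]
        self.bottleneck = Conv2d(_chans(b, d - 1), _chans(b, d - 1), 3, rng=rng)
        self.dec = []
        for k in reversed(range(d)):
            cin = _chans(b, k)
            if spec.skip_connections:
                cin += _chans(b, k)  # concatenated encoder feature
            cout = _chans(b, k - 1) if k > 0 else b
            self.dec.append(Conv2d(cin, cout, 3, rng=rng))
        self.head = Conv2d(b, 1, 3, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        m = 2**self.spec.depth
        ph, pw = (-h) % m, (-w) % m
        if ph or pw:  # pad leaf input to a multiple of the downsampling factor
            x = Tensor(np.pad(x.data, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect"))
        skips = []
        for conv in self.enc:
            x = conv(x).leaky_relu(0.2)
            skips.append(x)
        x = self.bottleneck(x).leaky_relu(0.2)
        for conv, skip in zip(self.dec, reversed(skips)):
            if self.spec.skip_connections:
                x = concat([x, skip], axis=1)
            x = upsample2x(conv(x).leaky_relu(0.2))
        out = self.head(x).sigmoid()
        if ph or pw:
            out = crop2d(out, h, w)
        return out


class CNNDiscriminator(Module):
    """Patch-level real/fake critic; returns a logit map."""

    def __init__(self, spec: CNNDiscriminatorSpec = CNNDiscriminatorSpec(), rng=None):
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        d, b = spec.depth, spec.base_channels
        self.convs = [
            Conv2d(1 if k == 0 else _chans(b, k - 1), _chans(b, k), 3, stride=2, rng=rng)
            for k in range(d)
        ]
        self.head = Conv2d(_chans(b, d - 1), 1, 3, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        for conv in self.convs:
            x = conv(x).leaky_relu(0.2)
        return self.head(x)  # logits


def wff_fuse(feature_maps: list[Tensor], weights: tuple[float, float, float]) -> Tensor:
    """Weighted feature fusion: pool each tap map, scale, concatenate.

    Each of the three NCHW maps is globally average-pooled over space, scaled
    by its fusion weight, and the scaled vectors are concatenated; the output
    length is the sum of the tap channel counts.  Weights (0, 0, 1) carry the
    information content of last-layer pooling alone (the no-WFF ablation).
    """
    if len(feature_maps) != 3 or len(weights) != 3:
        raise ValueError("wff_fuse expects exactly 3 feature maps and 3 weights")
    pooled = [fm.mean(axis=(2, 3)) * float(w) for fm, w in zip(feature_maps, weights)]
    return concat(pooled, axis=1)


class TwinDiscriminator(Module):
    """Weight-shared twin trunk + WFF + L1-distance similarity head.

    Both branches are literally the same ``Module`` (single parameter
    storage), so weight sharing holds by construction after any number of
    training steps.
    """

    def __init__(self, spec: TwinDiscriminatorSpec = TwinDiscriminatorSpec(), rng=None):
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        d, b = spec.depth, spec.base_channels
        self.trunk = [
            Conv2d(1 if k == 0 else _chans(b, k - 1), _chans(b, k), 3, stride=2, rng=rng)
            for k in range(d)
        ]
        fused_len = (
            _chans(b, spec.tap_levels[0])
            + _chans(b, spec.tap_levels[1])
            + _chans(b, d - 1)
        )
        self.head = Linear(fused_len, 1, rng=rng)

    def branch_features(self, x: Tensor) -> Tensor:
        taps = []
        for k, conv in enumerate(self.trunk):
            x = conv(x).leaky_relu(0.2)
            if k in self.spec.tap_levels:
                taps.append(x)
        taps.append(x)  # last convolutional level
        return wff_fuse(taps, self.spec.wff_weights)

    def similarity_logit(self, a: Tensor, b: Tensor) -> Tensor:
        if a.data.shape != b.data.shape:
            raise ValueError("twin inputs must share shape")
        fa = self.branch_features(a)
        fb = self.branch_features(b)
        return self.head((fa - fb).abs())

    def forward(self, a: Tensor, b: Tensor) -> Tensor:
        return self.similarity_logit(a, b).sigmoid()


def twin_similarity(d1: TwinDiscriminator, image_a: np.ndarray, image_b: np.ndarray) -> float:
    """Similarity score in [0, 1] between two images under the twin critic."""
    a = Tensor(_nchw(image_a))
    b = Tensor(_nchw(image_b))
    return float(d1(a, b).data.mean())


# --------------------------------------------------------------------------
# losses and training
# --------------------------------------------------------------------------

def _nchw(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=DTYPE)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[:, None]
    return x


def _bce_with_logits(logits: Tensor, target: float) -> Tensor:
    # mean softplus(z) - t*z  ==  BCE(sigmoid(z), t), numerically stable
    return (logits.softplus() - logits * float(target)).mean()


@dataclass
class PGANNets:
    generator: Generator
    d1: TwinDiscriminator | None
    d2: CNNDiscriminator | None
    opt_g: Adam
    opt_d1: Adam | None
    opt_d2: Adam | None


def build_nets(
    variant: AblationVariant = AblationVariant.PGAN,
    gen_spec: GeneratorSpec = GeneratorSpec(),
    twin_spec: TwinDiscriminatorSpec | None = None,
    cnn_spec: CNNDiscriminatorSpec = CNNDiscriminatorSpec(),
    train_cfg: TrainConfig = TrainConfig(),
) -> PGANNets:
    """Instantiate the networks and optimisers for an ablation variant."""
    variant = AblationVariant(variant)
    rng = np.random.default_rng(train_cfg.seed)
    g = Generator(gen_spec, rng=rng)
    use_d2 = variant in (AblationVariant.G_D2, AblationVariant.G_D2_D1_noWFF, AblationVariant.PGAN)
    use_d1 = variant in (AblationVariant.G_D1, AblationVariant.G_D2_D1_noWFF, AblationVariant.PGAN)
    d2 = CNNDiscriminator(cnn_spec, rng=rng) if use_d2 else None
    d1 = (
        TwinDiscriminator(twin_spec_for_variant(variant, twin_spec), rng=rng)
        if use_d1 else None
    )
    adam = lambda net: Adam(
        net.parameters(), lr=train_cfg.learning_rate,
        betas=(train_cfg.beta1, train_cfg.beta2),
    )
    return PGANNets(g, d1, d2, adam(g), adam(d1) if d1 else None, adam(d2) if d2 else None)


def pgan_step(
    batch: tuple[np.ndarray, np.ndarray, np.ndarray],
    nets: PGANNets,
    loss_cfg: LossConfig,
) -> dict[str, float]:
    """One simultaneous update of D2, D1 and G on a batch.

    ``batch`` is (speckled, averaged, averaged_alt) arrays of shape
    (n, patch, patch); ``averaged_alt`` holds a second averaged rendition of
    the same tissue (from a different reference frame) and forms D1's
    similar pair, while (generated, averaged) forms its dissimilar pair.
    Returns the finite loss components.
    """
    spk, avg, alt = (Tensor(_nchw(a)) for a in batch)
    if spk.data.shape[0] == 0:
        raise ValueError("empty batch")
    losses: dict[str, float] = {}

    fake = nets.generator(spk)
    fake_detached = Tensor(fake.data)

    if nets.d2 is not None:
        nets.opt_d2.zero_grad()
        loss_d2 = 0.5 * (
            _bce_with_logits(nets.d2(avg), 1.0)
            + _bce_with_logits(nets.d2(fake_detached), 0.0)
        )
        loss_d2.backward()
        nets.opt_d2.step()
        losses["d2_adv"] = loss_d2.item()

    if nets.d1 is not None:
        nets.opt_d1.zero_grad()
        loss_d1 = 0.5 * (
            _bce_with_logits(nets.d1.similarity_logit(avg, alt), 1.0)
            + _bce_with_logits(nets.d1.similarity_logit(fake_detached, avg), 0.0)
        )
        loss_d1.backward()
        nets.opt_d1.step()
        losses["d1_sim_adv"] = loss_d1.item()

    nets.opt_g.zero_grad()
    diff = fake - avg
    content = diff.abs().mean() if loss_cfg.content_norm == "L1" else (diff**2).mean()
    g_loss = content * loss_cfg.content_weight
    losses["content"] = content.item()
    if nets.d2 is not None and loss_cfg.adv_d2_weight > 0:
        adv2 = _bce_with_logits(nets.d2(fake), 1.0)
        g_loss = g_loss + adv2 * loss_cfg.adv_d2_weight
    if nets.d1 is not None and loss_cfg.adv_d1_weight > 0:
        adv1 = _bce_with_logits(nets.d1.similarity_logit(fake, avg), 1.0)
        g_loss = g_loss + adv1 * loss_cfg.adv_d1_weight
    # discriminator updates above must not touch their parameters via G's pass
    for p in (nets.d2.parameters() if nets.d2 else []) + (nets.d1.parameters() if nets.d1 else []):
        p.grad = None
    g_loss.backward()
    for p in (nets.d2.parameters() if nets.d2 else []) + (nets.d1.parameters() if nets.d1 else []):
        p.grad = None
    nets.opt_g.step()
    losses["generator_total"] = g_loss.item()

    for name, v in losses.items():
        if not np.isfinite(v):
            raise FloatingPointError(f"nonfinite loss component: {name}")
    return losses


def train_pgan(
    pairs,
    variant: AblationVariant = AblationVariant.PGAN,
    train_cfg: TrainConfig = TrainConfig(),
    loss_cfg: LossConfig | None = None,
    gen_spec: GeneratorSpec = GeneratorSpec(),
    twin_spec: TwinDiscriminatorSpec | None = None,
    cnn_spec: CNNDiscriminatorSpec = CNNDiscriminatorSpec(),
    log_callback=None,
):
    """Train a generator on (speckled, averaged) pairs.

    ``pairs`` is a :class:`~aorpe.acquire.TrainingPairSet` or a tuple of
    arrays (speckled, averaged[, averaged_alt]) of shape (n, p, p).  Returns
    ``(generator, log)`` where ``log`` is a list of per-step loss dicts; the
    discriminators are discarded.
    """
    if hasattr(pairs, "arrays"):
        x, y = pairs.arrays()
        alt = pairs.alt_arrays()
    else:
        x, y = pairs[0], pairs[1]
        alt = pairs[2] if len(pairs) > 2 else y
    n = x.shape[0]
    if n == 0:
        raise ValueError("no training pairs")
    if x.shape[1] != x.shape[2]:
        raise ValueError("patches must be square")
    variant = AblationVariant(variant)
    loss_cfg = loss_cfg or LossConfig.for_variant(variant)
    nets = build_nets(variant, gen_spec, twin_spec, cnn_spec, train_cfg)
    rng = np.random.default_rng(train_cfg.seed + 1)
    log: list[dict] = []
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            losses = pgan_step((x[idx], y[idx], alt[idx]), nets, loss_cfg)
            losses["epoch"] = epoch
            losses["step"] = len(log)
            if losses["generator_total"] > train_cfg.divergence_threshold:
                raise FloatingPointError(
                    f"training diverged at step {len(log)}: "
                    f"generator loss {losses['generator_total']:.3g}"
                )
            log.append(losses)
            if log_callback is not None:
                log_callback(losses)
    return nets.generator, log


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------

def _cosine_window(p: int) -> np.ndarray:
    w1 = np.sin(np.pi * (np.arange(p) + 0.5) / p)
    return np.outer(w1, w1)


def recover(
    generator: Generator,
    speckled_image: np.ndarray,
    patch_px: int | None = None,
    overlap_frac: float = 0.5,
) -> np.ndarray:
    """Recover the cell mosaic from a single speckled image.

    Inputs exactly patch-sized take a single forward pass; larger images are
    processed in overlapping tiles (overlap >= 25%) blended with a cosine
    window whose per-pixel weights are normalised to sum to one.
    """
    img = np.asarray(speckled_image, dtype=DTYPE)
    if img.ndim != 2:
        raise ValueError("expected a single 2D image")
    h, w = img.shape
    p = patch_px or min(h, w)
    if h < p or w < p:
        raise ValueError(f"image {img.shape} smaller than patch {p}")
    if not (0.25 <= overlap_frac < 1.0):
        raise ValueError("overlap_frac must be in [0.25, 1)")
    if (h, w) == (p, p):
        return generator(Tensor(img[None, None])).data[0, 0].astype(float)
    stride = max(1, int(round(p * (1.0 - overlap_frac))))
    offs_y = _cover_offsets(h, p, stride)
    offs_x = _cover_offsets(w, p, stride)
    win = _cosine_window(p)
    acc = np.zeros((h, w))
    wacc = np.zeros((h, w))
    for oy in offs_y:
        for ox in offs_x:
            tile = img[oy : oy + p, ox : ox + p]
            out = generator(Tensor(tile[None, None])).data[0, 0]
            acc[oy : oy + p, ox : ox + p] += out * win
            wacc[oy : oy + p, ox : ox + p] += win
    return acc / wacc


def _cover_offsets(size: int, patch: int, stride: int) -> list[int]:
    offs = list(range(0, size - patch + 1, stride))
    if offs[-1] != size - patch:
        offs.append(size - patch)
    return offs


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------

def save_generator(generator: Generator, path: str | Path, manifest: dict | None = None) -> None:
    """Save generator weights (.npz) with a JSON sidecar manifest."""
    path = Path(path)
    arrays = {f"p{i}": a for i, a in enumerate(generator.state_arrays())}
    np.savez(path, **arrays)
    spec = generator.spec
    meta = {
        "generator_spec": {f.name: getattr(spec, f.name) for f in fields(spec)},
        **(manifest or {}),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_generator(path: str | Path) -> Generator:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    gen = Generator(GeneratorSpec(**meta["generator_spec"]))
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        gen.load_state_arrays([z[f"p{i}"] for i in range(len(z.files))])
    return gen


# --------------------------------------------------------------------------
# scikit-learn style estimator
# --------------------------------------------------------------------------

class PGANRecovery:
    """Speckle-to-mosaic restorer with a scikit-learn estimator interface.

    Parameters mirror :func:`train_pgan`; after :meth:`fit` the trained
    generator is available as ``generator_`` and the per-step loss log as
    ``history_``.  :meth:`transform` recovers one or more speckled images.
    """

    def __init__(self, variant: str = "PGAN", epochs: int = 100, batch_size: int = 8,
                 learning_rate: float = 2e-4, depth: int = 4, base_channels: int = 16,
                 content_weight: float = 100.0, seed: int = 0):
        self.variant = variant
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.depth = depth
        self.base_channels = base_channels
        self.content_weight = content_weight
        self.seed = seed

    # sklearn protocol -------------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "variant": self.variant, "epochs": self.epochs,
            "batch_size": self.batch_size, "learning_rate": self.learning_rate,
            "depth": self.depth, "base_channels": self.base_channels,
            "content_weight": self.content_weight, "seed": self.seed,
        }

    def set_params(self, **params) -> "PGANRecovery":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None, alt=None):
        """Fit on speckled patches ``X`` and averaged targets ``y``."""
        X = np.asarray(X)
        if y is None:
            raise ValueError("supervised training requires averaged targets y")
        y = np.asarray(y)
        if X.shape != y.shape or X.ndim != 3:
            raise ValueError("X and y must both be (n, patch, patch)")
        cfg = TrainConfig(
            epochs=self.epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate, seed=self.seed,
        )
        gen_spec = GeneratorSpec(depth=self.depth, base_channels=self.base_channels)
        variant = AblationVariant(self.variant)
        self.generator_, self.history_ = train_pgan(
            (X, y, np.asarray(alt) if alt is not None else y),
            variant=variant, train_cfg=cfg,
            loss_cfg=LossConfig.for_variant(variant, self.content_weight),
            gen_spec=gen_spec,
        )
        self.patch_px_ = int(X.shape[1])
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "generator_"):
            raise RuntimeError("PGANRecovery is not fitted")
        X = np.asarray(X)
        single = X.ndim == 2
        imgs = X[None] if single else X
        out = np.stack(
            [recover(self.generator_, im, patch_px=min(self.patch_px_, *im.shape))
             for im in imgs]
        )
        return out[0] if single else out

    def fit_transform(self, X, y=None, **kw) -> np.ndarray:
        return self.fit(X, y, **kw).transform(X)
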