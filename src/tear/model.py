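"""The TEAR network: a ViT encoder over gated patch embeddings and a
convolutional up-sampling decoder that re-assembles the denoised B-scan.

Encoder: L pre-norm transformer blocks — multi-head self-attention with a
residual connection, then a two-layer GELU MLP with a residual connection —
followed by a final layer-norm + MLP head.  Decoder: the token sequence is
layer-normalized, reshaped onto its patch grid, and passed through
configurable (nearest-upsample, 3x3 conv) stages ending in a single-channel
map of exactly the input size (linear head offset to mid-gray; inference
clips to [0, 1]).

All parameters live in one flat name -> Tensor dict, so checkpoints are a
single ``.npz`` archive holding every array plus the JSON-encoded config;
reloading reproduces outputs bit-identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, conv2d_same, upsample_nearest
from .dataio import ImageRecord, extract_patches
from .patch_encoder import (AttentionGate, GatedEmbedding, LinearPatchEmbedder,
                            PatchEncoderConfig, PositionalEmbedding,
                            sliding_box_query, _glorot)

__all__ = ["TEARConfig", "ModelState", "TEAR", "forward",
           "save_checkpoint", "load_checkpoint"]


def _balanced_factors(n: int, k: int = 3) -> tuple[int, ...]:
    """Split n into k integer factors, largest first (for decoder stages)."""
    primes = []
    m, p = n, 2
    while m > 1 and p * p <= n:
        while m % p == 0:
            primes.append(p)
            m //= p
        p += 1
    if m > 1:
        primes.append(m)
    factors = [1] * k
    for prime in sorted(primes, reverse=True):
        factors[int(np.argmin(factors))] *= prime
    return tuple(sorted(factors, reverse=True))


@dataclass(frozen=True)
class TEARConfig:
    """Architecture hyperparameters of the denoiser.

    The full-scale defaults follow the reference settings (depth 8, 8 heads,
    32-px patches); tests and the smoke pipeline use a scaled-down variant.
    """
    image_h: int = 256
    image_w: int = 256
    patch: int = 32
    embed_dim: int = 64
    depth: int = 8
    heads: int = 8
    mlp_hidden: int | None = None        # defaults to 2 * embed_dim
    decoder_stages: tuple[tuple[int, int], ...] | None = None
    #   ((filters, upsample_factor), ...); default three stages with
    #   filters (64, 32, 1) and factors multiplying to ``patch``
    use_attention_gate: bool = True
    gate_temperature: float = 1.0
    conv_filters: tuple[int, int] = (32, 64)
    seed: int = 0

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.embed_dim % self.heads:
            raise ValueError(
                f"heads ({self.heads}) must divide embed_dim ({self.embed_dim})")
        if self.image_h % self.patch or self.image_w % self.patch:
            raise ValueError("image size must be a multiple of the patch size")
        prod = int(np.prod([f for _, f in self.stages]))
        if prod != self.patch:
            raise ValueError(
                f"decoder upsample factors multiply to {prod}, but must "
                f"equal the patch size {self.patch} to restore the image")
        if self.stages[-1][0] != 1:
            raise ValueError("the final decoder stage must emit 1 channel")

    @property
    def stages(self) -> tuple[tuple[int, int], ...]:
        if self.decoder_stages is not None:
            return tuple(tuple(s) for s in self.decoder_stages)
        return tuple(zip((64, 32, 1), _balanced_factors(self.patch)))

    @property
    def mlp_width(self) -> int:
        return self.mlp_hidden if self.mlp_hidden else 2 * self.embed_dim

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (self.image_h // self.patch, self.image_w // self.patch)

    @property
    def n_patches(self) -> int:
        r, c = self.grid_shape
        return r * c

    def to_json(self) -> str:
        d = asdict(self)
        d["decoder_stages"] = list(map(list, self.stages))
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "TEARConfig":
        d = json.loads(s)
        d["decoder_stages"] = tuple(tuple(x) for x in d["decoder_stages"])
        d["conv_filters"] = tuple(d["conv_filters"])
        return cls(**d)


def smoke_config(seed: int = 0) -> TEARConfig:
    """The scaled-down architecture used by the end-to-end tests: 64x64
    B-scans, 8-px patches, 32-dim tokens, 2 blocks, 4 heads."""
    return TEARConfig(image_h=64, image_w=64, patch=8, embed_dim=32,
                      depth=2, heads=4,
                      decoder_stages=((32, 2), (16, 2), (1, 2)), seed=seed)


class _TransformerBlock:
    def __init__(self, d: int, heads: int, hidden: int,
                 rng: np.random.Generator, prefix: str):
        self.d, self.heads, self.dh = d, heads, d // heads
        self.prefix = prefix
        g = lambda *s: Tensor(_glorot(rng, *s), True)
        z = lambda *s: Tensor(np.zeros(s), True)
        o = lambda *s: Tensor(np.ones(s), True)
        self.params = {
            f"{prefix}.ln1_g": o(d), f"{prefix}.ln1_b": z(d),
            f"{prefix}.wq": g(d, d), f"{prefix}.wk": g(d, d),
            f"{prefix}.wv": g(d, d), f"{prefix}.wo": g(d, d),
            f"{prefix}.ln2_g": o(d), f"{prefix}.ln2_b": z(d),
            f"{prefix}.mlp_w1": g(d, hidden), f"{prefix}.mlp_b1": z(hidden),
            f"{prefix}.mlp_w2": g(hidden, d), f"{prefix}.mlp_b2": z(d),
        }

    def __call__(self, z: Tensor) -> Tensor:
        if not np.isfinite(z.data).all():
            raise FloatingPointError(
                f"non-finite activations entering {self.prefix}")
        p, pre = self.params, self.prefix
        b, n, d = z.shape
        h, dh = self.heads, self.dh
        x = z.layer_norm(p[f"{pre}.ln1_g"], p[f"{pre}.ln1_b"])
        q = (x @ p[f"{pre}.wq"]).reshape(b, n, h, dh).transpose(0, 2, 1, 3)
        k = (x @ p[f"{pre}.wk"]).reshape(b, n, h, dh).transpose(0, 2, 1, 3)
        v = (x @ p[f"{pre}.wv"]).reshape(b, n, h, dh).transpose(0, 2, 1, 3)
        att = ((q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))) \
            .softmax(axis=-1)
        heads_out = (att @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
        z = heads_out @ p[f"{pre}.wo"] + z
        x = z.layer_norm(p[f"{pre}.ln2_g"], p[f"{pre}.ln2_b"])
        x = (x @ p[f"{pre}.mlp_w1"] + p[f"{pre}.mlp_b1"]).gelu()
        return x @ p[f"{pre}.mlp_w2"] + p[f"{pre}.mlp_b2"] + z


class TEAR:
    """The full denoiser; construction is deterministic given the config."""

    def __init__(self, config: TEARConfig):
        self.config = config
        cfg = config
        rng = np.random.default_rng(cfg.seed)
        gate_cfg = PatchEncoderConfig(
            embed_dim=cfg.embed_dim, conv_filters=cfg.conv_filters,
            gate_temperature=cfg.gate_temperature)
        if cfg.use_attention_gate:
            self.encoder_front = AttentionGate(
                cfg.patch, gate_cfg, seed=int(rng.integers(2 ** 31)))
        else:
            self.encoder_front = LinearPatchEmbedder(
                cfg.patch, cfg.embed_dim, seed=int(rng.integers(2 ** 31)))
        self.positions = PositionalEmbedding(
            cfg.n_patches, cfg.embed_dim, seed=int(rng.integers(2 ** 31)))
        self.blocks = [
            _TransformerBlock(cfg.embed_dim, cfg.heads, cfg.mlp_width,
                              rng, f"block{i}")
            for i in range(cfg.depth)]
        d = cfg.embed_dim
        g = lambda *s: Tensor(_glorot(rng, *s), True)
        z = lambda *s: Tensor(np.zeros(s), True)
        o = lambda *s: Tensor(np.ones(s), True)
        self.head_params = {
            "head.ln_g": o(d), "head.ln_b": z(d),
            "head.w1": g(d, cfg.mlp_width), "head.b1": z(cfg.mlp_width),
            "head.w2": g(cfg.mlp_width, d), "head.b2": z(d),
        }
        dec: dict[str, Tensor] = {"dec.ln_g": o(d), "dec.ln_b": z(d)}
        in_ch = d
        for i, (filters, _) in enumerate(cfg.stages):
            dec[f"dec.conv{i}_w"] = Tensor(
                _glorot(rng, filters, in_ch, 3, 3), True)
            dec[f"dec.conv{i}_b"] = Tensor(np.zeros(filters), True)
            in_ch = filters
        self.decoder_params = dec

    # -- parameter plumbing ------------------------------------------------
    @property
    def params(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        out.update(self.encoder_front.params)
        out.update(self.positions.params)
        for blk in self.blocks:
            out.update(blk.params)
        out.update(self.head_params)
        out.update(self.decoder_params)
        return out

    @property
    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.params.values())

    # -- forward pieces ------------------------------------------------------
    def embed_image(self, pixels: np.ndarray) -> GatedEmbedding:
        grid = extract_patches(pixels, self.config.patch)
        if self.config.use_attention_gate:
            queries = sliding_box_query(pixels, self.config.patch)
            return self.encoder_front(grid, queries)
        return self.encoder_front(grid)

    def transformer_block(self, z: Tensor, block_index: int) -> Tensor:
        """Apply one encoder block to an (N, D) or (B, N, D) sequence."""
        squeeze = z.ndim == 2
        if squeeze:
            z = z.reshape(1, *z.shape)
        try:
            out = self.blocks[block_index](z)
        except FloatingPointError as exc:
            raise FloatingPointError(
                f"block {block_index}: {exc}") from None
        return out.reshape(out.shape[1:]) if squeeze else out

    def encode(self, z0: Tensor) -> Tensor:
        """Run all transformer blocks, then the final LN + MLP head."""
        z = z0.reshape(1, *z0.shape) if z0.ndim == 2 else z0
        for blk in self.blocks:
            z = blk(z)
        p = self.head_params
        x = z.layer_norm(p["head.ln_g"], p["head.ln_b"])
        x = (x @ p["head.w1"] + p["head.b1"]).gelu()
        x = x @ p["head.w2"] + p["head.b2"]
        return x.reshape(x.shape[1:]) if z0.ndim == 2 else x

    def decode(self, z_l: Tensor) -> Tensor:
        """Tokens -> image(s): LN, reshape onto the patch grid, then the
        conv/upsample stages, ending in a linear single-channel map offset
        to mid-gray.  The head is deliberately unsquashed — a saturating
        output starves near-black OCT backgrounds of gradient and they can
        never recover (see the methods note); inference clips to [0, 1]."""
        cfg = self.config
        squeeze = z_l.ndim == 2
        if squeeze:
            z_l = z_l.reshape(1, *z_l.shape)
        p = self.decoder_params
        x = z_l.layer_norm(p["dec.ln_g"], p["dec.ln_b"])
        b = x.shape[0]
        rows, cols = cfg.grid_shape
        x = x.reshape(b, rows, cols, cfg.embed_dim).transpose(0, 3, 1, 2)
        n_stages = len(cfg.stages)
        for i, (filters, factor) in enumerate(cfg.stages):
            x = upsample_nearest(x, factor)
            x = conv2d_same(x, p[f"dec.conv{i}_w"], p[f"dec.conv{i}_b"],
                            stride=1)
            x = (x + 0.5) if i == n_stages - 1 else x.gelu()
        x = x.reshape(b, cfg.image_h, cfg.image_w)
        return x.reshape(cfg.image_h, cfg.image_w) if squeeze else x

    def forward_batch(self, images: list[np.ndarray]) -> Tensor:
        """Differentiable forward pass over a list of (H, W) arrays;
        returns a (B, H, W) tensor."""
        cfg = self.config
        grids = [extract_patches(px, cfg.patch) for px in images]
        if cfg.use_attention_gate:
            queries = [sliding_box_query(px, cfg.patch) for px in images]
            gated = self.encoder_front.forward_batch(grids, queries)
        else:
            gated = self.encoder_front.forward_batch(grids)
        z0 = self.positions(gated)
        return self.decode(self.encode(z0))

    def forward(self, noisy: ImageRecord | np.ndarray) -> np.ndarray:
        """Denoise one image (no gradients retained); output in [0, 1]."""
        px = noisy.pixels if isinstance(noisy, ImageRecord) else \
            np.asarray(noisy, dtype=np.float64)
        h, w = px.shape
        if (h, w) != (self.config.image_h, self.config.image_w):
            raise ValueError(
                f"expected a {self.config.image_h}x{self.config.image_w} "
                f"image, got {h}x{w}; resize upstream")
        return np.clip(self.forward_batch([px]).data[0], 0.0, 1.0)


@dataclass
class ModelState:
    """A trained (or initialized) model plus its training history."""
    model: TEAR
    train_history: list = field(default_factory=list)

    @property
    def config(self) -> TEARConfig:
        return self.model.config


def forward(noisy: ImageRecord | np.ndarray, state: ModelState) -> ImageRecord:
    """Denoise one image with a trained model."""
    out = state.model.forward(noisy)
    name = noisy.id if isinstance(noisy, ImageRecord) else "image"
    return ImageRecord(id=f"{name}_denoised", pixels=out)


def save_checkpoint(state: ModelState, path: str | Path) -> None:
    """Single-archive checkpoint: every parameter array plus the config and
    training history as JSON."""
    arrays = {k: v.data for k, v in state.model.params.items()}
    meta = {"config": json.loads(state.config.to_json()),
            "train_history": state.train_history}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> ModelState:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        cfg = TEARConfig.from_json(json.dumps(meta["config"]))
        model = TEAR(cfg)
        params = model.params
        for k, p in params.items():
            p.data = archive[k].copy()
    return ModelState(model=model, train_history=meta["train_history"])
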