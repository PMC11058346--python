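"""Attention-gated patch encoding.

Each non-overlapping P x P patch of the B-scan is embedded to a D-vector;
in parallel, overlapping "sliding box" query windows (stride P/2) are
embedded by a second map.  A scaled-dot-product score between each patch
embedding and its spatially nearest query embedding, normalized by a
softmax over all patches of the image, measures how much foreground content
the patch carries.  The gate weight ``g_i = clip(N * s_i, 0, 1)`` (1 for a
perfectly uniform image) multiplies the patch embedding, suppressing
background patches while staying differentiable almost everywhere — a soft
realization of hard-thresholding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, conv2d_same
from .dataio import ImageRecord, PatchGrid, extract_patches

__all__ = ["PatchEncoderConfig", "GatedEmbedding", "sliding_box_query",
           "PatchConvEmbedder", "AttentionGate", "PositionalEmbedding",
           "LinearPatchEmbedder"]


@dataclass(frozen=True)
class PatchEncoderConfig:
    embed_dim: int = 64
    conv_filters: tuple[int, int] = (32, 64)
    conv_kernel: int = 3
    conv_stride: int = 3
    gate_temperature: float = 1.0
    shared_embedder: bool = False   # one map E for input and query paths

    def __post_init__(self):
        if self.embed_dim < 8:
            raise ValueError("embed_dim must be at least 8")
        if min(self.conv_filters) < 1:
            raise ValueError("conv filter counts must be positive")
        if self.gate_temperature <= 0:
            raise ValueError("gate_temperature must be positive")


@dataclass
class GatedEmbedding:
    """Gated patch embeddings plus the diagnostic score/gate vectors."""
    embeddings: Tensor                    # (N, D) or (B, N, D)
    gate_weights: np.ndarray              # (..., N) in [0, 1]
    attention_scores: np.ndarray          # (..., N), sums to 1 per image
    grid_shape: tuple[int, int]


def sliding_box_query(image: ImageRecord | np.ndarray,
                      patch: int) -> PatchGrid:
    """Overlapping P x P query boxes at stride P/2 over the image.

    The image must already tile exactly into P x P patches (the same
    precondition as :func:`tear.dataio.extract_patches`); P must be even.
    """
    px = image.pixels if isinstance(image, ImageRecord) else np.asarray(image)
    h, w = px.shape
    if patch > min(h, w):
        raise ValueError(f"patch size {patch} exceeds image {px.shape}")
    if patch % 2:
        raise ValueError("sliding-box queries need an even patch size")
    stride = patch // 2
    if h % patch or w % patch:
        grid = extract_patches(px, patch)
        px = np.pad(px, ((0, grid.pad[0]), (0, grid.pad[1])), mode="edge")
        h, w = px.shape
    rows = (h - patch) // stride + 1
    cols = (w - patch) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(px, (patch, patch))
    win = win[::stride, ::stride]
    return PatchGrid(patches=win.reshape(rows * cols, patch * patch),
                     grid_shape=(rows, cols), patch=patch)


def _glorot(rng: np.random.Generator, *shape: int) -> np.ndarray:
    fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
    fan_out = shape[0]
    scale = math.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=shape)


class PatchConvEmbedder:
    """linear map (P^2 -> P^2) -> conv(32, k3, s3) -> conv(64, k3, s3)
    -> flatten -> linear -> D, the embedding tower ``E``."""

    def __init__(self, patch: int, cfg: PatchEncoderConfig,
                 rng: np.random.Generator, prefix: str):
        self.patch = patch
        self.cfg = cfg
        f1, f2 = cfg.conv_filters
        k, s = cfg.conv_kernel, cfg.conv_stride
        n1 = -(-patch // s)          # ceil-mode output of each conv stage
        n2 = -(-n1 // s)
        p2 = patch * patch
        self.params: dict[str, Tensor] = {
            f"{prefix}.lin0_w": Tensor(_glorot(rng, p2, p2), True),
            f"{prefix}.lin0_b": Tensor(np.zeros(p2), True),
            f"{prefix}.conv1_w": Tensor(_glorot(rng, f1, 1, k, k), True),
            f"{prefix}.conv1_b": Tensor(np.zeros(f1), True),
            f"{prefix}.conv2_w": Tensor(_glorot(rng, f2, f1, k, k), True),
            f"{prefix}.conv2_b": Tensor(np.zeros(f2), True),
            f"{prefix}.proj_w": Tensor(
                _glorot(rng, f2 * n2 * n2, cfg.embed_dim), True),
            f"{prefix}.proj_b": Tensor(np.zeros(cfg.embed_dim), True),
        }
        self.prefix = prefix

    def __call__(self, patches: Tensor) -> Tensor:
        """patches: (M, P*P) -> embeddings (M, D)."""
        p = self.params
        pre = self.prefix
        m = patches.shape[0]
        x = patches @ p[f"{pre}.lin0_w"] + p[f"{pre}.lin0_b"]
        x = x.reshape(m, 1, self.patch, self.patch)
        x = conv2d_same(x, p[f"{pre}.conv1_w"], p[f"{pre}.conv1_b"],
                        stride=self.cfg.conv_stride).gelu()
        x = conv2d_same(x, p[f"{pre}.conv2_w"], p[f"{pre}.conv2_b"],
                        stride=self.cfg.conv_stride).gelu()
        x = x.reshape(m, x.data[0].size)
        return x @ p[f"{pre}.proj_w"] + p[f"{pre}.proj_b"]


class AttentionGate:
    """Scores patches against their nearest sliding-box query and gates the
    patch embeddings by ``clip(N * softmax_score, 0, 1)``."""

    def __init__(self, patch: int, cfg: PatchEncoderConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.input_embed = PatchConvEmbedder(patch, cfg, rng, "gate.input")
        if cfg.shared_embedder:
            self.query_embed = self.input_embed
        else:
            self.query_embed = PatchConvEmbedder(patch, cfg, rng, "gate.query")

    @property
    def params(self) -> dict[str, Tensor]:
        d = dict(self.input_embed.params)
        d.update(self.query_embed.params)
        return d

    @staticmethod
    def nearest_query_indices(patch_grid: tuple[int, int],
                              query_grid: tuple[int, int]) -> np.ndarray:
        """Flat index of the stride-P/2 query box centred on each patch."""
        pr, pc = patch_grid
        qr, qc = query_grid
        rows = np.minimum(2 * np.arange(pr), qr - 1)
        cols = np.minimum(2 * np.arange(pc), qc - 1)
        return (rows[:, None] * qc + cols[None, :]).reshape(-1)

    def __call__(self, input_grid: PatchGrid,
                 query_grid: PatchGrid) -> GatedEmbedding:
        g = self.forward_batch([input_grid], [query_grid])
        n, d = input_grid.n_patches, self.cfg.embed_dim
        return GatedEmbedding(embeddings=g.embeddings.reshape(n, d),
                              gate_weights=g.gate_weights[0],
                              attention_scores=g.attention_scores[0],
                              grid_shape=input_grid.grid_shape)

    def forward_batch(self, input_grids: list[PatchGrid],
                      query_grids: list[PatchGrid]) -> GatedEmbedding:
        """Gate a whole minibatch at once; embeddings come out (B, N, D)
        with the score softmax taken per image."""
        g0, q0 = input_grids[0], query_grids[0]
        for gi, qi in zip(input_grids, query_grids):
            if gi.patch != qi.patch:
                raise ValueError(
                    f"patch size mismatch: input {gi.patch}, query {qi.patch}")
            if gi.grid_shape != g0.grid_shape or qi.grid_shape != q0.grid_shape:
                raise ValueError("all grids in a batch must share a shape")
        b = len(input_grids)
        n = g0.n_patches
        d = self.cfg.embed_dim
        idx = self.nearest_query_indices(g0.grid_shape, q0.grid_shape)
        patches = np.concatenate([g.patches for g in input_grids])
        qpatches = np.concatenate([q.patches[idx] for q in query_grids])
        keys = self.input_embed(Tensor(patches))       # (B*N, D)
        queries = self.query_embed(Tensor(qpatches))   # (B*N, D)
        logits = ((keys * queries).sum(axis=1)
                  * (1.0 / (math.sqrt(d) * self.cfg.gate_temperature))
                  ).reshape(b, n)
        scores = logits.softmax(axis=-1)               # (B, N)
        gates = (scores * float(n)).clip(0.0, 1.0)
        gated = keys.reshape(b, n, d) * gates.reshape(b, n, 1)
        return GatedEmbedding(embeddings=gated,
                              gate_weights=gates.data.copy(),
                              attention_scores=scores.data.copy(),
                              grid_shape=g0.grid_shape)


class LinearPatchEmbedder:
    """The ungated ViT path: a plain learned linear map P^2 -> D, used when
    the attention gate is ablated away."""

    def __init__(self, patch: int, embed_dim: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.params = {
            "embed.w": Tensor(_glorot(rng, patch * patch, embed_dim), True),
            "embed.b": Tensor(np.zeros(embed_dim), True),
        }

    def __call__(self, grid: PatchGrid) -> GatedEmbedding:
        n = grid.n_patches
        emb = Tensor(grid.patches) @ self.params["embed.w"] \
            + self.params["embed.b"]
        ones = np.ones(n)
        return GatedEmbedding(embeddings=emb, gate_weights=ones,
                              attention_scores=ones / n,
                              grid_shape=grid.grid_shape)

    def forward_batch(self, grids: list[PatchGrid]) -> GatedEmbedding:
        b, n = len(grids), grids[0].n_patches
        patches = np.concatenate([g.patches for g in grids])
        emb = Tensor(patches) @ self.params["embed.w"] + self.params["embed.b"]
        ones = np.ones((b, n))
        return GatedEmbedding(
            embeddings=emb.reshape(b, n, self.params["embed.b"].shape[0]),
            gate_weights=ones, attention_scores=ones / n,
            grid_shape=grids[0].grid_shape)


class PositionalEmbedding:
    """A learned N x D positional table added to the token sequence."""

    def __init__(self, n_patches: int, embed_dim: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.params = {"pos.table": Tensor(
            rng.normal(0.0, 0.02, size=(n_patches, embed_dim)), True)}

    def __call__(self, g: GatedEmbedding) -> Tensor:
        table = self.params["pos.table"]
        if g.embeddings.shape[-2:] != table.shape:
            raise ValueError(
                f"sequence shape {g.embeddings.shape} does not match the "
                f"positional table {table.shape}")
        return g.embeddings + table


def add_positions(g: GatedEmbedding, table: PositionalEmbedding) -> Tensor:
    """Functional alias for applying a positional table to gated tokens."""
    return table(g)
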