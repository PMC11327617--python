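"""Self-supervised 3D vision-transformer encoder.

The encoder is pretrained on unlabeled multi-channel volumes with two proxy
tasks and is then frozen for the downstream survival model:

* **context restoration** — each volume is corrupted by random patch
  swapping and cutout, and a linear unpatchify head must reconstruct the
  original intensities (mean-absolute-error objective);
* **contrastive learning** — two independently corrupted views of the same
  volume must project to nearby points on the unit sphere while views of
  different volumes are pushed apart (NT-Xent objective on cosine
  similarities).

The two losses are combined either additively (rec + λ·con) or, by default,
with the contrastive term acting as a multiplicative regularizer of the
reconstruction term (rec + λ·con·rec); single-task modes are available for
ablations.

Patch-swap blocks coincide with the tokenizer patch size, keeping the
corruption aligned with what a single token sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .autodiff import Tensor, no_grad
from .nn import MLP, Adam, LayerNorm, Linear, Module, MultiHeadAttention, Parameter

__all__ = [
    "ViTConfig",
    "ViT3D",
    "patchify",
    "unpatchify",
    "augment_view",
    "apply_alterations",
    "reconstruction_loss",
    "contrastive_loss",
    "combined_ssl_loss",
    "pretrain",
    "pooled_embeddings",
    "lesion_probe_r2",
]

LossMode = Literal["additive", "product_regularized", "contrastive_only", "reconstruction_only"]


@dataclass
class ViTConfig:
    patch_size: tuple[int, int, int] = (8, 8, 8)
    embed_dim: int = 32
    depth: int = 2
    n_heads: int = 4
    mlp_ratio: float = 2.0
    projection_dim: int = 16
    temperature: float = 0.1
    loss_mode: LossMode = "product_regularized"
    lambda_con: float = 1.0
    n_channels: int = 4

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.lambda_con < 0:
            raise ValueError("lambda_con must be nonnegative")

    @property
    def token_dim(self) -> int:
        return self.n_channels * int(np.prod(self.patch_size))


# ------------------------------------------------------------- tokenization


def _as_array(stack) -> np.ndarray:
    data = stack.data if hasattr(stack, "data") else stack
    return np.asarray(data)


def patchify(stack, patch_size) -> np.ndarray:
    """Split a (C, X, Y, Z) volume into non-overlapping patch tokens.

    Tokens are ordered C-contiguously over the block grid (x-major raster);
    each token is the (C, p, p, p) block flattened in C order.  Returns
    (n_tokens, C·∏patch).
    """
    data = _as_array(stack)
    C, X, Y, Z = data.shape
    px, py, pz = patch_size
    if X % px or Y % py or Z % pz:
        raise ValueError(f"volume shape {(X, Y, Z)} not divisible by patch {patch_size}")
    nx, ny, nz = X // px, Y // py, Z // pz
    t = data.reshape(C, nx, px, ny, py, nz, pz)
    t = t.transpose(1, 3, 5, 0, 2, 4, 6)  # (nx, ny, nz, C, px, py, pz)
    return t.reshape(nx * ny * nz, C * px * py * pz)


def unpatchify(tokens, volume_shape, patch_size) -> np.ndarray:
    """Inverse of :func:`patchify`: tokens back to a (C, X, Y, Z) volume."""
    tokens = np.asarray(tokens)
    C, X, Y, Z = volume_shape
    px, py, pz = patch_size
    nx, ny, nz = X // px, Y // py, Z // pz
    t = tokens.reshape(nx, ny, nz, C, px, py, pz)
    t = t.transpose(3, 0, 4, 1, 5, 2, 6)
    return t.reshape(C, X, Y, Z)


# ------------------------------------------------------------- augmentation


def augment_view(stack, n_swaps: int, cutout, rng, block=(8, 8, 8)):
    """One corrupted view: swap ``n_swaps`` disjoint aligned block pairs,
    then zero ``cutout = (count, max_extent)`` random boxes.

    Returns (augmented array, alteration_log).  Replaying a swap log twice
    restores the original volume; the log records every choice made.
    """
    data = _as_array(stack).copy()
    _, X, Y, Z = data.shape
    bx, by, bz = block
    grid = [(i, j, k) for i in range(X // bx) for j in range(Y // by) for k in range(Z // bz)]
    if n_swaps < 0:
        raise ValueError("n_swaps must be nonnegative")
    if 2 * n_swaps > len(grid):
        raise ValueError("not enough disjoint blocks for the requested swaps")
    log: list[tuple] = []
    if n_swaps > 0:
        chosen = rng.choice(len(grid), size=2 * n_swaps, replace=False)
        for a, b in zip(chosen[:n_swaps], chosen[n_swaps:]):
            log.append(("swap", grid[a], grid[b], block))
    count, max_extent = cutout
    for _ in range(count):
        ext = tuple(int(rng.integers(1, m + 1)) for m in np.broadcast_to(max_extent, (3,)))
        if any(e > s for e, s in zip(ext, (X, Y, Z))):
            raise ValueError("cutout extent exceeds the volume")
        corner = tuple(int(rng.integers(0, s - e + 1)) for s, e in zip((X, Y, Z), ext))
        log.append(("cutout", corner, ext))
    apply_alterations(data, log)
    return data, log


def apply_alterations(data: np.ndarray, log) -> np.ndarray:
    """Replay an alteration log in place (swap entries are involutions)."""
    for entry in log:
        if entry[0] == "swap":
            _, (ai, aj, ak), (bi, bj, bk), (bx, by, bz) = entry
            sa = (slice(None), slice(ai * bx, (ai + 1) * bx),
                  slice(aj * by, (aj + 1) * by), slice(ak * bz, (ak + 1) * bz))
            sb = (slice(None), slice(bi * bx, (bi + 1) * bx),
                  slice(bj * by, (bj + 1) * by), slice(bk * bz, (bk + 1) * bz))
            tmp = data[sa].copy()
            data[sa] = data[sb]
            data[sb] = tmp
        elif entry[0] == "cutout":
            _, (cx, cy, cz), (ex, ey, ez) = entry
            data[:, cx : cx + ex, cy : cy + ey, cz : cz + ez] = 0.0
        else:
            raise ValueError(f"unknown alteration {entry[0]!r}")
    return data


# ------------------------------------------------------------------- losses


def reconstruction_loss(decoded, original):
    """Mean absolute voxel error over the full volume (works on numpy arrays
    or autodiff tensors; token and voxel layouts give the same mean)."""
    if isinstance(decoded, Tensor) or isinstance(original, Tensor):
        d = decoded if isinstance(decoded, Tensor) else Tensor(np.asarray(decoded))
        o = original if isinstance(original, Tensor) else Tensor(np.asarray(original))
        if d.shape != o.shape:
            raise ValueError("shape mismatch")
        return (d - o).abs().mean()
    d, o = np.asarray(decoded), np.asarray(original)
    if d.shape != o.shape:
        raise ValueError("shape mismatch")
    return float(np.mean(np.abs(d - o)))


def contrastive_loss(z, temperature: float = 0.1):
    """NT-Xent over 2N projected view embeddings.

    Rows [0..N) and [N..2N) are the two views of the same N subjects, so the
    positive of anchor i is i±N.  Cosine similarities are divided by the
    temperature; each anchor's loss is −log of the softmax mass on its
    positive over all 2N−1 non-self entries.  Under embedding collapse the
    loss equals log(2N−1), which is used as a collapse detector.
    """
    is_tensor = isinstance(z, Tensor)
    zt = z if is_tensor else Tensor(np.asarray(z, dtype=float))
    two_n = zt.shape[0]
    if two_n < 4 or two_n % 2:
        raise ValueError("need an even number >= 4 of view embeddings")
    norms = np.linalg.norm(zt.data, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-norm embedding")
    zn = zt / (zt * zt).sum(axis=1, keepdims=True).sqrt()
    sim = (zn @ zn.swapaxes(0, 1)) * (1.0 / temperature)
    sim = sim + Tensor(np.diag(np.full(two_n, -1e9)))  # exclude self-similarity
    n = two_n // 2
    pos = np.concatenate([np.arange(n) + n, np.arange(n)])
    lse = sim.logsumexp(axis=1)
    loss = (lse - sim[np.arange(two_n), pos]).mean()
    return loss if is_tensor else float(loss.item())


def combined_ssl_loss(rec, con, mode: LossMode = "product_regularized", lambda_con: float = 1.0):
    """Combine the two proxy-task losses.

    ``additive``: rec + λ·con; ``product_regularized``: rec + λ·con·rec
    (the contrastive term scales the reconstruction term); single-loss modes
    pass the respective term through.
    """
    if mode == "reconstruction_only":
        return rec
    if mode == "contrastive_only":
        return con
    if mode == "additive":
        return rec + lambda_con * con
    if mode == "product_regularized":
        return rec + lambda_con * con * rec
    raise ValueError(f"unknown loss mode {mode!r}")


# ------------------------------------------------------------------ encoder


class _Block(Module):
    def __init__(self, dim: int, n_heads: int, mlp_ratio: float, rng):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = MLP(dim, int(dim * mlp_ratio), dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.norm1(x)
        x = x + self.attn(h, h)
        x = x + self.mlp(self.norm2(x))
        return x


class ViT3D(Module):
    """Small 3D vision transformer with a linear unpatchify decoder and a
    projection head for the contrastive task."""

    def __init__(self, config: ViTConfig, n_tokens: int, rng: np.random.Generator):
        self.config = config
        self.n_tokens = n_tokens
        d = config.embed_dim
        self.patch_embed = Linear(config.token_dim, d, rng)
        self.pos = Parameter(rng.normal(scale=0.02, size=(n_tokens, d)))
        self.blocks = [_Block(d, config.n_heads, config.mlp_ratio, rng) for _ in range(config.depth)]
        self.final_norm = LayerNorm(d)
        self.decoder = Linear(d, config.token_dim, rng)
        self.proj = MLP(d, d, config.projection_dim, rng)
        self.trained = False

    # tokens: (B, n_tokens, token_dim) Tensor or array
    def forward_tokens(self, tokens) -> Tensor:
        x = tokens if isinstance(tokens, Tensor) else Tensor(np.asarray(tokens, dtype=float))
        x = self.patch_embed(x) + self.pos
        for blk in self.blocks:
            x = blk(x)
        return self.final_norm(x)

    def decode_tokens(self, encoded: Tensor) -> Tensor:
        return self.decoder(encoded)

    def project(self, encoded: Tensor) -> Tensor:
        return self.proj(encoded.mean(axis=-2))

    def encode(self, stack, allow_untrained: bool = False) -> np.ndarray:
        """Frozen-path encoding of one volume to a (n_tokens, embed_dim)
        array.  Refuses to run untrained unless explicitly allowed (for
        random-encoder baselines)."""
        if not self.trained and not allow_untrained:
            raise RuntimeError(
                "encoder has not been pretrained; pass allow_untrained=True "
                "for an explicitly random-initialized baseline"
            )
        tokens = patchify(stack, self.config.patch_size)
        with no_grad():
            out = self.forward_tokens(tokens[None, :, :])
        return out.data[0]


# --------------------------------------------------------------- pretraining


def pretrain(
    volumes,
    config: ViTConfig,
    epochs: int = 30,
    batch_size: int = 8,
    lr: float = 1e-3,
    n_swaps: int = 4,
    cutout=(2, 6),
    seed: int = 0,
    log: list | None = None,
) -> ViT3D:
    """Two-view self-supervised pretraining on a stack of volumes.

    ``volumes`` is (n, C, X, Y, Z).  Each step corrupts every volume twice,
    reconstructs the clean volume from each view, computes the NT-Xent loss
    on the pooled projections of the two views, and follows the combined
    objective of ``config.loss_mode``.  Returns the trained encoder with
    ``trained=True``; per-epoch means are appended to ``log`` if given.
    """
    vols = np.asarray(volumes, dtype=np.float32)
    n, C = vols.shape[:2]
    shape = vols.shape[1:]
    rng = np.random.default_rng(seed)
    n_tokens = patchify(vols[0], config.patch_size).shape[0]
    model = ViT3D(config, n_tokens, rng)
    clean_tokens = np.stack([patchify(v, config.patch_size) for v in vols])
    opt = Adam(model.parameters(), lr=lr)

    for epoch in range(epochs):
        order = rng.permutation(n)
        ep_rec, ep_con, n_steps = 0.0, 0.0, 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            if idx.size < 2:
                continue  # NT-Xent needs at least two subjects
            views = []
            for v_i in range(2):
                toks = np.empty((idx.size, n_tokens, config.token_dim))
                for row, i in enumerate(idx):
                    aug, _ = augment_view(
                        vols[i], n_swaps, cutout, rng, block=config.patch_size
                    )
                    toks[row] = patchify(aug, config.patch_size)
                views.append(Tensor(toks))
            target = Tensor(clean_tokens[idx])
            enc1 = model.forward_tokens(views[0])
            enc2 = model.forward_tokens(views[1])
            rec = 0.5 * (
                reconstruction_loss(model.decode_tokens(enc1), target)
                + reconstruction_loss(model.decode_tokens(enc2), target)
            )
            z = Tensor.concatenate([model.project(enc1), model.project(enc2)], axis=0)
            con = contrastive_loss(z, config.temperature)
            loss = combined_ssl_loss(rec, con, config.loss_mode, config.lambda_con)
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_rec += float(rec.item())
            ep_con += float(con.item())
            n_steps += 1
        if log is not None:
            log.append(
                {
                    "epoch": epoch,
                    "reconstruction": ep_rec / max(n_steps, 1),
                    "contrastive": ep_con / max(n_steps, 1),
                }
            )
    model.trained = True
    return model


# -------------------------------------------------------------------- probes


def pooled_embeddings(model: ViT3D, volumes, allow_untrained: bool = False) -> np.ndarray:
    """Mean-pooled frozen embeddings, one row per volume."""
    return np.stack(
        [model.encode(v, allow_untrained=allow_untrained).mean(axis=0) for v in volumes]
    )


def lesion_probe_r2(model: ViT3D, volumes, targets, seed: int = 0,
                    allow_untrained: bool = False) -> float:
    """Held-out R² of an ordinary-least-squares readout of the pooled
    embedding predicting a per-volume scalar (e.g. lesion volume fraction).
    Half the volumes fit the probe, the other half evaluate it."""
    E = pooled_embeddings(model, volumes, allow_untrained=allow_untrained)
    y = np.asarray(targets, dtype=float)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    half = len(y) // 2
    tr, te = order[:half], order[half:]
    A = np.column_stack([E, np.ones(len(y))])
    coef, *_ = np.linalg.lstsq(A[tr], y[tr], rcond=None)
    pred = A[te] @ coef
    ss_res = float(((y[te] - pred) ** 2).sum())
    ss_tot = float(((y[te] - y[te].mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot
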