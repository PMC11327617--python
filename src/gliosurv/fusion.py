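"""Cross-attention fusion of frozen image embeddings with clinical data.

The fusion stage follows the attention recipe α̂ = softmax(QαKβᵀ/√d_k)Vβ
applied twice — once with the image sequence as query against the clinical
sequence, once the other way around, with independent projection weights per
direction — followed by a final attention layer whose keys and values are
the concatenation of both enriched sequences and whose query is the raw
clinical projection (the nonimaging modality empirically carries more
prognostic signal, so it steers the final read-out).  Attention pooling with
a learned query collapses the result to one vector, and two fully connected
layers emit the discrete-survival logits.

A clinical-only configuration swaps cross-attention for self-attention
(α = β = clinical sequence) so the model runs with no imaging input at all;
an imaging-only configuration does the symmetric thing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .autodiff import Tensor, no_grad
from .nn import MLP, LayerNorm, Linear, Module, MultiHeadAttention, Parameter

__all__ = [
    "FusionConfig",
    "ClinicalEncoder",
    "CrossAttentionBlock",
    "AttentionPool",
    "SurvivalTransformer",
    "Modality",
]

Modality = Literal["multimodal", "clinical", "imaging"]


@dataclass
class FusionConfig:
    embed_dim: int = 32
    n_heads: int = 4
    clin_tokens: int = 4  # length of the clinical token sequence L_c
    img_dim: int = 32  # embedding dim of the frozen image encoder
    n_img_tokens: int = 64
    n_bins: int = 5
    modality: Modality = "multimodal"
    hidden: int = 32  # width of the prediction head's hidden layer

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")

    @property
    def n_outputs(self) -> int:
        # K·T_bins + 1: single event over the grid bins plus beyond-horizon
        return self.n_bins + 1


class ClinicalEncoder(Module):
    """Fully connected module mapping the encoded covariate vector to a short
    token sequence (L_c, embed_dim), trained end-to-end."""

    def __init__(self, d_in: int, n_tokens: int, dim: int, rng):
        self.n_tokens = n_tokens
        self.dim = dim
        self.fc1 = Linear(d_in, n_tokens * dim, rng)
        self.fc2 = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        if not np.all(np.isfinite(x.data)):
            raise ValueError("covariates must be finite (encode missing values first)")
        B = x.shape[0]
        h = self.fc1(x).gelu().reshape(B, self.n_tokens, self.dim)
        return self.fc2(h)


class CrossAttentionBlock(Module):
    """Pre-norm cross-attention with residual connection and feed-forward;
    queries from ``alpha``, keys/values from ``beta``."""

    def __init__(self, dim: int, n_heads: int, rng, mlp_ratio: float = 2.0):
        self.norm_q = LayerNorm(dim)
        self.norm_kv = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = MLP(dim, int(dim * mlp_ratio), dim, rng)

    def __call__(self, alpha: Tensor, beta: Tensor) -> Tensor:
        h = alpha + self.attn(self.norm_q(alpha), self.norm_kv(beta))
        return h + self.mlp(self.norm2(h))


class AttentionPool(Module):
    """Learned-query attention pooling: a single query attends over the
    sequence; the output is a convex combination of the value projections."""

    def __init__(self, dim: int, rng):
        self.query = Parameter(rng.normal(scale=0.02, size=(1, dim)))
        self.w_k = Linear(dim, dim, rng, bias=False)
        self.w_v = Linear(dim, dim, rng, bias=False)
        self.d_k = dim

    def __call__(self, seq: Tensor) -> Tensor:
        if seq.shape[-2] == 0:
            raise ValueError("cannot pool an empty sequence")
        k = self.w_k(seq)
        v = self.w_v(seq)
        scores = (self.query @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_k))
        attn = scores.softmax(axis=-1)  # (..., 1, L)
        out = attn @ v
        return out.reshape(*out.shape[:-2], out.shape[-1])

    def weights(self, seq: Tensor) -> np.ndarray:
        k = self.w_k(seq)
        scores = (self.query @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_k))
        return scores.softmax(axis=-1).data


class SurvivalTransformer(Module):
    """Cross-attention survival model over (frozen image tokens, covariates).

    Forward contract: ``img_seq`` is a constant (B, n_img_tokens, img_dim)
    array from the frozen encoder (ignored for the clinical-only modality),
    ``x_clin`` a finite (B, d_clin) covariate matrix.  Output is the logit
    matrix (B, n_bins + 1) feeding the discrete-survival softmax.
    """

    def __init__(self, config: FusionConfig, d_clin: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        d = config.embed_dim
        self.clinical_encoder = ClinicalEncoder(d_clin, config.clin_tokens, d, rng)
        if config.modality != "clinical":
            self.img_proj = Linear(config.img_dim, d, rng)
            self.img_pos = Parameter(
                rng.normal(scale=0.02, size=(config.n_img_tokens, d))
            )
            self.cross_img = CrossAttentionBlock(d, config.n_heads, rng)
        self.cross_clin = CrossAttentionBlock(d, config.n_heads, rng)
        self.final_attn = CrossAttentionBlock(d, config.n_heads, rng)
        self.pool = AttentionPool(d, rng)
        self.head1 = Linear(d, config.hidden, rng)
        self.head2 = Linear(config.hidden, config.n_outputs, rng)

    # ------------------------------------------------------------ components
    def embed_images(self, img_seq) -> Tensor:
        """Project frozen encoder tokens into the fusion width and add the
        learned positional term (images only; the clinical sequence is
        position-free)."""
        x = img_seq if isinstance(img_seq, Tensor) else Tensor(np.asarray(img_seq, dtype=float))
        return self.img_proj(x) + self.img_pos

    def bidirectional_fusion(self, img_seq: Tensor, clin_seq: Tensor) -> tuple[Tensor, Tensor]:
        """Cross-attention applied twice with independent parameters:
        image tokens enriched by the clinical sequence and vice versa."""
        img_hat = self.cross_img(img_seq, clin_seq)
        clin_hat = self.cross_clin(clin_seq, img_seq)
        return img_hat, clin_hat

    def final_attention(self, img_hat: Tensor, clin_hat: Tensor, clin_proj: Tensor) -> Tensor:
        """Concatenate the enriched sequences along the sequence axis as
        keys/values; the clinical projection is the query."""
        kv = Tensor.concatenate([img_hat, clin_hat], axis=-2)
        return self.final_attn(clin_proj, kv)

    def predict_logits(self, pooled: Tensor) -> Tensor:
        if not np.all(np.isfinite(pooled.data)):
            raise ValueError("non-finite pooled representation")
        return self.head2(self.head1(pooled).gelu())

    # --------------------------------------------------------------- forward
    def __call__(self, img_seq, x_clin) -> Tensor:
        mode = self.config.modality
        if mode == "imaging":
            # no clinical input: self-attention over image tokens, with the
            # mean image token standing in as the final query
            img = self.embed_images(img_seq)
            img_hat = self.cross_img(img, img)
            fused = self.final_attn(self._imaging_query(img_hat), img_hat)
        else:
            x = x_clin if isinstance(x_clin, Tensor) else Tensor(np.asarray(x_clin, dtype=float))
            clin_seq = self.clinical_encoder(x)
            if mode == "clinical":
                # self-attention variant: cross-attention with alpha = beta
                clin_hat = self.cross_clin(clin_seq, clin_seq)
                fused = self.final_attn(clin_seq, clin_hat)
            else:
                img = self.embed_images(img_seq)
                img_hat, clin_hat = self.bidirectional_fusion(img, clin_seq)
                fused = self.final_attention(img_hat, clin_hat, clin_seq)
        pooled = self.pool(fused)
        return self.predict_logits(pooled)

    def _imaging_query(self, img_hat: Tensor) -> Tensor:
        # imaging-only model: mean image token stands in as the query tokens
        B, L, D = img_hat.shape
        q = img_hat.mean(axis=-2, keepdims=True)
        return Tensor.concatenate([q] * self.config.clin_tokens, axis=-2)

    def predict(self, img_seq, x_clin) -> np.ndarray:
        """Inference path: logits as a plain array, no graph."""
        with no_grad():
            return self(img_seq, x_clin).data
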