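"""DSNet: a dual-branch 3D encoder-decoder for hippocampal subfield
segmentation.

The network is U-shaped: a convolutional encoder of 5 ConvBlocks
(conv 3x3x3 + batch norm + ReLU) with max-pooling between stages and a
channel schedule ``base * 2**(l-1)``; a transformer applied to the
bottleneck feature map (tokenize -> pre-norm multi-head self-attention ->
GELU feed-forward, with learnable positional embeddings); CBAM
(channel-then-spatial sigmoid gating) on every skip connection; and a
decoder of transposed convolutions (kernel 2, stride 2) that splits into
two branches after two upsamplings - one head segments the whole
hippocampus (binary), the other its subfields (4 classes) - with the
hippocampus branch's features added residually into the subfield branch
at each post-split stage.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .nn import (
    BatchNorm3d, Conv3d, ConvTranspose3d, LayerNorm, Linear, Module,
    ModuleList, Parameter, Tensor, as_tensor, concat, maxpool3d, softmax,
)


@dataclasses.dataclass
class ModelConfig:
    """Every architectural degree of freedom of DSNet."""
    in_channels: int = 2
    base_channels: int = 16
    n_stages: int = 5
    n_classes_subfield: int = 4
    n_classes_binary: int = 2
    cbam_enabled: bool = True
    transformer_stages: tuple[int, ...] = (5,)
    transformer_blocks: int = 1
    n_heads: int = 8
    token_dim: int = 512
    dual_branch: bool = True
    branch_split_after: int = 2
    spatial_attn_kernel: int = 7
    cbam_reduction: int = 16

    def validate(self) -> None:
        if self.token_dim % self.n_heads:
            raise ValueError(f"token_dim {self.token_dim} not divisible by "
                             f"n_heads {self.n_heads}")
        if not self.branch_split_after < self.n_stages - 1:
            raise ValueError("branch_split_after must be < n_stages - 1")
        if any(not 1 <= s <= self.n_stages for s in self.transformer_stages):
            raise ValueError(f"transformer stages {self.transformer_stages} "
                             f"outside 1..{self.n_stages}")

    def stage_channels(self, stage: int) -> int:
        """Channel count at encoder stage `stage` (1-based): base * 2^(l-1)."""
        return self.base_channels * 2 ** (stage - 1)


class ConvBlock(Module):
    """conv 3x3x3 (padding 1) -> batch norm -> ReLU; spatial dims preserved."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.conv = Conv3d(in_channels, out_channels, 3, rng=rng, dtype=dtype)
        self.bn = BatchNorm3d(out_channels, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


# ---------------------------------------------------------------- attention

class ChannelAttention(Module):
    """Per-channel sigmoid gate from global max- and avg-pooled descriptors.

    M_c(F) = sigmoid(MLP(maxpool(F)) + MLP(avgpool(F))) * F, with a single
    shared two-layer MLP (reduction ratio r, hidden width >= 1).
    """

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng=rng, dtype=dtype)
        self.fc2 = Linear(hidden, channels, rng=rng, dtype=dtype)

    def _mlp(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())

    def forward(self, f: Tensor) -> Tensor:
        b, c = f.shape[:2]
        mx = f.max(axis=(2, 3, 4))
        av = f.mean(axis=(2, 3, 4))
        gate = (self._mlp(mx) + self._mlp(av)).sigmoid().reshape(b, c, 1, 1, 1)
        return gate * f


class SpatialAttention(Module):
    """Per-voxel sigmoid gate from channelwise max/avg maps.

    M_s(F) = sigmoid(Conv_k([chan-max(F), chan-avg(F)])) * F with a
    k x k x k convolution (default 7) and shape-preserving padding.
    """

    def __init__(self, kernel_size: int = 7,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.conv = Conv3d(2, 1, kernel_size, rng=rng, dtype=dtype)

    def forward(self, f: Tensor) -> Tensor:
        mx = f.max(axis=1, keepdims=True)
        av = f.mean(axis=1, keepdims=True)
        gate = self.conv(concat([mx, av], axis=1)).sigmoid()
        return gate * f


class CBAM(Module):
    """Channel attention followed by spatial attention (both gates < 1)."""

    def __init__(self, channels: int, reduction: int = 16, kernel_size: int = 7,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction, rng=rng, dtype=dtype)
        self.spatial = SpatialAttention(kernel_size, rng=rng, dtype=dtype)

    def forward(self, f: Tensor) -> Tensor:
        return self.spatial(self.channel(f))


# ---------------------------------------------------------------- transformer

def tokenize(f: Tensor, proj: Tensor, pos: Tensor | None = None) -> Tensor:
    """Flatten a feature map to tokens: F_token = flatten(F) W + P.

    f: (B, C, D, H, W) -> (B, D*H*W, C'), one token per spatial location.
    """
    f = as_tensor(f)
    b, c = f.shape[:2]
    n_tokens = int(np.prod(f.shape[2:]))
    seq = f.reshape(b, c, n_tokens).transpose(0, 2, 1)  # (B, N, C)
    tok = seq @ proj
    if pos is not None:
        if tuple(pos.shape[-2:]) != (n_tokens, tok.shape[-1]):
            raise ValueError(f"positional table {pos.shape} does not match "
                             f"tokens ({n_tokens}, {tok.shape[-1]})")
        tok = tok + pos
    return tok


def detokenize(tokens: Tensor, proj: Tensor,
               spatial_dims: tuple[int, int, int]) -> Tensor:
    """Project tokens back to channels and fold to a feature map."""
    tokens = as_tensor(tokens)
    b, n, _ = tokens.shape
    if n != int(np.prod(spatial_dims)):
        raise ValueError(f"{n} tokens cannot fill spatial dims {spatial_dims}")
    out = tokens @ proj  # (B, N, C_out)
    c_out = out.shape[-1]
    return out.transpose(0, 2, 1).reshape(b, c_out, *spatial_dims)


class MultiHeadSelfAttention(Module):
    """Pre-norm multi-head self-attention.

    Q_i = LN(x) W^Q_i (likewise K_i, V_i); head_i = softmax(Q K^T/sqrt(d_k)) V;
    output = [head_1..head_N] W^O. Head i owns the contiguous column block
    ``[i*d_k, (i+1)*d_k)`` of each projection matrix.
    """

    def __init__(self, dim: int, n_heads: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.dk = dim // n_heads
        if self.dk == 0:
            raise ValueError("head dimension d_k is zero")
        rng = rng or np.random.default_rng()
        bound = math.sqrt(6.0 / (2 * dim))
        def w():
            return Parameter(rng.uniform(-bound, bound, (dim, dim)).astype(dtype))
        self.ln = LayerNorm(dim, dtype=dtype)
        self.wq, self.wk, self.wv, self.wo = w(), w(), w(), w()

    def attention_weights(self, tokens: Tensor) -> np.ndarray:
        """Softmax attention maps (B, heads, N, N) — diagnostic only."""
        h = self.ln(as_tensor(tokens))
        b, n, c = h.shape
        q = (h @ self.wq).reshape(b, n, self.n_heads, self.dk).transpose(0, 2, 1, 3)
        k = (h @ self.wk).reshape(b, n, self.n_heads, self.dk).transpose(0, 2, 1, 3)
        att = softmax((q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.dk)),
                      axis=-1)
        return att.data

    def forward(self, tokens: Tensor) -> Tensor:
        tokens = as_tensor(tokens)
        b, n, c = tokens.shape
        h = self.ln(tokens)
        def heads(wm):
            return (h @ wm).reshape(b, n, self.n_heads, self.dk).transpose(0, 2, 1, 3)
        q, k, v = heads(self.wq), heads(self.wk), heads(self.wv)
        att = softmax((q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.dk)),
                      axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(b, n, c)
        return out @ self.wo


class FeedForward(Module):
    """Position-wise two-layer perceptron with GELU; hidden width 4x."""

    def __init__(self, dim: int, hidden: int | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        hidden = hidden or 4 * dim
        self.fc1 = Linear(dim, hidden, rng=rng, dtype=dtype)
        self.fc2 = Linear(hidden, dim, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class TransformerBlock(Module):
    """Pre-norm block: y = MSA(LN(x)) + x; out = FFN(LN(y)) + y."""

    def __init__(self, dim: int, n_heads: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.msa = MultiHeadSelfAttention(dim, n_heads, rng=rng, dtype=dtype)
        self.ln2 = LayerNorm(dim, dtype=dtype)
        self.ffn = FeedForward(dim, rng=rng, dtype=dtype)

    def forward(self, tokens: Tensor) -> Tensor:
        y = self.msa(tokens) + tokens
        return self.ffn(self.ln2(y)) + y


class BottleneckTransformer(Module):
    """Tokenize -> N transformer blocks -> detokenize, at one stage.

    The positional table P is created on first forward (its length is the
    token count of the incoming map) from a generator fixed at build time,
    so creation order does not affect reproducibility.
    """

    def __init__(self, channels: int, token_dim: int, n_heads: int,
                 n_blocks: int = 1, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.dtype = dtype
        bound = math.sqrt(6.0 / (channels + token_dim))
        self.proj_in = Parameter(rng.uniform(-bound, bound,
                                             (channels, token_dim)).astype(dtype))
        self.proj_out = Parameter(rng.uniform(-bound, bound,
                                              (token_dim, channels)).astype(dtype))
        self.blocks = ModuleList([TransformerBlock(token_dim, n_heads, rng=rng,
                                                   dtype=dtype)
                                  for _ in range(n_blocks)])
        self.pos: Parameter | None = None
        self._pos_rng = np.random.default_rng(rng.integers(0, 2 ** 31 - 1))

    def forward(self, f: Tensor) -> Tensor:
        spatial = tuple(f.shape[2:])
        n_tokens = int(np.prod(spatial))
        if self.pos is None:
            self.pos = Parameter(self._pos_rng.normal(
                0.0, 0.02, (n_tokens, self.proj_in.shape[1])).astype(self.dtype))
        tok = tokenize(f, self.proj_in, self.pos)
        for blk in self.blocks:
            tok = blk(tok)
        return detokenize(tok, self.proj_out, spatial)


# ---------------------------------------------------------------- the network

class DSNet(Module):
    """The full dual-branch segmentation network (see module docstring)."""

    def __init__(self, cfg: ModelConfig, seed: int = 0, dtype=np.float32):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        ch = {l: cfg.stage_channels(l) for l in range(1, cfg.n_stages + 1)}

        self.encoder = ModuleList()
        prev = cfg.in_channels
        for l in range(1, cfg.n_stages + 1):
            self.encoder.append(ConvBlock(prev, ch[l], rng=rng, dtype=dtype))
            prev = ch[l]

        self.transformers = {
            stage: BottleneckTransformer(ch[stage], cfg.token_dim, cfg.n_heads,
                                         cfg.transformer_blocks, rng=rng,
                                         dtype=dtype)
            for stage in sorted(cfg.transformer_stages)
        }

        self.cbams = {}
        if cfg.cbam_enabled:
            self.cbams = {stage: CBAM(ch[stage], cfg.cbam_reduction,
                                      cfg.spatial_attn_kernel, rng=rng,
                                      dtype=dtype)
                          for stage in range(1, cfg.n_stages)}

        n_up = cfg.n_stages - 1
        split = cfg.branch_split_after if cfg.dual_branch else n_up
        self.n_up, self.split = n_up, split

        def up_stage(cur: int):
            # decoder step landing on encoder stage `cur`
            return {"up": ConvTranspose3d(ch[cur + 1], ch[cur], rng=rng, dtype=dtype),
                    "conv": ConvBlock(2 * ch[cur], ch[cur], rng=rng, dtype=dtype)}

        self.shared_up = ModuleList()
        self.shared_conv = ModuleList()
        for j in range(1, split + 1):
            st = up_stage(cfg.n_stages - j)
            self.shared_up.append(st["up"])
            self.shared_conv.append(st["conv"])

        self.bin_up = ModuleList()
        self.bin_conv = ModuleList()
        self.sub_up = ModuleList()
        self.sub_conv = ModuleList()
        for j in range(split + 1, n_up + 1):
            if cfg.dual_branch:
                st = up_stage(cfg.n_stages - j)
                self.bin_up.append(st["up"])
                self.bin_conv.append(st["conv"])
            st = up_stage(cfg.n_stages - j)
            self.sub_up.append(st["up"])
            self.sub_conv.append(st["conv"])

        if cfg.dual_branch:
            self.head_binary = Conv3d(ch[1], cfg.n_classes_binary, 1, rng=rng,
                                      dtype=dtype)
        self.head_subfield = Conv3d(ch[1], cfg.n_classes_subfield, 1, rng=rng,
                                    dtype=dtype)

    # -- pieces ---------------------------------------------------------
    def _check_divisible(self, shape) -> None:
        div = 2 ** (self.cfg.n_stages - 1)
        for name, s in zip("DHW", shape):
            if s % div:
                raise ValueError(f"input axis {name}={s} not divisible by {div}")

    def encode(self, x: Tensor) -> list[Tensor]:
        """Run the encoder; returns the 5 per-stage feature maps.

        Transformer stages transform their feature map in place on the
        main path, so both the skip and the downstream pooling see the
        globally contextualized features.
        """
        x = as_tensor(x)
        self._check_divisible(x.shape[2:])
        feats = []
        h = x
        for l, block in enumerate(self.encoder, start=1):
            if l > 1:
                h = maxpool3d(h)
            h = block(h)
            if l in self.transformers:
                h = self.transformers[l](h)
            feats.append(h)
        return feats

    def _skip(self, stage: int, feat: Tensor) -> Tensor:
        cb = self.cbams.get(stage)
        return cb(feat) if cb is not None else feat

    def forward(self, x) -> tuple[Tensor | None, Tensor]:
        """Returns (binary logits, subfield logits); binary is None when
        the dual branch is disabled."""
        cfg = self.cfg
        feats = self.encode(x)
        h = feats[-1]
        # shared decoder path
        for j in range(self.split):
            stage = cfg.n_stages - 1 - j
            up = self.shared_up[j](h)
            cat = concat([up, self._skip(stage, feats[stage - 1])], axis=1)
            h = self.shared_conv[j](cat)
        if not cfg.dual_branch:
            return None, self.head_subfield(h)
        # branched path with residual fusion binary -> subfield
        hb = hs = h
        for j in range(self.n_up - self.split):
            stage = cfg.n_stages - 1 - self.split - j
            skip = self._skip(stage, feats[stage - 1])
            b_cat = concat([self.bin_up[j](hb), skip], axis=1)
            s_cat = concat([self.sub_up[j](hs), skip], axis=1)
            hb = self.bin_conv[j](b_cat)
            hs = self.sub_conv[j](s_cat + b_cat)  # residual guidance
        return self.head_binary(hb), self.head_subfield(hs)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def warmup(self, patch_size: tuple[int, int, int]) -> None:
        """Materialize lazily-sized parameters (positional tables) for a
        given patch size, e.g. before loading a checkpoint."""
        from .nn import no_grad
        x = np.zeros((1, self.cfg.in_channels) + tuple(patch_size),
                     dtype=np.float32)
        mode = self.training
        with no_grad():
            self.eval()
            self.forward(x)
        self.training = mode
        (self.train() if mode else self.eval())


def stage5_token_count(patch_size: tuple[int, int, int], stage: int = 5) -> int:
    """Token count of a transformer at `stage`: D*H*W / 2^(3*(l-1))."""
    return int(np.prod(patch_size) // 2 ** (3 * (stage - 1)))
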