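"""Architecture contracts and literal-formula oracles for DSNet.

The attention modules are checked against direct, independent numpy
evaluations of their defining equations (pre-norm multi-head attention;
channel gate sigmoid(MLP(maxpool)+MLP(avgpool)); spatial gate
sigmoid(conv([chan-max, chan-avg]))).
"""

import numpy as np
import pytest

from hipposeg.model import (
    CBAM, ChannelAttention, ConvBlock, DSNet, ModelConfig,
    MultiHeadSelfAttention, SpatialAttention, TransformerBlock,
    BottleneckTransformer, detokenize, stage5_token_count, tokenize,
)
from hipposeg.losses import total_loss
from hipposeg.nn import Tensor


def _zero_params(module):
    for p in module.parameters():
        p.data[...] = 0.0


# ------------------------------------------------------------- encoder

def test_channel_schedule_is_base_times_powers_of_two():
    cfg = ModelConfig()
    assert [cfg.stage_channels(l) for l in range(1, 6)] == [16, 32, 64, 128, 256]
    tiny = ModelConfig(base_channels=4)
    assert [tiny.stage_channels(l) for l in range(1, 6)] == [4, 8, 16, 32, 64]


def test_encoder_shapes_halve_per_stage(micro_cfg):
    model = DSNet(micro_cfg, seed=0)
    feats = model.encode(np.zeros((1, 2, 16, 16, 16), dtype=np.float32))
    shapes = [f.shape for f in feats]
    assert shapes == [(1, 2, 16, 16, 16), (1, 4, 8, 8, 8), (1, 8, 4, 4, 4),
                      (1, 16, 2, 2, 2), (1, 32, 1, 1, 1)]


def test_encoder_rejects_indivisible_input(micro_cfg):
    model = DSNet(micro_cfg, seed=0)
    with pytest.raises(ValueError, match="axis H"):
        model.encode(np.zeros((1, 2, 16, 24, 16), dtype=np.float32))


def test_conv_block_contract(rng):
    blk = ConvBlock(16, 32, rng=rng)
    out = blk(Tensor(rng.normal(size=(1, 16, 8, 8, 8)).astype(np.float32)))
    assert out.shape == (1, 32, 8, 8, 8)
    assert out.data.min() >= 0  # ReLU range
    blk.eval()
    x = Tensor(rng.normal(size=(1, 16, 4, 4, 4)).astype(np.float32))
    np.testing.assert_array_equal(blk(x).data, blk(x).data)


# ------------------------------------------------------------- tokenizer

def test_stage5_token_count_formula():
    assert stage5_token_count((128, 128, 128)) == 512
    assert stage5_token_count((32, 32, 32)) == 8


def test_tokenize_identity_projection_recovers_features(rng):
    f = rng.normal(size=(1, 4, 2, 2, 2))
    tok = tokenize(Tensor(f), Tensor(np.eye(4)), None)
    assert tok.shape == (1, 8, 4)
    np.testing.assert_allclose(tok.data, f.reshape(1, 4, 8).transpose(0, 2, 1))


def test_detokenize_inverts_tokenize(rng):
    f = rng.normal(size=(2, 4, 2, 2, 2))
    tok = tokenize(Tensor(f), Tensor(np.eye(4)), None)
    back = detokenize(tok, Tensor(np.eye(4)), (2, 2, 2))
    np.testing.assert_allclose(back.data, f)
    zero = detokenize(tok, Tensor(np.zeros((4, 6))), (2, 2, 2))
    assert not zero.data.any()
    assert zero.shape == (2, 6, 2, 2, 2)


# ------------------------------------------------------------- attention

def _literal_msa(tokens, msa):
    """Independent evaluation of the multi-head attention equations."""
    g, b = msa.ln.gamma.data, msa.ln.beta.data
    mu = tokens.mean(-1, keepdims=True)
    var = tokens.var(-1, keepdims=True)
    h = (tokens - mu) / np.sqrt(var + msa.ln.eps) * g + b
    dk = msa.dk
    heads = []
    for i in range(msa.n_heads):
        sl = slice(i * dk, (i + 1) * dk)
        q = h @ msa.wq.data[:, sl]
        k = h @ msa.wk.data[:, sl]
        v = h @ msa.wv.data[:, sl]
        scores = q @ k.transpose(0, 2, 1) / np.sqrt(dk)
        e = np.exp(scores - scores.max(-1, keepdims=True))
        att = e / e.sum(-1, keepdims=True)
        heads.append(att @ v)
    return np.concatenate(heads, axis=-1) @ msa.wo.data


def test_msa_matches_literal_equations():
    rng = np.random.default_rng(3)
    msa = MultiHeadSelfAttention(16, 4, rng=rng, dtype=np.float64)
    tokens = rng.normal(size=(2, 4, 16))
    got = msa(Tensor(tokens)).data
    np.testing.assert_allclose(got, _literal_msa(tokens, msa), atol=1e-6)


def test_msa_single_token_identity_projections_gives_layernorm():
    msa = MultiHeadSelfAttention(6, 1, dtype=np.float64)
    for p in (msa.wq, msa.wk, msa.wv, msa.wo):
        p.data = np.eye(6)
    tok = np.array([[[3.0, -1.0, 2.0, 0.5, 1.0, -2.0]]])
    out = msa(Tensor(tok)).data
    mu, sd = tok.mean(), tok.std()
    np.testing.assert_allclose(out, (tok - mu) / np.sqrt(sd ** 2 + msa.ln.eps),
                               atol=1e-9)


def test_msa_identical_tokens_get_identical_outputs(rng):
    msa = MultiHeadSelfAttention(8, 2, rng=rng, dtype=np.float64)
    tok = np.tile(rng.normal(size=(1, 1, 8)), (1, 2, 1))
    out = msa(Tensor(tok)).data
    np.testing.assert_allclose(out[0, 0], out[0, 1], atol=1e-12)


def test_attention_rows_sum_to_one(rng):
    msa = MultiHeadSelfAttention(8, 2, rng=rng, dtype=np.float64)
    att = msa.attention_weights(Tensor(rng.normal(size=(1, 5, 8))))
    np.testing.assert_allclose(att.sum(axis=-1), 1.0, atol=1e-6)


def test_transformer_block_zero_weights_is_identity(rng):
    blk = TransformerBlock(8, 2, rng=rng, dtype=np.float64)
    _zero_params(blk.msa)
    _zero_params(blk.ffn)
    # layer norms keep their (gamma=1, beta=0) defaults
    blk.msa.ln.gamma.data[:] = 1.0
    blk.ln2.gamma.data[:] = 1.0
    tok = rng.normal(size=(1, 4, 8))
    np.testing.assert_allclose(blk(Tensor(tok)).data, tok, atol=1e-12)


def test_transformer_block_preserves_shape_and_stacks(rng):
    bt = BottleneckTransformer(4, 8, 2, n_blocks=2, rng=rng, dtype=np.float64)
    f = rng.normal(size=(1, 4, 2, 2, 2))
    out = bt(Tensor(f))
    assert out.shape == f.shape
    # stacking 2 blocks == applying them sequentially on the token path
    tok = tokenize(Tensor(f), bt.proj_in, bt.pos)
    for blk in bt.blocks:
        tok = blk(tok)
    np.testing.assert_allclose(
        out.data, detokenize(tok, bt.proj_out, (2, 2, 2)).data, atol=1e-12)


def test_channel_attention_matches_literal_equation():
    rng = np.random.default_rng(5)
    ca = ChannelAttention(8, reduction=2, rng=rng, dtype=np.float64)
    f = rng.normal(size=(1, 8, 4, 4, 4))

    def mlp(v):
        h = np.maximum(v @ ca.fc1.weight.data + ca.fc1.bias.data, 0)
        return h @ ca.fc2.weight.data + ca.fc2.bias.data

    mx = f.max(axis=(2, 3, 4))
    av = f.mean(axis=(2, 3, 4))
    gate = 1 / (1 + np.exp(-(mlp(mx) + mlp(av))))
    want = gate[:, :, None, None, None] * f
    np.testing.assert_allclose(ca(Tensor(f)).data, want, atol=1e-6)


def test_channel_attention_zero_weights_halves_input(rng):
    ca = ChannelAttention(4, rng=rng, dtype=np.float64)
    _zero_params(ca)
    f = rng.normal(size=(1, 4, 2, 2, 2))
    np.testing.assert_allclose(ca(Tensor(f)).data, 0.5 * f, atol=1e-12)


def test_channel_attention_pathways_agree_on_constant_channels(rng):
    ca = ChannelAttention(3, reduction=1, rng=rng, dtype=np.float64)
    const = np.array([1.5, -2.0, 0.25])
    f = np.broadcast_to(const[None, :, None, None, None], (1, 3, 2, 2, 2)).copy()

    def mlp(v):
        h = np.maximum(v @ ca.fc1.weight.data + ca.fc1.bias.data, 0)
        return h @ ca.fc2.weight.data + ca.fc2.bias.data

    # max-pool and avg-pool descriptors coincide, so the gate is sigma(2 MLP(c))
    gate = 1 / (1 + np.exp(-2 * mlp(const[None])))
    np.testing.assert_allclose(ca(Tensor(f)).data,
                               gate[:, :, None, None, None] * f, atol=1e-9)


def test_spatial_attention_matches_literal_equation():
    rng = np.random.default_rng(6)
    sa = SpatialAttention(kernel_size=3, rng=rng, dtype=np.float64)
    f = rng.normal(size=(1, 4, 4, 4, 4))
    stacked = np.stack([f.max(axis=1), f.mean(axis=1)], axis=1)
    pad = np.pad(stacked, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    wk = sa.conv.weight.data
    conv = np.zeros((1, 4, 4, 4))
    for a in range(3):
        for bb in range(3):
            for c in range(3):
                conv += np.einsum("bidhw,i->bdhw",
                                  pad[:, :, a:a + 4, bb:bb + 4, c:c + 4],
                                  wk[0, :, a, bb, c])
    gate = 1 / (1 + np.exp(-(conv + sa.conv.bias.data[0])))
    np.testing.assert_allclose(sa(Tensor(f)).data, gate[:, None] * f, atol=1e-6)


def test_spatial_attention_single_channel_pools_to_input(rng):
    sa = SpatialAttention(kernel_size=3, rng=rng, dtype=np.float64)
    f = Tensor(rng.normal(size=(1, 1, 3, 3, 3)))
    assert np.array_equal(f.data.max(axis=1), f.data.mean(axis=1))
    assert sa(f).shape == f.shape


def test_cbam_zero_weights_quarters_input(rng):
    cb = CBAM(4, rng=rng, dtype=np.float64)
    _zero_params(cb)
    f = rng.normal(size=(1, 4, 3, 3, 3))
    np.testing.assert_allclose(cb(Tensor(f)).data, 0.25 * f, atol=1e-12)


def test_cbam_gates_shrink_magnitudes(rng):
    cb = CBAM(4, rng=rng, dtype=np.float64)
    f = rng.normal(size=(1, 4, 3, 3, 3))
    out = cb(Tensor(f)).data
    assert np.all(np.abs(out) <= np.abs(f) + 1e-12)


def test_cbam_disabled_gives_identity_skips(micro_cfg):
    import dataclasses
    cfg = dataclasses.replace(micro_cfg, cbam_enabled=False)
    model = DSNet(cfg, seed=0)
    t = Tensor(np.ones((1, 2, 4, 4, 4)))
    assert model._skip(1, t) is t


# ------------------------------------------------------------- full network

def test_dsnet_forward_output_shapes(micro_cfg):
    model = DSNet(micro_cfg, seed=0)
    x = np.random.default_rng(0).normal(size=(1, 2, 16, 16, 16)).astype(np.float32)
    b, s = model(x)
    assert b.shape == (1, 2, 16, 16, 16)
    assert s.shape == (1, 4, 16, 16, 16)


@pytest.mark.parametrize("stages", [(4,), (5,), (4, 5)])
def test_transformer_placement_variants_run(micro_cfg, stages):
    import dataclasses
    cfg = dataclasses.replace(micro_cfg, transformer_stages=stages)
    model = DSNet(cfg, seed=0)
    b, s = model(np.zeros((1, 2, 16, 16, 16), dtype=np.float32))
    assert s.shape == (1, 4, 16, 16, 16)


def test_single_branch_drops_binary_output_and_parameters(micro_cfg):
    import dataclasses
    dual = DSNet(micro_cfg, seed=0)
    single = DSNet(dataclasses.replace(micro_cfg, dual_branch=False), seed=0)
    b, s = single(np.zeros((1, 2, 16, 16, 16), dtype=np.float32))
    assert b is None
    assert s.shape == (1, 4, 16, 16, 16)
    assert single.n_parameters() < dual.n_parameters()


def test_gradients_reach_every_parameter_group(micro_cfg):
    model = DSNet(micro_cfg, seed=0)
    rng = np.random.default_rng(2)
    # 32^3 input: the bottleneck then has 8 tokens and 8 voxels, so the
    # attention projections and the deepest batch norm see real statistics
    x = rng.normal(size=(1, 2, 32, 32, 32)).astype(np.float32)
    y = rng.integers(0, 4, (1, 32, 32, 32))
    b, s = model(x)
    loss = total_loss(b, s, y)
    loss.backward()
    for name, p in model.named_parameters():
        assert p.grad is not None, f"no gradient for {name}"
        assert np.isfinite(p.grad).all(), f"non-finite gradient for {name}"
        assert np.any(p.grad != 0), f"dead parameter group {name}"
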