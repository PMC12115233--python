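"""Block semantics: tokenization round-trips, attention equivalences and
isolation, ResConv's reduction to a plain convolution, C2fCS wiring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from voidnet.autodiff import Tensor
from voidnet.blocks import (C2f, C2fCS, ResConv, TokAtt, TokenGrid,
                            c2fcs_forward, resconv_forward,
                            scaled_dot_attention, token_attention, tokatt_forward,
                            tokenize, untokenize)
from voidnet.nnlayers import conv2d


# ------------------------------------------------------------- tokenization

def test_tokenize_examples(rng):
    x = rng.normal(0, 1, (6, 6, 2))
    g = tokenize(x, 1)
    np.testing.assert_array_equal(g.tokens[0, 0], x)
    x4 = np.arange(16, dtype=float).reshape(4, 4, 1)
    g = tokenize(x4, 2)
    np.testing.assert_array_equal(g.tokens[0, 0][:, :, 0], [[0, 1], [4, 5]])
    np.testing.assert_array_equal(untokenize(g), x4)
    with pytest.raises(ValueError, match="H=6"):
        tokenize(x, 4)


@settings(max_examples=25, deadline=None)
@given(S=st.sampled_from([1, 2, 3, 4]), mult=st.integers(1, 3),
       c=st.integers(1, 3), seed=st.integers(0, 10 ** 6))
def test_tokenize_untokenize_roundtrip(S, mult, c, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, (S * mult, S * mult * 2, c))
    g = tokenize(x, S)
    assert (untokenize(g) == x).all()          # bit-identical
    g2 = tokenize(untokenize(g), S)
    assert (g2.tokens == g.tokens).all()


def test_tokengrid_validates_shape():
    with pytest.raises(ValueError):
        TokenGrid(tokens=np.zeros((2, 3, 4, 4, 1)), S=2)


# ---------------------------------------------------------------- attention

def test_attention_weight_rows_sum_to_one(rng):
    q, k, v = (rng.normal(0, 3, (7, 5)) for _ in range(3))
    out, w = scaled_dot_attention(q, k, v)
    assert (w >= 0).all()
    np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)
    assert out.shape == (7, 5)


def test_single_pixel_token_returns_value_projection(rng):
    x = rng.normal(0, 1, (2, 2, 3))
    g = tokenize(x, 2)                          # 1-pixel tokens
    wv = rng.normal(0, 1, (3, 3))
    p = {"wq": np.eye(3), "wk": np.eye(3), "wv": wv}
    out = token_attention(g, p)
    np.testing.assert_allclose(untokenize(out), x @ wv, atol=1e-12)


def test_identical_rows_give_input_back_under_identity_projections(rng):
    row = rng.normal(0, 1, 4)
    x = np.tile(row, (2, 2, 1))
    g = tokenize(x, 1)
    p = {"wq": np.eye(4), "wk": np.eye(4), "wv": np.eye(4)}
    out = token_attention(g, p)
    np.testing.assert_allclose(untokenize(out), x, atol=1e-12)


def test_two_pixel_token_matches_hand_softmax(rng):
    x = rng.normal(0, 1, (1, 2, 3))             # one token, two pixels
    g = tokenize(x, 1)
    p = {"wq": np.eye(3), "wk": np.eye(3), "wv": np.eye(3)}
    out = untokenize(token_attention(g, p))
    a, b = x[0, 0], x[0, 1]
    scale = np.sqrt(3)
    for i, q in enumerate((a, b)):
        logits = np.array([q @ a, q @ b]) / scale
        e = np.exp(logits - logits.max())
        w = e / e.sum()
        np.testing.assert_allclose(out[0, i], w[0] * a + w[1] * b, atol=1e-12)


def test_token_attention_rejects_bad_projection(rng):
    g = tokenize(rng.normal(0, 1, (4, 4, 3)), 2)
    with pytest.raises(ValueError, match="wq"):
        token_attention(g, {"wq": np.eye(2), "wk": np.eye(3), "wv": np.eye(3)})


# ------------------------------------------------------------- TokAtt layer

def _global_attention_reference(x_hwc, block):
    """Independent global self-attention with the block's parameters."""
    H, W, C = x_hwc.shape
    rows = x_hwc.reshape(H * W, C).astype(np.float64)
    ln_g = block.ln.weight.data.astype(np.float64)
    ln_b = block.ln.bias.data.astype(np.float64)
    mu = rows.mean(axis=1, keepdims=True)
    sd = np.sqrt(rows.var(axis=1, keepdims=True) + block.ln.eps)
    t = ln_g * (rows - mu) / sd + ln_b
    t = t @ block.embed.weight.data + block.embed.bias.data
    q = t @ block.wq.weight.data + block.wq.bias.data
    k = t @ block.wk.weight.data + block.wk.bias.data
    v = t @ block.wv.weight.data + block.wv.bias.data
    out, _ = scaled_dot_attention(q, k, v, scale=np.sqrt(C))
    out = out @ block.proj.weight.data + block.proj.bias.data
    return x_hwc + out.reshape(H, W, C)


def _randomize(block, rng):
    for _, p in block.named_parameters():
        p.data = rng.normal(0, 0.3, p.data.shape).astype(p.data.dtype)


def test_tokatt_s1_equals_global_attention(rng):
    block = TokAtt(c=6, S=1, rng=np.random.default_rng(3))
    _randomize(block, rng)
    x = rng.normal(0, 1, (4, 4, 6))
    got = tokatt_forward(x.astype(np.float32), block)
    ref = _global_attention_reference(x, block)
    np.testing.assert_allclose(got, ref, atol=1e-5)


def test_tokatt_shape_and_finiteness(rng):
    block = TokAtt(c=8, S=4, rng=np.random.default_rng(0))
    x = rng.normal(0, 1, (8, 16, 8))
    y = tokatt_forward(x, block)
    assert y.shape == x.shape
    assert np.isfinite(y).all()
    with pytest.raises(ValueError, match="S=4"):
        tokatt_forward(rng.normal(0, 1, (6, 6, 8)), block)


def test_tokatt_block_permutation_equivariance(rng):
    """Permuting token blocks of the input permutes output blocks the same
    way (parameters are shared across tokens).  Uses the no-residual inner
    path so the comparison is exact."""
    S, c = 2, 5
    block = TokAtt(c=c, S=S, residual=False, rng=np.random.default_rng(1))
    _randomize(block, rng)
    x = rng.normal(0, 1, (6, 6, c)).astype(np.float32)
    perm = [(1, 1), (1, 0), (0, 1), (0, 0)]     # reversal of the 2x2 grid

    def permute(img):
        g = tokenize(img, S)
        t = g.tokens.reshape(S * S, *g.tokens.shape[2:])
        src = [p[0] * S + p[1] for p in perm]
        return untokenize(TokenGrid(t[src].reshape(g.tokens.shape), S))

    y = tokatt_forward(x, block)
    y_perm = tokatt_forward(permute(x).astype(np.float32), block)
    np.testing.assert_allclose(y_perm, permute(y), atol=1e-5)


def test_tokatt_cross_token_isolation(rng):
    """Perturbing one token changes only that token's slot of the fused
    attention output (pre output-projection)."""
    S, c = 2, 4
    block = TokAtt(c=c, S=S, rng=np.random.default_rng(2))
    _randomize(block, rng)
    x = rng.normal(0, 1, (8, 8, c)).astype(np.float32)
    xt = Tensor(x.transpose(2, 0, 1)[None])
    _, inner0 = block(xt, return_inner=True)
    x2 = x.copy()
    # non-uniform perturbation of token (0,0) only (a per-pixel constant
    # would be removed by the channel LayerNorm)
    x2[:4, :4] += rng.normal(0, 1, (4, 4, c)).astype(np.float32)
    _, inner1 = block(Tensor(x2.transpose(2, 0, 1)[None]), return_inner=True)
    d = np.abs(inner1.data - inner0.data)[0]    # (H, W, C)
    assert d[:4, :4].max() > 1e-4
    assert d[:4, 4:].max() == 0.0
    assert d[4:, :].max() == 0.0


# ----------------------------------------------------------------- ResConv

def test_resconv_silenced_branch_is_plain_convolution(rng):
    block = ResConv(3, 5, stride=1, norm=False, act=False,
                    rng=np.random.default_rng(4))
    block.dw.weight.data[...] = 0.0
    block.dw.bias.data[...] = 0.0
    x = rng.normal(0, 1, (7, 7, 3)).astype(np.float32)
    got = resconv_forward(x, block)
    ref = conv2d(Tensor(x.transpose(2, 0, 1)[None]), block.conv.weight,
                 block.conv.bias, 1, 1).data[0].transpose(1, 2, 0)
    np.testing.assert_allclose(got, ref, atol=1e-6)


def test_resconv_constant_input_affine_value():
    """Constant input + known kernel sums -> hand-computable activations."""
    block = ResConv(1, 1, stride=1, norm=False, act=False,
                    rng=np.random.default_rng(0))
    block.conv.weight.data[...] = 0.5
    block.conv.bias.data[...] = 0.25
    block.dw.weight.data[...] = 0.1
    block.dw.bias.data[...] = 0.0
    x = np.full((5, 5, 1), 2.0, dtype=np.float32)
    y = resconv_forward(x, block)
    # interior: conv = 9*0.5*2 + 0.25 = 9.25; dw = 9*0.1*9.25; out = conv + dw
    expect = 9.25 + 0.9 * 9.25
    assert y[2, 2, 0] == pytest.approx(expect, rel=1e-6)


@pytest.mark.parametrize("stride,expect_hw", [(1, (8, 8)), (2, (4, 4))])
def test_resconv_shape_contract(rng, stride, expect_hw):
    block = ResConv(4, 8, stride=stride, rng=np.random.default_rng(0))
    y = resconv_forward(rng.normal(0, 1, (8, 8, 4)), block)
    assert y.shape == (*expect_hw, 8)
    with pytest.raises(ValueError, match="channels"):
        resconv_forward(rng.normal(0, 1, (8, 8, 3)), block)


def test_resconv_zero_init_depthwise_makes_identity_start(rng):
    """At initialisation the depthwise branch is silent by design."""
    block = ResConv(2, 4, stride=1, norm=False, act=False,
                    rng=np.random.default_rng(5))
    x = rng.normal(0, 1, (6, 6, 2)).astype(np.float32)
    ref = conv2d(Tensor(x.transpose(2, 0, 1)[None]), block.conv.weight,
                 block.conv.bias, 1, 1).data[0].transpose(1, 2, 0)
    np.testing.assert_allclose(resconv_forward(x, block), ref, atol=1e-6)


# ------------------------------------------------------------------- C2fCS

def test_c2fcs_silenced_attention_equals_plain_fusion(rng):
    blk = C2fCS(6, 6, S=2, rng=np.random.default_rng(6))
    blk.att.proj.weight.data[...] = 0.0
    blk.att.proj.bias.data[...] = 0.0
    x = rng.normal(0, 1, (8, 8, 6)).astype(np.float32)
    got = c2fcs_forward(x, blk)
    blk.c2f.eval()
    ref = blk.c2f(Tensor(x.transpose(2, 0, 1)[None])).data[0].transpose(1, 2, 0)
    np.testing.assert_allclose(got, ref, atol=1e-6)


def test_c2fcs_shape_contract_and_finiteness(rng):
    blk = C2fCS(6, 10, S=2, rng=np.random.default_rng(7))
    y = c2fcs_forward(rng.normal(0, 1, (8, 12, 6)), blk)
    assert y.shape == (8, 12, 10)
    assert np.isfinite(y).all()


def test_c2fcs_gradient_reaches_every_parameter(rng):
    blk = C2fCS(4, 4, S=2, rng=np.random.default_rng(8))
    _randomize(blk.att, np.random.default_rng(9))   # wake the zero-init proj
    blk.train()
    x = Tensor(rng.normal(0, 1, (2, 4, 8, 8)).astype(np.float32),
               requires_grad=True)
    y = blk(x)
    (y * y).sum().backward()
    for name, p in blk.named_parameters():
        assert p.grad is not None and np.abs(p.grad).max() > 0, name


def test_block_outputs_finite_for_gaussian_inputs(rng):
    for blk, cin in [(ResConv(3, 8, 2, rng=np.random.default_rng(0)), 3),
                     (C2f(8, 8, rng=np.random.default_rng(1)), 8),
                     (TokAtt(8, 2, rng=np.random.default_rng(2)), 8)]:
        x = Tensor(rng.normal(0, 1, (2, cin, 8, 8)).astype(np.float32))
        assert np.isfinite(blk(x).data).all()
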