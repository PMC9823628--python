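"""Structural contracts of the network blocks and assembled variants."""

import numpy as np
import pytest

from pearnet import nn
from pearnet.arch import (AFF, CBS, CSP, CSPFF, SPP, ChannelReduce, Focus,
                          ModelConfig, MultiHeadSelfAttention,
                          TransformerEncoder, build_model, count_params_flops)
from pearnet.nn import Tensor


def t(shape, rng, scale=1.0):
    return Tensor(rng.standard_normal(shape).astype(np.float32) * scale)


# ---------------------------------------------------------------------------
# Focus
# ---------------------------------------------------------------------------


def test_focus_halves_spatial_size(rng):
    f = Focus(3, 16, rng=rng).eval()
    y = f(t((1, 3, 8, 8), rng))
    assert y.shape == (1, 16, 4, 4)


def test_focus_slicing_is_lossless(rng):
    x = t((1, 3, 4, 4), rng)
    sliced = Focus.space_to_depth(x)
    assert sliced.shape == (1, 12, 2, 2)
    assert np.allclose(np.sort(sliced.data.ravel()), np.sort(x.data.ravel()))


def test_focus_rejects_odd_size(rng):
    f = Focus(3, 16, rng=rng)
    with pytest.raises(ValueError, match="even"):
        f(t((1, 3, 7, 8), rng))


# ---------------------------------------------------------------------------
# CSP / SPP
# ---------------------------------------------------------------------------


def test_csp_preserves_spatial_size_and_handles_single_pixel(rng):
    for shortcut in (True, False):
        m = CSP(64, 64, n=1, shortcut=shortcut, rng=rng).eval()
        assert m(t((1, 64, 5, 7), rng)).shape == (1, 64, 5, 7)
        assert m(t((1, 64, 1, 1), rng)).shape == (1, 64, 1, 1)


def test_csp_parameter_count_monotone_in_n(rng):
    counts = [CSP(64, 64, n=n, rng=np.random.default_rng(0)).n_params()
              for n in (1, 2, 3)]
    assert counts[0] < counts[1] < counts[2]


def test_csp_rejects_zero_bottlenecks(rng):
    with pytest.raises(ValueError):
        CSP(64, 64, n=0, rng=rng)


def test_spp_shape_and_constant_pooling(rng):
    m = SPP(32, 32, rng=rng).eval()
    assert m(t((1, 32, 20, 20), rng)).shape == (1, 32, 20, 20)
    # max pooling of a constant map is the constant everywhere
    const = Tensor(np.full((1, 8, 6, 6), 2.5, dtype=np.float32))
    for k in (5, 9, 13):
        assert np.allclose(nn.max_pool2d(const, k, 1, k // 2).data, 2.5)
    single = nn.max_pool2d(Tensor(np.full((1, 8, 1, 1), 3.0)), 5, 1, 2)
    assert single.shape == (1, 8, 1, 1) and np.allclose(single.data, 3.0)


# ---------------------------------------------------------------------------
# Transformer encoder
# ---------------------------------------------------------------------------


def test_transformer_encoder_shape_preserving(rng):
    te = TransformerEncoder(16, heads=4, dropout=0.1, rng=rng).eval()
    assert te(t((2, 16, 5, 5), rng)).shape == (2, 16, 5, 5)


def test_transformer_encoder_deterministic_at_zero_dropout(rng):
    te = TransformerEncoder(16, heads=4, dropout=0.0, rng=rng).eval()
    x = t((1, 16, 4, 4), rng)
    y1, y2 = te(x), te(x)
    assert np.array_equal(y1.data, y2.data)


def test_transformer_encoder_rejects_bad_head_count(rng):
    with pytest.raises(ValueError, match="divisible"):
        TransformerEncoder(10, heads=4, rng=rng)


def test_self_attention_permutation_equivariant(rng):
    """Without positional encoding, permuting the spatial flattening order
    and inverse-permuting the output leaves self-attention unchanged."""
    mhsa = MultiHeadSelfAttention(8, heads=2, rng=rng).eval()
    x = t((1, 8, 2, 2), rng)
    y = mhsa(x).data.reshape(8, 4)
    perm = np.array([2, 0, 3, 1])
    xp = Tensor(x.data.reshape(1, 8, 4)[:, :, perm].reshape(1, 8, 2, 2))
    yp = mhsa(xp).data.reshape(8, 4)
    unperm = np.argsort(perm)
    assert np.allclose(yp[:, unperm], y, atol=1e-5)


# ---------------------------------------------------------------------------
# AFF / CSP-FF
# ---------------------------------------------------------------------------


def test_aff_equal_inputs_pass_through(rng):
    aff = AFF(8, rng=rng).eval()
    x = t((1, 8, 3, 3), rng)
    assert np.allclose(aff(x, x).data, x.data, atol=1e-6)


def test_aff_endpoints_and_convex_combination(rng):
    aff = AFF(4, rng=rng).eval()
    x, y = t((2, 4, 3, 3), rng), t((2, 4, 3, 3), rng)
    m = aff.attention(x + y).data
    assert (m > 0).all() and (m < 1).all()
    out = aff(x, y).data
    lo = np.minimum(x.data, y.data) - 1e-6
    hi = np.maximum(x.data, y.data) + 1e-6
    assert (out >= lo).all() and (out <= hi).all()
    # endpoint identities out = M*X + (1-M)*Y
    assert np.allclose(out, m * x.data + (1 - m) * y.data, atol=1e-6)


def test_aff_rejects_shape_mismatch(rng):
    aff = AFF(4, rng=rng)
    with pytest.raises(ValueError, match="mismatch"):
        aff(t((1, 4, 3, 3), rng), t((1, 4, 2, 3), rng))


def test_csp_ff_shape_params_and_two_path_gradients(rng):
    ff = CSPFF(32, 32, rng=np.random.default_rng(1))
    plain = CSP(32, 32, n=1, shortcut=False, rng=np.random.default_rng(1))
    assert ff.n_params() > plain.n_params()
    ff.eval()
    x = t((1, 32, 4, 4), rng)
    assert ff(x).shape == (1, 32, 4, 4)
    ff.train()
    ff.te_path.dropout_p = 0.0
    (ff(x) ** 2).mean().backward()
    conv_g = ff.conv_path.cv2.conv.weight.grad
    te_g = ff.te_path.attn.qkv.weight.grad
    assert conv_g is not None and np.abs(conv_g).sum() > 0
    assert te_g is not None and np.abs(te_g).sum() > 0


# ---------------------------------------------------------------------------
# Assembled variants
# ---------------------------------------------------------------------------


def test_head_grids_follow_strides(rng):
    cfg = ModelConfig(variant="FP", input_size=128, width_multiple=0.25)
    m = build_model(cfg, seed=0).eval()
    raw = m(t((1, 3, 128, 128), rng))
    assert [r.shape[2:4] for r in raw] == [(16, 16), (8, 8), (4, 4)]
    assert all(r.shape[1] == 3 and r.shape[4] == 6 for r in raw)


def test_parameter_counts_monotone_across_variants():
    counts = {v: build_model(ModelConfig(variant=v), seed=0).n_params()
              for v in ("baseline", "SC", "TE", "TC", "FP")}
    assert counts["baseline"] < counts["SC"]
    assert counts["SC"] < counts["TE"] < counts["FP"]
    assert counts["SC"] < counts["TC"] < counts["FP"]


def test_skip_connections_bypass_one_and_two_extractors():
    """Graph inspection: the new skips reach the medium-resolution fusion
    bypassing one feature-extraction module and the low-resolution fusion
    bypassing two."""
    m = build_model(ModelConfig(variant="SC"), seed=0)
    src = m._pre_fusion["P2"]
    for dest, expected_bypassed in ((m._fusion_points["P2"], 1),
                                    (m._fusion_points["P3"], 2)):
        paths = m.paths_between(src, dest)
        counts = sorted(m.extraction_count(p) for p in paths)
        assert counts[0] == 0, "skip path should traverse no extractor"
        assert max(counts) == expected_bypassed


def test_variant_validation():
    with pytest.raises(ValueError, match="variant"):
        ModelConfig(variant="bogus")


def test_model_config_yaml_roundtrip():
    cfg = ModelConfig(variant="TC", input_size=128, te_heads=2)
    again = ModelConfig.from_yaml(cfg.to_yaml())
    assert again == cfg


# ---------------------------------------------------------------------------
# Profiling
# ---------------------------------------------------------------------------


def test_flop_count_matches_hand_oracle_single_conv(rng):
    conv = nn.Conv2d(3, 16, 3, 1, padding=1, bias=True, rng=rng)
    n_params, flops = count_params_flops(conv, input_size=64)
    assert n_params == 3 * 3 * 3 * 16 + 16 == 448
    expected = 2 * (3 * 3 * 3) * 16 * 64 * 64
    assert abs(flops - expected) / expected < 1e-3


def test_conv_flops_scale_quadratically_with_input(rng):
    conv = nn.Conv2d(3, 8, 3, 1, padding=1, bias=False,
                     rng=np.random.default_rng(0))
    _, f1 = count_params_flops(conv, input_size=32)
    _, f2 = count_params_flops(conv, input_size=64)
    assert f2 / f1 == pytest.approx(4.0)
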