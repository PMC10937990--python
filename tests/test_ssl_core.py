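"""Mixed-view construction, the siamese objectives, and stop-gradient."""

import numpy as np
import pytest

from cmixup import (
    EncoderSpec,
    MixCoefficient,
    build_model,
    cmixup_loss,
    forward_quad,
    mix_views,
    negative_cosine,
    simsiam_loss,
)
from cmixup.nn import Tensor
from cmixup.ssl_core import EmbeddingQuad

from conftest import TINY_ENCODER


# -- mixing -------------------------------------------------------------------

def test_lambda_zero_returns_second_view():
    rng = np.random.default_rng(0)
    x_i, x_j = rng.random((3, 8, 8)), rng.random((3, 8, 8))
    pair = mix_views(x_i, x_j, 0.0)
    np.testing.assert_array_equal(pair.x_tilde_j, x_j)
    np.testing.assert_array_equal(pair.x_i, x_i)


def test_constant_images_mix_arithmetically():
    x_i = np.full((3, 4, 4), 0.2)
    x_j = np.full((3, 4, 4), 0.6)
    pair = mix_views(x_i, x_j, 0.25)
    np.testing.assert_allclose(pair.x_tilde_j, 0.5)


def test_mixing_identical_views_is_idempotent():
    x = np.random.default_rng(1).random((3, 4, 4))
    pair = mix_views(x, x.copy(), 0.5)
    np.testing.assert_allclose(pair.x_tilde_j, x)


def test_mix_is_exact_convex_combination():
    rng = np.random.default_rng(2)
    x_i, x_j = rng.random((2, 3, 8, 8)), rng.random((2, 3, 8, 8))
    for lam in (0.0, 0.1, 0.37, 0.5):
        pair = mix_views(x_i, x_j, lam)
        np.testing.assert_allclose(pair.x_tilde_j, lam * x_i + (1 - lam) * x_j,
                                   rtol=0, atol=1e-15)
        assert pair.x_tilde_j.min() >= 0.0 and pair.x_tilde_j.max() <= 1.0


def test_per_sample_lambda_broadcasts_over_batch():
    rng = np.random.default_rng(3)
    x_i, x_j = rng.random((4, 3, 4, 4)), rng.random((4, 3, 4, 4))
    lam = np.array([0.0, 0.1, 0.3, 0.5])
    pair = mix_views(x_i, x_j, lam)
    for k in range(4):
        np.testing.assert_allclose(
            pair.x_tilde_j[k], lam[k] * x_i[k] + (1 - lam[k]) * x_j[k]
        )


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        mix_views(np.zeros((3, 4, 4)), np.zeros((3, 5, 5)), 0.2)


# -- negative cosine ----------------------------------------------------------

def test_aligned_vectors_give_minus_one():
    e = np.zeros(8)
    e[0] = 1.0
    assert float(negative_cosine(e, e).data) == pytest.approx(-1.0)


def test_orthogonal_vectors_give_zero():
    p, z = np.zeros(8), np.zeros(8)
    p[0], z[1] = 1.0, 1.0
    assert float(negative_cosine(p, z).data) == pytest.approx(0.0)


def test_opposed_vectors_give_plus_one():
    e = np.zeros(8)
    e[0] = 1.0
    assert float(negative_cosine(e, -e).data) == pytest.approx(1.0)


def test_zero_norm_vector_rejected():
    with pytest.raises(ValueError):
        negative_cosine(np.zeros(4), np.ones(4))


# -- loss identities ----------------------------------------------------------

def _oracle_simsiam(p1, z1, p2, z2):
    """Independently coded formula: symmetric negative cosine, batch mean."""
    def cos(a, b):
        a = a / np.linalg.norm(a, axis=-1, keepdims=True)
        b = b / np.linalg.norm(b, axis=-1, keepdims=True)
        return (a * b).sum(axis=-1).mean()

    return -0.5 * cos(p1, z2) - 0.5 * cos(p2, z1)


def test_simsiam_loss_matches_formula_oracle():
    rng = np.random.default_rng(0)
    worst = 0.0
    for _ in range(1000):
        p1, z1, p2, z2 = rng.standard_normal((4, 3, 8))
        ours = float(simsiam_loss(p1, z1, p2, z2).data)
        ref = _oracle_simsiam(p1, z1, p2, z2)
        worst = max(worst, abs(ours - ref))
    assert worst < 1e-6


def test_loss_always_in_unit_interval():
    rng = np.random.default_rng(1)
    for _ in range(200):
        p1, z1, p2, z2 = rng.standard_normal((4, 5, 6)) * 10
        v = float(simsiam_loss(p1, z1, p2, z2).data)
        assert -1.0 - 1e-12 <= v <= 1.0 + 1e-12


def test_aligned_quad_gives_minus_one():
    v = np.ones((2, 8))
    quad = EmbeddingQuad(p_i=Tensor(v), z_i=Tensor(v),
                         p_tilde_j=Tensor(v), z_tilde_j=Tensor(v))
    assert float(cmixup_loss(quad).data) == pytest.approx(-1.0)


def test_orthogonal_quad_gives_zero():
    a, b = np.zeros((1, 4)), np.zeros((1, 4))
    a[0, 0], b[0, 1] = 1.0, 1.0
    quad = EmbeddingQuad(p_i=Tensor(a), z_i=Tensor(a),
                         p_tilde_j=Tensor(b), z_tilde_j=Tensor(b))
    assert float(cmixup_loss(quad).data) == pytest.approx(0.0)


def test_loss_symmetric_under_branch_swap():
    rng = np.random.default_rng(2)
    p_i, z_i, p_j, z_j = rng.standard_normal((4, 3, 8))
    q1 = EmbeddingQuad(Tensor(p_i), Tensor(z_i), Tensor(p_j), Tensor(z_j))
    q2 = EmbeddingQuad(Tensor(p_j), Tensor(z_j), Tensor(p_i), Tensor(z_i))
    assert float(cmixup_loss(q1).data) == pytest.approx(float(cmixup_loss(q2).data))


def test_lambda_zero_reduces_to_plain_siamese_end_to_end(tiny_model):
    """Images in, scalar out: at λ=0 the mixed-view objective is exactly the
    plain siamese objective on the unmixed pair."""
    rng = np.random.default_rng(5)
    x_i, x_j = rng.random((2, 3, 16, 16)), rng.random((2, 3, 16, 16))
    tiny_model.eval()  # freeze batch statistics so both paths see one regime
    quad = forward_quad(tiny_model, mix_views(x_i, x_j, 0.0))
    mixed_value = float(cmixup_loss(quad).data)
    p1, z1 = tiny_model(Tensor(x_i))
    p2, z2 = tiny_model(Tensor(x_j))
    plain_value = float(simsiam_loss(p1, z1, p2, z2).data)
    assert mixed_value == plain_value


# -- stop-gradient ------------------------------------------------------------

def test_stopped_operands_receive_no_gradient():
    rng = np.random.default_rng(0)
    p = Tensor(rng.standard_normal((3, 8)), requires_grad=True)
    z = Tensor(rng.standard_normal((3, 8)), requires_grad=True)
    negative_cosine(p, z).backward()
    assert p.grad is not None and np.any(p.grad != 0)
    assert z.grad is None  # z enters only under stop-gradient


def test_stop_gradient_on_two_parameter_toy_model():
    """p = w1·x, z = w2·x. Autodiff gives dL/dw2 = 0 exactly; dL/dw1 matches
    the finite difference of the loss with the stopped branch held constant
    (which is the semantics stop-gradient defines)."""
    x = np.array([[0.3, -1.2, 0.7]])
    w1_val, w2_val = 1.3, -0.8

    def loss_with_frozen_z(w1, z_const):
        p = Tensor(np.array(w1)) * Tensor(x)
        return negative_cosine(p, Tensor(z_const))

    w1 = Tensor(np.array(w1_val), requires_grad=True)
    w2 = Tensor(np.array(w2_val), requires_grad=True)
    p = w1 * Tensor(x)
    z = w2 * Tensor(x)
    negative_cosine(p, z).backward()
    assert w2.grad is None  # identically zero gradient along the stopped branch

    z_const = w2_val * x
    eps = 1e-7
    lp = float(loss_with_frozen_z(w1_val + eps, z_const).data)
    lm = float(loss_with_frozen_z(w1_val - eps, z_const).data)
    fd = (lp - lm) / (2 * eps)
    assert w1.grad == pytest.approx(fd, abs=1e-6)


def test_predictor_only_weights_match_finite_differences(tiny_model):
    """The predictor sits exclusively on the unstopped branch, so its autodiff
    gradient must equal the true finite difference of the loss."""
    rng = np.random.default_rng(3)
    x_i, x_j = rng.random((2, 3, 16, 16)), rng.random((2, 3, 16, 16))
    tiny_model.eval()

    def compute():
        return cmixup_loss(forward_quad(tiny_model, mix_views(x_i, x_j, 0.3)))

    loss = compute()
    loss.backward()
    w = list(tiny_model.predictor.parameters())[0]
    g = w.grad.copy()
    idx = tuple(0 for _ in w.shape)
    eps = 1e-6
    orig = w.data[idx]
    w.data[idx] = orig + eps
    lp = float(compute().data)
    w.data[idx] = orig - eps
    lm = float(compute().data)
    w.data[idx] = orig
    assert g[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)


# -- forward_quad -------------------------------------------------------------

def test_identical_inputs_share_weights(tiny_model):
    x = np.random.default_rng(4).random((2, 3, 16, 16))
    tiny_model.eval()
    quad = forward_quad(tiny_model, mix_views(x, x.copy(), 0.5))
    np.testing.assert_array_equal(quad.z_i.data, quad.z_tilde_j.data)
    np.testing.assert_array_equal(quad.p_i.data, quad.p_tilde_j.data)


def test_embedding_widths_follow_spec(tiny_model):
    x = np.random.default_rng(5).random((2, 3, 32, 32))
    quad = forward_quad(tiny_model, mix_views(x, x, 0.2))
    for t in (quad.p_i, quad.z_i, quad.p_tilde_j, quad.z_tilde_j):
        assert t.shape == (2, TINY_ENCODER.projector_out_dim)


def test_eval_forward_is_bit_stable(tiny_model):
    x = np.random.default_rng(6).random((2, 3, 16, 16))
    tiny_model.eval()
    q1 = forward_quad(tiny_model, mix_views(x, x, 0.1))
    q2 = forward_quad(tiny_model, mix_views(x, x, 0.1))
    np.testing.assert_array_equal(q1.p_i.data, q2.p_i.data)


def test_single_image_promoted_to_batch(tiny_model):
    x = np.random.default_rng(7).random((3, 16, 16))
    quad = forward_quad(tiny_model, mix_views(x, x, 0.2))
    assert quad.z_i.shape[0] == 1


def test_unknown_backbone_rejected():
    with pytest.raises(ValueError):
        build_model(EncoderSpec(backbone="vit"), np.random.default_rng(0))
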