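"""Knowledge-vision alignment: projection, contrastive loss, injection."""

import numpy as np
import pytest

from seedfusion._rng import spawn
from seedfusion.kva import (CrossAttention, ProjectionHead, TinyTextEncoder,
                            TinyVisualEncoder, contrastive_loss)
from seedfusion.nn import AdamW, Parameter, Tensor
from seedfusion.preprocessing import Vocabulary, tokenize


# ----------------------------------------------------------------- encoders
def test_visual_encoder_is_deterministic_and_shaped():
    enc = TinyVisualEncoder(out_dim=32, seed=3)
    imgs = np.random.default_rng(0).uniform(size=(2, 64, 64, 3))
    a = enc(imgs).data
    b = enc(imgs).data
    assert a.shape == (2, 32)
    np.testing.assert_array_equal(a, b)


def test_text_encoder_mean_of_embeddings():
    vocab = Vocabulary.from_corpus(["oval seed"])
    enc = TinyTextEncoder(len(vocab), out_dim=16, seed=0)
    tok = tokenize("oval seed", vocab)
    out = enc(tok).data
    ids = tok.token_ids[tok.attention_mask.astype(bool)]
    np.testing.assert_allclose(out, enc.embeddings.data[ids].mean(axis=0))


def test_frozen_encoders_survive_an_optimizer_step():
    enc = TinyVisualEncoder(out_dim=16, seed=1)
    before = [p.data.copy() for p in [enc.conv1.weight, enc.conv2.weight]]
    head = ProjectionHead(16, 16, spawn(0, "h"))
    opt = AdamW(enc.parameters() + head.parameters(), lr=0.1)
    imgs = np.random.default_rng(1).uniform(size=(2, 32, 32, 3))
    loss = (head(enc(imgs)) ** 2.0).sum()
    opt.zero_grad()
    loss.backward()
    opt.step()
    # gradient isolation: frozen parameters receive no gradient at all
    assert enc.conv1.weight.grad is None
    for p, b in zip([enc.conv1.weight, enc.conv2.weight], before):
        np.testing.assert_array_equal(p.data, b)


# --------------------------------------------------------------- projection
def test_projection_zero_weights_give_zero():
    head = ProjectionHead(4, 4, np.random.default_rng(0))
    for p in head.parameters():
        p.data = np.zeros_like(p.data)
    out = head(Tensor(np.ones((2, 4))))
    np.testing.assert_array_equal(out.data, 0.0)


def test_projection_matches_hand_computed_affine():
    rng = np.random.default_rng(4)
    head = ProjectionHead(3, 2, rng)
    x = rng.normal(size=(1, 3))
    l1, _, l2 = head.net.modules
    h = x @ l1.weight.data + l1.bias.data
    from scipy.special import erf
    h = h * 0.5 * (1 + erf(h / np.sqrt(2)))
    expected = h @ l2.weight.data + l2.bias.data
    np.testing.assert_allclose(head(Tensor(x)).data, expected, atol=1e-12)


def test_projection_dimension_mismatch_raises():
    head = ProjectionHead(4, 4, np.random.default_rng(0))
    with pytest.raises(ValueError):
        head(Tensor(np.ones((2, 5))))


# --------------------------------------------------------- contrastive loss
def test_contrastive_single_pair_is_zero():
    z = Tensor(np.array([[0.6, 0.8]]))
    assert contrastive_loss(z, z, 1.0).item() == pytest.approx(0.0, abs=1e-12)


def test_contrastive_orthogonal_two_pair_value():
    """Frozen oracle: all four log terms equal -log(e/(e+1)) ~ 0.31326."""
    z = Tensor(np.eye(2))
    loss = contrastive_loss(z, z, 1.0)
    expected = -np.log(np.e / (np.e + 1.0))  # 0.3132616875...
    assert loss.item() == pytest.approx(expected, abs=1e-9)
    assert loss.item() == pytest.approx(0.31326, abs=1e-5)


def test_contrastive_symmetric_in_modalities():
    rng = np.random.default_rng(6)
    zv = Tensor(rng.normal(size=(5, 8)))
    zt = Tensor(rng.normal(size=(5, 8)))
    assert contrastive_loss(zv, zt, 0.5).item() == pytest.approx(
        contrastive_loss(zt, zv, 0.5).item(), abs=1e-12)


def test_contrastive_rejects_bad_temperature_and_empty_batch():
    z = Tensor(np.eye(2))
    with pytest.raises(ValueError):
        contrastive_loss(z, z, 0.0)
    empty = Tensor(np.zeros((0, 2)))
    with pytest.raises(ValueError):
        contrastive_loss(empty, empty, 1.0)


def test_contrastive_training_aligns_toy_classes():
    """200 steps on a 4-class toy raise diagonal cosine above off-diagonal."""
    rng = np.random.default_rng(0)
    k, dim = 4, 8
    centers = rng.normal(size=(k, dim)) * 2
    fv = np.concatenate([c + 0.1 * rng.normal(size=(8, dim)) for c in centers])
    labels = np.repeat(np.arange(k), 8)
    ft = rng.normal(size=(k, dim))
    pv = ProjectionHead(dim, dim, spawn(1, "pv"))
    pt = ProjectionHead(dim, dim, spawn(1, "pt"))
    log_tau = Parameter(np.log(0.07))
    opt = AdamW(pv.parameters() + pt.parameters() + [log_tau], lr=3e-3)
    for _ in range(200):
        zv = pv(Tensor(fv))
        zt = pt(Tensor(ft[labels]))
        loss = contrastive_loss(zv, zt, log_tau.exp())
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert np.exp(log_tau.data) > 0  # positivity preserved under training

    def unit(x):
        return x / np.linalg.norm(x, axis=1, keepdims=True)

    zv = unit(pv(Tensor(fv)).data)
    zt = unit(pt(Tensor(ft)).data)
    sims = zv @ zt.T
    diag = sims[np.arange(len(labels)), labels].mean()
    off_mask = labels[:, None] != np.arange(k)[None, :]
    off = sims[off_mask].mean()
    assert diag - off >= 0.2


# ---------------------------------------------------------------- injection
def test_inject_single_token_identity_weights():
    d = 3
    attn = CrossAttention(d, d, np.random.default_rng(0))
    attn.wq.data = np.eye(d)
    attn.wk.data = np.eye(d)
    attn.wv.data = np.eye(d)
    zv = Tensor(np.array([[0.5, -1.0, 2.0]]))
    zt = Tensor(np.array([[1.0, 1.0, 0.0]]))
    sem = attn(zv, zt)
    np.testing.assert_allclose(sem.attention_weights.data, [[1.0]], atol=0)
    # pre-norm sum equals zv + zt; check through the LayerNorm algebra
    pre = zv.data + zt.data
    mu, var = pre.mean(), pre.var()
    expected = (pre - mu) / np.sqrt(var + 1e-5)
    np.testing.assert_allclose(sem.fsem.data, expected, atol=1e-12)


def test_inject_rows_sum_to_one_and_residual_identity():
    rng = np.random.default_rng(8)
    attn = CrossAttention(6, 4, rng)
    zv = Tensor(rng.normal(size=(5, 6)))
    zt = Tensor(rng.normal(size=(3, 6)))
    sem = attn(zv, zt)
    np.testing.assert_allclose(sem.attention_weights.data.sum(axis=1), 1.0,
                               atol=1e-6)
    # Fres + zv reconstructs Fsem exactly (same float path)
    np.testing.assert_array_equal(sem.fres.data + zv.data, sem.fsem.data)


def test_inject_matches_manual_two_dim_oracle():
    d = 2
    attn = CrossAttention(d, d, np.random.default_rng(0))
    wq = np.array([[1.0, 0.0], [0.0, 2.0]])
    wk = np.array([[0.5, 0.0], [0.0, 0.5]])
    wv = np.array([[1.0, 1.0], [0.0, 1.0]])
    attn.wq.data, attn.wk.data, attn.wv.data = wq, wk, wv
    zv = np.array([[1.0, 1.0]])
    zt = np.array([[1.0, 0.0], [0.0, 1.0]])
    # manual scaled dot-product attention
    q = zv @ wq
    k = zt @ wk
    v = zt @ wv
    scores = q @ k.T / np.sqrt(d)
    w = np.exp(scores - scores.max())
    w /= w.sum()
    pre = zv + w @ v
    mu, var = pre.mean(), pre.var()
    expected = (pre - mu) / np.sqrt(var + 1e-5)
    sem = attn(Tensor(zv), Tensor(zt))
    np.testing.assert_allclose(sem.fsem.data, expected, atol=1e-10)


def test_inject_zero_key_dim_rejected():
    with pytest.raises(ValueError):
        CrossAttention(4, 0, np.random.default_rng(0))
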