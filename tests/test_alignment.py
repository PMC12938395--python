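"""Projection, normalization, similarity, the symmetric InfoNCE objective
and the contrastive training loop."""

import numpy as np
import pytest

from radpath._autodiff import Tensor
from radpath.alignment import (AlignmentModel, ProjectionHead, TrainConfig,
                               infonce_symmetric, infonce_symmetric_grad,
                               l2_normalize, load_checkpoint, make_random_head,
                               make_random_model, project, save_checkpoint,
                               similarity_matrix, train_alignment, _infonce_t)
from radpath.encoders import AggregatorConfig
from radpath.evaluation import expected_recall_at_k, rank_matches, recall_at_k
from radpath.synthetic import generate_cohort, low_noise_config


# -- projection head -----------------------------------------------------------

def test_project_zero_second_map_gives_zero():
    head = make_random_head(4, 4, 4, seed=0)
    head.fc2.W.data[:] = 0.0
    head.fc2.b.data[:] = 0.0
    assert np.allclose(project(np.ones(4), head), 0.0)


def test_project_rectifier_floor():
    head = make_random_head(3, 3, 2, seed=1)
    head.ln.gamma.data[:] = 1.0
    head.ln.beta.data[:] = -100.0  # push all pre-activations negative
    out = project(np.array([0.4, -1.0, 2.0]), head)
    assert np.allclose(out, head.fc2.b.data)  # W2 @ 0 + bias


def test_project_tiny_head_matches_hand_arithmetic():
    head = ProjectionHead(2, 2, 2, np.random.default_rng(0))
    head.fc1.W.data = np.array([[1.0, 2.0], [0.5, -1.0]])
    head.fc1.b.data = np.array([0.1, -0.2])
    head.ln.gamma.data = np.array([2.0, 1.0])
    head.ln.beta.data = np.array([0.0, 0.5])
    head.fc2.W.data = np.array([[1.0, -1.0], [3.0, 0.0]])
    head.fc2.b.data = np.array([0.0, 1.0])
    x = np.array([1.0, 2.0])
    # hand trace: h = W1.T x + b (module computes x @ W1)
    h = x @ head.fc1.W.data + head.fc1.b.data
    mu, var = h.mean(), h.var()
    n = (h - mu) / np.sqrt(var + 1e-5) * head.ln.gamma.data + head.ln.beta.data
    r = np.maximum(n, 0.0)
    expected = r @ head.fc2.W.data + head.fc2.b.data
    assert np.allclose(project(x, head), expected, atol=1e-12)
    with pytest.raises(ValueError):
        project(np.ones(3), head)


# -- l2 normalization ------------------------------------------------------------

def test_l2_normalize_examples():
    assert np.allclose(l2_normalize(np.array([3.0, 4.0])), [0.6, 0.8])
    u = np.array([-2.0, 0.0, 0.0])
    assert np.allclose(l2_normalize(u), [-1.0, 0.0, 0.0])
    unit = np.array([0.0, 1.0])
    assert np.array_equal(l2_normalize(unit), unit)
    with pytest.raises(ValueError):
        l2_normalize(np.zeros(4))


# -- similarity matrix ------------------------------------------------------------

def test_similarity_matrix_examples():
    eye = np.eye(3)
    S = similarity_matrix(eye, eye, tau=1.0)
    assert np.allclose(S.values, np.eye(3))

    v = l2_normalize(np.array([1.0, 1.0]))
    S = similarity_matrix(v[None], v[None], tau=0.07)
    assert S.values[0, 0] == pytest.approx(1 / 0.07)

    S = similarity_matrix(v[None], -v[None], tau=0.5)
    assert S.values[0, 0] == pytest.approx(-2.0)

    with pytest.raises(ValueError):
        similarity_matrix(np.eye(3), np.eye(2), tau=1.0)
    with pytest.raises(ValueError):
        similarity_matrix(eye, eye, tau=0.0)


# -- InfoNCE -----------------------------------------------------------------------

def test_infonce_single_pair_is_zero():
    assert infonce_symmetric(np.array([[3.7]])) == pytest.approx(0.0)


@pytest.mark.parametrize("n", [2, 5, 15, 38])
def test_infonce_constant_matrix_equals_log_n(n):
    S = np.full((n, n), 0.3)
    assert infonce_symmetric(S) == pytest.approx(np.log(n), abs=1e-12)


def test_infonce_two_by_two_hand_value():
    S = np.array([[2.0, 0.0], [0.0, 2.0]])
    assert infonce_symmetric(S) == pytest.approx(np.log1p(np.exp(-2.0)), abs=1e-12)


def test_infonce_transpose_symmetry_exact():
    rng = np.random.default_rng(0)
    for _ in range(10):
        S = rng.normal(size=(6, 6))
        assert infonce_symmetric(S.T) == infonce_symmetric(S)


def test_infonce_nonnegative_with_diagonal_dominance_limit():
    rng = np.random.default_rng(1)
    for _ in range(20):
        assert infonce_symmetric(rng.normal(size=(5, 5))) >= 0.0
    S = np.eye(4) * 1e4
    assert infonce_symmetric(S) == pytest.approx(0.0, abs=1e-10)


def test_infonce_rejects_non_square():
    with pytest.raises(ValueError):
        infonce_symmetric(np.zeros((2, 3)))


def test_infonce_monotone_in_temperature_with_dominant_diagonal():
    rng = np.random.default_rng(2)
    cos = rng.uniform(-0.5, 0.5, size=(8, 8))
    np.fill_diagonal(cos, rng.uniform(0.8, 1.0, 8))
    losses = [infonce_symmetric(cos / tau) for tau in (0.2, 0.1, 0.07, 0.05, 0.01)]
    assert all(a >= b - 1e-12 for a, b in zip(losses, losses[1:]))


def test_infonce_gradients_match_finite_differences():
    rng = np.random.default_rng(3)
    for _ in range(5):
        S = rng.normal(size=(4, 4))
        g = infonce_symmetric_grad(S)
        st = Tensor(S, requires_grad=True)
        _infonce_t(st).backward()
        fd = np.zeros_like(S)
        eps = 1e-6
        for i in range(4):
            for j in range(4):
                Sp, Sm = S.copy(), S.copy()
                Sp[i, j] += eps
                Sm[i, j] -= eps
                fd[i, j] = (infonce_symmetric(Sp) - infonce_symmetric(Sm)) / (2 * eps)
        scale = max(np.abs(fd).max(), 1e-12)
        assert np.abs(g - fd).max() / scale < 1e-5
        assert np.abs(st.grad - fd).max() / scale < 1e-5


# -- training loop ------------------------------------------------------------------

def _tiny_cohort(n=16, seed=0):
    return generate_cohort(low_noise_config(
        n_patients=n, imaging_dim=24, patch_dim=8, latent_dim=3,
        patch_count_range=(2, 5), seed=seed))


def _tiny_config(**kw):
    base = dict(epochs=4, tau=0.1, batch_size=4, seed=0)
    base.update(kw)
    return TrainConfig(**base)


def test_training_reduces_loss():
    cohort = _tiny_cohort()
    agg = AggregatorConfig(feature_dim=8, num_heads=2, depth=1)
    res = train_alignment(cohort.samples[:12], cohort.samples[12:],
                          config=_tiny_config(epochs=8), agg_config=agg,
                          embed_dim=8, hidden_imaging=8, hidden_pathology=8)
    losses = res.history["train_loss"].to_numpy()
    assert losses[-1] < losses[0]


def test_training_is_seed_deterministic():
    cohort = _tiny_cohort()
    agg = AggregatorConfig(feature_dim=8, num_heads=2, depth=1)
    kw = dict(config=_tiny_config(), agg_config=agg,
              embed_dim=8, hidden_imaging=8, hidden_pathology=8)
    r1 = train_alignment(cohort.samples[:12], cohort.samples[12:], **kw)
    r2 = train_alignment(cohort.samples[:12], cohort.samples[12:], **kw)
    assert r1.history["train_loss"].tolist() == r2.history["train_loss"].tolist()
    s1, s2 = r1.model.state_dict(), r2.model.state_dict()
    assert all(np.array_equal(s1[k], s2[k]) for k in s1)


def test_training_rejects_degenerate_cohorts():
    cohort = _tiny_cohort(n=4)
    with pytest.raises(ValueError):
        train_alignment(cohort.samples[:1], cohort.samples[1:], config=_tiny_config())
    with pytest.raises(ValueError):
        TrainConfig(batch_size=1)


def test_tau_grid_selects_one_temperature():
    cohort = _tiny_cohort(n=20)
    agg = AggregatorConfig(feature_dim=8, num_heads=2, depth=1)
    res = train_alignment(cohort.samples[:14], cohort.samples[14:],
                          config=_tiny_config(tau=None, tau_grid=(0.07, 0.2), epochs=3),
                          agg_config=agg, embed_dim=8,
                          hidden_imaging=8, hidden_pathology=8)
    assert res.tau in (0.07, 0.2)
    assert set(res.history["tau"]) == {0.07, 0.2}


def test_trained_model_beats_random_retrieval(low_noise_alignment):
    cohort, result = low_noise_alignment
    heldout = cohort.samples[60:]
    e_img, e_path = result.model.embed_samples(heldout)
    r1 = recall_at_k(rank_matches(e_img @ e_path.T), 1)
    assert r1 >= 5 * expected_recall_at_k(len(heldout), 1)


def test_checkpoint_round_trip(tmp_path, low_noise_alignment):
    cohort, result = low_noise_alignment
    path = tmp_path / "ckpt.npz"
    save_checkpoint(result.model, path)
    back = load_checkpoint(path)
    e1, p1 = result.model.embed_samples(cohort.samples[:5])
    e2, p2 = back.embed_samples(cohort.samples[:5])
    assert np.array_equal(e1, e2) and np.array_equal(p1, p2)
    assert back.tau == result.model.tau


# -- random-projection control --------------------------------------------------

def test_random_head_seeding():
    h1 = make_random_head(8, 8, 4, seed=3)
    h2 = make_random_head(8, 8, 4, seed=3)
    h3 = make_random_head(8, 8, 4, seed=4)
    assert np.array_equal(h1.fc1.W.data, h2.fc1.W.data)
    assert not np.array_equal(h1.fc1.W.data, h3.fc1.W.data)


def test_random_heads_retrieve_at_chance_level():
    """Monte-Carlo over 500 random head pairs: held-out Recall@1 must sit at
    the analytic 1/N uniform-ranking level."""
    rng = np.random.default_rng(0)
    n, d_in = 38, 16
    x_img = rng.normal(size=(n, d_in))
    x_path = rng.normal(size=(n, d_in))  # unrelated modalities: no true signal
    hits = []
    for seed in range(500):
        hi = make_random_head(d_in, 8, 8, seed=2 * seed)
        hp = make_random_head(d_in, 8, 8, seed=2 * seed + 1)
        e_img = hi(Tensor(x_img)).data
        e_path = hp(Tensor(x_path)).data
        e_img /= np.linalg.norm(e_img, axis=1, keepdims=True)
        e_path /= np.linalg.norm(e_path, axis=1, keepdims=True)
        hits.append(recall_at_k(rank_matches(e_img @ e_path.T), 1))
    assert abs(np.mean(hits) - 1 / n) < 0.005


def test_random_model_is_untrained_control(low_noise_alignment):
    cohort, _ = low_noise_alignment
    m1 = make_random_model(512, AggregatorConfig(feature_dim=64), seed=5)
    m2 = make_random_model(512, AggregatorConfig(feature_dim=64), seed=5)
    e1, _ = m1.embed_samples(cohort.samples[:4])
    e2, _ = m2.embed_samples(cohort.samples[:4])
    assert np.array_equal(e1, e2)
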