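"""Latent parameterization, sampling and the four loss primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divqg.mic import MicConfig
from divqg.multi_latent import (
    FeatureReconstructor,
    LatentConfig,
    LatentHeads,
    kl_loss,
    mic_loss,
    pairwise_mic_matrix,
    reconstruction_loss,
    sample_latents,
)
from divqg.nn import Tensor

LCFG = LatentConfig(n_spaces=3, d_z=4, mlp_hidden=8)


@pytest.fixture(scope="module")
def heads():
    return LatentHeads(6, LCFG, np.random.default_rng(0))


def test_sigma_strictly_positive_everywhere(heads, rng):
    f = Tensor(rng.normal(size=(5, 6)))
    for k in range(LCFG.n_spaces):
        _, sigma = heads.space_params(f, k)
        assert np.all(sigma.data > 0)


def test_distinct_spaces_have_distinct_parameters(heads, rng):
    f = Tensor(rng.normal(size=(2, 6)))
    mu0, sg0 = heads.space_params(f, 0)
    mu1, sg1 = heads.space_params(f, 1)
    assert not np.allclose(mu0.data, mu1.data)
    assert not np.allclose(sg0.data, sg1.data)


def test_same_input_same_parameters(heads, rng):
    f = Tensor(rng.normal(size=(2, 6)))
    a = heads.space_params(f, 1)
    b = heads.space_params(f, 1)
    assert np.array_equal(a[0].data, b[0].data)


def test_space_index_out_of_range(heads):
    with pytest.raises(IndexError):
        heads.space_params(Tensor(np.zeros((1, 6))), LCFG.n_spaces)


# -- sampling ---------------------------------------------------------------


def test_zero_noise_returns_means():
    params = [(np.array([[1.0, -2.0]]), np.array([[0.5, 3.0]]))]
    (s,) = sample_latents(params, noise=[np.zeros((1, 2))])
    assert np.array_equal(s.data, [[1.0, -2.0]])


def test_reparameterization_formula_scalar_case():
    """mu=0, sigma=1, eta=0.5 -> s = 0.5."""
    (s,) = sample_latents([(np.zeros((1, 1)), np.ones((1, 1)))],
                          noise=[np.full((1, 1), 0.5)])
    assert s.item() == pytest.approx(0.5)


def test_zero_sigma_limit_ignores_noise():
    (s,) = sample_latents([(np.array([[2.0]]), np.array([[0.0]]))],
                          noise=[np.array([[7.0]])])
    assert s.item() == pytest.approx(2.0)


def test_noise_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="shape"):
        sample_latents([(np.zeros((1, 2)), np.ones((1, 2)))],
                       noise=[np.zeros((1, 3))])


# -- reconstruction loss ----------------------------------------------------


def test_perfect_reconstruction_gives_zero():
    f = np.array([1.0, 2.0, 3.0])
    assert reconstruction_loss(f, [f, f]).item() == pytest.approx(0.0)


def test_squared_norm_convention():
    """f=(3,4) vs zero reconstruction -> squared distance 25."""
    assert reconstruction_loss(np.array([3.0, 4.0]),
                               [np.zeros(2)]).item() == pytest.approx(25.0)


def test_loss_sums_over_spaces():
    f = np.array([3.0, 4.0])
    one = reconstruction_loss(f, [np.zeros(2)]).item()
    three = reconstruction_loss(f, [np.zeros(2)] * 3).item()
    assert three == pytest.approx(3 * one)


def test_reconstructor_output_dimension():
    recon = FeatureReconstructor(7, LCFG, np.random.default_rng(1))
    out = recon(Tensor(np.zeros((2, LCFG.d_z))), 0)
    assert out.data.shape == (2, 7)


# -- KL loss ----------------------------------------------------------------


@pytest.mark.parametrize(
    "mu,sigma,expected",
    [(0.0, 1.0, 0.0), (1.0, 1.0, 0.5), (2.0, 1.0, 2.0)],
)
def test_kl_closed_form_cases(mu, sigma, expected):
    params = [(np.array([[mu]]), np.array([[sigma]]))]
    assert kl_loss(params).item() == pytest.approx(expected)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    mu=st.lists(st.floats(-3, 3), min_size=1, max_size=5),
    log_sigma=st.lists(st.floats(-2, 1), min_size=1, max_size=5),
)
def test_kl_matches_independent_high_precision_formula(mu, log_sigma):
    d = min(len(mu), len(log_sigma))
    mu_v = np.asarray(mu[:d])
    sg_v = np.exp(np.asarray(log_sigma[:d]))
    got = kl_loss([(mu_v[None, :], sg_v[None, :])]).item()
    # independent evaluation: elementwise Gaussian KL, python floats
    import math

    expected = sum(
        0.5 * (-math.log(s * s) + m * m + s * s - 1.0)
        for m, s in zip(mu_v, sg_v)
    )
    assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)
    assert got >= -1e-12


def test_kl_rejects_nonpositive_sigma():
    with pytest.raises(ValueError, match="positive"):
        kl_loss([(np.zeros((1, 1)), np.zeros((1, 1)))])


# -- MIC loss ---------------------------------------------------------------

MCFG = MicConfig(grid_bound_override=9, max_grid_side=4)


def test_single_space_has_no_pairs():
    rng = np.random.default_rng(0)
    assert mic_loss([rng.normal(size=(16, 3))], MCFG).item() == 0.0


def test_identical_spaces_have_unit_exact_mic():
    rng = np.random.default_rng(1)
    s = rng.normal(size=(16, 3))
    assert mic_loss([s, s.copy()], MCFG, mode="exact").item() == pytest.approx(1.0)


def test_exact_mode_equals_oracle_average(rng):
    from divqg.mic import mic_exact

    a, b = rng.normal(size=(12, 2)), rng.normal(size=(12, 2))
    got = mic_loss([a, b], MCFG, mode="exact").item()
    expected = np.mean([mic_exact(a[:, j], b[:, j], MCFG) for j in range(2)])
    assert got == pytest.approx(expected)


def test_surrogate_is_differentiable_and_nonnegative(rng):
    x = Tensor(rng.normal(size=(16, 3)), requires_grad=True)
    y = Tensor(rng.normal(size=(16, 3)) + 0.5 * x.data, requires_grad=True)
    loss = mic_loss([x, y], MCFG, mode="surrogate")
    assert loss.item() >= 0
    loss.backward()
    assert x.grad is not None and np.any(x.grad != 0)


def test_small_batch_rejected():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError, match="at least 4"):
        mic_loss([rng.normal(size=(3, 2)), rng.normal(size=(3, 2))], MCFG)


def test_pairwise_matrix_properties(rng):
    a, b, c = (rng.normal(size=(14, 2)) for _ in range(3))
    m = pairwise_mic_matrix([a, b, c], MCFG)
    assert m.shape == (3, 3)
    assert np.allclose(np.diag(m), 1.0)
    assert np.array_equal(m, m.T)
    assert np.all((m >= 0) & (m <= 1))


def test_duplicated_spaces_score_above_independent(rng):
    a = rng.normal(size=(20, 2))
    independent = rng.normal(size=(20, 2))
    m_dup = pairwise_mic_matrix([a, a.copy()], MCFG)
    m_ind = pairwise_mic_matrix([a, independent], MCFG)
    assert m_dup[0, 1] > m_ind[0, 1]
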