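import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from interblock.priors import (
    HyperParams,
    PriorSpec,
    constrain_phi,
    corr_from_fisher_z,
    latent_to_sigma,
    log_prior_density,
    sample_sigma,
    sigma_to_latent,
    unconstrain_phi,
)


def lognormal_spec(theta=(0.0, 0.0, 0.0), phi=None):
    return PriorSpec(
        "lognormal",
        HyperParams(theta=np.asarray(theta, float), phi=np.eye(3) if phi is None else phi),
    )


def gamma_spec(shape=(2.0, 2.0, 2.0), scale=(1.0, 1.0, 1.0), corr=None):
    return PriorSpec("gamma", HyperParams(shape=shape, scale=scale, corr=corr))


def test_constrain_phi_identity_at_zero():
    assert constrain_phi(np.zeros(6)) == pytest.approx(np.eye(3))


def test_constrain_phi_fisher_z_value():
    lam = np.zeros(6)
    lam[3] = 0.5 * np.log(3.0)  # exp(2*lam) = 3 -> corr = (3-1)/(3+1) = 0.5
    phi = constrain_phi(lam)
    assert phi[0, 1] == pytest.approx(0.5)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(-2.0, 2.0), min_size=6, max_size=6))
def test_constrain_phi_round_trip(lam):
    lam = np.asarray(lam)
    phi = constrain_phi(lam)
    assert np.allclose(phi, phi.T)
    assert np.all(np.diag(phi) > 0)
    assert np.allclose(unconstrain_phi(phi), lam, atol=1e-10)


def test_lognormal_zero_latent_gives_exp_theta():
    theta = np.array([-1.6, -0.9, 0.0])
    spec = lognormal_spec(theta=theta, phi=0.25 * np.eye(3))
    assert latent_to_sigma(np.zeros(3), spec) == pytest.approx(np.exp(theta))


def test_gamma_zero_latent_gives_median():
    spec = gamma_spec(shape=(2.0, 2.0, 2.0), scale=(1.0, 1.0, 1.0))
    med = stats.gamma(a=2.0).median()
    assert latent_to_sigma(np.zeros(3), spec) == pytest.approx([med] * 3, rel=1e-9)


@pytest.mark.parametrize("family", ["lognormal", "gamma", "inverse_gamma"])
def test_latent_map_monotone(family):
    if family == "lognormal":
        spec = lognormal_spec(phi=np.diag([0.3, 0.2, 0.4]))
    else:
        spec = PriorSpec(family, HyperParams(shape=(2.0, 3.0, 4.0), scale=(0.5, 1.0, 2.0)))
    grid = np.linspace(-3, 3, 21)
    for dim in range(3):
        z = np.zeros((21, 3))
        z[:, dim] = grid
        vals = latent_to_sigma(z, spec)[:, dim]
        d = np.diff(vals)
        if family == "inverse_gamma":
            assert np.all(d < 0)  # reciprocal of an increasing map
        else:
            assert np.all(d > 0)
        assert np.all(vals > 0)


@pytest.mark.parametrize(
    "spec",
    [
        lognormal_spec(theta=(-1.0, 0.2, 0.5), phi=np.array([[0.4, 0.1, 0.0], [0.1, 0.3, -0.05], [0.0, -0.05, 0.2]])),
        gamma_spec(shape=(1.5, 2.5, 4.0), scale=(0.2, 0.5, 0.3), corr=corr_from_fisher_z([0.3, -0.2, 0.1])),
        PriorSpec("inverse_gamma", HyperParams(shape=(3.0, 4.0, 5.0), scale=(0.5, 0.8, 1.2), corr=corr_from_fisher_z([0.2, 0.0, -0.3]))),
    ],
    ids=["lognormal", "gamma", "inverse_gamma"],
)
def test_latent_round_trip(spec):
    rng = np.random.default_rng(3)
    z = rng.standard_normal((200, 3)).clip(-4, 4)
    sig = latent_to_sigma(z, spec)
    assert np.allclose(sigma_to_latent(sig, spec), z, atol=1e-8)


def test_prior_moments_match_closed_forms():
    """Sample moments of large draws match the families' analytic means."""
    rng = np.random.default_rng(9)
    n = 10**6
    theta = np.array([-1.6, -0.9, 0.0])
    spec = lognormal_spec(theta=theta, phi=0.25 * np.eye(3))
    m = sample_sigma(spec, n, rng).mean(axis=0)
    assert m == pytest.approx(np.exp(theta + 0.125), rel=0.01)

    alpha, beta = np.array([2.0, 3.0, 4.0]), np.array([0.1, 0.2, 0.3])
    m = sample_sigma(gamma_spec(shape=alpha, scale=beta), n, rng).mean(axis=0)
    assert m == pytest.approx(alpha * beta, rel=0.01)

    # reciprocal construction: IG mean is beta'/(alpha-1) with beta' = 1/beta
    spec_ig = PriorSpec("inverse_gamma", HyperParams(shape=alpha, scale=beta))
    m = sample_sigma(spec_ig, n, rng).mean(axis=0)
    assert m == pytest.approx(1.0 / (beta * (alpha - 1.0)), rel=0.01)


def test_lognormal_density_standard_value():
    spec = lognormal_spec()
    val = log_prior_density(np.ones(3), spec)
    assert val == pytest.approx(3 * (-0.5 * np.log(2 * np.pi)), abs=1e-12)


def test_gamma_density_factorises_under_independence():
    alpha, beta = np.array([1.5, 2.5, 4.0]), np.array([0.2, 0.5, 0.3])
    spec = gamma_spec(shape=alpha, scale=beta)
    x = np.array([0.3, 1.2, 0.9])
    expect = sum(stats.gamma(a=a, scale=b).logpdf(xi) for a, b, xi in zip(alpha, beta, x))
    assert log_prior_density(x, spec) == pytest.approx(expect, rel=1e-9)


def test_inverse_gamma_marginal_density():
    alpha, beta = np.array([3.0, 3.0, 3.0]), np.array([0.5, 0.5, 0.5])
    spec = PriorSpec("inverse_gamma", HyperParams(shape=alpha, scale=beta))
    x = np.array([0.4, 0.7, 1.1])
    expect = sum(stats.invgamma(a=3.0, scale=2.0).logpdf(xi) for xi in x)
    assert log_prior_density(x, spec) == pytest.approx(expect, rel=1e-9)


def test_sampling_consistent_with_density():
    """Draws from the latent construction follow the stated joint density.

    Marginals: the probability integral transform of each component under
    its analytic marginal c.d.f. is uniform (KS test).  Dependence: the
    normal scores of the transformed draws reproduce the latent correlation
    matrix R of the Gaussian copula.
    """
    R = corr_from_fisher_z([0.4, -0.1, 0.2])
    alpha, beta = np.array([3.0, 4.0, 5.0]), np.array([0.3, 0.2, 0.4])
    spec = gamma_spec(shape=alpha, scale=beta, corr=R)
    rng = np.random.default_rng(21)
    draws = sample_sigma(spec, 100_000, rng)
    u = np.column_stack(
        [stats.gamma(a=a, scale=b).cdf(draws[:, i]) for i, (a, b) in enumerate(zip(alpha, beta))]
    )
    for i in range(3):
        assert stats.kstest(u[:5000, i], "uniform").pvalue > 0.01
    scores = stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
    assert np.corrcoef(scores.T) == pytest.approx(R, abs=0.02)


def test_density_normalises_on_grid():
    # compactly concentrated lognormal: 3-D trapezoid integral ~ 1
    spec = lognormal_spec(theta=(-1.0, -0.5, 0.0), phi=0.04 * np.eye(3))
    g = [np.exp(np.linspace(t - 1.2, t + 1.2, 81)) for t in (-1.0, -0.5, 0.0)]
    G = np.stack(np.meshgrid(*g, indexing="ij"), axis=-1).reshape(-1, 3)
    vals = np.exp(log_prior_density(G, spec)).reshape(81, 81, 81)
    integral = np.trapezoid(np.trapezoid(np.trapezoid(vals, g[2], axis=2), g[1], axis=1), g[0])
    assert integral == pytest.approx(1.0, abs=5e-3)


def test_invalid_specs_rejected():
    with pytest.raises(ValueError, match="family"):
        PriorSpec("weibull", HyperParams())
    with pytest.raises(ValueError):
        PriorSpec("lognormal", HyperParams(theta=np.zeros(3)))  # missing phi
    with pytest.raises(ValueError):
        gamma_spec(shape=(-1.0, 2.0, 2.0))
    with pytest.raises(ValueError, match="positive"):
        log_prior_density(np.array([0.0, 1.0, 1.0]), lognormal_spec())
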