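import numpy as np
import pytest

from interblock.anova import TrialData, design_matrices
from interblock.design import generate_alpha_design
from interblock.likelihood import VarianceComponents
from interblock.mixed_model import (
    gls_blue,
    pairwise_differences,
    reml_fit,
    reml_loglik,
)
from interblock.simulate import DEFAULT_PRIOR, simulate_trial


def grid_search_reml(data, hi=None, rounds=8, m=11):
    """Independent nested grid search of the REML criterion (the oracle)."""
    hi0 = hi if hi is not None else 4.0 * np.var(data.response)
    lo = np.zeros(3)
    hi = np.array([hi0] * 3)
    best = None
    for _ in range(rounds):
        axes = [np.linspace(lo[i], hi[i], m) for i in range(3)]
        G = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        G = G[G[:, 2] > 1e-9]
        vals = np.array([reml_loglik(data, g) for g in G])
        best = G[np.argmax(vals)]
        span = (hi - lo) / (m - 1)
        lo = np.maximum(best - span, 0.0)
        hi = best + span
    return best


def henderson_mme(data, sigma):
    """Direct solve of the Henderson mixed-model equations (the oracle)."""
    y = data.response
    X, Zr, Zb = design_matrices(data)
    Xt = X[:, 1:]
    Z = np.hstack([Zr, Zb])
    sr2, sb2, se2 = sigma.as_array()
    G = np.diag([max(sr2, 1e-12)] * Zr.shape[1] + [max(sb2, 1e-12)] * Zb.shape[1])
    A = np.block(
        [
            [Xt.T @ Xt / se2, Xt.T @ Z / se2],
            [Z.T @ Xt / se2, Z.T @ Z / se2 + np.linalg.inv(G)],
        ]
    )
    b = np.concatenate([Xt.T @ y / se2, Z.T @ y / se2])
    return np.linalg.solve(A, b)[: Xt.shape[1]]


@pytest.fixture(scope="module")
def trial(layout_a):
    return simulate_trial(
        layout_a, DEFAULT_PRIOR(), 1.0, np.random.default_rng(5)
    ).data


def test_reml_matches_grid_search_oracle(layout_a):
    rng = np.random.default_rng(17)
    for _ in range(3):
        data = simulate_trial(layout_a, DEFAULT_PRIOR(), 1.0, rng).data
        fit = reml_fit(data)
        oracle = grid_search_reml(data)
        assert np.allclose(fit.sigma.as_array(), oracle, atol=1e-4)
        # criterion dominance: the fit is at least as good as every grid point
        assert fit.reml_loglik >= reml_loglik(data, oracle) - 1e-8


def test_reml_matches_statsmodels():
    """Independent cross-check against the MixedLM REML engine on an
    interior (non-boundary) trial."""
    import warnings

    import pandas as pd
    import statsmodels.formula.api as smf

    layout = generate_alpha_design(12, 4, 4, seed=9)
    sim = simulate_trial(
        layout,
        DEFAULT_PRIOR(),
        1.0,
        np.random.default_rng(77),
        sigma=VarianceComponents(0.5, 0.8, 1.0),
    )
    fit = reml_fit(sim.data)
    rep, blk, trt = layout.arrays()
    df = pd.DataFrame(
        {
            "y": sim.data.response,
            "trt": trt.astype(str),
            "rep": rep.astype(str),
            "blk": blk.astype(str),
            "g": 1,
        }
    )
    md = smf.mixedlm(
        "y ~ 0 + trt", df, groups="g",
        vc_formula={"rep": "0 + C(rep)", "blk": "0 + C(blk)"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mf = md.fit(reml=True)
    names = list(md.exog_vc.names)
    sm_sigma = np.array(
        [mf.vcomp[names.index("rep")], mf.vcomp[names.index("blk")], mf.scale]
    )
    assert np.allclose(fit.sigma.as_array(), sm_sigma, rtol=1e-3, atol=1e-4)


def test_reml_zero_boundary_frequency(layout_a):
    """Small trials with block variance ~ half the error variance: REML hits
    the zero boundary for blocks in a substantial fraction of trials, the
    phenomenon that motivates the hierarchical approach."""
    rng = np.random.default_rng(23)
    fixed = VarianceComponents(0.2, 0.5, 1.0)
    zeros = 0
    n = 300
    for _ in range(n):
        data = simulate_trial(layout_a, DEFAULT_PRIOR(), 1.0, rng, sigma=fixed).data
        fit = reml_fit(data)
        zeros += fit.sigma.sigma_b2 == 0.0
        assert fit.sigma.sigma_e2 > 0
    assert zeros / n > 0.10


def test_degenerate_all_equal_response(layout_a):
    data = TrialData(layout_a, np.full(12, 2.0))
    fit = reml_fit(data)
    assert fit.boundary_flags == (True, True, True)
    assert fit.sigma.sigma_e2 > 0  # floored, not zero


def test_gls_reduces_to_raw_means_without_design_variances(trial):
    est = gls_blue(trial, VarianceComponents(0.0, 0.0, 1.0))
    _, _, trt = trial.layout.arrays()
    raw = np.array([trial.response[trt == i].mean() for i in range(6)])
    assert est.blue == pytest.approx(raw, abs=1e-10)


def test_gls_translation_equivariance(trial):
    sig = VarianceComponents(0.2, 0.4, 1.0)
    base = gls_blue(trial, sig)
    shifted = gls_blue(
        TrialData(trial.layout, trial.response + 5.0, trial.trial_id), sig
    )
    assert shifted.blue == pytest.approx(base.blue + 5.0, abs=1e-9)
    assert shifted.vcov_diff == pytest.approx(base.vcov_diff, abs=1e-12)


def test_gls_equals_henderson_mme(trial):
    sig = VarianceComponents(0.2, 0.4, 1.0)
    est = gls_blue(trial, sig)
    assert np.allclose(est.blue, henderson_mme(trial, sig), atol=1e-10)
    d = est.vcov_diff
    assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)
    iu = np.triu_indices(6, k=1)
    assert np.all(d[iu] > 0)


def test_interpolation_between_block_estimators(trial):
    """Recovery of inter-block information: as sigma_b^2 sweeps 0 -> inf the
    BLUE differences move from the unadjusted to the fully block-adjusted
    (intra-block) estimator."""
    X, Zr, Zb = design_matrices(trial)
    y = trial.response
    # fixed-block (intra-block) estimator: OLS with blocks as fixed effects
    M = np.hstack([X[:, 1:], Zb])
    beta = np.linalg.pinv(M) @ y
    intra = beta[:6]
    intra_diff = intra[0] - intra[1]

    no_block = gls_blue(trial, VarianceComponents(0.0, 0.0, 1.0))
    lo_diff = no_block.blue[0] - no_block.blue[1]
    prev = lo_diff
    path = [prev]
    for sb2 in (0.1, 1.0, 10.0, 1e4, 1e6):
        est = gls_blue(trial, VarianceComponents(0.0, sb2, 1.0))
        path.append(est.blue[0] - est.blue[1])
    assert path[-1] == pytest.approx(intra_diff, abs=1e-3)
    # monotone interpolation between the two limits
    diffs = np.diff(path)
    assert np.all(diffs >= -1e-9) or np.all(diffs <= 1e-9)


def test_gls_at_zero_block_variance_equals_no_block_model(trial):
    """The 'dropped stratum' behaviour: plugging sigma_b^2 = 0 is the same
    as fitting a model with no block effects at all."""
    fit = reml_fit(trial)
    sig0 = VarianceComponents(fit.sigma.sigma_r2, 0.0, fit.sigma.sigma_e2)
    est = gls_blue(trial, sig0)
    X, Zr, _ = design_matrices(trial)
    sr2, se2 = fit.sigma.sigma_r2, fit.sigma.sigma_e2
    V = sr2 * (Zr @ Zr.T) + se2 * np.eye(12)
    Xt = X[:, 1:]
    beta = np.linalg.solve(Xt.T @ np.linalg.solve(V, Xt), Xt.T @ np.linalg.solve(V, trial.response))
    assert est.blue == pytest.approx(beta, abs=1e-9)


def test_complete_block_reml_equals_anova_means():
    """For k = t (randomised complete blocks) treatment differences are
    orthogonal to blocks: REML-based BLUEs equal raw mean differences."""
    layout = generate_alpha_design(6, 2, 6, seed=4)
    sim = simulate_trial(layout, DEFAULT_PRIOR(), 1.0, np.random.default_rng(31))
    fit = reml_fit(sim.data)
    est = gls_blue(sim.data, fit.sigma)
    _, _, trt = layout.arrays()
    raw = np.array([sim.data.response[trt == i].mean() for i in range(6)])
    d_est = est.blue[:, None] - est.blue[None, :]
    d_raw = raw[:, None] - raw[None, :]
    assert np.allclose(d_est, d_raw, atol=1e-8)


@pytest.mark.parametrize("t,expect", [(6, 15), (100, 4950)])
def test_pairwise_difference_count(t, expect):
    from interblock.mixed_model import TreatmentEstimates

    te = TreatmentEstimates(
        blue=np.arange(t, dtype=float),
        vcov_diff=np.zeros((t, t)),
        sigma_used=VarianceComponents(0.1, 0.1, 1.0),
    )
    pairs = pairwise_differences(te)
    assert len(pairs) == expect
    # antisymmetry through the stored ordered pairs
    i, j, d = pairs[0]
    assert d == pytest.approx(-(te.blue[j - 1] - te.blue[i - 1]))


def test_gls_requires_positive_error_variance(trial):
    with pytest.raises(ValueError):
        gls_blue(trial, VarianceComponents(0.1, 0.1, 0.0))
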