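"""Empirical Bayes fitting of the hierarchical variance-component model.

The marginal likelihood of one trial's sums of squares under a prior family
is the integral, over the trivariate standard-normal latent scale,

    L_t = int exp( l(SS_t | sigma(z)) ) phi_3(z) dz

with sigma(z) the family's inverse-c.d.f. map (:func:`interblock.priors
.latent_to_sigma`).  The integral is evaluated by Gauss--Hermite quadrature,
adaptively recentred and rescaled at each trial's conditional mode, and the
sum over trials is maximised over the hyper-parameters by a quasi-Newton
optimiser on an unconstrained parameterisation.  Per-trial variance
components are then predicted by their posterior means (ratios of
quadrature sums).

Everything is vectorised across trials: the mode search is a damped Newton
iteration run simultaneously for all trials with finite-difference
derivatives, warm-started between optimiser evaluations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import logsumexp

from .anova import AnovaSummary
from .likelihood import VarianceComponents, pack_summaries, trial_loglik_arrays
from .priors import (
    FAMILIES,
    HyperParams,
    PriorSpec,
    constrain_phi,
    corr_from_fisher_z,
    fisher_z_from_corr,
    latent_to_sigma,
    sigma_to_latent,
    unconstrain_phi,
)

__all__ = [
    "QuadratureConfig",
    "EBFit",
    "marginal_loglik",
    "fit_eb",
    "predict_sigma_eb",
    "anova_sigma_estimates",
]

_LOG2PI = np.log(2.0 * np.pi)
N_HYPER = 9  # every family exposes 9 free hyper-parameters


@dataclass
class QuadratureConfig:
    """Gauss--Hermite settings for the 3-D latent integral.

    nodes_per_dim   nodes per latent dimension (total nodes_per_dim**3)
    adaptive        recentre/rescale nodes at each trial's conditional mode,
                    using the mode's curvature (recommended; without it the
                    nodes sit at the prior's origin and large-df trials are
                    integrated poorly)
    mode_tol        gradient tolerance of the per-trial mode search
    """

    nodes_per_dim: int = 7
    adaptive: bool = True
    mode_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.nodes_per_dim < 3:
            raise ValueError("need at least 3 quadrature nodes per dimension")

    @property
    def total_nodes(self) -> int:
        return self.nodes_per_dim**3


@dataclass
class EBFit:
    """Result of an empirical-Bayes fit."""

    spec: PriorSpec
    loglik: float
    n_params: int
    aic: float
    per_trial_sigma: list[VarianceComponents]
    convergence: dict = field(default_factory=dict)
    quad: QuadratureConfig = field(default_factory=QuadratureConfig)


# ---------------------------------------------------------------------------
# ANOVA moment estimates (starting values)

def anova_sigma_estimates(trials: list[AnovaSummary], floor_frac: float = 1e-3) -> np.ndarray:
    """Classical ANOVA (moment) estimates of sigma per trial, floored positive.

    Solves MS_i = E(MS_i) stratum by stratum; nonpositive replicate/block
    solutions (the very phenomenon that motivates the hierarchical model)
    are floored at ``floor_frac * MS_e`` so logs exist.  Returns (n, 3).
    """
    V, SS, C = pack_summaries(trials)
    return anova_sigma_from_arrays(V, SS, C, floor_frac)


def anova_sigma_from_arrays(V, SS, C, floor_frac: float = 1e-3) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        MS = np.where(V > 0, SS / np.where(V > 0, V, 1.0), np.nan)
    se2 = MS[:, 2]
    sb2 = np.where(V[:, 1] > 0, (MS[:, 1] - se2) / np.where(C[:, 2] > 0, C[:, 2], 1.0), 0.0)
    sr2 = np.where(
        V[:, 0] > 0,
        (MS[:, 0] - se2 - C[:, 0] * sb2) / np.where(C[:, 1] > 0, C[:, 1], 1.0),
        0.0,
    )
    out = np.stack([sr2, sb2, se2], axis=1)
    floor = floor_frac * np.maximum(se2, 1e-300)[:, None]
    return np.maximum(out, floor)


# ---------------------------------------------------------------------------
# vectorised conditional-mode search

def _integrand_log(z, V, SS, C, spec):
    """log[ exp(trial_loglik) * phi_3(z) ] for z of shape (n, 3) or (n, m, 3).

    Nodes where the likelihood overflows (e.g. exp overflow in the latent
    map far in the tails) contribute -inf, not NaN, so they simply drop out
    of the logsumexp.
    """
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        sigma = latent_to_sigma(z, spec)
        if z.ndim == 3:
            ll = trial_loglik_arrays(V[:, None, :], SS[:, None, :], C[:, None, :], sigma)
        else:
            ll = trial_loglik_arrays(V, SS, C, sigma)
        out = ll - 0.5 * np.sum(z * z, axis=-1) - 1.5 * _LOG2PI
    return np.where(np.isnan(out), -np.inf, out)


def _fd_grad_hess(f, z, eps=1e-4):
    """Central finite-difference gradient (n,3) and Hessian (n,3,3) of f over z."""
    n = z.shape[0]
    g = np.empty((n, 3))
    H = np.empty((n, 3, 3))
    f0 = f(z)
    fp = np.empty((3, n))
    fm = np.empty((3, n))
    for d in range(3):
        e = np.zeros(3)
        e[d] = eps
        fp[d] = f(z + e)
        fm[d] = f(z - e)
        g[:, d] = (fp[d] - fm[d]) / (2 * eps)
        H[:, d, d] = (fp[d] - 2 * f0 + fm[d]) / eps**2
    for a in range(3):
        for b in range(a + 1, 3):
            ea = np.zeros(3)
            eb = np.zeros(3)
            ea[a] = eps
            eb[b] = eps
            mixed = (
                f(z + ea + eb) - f(z + ea - eb) - f(z - ea + eb) + f(z - ea - eb)
            ) / (4 * eps**2)
            H[:, a, b] = H[:, b, a] = mixed
    return f0, g, H


def _neg_hess_pd(H, floor=0.25):
    """Project -H to positive definite via batched eigendecomposition.

    The integrand is likelihood x standard-normal prior, and the prior
    alone contributes +1 curvature per latent dimension; flat or convex
    likelihood directions are floored at 0.25 so the quadrature's scaling
    covariance never exceeds 4 (twice the prior sd per axis).
    """
    H = np.where(np.isfinite(H), H, 0.0)
    w, v = np.linalg.eigh(-H)
    w = np.maximum(w, floor)
    return w, v


def _find_modes(V, SS, C, spec, z0, tol=1e-8, max_iter=40):
    """Damped Newton search for the per-trial conditional modes, vectorised.

    Returns (z_hat, cov) where cov is the inverse of the (PD-projected)
    negative Hessian at the mode — the adaptive quadrature's scaling matrix.
    """
    f = lambda z: _integrand_log(z, V, SS, C, spec)
    z = np.array(z0, dtype=float)
    bad = ~np.isfinite(f(z))
    if np.any(bad):
        z[bad] = 0.0
    w = v = None
    for _ in range(max_iter):
        f0, g, H = _fd_grad_hess(f, z)
        w, v = _neg_hess_pd(H)
        if np.max(np.abs(g)) < tol:
            break
        # Newton step: (-H)^{-1} g via the eigendecomposition, trust-region capped
        step = np.einsum("nij,nj->ni", v, np.einsum("nij,ni->nj", v, g) / w)
        norms = np.linalg.norm(step, axis=1)
        cap = np.where(norms > 2.0, 2.0 / np.maximum(norms, 1e-300), 1.0)
        step = step * cap[:, None]
        alpha = np.ones(V.shape[0])
        fnew = f(z + alpha[:, None] * step)
        for _bt in range(8):
            worse = ~(fnew >= f0 - 1e-12) | ~np.isfinite(fnew)
            if not np.any(worse):
                break
            alpha[worse] *= 0.5
            fnew = f(z + alpha[:, None] * step)
        improve = np.isfinite(fnew) & (fnew >= f0 - 1e-12)
        z = np.where(improve[:, None], z + alpha[:, None] * step, z)
        if not np.any(improve):
            break
        if np.max(np.abs(alpha[improve, None] * step[improve])) < 1e-12:
            break
    if w is None:
        _, _, H = _fd_grad_hess(f, z)
        w, v = _neg_hess_pd(H)
    # scaling factor A with A A^T = (-H)^{-1}, straight from the eigensystem
    A = v / np.sqrt(w)[:, None, :]
    logdetA = -0.5 * np.log(w).sum(axis=1)
    return z, A, logdetA


# ---------------------------------------------------------------------------
# quadrature

def _gh_nodes(m: int) -> tuple[np.ndarray, np.ndarray]:
    """3-D tensor Gauss--Hermite nodes (M,3) and adjusted log-weights (M,).

    The weights absorb the e^{+||x||^2} factor so that
    int g(z) dz ~= sum_j exp(logw[j]) * g(zhat + sqrt2 * A x_j) * 2^{3/2} |A|.
    """
    x, w = hermgauss(m)
    X = np.stack(np.meshgrid(x, x, x, indexing="ij"), axis=-1).reshape(-1, 3)
    lw = np.log(w)
    logw = (
        np.stack(np.meshgrid(lw, lw, lw, indexing="ij"), axis=-1).reshape(-1, 3).sum(axis=1)
        + np.sum(X * X, axis=1)
    )
    return X, logw


class _QuadWorkspace:
    """Per-collection state: packed arrays, GH nodes and warm-started modes."""

    def __init__(self, trials: list[AnovaSummary], quad: QuadratureConfig):
        self.V, self.SS, self.C = pack_summaries(trials)
        self.n = len(trials)
        self.quad = quad
        self.X, self.logw = _gh_nodes(quad.nodes_per_dim)
        self.z_warm: np.ndarray | None = None

    def node_values(self, spec: PriorSpec):
        """Quadrature nodes, their log-weights and log-integrand per trial.

        Returns (logint (n,M), z_nodes (n,M,3)) with logint the log of each
        node's weighted contribution; logsumexp over M gives the per-trial
        marginal log-likelihood.
        """
        n, M = self.n, self.X.shape[0]
        if self.quad.adaptive:
            z0 = self.z_warm if self.z_warm is not None else np.zeros((n, 3))
            zhat, A, logdetA = _find_modes(
                self.V, self.SS, self.C, spec, z0, tol=self.quad.mode_tol
            )
            self.z_warm = zhat
            znodes = zhat[:, None, :] + np.sqrt(2.0) * np.einsum(
                "nij,mj->nmi", A, self.X
            )
            logjac = 1.5 * np.log(2.0) + logdetA
        else:
            znodes = np.broadcast_to(np.sqrt(2.0) * self.X, (n, M, 3)).copy()
            logjac = np.full(n, 1.5 * np.log(2.0))
        h = _integrand_log(znodes, self.V, self.SS, self.C, spec)
        logint = h + self.logw[None, :] + logjac[:, None]
        return logint, znodes

    def per_trial_loglik(self, spec: PriorSpec) -> np.ndarray:
        logint, _ = self.node_values(spec)
        with np.errstate(invalid="ignore"):
            ll = logsumexp(logint, axis=1)
        if not np.all(np.isfinite(ll)):
            bad = np.flatnonzero(~np.isfinite(ll))
            raise FloatingPointError(
                f"quadrature failed (non-finite integrand) for trial indices {bad.tolist()}"
            )
        return ll

    def posterior_mean_sigma(self, spec: PriorSpec) -> np.ndarray:
        """Posterior mean of sigma per trial: ratio of quadrature sums, (n, 3)."""
        logint, znodes = self.node_values(spec)
        wts = np.exp(logint - logsumexp(logint, axis=1, keepdims=True))
        with np.errstate(over="ignore"):
            sigma_nodes = latent_to_sigma(znodes, spec)
        # overflowing far-tail nodes carry zero weight; drop them from the mean
        sigma_nodes = np.where(np.isfinite(sigma_nodes), sigma_nodes, 0.0)
        return np.einsum("nm,nmi->ni", wts, sigma_nodes)


def marginal_loglik(
    trials: list[AnovaSummary],
    spec: PriorSpec,
    quad: QuadratureConfig | None = None,
) -> float:
    """Marginal log-likelihood of all trials' SS under the prior spec."""
    if not trials:
        raise ValueError("need at least one trial")
    ws = _QuadWorkspace(trials, quad or QuadratureConfig())
    return float(ws.per_trial_loglik(spec).sum())


# ---------------------------------------------------------------------------
# hyper-parameter packing per family

def _params_from_spec(spec: PriorSpec) -> np.ndarray:
    h = spec.hyper
    if spec.family == "lognormal":
        p = np.concatenate([h.theta, np.diag(h.phi), h.phi[[0, 0, 1], [1, 2, 2]]])
    elif spec.family == "lognormal_constrained":
        p = np.concatenate([h.theta, unconstrain_phi(h.phi)])
    else:
        p = np.concatenate([np.log(h.shape), np.log(h.scale), fisher_z_from_corr(h.corr)])
    return p


def _spec_from_params(family: str, p: np.ndarray) -> PriorSpec | None:
    """Unpack a 9-vector into a PriorSpec; None if outside the admissible set."""
    p = np.asarray(p, dtype=float)
    if family == "lognormal":
        phi = np.empty((3, 3))
        phi[np.diag_indices(3)] = p[3:6]
        phi[0, 1] = phi[1, 0] = p[6]
        phi[0, 2] = phi[2, 0] = p[7]
        phi[1, 2] = phi[2, 1] = p[8]
        if np.linalg.eigvalsh(phi).min() < 1e-8:
            return None
        return PriorSpec(family, HyperParams(theta=p[:3], phi=phi))
    try:
        if family == "lognormal_constrained":
            # pairwise |corr| < 1 does not guarantee joint positive definiteness
            return PriorSpec(family, HyperParams(theta=p[:3], phi=constrain_phi(p[3:])))
        return PriorSpec(
            family,
            HyperParams(
                shape=np.exp(p[:3]), scale=np.exp(p[3:6]), corr=corr_from_fisher_z(p[6:])
            ),
        )
    except np.linalg.LinAlgError:
        return None


def _default_start(family: str, trials: list[AnovaSummary]) -> np.ndarray:
    """Method-of-moments start from the per-trial ANOVA estimates.

    The raw moment estimates are marginally unbiased for the prior means, so
    theta starts at log(mean) - phi/2; the covariance of the floored logs is
    clipped to a moderate range because the flooring inflates it grossly
    whenever many replicate/block estimates are nonpositive (the motivating
    phenomenon), which would start the optimiser in a pathological region.
    """
    est = anova_sigma_estimates(trials)
    logs = np.log(est)
    phi0 = np.cov(logs.T) if est.shape[0] > 3 else np.eye(3)
    d0 = np.clip(np.diag(phi0), 0.05, 1.5)
    sd = np.sqrt(np.maximum(np.diag(phi0), 1e-12))
    R0_ = np.clip(phi0 / np.outer(sd, sd), -0.6, 0.6)
    np.fill_diagonal(R0_, 1.0)
    phi0 = R0_ * np.sqrt(np.outer(d0, d0))
    theta0 = np.log(np.maximum(est.mean(axis=0), 1e-8)) - 0.5 * np.diag(phi0)
    if family in ("lognormal", "lognormal_constrained"):
        return _params_from_spec(PriorSpec(family, HyperParams(theta=theta0, phi=phi0)))
    m = est.mean(axis=0)
    v = est.var(axis=0) + 1e-8
    if family == "gamma":
        alpha = np.clip(m * m / v, 0.05, 1e3)
        beta = m / alpha
    else:  # inverse_gamma: match mean/variance of IG(a, s=1/beta)
        alpha = np.clip(m * m / v + 2.0, 2.05, 1e3)
        beta = 1.0 / (m * (alpha - 1.0))
    d = np.sqrt(np.diag(phi0))
    R0 = np.clip(phi0 / np.outer(d, d), -0.9, 0.9)
    np.fill_diagonal(R0, 1.0)
    return np.concatenate([np.log(alpha), np.log(beta), fisher_z_from_corr(R0)])


# ---------------------------------------------------------------------------
# fitting and prediction

def fit_eb(
    trials: list[AnovaSummary],
    family: str = "lognormal",
    quad: QuadratureConfig | None = None,
    start: HyperParams | None = None,
) -> EBFit:
    """Maximise the marginal likelihood over the family's hyper-parameters.

    The optimisation runs on an unconstrained parameterisation (lambda for
    covariances, logs for Gamma shapes/scales, Fisher z for correlations;
    the plain-lognormal family keeps raw phi entries behind a positive-
    definiteness barrier).  Deterministic given the data and start.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if not trials:
        raise ValueError("need at least one trial")
    under_identified = len(trials) < 2
    if len(trials) < 10:
        warnings.warn(
            f"only {len(trials)} trials: hyper-parameters are weakly identified",
            stacklevel=2,
        )
    quad = quad or QuadratureConfig()
    ws = _QuadWorkspace(trials, quad)
    # search on a lighter grid; report values/predictions on the configured one
    search_quad = QuadratureConfig(
        nodes_per_dim=min(5, quad.nodes_per_dim),
        adaptive=quad.adaptive,
        mode_tol=quad.mode_tol,
    )
    ws_search = _QuadWorkspace(trials, search_quad)

    # The plain-lognormal and Fisher-z parameterisations describe the same
    # family; both are optimised on the unconstrained (lambda) scale, where
    # quasi-Newton line searches behave, and reported in their own form.
    opt_family = "lognormal_constrained" if family == "lognormal" else family

    if start is not None:
        p0 = _params_from_spec(PriorSpec(opt_family, start))
    else:
        p0 = _default_start(opt_family, trials)

    def objective(p: np.ndarray, workspace=None) -> float:
        spec = _spec_from_params(opt_family, p)
        if spec is None:  # positive-definiteness barrier
            return 1e10
        try:
            return -float((workspace or ws_search).per_trial_loglik(spec).sum())
        except FloatingPointError:
            return 1e10

    res = minimize(
        objective,
        p0,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-9, "eps": 1e-4},
    )
    # restart to escape premature line-search termination on this curved surface
    for _ in range(3):
        res2 = minimize(
            objective,
            res.x,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-9, "eps": 1e-4},
        )
        improved = res2.fun < res.fun - 0.01
        if res2.fun <= res.fun:
            res = res2
        if not improved:
            break
    polish = minimize(
        objective,
        res.x,
        method="Powell",
        options={"maxiter": 5000, "maxfev": 1500, "xtol": 1e-5, "ftol": 1e-8},
    )
    if polish.fun < res.fun:
        res = polish
    p_hat = res.x if res.fun <= objective(p0) else p0
    spec_opt = _spec_from_params(opt_family, p_hat)
    spec = PriorSpec(family, spec_opt.hyper)
    loglik = -objective(p_hat, workspace=ws)
    aic = -2.0 * loglik + 2.0 * N_HYPER
    sig = ws.posterior_mean_sigma(spec)
    fit = EBFit(
        spec=spec,
        loglik=loglik,
        n_params=N_HYPER,
        aic=aic,
        per_trial_sigma=[VarianceComponents.from_array(s) for s in sig],
        convergence={
            "success": bool(res.success),
            "iterations": int(res.nit),
            "message": str(res.message),
            "under_identified": under_identified,
        },
        quad=quad,
    )
    if not res.success:
        fit.convergence["flag"] = "non-convergence: best iterate returned"
    return fit


def predict_sigma_eb(
    trial: AnovaSummary, fit: EBFit, quad: QuadratureConfig | None = None
) -> VarianceComponents:
    """Posterior mean of sigma for one trial under the fitted prior."""
    ws = _QuadWorkspace([trial], quad or fit.quad)
    return VarianceComponents.from_array(ws.posterior_mean_sigma(fit.spec)[0])


def predict_sigma_eb_all(
    trials: list[AnovaSummary], spec: PriorSpec, quad: QuadratureConfig | None = None
) -> np.ndarray:
    """Posterior-mean predictions for a whole collection, (n, 3)."""
    ws = _QuadWorkspace(trials, quad or QuadratureConfig())
    return ws.posterior_mean_sigma(spec)
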