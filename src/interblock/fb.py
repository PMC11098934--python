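"""Fully Bayesian estimation by Metropolis-within-Gibbs MCMC.

For the lognormal families the sampler alternates

  (a) per-trial log variance components u_t = log sigma_t^2 by random-walk
      Metropolis targeting the SS likelihood times the MVN(theta, phi) prior,
  (b) theta by its conjugate normal full conditional (flat hyperprior),
  (c) phi by its conjugate inverse-Wishart full conditional
      IW(nu + n, Omega + sum_t (u_t - theta)(u_t - theta)^T).

For the Gamma / inverse-Gamma families the marginal shapes and scales are
fixed at their maximum-likelihood (EB) estimates and the sampler alternates
(a') per-trial latent normals ztilde_t ~ MVN(0, R) by random-walk Metropolis
and (d) the latent correlations of R by Metropolis on the Fisher-z scale.

Proposal scales adapt towards ~30% acceptance during burn-in and are frozen
afterwards, preserving detailed balance of the retained draws.  Full
conditionals are re-derived here from the hierarchical model, not
transcribed from any external code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .anova import AnovaSummary
from .eb import (
    N_HYPER,
    QuadratureConfig,
    anova_sigma_from_arrays,
    fit_eb,
    marginal_loglik,
)
from .likelihood import VarianceComponents, pack_summaries, trial_loglik_arrays
from .priors import (
    HyperParams,
    PriorSpec,
    corr_from_fisher_z,
    fisher_z_from_corr,
    latent_to_sigma,
)

__all__ = [
    "MCMCConfig",
    "MCMCResult",
    "run_mcmc",
    "gelman_rubin",
    "posterior_sigma_fb",
    "fb_aic",
]


@dataclass
class MCMCConfig:
    """Sampler settings; the defaults are the operational ones reported for
    this class of model (10,000 iterations, 1,000 burn-in, thinning 10)."""

    n_iter: int = 10000
    burn_in: int = 1000
    thin: int = 10
    n_chains: int = 4
    seed: int = 0
    proposal_scale: float = 0.4
    iw_df: float = 3.0
    iw_scale: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.iw_scale = np.asarray(self.iw_scale, dtype=float).reshape(3, 3)
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.iw_df < 3:
            raise ValueError("inverse-Wishart df must be >= dimension (3)")

    @property
    def n_retained(self) -> int:
        return len(range(self.burn_in, self.n_iter, self.thin))


@dataclass
class MCMCResult:
    """Retained draws, convergence diagnostics and posterior summaries."""

    family: str
    draws: dict[str, np.ndarray]
    psrf: dict[str, float]
    acceptance_rates: dict[str, float]
    posterior_summary: dict[str, dict[str, float]]
    config: MCMCConfig
    fixed_hyper: dict[str, np.ndarray] = field(default_factory=dict)

    def posterior_mean_spec(self) -> PriorSpec:
        """PriorSpec at the posterior means of the hyper-parameters."""
        if self.family in ("lognormal", "lognormal_constrained"):
            theta = self.draws["theta"].reshape(-1, 3).mean(axis=0)
            phi = self.draws["phi"].reshape(-1, 3, 3).mean(axis=0)
            w, v = np.linalg.eigh(phi)
            phi = (v * np.maximum(w, 1e-8)) @ v.T
            return PriorSpec(self.family, HyperParams(theta=theta, phi=phi))
        zeta = self.draws["corr_z"].reshape(-1, 3).mean(axis=0)
        return PriorSpec(
            self.family,
            HyperParams(
                shape=self.fixed_hyper["shape"],
                scale=self.fixed_hyper["scale"],
                corr=corr_from_fisher_z(zeta),
            ),
        )


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor for one scalar parameter.

    ``chains`` is an (m, n) array of m >= 2 chains of equal retained length.
    Uses the classical between/within estimator
    PSRF = sqrt( [ (n-1)/n * W + (1 + 1/m) * B/n ] / W ).
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = c.shape
    if n < 10:
        raise ValueError("chains too short for the diagnostic")
    W = c.var(axis=1, ddof=1).mean()
    B_over_n = c.mean(axis=1).var(ddof=1)
    if W <= 0:
        return 1.0
    vhat = (n - 1) / n * W + (1.0 + 1.0 / m) * B_over_n
    return float(np.sqrt(vhat / W))


def _sample_invwishart(df: float, Psi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from IW(df, Psi) via the Bartlett decomposition (3-D)."""
    p = Psi.shape[0]
    A = np.zeros((p, p))
    for i in range(p):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
        for j in range(i):
            A[i, j] = rng.standard_normal()
    L = np.linalg.cholesky(np.linalg.inv(Psi))
    W = L @ A @ A.T @ L.T  # Wishart(df, Psi^{-1})
    return np.linalg.inv(W)


def _mvn_logpdf_quad(u: np.ndarray, mean: np.ndarray, prec: np.ndarray) -> np.ndarray:
    d = u - mean
    return -0.5 * np.einsum("...i,ij,...j->...", d, prec, d)


def _identity_spec(family: str, shape: np.ndarray, scale: np.ndarray) -> PriorSpec:
    return PriorSpec(family, HyperParams(shape=shape, scale=scale, corr=np.eye(3)))


class _Adapter:
    """Robbins-Monro-style scale adaptation towards a target acceptance."""

    def __init__(self, scale: float, target: float = 0.3):
        self.scale = scale
        self.target = target
        self.accepted = 0.0
        self.attempts = 0

    def record(self, rate_increment: float, n: int = 1) -> None:
        self.accepted += rate_increment
        self.attempts += n

    def maybe_adapt(self, frozen: bool) -> None:
        if self.attempts >= 50:
            rate = self.accepted / self.attempts
            if not frozen:
                self.scale *= float(np.exp(1.2 * (rate - self.target)))
                self.scale = float(np.clip(self.scale, 1e-3, 10.0))
            self.accepted = 0.0
            self.attempts = 0


def _run_chain_lognormal(V, SS, C, family, config, rng):
    n = V.shape[0]
    est = np.log(np.maximum(anova_sigma_from_arrays(V, SS, C), 1e-8))
    theta = est.mean(axis=0) + 0.5 * rng.standard_normal(3)
    phi = np.cov(est.T) + 0.1 * np.eye(3) if n > 3 else np.eye(3)
    u = est + 0.3 * rng.standard_normal((n, 3))

    prec = np.linalg.inv(phi)
    ll = trial_loglik_arrays(V, SS, C, np.exp(u))
    if not np.all(np.isfinite(ll)):
        bad = int(np.flatnonzero(~np.isfinite(ll))[0])
        raise FloatingPointError(f"non-finite posterior at initial state (trial {bad})")
    lp = _mvn_logpdf_quad(u, theta, prec)

    kept_idx = set(range(config.burn_in, config.n_iter, config.thin))
    keep_t, keep_p, keep_s = [], [], []
    ad = _Adapter(config.proposal_scale)
    acc_total = 0.0
    acc_count = 0
    for it in range(config.n_iter):
        # (a) per-trial u by random-walk Metropolis
        prop = u + ad.scale * rng.standard_normal((n, 3))
        ll_p = trial_loglik_arrays(V, SS, C, np.exp(prop))
        lp_p = _mvn_logpdf_quad(prop, theta, prec)
        logr = (ll_p + lp_p) - (ll + lp)
        acc = np.log(rng.random(n)) < logr
        u[acc] = prop[acc]
        ll = np.where(acc, ll_p, ll)
        lp = np.where(acc, lp_p, lp)
        ad.record(acc.mean())
        ad.maybe_adapt(frozen=it >= config.burn_in)
        if it >= config.burn_in:
            acc_total += acc.mean()
            acc_count += 1
        # (b) theta | u, phi  ~ N(mean(u), phi / n)   (flat hyperprior)
        theta = u.mean(axis=0) + np.linalg.cholesky(phi / n) @ rng.standard_normal(3)
        # (c) phi | u, theta ~ IW(nu + n, Omega + S)
        d = u - theta
        S = d.T @ d
        phi = _sample_invwishart(config.iw_df + n, config.iw_scale + S, rng)
        prec = np.linalg.inv(phi)
        lp = _mvn_logpdf_quad(u, theta, prec)
        if it in kept_idx:
            keep_t.append(theta.copy())
            keep_p.append(phi.copy())
            keep_s.append(np.exp(u))
    return (
        {"theta": np.array(keep_t), "phi": np.array(keep_p), "sigma": np.array(keep_s)},
        {"u_scale": ad.scale, "u_accept": acc_total / max(acc_count, 1)},
    )


def anova_sigma_estimates_from_arrays(V, SS, C, floor_frac: float = 1e-3) -> np.ndarray:
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
    return np.maximum(out, floor_frac * np.maximum(se2, 1e-300)[:, None])


def _run_chain_copula(V, SS, C, family, shape, scale, config, rng):
    n = V.shape[0]
    ident = _identity_spec(family, shape, scale)
    zt = 0.5 * rng.standard_normal((n, 3))
    zeta = 0.3 * rng.standard_normal(3)
    R = corr_from_fisher_z(zeta)
    Rinv = np.linalg.inv(R)
    _, logdetR = np.linalg.slogdet(R)

    ll = trial_loglik_arrays(V, SS, C, latent_to_sigma_direct(zt, ident))
    if not np.all(np.isfinite(ll)):
        bad = int(np.flatnonzero(~np.isfinite(ll))[0])
        raise FloatingPointError(f"non-finite posterior at initial state (trial {bad})")
    lp = _mvn_logpdf_quad(zt, 0.0, Rinv)

    kept_idx = set(range(config.burn_in, config.n_iter, config.thin))
    keep_z, keep_s = [], []
    ad_z = _Adapter(config.proposal_scale)
    ad_r = _Adapter(0.2)
    acc_total = 0.0
    acc_count = 0
    for it in range(config.n_iter):
        frozen = it >= config.burn_in
        prop = zt + ad_z.scale * rng.standard_normal((n, 3))
        ll_p = trial_loglik_arrays(V, SS, C, latent_to_sigma_direct(prop, ident))
        lp_p = _mvn_logpdf_quad(prop, 0.0, Rinv)
        logr = (ll_p + lp_p) - (ll + lp)
        acc = np.log(rng.random(n)) < logr
        zt[acc] = prop[acc]
        ll = np.where(acc, ll_p, ll)
        lp = np.where(acc, lp_p, lp)
        ad_z.record(acc.mean())
        ad_z.maybe_adapt(frozen)
        if frozen:
            acc_total += acc.mean()
            acc_count += 1
        # (d) correlations of R on the Fisher-z scale, flat prior on zeta
        zeta_p = zeta + ad_r.scale * rng.standard_normal(3)
        Rp = corr_from_fisher_z(zeta_p)
        try:
            Rp_inv = np.linalg.inv(Rp)
            sgn, logdetRp = np.linalg.slogdet(Rp)
            ok = sgn > 0
        except np.linalg.LinAlgError:
            ok = False
        if ok:
            cur = -0.5 * n * logdetR + _mvn_logpdf_quad(zt, 0.0, Rinv).sum()
            new = -0.5 * n * logdetRp + _mvn_logpdf_quad(zt, 0.0, Rp_inv).sum()
            if np.log(rng.random()) < new - cur:
                zeta, R, Rinv, logdetR = zeta_p, Rp, Rp_inv, logdetRp
                lp = _mvn_logpdf_quad(zt, 0.0, Rinv)
                ad_r.record(1.0)
            else:
                ad_r.record(0.0)
            ad_r.maybe_adapt(frozen)
        if it in kept_idx:
            keep_z.append(zeta.copy())
            keep_s.append(latent_to_sigma_direct(zt, ident))
    return (
        {"corr_z": np.array(keep_z), "sigma": np.array(keep_s)},
        {
            "z_scale": ad_z.scale,
            "zeta_scale": ad_r.scale,
            "z_accept": acc_total / max(acc_count, 1),
        },
    )


def latent_to_sigma_direct(zt: np.ndarray, ident_spec: PriorSpec) -> np.ndarray:
    """sigma from the *correlated* latent ztilde (identity-R spec applies no mixing)."""
    return latent_to_sigma(zt, ident_spec)


def run_mcmc(
    trials: list[AnovaSummary],
    family: str = "lognormal",
    config: MCMCConfig | None = None,
    eb_fit=None,
) -> MCMCResult:
    """Run the Metropolis-within-Gibbs sampler over all trials.

    For the Gamma / inverse-Gamma families the marginal shape and scale are
    fixed at their marginal-ML estimates before sampling (``eb_fit``
    supplies them; if absent an EB fit of the same family is run first).
    Reproducible bit-for-bit given the config seed.
    """
    config = config or MCMCConfig()
    V, SS, C = pack_summaries(trials)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)

    fixed: dict[str, np.ndarray] = {}
    if family in ("gamma", "inverse_gamma"):
        if eb_fit is None:
            eb_fit = fit_eb(trials, family=family, quad=QuadratureConfig(nodes_per_dim=5))
        fixed = {"shape": eb_fit.spec.hyper.shape, "scale": eb_fit.spec.hyper.scale}

    chains = []
    acc_rates: dict[str, float] = {}
    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        if family in ("lognormal", "lognormal_constrained"):
            draws, info = _run_chain_lognormal(V, SS, C, family, config, rng)
        else:
            draws, info = _run_chain_copula(
                V, SS, C, family, fixed["shape"], fixed["scale"], config, rng
            )
        chains.append(draws)
        for k, v in info.items():
            acc_rates[f"chain{c}_{k}"] = float(v)
    for k, v in acc_rates.items():
        if k.endswith("_accept") and not 0.05 <= v <= 0.8:
            warnings.warn(
                f"Metropolis acceptance rate {v:.2f} outside [0.05, 0.8] ({k})",
                stacklevel=2,
            )

    draws = {k: np.stack([c[k] for c in chains]) for k in chains[0]}

    monitored: dict[str, np.ndarray] = {}
    if family in ("lognormal", "lognormal_constrained"):
        for i, nm in enumerate(("theta_r", "theta_b", "theta_e")):
            monitored[nm] = draws["theta"][..., i]
        for i, nm in enumerate(("phi_r2", "phi_b2", "phi_e2")):
            monitored[nm] = draws["phi"][..., i, i]
    else:
        for i, nm in enumerate(("zeta_rb", "zeta_re", "zeta_be")):
            monitored[nm] = draws["corr_z"][..., i]
    monitored["mean_log_sigma_e2"] = np.log(draws["sigma"][..., 2]).mean(axis=2)

    psrf = (
        {k: gelman_rubin(v) for k, v in monitored.items()}
        if config.n_chains >= 2
        else {}
    )
    summary = {
        k: {
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)),
            "q2.5": float(np.quantile(v, 0.025)),
            "q50": float(np.quantile(v, 0.5)),
            "q97.5": float(np.quantile(v, 0.975)),
        }
        for k, v in monitored.items()
    }
    return MCMCResult(
        family=family,
        draws=draws,
        psrf=psrf,
        acceptance_rates=acc_rates,
        posterior_summary=summary,
        config=config,
        fixed_hyper=fixed,
    )


def posterior_sigma_fb(result: MCMCResult, trial_index: int) -> VarianceComponents:
    """Posterior mean of sigma for one trial across all chains' retained draws."""
    import warnings as _w

    if result.psrf and max(result.psrf.values()) >= 1.1:
        _w.warn("chains may not have converged (max PSRF >= 1.1)", stacklevel=2)
    s = result.draws["sigma"][:, :, trial_index, :].reshape(-1, 3).mean(axis=0)
    return VarianceComponents.from_array(s)


def posterior_sigma_fb_all(result: MCMCResult) -> np.ndarray:
    """Posterior means of sigma for every trial, (n, 3)."""
    return result.draws["sigma"].mean(axis=(0, 1))


def fb_aic(
    trials: list[AnovaSummary],
    result: MCMCResult,
    family: str | None = None,
    quad: QuadratureConfig | None = None,
) -> float:
    """Plug-in AIC: -2 * marginal log-likelihood at the posterior means of the
    hyper-parameters + 2 * (number of hyper-parameters).

    This is a convention of this package (labelled as such in reports), not
    a uniquely defined quantity for an MCMC fit.
    """
    spec = result.posterior_mean_spec()
    ll = marginal_loglik(trials, spec, quad or QuadratureConfig())
    return float(-2.0 * ll + 2.0 * N_HYPER)
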