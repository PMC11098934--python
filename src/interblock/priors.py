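"""Cross-trial prior families for the variance-component vector sigma.

Four families, all built on a trivariate standard-normal latent vector z so
that Empirical Bayes quadrature and MCMC can work on an unconstrained scale:

* ``lognormal`` — log sigma^2 ~ MVN(theta, phi), phi an unconstrained
  (positive-definite) covariance matrix.
* ``lognormal_constrained`` — same law, but phi parameterised through
  lambda: variances exp(lambda_ii) and correlations tanh(lambda_ij)
  (inverse Fisher z), so every lambda in R^6 is admissible.
* ``gamma`` — marginal Gamma(alpha_i, scale beta_i) per component, coupled
  through a Gaussian copula with correlation matrix R (inverse-c.d.f.
  construction: sigma_i^2 = beta_i * Q_gamma(alpha_i, Phi(ztilde_i)) with
  ztilde = R^{1/2} z).
* ``inverse_gamma`` — the reciprocal of the Gamma construction, giving
  inverse-Gamma(alpha_i, scale 1/beta_i) marginals.

All four guarantee strictly positive variance components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc, gammaincinv, gammaln, ndtr, ndtri

from .likelihood import VarianceComponents

__all__ = [
    "FAMILIES",
    "HyperParams",
    "PriorSpec",
    "constrain_phi",
    "unconstrain_phi",
    "corr_from_fisher_z",
    "fisher_z_from_corr",
    "latent_to_sigma",
    "sigma_to_latent",
    "log_prior_density",
    "sample_sigma",
]

FAMILIES = ("lognormal", "lognormal_constrained", "gamma", "inverse_gamma")

_CLAMP = 1e-12
_EIG_FLOOR = 1e-10
# (row, col) order of the packed 6-vector (lam_rr, lam_bb, lam_ee, lam_rb, lam_re, lam_be)
_DIAG = [(0, 0), (1, 1), (2, 2)]
_OFF = [(0, 1), (0, 2), (1, 2)]


def constrain_phi(lam: np.ndarray) -> np.ndarray:
    """Map the unconstrained 6-vector lambda to a valid 3x3 covariance matrix.

    Variances are exp(lambda_ii); correlations are the inverse Fisher z
    transform tanh(lambda_ij) = (exp(2*lambda_ij) - 1)/(exp(2*lambda_ij) + 1),
    so the result is symmetric with positive diagonal and |corr| < 1 for any
    finite lambda.
    """
    lam = np.asarray(lam, dtype=float).ravel()
    if lam.size != 6 or not np.all(np.isfinite(lam)):
        raise ValueError("lambda must be a finite 6-vector")
    sd = np.exp(lam[:3] / 2.0)
    rho = np.tanh(lam[3:])
    phi = np.empty((3, 3))
    for d, (i, _) in enumerate(_DIAG):
        phi[i, i] = sd[d] ** 2
    for o, (i, j) in enumerate(_OFF):
        phi[i, j] = phi[j, i] = rho[o] * sd[i] * sd[j]
    return phi


def unconstrain_phi(phi: np.ndarray) -> np.ndarray:
    """Inverse of :func:`constrain_phi` for a positive-definite covariance."""
    phi = np.asarray(phi, dtype=float)
    sd = np.sqrt(np.diag(phi))
    lam = np.empty(6)
    lam[:3] = 2.0 * np.log(sd)
    for o, (i, j) in enumerate(_OFF):
        lam[3 + o] = np.arctanh(phi[i, j] / (sd[i] * sd[j]))
    return lam


def corr_from_fisher_z(zeta: np.ndarray) -> np.ndarray:
    """3x3 correlation matrix with off-diagonals tanh(zeta) (order rb, re, be)."""
    zeta = np.asarray(zeta, dtype=float).ravel()
    R = np.eye(3)
    for o, (i, j) in enumerate(_OFF):
        R[i, j] = R[j, i] = np.tanh(zeta[o])
    return R


def fisher_z_from_corr(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    return np.array([np.arctanh(R[i, j]) for i, j in _OFF])


def _sqrtm_psd(R: np.ndarray) -> np.ndarray:
    """Symmetric matrix square root with eigenvalue floor (spectral)."""
    w, v = np.linalg.eigh(R)
    w = np.maximum(w, _EIG_FLOOR)
    return (v * np.sqrt(w)) @ v.T


@dataclass
class HyperParams:
    """Hyper-parameters of a prior family; which fields are active depends on it.

    theta, phi      lognormal families — mean vector and covariance of log sigma^2
    shape, scale    gamma / inverse_gamma — per-component alpha and beta of the
                    underlying Gamma(alpha, scale beta) construction
    corr            gamma / inverse_gamma — latent-normal correlation matrix R
                    (unit diagonal; latent means 0 and variances 1 are fixed)
    """

    theta: np.ndarray | None = None
    phi: np.ndarray | None = None
    shape: np.ndarray | None = None
    scale: np.ndarray | None = None
    corr: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        for name in ("theta", "shape", "scale"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float).ravel())
        for name in ("phi", "corr"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float).reshape(3, 3))


@dataclass
class PriorSpec:
    """A prior family plus its hyper-parameters."""

    family: str
    hyper: HyperParams

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        h = self.hyper
        if self.family in ("lognormal", "lognormal_constrained"):
            if h.theta is None or h.phi is None:
                raise ValueError(f"{self.family} prior needs theta and phi")
            np.linalg.cholesky(h.phi)  # raises if not positive definite
        else:
            if h.shape is None or h.scale is None:
                raise ValueError(f"{self.family} prior needs shape and scale")
            if np.any(h.shape <= 0) or np.any(h.scale <= 0):
                raise ValueError("shape and scale must be positive")
            if h.corr is None:
                h.corr = np.eye(3)

    @property
    def is_lognormal(self) -> bool:
        return self.family in ("lognormal", "lognormal_constrained")

    def chol(self) -> np.ndarray:
        """Cholesky-type factor of the latent covariance (phi or R)."""
        if self.is_lognormal:
            return np.linalg.cholesky(self.hyper.phi)
        return _sqrtm_psd(self.hyper.corr)


def latent_to_sigma(z: np.ndarray, spec: PriorSpec) -> np.ndarray:
    """Map standard-normal latent coordinates z (..., 3) to sigma^2 (..., 3).

    lognormal families: sigma^2 = exp(theta + L z), L = chol(phi).
    gamma: sigma_i^2 = beta_i * Q_gamma(alpha_i, Phi(ztilde_i)) with
    ztilde = R^{1/2} z;  inverse_gamma: the reciprocal of that.  Normal
    c.d.f. values numerically at 0 or 1 are clamped to keep the quantile
    finite.
    """
    z = np.asarray(z, dtype=float)
    L = spec.chol()
    if spec.is_lognormal:
        return np.exp(spec.hyper.theta + z @ L.T)
    zt = z @ L.T  # R^{1/2} is symmetric, but keep the transpose for clarity
    u = np.clip(ndtr(zt), _CLAMP, 1.0 - _CLAMP)
    g = gammaincinv(spec.hyper.shape, u) * spec.hyper.scale
    if spec.family == "gamma":
        return g
    return 1.0 / g


def sigma_to_latent(sigma: np.ndarray, spec: PriorSpec) -> np.ndarray:
    """Inverse of :func:`latent_to_sigma` (exact away from the clamping region)."""
    sigma = np.asarray(sigma, dtype=float)
    Linv = np.linalg.inv(spec.chol())
    if spec.is_lognormal:
        return (np.log(sigma) - spec.hyper.theta) @ Linv.T
    if spec.family == "gamma":
        u = gammainc(spec.hyper.shape, sigma / spec.hyper.scale)
    else:
        # the construction's latent satisfies Phi(zt) = F_gamma(1/(sigma*beta))
        u = gammainc(spec.hyper.shape, 1.0 / (sigma * spec.hyper.scale))
    zt = ndtri(np.clip(u, _CLAMP, 1.0 - _CLAMP))
    return zt @ Linv.T


def _gamma_logpdf(x, a, scale):
    return (a - 1.0) * np.log(x) - x / scale - gammaln(a) - a * np.log(scale)


def _invgamma_logpdf(x, a, scale):
    # X ~ InvGamma(a, scale s): f(x) = s^a / Gamma(a) x^{-a-1} exp(-s/x)
    return a * np.log(scale) - gammaln(a) - (a + 1.0) * np.log(x) - scale / x


def log_prior_density(sigma, spec: PriorSpec):
    """Log joint prior density of sigma^2 (..., 3) under the family.

    Lognormal families: trivariate normal on the logs with the Jacobian
    product 1/sigma_i^2.  Gamma / inverse-Gamma: product of the marginal
    densities times the Gaussian-copula density with correlation R.
    """
    arr = sigma.as_array() if isinstance(sigma, VarianceComponents) else np.asarray(sigma, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("prior density requires strictly positive variance components")
    h = spec.hyper
    if spec.is_lognormal:
        u = np.log(arr) - h.theta
        P = np.linalg.inv(h.phi)
        _, logdet = np.linalg.slogdet(h.phi)
        quad = np.einsum("...i,ij,...j->...", u, P, u)
        out = -0.5 * (3 * np.log(2 * np.pi) + logdet + quad) - np.log(arr).sum(axis=-1)
    else:
        if spec.family == "gamma":
            marg = _gamma_logpdf(arr, h.shape, h.scale)
            u = gammainc(h.shape, arr / h.scale)
        else:
            marg = _invgamma_logpdf(arr, h.shape, 1.0 / h.scale)
            u = gammainc(h.shape, 1.0 / (arr * h.scale))  # the construction's latent
        zt = ndtri(np.clip(u, _CLAMP, 1.0 - _CLAMP))
        Rinv = np.linalg.inv(h.corr)
        _, logdetR = np.linalg.slogdet(h.corr)
        cop = -0.5 * logdetR - 0.5 * np.einsum("...i,ij,...j->...", zt, Rinv - np.eye(3), zt)
        out = marg.sum(axis=-1) + cop
    return out if out.ndim else float(out)


def sample_sigma(spec: PriorSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n variance-component vectors from the prior (via the latent normal)."""
    z = rng.standard_normal((n, 3))
    return latent_to_sigma(z, spec)
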