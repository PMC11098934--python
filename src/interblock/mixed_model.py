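"""Single-trial linear mixed model: REML baseline and GLS/mixed-model-equation
estimation of treatment means at plugged-in variance components.

The model is y = X tau + Z_r gamma + Z_b rho + e with random replicate and
block-within-replicate effects, V = sigma_r^2 Z_r Z_r' + sigma_b^2 Z_b Z_b'
+ sigma_e^2 I.  ``reml_fit`` maximises the residual log-likelihood directly
(trials are tiny), with the non-negativity constraint enforced through a log
parameterisation plus an explicit boundary comparison at sigma_r^2 = 0 and
sigma_b^2 = 0 — mirroring how standard mixed-model packages drop a stratum
whose variance converges to zero.  ``gls_blue`` plugs any sigma into
generalised least squares, which coincides with solving the Henderson
mixed-model equations and interpolates between the unadjusted (sigma_b^2 ->
0) and fully block-adjusted (sigma_b^2 -> inf) treatment estimators — the
recovery of inter-block information.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import minimize

from .anova import TrialData, design_matrices
from .likelihood import VarianceComponents

__all__ = [
    "TreatmentEstimates",
    "RemlFit",
    "reml_loglik",
    "reml_fit",
    "gls_blue",
    "pairwise_differences",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class TreatmentEstimates:
    """BLUEs of treatment means and the covariance of their pairwise differences."""

    blue: np.ndarray
    vcov_diff: np.ndarray
    sigma_used: VarianceComponents
    method: str = "gls"


@dataclass
class RemlFit:
    """REML estimates; replicate/block components may sit on the zero boundary."""

    sigma: VarianceComponents
    reml_loglik: float
    aic: float
    boundary_flags: tuple[bool, bool, bool] = (False, False, False)


def _model_arrays(data: TrialData) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    X_full, Zr, Zb = design_matrices(data)
    X = X_full[:, 1:]  # treatment one-hot spans the intercept; full rank t
    return data.response, X, Zr, Zb


def _build_v(sigma, Zr, Zb) -> np.ndarray:
    sr2, sb2, se2 = sigma
    n = Zr.shape[0]
    return sr2 * (Zr @ Zr.T) + sb2 * (Zb @ Zb.T) + se2 * np.eye(n)


def reml_loglik(data: TrialData, sigma) -> float:
    """Residual log-likelihood at a given sigma (the REML criterion).

    Exposed separately so an independent grid search can serve as an oracle
    for :func:`reml_fit`.
    """
    arr = sigma.as_array() if isinstance(sigma, VarianceComponents) else np.asarray(sigma, float)
    y, X, Zr, Zb = _model_arrays(data)
    V = _build_v(arr, Zr, Zb)
    n, p = X.shape
    try:
        cf = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf
    logdetV = 2.0 * np.sum(np.log(np.diag(cf)))
    Vinv_X = np.linalg.solve(V, X)
    Vinv_y = np.linalg.solve(V, y)
    XtVX = X.T @ Vinv_X
    sign, logdetXtVX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtVX, X.T @ Vinv_y)
    resid = y - X @ beta
    quad = resid @ np.linalg.solve(V, resid)
    return -0.5 * ((n - p) * _LOG2PI + logdetV + logdetXtVX + quad)


def _optimise(data: TrialData, free: tuple[bool, bool]) -> tuple[np.ndarray, float]:
    """Maximise the REML criterion with sigma_r2/sigma_b2 optionally pinned at 0."""
    y = data.response
    s0 = max(np.var(y), 1e-10)

    def expand(logp):
        sig = np.zeros(3)
        i = 0
        for d, on in enumerate(free):
            if on:
                sig[d] = np.exp(logp[i])
                i += 1
        sig[2] = np.exp(logp[i])
        return sig

    k = sum(free) + 1
    x0 = np.full(k, np.log(s0 / 2.0))
    res = minimize(
        lambda p: -reml_loglik(data, expand(p)),
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 2000},
    )
    return expand(res.x), -res.fun


def reml_fit(data: TrialData) -> RemlFit:
    """REML variance components with non-negativity constraints.

    Fits the full model and the three boundary candidates (sigma_r^2 = 0,
    sigma_b^2 = 0, both = 0) and keeps the best criterion value; a boundary
    solution sets the corresponding flag.  All-equal responses floor
    sigma_e^2 with a warning flag on every component.
    """
    if data.layout.n_treatments < 2:
        raise ValueError("need at least 2 treatments")
    if np.var(data.response) < 1e-300:
        floor = 1e-10
        return RemlFit(
            sigma=VarianceComponents(0.0, 0.0, floor),
            reml_loglik=reml_loglik(data, np.array([0.0, 0.0, floor])),
            aic=np.nan,
            boundary_flags=(True, True, True),
        )
    best = None
    for free in ((True, True), (False, True), (True, False), (False, False)):
        sig, ll = _optimise(data, free)
        if best is None or ll > best[1] + 1e-9:
            best = (sig, ll, free)
    sig, ll, free = best
    flags = (
        bool(not free[0] or sig[0] < 1e-12),
        bool(not free[1] or sig[1] < 1e-12),
        False,
    )
    sig = np.where(np.array([flags[0], flags[1], False]), 0.0, sig)
    return RemlFit(
        sigma=VarianceComponents.from_array(sig),
        reml_loglik=ll,
        aic=-2.0 * ll + 2.0 * 3,
        boundary_flags=flags,
    )


def gls_blue(data: TrialData, sigma: VarianceComponents) -> TreatmentEstimates:
    """Generalised least squares for treatment means at plugged-in sigma.

    Equals the fixed-effect solution of the Henderson mixed-model equations;
    treatment effects are reported as estimated means (intercept absorbed by
    the one-hot treatment coding), and ``vcov_diff`` holds the variances of
    all pairwise mean differences.
    """
    arr = sigma.as_array()
    if not arr[2] > 0:
        raise ValueError("sigma_e^2 must be strictly positive")
    y, X, Zr, Zb = _model_arrays(data)
    V = _build_v(arr, Zr, Zb)
    try:
        Vinv_X = np.linalg.solve(V, X)
        Vinv_y = np.linalg.solve(V, y)
    except np.linalg.LinAlgError as exc:
        raise ValueError("non-invertible marginal covariance V") from exc
    XtVX = X.T @ Vinv_X
    Cov = np.linalg.inv(XtVX)
    beta = Cov @ (X.T @ Vinv_y)
    d = np.diag(Cov)
    vdiff = d[:, None] + d[None, :] - 2.0 * Cov
    np.fill_diagonal(vdiff, 0.0)
    return TreatmentEstimates(
        blue=beta, vcov_diff=vdiff, sigma_used=sigma, method="gls"
    )


def pairwise_differences(est: TreatmentEstimates) -> list[tuple[int, int, float]]:
    """All t(t-1)/2 ordered-pair treatment-mean differences (1-based labels)."""
    t = est.blue.size
    return [
        (i + 1, j + 1, float(est.blue[i] - est.blue[j]))
        for i, j in combinations(range(t), 2)
    ]
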