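"""Conditional likelihood of ANOVA sums of squares given variance components.

Conditionally on sigma, each design-stratum sum of squares satisfies
SS_i / E(MS_i) ~ chi-squared(v_i), independently across strata.  The
chi-squared law is the Gamma(shape v/2, scale 2) distribution (equating the
first two moments v and 2v), and the density of SS_i itself follows by the
change of variable W = SS_i / E(MS_i):

    g(SS_i | sigma) = f_chi2( SS_i / E(MS_i); v_i ) / E(MS_i)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .anova import AnovaSummary

__all__ = [
    "VarianceComponents",
    "ScaledChiSqLaw",
    "ems_value",
    "ems_values",
    "ss_loglik",
    "trial_loglik",
    "trial_loglik_arrays",
    "pack_summaries",
]

_STRATA = ("replicates", "blocks", "error")


@dataclass(frozen=True)
class VarianceComponents:
    """The vector sigma = (sigma_r^2, sigma_b^2, sigma_e^2), response units squared."""

    sigma_r2: float
    sigma_b2: float
    sigma_e2: float

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.as_array())):
            raise ValueError("variance components must be finite")
        if self.sigma_e2 < 0 or self.sigma_b2 < 0 or self.sigma_r2 < 0:
            raise ValueError("variance components must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma_r2, self.sigma_b2, self.sigma_e2])

    @classmethod
    def from_array(cls, a) -> "VarianceComponents":
        a = np.asarray(a, dtype=float).ravel()
        return cls(float(a[0]), float(a[1]), float(a[2]))


@dataclass(frozen=True)
class ScaledChiSqLaw:
    """Law of one stratum's SS: scale * chi-squared(df), i.e. Gamma(df/2, 2*scale)."""

    df: int
    scale: float

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be a positive integer")
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    @property
    def gamma_shape(self) -> float:
        return self.df / 2.0

    @property
    def gamma_scale(self) -> float:
        return 2.0


def ems_values(sigma: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Expected mean squares for the three strata, vectorised.

    ``sigma`` has shape (..., 3) ordered (r, b, e); ``coeffs`` shape (..., 3)
    ordered (c1, c2, c3).  Returns shape (..., 3) ordered
    (replicates, blocks, error).
    """
    sigma = np.asarray(sigma, dtype=float)
    coeffs = np.asarray(coeffs, dtype=float)
    sr2, sb2, se2 = sigma[..., 0], sigma[..., 1], sigma[..., 2]
    c1, c2, c3 = coeffs[..., 0], coeffs[..., 1], coeffs[..., 2]
    return np.stack(
        np.broadcast_arrays(se2 + c1 * sb2 + c2 * sr2, se2 + c3 * sb2, se2), axis=-1
    )


def ems_value(stratum: str, sigma: VarianceComponents, coeffs) -> float:
    """E(MS) for one stratum ('replicates', 'blocks' or 'error')."""
    if stratum not in _STRATA:
        raise ValueError(f"unknown stratum {stratum!r}; expected one of {_STRATA}")
    vals = ems_values(sigma.as_array(), np.asarray(coeffs, dtype=float))
    return float(vals[_STRATA.index(stratum)])


def _chi2_logpdf(w, df):
    w = np.asarray(w, dtype=float)
    df = np.asarray(df, dtype=float)
    half = df / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (half - 1.0) * np.log(w) - w / 2.0 - half * np.log(2.0) - gammaln(half)
    return np.where(w > 0, out, np.where(w == 0, np.where(df >= 2, -np.inf, np.inf), np.nan))


def ss_loglik(ss: float, law: ScaledChiSqLaw) -> float:
    """Log density of an observed SS under its scaled chi-squared law.

    ss = 0 is a valid boundary of the support and returns -inf for df >= 2.
    """
    if ss < 0:
        raise ValueError("sum of squares must be nonnegative")
    return float(_chi2_logpdf(ss / law.scale, law.df) - np.log(law.scale))


def trial_loglik_arrays(V: np.ndarray, SS: np.ndarray, C: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Vectorised per-trial conditional log-likelihood.

    ``V``, ``SS``, ``C`` are (n, 3) arrays of stratum df, sums of squares and
    EMS coefficients; ``sigma`` broadcasts against (n, 3) (e.g. shape
    (n, m, 3) for m candidate sigma per trial, with V/SS/C expanded).
    Strata with zero df contribute nothing.
    """
    V = np.asarray(V, dtype=float)
    SS = np.asarray(SS, dtype=float)
    scales = ems_values(sigma, C)
    w = SS / scales
    ll = _chi2_logpdf(w, V) - np.log(scales)
    return np.where(V > 0, ll, 0.0).sum(axis=-1)


def trial_loglik(summary: AnovaSummary, sigma: VarianceComponents) -> float:
    """Conditional log-likelihood of one trial's (SS_r, SS_b, SS_e) given sigma."""
    V = np.array(summary.df, dtype=float)
    SS = np.array(summary.ss, dtype=float)
    C = np.array(summary.ems_coeffs, dtype=float)
    C = np.nan_to_num(C, nan=0.0)  # degenerate-stratum coefficients are unused
    return float(trial_loglik_arrays(V, SS, C, sigma.as_array()))


def pack_summaries(trials: list[AnovaSummary]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack a collection of trials into (V, SS, C) arrays of shape (n, 3)."""
    V = np.array([t.df for t in trials], dtype=float)
    SS = np.array([t.ss for t in trials], dtype=float)
    C = np.nan_to_num(
        np.array([t.ems_coeffs for t in trials], dtype=float), nan=0.0
    )
    return V, SS, C
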