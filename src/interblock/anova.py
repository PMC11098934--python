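"""Sequential (Type I) ANOVA for a single alpha-design trial.

Treatments are fitted *before* the design effects, so the replicate, block
and error sums of squares are central and carry all the information about
the variance components sigma = (sigma_r^2, sigma_b^2, sigma_e^2).  The
expected mean squares are

    E(MS_r) = sigma_e^2 + c1 * sigma_b^2 + c2 * sigma_r^2
    E(MS_b) = sigma_e^2 + c3 * sigma_b^2
    E(MS_e) = sigma_e^2

with design-dependent constants c1, c2, c3 obtained here from traces of the
sequential projection increments (equivalent to the classical tabular
EMS algorithm for Type I expectations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import TrialLayout

__all__ = [
    "TrialData",
    "AnovaSummary",
    "design_matrices",
    "sequential_ss",
    "ems_coefficients",
    "AnovaOperator",
]

_RANK_TOL = 1e-10


@dataclass
class TrialData:
    """Plot-level responses for one trial laid out as an alpha design."""

    layout: TrialLayout
    response: np.ndarray
    trial_id: str = "trial"

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float).ravel()
        if self.response.size != self.layout.n_plots:
            raise ValueError(
                f"response length {self.response.size} != {self.layout.n_plots} plots"
            )
        if not np.all(np.isfinite(self.response)):
            raise ValueError("response contains non-finite values")


@dataclass
class AnovaSummary:
    """Sequential ANOVA of one trial: df, SS, MS per design stratum plus EMS constants.

    ``df``/``ss``/``ms`` are ordered (replicates, blocks, error).  A stratum
    with zero rank increment (e.g. blocks aliased with replicates when
    k = t) is carried as degenerate: df 0, SS 0, MS nan.
    """

    df: tuple[int, int, int]
    ss: tuple[float, float, float]
    ems_coeffs: tuple[float, float, float]
    total_df: int
    total_ss: float
    ss_treat: float = 0.0
    df_treat: int = 0
    trial_id: str = "trial"
    degenerate: tuple[bool, bool, bool] = field(init=False)

    def __post_init__(self) -> None:
        self.degenerate = tuple(v == 0 for v in self.df)

    @property
    def ms(self) -> tuple[float, float, float]:
        return tuple(
            s / v if v > 0 else float("nan") for s, v in zip(self.ss, self.df)
        )


def design_matrices(data: TrialData) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (X, Z_r, Z_b): intercept+treatment fixed-effect matrix and the
    0/1 incidence matrices for replicates and blocks-within-replicates.

    Rows follow the layout's (replicate, block, plot) plot order; block
    columns are nested within replicate columns.
    """
    layout = data.layout
    rep, blk, trt = layout.arrays()
    n = layout.n_plots
    X = np.zeros((n, 1 + layout.n_treatments))
    X[:, 0] = 1.0
    X[np.arange(n), 1 + trt] = 1.0
    Zr = np.zeros((n, layout.n_replicates))
    Zr[np.arange(n), rep] = 1.0
    Zb = np.zeros((n, layout.n_replicates * layout.blocks_per_replicate))
    Zb[np.arange(n), blk] = 1.0
    return X, Zr, Zb


def _orth_increment(Q: np.ndarray | None, cols: np.ndarray) -> np.ndarray:
    """Orthonormal basis for the part of span(cols) orthogonal to span(Q)."""
    resid = cols - Q @ (Q.T @ cols) if Q is not None else cols.copy()
    u, s, _ = np.linalg.svd(resid, full_matrices=False)
    scale = max(s[0], 1.0) if s.size else 1.0
    rank = int(np.sum(s > _RANK_TOL * scale))
    return u[:, :rank]


class AnovaOperator:
    """Precomputed sequential-projection operator for one layout.

    Builds, once, the orthonormal bases of the successive column-space
    increments (intercept -> treatments -> replicates -> blocks) so many
    response vectors can be decomposed with matrix products.  Used by the
    simulation oracles; :func:`sequential_ss` wraps the single-response case.
    """

    def __init__(self, layout: TrialLayout):
        self.layout = layout
        rep = np.zeros((layout.n_plots, 1))
        data = TrialData(layout, rep[:, 0], trial_id="_op")
        X, Zr, Zb = design_matrices(data)
        ones = X[:, :1]
        T = X[:, 1:]
        Q0 = _orth_increment(None, ones)  # intercept
        basis = Q0
        self.Q_treat = _orth_increment(basis, T)
        basis = np.hstack([basis, self.Q_treat])
        self.Q_rep = _orth_increment(basis, Zr)
        basis = np.hstack([basis, self.Q_rep])
        self.Q_blk = _orth_increment(basis, Zb)
        basis = np.hstack([basis, self.Q_blk])
        self.Q_model = basis  # intercept + treat + rep + blk
        self.Zr, self.Zb = Zr, Zb
        n = layout.n_plots
        self.df = (
            self.Q_rep.shape[1],
            self.Q_blk.shape[1],
            n - basis.shape[1],
        )
        self.df_treat = self.Q_treat.shape[1]
        self.total_df = n - 1
        self.ems_coeffs = self._ems_coeffs()

    def _ems_coeffs(self) -> tuple[float, float, float]:
        vr, vb, _ = self.df
        # tr(Q_i Z Z^T) = ||Z^T B_i||_F^2 for B_i the orthonormal increment basis
        c1 = float(np.sum((self.Zb.T @ self.Q_rep) ** 2) / vr) if vr > 0 else float("nan")
        c2 = float(np.sum((self.Zr.T @ self.Q_rep) ** 2) / vr) if vr > 0 else float("nan")
        c3 = float(np.sum((self.Zb.T @ self.Q_blk) ** 2) / vb) if vb > 0 else float("nan")
        return c1, c2, c3

    def ss_many(self, Y: np.ndarray) -> dict[str, np.ndarray]:
        """Sequential SS for responses in the rows of ``Y`` (m, n_plots)."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        ybar = Y.mean(axis=1, keepdims=True)
        total = np.sum((Y - ybar) ** 2, axis=1)
        ss_t = np.sum((Y @ self.Q_treat) ** 2, axis=1)
        ss_r = np.sum((Y @ self.Q_rep) ** 2, axis=1)
        ss_b = np.sum((Y @ self.Q_blk) ** 2, axis=1)
        ss_e = total - ss_t - ss_r - ss_b
        return {
            "treat": ss_t,
            "rep": ss_r,
            "block": ss_b,
            "error": np.maximum(ss_e, 0.0),
            "total": total,
        }

    def summaries(self, Y: np.ndarray, trial_ids=None) -> list[AnovaSummary]:
        ss = self.ss_many(Y)
        m = ss["total"].size
        ids = trial_ids if trial_ids is not None else [f"trial{i}" for i in range(m)]
        return [
            AnovaSummary(
                df=self.df,
                ss=(float(ss["rep"][i]), float(ss["block"][i]), float(ss["error"][i])),
                ems_coeffs=self.ems_coeffs,
                total_df=self.total_df,
                total_ss=float(ss["total"][i]),
                ss_treat=float(ss["treat"][i]),
                df_treat=self.df_treat,
                trial_id=str(ids[i]),
            )
            for i in range(m)
        ]


def sequential_ss(data: TrialData) -> AnovaSummary:
    """Treatments-first sequential ANOVA decomposition of one trial.

    Fitting order is intercept -> treatments -> replicates -> blocks ->
    residual; each stratum's SS is the increment in regression sum of
    squares as its columns enter, and its df the rank increment.
    """
    op = AnovaOperator(data.layout)
    return op.summaries(data.response[None, :], trial_ids=[data.trial_id])[0]


def ems_coefficients(layout: TrialLayout) -> tuple[float, float, float]:
    """EMS constants (c1, c2, c3) of the sequential ANOVA for this layout.

    Computed as normalised traces of the sequential projection increments
    against the replicate/block incidence Gram matrices:
    c1 = tr(Q_r Z_b Z_b^T)/v_r, c2 = tr(Q_r Z_r Z_r^T)/v_r,
    c3 = tr(Q_b Z_b Z_b^T)/v_b.  For resolvable designs c2 = b*k and c1 = k;
    a degenerate stratum yields nan for its coefficients.
    """
    return AnovaOperator(layout).ems_coeffs
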