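"""Plain-text readers and writers.

Trial tables are CSV with the mandatory header
``trial_id,replicate,block,plot,treatment,response`` and 1-based indices
(field-book convention); evaluation reports are CSV with one row per
method.  JSON is used for fitted-model artifacts elsewhere; no bespoke
binary formats.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .anova import TrialData
from .design import PlotRecord, TrialLayout
from .simulate import EvaluationReport

__all__ = ["read_trials", "write_trials", "write_report", "read_report"]

log = logging.getLogger("interblock")

_COLUMNS = ["trial_id", "replicate", "block", "plot", "treatment", "response"]
_REPORT_COLUMNS = [
    "method",
    "msed",
    "mse_replicate",
    "mse_block",
    "mse_error",
    "mean_aic",
    "zero_rate_rep",
    "zero_rate_block",
]


def read_trials(path, sep: str = ",") -> list[TrialData]:
    """Read a plot-level trial table into one validated TrialData per trial_id.

    Layout invariants (resolvability, one occurrence per replicate, no
    repeats within a block) are enforced; violations raise ValueError naming
    the broken rule and the trial.  Trials are returned ordered by trial_id.
    """
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing required columns: {missing}")
    dup = df.duplicated(subset=["trial_id", "replicate", "block", "plot"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()  # +2: header + 1-based file rows
        raise ValueError(f"duplicate (trial_id, replicate, block, plot) at file rows {rows}")
    if not np.all(np.isfinite(df["response"].to_numpy(dtype=float))):
        raise ValueError("response column contains non-finite values")

    out: list[TrialData] = []
    for tid, g in sorted(df.groupby("trial_id"), key=lambda kv: str(kv[0])):
        r = int(g["replicate"].max())
        b = int(g["block"].max())
        k = int(g["plot"].max())
        t = int(g["treatment"].max())
        records = [
            PlotRecord(int(row.replicate), int(row.block), int(row.plot), int(row.treatment))
            for row in g.itertuples()
        ]
        try:
            layout = TrialLayout(
                n_treatments=t,
                n_replicates=r,
                blocks_per_replicate=b,
                block_size=k,
                assignment=records,
            )
        except ValueError as exc:
            raise ValueError(f"trial {tid!r}: {exc}") from exc
        g2 = g.sort_values(["replicate", "block", "plot"])
        out.append(TrialData(layout, g2["response"].to_numpy(dtype=float), trial_id=str(tid)))
        log.debug("read trial %s: t=%d r=%d b=%d k=%d", tid, t, r, b, k)
    return out


def write_trials(trials: list[TrialData], path, sep: str = ",") -> None:
    """Write plot-level trial data as a CSV trial table (1-based indices)."""
    rows = []
    for td in trials:
        recs = sorted(td.layout.assignment, key=lambda p: (p.replicate, p.block, p.plot))
        for rec, y in zip(recs, td.response):
            rows.append(
                {
                    "trial_id": td.trial_id,
                    "replicate": rec.replicate,
                    "block": rec.block,
                    "plot": rec.plot,
                    "treatment": rec.treatment,
                    "response": y,
                }
            )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep=sep, index=False)


def write_report(report: EvaluationReport, path) -> None:
    """Write an evaluation report as CSV, one row per method (12 sig. digits)."""
    df = pd.DataFrame(report.as_rows(), columns=_REPORT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def read_report(path) -> pd.DataFrame:
    """Read back an evaluation-report CSV."""
    return pd.read_csv(path)
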