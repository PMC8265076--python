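"""Tabular report bundle mirroring the analysis panels of the fitted model:
the existence-test table, parameter-estimate tables, effect summaries,
likelihood profile, and residual diagnostics, with CSV/JSON export and
optional static plots.

Every number in the bundle is copied from the ModelFit / SWTResult it was
built from; nothing is recomputed, so the tables cannot drift from the fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import acf as _acf

from .estimation import ModelFit
from .model import phase_slices
from .swt import SWTResult

__all__ = ["ReportBundle", "build_report"]

_TABLE_FIELDS = (
    "swt_table",
    "unit_table",
    "estimates",
    "summaries",
    "profile",
    "residuals",
    "acf",
)


@dataclass(frozen=True)
class ReportBundle:
    """All report tables for one fitted dataset.

    Date-valued cells are ISO strings so the bundle serialises losslessly.
    """

    tau_hat: int
    tau_date: str
    exists: bool
    alpha: float
    structure: str
    swt_table: pd.DataFrame
    unit_table: pd.DataFrame
    estimates: pd.DataFrame
    summaries: pd.DataFrame
    profile: pd.DataFrame
    residuals: pd.DataFrame
    acf: pd.DataFrame

    def to_json(self) -> str:
        payload = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in _TABLE_FIELDS:
                payload[f.name] = v.to_dict(orient="split")
                payload[f.name].pop("index", None)
            else:
                payload[f.name] = v
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ReportBundle":
        payload = json.loads(text)
        kwargs = {}
        for f in fields(cls):
            v = payload[f.name]
            if f.name in _TABLE_FIELDS:
                kwargs[f.name] = pd.DataFrame(v["data"], columns=v["columns"])
            else:
                kwargs[f.name] = v
        return cls(**kwargs)

    def write(self, outdir) -> None:
        """Write every table as CSV plus the whole bundle as report.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in _TABLE_FIELDS:
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "report.json").write_text(self.to_json())

    def plot(self, outdir) -> list:
        """Static diagnostic plots (series fit, profile, residual ACF)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        fig, ax = plt.subplots(figsize=(7, 3.5))
        ax.plot(self.profile["tau"], self.profile["loglik"], marker="o", ms=3)
        ax.axvline(self.tau_hat, color="crimson", ls="--", lw=1)
        ax.set_xlabel("candidate change-point (tick)")
        ax.set_ylabel("conditional log-likelihood")
        fig.tight_layout()
        p = outdir / "profile.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
        for unit, grp in self.residuals.groupby("unit", sort=False):
            fig, axes = plt.subplots(2, 1, figsize=(7, 5), sharex=False)
            axes[0].plot(grp["tick"], grp["value"], lw=0.8, label="observed")
            axes[0].plot(grp["tick"], grp["fitted"], lw=1.4, label="fitted mean")
            axes[0].axvline(self.tau_hat, color="crimson", ls="--", lw=1)
            axes[0].legend(loc="best", fontsize=8)
            axes[0].set_title(f"{unit}: fit")
            axes[1].stem(grp["tick"], grp["residual"])
            axes[1].axvline(self.tau_hat, color="crimson", ls="--", lw=1)
            axes[1].set_title("residuals")
            fig.tight_layout()
            p = outdir / f"fit_{unit}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
        return written


def _residual_tables(fit: ModelFit):
    res_rows, acf_rows = [], []
    for uf in fit.unit_fits:
        n = len(uf.residuals)
        pre, post = phase_slices(n, fit.tau_hat)
        for t in range(n):
            res_rows.append(
                {
                    "unit": uf.unit_id,
                    "tick": t + 1,
                    "phase": 1 if t < fit.tau_hat - 1 else 2,
                    "value": float(uf.residuals[t] + uf.fitted[t]),
                    "fitted": float(uf.fitted[t]),
                    "residual": float(uf.residuals[t]),
                }
            )
        for phase, sl in ((1, pre), (2, post)):
            z = uf.residuals[sl]
            nlags = min(10, len(z) - 2)
            if nlags < 1:
                continue
            vals = _acf(z, nlags=nlags, fft=False)
            for lag, v in enumerate(vals):
                acf_rows.append(
                    {"unit": uf.unit_id, "phase": phase, "lag": lag, "acf": float(v)}
                )
    return pd.DataFrame(res_rows), pd.DataFrame(acf_rows)


def build_report(fit: ModelFit, swt: SWTResult) -> ReportBundle:
    """Assemble the report bundle from a fit and an existence-test result.

    The two must come from the same dataset and candidate set: the test's
    internal change-point estimate has to agree with the fit's.
    """
    if swt.tau_hat != fit.tau_hat:
        raise ValueError(
            f"fit (tau_hat={fit.tau_hat}) and test (tau_hat={swt.tau_hat}) "
            "disagree; were they run on the same dataset and candidates?"
        )
    if swt.df != 2 * fit.N:
        raise ValueError("fit and test disagree on the number of units")
    profile = pd.DataFrame(
        {
            "tau": fit.profile.candidates.indices,
            "loglik": fit.profile.logliks,
            "valid": fit.profile.valid,
        }
    )
    residuals, acf_table = _residual_tables(fit)
    return ReportBundle(
        tau_hat=fit.tau_hat,
        tau_date=str(np.datetime64(fit.tau_date, "D"))
        if isinstance(fit.tau_date, (np.datetime64, pd.Timestamp))
        else str(fit.tau_date),
        exists=swt.exists,
        alpha=fit.alpha,
        structure=fit.structure,
        swt_table=swt.table.copy(),
        unit_table=swt.unit_table.copy(),
        estimates=fit.estimates.copy(),
        summaries=fit.summaries.copy(),
        profile=profile,
        residuals=residuals,
        acf=acf_table,
    )
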