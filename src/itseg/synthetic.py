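"""Synthetic multi-unit interrupted time series with the model's exact
generative structure: piecewise-linear unit means sharing one global
change-point, plus phase-specific AR(1) residuals started from the pre-phase
stationary distribution.

Used for tests, calibration studies and demo fixtures.  The generator mirrors
the estimator's conventions: the innovation at t = tau is the first post-phase
one and regresses on r_{tau-1} across the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import (
    ITSDataset,
    NoiseParams,
    SegmentedMeanParams,
    UnitSeries,
    marginal_variance,
    mean_vector,
)

__all__ = ["ScenarioSpec", "simulate_unit", "simulate_frame", "simulate_dataset", "preset_scenarios"]


@dataclass(frozen=True)
class ScenarioSpec:
    """Fully specified generating scenario.

    One global change-point ``tau`` is shared by all units; mean and noise
    parameters are unit-specific.  ``start``/``step_days`` define a calendar
    grid (``start=None`` gives plain integer ticks).  ``missing_rate`` blanks
    a fraction of interior cells when exporting a raw frame, to exercise the
    ingestion-side interpolation.
    """

    N: int
    n: int
    tau: int
    mean_params: tuple
    noise_params: tuple
    seed: int = 0
    start: str | None = "2010-01-01"
    step_days: int = 14
    missing_rate: float = 0.0
    unit_ids: tuple = ()

    def __post_init__(self):
        if self.N < 1 or self.n < 3:
            raise ValueError("need N >= 1 units and n >= 3 time points")
        if not 1 < self.tau <= self.n:
            raise ValueError(f"tau={self.tau} not admissible for n={self.n}")
        if len(self.mean_params) != self.N or len(self.noise_params) != self.N:
            raise ValueError("need one mean/noise parameter set per unit")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        ids = self.unit_ids or tuple(f"unit_{chr(ord('A') + i)}" for i in range(self.N))
        if len(ids) != self.N:
            raise ValueError("unit_ids length must equal N")
        object.__setattr__(self, "unit_ids", tuple(ids))
        object.__setattr__(self, "mean_params", tuple(self.mean_params))
        object.__setattr__(self, "noise_params", tuple(self.noise_params))

    @property
    def times(self) -> np.ndarray:
        if self.start is None:
            return np.arange(1, self.n + 1)
        start = np.datetime64(self.start, "D")
        return start + np.arange(self.n) * np.timedelta64(self.step_days, "D")


def _unit_rng(spec: ScenarioSpec, i: int) -> np.random.Generator:
    children = np.random.SeedSequence(spec.seed).spawn(spec.N + 1)
    return np.random.default_rng(children[i])


def simulate_residuals(noise: NoiseParams, n: int, tau: int, rng: np.random.Generator) -> np.ndarray:
    """Phase-switching AR(1) residual path, stationary phase-1 start."""
    r = np.empty(n)
    r[0] = rng.normal(0.0, np.sqrt(marginal_variance(noise, 1)))
    s1, s2 = np.sqrt(noise.sigma2_w1), np.sqrt(noise.sigma2_w2)
    e = rng.normal(size=n - 1)
    for t in range(2, n + 1):  # 1-based tick
        phase = 1 if t <= tau - 1 else 2
        phi, s = (noise.phi1, s1) if phase == 1 else (noise.phi2, s2)
        r[t - 1] = phi * r[t - 2] + s * e[t - 2]
    return r


def simulate_unit(spec: ScenarioSpec, i: int) -> UnitSeries:
    """Simulate unit i of the scenario (independently reproducible)."""
    if not 0 <= i < spec.N:
        raise IndexError(f"unit index {i} out of range for N={spec.N}")
    rng = _unit_rng(spec, i)
    mu = mean_vector(spec.mean_params[i], spec.n, spec.tau)
    r = simulate_residuals(spec.noise_params[i], spec.n, spec.tau, rng)
    return UnitSeries(unit_id=spec.unit_ids[i], times=spec.times, values=mu + r)


def simulate_frame(spec: ScenarioSpec) -> pd.DataFrame:
    """Wide data frame (date column + one column per unit), with
    ``missing_rate`` of interior cells blanked to NaN."""
    units = [simulate_unit(spec, i) for i in range(spec.N)]
    df = pd.DataFrame({"date": spec.times})
    for u in units:
        df[u.unit_id] = u.values
    if spec.missing_rate > 0:
        rng = _unit_rng(spec, spec.N)  # reserved child seed for the mask
        mask = rng.random((spec.n, spec.N)) < spec.missing_rate
        mask[0, :] = False
        mask[-1, :] = False
        vals = df.iloc[:, 1:].to_numpy()
        vals[mask] = np.nan
        df.iloc[:, 1:] = vals
    return df


def simulate_dataset(spec: ScenarioSpec, csv_path=None) -> ITSDataset:
    """Simulate the full panel; optionally also write the wide CSV.

    The returned in-memory dataset never contains missing values; blanking
    only applies to the written file (read it back through
    :func:`itseg.io.load_dataset` to exercise interpolation).
    """
    units = tuple(simulate_unit(spec, i) for i in range(spec.N))
    if csv_path is not None:
        simulate_frame(spec).to_csv(csv_path, index=False)
    t_star = spec.times[spec.tau - 1]
    return ITSDataset(units=units, intervention_time=t_star)


def preset_scenarios(seed: int = 0) -> dict[str, ScenarioSpec]:
    """Named generating scenarios covering the study conditions.

    - ``null``: no change of any kind (type-I calibration).
    - ``level-jump``: level change of 2 pre-phase marginal SDs, no trend change.
    - ``slope-change``: pure trend change (level change 0 at the change-point).
    - ``noise-only-change``: mean unchanged but stronger autocorrelation and
      smaller variance after the change-point — the motivating case where an
      intervention stabilises an outcome without moving its level.
    - ``biweekly-panel``: 4 units on a bi-weekly calendar grid spanning about
      7 years, with unit-specific modest changes (demo-data shape).
    """
    base_mean = SegmentedMeanParams(10.0, 0.05, 0.0, 0.0)
    ar = NoiseParams("ar1", 0.3, 0.3, 1.0, 1.0)
    sd = np.sqrt(marginal_variance(ar, 1))
    n, tau, N = 100, 50, 4

    def means(delta, Delta):
        return tuple(replace(base_mean, delta=delta, Delta=Delta) for _ in range(N))

    scenarios = {
        "null": ScenarioSpec(N, n, tau, means(0.0, 0.0), (ar,) * N, seed=seed),
        "level-jump": ScenarioSpec(N, n, tau, means(2.0 * sd, 0.0), (ar,) * N, seed=seed),
        "slope-change": ScenarioSpec(
            N, n, tau, means(-0.05 * tau, 0.05), (ar,) * N, seed=seed
        ),
        "noise-only-change": ScenarioSpec(
            N,
            n,
            tau,
            means(0.0, 0.0),
            (NoiseParams("ar1", 0.2, 0.6, 1.0, 0.4),) * N,
            seed=seed,
        ),
    }
    # ~7 years of bi-weekly data for 4 units: the shape of the demo panel
    n_bw, tau_bw = 193, 75
    rng = np.random.default_rng(seed)
    mean_bw = tuple(
        SegmentedMeanParams(
            beta0=float(rng.uniform(40, 60)),
            beta1=float(rng.uniform(-0.02, 0.02)),
            delta=float(rng.uniform(1.0, 3.0)),
            Delta=float(rng.uniform(-0.03, -0.01)),
        )
        for _ in range(4)
    )
    scenarios["biweekly-panel"] = ScenarioSpec(
        4,
        n_bw,
        tau_bw,
        mean_bw,
        (NoiseParams("ar1", 0.4, 0.5, 1.0, 0.8),) * 4,
        seed=seed,
        start="2010-01-01",
        step_days=14,
    )
    return scenarios
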