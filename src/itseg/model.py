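"""Core model objects for segmented interrupted time-series (ITS) regression.

The model decomposes each unit's outcome into a piecewise-linear mean with a
single change-point ``tau`` and a stochastic residual process whose dependence
parameters may differ between the pre- and post-change-point phases:

    y_t = mu_t + r_t,
    mu_t = beta0 + beta1 * t              for t <  tau,
    mu_t = (beta0 + delta) + (beta1 + Delta) * t   for t >= tau,

with residuals following, per phase j in {1, 2},

    r_t = phi_j * r_{t-1} + e_t,   e_t ~ N(0, sigma2_w_j)   (AR(1) case).

Internally time is the 1-based integer tick t = 1..n on the unit's evenly
spaced measurement grid; ``tau`` is the FIRST tick of the post phase.  The
innovation at t = tau already belongs to phase 2 and regresses on r_{tau-1}
across the boundary; phase-1 innovations cover 1 < t <= tau - 1.

Everything here is deterministic and in-memory; parsing, date handling and
report generation live in :mod:`itseg.io` / :mod:`itseg.report`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MIN_SEGMENT",
    "PHI_CLAMP",
    "Structure",
    "UnitSeries",
    "ITSDataset",
    "CandidateSet",
    "SegmentedMeanParams",
    "NoiseParams",
    "design_matrix",
    "mean_at",
    "mean_vector",
    "level_change",
    "trend_change",
    "marginal_variance",
    "phase_index",
    "phase_slices",
    "Whitener",
    "whitening_weights",
]

#: Minimum number of observations per phase for a change-point candidate to be
#: admissible: 2 points pin down intercept+slope, 2 more give at least a pair
#: of lagged residuals for the dependence parameter.
MIN_SEGMENT = 4

#: Dependence parameters are clamped into [-PHI_CLAMP, PHI_CLAMP] during
#: estimation so that marginal variances stay finite.
PHI_CLAMP = 0.99

#: Valid correlation-structure names.
Structure = str
STRUCTURES = ("ar1", "exchangeable", "independent")


def _check_structure(structure: str) -> str:
    if structure not in STRUCTURES:
        raise ValueError(
            f"unknown correlation structure {structure!r}; expected one of {STRUCTURES}"
        )
    return structure


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UnitSeries:
    """One unit's evenly spaced outcome series.

    Parameters
    ----------
    unit_id : str
        Label for the unit (e.g. a hospital ward).
    times : ndarray
        Strictly increasing measurement times: ``datetime64`` values or
        numeric ticks.  Spacing must be constant up to ``grid_tol`` relative
        tolerance.
    values : ndarray of float
        Outcome values, same length as ``times``, no missing entries
        (missing-data handling happens upstream during ingestion).
    """

    unit_id: str
    times: np.ndarray
    values: np.ndarray
    grid_tol: float = 0.01

    def __post_init__(self):
        times = np.asarray(self.times)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or len(times) != len(values):
            raise ValueError(
                f"unit {self.unit_id!r}: times and values must be 1-d of equal length"
            )
        if len(times) < 2:
            raise ValueError(f"unit {self.unit_id!r}: need at least 2 observations")
        if not np.all(np.isfinite(values)):
            raise ValueError(
                f"unit {self.unit_id!r}: values contain non-finite entries; "
                "interpolate or drop missing data before model construction"
            )
        steps = np.diff(times)
        if np.issubdtype(times.dtype, np.datetime64):
            steps = steps.astype("timedelta64[s]").astype(float)
        else:
            steps = steps.astype(float)
        if np.any(steps <= 0):
            raise ValueError(f"unit {self.unit_id!r}: times must be strictly increasing")
        step = np.median(steps)
        if np.any(np.abs(steps - step) > self.grid_tol * step):
            raise ValueError(
                f"unit {self.unit_id!r}: measurement grid is not evenly spaced "
                f"(median step {step}, max deviation {np.max(np.abs(steps - step))})"
            )

    @property
    def n(self) -> int:
        return len(self.values)

    def index_of(self, time) -> int:
        """1-based tick of ``time`` on this unit's grid."""
        matches = np.nonzero(self.times == np.asarray(time).astype(self.times.dtype))[0]
        if len(matches) == 0:
            raise KeyError(f"time {time!r} not on the grid of unit {self.unit_id!r}")
        return int(matches[0]) + 1


@dataclass(frozen=True)
class ITSDataset:
    """A panel of units sharing one measurement grid and one intervention time.

    All units must have identical ``times`` vectors (apply the overlap
    restriction in :func:`itseg.io.restrict_overlap` first).  The formal
    intervention time ``intervention_time`` anchors the candidate window but
    the estimated change-point need not coincide with it.
    """

    units: tuple
    intervention_time: object = None

    def __post_init__(self):
        units = tuple(self.units)
        object.__setattr__(self, "units", units)
        if len(units) == 0:
            raise ValueError("dataset needs at least one unit")
        t0 = units[0].times
        for u in units[1:]:
            if len(u.times) != len(t0) or not np.all(u.times == t0):
                raise ValueError(
                    f"unit {u.unit_id!r} is not on the common grid; "
                    "restrict to overlapping time points first"
                )
        if self.intervention_time is not None:
            t = np.asarray(self.intervention_time).astype(t0.dtype)
            if t < t0[0] or t > t0[-1]:
                raise ValueError("intervention_time lies outside the observed grid")

    @property
    def N(self) -> int:
        return len(self.units)

    @property
    def times(self) -> np.ndarray:
        return self.units[0].times

    @property
    def n(self) -> int:
        return self.units[0].n

    @property
    def grid_step(self):
        return self.times[1] - self.times[0]


@dataclass(frozen=True)
class CandidateSet:
    """Ordered set Q of 1-based ticks that are potential change-points.

    ``theoretical_index`` records the tick mapped from the formal intervention
    time; it need not belong to Q.
    """

    indices: np.ndarray
    theoretical_index: int | None = None

    def __post_init__(self):
        idx = np.unique(np.asarray(self.indices, dtype=int))
        object.__setattr__(self, "indices", idx)
        if len(idx) == 0:
            raise ValueError("candidate set is empty")

    def validate(self, n: int, min_segment: int = MIN_SEGMENT) -> None:
        lo, hi = min_segment + 1, n - min_segment + 1
        bad = self.indices[(self.indices < lo) | (self.indices > hi)]
        if len(bad):
            raise ValueError(
                f"candidates {bad.tolist()} inadmissible for n={n}: each phase "
                f"needs >= {min_segment} observations (valid range [{lo}, {hi}])"
            )

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices.tolist())


@dataclass(frozen=True)
class SegmentedMeanParams:
    """Mean-function parameters of one unit at a given change-point.

    ``beta0``/``beta1`` are the pre-phase intercept and per-tick slope;
    ``delta`` and ``Delta`` are the post-phase shifts in intercept and slope.
    ``delta == Delta == 0`` encodes "no change in the mean function".
    """

    beta0: float
    beta1: float
    delta: float = 0.0
    Delta: float = 0.0

    def __post_init__(self):
        vals = (self.beta0, self.beta1, self.delta, self.Delta)
        if not all(np.isfinite(vals)):
            raise ValueError(f"mean parameters must be finite, got {vals}")

    def as_array(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.delta, self.Delta])

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "SegmentedMeanParams":
        b0, b1, d, D = (float(v) for v in arr)
        return cls(b0, b1, d, D)


@dataclass(frozen=True)
class NoiseParams:
    """Phase-specific stochastic-component parameters.

    ``phi1``/``phi2`` are the pre/post dependence parameters: the lag-one
    autocorrelation for ``ar1``, the common within-phase pairwise correlation
    for ``exchangeable``, and exactly 0 for ``independent``.
    ``sigma2_w1``/``sigma2_w2`` are the innovation variances (for
    ``exchangeable``/``independent`` they equal the residual variances).
    """

    structure: Structure
    phi1: float
    phi2: float
    sigma2_w1: float
    sigma2_w2: float

    def __post_init__(self):
        _check_structure(self.structure)
        if not (abs(self.phi1) < 1 and abs(self.phi2) < 1):
            raise ValueError(
                f"dependence parameters must lie in (-1, 1); got phi1={self.phi1}, phi2={self.phi2}"
            )
        if not (self.sigma2_w1 > 0 and self.sigma2_w2 > 0):
            raise ValueError(
                f"innovation variances must be positive; got "
                f"{self.sigma2_w1}, {self.sigma2_w2}"
            )
        if self.structure == "independent" and (self.phi1 != 0 or self.phi2 != 0):
            raise ValueError("independent structure requires phi1 = phi2 = 0")

    def phi(self, phase: int) -> float:
        return self.phi1 if phase == 1 else self.phi2

    def sigma2_w(self, phase: int) -> float:
        return self.sigma2_w1 if phase == 1 else self.sigma2_w2


# ---------------------------------------------------------------------------
# Deterministic operations
# ---------------------------------------------------------------------------


def design_matrix(n: int, tau: int) -> np.ndarray:
    """Design matrix of the segmented mean on ticks 1..n with change-point tau.

    Row t is ``[1, t, I(t >= tau), t * I(t >= tau)]`` so that
    ``X @ (beta0, beta1, delta, Delta)`` is the piecewise mean.

    ``tau`` must satisfy ``1 < tau <= n``; admissibility relative to
    ``MIN_SEGMENT`` is the caller's concern (candidate construction).
    """
    n = int(n)
    tau = int(tau)
    if not 1 < tau <= n:
        raise ValueError(f"tau={tau} out of range (1, {n}] for n={n}")
    t = np.arange(1, n + 1, dtype=float)
    post = (t >= tau).astype(float)
    return np.column_stack([np.ones(n), t, post, t * post])


def mean_at(params: SegmentedMeanParams, t: int, tau: int) -> float:
    """Piecewise mean at tick ``t`` for change-point ``tau``."""
    if t < tau:
        return params.beta0 + params.beta1 * t
    return (params.beta0 + params.delta) + (params.beta1 + params.Delta) * t


def mean_vector(params: SegmentedMeanParams, n: int, tau: int) -> np.ndarray:
    """Piecewise mean over ticks 1..n (vectorised :func:`mean_at`)."""
    return design_matrix(n, tau) @ params.as_array()


def level_change(params: SegmentedMeanParams, tau: int) -> float:
    """Discontinuity delta + Delta * tau between the projected pre-phase mean
    and the post-phase mean at the change-point (the anchored-intercept
    change reported in ITS studies)."""
    return params.delta + params.Delta * tau


def trend_change(params: SegmentedMeanParams) -> float:
    """Change in slope, Delta = (post slope) - (pre slope)."""
    return params.Delta


def marginal_variance(noise: NoiseParams, phase: int) -> float:
    """Variance of the response at any time point of the given phase.

    AR(1): sigma2_w / (1 - phi^2).  For exchangeable and independent the
    stored variance already is the marginal variance.
    """
    if phase not in (1, 2):
        raise ValueError(f"phase must be 1 or 2, got {phase}")
    s2 = noise.sigma2_w(phase)
    if noise.structure == "ar1":
        phi = noise.phi(phase)
        return s2 / (1.0 - phi * phi)
    return s2


def phase_index(t: int, tau: int) -> int:
    """Phase of the innovation at tick t: 1 while t <= tau - 1, else 2.

    The innovation at t = tau is the first post-phase one; it regresses on
    r_{tau-1} across the boundary.
    """
    return 1 if t <= tau - 1 else 2


def phase_slices(n: int, tau: int) -> tuple[slice, slice]:
    """0-based slices of the pre-phase (ticks 1..tau-1) and post-phase
    (ticks tau..n) observations."""
    return slice(0, tau - 1), slice(tau - 1, n)


class Whitener:
    """Linear transform L mapping residuals to (approximately) iid unit-variance
    innovations; implements both GLS weighting and the conditional likelihood.

    For ``ar1``/``independent`` the transform is lower bidiagonal: row 1
    scales r_1 by the reciprocal root of the phase-1 marginal variance, and
    row t >= 2 computes ``(r_t - phi_{j(t)} r_{t-1}) / sigma_{w,j(t)}`` with
    the phase assignment of :func:`phase_index`.  For ``exchangeable`` it is
    the symmetric inverse square root of the block compound-symmetry
    covariance (one block per phase).
    """

    def __init__(self, noise: NoiseParams, n: int, tau: int):
        n = int(n)
        tau = int(tau)
        if not 1 < tau <= n + 1:
            raise ValueError(f"tau={tau} out of range (1, {n + 1}] for n={n}")
        self.noise = noise
        self.n = n
        self.tau = tau
        if noise.structure == "exchangeable":
            self._dense = self._cs_inv_sqrt()
        else:
            self._dense = None
            t = np.arange(1, n + 1)
            phase = np.where(t <= tau - 1, 1, 2)
            sigma = np.where(phase == 1, np.sqrt(noise.sigma2_w1), np.sqrt(noise.sigma2_w2))
            phi = np.where(phase == 1, noise.phi1, noise.phi2)
            self._diag = 1.0 / sigma
            self._sub = -phi[1:] / sigma[1:]  # coefficient on r_{t-1} in row t
            # r_1 has no predecessor: scale by its stationary (phase-1) sd
            self._diag[0] = 1.0 / np.sqrt(marginal_variance(noise, 1))

    def _cs_inv_sqrt(self) -> np.ndarray:
        n, tau, noise = self.n, self.tau, self.noise
        L = np.zeros((n, n))
        for phase, sl in zip((1, 2), phase_slices(n, tau)):
            m = sl.stop - sl.start
            if m == 0:
                continue
            rho, s2 = noise.phi(phase), noise.sigma2_w(phase)
            # Sigma = s2 [(1-rho) I + rho J]; inverse sqrt via its two eigenspaces
            if m == 1:
                L[sl, sl] = 1.0 / np.sqrt(s2)
                continue
            lam_mean = s2 * (1 - rho + m * rho)   # eigenvalue along the 1-vector
            lam_perp = s2 * (1 - rho)
            if lam_mean <= 0 or lam_perp <= 0:
                raise ValueError(
                    f"compound-symmetry block not positive definite (rho={rho}, m={m})"
                )
            P = np.full((m, m), 1.0 / m)
            block = P / np.sqrt(lam_mean) + (np.eye(m) - P) / np.sqrt(lam_perp)
            L[sl, sl] = block
        return L

    def matrix(self) -> np.ndarray:
        """Dense n x n form of L."""
        if self._dense is not None:
            return self._dense
        L = np.zeros((self.n, self.n))
        L[np.arange(self.n), np.arange(self.n)] = self._diag
        L[np.arange(1, self.n), np.arange(self.n - 1)] = self._sub
        return L

    def apply(self, arr: np.ndarray) -> np.ndarray:
        """L @ arr for a vector or column-stacked matrix, in O(n) per column
        for the bidiagonal structures."""
        arr = np.asarray(arr, dtype=float)
        if self._dense is not None:
            return self._dense @ arr
        if arr.ndim == 1:
            out = arr * self._diag
            out[1:] += arr[:-1] * self._sub
            return out
        out = arr * self._diag[:, None]
        out[1:] += arr[:-1] * self._sub[:, None]
        return out

    def inverse_apply(self, w: np.ndarray) -> np.ndarray:
        """Solve L r = w (reconstructs residuals from innovations)."""
        if self._dense is not None:
            return np.linalg.solve(self._dense, np.asarray(w, dtype=float))
        w = np.asarray(w, dtype=float)
        r = np.empty_like(w)
        r[0] = w[0] / self._diag[0]
        for t in range(1, self.n):
            r[t] = (w[t] - self._sub[t - 1] * r[t - 1]) / self._diag[t]
        return r


def whitening_weights(noise: NoiseParams, n: int, tau: int) -> Whitener:
    """Whitening transform for a length-n residual vector with change-point tau.

    ``tau = n + 1`` is allowed and means "no post phase" (single-phase
    structure), which is how the null model of the existence test weights its
    residuals.
    """
    return Whitener(noise, n, tau)
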