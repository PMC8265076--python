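"""Joint estimation of mean, noise, and change-point parameters.

The fitting strategy, per change-point candidate tau:

1. GLS of the segmented design with the current whitening transform,
2. method-of-moments update of the phase-specific noise parameters from the
   new residuals,

iterated to convergence (IRLS, initialised at phi = 0 so the first pass is
OLS).  The global change-point is the candidate maximising the summed
per-unit conditional log-likelihood (conditioning on each unit's first
observation); ties break to the earliest candidate.  Units are assumed
independent, so the panel profile is the sum of unit profiles and all
covariance matrices are block diagonal across units.

Confidence intervals and p-values for the mean-function contrasts are
Wald-type with standard-normal quantiles from the GLS covariance, computed
conditionally on the estimated change-point (uncertainty in tau_hat is not
propagated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    MIN_SEGMENT,
    PHI_CLAMP,
    CandidateSet,
    ITSDataset,
    NoiseParams,
    SegmentedMeanParams,
    Structure,
    UnitSeries,
    Whitener,
    design_matrix,
    marginal_variance,
    phase_slices,
    whitening_weights,
)

__all__ = [
    "UnitFit",
    "LikelihoodProfile",
    "ModelFit",
    "gls_fit",
    "mom_noise",
    "irls_unit_fit",
    "conditional_loglik",
    "changepoint_profile",
    "fit_its_model",
]

IRLS_TOL = 1e-8
IRLS_MAX_ITER = 50


class SingularDesignError(np.linalg.LinAlgError):
    pass


class DegenerateDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UnitFit:
    """Converged fit of one unit at a fixed change-point."""

    unit_id: str
    tau: int
    mean: SegmentedMeanParams
    mean_cov: np.ndarray
    noise: NoiseParams
    loglik: float
    residuals: np.ndarray
    fitted: np.ndarray
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class LikelihoodProfile:
    """Summed conditional log-likelihood over the candidate set."""

    candidates: CandidateSet
    logliks: np.ndarray
    valid: np.ndarray

    @property
    def argmax_index(self) -> int:
        """Candidate tick maximising the profile (earliest on ties)."""
        ll = np.where(self.valid, self.logliks, -np.inf)
        return int(self.candidates.indices[int(np.argmax(ll))])


@dataclass(frozen=True)
class ModelFit:
    """Joint multi-unit fit at the estimated change-point."""

    tau_hat: int
    tau_date: object
    unit_fits: tuple
    profile: LikelihoodProfile
    structure: Structure
    summaries: pd.DataFrame
    estimates: pd.DataFrame
    alpha: float

    @property
    def N(self) -> int:
        return len(self.unit_fits)


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------


def gls_fit(y: np.ndarray, X: np.ndarray, L) -> tuple[np.ndarray, np.ndarray]:
    """Generalized least squares via whitening.

    Minimises ``||L (y - X b)||^2`` and returns ``(b, cov)`` with
    ``cov = (X' L' L X)^{-1}`` — the innovation variance is already folded
    into L, so no extra scale estimate is applied here.

    ``L`` may be a dense matrix or a :class:`~itseg.model.Whitener`.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if isinstance(L, Whitener):
        Xw = L.apply(X)
        yw = L.apply(y)
    else:
        L = np.asarray(L, dtype=float)
        Xw = L @ X
        yw = L @ y
    xtx = Xw.T @ Xw
    p = X.shape[1]
    if np.linalg.matrix_rank(Xw, tol=1e-10) < p:
        raise SingularDesignError(
            f"whitened design is rank deficient (p={p}); "
            "the change-point candidate leaves a phase with no information"
        )
    coef = np.linalg.solve(xtx, Xw.T @ yw)
    cov = np.linalg.inv(xtx)
    return coef, cov


def _mom_phase(z: np.ndarray, structure: Structure, ddof: int = 2) -> tuple[float, float]:
    """Method-of-moments (phi, sigma2_w) for one phase's residual subsequence.

    The residual variance uses ``m - ddof`` in the denominator, accounting for
    the intercept and slope fitted within the phase.
    """
    m = len(z)
    if m < MIN_SEGMENT:
        raise DegenerateDataError(f"phase too short for noise estimation (m={m})")
    zc = z - z.mean()
    ss = float(zc @ zc)
    if ss <= 0 or not np.isfinite(ss):
        raise DegenerateDataError("zero-variance residuals; data are degenerate")
    s2 = ss / max(m - ddof, 1)
    if structure == "independent":
        return 0.0, s2
    if structure == "ar1":
        phi = float(zc[:-1] @ zc[1:]) / ss
        phi = float(np.clip(phi, -PHI_CLAMP, PHI_CLAMP))
        return phi, s2 * (1.0 - phi * phi)
    # exchangeable: mean off-diagonal product over all within-phase pairs,
    # scaled by the variance.  sum_{t != s} z_t z_s = (sum z)^2 - sum z^2.
    num = (float(zc.sum()) ** 2 - ss) / (m * (m - 1))
    rho = num / (ss / m)
    lo = max(-PHI_CLAMP, -1.0 / (m - 1) + 1e-6)
    rho = float(np.clip(rho, lo, PHI_CLAMP))
    return rho, s2


def mom_noise(residuals: np.ndarray, tau: int, structure: Structure) -> NoiseParams:
    """Phase-specific noise parameters from residuals at change-point tau.

    The pre phase covers ticks 1..tau-1 and the post phase ticks tau..n; each
    needs at least ``MIN_SEGMENT`` points.  ``tau = n + 1`` fits a single
    phase and copies its parameters into both slots (null-model path).
    """
    r = np.asarray(residuals, dtype=float)
    n = len(r)
    if tau == n + 1:
        phi, s2 = _mom_phase(r, structure)
        return NoiseParams(structure, phi, phi, s2, s2)
    pre, post = phase_slices(n, tau)
    phi1, s2_1 = _mom_phase(r[pre], structure)
    phi2, s2_2 = _mom_phase(r[post], structure)
    return NoiseParams(structure, phi1, phi2, s2_1, s2_2)


def conditional_loglik(
    residuals: np.ndarray,
    noise: NoiseParams,
    tau: int,
    include_first_marginal: bool = False,
) -> float:
    """Gaussian log-likelihood of the residual vector given its first element.

    For ``ar1``/``independent`` this is the sum over t = 2..n of the normal
    log-density of the innovation ``e_t = r_t - phi_{j(t)} r_{t-1}`` with the
    phase-specific innovation variance.  ``include_first_marginal`` adds the
    stationary marginal term for t = 1.  For ``exchangeable`` the innovation
    form has no meaning, so the full joint Gaussian log-density under the
    block compound-symmetry covariance is returned instead (the first-
    observation term is then always included).
    """
    r = np.asarray(residuals, dtype=float)
    n = len(r)
    if noise.structure == "exchangeable":
        L = whitening_weights(noise, n, tau)
        w = L.apply(r)
        sign, logdet = np.linalg.slogdet(L.matrix())
        if sign <= 0:
            raise ValueError("whitening transform is not positive definite")
        return float(-0.5 * n * np.log(2 * np.pi) + logdet - 0.5 * w @ w)
    t = np.arange(2, n + 1)
    phase = np.where(t <= tau - 1, 1, 2)
    phi = np.where(phase == 1, noise.phi1, noise.phi2)
    s2 = np.where(phase == 1, noise.sigma2_w1, noise.sigma2_w2)
    if np.any(s2 <= 0):
        raise ValueError("non-positive innovation variance")
    e = r[1:] - phi * r[:-1]
    ll = -0.5 * np.sum(np.log(2 * np.pi * s2) + e * e / s2)
    if include_first_marginal:
        v1 = marginal_variance(noise, 1)
        ll += -0.5 * (np.log(2 * np.pi * v1) + r[0] * r[0] / v1)
    return float(ll)


def irls_unit_fit(
    series: UnitSeries,
    tau: int,
    structure: Structure = "ar1",
    tol: float = IRLS_TOL,
    max_iter: int = IRLS_MAX_ITER,
    include_first_marginal: bool = False,
) -> UnitFit:
    """Fit one unit at a fixed change-point by IRLS.

    Alternates GLS on the segmented design with moment updates of the noise
    parameters, starting from identity weights (phi = 0), until the largest
    absolute change across all parameters drops below ``tol``.  On
    non-convergence the best iterate is returned with ``converged=False`` and
    a warning.
    """
    y = series.values
    n = series.n
    if tau == n + 1:  # null model: single line, single-phase noise
        X = np.column_stack([np.ones(n), np.arange(1, n + 1, dtype=float)])
    else:
        X = design_matrix(n, tau)
    coef, _ = gls_fit(y, X, np.eye(n))
    resid = y - X @ coef
    noise = mom_noise(resid, tau, structure)
    prev = np.concatenate([coef, [noise.phi1, noise.phi2, noise.sigma2_w1, noise.sigma2_w2]])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        L = whitening_weights(noise, n, tau)
        coef, cov = gls_fit(y, X, L)
        resid = y - X @ coef
        noise = mom_noise(resid, tau, structure)
        cur = np.concatenate(
            [coef, [noise.phi1, noise.phi2, noise.sigma2_w1, noise.sigma2_w2]]
        )
        if np.max(np.abs(cur - prev)) < tol:
            converged = True
            prev = cur
            break
        prev = cur
    if not converged:
        warnings.warn(
            f"IRLS did not converge within {max_iter} iterations for unit "
            f"{series.unit_id!r} at tau={tau}; returning last iterate",
            RuntimeWarning,
        )
    L = whitening_weights(noise, n, tau)
    coef, cov = gls_fit(y, X, L)
    resid = y - X @ coef
    ll = conditional_loglik(resid, noise, tau, include_first_marginal)
    if X.shape[1] == 2:
        mean = SegmentedMeanParams(float(coef[0]), float(coef[1]), 0.0, 0.0)
        full_cov = np.zeros((4, 4))
        full_cov[:2, :2] = cov
    else:
        mean = SegmentedMeanParams.from_array(coef)
        full_cov = cov
    return UnitFit(
        unit_id=series.unit_id,
        tau=tau,
        mean=mean,
        mean_cov=full_cov,
        noise=noise,
        loglik=ll,
        residuals=resid,
        fitted=X @ coef,
        converged=converged,
        n_iter=it,
    )


def changepoint_profile(
    dataset: ITSDataset,
    candidates: CandidateSet,
    structure: Structure = "ar1",
    include_first_marginal: bool = False,
) -> LikelihoodProfile:
    """Summed per-unit conditional log-likelihood over the candidate set.

    Units are independent, so each candidate's profile value is the sum of
    unit log-likelihoods from :func:`irls_unit_fit`.  Candidates whose fit
    fails (e.g. rank deficiency near the grid edge) are excluded with a
    warning; at least one candidate must survive.
    """
    candidates.validate(dataset.n)
    logliks = np.full(len(candidates), np.nan)
    valid = np.zeros(len(candidates), dtype=bool)
    for k, q in enumerate(candidates):
        try:
            logliks[k] = sum(
                irls_unit_fit(u, q, structure, include_first_marginal=include_first_marginal).loglik
                for u in dataset.units
            )
            valid[k] = True
        except (SingularDesignError, DegenerateDataError) as exc:
            warnings.warn(f"candidate tau={q} dropped: {exc}", RuntimeWarning)
    if not valid.any():
        raise DegenerateDataError("no change-point candidate could be fit")
    return LikelihoodProfile(candidates=candidates, logliks=logliks, valid=valid)


def _phi_se(phi: float, m: int) -> float:
    # delta-method/asymptotic sd of the lag-1 autocorrelation of an AR(1)
    return float(np.sqrt(max(1.0 - phi * phi, 1e-12) / m))


def _summaries(unit_fits, tau: int, structure: Structure, alpha: float) -> pd.DataFrame:
    z = stats.norm.ppf(1 - alpha / 2)
    rows = []
    for uf in unit_fits:
        a = np.array([0.0, 0.0, 1.0, float(tau)])
        lc = float(a @ uf.mean.as_array())
        lc_se = float(np.sqrt(a @ uf.mean_cov @ a))
        tc = uf.mean.Delta
        tc_se = float(np.sqrt(uf.mean_cov[3, 3]))
        n = len(uf.residuals)
        m1, m2 = tau - 1, n - tau + 1
        cc = uf.noise.phi2 - uf.noise.phi1
        if structure == "ar1":
            cc_se = float(np.hypot(_phi_se(uf.noise.phi1, m1), _phi_se(uf.noise.phi2, m2)))
        else:
            cc_se = np.nan  # descriptive for exchangeable/independent
        v1 = marginal_variance(uf.noise, 1)
        v2 = marginal_variance(uf.noise, 2)
        vc = v2 - v1
        # Gaussian-theory approximation Var(s^2) ~ 2 sigma^4 / m, treating the
        # phases as independent; ignores autocorrelation (descriptive CI)
        vc_se = float(np.sqrt(2 * v1 * v1 / m1 + 2 * v2 * v2 / m2))
        for name, est, se in (
            ("level_change", lc, lc_se),
            ("trend_change", tc, tc_se),
            ("corr_change", cc, cc_se),
            ("variance_change", vc, vc_se),
        ):
            if np.isfinite(se) and se > 0:
                p = 2 * stats.norm.sf(abs(est) / se)
                lo, hi = est - z * se, est + z * se
            else:
                p, lo, hi = np.nan, np.nan, np.nan
            rows.append(
                {
                    "unit": uf.unit_id,
                    "quantity": name,
                    "estimate": est,
                    "se": se,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def _estimates_table(unit_fits, alpha: float) -> pd.DataFrame:
    """Pre/post intercepts and slopes with Wald CIs, per unit."""
    z = stats.norm.ppf(1 - alpha / 2)
    combos = {
        "intercept_pre": np.array([1.0, 0, 0, 0]),
        "slope_pre": np.array([0, 1.0, 0, 0]),
        "intercept_post": np.array([1.0, 0, 1.0, 0]),
        "slope_post": np.array([0, 1.0, 0, 1.0]),
    }
    rows = []
    for uf in unit_fits:
        beta = uf.mean.as_array()
        for name, a in combos.items():
            est = float(a @ beta)
            se = float(np.sqrt(a @ uf.mean_cov @ a))
            p = 2 * stats.norm.sf(abs(est) / se) if se > 0 else np.nan
            rows.append(
                {
                    "unit": uf.unit_id,
                    "parameter": name,
                    "estimate": est,
                    "se": se,
                    "ci_low": est - z * se,
                    "ci_high": est + z * se,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def fit_its_model(
    dataset: ITSDataset,
    candidates: CandidateSet,
    structure: Structure = "ar1",
    alpha: float = 0.05,
    include_first_marginal: bool = False,
) -> ModelFit:
    """Full fit: profile the candidate set, refit at the estimated
    change-point, and assemble per-unit effect summaries.

    With a single unit this is exactly the single-series model; with several
    units the change-point is global while all other parameters remain
    unit-specific.
    """
    profile = changepoint_profile(dataset, candidates, structure, include_first_marginal)
    tau_hat = profile.argmax_index
    unit_fits = tuple(
        irls_unit_fit(u, tau_hat, structure, include_first_marginal=include_first_marginal)
        for u in dataset.units
    )
    summaries = _summaries(unit_fits, tau_hat, structure, alpha)
    estimates = _estimates_table(unit_fits, alpha)
    tau_date = dataset.times[tau_hat - 1]
    return ModelFit(
        tau_hat=tau_hat,
        tau_date=tau_date,
        unit_fits=unit_fits,
        profile=profile,
        structure=structure,
        summaries=summaries,
        estimates=estimates,
        alpha=alpha,
    )
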