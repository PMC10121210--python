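"""Within-subject treatment-effect estimation on daily step totals.

The daily series is modeled as a linear regression of total steps on
treatment indicators (usual care as reference) with stationary AR(1)
errors: equal variances sigma^2 and correlation rho^k between days k
apart. Since (rho, sigma^2) are unknown they are estimated from residuals
and the generalized-least-squares fit is iterated to convergence
(Cochrane-Orcutt-style feasible GLS):

    beta_hat = (X' V^-1 X)^-1 X' V^-1 Y

computed by whitening with a Cholesky factor of V rather than an explicit
inverse. Each contrast is classified from its 95% CI: POSITIVE when the
whole interval is above 0, NEGATIVE when below, NO_EFFECT otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .design import ACTIVE_TREATMENTS, BASELINE, MASSAGE, USUAL_CARE, YOGA

YOGA_VS_UC = "YOGA_VS_UC"
MASSAGE_VS_UC = "MASSAGE_VS_UC"
MASSAGE_VS_YOGA = "MASSAGE_VS_YOGA"
CONTRASTS = (YOGA_VS_UC, MASSAGE_VS_UC, MASSAGE_VS_YOGA)

POSITIVE = "POSITIVE"
NEGATIVE = "NEGATIVE"
NO_EFFECT = "NO_EFFECT"

_RHO_CLAMP = 0.999


class RankDeficiencyError(ValueError):
    """The design matrix cannot identify the requested contrasts."""


@dataclass
class RegressionProblem:
    """Response, design matrix and column bookkeeping for one participant."""

    y: np.ndarray
    X: np.ndarray
    columns: List[str]
    day_index: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.y.ndim != 1 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("incompatible response/design shapes")
        if self.n <= self.p:
            raise ValueError("need more observations than parameters")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class Ar1Model:
    """Stationary AR(1) error model: variance sigma2, lag-k correlation rho^k."""

    rho: float
    sigma2: float

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError(f"|rho| must be < 1, got {self.rho}")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


@dataclass
class EffectEstimate:
    contrast: str
    beta_hat: float
    se: float
    ci_low: float
    ci_high: float
    label: str


@dataclass
class FeasibleGlsResult:
    beta: np.ndarray
    cov: np.ndarray
    ar1: Ar1Model
    converged: bool
    n_iter: int
    problem: RegressionProblem


def build_design(
    daily_series: pd.DataFrame,
    include_baseline: bool = False,
    carryover_lag_days: int = 0,
) -> RegressionProblem:
    """Build the regression problem from a block-labeled daily series.

    Rows are analysis days (baseline excluded unless ``include_baseline``);
    columns are an intercept plus yoga and massage indicators, usual care
    (and any baseline days) forming the reference. With
    ``carryover_lag_days = d > 0`` an extra column flags the first ``d``
    days of every block that follows an active treatment.
    """
    df = daily_series.sort_values("day_index")
    if not include_baseline:
        df = df[df["block"] != BASELINE]
    block = df["block"].to_numpy()
    for treatment, contrast in ((YOGA, YOGA_VS_UC), (MASSAGE, MASSAGE_VS_UC)):
        if not np.any(block == treatment):
            raise RankDeficiencyError(
                f"no {treatment} days: contrast {contrast} is not identifiable"
            )
    if not np.any(block == USUAL_CARE):
        raise RankDeficiencyError("no usual-care days: reference level is empty")

    cols = [np.ones(len(df)), (block == YOGA).astype(float), (block == MASSAGE).astype(float)]
    names = ["intercept", "yoga", "massage"]
    if carryover_lag_days > 0:
        carry = _carryover_indicator(daily_series, carryover_lag_days)
        carry = carry.loc[df.index].to_numpy(dtype=float)
        cols.append(carry)
        names.append("carryover")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError("design matrix is rank deficient")
    return RegressionProblem(
        y=df["total_steps"].to_numpy(dtype=float),
        X=X,
        columns=names,
        day_index=df["day_index"].to_numpy(),
    )


def _carryover_indicator(daily_series: pd.DataFrame, lag_days: int) -> pd.Series:
    """1 for the first ``lag_days`` days of a block whose predecessor was active."""
    df = daily_series.sort_values("day_index")
    block = df["block"].to_numpy()
    change = np.r_[True, block[1:] != block[:-1]]
    block_id = np.cumsum(change) - 1
    starts = np.flatnonzero(change)
    prev_label = {0: None}
    for b in range(1, block_id.max() + 1):
        prev_label[b] = block[starts[b] - 1]
    day_in_block = np.arange(len(df)) - starts[block_id]
    flag = np.array(
        [
            prev_label[b] in ACTIVE_TREATMENTS and d < lag_days
            for b, d in zip(block_id, day_in_block)
        ],
        dtype=float,
    )
    return pd.Series(flag, index=df.index)


def ols_fit(problem: RegressionProblem) -> Tuple[np.ndarray, np.ndarray]:
    """Ordinary least squares; returns (beta_hat, residuals)."""
    beta, _, rank, _ = np.linalg.lstsq(problem.X, problem.y, rcond=None)
    if rank < problem.p:
        raise RankDeficiencyError("design matrix is rank deficient")
    resid = problem.y - problem.X @ beta
    return beta, resid


def estimate_ar1(residuals: np.ndarray, n_params: int = 0) -> Ar1Model:
    """Estimate AR(1) parameters from regression residuals.

    rho is the lag-1 sample autocorrelation, clamped away from +-1; sigma2
    is the residual sum of squares over ``n - n_params``.
    """
    e = np.asarray(residuals, dtype=float)
    n = e.shape[0]
    if n < 3:
        raise ValueError("need at least 3 residuals")
    denom = float(e @ e)
    if denom == 0.0:
        warnings.warn("zero-variance residuals; rho set to 0", RuntimeWarning)
        return Ar1Model(rho=0.0, sigma2=np.finfo(float).tiny)
    rho = float(e[1:] @ e[:-1]) / denom
    rho = float(np.clip(rho, -_RHO_CLAMP, _RHO_CLAMP))
    dof = max(n - n_params, 1)
    sigma2 = denom / dof
    return Ar1Model(rho=rho, sigma2=sigma2)


def ar1_covariance(model: Ar1Model, n: int) -> np.ndarray:
    """The n x n AR(1) covariance matrix V[a, b] = sigma2 * rho^|a-b|."""
    if n < 1:
        raise ValueError("n must be >= 1")
    k = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    return model.sigma2 * model.rho**k


def ar1_correlation(rho: float, n: int) -> np.ndarray:
    """Correlation-only AR(1) matrix (unit diagonal)."""
    return ar1_covariance(Ar1Model(rho=rho, sigma2=1.0), n)


def gls_fit(
    problem: RegressionProblem, V: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Generalized least squares via Cholesky whitening.

    With L the lower Cholesky factor of V, the model is whitened by L^-1
    and solved by ordinary least squares, which equals
    (X' V^-1 X)^-1 X' V^-1 Y without forming any explicit inverse of V.
    Returns ``(beta_hat, cov_beta)`` with
    ``cov_beta = s2 * (X' V^-1 X)^-1`` where s2 is the whitened residual
    mean square on n - p degrees of freedom.
    """
    V = np.asarray(V, dtype=float)
    if V.shape != (problem.n, problem.n):
        raise ValueError("V has the wrong shape")
    try:
        L = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError("V is not positive definite") from exc
    Xw = linalg.solve_triangular(L, problem.X, lower=True)
    yw = linalg.solve_triangular(L, problem.y, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < problem.p:
        raise RankDeficiencyError("whitened design matrix is rank deficient")
    resid_w = yw - Xw @ beta
    s2 = float(resid_w @ resid_w) / (problem.n - problem.p)
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    return beta, s2 * xtx_inv


def feasible_gls(
    problem: RegressionProblem,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> FeasibleGlsResult:
    """Iterated feasible GLS under AR(1) errors.

    Starts from OLS, alternates residual-based AR(1) estimation with a GLS
    refit on the correlation-only matrix, and stops when successive rho
    estimates differ by less than ``tol``. Non-convergence returns the last
    iterate with ``converged=False`` and a warning.
    """
    beta, resid = ols_fit(problem)
    ar1 = estimate_ar1(resid, n_params=problem.p)
    cov = None
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        V0 = ar1_correlation(ar1.rho, problem.n)
        beta, cov = gls_fit(problem, V0)
        resid = problem.y - problem.X @ beta
        new = estimate_ar1(resid, n_params=problem.p)
        delta = abs(new.rho - ar1.rho)
        ar1 = new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"feasible GLS did not converge in {max_iter} iterations", RuntimeWarning
        )
    return FeasibleGlsResult(
        beta=beta, cov=cov, ar1=ar1, converged=converged, n_iter=n_iter, problem=problem
    )


def classify_effect(ci_low: float, ci_high: float) -> str:
    """Label an effect by where its 95% CI sits relative to 0."""
    if ci_low > 0:
        return POSITIVE
    if ci_high < 0:
        return NEGATIVE
    return NO_EFFECT


def contrasts(result: FeasibleGlsResult) -> List[EffectEstimate]:
    """The three treatment contrasts with t-based 95% CIs.

    Yoga and massage versus usual care are the corresponding coefficients;
    massage versus yoga is their difference, with variance from the full
    coefficient covariance. Degrees of freedom are n - p.
    """
    cols = result.problem.columns
    if "yoga" not in cols or "massage" not in cols:
        raise ValueError("design must contain yoga and massage columns")
    iy, im = cols.index("yoga"), cols.index("massage")
    df = result.problem.n - result.problem.p
    tcrit = float(stats.t.ppf(0.975, df))
    out = []
    specs = [
        (YOGA_VS_UC, _unit_vector(len(cols), {iy: 1.0})),
        (MASSAGE_VS_UC, _unit_vector(len(cols), {im: 1.0})),
        (MASSAGE_VS_YOGA, _unit_vector(len(cols), {im: 1.0, iy: -1.0})),
    ]
    for name, c in specs:
        est = float(c @ result.beta)
        var = float(c @ result.cov @ c)
        se = float(np.sqrt(var))
        lo, hi = est - tcrit * se, est + tcrit * se
        out.append(
            EffectEstimate(
                contrast=name,
                beta_hat=est,
                se=se,
                ci_low=lo,
                ci_high=hi,
                label=classify_effect(lo, hi),
            )
        )
    return out


def _unit_vector(p: int, entries: dict) -> np.ndarray:
    c = np.zeros(p)
    for i, v in entries.items():
        c[i] = v
    return c


def analyze_participant(
    daily_series: pd.DataFrame,
    include_baseline: bool = False,
    carryover_lag_days: int = 0,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> Tuple[List[EffectEstimate], FeasibleGlsResult]:
    """Daily series in, effect estimates out (feasible GLS + contrasts)."""
    problem = build_design(
        daily_series,
        include_baseline=include_baseline,
        carryover_lag_days=carryover_lag_days,
    )
    result = feasible_gls(problem, tol=tol, max_iter=max_iter)
    return contrasts(result), result


def effects_frame(
    estimates: List[EffectEstimate],
    result: FeasibleGlsResult,
    participant_id: str,
) -> pd.DataFrame:
    """One participant's estimates as rows of the effects CSV schema."""
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "contrast": [e.contrast for e in estimates],
            "beta_hat": [e.beta_hat for e in estimates],
            "se": [e.se for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
            "label": [e.label for e in estimates],
            "rho_hat": result.ar1.rho,
            "n_days": result.problem.n,
            "converged": result.converged,
        }
    )
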