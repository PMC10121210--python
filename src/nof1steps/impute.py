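"""Minute-level Poisson imputation of missing step counts.

For each minute-of-day ``t`` a Poisson log-linear model

    log rate_t(day) = alpha_t + beta_t * weekday + gamma_t * temperature

is fit by maximum likelihood across the days where minute ``t`` is observed
(WORN or CARRIED). MISSING minutes are filled with the fitted rate for
their day's covariates, a penalized cubic smoothing spline (penalty chosen
by generalized cross-validation) is fit over the whole day and its values
replace the imputed positions only, and days are summed into the daily
series consumed by the effect analysis.

Sparse or degenerate minutes fall back to a pooled fit over the enclosing
hour, then over the whole day; minutes whose pooled data is all-zero get a
zero rate rather than a divergent intercept.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .design import BASELINE, MINUTES_PER_DAY, TrialDesign
from .ingest import MISSING, StructuralError


class ImputationInfeasibleError(RuntimeError):
    """No complete minutes anywhere: the imputation model cannot be fit."""


class _FitError(RuntimeError):
    pass


@dataclass
class MinuteModelFit:
    """Fitted coefficients for one minute-of-day.

    ``pooled`` marks fits that fell back to hour/day pooling; ``zero_rate``
    marks minutes whose (pooled) data was all zero, for which the fitted
    rate is exactly 0 and no coefficients are meaningful.
    """

    minute: int
    alpha: float
    beta: float
    gamma: float
    n_complete: int
    pooled: bool = False
    zero_rate: bool = False

    def rate(self, weekday: float, temperature: float) -> float:
        if self.zero_rate:
            return 0.0
        return float(np.exp(self.alpha + self.beta * weekday + self.gamma * temperature))


def _poisson_irls(
    X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> np.ndarray:
    """Newton/IRLS maximum likelihood for a Poisson log-linear model."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-12))
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        grad = X.T @ (y - mu)
        hess = (X * mu[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise _FitError("singular information matrix") from exc
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        raise _FitError("IRLS did not converge")
    if not np.all(np.isfinite(beta)):
        raise _FitError("non-finite coefficients")
    return beta


def _fit_with_drops(
    y: np.ndarray, r: np.ndarray, z: np.ndarray
) -> Tuple[float, float, float]:
    """Fit (alpha, beta, gamma), dropping covariates constant in this subset."""
    cols = [np.ones_like(y, dtype=float)]
    use_r = np.ptp(r) > 0
    use_z = np.ptp(z) > 0
    if use_r:
        cols.append(r.astype(float))
    if use_z:
        cols.append(z.astype(float))
    X = np.column_stack(cols)
    coef = _poisson_irls(X, y.astype(float))
    alpha = coef[0]
    k = 1
    beta = gamma = 0.0
    if use_r:
        beta = coef[k]
        k += 1
    if use_z:
        gamma = coef[k]
    return float(alpha), float(beta), float(gamma)


def _pooled_fit(
    ymat: np.ndarray, r: np.ndarray, z: np.ndarray, minute_slice: slice
) -> Optional[Tuple[float, float, float]]:
    """Pooled Poisson fit over a block of minutes; None when degenerate."""
    block = ymat[:, minute_slice]
    mask = ~np.isnan(block)
    if mask.sum() == 0:
        return None
    y = block[mask]
    if y.sum() == 0:
        return None
    day_idx = np.nonzero(mask)[0] if block.ndim == 1 else np.where(mask)[0]
    rr, zz = r[day_idx], z[day_idx]
    try:
        return _fit_with_drops(y, rr, zz)
    except _FitError:
        return None


def fit_minute_models(
    classified: pd.DataFrame,
    covariates: pd.DataFrame,
    min_obs: int = 5,
) -> List[MinuteModelFit]:
    """Fit the per-minute Poisson model on complete (non-MISSING) data.

    Parameters
    ----------
    classified
        One participant's classified minutes with ``day_index``, ``minute``
        and ``resolved_steps`` (NaN where MISSING) columns.
    covariates
        Day-level table with ``weekday`` and ``temperature_f`` keyed by
        ``day_index`` or ``date``.
    min_obs
        Minimum observed days for a dedicated per-minute fit; sparser
        minutes use the pooled fallback.

    Returns one :class:`MinuteModelFit` per minute of day (1440 entries).
    """
    ymat, days = _response_matrix(classified)
    r, z = _covariate_arrays(classified, covariates, days)
    if np.all(np.isnan(ymat)):
        raise ImputationInfeasibleError("no complete minutes in the input")

    day_fit = _pooled_fit(ymat, r, z, slice(0, MINUTES_PER_DAY))
    hour_fits: Dict[int, Optional[Tuple[float, float, float]]] = {}

    def fallback(t: int, n_complete: int) -> MinuteModelFit:
        hour = t // 60
        if hour not in hour_fits:
            hour_fits[hour] = _pooled_fit(ymat, r, z, slice(hour * 60, hour * 60 + 60))
        coef = hour_fits[hour] or day_fit
        if coef is None:
            return MinuteModelFit(t, 0.0, 0.0, 0.0, n_complete, pooled=True, zero_rate=True)
        return MinuteModelFit(t, *coef, n_complete=n_complete, pooled=True)

    fits: List[MinuteModelFit] = []
    for t in range(MINUTES_PER_DAY):
        col = ymat[:, t]
        mask = ~np.isnan(col)
        n_complete = int(mask.sum())
        if n_complete < min_obs:
            fits.append(fallback(t, n_complete))
            continue
        y = col[mask]
        if y.sum() == 0:
            fits.append(fallback(t, n_complete))
            continue
        try:
            alpha, beta, gamma = _fit_with_drops(y, r[mask], z[mask])
        except _FitError:
            fits.append(fallback(t, n_complete))
            continue
        fits.append(MinuteModelFit(t, alpha, beta, gamma, n_complete))
    return fits


def fits_to_arrays(fits: Sequence[MinuteModelFit]) -> Dict[str, np.ndarray]:
    """Column arrays (alpha, beta, gamma, zero_rate) over the minute grid."""
    fits = sorted(fits, key=lambda f: f.minute)
    return {
        "alpha": np.array([f.alpha for f in fits]),
        "beta": np.array([f.beta for f in fits]),
        "gamma": np.array([f.gamma for f in fits]),
        "zero_rate": np.array([f.zero_rate for f in fits], dtype=bool),
    }


def impute_day(
    resolved_steps: np.ndarray,
    fits: Sequence[MinuteModelFit],
    weekday: float,
    temperature: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Fill one day's MISSING minutes with fitted rates.

    ``resolved_steps`` is the day's length-1440 vector with NaN at MISSING
    positions. Returns ``(values, imputed_mask)``; observed positions pass
    through unchanged.
    """
    resolved_steps = np.asarray(resolved_steps, dtype=float)
    if resolved_steps.shape != (MINUTES_PER_DAY,):
        raise StructuralError(f"expected a {MINUTES_PER_DAY}-minute day")
    if not np.isfinite(weekday) or not np.isfinite(temperature):
        raise ValueError("missing covariate for the day")
    arrays = fits_to_arrays(fits)
    with np.errstate(over="ignore"):
        rates = np.exp(
            arrays["alpha"] + arrays["beta"] * weekday + arrays["gamma"] * temperature
        )
    rates = np.where(arrays["zero_rate"], 0.0, rates)
    mask = np.isnan(resolved_steps)
    values = np.where(mask, rates, resolved_steps)
    return values, mask


def smooth_imputed(
    values: np.ndarray, imputed_mask: np.ndarray, lam: Optional[float] = None
) -> np.ndarray:
    """Smooth imputed positions with a penalized cubic spline over the day.

    The spline is fit to the entire day's vector (observed + imputed) with
    penalty ``lam`` (GCV-selected when None); its values replace only the
    imputed positions, clamped at 0.
    """
    values = np.asarray(values, dtype=float)
    imputed_mask = np.asarray(imputed_mask, dtype=bool)
    if values.shape != (MINUTES_PER_DAY,) or imputed_mask.shape != (MINUTES_PER_DAY,):
        raise StructuralError(f"expected length-{MINUTES_PER_DAY} vectors")
    if not imputed_mask.any():
        return values.copy()
    x = np.arange(MINUTES_PER_DAY, dtype=float)
    spline = make_smoothing_spline(x, values, lam=lam)
    smoothed = np.asarray(spline(x), dtype=float)
    out = values.copy()
    out[imputed_mask] = np.maximum(smoothed[imputed_mask], 0.0)
    return out


def select_smoothing_penalty(
    values: np.ndarray, grid: Optional[np.ndarray] = None
) -> float:
    """Pick a spline penalty for one day's vector by held-out cross-validation.

    Fits candidate penalties on the even minutes and scores squared error on
    the odd minutes. Much cheaper than a full GCV search and close enough
    for a penalty that is reused across a participant's days.
    """
    values = np.asarray(values, dtype=float)
    if grid is None:
        grid = np.logspace(-1, 7, 9)
    x = np.arange(MINUTES_PER_DAY, dtype=float)
    xe, ye = x[::2], values[::2]
    xo, yo = x[1::2], values[1::2]
    best_lam, best_sse = float(grid[0]), np.inf
    for lam in grid:
        spline = make_smoothing_spline(xe, ye, lam=float(lam))
        sse = float(np.sum((spline(xo) - yo) ** 2))
        if sse < best_sse:
            best_lam, best_sse = float(lam), sse
    return best_lam


def daily_totals(
    minute_values: np.ndarray,
    imputed_masks: np.ndarray,
    design: TrialDesign,
    sequence_index: int,
    weekday: np.ndarray,
    temperature: np.ndarray,
    participant_id: str = "P001",
) -> pd.DataFrame:
    """Aggregate imputed days into the daily analysis series.

    ``minute_values`` and ``imputed_masks`` are (n_days, 1440) arrays over
    the full trial grid; the day count must match the design exactly.
    """
    minute_values = np.asarray(minute_values, dtype=float)
    n_days = minute_values.shape[0]
    if n_days != design.n_days:
        raise StructuralError(
            f"expected {design.n_days} days for this design, got {n_days}"
        )
    labels = design.day_labels(sequence_index)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "day_index": np.arange(n_days),
            "block": labels,
            "total_steps": minute_values.sum(axis=1),
            "fraction_imputed": np.asarray(imputed_masks, dtype=float).mean(axis=1),
            "weekday": np.asarray(weekday, dtype=int),
            "temperature_f": np.asarray(temperature, dtype=float),
        }
    )


def impute_participant(
    classified: pd.DataFrame,
    covariates: pd.DataFrame,
    design: TrialDesign,
    sequence_index: int,
    min_obs: int = 5,
    smooth: bool = True,
    lam: Optional[float] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full imputation pipeline for one participant.

    Returns ``(imputed_minutes, daily_series)``. ``imputed_minutes`` is the
    long minute frame with ``value`` and ``imputed`` columns; days entirely
    absent from the input are treated as 1440 MISSING minutes.
    """
    pid = str(classified["participant_id"].iloc[0]) if len(classified) else "P001"
    ymat, days = _response_matrix(classified, n_days=design.n_days)
    r, z = _covariate_arrays(classified, covariates, days)
    if np.any(~np.isfinite(r)) or np.any(~np.isfinite(z)):
        bad = int(days[~(np.isfinite(r) & np.isfinite(z))][0])
        raise ValueError(f"missing covariate for day {bad}")
    fits = fit_minute_models(classified, covariates, min_obs=min_obs)
    arrays = fits_to_arrays(fits)

    masks = np.isnan(ymat)
    with np.errstate(over="ignore"):
        rates = np.exp(
            arrays["alpha"][None, :]
            + arrays["beta"][None, :] * r[:, None]
            + arrays["gamma"][None, :] * z[:, None]
        )
    rates = np.where(arrays["zero_rate"][None, :], 0.0, rates)
    values = np.where(masks, rates, ymat)
    if smooth:
        n_imputed = masks.sum(axis=1)
        if lam is None and n_imputed.any():
            # one penalty per participant, chosen on the most-imputed day;
            # a per-day GCV search costs ~100x more for the same totals
            lam = select_smoothing_penalty(values[int(np.argmax(n_imputed))])
        for i in range(values.shape[0]):
            if masks[i].any():
                values[i] = smooth_imputed(values[i], masks[i], lam=lam)

    daily = daily_totals(
        values, masks, design, sequence_index, r, z, participant_id=pid
    )
    n_days = design.n_days
    minutes_out = pd.DataFrame(
        {
            "participant_id": pid,
            "day_index": np.repeat(days, MINUTES_PER_DAY),
            "minute": np.tile(np.arange(MINUTES_PER_DAY), n_days),
            "value": values.ravel(),
            "imputed": masks.ravel(),
        }
    )
    return minutes_out, daily


def zero_filled_daily_totals(
    classified: pd.DataFrame,
    covariates: pd.DataFrame,
    design: TrialDesign,
    sequence_index: int,
) -> pd.DataFrame:
    """Daily totals with MISSING minutes counted as zero (no imputation)."""
    pid = str(classified["participant_id"].iloc[0]) if len(classified) else "P001"
    ymat, days = _response_matrix(classified, n_days=design.n_days)
    r, z = _covariate_arrays(classified, covariates, days)
    values = np.nan_to_num(ymat, nan=0.0)
    masks = np.isnan(ymat)
    return daily_totals(
        values, masks, design, sequence_index, r, z, participant_id=pid
    )


def _response_matrix(
    classified: pd.DataFrame, n_days: Optional[int] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """(n_days, 1440) resolved-steps matrix (NaN = MISSING) and day indices."""
    if len(classified) == 0:
        raise ImputationInfeasibleError("empty input")
    if n_days is None:
        days = np.sort(classified["day_index"].unique())
    else:
        days = np.arange(n_days)
    ymat = np.full((len(days), MINUTES_PER_DAY), np.nan)
    di = classified["day_index"].to_numpy()
    keep = np.isin(di, days)
    rows = np.searchsorted(days, di[keep])
    cols = classified["minute"].to_numpy()[keep]
    ymat[rows, cols] = classified["resolved_steps"].to_numpy()[keep]
    return ymat, days


def _covariate_arrays(
    classified: pd.DataFrame, covariates: pd.DataFrame, days: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Weekday and temperature arrays aligned to ``days``.

    Covariates may be keyed by ``day_index`` or by ``date``; in the latter
    case day indices map to dates through the participant's first recorded
    date. A missing ``weekday`` column is derived from the date.
    """
    cov = covariates.copy()
    if "day_index" not in cov.columns:
        if "date" not in cov.columns:
            raise ValueError("covariates need a day_index or date column")
        dates = pd.to_datetime(cov["date"])
        first = pd.to_datetime(classified["date"]).min() - pd.to_timedelta(
            int(classified["day_index"].min()), unit="D"
        )
        cov["day_index"] = (dates - first).dt.days
        if "weekday" not in cov.columns:
            cov["weekday"] = (dates.dt.weekday < 5).astype(int)
    elif "weekday" not in cov.columns:
        if "date" in cov.columns:
            cov["weekday"] = (pd.to_datetime(cov["date"]).dt.weekday < 5).astype(int)
        else:
            raise ValueError("covariates need a weekday column or dates to derive it")
    cov = cov.set_index("day_index")
    r = np.full(len(days), np.nan)
    z = np.full(len(days), np.nan)
    for i, d in enumerate(days):
        if int(d) in cov.index:
            r[i] = cov.loc[int(d), "weekday"]
            z[i] = cov.loc[int(d), "temperature_f"]
    return r, z
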