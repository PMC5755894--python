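"""Carrying-capacity calibration from weekly trap indices.

One free parameter, the carrying capacity ``K``, is fitted per area by
minimising the mean squared error between the model's weekly IMFA (at the
forcing-driven steady state) and the observed weekly IMFA, the latter first
smoothed with a degree-2 local polynomial regression (span 0.08 of the
series, tricube weights).

A structural fact makes the fit cheap and exact: every term of the model is
homogeneous of degree 1 in the state jointly with ``K`` (scaling
``(E, L, P, A, Trapped, K)`` by a common factor maps solutions to
solutions), so the steady-state weekly IMFA is exactly proportional to
``K``.  The MSE is therefore a quadratic in ``K`` whose bounded minimiser is
available in closed form from a single simulation at a reference ``K``.
That is the default method; ``method="brent"`` performs the equivalent
bounded scalar minimisation with a fresh simulation per candidate ``K`` and
is used as a cross-check.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .imfa import ImfaSeries
from .model import LifeHistoryParams, TrapConfig, simulate, weekly_imfa
from .temperature import TemperatureSeries

__all__ = [
    "FitResult",
    "smooth_imfa",
    "mse",
    "fit_K",
    "fit_all_areas",
    "summarize_fits",
]

logger = logging.getLogger(__name__)

DEFAULT_K_BOUNDS = (10.0, 1e5)


@dataclass(frozen=True)
class FitResult:
    """Estimated carrying capacity and goodness of fit for one area."""

    K_hat: float
    mse: float
    n_traps: int
    converged: bool
    K_bounds: tuple[float, float]
    area_id: str | None = None

    def __post_init__(self) -> None:
        lo, hi = self.K_bounds
        if not lo <= self.K_hat <= hi:
            raise ValueError("K_hat must lie within K_bounds")
        if self.mse < 0:
            raise ValueError("mse must be non-negative")

    @property
    def rmse(self) -> float:
        return math.sqrt(self.mse)


def smooth_imfa(series: ImfaSeries, degree: int = 2, span: float = 0.08) -> ImfaSeries:
    """Local polynomial regression smoother (loess-style) of a weekly index.

    For each observation week the ``span * n`` nearest weeks (by time) are
    fitted with a tricube-weighted polynomial of the given degree and the fit
    is evaluated at that week.  Windows too small to determine the polynomial
    are widened to ``degree + 2`` points with a logged warning.  Negative
    fitted values are clipped to zero (the index is a non-negative ratio).
    Missing weeks are ignored as predictors and left missing in the output.
    """
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if len(series) < 10:
        raise ValueError("need at least 10 observations to smooth")
    x_all = (series.weeks.asi8 / 86_400_000_000_000.0)
    x_all = x_all - x_all[0]
    y_all = series.values
    valid = np.isfinite(y_all)
    x, y = x_all[valid], y_all[valid]
    n = len(x)
    window = int(math.ceil(span * n))
    min_window = degree + 2
    if window < min_window:
        logger.warning(
            "span %.3f gives a %d-point window, below the %d needed for a "
            "degree-%d fit; widening", span, window, min_window, degree,
        )
        window = min_window
    window = min(window, n)

    fitted = np.full(n, np.nan)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:window]
        dmax = d[idx].max()
        if dmax == 0:
            fitted[i] = y[idx].mean()
            continue
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 1e-12, None)  # keep the window-edge point from degenerating
        # weighted polynomial fit centred at x[i] for conditioning
        xc = x[idx] - x[i]
        design = np.vander(xc, degree + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(design * sw[:, None], y[idx] * sw, rcond=None)
        fitted[i] = beta[0]

    out = np.full(len(y_all), np.nan)
    out[valid] = np.clip(fitted, 0.0, None)
    return series.with_values(out, smoothed=True)


def mse(model: ImfaSeries, observed: ImfaSeries) -> float:
    """Mean squared error over the weeks common to both series.

    Weeks missing (NaN) in either series are excluded pairwise.
    """
    m = model.to_series()
    o = observed.to_series()
    joined = pd.concat([m, o], axis=1, join="inner", keys=["model", "obs"]).dropna()
    if joined.empty:
        raise ValueError("model and observed series share no weeks")
    diff = joined["model"].to_numpy() - joined["obs"].to_numpy()
    return float(np.mean(diff**2))


def _model_imfa(
    params: LifeHistoryParams,
    trap: TrapConfig,
    K: float,
    forcing: TemperatureSeries,
    **sim_kwargs,
) -> ImfaSeries:
    traj = simulate(params, trap, K, forcing, **sim_kwargs)
    return weekly_imfa(traj, trap)


def fit_K(
    observed: ImfaSeries,
    forcing: TemperatureSeries,
    params: LifeHistoryParams,
    trap: TrapConfig,
    bounds: tuple[float, float] = DEFAULT_K_BOUNDS,
    smooth: bool = True,
    span: float = 0.08,
    method: str = "scaling",
    **sim_kwargs,
) -> FitResult:
    """Fit the carrying capacity of one area.

    Parameters
    ----------
    observed
        Weekly observed IMFA (raw; smoothing is applied here unless
        ``smooth=False``).
    forcing
        Daily mean-temperature series covering the observation window.
    bounds
        Search interval for ``K`` (eggs).
    method
        ``"scaling"`` (default): single simulation at a reference ``K`` plus
        the closed-form bounded minimiser of the quadratic MSE, exploiting
        the exact proportionality of model IMFA to ``K``.  ``"brent"``:
        bounded scalar minimisation re-simulating at every candidate ``K``.

    Both methods are deterministic for fixed inputs.  A fit whose optimum
    sits on a bound is flagged ``converged=False``.
    """
    lo, hi = float(bounds[0]), float(bounds[1])
    if not 0 < lo < hi:
        raise ValueError("bounds must satisfy 0 < lower < upper")
    target = smooth_imfa(observed, span=span) if smooth else observed
    t = target.to_series().dropna()
    if len(t) == 0:
        raise ValueError("observed series has no usable weeks")

    if method == "scaling":
        k_ref = math.sqrt(lo * hi)
        ref = _model_imfa(params, trap, k_ref, forcing, **sim_kwargs).to_series()
        joined = pd.concat([ref, t], axis=1, join="inner", keys=["ref", "obs"]).dropna()
        if joined.empty:
            raise ValueError("model weeks do not overlap the observed weeks")
        r = joined["ref"].to_numpy() / k_ref   # weekly IMFA per unit K
        s = joined["obs"].to_numpy()
        denom = float(r @ r)
        if denom == 0:
            raise RuntimeError("model IMFA is identically zero; cannot identify K")
        k_hat = float(r @ s) / denom
        k_hat_clipped = min(max(k_hat, lo), hi)
        attained = float(np.mean((k_hat_clipped * r - s) ** 2))
        converged = lo < k_hat < hi
        if not converged:
            warnings.warn(
                f"K optimum {k_hat:.1f} lies at or outside the search bounds "
                f"[{lo:g}, {hi:g}]", stacklevel=2,
            )
        return FitResult(
            K_hat=k_hat_clipped, mse=attained, n_traps=trap.n_traps,
            converged=converged, K_bounds=(lo, hi), area_id=observed.area_id,
        )

    if method == "brent":
        def objective(k: float) -> float:
            return mse(_model_imfa(params, trap, k, forcing, **sim_kwargs), target)

        res = minimize_scalar(
            objective, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-4 * hi},
        )
        k_hat = float(res.x)
        edge = 1e-3 * (hi - lo)
        converged = bool(res.success) and (lo + edge < k_hat < hi - edge)
        if not converged:
            warnings.warn("K optimum is at a search bound; widen the interval",
                          stacklevel=2)
        return FitResult(
            K_hat=k_hat, mse=float(res.fun), n_traps=trap.n_traps,
            converged=converged, K_bounds=(lo, hi), area_id=observed.area_id,
        )

    raise ValueError(f"unknown method {method!r}")


def fit_all_areas(dataset, **fit_kwargs) -> pd.DataFrame:
    """Fit every area of a study dataset independently.

    ``dataset`` is anything yielding ``(area_id, observed ImfaSeries,
    forcing TemperatureSeries, TrapConfig)`` tuples from ``.items()`` or
    direct iteration (the io module's ``StudyDataset`` qualifies).  Per-area
    failures are recorded (``error`` column) without aborting the batch.

    Returns a DataFrame with one row per area: ``area_id, K_hat, mse, rmse,
    n_traps, converged, error``.
    """
    items = dataset.items() if hasattr(dataset, "items") else dataset
    params = fit_kwargs.pop("params", None)
    if params is None:
        params = LifeHistoryParams()
    rows = []
    n = 0
    for area_id, observed, forcing, trap in items:
        n += 1
        try:
            fit = fit_K(observed, forcing, params, trap, **fit_kwargs)
            rows.append(
                {
                    "area_id": area_id,
                    "K_hat": fit.K_hat,
                    "mse": fit.mse,
                    "rmse": fit.rmse,
                    "n_traps": fit.n_traps,
                    "converged": fit.converged,
                    "error": "",
                }
            )
        except Exception as exc:  # noqa: BLE001 - batch must survive bad areas
            logger.warning("fit failed for area %s: %s", area_id, exc)
            rows.append(
                {
                    "area_id": area_id,
                    "K_hat": np.nan,
                    "mse": np.nan,
                    "rmse": np.nan,
                    "n_traps": trap.n_traps,
                    "converged": False,
                    "error": str(exc),
                }
            )
    if n == 0:
        raise ValueError("dataset contains no areas")
    return pd.DataFrame(rows)


def summarize_fits(fits: pd.DataFrame) -> dict:
    """Summary statistics of a batch fit (K spread and MSE distribution)."""
    ok = fits.dropna(subset=["K_hat"])
    if ok.empty:
        raise ValueError("no successful fits to summarise")
    q1, q3 = np.percentile(ok["mse"], [25, 75])
    return {
        "n_areas": int(len(fits)),
        "n_fitted": int(len(ok)),
        "K_min": float(ok["K_hat"].min()),
        "K_max": float(ok["K_hat"].max()),
        "K_mean": float(ok["K_hat"].mean()),
        "K_sd": float(ok["K_hat"].std(ddof=1)) if len(ok) > 1 else 0.0,
        "mse_median": float(ok["mse"].median()),
        "mse_iqr": (float(q1), float(q3)),
    }
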