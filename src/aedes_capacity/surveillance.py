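"""Surveillance metrics: trap index, fit classification, ROC threshold and
descriptor associations.

The sampling-effort question — how many traps does an area need before its
weekly index is informative enough to calibrate the model — is answered by
classifying per-area fits as good/poor relative to the mean MSE and sweeping
a ROC over trap counts to find the count that best discriminates the two
groups (Youden's J).  The descriptor screen regresses the fitted carrying
capacity and the average index on census infrastructure descriptors, one at
a time with unadjusted p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from .imfa import ImfaSeries

__all__ = [
    "DESCRIPTOR_COLUMNS",
    "AreaDescriptors",
    "RocResult",
    "observed_imfa",
    "aimfa",
    "classify_fits",
    "roc_threshold",
    "descriptor_regressions",
]

logger = logging.getLogger(__name__)

#: Census descriptor columns screened against K and aIMFA.  ``population`` is
#: log-transformed before regression.
DESCRIPTOR_COLUMNS = (
    "population",
    "households",
    "area_km2",
    "pop_density",
    "pct_illegal_energy",
    "pct_garbage_streets",
    "pct_unpaved",
    "pct_open_sewage",
    "pct_no_manhole",
)

_PCT_COLUMNS = tuple(c for c in DESCRIPTOR_COLUMNS if c.startswith("pct_"))


@dataclass(frozen=True)
class AreaDescriptors:
    """Census descriptors of one area (counts, area, infrastructure shares)."""

    population: float
    households: float
    area_km2: float
    pop_density: float
    pct_illegal_energy: float
    pct_garbage_streets: float
    pct_unpaved: float
    pct_open_sewage: float
    pct_no_manhole: float
    area_id: str | None = None

    def __post_init__(self) -> None:
        for name in _PCT_COLUMNS:
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        for name in ("population", "households", "area_km2", "pop_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class RocResult:
    """ROC sweep over candidate trap-count thresholds."""

    threshold: float
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    youden_j: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivities,
                "specificity": self.specificities,
                "youden_j": self.youden_j,
            }
        )


def observed_imfa(captured: float, inspected_traps: int) -> float:
    """Weekly index: females captured per inspected trap."""
    if inspected_traps < 1:
        raise ZeroDivisionError("IMFA is undefined with no inspected traps")
    if captured < 0:
        raise ValueError("captured count must be non-negative")
    return captured / inspected_traps


def aimfa(series: ImfaSeries) -> float:
    """Average IMFA of one area over the study period (missing weeks excluded)."""
    values = series.values[np.isfinite(series.values)]
    if values.size == 0:
        raise ValueError("series has no observed weeks")
    return float(values.mean())


def classify_fits(fits: pd.DataFrame) -> pd.Series:
    """Label each area's fit quality relative to the batch.

    ``"poor"`` iff the area's MSE is strictly above the mean MSE across
    areas, ``"good"`` otherwise (ties and the all-equal case are good).
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 areas to classify")
    mean_mse = fits["mse"].mean()
    labels = np.where(fits["mse"] > mean_mse, "poor", "good")
    return pd.Series(labels, index=fits.index, name="fit_quality")


def roc_threshold(trap_counts, labels) -> RocResult:
    """Trap count that best separates good from poor fits (max Youden's J).

    Orientation: an area is predicted "good" iff its trap count is at least
    the threshold (poor fits concentrate where traps are few).  Candidate
    thresholds are the distinct observed trap counts; ties on J resolve to
    the smallest threshold.
    """
    counts = np.asarray(trap_counts, dtype=float)
    lab = np.asarray(labels)
    if counts.shape != lab.shape:
        raise ValueError("trap_counts and labels must be aligned")
    good = lab == "good"
    if good.all() or (~good).all():
        raise ValueError("both label classes must be present for a ROC")
    n_pos = int(good.sum())
    n_neg = int((~good).sum())
    thresholds = np.unique(counts)
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, thr in enumerate(thresholds):
        predicted_good = counts >= thr
        sens[i] = (predicted_good & good).sum() / n_pos
        spec[i] = (~predicted_good & ~good).sum() / n_neg
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax takes the first = smallest threshold on ties
    auc = float(roc_auc_score(good.astype(int), counts))
    return RocResult(
        threshold=float(thresholds[best]),
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        youden_j=j,
        auc=auc,
    )


def _stars(p: float) -> str:
    if p < 0.05:
        return "***"
    if p < 0.1:
        return "**"
    return ""


def descriptor_regressions(
    fits: pd.DataFrame,
    aimfas: pd.Series,
    descriptors: pd.DataFrame,
    min_areas: int = 10,
) -> pd.DataFrame:
    """Univariate association screen of K and aIMFA against area descriptors.

    For each descriptor column present, two simple linear regressions are
    fitted — ``K_hat ~ descriptor`` and ``aIMFA ~ descriptor`` — with
    ``population`` log-transformed first.  p-values are unadjusted (each row
    is a separate univariate hypothesis).  Star codes follow the convention
    ``***`` for p < 0.05 and ``**`` for p < 0.1.  Constant descriptors are
    skipped with a warning.

    All three inputs are indexed/keyed by ``area_id``.
    """
    merged = fits.set_index("area_id")[["K_hat"]].join(
        aimfas.rename("aimfa"), how="inner"
    ).join(descriptors.set_index("area_id"), how="inner").dropna(subset=["K_hat"])
    if len(merged) < min_areas:
        raise ValueError(
            f"need at least {min_areas} areas with fits and descriptors, "
            f"got {len(merged)}"
        )
    rows = []
    for col in DESCRIPTOR_COLUMNS:
        if col not in merged.columns:
            continue
        x = merged[col].astype(float)
        label = col
        if col == "population":
            x = np.log(x)
            label = "log_population"
        if np.ptp(x.to_numpy()) == 0:
            logger.warning("descriptor %s is constant; skipped", col)
            continue
        for response in ("K_hat", "aimfa"):
            y = merged[response].astype(float)
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            slope = float(fit.params.iloc[1])
            p = float(fit.pvalues.iloc[1])
            rows.append(
                {
                    "descriptor": label,
                    "response": "K" if response == "K_hat" else "aIMFA",
                    "slope": slope,
                    "p_value": p,
                    "stars": _stars(p),
                    "n": int(len(merged)),
                }
            )
    return pd.DataFrame(rows)
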