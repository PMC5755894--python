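"""Synthetic study data with known ground truth.

Emulates the inputs of a multi-year sticky-trap surveillance study in a
humid-tropical city: a seasonal daily mean-temperature forcing, the model's
population trajectory at a known carrying capacity, and weekly trap counts
with Poisson sampling noise whose information content scales with the number
of traps.  Every downstream stage (smoothing, calibration, classification,
ROC, descriptor screen) can be exercised against the generator's truth.

Noise model: the weekly total capture across an area's traps is Poisson with
mean ``lambda_w = T_n * imfa_model(w)`` — counts summed over identical traps
— so the observed index ``count / T_n`` has variance ``imfa_model / T_n``,
shrinking as traps are added.  Temperature noise is AR(1) (lag-one
correlation 0.8) with the stated marginal standard deviation, superimposed
on a sinusoidal annual cycle peaking in the austral summer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .imfa import ImfaSeries
from .model import LifeHistoryParams, Trajectory, TrapConfig, simulate, weekly_imfa
from .surveillance import DESCRIPTOR_COLUMNS
from .temperature import TemperatureSeries

__all__ = [
    "SyntheticScenario",
    "TrapCountData",
    "CityDataset",
    "generate_temperature",
    "generate_trap_counts",
    "generate_city",
]

_NS_PER_DAY = 86_400_000_000_000
_AR1_PHI = 0.8
_YEAR_DAYS = 365.25


@dataclass(frozen=True)
class SyntheticScenario:
    """One area's generating conditions.

    Defaults mimic the study city: annual mean 26 °C with a 4 °C seasonal
    amplitude peaking around the turn of the year, four years of weekly
    surveillance, carrying capacity in the low thousands of eggs, trap
    attractiveness 0.2/day.
    """

    K_true: float = 2500.0
    t_mean: float = 26.0
    t_amplitude: float = 4.0
    t_phase: float = 274.0     # day-of-year; peak ~91 days later (early January)
    noise_sd: float = 1.0
    n_traps: int = 16
    n_households: int = 8000
    n_years: int = 4
    seed: int = 0
    alpha: float = 0.2
    start_date: str = "2008-01-01"

    def __post_init__(self) -> None:
        if self.t_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.n_years < 1:
            raise ValueError("n_years must be at least 1")

    @property
    def trap_config(self) -> TrapConfig:
        return TrapConfig(n_traps=self.n_traps, n_households=self.n_households)

    def life_history(self, base: LifeHistoryParams | None = None) -> LifeHistoryParams:
        base = base or LifeHistoryParams()
        return replace(base, alpha=self.alpha)


@dataclass(frozen=True)
class TrapCountData:
    """Weekly synthetic observations plus the noiseless truth behind them."""

    observed: ImfaSeries
    truth: ImfaSeries
    counts: np.ndarray
    expected_counts: np.ndarray
    trajectory: Trajectory
    forcing: TemperatureSeries
    scenario: SyntheticScenario


def generate_temperature(scenario: SyntheticScenario) -> TemperatureSeries:
    """Daily mean-temperature series: annual sinusoid plus AR(1) noise.

    The noise is stationary Gaussian with marginal standard deviation
    ``noise_sd`` and lag-one autocorrelation 0.8, mimicking weather
    persistence.  Fully reproducible from ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    n_days = int(round(_YEAR_DAYS * scenario.n_years)) + 1
    dates = pd.date_range(scenario.start_date, periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    seasonal = scenario.t_mean + scenario.t_amplitude * np.sin(
        2.0 * np.pi * (doy - scenario.t_phase) / _YEAR_DAYS
    )
    if scenario.noise_sd > 0:
        innovation_sd = scenario.noise_sd * np.sqrt(1.0 - _AR1_PHI**2)
        eps = rng.normal(0.0, innovation_sd, size=n_days)
        noise = np.empty(n_days)
        noise[0] = rng.normal(0.0, scenario.noise_sd)
        for i in range(1, n_days):
            noise[i] = _AR1_PHI * noise[i - 1] + eps[i]
    else:
        noise = np.zeros(n_days)
    return TemperatureSeries(dates=dates, values=seasonal + noise, unit="C")


def generate_trap_counts(
    scenario: SyntheticScenario,
    params: LifeHistoryParams | None = None,
    count_seed: int | None = None,
    **sim_kwargs,
) -> TrapCountData:
    """Simulate the model at ``K_true`` and draw noisy weekly trap counts.

    The weekly total capture is Poisson with mean ``T_n * imfa_model(w)``;
    the observed index is the count divided by ``T_n``.  ``count_seed``
    overrides the seed of the Poisson stream only (the temperature forcing
    and trajectory stay fixed), which lets repeated draws share one
    simulation.
    """
    params = scenario.life_history(params)
    trap = scenario.trap_config
    forcing = generate_temperature(scenario)
    traj = simulate(params, trap, scenario.K_true, forcing, **sim_kwargs)
    truth = weekly_imfa(traj, trap)
    lam = truth.values * trap.n_traps
    # independent child stream so temperature and counts decouple
    if count_seed is None:
        rng = np.random.default_rng(np.random.SeedSequence(scenario.seed).spawn(1)[0])
    else:
        rng = np.random.default_rng(count_seed)
    counts = rng.poisson(lam)
    observed = ImfaSeries(
        weeks=truth.weeks,
        values=counts / trap.n_traps,
        n_traps=trap.n_traps,
        smoothed=False,
        area_id=truth.area_id,
    )
    return TrapCountData(
        observed=observed,
        truth=truth,
        counts=counts,
        expected_counts=lam,
        trajectory=traj,
        forcing=forcing,
        scenario=scenario,
    )


@dataclass(frozen=True)
class CityDataset:
    """A multi-area synthetic study bundle in the package's file schemas."""

    imfa_table: pd.DataFrame          # area_id, week_start_date, imfa, n_traps, n_households
    temperature_table: pd.DataFrame   # date, area_id, tmean_C
    descriptors: pd.DataFrame         # area_id + descriptor columns
    ground_truth: pd.DataFrame        # area_id, K_true, n_traps, n_households, seed
    areas: dict = field(repr=False, default_factory=dict)

    def items(self):
        """Yield ``(area_id, observed ImfaSeries, forcing, TrapConfig)`` per area."""
        for area_id, data in self.areas.items():
            yield area_id, data.observed, data.forcing, data.scenario.trap_config

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit the four CSVs (IMFA, temperature, descriptors, ground truth)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "imfa": out / "imfa.csv",
            "temperature": out / "temperature.csv",
            "descriptors": out / "descriptors.csv",
            "ground_truth": out / "ground_truth.csv",
        }
        self.imfa_table.to_csv(paths["imfa"], index=False)
        self.temperature_table.to_csv(paths["temperature"], index=False)
        self.descriptors.to_csv(paths["descriptors"], index=False)
        self.ground_truth.to_csv(paths["ground_truth"], index=False)
        return paths


# baseline descriptor levels (means) and noise scales for a city where the
# stated effects are planted on top; percentage columns are clipped to [0, 100]
_DESCRIPTOR_BASE = {
    "area_km2": (0.8, 0.5),
    "pct_illegal_energy": (8.0, 6.0),
    "pct_garbage_streets": (3.0, 2.0),
    "pct_unpaved": (8.0, 5.0),
    "pct_open_sewage": (45.0, 4.0),
    "pct_no_manhole": (30.0, 18.0),
}


def generate_city(
    n_areas: int,
    K_range: tuple[float, float] = (1300.0, 4200.0),
    descriptor_effects: dict[str, float] | None = None,
    seed: int = 0,
    n_years: int = 4,
    trap_range: tuple[int, int] = (2, 149),
    n_traps: int | None = None,
    base_params: LifeHistoryParams | None = None,
    **sim_kwargs,
) -> CityDataset:
    """Generate a heterogeneous multi-area study with known truth.

    Per area, ``K_true`` is uniform on ``K_range`` and the trap count is
    drawn log-normally (median near the observed median of real networks)
    clipped to ``trap_range`` — unless ``n_traps`` pins it.
    ``descriptor_effects`` maps a descriptor column to a slope in descriptor
    units per 1000 eggs of ``K_true``; descriptors not named get no planted
    effect.  Seeded end to end.
    """
    if n_areas < 2:
        raise ValueError("need at least 2 areas")
    lo, hi = K_range
    if not 0 < lo <= hi:
        raise ValueError("invalid K_range")
    effects = descriptor_effects or {}
    unknown = set(effects) - set(DESCRIPTOR_COLUMNS)
    if unknown:
        raise KeyError(f"unknown descriptor(s) in effects: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    area_seeds = rng.integers(0, 2**31 - 1, size=n_areas)

    areas: dict[str, TrapCountData] = {}
    imfa_rows, temp_frames, desc_rows, truth_rows = [], [], [], []
    k_center = 0.5 * (lo + hi)
    for i in range(n_areas):
        area_id = f"area_{i:03d}"
        k_true = float(rng.uniform(lo, hi))
        if n_traps is not None:
            traps = int(n_traps)
        else:
            traps = int(np.clip(round(rng.lognormal(np.log(13.0), 0.8)), *trap_range))
        households = int(np.clip(round(rng.lognormal(np.log(8000.0), 0.4)), 200, 60000))
        scenario = SyntheticScenario(
            K_true=k_true,
            n_traps=traps,
            n_households=households,
            n_years=n_years,
            seed=int(area_seeds[i]),
        )
        data = generate_trap_counts(scenario, base_params, **sim_kwargs)
        areas[area_id] = data

        imfa_rows.append(
            pd.DataFrame(
                {
                    "area_id": area_id,
                    "week_start_date": data.observed.weeks.strftime("%Y-%m-%d"),
                    "imfa": data.observed.values,
                    "n_traps": traps,
                    "n_households": households,
                }
            )
        )
        temp_frames.append(
            pd.DataFrame(
                {
                    "date": data.forcing.dates.strftime("%Y-%m-%d"),
                    "area_id": area_id,
                    "tmean_C": data.forcing.values,
                }
            )
        )

        k_dev = (k_true - k_center) / 1000.0
        desc = {"area_id": area_id, "households": float(households)}
        desc["population"] = float(max(households * rng.normal(3.1, 0.2), 50.0))
        for col, (mean, sd) in _DESCRIPTOR_BASE.items():
            value = mean + effects.get(col, 0.0) * k_dev + rng.normal(0.0, sd)
            if col.startswith("pct_"):
                value = float(np.clip(value, 0.0, 100.0))
            else:
                value = float(max(value, 0.01))
            desc[col] = value
        desc["pop_density"] = desc["population"] / desc["area_km2"]
        if "pop_density" in effects:
            desc["pop_density"] += effects["pop_density"] * k_dev
        desc_rows.append(desc)

        truth_rows.append(
            {
                "area_id": area_id,
                "K_true": k_true,
                "n_traps": traps,
                "n_households": households,
                "seed": int(area_seeds[i]),
            }
        )

    descriptors = pd.DataFrame(desc_rows)[
        ["area_id", *[c for c in DESCRIPTOR_COLUMNS if c in desc_rows[0]]]
    ]
    return CityDataset(
        imfa_table=pd.concat(imfa_rows, ignore_index=True),
        temperature_table=pd.concat(temp_frames, ignore_index=True),
        descriptors=descriptors,
        ground_truth=pd.DataFrame(truth_rows),
        areas=areas,
    )
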