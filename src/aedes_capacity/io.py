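"""Readers/writers for study tables and the end-to-end pipeline.

File schemas (CSV; a spreadsheet with the same columns is accepted
read-only):

- IMFA table: ``area_id, week_start_date, imfa, n_traps, n_households``
  (one row per area-week; ``captured`` may replace ``imfa``).
- Temperature table: ``date, area_id, tmean_C`` (or ``tmax_C`` plus a
  regression prepared upstream); any cadence, interpolated to daily here.
- Descriptors table: ``area_id`` plus the census descriptor columns.

Dates are ISO-8601; areas are string ids; numbers use full precision with
``.`` as the decimal separator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import (
    DEFAULT_K_BOUNDS,
    fit_all_areas,
    summarize_fits,
)
from .imfa import ImfaSeries
from .model import LifeHistoryParams, TrapConfig
from .surveillance import aimfa, classify_fits, descriptor_regressions, roc_threshold
from .temperature import TemperatureSeries, interpolate_daily

__all__ = [
    "StudyDataset",
    "read_study_data",
    "pool_city",
    "run_pipeline",
    "convert_supplementary",
]

logger = logging.getLogger(__name__)

_IMFA_REQUIRED = {"area_id", "week_start_date", "n_traps", "n_households"}
_TEMP_REQUIRED = {"date", "area_id"}


@dataclass
class StudyDataset:
    """Aligned per-area surveillance series, forcings and trap configs."""

    imfa_tables: dict[str, ImfaSeries]
    temperatures: dict[str, TemperatureSeries]
    trap_configs: dict[str, TrapConfig]
    descriptors: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing_temp = sorted(set(self.imfa_tables) - set(self.temperatures))
        missing_trap = sorted(set(self.imfa_tables) - set(self.trap_configs))
        if missing_temp or missing_trap:
            raise ValueError(
                "areas missing inputs — "
                f"no temperature series: {missing_temp}; no trap config: {missing_trap}"
            )

    @property
    def area_ids(self) -> list[str]:
        return list(self.imfa_tables)

    def items(self):
        for area_id in self.area_ids:
            yield (
                area_id,
                self.imfa_tables[area_id],
                self.temperatures[area_id],
                self.trap_configs[area_id],
            )


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xls", ".xlsx"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def _require_columns(df: pd.DataFrame, required: set[str], what: str) -> None:
    missing = sorted(required - set(df.columns))
    if missing:
        raise KeyError(f"{what} is missing required column(s): {missing}")


def read_study_data(
    imfa_path: str | Path,
    temperature_path: str | Path,
    descriptors_path: str | Path | None = None,
    junction_map: dict[str, list[str]] | None = None,
) -> StudyDataset:
    """Load a study dataset from tidy tables.

    ``junction_map`` maps a merged area id to its member ids; member
    captures and traps are summed per week *before* the index is formed
    (ratio of sums, not mean of ratios), households likewise summed, and
    temperature averaged across members.
    """
    imfa_df = _read_table(imfa_path)
    _require_columns(imfa_df, _IMFA_REQUIRED, "IMFA table")
    if "imfa" not in imfa_df.columns and "captured" not in imfa_df.columns:
        raise KeyError("IMFA table needs an 'imfa' or 'captured' column")
    temp_df = _read_table(temperature_path)
    _require_columns(temp_df, _TEMP_REQUIRED, "temperature table")
    temp_col = "tmean_C" if "tmean_C" in temp_df.columns else "tmax_C"
    if temp_col not in temp_df.columns:
        raise KeyError("temperature table needs a 'tmean_C' or 'tmax_C' column")

    imfa_df = imfa_df.copy()
    imfa_df["week_start_date"] = pd.to_datetime(imfa_df["week_start_date"])
    if "captured" not in imfa_df.columns:
        imfa_df["captured"] = imfa_df["imfa"] * imfa_df["n_traps"]
    temp_df = temp_df.copy()
    temp_df["date"] = pd.to_datetime(temp_df["date"])

    if junction_map:
        member_to_junction = {
            member: junction
            for junction, members in junction_map.items()
            for member in members
        }
        imfa_df["area_id"] = imfa_df["area_id"].map(
            lambda a: member_to_junction.get(a, a)
        )
        temp_df["area_id"] = temp_df["area_id"].map(
            lambda a: member_to_junction.get(a, a)
        )
        # ratio of sums: sum captures and traps within the merged area-week
        imfa_df = (
            imfa_df.groupby(["area_id", "week_start_date"], as_index=False)
            .agg(
                captured=("captured", "sum"),
                n_traps=("n_traps", "sum"),
                n_households=("n_households", "sum"),
            )
        )
        imfa_df["imfa"] = imfa_df["captured"] / imfa_df["n_traps"]
        temp_df = temp_df.groupby(["area_id", "date"], as_index=False)[temp_col].mean()

    temp_areas = set(temp_df["area_id"].unique())
    imfa_areas = set(imfa_df["area_id"].unique())
    orphans = sorted(imfa_areas - temp_areas)
    if orphans:
        raise ValueError(
            f"areas present in the IMFA table but absent from the temperature "
            f"table: {orphans}"
        )

    imfa_tables: dict[str, ImfaSeries] = {}
    trap_configs: dict[str, TrapConfig] = {}
    temperatures: dict[str, TemperatureSeries] = {}
    for area_id, group in imfa_df.groupby("area_id"):
        group = group.sort_values("week_start_date")
        n_traps = int(round(group["n_traps"].iloc[0]))
        n_households = int(round(group["n_households"].iloc[0]))
        values = (
            group["imfa"]
            if "imfa" in group.columns
            else group["captured"] / n_traps
        )
        imfa_tables[str(area_id)] = ImfaSeries(
            weeks=pd.DatetimeIndex(group["week_start_date"]),
            values=values.to_numpy(dtype=float),
            n_traps=n_traps,
            area_id=str(area_id),
        )
        trap_configs[str(area_id)] = TrapConfig(
            n_traps=n_traps, n_households=n_households
        )
    for area_id, group in temp_df.groupby("area_id"):
        if str(area_id) not in imfa_tables:
            continue
        group = group.sort_values("date")
        series = TemperatureSeries(
            dates=pd.DatetimeIndex(group["date"]),
            values=group[temp_col].to_numpy(dtype=float),
            unit="C",
        )
        temperatures[str(area_id)] = interpolate_daily(series)

    descriptors = None
    if descriptors_path is not None:
        descriptors = _read_table(descriptors_path)
        _require_columns(descriptors, {"area_id"}, "descriptors table")
        descriptors["area_id"] = descriptors["area_id"].astype(str)

    logger.info(
        "loaded %d areas, %d IMFA rows, %d temperature rows",
        len(imfa_tables), len(imfa_df), len(temp_df),
    )
    return StudyDataset(
        imfa_tables=imfa_tables,
        temperatures=temperatures,
        trap_configs=trap_configs,
        descriptors=descriptors,
        provenance={
            "imfa_path": str(imfa_path),
            "temperature_path": str(temperature_path),
            "descriptors_path": str(descriptors_path) if descriptors_path else None,
            "junction_map": junction_map,
        },
    )


def pool_city(dataset: StudyDataset, city_id: str = "city") -> StudyDataset:
    """Collapse all areas into a single city-wide series (sums of captures,
    traps and households; unweighted mean temperature)."""
    captured = []
    for area_id, series in dataset.imfa_tables.items():
        traps = dataset.trap_configs[area_id].n_traps
        captured.append(series.to_series() * traps)
    total_captured = pd.concat(captured, axis=1).sum(axis=1, min_count=1)
    total_traps = sum(t.n_traps for t in dataset.trap_configs.values())
    total_households = sum(t.n_households for t in dataset.trap_configs.values())
    pooled = ImfaSeries(
        weeks=pd.DatetimeIndex(total_captured.index),
        values=(total_captured / total_traps).to_numpy(),
        n_traps=total_traps,
        area_id=city_id,
    )
    temp_frames = [
        pd.Series(s.values, index=s.dates) for s in dataset.temperatures.values()
    ]
    mean_temp = pd.concat(temp_frames, axis=1).mean(axis=1)
    city_temp = interpolate_daily(
        TemperatureSeries(
            dates=pd.DatetimeIndex(mean_temp.index),
            values=mean_temp.to_numpy(),
            unit="C",
        )
    )
    return StudyDataset(
        imfa_tables={city_id: pooled},
        temperatures={city_id: city_temp},
        trap_configs={
            city_id: TrapConfig(n_traps=total_traps, n_households=total_households)
        },
        descriptors=None,
        provenance={**dataset.provenance, "pooled": True},
    )


def convert_supplementary(
    spreadsheet_path: str | Path, out_dir: str | Path
) -> dict[str, Path]:
    """Convert a supplementary spreadsheet in the tidy schema to CSVs.

    Column names are matched case-insensitively.  Sheets whose columns do not
    match the IMFA or temperature schema are reported and skipped.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sheets = pd.read_excel(spreadsheet_path, sheet_name=None)
    written: dict[str, Path] = {}
    for name, df in sheets.items():
        df = df.rename(columns=lambda c: str(c).strip().lower())
        cols = set(df.columns)
        if _IMFA_REQUIRED <= cols and ({"imfa", "captured"} & cols):
            path = out / "imfa.csv"
            df.to_csv(path, index=False)
            written["imfa"] = path
        elif _TEMP_REQUIRED <= cols and ({"tmean_c", "tmax_c"} & cols):
            df = df.rename(columns={"tmean_c": "tmean_C", "tmax_c": "tmax_C"})
            path = out / "temperature.csv"
            df.to_csv(path, index=False)
            written["temperature"] = path
        else:
            logger.warning("sheet %r does not match a known schema; skipped", name)
    if not written:
        raise ValueError(
            "no sheet matched the tidy IMFA or temperature schema; see the io "
            "module docstring for expected columns"
        )
    return written


def run_pipeline(config: dict) -> dict:
    """Execute the study pipeline from a configuration mapping.

    Keys: ``imfa_path``, ``temperature_path`` (required unless ``dataset``
    is passed directly), optional ``descriptors_path``, ``junction_map``,
    ``out_dir``, ``alpha``, ``k_bounds``, ``span``, ``raw_imfa`` (fit the
    unsmoothed index), ``fit_city`` / ``fit_neighborhoods`` booleans.

    Writes ``fits.csv``, ``roc.csv``, ``associations.csv`` and
    ``summary.txt`` under ``out_dir`` and returns the report as a dict of
    DataFrames/objects.  Per-area failures are recorded in the fits table;
    only a total failure raises.
    """
    if not config:
        raise ValueError("empty configuration: at least input paths are required")
    dataset: StudyDataset | None = config.get("dataset")
    if dataset is None:
        if "imfa_path" not in config or "temperature_path" not in config:
            raise ValueError("config must provide imfa_path and temperature_path")
        dataset = read_study_data(
            config["imfa_path"],
            config["temperature_path"],
            config.get("descriptors_path"),
            config.get("junction_map"),
        )
    params = LifeHistoryParams(alpha=float(config.get("alpha", 0.2)))
    fit_kwargs = {
        "params": params,
        "bounds": tuple(config.get("k_bounds", DEFAULT_K_BOUNDS)),
        "smooth": not config.get("raw_imfa", False),
        "span": float(config.get("span", 0.08)),
    }
    out_dir = Path(config.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    lines: list[str] = []

    if config.get("fit_city", False):
        city = pool_city(dataset)
        city_fits = fit_all_areas(city, **fit_kwargs)
        report["city_fit"] = city_fits
        city_fits.to_csv(out_dir / "city_fit.csv", index=False)
        row = city_fits.iloc[0]
        lines.append(
            f"city fit: K = {row.K_hat:.1f} eggs, MSE = {row.mse:.3f}, "
            f"RMSE = {row.rmse:.3f} ({row.n_traps} traps)"
        )

    if config.get("fit_neighborhoods", True):
        fits = fit_all_areas(dataset, **fit_kwargs)
        report["fits"] = fits
        fits.to_csv(out_dir / "fits.csv", index=False)
        summary = summarize_fits(fits)
        report["summary"] = summary
        lines.append(
            "neighborhood fits: K range [{K_min:.0f}, {K_max:.0f}], "
            "mean {K_mean:.0f}, sd {K_sd:.0f} over {n_fitted}/{n_areas} areas".format(
                **summary
            )
        )
        lines.append(
            "MSE median {mse_median:.2f}, IQR [{lo:.2f}, {hi:.2f}]".format(
                mse_median=summary["mse_median"],
                lo=summary["mse_iqr"][0],
                hi=summary["mse_iqr"][1],
            )
        )

        ok = fits.dropna(subset=["mse"])
        if len(ok) >= 2 and ok["mse"].nunique() > 1:
            labels = classify_fits(ok)
            try:
                roc = roc_threshold(ok["n_traps"].to_numpy(), labels.to_numpy())
                report["roc"] = roc
                roc.to_frame().to_csv(out_dir / "roc.csv", index=False)
                lines.append(
                    f"ROC: {roc.threshold:.0f} traps best separates good from "
                    f"poor fits (AUC = {roc.auc:.3f})"
                )
            except ValueError as exc:
                lines.append(f"ROC skipped: {exc}")

        if dataset.descriptors is not None and len(ok) >= 10:
            aimfas = pd.Series(
                {a: aimfa(s) for a, s in dataset.imfa_tables.items()}, name="aimfa"
            )
            assoc = descriptor_regressions(ok, aimfas, dataset.descriptors)
            report["associations"] = assoc
            assoc.to_csv(out_dir / "associations.csv", index=False)
            starred = assoc[assoc.stars != ""]
            lines.append(f"descriptor screen: {len(starred)} starred associations")

    summary_path = out_dir / "summary.txt"
    summary_path.write_text("\n".join(lines) + "\n")
    report["summary_text"] = "\n".join(lines)
    report["out_dir"] = out_dir
    return report
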