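"""County-year data model and preprocessing.

Raw inputs are four county-year tables: daily (or weekly) weather for six
variables, a soil profile of ten variables at nine depths plus four surface
variables, weekly cumulative planting progress per state, and observed yield
in bushels/acre.  This module turns them into model-ready arrays: weekly
averaging of daily weather, cross-county mean imputation of soil, per-year
mean imputation of planting progress, z-score standardization under training
statistics, and assembly of k-year sequences for the recurrent model.

Week convention: weeks are consecutive 7-day blocks from January 1; days 365
and 366 fold into week 52.  Planting progress covers ``N_MGMT_WEEKS`` weeks
starting the first week of April.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

N_WEATHER_VARS = 6
N_WEEKS = 52
N_SOIL_VARS = 10
N_DEPTHS = 9
N_SURFACE = 4
N_MGMT_WEEKS = 16

WEATHER_VAR_NAMES = (
    "precipitation",
    "solar_radiation",
    "snow_water_equivalent",
    "max_temperature",
    "min_temperature",
    "vapor_pressure",
)
SOIL_VAR_NAMES = (
    "wet_bulk_density",
    "dry_bulk_density",
    "clay_pct",
    "awc_upper",
    "awc_lower",
    "hydraulic_conductivity",
    "organic_matter_pct",
    "ph",
    "sand_pct",
    "sat_water_content",
)
SOIL_DEPTH_LABELS = (
    "0-5", "5-10", "10-15", "15-30", "30-45", "45-60", "60-80", "80-100", "100-120",
)
SURFACE_VAR_NAMES = ("slope_pct", "nccpi_corn", "nccpi_all", "root_zone_depth")


class DimensionError(ValueError):
    """An input array has the wrong shape or length."""


class ImputationError(ValueError):
    """A feature (or feature-year group) is missing everywhere it is needed."""


class EmptyDatasetError(ValueError):
    """Sequence assembly produced no samples for the requested target years."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class WeatherSeries:
    """Weekly weather, 6 variables x 52 weeks, in the fixed variable order
    (precipitation, solar radiation, snow water equivalent, max temperature,
    min temperature, vapor pressure)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_WEATHER_VARS, N_WEEKS):
            raise DimensionError(
                f"weather must be {N_WEATHER_VARS}x{N_WEEKS}, got {self.values.shape}"
            )


@dataclass
class SoilProfile:
    """Soil: 10 variables at 9 depths (0-5 ... 100-120 cm) plus 4 surface
    variables (slope %, NCCPI-corn, NCCPI-all-crops, root zone depth)."""

    depth_values: np.ndarray
    surface_values: np.ndarray

    def __post_init__(self):
        self.depth_values = np.asarray(self.depth_values, dtype=np.float64)
        self.surface_values = np.asarray(self.surface_values, dtype=np.float64)
        if self.depth_values.shape != (N_SOIL_VARS, N_DEPTHS):
            raise DimensionError(
                f"soil depth matrix must be {N_SOIL_VARS}x{N_DEPTHS}, got {self.depth_values.shape}"
            )
        if self.surface_values.shape != (N_SURFACE,):
            raise DimensionError(
                f"surface soil vector must have {N_SURFACE} entries, got {self.surface_values.shape}"
            )


@dataclass
class ManagementSeries:
    """Weekly cumulative percentage of planted fields (state level), covering
    ``N_MGMT_WEEKS`` weeks from the first week of April; in [0, 100] and
    non-decreasing once imputed."""

    cumulative_planted: np.ndarray

    def __post_init__(self):
        self.cumulative_planted = np.asarray(self.cumulative_planted, dtype=np.float64)
        if self.cumulative_planted.shape != (N_MGMT_WEEKS,):
            raise DimensionError(
                f"management series must have {N_MGMT_WEEKS} weeks, got {self.cumulative_planted.shape}"
            )


@dataclass
class CountyYearRecord:
    """One county-year observation.  ``yield_value`` is bushels/acre or NaN
    when unobserved; missing soil/management entries are NaN until imputed."""

    county_id: str
    state_id: str
    year: int
    weather: WeatherSeries
    soil: SoilProfile
    management: ManagementSeries
    yield_value: float = float("nan")

    def copy(self) -> "CountyYearRecord":
        return CountyYearRecord(
            county_id=self.county_id,
            state_id=self.state_id,
            year=self.year,
            weather=WeatherSeries(self.weather.values.copy()),
            soil=SoilProfile(
                self.soil.depth_values.copy(), self.soil.surface_values.copy()
            ),
            management=ManagementSeries(self.management.cumulative_planted.copy()),
            yield_value=self.yield_value,
        )


@dataclass
class SequenceSample:
    """A k-year window for one county ending at ``target_year``: the unit of
    input to the recurrent model.

    Per-step arrays are ordered oldest to newest; ``avg_yield`` holds the
    cross-county mean observed yield of each step's year (the trend signal
    the LSTM receives; substituted by the previous year's mean at test time).
    """

    county_id: str
    state_id: str
    target_year: int
    k: int
    weather: np.ndarray      # (k, 6, 52)
    soil: np.ndarray         # (k, 10, 9)
    surface: np.ndarray      # (k, 4)
    management: np.ndarray   # (k, 16)
    avg_yield: np.ndarray    # (k,)
    target: float


@dataclass
class Standardizer:
    """Per-feature mean/sd computed on training records; sd==0 features map
    to zero.  ``avg_yield`` shares the yield statistics so the trend input is
    on the same scale as every other input."""

    weather_mean: np.ndarray = field(default=None)
    weather_sd: np.ndarray = field(default=None)
    soil_mean: np.ndarray = field(default=None)
    soil_sd: np.ndarray = field(default=None)
    surface_mean: np.ndarray = field(default=None)
    surface_sd: np.ndarray = field(default=None)
    mgmt_mean: np.ndarray = field(default=None)
    mgmt_sd: np.ndarray = field(default=None)
    yield_mean: float = 0.0
    yield_sd: float = 1.0

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        kwargs = {}
        for f in dataclasses.fields(cls):
            v = d[f.name]
            kwargs[f.name] = np.asarray(v, dtype=np.float64) if isinstance(v, list) else v
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def weekly_average(daily: np.ndarray) -> np.ndarray:
    """Reduce a daily series (365 or 366 values) to 52 weekly means.

    Week j (1-based) covers days 7(j-1)+1 ... 7j; days beyond 364 fold into
    week 52's mean.
    """
    daily = np.asarray(daily, dtype=np.float64)
    if daily.ndim != 1 or daily.shape[0] not in (365, 366):
        raise DimensionError(
            f"daily series must have 365 or 366 values, got shape {daily.shape}"
        )
    weekly = daily[: 51 * 7].reshape(51, 7).mean(axis=1)
    last = daily[51 * 7 :].mean()
    return np.concatenate([weekly, [last]])


def _nanmean_allow_empty(stack: np.ndarray) -> np.ndarray:
    """Column nanmean returning NaN (silently) for all-NaN columns."""
    count = (~np.isnan(stack)).sum(axis=0)
    total = np.nansum(stack, axis=0)
    return np.divide(
        total, count, out=np.full(stack.shape[1:], np.nan), where=count > 0
    )


def _soil_flat(record: CountyYearRecord) -> np.ndarray:
    return np.concatenate(
        [record.soil.depth_values.ravel(), record.soil.surface_values]
    )


def _set_soil_flat(record: CountyYearRecord, flat: np.ndarray) -> None:
    record.soil.depth_values = flat[: N_SOIL_VARS * N_DEPTHS].reshape(
        N_SOIL_VARS, N_DEPTHS
    )
    record.soil.surface_values = flat[N_SOIL_VARS * N_DEPTHS :]


def soil_feature_name(flat_index: int) -> str:
    if flat_index < N_SOIL_VARS * N_DEPTHS:
        v, d = divmod(flat_index, N_DEPTHS)
        return f"{SOIL_VAR_NAMES[v]}@{SOIL_DEPTH_LABELS[d]}cm"
    return SURFACE_VAR_NAMES[flat_index - N_SOIL_VARS * N_DEPTHS]


def impute_soil(
    records: list[CountyYearRecord],
    reference: list[CountyYearRecord] | None = None,
) -> list[CountyYearRecord]:
    """Fill missing soil entries with the cross-county mean of the same
    feature.  ``reference`` (default: the records themselves) supplies the
    means, so a training-period reference avoids leakage from validation
    counties.  Observed entries are never altered."""
    reference = records if reference is None else reference
    ref = np.stack([_soil_flat(r) for r in reference])
    means = _nanmean_allow_empty(ref)
    out = [r.copy() for r in records]
    for r in out:
        flat = _soil_flat(r)
        miss = np.isnan(flat)
        if miss.any():
            bad = miss & np.isnan(means)
            if bad.any():
                raise ImputationError(
                    "soil feature observed nowhere: "
                    + soil_feature_name(int(np.flatnonzero(bad)[0]))
                )
            flat[miss] = means[miss]
            _set_soil_flat(r, flat)
    return out


def impute_management(
    records: list[CountyYearRecord],
    reference: list[CountyYearRecord] | None = None,
) -> list[CountyYearRecord]:
    """Fill missing planting-progress entries with the mean of the same week
    among other counties *of the same year*; then re-clip each series to be
    non-decreasing in [0, 100]."""
    reference = records if reference is None else reference
    by_year: dict[int, list[np.ndarray]] = {}
    for r in reference:
        by_year.setdefault(r.year, []).append(r.management.cumulative_planted)
    year_means: dict[int, np.ndarray] = {}
    for year, rows in by_year.items():
        year_means[year] = _nanmean_allow_empty(np.stack(rows))
    out = [r.copy() for r in records]
    for r in out:
        series = r.management.cumulative_planted
        miss = np.isnan(series)
        if miss.any():
            means = year_means.get(r.year)
            if means is None or np.isnan(means[miss]).any():
                week = (
                    int(np.flatnonzero(miss)[0])
                    if means is None
                    else int(np.flatnonzero(miss & np.isnan(means))[0])
                )
                raise ImputationError(
                    f"management week {week + 1} has no observation in year {r.year}"
                )
            series[miss] = means[miss]
            series = np.clip(np.maximum.accumulate(series), 0.0, 100.0)
            r.management.cumulative_planted = series
    return out


def _masked_stats(stack: np.ndarray, axis=0) -> tuple[np.ndarray, np.ndarray]:
    mean = stack.mean(axis=axis)
    sd = stack.std(axis=axis)
    return mean, sd


def standardize(
    records: list[CountyYearRecord],
    stats: Standardizer | None = None,
) -> tuple[list[CountyYearRecord], Standardizer]:
    """Z-score every input feature.  With ``stats`` absent the statistics are
    computed from ``records`` (the training set) and returned for reuse on
    validation data; sd==0 features map to 0.  Yields are left in natural
    units (bushels/acre); their mean/sd are recorded for scaling the
    average-yield trend input downstream."""
    if stats is None:
        W = np.stack([r.weather.values for r in records])
        S = np.stack([r.soil.depth_values for r in records])
        U = np.stack([r.soil.surface_values for r in records])
        M = np.stack([r.management.cumulative_planted for r in records])
        y = np.array([r.yield_value for r in records], dtype=np.float64)
        y = y[~np.isnan(y)]
        stats = Standardizer()
        stats.weather_mean, stats.weather_sd = _masked_stats(W)
        stats.soil_mean, stats.soil_sd = _masked_stats(S)
        stats.surface_mean, stats.surface_sd = _masked_stats(U)
        stats.mgmt_mean, stats.mgmt_sd = _masked_stats(M)
        stats.yield_mean = float(y.mean()) if y.size else 0.0
        stats.yield_sd = float(y.std()) if y.size else 1.0
        if stats.yield_sd == 0.0:
            stats.yield_sd = 1.0

    def z(x, m, s):
        out = np.zeros_like(x)
        np.divide(x - m, s, out=out, where=s > 0)
        return out

    out = []
    for r in records:
        c = r.copy()
        c.weather.values = z(c.weather.values, stats.weather_mean, stats.weather_sd)
        c.soil.depth_values = z(c.soil.depth_values, stats.soil_mean, stats.soil_sd)
        c.soil.surface_values = z(
            c.soil.surface_values, stats.surface_mean, stats.surface_sd
        )
        c.management.cumulative_planted = z(
            c.management.cumulative_planted, stats.mgmt_mean, stats.mgmt_sd
        )
        out.append(c)
    return out, stats


def yearly_average_yield(records: list[CountyYearRecord]) -> dict[int, float]:
    """Mean observed yield over all counties, per year."""
    by_year: dict[int, list[float]] = {}
    for r in records:
        if not np.isnan(r.yield_value):
            by_year.setdefault(r.year, []).append(r.yield_value)
    return {year: float(np.mean(v)) for year, v in by_year.items()}


def build_sequences(
    records: list[CountyYearRecord],
    k: int,
    target_years: set[int] | None = None,
    avg_yield_by_year: dict[int, float] | None = None,
    stats: Standardizer | None = None,
) -> list[SequenceSample]:
    """Assemble one k-year sample per (county, target year) for which all k
    consecutive years are present and the target year's yield is observed.

    The per-step average yield is the cross-county mean observed yield of
    that step's year, computed once over the full dataset (or supplied via
    ``avg_yield_by_year``).  If ``stats`` is given, the average-yield input
    is z-scored with the training yield statistics.
    """
    if k < 1:
        raise ValueError("window length k must be >= 1")
    if avg_yield_by_year is None:
        avg_yield_by_year = yearly_average_yield(records)
    by_county: dict[str, dict[int, CountyYearRecord]] = {}
    for r in records:
        by_county.setdefault(r.county_id, {})[r.year] = r
    samples: list[SequenceSample] = []
    for county, by_year in sorted(by_county.items()):
        years = sorted(by_year)
        for t in years:
            if target_years is not None and t not in target_years:
                continue
            window = list(range(t - k + 1, t + 1))
            if not all(y in by_year for y in window):
                continue
            target = by_year[t].yield_value
            if np.isnan(target):
                continue
            if not all(y in avg_yield_by_year for y in window):
                continue
            ybar = np.array([avg_yield_by_year[y] for y in window])
            if stats is not None:
                ybar = (ybar - stats.yield_mean) / stats.yield_sd
            samples.append(
                SequenceSample(
                    county_id=county,
                    state_id=by_year[t].state_id,
                    target_year=t,
                    k=k,
                    weather=np.stack([by_year[y].weather.values for y in window]),
                    soil=np.stack([by_year[y].soil.depth_values for y in window]),
                    surface=np.stack(
                        [by_year[y].soil.surface_values for y in window]
                    ),
                    management=np.stack(
                        [by_year[y].management.cumulative_planted for y in window]
                    ),
                    avg_yield=ybar,
                    target=float(target),
                )
            )
    if not samples:
        wanted = "any year" if target_years is None else sorted(target_years)
        raise EmptyDatasetError(
            f"no (county, year) window of length k={k} with an observed target "
            f"yield exists for target years {wanted}"
        )
    return samples


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------


def weather_columns(daily: bool = False) -> list[str]:
    n = 365 if daily else N_WEEKS
    tag = "d" if daily else "w"
    return [f"v{i + 1}_{tag}{j + 1}" for i in range(N_WEATHER_VARS) for j in range(n)]


def soil_columns() -> list[str]:
    cols = [
        f"soil{v + 1}_d{d + 1}" for v in range(N_SOIL_VARS) for d in range(N_DEPTHS)
    ]
    return cols + list(SURFACE_VAR_NAMES)


def management_columns() -> list[str]:
    return [f"m_w{j + 1}" for j in range(N_MGMT_WEEKS)]


PROCESSED_SCHEMA_VERSION = 1


def save_processed(records: list[CountyYearRecord], path: str | Path) -> None:
    """Serialize a record collection to one ``.npz`` container with an
    embedded schema version."""
    np.savez_compressed(
        path,
        schema_version=np.array(PROCESSED_SCHEMA_VERSION),
        county=np.array([r.county_id for r in records]),
        state=np.array([r.state_id for r in records]),
        year=np.array([r.year for r in records]),
        weather=np.stack([r.weather.values for r in records]),
        soil_depth=np.stack([r.soil.depth_values for r in records]),
        soil_surface=np.stack([r.soil.surface_values for r in records]),
        management=np.stack([r.management.cumulative_planted for r in records]),
        yield_value=np.array([r.yield_value for r in records]),
    )


def load_processed(path: str | Path) -> list[CountyYearRecord]:
    with np.load(path, allow_pickle=False) as data:
        version = int(data["schema_version"])
        if version != PROCESSED_SCHEMA_VERSION:
            raise ValueError(f"unsupported processed-dataset schema {version}")
        return [
            CountyYearRecord(
                county_id=str(data["county"][i]),
                state_id=str(data["state"][i]),
                year=int(data["year"][i]),
                weather=WeatherSeries(data["weather"][i]),
                soil=SoilProfile(data["soil_depth"][i], data["soil_surface"][i]),
                management=ManagementSeries(data["management"][i]),
                yield_value=float(data["yield_value"][i]),
            )
            for i in range(len(data["county"]))
        ]


def load_csv_dataset(directory: str | Path) -> list[CountyYearRecord]:
    """Read ``weather.csv``, ``soil.csv``, ``management.csv`` and
    ``yield.csv`` from a directory into county-year records.

    Weather may be weekly (``v1_w1``...) or daily (``v1_d1``...; reduced with
    :func:`weekly_average` on load).  Management is state-level and is
    broadcast to every county in the state.  Missing soil/management cells
    stay NaN for the imputation steps.
    """
    directory = Path(directory)
    weather = pd.read_csv(directory / "weather.csv")
    soil = pd.read_csv(directory / "soil.csv")
    mgmt = pd.read_csv(directory / "management.csv")
    yields = pd.read_csv(directory / "yield.csv")

    daily = f"v1_d1" in weather.columns
    wcols = weather_columns(daily=daily)
    for frame, cols, name in (
        (weather, ["county", "state", "year"] + wcols, "weather.csv"),
        (soil, ["county"] + soil_columns(), "soil.csv"),
        (mgmt, ["state", "year"] + management_columns(), "management.csv"),
        (yields, ["county", "year", "yield"], "yield.csv"),
    ):
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise ValueError(f"{name} is missing columns: {missing[:5]}")

    soil_by_county = {
        str(row["county"]): np.array([row[c] for c in soil_columns()], dtype=float)
        for _, row in soil.iterrows()
    }
    mgmt_by_state_year = {
        (str(row["state"]), int(row["year"])): np.array(
            [row[c] for c in management_columns()], dtype=float
        )
        for _, row in mgmt.iterrows()
    }
    yield_by_county_year = {
        (str(row["county"]), int(row["year"])): float(row["yield"])
        for _, row in yields.iterrows()
    }

    records = []
    n_daily = 365
    for _, row in weather.iterrows():
        county, state, year = str(row["county"]), str(row["state"]), int(row["year"])
        vals = row[wcols].to_numpy(dtype=float)
        if daily:
            mat = vals.reshape(N_WEATHER_VARS, n_daily)
            mat = np.stack([weekly_average(mat[i]) for i in range(N_WEATHER_VARS)])
        else:
            mat = vals.reshape(N_WEATHER_VARS, N_WEEKS)
        soil_flat = soil_by_county.get(county, np.full(len(soil_columns()), np.nan))
        m = mgmt_by_state_year.get((state, year), np.full(N_MGMT_WEEKS, np.nan))
        records.append(
            CountyYearRecord(
                county_id=county,
                state_id=state,
                year=year,
                weather=WeatherSeries(mat),
                soil=SoilProfile(
                    soil_flat[: N_SOIL_VARS * N_DEPTHS].reshape(N_SOIL_VARS, N_DEPTHS),
                    soil_flat[N_SOIL_VARS * N_DEPTHS :],
                ),
                management=ManagementSeries(m.copy()),
                yield_value=yield_by_county_year.get((county, year), float("nan")),
            )
        )
    return records
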