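"""Synthetic county-year data generator with a known ground-truth response.

The generator emulates the statistical structure the yield model assumes:
six weekly weather channels with seasonal shape (snow only in winter, max
temperature above min temperature), soil variables that vary smoothly with
depth, a sigmoidal cumulative planting curve per state-year, and yields that
combine a yearly increasing trend, documented weather/soil/management driver
effects, a planting-date penalty, county random effects and Gaussian noise.
Because every driver is an explicit analytic function of one designated
feature, recovery tests (effect estimation, feature importance, ablations)
have an unambiguous right answer.

All randomness is keyed by ``(seed, stream, entity)`` so any record can be
regenerated bit-identically regardless of generation order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import (
    N_DEPTHS,
    N_MGMT_WEEKS,
    N_SOIL_VARS,
    N_SURFACE,
    N_WEATHER_VARS,
    N_WEEKS,
    CountyYearRecord,
    ManagementSeries,
    SoilProfile,
    WeatherSeries,
    management_columns,
    soil_columns,
    weather_columns,
)

_WEEKS = np.arange(1, N_WEEKS + 1, dtype=np.float64)

# Seasonal templates (mean weekly value per channel). Units are Daymet-like:
# mm, W/m2, mm, degC, degC, Pa.
_PRECIP_BASE = 15.0 + 8.0 * np.sin(2 * np.pi * (_WEEKS - 12) / 52)
_SOLAR_BASE = 350.0 + 150.0 * np.sin(2 * np.pi * (_WEEKS - 13) / 52)
_SNOW_BASE = 40.0 * np.clip(np.cos(2 * np.pi * (_WEEKS - 1) / 52), 0.0, None) ** 2
_TMAX_BASE = 16.0 + 14.0 * np.sin(2 * np.pi * (_WEEKS - 13) / 52)
_VP_BASE = 900.0 + 600.0 * np.sin(2 * np.pi * (_WEEKS - 13) / 52)

# Per-channel spread of county offsets, year offsets and weekly noise.
# Week-specific variation dominates the channel-global offsets: a channel's
# county/year level can otherwise be read off any week, which confounds
# week-level attribution (every week becomes a proxy for the global offset).
_COUNTY_SD = np.array([1.0, 5.0, 2.0, 0.5, 0.5, 20.0])
_YEAR_SD = np.array([1.0, 5.0, 2.0, 0.7, 0.7, 25.0])
_WEEK_SD = np.array([4.0, 20.0, 5.0, 2.0, 1.0, 80.0])

# Soil generator: per-variable base level, spread across counties, and a
# monotone depth trend (e.g. organic matter declines with depth).
_SOIL_BASE = np.array([1.6, 1.4, 25.0, 0.30, 0.15, 10.0, 3.0, 6.5, 35.0, 0.45])
_SOIL_SCALE = np.array([0.15, 0.12, 5.0, 0.05, 0.03, 3.0, 0.8, 0.5, 8.0, 0.05])
_SOIL_TREND = np.array([0.1, 0.1, 3.0, -0.03, -0.01, -2.0, -1.5, 0.4, -4.0, -0.03])
_DEPTH_FRAC = np.linspace(0.0, 1.0, N_DEPTHS)


@dataclass(frozen=True)
class Driver:
    """One injected yield driver: an analytic effect of a single feature.

    ``group`` is one of ``weather`` (index = (variable, week)), ``soil``
    (index = (variable, depth)), ``surface`` (index = position) or
    ``management`` (index = week); indices are 0-based.  The effect on yield
    is, with z = (x - loc) / scale:

    - ``linear``:      effect_size * z
    - ``saturating``:  effect_size * (1 - exp(-max(z, 0)))
    """

    group: str
    var_index: int
    pos_index: int
    effect_size: float
    kind: str = "linear"
    loc: float = 0.0
    scale: float = 1.0

    def response(self, x: float) -> float:
        z = (x - self.loc) / self.scale
        if self.kind == "linear":
            return self.effect_size * z
        if self.kind == "saturating":
            return self.effect_size * (1.0 - np.exp(-max(z, 0.0)))
        raise ValueError(f"unknown driver kind {self.kind!r}")


# Effect sizes are calibrated so every driver's marginal yield effect is on
# the order of 4-6 bu/acre — comparable to the default noise level — which
# makes each one recoverable in principle by an oracle regression at the
# bundled study sizes; a driver that no estimator could detect would make
# recovery experiments vacuous.
DEFAULT_DRIVERS: tuple[Driver, ...] = (
    Driver("weather", 0, 27, 6.0, "linear", loc=15.0, scale=5.0),      # July precip
    Driver("weather", 3, 29, -7.5, "linear", loc=30.0, scale=3.0),     # heat stress
    # loc references the seasonal template value at the driver's week
    Driver("weather", 1, 23, 21.0, "saturating", loc=470.0, scale=30.0),
    Driver("weather", 5, 19, 9.5, "linear", loc=1300.0, scale=150.0),
    Driver("soil", 6, 0, 5.0, "linear", loc=3.0, scale=0.8),           # topsoil OM
    Driver("soil", 2, 3, 15.0, "saturating", loc=25.0, scale=5.0),     # clay 15-30cm
    Driver("surface", 0, 1, 6.0, "linear", loc=0.6, scale=0.15),       # NCCPI corn
    Driver("management", 0, 7, 6.0, "linear", loc=75.0, scale=15.0),
)


# A broad growing-season response: yield depends on precipitation, heat and
# radiation across many consecutive weeks with a mid-season peak and decaying
# tails, on organic matter and clay through the profile, on site
# productivity, and on planting timing.  Useful for studies of how
# predictive skill decays as features are discarded: the informative set
# (~90 features, individually modest and near-equal in effect) deliberately
# exceeds a 10% feature budget, so aggressive selection must lose real
# signal rather than only noise.


BROAD_DRIVERS: tuple[Driver, ...] = (
    *(
        Driver("weather", 0, w, 1.3, "linear", loc=15.0, scale=5.0)
        for w in range(14, 40)
    ),
    *(
        Driver("weather", 3, w, -1.2, "linear", loc=30.0, scale=3.0)
        for w in range(18, 36)
    ),
    *(
        Driver("weather", 1, w, 1.1, "linear", loc=450.0, scale=25.0)
        for w in range(20, 33)
    ),
    *(Driver("soil", 6, d, 1.3, "linear", loc=3.0, scale=0.8) for d in range(9)),
    *(Driver("soil", 2, d, 1.0, "linear", loc=25.0, scale=5.0) for d in range(9)),
    Driver("surface", 0, 1, 3.0, "linear", loc=0.6, scale=0.15),
    Driver("surface", 0, 2, 2.0, "linear", loc=0.55, scale=0.15),
    *(
        Driver("management", 0, w, 1.1, "linear", loc=75.0, scale=15.0)
        for w in range(4, 13)
    ),
)


def driver_flat_index(d: Driver) -> int:
    """Position of a driver's feature in the flat per-step feature order
    (weather, soil depth, surface, management)."""
    if d.group == "weather":
        return d.var_index * N_WEEKS + d.pos_index
    if d.group == "soil":
        return N_WEATHER_VARS * N_WEEKS + d.var_index * N_DEPTHS + d.pos_index
    if d.group == "surface":
        return N_WEATHER_VARS * N_WEEKS + N_SOIL_VARS * N_DEPTHS + d.pos_index
    if d.group == "management":
        return (
            N_WEATHER_VARS * N_WEEKS + N_SOIL_VARS * N_DEPTHS + N_SURFACE + d.pos_index
        )
    raise ValueError(f"unknown driver group {d.group!r}")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic study.

    Defaults describe the reference synthetic study: 200 counties in 10
    states over 15 years, a 2 bu/acre/year technology trend on a 100
    bu/acre baseline, drivers in all three input groups, and missingness
    rates matching typical county soil/management tables.
    """

    n_counties: int = 200
    n_states: int = 10
    year_start: int = 2000
    year_end: int = 2014
    seed: int = 0
    baseline: float = 100.0
    trend_slope: float = 2.0
    drivers: tuple[Driver, ...] = DEFAULT_DRIVERS
    noise_sd: float = 8.0
    county_effect_sd: float = 6.0
    planting_penalty: float = 0.5
    planting_optimum_week: float = 6.0
    missing_frac_soil: float = 0.067
    missing_frac_management: float = 0.063

    def __post_init__(self):
        if self.year_start >= self.year_end:
            raise ValueError("year_start must precede year_end")
        if min(self.noise_sd, self.county_effect_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if not (0 <= self.missing_frac_soil < 1 and 0 <= self.missing_frac_management < 1):
            raise ValueError("missing fractions must lie in [0, 1)")
        for d in self.drivers:
            bounds = {
                "weather": (N_WEATHER_VARS, N_WEEKS),
                "soil": (N_SOIL_VARS, N_DEPTHS),
                "surface": (1, N_SURFACE),
                "management": (1, N_MGMT_WEEKS),
            }[d.group]
            if not (0 <= d.var_index < bounds[0] and 0 <= d.pos_index < bounds[1]):
                raise ValueError(f"driver index out of bounds: {d}")

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)


@dataclass
class GroundTruth:
    """The generating process: config, per-county random effects, and the
    documented response function (see :meth:`expected_yield`)."""

    config: SimConfig
    county_effects: dict[str, float] = field(default_factory=dict)

    def expected_yield(self, record: CountyYearRecord) -> float:
        """Noise-free response for a record (before truncation at 1.0)."""
        c = self.config
        y = c.baseline + c.trend_slope * (record.year - c.year_start)
        for d in c.drivers:
            y += d.response(_driver_feature(record, d))
        cross = _crossing_week(record.management.cumulative_planted)
        y -= c.planting_penalty * (cross - c.planting_optimum_week) ** 2
        y += self.county_effects.get(record.county_id, 0.0)
        return y


def _driver_feature(record: CountyYearRecord, d: Driver) -> float:
    if d.group == "weather":
        return float(record.weather.values[d.var_index, d.pos_index])
    if d.group == "soil":
        return float(record.soil.depth_values[d.var_index, d.pos_index])
    if d.group == "surface":
        return float(record.soil.surface_values[d.pos_index])
    if d.group == "management":
        return float(record.management.cumulative_planted[d.pos_index])
    raise ValueError(f"unknown driver group {d.group!r}")


def _crossing_week(curve: np.ndarray) -> float:
    """First week (1-based) at which cumulative planting reaches 50%."""
    over = np.flatnonzero(curve >= 50.0)
    return float(over[0] + 1) if over.size else float(len(curve) + 1)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


def county_name(i: int) -> str:
    return f"C{i:04d}"


def state_of(i: int, config: SimConfig) -> int:
    return i % config.n_states


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def gen_weather(county: int, year: int, config: SimConfig) -> WeatherSeries:
    """Seasonal weekly weather for one county-year: channel templates plus
    county- and year-level offsets and weekly noise."""
    c_off = _rng(config.seed, 1, county).normal(0.0, _COUNTY_SD)
    y_off = _rng(config.seed, 2, year).normal(0.0, _YEAR_SD)
    rng = _rng(config.seed, 3, county, year)
    noise = rng.normal(0.0, 1.0, size=(N_WEATHER_VARS, N_WEEKS)) * _WEEK_SD[:, None]

    vals = np.empty((N_WEATHER_VARS, N_WEEKS))
    vals[0] = np.clip(_PRECIP_BASE + c_off[0] + y_off[0] + noise[0], 0.0, None)
    vals[1] = np.clip(_SOLAR_BASE + c_off[1] + y_off[1] + noise[1], 10.0, None)
    winter = _SNOW_BASE > 0
    snow = _SNOW_BASE * np.exp(0.05 * (c_off[2] + y_off[2])) + noise[2]
    vals[2] = np.where(winter, np.clip(snow, 0.0, None), 0.0)
    tmax = _TMAX_BASE + c_off[3] + y_off[3] + noise[3]
    gap = np.clip(9.0 + rng.normal(0.0, 1.5, size=N_WEEKS), 0.5, None)
    vals[3] = tmax
    vals[4] = tmax - gap
    vals[5] = np.clip(_VP_BASE + c_off[5] + y_off[5] + noise[5], 100.0, None)
    return WeatherSeries(vals)


def gen_soil(county: int, config: SimConfig) -> SoilProfile:
    """Depth profiles that vary smoothly with depth (a monotone trend plus a
    random walk along depth) and four surface variables."""
    rng = _rng(config.seed, 4, county)
    county_level = rng.normal(0.0, 1.0, size=N_SOIL_VARS) * _SOIL_SCALE
    walk = np.cumsum(
        rng.normal(0.0, 1.0, size=(N_SOIL_VARS, N_DEPTHS)) * (0.25 * _SOIL_SCALE)[:, None],
        axis=1,
    )
    depth = (
        _SOIL_BASE[:, None]
        + county_level[:, None]
        + _SOIL_TREND[:, None] * _DEPTH_FRAC[None, :]
        + walk
    )
    surface = np.array(
        [
            abs(rng.normal(2.0, 1.5)),
            float(np.clip(rng.normal(0.6, 0.15), 0.0, 1.0)),
            float(np.clip(rng.normal(0.55, 0.15), 0.0, 1.0)),
            rng.normal(100.0, 15.0),
        ]
    )
    return SoilProfile(depth, surface)


def gen_management(state: int, year: int, config: SimConfig) -> ManagementSeries:
    """Logistic cumulative planting-progress curve with a state/year-specific
    midpoint and slope, clipped to [0, 100]."""
    rng = _rng(config.seed, 5, state, year)
    mid = rng.normal(6.5, 1.2)
    rate = max(rng.normal(1.2, 0.2), 0.5)
    weeks = np.arange(1, N_MGMT_WEEKS + 1, dtype=np.float64)
    curve = 100.0 / (1.0 + np.exp(-(weeks - mid) / rate))
    return ManagementSeries(np.clip(curve, 0.0, 100.0))


def gen_yield(record: CountyYearRecord, truth: GroundTruth) -> float:
    """Ground-truth response plus Gaussian noise, truncated below at 1.0."""
    c = truth.config
    rng = _rng(c.seed, 6, int(record.county_id[1:]), record.year)
    y = truth.expected_yield(record) + rng.normal(0.0, c.noise_sd)
    return float(max(y, 1.0))


def gen_dataset(config: SimConfig) -> tuple[list[CountyYearRecord], GroundTruth]:
    """Generate the full county-year collection with missingness injected
    completely at random into soil and management cells."""
    county_rng = _rng(config.seed, 7)
    truth = GroundTruth(
        config=config,
        county_effects={
            county_name(i): float(county_rng.normal(0.0, config.county_effect_sd))
            for i in range(config.n_counties)
        },
    )
    soils = {i: gen_soil(i, config) for i in range(config.n_counties)}
    mgmt = {
        (s, y): gen_management(s, y, config)
        for s in range(config.n_states)
        for y in config.years
    }

    records: list[CountyYearRecord] = []
    for i in range(config.n_counties):
        state = state_of(i, config)
        for year in config.years:
            rec = CountyYearRecord(
                county_id=county_name(i),
                state_id=f"S{state:02d}",
                year=year,
                weather=gen_weather(i, year, config),
                soil=SoilProfile(
                    soils[i].depth_values.copy(), soils[i].surface_values.copy()
                ),
                management=ManagementSeries(
                    mgmt[(state, year)].cumulative_planted.copy()
                ),
            )
            rec.yield_value = gen_yield(rec, truth)
            records.append(rec)

    # soil is static per county: missingness is injected per county cell
    if config.missing_frac_soil > 0:
        n_cells = N_SOIL_VARS * N_DEPTHS + N_SURFACE
        miss_rng = _rng(config.seed, 8)
        masks = {
            i: miss_rng.random(n_cells) < config.missing_frac_soil
            for i in range(config.n_counties)
        }
        for rec in records:
            mask = masks[int(rec.county_id[1:])]
            depth_mask = mask[: N_SOIL_VARS * N_DEPTHS].reshape(N_SOIL_VARS, N_DEPTHS)
            rec.soil.depth_values[depth_mask] = np.nan
            rec.soil.surface_values[mask[N_SOIL_VARS * N_DEPTHS :]] = np.nan
    if config.missing_frac_management > 0:
        miss_rng = _rng(config.seed, 9)
        masks = {
            key: miss_rng.random(N_MGMT_WEEKS) < config.missing_frac_management
            for key in sorted(mgmt)
        }
        for rec in records:
            key = (int(rec.state_id[1:]), rec.year)
            rec.management.cumulative_planted[masks[key]] = np.nan
    return records, truth


# ---------------------------------------------------------------------------
# CSV export
# ---------------------------------------------------------------------------


def write_csvs(
    records: list[CountyYearRecord], truth: GroundTruth, directory: str | Path
) -> None:
    """Write the four-table CSV interface plus a ``truth.json`` sidecar
    describing the generating process."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    wcols = weather_columns()
    weather_rows, yield_rows = [], []
    soil_seen: dict[str, np.ndarray] = {}
    mgmt_seen: dict[tuple[str, int], np.ndarray] = {}
    for r in records:
        weather_rows.append(
            {"county": r.county_id, "state": r.state_id, "year": r.year}
            | dict(zip(wcols, r.weather.values.ravel()))
        )
        yield_rows.append({"county": r.county_id, "year": r.year, "yield": r.yield_value})
        soil_seen.setdefault(
            r.county_id,
            np.concatenate([r.soil.depth_values.ravel(), r.soil.surface_values]),
        )
        mgmt_seen.setdefault((r.state_id, r.year), r.management.cumulative_planted)

    fmt = "%.6f"
    pd.DataFrame(weather_rows).to_csv(directory / "weather.csv", index=False, float_format=fmt)
    pd.DataFrame(
        [{"county": c} | dict(zip(soil_columns(), v)) for c, v in sorted(soil_seen.items())]
    ).to_csv(directory / "soil.csv", index=False, float_format=fmt)
    pd.DataFrame(
        [
            {"state": s, "year": y} | dict(zip(management_columns(), v))
            for (s, y), v in sorted(mgmt_seen.items())
        ]
    ).to_csv(directory / "management.csv", index=False, float_format=fmt)
    pd.DataFrame(yield_rows).to_csv(directory / "yield.csv", index=False, float_format=fmt)

    sidecar = {
        "config": {
            **{
                k: v
                for k, v in dataclasses.asdict(truth.config).items()
                if k != "drivers"
            },
            "drivers": [dataclasses.asdict(d) for d in truth.config.drivers],
        },
        "county_effects": truth.county_effects,
        "response": (
            "yield = baseline + trend_slope*(year-year_start) + sum(driver effects) "
            "- planting_penalty*(week50 - optimum)^2 + county_effect + N(0, noise_sd), "
            "truncated below at 1.0; driver effects: linear=size*(x-loc)/scale, "
            "saturating=size*(1-exp(-max((x-loc)/scale,0)))"
        ),
    }
    (directory / "truth.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
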