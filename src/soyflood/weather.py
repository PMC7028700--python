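"""Daily weather series: reading/writing (CSV and a met-like text dialect),
a seeded synthetic weather generator, and the rainfall perturbations used by
the climate-change risk scenarios.

A series is a validated wrapper around a pandas DataFrame with columns
``date`` (datetime64), ``tmax``, ``tmin`` (degC), ``radn`` (MJ m^-2 d^-1) and
``rain`` (mm d^-1).  Dates must be strictly increasing and gap-free.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WeatherSeries",
    "ClimateParams",
    "ClimateScenario",
    "read_weather",
    "write_weather",
    "generate_synthetic_weather",
    "apply_monthly_rain_increase",
    "inject_extreme_events",
]

COLUMNS = ("date", "tmax", "tmin", "radn", "rain")


class WeatherSeries:
    """Validated daily weather driver."""

    def __init__(self, df: pd.DataFrame):
        self._df = _validate(df)

    @property
    def df(self) -> pd.DataFrame:
        return self._df.copy()

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeatherSeries):
            return NotImplemented
        return self._df.equals(other._df)

    def year_slice(self, year: int) -> "WeatherSeries":
        d = self._df[self._df["date"].dt.year == year].reset_index(drop=True)
        return WeatherSeries(d)

    @property
    def years(self) -> list[int]:
        return sorted(self._df["date"].dt.year.unique().tolist())


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weather series missing column(s): {missing}")
    df = df.loc[:, list(COLUMNS)].reset_index(drop=True)
    df["date"] = pd.to_datetime(df["date"])
    if len(df) == 0:
        raise ValueError("weather series is empty")
    bad = df.index[df["tmax"] < df["tmin"]]
    if len(bad):
        d = df.loc[bad[0], "date"].date()
        raise ValueError(f"tmax < tmin on {d}")
    for col in ("radn", "rain"):
        bad = df.index[df[col] < 0]
        if len(bad):
            d = df.loc[bad[0], "date"].date()
            raise ValueError(f"negative {col} on {d}")
    deltas = df["date"].diff().dropna()
    if len(deltas) and not (deltas == pd.Timedelta(days=1)).all():
        i = deltas.index[deltas != pd.Timedelta(days=1)][0]
        raise ValueError(f"dates not strictly increasing/gap-free near {df.loc[i, 'date'].date()}")
    return df


def read_weather(path: str | Path, dialect: str = "csv") -> WeatherSeries:
    """Read a weather series from ``path``.

    ``dialect='csv'`` expects the five named columns with ISO dates;
    ``dialect='met-like'`` expects a header of column names (year, day, radn,
    maxt, mint, rain), a units line in parentheses, then whitespace-delimited
    rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        return WeatherSeries(pd.read_csv(path))
    if dialect == "met-like":
        return _read_met_like(path)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_met_like(path: Path) -> WeatherSeries:
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("!")
    ]
    header_i = next(
        (i for i, ln in enumerate(lines) if ln.split() and ln.split()[0] == "year"), None
    )
    if header_i is None:
        raise ValueError("met-like file lacks a 'year ...' header line")
    names = lines[header_i].split()
    rows = [ln.split() for ln in lines[header_i + 1 :] if not ln.lstrip().startswith("(")]
    data = pd.DataFrame(rows, columns=names).astype(float)
    for col in ("year", "day", "radn", "maxt", "mint", "rain"):
        if col not in data.columns:
            raise ValueError(f"met-like file missing column {col!r}")
    date = pd.to_datetime(data["year"].astype(int).astype(str), format="%Y") + pd.to_timedelta(
        data["day"].astype(int) - 1, unit="D"
    )
    return WeatherSeries(
        pd.DataFrame(
            {
                "date": date,
                "tmax": data["maxt"],
                "tmin": data["mint"],
                "radn": data["radn"],
                "rain": data["rain"],
            }
        )
    )


def write_weather(series: WeatherSeries, path: str | Path, dialect: str = "csv") -> None:
    path = Path(path)
    df = series.df
    if dialect == "csv":
        out = df.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)
        return
    if dialect == "met-like":
        lines = ["year day radn maxt mint rain", "() () (MJ/m2) (oC) (oC) (mm)"]
        for _, r in df.iterrows():
            lines.append(
                f"{r['date'].year} {r['date'].dayofyear} "
                f"{r['radn']:.2f} {r['tmax']:.2f} {r['tmin']:.2f} {r['rain']:.2f}"
            )
        path.write_text("\n".join(lines) + "\n")
        return
    raise ValueError(f"unknown dialect: {dialect!r}")


@dataclass(frozen=True)
class ClimateParams:
    """Parameters of the synthetic weather generator.

    Temperatures and radiation follow sinusoidal annual cycles (peak at
    ``peak_doy``) with Gaussian day-to-day noise; rainfall occurrence is a
    two-state (wet/dry) first-order Markov chain with monthly wet-day
    frequencies implied by ``monthly_rain_mm`` and ``wet_day_freq``, and wet
    day depths are exponential.
    """

    tmax_mean: float = 22.0
    tmax_amp: float = 12.0
    tmin_mean: float = 10.0
    tmin_amp: float = 11.0
    radn_mean: float = 16.0
    radn_amp: float = 9.0
    peak_doy: int = 197  # mid July
    temp_sd: float = 2.5
    monthly_rain_mm: tuple[float, ...] = (90.0,) * 12  # Jan..Dec
    wet_day_freq: tuple[float, ...] = (0.30,) * 12
    p_wet_wet: float = 0.35  # persistence of wet spells

    def __post_init__(self) -> None:
        if len(self.monthly_rain_mm) != 12 or len(self.wet_day_freq) != 12:
            raise ValueError("monthly_rain_mm and wet_day_freq need 12 entries")


def generate_synthetic_weather(
    climate_params: ClimateParams, seed: int, n_years: int, start_year: int = 2001
) -> WeatherSeries:
    """Generate a reproducible synthetic daily weather series.

    Long-run monthly rainfall means converge to ``monthly_rain_mm``; the
    generator exists so simulation experiments can run without external
    reanalysis data.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    p = climate_params
    rng = np.random.default_rng(seed)
    dates = pd.date_range(f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    month = dates.month.to_numpy()
    ndays = len(dates)

    phase = 2.0 * np.pi * (doy - p.peak_doy) / 365.25
    anom = rng.normal(0.0, p.temp_sd, ndays)
    tmax = p.tmax_mean + p.tmax_amp * np.cos(phase) + anom
    tmin = p.tmin_mean + p.tmin_amp * np.cos(phase) + anom * 0.8
    tmin = np.minimum(tmin, tmax - 1.0)

    freq = np.array(p.wet_day_freq)[month - 1]
    # stationary wet fraction pi = p01 / (1 - p11 + p01)  =>  p01 from target pi
    p11 = p.p_wet_wet
    p01 = np.clip(freq * (1.0 - p11) / np.maximum(1e-9, 1.0 - freq), 0.0, 1.0)
    wet = np.zeros(ndays, dtype=bool)
    u = rng.random(ndays)
    prev = False
    for i in range(ndays):
        prob = p11 if prev else p01[i]
        wet[i] = u[i] < prob
        prev = wet[i]
    monthly = np.array(p.monthly_rain_mm)[month - 1]
    days_in_month = np.array(
        [calendar.monthrange(d.year, d.month)[1] for d in dates]
    )
    mean_depth = monthly / np.maximum(1e-9, days_in_month * freq)
    rain = np.where(wet, rng.exponential(1.0, ndays) * mean_depth, 0.0)

    radn = p.radn_mean + p.radn_amp * np.cos(phase) + rng.normal(0.0, 1.5, ndays)
    radn = np.where(wet, radn * 0.65, radn)
    radn = np.clip(radn, 1.0, None)

    return WeatherSeries(
        pd.DataFrame(
            {
                "date": dates,
                "tmax": np.round(tmax, 2),
                "tmin": np.round(tmin, 2),
                "radn": np.round(radn, 2),
                "rain": np.round(rain, 2),
            }
        )
    )


def apply_monthly_rain_increase(
    series: WeatherSeries, months: set[int], scale_factor: float
) -> WeatherSeries:
    """Scale rain by ``scale_factor`` on every day of the named calendar
    months; all other fields and days are unchanged."""
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    df = series.df
    mask = df["date"].dt.month.isin(list(months))
    df.loc[mask, "rain"] = df.loc[mask, "rain"] * scale_factor
    return WeatherSeries(df)


def inject_extreme_events(
    series: WeatherSeries,
    event_depth: float,
    events_per_month: int,
    months: set[int],
) -> WeatherSeries:
    """Add ``event_depth`` mm rain events, ``events_per_month`` per named
    month, on days evenly distributed within the month: for f events in a
    month of L days, event days are round(L*k/(f+1)) for k = 1..f.
    Deterministic; events add to any existing rain."""
    if event_depth < 0:
        raise ValueError("event_depth must be non-negative")
    if not 0 <= events_per_month <= 4:
        raise ValueError("events_per_month must be in 0..4")
    if events_per_month == 0 or not months:
        return WeatherSeries(series.df)
    df = series.df
    f = events_per_month
    for (year, mon), grp in df.groupby([df["date"].dt.year, df["date"].dt.month]):
        if mon not in months:
            continue
        L = calendar.monthrange(year, mon)[1]
        for k in range(1, f + 1):
            day = int(round(L * k / (f + 1)))
            day = min(max(day, 1), L)
            idx = grp.index[grp["date"].dt.day == day]
            if len(idx):
                df.loc[idx[0], "rain"] += event_depth
    return WeatherSeries(df)


@dataclass(frozen=True)
class ClimateScenario:
    """A rainfall perturbation: monthly scaling, added extreme events, or
    none (identity)."""

    kind: str = "none"  # monthly_scale | extreme_events | none
    months: frozenset[int] = frozenset()
    scale_factor: float = 1.0
    event_depth: float = 0.0
    events_per_month: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("monthly_scale", "extreme_events", "none"):
            raise ValueError(f"unknown scenario kind: {self.kind!r}")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if self.event_depth < 0 or self.events_per_month < 0:
            raise ValueError("event_depth and events_per_month must be non-negative")
        object.__setattr__(self, "months", frozenset(self.months))

    def apply(self, series: WeatherSeries) -> WeatherSeries:
        if self.kind == "none":
            return WeatherSeries(series.df)
        if self.kind == "monthly_scale":
            return apply_monthly_rain_increase(series, set(self.months), self.scale_factor)
        return inject_extreme_events(
            series, self.event_depth, self.events_per_month, set(self.months)
        )


def paper8_scenarios() -> list[ClimateScenario]:
    """The eight rainfall scenarios of the risk analysis: +25% rain in June,
    July or August separately, +25% in all three together, and 50 mm extreme
    events one to four times per month in June-August."""
    out = [
        ClimateScenario("monthly_scale", frozenset({6}), 1.25, name="jun+25%"),
        ClimateScenario("monthly_scale", frozenset({7}), 1.25, name="jul+25%"),
        ClimateScenario("monthly_scale", frozenset({8}), 1.25, name="aug+25%"),
        ClimateScenario("monthly_scale", frozenset({6, 7, 8}), 1.25, name="jja+25%"),
    ]
    for f in (1, 2, 3, 4):
        out.append(
            ClimateScenario(
                "extreme_events",
                frozenset({6, 7, 8}),
                event_depth=50.0,
                events_per_month=f,
                name=f"events{f}x50mm",
            )
        )
    return out


__all__.append("paper8_scenarios")
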