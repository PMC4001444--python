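"""Synthetic daily climate series with linear elevational lapse adjustment.

The simulator is driven by a 5-year daily sequence of mean/minimum
temperature, precipitation and a radiation proxy at a reference elevation.
The generator emulates a temperate mountain climate: a sinusoidal seasonal
temperature cycle with AR(1) daily noise, occasional spring frost snaps, and
one anomalously hot and dry year per 5-year block (a 2003-like summer).
The base sequence is lapse-adjusted to any elevation with linear models and
looped (six loops of the 5-year block) to cover the 30-year adult stage of
each generation.

Years are 365 days long; day-of-year is all the phenology model consumes.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365

__all__ = [
    "DAYS_PER_YEAR",
    "LapseModel",
    "ClimateGenParams",
    "ClimateSeries",
    "generate_base_series",
    "lapse_adjust",
    "loop_sequence",
]


@dataclass(frozen=True)
class LapseModel:
    """Linear elevational lapse rates, applied relative to the reference.

    Defaults use the standard environmental lapse rate of -0.6 degC / 100 m
    for both mean and minimum temperature; precipitation and radiation are
    left unadjusted by default.  All slopes are per metre of elevation.
    """

    t_slope: float = -0.006
    tmin_slope: float = -0.006
    precip_slope: float = 0.0
    radiation_slope: float = 0.0


@dataclass(frozen=True)
class ClimateGenParams:
    """Settings of the synthetic weather generator (at the reference elevation)."""

    mean_annual_t: float = 7.5        # degC, annual mean at reference elevation
    seasonal_amplitude: float = 8.5   # degC, half peak-to-trough of the cycle
    coldest_doy: int = 15
    ar1_phi: float = 0.65             # day-to-day temperature autocorrelation
    ar1_sigma: float = 2.2            # degC, innovation s.d.
    diurnal_half_range: float = 4.0   # degC, mean (t_mean - t_min)
    diurnal_sigma: float = 1.0
    frost_snap_prob: float = 0.08     # per-day probability within the window
    frost_snap_window: tuple[int, int] = (90, 150)
    frost_snap_depth: tuple[float, float] = (2.0, 6.0)  # extra t_min drop, degC
    wet_day_prob: float = 0.35
    precip_event_shape: float = 0.9   # gamma shape of wet-day totals
    precip_event_scale: float = 9.0   # mm
    rad_mean: float = 13.0            # MJ m-2 d-1
    rad_amplitude: float = 9.0
    cloud_attenuation: float = 0.45   # radiation reduction on wet days
    hot_year_index: int = 1           # which year of each 5-year block is hot/dry
    hot_year_dt: float = 2.5          # degC added in the summer window
    hot_year_precip_factor: float = 0.4
    hot_year_window: tuple[int, int] = (152, 243)  # Jun-Aug


@dataclass
class ClimateSeries:
    """Daily weather over whole years, shape ``(n_years, 365)`` per variable."""

    t_mean: np.ndarray
    t_min: np.ndarray
    precip: np.ndarray
    radiation: np.ndarray
    reference_elevation: float = 1200.0

    def __post_init__(self) -> None:
        arrs = (self.t_mean, self.t_min, self.precip, self.radiation)
        shapes = {a.shape for a in arrs}
        if len(shapes) != 1:
            raise ValueError("climate variables must share one shape")
        shape = shapes.pop()
        if len(shape) != 2 or shape[1] != DAYS_PER_YEAR:
            raise ValueError(f"expected shape (n_years, {DAYS_PER_YEAR}), got {shape}")
        if np.any(self.t_min > self.t_mean + 1e-9):
            raise ValueError("t_min must not exceed t_mean")
        if np.any(self.precip < 0) or np.any(self.radiation < 0):
            raise ValueError("precip and radiation must be non-negative")

    @property
    def n_years(self) -> int:
        return self.t_mean.shape[0]

    def year(self, i: int) -> dict[str, np.ndarray]:
        """The four daily variables of year ``i`` as 1-D arrays."""
        return {
            "t_mean": self.t_mean[i],
            "t_min": self.t_min[i],
            "precip": self.precip[i],
            "radiation": self.radiation[i],
        }

    # -- CSV interchange (year, doy, t_mean, t_min, precip, radiation) --

    def to_frame(self) -> pd.DataFrame:
        n = self.n_years
        doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), n)
        return pd.DataFrame(
            {
                "year": np.repeat(np.arange(n), DAYS_PER_YEAR),
                "doy": doy,
                "t_mean": self.t_mean.ravel(),
                "t_min": self.t_min.ravel(),
                "precip": self.precip.ravel(),
                "radiation": self.radiation.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, reference_elevation: float = 1200.0) -> "ClimateSeries":
        df = df.sort_values(["year", "doy"])
        n = df["year"].nunique()
        if len(df) != n * DAYS_PER_YEAR:
            raise ValueError("every year must have exactly 365 days")
        shp = (n, DAYS_PER_YEAR)
        return cls(
            t_mean=df["t_mean"].to_numpy(float).reshape(shp),
            t_min=df["t_min"].to_numpy(float).reshape(shp),
            precip=df["precip"].to_numpy(float).reshape(shp),
            radiation=df["radiation"].to_numpy(float).reshape(shp),
            reference_elevation=reference_elevation,
        )

    @classmethod
    def from_csv(cls, path, reference_elevation: float = 1200.0) -> "ClimateSeries":
        return cls.from_frame(pd.read_csv(path), reference_elevation)


def generate_base_series(
    n_years: int,
    seed: int | np.random.Generator,
    params: ClimateGenParams | None = None,
    reference_elevation: float = 1200.0,
) -> ClimateSeries:
    """Generate a seeded ``n_years`` x 365-day synthetic weather sequence."""
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    p = params or ClimateGenParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    doy = np.arange(1, DAYS_PER_YEAR + 1)
    seasonal = p.mean_annual_t - p.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - p.coldest_doy) / DAYS_PER_YEAR
    )
    rad_seasonal = p.rad_mean - p.rad_amplitude * np.cos(
        2.0 * np.pi * (doy - p.coldest_doy) / DAYS_PER_YEAR
    )

    t_mean = np.empty((n_years, DAYS_PER_YEAR))
    t_min = np.empty_like(t_mean)
    precip = np.empty_like(t_mean)
    radiation = np.empty_like(t_mean)

    noise_prev = 0.0
    for y in range(n_years):
        innov = rng.normal(0.0, p.ar1_sigma, DAYS_PER_YEAR)
        noise = np.empty(DAYS_PER_YEAR)
        for d in range(DAYS_PER_YEAR):
            noise_prev = p.ar1_phi * noise_prev + innov[d]
            noise[d] = noise_prev
        tm = seasonal + noise

        diurnal = np.maximum(0.5, rng.normal(p.diurnal_half_range, p.diurnal_sigma, DAYS_PER_YEAR))
        tmin = tm - diurnal
        lo, hi = p.frost_snap_window
        window = (doy >= lo) & (doy <= hi)
        snap = window & (rng.random(DAYS_PER_YEAR) < p.frost_snap_prob)
        tmin = tmin - snap * rng.uniform(*p.frost_snap_depth, DAYS_PER_YEAR)

        wet = rng.random(DAYS_PER_YEAR) < p.wet_day_prob
        pr = wet * rng.gamma(p.precip_event_shape, p.precip_event_scale, DAYS_PER_YEAR)

        rad = np.clip(rad_seasonal + rng.normal(0.0, 1.0, DAYS_PER_YEAR), 0.5, None)
        rad = np.where(wet, rad * (1.0 - p.cloud_attenuation), rad)

        if y % 5 == p.hot_year_index:
            lo, hi = p.hot_year_window
            summer = (doy >= lo) & (doy <= hi)
            tm = tm + summer * p.hot_year_dt
            tmin = tmin + summer * p.hot_year_dt
            pr = np.where(summer, pr * p.hot_year_precip_factor, pr)

        t_mean[y], t_min[y], precip[y], radiation[y] = tm, tmin, pr, rad

    return ClimateSeries(t_mean, t_min, precip, radiation, reference_elevation)


def lapse_adjust(
    series: ClimateSeries, elevation: float, lapse: LapseModel | None = None
) -> ClimateSeries:
    """Shift every variable linearly by its lapse slope times the elevation offset.

    Adjustment at the reference elevation is the identity.  The adjusted
    series records ``elevation`` as its own reference, so successive
    adjustments compose additively (two +500 m steps equal one +1000 m
    step).
    """
    lp = lapse or LapseModel()
    de = elevation - series.reference_elevation
    return replace(
        series,
        reference_elevation=float(elevation),
        t_mean=series.t_mean + lp.t_slope * de,
        t_min=series.t_min + lp.tmin_slope * de,
        precip=np.maximum(series.precip + lp.precip_slope * de, 0.0),
        radiation=np.maximum(series.radiation + lp.radiation_slope * de, 0.0),
    )


def loop_sequence(series: ClimateSeries, n_loops: int) -> ClimateSeries:
    """Concatenate ``n_loops`` copies of the series (5-year base x 6 = 30 years)."""
    if n_loops < 1:
        raise ValueError("n_loops must be >= 1")
    tile = lambda a: np.tile(a, (n_loops, 1))
    return replace(
        series,
        t_mean=tile(series.t_mean),
        t_min=tile(series.t_min),
        precip=tile(series.precip),
        radiation=tile(series.radiation),
    )
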