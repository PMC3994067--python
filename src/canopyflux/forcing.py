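"""Half-hourly forcing tables: reading, validation, and clear-sky synthesis.

Forcing is carried as a pandas DataFrame with one row per half hour and
the columns listed in :data:`FORCING_COLUMNS`.  The reader validates
physical ranges and never fills gaps silently; the generator produces a
deterministic clear-sky day for a site (solar-geometry-driven PAR with
single-transmittance attenuation, sinusoidal temperature and humidity
phased to solar noon), which is the study condition used throughout the
examples and acceptance runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .solar import (
    PAR_FRACTION,
    SOLAR_CONSTANT,
    SiteGeometry,
    diffuse_fraction,
    solar_zenith,
)

#: canonical forcing columns and their physical ranges
FORCING_COLUMNS = {
    "solar_time": (0.0, 24.0),     # hours
    "q_par": (0.0, 700.0),         # W m-2 incident PAR
    "r_n": (-200.0, 1100.0),       # W m-2 net radiation
    "g_soil": (-200.0, 400.0),     # W m-2 soil heat flux
    "t_air": (-20.0, 50.0),        # degC
    "rh": (0.0, 100.0),            # %
    "wind": (0.0, 30.0),           # m s-1
    "pressure": (50.0, 105.0),     # kPa
    "lai": (0.0, 12.0),
    "h_c": (0.0, 6.0),             # m
    "theta": (0.0, 0.6),           # m3 m-3 root zone
    "theta_g": (0.0, 0.6),         # m3 m-3 surface 0-10 cm
}

#: conversion used when a file carries broadband shortwave instead of PAR
SW_TO_PAR = PAR_FRACTION


@dataclass(frozen=True)
class WeatherParams:
    """Diurnal-envelope parameters for the clear-sky generator."""

    t_min: float = 14.0
    t_max: float = 28.0
    rh_min: float = 30.0
    rh_max: float = 75.0
    wind: float = 2.0
    rn_fraction: float = 0.65   # net radiation as a fraction of total shortwave
    g_fraction: float = 0.1     # soil heat flux as a fraction of net radiation
    rn_night: float = -40.0     # W m-2 nocturnal net radiation


def read_forcing(
    path,
    column_map: dict[str, str] | None = None,
    shortwave_input: bool = False,
    max_bad_fraction: float = 0.05,
) -> pd.DataFrame:
    """Read and validate a half-hourly forcing CSV.

    Parameters
    ----------
    path : str or file-like
        Comma-separated text with a header row; missing token "NA".
    column_map : dict, optional
        Mapping from file column names to canonical names
        (:data:`FORCING_COLUMNS`).
    shortwave_input : bool
        If True the radiation column holds broadband shortwave and is
        converted to PAR with the standard 0.45 fraction.
    max_bad_fraction : float
        Abort if more than this fraction of values fall outside
        physical ranges.

    Out-of-range values are set to NaN (marked missing), never
    interpolated.  Non-monotone time stamps are a hard error.
    """
    df = pd.read_csv(path, na_values=["NA"])
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in FORCING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"forcing file lacks required columns: {missing}")
    df = df[list(FORCING_COLUMNS)].astype(float)
    if shortwave_input:
        df["q_par"] = df["q_par"] * SW_TO_PAR
    t = df["solar_time"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValueError("time stamps must be strictly increasing")
    n_bad = 0
    for col, (lo, hi) in FORCING_COLUMNS.items():
        vals = df[col]
        bad = vals.notna() & ((vals < lo) | (vals > hi))
        n_bad += int(bad.sum())
        df.loc[bad, col] = np.nan
    if n_bad > max_bad_fraction * df.size:
        raise ValueError(
            f"{n_bad} out-of-range values (> {max_bad_fraction:.0%} of table); refusing to load"
        )
    return df


def write_forcing(df: pd.DataFrame, path) -> None:
    """Write a forcing table in the canonical CSV dialect."""
    df.to_csv(path, index=False, na_rep="NA")


def generate_clearsky_forcing(
    site: SiteGeometry,
    day_of_year: int,
    lai: float,
    h_c: float,
    theta: float = 0.28,
    theta_g: float = 0.25,
    weather: WeatherParams | None = None,
    tau_a: float = 0.72,
    f_a: float = 0.43,
) -> pd.DataFrame:
    """Deterministic synthetic clear-sky day at half-hourly cadence.

    48 records at solar times 0.25, 0.75, ... 23.75 h.  Incident PAR is
    the extraterrestrial PAR (``0.45 S_0 cos z``) depleted along the
    slant path by ``tau_a ** m_a``; net radiation is a fixed fraction
    of the implied total shortwave; temperature and relative humidity
    follow sinusoids between their stated extremes, warmest / driest at
    solar noon; soil heat flux is a fixed fraction of net radiation.

    The generator emulates a high-altitude semi-arid site on a
    cloudless day; it has no stochastic weather, no cloud, and constant
    wind - see the methods note for what that does and does not test.
    """
    if weather is None:
        weather = WeatherParams()
    times = np.arange(0.25, 24.0, 0.5)
    rows = []
    for st_hours in times:
        state = solar_zenith(site, day_of_year, float(st_hours))
        if state.sun_up:
            cos_z = math.cos(math.radians(state.zenith_deg))
            q_par = PAR_FRACTION * SOLAR_CONSTANT * cos_z * tau_a ** state.air_mass
            sw_total = q_par / PAR_FRACTION
            r_n = weather.rn_fraction * sw_total
        else:
            q_par = 0.0
            r_n = weather.rn_night
        phase = math.cos(2.0 * math.pi * (st_hours - 12.0) / 24.0)
        t_air = 0.5 * (weather.t_min + weather.t_max) + 0.5 * (weather.t_max - weather.t_min) * phase
        rh = 0.5 * (weather.rh_min + weather.rh_max) - 0.5 * (weather.rh_max - weather.rh_min) * phase
        rows.append(
            {
                "solar_time": float(st_hours),
                "q_par": q_par,
                "r_n": r_n,
                "g_soil": weather.g_fraction * r_n,
                "t_air": t_air,
                "rh": rh,
                "wind": weather.wind,
                "pressure": site.pressure,
                "lai": lai,
                "h_c": h_c,
                "theta": theta,
                "theta_g": theta_g,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LysimeterRecord:
    """One day of micro-lysimeter weighing.

    delta_w : mean weight change, g d-1
    area    : cross-sectional area of the cylinder, cm2 (78.5)
    rho_w   : water density, g cm-3
    f_mulch : fraction of ground sealed by plastic film
    """

    delta_w: float
    area: float = 78.5
    rho_w: float = 1.0
    f_mulch: float = 0.0

    def __post_init__(self) -> None:
        if self.area <= 0.0:
            raise ValueError("lysimeter area must be positive")


def lysimeter_upscale(rec: LysimeterRecord) -> float:
    """Field-scale soil evaporation (mm d-1) from a micro-lysimeter.

    ``E_s = (1 - f_m) 10 dW / (A_e rho_w)``: the weight change per unit
    cylinder area converted from cm to mm of water, then weighted by
    the exposed (non-mulched) ground fraction.
    """
    return (1.0 - rec.f_mulch) * 10.0 * rec.delta_w / (rec.area * rec.rho_w)
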