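"""Solar geometry and the beam/diffuse split of incident PAR.

The canopy radiative-transfer scheme needs three things from the sky:
the solar zenith angle, the optical air mass along the slant path, and
the fraction of incident photosynthetically active radiation (PAR) that
arrives as diffuse sky light rather than direct beam.  The diffuse
fraction follows a single-transmittance clear-sky attenuation model: a
beam of extraterrestrial PAR is depleted by ``tau_a ** m_a`` and a
fraction ``f_a`` of the scattered light is forward-scattered back into
the downward diffuse stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: sea-level standard atmospheric pressure, kPa
P0_KPA = 101.325

#: solar constant, W m-2
SOLAR_CONSTANT = 1367.0

#: PAR fraction of broadband shortwave (used when deriving PAR from SW)
PAR_FRACTION = 0.45


@dataclass(frozen=True)
class SiteGeometry:
    """Location and pressure of the study site.

    Parameters
    ----------
    latitude : float
        Degrees north, in [-90, 90].
    longitude : float
        Degrees east.
    altitude : float
        Metres above sea level.
    pressure : float, optional
        Local atmospheric pressure in kPa.  If omitted it is derived
        from altitude with the standard barometric formula.
    """

    latitude: float
    longitude: float = 0.0
    altitude: float = 0.0
    pressure: float | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if self.pressure is None:
            object.__setattr__(self, "pressure", pressure_from_altitude(self.altitude))
        if not 0.0 < self.pressure <= P0_KPA:
            raise ValueError(f"pressure {self.pressure} kPa outside (0, {P0_KPA}]")


@dataclass(frozen=True)
class SolarState:
    """Sun position for one site and instant."""

    zenith_deg: float
    air_mass: float | None
    sun_up: bool


@dataclass(frozen=True)
class IncidentPAR:
    """Incident PAR above the canopy split into beam and diffuse streams.

    The closure ``beam + diffuse == total`` holds exactly by
    construction.
    """

    total: float
    beam: float
    diffuse: float
    diffuse_fraction: float


def pressure_from_altitude(altitude_m: float) -> float:
    """Barometric pressure (kPa) at a given altitude (FAO-56 form)."""
    return P0_KPA * ((293.0 - 0.0065 * altitude_m) / 293.0) ** 5.26


def solar_declination(day_of_year):
    """Solar declination (degrees), eccentricity-corrected approximation.

    ``delta = -asin(0.39779 cos(0.98565 (N+10) + 1.914 sin(0.98565 (N-2))))``
    (angles in degrees).  Accurate to about 0.2 degrees, cross-checked
    against an independent Fourier-series algorithm in the test suite.
    """
    n = np.asarray(day_of_year, dtype=float)
    inner = np.radians(0.98565 * (n + 10.0)) + np.radians(1.914) * np.sin(
        np.radians(0.98565 * (n - 2.0))
    )
    return -np.degrees(np.arcsin(0.39779 * np.cos(inner)))


def equation_of_time(day_of_year):
    """Equation of time in minutes (Spencer Fourier series)."""
    b = 2.0 * np.pi * (np.asarray(day_of_year) - 1) / 365.0
    return 229.18 * (
        0.000075
        + 0.001868 * np.cos(b)
        - 0.032077 * np.sin(b)
        - 0.014615 * np.cos(2 * b)
        - 0.040849 * np.sin(2 * b)
    )


def local_to_solar_time(local_hours, day_of_year, longitude_deg, utc_offset_hours):
    """Convert local standard time (hours) to apparent solar time.

    Applies the longitude offset from the time-zone meridian plus the
    equation of time.  Matters for sites well away from their zone
    meridian (e.g. 102.85 E in UTC+8 runs ~49 min behind clock noon).
    """
    meridian = 15.0 * utc_offset_hours
    correction_min = 4.0 * (np.asarray(longitude_deg) - meridian) + equation_of_time(day_of_year)
    return np.asarray(local_hours) + correction_min / 60.0


def solar_zenith(site: SiteGeometry, day_of_year: int, solar_time: float) -> SolarState:
    """Solar zenith angle from the hour-angle formula.

    cos(zenith) = sin(lat) sin(decl) + cos(lat) cos(decl) cos(hour angle)
    with the hour angle 15 deg per hour away from solar noon.  Returns a
    :class:`SolarState` whose ``air_mass`` is filled only when the sun
    is up.
    """
    if not 1 <= day_of_year <= 366:
        raise ValueError("day_of_year must be in [1, 366]")
    if not 0.0 <= solar_time < 24.0:
        raise ValueError("solar_time must be in [0, 24)")
    phi = math.radians(site.latitude)
    delta = math.radians(float(solar_declination(day_of_year)))
    hour_angle = math.radians(15.0 * (solar_time - 12.0))
    cos_z = math.sin(phi) * math.sin(delta) + math.cos(phi) * math.cos(delta) * math.cos(hour_angle)
    zenith = math.degrees(math.acos(min(1.0, max(-1.0, cos_z))))
    up = zenith < 90.0
    m_a = optical_air_mass(site, zenith) if up else None
    return SolarState(zenith_deg=zenith, air_mass=m_a, sun_up=up)


def optical_air_mass(site: SiteGeometry, zenith_deg: float) -> float:
    """Pressure-corrected optical air mass ``(P/P0)/cos(zenith)``.

    Raises
    ------
    ValueError
        If the sun is at or below the horizon; callers must branch to
        the night path instead.
    """
    if zenith_deg >= 90.0:
        raise ValueError("sun below horizon: optical air mass undefined")
    return (site.pressure / P0_KPA) / math.cos(math.radians(zenith_deg))


def diffuse_fraction(tau_a: float, f_a: float, m_a: float) -> float:
    """Diffuse fraction of incident PAR under a clear sky.

    ``f_d = f_a (1 - tau^m) / (f_a (1 - tau^m) + tau^m)``: the surviving
    beam is ``tau_a**m_a`` of the extraterrestrial flux and a fraction
    ``f_a`` of what was scattered arrives as downward diffuse light.
    Monotone increasing in air mass, decreasing in transmittance.
    """
    if not 0.0 < tau_a <= 1.0:
        raise ValueError("atmospheric transmittance must be in (0, 1]")
    if not 0.0 <= f_a <= 1.0:
        raise ValueError("forward-scattering coefficient must be in [0, 1]")
    if m_a <= 0.0:
        raise ValueError("optical air mass must be positive")
    beam = tau_a ** m_a
    scattered = f_a * (1.0 - beam)
    return scattered / (scattered + beam)


def partition_incident(q_total: float, f_d: float) -> IncidentPAR:
    """Split total incident PAR into beam and diffuse streams exactly."""
    if q_total < 0.0:
        raise ValueError("incident PAR must be nonnegative")
    if not 0.0 <= f_d <= 1.0:
        raise ValueError("diffuse fraction must be in [0, 1]")
    diffuse = f_d * q_total
    beam = q_total - diffuse
    return IncidentPAR(total=q_total, beam=beam, diffuse=diffuse, diffuse_fraction=f_d)


def night_incident() -> IncidentPAR:
    """Incident PAR for a sun-below-horizon timestep (all zero, f_d = 1)."""
    return IncidentPAR(total=0.0, beam=0.0, diffuse=0.0, diffuse_fraction=1.0)
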