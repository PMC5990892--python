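"""Solar geometry and the incident-PAR model.

The sun's apparent position is computed from the NOAA solar-calculator
series for declination and the equation of time (evaluated for the leap
study year, 2012), a local-clock to solar-time correction for the site's
offset from its time-zone meridian, and the standard spherical-astronomy
transforms.  Accuracy is a few hundredths of a degree in declination and
well under half a degree in elevation, ample for hourly canopy light
budgets.

Incident photosynthetically active radiation (PAR, µmol m⁻² s⁻¹) on a
horizontal plane is modelled as a clear-sky direct beam attenuated by a
broadband transmittance per unit optical air mass,

    direct = I0 · tau^m · sin(elevation),

plus a diffuse component proportional to the direct one through the
configured diffuse:direct ratio.  The angular distribution of the diffuse
sky used to weight sky sectors follows the standard-overcast-sky (SOC)
radiance model, L(theta) ∝ (1 + 2 cos theta)/3 with theta the zenith
angle, i.e. a sky three times brighter at the zenith than at the horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import SiteConfig, SkyConfig

#: Scale height (m) of the barometric pressure correction p/p0 = exp(-z/H).
PRESSURE_SCALE_HEIGHT_M = 8434.0


@dataclass(frozen=True)
class SolarPosition:
    """Sun elevation/azimuth at one instant.

    ``elevation`` is degrees above the horizon, ``azimuth`` degrees
    clockwise from North in ``[0, 360)``.
    """

    elevation: float
    azimuth: float
    day_of_year: int
    hour_local: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.elevation <= 90.0:
            raise ValueError("elevation outside [-90, 90]")

    @property
    def zenith(self) -> float:
        return 90.0 - self.elevation


@dataclass(frozen=True)
class IncidentPAR:
    """Direct and diffuse PAR on a horizontal plane (µmol m⁻² s⁻¹)."""

    direct: float
    diffuse: float

    def __post_init__(self) -> None:
        if self.direct < 0 or self.diffuse < 0:
            raise ValueError("PAR components must be non-negative")

    @property
    def total(self) -> float:
        return self.direct + self.diffuse


def _check_day(day_of_year: int) -> None:
    if not 1 <= int(day_of_year) <= 366:
        raise ValueError(f"day_of_year {day_of_year} outside [1, 366]")


#: Julian date of 2012-01-01 00:00 UTC; day-of-year tables refer to the
#: (leap) study year 2012.
_JD_YEAR_START = 2455927.5


def _sun_ephemeris(day_of_year: float, hour_utc: float = 12.0
                   ) -> tuple[float, float]:
    """(declination degrees, equation of time minutes), NOAA solar
    calculator series evaluated for the study year."""
    jd = _JD_YEAR_START + (day_of_year - 1) + hour_utc / 24.0
    jc = (jd - 2451545.0) / 36525.0
    gml = math.radians((280.46646 + jc * (36000.76983 + 0.0003032 * jc))
                       % 360.0)
    gma = math.radians(357.52911 + jc * (35999.05029 - 0.0001537 * jc))
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    eq_centre = (math.sin(gma) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
                 + math.sin(2 * gma) * (0.019993 - 0.000101 * jc)
                 + math.sin(3 * gma) * 0.000289)
    true_long = math.degrees(gml) + eq_centre
    omega = math.radians(125.04 - 1934.136 * jc)
    app_long = math.radians(true_long - 0.00569
                            - 0.00478 * math.sin(omega))
    mean_obl = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059
                       - jc * 0.001813))) / 60.0) / 60.0
    obl = math.radians(mean_obl + 0.00256 * math.cos(omega))
    decl = math.degrees(math.asin(math.sin(obl) * math.sin(app_long)))
    var_y = math.tan(obl / 2.0) ** 2
    eot = 4.0 * math.degrees(
        var_y * math.sin(2 * gml) - 2.0 * ecc * math.sin(gma)
        + 4.0 * ecc * var_y * math.sin(gma) * math.cos(2 * gml)
        - 0.5 * var_y ** 2 * math.sin(4 * gml)
        - 1.25 * ecc ** 2 * math.sin(2 * gma))
    return decl, eot


def solar_declination(day_of_year: int, hour_utc: float = 12.0) -> float:
    """Solar declination (degrees) for a day of the (leap) study year."""
    _check_day(day_of_year)
    return _sun_ephemeris(day_of_year, hour_utc)[0]


def equation_of_time(day_of_year: int, hour_utc: float = 12.0) -> float:
    """Equation of time in minutes (apparent minus mean solar time)."""
    _check_day(day_of_year)
    return _sun_ephemeris(day_of_year, hour_utc)[1]


def solar_time(site: SiteConfig, day_of_year: int, hour_local: float) -> float:
    """Apparent solar time (decimal hours) for a civil-clock hour.

    Corrects for the site longitude's offset from the time-zone meridian
    (4 min per degree) and for the equation of time.
    """
    correction_min = 4.0 * (site.longitude - 15.0 * site.utc_offset) \
        + equation_of_time(day_of_year, hour_local - site.utc_offset)
    return hour_local + correction_min / 60.0


def solar_position(site: SiteConfig, day_of_year: int, hour_local: float,
                   *, hour_is_solar: bool = False) -> SolarPosition:
    """Sun elevation and azimuth at a clock hour of the given day.

    With ``hour_is_solar=True`` the hour is taken as apparent solar time
    (solar noon at 12.0) and no clock correction is applied.
    """
    _check_day(day_of_year)
    if not 0.0 <= hour_local < 24.0:
        raise ValueError(f"hour_local {hour_local} outside [0, 24)")
    t_solar = hour_local if hour_is_solar \
        else solar_time(site, day_of_year, hour_local)
    hour_angle = math.radians(15.0 * (t_solar - 12.0))
    lat = math.radians(site.latitude)
    dec = math.radians(solar_declination(
        day_of_year,
        (hour_local - site.utc_offset) if not hour_is_solar else 12.0))
    sin_elev = (math.sin(lat) * math.sin(dec)
                + math.cos(lat) * math.cos(dec) * math.cos(hour_angle))
    elev = math.degrees(math.asin(max(-1.0, min(1.0, sin_elev))))
    # Horizontal components of the unit sun vector.
    east = -math.cos(dec) * math.sin(hour_angle)
    north = (math.sin(dec) * math.cos(lat)
             - math.cos(dec) * math.sin(lat) * math.cos(hour_angle))
    azim = math.degrees(math.atan2(east, north)) % 360.0
    return SolarPosition(elevation=elev, azimuth=azim,
                         day_of_year=int(day_of_year), hour_local=hour_local)


def optical_air_mass(elevation: float, altitude: float = 0.0) -> float:
    """Relative optical air mass (Kasten–Young) with barometric correction.

    Raises ``ValueError`` when the sun is at or below the horizon; callers
    treating night hours should zero the beam instead of calling this.
    """
    if elevation <= 0.0:
        raise ValueError("sun at or below the horizon: air mass undefined")
    pressure_ratio = math.exp(-altitude / PRESSURE_SCALE_HEIGHT_M)
    denom = math.sin(math.radians(elevation)) \
        + 0.50572 * (elevation + 6.07995) ** -1.6364
    return pressure_ratio / denom


def _direct_horizontal(site: SiteConfig, sky: SkyConfig, day_of_year: int,
                       hour: float, *, hour_is_solar: bool = False) -> float:
    pos = solar_position(site, day_of_year, hour, hour_is_solar=hour_is_solar)
    if pos.elevation <= 0.0:
        return 0.0
    m = optical_air_mass(pos.elevation, site.altitude)
    return sky.par_extraterrestrial * sky.tau ** m \
        * math.sin(math.radians(pos.elevation))


def _daily_diffuse_scale(site: SiteConfig, sky: SkyConfig,
                         day_of_year: int) -> float:
    """Ratio k such that diffuse = k·sin(elev)·I0 integrates, over the day,
    to ``diffuse_direct_ratio`` times the daily direct integral."""
    hours = np.arange(0.0, 24.0, 0.25)
    direct_sum = 0.0
    sin_sum = 0.0
    for h in hours:
        pos = solar_position(site, day_of_year, h)
        if pos.elevation <= 0.0:
            continue
        s = math.sin(math.radians(pos.elevation))
        direct_sum += sky.par_extraterrestrial \
            * sky.tau ** optical_air_mass(pos.elevation, site.altitude) * s
        sin_sum += sky.par_extraterrestrial * s
    if sin_sum == 0.0:
        return 0.0
    return sky.diffuse_direct_ratio * direct_sum / sin_sum


def incident_par(site: SiteConfig, sky: SkyConfig, day_of_year: int,
                 hour_local: float, *, hour_is_solar: bool = False) -> IncidentPAR:
    """Clear-sky direct + diffuse PAR on a horizontal plane.

    Night hours (sun at or below the horizon) return an all-zero record.
    """
    pos = solar_position(site, day_of_year, hour_local,
                         hour_is_solar=hour_is_solar)
    if pos.elevation <= 0.0:
        return IncidentPAR(0.0, 0.0)
    direct = _direct_horizontal(site, sky, day_of_year, hour_local,
                                hour_is_solar=hour_is_solar)
    if sky.diffuse_mode == "daily":
        k = _daily_diffuse_scale(site, sky, day_of_year)
        diffuse = k * sky.par_extraterrestrial \
            * math.sin(math.radians(pos.elevation))
    else:
        diffuse = sky.diffuse_direct_ratio * direct
    return IncidentPAR(direct=direct, diffuse=diffuse)


def soc_radiance(zenith_deg: np.ndarray | float) -> np.ndarray | float:
    """Relative SOC sky radiance (1 + 2 cos theta)/3 at zenith angle theta."""
    return (1.0 + 2.0 * np.cos(np.radians(zenith_deg))) / 3.0


def _soc_ring_integral(z_lo_deg: float, z_hi_deg: float) -> float:
    """∫ (1 + 2 cos t) cos t sin t dt over [z_lo, z_hi] (closed form).

    The SOC radiance (up to the 1/3 constant) times the cosine-projected
    solid-angle element cos t sin t dt; antiderivative
    F(t) = sin²t / 2 − (2/3) cos³t.
    """
    def anti(t: float) -> float:
        return 0.5 * math.sin(t) ** 2 - (2.0 / 3.0) * math.cos(t) ** 3
    a, b = math.radians(z_lo_deg), math.radians(z_hi_deg)
    if b <= a:
        return 0.0
    return anti(b) - anti(a)


def soc_segment_weights(grid) -> np.ndarray:
    """SOC-weighted fraction of horizontal diffuse PAR from each sky segment.

    Returns an ``(n_zenith, n_azimuth)`` array summing to 1 over *all*
    segments (including any rings a :class:`~canolux.hemiphoto.SkyGrid`
    discards from structural analyses — the sky still shines from them).
    The SOC radiance is azimuth-independent so weights are constant along
    each ring.
    """
    edges = grid.zenith_edges
    ring = np.array([_soc_ring_integral(edges[i], edges[i + 1])
                     for i in range(grid.n_zenith)])
    weights = np.repeat(ring[:, None] / grid.n_azimuth, grid.n_azimuth, axis=1)
    total = weights.sum()
    if total <= 0:
        raise ValueError("degenerate sky grid: zero total SOC weight")
    return weights / total
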