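"""Independent numerical oracles used by the test suite.

These deliberately share no code with the package: the solar oracle is
the Michalsky (1988) Astronomical Almanac algorithm, and the SOC weight
oracle is adaptive quadrature over the exact integrand.
"""

import math

from scipy import integrate


def almanac_elevation(lat: float, lon: float, year: int, day_of_year: int,
                      hour_utc: float) -> float:
    """Sun elevation (degrees, no refraction) from the Astronomical
    Almanac low-precision formulae (Michalsky 1988)."""
    delta = year - 1949
    leap = delta // 4
    jd = 2432916.5 + delta * 365 + leap + day_of_year + hour_utc / 24.0
    n = jd - 2451545.0
    mean_long = (280.460 + 0.9856474 * n) % 360.0
    mean_anom = math.radians((357.528 + 0.9856003 * n) % 360.0)
    ecl_long = math.radians((mean_long + 1.915 * math.sin(mean_anom)
                             + 0.020 * math.sin(2 * mean_anom)) % 360.0)
    obliquity = math.radians(23.439 - 0.0000004 * n)
    declination = math.asin(math.sin(obliquity) * math.sin(ecl_long))
    right_asc = math.atan2(math.cos(obliquity) * math.sin(ecl_long),
                           math.cos(ecl_long))
    gmst = (6.697375 + 0.0657098242 * n + hour_utc) % 24.0
    lmst = (gmst + lon / 15.0) % 24.0
    hour_angle = math.radians(lmst * 15.0) - right_asc
    hour_angle = (hour_angle + math.pi) % (2 * math.pi) - math.pi
    lat_r = math.radians(lat)
    return math.degrees(math.asin(
        math.sin(declination) * math.sin(lat_r)
        + math.cos(declination) * math.cos(lat_r) * math.cos(hour_angle)))


def soc_band_integral(zenith_lo_deg: float, zenith_hi_deg: float) -> float:
    """Quadrature of the SOC radiance times the projected solid-angle
    element over a zenith band (full azimuth)."""
    def integrand(theta):
        radiance = (1.0 + 2.0 * math.cos(theta)) / 3.0
        return radiance * math.cos(theta) * math.sin(theta)

    val, _ = integrate.quad(integrand, math.radians(zenith_lo_deg),
                            math.radians(zenith_hi_deg))
    return 2.0 * math.pi * val
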