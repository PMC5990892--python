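"""Diurnal, monthly and annual crown light interception.

PAR transmitted to the measurement point below/inside the crown is
modelled from the per-segment gap fractions of its hemispherical
photograph: the direct beam is transmitted through the single sky segment
containing the sun, and the diffuse flux through the SOC-weighted average
gap fraction of the whole sky,

    PARt = direct · G(sun segment) + diffuse · Σ_seg w_seg · G_seg.

Crown light interception is expressed as the percentage of incident PAR
intercepted, PARi = 100 · (PARs − PARt) / PARs.

Diurnal courses run hourly from 0600 to 1800 local time; annual figures
sample every 4th day of the (leap) year 2012 and accumulate PAR over the
same hour window.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SiteConfig, SkyConfig
from .hemiphoto import CrownStructure, SkyGrid
from .solar import IncidentPAR, SolarPosition, incident_par, soc_segment_weights, solar_position

HOURS = tuple(range(6, 19))  # 0600–1800 local, 13 hourly points


def transmitted_par(crown: CrownStructure, sun: SolarPosition,
                    inc: IncidentPAR, weights: np.ndarray | None = None
                    ) -> float:
    """PAR (µmol m⁻² s⁻¹) transmitted to the crown photo point.

    ``weights`` are the SOC segment weights on the crown's grid (computed
    on the fly when omitted).  The sun below the horizon transmits
    nothing.  When the sun occupies a ring that the grid discards from
    structural analyses, its computed gap fraction is still used for the
    direct term — excluding it would zero real early/late-hour light.
    """
    grid = crown.grid
    if weights is None:
        weights = soc_segment_weights(grid)
    if weights.shape != (grid.n_zenith, grid.n_azimuth):
        raise ValueError("SOC weight array does not match the crown's grid")
    if sun.elevation <= 0.0:
        return 0.0
    g = crown.gap_matrix()
    ring = grid.ring_of(sun.zenith)
    sl = grid.slice_of(sun.azimuth)
    g_sun = g[ring, sl]
    if math.isnan(g_sun):
        g_sun = np.nanmean(g[ring])  # missing segment: ring-mean fallback
    gm = np.where(np.isnan(g), np.nanmean(g), g)
    diffuse_t = float((weights * gm).sum())
    return float(inc.direct * g_sun + inc.diffuse * diffuse_t)


def interception_percent(par_incident: float, par_transmitted: float) -> float:
    """Percentage of incident PAR intercepted by the crown."""
    if par_incident <= 0.0:
        return math.nan
    return 100.0 * (par_incident - par_transmitted) / par_incident


def diurnal_course(crown: CrownStructure, site: SiteConfig, sky: SkyConfig,
                   day_of_year: int, hours=HOURS) -> pd.DataFrame:
    """Hourly PARs, PARt and PARi for one day (NaN while the sun is down)."""
    weights = soc_segment_weights(crown.grid)
    rows = []
    for h in hours:
        sun = solar_position(site, day_of_year, float(h))
        inc = incident_par(site, sky, day_of_year, float(h))
        part = transmitted_par(crown, sun, inc, weights)
        rows.append({"hour": h, "elevation": sun.elevation,
                     "pars": inc.total, "part": part,
                     "pari": interception_percent(inc.total, part)})
    return pd.DataFrame(rows)


def sampled_days(year: int = 2012, step_days: int = 4) -> np.ndarray:
    """The every-``step_days`` day-of-year grid starting January 1."""
    n = 366 if _is_leap(year) else 365
    return np.arange(1, n + 1, step_days)


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def _month_of_day(day_of_year: int, year: int) -> int:
    return (_dt.date(year, 1, 1) + _dt.timedelta(days=int(day_of_year) - 1)).month


def monthly_average_day(crown: CrownStructure, site: SiteConfig,
                        sky: SkyConfig, year: int = 2012,
                        step_days: int = 4, hours=HOURS) -> pd.DataFrame:
    """Month x hour matrix of mean PARi over the sampled days.

    Rows are months 1–12, columns the hourly points; each cell averages
    the hourly PARi over the sampled days falling in that month.
    """
    weights = soc_segment_weights(crown.grid)
    days = sampled_days(year, step_days)
    acc = np.zeros((12, len(hours)))
    cnt = np.zeros((12, len(hours)))
    for d in days:
        m = _month_of_day(d, year) - 1
        for j, h in enumerate(hours):
            sun = solar_position(site, int(d), float(h))
            inc = incident_par(site, sky, int(d), float(h))
            if inc.total <= 0:
                continue
            part = transmitted_par(crown, sun, inc, weights)
            acc[m, j] += interception_percent(inc.total, part)
            cnt[m, j] += 1
    with np.errstate(invalid="ignore"):
        mat = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return pd.DataFrame(mat, index=pd.RangeIndex(1, 13, name="month"),
                        columns=pd.Index(hours, name="hour"))


def month_average_course(crown: CrownStructure, site: SiteConfig,
                         sky: SkyConfig, month: int, year: int = 2012,
                         step_days: int = 4, hours=HOURS) -> pd.DataFrame:
    """Hourly PARi averaged over the sampled days of one month."""
    mat = monthly_average_day(crown, site, sky, year, step_days, hours)
    return pd.DataFrame({"hour": list(hours), "pari": mat.loc[month].values})


@dataclass(frozen=True)
class AnnualSummary:
    """Annual cumulative interception and its month x hour breakdown."""

    annual_interception: float
    sampled_days: np.ndarray
    monthly_matrix: pd.DataFrame


def annual_interception(crown: CrownStructure, site: SiteConfig,
                        sky: SkyConfig, year: int = 2012,
                        step_days: int = 4, hours=HOURS) -> float:
    """Annual cumulative PARi / annual cumulative PARs x 100.

    Sums PARs and PARs − PARt over every sampled day and hourly point of
    the 0600–1800 window.
    """
    weights = soc_segment_weights(crown.grid)
    pars_sum = 0.0
    intercepted_sum = 0.0
    for d in sampled_days(year, step_days):
        for h in hours:
            sun = solar_position(site, int(d), float(h))
            inc = incident_par(site, sky, int(d), float(h))
            if inc.total <= 0:
                continue
            part = transmitted_par(crown, sun, inc, weights)
            pars_sum += inc.total
            intercepted_sum += inc.total - part
    if pars_sum == 0.0:
        return math.nan
    return 100.0 * intercepted_sum / pars_sum


def annual_summary(crown: CrownStructure, site: SiteConfig, sky: SkyConfig,
                   year: int = 2012, step_days: int = 4) -> AnnualSummary:
    return AnnualSummary(
        annual_interception=annual_interception(crown, site, sky, year,
                                                step_days),
        sampled_days=sampled_days(year, step_days),
        monthly_matrix=monthly_average_day(crown, site, sky, year, step_days),
    )


def plot_monthly_contour(matrix: pd.DataFrame, ax=None):
    """Month x hour filled-contour plot of mean PARi (lazy matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    cs = ax.contourf(matrix.columns.values, matrix.index.values,
                     matrix.values, levels=12, cmap="viridis")
    ax.set_xlabel("hour of day")
    ax.set_ylabel("month")
    ax.figure.colorbar(cs, ax=ax, label="PARi (%)")
    return ax
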