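"""Leaf position geometry and the silhouette-to-area ratio (STAR).

A leaf's position is recorded in the field by three angles: pitch (the
angular elevation of the midrib relative to the horizontal), roll (the
rotation of the lamina around the midrib) and course (the azimuth,
degrees clockwise from North, of the vector normal to the lamina).  The
lamina's tilt from the horizontal plane follows from pitch and roll as

    tilt = arccos(cos(pitch) · cos(roll)),    tilt in [0°, 90°],

which is also the zenith angle of the lamina normal.  The silhouette to
total leaf area ratio (STAR, %) of a flat one-sided lamina facing a
directional source at solar elevation gamma_s and azimuth alpha_s is the
cosine of the incidence angle,

    cos(theta_i) = cos(tilt) sin(gamma_s)
                 + sin(tilt) cos(gamma_s) cos(alpha_s − alpha_l),
    STAR = 100 · max(0, cos(theta_i)),

clamped at zero because the adaxial surface cannot receive direct light
from behind (``one_sided=False`` takes the absolute value instead, the
bifacial alternative).  STAR ignores leaf overlap and clumping: it is an
upper bound on leaf exposure to the direct beam.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SiteConfig
from .solar import SolarPosition, solar_position

HOURS = tuple(range(6, 19))

LEAF_COLUMNS = ("tree_id", "sector", "pitch_deg", "roll_deg", "course_deg")
SECTORS = ("A", "N", "E", "S", "W")


def leaf_tilt(pitch: np.ndarray | float, roll: np.ndarray | float
              ) -> np.ndarray | float:
    """Lamina tilt from the horizontal (degrees in [0, 90])."""
    pitch = np.asarray(pitch, dtype=float)
    roll = np.asarray(roll, dtype=float)
    if np.any(np.abs(pitch) > 90) or np.any(np.abs(roll) > 90):
        raise ValueError("pitch and roll must lie in [-90, 90] degrees")
    c = np.cos(np.radians(pitch)) * np.cos(np.radians(roll))
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))[()]


def tilt180(pitch: np.ndarray | float, roll: np.ndarray | float,
            tip_up: np.ndarray | bool | None = None) -> np.ndarray | float:
    """Tilt on the 0–180° display convention.

    0° is a vertical leaf with the tip toward the zenith, 90° horizontal,
    180° vertical with the tip pointing down.  The tip direction defaults
    to the sign of the pitch (non-negative pitch = tip up), the convention
    under which the field data are entered.
    """
    t = np.asarray(leaf_tilt(pitch, roll), dtype=float)
    if tip_up is None:
        tip_up = np.asarray(pitch, dtype=float) >= 0
    tip_up = np.asarray(tip_up, dtype=bool)
    return np.where(tip_up, 90.0 - t, 90.0 + t)[()]


def star(tilt: np.ndarray | float, course: np.ndarray | float,
         sun: SolarPosition, one_sided: bool = True) -> np.ndarray | float:
    """STAR (%) of a lamina with the given tilt and course under ``sun``."""
    tilt = np.asarray(tilt, dtype=float)
    course = np.asarray(course, dtype=float)
    if np.any(tilt < 0) or np.any(tilt > 90):
        raise ValueError("tilt must lie in [0, 90] degrees")
    if sun.elevation <= 0.0:
        return np.zeros_like(tilt)[()]
    gs = math.radians(sun.elevation)
    cos_inc = (np.cos(np.radians(tilt)) * math.sin(gs)
               + np.sin(np.radians(tilt)) * math.cos(gs)
               * np.cos(np.radians(sun.azimuth - course)))
    exposed = np.abs(cos_inc) if not one_sided else np.maximum(cos_inc, 0.0)
    return (100.0 * exposed)[()]


def read_leaves(path: str | Path) -> pd.DataFrame:
    """Read a leaf-angle CSV and append the derived tilt columns.

    Expects columns ``tree_id, sector, pitch_deg, roll_deg, course_deg``;
    adds ``tilt_deg`` (0–90 convention) and ``tilt180_deg``.
    """
    df = pd.read_csv(path)
    missing = [c for c in LEAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"leaf CSV missing columns: {missing}")
    return add_derived_angles(df)


def add_derived_angles(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["tilt_deg"] = leaf_tilt(df["pitch_deg"].values, df["roll_deg"].values)
    df["tilt180_deg"] = tilt180(df["pitch_deg"].values, df["roll_deg"].values)
    df["course_deg"] = df["course_deg"] % 360.0
    return df


def star_table(leaves: pd.DataFrame, site: SiteConfig, day_of_year: int,
               hours=HOURS, one_sided: bool = True) -> pd.DataFrame:
    """Per-leaf STAR at each hour (long format)."""
    if "tilt_deg" not in leaves.columns:
        leaves = add_derived_angles(leaves)
    frames = []
    for h in hours:
        sun = solar_position(site, day_of_year, float(h))
        vals = star(leaves["tilt_deg"].values, leaves["course_deg"].values,
                    sun, one_sided=one_sided)
        frames.append(pd.DataFrame({
            "hour": h,
            "tree_id": leaves["tree_id"].values,
            "sector": leaves["sector"].values,
            "star": np.atleast_1d(vals),
        }))
    return pd.concat(frames, ignore_index=True)


def diurnal_star(leaves: pd.DataFrame, site: SiteConfig, day_of_year: int,
                 hours=HOURS, by: str = "tree", one_sided: bool = True
                 ) -> pd.DataFrame:
    """Mean diurnal STAR curves aggregated per tree (or sector, or leaf).

    Returns a wide table: one ``hour`` column and one column per group
    holding the group's mean STAR at that hour.
    """
    if leaves.empty:
        raise ValueError("no leaves to aggregate")
    table = star_table(leaves, site, day_of_year, hours, one_sided)
    key = {"tree": "tree_id", "sector": "sector"}.get(by)
    if by == "leaf":
        table["leaf"] = table.groupby("hour").cumcount()
        key = "leaf"
    elif key is None:
        raise ValueError(f"unknown aggregation level {by!r}")
    wide = table.pivot_table(index="hour", columns=key, values="star",
                             aggfunc="mean")
    return wide.reset_index()
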