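"""Site and sky configuration objects.

A :class:`SiteConfig` locates the stand on the globe (needed for solar
geometry) and a :class:`SkyConfig` holds the radiation constants of the
incident-PAR model: the broadband atmospheric transmittance of the direct
beam, the diffuse:direct PAR ratio, and the extraterrestrial PAR flux.
Both are plain frozen dataclasses and can be round-tripped through a small
JSON file (``{"site": {...}, "sky": {...}}``).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class SiteConfig:
    """Geographic location and clock convention of the study site.

    Parameters
    ----------
    latitude : float
        Degrees north of the equator, in ``[-90, 90]``.
    longitude : float
        Degrees east of Greenwich, in ``[-180, 180]`` (west negative).
    altitude : float
        Metres above sea level; used for the barometric air-mass correction.
    utc_offset : float
        Hours of the local civil clock relative to UTC (e.g. ``-5``).
    """

    latitude: float
    longitude: float
    altitude: float = 0.0
    utc_offset: float = 0.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass(frozen=True)
class SkyConfig:
    """Radiation constants of the clear-sky incident-PAR model.

    ``tau`` is the broadband atmospheric transmittance applied per unit of
    optical air mass; ``diffuse_direct_ratio`` converts direct to diffuse
    PAR; ``par_extraterrestrial`` is the top-of-atmosphere PAR photon flux
    on a surface normal to the beam (µmol m⁻² s⁻¹).

    ``diffuse_mode`` selects how the diffuse:direct ratio is applied:
    ``"instantaneous"`` multiplies the ratio onto the horizontal direct
    component at the same instant; ``"daily"`` constrains the *daily
    integral* of diffuse to the ratio times the daily direct integral while
    keeping the diffuse diurnal shape proportional to sin(solar elevation).
    """

    tau: float = 0.63
    diffuse_direct_ratio: float = 0.44
    par_extraterrestrial: float = 2400.0
    diffuse_mode: str = "instantaneous"

    def __post_init__(self) -> None:
        if not 0.0 < self.tau <= 1.0:
            raise ValueError(f"tau {self.tau} outside (0, 1]")
        if self.diffuse_direct_ratio < 0.0:
            raise ValueError("diffuse_direct_ratio must be >= 0")
        if self.par_extraterrestrial <= 0.0:
            raise ValueError("par_extraterrestrial must be > 0")
        if self.diffuse_mode not in ("instantaneous", "daily"):
            raise ValueError("diffuse_mode must be 'instantaneous' or 'daily'")


#: The guava stand on the Popayán plateau (Colombia): 2°23'28" N,
#: 76°39'24" W, 1760 m a.s.l., civil clock UTC-5.
GUAVA_SITE = SiteConfig(latitude=2.391, longitude=-76.657, altitude=1760.0,
                        utc_offset=-5.0)

#: Radiation constants used for that site.
GUAVA_SKY = SkyConfig()


def load_config(path: str | Path) -> tuple[SiteConfig, SkyConfig]:
    """Read ``{"site": {...}, "sky": {...}}`` JSON; missing keys default."""
    with open(path) as fh:
        raw = json.load(fh)
    site = SiteConfig(**raw.get("site", {}))
    sky = SkyConfig(**raw.get("sky", {}))
    return site, sky


def save_config(site: SiteConfig, sky: SkyConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"site": asdict(site), "sky": asdict(sky)}, fh, indent=2)
        fh.write("\n")
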