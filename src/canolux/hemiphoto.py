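"""Hemispherical-photograph analysis.

An upward-looking fisheye photograph with an equidistant projection maps
the sky hemisphere onto a disc: zenith angle grows linearly with distance
from the optical centre (90° at the image-circle rim) and azimuth runs
clockwise from North at the image top.  The sky is partitioned into an
azimuth-by-zenith grid of segments (default 24 x 10 = 240; the lowest
ring, 81–90°, is discarded from structural analyses because it is prone
to optical errors, leaving 216 used segments).

Per segment this module computes

* the gap fraction G — the fraction of segment pixels classified as sky
  after a fixed-threshold binarization (default threshold 131 on 0–255
  grey levels), and
* the foliage clumping index Ω — a gap-size-distribution estimator in
  the Chen–Cihlar/Leblanc gap-removal family: gaps larger than a random
  (Poisson) canopy of equivalent leaf area would produce are iteratively
  removed, and

      Ω = [ln(Fm) / ln(Fmr)] · [(1 − Fmr) / (1 − Fm)],

  with Fm the measured total gap fraction along the transects and Fmr the
  reduced gap fraction after removal.  Ω = 1 indicates random foliage,
  Ω < 1 clumped foliage.

Gap sizes are measured as angular run lengths of sky pixels along
concentric pixel arcs (azimuthal transects) inside each segment.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# geometry containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HemiImage:
    """A grayscale fisheye photograph plus its circle geometry.

    ``center`` is the (x, y) pixel of the optical axis, ``radius`` the
    image-circle radius in pixels (zenith 90°), ``north_offset`` the
    azimuth (degrees clockwise) of the direction mapped to the image top.
    """

    pixels: np.ndarray
    center: tuple[float, float]
    radius: float
    north_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("hemispherical image must be 2-D grayscale")
        if self.radius <= 0:
            raise ValueError("image-circle radius must be > 0")
        h, w = self.pixels.shape
        cx, cy = self.center
        if (cx - self.radius < -0.5 or cx + self.radius > w - 0.5
                or cy - self.radius < -0.5 or cy + self.radius > h - 0.5):
            raise ValueError("image circle does not fit within the raster")

    @classmethod
    def from_array(cls, pixels: np.ndarray, north_offset: float = 0.0
                   ) -> "HemiImage":
        """Wrap a square array, inferring centre and radius from its shape."""
        h, w = pixels.shape
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        return cls(pixels=pixels, center=(cx, cy),
                   radius=min(cx, cy), north_offset=north_offset)

    @classmethod
    def from_file(cls, path: str | Path, meta: str | Path | None = None
                  ) -> "HemiImage":
        """Read a PNG/TIFF image and an optional JSON geometry sidecar.

        The sidecar may define ``cx, cy, radius, north_offset``; without it
        the geometry is inferred from the raster shape.
        """
        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            raise ValueError(f"{path}: expected a grayscale image, got "
                             f"{arr.shape[-1]} channels")
        img = cls.from_array(arr)
        if meta is not None:
            with open(meta) as fh:
                m = json.load(fh)
            img = cls(pixels=arr,
                      center=(m.get("cx", img.center[0]),
                              m.get("cy", img.center[1])),
                      radius=m.get("radius", img.radius),
                      north_offset=m.get("north_offset", img.north_offset))
        return img

    def save(self, path: str | Path, meta: str | Path | None = None) -> None:
        iio.imwrite(path, self.pixels.astype(np.uint8))
        if meta is not None:
            with open(meta, "w") as fh:
                json.dump({"cx": self.center[0], "cy": self.center[1],
                           "radius": self.radius,
                           "north_offset": self.north_offset}, fh)
                fh.write("\n")


@dataclass(frozen=True)
class SkyGrid:
    """The azimuth-by-zenith partition of the sky hemisphere.

    Defaults: 24 equiangular azimuth slices x 10 zenith rings of 9° each,
    i.e. 240 segments, with the lowest ring (81–90°, ring index 9)
    discarded from structural analyses, leaving 216 used segments.
    """

    n_azimuth: int = 24
    n_zenith: int = 10
    discarded_rings: frozenset[int] = frozenset({9})

    def __post_init__(self) -> None:
        if self.n_azimuth < 1 or self.n_zenith < 1:
            raise ValueError("grid dimensions must be positive")
        if any(r < 0 or r >= self.n_zenith for r in self.discarded_rings):
            raise ValueError("discarded ring index outside the grid")

    @property
    def n_segments(self) -> int:
        return self.n_azimuth * self.n_zenith

    @property
    def n_used(self) -> int:
        return (self.n_zenith - len(self.discarded_rings)) * self.n_azimuth

    @property
    def ring_width(self) -> float:
        return 90.0 / self.n_zenith

    @property
    def slice_width(self) -> float:
        return 360.0 / self.n_azimuth

    @property
    def zenith_edges(self) -> np.ndarray:
        return np.linspace(0.0, 90.0, self.n_zenith + 1)

    @property
    def azimuth_edges(self) -> np.ndarray:
        return np.linspace(0.0, 360.0, self.n_azimuth + 1)

    def ring_of(self, zenith: np.ndarray | float) -> np.ndarray | int:
        """Ring index of a zenith angle; zenith 90° folds into the last ring."""
        idx = np.floor(np.asarray(zenith) / self.ring_width).astype(int)
        return np.clip(idx, 0, self.n_zenith - 1)[()]

    def slice_of(self, azimuth: np.ndarray | float) -> np.ndarray | int:
        idx = np.floor((np.asarray(azimuth) % 360.0)
                       / self.slice_width).astype(int)
        return np.clip(idx, 0, self.n_azimuth - 1)[()]


# ---------------------------------------------------------------------------
# projection and binarization
# ---------------------------------------------------------------------------

def pixel_to_sky(x: np.ndarray | float, y: np.ndarray | float,
                 image: HemiImage) -> tuple[np.ndarray, np.ndarray]:
    """(zenith, azimuth) in degrees for pixel coordinates.

    Equidistant projection: zenith = 90° · r / radius.  Azimuth is 0° at
    the image top (North by default), increasing clockwise; raises for
    pixels outside the image circle.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx, dy = x - image.center[0], y - image.center[1]
    r = np.hypot(dx, dy)
    if np.any(r > image.radius * (1 + 1e-9)):
        raise ValueError("pixel outside the image circle")
    zen = 90.0 * r / image.radius
    az = (np.degrees(np.arctan2(dx, -dy)) + image.north_offset) % 360.0
    return zen[()], az[()]


def sky_to_pixel(zenith: np.ndarray | float, azimuth: np.ndarray | float,
                 image: HemiImage) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`pixel_to_sky` (continuous coordinates)."""
    zen = np.asarray(zenith, dtype=float)
    az = np.radians(np.asarray(azimuth, dtype=float) - image.north_offset)
    r = image.radius * zen / 90.0
    x = image.center[0] + r * np.sin(az)
    y = image.center[1] - r * np.cos(az)
    return x[()], y[()]


@dataclass(frozen=True)
class SkyMask:
    """Binarized photograph: boolean sky map plus the circle geometry."""

    sky: np.ndarray
    valid: np.ndarray
    image: HemiImage

    @property
    def gap_fraction(self) -> float:
        """Global gap fraction over the image circle."""
        return float(self.sky[self.valid].mean())


def binarize(image: HemiImage, threshold: int = 131) -> SkyMask:
    """Threshold the photograph into sky (grey level > threshold) and
    vegetation; pixels outside the image circle are flagged invalid."""
    px = image.pixels
    if px.ndim != 2:
        raise ValueError("binarize expects a 2-D grayscale image")
    h, w = px.shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(xx - image.center[0], yy - image.center[1])
    valid = r <= image.radius
    sky = (px > threshold) & valid
    return SkyMask(sky=sky, valid=valid, image=image)


# ---------------------------------------------------------------------------
# per-segment gap fraction
# ---------------------------------------------------------------------------

def _segment_index_maps(mask: SkyMask, grid: SkyGrid
                        ) -> tuple[np.ndarray, np.ndarray]:
    h, w = mask.sky.shape
    yy, xx = np.mgrid[0:h, 0:w]
    img = mask.image
    dx, dy = xx - img.center[0], yy - img.center[1]
    r = np.hypot(dx, dy)
    zen = 90.0 * np.minimum(r, img.radius) / img.radius
    az = (np.degrees(np.arctan2(dx, -dy)) + img.north_offset) % 360.0
    ring = np.clip((zen / grid.ring_width).astype(int), 0, grid.n_zenith - 1)
    sl = np.clip((az / grid.slice_width).astype(int), 0, grid.n_azimuth - 1)
    return ring, sl


def segment_gap_fraction(mask: SkyMask, grid: SkyGrid = SkyGrid()
                         ) -> pd.DataFrame:
    """Gap fraction per sky segment.

    Returns one row per segment with ring/slice indices, angular bounds,
    ``pixel_count``, ``sky_count``, ``gap_fraction`` (NaN when the segment
    holds no valid pixels) and a ``used`` flag that is False for segments
    in discarded rings.
    """
    ring, sl = _segment_index_maps(mask, grid)
    seg = ring * grid.n_azimuth + sl
    n = grid.n_segments
    valid_flat = mask.valid.ravel()
    total = np.bincount(seg.ravel()[valid_flat], minlength=n)
    sky = np.bincount(seg.ravel()[valid_flat],
                      weights=mask.sky.ravel()[valid_flat], minlength=n)
    rings = np.repeat(np.arange(grid.n_zenith), grid.n_azimuth)
    slices = np.tile(np.arange(grid.n_azimuth), grid.n_zenith)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(total > 0, sky / np.maximum(total, 1), np.nan)
    return pd.DataFrame({
        "ring": rings,
        "slice": slices,
        "zenith_lo": grid.zenith_edges[rings],
        "zenith_hi": grid.zenith_edges[rings + 1],
        "azimuth_lo": grid.azimuth_edges[slices],
        "azimuth_hi": grid.azimuth_edges[slices + 1],
        "pixel_count": total.astype(int),
        "sky_count": sky,
        "gap_fraction": g,
        "used": ~np.isin(rings, list(grid.discarded_rings)),
    })


# ---------------------------------------------------------------------------
# gap runs along concentric arcs
# ---------------------------------------------------------------------------

def _arc_samples(mask: SkyMask, grid: SkyGrid):
    """Sample the sky mask along concentric pixel arcs.

    Yields ``(ring, step_deg, sky_bool_by_slice)`` per arc radius: the
    mask sampled at ~1-pixel arc spacing over the full circle, split into
    azimuth slices.  Used by both gap-run extraction and the clumping
    index.
    """
    img = mask.image
    for r_px in range(1, int(math.floor(img.radius)) + 1):
        ring = min(int((90.0 * r_px / img.radius) / grid.ring_width),
                   grid.n_zenith - 1)
        # angular step giving ~1 px spacing along the arc, snapped so the
        # slice width holds an integer number of samples
        n_per_slice = max(1, round(math.radians(grid.slice_width) * r_px))
        step = grid.slice_width / n_per_slice
        az = (np.arange(grid.n_azimuth * n_per_slice) + 0.5) * step
        theta = np.radians(az - img.north_offset)
        x = np.rint(img.center[0] + r_px * np.sin(theta)).astype(int)
        y = np.rint(img.center[1] - r_px * np.cos(theta)).astype(int)
        x = np.clip(x, 0, mask.sky.shape[1] - 1)
        y = np.clip(y, 0, mask.sky.shape[0] - 1)
        sky = mask.sky[y, x].reshape(grid.n_azimuth, n_per_slice)
        yield ring, step, sky


def _runs_from_bool(arr: np.ndarray) -> np.ndarray:
    """Lengths (in samples) of maximal runs of True."""
    if arr.size == 0:
        return np.empty(0, dtype=int)
    padded = np.concatenate(([False], arr, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return ends - starts


@dataclass
class SegmentRuns:
    """Gap runs pooled over the concentric arcs crossing one segment."""

    runs: list[float] = field(default_factory=list)
    total_deg: float = 0.0
    step_sum: float = 0.0
    n_arcs: int = 0

    @property
    def mean_step(self) -> float:
        """Mean angular sampling quantum (degrees) of the segment's arcs.

        The coarse quantum of short inner arcs limits the smallest gap
        the transects can resolve; the clumping estimator widens its
        element width to this resolution limit.
        """
        return self.step_sum / self.n_arcs if self.n_arcs else math.nan


def gap_runs(mask: SkyMask, grid: SkyGrid = SkyGrid()
             ) -> dict[tuple[int, int], SegmentRuns]:
    """Angular gap runs per segment.

    Returns ``{(ring, slice): SegmentRuns}`` where the runs are the
    angular lengths of maximal sky runs along each concentric arc
    crossing the segment (runs are never merged across arcs) and
    ``total_deg`` is the total transect length sampled in the segment.
    """
    out: dict[tuple[int, int], SegmentRuns] = {
        (r, s): SegmentRuns()
        for r in range(grid.n_zenith) for s in range(grid.n_azimuth)
    }
    for ring, step, sky in _arc_samples(mask, grid):
        for sl in range(grid.n_azimuth):
            rec = out[(ring, sl)]
            arc = sky[sl]
            lens = _runs_from_bool(arc)
            rec.runs.extend((lens * step).tolist())
            rec.total_deg += arc.size * step
            rec.step_sum += step
            rec.n_arcs += 1
    return out


# ---------------------------------------------------------------------------
# clumping index
# ---------------------------------------------------------------------------

def _random_canopy_curve(lam: np.ndarray, lp: float, wp: float) -> np.ndarray:
    """Accumulated gap fraction F(lambda) of a random canopy with projected
    leaf area index ``lp`` and element width ``wp`` (same angular units as
    ``lam``); F(0) = exp(-lp)."""
    x = lam / wp
    return (1.0 + lp * x) * np.exp(-lp * (1.0 + x))


def clumping_index_cc(runs: list[float] | np.ndarray, total_length: float,
                      element_width: float = 2.0) -> float:
    """Gap-size-distribution clumping index (gap-removal estimator).

    Parameters
    ----------
    runs : sequence of float
        Angular lengths of the measured gaps along the transects.
    total_length : float
        Total transect length sampled, same units as ``runs``.
    element_width : float
        Characteristic width of a foliage element projected on the
        transect (angular degrees); sets the scale of the random-canopy
        reference curve.

    Returns NaN for fully open, fully closed or empty segments (the
    estimator is undefined there); callers exclude NaN from summaries.
    """
    if total_length <= 0:
        return math.nan
    gaps = np.sort(np.asarray(runs, dtype=float))[::-1]
    fm = gaps.sum() / total_length
    if not 0.0 < fm < 1.0 or gaps.size == 0:
        return math.nan
    kept = gaps.copy()
    fmr = fm
    # Iteratively remove the largest gap whenever the measured accumulated
    # gap fraction at that size exceeds the random-canopy expectation.
    # Only gaps wider than one foliage element are candidates: narrower
    # runs cannot be between-crown gaps, and the accumulated curves of
    # any canopy converge as lambda -> 0.
    while kept.size > 0:
        lp = -math.log(fmr)
        lam = kept[0]
        if lam <= element_width:
            break
        # accumulated gap fraction at lam: length in gaps of size >= lam
        measured = kept[kept >= lam * (1 - 1e-12)].sum() / total_length
        expected = _random_canopy_curve(np.array([lam]), lp, element_width)[0]
        if measured > expected:
            kept = kept[1:]
            fmr = kept.sum() / total_length
            if fmr <= 0.0:
                # pathological: everything removed; treat as maximally clumped
                fmr = min(fm, 1e-6)
                break
        else:
            break
    if fmr == fm:
        return 1.0
    return (math.log(fm) / math.log(fmr)) * ((1.0 - fmr) / (1.0 - fm))


# ---------------------------------------------------------------------------
# crown-level summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrownStructure:
    """Per-segment structure table and whole-crown summaries.

    ``segments`` has one row per grid segment (gap fraction, clumping,
    used flag); ``ci_cv`` is the coefficient of variation of the clumping
    index over the used, non-missing segments; ``grid`` the partition the
    table refers to.
    """

    segments: pd.DataFrame
    grid: SkyGrid
    element_width: float

    @property
    def ci_cv(self) -> float:
        om = self.segments.loc[self.segments["used"], "clumping"].dropna()
        if om.empty or om.mean() == 0:
            return math.nan
        return float(om.std(ddof=1) / om.mean())

    def gap_matrix(self) -> np.ndarray:
        """(n_zenith, n_azimuth) gap-fraction array over all rings."""
        g = np.full((self.grid.n_zenith, self.grid.n_azimuth), np.nan)
        g[self.segments["ring"], self.segments["slice"]] = \
            self.segments["gap_fraction"]
        return g

    def ring_summary(self, eight_bands: bool = False) -> pd.DataFrame:
        """Mean and SD of gap fraction and clumping per used zenith ring.

        With ``eight_bands=True`` the two lowest used rings are merged so
        the table has 8 zenith bands instead of 9 (an alternative
        convention for displaying the used 0–81° range).
        """
        df = self.segments[self.segments["used"]].copy()
        df["band"] = df["ring"]
        if eight_bands:
            used_rings = sorted(df["ring"].unique())
            if len(used_rings) >= 2:
                lo = used_rings[-2:]
                df.loc[df["ring"].isin(lo), "band"] = lo[0]
        rows = []
        for band, grp in df.groupby("band"):
            rows.append({
                "band": int(band),
                "zenith_lo": grp["zenith_lo"].min(),
                "zenith_hi": grp["zenith_hi"].max(),
                "gap_mean": grp["gap_fraction"].mean(),
                "gap_sd": grp["gap_fraction"].std(ddof=1),
                "clumping_mean": grp["clumping"].mean(),
                "clumping_sd": grp["clumping"].std(ddof=1),
                "n_segments": len(grp),
                "n_clumping": int(grp["clumping"].notna().sum()),
            })
        return pd.DataFrame(rows).sort_values("band").reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.segments.to_csv(path, index=False)


def crown_structure(mask: SkyMask, grid: SkyGrid = SkyGrid(),
                    element_width: float = 2.0) -> CrownStructure:
    """Full per-segment analysis of a binarized hemispherical photograph."""
    seg = segment_gap_fraction(mask, grid)
    runs = gap_runs(mask, grid)
    clump = np.full(len(seg), np.nan)
    for i, (ring, sl) in enumerate(zip(seg["ring"], seg["slice"])):
        rec = runs[(int(ring), int(sl))]
        # the element width cannot be narrower than the transects resolve
        wp_eff = max(element_width, rec.mean_step)
        clump[i] = clumping_index_cc(rec.runs, rec.total_deg, wp_eff)
    seg = seg.assign(clumping=clump)
    return CrownStructure(segments=seg, grid=grid,
                          element_width=element_width)


def analyze_image(path: str | Path, meta: str | Path | None = None,
                  threshold: int = 131, element_width: float = 2.0,
                  grid: SkyGrid = SkyGrid()) -> CrownStructure:
    """Convenience: read, binarize and summarize a photograph."""
    img = HemiImage.from_file(path, meta)
    return crown_structure(binarize(img, threshold), grid, element_width)
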