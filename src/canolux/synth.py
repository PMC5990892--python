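"""Synthetic study generator with known ground truth.

Creates the raw materials of a crown light-interception field study —
binary-valued fisheye canopy photographs with a prescribed per-ring gap
fraction and clumping regime, and leaf-angle tables drawn from von Mises
distributions — together with truth tables recording what was generated,
so every estimator in the package can be validated on data whose answer
is known.

The default :class:`StudyDesign` emulates a 9-tree study: per tree one
crown photograph and 5 leaf sectors (central top A plus the basal N, E,
S, W) x 10 leaves = 50 leaves, 450 in total; leaf tilt centred near 45°
with moderate concentration, lamina course centred on south (180°) with
high dispersion.  Crowns are "doughnut"-shaped: open, clumped tops over
dense, randomly-foliated lateral rings — the top's extra openness and
clumping default to the 46.1% / 51.4% ring contrasts of the motivating
field study.

Foliage regimes per ring:

* ``random`` — each pixel is vegetation independently with probability
  1 − G (a Poisson/binomial canopy; clumping index ≈ 1);
* ``clustered`` — vegetation is laid down as randomly-centred angular
  blobs (a Neyman–Scott-style Boolean process) whose count is chosen so
  the expected coverage matches the same G but with super-random gap
  sizes (clumping index < 1).  The blob angular radius is the clumping
  knob.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .circstats import sample_vonmises
from .config import GUAVA_SITE, GUAVA_SKY, SiteConfig, SkyConfig, save_config
from .hemiphoto import HemiImage, SkyGrid, binarize, segment_gap_fraction

SKY_LEVEL = 255
VEG_LEVEL = 0


@dataclass(frozen=True)
class CrownTruth:
    """Per-ring generation targets for one crown photograph.

    ``ring_gap`` are target gap fractions per zenith ring; rings with a
    positive ``ring_cluster_scale`` (blob angular radius, degrees) use
    the clustered regime, the rest the random regime.
    """

    ring_gap: np.ndarray
    ring_cluster_scale: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.ring_gap, dtype=float)
        if np.any(g < 0) or np.any(g > 1):
            raise ValueError("ring gap-fraction targets must lie in [0, 1]")
        if len(self.ring_gap) != len(self.ring_cluster_scale):
            raise ValueError("ring_gap and ring_cluster_scale lengths differ")


@dataclass(frozen=True)
class StudyDesign:
    """Shape and distributional knobs of a synthetic study."""

    n_trees: int = 9
    sectors: tuple[str, ...] = ("A", "N", "E", "S", "W")
    leaves_per_sector: int = 10
    tilt_mean: float = 45.0
    tilt_kappa: float = 3.0
    course_mean: float = 180.0
    course_kappa: float = 0.6
    tip_down_prob: float = 0.05
    height_mean: float = 5.45
    height_sd: float = 0.52
    # between-tree spread of top-ring structure (openness contrast and
    # blob angular radius ranges); lateral rings are identical across trees
    openness_contrast_range: tuple[float, float] = (0.15, 1.1)
    cluster_scale_range: tuple[float, float] = (1.0, 8.0)
    base_gap: float = 0.30
    image_size: int = 481

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.leaves_per_sector < 1:
            raise ValueError("counts must be positive")

    @property
    def leaves_per_tree(self) -> int:
        return len(self.sectors) * self.leaves_per_sector

    @property
    def total_leaves(self) -> int:
        return self.n_trees * self.leaves_per_tree


@dataclass
class TreeData:
    tree_id: str
    image: HemiImage
    truth: CrownTruth
    segment_truth: pd.DataFrame
    height: float


@dataclass
class StudyDataset:
    """A full synthetic study bundle with its truth tables."""

    design: StudyDesign
    site: SiteConfig
    sky: SkyConfig
    trees: list[TreeData]
    leaves: pd.DataFrame
    leaf_truth: pd.DataFrame
    seed: int | None = None


# ---------------------------------------------------------------------------
# canopy images
# ---------------------------------------------------------------------------

def _ring_maps(size: int, grid: SkyGrid):
    cx = cy = (size - 1) / 2.0
    radius = cx
    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - cx, yy - cy
    r = np.hypot(dx, dy)
    valid = r <= radius
    zen = 90.0 * np.minimum(r, radius) / radius
    az = np.degrees(np.arctan2(dx, -dy)) % 360.0
    ring = np.clip((zen / grid.ring_width).astype(int), 0, grid.n_zenith - 1)
    return valid, zen, az, ring


def _clustered_ring(zen: np.ndarray, az: np.ndarray, sel: np.ndarray,
                    z_lo: float, z_hi: float, gap: float, scale: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Boolean vegetation map for one ring from an angular blob process."""
    veg = np.zeros(zen.shape, dtype=bool)
    if gap >= 1.0:
        return veg
    if gap <= 0.0:
        veg[sel] = True
        return veg
    z_mid = 0.5 * (z_lo + z_hi)
    sin_m = max(math.sin(math.radians(max(z_mid, 4.0))), 0.05)
    zs, azs = zen[sel], az[sel]
    hit = np.zeros(zs.shape, dtype=bool)
    target_cover = 1.0 - gap
    # sequential Boolean process: drop randomly-centred blobs until the
    # ring reaches its target coverage (centres drawn from a band
    # extended by the blob radius so edge pixels are not thinned); a
    # final blob that would overshoot the target by more than the
    # current shortfall is rejected and redrawn, pinning the realized
    # gap fraction near its target
    max_blobs = 10_000
    rejects = 0
    for _ in range(max_blobs):
        cover = hit.mean() if zs.size else 1.0
        if cover >= target_cover:
            break
        bz = rng.uniform(z_lo - scale, z_hi + scale)
        ba = rng.uniform(0.0, 360.0)
        da = (azs - ba + 180.0) % 360.0 - 180.0
        new = hit | ((zs - bz) ** 2 + (da * sin_m) ** 2 <= scale ** 2)
        new_cover = new.mean()
        if new_cover - target_cover > target_cover - cover and rejects < 50:
            rejects += 1
            continue
        rejects = 0
        hit = new
    veg[sel] = hit
    return veg


def gen_canopy_mask(truth: CrownTruth, image_size: int = 481,
                    seed: int | np.random.Generator | None = None,
                    grid: SkyGrid = SkyGrid()
                    ) -> tuple[HemiImage, pd.DataFrame]:
    """Render a fisheye canopy image for a :class:`CrownTruth`.

    Returns the grayscale image (sky 255, vegetation 0) and a truth table
    with, per segment, the ring's target gap fraction, its regime, and
    the realized pixel gap fraction of the rendered image.
    """
    if len(truth.ring_gap) != grid.n_zenith:
        raise ValueError("truth profile length does not match the grid")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    valid, zen, az, ring = _ring_maps(image_size, grid)
    veg = np.zeros(zen.shape, dtype=bool)
    edges = grid.zenith_edges
    for k in range(grid.n_zenith):
        sel = valid & (ring == k)
        gap = float(truth.ring_gap[k])
        scale = float(truth.ring_cluster_scale[k])
        if scale > 0:
            veg |= _clustered_ring(zen, az, sel, edges[k], edges[k + 1],
                                   gap, scale, rng)
        else:
            veg[sel] = rng.random(int(sel.sum())) > gap
    img_arr = np.full(zen.shape, SKY_LEVEL, dtype=np.uint8)
    img_arr[veg] = VEG_LEVEL
    img_arr[~valid] = VEG_LEVEL
    image = HemiImage.from_array(img_arr)
    seg = segment_gap_fraction(binarize(image, threshold=131), grid)
    table = seg[["ring", "slice", "pixel_count", "used"]].copy()
    table["target_gap"] = np.asarray(truth.ring_gap)[table["ring"]]
    table["regime"] = np.where(
        np.asarray(truth.ring_cluster_scale)[table["ring"]] > 0,
        "clustered", "random")
    table["realized_gap"] = seg["gap_fraction"]
    return image, table


def doughnut_truth(openness_contrast: float = 0.461,
                   clumping_contrast: float = 0.514,
                   base_gap: float = 0.30,
                   grid: SkyGrid = SkyGrid(),
                   cluster_scale_max: float | None = None,
                   ramp_exponent: float = 1.0) -> CrownTruth:
    """Ring profile of a doughnut crown: open, clumped top rings grading
    into dense, random lateral rings.

    ``openness_contrast`` is the fractional extra gap fraction of the
    top rings over the lateral rings (default the 46.1% field contrast);
    ``clumping_contrast`` maps onto the blob angular radius of the
    clustered top rings (default scaled so the 51.4% field contrast
    gives a ~2° blob radius).  The openness profile is a plateau over
    the doughnut hole (rings 0–2, zenith 0–27°, the band the noon sun
    crosses year-round at a near-equatorial site) fading to the lateral
    value by ring 5 — monotone from zenith to horizon.
    """
    if openness_contrast < 0 or clumping_contrast < 0:
        raise ValueError("contrasts must be >= 0")
    if ramp_exponent <= 0:
        raise ValueError("ramp_exponent must be > 0")
    n = grid.n_zenith
    # monotone openness/clumping profile from zenith to horizon; a
    # ramp_exponent < 1 deepens the doughnut hole (rings 0-3) without
    # touching the transition ring or the lateral rings
    ramp = np.array([1.0, 0.85, 0.65, 0.35, 0.1] + [0.0] * (n - 5))[:n]
    ramp[:4] = ramp[:4] ** ramp_exponent
    ring_gap = np.clip(base_gap * (1.0 + openness_contrast * ramp), 0.0, 0.95)
    if cluster_scale_max is None:
        cluster_scale_max = 2.0 * clumping_contrast / 0.514
    scale = cluster_scale_max * ramp
    scale[scale < 1.5] = 0.0        # sub-pixel blobs degenerate to random
    return CrownTruth(ring_gap=ring_gap, ring_cluster_scale=scale)


def gen_doughnut_crown(openness_contrast: float = 0.461,
                       clumping_contrast: float = 0.514,
                       image_size: int = 481,
                       seed: int | np.random.Generator | None = None,
                       base_gap: float = 0.30,
                       grid: SkyGrid = SkyGrid()
                       ) -> tuple[HemiImage, pd.DataFrame]:
    """Render one doughnut crown (see :func:`doughnut_truth`)."""
    truth = doughnut_truth(openness_contrast, clumping_contrast, base_gap,
                           grid)
    return gen_canopy_mask(truth, image_size, seed, grid)


# ---------------------------------------------------------------------------
# leaf populations
# ---------------------------------------------------------------------------

def _tilt_to_pitch_roll(tilt: np.ndarray, tip_up: np.ndarray,
                        rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Random (pitch, roll) pairs realizing the given tilts.

    cos(tilt) = cos(pitch) cos(roll): roll is drawn uniformly within the
    admissible band and pitch solves the identity; pitch sign encodes the
    tip direction.
    """
    roll = rng.uniform(-1.0, 1.0, size=tilt.shape) * tilt
    cp = np.cos(np.radians(tilt)) / np.maximum(np.cos(np.radians(roll)), 1e-9)
    pitch = np.degrees(np.arccos(np.clip(cp, -1.0, 1.0)))
    pitch = np.where(tip_up, pitch, -pitch)
    return pitch, roll


def gen_leaf_population(design: StudyDesign = StudyDesign(),
                        seed: int | np.random.Generator | None = None
                        ) -> pd.DataFrame:
    """Draw the full leaf-angle table of a study design.

    Course angles are von Mises around ``course_mean``; tilt angles are
    von Mises around ``tilt_mean`` truncated by resampling to [0, 90] on
    the field convention, with a small probability of a tip-down leaf.
    Returns one row per leaf with pitch/roll/course plus the derived tilt
    columns.
    """
    from .leaf_star import add_derived_angles

    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    frames = []
    for t in range(design.n_trees):
        tree_id = f"T{t + 1:02d}"
        for sector in design.sectors:
            m = design.leaves_per_sector
            course = sample_vonmises(m, design.course_mean,
                                     design.course_kappa, rng)
            tilt = np.empty(m)
            filled = 0
            while filled < m:
                cand = sample_vonmises(m, design.tilt_mean,
                                       design.tilt_kappa, rng)
                cand = np.where(cand > 180.0, cand - 360.0, cand)
                good = cand[(cand >= 0.0) & (cand <= 90.0)]
                take = min(good.size, m - filled)
                tilt[filled:filled + take] = good[:take]
                filled += take
            tip_up = rng.random(m) >= design.tip_down_prob
            pitch, roll = _tilt_to_pitch_roll(tilt, tip_up, rng)
            frames.append(pd.DataFrame({
                "tree_id": tree_id, "sector": sector,
                "pitch_deg": pitch, "roll_deg": roll,
                "course_deg": course,
            }))
    return add_derived_angles(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# full study bundles
# ---------------------------------------------------------------------------

def gen_study(design: StudyDesign = StudyDesign(),
              seed: int | None = None,
              site: SiteConfig = GUAVA_SITE,
              sky: SkyConfig = GUAVA_SKY,
              grid: SkyGrid = SkyGrid()) -> StudyDataset:
    """Generate a complete synthetic study (crowns, leaves, truth tables).

    Between-tree variation is confined to the top rings: each tree draws
    its own top-ring openness contrast and blob radius from the design's
    ranges (evenly spread, then jittered), while the lateral rings are
    identical across trees.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n = design.n_trees
    # evenly spread top-ring knobs so the study spans the configured ranges
    frac = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
    frac = rng.permutation(frac)
    o_lo, o_hi = design.openness_contrast_range
    s_lo, s_hi = design.cluster_scale_range
    trees: list[TreeData] = []
    for t in range(n):
        truth = doughnut_truth(
            openness_contrast=o_lo + (o_hi - o_lo) * frac[t],
            clumping_contrast=0.514,
            base_gap=design.base_gap, grid=grid,
            cluster_scale_max=s_lo + (s_hi - s_lo) * frac[t],
            ramp_exponent=1.0 / (1.0 + frac[t]))
        image, table = gen_canopy_mask(truth, design.image_size, rng, grid)
        table.insert(0, "tree_id", f"T{t + 1:02d}")
        trees.append(TreeData(
            tree_id=f"T{t + 1:02d}", image=image, truth=truth,
            segment_truth=table,
            height=float(rng.normal(design.height_mean, design.height_sd))))
    leaves = gen_leaf_population(design, rng)
    leaf_truth = pd.DataFrame([{
        "course_mean": design.course_mean, "course_kappa": design.course_kappa,
        "tilt_mean": design.tilt_mean, "tilt_kappa": design.tilt_kappa,
        "tip_down_prob": design.tip_down_prob, "seed": seed,
    }])
    return StudyDataset(design=design, site=site, sky=sky, trees=trees,
                        leaves=leaves, leaf_truth=leaf_truth, seed=seed)


def write_study(dataset: StudyDataset, outdir: str | Path) -> Path:
    """Write a study bundle to disk (PNG + JSON sidecars, CSV, config)."""
    out = Path(outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    for tree in dataset.trees:
        stem = out / f"crown_{tree.tree_id}"
        tree.image.save(stem.with_suffix(".png"), stem.with_suffix(".json"))
        tree.segment_truth.to_csv(out / "truth" / f"{tree.tree_id}_segments.csv",
                                  index=False)
    dataset.leaves.to_csv(out / "leaves.csv", index=False)
    dataset.leaf_truth.to_csv(out / "truth" / "leaf_distribution.csv",
                              index=False)
    heights = pd.DataFrame([{"tree_id": t.tree_id, "height_m": t.height}
                            for t in dataset.trees])
    heights.to_csv(out / "tree_heights.csv", index=False)
    save_config(dataset.site, dataset.sky, out / "site.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump({"n_trees": dataset.design.n_trees,
                   "seed": dataset.seed,
                   "trees": [t.tree_id for t in dataset.trees]}, fh, indent=2)
        fh.write("\n")
    return out
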