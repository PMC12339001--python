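"""The named statistics of the quantification pipeline.

Each function here composes :mod:`mitoquant.images` primitives into one of
the figure-style measurements: perinuclear/perispindle accumulation ratio,
two-blastomere partition measures (symmetry index, inheritance ratio),
cleavage-plane intensity splitting, mitochondrial cluster statistics,
angular non-uniformity around the spindle axis, ROS enrichment inside
mitochondria, masked pixel correlation, and chromosome-track projection.

Interpretation choices (documented because the underlying protocol leaves
them open):

* "Fluorescence intensity" in the ring and enrichment ratios means the
  *mean per-pixel* intensity of each region, so ratios are independent of
  region size.
* The outside-periphery comparison region excludes the organizer mask
  itself, keeping the inner and outer regions disjoint.
* The pixel correlation coefficient is Pearson's r on masked pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .images import (
    BinaryMask,
    DegenerateInputError,
    Image,
    ParameterError,
    dilate_mask,
    gaussian_smooth,
    mask_orientation,
    measure_regions,
    rolling_ball_subtract,
    threshold_moments,
    threshold_yen,
)

__all__ = [
    "RingRatioResult",
    "PartitionMeasures",
    "AngularProfile",
    "TrackProjection",
    "ClusterStatsResult",
    "accumulation_ratio",
    "partition_measures",
    "split_totals_by_plane",
    "cluster_stats",
    "angular_uniformity",
    "ros_enrichment",
    "pixel_correlation",
    "track_projection",
    "embryo_mask_from_mito",
]

N_SECTORS = 6  # 360 deg / 60 deg


@dataclass(frozen=True)
class RingRatioResult:
    """Accumulation of a channel in a ring around an organizer mask."""

    mean_inner: float
    mean_outer: float
    ratio: float
    ring_px: int
    outside_px: int


@dataclass(frozen=True)
class PartitionMeasures:
    """Symmetry of a conserved quantity split between two daughter cells.

    ``symmetry_index`` = greater/smaller (>= 1, 1 = perfect symmetry);
    ``inheritance_ratio`` = smaller/greater (in (0, 1], 1 = perfect
    symmetry). Their product is 1 whenever both are finite.
    """

    total_a: float
    total_b: float
    symmetry_index: float
    inheritance_ratio: float


@dataclass(frozen=True)
class AngularProfile:
    """Sector statistics of a channel around the spindle long axis."""

    axis_angle_rad: float
    sector_means: np.ndarray
    nonuniformity_sd: float
    center_xy: tuple[float, float]
    axis_degenerate: bool = False


@dataclass(frozen=True)
class TrackProjection:
    """A centroid track projected on its net-displacement direction."""

    times: np.ndarray
    positions_xy: np.ndarray
    direction_unit: np.ndarray
    projected_displacements: np.ndarray
    final_distance_to_center_um: float


@dataclass(frozen=True)
class ClusterStatsResult:
    regions: pd.DataFrame
    n_clusters: int
    mean_area_um2: float
    threshold_used: float


def accumulation_ratio(
    mito: Image,
    organizer_mask: BinaryMask,
    cell_mask: BinaryMask,
    ring_width_px: int = 10,
) -> RingRatioResult:
    """Mean channel intensity in a ring around the organizer over the mean outside.

    The ring is the dilation of the organizer mask by ``ring_width_px``
    minus the organizer mask itself; the outside region is the cell mask
    minus the dilated organizer. Ratios near 1 indicate no accumulation at
    the organizer periphery; larger values indicate enrichment there.
    """
    if organizer_mask.shape != mito.shape or cell_mask.shape != mito.shape:
        raise ParameterError("masks must match the image shape")
    dilated = dilate_mask(organizer_mask, ring_width_px)
    ring = dilated.pixels & ~organizer_mask.pixels
    outside = cell_mask.pixels & ~dilated.pixels
    if not ring.any() or not outside.any():
        raise DegenerateInputError("empty ring or outside region")
    mean_inner = float(mito.pixels[ring].mean())
    mean_outer = float(mito.pixels[outside].mean())
    if mean_outer <= 0:
        raise DegenerateInputError("outside region has zero mean intensity")
    return RingRatioResult(
        mean_inner=mean_inner,
        mean_outer=mean_outer,
        ratio=mean_inner / mean_outer,
        ring_px=int(ring.sum()),
        outside_px=int(outside.sum()),
    )


def partition_measures(total_a: float, total_b: float) -> PartitionMeasures:
    """Symmetry index (greater/smaller) and inheritance ratio (smaller/greater).

    Order-invariant in the two totals. A zero total is allowed (fully
    asymmetric partition): the symmetry index is +inf and the inheritance
    ratio 0, with a warning. Negative totals are an error.
    """
    if total_a < 0 or total_b < 0:
        raise ParameterError("totals must be non-negative")
    if total_a == 0 and total_b == 0:
        raise ParameterError("both totals are zero; measures undefined")
    smaller = min(total_a, total_b)
    greater = max(total_a, total_b)
    if smaller == 0:
        warnings.warn("one total is zero: fully asymmetric partition", stacklevel=2)
        return PartitionMeasures(total_a, total_b, np.inf, 0.0)
    return PartitionMeasures(total_a, total_b, greater / smaller, smaller / greater)


def split_totals_by_plane(
    img: Image,
    cell_mask: BinaryMask,
    plane: tuple[tuple[float, float], tuple[float, float]],
) -> tuple[float, float]:
    """Sum the channel on either side of a cleavage line within the cell mask.

    ``plane`` is two distinct (x, y) points defining the line. A pixel at
    (x, y) is assigned by the sign of the 2D cross product
    ``d x (p - p0)``; pixels exactly on the line go to the positive side
    (side A).
    """
    (x0, y0), (x1, y1) = plane
    dx, dy = x1 - x0, y1 - y0
    if dx == 0 and dy == 0:
        raise ParameterError("cleavage plane needs two distinct points")
    if cell_mask.shape != img.shape:
        raise ParameterError("cell mask must match the image shape")
    h, w = img.shape
    xs = np.arange(w, dtype=np.float64)[None, :]
    ys = np.arange(h, dtype=np.float64)[:, None]
    side = dx * (ys - y0) - dy * (xs - x0)  # signed side of the line
    inside = cell_mask.pixels
    total_a = float(img.pixels[inside & (side >= 0)].sum())
    total_b = float(img.pixels[inside & (side < 0)].sum())
    return total_a, total_b


def cluster_stats(
    mito: Image,
    min_area_um2: float = 0.15,
    intensity_from: Image | None = None,
) -> ClusterStatsResult:
    """Mitochondrial cluster size and number.

    The channel is Yen-thresholded and 8-connected particles with area
    strictly greater than ``min_area_um2`` (default 0.15 um^2, the average
    single-mitochondrion footprint from electron microscopy) are counted
    as clusters.
    """
    mask = threshold_yen(mito)
    src = intensity_from.pixels if intensity_from is not None else mito.pixels
    regions = measure_regions(mask, mito.pixel_size_um, min_area_um2, intensity=src)
    n = len(regions)
    mean_area = float(regions["area_um2"].mean()) if n else float("nan")
    return ClusterStatsResult(
        regions=regions,
        n_clusters=n,
        mean_area_um2=mean_area,
        threshold_used=float(mask.threshold_used),
    )


def angular_uniformity(
    mito: Image,
    spindle_mask: BinaryMask,
    cell_mask: BinaryMask | None = None,
    smooth_radius_px: float = 2.0,
) -> AngularProfile:
    """Standard deviation of mean channel intensity over six 60-degree sectors.

    The channel is Gaussian-smoothed (radius ``smooth_radius_px``), pixels
    (optionally restricted to ``cell_mask``) are converted to polar
    coordinates about the spindle-mask centroid, and binned into six
    sectors anchored at the spindle long axis. Higher SD of the sector
    means indicates a less uniform angular distribution. The long axis has
    a 180-degree ambiguity, so the sector means are meaningful as an
    unordered set; the SD is the order-free primary statistic.
    """
    if spindle_mask.shape != mito.shape:
        raise ParameterError("spindle mask must match the image shape")
    if spindle_mask.n_foreground < 3:
        raise DegenerateInputError("spindle mask needs >= 3 pixels")
    smoothed = gaussian_smooth(mito, smooth_radius_px) if smooth_radius_px else mito
    (cx, cy), axis = mask_orientation(spindle_mask)
    degenerate = False
    ys, xs = np.nonzero(spindle_mask.pixels)
    dx0 = xs - xs.mean()
    dy0 = ys - ys.mean()
    if np.isclose(np.mean(dx0 * dx0), np.mean(dy0 * dy0)) and np.isclose(
        np.mean(dx0 * dy0), 0.0
    ):
        degenerate = True  # isotropic spindle: axis tie broken toward 0 rad

    h, w = mito.shape
    xg = np.arange(w, dtype=np.float64)[None, :]
    yg = np.arange(h, dtype=np.float64)[:, None]
    theta = np.arctan2(yg - cy, xg - cx) - axis
    sector = np.floor(np.mod(theta, 2.0 * np.pi) / (2.0 * np.pi / N_SECTORS))
    sector = np.clip(sector.astype(np.int64), 0, N_SECTORS - 1)
    if cell_mask is not None:
        if cell_mask.shape != mito.shape:
            raise ParameterError("cell mask must match the image shape")
        select = cell_mask.pixels
    else:
        select = np.ones(mito.shape, dtype=bool)
    vals = smoothed.pixels
    means = np.empty(N_SECTORS)
    for s in range(N_SECTORS):
        pick = select & (sector == s)
        if not pick.any():
            raise DegenerateInputError(f"sector {s} contains no pixels")
        means[s] = vals[pick].mean()
    return AngularProfile(
        axis_angle_rad=axis,
        sector_means=means,
        nonuniformity_sd=float(np.std(means)),
        center_xy=(cx, cy),
        axis_degenerate=degenerate,
    )


def embryo_mask_from_mito(mito: Image, smooth_radius_px: float = 2.0) -> BinaryMask:
    """Whole-embryo mask: convex hull of the Moments threshold of the smoothed channel."""
    from skimage.morphology import convex_hull_image

    smoothed = gaussian_smooth(mito, smooth_radius_px)
    seed = threshold_moments(smoothed)
    hull = convex_hull_image(seed.pixels)
    return BinaryMask(hull, threshold_used=seed.threshold_used, method=seed.method)


def ros_enrichment(
    ros: Image,
    mito: Image,
    embryo_mask: BinaryMask | None = None,
    rolling_ball_radius_px: float = 5.0,
    smooth_radius_px: float = 2.0,
) -> tuple[float, BinaryMask]:
    """Ratio of mean ROS-channel intensity inside vs outside mitochondria.

    The mitochondrial channel is background-subtracted (rolling ball),
    Gaussian-smoothed, and Moments-thresholded to give the inside-mask;
    "outside" is the whole-embryo area minus that mask. When no embryo
    mask is supplied it is derived as the convex hull of the Moments
    threshold of the smoothed mitochondrial channel.
    Returns ``(ratio, inside_mask)``.
    """
    if ros.shape != mito.shape:
        raise ParameterError("channels must be co-registered (same shape)")
    cleaned = rolling_ball_subtract(mito, rolling_ball_radius_px)
    smoothed = gaussian_smooth(cleaned, smooth_radius_px)
    inside = threshold_moments(smoothed)
    if embryo_mask is None:
        embryo_mask = embryo_mask_from_mito(mito, smooth_radius_px)
    outside = embryo_mask.pixels & ~inside.pixels
    if not inside.pixels.any() or not outside.any():
        raise DegenerateInputError("empty inside or outside region")
    mean_in = float(ros.pixels[inside.pixels].mean())
    mean_out = float(ros.pixels[outside].mean())
    if mean_out <= 0:
        raise DegenerateInputError("outside region has zero mean ROS intensity")
    return mean_in / mean_out, inside


def pixel_correlation(ch_a: Image, ch_b: Image, mask: BinaryMask) -> float:
    """Pearson correlation of per-pixel intensities of two channels within a mask."""
    if ch_a.shape != ch_b.shape or mask.shape != ch_a.shape:
        raise ParameterError("channels and mask must share one shape")
    a = ch_a.pixels[mask.pixels]
    b = ch_b.pixels[mask.pixels]
    if a.size < 10:
        raise ParameterError("need >= 10 pixels in the mask")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("a channel is constant within the mask")
    r, _ = stats.pearsonr(a, b)
    return float(r)


def track_projection(
    track: pd.DataFrame | np.ndarray,
    center_xy: tuple[float, float],
    pixel_size_um: float,
) -> TrackProjection:
    """Project a centroid track onto its net initial-to-final direction.

    ``track`` holds ordered (t, x, y) rows (DataFrame with those columns,
    or an (n, 3) array). The projected displacement at each time is the
    dot product of (position - initial) with the unit vector pointing from
    the initial to the final position, so the final projection equals the
    net displacement magnitude. Also reports the final distance to the
    given center in micrometres.
    """
    if isinstance(track, pd.DataFrame):
        arr = track[["t", "x", "y"]].to_numpy(dtype=np.float64)
    else:
        arr = np.asarray(track, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
        raise ParameterError("track needs >= 2 rows of (t, x, y)")
    times = arr[:, 0]
    pos = arr[:, 1:3]
    delta = pos[-1] - pos[0]
    norm = float(np.hypot(*delta))
    if norm == 0:
        raise DegenerateInputError("initial and final positions coincide")
    u = delta / norm
    proj = (pos - pos[0]) @ u
    final_dist = float(np.hypot(*(pos[-1] - np.asarray(center_xy)))) * pixel_size_um
    return TrackProjection(
        times=times,
        positions_xy=pos,
        direction_unit=u,
        projected_displacements=proj,
        final_distance_to_center_um=final_dist,
    )
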