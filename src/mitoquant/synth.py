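"""Synthetic two-channel embryo scenes with planted ground truth.

The generator emulates the statistical structure the quantifications
assume — a circular embryo (~80 um across) containing diffraction-limited
mitochondrial puncta plus a nuclear/spindle organizer rendered in a second
channel — with controllable:

* fragmentation (``n_clumps`` = 0 for fully dispersed puncta, or puncta
  gathered into clump-centered Gaussians),
* perinuclear enrichment (relative punctum density ``f`` >= 1 in a shell
  around the organizer),
* angular concentration (von-Mises concentration ``kappa`` of punctum
  angles about the organizer long axis, symmetric under 180-degree flip),
* division-plane partition fraction (two-cell scenes), and
* Poisson photon noise + Gaussian read noise over a background offset and
  gradient.

Puncta are rendered as isotropic Gaussian spots with sigma equal to half
the punctum radius, approximating diffraction-limited imaging; all
randomness flows from one seed through ``numpy.random.SeedSequence``
spawning (children, in order: geometry, mito-channel noise, second-channel
noise), so individual channels are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import BinaryMask, ChannelRole, Image, ParameterError

__all__ = [
    "SceneParams",
    "SyntheticScene",
    "generate_zygote_scene",
    "generate_two_cell_scene",
    "generate_em_ellipses",
    "generate_track",
]


@dataclass(frozen=True)
class SceneParams:
    """Ground-truth parameters of a synthetic embryo scene.

    Defaults describe a mouse zygote imaged at 0.25 um/px in a 512x512
    field: an 80-um-diameter embryo, a 10x6-um organizer (pronucleus or
    spindle) at the center, and 200 dispersed puncta whose planted
    footprint is ~0.3 um^2 each. Noise defaults emulate a modest confocal
    acquisition (shot noise at 0.25 ADU/photon, 2 ADU read noise over a
    100 ADU offset); set ``photon_gain`` and ``read_noise_sd`` to 0 and
    ``background_offset``/``background_gradient`` to 0 for noise-free
    rendering.
    """

    image_size_px: int = 512
    pixel_size_um: float = 0.25
    embryo_radius_um: float = 40.0
    organizer_center_um: tuple[float, float] | None = None  # None = embryo center
    organizer_radii_um: tuple[float, float] = (10.0, 6.0)
    organizer_angle_rad: float = 0.0
    n_puncta: int = 200
    punctum_radius_um: float = 0.309  # pi r^2 ~= 0.3 um^2
    punctum_peak: float = 1000.0
    organizer_peak: float = 600.0
    n_clumps: int = 0
    clump_spread_um: float = 0.3  # contact-scale: a clump renders as one object
    min_separation_um: float = 1.0  # hard-core distance between dispersed puncta
    perinuclear_enrichment: float = 1.0
    shell_width_um: float = 2.5
    angular_kappa: float = 0.0
    partition_fraction: float = 0.5
    photon_gain: float = 0.25
    read_noise_sd: float = 2.0
    background_offset: float = 100.0
    background_gradient: float = 0.0
    seed: int = 0

    def noise_free(self) -> "SceneParams":
        """Copy with all noise and background sources switched off."""
        return replace(
            self,
            photon_gain=0.0,
            read_noise_sd=0.0,
            background_offset=0.0,
            background_gradient=0.0,
        )

    def validate(self) -> None:
        if self.image_size_px < 16:
            raise ParameterError("image_size_px must be >= 16")
        for name in (
            "pixel_size_um",
            "embryo_radius_um",
            "punctum_radius_um",
            "clump_spread_um",
            "shell_width_um",
        ):
            if not (getattr(self, name) > 0):
                raise ParameterError(f"{name} must be > 0")
        if max(self.organizer_radii_um) >= self.embryo_radius_um:
            raise ParameterError("organizer does not fit inside the embryo")
        if self.perinuclear_enrichment < 1:
            raise ParameterError("perinuclear_enrichment must be >= 1")
        if self.angular_kappa < 0:
            raise ParameterError("angular_kappa must be >= 0")
        if not (0.0 < self.partition_fraction < 1.0):
            raise ParameterError("partition_fraction must lie in (0, 1)")
        fov_um = self.image_size_px * self.pixel_size_um
        if 2 * self.embryo_radius_um > fov_um:
            raise ParameterError("embryo does not fit in the field of view")


@dataclass(frozen=True)
class SyntheticScene:
    """A rendered scene plus everything needed to score a recovery."""

    mito: Image
    chromatin_or_spindle: Image
    params: SceneParams
    punctum_centers_um: np.ndarray  # (n, 2) of (x, y) relative to image origin
    cluster_labels: np.ndarray  # clump index per punctum; -1 = dispersed
    noise_free_mito: np.ndarray
    truth: dict = field(default_factory=dict)


def _center_um(params: SceneParams) -> np.ndarray:
    if params.organizer_center_um is not None:
        return np.asarray(params.organizer_center_um, dtype=np.float64)
    half = params.image_size_px * params.pixel_size_um / 2.0
    return np.array([half, half])


def _organizer_rho(points_um: np.ndarray, params: SceneParams) -> np.ndarray:
    """Ellipse-scaled radius of points in the organizer frame (<=1 inside)."""
    c = _center_um(params)
    a, b = params.organizer_radii_um
    ang = params.organizer_angle_rad
    d = points_um - c
    u = d[:, 0] * np.cos(ang) + d[:, 1] * np.sin(ang)
    v = -d[:, 0] * np.sin(ang) + d[:, 1] * np.cos(ang)
    return np.sqrt((u / a) ** 2 + (v / b) ** 2)


def _sample_angles(rng: np.random.Generator, n: int, params: SceneParams) -> np.ndarray:
    """Punctum polar angles about the embryo center.

    kappa = 0 gives uniform angles; kappa > 0 concentrates angles about
    the organizer long axis, symmetrically about both ends of the axis
    (equal mixture of von-Mises at axis and axis + pi).
    """
    if params.angular_kappa == 0:
        return rng.uniform(0.0, 2.0 * np.pi, n)
    mu = params.organizer_angle_rad + np.where(rng.random(n) < 0.5, 0.0, np.pi)
    return rng.vonmises(mu, params.angular_kappa, n)


def _sample_puncta(rng: np.random.Generator, params: SceneParams) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample punctum centers (um) and their clump labels."""
    c = _center_um(params)
    R = params.embryo_radius_um
    f = params.perinuclear_enrichment
    # shell membership via the Euclidean distance transform of the
    # organizer pixel mask: the same geometry a ring built by mask
    # dilation measures, so planted enrichment is recovered unbiased
    n = params.image_size_px
    xs = (np.arange(n) + 0.5) * params.pixel_size_um
    xg, yg = np.meshgrid(xs, xs)
    grid_pts = np.column_stack([xg.ravel(), yg.ravel()])
    organizer_grid = (_organizer_rho(grid_pts, params) <= 1.0).reshape(n, n)
    dist_um = (
        ndimage.distance_transform_edt(~organizer_grid) * params.pixel_size_um
        if organizer_grid.any()
        else np.full((n, n), np.inf)
    )

    def grid_index(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ix = np.clip((points[:, 0] / params.pixel_size_um).astype(int), 0, n - 1)
        iy = np.clip((points[:, 1] / params.pixel_size_um).astype(int), 0, n - 1)
        return ix, iy

    def in_shell_um(points: np.ndarray) -> np.ndarray:
        ix, iy = grid_index(points)
        return dist_um[iy, ix] <= params.shell_width_um

    def in_organizer(points: np.ndarray) -> np.ndarray:
        # membership of the nearest pixel, i.e. the same pixel-mask
        # geometry the downstream analysis segments
        ix, iy = grid_index(points)
        return organizer_grid[iy, ix]

    clump_centers = None
    if params.n_clumps > 0:
        # clumps are distinct aggregates: keep their centers far enough
        # apart that two clumps never fuse into one connected object
        clump_sep = 10.0 * params.clump_spread_um
        clump_centers = np.empty((params.n_clumps, 2))
        got = 0
        tries = 0
        while got < params.n_clumps:
            tries += 1
            if tries > 10000:
                raise ParameterError("could not place clump centers; too crowded")
            theta = _sample_angles(rng, 1, params)[0]
            r = R * np.sqrt(rng.random())
            pt = c + r * np.array([np.cos(theta), np.sin(theta)])
            if _organizer_rho(pt[None, :], params)[0] <= 1.0:
                continue
            if got > 0:
                d2 = np.sum((clump_centers[:got] - pt) ** 2, axis=1)
                if d2.min() < clump_sep * clump_sep:
                    continue
            clump_centers[got] = pt
            got += 1

    pts = np.empty((params.n_puncta, 2))
    labels = np.full(params.n_puncta, -1, dtype=np.int64)
    # hard-core separation applies to dispersed puncta only: clumps are
    # intended to merge, and it keeps dispersed scenes resolvable so that
    # particle counting tests detection, not deblending
    sep = params.min_separation_um if clump_centers is None else 0.0
    got = 0
    attempts = 0
    while got < params.n_puncta:
        attempts += 1
        if attempts > 2000:
            raise ParameterError(
                "could not place puncta; lower n_puncta or min_separation_um"
            )
        m = 4 * (params.n_puncta - got) + 16
        if clump_centers is None:
            theta = _sample_angles(rng, m, params)
            r = R * np.sqrt(rng.random(m))
            cand = c + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
            lab = np.full(m, -1, dtype=np.int64)
        else:
            lab = rng.integers(0, params.n_clumps, m)
            cand = clump_centers[lab] + rng.normal(0.0, params.clump_spread_um, (m, 2))
        inside_embryo = np.hypot(*(cand - c).T) <= R
        in_cytoplasm = inside_embryo & ~in_organizer(cand)
        # shell enrichment: keep shell points, thin non-shell points by 1/f
        in_shell = in_cytoplasm & in_shell_um(cand)
        keep = in_cytoplasm & (in_shell | (rng.random(m) < 1.0 / f))
        cand = cand[keep]
        lab = lab[keep]
        for point, point_lab in zip(cand, lab):
            if got >= params.n_puncta:
                break
            if sep > 0 and got > 0:
                d2 = np.sum((pts[:got] - point) ** 2, axis=1)
                if d2.min() < sep * sep:
                    continue
            pts[got] = point
            labels[got] = point_lab
            got += 1
    return pts, labels


def _render_puncta(params: SceneParams, pts_um: np.ndarray) -> np.ndarray:
    """Sum of analytic Gaussian spots, evaluated on local windows.

    Each punctum contributes ``peak * exp(-d^2 / 2 sigma^2)`` sampled at
    pixel centers, so spot profiles are exact irrespective of sub-pixel
    position (no splat-and-blur approximation error).
    """
    sigma_px = (params.punctum_radius_um / 2.0) / params.pixel_size_um
    n = params.image_size_px
    img = np.zeros((n, n))
    w = int(np.ceil(5.0 * sigma_px)) + 1
    # pixel i center sits at (i + 0.5) * pixel_size
    centers_px = pts_um / params.pixel_size_um - 0.5
    for cx, cy in centers_px:
        x0 = max(int(np.floor(cx)) - w, 0)
        x1 = min(int(np.floor(cx)) + w + 1, n)
        y0 = max(int(np.floor(cy)) - w, 0)
        y1 = min(int(np.floor(cy)) + w + 1, n)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1) - cx
        ys = np.arange(y0, y1) - cy
        d2 = ys[:, None] ** 2 + xs[None, :] ** 2
        img[y0:y1, x0:x1] += params.punctum_peak * np.exp(-d2 / (2.0 * sigma_px**2))
    return img


def _render_organizer(params: SceneParams) -> np.ndarray:
    n = params.image_size_px
    xs = (np.arange(n) + 0.5) * params.pixel_size_um
    xg, yg = np.meshgrid(xs, xs)
    pts = np.column_stack([xg.ravel(), yg.ravel()])
    rho = _organizer_rho(pts, params).reshape(n, n)
    img = np.where(rho <= 1.0, params.organizer_peak, 0.0)
    return ndimage.gaussian_filter(img, sigma=1.0, mode="constant")


def _apply_noise(
    rng: np.random.Generator, clean: np.ndarray, params: SceneParams
) -> np.ndarray:
    n = clean.shape[1]
    out = clean + params.background_offset
    if params.background_gradient:
        out = out + params.background_gradient * np.arange(n)[None, :]
    if params.photon_gain > 0:
        out = rng.poisson(out / params.photon_gain) * params.photon_gain
    if params.read_noise_sd > 0:
        out = out + rng.normal(0.0, params.read_noise_sd, out.shape)
    return np.clip(out, 0.0, None)


def _spawn(params: SceneParams) -> tuple[np.random.Generator, ...]:
    children = np.random.SeedSequence(params.seed).spawn(3)
    return tuple(np.random.default_rng(s) for s in children)


def generate_zygote_scene(params: SceneParams) -> SyntheticScene:
    """Render a one-cell scene: mito puncta + organizer channel.

    Punctum placement follows the configured mixture (dispersed vs
    clump-centered, shell enrichment, angular concentration); channels are
    sums of Gaussian spots; Poisson + Gaussian noise is applied last.
    Bit-identical for a fixed seed.
    """
    params.validate()
    rng_geom, rng_mito, rng_org = _spawn(params)
    pts, labels = _sample_puncta(rng_geom, params)
    clean_mito = _render_puncta(params, pts)
    clean_org = _render_organizer(params)
    mito = Image(
        _apply_noise(rng_mito, clean_mito, params),
        params.pixel_size_um,
        ChannelRole.MITO,
    )
    org = Image(
        _apply_noise(rng_org, clean_org, params),
        params.pixel_size_um,
        ChannelRole.CHROMATIN,
    )
    return SyntheticScene(
        mito=mito,
        chromatin_or_spindle=org,
        params=params,
        punctum_centers_um=pts,
        cluster_labels=labels,
        noise_free_mito=clean_mito,
        truth={"total_mito_noise_free": float(clean_mito.sum())},
    )


def generate_two_cell_scene(params: SceneParams) -> SyntheticScene:
    """Render a two-cell scene with an exact pre-noise mass split.

    Puncta are placed as in the one-cell scene; the field is then divided
    by a vertical cleavage line through the embryo center, and the two
    half-images are rescaled so side A carries exactly
    ``partition_fraction`` of the total noise-free mitochondrial mass.
    The truth dict records both side totals and the cleavage line.
    """
    params.validate()
    rng_geom, rng_mito, rng_org = _spawn(params)
    pts, labels = _sample_puncta(rng_geom, params)
    clean = _render_puncta(params, pts)
    c = _center_um(params)
    cx_px = c[0] / params.pixel_size_um
    n = params.image_size_px
    # same sign convention as split_totals_by_plane with the recorded plane:
    # plane (p0, p1) runs downward, side A is x <= cx
    plane = ((cx_px, 0.0), (cx_px, float(n - 1)))
    xs = np.arange(n)[None, :]
    side_a = np.broadcast_to(xs <= cx_px, clean.shape)
    s_a = clean[side_a].sum()
    s_b = clean[~side_a].sum()
    if s_a == 0 or s_b == 0:
        raise ParameterError("degenerate scene: one side holds no mass")
    total = s_a + s_b
    f = params.partition_fraction
    scaled = np.where(side_a, clean * (f * total / s_a), clean * ((1 - f) * total / s_b))
    mito = Image(
        _apply_noise(rng_mito, scaled, params),
        params.pixel_size_um,
        ChannelRole.MITO,
    )
    org = Image(
        _apply_noise(rng_org, _render_organizer(params), params),
        params.pixel_size_um,
        ChannelRole.CHROMATIN,
    )
    return SyntheticScene(
        mito=mito,
        chromatin_or_spindle=org,
        params=params,
        punctum_centers_um=pts,
        cluster_labels=labels,
        noise_free_mito=scaled,
        truth={
            "total_a": float(f * total),
            "total_b": float((1 - f) * total),
            "plane": plane,
            "total_mito_noise_free": float(total),
        },
    )


def generate_em_ellipses(
    n: int,
    axis_ranges_um: tuple[tuple[float, float], tuple[float, float]] = (
        (0.8, 3.0),
        (0.4, 1.2),
    ),
    pixel_size_um: float = 0.05,
    seed: int = 0,
) -> tuple[Image, pd.DataFrame]:
    """Render non-overlapping filled ellipses with known axes (EM morphometry fixture).

    ``axis_ranges_um`` gives (major, minor) full-axis sampling ranges;
    drawn pairs are sorted so major >= minor. Ellipses are laid out on a
    jittered grid with random orientations so they never touch. Returns
    the rendered image and a truth table with columns ``major_axis_um``,
    ``minor_axis_um``, ``aspect_ratio``, ``center_x_px``, ``center_y_px``,
    ``angle_rad``.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    (maj_lo, maj_hi), (min_lo, min_hi) = axis_ranges_um
    major = rng.uniform(maj_lo, maj_hi, n)
    minor = rng.uniform(min_lo, min_hi, n)
    swap = minor > major
    major[swap], minor[swap] = minor[swap].copy(), major[swap].copy()
    angle = rng.uniform(0.0, np.pi, n)

    cell_um = maj_hi + 2.0  # grid pitch: max diameter/2 margin each side
    cols = int(np.ceil(np.sqrt(n)))
    rows_n = int(np.ceil(n / cols))
    size_px = int(np.ceil(cols * cell_um / pixel_size_um)) + 1
    size_py = int(np.ceil(rows_n * cell_um / pixel_size_um)) + 1
    img = np.zeros((size_py, size_px))
    yy, xx = np.mgrid[0:size_py, 0:size_px]
    rows = []
    for i in range(n):
        gx, gy = i % cols, i // cols
        cx = (gx + 0.5) * cell_um / pixel_size_um + rng.uniform(-2, 2)
        cy = (gy + 0.5) * cell_um / pixel_size_um + rng.uniform(-2, 2)
        a = major[i] / 2.0 / pixel_size_um  # semi-axes in px
        b = minor[i] / 2.0 / pixel_size_um
        dx = xx - cx
        dy = yy - cy
        u = dx * np.cos(angle[i]) + dy * np.sin(angle[i])
        v = -dx * np.sin(angle[i]) + dy * np.cos(angle[i])
        img[(u / a) ** 2 + (v / b) ** 2 <= 1.0] = 255.0
        rows.append(
            {
                "major_axis_um": major[i],
                "minor_axis_um": minor[i],
                "aspect_ratio": major[i] / minor[i],
                "center_x_px": cx,
                "center_y_px": cy,
                "angle_rad": angle[i],
            }
        )
    image = Image(img, pixel_size_um, ChannelRole.OTHER, "u8")
    return image, pd.DataFrame(rows)


def generate_track(
    waypoints: np.ndarray,
    noise_sd_px: float = 0.0,
    seed: int = 0,
    n_points: int | None = None,
    dt: float = 1.0,
) -> pd.DataFrame:
    """Centroid track through given (x, y) waypoints with optional position noise.

    The waypoints are connected by piecewise-linear interpolation sampled
    at ``n_points`` times (default: one per waypoint) spaced ``dt`` apart;
    isotropic Gaussian noise of ``noise_sd_px`` is added to every sampled
    position. Returns a DataFrame with columns ``t``, ``x``, ``y``.
    """
    wp = np.asarray(waypoints, dtype=np.float64)
    if wp.ndim != 2 or wp.shape[1] != 2 or wp.shape[0] < 2:
        raise ParameterError("need >= 2 waypoints of (x, y)")
    if n_points is None:
        n_points = wp.shape[0]
    s = np.linspace(0.0, wp.shape[0] - 1.0, n_points)
    x = np.interp(s, np.arange(wp.shape[0]), wp[:, 0])
    y = np.interp(s, np.arange(wp.shape[0]), wp[:, 1])
    if noise_sd_px > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd_px, n_points)
        y = y + rng.normal(0.0, noise_sd_px, n_points)
    return pd.DataFrame({"t": np.arange(n_points) * dt, "x": x, "y": y})


def spindle_mask_from_truth(params: SceneParams) -> BinaryMask:
    """Ground-truth organizer mask (ellipse interior), bypassing segmentation."""
    n = params.image_size_px
    xs = (np.arange(n) + 0.5) * params.pixel_size_um
    xg, yg = np.meshgrid(xs, xs)
    pts = np.column_stack([xg.ravel(), yg.ravel()])
    rho = _organizer_rho(pts, params).reshape(n, n)
    return BinaryMask(rho <= 1.0, threshold_used="manual", method="manual")
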