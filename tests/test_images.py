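"""Unit tests of the image primitives against independent oracles."""

import numpy as np
import pytest
from scipy import ndimage

from mitoquant.images import (
    BinaryMask,
    DegenerateInputError,
    Image,
    ParameterError,
    ZStack,
    dilate_mask,
    disk_footprint,
    gaussian_smooth,
    label_regions,
    max_project,
    measure_regions,
    moments_level,
    region_ellipse_axes,
    rolling_ball_subtract,
    threshold_moments,
    threshold_yen,
    yen_criterion,
)


def img_of(arr, ps=1.0):
    return Image(np.asarray(arr, dtype=float), ps)


# ---------------------------------------------------------------- validation


def test_image_validation_errors():
    with pytest.raises(ParameterError):
        Image(np.ones((1, 5)), 1.0)  # too small
    with pytest.raises(ParameterError):
        Image(-np.ones((4, 4)), 1.0)  # negative
    with pytest.raises(ParameterError):
        Image(np.full((4, 4), np.nan), 1.0)
    with pytest.raises(ParameterError):
        Image(np.ones((4, 4)), 0.0)  # bad pixel size


def test_zstack_validation():
    a = img_of(np.ones((4, 4)))
    b = img_of(np.ones((5, 4)))
    with pytest.raises(ParameterError):
        ZStack([a, b], 1.0)
    with pytest.raises(ParameterError):
        ZStack([], 1.0)


# ------------------------------------------------------------ gaussian_smooth


def test_gaussian_smooth_constant_invariance():
    out = gaussian_smooth(img_of(np.full((32, 32), 7.5)), 2.0)
    np.testing.assert_allclose(out.pixels, 7.5)


def test_gaussian_smooth_spreads_single_pixel():
    arr = np.zeros((33, 33))
    arr[16, 16] = 100.0
    out = gaussian_smooth(img_of(arr), 2.0)
    assert out.pixels[16, 16] < 100.0
    assert out.pixels.max() == out.pixels[16, 16]
    # radial symmetry of the blob
    np.testing.assert_allclose(out.pixels, out.pixels.T)
    np.testing.assert_allclose(out.pixels, out.pixels[::-1, ::-1])


def test_gaussian_smooth_conserves_interior_mass(rng):
    arr = np.zeros((64, 64))
    arr[16:48, 16:48] = rng.uniform(0, 100, (32, 32))
    out = gaussian_smooth(img_of(arr), 2.0)
    assert abs(out.pixels.sum() - arr.sum()) / arr.sum() < 0.005


def test_gaussian_smooth_matches_direct_convolution(rng):
    """Separable filtering equals brute-force 2D convolution with the
    sampled kernel (edge replication)."""
    arr = rng.uniform(0, 255, (64, 64))
    sigma = 2.0
    # sample the kernel the filter actually uses (impulse response)
    lw = int(4.0 * sigma + 0.5)
    imp = np.zeros(2 * lw + 1)
    imp[lw] = 1.0
    k1 = ndimage.gaussian_filter1d(imp, sigma)
    kernel = np.outer(k1, k1)
    padded = np.pad(arr, lw, mode="edge")
    expected = np.empty_like(arr)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            expected[i, j] = np.sum(padded[i : i + 2 * lw + 1, j : j + 2 * lw + 1] * kernel)
    out = gaussian_smooth(img_of(arr), sigma)
    np.testing.assert_allclose(out.pixels, expected, rtol=1e-6)


def test_gaussian_smooth_commutes_with_transpose(rng):
    arr = rng.uniform(0, 50, (40, 24))
    a = gaussian_smooth(img_of(arr), 2.0).pixels.T
    b = gaussian_smooth(img_of(arr.T), 2.0).pixels
    np.testing.assert_allclose(a, b, rtol=1e-12)


def test_gaussian_smooth_rejects_bad_radius():
    with pytest.raises(ParameterError):
        gaussian_smooth(img_of(np.ones((4, 4))), 0.0)


# ------------------------------------------------------- rolling_ball_subtract


def test_rolling_ball_flat_background_removed():
    out = rolling_ball_subtract(img_of(np.full((32, 32), 40.0)), 5)
    np.testing.assert_allclose(out.pixels, 0.0)


def test_rolling_ball_preserves_small_spike():
    arr = np.zeros((32, 32))
    arr[10, 12] = 77.0
    out = rolling_ball_subtract(img_of(arr), 5)
    assert out.pixels[10, 12] == pytest.approx(77.0)
    assert out.pixels.sum() == pytest.approx(77.0)


def test_rolling_ball_ramp_plus_spike():
    """A planar ramp is its own opening in the interior, so only the spike
    survives (within 1 gray level)."""
    ramp = np.arange(32, dtype=float)[None, :] * np.ones((32, 1))
    arr = ramp.copy()
    arr[15, 16] += 120.0
    out = rolling_ball_subtract(img_of(arr), 5)
    expected = np.zeros_like(arr)
    expected[15, 16] = 120.0
    interior = np.s_[6:-6, 6:-6]
    np.testing.assert_allclose(out.pixels[interior], expected[interior], atol=1.0)


def test_rolling_ball_background_below_image(rng):
    arr = rng.uniform(0, 255, (32, 32))
    img = img_of(arr)
    fp = disk_footprint(5)
    bg = ndimage.grey_opening(arr, footprint=fp, mode="nearest")
    assert np.all(bg <= arr + 1e-9)
    out = rolling_ball_subtract(img, 5)
    np.testing.assert_allclose(out.pixels, arr - bg)


def test_rolling_ball_commutes_with_transpose(rng):
    arr = rng.uniform(0, 100, (30, 30))
    a = rolling_ball_subtract(img_of(arr), 5).pixels.T
    b = rolling_ball_subtract(img_of(arr.T), 5).pixels
    np.testing.assert_allclose(a, b)


def test_rolling_ball_radius_errors():
    with pytest.raises(ParameterError):
        rolling_ball_subtract(img_of(np.ones((8, 8))), 0.5)
    with pytest.raises(ParameterError):
        rolling_ball_subtract(img_of(np.ones((8, 8))), 20)


# ----------------------------------------------------------------- thresholds


def naive_yen_level(p):
    """Exhaustive per-level criterion search, written independently as
    plain loops (the oracle the vectorized selection must match)."""
    import math

    best, best_t = -math.inf, None
    for t in range(256):
        p1 = sum(p[: t + 1])
        p2 = 1.0 - p1
        s1 = sum(x * x for x in p[: t + 1])
        s2 = sum(x * x for x in p[t + 1 :])
        if p1 <= 0 or p2 <= 0 or s1 <= 0 or s2 <= 0:
            continue
        crit = 2.0 * math.log(p1 * p2) - math.log(s1 * s2)
        if crit > best:
            best, best_t = crit, t
    return best_t


def naive_moments_level(p):
    """Moment-preserving search by direct evaluation of the closed form,
    then scanning all 256 cumulative fractions for the nearest match."""
    import math

    m1 = sum(i * p[i] for i in range(256))
    m2 = sum(i * i * p[i] for i in range(256))
    m3 = sum(i * i * i * p[i] for i in range(256))
    cd = m2 - m1 * m1
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = max(c1 * c1 - 4.0 * c0, 0.0)
    z0 = 0.5 * (-c1 - math.sqrt(disc))
    z1 = 0.5 * (-c1 + math.sqrt(disc))
    p0 = (z1 - m1) / (z1 - z0)
    best, best_t = math.inf, None
    cum = 0.0
    for t in range(256):
        cum += p[t]
        if abs(cum - p0) < best:
            best, best_t = abs(cum - p0), t
    return best_t


def random_256_image(rng, size=(48, 48)):
    """Image whose values are integers 0..255, so bins = gray levels."""
    arr = rng.integers(0, 256, size).astype(float)
    # force both extremes present so bin i <-> gray level i
    arr.flat[0], arr.flat[1] = 0.0, 255.0
    return arr


@pytest.mark.parametrize("case", range(20))
def test_threshold_selections_match_exhaustive_search(case):
    rng = np.random.default_rng(1000 + case)
    arr = random_256_image(rng)
    p = np.bincount(arr.astype(int).ravel(), minlength=256) / arr.size
    img = img_of(arr)
    got_yen = threshold_yen(img)
    assert int(np.argmax(yen_criterion(p))) == naive_yen_level(list(p))
    assert got_yen.pixels.sum() == (arr > naive_yen_level(list(p))).sum()
    got_mom = threshold_moments(img)
    assert moments_level(p) == naive_moments_level(list(p))
    assert got_mom.pixels.sum() == (arr > naive_moments_level(list(p))).sum()


def test_yen_bimodal_two_values():
    arr = np.concatenate([np.full(2000, 10.0), np.full(2000, 200.0)])
    img = img_of(arr.reshape(50, 80))
    mask = threshold_yen(img)
    assert 10.0 < float(mask.threshold_used) < 200.0
    assert mask.n_foreground == 2000


def test_yen_sparse_bright_minority(rng):
    arr = np.full(10000, 5.0)
    idx = rng.choice(10000, 100, replace=False)
    arr[idx] = 250.0
    mask = threshold_yen(img_of(arr.reshape(100, 100)))
    assert mask.n_foreground == 100
    assert np.array_equal(np.flatnonzero(mask.pixels.ravel()), np.sort(idx))


def test_yen_agrees_with_skimage(rng):
    from skimage.filters import threshold_yen as sk_yen

    arr = rng.normal(100, 30, (64, 64)).clip(0) + (rng.random((64, 64)) < 0.1) * 300
    thr = float(threshold_yen(img_of(arr)).threshold_used)
    ref = sk_yen(arr, nbins=256)
    bin_w = np.ptp(arr) / 256
    assert abs(thr - ref) <= bin_w  # same bin, different edge convention


def test_moments_two_valued_image():
    arr = np.concatenate([np.full(3000, 20.0), np.full(3000, 180.0)])
    mask = threshold_moments(img_of(arr.reshape(60, 100)))
    assert 20.0 < float(mask.threshold_used) < 180.0
    frac = mask.n_foreground / arr.size
    assert frac == pytest.approx(0.5, abs=1.0 / 256)


@pytest.mark.parametrize("fn", [threshold_yen, threshold_moments])
def test_threshold_constant_image_errors(fn):
    with pytest.raises(DegenerateInputError):
        fn(img_of(np.full((16, 16), 42.0)))


# ---------------------------------------------------------------- dilate_mask


def test_dilate_single_pixel_width1_is_cross():
    m = np.zeros((7, 7), bool)
    m[3, 3] = True
    out = dilate_mask(BinaryMask(m), 1)
    assert out.n_foreground == 5
    assert out.pixels[3, 3] and out.pixels[2, 3] and out.pixels[3, 2]


def test_dilate_full_frame_saturates():
    m = np.ones((9, 9), bool)
    out = dilate_mask(BinaryMask(m), 3)
    assert out.pixels.all()


def test_dilate_contains_input_and_grows(rng):
    m = rng.random((32, 32)) < 0.05
    once = dilate_mask(BinaryMask(m), 2)
    twice = dilate_mask(once, 2)
    assert np.all(~m | once.pixels)
    assert twice.n_foreground >= once.n_foreground


@pytest.mark.parametrize("width", [1, 3, 10])
def test_dilate_matches_distance_transform(rng, width):
    """Dilation by a 'distance <= r' disk equals thresholding the EDT."""
    m = rng.random((48, 48)) < 0.03
    m[0, 0] = True  # guarantee non-empty
    out = dilate_mask(BinaryMask(m), width)
    edt = ndimage.distance_transform_edt(~m)
    np.testing.assert_array_equal(out.pixels, edt <= width)


def test_dilate_width_error():
    with pytest.raises(ParameterError):
        dilate_mask(BinaryMask(np.ones((4, 4), bool)), 0)


# -------------------------------------------------------------- label_regions


def disks_mask(centers, r_px, shape):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    m = np.zeros(shape, bool)
    for cx, cy in centers:
        m |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px**2
    return m


def test_label_regions_size_filter_counts():
    # 20 disks of ~0.3 um^2 (r=2 px at 0.16 um/px -> area 13 px * 0.0256)
    ps = 0.16
    centers = [(10 + 14 * (i % 5), 10 + 14 * (i // 5)) for i in range(20)]
    m = disks_mask(centers, 2, (80, 80))
    big_only = label_regions(BinaryMask(m), ps, min_area_um2=0.15)
    assert len(big_only) == 20
    # add 5 single-pixel particles (0.0256 um^2 < 0.15): still 20 rows
    m2 = m.copy()
    for i in range(5):
        m2[70, 5 + 3 * i] = True
    tab = label_regions(BinaryMask(m2), ps, min_area_um2=0.15)
    assert len(tab) == 20
    assert list(tab["label"]) == list(range(1, 21))


def test_label_regions_area_conservation(rng):
    m = rng.random((64, 64)) < 0.2
    ps = 0.25
    tab = label_regions(BinaryMask(m), ps, min_area_um2=0.0)
    assert tab["area_um2"].sum() == pytest.approx(m.sum() * ps * ps)


def test_label_regions_circle_is_isotropic():
    m = disks_mask([(32, 32)], 12, (64, 64))
    tab = label_regions(BinaryMask(m), 1.0)
    assert len(tab) == 1
    assert tab.loc[0, "aspect_ratio"] == pytest.approx(1.0, abs=0.05)


def test_measure_regions_mean_intensity(rng):
    m = np.zeros((16, 16), bool)
    m[4:8, 4:8] = True
    inten = np.full((16, 16), 3.0)
    tab = measure_regions(BinaryMask(m), 1.0, intensity=inten)
    assert tab.loc[0, "mean_intensity"] == pytest.approx(3.0)


# -------------------------------------------------------- region_ellipse_axes


def filled_ellipse_coords(a, b, angle=0.0, n=201):
    lim = int(np.ceil(max(a, b))) + 2
    yy, xx = np.mgrid[-lim : lim + 1, -lim : lim + 1]
    u = xx * np.cos(angle) + yy * np.sin(angle)
    v = -xx * np.sin(angle) + yy * np.cos(angle)
    keep = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return np.column_stack([xx[keep], yy[keep]])


def test_ellipse_axes_two_to_one():
    pts = filled_ellipse_coords(40, 20)
    major, minor, aspect = region_ellipse_axes(pts, 1.0)
    assert aspect == pytest.approx(2.0, abs=0.05)
    assert major == pytest.approx(80, rel=0.02)


def test_ellipse_axes_rotation_invariant():
    p0 = filled_ellipse_coords(40, 20, 0.0)
    p37 = filled_ellipse_coords(40, 20, np.deg2rad(37))
    m0 = region_ellipse_axes(p0, 1.0)
    m37 = region_ellipse_axes(p37, 1.0)
    assert m37[0] == pytest.approx(m0[0], rel=0.02)
    assert m37[1] == pytest.approx(m0[1], rel=0.02)


def test_ellipse_axes_matches_covariance_enumeration(rng):
    pts = rng.integers(0, 30, (200, 2)).astype(float)
    major, minor, aspect = region_ellipse_axes(pts, 0.5)
    # direct covariance eigenvalue computation
    c = pts - pts.mean(axis=0)
    cov = np.array(
        [
            [np.mean(c[:, 0] ** 2), np.mean(c[:, 0] * c[:, 1])],
            [np.mean(c[:, 0] * c[:, 1]), np.mean(c[:, 1] ** 2)],
        ]
    )
    ev = np.sort(np.linalg.eigvalsh(cov))
    assert minor == pytest.approx(4 * np.sqrt(ev[0]) * 0.5, rel=1e-9)
    assert major == pytest.approx(4 * np.sqrt(ev[1]) * 0.5, rel=1e-9)
    assert aspect == pytest.approx(major / minor, rel=1e-12)


def test_ellipse_axes_needs_three_points():
    with pytest.raises(ParameterError):
        region_ellipse_axes(np.array([[0.0, 0.0], [1.0, 1.0]]), 1.0)


# ---------------------------------------------------------------- max_project


def test_max_project_identity_and_zero():
    a = img_of(np.zeros((8, 8)))
    assert np.array_equal(max_project(ZStack([a], 1.0)).pixels, a.pixels)
    stack = ZStack([a, a, a], 2.5)
    assert max_project(stack).pixels.sum() == 0.0


def test_max_project_matches_enumeration(rng):
    planes = [img_of(rng.uniform(0, 100, (12, 12))) for _ in range(5)]
    stack = ZStack(planes, 1.0)
    out = max_project(stack).pixels
    for i in range(12):
        for j in range(12):
            assert out[i, j] == max(p.pixels[i, j] for p in planes)
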