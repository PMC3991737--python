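"""Scanner-image restoration, segmentation, and global root-system traits.

The imaging pipeline mirrors the classic flatbed-scanner workflow for roots
grown on germination paper: take the red channel of the colour scan, remove
speckle noise (median then Gaussian), flatten long-range moisture/illumination
gradients by local-mean subtraction, binarize with the moment-preserving
(Tsai) threshold, drop objects unconnected to the root system, and measure
global traits (total root length, projected area, perimeter, convex hull).

All physical quantities are returned in cm / cm**2; pixel-to-cm conversion
uses the image dpi (2.54 cm per inch).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.morphology import skeletonize

CM_PER_INCH = 2.54

# clockwise Moore neighbourhood starting East, as (dy, dx)
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


@dataclass(frozen=True)
class RasterImage:
    """A 2D intensity image (1 or 3 channels, values in [0, 255]) plus dpi."""

    pixels: np.ndarray
    dpi: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3):
            raise ValueError(f"expected 2D or 3D pixel array, got ndim={px.ndim}")
        if px.ndim == 3 and px.shape[2] not in (1, 3):
            raise ValueError(f"expected 1 or 3 channels, got {px.shape[2]}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have height >= 1 and width >= 1")
        if not np.isfinite(self.dpi) or self.dpi <= 0:
            raise ValueError(f"dpi must be a positive finite number, got {self.dpi}")
        if px.size and (px.min() < 0 or px.max() > 255):
            raise ValueError("intensities must lie within [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class BinaryMask:
    """Boolean foreground mask with the dpi of its source image."""

    pixels: np.ndarray
    dpi: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("mask must be 2D")
        if not np.isfinite(self.dpi) or self.dpi <= 0:
            raise ValueError(f"dpi must be a positive finite number, got {self.dpi}")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def cm_per_px(self) -> float:
        return CM_PER_INCH / self.dpi


@dataclass(frozen=True)
class GlobalTraits:
    """Whole-root-system traits measured on a binary mask, in cm units."""

    total_root_length: float  # cm, skeleton length
    total_area: float  # cm^2, projected foreground area
    perimeter: float  # cm, traced boundary length
    convex_hull_area: float  # cm^2


def to_grayscale_red(image: RasterImage) -> RasterImage:
    """Extract the red channel of a colour scan as a grayscale image.

    Roots on wet germination paper show their best contrast in the red
    channel, so the rest of the pipeline operates on it alone.
    """
    if image.n_channels == 1:
        warnings.warn("input is already single-channel; returning it unchanged")
        px = image.pixels if image.pixels.ndim == 2 else image.pixels[:, :, 0]
        return RasterImage(px, image.dpi)
    if image.n_channels != 3:
        raise ValueError(f"expected a 3-channel image, got {image.n_channels}")
    return RasterImage(image.pixels[:, :, 0], image.dpi)


def denoise(image: RasterImage, median_radius: int = 1, gaussian_sigma: float = 1.0) -> RasterImage:
    """Median filter (radius in px) followed by a Gaussian blur (sigma in px).

    A radius or sigma of 0 disables that filter. The median removes
    salt-and-pepper specks (condensation droplets); the Gaussian suppresses
    paper-texture grain.
    """
    if not np.isfinite(median_radius) or not np.isfinite(gaussian_sigma):
        raise ValueError("filter parameters must be finite")
    if median_radius < 0 or gaussian_sigma < 0:
        raise ValueError("filter parameters must be >= 0")
    if image.n_channels != 1:
        raise ValueError("denoise expects a single-channel image")
    px = image.pixels.astype(float)
    if median_radius > 0:
        px = ndimage.median_filter(px, size=2 * int(median_radius) + 1, mode="reflect")
    if gaussian_sigma > 0:
        px = ndimage.gaussian_filter(px, sigma=gaussian_sigma, mode="reflect")
    return RasterImage(np.clip(px, 0, 255), image.dpi)


def flatten_background(image: RasterImage, window_radius: int = 25) -> RasterImage:
    """Remove long-range intensity gradients by local-mean subtraction.

    Subtracts, from every pixel, the mean intensity of a square window of
    half-width ``window_radius`` centred on it, then re-offsets the result to
    a mid-grey of 128 and clips to [0, 255]. The window must be wider than
    the roots so they do not flatten themselves away; gradients on scales
    much larger than the window (paper moisture, lamp falloff) are removed.
    """
    if window_radius <= 0:
        raise ValueError("window_radius must be > 0")
    if image.n_channels != 1:
        raise ValueError("flatten_background expects a single-channel image")
    px = image.pixels.astype(float)
    local_mean = ndimage.uniform_filter(px, size=2 * int(window_radius) + 1, mode="reflect")
    flat = px - local_mean + 128.0
    return RasterImage(np.clip(flat, 0, 255), image.dpi)


def _histogram_moments(hist: np.ndarray) -> tuple[float, float, float]:
    p = hist / hist.sum()
    levels = np.arange(hist.size, dtype=float)
    m1 = float((p * levels).sum())
    m2 = float((p * levels**2).sum())
    m3 = float((p * levels**3).sum())
    return m1, m2, m3


def tsai_moment_threshold(image: RasterImage | np.ndarray) -> int:
    """Moment-preserving (Tsai) threshold of an 8-bit image.

    Finds the two representative grey levels z0 < z1 and the mass fraction
    p0 such that a two-level image with fraction p0 at z0 and 1 - p0 at z1
    preserves the first three moments of the input histogram, then returns
    the grey level t whose cumulative histogram fraction is closest to p0
    (ties broken toward the lower level). Deterministic given the histogram.
    """
    px = image.pixels if isinstance(image, RasterImage) else np.asarray(image)
    flat = np.round(px.astype(float)).astype(int).ravel()
    hist = np.bincount(flat, minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise ValueError("image has fewer than 2 distinct intensity values; no threshold exists")
    m1, m2, m3 = _histogram_moments(hist)
    cd = m2 - m1 * m1
    # cd > 0 whenever there are >= 2 distinct levels
    c0 = (m1 * m3 - m2 * m2) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = c1 * c1 - 4.0 * c0
    root = np.sqrt(max(disc, 0.0))
    z0 = (-c1 - root) / 2.0
    z1 = (-c1 + root) / 2.0
    p0 = (z1 - m1) / (z1 - z0)
    cum = np.cumsum(hist) / hist.sum()
    # nearest cumulative bin; np.argmin returns the first (lowest) on ties
    t = int(np.argmin(np.abs(cum - p0)))
    return t


def segment(image: RasterImage, threshold: float, invert: bool = False) -> BinaryMask:
    """Binarize at ``threshold``: foreground is the brighter class (> t).

    After background flattening, roots scan brighter than the wet paper, so
    the default polarity keeps pixels above the threshold. ``invert=True``
    flips the mask exactly (foreground <= t) for dark-root setups.
    """
    if image.n_channels != 1:
        raise ValueError("segment expects a single-channel image")
    fg = image.pixels.astype(float) > threshold
    if invert:
        fg = ~fg
    if not fg.any():
        warnings.warn("segmentation produced an empty foreground")
    return BinaryMask(fg, image.dpi)


def filter_objects(
    mask: BinaryMask,
    seed: tuple[int, int] | None = None,
    min_area: int = 50,
    search_radius: int = 300,
) -> BinaryMask:
    """Keep the root-system component, drop condensation specks and debris.

    Retains the 8-connected component containing the seed pixel (row, col) —
    or the component nearest to it within ``search_radius`` px — plus any
    component of area >= ``min_area`` px^2 lying within a one-pixel gap of
    the retained region (fragments of root severed by noise). Everything
    else is removed; no foreground pixel is ever added. The default seed is
    the top-centre of the image, where the seedling is transferred onto the
    paper.
    """
    px = mask.pixels
    if seed is None:
        seed = (0, px.shape[1] // 2)
    r, c = int(seed[0]), int(seed[1])
    if not (0 <= r < px.shape[0] and 0 <= c < px.shape[1]):
        raise ValueError(f"seed {seed} outside image bounds {px.shape}")
    labels, n = ndimage.label(px, structure=np.ones((3, 3), int))
    if n == 0:
        warnings.warn("mask is empty; nothing to filter")
        return BinaryMask(np.zeros_like(px), mask.dpi)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    target = labels[r, c]
    if target == 0 or areas[target - 1] < min_area:
        # seed sits on background or on a speck: snap to the nearest component
        # large enough to be the root system
        big = np.isin(labels, 1 + np.flatnonzero(areas >= min_area)) & px
        if target != 0 and not big.any():
            big = px  # everything is below min_area; fall back to any component
        ys, xs = np.nonzero(big)
        if len(ys) == 0:
            raise ValueError(f"no component of area >= {min_area} px^2 in the mask")
        d2 = (ys - r) ** 2 + (xs - c) ** 2
        imin = int(np.argmin(d2))
        if d2[imin] > search_radius**2 and target == 0:
            raise ValueError(
                f"no root-system component within {search_radius} px of seed {seed}"
            )
        target = labels[ys[imin], xs[imin]]
    keep = labels == target
    # attach >= min_area components that come within a 1-px gap of the kept set
    changed = True
    while changed:
        changed = False
        halo = ndimage.binary_dilation(keep, structure=np.ones((3, 3), bool), iterations=2)
        touching = np.unique(labels[halo & px])
        for lab in touching:
            if lab == 0 or keep[labels == lab].all():
                continue
            if areas[lab - 1] >= min_area:
                keep |= labels == lab
                changed = True
    return BinaryMask(keep, mask.dpi)


def _trace_component_boundary(comp: np.ndarray) -> float:
    """Moore-neighbour boundary trace of one 8-connected component.

    Returns the traced path length in pixel steps (1 axial, sqrt(2)
    diagonal). A single-pixel component has, by this step convention, a
    perimeter of 0.
    """
    ys, xs = np.nonzero(comp)
    if len(ys) <= 1:
        return 0.0
    h, w = comp.shape
    order = np.lexsort((xs, ys))  # topmost, then leftmost
    start = (int(ys[order[0]]), int(xs[order[0]]))
    came_from = 4  # pretend we arrived heading East, so backtrack points West
    cur = start
    length = 0.0
    max_steps = 4 * comp.size
    for _ in range(max_steps):
        nxt = None
        for k in range(8):
            d = (came_from + 1 + k) % 8
            ny, nx = cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1]
            if 0 <= ny < h and 0 <= nx < w and comp[ny, nx]:
                nxt = (ny, nx)
                step = 1.0 if _MOORE[d][0] == 0 or _MOORE[d][1] == 0 else np.sqrt(2.0)
                came_from = (d + 4) % 8
                break
        if nxt is None:  # isolated pixel
            return 0.0
        length += step
        cur = nxt
        if cur == start:
            return length
    return length  # unreachable in practice; guards malformed masks


def boundary_perimeter(mask: BinaryMask) -> float:
    """Total outer-boundary length of all components, in cm.

    Each component's outer edge is traced through the Moore neighbourhood;
    axial steps count 1 px and diagonal steps sqrt(2) px.
    """
    px = mask.pixels
    if not px.any():
        warnings.warn("empty mask; perimeter is 0")
        return 0.0
    labels, n = ndimage.label(px, structure=np.ones((3, 3), int))
    total_px = 0.0
    for lab in range(1, n + 1):
        total_px += _trace_component_boundary(labels == lab)
    return total_px * mask.cm_per_px


def skeleton_length(mask: BinaryMask) -> float:
    """Total root length in cm from the 1-px skeleton of the mask.

    The mask is thinned to a unit-width skeleton; length is the sum over
    adjacent skeleton-pixel pairs of 1 (axial) or sqrt(2) (diagonal) pixel
    steps. A diagonal pair is skipped whenever the two pixels also share an
    axial skeleton neighbour, so staircase corners are not double counted.
    """
    px = mask.pixels
    if not px.any():
        return 0.0
    skel = skeletonize(px)
    length_px = _skeleton_length_px(skel)
    return length_px * mask.cm_per_px


def _skeleton_length_px(skel: np.ndarray) -> float:
    s = skel.astype(bool)
    # axial adjacencies
    n_horiz = np.count_nonzero(s[:, :-1] & s[:, 1:])
    n_vert = np.count_nonzero(s[:-1, :] & s[1:, :])
    # diagonal adjacencies, discounting those bridged by an axial neighbour
    pad = np.pad(s, 1, constant_values=False)
    core = pad[1:-1, 1:-1]
    diag = 0
    for dy, dx in ((1, 1), (1, -1)):
        a = core
        b = pad[1 + dy : pad.shape[0] - 1 + dy, 1 + dx : pad.shape[1] - 1 + dx]
        # shared axial neighbours of the diagonal pair
        c1 = pad[1 + dy : pad.shape[0] - 1 + dy, 1:-1]
        c2 = pad[1:-1, 1 + dx : pad.shape[1] - 1 + dx]
        diag += np.count_nonzero(a & b & ~(c1 | c2))
    return float(n_horiz + n_vert) + float(diag) * np.sqrt(2.0)


def convex_hull_area(mask: BinaryMask) -> float:
    """Area of the convex hull of foreground pixel centres, in cm^2."""
    ys, xs = np.nonzero(mask.pixels)
    if len(ys) < 3:
        warnings.warn("fewer than 3 foreground pixels; hull area is 0")
        return 0.0
    pts = np.column_stack([xs, ys]).astype(float)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        warnings.warn("collinear foreground; hull area is 0")
        return 0.0
    return float(hull.volume) * mask.cm_per_px**2


def measure_global_traits(mask: BinaryMask) -> GlobalTraits:
    """Bundle the four global traits measured on a cleaned mask."""
    px = mask.pixels
    if not px.any():
        warnings.warn("empty mask; all global traits are 0")
        return GlobalTraits(0.0, 0.0, 0.0, 0.0)
    area = float(np.count_nonzero(px)) * mask.cm_per_px**2
    return GlobalTraits(
        total_root_length=skeleton_length(mask),
        total_area=area,
        perimeter=boundary_perimeter(mask),
        convex_hull_area=convex_hull_area(mask),
    )


def segment_pipeline(
    image: RasterImage,
    median_radius: int = 1,
    gaussian_sigma: float = 1.0,
    window_radius: int = 25,
    min_area: int = 50,
    seed: tuple[int, int] | None = None,
    invert: bool = False,
) -> BinaryMask:
    """Full restoration + segmentation chain from a raw scan to a clean mask."""
    img = to_grayscale_red(image) if image.n_channels == 3 else image
    img = denoise(img, median_radius, gaussian_sigma)
    img = flatten_background(img, window_radius)
    t = tsai_moment_threshold(img)
    mask = segment(img, t, invert=invert)
    if not mask.pixels.any():
        return mask
    return filter_objects(mask, seed=seed, min_area=min_area)
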