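"""Geometric shape descriptors for seed outlines.

Descriptors are computed from a closed simple polygon (coordinates in
cm) or a binary raster mask with a known pixel size. Definitions:

* area, perimeter — surface enclosed by / length of the contour;
* max/min diameter — the longest/shortest straight chord through the
  centroid (evaluated on a fan of equally spaced directions), not Feret
  calipers;
* circularity — area divided by the area of the circle whose diameter
  equals the maximum diameter; 1 for a circle, < 1 for anything else
  with the same maximum diameter. This form is sensitive to elongation
  and insensitive to contour roughness;
* sphericity — perimeter^2 / area, equal to 4*pi (~12.57) for a circle
  and larger for any other shape;
* rectangularity — area over the area of the minimum-area enclosing
  rectangle; 1 for rectangles;
* irregularity — convexity deficit 1 - P_hull / P (0 for convex
  outlines, growing with contour roughness). This is a documented proxy
  for instrument-specific "contour irregularity" measures whose exact
  algorithms are proprietary;
* n_corners — count of local maxima of contour curvature exceeding a
  multiple of the median curvature, on a smoothed arc-length-resampled
  contour. Also a documented proxy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from shapely.geometry import LineString, Polygon
from skimage import measure as skmeasure


@dataclass
class ShapeDescriptors:
    area: float
    perimeter: float
    max_diameter: float
    min_diameter: float
    circularity: float
    sphericity: float
    rectangularity: float
    irregularity: float
    n_corners: int

    def as_dict(self) -> dict:
        return dict(vars(self))


def polygon_from_mask(mask: np.ndarray, pixel_size: float = 1.0) -> Polygon:
    """Trace the outline of a single-component binary mask as a polygon.

    Raises if the foreground has zero or more than one connected
    component. Coordinates are scaled by ``pixel_size`` (cm/pixel).
    """
    mask = np.asarray(mask).astype(bool)
    labels, n = skmeasure.label(mask, return_num=True)
    if n == 0:
        raise ValueError("mask has no foreground component")
    if n > 1:
        raise ValueError(f"mask has {n} connected foreground components; expected one")
    padded = np.pad(mask.astype(float), 1)
    contours = skmeasure.find_contours(padded, 0.5)
    contour = max(contours, key=len)
    # find_contours yields (row, col); convert to (x, y) and undo padding
    xy = np.column_stack([contour[:, 1] - 1, contour[:, 0] - 1]) * pixel_size
    poly = Polygon(xy)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def _as_polygon(shape) -> Polygon:
    if isinstance(shape, Polygon):
        poly = shape
    elif isinstance(shape, tuple) and len(shape) == 2 and isinstance(shape[0], np.ndarray):
        poly = polygon_from_mask(shape[0], shape[1])
    else:
        coords = np.asarray(shape, float)
        if coords.ndim != 2 or coords.shape[0] < 3 or coords.shape[1] != 2:
            raise ValueError("polygon must be an (n>=3) x 2 coordinate array")
        poly = Polygon(coords)
    if not poly.is_valid or not poly.is_simple:
        raise ValueError("polygon must be simple (non-self-intersecting)")
    if poly.area <= 0:
        raise ValueError("degenerate shape: zero area")
    return poly


def _centroid_chords(poly: Polygon, n_directions: int) -> tuple[float, float]:
    cx, cy = poly.centroid.x, poly.centroid.y
    minx, miny, maxx, maxy = poly.bounds
    reach = 2.0 * max(maxx - minx, maxy - miny)
    lengths = np.empty(n_directions)
    for i, theta in enumerate(np.linspace(0.0, math.pi, n_directions, endpoint=False)):
        dx, dy = reach * math.cos(theta), reach * math.sin(theta)
        line = LineString([(cx - dx, cy - dy), (cx + dx, cy + dy)])
        lengths[i] = poly.intersection(line).length
    return float(lengths.max()), float(lengths.min())


def _resample_contour(poly: Polygon, n_points: int) -> np.ndarray:
    xy = np.asarray(poly.exterior.coords)  # closed: first == last
    seg = np.hypot(*np.diff(xy, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    target = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(target, s, xy[:, 0])
    y = np.interp(target, s, xy[:, 1])
    return np.column_stack([x, y])


def _count_corners(
    poly: Polygon, n_points: int, smooth_frac: float, threshold_factor: float
) -> int:
    pts = _resample_contour(poly, n_points)
    sigma = max(smooth_frac * n_points, 1.0)
    x = gaussian_filter1d(pts[:, 0], sigma, mode="wrap")
    y = gaussian_filter1d(pts[:, 1], sigma, mode="wrap")
    dx, dy = np.gradient(x), np.gradient(y)
    ddx, ddy = np.gradient(dx), np.gradient(dy)
    denom = (dx * dx + dy * dy) ** 1.5
    denom[denom == 0] = np.finfo(float).tiny
    kappa = np.abs(dx * ddy - dy * ddx) / denom
    thresh = threshold_factor * np.median(kappa)
    # circular peak finding: pad with wrap, require a minimum separation
    # so one rounded corner is never counted twice
    pad = n_points // 8
    extended = np.concatenate([kappa[-pad:], kappa, kappa[:pad]])
    idx, _ = find_peaks(extended, height=thresh, distance=max(3, n_points // 64))
    idx = idx[(idx >= pad) & (idx < pad + n_points)]
    return int(len(idx))


def measure_shape(
    shape,
    *,
    n_directions: int = 360,
    corner_points: int = 512,
    corner_smooth_frac: float = 0.01,
    corner_threshold_factor: float = 2.0,
) -> ShapeDescriptors:
    """Compute all geometric descriptors of one shape.

    ``shape`` may be a shapely Polygon, an (n, 2) vertex array, or a
    ``(mask, pixel_size)`` pair for a binary raster.
    """
    poly = _as_polygon(shape)
    area = poly.area
    perimeter = poly.exterior.length
    dmax, dmin = _centroid_chords(poly, n_directions)
    if dmax <= 0:
        raise ValueError("degenerate shape: zero maximum diameter")
    circularity = area / (math.pi * (dmax / 2.0) ** 2)
    sphericity = perimeter**2 / area
    rect = poly.minimum_rotated_rectangle.area
    rectangularity = area / rect if rect > 0 else 1.0
    hull_perimeter = poly.convex_hull.exterior.length
    irregularity = max(1.0 - hull_perimeter / perimeter, 0.0)
    n_corners = _count_corners(poly, corner_points, corner_smooth_frac, corner_threshold_factor)
    return ShapeDescriptors(
        area=float(area),
        perimeter=float(perimeter),
        max_diameter=dmax,
        min_diameter=dmin,
        circularity=float(circularity),
        sphericity=float(sphericity),
        rectangularity=float(min(rectangularity, 1.0)),
        irregularity=float(irregularity),
        n_corners=n_corners,
    )


def circle_polygon(radius: float = 1.0, n_vertices: int = 4096, center=(0.0, 0.0)) -> Polygon:
    """Regular n-gon approximation of a circle (analytic test shape)."""
    t = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    return Polygon(np.column_stack([center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)]))


def superellipse_polygon(
    a: float, b: float, exponent: float = 2.0, n_vertices: int = 256
) -> Polygon:
    """Superellipse |x/a|^m + |y/b|^m = 1 as a polygon.

    ``m = 2`` gives an ellipse; larger exponents approach a rectangle,
    which mimics the range of bean outlines.
    """
    if a <= 0 or b <= 0 or exponent <= 0:
        raise ValueError(f"degenerate superellipse parameters a={a}, b={b}, m={exponent}")
    t = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    c, s = np.cos(t), np.sin(t)
    x = a * np.sign(c) * np.abs(c) ** (2.0 / exponent)
    y = b * np.sign(s) * np.abs(s) ** (2.0 / exponent)
    return Polygon(np.column_stack([x, y]))
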