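"""Foci as nested iso-intensity contour loops and curvature-maximum outlines.

A focus candidate is a pair of closed marching-squares contour loops
``(outer C_k, inner C_j)`` in one cell: the outer at the lower intensity
``I_k`` with perimeter at most ``L_max``, the inner at the higher intensity
``I_j`` with perimeter at least ``L_min``, the outer containing the inner.
Because iso-contours at different levels never cross, candidates nest and
clumped foci need no explicit splitting.

The final outline of a candidate is the contour at the intensity ``I_opt``
(``I_k < I_opt < I_j``) where the radial intensity profile — reconstructed
by inverting ``r(I) = sqrt(a(I)/pi)``, with ``a(I)`` the enclosed-area
function sampled between the two loops — has its maximum second derivative.
For a Gaussian profile ``exp(-r^2/2s^2)`` this radius is ``sqrt(3)*s``;
unlike the inflection point it exists even for profiles without one, and it
introduces no free parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Point, Polygon
from skimage import measure

from .preprocess import CellRegion


@dataclass
class ContourLoop:
    """Closed sub-pixel iso-intensity polygon."""

    vertices: np.ndarray  # (n, 2) closed (row, col), first == last
    level: float  # iso-intensity in normalized units
    length: float  # perimeter, px
    area: float  # enclosed area, px^2 (shoelace)

    def shapely_polygon(self) -> Polygon:
        poly = getattr(self, "_poly", None)
        if poly is None:
            poly = Polygon(self.vertices[:, ::-1])
            if not poly.is_valid:
                poly = poly.buffer(0)
            object.__setattr__(self, "_poly", poly)
        return poly

    def contains_point(self, point: tuple[float, float]) -> bool:
        return bool(self.shapely_polygon().contains(Point(point[1], point[0])))

    @property
    def centroid(self) -> tuple[float, float]:
        v = self.vertices[:-1]
        return float(v[:, 0].mean()), float(v[:, 1].mean())

    @property
    def interior_point(self) -> tuple[float, float]:
        return self.centroid


@dataclass
class FocusCandidate:
    """(outer, inner) loop pair; the outer (dimmer) contains the inner."""

    outer: ContourLoop
    inner: ContourLoop
    region: CellRegion | None = None

    def __post_init__(self) -> None:
        if self.outer.level >= self.inner.level:
            raise ValueError("outer contour must sit at a lower intensity")


@dataclass
class FocusOutline:
    """Final focus boundary at the curvature-maximum intensity."""

    contour: ContourLoop
    area: float  # px^2, after optional area scaling
    centroid: tuple[float, float]
    intensity_max: float  # raw-patch statistics inside the contour
    intensity_min: float
    intensity_mean: float
    source_candidates: list[int] = field(default_factory=list)
    fallback_midpoint: bool = False

    @property
    def equivalent_radius(self) -> float:
        return math.sqrt(self.area / math.pi)


def _loop_length(vertices: np.ndarray) -> float:
    d = np.diff(vertices, axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def _shoelace(vertices: np.ndarray) -> float:
    r, c = vertices[:, 0], vertices[:, 1]
    return float(abs(np.sum(r[:-1] * c[1:] - r[1:] * c[:-1])) / 2.0)


def _closed(contour: np.ndarray) -> bool:
    return bool(np.allclose(contour[0], contour[-1]))


def _inside_mask(contour: np.ndarray, mask: np.ndarray) -> bool:
    rr = np.clip(np.round(contour[:, 0]).astype(int), 0, mask.shape[0] - 1)
    cc = np.clip(np.round(contour[:, 1]).astype(int), 0, mask.shape[1] - 1)
    return bool(mask[rr, cc].all())


def extract_loops(
    region: CellRegion, n_levels: int = 64, min_vertices: int = 4
) -> list[ContourLoop]:
    """All closed in-mask iso-contour loops at evenly spaced levels in (0, 1)."""
    if n_levels < 8:
        raise ValueError("n_levels must be >= 8")
    img = region.normalized
    loops: list[ContourLoop] = []
    levels = np.linspace(0.0, 1.0, n_levels + 2)[1:-1]
    for level in levels:
        for contour in measure.find_contours(img, level):
            if len(contour) < min_vertices or not _closed(contour):
                continue
            if not _inside_mask(contour, region.mask):
                continue
            area = _shoelace(contour)
            if area <= 0:
                continue
            loops.append(
                ContourLoop(
                    vertices=contour,
                    level=float(level),
                    length=_loop_length(contour),
                    area=area,
                )
            )
    return loops


def build_candidates(
    loops: list[ContourLoop],
    L_min: float,
    L_max: float,
    region: CellRegion | None = None,
) -> list[FocusCandidate]:
    """Pair qualifying inner loops with their outermost qualifying container.

    An inner loop qualifies with perimeter >= ``L_min``; among nested
    qualifying loops around one peak only the innermost (highest level) is
    kept, so a single peak yields a single candidate. Its outer partner is
    the outermost containing loop (lowest level) with perimeter <= ``L_max``.
    An outer shared by several inner loops produces one candidate per inner;
    the final-outline step later merges or keeps them.
    """
    if not (0 < L_min < L_max):
        raise ValueError("need 0 < L_min < L_max")
    qualifying = [lp for lp in loops if lp.length >= L_min]
    inners: list[ContourLoop] = []
    for lp in qualifying:
        contains_other = any(
            other is not lp
            and other.level > lp.level
            and lp.contains_point(other.interior_point)
            for other in qualifying
        )
        if not contains_other:
            inners.append(lp)
    candidates: list[FocusCandidate] = []
    for inner in inners:
        containers = [
            lp
            for lp in loops
            if lp.length <= L_max
            and lp.level < inner.level
            and lp.contains_point(inner.interior_point)
        ]
        if not containers:
            continue
        outer = min(containers, key=lambda lp: (lp.level, -lp.length))
        candidates.append(FocusCandidate(outer=outer, inner=inner, region=region))
    return candidates


def _bbox(vertices: np.ndarray, shape: tuple[int, int], margin: int = 3):
    r0 = max(int(np.floor(vertices[:, 0].min())) - margin, 0)
    r1 = min(int(np.ceil(vertices[:, 0].max())) + margin + 1, shape[0])
    c0 = max(int(np.floor(vertices[:, 1].min())) - margin, 0)
    c1 = min(int(np.ceil(vertices[:, 1].max())) + margin + 1, shape[1])
    return r0, r1, c0, c1


def _contour_containing(
    img: np.ndarray,
    level: float,
    point: tuple[float, float],
    mask: np.ndarray,
    bbox: tuple[int, int, int, int] | None = None,
) -> ContourLoop | None:
    """The closed in-mask contour at ``level`` that contains ``point``.

    ``bbox`` restricts the marching-squares search to a subimage known to
    contain the sought contour (iso-contours between a candidate's levels
    all nest inside its outer loop).
    """
    if bbox is not None:
        r0, r1, c0, c1 = bbox
        sub_img = img[r0:r1, c0:c1]
        sub_mask = mask[r0:r1, c0:c1]
        found = _contour_containing(
            sub_img, level, (point[0] - r0, point[1] - c0), sub_mask
        )
        if found is None:
            return None
        verts = found.vertices + np.array([r0, c0])
        return ContourLoop(
            vertices=verts, level=found.level, length=found.length, area=found.area
        )
    for contour in measure.find_contours(img, level):
        if len(contour) < 4 or not _closed(contour):
            continue
        if not _inside_mask(contour, mask):
            continue
        poly = Polygon(contour[:, ::-1])
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.contains(Point(point[1], point[0])):
            return ContourLoop(
                vertices=contour,
                level=float(level),
                length=_loop_length(contour),
                area=_shoelace(contour),
            )
    return None


def area_function(
    candidate: FocusCandidate,
    region: CellRegion,
    n_eval: int = 32,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled enclosed-area function ``a(I)`` between the two loops.

    Returns ``(levels, areas)`` with levels increasing from ``I_k`` to
    ``I_j``; ``a`` is monotone non-increasing (the contour at a higher level
    is nested inside the one at a lower level). Levels whose contour is
    broken by the cell mask are skipped with a warning.
    """
    img = region.normalized
    point = candidate.inner.interior_point
    bbox = _bbox(candidate.outer.vertices, img.shape)
    levels = np.linspace(candidate.outer.level, candidate.inner.level, n_eval)
    out_levels: list[float] = []
    out_areas: list[float] = []
    for lv in levels:
        loop = _contour_containing(img, float(lv), point, region.mask, bbox=bbox)
        if loop is None:
            warnings.warn(f"contour broken at level {lv:.3f}; skipped", stacklevel=2)
            continue
        out_levels.append(float(lv))
        out_areas.append(loop.area)
    return np.asarray(out_levels), np.asarray(out_areas)


def optimal_intensity(
    levels: np.ndarray,
    areas: np.ndarray,
    n_grid: int = 64,
    smooth_window: int | None = None,
) -> tuple[float, bool]:
    """Intensity of maximum curvature of the reconstructed radial profile.

    Inverts ``r(I) = sqrt(a(I)/pi)`` to the radial intensity profile
    ``I(r)``, resamples it on a uniform radius grid and estimates the
    second derivative with a Savitzky-Golay quadratic fit whose window
    adapts to the largest sample gap (piecewise-linear interpolation
    concentrates curvature at the knots; a local parabola fit spanning
    several knots recovers the underlying profile's curvature instead of
    the kinks). ``I_opt`` is the level at the global maximum of
    ``d^2 I / d r^2``; ties prefer the lower intensity (larger contour).
    Returns ``(I_opt, fallback)``; with fewer than 5 usable samples the
    midpoint intensity is returned with ``fallback`` True.
    """
    from scipy.signal import savgol_filter

    levels = np.asarray(levels, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if len(levels) != len(areas):
        raise ValueError("levels and areas must have equal length")
    if len(levels) < 5:
        warnings.warn("fewer than 5 area samples; midpoint fallback", stacklevel=2)
        mid = float(levels.mean()) if len(levels) else 0.5
        return mid, True
    # enforce monotone non-increasing a(I) (resolve sampling ties)
    areas = np.minimum.accumulate(areas)
    r = np.sqrt(areas / math.pi)
    # r decreases with I; build I(r) on an increasing-r grid
    order = np.argsort(r)
    r_sorted = r[order]
    I_sorted = levels[order]
    keep = np.concatenate([[True], np.diff(r_sorted) > 1e-12])
    r_sorted, I_sorted = r_sorted[keep], I_sorted[keep]
    if len(r_sorted) < 5:
        return float(levels.mean()), True
    r_grid = np.linspace(r_sorted[0], r_sorted[-1], n_grid)
    h = r_grid[1] - r_grid[0]
    I_grid = np.interp(r_grid, r_sorted, I_sorted)
    if smooth_window is None:
        max_gap = float(np.max(np.diff(r_sorted)))
        smooth_window = 2 * max(2, math.ceil(max_gap / h)) + 1
    window = int(min(max(smooth_window, 5), n_grid - 1 - (n_grid % 2 == 0)))
    if window % 2 == 0:
        window += 1
    d2 = savgol_filter(I_grid, window_length=window, polyorder=2, deriv=2, delta=h)
    # suppress half-window edge artifacts of the local fits
    guard = window // 2
    interior = slice(guard, n_grid - guard) if n_grid > 2 * guard + 1 else slice(None)
    d2_int = d2[interior]
    offset = interior.start or 0
    best = float(np.max(d2_int))
    ties = np.flatnonzero(d2_int >= best - 1e-12)
    # lower intensity = larger radius = later grid index
    idx = int(ties.max()) + offset
    I_opt = float(I_grid[idx])
    lo, hi = float(levels.min()), float(levels.max())
    eps = 1e-9 + (hi - lo) * 1e-6
    return float(np.clip(I_opt, lo + eps, hi - eps)), False


def _raw_stats_inside(
    loop: ContourLoop, region: CellRegion
) -> tuple[float, float, float]:
    rr, cc = np.nonzero(region.mask)
    poly = Polygon(loop.vertices[:, ::-1])
    if not poly.is_valid:
        poly = poly.buffer(0)
    inside = shapely.contains_xy(poly, cc, rr)
    if not inside.any():
        # tiny contour: fall back to the nearest pixel to the centroid
        cen = loop.centroid
        r0 = int(np.clip(round(cen[0]), 0, region.raw.shape[0] - 1))
        c0 = int(np.clip(round(cen[1]), 0, region.raw.shape[1] - 1))
        v = float(region.raw[r0, c0])
        return v, v, v
    vals = region.raw[rr[inside], cc[inside]]
    return float(vals.max()), float(vals.min()), float(vals.mean())


def _scale_about_centroid(loop: ContourLoop, area_scale: float) -> ContourLoop:
    if area_scale == 1.0:
        return loop
    factor = math.sqrt(area_scale)
    cen = np.array(loop.centroid)
    verts = cen + factor * (loop.vertices - cen)
    return ContourLoop(
        vertices=verts,
        level=loop.level,
        length=_loop_length(verts),
        area=_shoelace(verts),
    )


def finalize_foci(
    candidates: list[FocusCandidate],
    region: CellRegion,
    area_scale: float = 1.0,
    n_eval: int = 32,
) -> list[FocusOutline]:
    """Final outline per candidate; coinciding outlines merge into one focus.

    Two candidates around nearby peaks merge exactly when their optimal
    contours are the same loop, i.e. ``I_opt`` falls below the saddle
    between the peaks.
    """
    found: list[tuple[ContourLoop, int, bool]] = []
    for idx, cand in enumerate(candidates):
        levels, areas = area_function(cand, region, n_eval=n_eval)
        I_opt, fallback = optimal_intensity(levels, areas)
        loop = _contour_containing(
            region.normalized,
            I_opt,
            cand.inner.interior_point,
            region.mask,
            bbox=_bbox(cand.outer.vertices, region.normalized.shape),
        )
        if loop is not None:
            found.append((loop, idx, fallback))

    # candidates whose optimal contours coincide or nest are one focus;
    # cluster by polygon overlap and keep each cluster's outermost contour
    n = len(found)
    parent = list(range(n))

    def _root(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            pi = found[i][0].shapely_polygon()
            pj = found[j][0].shapely_polygon()
            if pi.intersection(pj).area > 1e-9:
                parent[_root(j)] = _root(i)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(_root(i), []).append(i)

    results: list[FocusOutline] = []
    for members in clusters.values():
        outer_i = max(members, key=lambda i: found[i][0].area)
        loop = found[outer_i][0]
        scaled = _scale_about_centroid(loop, area_scale)
        imax, imin, imean = _raw_stats_inside(scaled, region)
        results.append(
            FocusOutline(
                contour=scaled,
                area=scaled.area,
                centroid=scaled.centroid,
                intensity_max=imax,
                intensity_min=imin,
                intensity_mean=imean,
                source_candidates=sorted(found[i][1] for i in members),
                fallback_midpoint=any(found[i][2] for i in members),
            )
        )
    results.sort(key=lambda f: f.source_candidates[0])
    return results


def detect_foci(
    region: CellRegion,
    L_min: float,
    L_max: float,
    n_levels: int = 64,
    n_eval: int = 32,
    area_scale: float = 1.0,
) -> tuple[list[FocusCandidate], list[FocusOutline]]:
    """Convenience chain: loops -> candidates -> final outlines for one cell."""
    loops = extract_loops(region, n_levels=n_levels)
    candidates = build_candidates(loops, L_min, L_max, region=region)
    foci = finalize_foci(candidates, region, area_scale=area_scale, n_eval=n_eval)
    return candidates, foci
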