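"""Cell segmentation from brightfield images.

Yeast cells appear in brightfield as roughly elliptical rings. The chain is:

1. ridge detection (Frangi vesselness, thresholded) -> draft outline mask
2. mask cleaning by blob size / eccentricity / solidity
3. thinning to a 1-px skeleton
4. ellipse-approximation scoring of candidate center points: for every pixel
   whose distance to the skeleton lies in ``[r_min, r_max]`` an ellipse is
   fitted to nearby skeleton points and the sum of squared distances is the
   score; local minima of the score map are cell-center hypotheses
5. boundary snapping of the fitted ellipse with a greedy active contour

All steps are deterministic; physical parameters are given in pixels here,
with nm -> px conversion handled by the pipeline configuration so that
settings transfer between magnifications.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw, filters, measure, morphology


@dataclass
class CellOutline:
    """Closed sub-pixel cell boundary with its raster mask."""

    polygon: np.ndarray  # (n, 2) closed (row, col) vertices, first == last
    mask: np.ndarray  # binary image, full-frame
    centroid: tuple[float, float]
    area: float  # px^2
    rejected: bool = False
    reject_reason: str = ""

    @property
    def equivalent_radius(self) -> float:
        return math.sqrt(self.area / math.pi)


@dataclass
class CenterScoreMap:
    """Ellipse-approximation error per candidate center point."""

    score: np.ndarray  # 2-D, NaN where not a candidate
    candidate_points: np.ndarray  # (n, 2) int (row, col)
    minima: list[tuple[tuple[int, int], "FittedEllipse", float]] = field(
        default_factory=list
    )


@dataclass(frozen=True)
class FittedEllipse:
    center: tuple[float, float]  # (row, col)
    semi_axes: tuple[float, float]
    orientation: float

    def polygon(self, n: int = 100) -> np.ndarray:
        t = np.linspace(0, 2 * math.pi, n + 1)
        a, b = self.semi_axes
        u = a * np.cos(t)
        v = b * np.sin(t)
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        rows = self.center[0] + c * u - s * v
        cols = self.center[1] + s * u + c * v
        return np.column_stack([rows, cols])


def detect_ridges(
    brightfield: np.ndarray,
    scale_range: tuple[float, float] = (1.0, 3.0),
    threshold: float = 0.05,
    n_scales: int = 5,
    black_ridges: bool = False,
) -> np.ndarray:
    """Frangi vesselness filter thresholded into a draft outline mask.

    ``black_ridges`` selects whether cell edges appear dark or bright in
    the brightfield modality at hand.
    """
    img = np.asarray(brightfield, dtype=float)
    if img.ndim != 2:
        raise ValueError("brightfield must be 2-D grayscale")
    if img.size == 0 or np.ptp(img) == 0:
        warnings.warn("constant or empty image: no ridges", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    sigmas = np.linspace(scale_range[0], scale_range[1], n_scales)
    vesselness = filters.frangi(img, sigmas=sigmas, black_ridges=black_ridges)
    return vesselness > threshold


def clean_mask(
    mask: np.ndarray,
    min_size: float = 50,
    max_size: float = 1e5,
    eccentricity_bounds: tuple[float, float] = (0.0, 1.0),
    solidity_bounds: tuple[float, float] = (0.0, 1.0),
) -> np.ndarray:
    """Keep only connected blobs satisfying area/eccentricity/solidity bounds."""
    labeled = measure.label(np.asarray(mask, dtype=bool))
    out = np.zeros(mask.shape, dtype=bool)
    for prop in measure.regionprops(labeled):
        if not (min_size <= prop.area <= max_size):
            continue
        if not (eccentricity_bounds[0] <= prop.eccentricity <= eccentricity_bounds[1]):
            continue
        if not (solidity_bounds[0] <= prop.solidity <= solidity_bounds[1]):
            continue
        out[labeled == prop.label] = True
    return out


def skeletonize_outlines(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning to a 1-px-wide skeleton."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    skel = morphology.skeletonize(mask)
    # thinning may drop isolated single pixels; they are already thin, keep them
    n_neighbors = ndimage.convolve(mask.astype(int), np.ones((3, 3)), mode="constant")
    skel |= mask & (n_neighbors == 1)
    return skel


def _fit_ellipse(points: np.ndarray) -> FittedEllipse | None:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = measure.EllipseModel.from_estimate(points[:, ::-1].astype(float))
    if not model:
        return None
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not all(np.isfinite([xc, yc, a, b, theta])) or a <= 0 or b <= 0:
        return None
    return FittedEllipse(center=(yc, xc), semi_axes=(a, b), orientation=theta)


def _ellipse_sq_error(points: np.ndarray, ell: FittedEllipse) -> float:
    """Sum of squared point-to-ellipse distances (algebraic, gradient-normalized)."""
    dr = points[:, 0] - ell.center[0]
    dc = points[:, 1] - ell.center[1]
    c, s = math.cos(ell.orientation), math.sin(ell.orientation)
    # orientation is measured in (x, y) = (col, row) space
    u = c * dc + s * dr
    v = -s * dc + c * dr
    a, b = ell.semi_axes
    f = (u / a) ** 2 + (v / b) ** 2 - 1.0
    grad = 2 * np.sqrt((u / a**2) ** 2 + (v / b**2) ** 2)
    d = np.abs(f) / np.maximum(grad, 1e-12)
    return float(np.sum(d**2))


def score_cell_centers(
    skeleton: np.ndarray,
    r_min: float,
    r_max: float,
    angular_coverage_min: float = 0.75,
    error_per_point_max: float = 4.0,
    grid_stride: int = 1,
) -> CenterScoreMap:
    """Score candidate cell centers by local ellipse-approximation error.

    Candidate points are pixels whose Euclidean distance to the skeleton
    lies in ``[r_min, r_max]``. For each, skeleton points within ``r_max``
    are collected, an ellipse is fitted, and the summed squared distance is
    the score. Candidates whose surrounding skeleton leaves an angular gap
    larger than ``1 - angular_coverage_min`` of the full circle are dropped
    (open outlines are not cells). Local minima of the (lightly smoothed)
    score map are returned as cell-center hypotheses.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    if not (0 < r_min < r_max):
        raise ValueError("need 0 < r_min < r_max")
    score = np.full(skeleton.shape, np.nan)
    if not skeleton.any():
        return CenterScoreMap(score=score, candidate_points=np.empty((0, 2), int))

    dist = ndimage.distance_transform_edt(~skeleton)
    cand_mask = (dist >= r_min) & (dist <= r_max)
    if grid_stride > 1:
        sub = np.zeros_like(cand_mask)
        sub[::grid_stride, ::grid_stride] = True
        cand_mask &= sub
    cand = np.argwhere(cand_mask)
    skel_pts = np.argwhere(skeleton).astype(float)

    fits: dict[tuple[int, int], FittedEllipse] = {}
    for r, c in cand:
        d2 = (skel_pts[:, 0] - r) ** 2 + (skel_pts[:, 1] - c) ** 2
        near = skel_pts[d2 <= r_max**2]
        if len(near) < 5:
            continue  # ellipse under-determined
        ang = np.sort(np.arctan2(near[:, 0] - r, near[:, 1] - c))
        # an open outline leaves one large contiguous gap of directions;
        # coverage = 1 - largest circular gap between consecutive angles
        gaps = np.diff(ang)
        wrap = 2 * math.pi - (ang[-1] - ang[0])
        largest_gap = max(float(gaps.max(initial=0.0)), wrap)
        if 1.0 - largest_gap / (2 * math.pi) < angular_coverage_min:
            continue
        ell = _fit_ellipse(near)
        if ell is None:
            continue
        err = _ellipse_sq_error(near, ell)
        if err / len(near) > error_per_point_max:
            continue
        score[r, c] = err
        fits[(r, c)] = ell

    result = CenterScoreMap(score=score, candidate_points=cand)
    if not fits:
        return result

    # smooth to suppress plateau duplicates, then 8-neighborhood minima
    filled = np.where(np.isnan(score), np.nanmax(score) + 1.0, score)
    smooth = ndimage.gaussian_filter(filled, sigma=1.0)
    footprint = np.ones((3, 3), bool)
    local_min = smooth <= ndimage.minimum_filter(smooth, footprint=footprint)
    minima = [
        ((r, c), fits[(r, c)], float(score[r, c]))
        for r, c in fits
        if local_min[r, c]
    ]
    minima.sort(key=lambda m: m[2])
    # deduplicate: keep the lower-error minimum within r_min of another
    kept: list[tuple[tuple[int, int], FittedEllipse, float]] = []
    for m in minima:
        if all(
            (m[0][0] - k[0][0]) ** 2 + (m[0][1] - k[0][1]) ** 2 >= r_min**2
            for k in kept
        ):
            kept.append(m)
    result.minima = kept
    return result


def _bilinear(img: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(img, [rows, cols], order=1, mode="nearest")


def _polygon_mask(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = draw.polygon(polygon[:, 0], polygon[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def snap_boundary(
    ellipse: FittedEllipse,
    brightfield: np.ndarray,
    n_vertices: int = 64,
    search_px: float = 3.0,
    search_step: float = 0.5,
    alpha: float = 0.4,
    beta: float = 0.4,
    max_iter: int = 50,
    tol: float = 0.05,
    min_area: float = 20.0,
    max_area: float = 1e5,
    edge_image: np.ndarray | None = None,
) -> CellOutline:
    """Snap an ellipse to the cell boundary with a greedy active contour.

    Each vertex searches along its outward normal within ``±search_px`` for
    the position maximizing local edge strength, penalized by deviation
    from neighbor midpoints (elasticity ``alpha``) and local curvature
    (``beta``). Edge strength defaults to the brightfield intensity itself,
    since cell boundaries appear as bright ridges whose crest is the
    outline; pass ``edge_image`` (e.g. a gradient magnitude) to override.
    """
    img = np.asarray(brightfield, dtype=float)
    edge = img if edge_image is None else np.asarray(edge_image, dtype=float)
    rng_edge = float(np.ptp(edge))
    poly = ellipse.polygon(n_vertices)[:-1]  # open ring of n vertices

    if rng_edge <= 1e-12:
        return _make_outline(
            np.vstack([poly, poly[:1]]), img.shape, rejected=True, reason="flat image"
        )
    edge_n = (edge - edge.min()) / rng_edge
    offsets = np.arange(-search_px, search_px + 1e-9, search_step)

    for _ in range(max_iter):
        prev = np.roll(poly, 1, axis=0)
        nxt = np.roll(poly, -1, axis=0)
        tangent = nxt - prev
        norm = np.hypot(tangent[:, 0], tangent[:, 1])
        normal = np.column_stack([-tangent[:, 1], tangent[:, 0]]) / np.maximum(
            norm, 1e-12
        )[:, None]
        mid = 0.5 * (prev + nxt)
        best = poly.copy()
        best_energy = np.full(len(poly), np.inf)
        for off in offsets:
            trial = poly + off * normal
            e_ext = -_bilinear(edge_n, trial[:, 0], trial[:, 1])
            e_elastic = np.sum((trial - mid) ** 2, axis=1)
            e_curv = np.sum((prev - 2 * trial + nxt) ** 2, axis=1)
            energy = e_ext + alpha * e_elastic / max(search_px, 1.0) ** 2 + beta * e_curv / max(search_px, 1.0) ** 2
            improved = energy < best_energy
            best[improved] = trial[improved]
            best_energy[improved] = energy[improved]
        disp = np.max(np.hypot(*(best - poly).T))
        poly = best
        if disp < tol:
            break

    closed = np.vstack([poly, poly[:1]])
    area = _shoelace(closed)
    if not (min_area <= area <= max_area):
        return _make_outline(
            closed, img.shape, rejected=True, reason=f"area {area:.1f} out of bounds"
        )
    return _make_outline(closed, img.shape)


def _shoelace(closed_poly: np.ndarray) -> float:
    r, c = closed_poly[:, 0], closed_poly[:, 1]
    return float(abs(np.sum(r[:-1] * c[1:] - r[1:] * c[:-1])) / 2.0)


def _make_outline(
    closed_poly: np.ndarray,
    shape: tuple[int, int],
    rejected: bool = False,
    reason: str = "",
) -> CellOutline:
    mask = _polygon_mask(closed_poly, shape)
    area = _shoelace(closed_poly)
    if mask.any():
        centroid = tuple(np.mean(closed_poly[:-1], axis=0))
    else:
        centroid = (float("nan"), float("nan"))
    return CellOutline(
        polygon=closed_poly,
        mask=mask,
        centroid=centroid,  # type: ignore[arg-type]
        area=area,
        rejected=rejected,
        reject_reason=reason,
    )


def outline_from_mask(mask: np.ndarray) -> CellOutline:
    """Wrap an externally produced binary mask (segmentation bypass)."""
    mask = np.asarray(mask, dtype=bool)
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("empty mask")
    poly = max(contours, key=len)
    area = float(mask.sum())
    com = ndimage.center_of_mass(mask)
    return CellOutline(
        polygon=poly, mask=mask, centroid=(float(com[0]), float(com[1])), area=area
    )


@dataclass
class SegmentationParams:
    frangi_scales: tuple[float, float] = (1.0, 3.0)
    frangi_threshold: float = 0.05
    black_ridges: bool = False
    min_blob: float = 40
    max_blob: float = 1e5
    eccentricity_bounds: tuple[float, float] = (0.0, 1.0)
    solidity_bounds: tuple[float, float] = (0.0, 1.0)
    r_min: float = 8.0
    r_max: float = 30.0
    angular_coverage_min: float = 0.75
    grid_stride: int = 2
    min_area: float = 80.0
    max_area: float = 1e5
    max_overlap: float = 0.2
    snap_search_px: float = 3.0


def segment_cells(
    brightfield: np.ndarray, params: SegmentationParams | None = None
) -> list[CellOutline]:
    """Full brightfield -> cell outlines chain; deterministic and seed-free."""
    params = params or SegmentationParams()
    img = np.asarray(brightfield, dtype=float)
    ridges = detect_ridges(
        img,
        scale_range=params.frangi_scales,
        threshold=params.frangi_threshold,
        black_ridges=params.black_ridges,
    )
    cleaned = clean_mask(
        ridges,
        min_size=params.min_blob,
        max_size=params.max_blob,
        eccentricity_bounds=params.eccentricity_bounds,
        solidity_bounds=params.solidity_bounds,
    )
    skel = skeletonize_outlines(cleaned)
    centers = score_cell_centers(
        skel,
        r_min=params.r_min,
        r_max=params.r_max,
        angular_coverage_min=params.angular_coverage_min,
        grid_stride=params.grid_stride,
    )
    outlines: list[CellOutline] = []
    for _, ell, _err in centers.minima:
        out = snap_boundary(
            ell,
            img,
            search_px=params.snap_search_px,
            min_area=params.min_area,
            max_area=params.max_area,
        )
        if out.rejected:
            continue
        overlap_bad = False
        for prev in outlines:
            inter = np.logical_and(out.mask, prev.mask).sum()
            if inter / max(min(out.mask.sum(), prev.mask.sum()), 1) > params.max_overlap:
                overlap_bad = True
                break
        if not overlap_bad:
            outlines.append(out)
    return outlines
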