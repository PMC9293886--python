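"""Two-channel colocalization: Pearson correlation and foci geometry.

Given two fluorescence channels extracted with the *same* cell outlines,
computes per-cell and per-focus Pearson correlations on the raw patches,
and for every cross-channel focus pair the centroid distance, the boundary
(polygon edge-to-edge) distance, the overlap area and per-partner overlap
fractions, plus nearest-neighbor assignments. Distances and areas are
reported both in px and in nm via the pixel size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from shapely.geometry import Polygon

from .contours import FocusOutline
from .preprocess import CellRegion


@dataclass
class PairRecord:
    index_a: int
    index_b: int
    centroid_distance_px: float
    boundary_distance_px: float
    overlap_area_px2: float
    overlap_fraction_a: float
    overlap_fraction_b: float

    def scaled(self, pixel_size: float) -> dict:
        return {
            "index_a": self.index_a,
            "index_b": self.index_b,
            "centroid_distance_px": self.centroid_distance_px,
            "centroid_distance_nm": self.centroid_distance_px * pixel_size,
            "boundary_distance_px": self.boundary_distance_px,
            "boundary_distance_nm": self.boundary_distance_px * pixel_size,
            "overlap_area_px2": self.overlap_area_px2,
            "overlap_area_nm2": self.overlap_area_px2 * pixel_size**2,
            "overlap_fraction_a": self.overlap_fraction_a,
            "overlap_fraction_b": self.overlap_fraction_b,
        }


@dataclass
class ColocRecord:
    cell_id: int
    pearson: float | None
    pairs: list[PairRecord] = field(default_factory=list)
    nearest_in_b: dict[int, int] = field(default_factory=dict)
    nearest_in_a: dict[int, int] = field(default_factory=dict)


def _check_same_geometry(ch0: CellRegion, ch1: CellRegion) -> None:
    if ch0.raw.shape != ch1.raw.shape or not np.array_equal(ch0.mask, ch1.mask):
        raise ValueError(
            "channels must be extracted with identical cell outlines/masks"
        )


def pearson_cell(ch0: CellRegion, ch1: CellRegion) -> float | None:
    """Pearson r over in-mask raw pixels; None if either channel is constant."""
    _check_same_geometry(ch0, ch1)
    a = ch0.raw[ch0.mask]
    b = ch1.raw[ch1.mask]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    return float(stats.pearsonr(a, b).statistic)


def pearson_focus(
    focus: FocusOutline, ch0: CellRegion, ch1: CellRegion
) -> float | None:
    """Pearson r over raw pixels inside one focus contour (None if < 4 px)."""
    _check_same_geometry(ch0, ch1)
    from skimage import draw

    rr, cc = draw.polygon(
        focus.contour.vertices[:, 0], focus.contour.vertices[:, 1], shape=ch0.raw.shape
    )
    keep = ch0.mask[rr, cc]
    rr, cc = rr[keep], cc[keep]
    if len(rr) < 4:
        return None
    a, b = ch0.raw[rr, cc], ch1.raw[rr, cc]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    return float(stats.pearsonr(a, b).statistic)


def _poly(focus: FocusOutline) -> Polygon:
    p = Polygon(focus.contour.vertices[:, ::-1])
    return p if p.is_valid else p.buffer(0)


def pair_geometry(
    foci_a: list[FocusOutline],
    foci_b: list[FocusOutline],
) -> tuple[list[PairRecord], dict[int, int], dict[int, int]]:
    """All A x B pair geometries plus nearest neighbors by centroid distance.

    Boundary distance is the minimum distance between the two polygons'
    edges, 0 when they overlap or touch; overlap fractions are relative to
    each partner's own area (symmetric area, asymmetric fractions).
    """
    polys_a = [_poly(f) for f in foci_a]
    polys_b = [_poly(f) for f in foci_b]
    records: list[PairRecord] = []
    dist_matrix = np.full((len(foci_a), len(foci_b)), np.inf)
    for i, fa in enumerate(foci_a):
        for j, fb in enumerate(foci_b):
            cd = math.hypot(
                fa.centroid[0] - fb.centroid[0], fa.centroid[1] - fb.centroid[1]
            )
            dist_matrix[i, j] = cd
            bd = float(polys_a[i].distance(polys_b[j]))
            inter = float(polys_a[i].intersection(polys_b[j]).area)
            records.append(
                PairRecord(
                    index_a=i,
                    index_b=j,
                    centroid_distance_px=cd,
                    boundary_distance_px=bd,
                    overlap_area_px2=inter,
                    overlap_fraction_a=inter / polys_a[i].area if polys_a[i].area else 0.0,
                    overlap_fraction_b=inter / polys_b[j].area if polys_b[j].area else 0.0,
                )
            )
    nearest_in_b = {
        i: int(np.argmin(dist_matrix[i])) for i in range(len(foci_a)) if len(foci_b)
    }
    nearest_in_a = {
        j: int(np.argmin(dist_matrix[:, j])) for j in range(len(foci_b)) if len(foci_a)
    }
    return records, nearest_in_b, nearest_in_a


def colocalize_cell(
    cell_id: int,
    ch0: CellRegion,
    ch1: CellRegion,
    foci_a: list[FocusOutline],
    foci_b: list[FocusOutline],
) -> ColocRecord:
    pairs, nb, na = pair_geometry(foci_a, foci_b)
    return ColocRecord(
        cell_id=cell_id,
        pearson=pearson_cell(ch0, ch1),
        pairs=pairs,
        nearest_in_b=nb,
        nearest_in_a=na,
    )


def trend_fit(
    x: np.ndarray, y: np.ndarray, model: str = "linear"
) -> tuple[dict[str, float], float]:
    """Least-squares trend fit of a scatter: linear, power or exponential.

    power (``y = a * x**b``) and exponential (``y = a * exp(b*x)``) are fit
    by linear regression in log space. Returns (parameters, R^2), with R^2
    computed on the original scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; trend undefined")
    if model == "linear":
        slope, intercept = np.polyfit(x, y, 1)
        pred = slope * x + intercept
        params = {"slope": float(slope), "intercept": float(intercept)}
    elif model == "power":
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("power fit requires positive x and y")
        b, log_a = np.polyfit(np.log(x), np.log(y), 1)
        a = math.exp(log_a)
        pred = a * x**b
        params = {"prefactor": float(a), "exponent": float(b)}
    elif model == "exponential":
        if np.any(y <= 0):
            raise ValueError("exponential fit requires positive y")
        b, log_a = np.polyfit(x, np.log(y), 1)
        a = math.exp(log_a)
        pred = a * np.exp(b * x)
        params = {"prefactor": float(a), "rate": float(b)}
    else:
        raise ValueError(f"unknown model {model!r}")
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return params, r2
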