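"""Per-candidate feature vectors and dataset-level whitening/rescaling.

Eight features summarize each focus candidate, computed on the cell's
min-max-normalized patch (so they are invariant to affine rescaling of the
raw intensities):

1. maximum, minimum, mean intensity inside the final outline
2. area (px^2), eccentricity and solidity of the outline
3. outline area relative to cell area
4. mean intensity on the predicted outline / center intensity
5. mean intensity on the outer (longest) contour / center intensity
6. center intensity minus mean intensity on the predicted outline
7. centroid distance to the cell centroid, normalized by the cell's
   equivalent radius
8. brightness rank of the candidate among its cell's candidates, mapped
   to [0, 1] (1 brightest, 0 dimmest; a lone candidate counts brightest)

The "center" intensity is the maximum normalized intensity inside the
inner contour. Before classification the feature matrix is whitened
(zero mean, unit variance per feature) and then min-max rescaled to [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import draw, measure

from .contours import ContourLoop, FocusCandidate, FocusOutline
from .preprocess import CellRegion

FEATURE_NAMES = [
    "f1_max",
    "f1_min",
    "f1_mean",
    "f2_area",
    "f2_eccentricity",
    "f2_solidity",
    "f3_rel_size",
    "f4_ratio_pred",
    "f5_ratio_outer",
    "f6_abs_diff",
    "f7_center_dist",
    "f8_brightness_index",
]


@dataclass
class FeatureVector:
    f1_max: float
    f1_min: float
    f1_mean: float
    f2_area: float
    f2_eccentricity: float
    f2_solidity: float
    f3_rel_size: float
    f4_ratio_pred: float
    f5_ratio_outer: float
    f6_abs_diff: float
    f7_center_dist: float
    f8_brightness_index: float = np.nan

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)


def _interp(img: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(img, [pts[:, 0], pts[:, 1]], order=1, mode="nearest")


def _pixels_inside(loop: ContourLoop, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = draw.polygon(loop.vertices[:, 0], loop.vertices[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _region_shape(loop: ContourLoop, shape: tuple[int, int]) -> tuple[float, float]:
    """(eccentricity, solidity) of the rasterized outline."""
    mask = _pixels_inside(loop, shape)
    if not mask.any():
        return 0.0, 1.0
    props = measure.regionprops(mask.astype(int))
    if not props:
        return 0.0, 1.0
    p = props[0]
    try:
        solidity = float(p.solidity)
    except Exception:
        solidity = 1.0
    return float(p.eccentricity), solidity


def extract_features(
    candidate: FocusCandidate,
    outline: FocusOutline,
    region: CellRegion,
) -> FeatureVector | None:
    """The 8 features for one (candidate, final outline) pair.

    Returns None for a degenerate outline (area below 1 px^2); ``f8`` is
    filled in afterwards by :func:`rank_brightness` once all of a cell's
    candidates are known.
    """
    if outline.area < 1.0:
        warnings.warn("degenerate outline rejected", stacklevel=2)
        return None
    img = region.normalized
    inside = _pixels_inside(outline.contour, img.shape) & region.mask
    if inside.any():
        vals = img[inside]
        f1_max, f1_min, f1_mean = float(vals.max()), float(vals.min()), float(vals.mean())
    else:
        v = float(_interp(img, np.array([outline.centroid]))[0])
        f1_max = f1_min = f1_mean = v

    ecc, sol = _region_shape(outline.contour, img.shape)

    inner_inside = _pixels_inside(candidate.inner, img.shape) & region.mask
    if inner_inside.any():
        center_int = float(img[inner_inside].max())
    else:
        center_int = float(
            _interp(img, np.array([candidate.inner.interior_point]))[0]
        )
    center_int = max(center_int, 1e-12)

    pred_boundary = float(_interp(img, outline.contour.vertices).mean())
    outer_boundary = float(_interp(img, candidate.outer.vertices).mean())

    cell_cen = region.centroid
    dist = float(np.hypot(outline.centroid[0] - cell_cen[0], outline.centroid[1] - cell_cen[1]))

    return FeatureVector(
        f1_max=f1_max,
        f1_min=f1_min,
        f1_mean=f1_mean,
        f2_area=float(outline.area),
        f2_eccentricity=ecc,
        f2_solidity=sol,
        f3_rel_size=float(outline.area / max(region.cell_area, 1.0)),
        f4_ratio_pred=min(pred_boundary / center_int, 1.0),
        f5_ratio_outer=min(outer_boundary / center_int, 1.0),
        f6_abs_diff=max(center_int - pred_boundary, 0.0),
        f7_center_dist=dist / max(region.equivalent_radius, 1e-12),
    )


def rank_brightness(vectors: list[FeatureVector]) -> None:
    """Fill ``f8``: brightness ranks of a cell's candidates mapped onto [0, 1].

    With n >= 2 candidates the ranks map onto {0, 1/(n-1), ..., 1}; a lone
    candidate is assigned 1 (the brightest in its cell).
    """
    n = len(vectors)
    if n == 0:
        return
    if n == 1:
        vectors[0].f8_brightness_index = 1.0
        return
    order = np.argsort([v.f1_max for v in vectors], kind="stable")
    for rank, idx in enumerate(order):
        vectors[idx].f8_brightness_index = rank / (n - 1)


class FeatureScaler:
    """Whitening (z-score) followed by min-max rescaling to [0, 1].

    Fitted on the training matrix and reapplied verbatim at prediction
    time. A zero-variance feature maps to the constant 0.5.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None
        self.zmin_: np.ndarray | None = None
        self.zmax_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need at least 2 feature vectors")
        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0)
        degenerate = self.std_ == 0
        if degenerate.any():
            warnings.warn("zero-variance feature mapped to 0.5", stacklevel=2)
        std = np.where(degenerate, 1.0, self.std_)
        Z = (X - self.mean_) / std
        self.zmin_ = Z.min(axis=0)
        self.zmax_ = Z.max(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("scaler not fitted")
        X = np.asarray(X, dtype=float)
        degenerate = self.std_ == 0
        std = np.where(degenerate, 1.0, self.std_)
        Z = (X - self.mean_) / std
        span = self.zmax_ - self.zmin_
        span = np.where(span == 0, 1.0, span)
        out = (Z - self.zmin_) / span
        out[:, degenerate] = 0.5
        return out

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    # -- JSON round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "mean": self.mean_.tolist(),
            "std": self.std_.tolist(),
            "zmin": self.zmin_.tolist(),
            "zmax": self.zmax_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        sc = cls()
        sc.mean_ = np.asarray(d["mean"], dtype=float)
        sc.std_ = np.asarray(d["std"], dtype=float)
        sc.zmin_ = np.asarray(d["zmin"], dtype=float)
        sc.zmax_ = np.asarray(d["zmax"], dtype=float)
        return sc

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "FeatureScaler":
        return cls.from_dict(json.loads(Path(path).read_text()))


def whiten_rescale(
    vectors: list[FeatureVector] | np.ndarray,
) -> tuple[np.ndarray, FeatureScaler]:
    """Whiten and min-max rescale a feature matrix; return (matrix, scaler)."""
    if isinstance(vectors, np.ndarray):
        X = vectors
    else:
        X = np.vstack([v.to_array() for v in vectors])
    scaler = FeatureScaler()
    return scaler.fit_transform(X), scaler


def feature_matrix(vectors: list[FeatureVector]) -> np.ndarray:
    return np.vstack([v.to_array() for v in vectors])
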