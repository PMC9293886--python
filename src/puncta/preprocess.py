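"""Fluorescence preprocessing: max-projection, denoising, per-cell extraction.

Z-stacks are collapsed by per-pixel maximum, optionally denoised with
non-local means, and then cut into per-cell patches using the cell outlines
from segmentation. Contouring and feature extraction operate on a per-cell
min-max-normalized patch; all exported brightness values come from the
untouched raw patch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.restoration import denoise_nl_means

from .segmentation import CellOutline


@dataclass
class CellRegion:
    """One cell cut out of the projected fluorescence image.

    ``normalized`` spans [0, 1] over in-mask pixels (all zeros for a
    constant cell); out-of-mask pixels are filled with the in-mask minimum
    so iso-contours cannot hug the mask edge. ``raw`` is never modified.
    """

    raw: np.ndarray
    normalized: np.ndarray
    mask: np.ndarray
    outline: CellOutline
    origin: tuple[int, int]  # top-left (row, col) of the patch in the frame
    pixel_size: float = 40.7  # nm / px

    @property
    def cell_area(self) -> float:
        return float(self.mask.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        """Mask centroid in patch coordinates."""
        rows, cols = np.nonzero(self.mask)
        return float(rows.mean()), float(cols.mean())

    @property
    def equivalent_radius(self) -> float:
        return float(np.sqrt(self.cell_area / np.pi))


def max_project(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum across z-slices. A 2-D input is returned unchanged."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack.copy()
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be (z, rows, cols) with z >= 1")
    return stack.max(axis=0)


def denoise(
    image: np.ndarray,
    patch_size: int = 5,
    patch_distance: int = 6,
    strength: float = 0.1,
) -> np.ndarray:
    """Non-local means denoising; ``strength`` 0 is the identity.

    ``strength`` is the cut-off h expressed as a fraction of the image
    intensity range (the settings are picked per image, since noise levels
    vary between experiments and microscopes).
    """
    if patch_size <= 0 or patch_distance <= 0:
        raise ValueError("patch sizes must be positive")
    img = np.asarray(image, dtype=float)
    rng = float(np.ptp(img))
    if strength <= 0 or rng == 0:
        return img.copy()
    sigma = strength * rng
    return denoise_nl_means(
        img,
        patch_size=patch_size,
        patch_distance=patch_distance,
        h=sigma,
        fast_mode=True,
    )


def extract_cells(
    image: np.ndarray,
    outlines: list[CellOutline],
    pixel_size: float = 40.7,
    min_area: float = 4.0,
) -> list[CellRegion]:
    """Cut per-cell patches and min-max normalize each over its mask."""
    img = np.asarray(image, dtype=float)
    regions: list[CellRegion] = []
    for outline in outlines:
        mask = outline.mask
        if mask.sum() < min_area:
            import warnings

            warnings.warn("degenerate outline skipped", stacklevel=2)
            continue
        rows, cols = np.nonzero(mask)
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        raw = img[r0:r1, c0:c1].copy()
        m = mask[r0:r1, c0:c1].copy()
        inside = raw[m]
        lo, hi = float(inside.min()), float(inside.max())
        if hi > lo:
            norm = (raw - lo) / (hi - lo)
        else:
            norm = np.zeros_like(raw)
        norm[~m] = 0.0 if hi == lo else 0.0
        # fill rule: outside-mask pixels take the in-mask minimum (0 after
        # normalization) so marching squares cannot form loops along the mask
        regions.append(
            CellRegion(
                raw=raw,
                normalized=np.clip(norm, 0.0, 1.0),
                mask=m,
                outline=outline,
                origin=(int(r0), int(c0)),
                pixel_size=pixel_size,
            )
        )
    return regions
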