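"""Synthetic microscopy scenes with known ground truth.

Generates brightfield-like images (elliptical cells drawn as bright ridge
rings over a flat background) and fluorescence-like z-stacks (cytoplasmic
background, dark vacuoles, radially symmetric foci) so that every stage of
the pipeline can be exercised against analytic ground truth: the curvature
maximum of a Gaussian radial profile ``a*exp(-r^2/2s^2)`` sits at radius
``sqrt(3)*s``, which is recorded per focus as the truth boundary radius.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import tifffile

#: curvature-maximum radius of a Gaussian profile, in units of sigma
GAUSSIAN_BOUNDARY_FACTOR = math.sqrt(3.0)

#: default physical pixel pitch of the emulated microscope, nm per pixel
DEFAULT_PIXEL_SIZE_NM = 40.7


@dataclass(frozen=True)
class Cell:
    """Elliptical cell: center (row, col) px, semi-axes px, orientation rad."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation: float = 0.0


@dataclass(frozen=True)
class Focus:
    """A single punctum inside a cell.

    ``amplitude`` is relative to the cytoplasmic background level;
    ``label`` is the ground-truth classification (1 = bona fide focus).
    """

    cell_index: int
    center: tuple[float, float]
    sigma: float
    amplitude: float
    label: int = 1
    profile: Literal["gaussian", "cone"] = "gaussian"

    @property
    def truth_radius(self) -> float:
        """Analytic curvature-maximum boundary radius, px."""
        if self.profile == "gaussian":
            return GAUSSIAN_BOUNDARY_FACTOR * self.sigma
        # cone a*(1 - r/R): no curvature maximum in the interior; the support
        # edge R (stored in sigma) is the only distinguished radius.
        return self.sigma


@dataclass(frozen=True)
class Vacuole:
    center: tuple[float, float]
    radius: float


@dataclass
class SyntheticScene:
    """Full description of a synthetic field of view.

    Identical ``(parameters, seed)`` produce bit-identical images.
    """

    shape: tuple[int, int] = (256, 256)
    cells: list[Cell] = field(default_factory=list)
    foci: list[Focus] = field(default_factory=list)
    vacuoles: list[Vacuole] = field(default_factory=list)
    background_level: float = 100.0
    noise_sd: float = 0.0
    pixel_size: float = DEFAULT_PIXEL_SIZE_NM
    seed: int = 0
    ridge_amplitude: float = 80.0
    ridge_sigma: float = 1.5
    noise_model: Literal["gaussian", "poisson"] = "gaussian"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for f in self.foci:
            if not (0 <= f.cell_index < len(self.cells)):
                raise ValueError(f"focus references unknown cell {f.cell_index}")
            if f.sigma <= 0:
                raise ValueError("focus sigma must be > 0")
            if f.amplitude < 0:
                raise ValueError("focus amplitude must be >= 0")
            cell = self.cells[f.cell_index]
            if _ellipse_q(np.array([f.center[0]]), np.array([f.center[1]]), cell) >= 1.0:
                raise ValueError(
                    f"focus at {f.center} lies outside cell {f.cell_index}"
                )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    # -- serialization ---------------------------------------------------
    def ground_truth(self) -> dict:
        """JSON-serializable ground truth (cells, foci, labels)."""
        return {
            "pixel_size_nm": self.pixel_size,
            "cells": [asdict(c) for c in self.cells],
            "foci": [
                {**asdict(f), "truth_radius_px": f.truth_radius} for f in self.foci
            ],
            "vacuoles": [asdict(v) for v in self.vacuoles],
        }

    def write_ground_truth(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.ground_truth(), indent=1, sort_keys=True))


def _ellipse_q(rows: np.ndarray, cols: np.ndarray, cell: Cell) -> np.ndarray:
    """Normalized elliptical radius: q<1 inside, q=1 on boundary."""
    dr = rows - cell.center[0]
    dc = cols - cell.center[1]
    c, s = math.cos(cell.orientation), math.sin(cell.orientation)
    u = c * dr + s * dc
    v = -s * dr + c * dc
    a, b = cell.semi_axes
    return np.sqrt((u / a) ** 2 + (v / b) ** 2)


def cell_masks(scene: SyntheticScene) -> np.ndarray:
    """Ground-truth label image: 0 background, k = cell k (1-based)."""
    rows, cols = np.mgrid[0 : scene.shape[0], 0 : scene.shape[1]].astype(float)
    labels = np.zeros(scene.shape, dtype=np.uint16)
    for k, cell in enumerate(scene.cells, start=1):
        inside = _ellipse_q(rows, cols, cell) <= 1.0
        labels[inside] = k
    return labels


def _check_overlap(scene: SyntheticScene, tolerance_px: int) -> None:
    rows, cols = np.mgrid[0 : scene.shape[0], 0 : scene.shape[1]].astype(float)
    masks = [_ellipse_q(rows, cols, c) <= 1.0 for c in scene.cells]
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if int((masks[i] & masks[j]).sum()) > tolerance_px:
                raise ValueError(
                    f"cells {i} and {j} overlap by more than {tolerance_px} px; "
                    "the segmenter does not handle merged cells"
                )


def _add_noise(img: np.ndarray, scene: SyntheticScene, rng: np.random.Generator) -> np.ndarray:
    if scene.noise_model == "poisson":
        if scene.noise_sd > 0:
            return rng.poisson(np.clip(img, 0, None)).astype(float)
        return img
    if scene.noise_sd > 0:
        return img + rng.normal(0.0, scene.noise_sd, size=img.shape)
    return img


def make_brightfield(
    scene: SyntheticScene, overlap_tolerance_px: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Render a brightfield-like image plus ground-truth cell label masks.

    Each cell contributes a bright ridge (Gaussian cross-section of width
    ``ridge_sigma``) along its ellipse boundary over a flat background.

    Returns ``(image, label_mask)`` where ``label_mask[r, c] == k`` for
    pixels inside cell ``k`` (1-based), 0 elsewhere.
    """
    _check_overlap(scene, overlap_tolerance_px)
    rng = np.random.default_rng(scene.seed)
    rows, cols = np.mgrid[0 : scene.shape[0], 0 : scene.shape[1]].astype(float)
    img = np.full(scene.shape, scene.background_level, dtype=float)
    for cell in scene.cells:
        q = _ellipse_q(rows, cols, cell)
        # signed distance to the ellipse boundary, exact for circles
        d = (q - 1.0) * math.sqrt(cell.semi_axes[0] * cell.semi_axes[1])
        img += scene.ridge_amplitude * np.exp(-(d**2) / (2 * scene.ridge_sigma**2))
    img = _add_noise(img, scene, rng)
    return img, cell_masks(scene)


def _focus_field(focus: Focus, rows, cols) -> np.ndarray:
    r2 = (rows - focus.center[0]) ** 2 + (cols - focus.center[1]) ** 2
    if focus.profile == "gaussian":
        return focus.amplitude * np.exp(-r2 / (2 * focus.sigma**2))
    r = np.sqrt(r2)
    return focus.amplitude * np.clip(1.0 - r / focus.sigma, 0.0, None)


def make_fluorescence(
    scene: SyntheticScene, z_slices: int = 1, z_sigma: float = 1.0
) -> tuple[np.ndarray, dict]:
    """Render a fluorescence z-stack plus per-focus ground truth.

    Inside every cell the cytoplasm sits at ``background_level``; vacuole
    discs are dark; each focus adds ``amplitude * exp(-r^2 / 2 sigma^2)``
    (or a cone) modulated along z by a Gaussian centered on a random slice
    whose peak slice carries the full amplitude, so the max-projection of a
    noiseless stack equals the analytic 2-D model exactly.

    Returns ``(stack, truth)`` with ``stack.shape == (z_slices, *scene.shape)``.
    """
    if z_slices < 1:
        raise ValueError("z_slices must be >= 1")
    rng = np.random.default_rng(scene.seed + 1)
    rows, cols = np.mgrid[0 : scene.shape[0], 0 : scene.shape[1]].astype(float)

    base = np.zeros(scene.shape, dtype=float)
    for cell in scene.cells:
        base[_ellipse_q(rows, cols, cell) <= 1.0] = scene.background_level
    for vac in scene.vacuoles:
        r2 = (rows - vac.center[0]) ** 2 + (cols - vac.center[1]) ** 2
        base[r2 <= vac.radius**2] *= 0.05

    stack = np.repeat(base[None, :, :], z_slices, axis=0)
    for focus in scene.foci:
        field2d = _focus_field(focus, rows, cols)
        z0 = int(rng.integers(0, z_slices))
        z = np.arange(z_slices)
        w = np.exp(-((z - z0) ** 2) / (2 * z_sigma**2))
        w /= w.max()  # peak slice carries the full amplitude
        stack += w[:, None, None] * field2d[None, :, :]

    noisy = np.empty_like(stack)
    for k in range(z_slices):
        noisy[k] = _add_noise(stack[k], scene, rng)

    truth = {
        "foci": [
            {
                "cell_index": f.cell_index,
                "center": list(f.center),
                "sigma": f.sigma,
                "amplitude": f.amplitude,
                "label": f.label,
                "truth_radius_px": f.truth_radius,
            }
            for f in scene.foci
        ],
        "pixel_size_nm": scene.pixel_size,
    }
    return noisy, truth


# -- convenience scene builders -----------------------------------------


def grid_scene(
    n_cells: int,
    shape: tuple[int, int] = (256, 256),
    cell_radius: float = 22.0,
    foci_per_cell: Sequence[int] | None = None,
    focus_sigma: float = 3.0,
    focus_amplitude: float = 150.0,
    background_level: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticScene:
    """Lay out ``n_cells`` well-separated near-circular cells on a grid."""
    rng = np.random.default_rng(seed)
    per_row = max(1, int(math.floor(shape[1] / (2.6 * cell_radius))))
    cells: list[Cell] = []
    for k in range(n_cells):
        r = cell_radius * 1.3 + (k // per_row) * 2.6 * cell_radius
        c = cell_radius * 1.3 + (k % per_row) * 2.6 * cell_radius
        if r + cell_radius >= shape[0] or c + cell_radius >= shape[1]:
            raise ValueError("scene shape too small for requested cell count")
        ecc = 1.0 + 0.15 * rng.random()
        cells.append(
            Cell(
                center=(r, c),
                semi_axes=(cell_radius * ecc, cell_radius / ecc),
                orientation=float(rng.uniform(0, math.pi)),
            )
        )
    foci: list[Focus] = []
    if foci_per_cell is not None:
        for idx, count in enumerate(foci_per_cell):
            for _ in range(count):
                ang = rng.uniform(0, 2 * math.pi)
                rad = rng.uniform(0, 0.45) * cell_radius
                center = (
                    cells[idx].center[0] + rad * math.sin(ang),
                    cells[idx].center[1] + rad * math.cos(ang),
                )
                foci.append(
                    Focus(
                        cell_index=idx,
                        center=center,
                        sigma=focus_sigma,
                        amplitude=focus_amplitude,
                    )
                )
    return SyntheticScene(
        shape=shape,
        cells=cells,
        foci=foci,
        background_level=background_level,
        noise_sd=noise_sd,
        seed=seed,
    )


def labeled_candidate_dataset(
    n_cells: int = 50,
    seed: int = 0,
    bright_per_cell: tuple[int, int] = (2, 4),
    dim_per_cell: tuple[int, int] = (8, 13),
    bright_amplitude: tuple[float, float] = (120.0, 180.0),
    dim_amplitude: tuple[float, float] = (15.0, 55.0),
    sigma_range: tuple[float, float] = (2.0, 3.5),
    noise_sd: float = 4.0,
    cell_radius: float = 26.0,
    L_min: float = 6.0,
    L_max: float = 90.0,
    rule_feature: str = "f1_max",
    rule_threshold: float = 0.55,
):
    """Feature matrix + rule labels from candidates detected in synthetic cells.

    Each cell is rendered on its own small frame with a few bright foci and
    many dim ones (ambiguous perturbations), the full candidate-detection
    and feature-extraction chain is run, and every candidate is labeled by
    the noiseless rule ``feature > threshold``. Returns
    ``(X, y, cell_ids)`` — one row per detected candidate.
    """
    from .contours import detect_foci
    from .features import FEATURE_NAMES, feature_matrix, rank_brightness
    from .features import extract_features
    from .preprocess import extract_cells, max_project
    from .segmentation import outline_from_mask

    rng = np.random.default_rng(seed)
    rows, labels, cell_ids = [], [], []
    frame = int(2 * cell_radius + 12)
    for cid in range(n_cells):
        center = (frame / 2, frame / 2)
        cell = Cell(center=center, semi_axes=(cell_radius, cell_radius))
        foci: list[Focus] = []
        n_bright = int(rng.integers(bright_per_cell[0], bright_per_cell[1] + 1))
        n_dim = int(rng.integers(dim_per_cell[0], dim_per_cell[1] + 1))
        for amp_range, count in ((bright_amplitude, n_bright), (dim_amplitude, n_dim)):
            for _ in range(count):
                ang = rng.uniform(0, 2 * math.pi)
                rad = rng.uniform(0.1, 0.72) * cell_radius
                foci.append(
                    Focus(
                        cell_index=0,
                        center=(
                            center[0] + rad * math.sin(ang),
                            center[1] + rad * math.cos(ang),
                        ),
                        sigma=float(rng.uniform(*sigma_range)),
                        amplitude=float(rng.uniform(*amp_range)),
                    )
                )
        scene = SyntheticScene(
            shape=(frame, frame),
            cells=[cell],
            foci=foci,
            background_level=100.0,
            noise_sd=noise_sd,
            seed=seed * 100003 + cid,
        )
        img = max_project(make_fluorescence(scene, z_slices=1)[0])
        region = extract_cells(img, [outline_from_mask(cell_masks(scene) == 1)])[0]
        candidates, final = detect_foci(region, L_min=L_min, L_max=L_max)
        vectors = []
        for focus in final:
            cand = candidates[focus.source_candidates[0]]
            vec = extract_features(cand, focus, region)
            if vec is not None:
                vectors.append(vec)
        rank_brightness(vectors)
        if not vectors:
            continue
        X_cell = feature_matrix(vectors)
        col = FEATURE_NAMES.index(rule_feature)
        rows.append(X_cell)
        labels.append((X_cell[:, col] > rule_threshold).astype(int))
        cell_ids.append(np.full(len(vectors), cid))
    X = np.vstack(rows)
    return X, np.concatenate(labels), np.concatenate(cell_ids)


def write_scene(
    scene: SyntheticScene, outdir: str | Path, z_slices: int = 5
) -> dict[str, Path]:
    """Write brightfield TIFF, fluorescence stack TIFF and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bf, masks = make_brightfield(scene)
    stack, truth = make_fluorescence(scene, z_slices=z_slices)
    paths = {
        "brightfield": outdir / "brightfield.tif",
        "mask": outdir / "mask.tif",
        "stack": outdir / "stack.tif",
        "truth": outdir / "truth.json",
    }
    tifffile.imwrite(paths["brightfield"], bf.astype(np.float32))
    tifffile.imwrite(paths["mask"], masks)
    tifffile.imwrite(
        paths["stack"], stack.astype(np.float32), photometric="minisblack"
    )
    truth_all = scene.ground_truth()
    truth_all.update(truth)
    paths["truth"].write_text(json.dumps(truth_all, indent=1, sort_keys=True))
    return paths
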