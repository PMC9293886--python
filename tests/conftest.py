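"""Shared fixtures: synthetic cells, regions and the labeled candidate set."""

from __future__ import annotations

import numpy as np
import pytest

from puncta.preprocess import extract_cells, max_project
from puncta.segmentation import outline_from_mask
from puncta.synthetic import (
    Cell,
    Focus,
    SyntheticScene,
    cell_masks,
    labeled_candidate_dataset,
    make_fluorescence,
)


def region_with_foci(
    foci_spec: list[tuple[tuple[float, float], float, float]],
    shape: tuple[int, int] = (120, 120),
    cell_radius: float = 54.0,
    background: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 1,
    profile: str = "gaussian",
):
    """One circular cell with the given foci [(center, sigma, amplitude), ...]."""
    center = (shape[0] / 2, shape[1] / 2)
    scene = SyntheticScene(
        shape=shape,
        cells=[Cell(center=center, semi_axes=(cell_radius, cell_radius))],
        foci=[
            Focus(cell_index=0, center=c, sigma=s, amplitude=a, profile=profile)
            for c, s, a in foci_spec
        ],
        background_level=background,
        noise_sd=noise_sd,
        seed=seed,
    )
    img = max_project(make_fluorescence(scene, z_slices=1)[0])
    outline = outline_from_mask(cell_masks(scene) == 1)
    return extract_cells(img, [outline])[0]


@pytest.fixture(scope="session")
def single_gaussian_region():
    """Noiseless sigma=3 Gaussian focus centered in a circular cell."""
    return region_with_foci([((60.0, 60.0), 3.0, 150.0)])


@pytest.fixture(scope="session")
def labeled_dataset():
    """600+ candidates from synthetic cells, labeled by a noiseless rule.

    Shared across classifier tests: generating it runs the full contour and
    feature pipeline, which dominates the suite's runtime.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        X, y, cell_ids = labeled_candidate_dataset(n_cells=65, seed=7)
    return X, y, cell_ids
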