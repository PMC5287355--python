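"""Shared fixtures and image-rendering helpers for the test suite."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pytest

logging.disable(logging.WARNING)
warnings.filterwarnings("ignore", message="Covariance of the parameters")


def render_spot_field(
    rng: np.random.Generator,
    n_spots: int = 25,
    size: int = 256,
    sigma: float = 1.8,
    snr: float = 10.0,
    noise_sd: float = 5.0,
    min_sep_factor: float = 8.0,
    background: float = 100.0,
):
    """Gaussian spots on Gaussian noise with a minimum pairwise distance.

    Returns (image, true_positions) with positions as an (n, 2) array of
    (x, y).  Spot peak amplitude is ``snr * noise_sd``.
    """
    min_sep = min_sep_factor * sigma
    pts: list[np.ndarray] = []
    while len(pts) < n_spots:
        c = rng.uniform(4 * sigma, size - 4 * sigma, 2)
        if all(np.hypot(c[0] - p[0], c[1] - p[1]) >= min_sep for p in pts):
            pts.append(c)
    img = np.zeros((size, size))
    yy, xx = np.mgrid[0:size, 0:size]
    for x, y in pts:
        img += snr * noise_sd * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma ** 2)
        )
    img += rng.normal(background, noise_sd, img.shape)
    return img, np.array(pts)


def random_similarity(rng: np.random.Generator, reflection: bool = False, scale=None):
    """A random similarity Transform2D for round-trip style tests."""
    from cryoclem.geometry import Transform2D

    theta = rng.uniform(0, 2 * np.pi)
    s = scale if scale is not None else rng.uniform(0.5, 2.0)
    c, sn = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -sn], [sn, c]])
    if reflection:
        rot = rot @ np.diag([1.0, -1.0])
    return Transform2D(
        matrix=s * rot,
        translation=rng.uniform(-50, 50, 2),
        model="similarity",
    )


@pytest.fixture(scope="session")
def small_scene():
    """A quarter-scale 2x2-square scene shared by image-level tests.

    The mesh pitch and tile field are scaled to a quarter of the physical
    values so a full render-stitch-register loop stays fast; densities per
    square follow the full-scale defaults.
    """
    from cryoclem.synthetic_data import GridGeometry, SceneParams, generate_scene

    grid = GridGeometry(mesh=300, n_squares=(2, 2), pitch_um=21.25, bar_width_um=6.25)
    params = SceneParams(
        grid=grid,
        beads_per_square=25,
        gold_per_square=8,
        pois_per_square=2,
        n_broken_squares=4,
    )
    return generate_scene(params, 5)


@pytest.fixture(scope="session")
def small_render_params():
    from cryoclem.synthetic_data import RenderParams

    return RenderParams(fm_fov_um=(24.5, 24.5), z_range_um=4.0, z_step_um=2.0)
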