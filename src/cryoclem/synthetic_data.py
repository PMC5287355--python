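"""Synthetic cryo-CLEM scenes with exact ground truth.

A scene emulates a vitrified EM grid prepared for correlative imaging: a
200- or 300-mesh grid whose open squares carry a support film decorated
with multi-channel fluorescent beads (~100 nm, also electron-dense), 10 nm
colloidal gold fiducials, and diffraction-limited fluorescent positions of
interest.  The same scene is rendered twice — as FM tile Z-stacks on a
stage-scan lattice and as EM frames — under a known ground-truth FM->EM
transform, so that every stage of the registration workflow can be tested
against exact positions.

Brightness follows a volume law: a fluorophore-loaded sphere of half the
diameter carries one eighth of the dye, so 50 nm beads are 8x dimmer than
100 nm beads.

All randomness flows from a single seed; one generator stream is split per
renderer so FM and EM noise are independently reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import FrameID, Point2D, Transform2D
from .mosaic import Tile

__all__ = [
    "GridGeometry",
    "SceneParams",
    "RenderParams",
    "Scene",
    "generate_scene",
    "bead_brightness",
    "render_fm",
    "render_em",
]

#: nominal pitch and bar width (um) per mesh count; generator defaults,
#: chosen so one FM tile covers roughly one grid square
GRID_MESH_GEOMETRY = {200: (125.0, 35.0), 300: (85.0, 25.0)}

REFERENCE_BEAD_DIAMETER_NM = 100.0


def bead_brightness(diameter_nm: float, reference_diameter_nm: float = REFERENCE_BEAD_DIAMETER_NM) -> float:
    """Relative brightness of a dye-loaded sphere: proportional to volume,
    i.e. diameter cubed, normalized to the reference diameter."""
    if diameter_nm <= 0 or reference_diameter_nm <= 0:
        raise ValueError("diameters must be > 0")
    return (diameter_nm / reference_diameter_nm) ** 3


@dataclass(frozen=True)
class GridGeometry:
    """Mesh layout of the specimen grid region being simulated."""

    mesh: int = 300
    n_squares: tuple[int, int] = (3, 3)
    pitch_um: float | None = None
    bar_width_um: float | None = None

    def __post_init__(self) -> None:
        if self.mesh not in GRID_MESH_GEOMETRY:
            raise ValueError(f"mesh must be one of {sorted(GRID_MESH_GEOMETRY)}")
        pitch, bar = GRID_MESH_GEOMETRY[self.mesh]
        if self.pitch_um is None:
            object.__setattr__(self, "pitch_um", pitch)
        if self.bar_width_um is None:
            object.__setattr__(self, "bar_width_um", bar)

    @property
    def extent_um(self) -> tuple[float, float]:
        return (self.n_squares[0] * self.pitch_um, self.n_squares[1] * self.pitch_um)

    def on_film(self, x: float, y: float) -> bool:
        """True when (x, y) lies on open support film, not under a grid bar."""
        half_bar = self.bar_width_um / 2.0
        fx = x % self.pitch_um
        fy = y % self.pitch_um
        return (
            half_bar <= fx <= self.pitch_um - half_bar
            and half_bar <= fy <= self.pitch_um - half_bar
        )

    def square_of(self, x: float, y: float) -> tuple[int, int]:
        return (int(x // self.pitch_um), int(y // self.pitch_um))

    def square_center(self, ij: tuple[int, int]) -> Point2D:
        return Point2D(
            (ij[0] + 0.5) * self.pitch_um, (ij[1] + 0.5) * self.pitch_um
        )


@dataclass(frozen=True)
class SceneParams:
    """What to place on the grid, per square."""

    grid: GridGeometry = field(default_factory=GridGeometry)
    beads_per_square: int = 10
    gold_per_square: int = 20
    pois_per_square: int = 2
    n_broken_squares: int = 3
    bead_diameter_nm: float = 100.0
    bead_channels: tuple[str, ...] = ("green", "red", "farred")
    signal_channel: str = "green"
    # ground-truth FM->EM stage map: similarity with optional reflection
    em_scale: float = 1.0
    em_reflection: bool = True
    em_shear: float = 0.0  # set ~0.01 to exercise the affine fitting path
    em_translation_range_um: float = 200.0


@dataclass
class Scene:
    """Ground truth: everything the renderers and the oracles need."""

    grid: GridGeometry
    beads: list[tuple[Point2D, float, tuple[str, ...]]]  # position, diameter nm, channels
    gold: list[Point2D]  # 10 nm colloidal gold
    pois: list[tuple[Point2D, str, float]]  # position, channel, brightness
    broken_squares: list[tuple[int, int]]
    topography_um: dict[tuple[int, int], float]  # per-square Z offset
    truth_fm_to_em: Transform2D
    seed: int

    GOLD_DIAMETER_NM = 10.0

    def poi_z(self, p: Point2D) -> float:
        ij = self.grid.square_of(p.x, p.y)
        return self.topography_um.get(ij, 0.0)

    # -- manifest --------------------------------------------------------
    def to_manifest(self, path: str | Path) -> None:
        doc = {
            "seed": self.seed,
            "grid": {
                "mesh": self.grid.mesh,
                "n_squares": list(self.grid.n_squares),
                "pitch_um": self.grid.pitch_um,
                "bar_width_um": self.grid.bar_width_um,
            },
            "beads": [
                {"x": p.x, "y": p.y, "diameter_nm": d, "channels": list(ch)}
                for p, d, ch in self.beads
            ],
            "gold": [{"x": p.x, "y": p.y} for p in self.gold],
            "pois": [
                {"x": p.x, "y": p.y, "channel": ch, "brightness": b}
                for p, ch, b in self.pois
            ],
            "broken_squares": [list(ij) for ij in self.broken_squares],
            "topography_um": {f"{i},{j}": z for (i, j), z in self.topography_um.items()},
            "truth_fm_to_em": self.truth_fm_to_em.to_text(),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_manifest(cls, path: str | Path) -> "Scene":
        doc = json.loads(Path(path).read_text())
        g = doc["grid"]
        grid = GridGeometry(
            mesh=g["mesh"],
            n_squares=tuple(g["n_squares"]),
            pitch_um=g["pitch_um"],
            bar_width_um=g["bar_width_um"],
        )
        return cls(
            grid=grid,
            beads=[
                (Point2D(b["x"], b["y"]), b["diameter_nm"], tuple(b["channels"]))
                for b in doc["beads"]
            ],
            gold=[Point2D(g_["x"], g_["y"]) for g_ in doc["gold"]],
            pois=[
                (Point2D(p["x"], p["y"]), p["channel"], p["brightness"])
                for p in doc["pois"]
            ],
            broken_squares=[tuple(ij) for ij in doc["broken_squares"]],
            topography_um={
                tuple(int(v) for v in k.split(",")): z
                for k, z in doc["topography_um"].items()
            },
            truth_fm_to_em=Transform2D.from_text(doc["truth_fm_to_em"]),
            seed=doc["seed"],
        )


def _place_on_film(
    grid: GridGeometry, rng: np.random.Generator, count: int
) -> list[Point2D]:
    """Uniform placement on open film area by rejection sampling."""
    ex, ey = grid.extent_um
    out: list[Point2D] = []
    attempts = 0
    max_attempts = max(1000, 1000 * count)
    while len(out) < count:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"placement failed after {max_attempts} attempts; density too high?"
            )
        x = float(rng.uniform(0, ex))
        y = float(rng.uniform(0, ey))
        attempts += 1
        if grid.on_film(x, y):
            out.append(Point2D(x, y))
    return out


def _truth_transform(params: SceneParams, rng: np.random.Generator) -> Transform2D:
    theta = float(rng.uniform(0.0, 2.0 * math.pi))
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    if params.em_reflection:
        rot = rot @ np.diag([1.0, -1.0])
    matrix = params.em_scale * rot
    model = "similarity"
    if params.em_shear:
        matrix = matrix @ np.array([[1.0, params.em_shear], [0.0, 1.0]])
        model = "affine"
    t = rng.uniform(
        -params.em_translation_range_um, params.em_translation_range_um, size=2
    )
    return Transform2D(
        matrix=matrix,
        translation=t,
        source=FrameID("fm_stage_um"),
        target=FrameID("em_stage_um"),
        model=model,
        allow_reflection=True,
    )


def generate_scene(params: SceneParams, seed: int) -> Scene:
    """Build a reproducible ground-truth scene.

    Beads, gold and POIs are placed uniformly at random on the open film;
    a configurable number of squares is marked broken (these serve as
    grid-wide landmarks visible in both modalities); the ground-truth
    FM->EM transform is drawn with rotation uniform in [0, 2 pi).
    """
    rng = np.random.default_rng(seed)
    grid = params.grid
    nx, ny = grid.n_squares
    n_sq = nx * ny

    bead_pos = _place_on_film(grid, rng, params.beads_per_square * n_sq)
    gold_pos = _place_on_film(grid, rng, params.gold_per_square * n_sq)
    poi_pos = _place_on_film(grid, rng, params.pois_per_square * n_sq)

    beads = [(p, params.bead_diameter_nm, params.bead_channels) for p in bead_pos]
    pois = [
        (p, params.signal_channel, float(rng.uniform(0.5, 1.0))) for p in poi_pos
    ]

    all_sq = [(i, j) for i in range(nx) for j in range(ny)]
    k = min(params.n_broken_squares, n_sq)
    broken = [all_sq[i] for i in rng.choice(n_sq, size=k, replace=False)]
    topography = {ij: float(rng.uniform(-1.5, 1.5)) for ij in all_sq}

    return Scene(
        grid=grid,
        beads=beads,
        gold=gold_pos,
        pois=pois,
        broken_squares=broken,
        topography_um=topography,
        truth_fm_to_em=_truth_transform(params, rng),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# FM rendering


@dataclass(frozen=True)
class RenderParams:
    """Imaging parameters for both renderers.

    FM defaults: 0.13 um pixels (a 179 um field across a ~1400 px sensor),
    PSF sigma 0.18 um (high-NA cryo objective, green emission), Z-stack of
    10 um range in 1 um steps.  These are generator defaults chosen to be
    realistic for the instrument class, not measured values.  EM frames use
    a nominal medium-magnification pixel size of 10 nm.
    """

    fm_pixel_size_um: float = 0.13
    fm_fov_um: tuple[float, float] = (179.0, 134.0)
    psf_sigma_um: float = 0.18
    axial_sigma_factor: float = 3.0
    z_range_um: float = 10.0
    z_step_um: float = 1.0
    overlap_fraction: float = 0.10
    fm_background: float = 100.0
    bead_amplitude: float = 2000.0
    poi_amplitude: float = 1000.0
    autofluorescence: tuple[tuple[str, float], ...] = (("green", 25.0),)
    poisson_gain: float = 1.0
    read_noise_sd: float = 3.0

    em_pixel_size_nm: float = 10.0
    em_background: float = 1000.0
    em_bead_depth: float = 500.0
    em_gold_depth: float = 700.0
    em_poi_depth: float = 120.0
    em_texture_sd: float = 25.0
    em_noise_sd: float = 20.0


def _z_levels(params: RenderParams) -> np.ndarray:
    n = int(round(params.z_range_um / params.z_step_um)) + 1
    return (np.arange(n) - (n - 1) / 2.0) * params.z_step_um


def _add_gaussian(img: np.ndarray, cx: float, cy: float, amp: float, sigma: float) -> None:
    """Accumulate an isotropic Gaussian onto ``img`` on a local patch."""
    h, w = img.shape
    r = int(math.ceil(4 * sigma)) + 1
    x0, x1 = int(math.floor(cx)) - r, int(math.floor(cx)) + r + 1
    y0, y1 = int(math.floor(cy)) - r, int(math.floor(cy)) + r + 1
    x0, x1 = max(0, x0), min(w, x1)
    y0, y1 = max(0, y0), min(h, y1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - cx
    ys = np.arange(y0, y1) - cy
    img[y0:y1, x0:x1] += amp * np.exp(
        -(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * sigma ** 2)
    )


def render_fm(
    scene: Scene,
    params: RenderParams,
    channel: str,
    noise: bool = True,
) -> tuple[list[Tile], pd.DataFrame]:
    """Render one channel of the automated grid scan.

    Each tile is a Z-stack: every fluorescent object in the channel appears
    as a 3D Gaussian (axial sigma 3x lateral) centred at its position and
    the local surface height; grid bars are opaque; autofluorescence raises
    the support-film background in the configured channels; Poisson shot
    noise plus Gaussian read noise is added per plane.  Returns the tiles
    and a tile-metadata table (tile_id, stage_x_um, stage_y_um, channel,
    n_planes).
    """
    known = {ch for _, _, chs in scene.beads for ch in chs}
    known |= {ch for _, ch, _ in scene.pois}
    known |= {ch for ch, _ in params.autofluorescence}
    if channel not in known:
        raise ValueError(f"channel {channel!r} unknown to scene; known: {sorted(known)}")

    # independent, reproducible noise stream per (scene, channel)
    import zlib

    rng = np.random.default_rng([scene.seed, zlib.crc32(channel.encode())])
    px = params.fm_pixel_size_um
    fov_x, fov_y = params.fm_fov_um
    w = int(round(fov_x / px))
    h = int(round(fov_y / px))
    step_x = fov_x * (1.0 - params.overlap_fraction)
    step_y = fov_y * (1.0 - params.overlap_fraction)
    ex, ey = scene.grid.extent_um
    n_tx = max(1, int(math.ceil((ex - fov_x * params.overlap_fraction) / step_x)))
    n_ty = max(1, int(math.ceil((ey - fov_y * params.overlap_fraction) / step_y)))
    zs = _z_levels(params)
    sigma_px = params.psf_sigma_um / px
    sigma_ax = params.axial_sigma_factor * params.psf_sigma_um
    af = dict(params.autofluorescence)

    # fluorescent objects visible in this channel: (x, y, z, amplitude)
    objects: list[tuple[float, float, float, float]] = []
    for p, diameter, channels in scene.beads:
        if channel in channels:
            amp = params.bead_amplitude * bead_brightness(diameter)
            objects.append((p.x, p.y, scene.poi_z(p), amp))
    for p, ch, brightness in scene.pois:
        if ch == channel:
            objects.append((p.x, p.y, scene.poi_z(p), params.poi_amplitude * brightness))

    tiles: list[Tile] = []
    meta_rows = []
    for iy in range(n_ty):
        for ix in range(n_tx):
            origin = np.array([ix * step_x, iy * step_y])  # stage of pixel (0,0)
            stack = np.zeros((zs.size, h, w))

            # film vs bar masks in stage coordinates of the pixel centres
            xs_um = origin[0] + np.arange(w) * px
            ys_um = origin[1] + np.arange(h) * px
            half_bar = scene.grid.bar_width_um / 2.0
            pitch = scene.grid.pitch_um
            fx = xs_um % pitch
            fy = ys_um % pitch
            film_x = (fx >= half_bar) & (fx <= pitch - half_bar)
            film_y = (fy >= half_bar) & (fy <= pitch - half_bar)
            film = np.outer(film_y, film_x)

            base = np.full((h, w), params.fm_background)
            if channel in af:
                base = base + af[channel] * film

            for z_i, z in enumerate(zs):
                plane = base.copy()
                for ox, oy, oz, amp in objects:
                    cx = (ox - origin[0]) / px
                    cy = (oy - origin[1]) / px
                    if -4 * sigma_px < cx < w + 4 * sigma_px and -4 * sigma_px < cy < h + 4 * sigma_px:
                        axial = math.exp(-((z - oz) ** 2) / (2.0 * sigma_ax ** 2))
                        if axial > 1e-4:
                            _add_gaussian(plane, cx, cy, amp * axial, sigma_px)
                plane[~film] *= 0.05  # grid bars are opaque
                if noise:
                    plane = rng.poisson(
                        np.clip(plane * params.poisson_gain, 0, None)
                    ) / params.poisson_gain + rng.normal(0, params.read_noise_sd, plane.shape)
                stack[z_i] = plane

            center = origin + np.array([(w - 1) / 2.0 * px, (h - 1) / 2.0 * px])
            tile_id = f"t{ix:02d}_{iy:02d}"
            tiles.append(
                Tile(
                    pixels=stack,
                    nominal_stage=Point2D(float(center[0]), float(center[1])),
                    channel=channel,
                    z_positions=list(zs),
                    tile_id=tile_id,
                )
            )
            meta_rows.append(
                {
                    "tile_id": tile_id,
                    "stage_x_um": float(center[0]),
                    "stage_y_um": float(center[1]),
                    "channel": channel,
                    "n_planes": zs.size,
                }
            )
    return tiles, pd.DataFrame(meta_rows)


# ---------------------------------------------------------------------------
# EM rendering


def _add_disk(img: np.ndarray, cx: float, cy: float, depth: float, radius_px: float) -> None:
    """Subtract a soft-edged disk (dark object) from ``img``."""
    h, w = img.shape
    r = int(math.ceil(radius_px)) + 3
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - cx
    ys = np.arange(y0, y1) - cy
    dist = np.sqrt(ys[:, None] ** 2 + xs[None, :] ** 2)
    edge = max(0.8, radius_px * 0.25)
    profile = np.clip((radius_px - dist) / edge + 0.5, 0.0, 1.0)
    img[y0:y1, x0:x1] -= depth * profile


def render_em(
    scene: Scene,
    params: RenderParams,
    center: Point2D,
    fov_um: float,
    noise: bool = True,
    seed_offset: int = 1,
) -> np.ndarray:
    """Render an EM frame of side ``fov_um`` centred at ``center`` (EM stage um).

    Beads and gold appear as soft-edged dark disks of their physical
    diameter; POIs as fainter disks; grid bars as opaque dark regions; the
    support film as a smoothly textured background with Gaussian noise.
    """
    rng = np.random.default_rng(
        np.random.default_rng(scene.seed + seed_offset).integers(2 ** 31)
    )
    px_um = params.em_pixel_size_nm / 1000.0
    n = int(round(fov_um / px_um))
    origin = np.array([center.x - fov_um / 2.0, center.y - fov_um / 2.0])

    img = np.full((n, n), params.em_background, dtype=float)
    if params.em_texture_sd > 0:
        from scipy.ndimage import gaussian_filter

        tex = rng.normal(0.0, 1.0, size=(n, n))
        tex = gaussian_filter(tex, sigma=4.0)
        sd = tex.std()
        if sd > 0:
            img += params.em_texture_sd * tex / sd

    # grid bars: map every pixel centre back to the specimen frame
    inv = scene.truth_fm_to_em.inverse()
    xs_em = origin[0] + (np.arange(n) + 0.5) * px_um
    ys_em = origin[1] + (np.arange(n) + 0.5) * px_um
    gx, gy = np.meshgrid(xs_em, ys_em)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    specimen_xy = inv.apply(pts)
    pitch = scene.grid.pitch_um
    half_bar = scene.grid.bar_width_um / 2.0
    fx = specimen_xy[:, 0] % pitch
    fy = specimen_xy[:, 1] % pitch
    on_film = (
        (fx >= half_bar)
        & (fx <= pitch - half_bar)
        & (fy >= half_bar)
        & (fy <= pitch - half_bar)
    ).reshape(n, n)
    img[~on_film] = 0.12 * params.em_background

    def to_px(p_specimen: Point2D) -> tuple[float, float]:
        em = scene.truth_fm_to_em.apply(np.array([p_specimen.x, p_specimen.y]))
        return (
            (em[0] - origin[0]) / px_um - 0.5,
            (em[1] - origin[1]) / px_um - 0.5,
        )

    margin = 20.0
    for p, diameter, _channels in scene.beads:
        cx, cy = to_px(p)
        if -margin < cx < n + margin and -margin < cy < n + margin:
            _add_disk(img, cx, cy, params.em_bead_depth, (diameter / 2.0) / params.em_pixel_size_nm)
    for p in scene.gold:
        cx, cy = to_px(p)
        if -margin < cx < n + margin and -margin < cy < n + margin:
            _add_disk(
                img, cx, cy, params.em_gold_depth,
                (Scene.GOLD_DIAMETER_NM / 2.0) / params.em_pixel_size_nm,
            )
    for p, _ch, _b in scene.pois:
        cx, cy = to_px(p)
        if -margin < cx < n + margin and -margin < cy < n + margin:
            _add_disk(img, cx, cy, params.em_poi_depth, 50.0 / params.em_pixel_size_nm)

    if noise and params.em_noise_sd > 0:
        img = img + rng.normal(0.0, params.em_noise_sd, size=img.shape)
    return img
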