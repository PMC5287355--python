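"""Full-grid FM map construction: autofocus, focus maps, Z-projection and
tile stitching.

An automated grid scan acquires a multi-channel Z-stack at each node of a
rectangular stage lattice.  Because an EM grid is never flat, a focus map —
a bilinear surface over sparse autofocus measurements — supplies the Z
offset at every stage position.  Each stack is reduced by maximum
projection, and the projected tiles are stitched into one mosaic of the
whole specimen using the overlap between neighbours: phase correlation on
the overlap strips refines each tile's nominal stage-derived offset, the
refined pairwise shifts are reconciled by least squares over the tile-pair
graph, and overlapping pixels are blended with linear feathering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.registration import phase_cross_correlation

from .geometry import FrameID, Point2D, Transform2D, fit_transform

__all__ = [
    "Tile",
    "FocusMap",
    "MosaicMap",
    "autofocus_z",
    "build_focus_map",
    "max_project",
    "stitch_tiles",
]

log = logging.getLogger(__name__)

DEFAULT_OVERLAP_FRACTION = 0.10
PEAK_RATIO_THRESHOLD = 3.0  # correlation peak vs next off-peak maximum


@dataclass
class Tile:
    """One scan position: a 2D image or a (z, y, x) stack plus stage metadata."""

    pixels: np.ndarray
    nominal_stage: Point2D  # stage coordinates of the tile centre, um
    channel: str = ""
    z_positions: list[float] = field(default_factory=list)
    tile_id: str = ""

    @property
    def image2d(self) -> np.ndarray:
        """The tile as a single plane (maximum projection for stacks)."""
        return max_project(self.pixels) if self.pixels.ndim == 3 else self.pixels


# ---------------------------------------------------------------------------
# autofocus


def _brenner(img: np.ndarray) -> float:
    """Brenner gradient: sum of squared two-pixel horizontal differences."""
    img = np.asarray(img, dtype=float)
    d = img[:, 2:] - img[:, :-2]
    return float(np.sum(d * d))


def autofocus_z(zstack: np.ndarray, z_positions) -> float:
    """Best-focus height from a through-focus stack.

    Scores each plane with the Brenner gradient, takes the peak, and refines
    it by fitting a parabola through the peak and its two neighbours (exact
    for a locally quadratic score).  At the stack edges the edge plane's z
    is returned without interpolation.
    """
    zstack = np.asarray(zstack, dtype=float)
    z = np.asarray(z_positions, dtype=float)
    if zstack.ndim != 3 or zstack.shape[0] != z.size:
        raise ValueError("zstack must be (n_planes, h, w) matching z_positions")
    if z.size < 3:
        raise ValueError("autofocus needs at least 3 planes")
    scores = np.array([_brenner(p) for p in zstack])
    if np.ptp(scores) == 0:
        raise ValueError("no focus signal: constant sharpness across stack")
    k = int(np.argmax(scores))
    if k == 0 or k == z.size - 1:
        return float(z[k])
    s0, s1, s2 = scores[k - 1], scores[k], scores[k + 1]
    denom = s0 - 2 * s1 + s2
    if denom == 0:
        return float(z[k])
    delta = 0.5 * (s0 - s2) / denom  # vertex offset in plane units, in (-1, 1)
    delta = float(np.clip(delta, -1.0, 1.0))
    # uniform spacing near the peak is assumed for the sub-plane refinement
    step = 0.5 * (z[k + 1] - z[k - 1])
    return float(z[k] + delta * step)


# ---------------------------------------------------------------------------
# focus map


def _fit_plane(xy: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Least-squares plane z = a x + b y + c; returns (a, b, c)."""
    design = np.column_stack([xy, np.ones(len(z))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("focus map needs >= 3 non-collinear sample points")
    coef, *_ = np.linalg.lstsq(design, z, rcond=None)
    return coef


@dataclass
class FocusMap:
    """Grid topography: bilinear surface over autofocus samples.

    Inside the sampled lattice's bounding box the height is bilinearly
    interpolated; outside, the global least-squares plane through all
    samples is evaluated (extrapolating a bilinear patch is not meaningful).
    Lattice nodes without a measurement are filled from that plane before
    the interpolator is built.
    """

    sample_points: list[tuple[Point2D, float]]
    _xs: np.ndarray = field(repr=False, default=None)
    _ys: np.ndarray = field(repr=False, default=None)
    _zgrid: np.ndarray = field(repr=False, default=None)
    _plane: np.ndarray = field(repr=False, default=None)

    def interpolate(self, p: Point2D) -> float:
        x, y = float(p[0]), float(p[1])
        xs, ys = self._xs, self._ys
        if xs[0] <= x <= xs[-1] and ys[0] <= y <= ys[-1]:
            i = int(np.clip(np.searchsorted(xs, x) - 1, 0, xs.size - 2))
            j = int(np.clip(np.searchsorted(ys, y) - 1, 0, ys.size - 2))
            tx = (x - xs[i]) / (xs[i + 1] - xs[i])
            ty = (y - ys[j]) / (ys[j + 1] - ys[j])
            zg = self._zgrid
            return float(
                zg[j, i] * (1 - tx) * (1 - ty)
                + zg[j, i + 1] * tx * (1 - ty)
                + zg[j + 1, i] * (1 - tx) * ty
                + zg[j + 1, i + 1] * tx * ty
            )
        a, b, c = self._plane
        return float(a * x + b * y + c)


def build_focus_map(samples: list[tuple[Point2D, float]]) -> FocusMap:
    """Build a :class:`FocusMap` from ``(stage point, z)`` autofocus samples
    taken on (a subset of) the scan lattice."""
    if len(samples) < 3:
        raise ValueError("focus map needs >= 3 sample points")
    xy = np.array([[p[0][0], p[0][1]] for p in samples], dtype=float)
    z = np.array([p[1] for p in samples], dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("focus heights must be finite")
    plane = _fit_plane(xy, z)

    xs = np.unique(xy[:, 0])
    ys = np.unique(xy[:, 1])
    if xs.size < 2 or ys.size < 2:
        # degenerate lattice (all samples on one line): plane everywhere
        xs = np.array([xy[:, 0].min() - 1, xy[:, 0].min()])
        ys = np.array([xy[:, 1].min() - 1, xy[:, 1].min()])
    zgrid = np.full((ys.size, xs.size), np.nan)
    for (px, py), pz in zip(xy, z):
        i = int(np.searchsorted(xs, px))
        j = int(np.searchsorted(ys, py))
        if i < xs.size and j < ys.size and xs[i] == px and ys[j] == py:
            zgrid[j, i] = pz
    missing = ~np.isfinite(zgrid)
    if missing.any():
        gy, gx = np.nonzero(missing)
        zgrid[gy, gx] = plane[0] * xs[gx] + plane[1] * ys[gy] + plane[2]
    return FocusMap(
        sample_points=list(samples), _xs=xs, _ys=ys, _zgrid=zgrid, _plane=plane
    )


def interpolate_z(fm: FocusMap, p: Point2D) -> float:
    """Height of the focus surface at stage position ``p`` (um)."""
    return fm.interpolate(p)


# ---------------------------------------------------------------------------
# projection and stitching


def max_project(zstack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over the Z axis of a (z, y, x) stack."""
    zstack = np.asarray(zstack)
    if zstack.ndim == 2:
        return zstack
    if zstack.ndim != 3 or zstack.shape[0] < 1:
        raise ValueError("expected a (z, y, x) stack with >= 1 plane")
    return zstack.max(axis=0)


@dataclass
class MosaicMap:
    """A stitched full-grid image with per-tile offsets and the pixel->stage map."""

    image: np.ndarray
    tile_offsets: dict[str, tuple[float, float]]  # tile_id -> (x, y) mosaic px
    frame: FrameID
    to_stage: Transform2D  # fm_mosaic_px -> fm_stage_um


def _phase_corr_surface(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    fa = np.fft.fft2(a - a.mean())
    fb = np.fft.fft2(b - b.mean())
    cross = fa * np.conj(fb)
    mag = np.abs(cross)
    mag[mag == 0] = 1.0
    return np.real(np.fft.ifft2(cross / mag))


def _peak_and_ratio(surface: np.ndarray) -> tuple[tuple[int, int], float]:
    flat = int(np.argmax(surface))
    py, px = np.unravel_index(flat, surface.shape)
    peak = surface[py, px]
    masked = surface.copy()
    y0, y1 = max(0, py - 3), min(surface.shape[0], py + 4)
    x0, x1 = max(0, px - 3), min(surface.shape[1], px + 4)
    masked[y0:y1, x0:x1] = -np.inf
    runner = float(masked.max())
    ratio = float("inf") if runner <= 0 else float(peak / runner)
    return (py, px), ratio


def _overlap_crops(
    img_i: np.ndarray, img_j: np.ndarray, sx: int, sy: int
) -> tuple[np.ndarray, np.ndarray] | None:
    """Aligned overlap regions of two tiles when j sits at (sx, sy) in i's frame."""
    h, w = img_i.shape
    x0, x1 = max(0, sx), min(w, w + sx)
    y0, y1 = max(0, sy), min(h, h + sy)
    if x1 - x0 < 4 or y1 - y0 < 4:
        return None
    a = img_i[y0:y1, x0:x1]
    b = img_j[y0 - sy : y1 - sy, x0 - sx : x1 - sx]
    return a, b


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float((a * a).sum()) * float((b * b).sum()))
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _measure_pair_shift(
    img_i: np.ndarray,
    img_j: np.ndarray,
    nominal_shift: np.ndarray,
    upsample: int,
    margin: int = 12,
) -> tuple[np.ndarray, float] | None:
    """Refined shift of tile j relative to tile i, or None when the overlap
    correlation is untrustworthy.

    ``nominal_shift`` is (dx, dy) in pixels, tile j's origin relative to
    tile i's origin.  The integer shift is found by maximizing the
    normalized cross-correlation of the overlap over a ``+-margin`` search
    window around the nominal shift; the peak must beat the best
    correlation outside its immediate neighbourhood by the peak-ratio
    threshold, otherwise the pair is deemed featureless/ambiguous.  Phase
    correlation with subpixel upsampling on the aligned overlap then
    refines the integer shift.
    """
    h, w = img_i.shape
    rx, ry = int(round(nominal_shift[0])), int(round(nominal_shift[1]))
    if abs(rx) >= w or abs(ry) >= h:
        return None
    size = 2 * margin + 1
    surface = np.full((size, size), -np.inf)
    for iy, dy in enumerate(range(-margin, margin + 1)):
        for ix, dx in enumerate(range(-margin, margin + 1)):
            crops = _overlap_crops(img_i, img_j, rx + dx, ry + dy)
            if crops is None:
                continue
            a, b = crops
            if a.size < 64 or np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            surface[iy, ix] = _ncc(a, b)
    if not np.isfinite(surface).any():
        return None
    (py, px), ratio = _peak_and_ratio(surface)
    if ratio < PEAK_RATIO_THRESHOLD or surface[py, px] <= 0:
        return None
    best = np.array([rx + (px - margin), ry + (py - margin)])
    if surface[py, px] > 0.995:
        # overlap already matches to numerical precision at the integer lag
        return best.astype(float), ratio
    crops = _overlap_crops(img_i, img_j, int(best[0]), int(best[1]))
    if crops is None:
        return None
    a, b = crops
    # subpixel residual; phase_cross_correlation returns the (row, col)
    # shift that registers the moving image (b) onto the reference (a),
    # which equals the remaining true-minus-integer shift
    try:
        shift, _, _ = phase_cross_correlation(a, b, upsample_factor=upsample)
    except Exception:
        return best.astype(float), ratio
    sub = np.array([shift[1], shift[0]])
    if np.any(np.abs(sub) > 1.0):  # refinement should stay subpixel
        sub = np.zeros(2)
    return best.astype(float) + sub, ratio


def stitch_tiles(
    tiles: list[Tile],
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
    pixel_size_um: float = 0.13,
    upsample: int = 20,
    search_margin_px: int = 12,
    offsets_override: dict[str, tuple[float, float]] | None = None,
) -> MosaicMap:
    """Stitch scan-lattice tiles into one mosaic.

    Nominal pixel offsets come from the stage metadata; phase correlation
    on each neighbour pair's overlap refines them, pairs with an ambiguous
    correlation peak (peak ratio below threshold) fall back to nominal, and
    the pairwise measurements are reconciled by least squares over the pair
    graph anchored at the first tile.  Overlaps are blended by linear
    feathering.  ``to_stage`` maps mosaic pixels to stage micrometres,
    fitted from the tiles' nominal stage centres against their placed pixel
    centres.
    """
    if not 0 < overlap_fraction <= 0.5:
        raise ValueError("overlap_fraction must be in (0, 0.5]")
    if not tiles:
        raise ValueError("no tiles")
    shapes = {t.image2d.shape for t in tiles}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent tile shapes: {shapes}")
    h, w = shapes.pop()
    n = len(tiles)
    images = [np.asarray(t.image2d, dtype=float) for t in tiles]
    stage = np.array([[t.nominal_stage.x, t.nominal_stage.y] for t in tiles])
    nominal_px = (stage - stage.min(axis=0)) / pixel_size_um  # tile origins

    if offsets_override is not None:
        offsets = np.array(
            [offsets_override[t.tile_id or str(k)] for k, t in enumerate(tiles)]
        )
        return _assemble(tiles, images, offsets, stage, pixel_size_um)

    # neighbour pairs on the scan lattice: tiles whose nominal spacing is
    # about one tile pitch along exactly one axis
    pairs: list[tuple[int, int, np.ndarray, bool]] = []  # i, j, shift, refined
    for i in range(n):
        for j in range(i + 1, n):
            d = nominal_px[j] - nominal_px[i]
            adx, ady = abs(d[0]), abs(d[1])
            horiz = adx < w and ady < 0.5 * h and adx > 0.5 * w
            vert = ady < h and adx < 0.5 * w and ady > 0.5 * h
            if not (horiz or vert):
                continue
            measured = _measure_pair_shift(
                images[i], images[j], d, upsample, margin=search_margin_px
            )
            if measured is None:
                log.warning(
                    "tile pair (%s, %s): featureless or ambiguous overlap, "
                    "falling back to nominal placement",
                    tiles[i].tile_id or i,
                    tiles[j].tile_id or j,
                )
            else:
                pairs.append((i, j, measured[0], True))

    # least squares over the graph of accepted pairs; every connected
    # component is anchored by one tile's nominal offset, so tiles with no
    # trustworthy overlap measurement fall back to their nominal placement
    if n == 1 or not pairs:
        offsets = nominal_px.copy()
    else:
        comp = np.arange(n)

        def _root(i: int) -> int:
            while comp[i] != i:
                comp[i] = comp[comp[i]]
                i = comp[i]
            return i

        for i, j, _s, _r in pairs:
            comp[_root(i)] = _root(j)
        anchors = sorted({_root(i) for i in range(n)})
        rows = len(pairs) + len(anchors)
        a_mat = np.zeros((rows, n))
        rhs = np.zeros((rows, 2))
        for r, (i, j, shift, _refined) in enumerate(pairs):
            a_mat[r, i] = -1.0
            a_mat[r, j] = 1.0
            rhs[r] = shift
        for k, i in enumerate(anchors):
            a_mat[len(pairs) + k, i] = 1.0
            rhs[len(pairs) + k] = nominal_px[i]
        sol, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
        offsets = sol

    offsets = offsets - offsets.min(axis=0)
    return _assemble(tiles, images, offsets, stage, pixel_size_um)


def _assemble(
    tiles: list[Tile],
    images: list[np.ndarray],
    offsets: np.ndarray,
    stage: np.ndarray,
    pixel_size_um: float,
) -> MosaicMap:
    """Feather-blend tiles at the given offsets and fit the pixel->stage map."""
    h, w = images[0].shape
    # canvas assembly with linear feather blending
    int_off = np.round(offsets).astype(int)
    canvas_w = int(int_off[:, 0].max()) + w
    canvas_h = int(int_off[:, 1].max()) + h
    acc = np.zeros((canvas_h, canvas_w))
    wacc = np.zeros((canvas_h, canvas_w))
    fx = np.minimum(np.arange(w) + 1, np.arange(w)[::-1] + 1).astype(float)
    fy = np.minimum(np.arange(h) + 1, np.arange(h)[::-1] + 1).astype(float)
    feather = np.minimum.outer(fy, fx)
    for img, (ox, oy) in zip(images, int_off):
        acc[oy : oy + h, ox : ox + w] += img * feather
        wacc[oy : oy + h, ox : ox + w] += feather
    mosaic = np.where(wacc > 0, acc / np.where(wacc > 0, wacc, 1.0), 0.0)

    # mosaic px -> stage um from tile centres
    centers_px = offsets + np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    frame = FrameID("fm_mosaic_px", pixel_size=pixel_size_um)
    stage_frame = FrameID("fm_stage_um")
    uniq = np.unique(np.round(centers_px, 3), axis=0)
    if len(uniq) >= 3 and np.linalg.matrix_rank(
        np.column_stack([uniq, np.ones(len(uniq))])
    ) == 3:
        to_stage, _ = fit_transform(
            centers_px, stage, model="affine", source=frame, target=stage_frame,
            compute_loo=False,
        )
    else:
        # too few tiles / collinear lattice row: pure scale + translation
        translation = stage[0] - centers_px[0] * pixel_size_um
        to_stage = Transform2D(
            matrix=np.eye(2) * pixel_size_um,
            translation=translation,
            source=frame,
            target=stage_frame,
            model="similarity",
        )

    tile_offsets = {
        (t.tile_id or str(k)): (float(offsets[k, 0]), float(offsets[k, 1]))
        for k, t in enumerate(tiles)
    }
    return MosaicMap(image=mosaic, tile_offsets=tile_offsets, frame=frame, to_stage=to_stage)
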