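"""Point-source detection and subpixel localization in FM and EM images.

Fluorescent beads, diffraction-limited signals of interest and (after
contrast inversion) electron-dense beads in EM frames all appear as compact
blobs.  Detection runs a scale-normalized Laplacian-of-Gaussian filter at
the expected PSF width and keeps local maxima that clear a robust
noise-based threshold; localization refines each candidate with an
isotropic 2D Gaussian + constant-background least-squares fit.

Multi-colour beads (e.g. TetraSpecks, fluorescent in green, red and far
red) are told apart from single-channel specimen signal by cross-channel
coincidence: a spot found at the same position in two or more channels is a
bead, a spot present only in the designated signal channel is specimen
signal, anything else is rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .geometry import Point2D

__all__ = [
    "Spot",
    "SpotClass",
    "detect_spots",
    "fit_gaussian_2d",
    "localize_dark_beads_em",
    "classify_spots",
    "detect_and_fit",
    "write_spot_table",
    "read_spot_table",
]

MAD_TO_SD = 1.4826  # consistent normal-SD estimate from the MAD

DEFAULT_MIN_SNR = 5.0
DEFAULT_COINCIDENCE_RADIUS_PX = 2.0


@dataclass
class Spot:
    """A localized point source.

    ``center`` is in image pixels (0-based, pixel-centre convention);
    ``uncertainty`` is the estimated localization SD in pixels derived from
    the fit covariance.
    """

    center: Point2D
    amplitude: float
    background: float
    sigma: float
    channel: str = ""
    fit_ok: bool = True
    uncertainty: float = float("nan")


@dataclass
class SpotClass:
    """Classification of a spot by cross-channel coincidence."""

    label: str  # "bead" | "signal" | "reject"
    channels_present: frozenset[str] = field(default_factory=frozenset)


def robust_noise_sd(values: np.ndarray) -> float:
    """Noise SD via the median absolute deviation.

    The MAD is insensitive to the sparse bright spots that sit on top of the
    background, which would inflate a plain standard deviation.
    """
    v = np.asarray(values, dtype=float).ravel()
    med = np.median(v)
    return MAD_TO_SD * float(np.median(np.abs(v - med)))


def _log_response(image: np.ndarray, sigma: float) -> np.ndarray:
    # scale-normalized negative LoG: bright blobs of width ~sigma -> positive peaks
    return -(sigma ** 2) * ndimage.gaussian_laplace(image.astype(float), sigma)


def _local_threshold(
    resp: np.ndarray, min_snr: float, psf_sigma_px: float, block: int = 64
) -> np.ndarray:
    """Per-pixel detection threshold ``median + min_snr * MAD-SD``.

    Background and noise are estimated on coarse blocks and interpolated,
    because shot noise varies strongly across a grid image (bright support
    film vs dark grid bars) and one global estimate under-thresholds the
    noisy regions.
    """
    h, w = resp.shape
    if h <= 2 * block or w <= 2 * block:
        return np.full_like(resp, float(np.median(resp)) + min_snr * robust_noise_sd(resp))
    ny, nx = math.ceil(h / block), math.ceil(w / block)
    med = np.empty((ny, nx))
    mad = np.empty((ny, nx))
    for by in range(ny):
        for bx in range(nx):
            cell = resp[by * block : (by + 1) * block, bx * block : (bx + 1) * block]
            m = np.median(cell)
            med[by, bx] = m
            mad[by, bx] = np.median(np.abs(cell - m))
    thresh_blocks = med + min_snr * MAD_TO_SD * mad
    return np.kron(thresh_blocks, np.ones((block, block)))[:h, :w]


def detect_spots(
    image: np.ndarray,
    min_snr: float = DEFAULT_MIN_SNR,
    psf_sigma_px: float = 1.8,
) -> list[Point2D]:
    """Detect candidate point sources.

    Local maxima of the scale-normalized LoG response at ``psf_sigma_px``
    are kept when they exceed ``background + min_snr * noise_sd`` where the
    background is the median response and the noise SD is the MAD-based
    robust estimate.  Candidates closer than ``2 * psf_sigma_px`` are
    de-duplicated keeping the stronger; the returned list is sorted by
    response, strongest first.  A constant or empty image yields an empty
    list.
    """
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be > 0")
    image = np.asarray(image, dtype=float)
    if image.size == 0 or not np.all(np.isfinite(image)):
        if image.size and not np.all(np.isfinite(image)):
            raise ValueError("image contains non-finite values")
        return []
    if np.ptp(image) == 0:
        return []

    resp = _log_response(image, psf_sigma_px)
    thresh = _local_threshold(resp, min_snr, psf_sigma_px)
    size = max(3, 2 * int(math.ceil(psf_sigma_px)) + 1)
    maxima = (resp == ndimage.maximum_filter(resp, size=size)) & (resp > thresh)
    # the LoG filter's boundary handling creates edge artifacts
    border = int(math.ceil(2 * psf_sigma_px))
    maxima[:border, :] = maxima[-border:, :] = False
    maxima[:, :border] = maxima[:, -border:] = False
    ys, xs = np.nonzero(maxima)
    if xs.size == 0:
        return []
    strengths = resp[ys, xs]
    order = np.argsort(strengths)[::-1]
    xs, ys = xs[order], ys[order]

    min_sep2 = (2.0 * psf_sigma_px) ** 2
    kept_x: list[float] = []
    kept_y: list[float] = []
    for x, y in zip(xs, ys):
        ok = True
        for kx, ky in zip(kept_x, kept_y):
            if (x - kx) ** 2 + (y - ky) ** 2 < min_sep2:
                ok = False
                break
        if ok:
            kept_x.append(float(x))
            kept_y.append(float(y))
    return [Point2D(x, y) for x, y in zip(kept_x, kept_y)]


def _gauss2d(coords, x0, y0, amp, sigma, bg):
    x, y = coords
    return bg + amp * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2.0 * sigma ** 2))


def fit_gaussian_2d(
    image: np.ndarray,
    init: Point2D,
    window_halfwidth_px: int,
    channel: str = "",
) -> Spot:
    """Refine a candidate to subpixel precision.

    Fits ``bg + A exp(-r^2 / 2 sigma^2)`` by nonlinear least squares inside
    a square window centred on ``init``.  ``fit_ok`` is False when the
    solver fails, the amplitude is non-positive, or the fitted centre leaves
    the window; the position uncertainty is the RMS of the x/y standard
    errors from the fit covariance.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    cx, cy = int(round(init.x)), int(round(init.y))
    hw = int(window_halfwidth_px)
    x0, x1 = cx - hw, cx + hw + 1
    y0, y1 = cy - hw, cy + hw + 1
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise ValueError(
            f"fit window [{x0}:{x1}, {y0}:{y1}] extends outside image of shape {image.shape}"
        )
    win = image[y0:y1, x0:x1]
    yy, xx = np.mgrid[y0:y1, x0:x1]
    bg0 = float(np.median(win))
    amp0 = float(win.max() - bg0)
    sigma0 = max(hw / 3.0, 0.5)

    failed = Spot(
        center=Point2D(float(init.x), float(init.y)),
        amplitude=0.0,
        background=bg0,
        sigma=sigma0,
        channel=channel,
        fit_ok=False,
    )
    if amp0 <= 0:
        return failed
    try:
        popt, pcov = optimize.curve_fit(
            _gauss2d,
            (xx.ravel().astype(float), yy.ravel().astype(float)),
            win.ravel(),
            p0=[float(init.x), float(init.y), amp0, sigma0, bg0],
            maxfev=2000,
        )
    except (RuntimeError, optimize.OptimizeWarning, ValueError):
        return failed
    fx, fy, amp, sigma, bg = popt
    sigma = abs(float(sigma))
    inside = x0 <= fx <= x1 - 1 and y0 <= fy <= y1 - 1
    if amp <= 0 or sigma <= 0 or not inside or not np.all(np.isfinite(popt)):
        return failed
    if amp > 1.5 * np.ptp(win) or bg < win.min() - 0.05 * np.ptp(win) or bg > win.max():
        # degenerate broad fit trading amplitude against background; for a
        # real point source the background sits inside the window's data
        # range and the amplitude cannot much exceed its dynamic range
        return failed
    with np.errstate(invalid="ignore"):
        var_xy = np.diag(pcov)[:2]
    unc = float(np.sqrt(np.mean(var_xy))) if np.all(np.isfinite(var_xy)) else float("nan")
    return Spot(
        center=Point2D(float(fx), float(fy)),
        amplitude=float(amp),
        background=float(bg),
        sigma=sigma,
        channel=channel,
        fit_ok=True,
        uncertainty=unc,
    )


def detect_and_fit(
    image: np.ndarray,
    psf_sigma_px: float = 1.8,
    min_snr: float = DEFAULT_MIN_SNR,
    channel: str = "",
    window_halfwidth_px: int | None = None,
    sigma_bounds: tuple[float, float] = (0.4, 2.5),
) -> list[Spot]:
    """Detection followed by Gaussian refinement.

    Drops failed fits, candidates whose window would leave the image, and
    fits whose width strays outside ``sigma_bounds`` (as multiples of
    ``psf_sigma_px``): a true point source must fit at about the PSF width,
    whereas edges and extended structures converge to much wider or
    needle-thin Gaussians.
    """
    hw = window_halfwidth_px or int(math.ceil(3 * psf_sigma_px))
    lo, hi = sigma_bounds[0] * psf_sigma_px, sigma_bounds[1] * psf_sigma_px
    spots: list[Spot] = []
    h, w = np.asarray(image).shape
    for cand in detect_spots(image, min_snr=min_snr, psf_sigma_px=psf_sigma_px):
        cx, cy = int(round(cand.x)), int(round(cand.y))
        if cx - hw < 0 or cy - hw < 0 or cx + hw + 1 > w or cy + hw + 1 > h:
            continue
        spot = fit_gaussian_2d(image, cand, hw, channel=channel)
        if spot.fit_ok and lo <= spot.sigma <= hi:
            spots.append(spot)
    return spots


def localize_dark_beads_em(
    image: np.ndarray,
    bead_diameter_px: float,
    min_snr: float = DEFAULT_MIN_SNR,
    channel: str = "em",
) -> list[Spot]:
    """Localize electron-dense beads, which are darker than the background.

    The image is inverted and run through the same LoG-detect + Gaussian-fit
    pipeline; the detection scale is matched to the bead size so 10 nm gold
    (much smaller than a 100 nm bead at the same magnification) is not
    picked up.  Amplitudes are reported as positive depth below background.
    """
    if bead_diameter_px < 2:
        raise ValueError("bead_diameter_px must be >= 2")
    image = np.asarray(image, dtype=float)
    inverted = image.max() - image
    # a uniform disk of diameter d has LoG-optimal sigma ~ d / (2 sqrt 2)
    sigma = bead_diameter_px / (2.0 * math.sqrt(2.0))
    return detect_and_fit(
        inverted, psf_sigma_px=sigma, min_snr=min_snr, channel=channel
    )


def classify_spots(
    per_channel_spots: dict[str, list[Spot]],
    coincidence_radius_px: float = DEFAULT_COINCIDENCE_RADIUS_PX,
    signal_channel: str | None = None,
) -> list[tuple[Spot, SpotClass]]:
    """Classify spots as bead / signal / reject by cross-channel coincidence.

    Spots co-located within ``coincidence_radius_px`` in two or more
    channels are beads (multi-colour fiducials).  A spot present only in
    ``signal_channel`` is specimen signal; single-channel spots elsewhere
    are rejected.
    """
    if signal_channel is not None and signal_channel not in per_channel_spots:
        raise ValueError(
            f"unknown signal channel {signal_channel!r}; "
            f"available: {sorted(per_channel_spots)}"
        )
    if len(per_channel_spots) < 2 and signal_channel is None:
        raise ValueError("bead calling needs spots from at least 2 channels")

    flat: list[tuple[str, Spot]] = [
        (ch, s) for ch, spots in per_channel_spots.items() for s in spots
    ]
    n = len(flat)
    # union-find over coincidence links between different channels
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    r2 = coincidence_radius_px ** 2
    for i in range(n):
        ci, si = flat[i]
        for j in range(i + 1, n):
            cj, sj = flat[j]
            if ci == cj:
                continue
            dx = si.center.x - sj.center.x
            dy = si.center.y - sj.center.y
            if dx * dx + dy * dy <= r2:
                parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    out: list[tuple[Spot, SpotClass]] = []
    for members in clusters.values():
        channels = frozenset(flat[i][0] for i in members)
        if len(channels) >= 2:
            label = "bead"
        elif signal_channel is not None and channels == frozenset({signal_channel}):
            label = "signal"
        else:
            label = "reject"
        for i in members:
            out.append((flat[i][1], SpotClass(label=label, channels_present=channels)))
    return out


_TABLE_COLUMNS = [
    "x_px", "y_px", "channel", "amplitude", "background", "sigma", "uncertainty", "class",
]


def write_spot_table(
    path: str | Path, spots: list[tuple[Spot, SpotClass]] | list[Spot]
) -> None:
    """Write spots as tab-separated text with a header line."""
    rows = []
    for item in spots:
        spot, cls = item if isinstance(item, tuple) else (item, None)
        rows.append(
            {
                "x_px": spot.center.x,
                "y_px": spot.center.y,
                "channel": spot.channel,
                "amplitude": spot.amplitude,
                "background": spot.background,
                "sigma": spot.sigma,
                "uncertainty": spot.uncertainty,
                "class": cls.label if cls else "",
            }
        )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_spot_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
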