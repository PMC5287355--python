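"""Three-tier FM->EM coordinate registration.

Tier 1 (grid-wide): an affine fit through a handful of landmarks visible in
both modalities — broken grid squares, film defects — maps the full-grid FM
mosaic onto the EM stage.  Its accuracy only needs to put each position of
interest inside the right grid square.

Tier 2 (grid square): within one square, the multi-channel fluorescent
beads serve as fiducials.  Starting from the grid-wide transform, FM and EM
bead detections are matched by iterated mutual-nearest-neighbour search and
the local transform refitted, tightening targeting to the bead-localization
level so high-magnification acquisitions can be placed automatically.

Tier 3 (post-acquisition): after imaging, the bead coordinates measured in
the FM image and in a medium-magnification EM image of the same area give a
final high-accuracy transform; mapping the fluorescence positions through
it predicts where the signal source sits in the high-magnification frame,
with the leave-one-out RMS as the quoted prediction radius.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, cKDTree

from .geometry import FitReport, Point2D, Transform2D, fit_transform
from .spot_localization import Spot

__all__ = [
    "LandmarkPair",
    "FiducialPairSet",
    "CorrelationResult",
    "register_gridwide",
    "match_fiducials",
    "register_high_accuracy",
    "measure_deviation",
]

log = logging.getLogger(__name__)

DEFAULT_MATCH_GATE_UM = 1.0
PREDICTION_RADIUS_FLOOR_NM = 50.0
LOO_SANITY_CEILING_NM = 1000.0
_TIE_RTOL = 1e-6


@dataclass
class LandmarkPair:
    """The same physical feature located in both modalities."""

    fm: Point2D
    em: Point2D
    label: str = ""


@dataclass
class FiducialPairSet:
    """Matched FM/EM coordinates of the same physical beads."""

    pairs: list[LandmarkPair]
    source_images: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        if len(self.pairs) < 2:
            raise ValueError("need at least 2 fiducial pairs")
        labels = [p.label for p in self.pairs if p.label]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate bead labels in pair set")

    @property
    def fm_array(self) -> np.ndarray:
        return np.array([[p.fm.x, p.fm.y] for p in self.pairs])

    @property
    def em_array(self) -> np.ndarray:
        return np.array([[p.em.x, p.em.y] for p in self.pairs])

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class CorrelationResult:
    """High-accuracy registration output: the transform, its diagnostics,
    and the predicted EM coordinates of each position of interest.

    ``prediction_radius_nm`` is the radius of the confidence circle drawn
    around each prediction — the leave-one-out RMS converted to nanometres,
    floored at a display minimum so the circle stays visible.
    ``extrapolated`` flags POIs outside the convex hull of the fiducials,
    where the fit extrapolates and the error inflates.
    """

    transform: Transform2D
    fit: FitReport
    predicted_pois: list[Point2D]
    prediction_radius_nm: float
    extrapolated: list[bool] = field(default_factory=list)
    warning: str | None = None

    def to_text(self) -> str:
        lines = [
            "# high-accuracy correlation result",
            f"n_pairs = {self.fit.n_points}",
            f"rms_residual = {self.fit.rms_residual:.6g}",
            f"loo_rms = {self.fit.loo_rms if self.fit.loo_rms is not None else 'nan'}",
            f"prediction_radius_nm = {self.prediction_radius_nm:.6g}",
        ]
        if self.warning:
            lines.append(f"warning = {self.warning}")
        lines.append("# transform")
        lines.append(self.transform.to_text().rstrip("\n"))
        lines.append("# predicted POIs (x, y, extrapolated)")
        for p, ex in zip(self.predicted_pois, self.extrapolated):
            lines.append(f"poi = {p.x:.6f} {p.y:.6f} {int(ex)}")
        return "\n".join(lines) + "\n"


def register_gridwide(
    landmarks: list[LandmarkPair],
    warn_loo_threshold: float | None = None,
) -> Transform2D:
    """Tier-1 affine fit from grid-wide landmarks (FM mosaic/stage -> EM stage).

    At least 3 non-collinear pairs are required.  When
    ``warn_loo_threshold`` is given (typically half a grid-square pitch), a
    leave-one-out RMS above it logs a warning: the grid-wide tier only has
    to land inside the correct square, but worse than that means bad
    landmarks.
    """
    if len(landmarks) < 3:
        raise ValueError("grid-wide registration needs >= 3 landmark pairs")
    fm = np.array([[p.fm.x, p.fm.y] for p in landmarks])
    em = np.array([[p.em.x, p.em.y] for p in landmarks])
    t, report = fit_transform(fm, em, model="affine")
    if (
        warn_loo_threshold is not None
        and report.loo_rms is not None
        and report.loo_rms > warn_loo_threshold
    ):
        log.warning(
            "grid-wide registration leave-one-out RMS %.3g exceeds %.3g; "
            "POIs may land in the wrong grid square",
            report.loo_rms,
            warn_loo_threshold,
        )
    return t


def _spot_coords(spots: list[Spot] | np.ndarray) -> np.ndarray:
    if isinstance(spots, np.ndarray):
        return spots.astype(float)
    return np.array([[s.center.x, s.center.y] for s in spots], dtype=float)


def _mutual_nn(
    a: np.ndarray, b: np.ndarray, gate: float
) -> list[tuple[int, int]]:
    """Mutual nearest neighbours within ``gate``; ambiguous ties dropped.

    A point whose two nearest partners are (numerically) equidistant inside
    the gate has no defensible assignment and is excluded on either side.
    """
    tree_a = cKDTree(a)
    tree_b = cKDTree(b)
    k_b = min(2, len(b))
    d_ab, i_ab = tree_b.query(a, k=k_b)
    d_ab = np.atleast_2d(d_ab.T).T if k_b == 1 else d_ab
    i_ab = np.atleast_2d(i_ab.T).T if k_b == 1 else i_ab
    k_a = min(2, len(a))
    d_ba, i_ba = tree_a.query(b, k=k_a)
    d_ba = np.atleast_2d(d_ba.T).T if k_a == 1 else d_ba
    i_ba = np.atleast_2d(i_ba.T).T if k_a == 1 else i_ba

    def ambiguous(dists) -> bool:
        if len(dists) < 2 or not np.isfinite(dists[1]):
            return False
        if dists[1] >= gate:
            return False
        return (dists[1] - dists[0]) <= _TIE_RTOL * max(dists[1], 1e-300)

    matches = []
    for i in range(len(a)):
        if d_ab[i, 0] >= gate or ambiguous(d_ab[i]):
            continue
        j = int(i_ab[i, 0])
        if int(i_ba[j, 0]) != i or ambiguous(d_ba[j]):
            continue
        matches.append((i, j))
    return matches


def match_fiducials(
    fm_beads: list[Spot] | np.ndarray,
    em_beads: list[Spot] | np.ndarray,
    approx: Transform2D,
    gate: float = DEFAULT_MATCH_GATE_UM,
    max_iter: int = 10,
    source_images: tuple[str, str] = ("", ""),
) -> FiducialPairSet:
    """Tier-2 correspondence search between FM and EM bead detections.

    FM beads are mapped through ``approx`` (the transform from the previous
    tier), matched to EM beads by mutual nearest neighbour within ``gate``,
    and the loop (match -> refit similarity -> rematch) iterates until the
    pair set stabilizes or ``max_iter`` is reached.  Ties are broken by
    distance; genuinely ambiguous beads are dropped.
    """
    fm = _spot_coords(fm_beads)
    em = _spot_coords(em_beads)
    if fm.size == 0 or em.size == 0:
        raise ValueError("no correspondences within gate: empty bead list")

    def _match_rms(t: Transform2D, mset: list[tuple[int, int]]) -> float:
        mapped = t.apply(fm)
        return float(
            np.sqrt(
                np.mean([np.sum((mapped[i] - em[j]) ** 2) for i, j in mset])
            )
        )

    current = approx
    prev_matches: list[tuple[int, int]] | None = None
    matches: list[tuple[int, int]] = []
    best: tuple[int, float, list[tuple[int, int]], Transform2D] | None = None
    for _ in range(max_iter):
        mapped = current.apply(fm)
        matches = _mutual_nn(mapped, em, gate)
        if not matches:
            break
        rms = _match_rms(current, matches)
        # prefer more matches; among equal counts, tighter agreement
        if best is None or (len(matches), -rms) > (best[0], -best[1]):
            best = (len(matches), rms, matches, current)
        if matches == prev_matches:
            break
        prev_matches = matches
        # a 2-point similarity with free reflection is ambiguous (both
        # handednesses fit exactly), so only refit on >= 3 matches
        if len(matches) >= 3:
            idx_fm = [i for i, _ in matches]
            idx_em = [j for _, j in matches]
            try:
                current, _ = fit_transform(
                    fm[idx_fm], em[idx_em], model="similarity", allow_reflection=True
                )
            except ValueError:
                break
        else:
            break

    if best is not None:
        matches = best[2]
    if not matches:
        raise ValueError(
            f"no correspondences within gate {gate}: check the approximate transform"
        )
    pairs = [
        LandmarkPair(
            fm=Point2D(*fm[i]), em=Point2D(*em[j]), label=f"bead_{i}_{j}"
        )
        for i, j in matches
    ]
    return FiducialPairSet(pairs=pairs, source_images=source_images)


def _outside_hull(fiducials: np.ndarray, points: np.ndarray) -> np.ndarray:
    if len(fiducials) < 3:
        return np.ones(len(points), dtype=bool)
    try:
        tri = Delaunay(fiducials)
    except Exception:  # collinear fiducials: everything is extrapolation
        return np.ones(len(points), dtype=bool)
    return tri.find_simplex(points) < 0


def register_high_accuracy(
    pairs: FiducialPairSet,
    pois: list[Point2D],
    model: str = "similarity",
    allow_reflection: bool = True,
    units_to_nm: float = 1000.0,
    radius_floor_nm: float = PREDICTION_RADIUS_FLOOR_NM,
    loo_ceiling_nm: float = LOO_SANITY_CEILING_NM,
) -> CorrelationResult:
    """Tier-3 post-acquisition registration and POI prediction.

    Fits ``model`` on the bead pairs (needs at least the model minimum + 1
    so the leave-one-out RMS is defined), maps each POI into the EM frame,
    and quotes ``max(loo_rms, floor)`` as the prediction radius.
    ``units_to_nm`` converts pair coordinates to nanometres (1000 for
    micrometre coordinates, the pixel size for pixel coordinates).  A
    leave-one-out RMS above ``loo_ceiling_nm`` is flagged in ``warning``
    but does not fail the call.
    """
    min_pairs = {"similarity": 2, "affine": 3}[model]
    if len(pairs) < min_pairs + 1:
        raise ValueError(
            f"high-accuracy {model} registration needs >= {min_pairs + 1} pairs "
            f"(so leave-one-out is defined), got {len(pairs)}"
        )
    fm = pairs.fm_array
    em = pairs.em_array
    t, report = fit_transform(fm, em, model=model, allow_reflection=allow_reflection)

    poi_arr = np.array([[p.x, p.y] for p in pois], dtype=float).reshape(-1, 2)
    predicted = t.apply(poi_arr) if len(poi_arr) else np.empty((0, 2))
    extrapolated = _outside_hull(fm, poi_arr) if len(poi_arr) else np.array([], bool)

    loo_nm = (report.loo_rms or 0.0) * units_to_nm
    warning = None
    if loo_nm > loo_ceiling_nm:
        warning = (
            f"leave-one-out RMS {loo_nm:.0f} nm exceeds sanity ceiling "
            f"{loo_ceiling_nm:.0f} nm; check bead matching"
        )
        log.warning(warning)
    return CorrelationResult(
        transform=t,
        fit=report,
        predicted_pois=[Point2D(float(x), float(y)) for x, y in predicted],
        prediction_radius_nm=max(loo_nm, radius_floor_nm),
        extrapolated=[bool(b) for b in extrapolated],
        warning=warning,
    )


def measure_deviation(
    predicted: Point2D,
    observed_center: Point2D,
    pixel_size_nm: float | None = None,
    units_to_nm: float | None = None,
) -> tuple[float, float]:
    """Deviation of a prediction from the observed feature centre, in nm.

    Both points must be in the same EM frame.  Exactly one of
    ``pixel_size_nm`` (for pixel coordinates) or ``units_to_nm`` (a general
    unit factor, e.g. 1000 for micrometres) must be given.
    """
    if pixel_size_nm is None and units_to_nm is None:
        raise ValueError("pixel size (or unit factor) required to express nm")
    scale = pixel_size_nm if pixel_size_nm is not None else units_to_nm
    dx = (observed_center.x - predicted.x) * scale
    dy = (observed_center.y - predicted.y) * scale
    return (float(dx), float(dy))
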