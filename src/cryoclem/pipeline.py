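"""End-to-end orchestration of the correlative workflow on synthetic data.

The stages mirror the experimental workflow: an automated FM grid scan is
projected, stitched and annotated; the annotations are registered onto the
EM side grid-wide, refined per grid square with the fluorescent beads, and
exported as navigator items; simulated acquisitions at the predicted
positions then yield deviation statistics that close the loop with the
targeting-accuracy model.

Two simulation entry points support statistical checks without full image
rendering: :func:`simulate_high_accuracy_replicates` measures tier-3
prediction error under controlled bead-localization noise, and
:func:`simulate_targeting_experiment` emulates the automated-acquisition
tier (match + fit + stage/montage error) to produce deviation samples whose
hit rate can be compared with the closed-form prediction.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import accuracy_model
from .geometry import Point2D, Transform2D, fit_transform
from .mosaic import MosaicMap, Tile, max_project, stitch_tiles
from .navigator_io import AnnotationList, NavigatorItem, export_annotations
from .registration import (
    CorrelationResult,
    LandmarkPair,
    match_fiducials,
    register_gridwide,
    register_high_accuracy,
)
from .spot_localization import Spot, SpotClass, classify_spots, detect_and_fit
from .synthetic_data import RenderParams, Scene, render_em, render_fm

__all__ = [
    "RunConfig",
    "RunReport",
    "FMStageResult",
    "CorrelationStageResult",
    "run_fm_stage",
    "run_correlation_stage",
    "simulate_high_accuracy_replicates",
    "simulate_targeting_experiment",
]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Knobs of one synthetic end-to-end run."""

    channels: tuple[str, ...] = ("green", "red")
    signal_channel: str = "green"
    match_gate_um: float = 2.0
    landmark_noise_um: float = 2.0
    fov_nm: float = 1240.0
    em_local_fov_um: float = 12.0
    acquisition_noise_nm: float = 0.0  # extra per-acquisition stage error
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signal_channel not in self.channels:
            raise ValueError("signal channel must be among the rendered channels")


@dataclass
class RunReport:
    """Per-stage timings and object counts of a pipeline run."""

    timings_s: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def add(self, stage: str, t0: float, **counts: int) -> None:
        self.timings_s[stage] = time.perf_counter() - t0
        for k, v in counts.items():
            self.counts[k] = int(v)


@dataclass
class FMStageResult:
    mosaics: dict[str, MosaicMap]
    classified: list[tuple[Spot, SpotClass]]  # centres in fm_mosaic_px
    annotations: AnnotationList  # coordinates in fm_stage_um
    report: RunReport


def _mosaic_px_to_stage(mosaic: MosaicMap, xy: np.ndarray) -> np.ndarray:
    return mosaic.to_stage.apply(xy)


def run_fm_stage(
    scene: Scene,
    params: RenderParams,
    config: RunConfig,
    noise: bool = True,
) -> FMStageResult:
    """FM half of the workflow: render the scan, stitch, find and classify
    spots, and propose annotations.

    Positions of interest are auto-proposed from signal-channel spots that
    pass detection (manual selection in the real workflow); grid reference
    landmarks are the broken-square centres, perturbed by
    ``landmark_noise_um`` to emulate by-eye annotation on the mosaic.
    """
    report = RunReport()
    t0 = time.perf_counter()
    tiles_by_channel: dict[str, list[Tile]] = {}
    for ch in config.channels:
        tiles, _meta = render_fm(scene, params, ch, noise=noise)
        tiles_by_channel[ch] = tiles
    report.add("render", t0, tiles=sum(len(v) for v in tiles_by_channel.values()))

    # stitch on the first channel; reuse its refined offsets everywhere
    t0 = time.perf_counter()
    projected = {
        ch: [
            Tile(
                pixels=max_project(t.pixels),
                nominal_stage=t.nominal_stage,
                channel=t.channel,
                tile_id=t.tile_id,
            )
            for t in tiles
        ]
        for ch, tiles in tiles_by_channel.items()
    }
    ref_ch = config.channels[0]
    mosaics: dict[str, MosaicMap] = {
        ref_ch: stitch_tiles(
            projected[ref_ch],
            overlap_fraction=params.overlap_fraction,
            pixel_size_um=params.fm_pixel_size_um,
        )
    }
    # all channels of one scan share a placement: reuse the reference
    # channel's refined offsets so cross-channel coincidence stays exact
    for ch in config.channels[1:]:
        mosaics[ch] = stitch_tiles(
            projected[ch],
            overlap_fraction=params.overlap_fraction,
            pixel_size_um=params.fm_pixel_size_um,
            offsets_override=mosaics[ref_ch].tile_offsets,
        )
    report.add("stitch", t0)

    t0 = time.perf_counter()
    sigma_px = params.psf_sigma_um / params.fm_pixel_size_um
    per_channel = {
        ch: detect_and_fit(mosaics[ch].image, psf_sigma_px=sigma_px, channel=ch)
        for ch in config.channels
    }
    classified = classify_spots(
        per_channel,
        coincidence_radius_px=2.0,
        signal_channel=config.signal_channel,
    )
    report.add(
        "spots",
        t0,
        spots=len(classified),
        beads=sum(1 for _, c in classified if c.label == "bead"),
    )

    t0 = time.perf_counter()
    ref_mosaic = mosaics[config.channels[0]]
    # auto-proposal keeps signal spots well above the shot noise
    from .spot_localization import robust_noise_sd

    amp_floor = 5.0 * robust_noise_sd(mosaics[config.signal_channel].image)
    pois = []
    for k, (spot, cls) in enumerate(
        (s, c)
        for s, c in classified
        if c.label == "signal" and s.amplitude > amp_floor
    ):
        stage = _mosaic_px_to_stage(
            ref_mosaic, np.array([spot.center.x, spot.center.y])
        )
        pois.append((f"poi_{k:03d}", Point2D(float(stage[0]), float(stage[1])), spot.channel))
    rng = np.random.default_rng(config.seed)
    grid_refs = []
    for k, ij in enumerate(scene.broken_squares):
        c = scene.grid.square_center(ij)
        noise_xy = rng.normal(0.0, config.landmark_noise_um, size=2)
        grid_refs.append(
            (f"ref_{k}", Point2D(c.x + noise_xy[0], c.y + noise_xy[1]))
        )
    annotations = AnnotationList(pois=pois, grid_refs=grid_refs)
    report.add("annotate", t0, pois=len(pois), grid_refs=len(grid_refs))
    return FMStageResult(
        mosaics=mosaics, classified=classified, annotations=annotations, report=report
    )


@dataclass
class CorrelationStageResult:
    gridwide: Transform2D
    navigator_items: list[NavigatorItem]
    correlations: list[CorrelationResult]
    deviations_nm: np.ndarray  # (n, 2) predicted-vs-truth, when truth known
    hit_rate: float | None
    stats: accuracy_model.DeviationStats | None
    report: RunReport
    skipped_squares: list[tuple[int, int]] = field(default_factory=list)


def _em_spot_to_stage(
    spots: list[Spot], center: Point2D, fov_um: float, px_nm: float
) -> np.ndarray:
    px_um = px_nm / 1000.0
    origin = np.array([center.x - fov_um / 2.0, center.y - fov_um / 2.0])
    arr = np.array([[s.center.x, s.center.y] for s in spots], dtype=float)
    return origin + (arr + 0.5) * px_um


def run_correlation_stage(
    scene: Scene,
    params: RenderParams,
    fm_result: FMStageResult,
    config: RunConfig,
) -> CorrelationStageResult:
    """EM half of the workflow, against rendered EM frames.

    Grid-wide landmarks (broken-square centres located on both sides, with
    annotation noise) give the tier-1 affine; for every grid square holding
    POIs, an EM frame around the predicted area is rendered, its dark beads
    localized and matched against the FM beads of the same square, the
    tier-2/3 similarity fitted, and each POI's predicted EM position
    compared against ground truth.  Squares without enough matched beads
    are reported and skipped.
    """
    report = RunReport()
    rng = np.random.default_rng(config.seed + 1)

    # tier 1: grid-wide landmarks
    t0 = time.perf_counter()
    landmarks = []
    for label, p in fm_result.annotations.grid_refs:
        em_true = scene.truth_fm_to_em.apply(np.array([p.x, p.y]))
        em_noisy = em_true + rng.normal(0.0, config.landmark_noise_um, size=2)
        landmarks.append(
            LandmarkPair(fm=p, em=Point2D(*em_noisy), label=label)
        )
    gridwide = register_gridwide(
        landmarks, warn_loo_threshold=scene.grid.pitch_um / 2.0
    )
    report.add("gridwide", t0, landmarks=len(landmarks))

    # navigator export of the POIs through the grid-wide transform
    nav_items = export_annotations(fm_result.annotations, gridwide)

    # group POIs and FM beads by grid square (FM stage frame)
    ref_mosaic = fm_result.mosaics[config.channels[0]]
    bead_stage = []
    for spot, cls in fm_result.classified:
        if cls.label != "bead":
            continue
        st = ref_mosaic.to_stage.apply(np.array([spot.center.x, spot.center.y]))
        bead_stage.append((float(st[0]), float(st[1])))
    bead_stage = np.array(bead_stage).reshape(-1, 2)
    # one physical bead is detected once per channel; merge detections
    # closer than the coincidence radius into a single mean position
    merge_radius_um = 2.5 * params.fm_pixel_size_um
    merged: list[np.ndarray] = []
    used = np.zeros(len(bead_stage), dtype=bool)
    for i in range(len(bead_stage)):
        if used[i]:
            continue
        close = np.linalg.norm(bead_stage - bead_stage[i], axis=1) < merge_radius_um
        close &= ~used
        used |= close
        merged.append(bead_stage[close].mean(axis=0))
    bead_stage = np.array(merged).reshape(-1, 2)

    by_square: dict[tuple[int, int], list[tuple[str, Point2D]]] = {}
    for label, p, _ch in fm_result.annotations.pois:
        by_square.setdefault(scene.grid.square_of(p.x, p.y), []).append((label, p))

    t0 = time.perf_counter()
    correlations: list[CorrelationResult] = []
    deviations = []
    hits = []
    skipped: list[tuple[int, int]] = []
    em_px_nm = params.em_pixel_size_nm
    truth_pois_em = {
        k: scene.truth_fm_to_em.apply(np.array([p.x, p.y]))
        for k, (p, _c, _b) in enumerate(scene.pois)
    }

    for ij, poi_list in sorted(by_square.items()):
        centers = np.array([[p.x, p.y] for _l, p in poi_list])
        area_center_fm = centers.mean(axis=0)
        area_center_em = Point2D(*gridwide.apply(area_center_fm))

        # FM beads near this acquisition area
        if bead_stage.size:
            d = np.linalg.norm(bead_stage - area_center_fm, axis=1)
            local_fm = bead_stage[d < config.em_local_fov_um * 0.75]
        else:
            local_fm = np.empty((0, 2))
        if len(local_fm) < 3:
            log.warning("square %s: only %d FM beads nearby, skipped", ij, len(local_fm))
            skipped.append(ij)
            continue

        em_img = render_em(
            scene, params, area_center_em, config.em_local_fov_um, noise=True,
            seed_offset=100 + ij[0] * 37 + ij[1],
        )
        bead_diam_px = scene.beads[0][1] / em_px_nm if scene.beads else 10.0
        em_spots = [
            s
            for s in detect_and_fit(
                em_img.max() - em_img,  # dark beads -> bright
                psf_sigma_px=max(1.5, bead_diam_px / (2 * np.sqrt(2))),
                channel="em",
            )
        ]
        if len(em_spots) < 3:
            log.warning("square %s: only %d EM beads found, skipped", ij, len(em_spots))
            skipped.append(ij)
            continue
        em_stage = _em_spot_to_stage(
            em_spots, area_center_em, config.em_local_fov_um, em_px_nm
        )
        try:
            pair_set = match_fiducials(
                local_fm, em_stage, gridwide, gate=config.match_gate_um
            )
            corr = register_high_accuracy(
                pair_set,
                [p for _l, p in poi_list],
                model="similarity",
                units_to_nm=1000.0,
            )
        except ValueError as exc:
            log.warning("square %s: %s; skipped", ij, exc)
            skipped.append(ij)
            continue
        correlations.append(corr)

        for (label, p), pred in zip(poi_list, corr.predicted_pois):
            # match against the nearest ground-truth POI
            best_k, best_d = None, np.inf
            for k, em_true in truth_pois_em.items():
                dd = float(np.hypot(em_true[0] - pred.x, em_true[1] - pred.y))
                if dd < best_d:
                    best_k, best_d = k, dd
            if best_k is None or best_d > scene.grid.pitch_um:
                continue
            em_true = truth_pois_em[best_k]
            dev = (np.array([pred.x, pred.y]) - em_true) * 1000.0  # nm
            if config.acquisition_noise_nm > 0:
                dev = dev + rng.normal(0.0, config.acquisition_noise_nm, size=2)
            deviations.append(dev)
            half = config.fov_nm / 2.0
            hits.append(abs(dev[0]) <= half and abs(dev[1]) <= half)

    report.add(
        "correlate",
        t0,
        squares=len(by_square),
        skipped=len(skipped),
        acquisitions=len(deviations),
        hits=int(np.sum(hits)) if hits else 0,
    )
    deviations = np.array(deviations).reshape(-1, 2)
    stats = None
    hit_rate = None
    if len(deviations) >= 3:
        try:
            stats = accuracy_model.estimate_deviation_stats(deviations)
        except ValueError:
            stats = None
    if hits:
        hit_rate = float(np.mean(hits))
    return CorrelationStageResult(
        gridwide=gridwide,
        navigator_items=nav_items,
        correlations=correlations,
        deviations_nm=deviations,
        hit_rate=hit_rate,
        stats=stats,
        report=report,
        skipped_squares=skipped,
    )


# ---------------------------------------------------------------------------
# coordinate-level simulations


def simulate_high_accuracy_replicates(
    n_replicates: int = 100,
    n_beads: int = 15,
    noise_nm_per_side: float = 20.0,
    field_um: float = 10.0,
    seed: int = 0,
    model: str = "similarity",
) -> np.ndarray:
    """Tier-3 prediction error under controlled localization noise.

    Each replicate draws ``n_beads`` bead positions uniformly in a
    ``field_um`` square (the medium-magnification EM field), one position
    of interest in the central half of the field (interior to the bead
    hull), and a random ground-truth similarity-with-reflection transform.
    Both sides' bead coordinates are perturbed with independent per-axis
    Gaussian noise of ``noise_nm_per_side``; the transform is fitted on the
    noisy pairs and the POI mapped through it.  Returns the Euclidean
    prediction errors in nm, one per replicate.
    """
    rng = np.random.default_rng(seed)
    noise_um = noise_nm_per_side / 1000.0
    errors = np.empty(n_replicates)
    for r in range(n_replicates):
        beads = rng.uniform(0.0, field_um, size=(n_beads, 2))
        poi = rng.uniform(0.25 * field_um, 0.75 * field_um, size=2)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s], [s, c]]) @ np.diag([1.0, -1.0])
        truth = Transform2D(
            matrix=rot, translation=rng.uniform(-50, 50, size=2), model="similarity"
        )
        fm_obs = beads + rng.normal(0.0, noise_um, size=beads.shape)
        em_obs = truth.apply(beads) + rng.normal(0.0, noise_um, size=beads.shape)
        fitted, _ = fit_transform(fm_obs, em_obs, model=model, allow_reflection=True)
        pred = fitted.apply(poi)
        errors[r] = np.linalg.norm(pred - truth.apply(poi)) * 1000.0
    return errors


def simulate_targeting_experiment(
    n_trials: int = 400,
    n_beads: int = 12,
    fm_localization_sd_nm: float = 50.0,
    em_localization_sd_nm: float = 20.0,
    montage_error_sd_nm: float = 230.0,
    field_um: float = 12.0,
    gate_um: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Emulate the automated-acquisition tier and return deviations in nm.

    Each trial is one grid square: beads are placed, localized with noise
    on both sides, matched with :func:`match_fiducials` starting from a
    slightly-off approximate transform, the local similarity fitted, and a
    POI mapped through it.  An independent per-acquisition error of
    ``montage_error_sd_nm`` per axis emulates image-montage registration
    error, the dominant inaccuracy of this tier.  Returns an
    ``(n_trials, 2)`` array of deviations suitable for
    :func:`accuracy_model.estimate_deviation_stats`.
    """
    rng = np.random.default_rng(seed)
    fm_sd = fm_localization_sd_nm / 1000.0
    em_sd = em_localization_sd_nm / 1000.0
    deviations = np.empty((n_trials, 2))
    for r in range(n_trials):
        beads = rng.uniform(0.0, field_um, size=(n_beads, 2))
        poi = rng.uniform(0.2 * field_um, 0.8 * field_um, size=2)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s], [s, c]]) @ np.diag([1.0, -1.0])
        truth = Transform2D(
            matrix=rot, translation=rng.uniform(-50, 50, size=2), model="similarity"
        )
        fm_obs = beads + rng.normal(0.0, fm_sd, size=beads.shape)
        em_obs = truth.apply(beads) + rng.normal(0.0, em_sd, size=beads.shape)
        # approximate transform: truth perturbed by a small offset
        approx = Transform2D(
            matrix=truth.matrix,
            translation=truth.translation + rng.normal(0.0, 0.3, size=2),
            model="similarity",
        )
        pair_set = match_fiducials(fm_obs, em_obs, approx, gate=gate_um)
        idx = np.arange(len(pair_set))
        fitted, _ = fit_transform(
            pair_set.fm_array, pair_set.em_array, model="similarity"
        )
        pred = fitted.apply(poi)
        dev_um = pred - truth.apply(poi)
        deviations[r] = dev_um * 1000.0 + rng.normal(
            0.0, montage_error_sd_nm, size=2
        )
    return deviations
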