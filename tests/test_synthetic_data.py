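"""Scene generation and FM/EM rendering against ground truth."""

import numpy as np
import pytest

from cryoclem.geometry import Point2D
from cryoclem.spot_localization import (
    classify_spots,
    detect_and_fit,
    fit_gaussian_2d,
    localize_dark_beads_em,
)
from cryoclem.synthetic_data import (
    GridGeometry,
    RenderParams,
    Scene,
    SceneParams,
    bead_brightness,
    generate_scene,
    render_em,
    render_fm,
)


SMALL_GRID = GridGeometry(mesh=300, n_squares=(2, 2), pitch_um=21.25, bar_width_um=6.25)


def _small_params(**kw):
    defaults = dict(
        grid=SMALL_GRID,
        beads_per_square=8,
        gold_per_square=5,
        pois_per_square=2,
        n_broken_squares=2,
    )
    defaults.update(kw)
    return SceneParams(**defaults)


class TestGenerateScene:
    def test_deterministic_from_seed(self):
        a = generate_scene(_small_params(), 11)
        b = generate_scene(_small_params(), 11)
        assert a.beads == b.beads
        assert a.gold == b.gold
        assert a.pois == b.pois
        assert np.array_equal(a.truth_fm_to_em.matrix, b.truth_fm_to_em.matrix)
        c = generate_scene(_small_params(), 12)
        assert a.beads != c.beads

    def test_zero_beads_supported(self):
        scene = generate_scene(_small_params(beads_per_square=0), 1)
        assert scene.beads == []

    def test_no_placements_under_grid_bars(self):
        """All placed objects sit on open film across many placements."""
        params = _small_params(beads_per_square=600, gold_per_square=1600, pois_per_square=300)
        scene = generate_scene(params, 2)
        pts = (
            [p for p, _, _ in scene.beads]
            + list(scene.gold)
            + [p for p, _, _ in scene.pois]
        )
        assert len(pts) == 10_000
        assert all(scene.grid.on_film(p.x, p.y) for p in pts)

    def test_overdense_placement_fails_loudly(self):
        tiny = GridGeometry(mesh=300, n_squares=(1, 1), pitch_um=26.0, bar_width_um=25.9)
        with pytest.raises(RuntimeError, match="placement failed"):
            generate_scene(_small_params(grid=tiny, beads_per_square=50), 0)

    def test_mesh_geometry_defaults(self):
        assert GridGeometry(mesh=300).pitch_um == 85.0
        assert GridGeometry(mesh=200).pitch_um == 125.0
        with pytest.raises(ValueError):
            GridGeometry(mesh=400)


class TestBeadBrightness:
    def test_reference_is_unity(self):
        assert bead_brightness(100, 100) == 1.0

    def test_half_diameter_is_eightfold_dimmer(self):
        assert bead_brightness(50, 100) == pytest.approx(1 / 8)

    @pytest.mark.parametrize("d", [40.0, 100.0, 350.0])
    def test_volume_scaling_law(self, d):
        assert bead_brightness(d, d / 2) == pytest.approx(8.0)


class TestRenderFM:
    def test_noiseless_bead_recovered_subpixel(self):
        scene = generate_scene(_small_params(beads_per_square=2, pois_per_square=0), 3)
        params = RenderParams(fm_fov_um=(24.5, 24.5), z_range_um=4.0, z_step_um=2.0)
        tiles, _ = render_fm(scene, params, "green", noise=False)
        px = params.fm_pixel_size_um
        bead = scene.beads[0][0]
        hits = 0
        for t in tiles:
            ox = t.nominal_stage.x - (t.pixels.shape[2] - 1) / 2 * px
            oy = t.nominal_stage.y - (t.pixels.shape[1] - 1) / 2 * px
            cx, cy = (bead.x - ox) / px, (bead.y - oy) / px
            if 8 < cx < t.pixels.shape[2] - 8 and 8 < cy < t.pixels.shape[1] - 8:
                proj = t.pixels.max(axis=0)
                spot = fit_gaussian_2d(proj, Point2D(round(cx), round(cy)), 5)
                assert spot.fit_ok
                assert np.hypot(spot.center.x - cx, spot.center.y - cy) < 0.05
                hits += 1
        assert hits >= 1

    def test_multichannel_bead_classifies_as_bead(self):
        """A bead fluorescing in green, red and far red is called a bead."""
        scene = generate_scene(_small_params(beads_per_square=3, pois_per_square=0), 4)
        params = RenderParams(fm_fov_um=(24.5, 24.5), z_range_um=4.0, z_step_um=2.0)
        sigma_px = params.psf_sigma_um / params.fm_pixel_size_um
        per_channel = {}
        for ch in ("green", "red", "farred"):
            tiles, _ = render_fm(scene, params, ch, noise=False)
            per_channel[ch] = detect_and_fit(
                tiles[0].pixels.max(axis=0), psf_sigma_px=sigma_px, channel=ch
            )
        out = classify_spots(per_channel, signal_channel="green")
        assert any(cls.label == "bead" for _, cls in out)
        assert all(cls.label == "bead" for _, cls in out)

    def test_autofluorescence_raises_film_over_bars_in_green(self):
        scene = generate_scene(_small_params(beads_per_square=0, pois_per_square=0), 5)
        params = RenderParams(fm_fov_um=(24.5, 24.5), z_range_um=0.0, z_step_um=1.0)
        tiles, _ = render_fm(scene, params, "green", noise=False)
        plane = tiles[0].pixels[0]
        px = params.fm_pixel_size_um
        t = tiles[0]
        ox = t.nominal_stage.x - (plane.shape[1] - 1) / 2 * px
        oy = t.nominal_stage.y - (plane.shape[0] - 1) / 2 * px
        film_vals, bar_vals = [], []
        for iy in range(0, plane.shape[0], 7):
            for ix in range(0, plane.shape[1], 7):
                (film_vals if scene.grid.on_film(ox + ix * px, oy + iy * px) else bar_vals).append(
                    plane[iy, ix]
                )
        assert np.mean(film_vals) > np.mean(bar_vals)

    def test_unknown_channel_rejected(self):
        scene = generate_scene(_small_params(), 6)
        with pytest.raises(ValueError, match="unknown to scene"):
            render_fm(scene, RenderParams(), "uv")

    def test_tile_metadata_matches_lattice(self):
        scene = generate_scene(_small_params(), 7)
        params = RenderParams(fm_fov_um=(24.5, 24.5), z_range_um=2.0, z_step_um=1.0)
        tiles, meta = render_fm(scene, params, "green", noise=False)
        assert len(tiles) == len(meta)
        assert set(meta.columns) >= {"tile_id", "stage_x_um", "stage_y_um", "channel"}


class TestRenderEM:
    def test_bead_at_center_localized(self):
        scene = generate_scene(_small_params(), 8)
        params = RenderParams()
        bead = scene.beads[0][0]
        center = Point2D(*scene.truth_fm_to_em.apply(np.array([bead.x, bead.y])))
        img = render_em(scene, params, center, 4.0)
        spots = localize_dark_beads_em(img, bead_diameter_px=10.0)
        n = img.shape[0]
        d = min(
            np.hypot(s.center.x - (n - 1) / 2, s.center.y - (n - 1) / 2)
            for s in spots
        )
        assert d < 0.5

    def test_empty_region_has_no_detections(self):
        scene = generate_scene(
            _small_params(beads_per_square=0, gold_per_square=0, pois_per_square=0), 9
        )
        center = Point2D(*scene.truth_fm_to_em.apply(
            np.array([scene.grid.pitch_um, scene.grid.pitch_um])
        ))
        img = render_em(scene, RenderParams(), center, 4.0)
        assert localize_dark_beads_em(img, bead_diameter_px=10.0) == []

    def test_offset_from_center_matches_truth_in_nm(self):
        scene = generate_scene(_small_params(), 10)
        params = RenderParams()
        bead = scene.beads[1][0]
        em_true = scene.truth_fm_to_em.apply(np.array([bead.x, bead.y]))
        offset_um = np.array([0.45, -0.3])
        center = Point2D(em_true[0] - offset_um[0], em_true[1] - offset_um[1])
        img = render_em(scene, params, center, 4.0)
        spots = localize_dark_beads_em(img, bead_diameter_px=10.0)
        n = img.shape[0]
        px_um = params.em_pixel_size_nm / 1000.0
        best = min(
            spots,
            key=lambda s: np.hypot(s.center.x - (n - 1) / 2, s.center.y - (n - 1) / 2 ),
        )
        measured_um = (
            np.array([best.center.x, best.center.y]) - (n / 2 - 0.5)
        ) * px_um
        assert np.allclose(measured_um * 1000, offset_um * 1000, atol=10.0)  # nm


class TestCrossModality:
    def test_truth_transform_links_fm_and_em_measurements(self):
        """Mapping an FM-measured bead through the ground-truth transform
        lands within combined localization error of its EM-measured centre."""
        scene = generate_scene(_small_params(beads_per_square=4, pois_per_square=0), 12)
        params = RenderParams(fm_fov_um=(24.5, 24.5), z_range_um=4.0, z_step_um=2.0)
        px = params.fm_pixel_size_um
        tiles, _ = render_fm(scene, params, "green", noise=True)
        sigma_px = params.psf_sigma_um / px
        checked = 0
        for bead_pos, _, _ in scene.beads[:6]:
            for t in tiles:
                ox = t.nominal_stage.x - (t.pixels.shape[2] - 1) / 2 * px
                oy = t.nominal_stage.y - (t.pixels.shape[1] - 1) / 2 * px
                cx, cy = (bead_pos.x - ox) / px, (bead_pos.y - oy) / px
                if not (10 < cx < t.pixels.shape[2] - 10 and 10 < cy < t.pixels.shape[1] - 10):
                    continue
                spot = fit_gaussian_2d(t.pixels.max(axis=0), Point2D(round(cx), round(cy)), 5)
                if not spot.fit_ok:
                    continue
                fm_stage = np.array([ox + spot.center.x * px, oy + spot.center.y * px])
                em_pred = scene.truth_fm_to_em.apply(fm_stage)

                em_center = Point2D(*scene.truth_fm_to_em.apply(np.array([bead_pos.x, bead_pos.y])))
                img = render_em(scene, params, em_center, 3.0)
                spots = localize_dark_beads_em(img, bead_diameter_px=10.0)
                if not spots:
                    continue
                n = img.shape[0]
                best = min(
                    spots,
                    key=lambda s: np.hypot(s.center.x - (n - 1) / 2, s.center.y - (n - 1) / 2),
                )
                origin = np.array([em_center.x - 1.5, em_center.y - 1.5])
                em_meas = origin + (np.array([best.center.x, best.center.y]) + 0.5) * (
                    params.em_pixel_size_nm / 1000.0
                )
                # FM localization dominates: allow ~0.5 FM pixel combined
                assert np.linalg.norm(em_pred - em_meas) < 0.5 * px
                checked += 1
                break
        assert checked >= 3

    def test_photometry_follows_volume_law(self):
        """Measured amplitudes of 100 vs 50 nm beads differ ~8-fold."""
        grid = SMALL_GRID
        base = dict(grid=grid, gold_per_square=0, pois_per_square=0, n_broken_squares=0)
        params = RenderParams(fm_fov_um=(24.5, 24.5), z_range_um=0.0, z_step_um=1.0)
        px = params.fm_pixel_size_um
        amps = {}
        for diam in (100.0, 50.0):
            scene = generate_scene(
                SceneParams(beads_per_square=4, bead_diameter_nm=diam, **base), 13
            )
            tiles, _ = render_fm(scene, params, "green", noise=False)
            vals = []
            for bead_pos, _, _ in scene.beads:
                for t in tiles:
                    ox = t.nominal_stage.x - (t.pixels.shape[2] - 1) / 2 * px
                    oy = t.nominal_stage.y - (t.pixels.shape[1] - 1) / 2 * px
                    cx, cy = (bead_pos.x - ox) / px, (bead_pos.y - oy) / px
                    if 8 < cx < t.pixels.shape[2] - 8 and 8 < cy < t.pixels.shape[1] - 8:
                        s = fit_gaussian_2d(t.pixels[0], Point2D(round(cx), round(cy)), 5)
                        if s.fit_ok:
                            vals.append(s.amplitude)
                        break
            amps[diam] = np.mean(vals)
        assert amps[100.0] / amps[50.0] == pytest.approx(8.0, rel=0.05)


def test_manifest_roundtrip(tmp_path):
    scene = generate_scene(_small_params(), 14)
    path = tmp_path / "scene.json"
    scene.to_manifest(path)
    back = Scene.from_manifest(path)
    assert back.beads == scene.beads
    assert back.gold == scene.gold
    assert back.pois == scene.pois
    assert back.broken_squares == scene.broken_squares
    assert np.array_equal(back.truth_fm_to_em.matrix, scene.truth_fm_to_em.matrix)
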