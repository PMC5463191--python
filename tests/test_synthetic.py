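"""Synthetic scan generator: clean scenes, noise structure, averaging,
study simulation and dataset persistence."""

import numpy as np
import pytest

from octqc import (
    BScan,
    ConfigurationError,
    FormatError,
    FrameStack,
    NoiseConfig,
    SceneConfig,
    StudyDesign,
    average_frames,
    generate_clean_scan,
    generate_frames,
    image_quality,
    load_dataset,
    rasterize,
    read_scan_tiff,
    simulate_study,
    write_dataset,
    write_scan_tiff,
)
from octqc.image import round_half_up

from conftest import flat_scene


class TestCleanScan:
    def test_piecewise_constant_rows_between_flat_boundaries(self, small_flat):
        scene, clean, bs, _ = small_flat
        rows = (10, 20, 30, 40, 50, 60)
        for k in range(5):
            band = clean.image[rows[k]:rows[k + 1]]
            assert np.all(band == scene.layer_means[k])
        assert np.all(clean.image[:10] == scene.vitreous_mean)
        assert np.all(clean.image[60:80] == scene.sub_elm_mean)

    def test_pixel_values_restricted_to_region_means(self):
        clean, _ = generate_clean_scan(SceneConfig(width=64, depth=96))
        assert set(np.unique(clean.image)) <= set(
            SceneConfig(width=64, depth=96).region_means
        )

    def test_deterministic(self):
        cfg = SceneConfig(width=48, depth=64, seed=5)
        a, ba = generate_clean_scan(cfg)
        b, bb = generate_clean_scan(cfg)
        assert np.array_equal(a.image, b.image)
        assert ba == bb

    def test_out_of_range_geometry_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_clean_scan(flat_scene(depth=50))  # b6=60 beyond depth

    def test_crossing_geometry_rejected(self):
        with pytest.raises(ConfigurationError, match="cross"):
            generate_clean_scan(flat_scene(rows=(10, 30, 20, 40, 50, 60)))

    def test_invalid_means_rejected(self):
        with pytest.raises(ConfigurationError):
            SceneConfig(layer_means=(0.1, 0.2, 0.3, 0.4, 1.4))


class TestFrames:
    def test_zero_noise_limit_reproduces_clean(self, small_flat):
        _, clean, _, _ = small_flat
        noise = NoiseConfig(sigma_u=1e-12, sigma_c=0.0)
        stack = generate_frames(clean, 4, noise, seed=0)
        assert np.allclose(stack.frames, clean.image[None], atol=1e-9)
        assert np.allclose(average_frames(stack).image, clean.image, atol=1e-9)

    def test_per_pixel_noise_scale_matches_configuration(self):
        clean = BScan(np.full((24, 20), 0.5))
        stack = generate_frames(
            clean, 800, NoiseConfig(sigma_u=0.05, sigma_c=0.0), seed=3
        )
        stds = stack.frames.std(axis=0, ddof=1)
        assert abs(stds.mean() - 0.05) < 0.002  # Monte-Carlo tolerance
        assert np.all(np.abs(stds - 0.05) < 0.015)

    def test_same_seed_identical_stack(self, small_flat):
        _, clean, _, _ = small_flat
        noise = NoiseConfig(sigma_u=0.05, sigma_c=0.02, speckle_shape=8.0)
        a = generate_frames(clean, 3, noise, seed=11)
        b = generate_frames(clean, 3, noise, seed=11)
        c = generate_frames(clean, 3, noise, seed=12)
        assert np.array_equal(a.frames, b.frames)
        assert not np.array_equal(a.frames, c.frames)

    def test_opacity_attenuates_and_inflates_noise(self):
        clean = BScan(np.full((30, 30), 0.6))
        noise = NoiseConfig(
            sigma_u=0.02, sigma_c=0.0, opacity=0.5, noise_inflation=3.0
        )
        stack = generate_frames(clean, 400, noise, seed=7)
        assert abs(stack.frames.mean() - 0.3) < 0.005
        assert abs(stack.frames.std(axis=0, ddof=1).mean() - 0.06) < 0.005

    def test_invalid_frame_count_rejected(self, small_flat):
        _, clean, _, _ = small_flat
        with pytest.raises(ConfigurationError):
            generate_frames(clean, 0, NoiseConfig(), seed=0)


class TestAveraging:
    def test_idempotent_on_identical_frames(self):
        frame = np.random.default_rng(0).random((8, 9))
        stack = FrameStack.from_frames([frame, frame])
        assert np.array_equal(average_frames(stack).image, frame)

    def test_two_frame_arithmetic(self):
        stack = FrameStack.from_frames(
            [np.full((4, 4), 0.2), np.full((4, 4), 0.4)]
        )
        avg = average_frames(stack)
        assert np.allclose(avg.image, 0.3)
        assert avg.n_averaged == 2

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            FrameStack.from_frames([np.zeros((4, 4)), np.zeros((5, 4))])

    def test_empty_stack_rejected(self):
        with pytest.raises(ConfigurationError):
            FrameStack.from_frames([])


def _mean_image_snr(clean, mask, noise, m, reps, tag):
    vals = [
        image_quality(
            average_frames(
                generate_frames(
                    clean, m, noise, np.random.SeedSequence([tag, r, m])
                )
            ),
            mask,
        ).image_snr
        for r in range(reps)
    ]
    return float(np.mean(vals))


class TestNoiseStructure:
    """Statistical invariants of the correlated floor and jitter."""

    def test_correlated_floor_caps_snr_growth(self):
        scene = flat_scene(
            width=96, depth=80,
            layer_means=(0.7, 0.45, 0.3, 0.55, 0.35),
            vitreous_mean=0.25, sub_elm_mean=0.6,
        )
        clean, bs = generate_clean_scan(scene)
        mask = rasterize(bs, depth=scene.depth, band=scene.band)
        noise = NoiseConfig(sigma_u=0.06, sigma_c=0.03)
        snrs = [
            _mean_image_snr(clean, mask, noise, m, reps=15, tag=21)
            for m in (2, 8, 32, 128)
        ]
        diffs = np.diff(snrs)
        assert np.all(diffs > -0.05 * np.array(snrs[:-1]))  # non-decreasing
        # plateau: far less growth late than early, and bounded by mu/sigma_c
        assert snrs[3] / snrs[2] < 1.10 < snrs[1] / snrs[0]
        mu_bar = np.mean(scene.layer_means)
        assert snrs[3] < 1.15 * mu_bar / noise.sigma_c

    def test_jitter_smooths_edges_with_more_averaging(self):
        scene = flat_scene(width=48, depth=80)
        clean, _ = generate_clean_scan(scene)
        noise = NoiseConfig(sigma_u=0.01, sigma_c=0.0, jitter_px=0.8)
        grads = []
        for m in (1, 4, 16):
            g = [
                np.abs(
                    np.diff(
                        average_frames(
                            generate_frames(
                                clean, m, noise,
                                np.random.SeedSequence([31, r, m]),
                            )
                        ).image,
                        axis=0,
                    )
                ).mean()
                for r in range(6)
            ]
            grads.append(np.mean(g))
        assert grads[0] >= grads[1] >= grads[2]


class TestStudySimulation:
    def _small(self, seed=42):
        design = StudyDesign(n_eyes=2, settings=(2, 4))
        scene = flat_scene(width=40, depth=80)
        return simulate_study(
            design, scene,
            NoiseConfig.opaque_media(), NoiseConfig.clear_media(),
            seed=seed,
        )

    def test_enumeration_of_scans(self):
        ds = self._small()
        assert len(ds.eyes) == 2
        assert all(len(eye.scans) == 4 for eye in ds.eyes)
        design = StudyDesign()
        assert design.n_eyes * 2 * len(design.settings) == 182

    def test_pre_and_post_share_one_boundary_set(self, tmp_path):
        ds = self._small()
        write_dataset(ds, tmp_path / "d")
        import json

        manifest = json.loads((tmp_path / "d" / "manifest.json").read_text())
        for eye in ds.eyes:
            refs = {
                rec["boundaries"]
                for rec in manifest["scans"]
                if rec["eye"] == eye.eye_id
            }
            assert refs == {f"{eye.eye_id}/boundaries.csv"}

    def test_acquisition_order_is_recorded_permutation(self):
        for eye in self._small().eyes:
            for cond in ("pre", "post"):
                assert sorted(eye.acquisition_order[cond]) == [2, 4]

    def test_same_seed_reproduces_dataset(self):
        a, b = self._small(7), self._small(7)
        for ea, eb in zip(a.eyes, b.eyes):
            assert ea.boundaries == eb.boundaries
            for key in ea.scans:
                assert np.array_equal(ea.scans[key].image, eb.scans[key].image)

    def test_eyes_differ_from_each_other(self):
        ds = self._small()
        assert not np.array_equal(
            ds.eyes[0].scans[("post", 4)].image,
            ds.eyes[1].scans[("post", 4)].image,
        )

    def test_opacity_preconditions_enforced(self):
        design = StudyDesign(n_eyes=1, settings=(2,))
        scene = flat_scene()
        clear, opaque = NoiseConfig.clear_media(), NoiseConfig.opaque_media()
        with pytest.raises(ConfigurationError):
            simulate_study(design, scene, clear, clear, seed=0)
        with pytest.raises(ConfigurationError):
            simulate_study(design, scene, opaque, opaque, seed=0)


class TestPersistence:
    def test_tiff_round_trip_quantizes_half_up(self, tmp_path):
        img = np.array([[0.0, 0.5, 1.0], [0.25, 0.75, 127.4 / 255]])
        path = tmp_path / "s.tif"
        write_scan_tiff(BScan(img), path)
        back = read_scan_tiff(path)
        assert np.all(np.abs(back.image - img) <= 0.5 / 255 + 1e-12)
        assert back.image[0, 1] == 128 / 255  # 127.5 rounds up

    def test_round_half_up(self):
        assert list(round_half_up(np.array([0.5, 1.5, 2.49, -0.5]))) == [1, 2, 2, 0]

    def test_dataset_write_load_round_trip(self, tmp_path):
        design = StudyDesign(n_eyes=2, settings=(2, 4))
        ds = simulate_study(
            design, flat_scene(width=40, depth=80),
            NoiseConfig.opaque_media(), NoiseConfig.clear_media(), seed=5,
        )
        write_dataset(ds, tmp_path / "d")
        loaded = load_dataset(tmp_path / "d")
        assert loaded.design.settings == (2, 4)
        assert [e.eye_id for e in loaded.eyes] == ["eye01", "eye02"]
        for eye, l_eye in zip(ds.eyes, loaded.eyes):
            assert eye.boundaries == l_eye.boundaries
            for key, scan in eye.scans.items():
                err = np.abs(l_eye.scans[key].image - np.clip(scan.image, 0, 1))
                assert err.max() <= 0.5 / 255 + 1e-12

    def test_overwrite_guard(self, tmp_path):
        design = StudyDesign(n_eyes=1, settings=(2,))
        ds = simulate_study(
            design, flat_scene(width=16, depth=80),
            NoiseConfig.opaque_media(), NoiseConfig.clear_media(), seed=5,
        )
        write_dataset(ds, tmp_path / "d")
        with pytest.raises(ConfigurationError, match="overwrite"):
            write_dataset(ds, tmp_path / "d")
        write_dataset(ds, tmp_path / "d", overwrite=True)

    def test_missing_manifest_is_format_error(self, tmp_path):
        with pytest.raises(FormatError, match="manifest"):
            load_dataset(tmp_path)
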