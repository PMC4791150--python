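"""Grey-standard normalization: single, multi-standard, dark point, sequential."""

import numpy as np
import pytest

from multispec.images import MspecProject, MultispectralStack, polygon_mask
from multispec.normalization import (
    NormalizationModel,
    StandardMeasurement,
    apply_normalization,
    estimate_dark_point,
    fit_normalization,
    sequential_normalize,
)
from multispec.synth import (
    default_camera,
    flat_reflectance,
    patch_grid,
    render_scene,
    write_scene_project,
)


def std(percent, **means):
    return StandardMeasurement(percent, means)


class TestSingleStandard:
    def test_reproduces_through_origin_relation(self):
        # one standard S=99, G=60000: pixel 60000 maps to the 99% level,
        # i.e. 0.99 * 65535 = 64879.65 on the 16-bit export scale
        model = fit_normalization([std(99, vR=60000.0)])
        refl = model.predict(60000.0, "vR")
        assert refl == pytest.approx(0.99, abs=1e-12)
        assert model.to_16bit_scale(refl) == pytest.approx(64879.65, abs=1e-6)
        assert model.method == "single"
        assert model.intercepts[0] == 0.0

    def test_proportionality(self):
        g0 = 48000.0
        model = fit_normalization([std(20, vR=g0)])
        assert model.predict(g0 / 2, "vR") == pytest.approx(0.10, abs=1e-12)

    def test_multi_fit_with_forced_zero_intercept_degenerates_to_single(self):
        m1 = fit_normalization([std(40, vR=30000.0)])
        m2 = fit_normalization([std(40, vR=30000.0)], method="single")
        np.testing.assert_allclose(m1.slopes, m2.slopes)


class TestMultiStandard:
    def test_two_point_line_closed_form(self):
        # closed-form two-point regression oracle:
        # slope = (0.8-0.2)/(50000-14000); refl(32000) = 0.2 + 18000*slope = 0.5
        model = fit_normalization([std(80, vR=50000.0), std(20, vR=14000.0)])
        assert model.predict(32000.0, "vR") == pytest.approx(0.5, abs=1e-9)
        assert model.method == "multi"

    def test_exact_standards_lie_on_fitted_line(self):
        # noise-free standards: the line must pass through every point
        slope, intercept = 1.3e-5, -0.02
        standards = [
            std(p, vG=(p / 100 - intercept) / slope) for p in (5, 20, 40, 80, 99)
        ]
        model = fit_normalization(standards)
        for s in standards:
            assert model.predict(s.mean_pixel["vG"], "vG") == pytest.approx(
                s.reflectance_percent / 100, abs=1e-9
            )
        np.testing.assert_allclose(model.r_squared, 1.0)

    def test_low_fit_warning_below_0_98(self):
        # strongly curved response: linearisation fit under 0.98 warns
        standards = [std(5, vR=100.0), std(50, vR=110.0), std(99, vR=60000.0)]
        with pytest.warns(UserWarning, match="linearisation fit"):
            model = fit_normalization(standards)
        assert model.r_squared is not None and model.r_squared[0] < 0.98

    def test_identical_pixel_values_rejected(self):
        with pytest.raises(ValueError, match="same mean pixel"):
            fit_normalization([std(20, vR=5000.0), std(80, vR=5000.0)])

    def test_nonmonotone_standards_warn(self):
        with pytest.warns(UserWarning, match="do not increase"):
            fit_normalization([std(20, vR=30000.0), std(80, vR=10000.0), std(99, vR=60000.0)])


class TestApply:
    def _stack(self, data):
        return MultispectralStack(["vR"], np.asarray(data, np.float32)[None])

    def test_affine_map_and_no_clipping(self):
        model = NormalizationModel(["vR"], [2e-5], [-0.1], method="multi")
        stack = self._stack([[1000.0, 70000.0], [4000.0, 6000.0]])
        out = apply_normalization(stack, model)
        np.testing.assert_allclose(
            out.channel("vR"), np.array([[1000, 70000], [4000, 6000]]) * 2e-5 - 0.1, rtol=1e-6
        )
        assert out.channel("vR")[0, 0] < 0  # negatives preserved
        assert out.channel("vR")[0, 1] > 1  # >100% preserved
        assert out.normalized

    def test_rank_order_preserved(self, rng):
        model = NormalizationModel(["vR"], [3e-5], [0.01], method="multi")
        vals = rng.uniform(0, 65535, (6, 6)).astype(np.float32)
        out = apply_normalization(self._stack(vals), model)
        a, b = vals.ravel(), out.channel("vR").ravel()
        assert np.array_equal(np.argsort(a), np.argsort(b))

    def test_channel_mismatch_rejected(self):
        model = NormalizationModel(["vG"], [1e-5], [0.0], method="multi")
        with pytest.raises(ValueError, match="match"):
            apply_normalization(self._stack([[1.0]]), model)


class TestDarkPoint:
    def _glare_channel(self, glare_dn, rng, n=5000, k=600.0):
        # linear response pixel = glare + k * reflectance%, darkest content at 0.5%
        refl = rng.uniform(0.5, 99.0, n)
        refl[: n // 100] = 0.5  # the scene's darkest surfaces
        return glare_dn + k * refl, k

    def test_recovers_veiling_glare_intercept(self, rng):
        glare = 2000.0
        pixels, k = self._glare_channel(glare, rng)
        g_std = glare + k * 40.0
        model = estimate_dark_point({"vR": pixels}, std(40, vR=g_std))
        # ground truth: intercept = -glare * slope
        assert model.intercepts[0] == pytest.approx(-glare * model.slopes[0], rel=0.02)
        assert model.method == "histogram-dark-point"

    def test_glare_free_intercept_near_zero(self, rng):
        pixels, k = self._glare_channel(0.0, rng)
        model = estimate_dark_point({"vR": pixels}, std(40, vR=k * 40.0))
        assert abs(model.intercepts[0]) < 1e-3

    def test_constant_channel_rejected(self):
        with pytest.raises(ValueError, match="dark anchor"):
            estimate_dark_point({"vR": np.full(500, 1000.0)}, std(40, vR=1000.0))

    def test_too_few_pixels_rejected(self, rng):
        with pytest.raises(ValueError, match="200"):
            estimate_dark_point({"vR": rng.uniform(0, 100, 50)}, std(40, vR=90.0))


class TestExposureCommutation:
    def test_normalization_controls_for_exposure(self, tmp_path):
        # the same scene at exposure ratio 2, each normalized in-image,
        # must agree pixelwise within noise
        refl = [flat_reflectance(50, "half"), flat_reflectance(20), flat_reflectance(80)]
        scene = patch_grid(refl, standard_percents=[None, 20, 80])
        camera = default_camera(noise_a=5.0, noise_b=0.005)
        stacks = []
        for i, exposure in enumerate((0.4, 0.8)):
            from multispec.images import build_stack

            images, _ = render_scene(scene, camera, exposure=exposure, seed=20 + i)
            d = tmp_path / f"e{i}"
            project = write_scene_project(scene, images, d, name=f"e{i}")
            stacks.append(build_stack(project, base_dir=d))
        a, b = stacks
        mask = polygon_mask(scene.patches[0].vertices(), a.shape)
        for ch in a.channel_names:
            np.testing.assert_allclose(
                a.channel(ch)[mask].mean(), b.channel(ch)[mask].mean(), rtol=0.02
            )


class TestSequential:
    def _render_project(self, scene, camera, d, name, exposure=1.0, seed=0):
        images, _ = render_scene(scene, camera, exposure=exposure, seed=seed)
        return write_scene_project(scene, images, d, name=name)

    def test_same_photo_matches_in_image_normalization(self, tmp_path):
        from multispec.images import build_stack
        from multispec.normalization import fit_project_standards

        refl = [flat_reflectance(50, "half"), flat_reflectance(20), flat_reflectance(80)]
        scene = patch_grid(refl, standard_percents=[None, 20, 80])
        camera = default_camera()
        project = self._render_project(scene, camera, tmp_path, "same", seed=2)
        model, _ = sequential_normalize(project, project, tmp_path, tmp_path)
        raw = build_stack(
            MspecProject.from_dict({**project.to_dict(), "standards": []}), tmp_path
        )
        direct = fit_project_standards(raw, project)
        np.testing.assert_allclose(model.slopes, direct.slopes)
        np.testing.assert_allclose(model.intercepts, direct.intercepts)
        assert model.method == "sequential"

    def test_recovers_reflectance_from_separate_standard_photo(self, tmp_path):
        camera = default_camera(noise_a=2.0, noise_b=0.002)
        target_scene = patch_grid([flat_reflectance(50, "half"), flat_reflectance(10, "dark")])
        std_scene = patch_grid(
            [flat_reflectance(20), flat_reflectance(80)], standard_percents=[20, 80]
        )
        target = self._render_project(target_scene, camera, tmp_path / "t", "target", seed=3)
        standard = self._render_project(std_scene, camera, tmp_path / "s", "standard", seed=4)
        _, stack = sequential_normalize(target, standard, tmp_path / "t", tmp_path / "s")
        mask = polygon_mask(target_scene.patches[0].vertices(), stack.shape)
        for ch in stack.channel_names:
            assert stack.channel(ch)[mask].mean() == pytest.approx(0.5, rel=0.02)

    def test_brighter_standard_photo_biases_by_inverse_factor(self, tmp_path):
        # documented failure mode: standard frame twice as bright -> 0.5x bias
        camera = default_camera(noise_a=2.0, noise_b=0.002)
        target_scene = patch_grid([flat_reflectance(50, "half"), flat_reflectance(10, "dark")])
        std_scene = patch_grid(
            [flat_reflectance(20), flat_reflectance(40)], standard_percents=[20, 40]
        )
        target = self._render_project(target_scene, camera, tmp_path / "t", "target", seed=5)
        standard = self._render_project(
            std_scene, camera, tmp_path / "s", "standard", exposure=2.0, seed=6
        )
        _, stack = sequential_normalize(target, standard, tmp_path / "t", tmp_path / "s")
        mask = polygon_mask(target_scene.patches[0].vertices(), stack.shape)
        for ch in stack.channel_names:
            assert stack.channel(ch)[mask].mean() == pytest.approx(0.25, rel=0.05)

    def test_differing_channel_sets_rejected(self, tmp_path):
        camera = default_camera()
        scene = patch_grid([flat_reflectance(20)], standard_percents=[20])
        p1 = self._render_project(scene, camera, tmp_path / "a", "a", seed=7)
        p2 = MspecProject.from_dict(p1.to_dict())
        p2.sources = {"vR": p1.sources["vR"]}
        with pytest.raises(ValueError, match="channel sets differ"):
            sequential_normalize(p2, p1, tmp_path / "a", tmp_path / "a")
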