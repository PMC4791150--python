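"""Polynomial camera-to-receptor mapping: terms, training table, fit, apply."""

import numpy as np
import pandas as pd
import pytest

from multispec.conemap import (
    ConeMapModel,
    PolynomialTermSet,
    apply_cone_map,
    build_training_table,
    expand_terms,
    fit_cone_map,
)
from multispec.images import MultispectralStack
from multispec.spectral import ReflectanceLibrary, SensitivityBank, SpectralCurve

from conftest import flat_curve


class TestTermSet:
    def test_three_channel_level2_matches_six_term_form(self):
        ts = PolynomialTermSet(("R", "G", "B"), 2)
        assert ts.terms == (
            ("R",), ("G",), ("B",),
            ("G", "R"), ("B", "R"), ("B", "G"),
        )

    def test_level3_with_squares_matches_ten_term_form(self):
        ts = PolynomialTermSet(("R", "G", "B"), 3, include_squares=True)
        assert len(ts.terms) == 10
        assert ("B", "G", "R") in ts.terms
        assert ("R", "R") in ts.terms and ("B", "B") in ts.terms

    def test_expand_hand_products(self):
        vals = {"R": 2.0, "G": 3.0, "B": 4.0}
        out = expand_terms(vals, PolynomialTermSet(("R", "G", "B"), 2))
        np.testing.assert_allclose(out, [2, 3, 4, 6, 8, 12])

    def test_zero_channel_annihilates_its_terms(self):
        vals = {"R": 0.0, "G": 3.0, "B": 4.0}
        out = expand_terms(vals, PolynomialTermSet(("R", "G", "B"), 3, True))
        terms = PolynomialTermSet(("R", "G", "B"), 3, True).terms
        for t, v in zip(terms, out):
            assert (v == 0) == ("R" in t)

    def test_level1_is_identity(self):
        vals = {"R": 1.5, "G": 2.5}
        np.testing.assert_allclose(
            expand_terms(vals, PolynomialTermSet(("R", "G"), 1)), [1.5, 2.5]
        )

    def test_missing_channel_rejected(self):
        with pytest.raises(KeyError, match="'B'"):
            expand_terms({"R": 1.0}, [("R", "B")])


class TestTrainingTable:
    def test_flat_grey_gives_half_everywhere(self, camera, receptors, illuminant):
        lib = ReflectanceLibrary((flat_curve(0.5, name="g50"),))
        table = build_training_table(camera.bank, receptors, illuminant, lib)
        np.testing.assert_allclose(table.iloc[0].to_numpy(), 0.5, rtol=1e-12)

    def test_shape_is_rows_by_channels(self, camera, receptors, illuminant, small_library):
        table = build_training_table(camera.bank, receptors, illuminant, small_library)
        assert table.shape == (len(small_library), len(camera.bank) + len(receptors))
        assert table.attrs["camera_channels"] == list(camera.bank.channel_names)

    def test_three_wavelength_toy_hand_computed(self):
        grid = lambda v, n: SpectralCurve(500, np.asarray(v), n)
        cam = SensitivityBank((grid([1, 0, 0], "c1"), grid([0, 1, 1], "c2")), ("c1", "c2"))
        rec = SensitivityBank((grid([1, 1, 0], "r1"),), ("r1",))
        illum = grid([1.0, 2.0, 1.0], "I")
        lib = ReflectanceLibrary((grid([0.5, 0.25, 1.0], "q"),))
        table = build_training_table(cam, rec, illum, lib)
        # hand sums: c1: 0.5/1; c2: (2*0.25+1*1.0)/(2+1)=0.5; r1: (0.5+0.5)/3
        np.testing.assert_allclose(
            table.iloc[0].to_numpy(), [0.5, 0.5, 1.0 / 3.0], rtol=1e-12
        )

    def test_fewer_camera_channels_than_receptors_rejected(self, receptors, illuminant):
        c = SpectralCurve(300, np.ones(401), "only")
        cam = SensitivityBank((c,), ("only",))
        lib = ReflectanceLibrary((flat_curve(0.5),))
        with pytest.raises(ValueError, match="equal to or greater"):
            build_training_table(cam, receptors, illuminant, lib)

    def test_disjoint_spectral_range_rejected(self, camera, illuminant):
        ir = SensitivityBank((SpectralCurve(800, np.ones(101), "ir"),), ("ir",))
        lib = ReflectanceLibrary((flat_curve(0.5),))
        with pytest.raises(ValueError, match="overlap"):
            build_training_table(camera.bank, ir, illuminant, lib)


def _toy_table(rng, n=200, noise=0.0):
    r = rng.uniform(0.05, 1, n)
    g = rng.uniform(0.05, 1, n)
    df = pd.DataFrame({"R": r, "G": g})
    df["y"] = 0.7 * r + 0.3 * g + noise * rng.normal(size=n)
    df.attrs["camera_channels"] = ["R", "G"]
    df.attrs["receptor_channels"] = ["y"]
    return df


class TestFit:
    def test_identity_receptor_recovers_unit_coefficient(self, rng):
        df = _toy_table(rng)
        df["y"] = df["R"]
        model = fit_cone_map(df, terms=PolynomialTermSet(("R", "G"), 1))
        coefs = dict(zip(model.terms["y"], model.coefficients["y"]))
        assert coefs[("R",)] == pytest.approx(1.0, abs=1e-9)
        assert model.r_squared["y"] == pytest.approx(1.0, abs=1e-9)

    def test_exact_system_matches_closed_form_solve(self):
        # 2 channels, 3 spectra, level-1: the normal equations solved by hand
        X = np.array([[0.2, 0.8], [0.5, 0.1], [0.9, 0.4]])
        beta_true = np.array([0.6, 0.25])
        y = X @ beta_true
        df = pd.DataFrame({"R": X[:, 0], "G": X[:, 1], "y": y})
        model = fit_cone_map(
            df, ["R", "G"], ["y"], terms=PolynomialTermSet(("R", "G"), 1)
        )
        expected = np.linalg.solve(X.T @ X, X.T @ y)  # independent linear-algebra oracle
        np.testing.assert_allclose(model.coefficients["y"], expected, atol=1e-12)
        np.testing.assert_allclose(model.coefficients["y"], beta_true, atol=1e-12)

    def test_matches_statsmodels_no_intercept_ols(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        df = _toy_table(rng, noise=0.01)
        terms = PolynomialTermSet(("R", "G"), 2)
        model = fit_cone_map(df, terms=terms)
        X = np.column_stack([df["R"], df["G"], df["R"] * df["G"]])
        fit = sm.OLS(df["y"].to_numpy(), X).fit()  # no constant: through the origin
        np.testing.assert_allclose(model.coefficients["y"], fit.params, rtol=1e-8)
        assert model.r_squared["y"] == pytest.approx(fit.rsquared, abs=1e-10)

    def test_bic_removes_pure_noise_channel_terms(self, rng):
        df = _toy_table(rng, n=400, noise=0.002)
        df["N"] = rng.uniform(0.05, 1, len(df))  # carries no signal
        df.attrs["camera_channels"] = ["R", "G", "N"]
        model = fit_cone_map(
            df, terms=PolynomialTermSet(("R", "G", "N"), 2), simplification="BIC"
        )
        assert all("N" not in t for t in model.terms["y"])

    def test_r2_non_decreasing_with_interaction_level(self, camera, receptors, illuminant, small_library):
        table = build_training_table(camera.bank, receptors, illuminant, small_library)
        chans = tuple(camera.bank.channel_names)
        r2 = [
            min(
                fit_cone_map(table, terms=PolynomialTermSet(chans, lvl)).r_squared.values()
            )
            for lvl in (1, 2, 3)
        ]
        assert r2[0] <= r2[1] + 1e-12 and r2[1] <= r2[2] + 1e-12

    def test_bic_is_more_conservative_than_aic(self, rng):
        # over many noisy fits, BIC keeps at most as many terms on average
        counts = {"AIC": [], "BIC": []}
        for i in range(20):
            local = np.random.default_rng(1000 + i)
            df = _toy_table(local, n=120, noise=0.02)
            for crit in ("AIC", "BIC"):
                m = fit_cone_map(
                    df, terms=PolynomialTermSet(("R", "G"), 2, True), simplification=crit
                )
                counts[crit].append(len(m.terms["y"]))
        assert np.mean(counts["BIC"]) <= np.mean(counts["AIC"])

    def test_aliased_terms_dropped_with_warning(self, rng):
        df = _toy_table(rng)
        df["R2"] = df["R"]  # exact duplicate channel
        df.attrs["camera_channels"] = ["R", "G", "R2"]
        with pytest.warns(UserWarning, match="aliased"):
            model = fit_cone_map(df, terms=PolynomialTermSet(("R", "G", "R2"), 1))
        assert len(model.terms["y"]) == 2

    def test_too_few_rows_rejected(self, rng):
        df = _toy_table(rng, n=3)
        with pytest.raises(ValueError, match="identify"):
            fit_cone_map(df, terms=PolynomialTermSet(("R", "G"), 2, True))
        with pytest.warns(UserWarning, match="poorly constrained"):
            fit_cone_map(_toy_table(rng, n=7), terms=PolynomialTermSet(("R", "G"), 2, True))

    def test_model_json_round_trip(self, rng, tmp_path):
        model = fit_cone_map(_toy_table(rng), terms=PolynomialTermSet(("R", "G"), 2))
        path = tmp_path / "model.json"
        model.save(path)
        back = ConeMapModel.load(path)
        assert back.terms == model.terms
        np.testing.assert_allclose(back.coefficients["y"], model.coefficients["y"])


class TestApply:
    def _grey_stack(self, level=0.5, channels=("vR", "vG")):
        data = np.full((len(channels), 8, 8), level, np.float32)
        return MultispectralStack(list(channels), data, normalized=True)

    def test_identity_model_reproduces_channels(self):
        stack = self._grey_stack()
        model = ConeMapModel(
            ["vR", "vG"],
            ["vR", "vG"],
            {"vR": (("vR",),), "vG": (("vG",),)},
            {"vR": np.array([1.0]), "vG": np.array([1.0])},
            {"vR": 1.0, "vG": 1.0},
        )
        out = apply_cone_map(stack, model)
        np.testing.assert_allclose(out.data, stack.data)

    def test_grey_scene_maps_to_grey(self, camera, receptors, illuminant, small_library):
        table = build_training_table(camera.bank, receptors, illuminant, small_library)
        model = fit_cone_map(
            table, terms=PolynomialTermSet(tuple(camera.bank.channel_names), 2)
        )
        stack = self._grey_stack(0.5, camera.bank.channel_names)
        out = apply_cone_map(stack, model)
        np.testing.assert_allclose(out.data, 0.5, atol=0.01)

    def test_unnormalized_stack_rejected(self):
        stack = self._grey_stack()
        stack.normalized = False
        model = ConeMapModel(["vR"], ["x"], {"x": (("vR",),)}, {"x": np.array([1.0])}, {"x": 1.0})
        with pytest.raises(ValueError, match="normalized"):
            apply_cone_map(stack, model)
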