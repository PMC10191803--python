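"""RSS reporting, prediction surfaces, train/test split, validation metrics,
effect curves, ecoregion class proportions."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import spdesdm as s


class TestRSS:
    def test_zero_beta_gives_unit_rss(self):
        row = s.rss(0.0, -0.1, 0.2)
        assert row["rss"] == 1.0

    def test_monotone_and_ordered(self):
        row = s.rss(0.39, 0.25, 0.53)
        assert row["rss_lower"] < row["rss"] < row["rss_upper"]

    def test_misordered_interval_rejected(self):
        with pytest.raises(ValueError):
            s.rss(0.0, 0.5, 1.0)

    def test_rss_table_from_fit(self, logistic_data):
        dm, z = logistic_data
        f = s.fit(s.ModelSpec(("a", "b"), include_rf=False), dm, z)
        table = s.rss_table(f)
        assert list(table.index) == ["a", "b"]
        np.testing.assert_allclose(
            table["rss"], np.exp(f.beta.loc[["a", "b"], "mean"])
        )
        assert "intercept" not in table.index


@pytest.fixture(scope="module")
def fitted_surfaces(tiny_stack):
    """A small end-to-end fit over the 30 km stack, both surface variants."""
    truth = s.TrueModel(
        intercept=-0.5, coefficients={"northern_hardwoods": 0.9},
        grf_range_km=10.0, grf_sd=0.7,
    )
    occ = s.simulate_occurrences(tiny_stack, truth, 900, 3)
    mesh = s.build_mesh(tiny_stack.grid.polygon(), 3.0, buffer=8.0)
    spde = s.SPDEModel.from_mesh(mesh, 10.0, 1.0)
    bg = s.background_points(mesh, tiny_stack.grid.polygon(), 3.0)
    pts = np.vstack([occ.coords, bg.coords])
    z = np.concatenate([occ.labels, np.zeros(len(bg.coords), dtype=int)])
    raw = tiny_stack.values_at(pts, ["northern_hardwoods", "aspen_birch"])
    dm = s.scale_covariates(raw)
    A = s.projector(mesh, pts)
    f = s.fit(
        s.ModelSpec(("northern_hardwoods",)), dm, z, spde, A,
        hyper_grid=[(10.0, 1.0)], seed=4,
    )
    with_rf = s.predict_surface(f, tiny_stack, spde, "with-RF")
    no_rf = s.predict_surface(f, tiny_stack, None, "no-RF")
    return f, with_rf, no_rf, pts, z, raw


class TestPredictSurface:
    def test_intercept_only_no_rf_is_constant_ones(self, tiny_stack, logistic_data):
        dm, z = logistic_data
        f = s.fit(s.ModelSpec((), include_rf=False), dm, z)
        surf = s.predict_surface(f, tiny_stack, None, "no-RF")
        np.testing.assert_allclose(surf.values, 1.0, atol=1e-12)

    def test_maximum_is_one(self, fitted_surfaces):
        _, with_rf, no_rf, *_ = fitted_surfaces
        assert abs(with_rf.values.max() - 1.0) <= 1e-12
        assert abs(no_rf.values.max() - 1.0) <= 1e-12
        assert with_rf.values.min() >= 0.0

    def test_default_resolution_is_2km(self, fitted_surfaces):
        _, with_rf, *_ = fitted_surfaces
        assert with_rf.grid.resolution == 2.0
        assert with_rf.variant == "with-RF"

    def test_null_field_variants_agree(self, tiny_stack, logistic_data):
        # a fit whose posterior field is ~0 everywhere: with-RF and no-RF
        # surfaces agree closely
        dm, z = logistic_data
        f = s.fit(s.ModelSpec((), include_rf=False), dm, z)
        mesh = s.build_mesh(tiny_stack.grid.polygon(), 4.0, buffer=8.0)
        spde = s.SPDEModel.from_mesh(mesh, 10.0, 1.0)
        f.spec = s.ModelSpec((), include_rf=True)
        f.field_mean = np.zeros(mesh.n_vertices)
        with_rf = s.predict_surface(f, tiny_stack, spde, "with-RF")
        no_rf = s.predict_surface(f, tiny_stack, None, "no-RF")
        assert np.abs(with_rf.values - no_rf.values).max() < 0.05

    def test_training_auc_with_rf_not_worse(self, fitted_surfaces):
        f, with_rf, no_rf, pts, z, _ = fitted_surfaces
        auc_rf = s.auc_score(s.surface_values_at(with_rf, pts), z)
        auc_norf = s.auc_score(s.surface_values_at(no_rf, pts), z)
        assert auc_rf >= auc_norf


class TestSplitData:
    def _occ(self, n):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "x": rng.uniform(0, 10, n),
                "y": rng.uniform(0, 10, n),
                "label": rng.integers(0, 2, n),
                "role": "presence",
                "partition": "train",
            }
        )
        return s.OccurrenceSet(df)

    def test_exact_counts(self):
        out = s.split_data(self._occ(10), 0.8, seed=1)
        assert (out.points["partition"] == "train").sum() == 8
        assert (out.points["partition"] == "test").sum() == 2

    def test_deterministic(self):
        a = s.split_data(self._occ(50), 0.8, seed=7)
        b = s.split_data(self._occ(50), 0.8, seed=7)
        pd.testing.assert_frame_equal(a.points, b.points)

    def test_mean_test_fraction(self):
        # counts are exact per split, so the mean over seeds must sit at the
        # requested fraction; also check assignment varies across seeds
        occ = self._occ(50)
        splits = [s.split_data(occ, 0.8, seed=k).points["partition"] for k in range(1000)]
        fracs = [(p == "test").mean() for p in splits]
        assert abs(np.mean(fracs) - 0.2) <= 0.01
        assert not all(p.equals(splits[0]) for p in splits[1:])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            s.split_data(self._occ(4), 0.8, 0)


class TestValidate:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        rep = s.validate(scores, labels)
        assert rep.auc == 1.0 and rep.tss == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert 0.2 < rep.threshold <= 0.8

    def test_null_scores_auc_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        rep = s.validate(scores, labels)
        assert abs(rep.auc - 0.5) <= 0.03

    def test_hand_example_matches_pairwise_concordance(self):
        # six points with ties; oracle: exhaustive pairwise count, ties = 1/2
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.4, 0.8])
        labels = np.array([0, 0, 1, 1, 1, 0])
        num = 0.0
        npairs = 0
        for i in np.flatnonzero(labels == 1):
            for j in np.flatnonzero(labels == 0):
                npairs += 1
                if scores[i] > scores[j]:
                    num += 1.0
                elif scores[i] == scores[j]:
                    num += 0.5
        assert s.auc_score(scores, labels) == pytest.approx(num / npairs, abs=1e-12)
        rep = s.validate(scores, labels)
        assert rep.auc == pytest.approx(num / npairs, abs=1e-12)

    def test_tss_identity(self):
        rng = np.random.default_rng(3)
        scores = rng.random(500)
        labels = (rng.random(500) < scores).astype(int)
        rep = s.validate(scores, labels)
        assert rep.tss == pytest.approx(rep.sensitivity + rep.specificity - 1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            s.validate(np.array([0.1, 0.9]), np.array([1, 1]))


class TestEffectCurve:
    def test_positive_effect_curve_nondecreasing(self, fitted_surfaces):
        f, _, _, pts, z, raw = fitted_surfaces
        curve = s.effect_curve(f, raw, "northern_hardwoods")
        lo, hi = np.quantile(curve.grid, [0.05, 0.95])
        central = (curve.grid >= lo) & (curve.grid <= hi)
        vals = curve.fit[central]
        assert np.all(np.diff(vals) >= -1e-3)
        assert curve.fit.min() >= 0.0 and curve.fit.max() <= 1.0
        assert np.all(curve.lower <= curve.upper)
        assert np.all(np.diff(curve.grid) > 0)

    def test_basis_dimension_capped(self, fitted_surfaces):
        f, _, _, _, _, raw = fitted_surfaces
        with pytest.raises(ValueError, match="basis"):
            s.effect_curve(f, raw, "northern_hardwoods", basis_dim=6)

    def test_unfitted_covariate_rejected(self, fitted_surfaces):
        f, _, _, _, _, raw = fitted_surfaces
        with pytest.raises(ValueError):
            s.effect_curve(f, raw, "aspen_birch")


class TestEcoregionClasses:
    def _surface(self, values):
        grid = s.GridGeometry(0, 0, 1, values.shape[1], values.shape[0])
        return s.PredictionSurface(grid, values, "no-RF", 1.0)

    def test_constant_half_surface_all_class_three(self):
        surf = self._surface(np.full((10, 10), 0.5))
        regions = s.make_ecoregions(surf.grid, 3, seed=1)
        props = s.ecoregion_classes(surf, regions)
        np.testing.assert_allclose(props["class_3"], 1.0)
        np.testing.assert_allclose(props.drop(columns="class_3").to_numpy(), 0.0)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(5)
        surf = self._surface(rng.random((12, 12)))
        regions = s.make_ecoregions(surf.grid, 4, seed=2)
        props = s.ecoregion_classes(surf, regions)
        np.testing.assert_allclose(props.sum(axis=1), 1.0, atol=1e-12)

    def test_checkerboard_splits_between_extreme_classes(self):
        vals = np.indices((10, 10)).sum(axis=0) % 2
        surf = self._surface(np.where(vals == 0, 0.1, 0.9))
        props = s.ecoregion_classes(surf, [surf.grid.polygon()])
        assert props.loc["region_0", "class_1"] == pytest.approx(0.5)
        assert props.loc["region_0", "class_5"] == pytest.approx(0.5)

    def test_region_without_cells_fails(self):
        surf = self._surface(np.full((4, 4), 0.5))
        from shapely.geometry import box

        with pytest.raises(ValueError, match="1"):
            s.ecoregion_classes(surf, [surf.grid.polygon(), box(100, 100, 101, 101)])
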