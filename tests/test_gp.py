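import numpy as np
import pandas as pd
import pytest
from scipy.linalg import solve

import bhpm
from bhpm.gp import GPFit, cross_validate, fit_spatial_gp, impute_all, predict_missing


def grid_coords(n_side, spacing_deg=0.15, seed=None):
    lon, lat = np.meshgrid(
        -78.0 + spacing_deg * np.arange(n_side), 37.0 + spacing_deg * np.arange(n_side)
    )
    return np.column_stack([lon.ravel(), lat.ravel()])


def manual_fit(coords, values, mean, sill, decay, nugget):
    """A GPFit with fixed hyperparameters (single 'draw')."""
    draws = pd.DataFrame(
        {"mean": [mean], "sill": [sill], "decay": [decay], "nugget": [nugget]}
    )
    return GPFit("field", draws, np.asarray(coords, float), np.asarray(values, float))


class TestKriging:
    def test_nugget_free_interpolation_is_exact(self):
        coords = grid_coords(4)
        params = bhpm.GPHyperparams(mean=3.0, sill=1.0, decay=0.02, nugget=0.0)
        y = bhpm.simulate_gp_field(coords, params, seed=1)
        fit = manual_fit(coords, y, 3.0, 1.0, 0.02, 0.0)
        pred, sd = predict_missing(fit, coords)
        assert np.abs(pred - y).max() < 1e-5
        assert sd.max() < 1e-2

    def test_far_prediction_reverts_to_field_mean(self):
        coords = grid_coords(4)
        y = bhpm.simulate_gp_field(
            coords, bhpm.GPHyperparams(4.0, 1.0, 0.05, 0.1), seed=2
        )
        far = np.array([[-60.0, 10.0]])  # thousands of miles away
        fit = manual_fit(coords, y, 4.0, 1.0, 0.05, 0.1)
        pred, sd = predict_missing(fit, far)
        assert pred[0] == pytest.approx(4.0, abs=1e-6)
        assert sd[0] == pytest.approx(np.sqrt(1.1), rel=1e-3)

    def test_matches_dense_matrix_kriging_oracle(self):
        # direct solve of the conditional mean/variance on 20 sites, per draw
        from bhpm.geo import pairwise_distances

        g = np.random.default_rng(5)
        coords = grid_coords(5)[:20]
        new = coords[:4] + 0.31
        y = g.normal(2.0, 1.0, size=20)
        mean, sill, decay, nugget = 2.0, 0.8, 0.03, 0.2
        fit = manual_fit(coords, y, mean, sill, decay, nugget)
        pred, _ = predict_missing(fit, new)
        D = pairwise_distances(coords)
        K = sill * np.exp(-decay * D) + nugget * np.eye(20)
        Dx = pairwise_distances(new, coords)
        c = sill * np.exp(-decay * Dx)
        expected = mean + c @ solve(K, y - mean, assume_a="pos")
        assert np.abs(pred - expected).max() < 1e-8

    def test_translation_equivariance_of_prediction(self):
        # shifting the field by a constant shifts predictions by the same
        # constant (posterior-predictive weights act like ordinary kriging)
        coords = grid_coords(4)
        y = bhpm.simulate_gp_field(coords, bhpm.GPHyperparams(0.0, 1.0, 0.03, 0.1), seed=3)
        new = coords[:5] + 0.07
        base = manual_fit(coords, y, float(y.mean()), 1.0, 0.03, 0.1)
        shifted = manual_fit(coords, y + 10.0, float(y.mean() + 10.0), 1.0, 0.03, 0.1)
        p0, _ = predict_missing(base, new)
        p1, _ = predict_missing(shifted, new)
        assert np.abs(p1 - p0 - 10.0).max() < 1e-8


class TestFit:
    def test_same_seed_identical_draws(self):
        coords = grid_coords(4)
        y = bhpm.simulate_gp_field(coords, bhpm.GPHyperparams(1.0, 1.0, 0.03, 0.2), seed=4)
        f1 = fit_spatial_gp(coords, y, n_iter=200, n_burn=100, seed=8)
        f2 = fit_spatial_gp(coords, y, n_iter=200, n_burn=100, seed=8)
        pd.testing.assert_frame_equal(f1.draws, f2.draws)

    def test_too_few_sites_rejected(self):
        coords = grid_coords(3)[:6]
        with pytest.raises(ValueError, match=">= 10"):
            fit_spatial_gp(coords, np.zeros(6))

    def test_pure_nugget_data_favors_small_sill_share(self):
        g = np.random.default_rng(9)
        coords = grid_coords(7)
        y = g.normal(0.0, 1.0, size=len(coords))  # no spatial structure
        fit = fit_spatial_gp(coords, y, n_iter=800, n_burn=400, seed=10)
        share = fit.draws["sill"] / (fit.draws["sill"] + fit.draws["nugget"])
        assert share.median() < 0.5

    def test_hyperparameter_recovery_under_known_truth(self):
        # From a single realization in a fixed domain, sill and decay are
        # only weakly identified separately (non-microergodicity of the
        # exponential family); their product, the nugget, the mean and the
        # implied 40-mile correlation are the estimable functionals.
        decay = np.log((1.0 / 1.25) / 0.2) / 40.0  # corr@40mi = 0.2 with nugget 0.25
        params = bhpm.GPHyperparams(mean=4.0, sill=1.0, decay=decay, nugget=0.25)
        coords = bhpm.simulate_locations(241, seed=62)[["lon", "lat"]].to_numpy()
        y = bhpm.simulate_gp_field(coords, params, seed=72)
        fit = fit_spatial_gp(coords, y, n_iter=1200, n_burn=600, seed=82)
        d = fit.draws
        functionals = {
            "sill*decay": (d["sill"] * d["decay"], params.sill * params.decay),
            "nugget": (d["nugget"], params.nugget),
            "mean": (d["mean"], params.mean),
            "corr@40": (
                d["sill"] * np.exp(-40 * d["decay"]) / (d["sill"] + d["nugget"]),
                params.correlation_at(40.0),
            ),
        }
        for name, (post, truth) in functionals.items():
            assert abs(post.mean() - truth) < 3.5 * post.std() + 1e-9, name


class TestCrossValidation:
    def test_long_range_trend_gives_high_correlation(self):
        coords = grid_coords(6)
        y = 2.0 + 3.0 * (coords[:, 0] - coords[:, 0].mean())  # smooth in lon
        rep = cross_validate(coords, y, k=5, seed=0, n_iter=400, n_burn=200)
        assert rep.mean_correlation > 0.95

    def test_pure_nugget_field_has_low_correlation(self):
        g = np.random.default_rng(12)
        coords = grid_coords(6)
        y = g.normal(size=len(coords))
        rep = cross_validate(coords, y, k=5, seed=1, n_iter=400, n_burn=200)
        assert abs(rep.mean_correlation) < 0.45

    def test_metrics_invariant_to_site_relabeling(self):
        coords = grid_coords(5)
        y = bhpm.simulate_gp_field(coords, bhpm.GPHyperparams(0.0, 1.0, 0.03, 0.1), seed=13)
        rep1 = cross_validate(coords, y, k=4, seed=3, n_iter=300, n_burn=150)
        perm = np.random.default_rng(0).permutation(len(y))
        # relabel: same sites in a different storage order, same fold seed acts
        # on positions, so compare the pooled metrics via a fresh partition
        rep2 = cross_validate(coords[perm], y[perm], k=4, seed=3, n_iter=300, n_burn=150)
        assert rep2.sample_sd == pytest.approx(rep1.sample_sd)
        assert rep2.mean_rmse == pytest.approx(rep1.mean_rmse, rel=0.35)

    def test_fold_validation(self):
        coords = grid_coords(2)
        with pytest.raises(ValueError):
            cross_validate(coords, np.zeros(4), k=1)
        with pytest.raises(ValueError, match="fewer than 2"):
            cross_validate(coords, np.zeros(4), k=3)


class TestImputeAll:
    def test_no_missing_is_identity(self, small_study):
        coords = small_study.coords[["lon", "lat"]].to_numpy()
        out = impute_all(small_study.profiles, coords, n_iter=50, n_burn=25, seed=0)
        for a, b in zip(out, small_study.profiles):
            assert np.allclose(a.constituents, b.constituents)

    def test_observed_values_never_altered(self, small_study):
        coords = small_study.coords[["lon", "lat"]].to_numpy()
        masked, idx = bhpm.mask_constituents(small_study.profiles, 0.3, seed=1)
        out = impute_all(masked, coords, n_iter=300, n_burn=150, seed=2)
        masked_set = set(idx.tolist())
        for i, (a, b) in enumerate(zip(out, small_study.profiles)):
            if i not in masked_set:
                assert np.array_equal(a.constituents, b.constituents)
                assert a.observed.all()
            else:
                assert np.isfinite(a.constituents).all()  # filled
                assert not a.observed.any()  # provenance preserved

    def test_entirely_missing_constituent_rejected(self, small_study):
        import copy

        coords = small_study.coords[["lon", "lat"]].to_numpy()
        profiles = copy.deepcopy(small_study.profiles)
        for p in profiles:
            p.constituents[0] = np.nan
            p.observed[0] = False
        with pytest.raises(ValueError, match="fewer than 10 observed"):
            impute_all(profiles, coords, n_iter=50, n_burn=25)
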