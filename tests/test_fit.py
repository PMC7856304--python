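"""Generalized-EM fitting: NIW MAP updates, bias recovery, deformation
update, monotonicity and parameter recovery on phantoms."""

import numpy as np
import pytest

from wmlseg.appearance import (AppearanceParams, BiasBasis, make_bias_basis,
                               niw_log_prior)
from wmlseg.atlas import DeformationState
from wmlseg.fit import (FitConfig, fit_parameters, niw_map_update,
                        update_bias, update_deformation)
from wmlseg.geometry import ImageGeometry, MultiContrastImage
from wmlseg.phantom import PhantomSpec, generate_phantom, paint_labels


class TestNiwMapUpdate:
    WM_MEAN = np.array([2.0])
    WM_COV = np.array([[0.25]])

    def test_zero_responsibilities_return_prior_mode(self):
        mu, cov = niw_map_update(np.zeros(5), np.zeros((5, 1)),
                                 self.WM_MEAN, self.WM_COV, nu=50.0, kappa=4.0)
        np.testing.assert_allclose(mu, self.WM_MEAN)
        np.testing.assert_allclose(cov, 4.0 * self.WM_COV)

    def test_nu_zero_equals_weighted_ml(self):
        rng = np.random.default_rng(0)
        d = rng.normal(size=(30, 2))
        r = rng.uniform(0, 1, size=30)
        mu, cov = niw_map_update(r, d, np.zeros(2), np.eye(2), 0.0, 2.0)
        W = r.sum()
        m = (r[:, None] * d).sum(0) / W
        S = ((r[:, None] * (d - m)).T @ (d - m)) / W
        np.testing.assert_allclose(mu, m, rtol=1e-12)
        np.testing.assert_allclose(cov, S, rtol=1e-12)

    def test_large_nu_pins_to_wm(self):
        rng = np.random.default_rng(1)
        d = rng.normal(5.0, 1.0, size=(50, 1))
        mu, cov = niw_map_update(np.ones(50), d, self.WM_MEAN, self.WM_COV,
                                 nu=1e8, kappa=4.0)
        assert abs(mu[0] - 2.0) < 1e-3 * 2.0
        np.testing.assert_allclose(cov, 4.0 * self.WM_COV, rtol=1e-4)

    @pytest.mark.parametrize("case_seed", range(10))
    def test_matches_grid_search_oracle_1d(self, case_seed):
        # MAP of weighted log-likelihood + NIW log prior by brute force
        rng = np.random.default_rng(case_seed)
        nu, kappa = 10.0, 3.0
        d = rng.normal(2.5, 0.8, size=(5, 1))
        r = rng.uniform(0.2, 1.0, size=5)
        mu_hat, cov_hat = niw_map_update(r, d, self.WM_MEAN, self.WM_COV,
                                         nu, kappa)

        def objective(mu, var):
            ll = np.sum(r * (-0.5 * np.log(2 * np.pi * var)
                             - 0.5 * (d[:, 0] - mu) ** 2 / var))
            return ll + niw_log_prior(np.array([mu]), np.array([[var]]),
                                      self.WM_MEAN, self.WM_COV, nu, kappa)

        mus = np.linspace(mu_hat[0] - 0.5, mu_hat[0] + 0.5, 201)
        vars_ = np.linspace(max(cov_hat[0, 0] - 0.5, 1e-3),
                            cov_hat[0, 0] + 0.5, 201)
        vals = np.array([[objective(m, v) for v in vars_] for m in mus])
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        assert mu_hat[0] == pytest.approx(mus[i], abs=1e-3 + 0.005)
        assert cov_hat[0, 0] == pytest.approx(vars_[j], abs=1e-3 + 0.005)

    def test_continuous_in_responsibilities(self):
        rng = np.random.default_rng(2)
        d = rng.normal(size=(10, 1))
        r = rng.uniform(0, 1, size=10)
        a = niw_map_update(r, d, self.WM_MEAN, self.WM_COV, 5.0, 2.0)
        b = niw_map_update(r + 1e-9, d, self.WM_MEAN, self.WM_COV, 5.0, 2.0)
        np.testing.assert_allclose(a[0], b[0], atol=1e-8)

    def test_negative_responsibilities_raise(self):
        with pytest.raises(ValueError):
            niw_map_update(np.array([-0.1]), np.zeros((1, 1)),
                           self.WM_MEAN, self.WM_COV, 1.0, 2.0)


class TestUpdateBias:
    def geometry_and_basis(self, order=(3, 3)):
        geom = ImageGeometry((16, 16))
        basis = make_bias_basis(geom, order)
        return geom, basis

    def test_exact_recovery_when_bias_in_span_single_class(self):
        rng = np.random.default_rng(0)
        geom, basis = self.geometry_and_basis()
        C_true = rng.normal(0, 0.2, size=(2, basis.n_functions))
        mu = np.array([[1.0, 3.0]])
        D = np.tile(mu, (256, 1)) + (C_true @ basis.values).T
        params = AppearanceParams(class_means=mu,
                                  class_covs=np.array([np.eye(2) * 0.01]),
                                  bias_coeffs=np.zeros_like(C_true))
        C = update_bias(D, np.ones((256, 1)), params, basis)
        np.testing.assert_allclose(C, C_true, atol=1e-6)

    def test_zero_bias_data_yields_zero_nonconstant_terms(self):
        rng = np.random.default_rng(1)
        geom, basis = self.geometry_and_basis()
        mu = np.array([[2.0]])
        D = np.tile(mu, (256, 1))
        params = AppearanceParams(class_means=mu,
                                  class_covs=np.array([[[0.5]]]),
                                  bias_coeffs=np.zeros((1, basis.n_functions)))
        C = update_bias(D, np.ones((256, 1)), params, basis)
        assert np.abs(C[:, 1:]).max() < 1e-6

    def test_constant_multiplicative_bias_absorbed_in_constant_term(self):
        geom, basis = self.geometry_and_basis()
        b = 1.7   # constant multiplicative bias = constant log offset
        mu = np.array([[2.0]])
        D = np.tile(mu, (256, 1)) + np.log(b)
        params = AppearanceParams(class_means=mu,
                                  class_covs=np.array([[[0.5]]]),
                                  bias_coeffs=np.zeros((1, basis.n_functions)))
        C = update_bias(D, np.ones((256, 1)), params, basis)
        assert C[0, 0] == pytest.approx(np.log(b), abs=1e-9)
        assert np.abs(C[:, 1:]).max() < 1e-9

    def test_full_covariance_matches_diagonal_when_offdiag_zero(self):
        rng = np.random.default_rng(2)
        geom, basis = self.geometry_and_basis((2, 2))
        D = rng.normal(size=(256, 2))
        w = rng.uniform(0.1, 1, size=(256, 2))
        w /= w.sum(1, keepdims=True)
        cov = np.stack([np.diag([0.5, 1.5])] * 2)
        kwargs = dict(class_means=np.array([[0.0, 1.0], [1.0, 0.0]]),
                      class_covs=cov,
                      bias_coeffs=np.zeros((2, basis.n_functions)))
        C_diag = update_bias(D, w, AppearanceParams(**kwargs), basis)
        C_full = update_bias(D, w, AppearanceParams(**kwargs,
                                                    diagonal_covs=False),
                             basis)
        np.testing.assert_allclose(C_diag, C_full, atol=1e-9)

    def test_singular_system_falls_back_to_ridge_with_warning(self):
        geom = ImageGeometry((8, 8))
        basis = make_bias_basis(geom, (2, 1))
        # duplicate a basis function -> singular normal equations
        bad = BiasBasis(np.vstack([basis.values, basis.values[1]]), (3, 1))
        params = AppearanceParams(class_means=np.zeros((1, 1)),
                                  class_covs=np.ones((1, 1, 1)),
                                  bias_coeffs=np.zeros((1, 3)))
        with pytest.warns(UserWarning, match="ridge"):
            update_bias(np.zeros((64, 1)), np.ones((64, 1)), params, bad)


class TestUpdateDeformation:
    def test_stationary_when_weights_equal_carved_prior(self, study_atlas):
        # when the responsibilities equal the current carved prior, the
        # per-voxel prior columns sum to 1 for every deformation, so the
        # data term has zero gradient and the aligned mesh stays put
        from wmlseg.atlas import interpolation_weights
        geom = ImageGeometry((64, 64))
        points = geom.voxel_coords()
        defo = study_atlas.identity_deformation()
        interp = interpolation_weights(study_atlas, defo, points)
        pi = interp.interpolate(study_atlas.label_probs)
        rho = np.clip(interp.interpolate(study_atlas.lesion_probs), 0, 1)
        w = pi.copy()
        lesion_w = rho * pi[:, 3]
        w[:, 3] *= (1.0 - rho)
        new = update_deformation(w, lesion_w, study_atlas, defo, points,
                                 (3,), FitConfig())
        disp = np.linalg.norm(
            new.vertex_positions - study_atlas.reference_vertex_positions,
            axis=1)
        assert disp.mean() < 0.05

    def test_known_shift_recovered(self, study_atlas):
        # anatomy translated 2 voxels, small stiffness: the vertices that
        # carry boundary information chase the shift; interior plateau
        # vertices see no data gradient and only follow elastically
        from dataclasses import replace
        soft_atlas = replace(study_atlas, stiffness=0.05)
        shifted = paint_labels(PhantomSpec(), center_offset=(2.0, 2.0))
        geom = ImageGeometry((64, 64))
        points = geom.voxel_coords()
        w = np.eye(soft_atlas.n_labels)[shifted.ravel()]
        defo = soft_atlas.identity_deformation()
        cfg = FitConfig(deform_iters=100, deform_step=2.0,
                        deform_backtracks=20)
        for _ in range(10):
            defo = update_deformation(w, np.zeros(len(points)), soft_atlas,
                                      defo, points, (3,), cfg)
        ref = soft_atlas.reference_vertex_positions
        interior = ~np.any(np.isclose(ref, 0) | np.isclose(ref, 63), axis=1)
        mixed = soft_atlas.label_probs.max(axis=1) < 0.9
        disp = defo.vertex_positions[interior & mixed] - ref[interior & mixed]
        assert np.linalg.norm(disp.mean(axis=0) - [2.0, 2.0]) < 0.5

    def test_never_returns_folded_mesh(self, study_atlas):
        rng = np.random.default_rng(3)
        geom = ImageGeometry((64, 64))
        points = geom.voxel_coords()
        w = rng.dirichlet(np.ones(study_atlas.n_labels), size=len(points))
        cfg = FitConfig(deform_iters=10, deform_step=8.0)   # aggressive steps
        out = update_deformation(w, np.zeros(len(points)), study_atlas,
                                 study_atlas.identity_deformation(), points,
                                 (3,), cfg)
        assert out.is_valid(study_atlas)


class TestFitParameters:
    def test_objective_nondecreasing_on_default_phantom(self, default_fit):
        tr = default_fit["fit"].objective_trace
        denom = np.maximum(np.abs(tr[:-1]), 1.0)
        assert np.min(np.diff(tr) / denom) > -1e-6

    def test_recovered_means_on_separated_classes(self, default_fit):
        # tissue classes only: the near-zero background is dominated by
        # log-transform skew rather than estimation error
        fr = default_fit["fit"]
        truth = default_fit["truth"]
        for k in range(1, 5):
            est = np.exp(fr.params.class_means[k])
            true = truth["class_means"][k]
            assert np.linalg.norm(est - true) / np.linalg.norm(true) < 0.05

    def test_zero_lesion_prior_gives_zero_lesion_responsibilities(
            self, study_atlas):
        atlas0 = study_atlas.with_lesion_probs(
            np.zeros(study_atlas.n_vertices))
        image, *_ = generate_phantom(PhantomSpec(seed=5), 5)
        fr = fit_parameters(image, atlas0,
                            FitConfig(seed=5, max_outer_iters=8))
        np.testing.assert_array_equal(fr.lesion_responsibilities, 0.0)

    def test_nu_large_limit_ties_lesion_to_wm(self, study_atlas):
        image, *_ = generate_phantom(PhantomSpec(seed=6), 6)
        fr = fit_parameters(image, study_atlas,
                            FitConfig(seed=6, nu=1e8, max_outer_iters=10))
        mu_wm = fr.params.class_means[3]
        assert (np.linalg.norm(fr.params.lesion_mean - mu_wm)
                < 1e-3 * np.linalg.norm(mu_wm))
        np.testing.assert_allclose(fr.params.lesion_cov,
                                   fr.params.hyper_kappa
                                   * fr.params.class_covs[3], rtol=0.05)

    def test_nu_zero_with_abundant_lesions_is_unregularized_ml(
            self, study_atlas):
        spec = PhantomSpec(seed=8, lesion_count_range=(4, 6))
        image, _labels, lesions, *_ = generate_phantom(spec, 8)
        fr = fit_parameters(image, study_atlas, FitConfig(seed=8, nu=0.0))
        # the lesion update must equal the weighted ML statistics of the
        # final responsibilities (flat prior)
        from wmlseg.appearance import bias_field
        D = fr.image.masked() - bias_field(fr.params, fr.basis)
        r = fr.lesion_responsibilities
        W = r.sum()
        assert W > 10   # abundant lesion evidence
        m = (r[:, None] * D).sum(0) / W
        # responsibilities move a hair between the last M- and E-step, so
        # agreement is to convergence precision rather than exact
        np.testing.assert_allclose(fr.params.lesion_mean, m, atol=1e-3)
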