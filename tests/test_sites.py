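"""Per-ring binding-site estimation: shared-covariance EM, symmetric
initialization, and the symmetry-constrained quasi-Newton fit."""

import numpy as np
import pytest

import npcfusion as nf
from npcfusion.geometry import wrap_angle
from npcfusion.sites import _em_shared_diag
from tests.conftest import make_synthetic_ring


class TestSharedDiagEM:
    def test_responsibilities_match_bayes_rule(self):
        # 3 points, 2 components: one E-step against hand-computed posteriors
        X = np.array([[0.0, 0, 0], [4.0, 0, 0], [2.0, 1, 0]])
        means = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        sigma = np.array([2.0, 2.0, 2.0])
        _, _, _, _, resp = _em_shared_diag(X, means, sigma, max_iter=1,
                                           tol=0.0)
        var = sigma ** 2
        def dens(x, m):
            return np.exp(-0.5 * np.sum((x - m) ** 2 / var)) / np.sqrt(
                np.prod(2 * np.pi * var))
        for i, x in enumerate(X):
            p0, p1 = dens(x, means[0]), dens(x, means[1])
            np.testing.assert_allclose(resp[i], [p0 / (p0 + p1),
                                                 p1 / (p0 + p1)], rtol=1e-12)

    def test_recovers_planted_mixture(self, reference_nr_params):
        # sample straight from a known 16-component shared-covariance
        # mixture; the EM must land on the generating centers
        rng = np.random.default_rng(10)
        sites = nf.expand_eightfold(reference_nr_params).flat
        n_per = 6250  # 1e5 total
        X = (np.repeat(sites, n_per, 0)
             + rng.standard_normal((16 * n_per, 3)) * [4.0, 4.0, 8.0])
        cloud = nf.LocalizationCloud(X, 0)
        res = nf.fit_gmm16_unconstrained(cloud, seed=1, init_sites=sites,
                                         init_sigma_xy=4.0)
        d = np.linalg.norm(res.sites.flat[:, None] - sites[None], axis=-1)
        assert d.min(axis=1).max() < 0.5
        np.testing.assert_allclose(res.sigma, [4.0, 4.0, 8.0], rtol=0.02)

    def test_log_likelihood_monotone(self, synthetic_ring):
        res = nf.fit_gmm16_unconstrained(synthetic_ring, seed=2)
        ll = res.log_likelihoods
        assert np.all(np.diff(ll) >= -1e-7 * np.abs(ll[:-1]))

    def test_needs_enough_localizations(self):
        tiny = nf.LocalizationCloud(
            np.random.default_rng(0).normal(size=(50, 3)), 0)
        with pytest.raises(ValueError):
            nf.fit_gmm16_unconstrained(tiny)


class TestSymmetricInit:
    def test_nr_first_unit_center(self):
        ss, params = nf.init_symmetric_centers("NR", rng=0)
        s11, s12 = ss.sites[0]
        np.testing.assert_allclose(0.5 * (s11 + s12), [0.0, 53.5, 24.0],
                                   atol=1e-9)

    def test_planar_initialization(self):
        for lab, z in (("NR", 24.0), ("CR", -24.0)):
            ss, _ = nf.init_symmetric_centers(lab, rng=1)
            np.testing.assert_allclose(ss.flat[:, 2], z, atol=1e-9)
            d = np.linalg.norm(ss.sites[:, 0] - ss.sites[:, 1], axis=1)
            np.testing.assert_allclose(d, 13.0, atol=1e-9)

    def test_phi_modes(self):
        _, fixed = nf.init_symmetric_centers("NR", rng=0, phi_mode="fixed")
        assert fixed.phi == pytest.approx(np.pi / 4)
        rng = np.random.default_rng(3)
        phis = [nf.init_symmetric_centers("NR", rng=rng)[1].phi
                for _ in range(20)]
        assert all(0 <= p <= np.pi for p in phis)
        assert np.std(phis) > 0.1


class TestSymmetryConstrainedFit:
    def test_perfect_data_fixed_point(self, reference_nr_params):
        G = nf.expand_eightfold(reference_nr_params)
        G = nf.SiteSet(G.sites, kind="unconstrained", ring_label="NR")
        params, mse = nf.fit_symmetry_constrained(G, restarts=3, rng=0)
        assert mse < 1e-8
        assert params.R == pytest.approx(reference_nr_params.R, abs=1e-3)
        assert params.d == pytest.approx(reference_nr_params.d, abs=1e-3)
        assert params.theta == pytest.approx(reference_nr_params.theta,
                                             abs=1e-4)
        assert wrap_angle(params.phi - reference_nr_params.phi) == \
            pytest.approx(0.0, abs=1e-4)

    def test_noisy_recovery_is_unbiased(self, reference_nr_params):
        # Monte-Carlo oracle: iid 1-nm site noise leaves the mean estimate
        # within 0.3 nm / 1 degree of the truth
        rng = np.random.default_rng(4)
        flat = nf.expand_eightfold(reference_nr_params).flat
        est = []
        for _ in range(100):
            G = flat + rng.standard_normal((16, 3)) * 1.0
            p, _ = nf.fit_symmetry_constrained(G, restarts=1, rng=rng,
                                               ring_label="NR")
            est.append([p.R, p.d, p.theta, p.phi])
        mean = np.mean(est, axis=0)
        assert abs(mean[0] - reference_nr_params.R) < 0.3
        assert abs(mean[1] - reference_nr_params.d) < 0.3
        assert abs(mean[2] - reference_nr_params.theta) < np.radians(1.0)
        assert abs(wrap_angle(mean[3] - reference_nr_params.phi)) < np.radians(1.0)

    def test_objective_not_worse_than_init(self, reference_nr_params):
        rng = np.random.default_rng(5)
        G = nf.expand_eightfold(reference_nr_params).flat \
            + rng.standard_normal((16, 3)) * 2.0
        init = nf.init_symmetric_centers("NR", rng=0)[1]
        params, mse = nf.fit_symmetry_constrained(G, init=init, restarts=2,
                                                  rng=0, ring_label="NR")
        S0 = nf.expand_eightfold(init).flat
        d2 = ((S0[:, None] - G[None]) ** 2).sum(-1)
        from scipy.optimize import linear_sum_assignment
        r, c = linear_sum_assignment(d2)
        mse0 = d2[r, c].mean()
        assert mse <= mse0 + 1e-12

    def test_gauge_consistency_under_quarter_turn(self, reference_nr_params):
        rng = np.random.default_rng(6)
        G = nf.expand_eightfold(reference_nr_params).flat \
            + rng.standard_normal((16, 3)) * 0.5
        a = np.pi / 4
        R = np.array([[np.cos(a), -np.sin(a), 0],
                      [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])
        p1, _ = nf.fit_symmetry_constrained(G, restarts=2, rng=0)
        p2, _ = nf.fit_symmetry_constrained(G @ R.T, restarts=2, rng=0)
        assert p2.R == pytest.approx(p1.R, abs=1e-6)
        assert p2.d == pytest.approx(p1.d, abs=1e-6)
        assert p2.theta == pytest.approx(p1.theta, abs=1e-6)
        assert wrap_angle(p2.phi - p1.phi) == pytest.approx(0.0, abs=1e-6)
        assert abs(wrap_angle((p2.psi - p1.psi - a) * 8)) < 1e-5


class TestEightfoldRingModel:
    def test_fit_on_synthetic_ring(self, synthetic_ring):
        res = nf.EightfoldRingModel(synthetic_ring, ring_label="NR").fit(
            seed=3, restarts=5)
        assert res.params.R == pytest.approx(54.2, abs=1.0)
        assert res.params.d == pytest.approx(11.8, abs=1.5)
        assert np.degrees(res.params.theta) == pytest.approx(76.8, abs=5.0)
        assert np.degrees(res.params.phi) == pytest.approx(-32.6, abs=5.0)
        assert res.mean_site_distance < 2.0
        text = res.summary()
        assert "ring radius R" in text and "unit distance d" in text

    def test_from_dataframe_constructor(self, synthetic_ring):
        import pandas as pd
        df = pd.DataFrame(synthetic_ring.positions,
                          columns=["x_nm", "y_nm", "z_nm"])
        model = nf.EightfoldRingModel.from_dataframe(df, ring_label="NR")
        assert len(model.cloud) == len(synthetic_ring)
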