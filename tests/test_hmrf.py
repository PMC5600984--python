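import numpy as np
import pytest
from sklearn.mixture import GaussianMixture

from ldpo import (Volume, TissueModel, initialize_model, clique_potential, local_prior,
                  icm_update, em_fit, mrf_energy, posterior_probabilities,
                  make_slab_phantom, PhantomSpec)
from ldpo.exceptions import (ContractError, DegenerateModelError, DomainError,
                             InitializationError)
from ldpo.hmrf import CSF, GM, WM


def ones_mask(shape):
    return Volume(np.ones(shape, dtype=np.uint8), role="mask")


class TestInitializeModel:
    def test_recovers_well_separated_clusters(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(m, 5, 1000) for m in (50, 110, 170)])
        rng.shuffle(vals)
        y = Volume(vals.reshape(10, 10, 30))
        model = initialize_model(y, ones_mask(y.shape), seed=0)
        assert np.all(np.abs(model.mu - [50, 110, 170]) < 2)
        assert np.all(np.diff(model.mu) > 0)

    def test_deterministic_given_seed(self, rng):
        y = Volume(rng.normal(100, 30, (8, 8, 8)))
        m1 = initialize_model(y, ones_mask(y.shape), seed=7)
        m2 = initialize_model(y, ones_mask(y.shape), seed=7)
        assert np.array_equal(m1.mu, m2.mu) and np.array_equal(m1.sigma, m2.sigma)

    def test_too_few_voxels_rejected(self):
        y = Volume(np.arange(10.0).reshape(1, 2, 5))
        mask = Volume(np.ones((1, 2, 5), np.uint8), role="mask")
        with pytest.raises(InitializationError):
            initialize_model(y, mask, k=3)


class TestCliquePotential:
    @pytest.mark.parametrize("a,b,beta,expected", [
        (GM, GM, 1.0, 0.0),
        (GM, WM, 1.0, 0.5),
        (GM, WM, 2.0, 1.0),
        (CSF, CSF, 5.0, 0.0),
    ])
    def test_values(self, a, b, beta, expected):
        assert clique_potential(a, b, beta) == expected

    def test_invalid_label_rejected(self):
        with pytest.raises(DomainError):
            clique_potential(GM, 7)


class TestLocalPrior:
    def test_uniform_neighbourhood(self):
        # direct Gibbs oracle: U_gm = 0, U_other = 6 * 0.5 = 3
        labels = np.full((3, 3, 3), GM, dtype=np.int8)
        expected = 1.0 / (1.0 + 2.0 * np.exp(-3.0))
        assert local_prior(labels, (1, 1, 1), GM, beta=1.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.9095, abs=1e-4)

    def test_isolated_voxel_uniform(self):
        labels = np.zeros((1, 1, 1), dtype=np.int8)
        mask = np.zeros((1, 1, 1), dtype=bool)
        for cand in (CSF, GM, WM):
            assert local_prior(labels, (0, 0, 0), cand, mask=mask) == pytest.approx(1 / 3)

    def test_symmetric_split(self):
        labels = np.full((3, 3, 3), GM, dtype=np.int8)
        labels[2, 1, 1] = labels[1, 2, 1] = labels[1, 1, 2] = WM
        p_gm = local_prior(labels, (1, 1, 1), GM)
        p_wm = local_prior(labels, (1, 1, 1), WM)
        assert p_gm == pytest.approx(p_wm)

    def test_priors_sum_to_one(self, rng):
        labels = rng.integers(0, 3, (4, 4, 4)).astype(np.int8)
        total = sum(local_prior(labels, (2, 2, 2), c) for c in (CSF, GM, WM))
        assert total == pytest.approx(1.0)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(IndexError):
            local_prior(np.zeros((2, 2, 2), np.int8), (5, 0, 0), GM)


class TestIcmUpdate:
    def _model(self, beta=0.0):
        return TissueModel(mu=np.array([50.0, 110.0, 170.0]),
                           sigma=np.array([10.0, 10.0, 10.0]), beta=beta)

    def test_noiseless_slabs_beta0(self):
        y = np.full((4, 4, 8), 110.0)
        y[:, :, 4:] = 170.0
        yv = Volume(y)
        mask = ones_mask(y.shape)
        labels = np.zeros(y.shape, dtype=np.int8)
        out = icm_update(yv, labels, self._model(beta=0.0), mask)
        assert np.all(out[:, :, :4] == GM) and np.all(out[:, :, 4:] == WM)

    def test_beta0_equals_gaussian_argmax(self, rng):
        y = rng.uniform(30, 190, (5, 5, 5))
        model = self._model(beta=0.0)
        out = icm_update(Volume(y), np.zeros(y.shape, np.int8), model, ones_mask(y.shape))
        loglik = np.stack([-0.5 * ((y - model.mu[l]) / model.sigma[l]) ** 2
                           - np.log(model.sigma[l]) for l in range(3)])
        assert np.array_equal(out, loglik.argmax(axis=0))

    def test_salt_voxel_flips_with_strong_prior(self):
        # oracle: exhaustive evaluation of the three candidate energies
        y = np.full((3, 3, 3), 170.0)
        y[1, 1, 1] = 110.0  # GM-intensity voxel inside a WM slab
        model = self._model(beta=10.0)
        labels = np.full(y.shape, WM, dtype=np.int8)
        labels[1, 1, 1] = GM
        energies = []
        for cand in (CSF, GM, WM):
            d = (y[1, 1, 1] - model.mu[cand]) / model.sigma[cand]
            u = sum(clique_potential(cand, WM, model.beta) for _ in range(6))
            energies.append(0.5 * d * d + np.log(model.sigma[cand]) + u)
        assert int(np.argmin(energies)) == WM
        out = icm_update(Volume(y), labels, model, ones_mask(y.shape))
        assert out[1, 1, 1] == WM

    def test_zero_sigma_rejected(self):
        model = TissueModel(mu=np.array([1.0, 2.0, 3.0]), sigma=np.array([1.0, 1.0, 1.0]))
        model.sigma = np.array([1.0, 0.0, 1.0])  # bypass constructor check
        with pytest.raises(DegenerateModelError):
            icm_update(Volume(np.ones((2, 2, 2))), np.zeros((2, 2, 2), np.int8),
                       model, ones_mask((2, 2, 2)))

    def test_energy_never_increases_over_sweeps(self, rng):
        y = Volume(rng.normal(110, 40, (8, 8, 8)))
        mask = ones_mask(y.shape)
        model = self._model(beta=1.5)
        labels = rng.integers(0, 3, y.shape).astype(np.int8)
        prev = mrf_energy(y, labels, model, mask)
        for _ in range(5):
            labels = icm_update(y, labels, model, mask)
            e = mrf_energy(y, labels, model, mask)
            assert e <= prev + 1e-9
            prev = e


class TestEmFit:
    def _phantom(self, seed=0, shape=(30, 30, 30)):
        spec = PhantomSpec(shape=shape, gwb_thickness_mm=0.5, csf_margin_mm=10.0,
                           tissue_means=(50.0, 110.0, 170.0),
                           tissue_sds=(10.0, 10.0, 10.0), seed=seed)
        b = make_slab_phantom(spec)
        return b.image, ones_mask(shape)

    def test_parameter_recovery(self):
        y, mask = self._phantom()
        seg = em_fit(y, mask, beta=1.0, seed=0)
        assert np.all(np.abs(seg.model.mu - [50, 110, 170]) / [50, 110, 170] < 0.02)
        assert np.all(np.abs(seg.model.sigma - 10.0) / 10.0 < 0.10)

    def test_posteriors_sum_to_one(self):
        y, mask = self._phantom(seed=2)
        seg = em_fit(y, mask, seed=2)
        total = seg.p_csf.data + seg.p_gm.data + seg.p_wm.data
        assert np.abs(total - 1).max() < 1e-6

    def test_posteriors_zero_outside_mask(self):
        y, _ = self._phantom(seed=3)
        m = np.ones(y.shape, np.uint8)
        m[:2] = 0
        seg = em_fit(y, Volume(m, role="mask"), seed=3)
        for p in (seg.p_csf, seg.p_gm, seg.p_wm):
            assert np.all(p.data[:2] == 0)

    def test_labels_agree_with_argmax_posterior(self):
        y, mask = self._phantom(seed=4)
        seg = em_fit(y, mask, seed=4)
        stacked = np.stack([seg.p_csf.data, seg.p_gm.data, seg.p_wm.data])
        assert np.array_equal(seg.labels.data - 1, stacked.argmax(axis=0))

    def test_tol_inf_single_iteration(self):
        y, mask = self._phantom(seed=5)
        seg = em_fit(y, mask, tol=np.inf, seed=5)
        assert seg.em_iterations == 1 and seg.converged

    def test_deterministic(self):
        y, mask = self._phantom(seed=6)
        a = em_fit(y, mask, seed=6)
        b = em_fit(y, mask, seed=6)
        assert np.array_equal(a.labels.data, b.labels.data)
        assert np.array_equal(a.p_gm.data, b.p_gm.data)
        assert np.array_equal(a.model.mu, b.model.mu)

    def test_means_ordered_after_fit(self):
        y, mask = self._phantom(seed=7)
        seg = em_fit(y, mask, seed=7)
        assert np.all(np.diff(seg.model.mu) > 0)
        for mu, _sigma in seg.model.history:
            assert np.all(np.diff(mu) > 0)

    def test_beta0_matches_gaussian_mixture(self):
        # independent oracle: plain GMM EM on the flattened intensities
        y, mask = self._phantom(seed=8)
        seg = em_fit(y, mask, beta=0.0, tol=1e-8, max_em_iter=200, seed=8)
        gmm = GaussianMixture(3, covariance_type="spherical", tol=1e-10, max_iter=1000,
                              random_state=0,
                              means_init=np.array([[50.0], [110.0], [170.0]]))
        gmm.fit(y.data.reshape(-1, 1))
        ref = np.sort(gmm.means_.ravel())
        assert np.all(np.abs(seg.model.mu - ref) < 1e-3)

    def test_empty_mask_rejected(self):
        y = Volume(np.ones((4, 4, 4)))
        with pytest.raises(ContractError):
            em_fit(y, Volume(np.zeros((4, 4, 4), np.uint8), role="mask"))
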