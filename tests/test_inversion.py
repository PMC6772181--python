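"""ReML hyperparameter estimation, free energy and the MSP/EBB inverters."""

import warnings

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from megdeep.forward import LeadField, mesh_adjacency
from megdeep.inversion import (CovarianceComponents, HyperParameterState,
                               HyperPriors, apply_inverse, ebb_components,
                               ebb_invert, free_energy, msp_invert,
                               reml_optimize, sample_covariance)
from megdeep.inversion import _build_sigma, _inverse_operator
from megdeep.preprocess import ReducedData


def make_reduced(coeff, projector=None, basis=None, fs=300.0):
    n_t, n_s, n_k = coeff.shape
    return ReducedData(coeff, projector if projector is not None else np.eye(n_s),
                       basis if basis is not None else np.eye(n_k),
                       (0.0, 3.5), fs, n_s, n_k,
                       condition=np.array(["CS+"] * n_t),
                       block=np.ones(n_t, int), participant="P00")


FLAT = HyperPriors(eta=0.0, variance=1e8)


class TestSampleCovariance:
    def test_single_trial_case(self):
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((1, 5, 4))
        C = sample_covariance(make_reduced(Y))
        assert np.allclose(C, Y[0] @ Y[0].T / 4)

    def test_running_accumulation_matches_batch(self):
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((7, 4, 3))
        C = sample_covariance(make_reduced(Y))
        acc = np.zeros((4, 4))
        for t in range(7):  # running average, one trial at a time
            acc += Y[t] @ Y[t].T
        assert np.allclose(C, acc / (7 * 3), atol=1e-12)

    def test_psd(self):
        rng = np.random.default_rng(2)
        C = sample_covariance(make_reduced(rng.standard_normal((3, 6, 4))))
        w = np.linalg.eigvalsh(C)
        assert w.min() >= -1e-10 * w.max()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sample_covariance(make_reduced(np.zeros((0, 3, 2))))


def identity_components(n):
    return CovarianceComponents(
        sensor_rank1=np.zeros((n, 0)), source_rank1=None,
        sensor_dense=[np.eye(n)], source_diag=[None],
        provenance=[{"kind": "noise"}])


class TestReml:
    def test_single_component_closed_form(self):
        """C_y = 2 I with one identity component and a flat hyperprior has
        the closed-form ML solution exp(lambda) = 2."""
        n = 8
        state, *_ = reml_optimize(2.0 * np.eye(n), identity_components(n),
                                  N_t=10_000, hyperpriors=FLAT)
        assert np.exp(state.mu[0]) == pytest.approx(2.0, rel=0.05)

    def test_two_orthogonal_components_match_grid_search(self):
        """With a flat prior the optimum of F over two orthogonal-support
        components coincides with an exhaustive 2-D grid search of the
        Gaussian log likelihood."""
        n = 10
        Q1 = np.diag([1.0] * 5 + [0.0] * 5)
        Q2 = np.diag([0.0] * 5 + [1.0] * 5)
        C = 1.5 * Q1 + 0.5 * Q2
        comp = CovarianceComponents(np.zeros((n, 0)), None, [Q1, Q2],
                                    [None, None], [{}, {}])
        N_t = 1000
        state, *_ = reml_optimize(C, comp, N_t, hyperpriors=FLAT)

        grid = np.arange(-2.0, 2.0, 0.02)
        def loglik(l1, l2):
            S = np.exp(l1) * Q1 + np.exp(l2) * Q2
            P = np.linalg.inv(S)
            _, ld = np.linalg.slogdet(S)
            return -(N_t / 2) * (np.sum(P * C) + ld)
        vals = np.array([[loglik(a, b) for b in grid] for a in grid])
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        assert abs(state.mu[0] - grid[i]) <= 0.04
        assert abs(state.mu[1] - grid[j]) <= 0.04

    def test_trajectory_non_decreasing(self, small_reduced, leadfield,
                                       patches, anatomy):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = msp_invert(small_reduced, leadfield, patches, anatomy,
                             "HA", n_restarts=1, seed=0)
        assert np.all(np.diff(res.F_trajectory) >= -1e-6)

    def test_ard_shrinks_unsupported_component(self):
        """A component with no support in the data collapses towards the
        prior mean."""
        n = 6
        rng = np.random.default_rng(0)
        v = rng.standard_normal(n)
        v /= np.linalg.norm(v)
        comp = CovarianceComponents(v[:, None], v[:, None],
                                    [np.eye(n) / n], [None], [{}, {}])
        # data orthogonal to v
        C = np.eye(n) - 0.9 * np.outer(v, v)
        hp = HyperPriors()
        state, *_ = reml_optimize(C, comp, 1000, hp)
        assert state.mu[0] < hp.eta + 1.0


class TestFreeEnergy:
    def test_accuracy_equals_gaussian_log_density(self):
        rng = np.random.default_rng(3)
        n, N_t = 4, 50
        Y = rng.standard_normal((n, N_t))
        C = Y @ Y.T / N_t
        S = np.cov(rng.standard_normal((n, 200))) + np.eye(n)
        state = HyperParameterState(np.zeros(1), np.eye(1), np.zeros(1),
                                    np.ones(1))
        _, acc, _ = free_energy(C, S, state, N_t)
        ref = multivariate_normal(np.zeros(n), S).logpdf(Y.T).sum()
        assert acc == pytest.approx(ref, rel=1e-8)

    def test_complexity_zero_when_posterior_equals_prior(self):
        state = HyperParameterState(np.full(3, -4.0), np.eye(3) * 16.0,
                                    np.full(3, -4.0), np.full(3, 1 / 16.0))
        F, acc, cx = free_energy(np.eye(2), np.eye(2), state, 10)
        assert cx == pytest.approx(0.0, abs=1e-12)
        assert F == pytest.approx(acc)

    def test_scalar_closed_form(self):
        state = HyperParameterState(np.zeros(1), np.ones((1, 1)),
                                    np.zeros(1), np.ones(1))
        F, acc, cx = free_energy(np.eye(1), np.eye(1), state, 1)
        assert acc == pytest.approx(-0.5 * np.log(2 * np.pi) - 0.5)

    def test_non_pd_sigma_rejected(self):
        state = HyperParameterState(np.zeros(1), np.ones((1, 1)),
                                    np.zeros(1), np.ones(1))
        with pytest.raises(FloatingPointError):
            free_energy(np.eye(2), np.diag([1.0, -1.0]), state, 1)

    def test_invariant_under_joint_rotation(self):
        """F is unchanged by a joint orthonormal rotation of the data
        covariance and all components."""
        rng = np.random.default_rng(4)
        n = 6
        v = rng.standard_normal((n, 2))
        v /= np.linalg.norm(v, axis=0)
        C = np.cov(rng.standard_normal((n, 100)))
        R = np.linalg.qr(rng.standard_normal((n, n)))[0]
        comp1 = CovarianceComponents(v, v, [np.eye(n) / n], [None], [{}] * 3)
        comp2 = CovarianceComponents(R @ v, R @ v, [np.eye(n) / n],
                                     [None], [{}] * 3)
        _, F1, *_ = reml_optimize(C, comp1, 100)[0:2] + ()
        s1 = reml_optimize(C, comp1, 100)
        s2 = reml_optimize(R @ C @ R.T, comp2, 100)
        assert s1[1] == pytest.approx(s2[1], abs=1e-6)


@pytest.fixture(scope="module")
def single_source_sim(anatomy, leadfield, projector):
    """One active hippocampal source at comfortable SNR: the localisation
    benchmark both inverters must pass."""
    from megdeep.preprocess import reduce_modes
    from megdeep.simulate import (EpochsData, ExperimentDesign, GroundTruth,
                                  project_and_noise)

    d = ExperimentDesign(blocks_per_phase=1, trials_per_block=40,
                         fs=300.0)
    sl = anatomy.vertex_slice("hippocampus_L")
    vertex = sl.start + 20
    rng = np.random.default_rng(0)
    t = d.times
    sig = np.sin(2 * np.pi * 5 * t[None, None, :]
                 + rng.uniform(0, 2 * np.pi, (40, 1, 1)))
    truth = GroundTruth(["hippocampus_L"], np.array([vertex]), sig,
                        np.array(["CS+", "CS-"] * 20), np.ones(40, int),
                        np.zeros(40, bool), np.zeros(40))
    ep = project_and_noise(truth, leadfield, d, snr_db=10.0, seed=1)
    red = reduce_modes(ep, projector, 4, window=(0.0, 3.5))
    return red, vertex


@pytest.fixture(scope="module")
def inverted(small_reduced, leadfield, patches, anatomy):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return msp_invert(small_reduced, leadfield, patches, anatomy,
                          "HA", n_restarts=4, seed=5)


class TestMspInvert:

    def test_returns_max_over_restarts(self, inverted):
        assert inverted.F == pytest.approx(inverted.restart_F.max())
        assert len(inverted.restart_F) == 4

    def test_reproducible_given_seed(self, small_reduced, leadfield, patches,
                                     anatomy, inverted):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again = msp_invert(small_reduced, leadfield, patches, anatomy,
                               "HA", n_restarts=4, seed=5)
        assert again.F == inverted.F
        assert np.array_equal(again.prior_vertices, inverted.prior_vertices)

    def test_deep_source_localised_near_truth(self, single_source_sim,
                                              leadfield, patches, anatomy):
        """With a single active deep source at adequate SNR, the vertex of
        maximal posterior current lies within one patch radius (graph
        distance <= 2) of the true vertex."""
        red, vertex = single_source_sim
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = msp_invert(red, leadfield, patches, anatomy, "HA",
                             n_restarts=8, seed=3)
        J = apply_inverse(res.M, red)
        rms = np.sqrt((J ** 2).mean(axis=(0, 2)))
        # selection is region-restricted, as in the downstream extraction:
        # a cortical patch may mimic part of the deep field (the inverse
        # ambiguity the model comparison exists to resolve)
        sl = anatomy.vertex_slice("hippocampus_L")
        loc = int(np.argmax(rms[sl]))
        A = mesh_adjacency(anatomy.mesh("hippocampus_L"))
        reach = np.eye(len(A)) + A
        reach = reach @ reach               # graph distance <= 2
        assert reach[loc, vertex - sl.start] > 0

    def test_all_zero_data_gives_null_currents(self, leadfield, patches,
                                               anatomy):
        red = make_reduced(np.zeros((5, 100, 4)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = msp_invert(red, leadfield, patches, anatomy, "HA",
                             n_restarts=1, seed=0)
        J = apply_inverse(res.M, red)
        assert np.abs(J).max() <= 1e-8


class TestEbb:
    def test_identity_covariance_uniform_prior(self):
        rng = np.random.default_rng(5)
        L = rng.standard_normal((6, 20))
        L /= np.linalg.norm(L, axis=0)
        comp = ebb_components(L, np.eye(6))
        q = comp.source_diag[0]
        assert np.allclose(q, q[0])

    def test_sources_count_equals_model_vertices(self, small_reduced,
                                                 leadfield):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ebb_invert(small_reduced, leadfield)
        assert len(res.components.source_diag[0]) == leadfield.n_sources
        assert res.M.shape[0] == leadfield.n_sources

    def test_strong_source_peaks_near_truth(self, single_source_sim,
                                            leadfield, anatomy):
        """The empirical beamformer-power prior peaks within one vertex
        ring of the one strongly active source."""
        red, vertex = single_source_sim
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ebb_invert(red, leadfield)
        q = res.components.source_diag[0]
        sl = anatomy.vertex_slice("hippocampus_L")
        loc = int(np.argmax(q[sl]))
        A = mesh_adjacency(anatomy.mesh("hippocampus_L"))
        true_local = vertex - sl.start
        assert loc == true_local or A[loc, true_local] > 0


class TestApplyInverse:
    def test_linearity(self):
        rng = np.random.default_rng(6)
        M = rng.standard_normal((10, 5))
        Y1 = make_reduced(rng.standard_normal((3, 5, 4)))
        Y2 = make_reduced(rng.standard_normal((3, 5, 4)))
        combo = make_reduced(2.0 * Y1.coefficients + 3.0 * Y2.coefficients)
        lhs = apply_inverse(M, combo)
        rhs = 2.0 * apply_inverse(M, Y1) + 3.0 * apply_inverse(M, Y2)
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_matches_explicit_ridge_formula(self):
        """On a 3-source toy problem the posterior mean current equals
        C_J L' (L C_J L' + C_E)^-1 Y."""
        rng = np.random.default_rng(7)
        n_c, n_s = 4, 3
        L = rng.standard_normal((n_c, n_s))
        g = np.eye(n_s)                      # point patches
        V = L @ g
        nrm = np.linalg.norm(V, axis=0)
        comp = CovarianceComponents(V / nrm, g / nrm,
                                    [np.eye(n_c) / n_c], [None], [{}] * 4)
        mu = np.array([0.3, -1.0, 0.7, -2.0])
        state = HyperParameterState(mu, np.eye(4), np.full(4, -4.0),
                                    np.full(4, 1 / 16))
        S = _build_sigma(comp, mu)
        M = _inverse_operator(comp, state, L, S)
        w = np.exp(mu)
        C_J = (g / nrm) @ np.diag(w[:3]) @ (g / nrm).T
        C_E = w[3] * np.eye(n_c) / n_c
        ridge = C_J @ L.T @ np.linalg.inv(L @ C_J @ L.T + C_E)
        Y = rng.standard_normal((n_c, 2))
        assert np.allclose(M @ Y, ridge @ Y, atol=1e-10)

    def test_zero_data_zero_currents(self):
        M = np.ones((6, 3))
        assert np.all(apply_inverse(M, make_reduced(np.zeros((2, 3, 4)))) == 0)
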