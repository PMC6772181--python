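"""Generator contracts: trial arithmetic, ground-truth fidelity, coupling."""

import numpy as np
import pytest

from megdeep.connectivity import bandpass_theta, instantaneous_phase, pli
from megdeep.simulate import (DEEP_LABELS, ExperimentDesign, GroundTruth,
                              SourceDynamics, assign_source_vertices,
                              coupling_kappa, expected_pli, project_and_noise,
                              simulate_experiment, simulate_source_timecourses)


class TestDesignArithmetic:
    def test_default_maintenance_counts(self):
        d = ExperimentDesign()
        truth = simulate_source_timecourses(
            d, SourceDynamics(n_background_cortical_sources=0), seed=0)
        assert d.n_trials == 400
        assert (truth.condition == "CS+").sum() == 200
        assert (truth.condition == "CS-").sum() == 200
        assert truth.reinforced.sum() == 100
        # equal counts and 50% reinforcement per block
        for b in range(1, 11):
            m = truth.block == b
            assert (truth.condition[m] == "CS+").sum() == 20
            assert truth.reinforced[m].sum() == 10

    def test_us_never_on_cs_minus(self):
        truth = simulate_source_timecourses(
            ExperimentDesign(),
            SourceDynamics(n_background_cortical_sources=0), seed=1)
        assert not np.any(truth.reinforced[truth.condition == "CS-"])

    def test_extinction_has_no_us(self):
        d = ExperimentDesign(phase="extinction")
        truth = simulate_source_timecourses(
            d, SourceDynamics(n_background_cortical_sources=0), seed=2)
        assert truth.reinforced.sum() == 0

    def test_epoch_time_axis(self):
        d = ExperimentDesign()
        t = d.times
        assert t[0] == -1.0
        assert len(t) == 3000
        assert np.allclose(np.diff(t), 1 / 600.0)


class TestProjection:
    def test_same_seed_bit_identical(self, anatomy, leadfield, small_design):
        a = simulate_experiment(anatomy, leadfield, small_design,
                                SourceDynamics(), 0.0, 1, seed=9)[0]
        b = simulate_experiment(anatomy, leadfield, small_design,
                                SourceDynamics(), 0.0, 1, seed=9)[0]
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.condition, b.condition)

    def test_noiseless_data_is_gain_times_sources(self, small_epochs, leadfield):
        gt = small_epochs.ground_truth
        noiseless = np.matmul(leadfield.gain @ gt.source_patterns, gt.signals)
        resid = small_epochs.data - noiseless
        # residual must be exactly the white noise realisation: variance
        # matches sigma and is uncorrelated with the signal
        assert np.isclose(resid.std(), gt.noise_sigma, rtol=0.01)
        corr = np.corrcoef(resid.ravel()[::17], noiseless.ravel()[::17])[0, 1]
        assert abs(corr) < 0.01

    def test_single_source_zero_noise_rank_one(self, leadfield):
        d = ExperimentDesign(blocks_per_phase=1, trials_per_block=4)
        rng = np.random.default_rng(0)
        sig = np.sin(2 * np.pi * 5 * d.times)[None, None, :] * np.ones((4, 1, 1))
        truth = GroundTruth(["hippocampus_L"], np.array([650]), sig,
                            np.array(["CS+", "CS-", "CS+", "CS-"]),
                            np.ones(4, int), np.zeros(4, bool), np.zeros(4))
        ep = project_and_noise(truth, leadfield, d, snr_db=300.0, seed=0)
        s = np.linalg.svd(ep.data[0], compute_uv=False)
        assert s[1] < 1e-8 * s[0]

    def test_realised_snr_within_1db(self, small_epochs, leadfield):
        gt = small_epochs.ground_truth
        noiseless = np.matmul(leadfield.gain @ gt.source_patterns, gt.signals)
        noise = small_epochs.data - noiseless
        snr = 10 * np.log10(noiseless.var() / noise.var())
        assert abs(snr - 0.0) < 1.0

    def test_non_finite_snr_rejected(self, leadfield, small_design):
        truth = simulate_source_timecourses(small_design, SourceDynamics(), 0)
        with pytest.raises(ValueError, match="finite"):
            project_and_noise(truth, leadfield, small_design, snr_db=np.inf)

    def test_participants_get_distinct_data(self, anatomy, leadfield,
                                            small_design):
        eps = simulate_experiment(anatomy, leadfield, small_design,
                                  SourceDynamics(), 0.0, 3, seed=4)
        assert len(eps) == 3
        assert len({ep.participant for ep in eps}) == 3
        assert not np.array_equal(eps[0].data, eps[1].data)


class TestEffectStructure:
    def test_theta_amplitude_ratio_recovered(self):
        d = ExperimentDesign()  # 400 trials
        dyn = SourceDynamics(n_background_cortical_sources=0)
        truth = simulate_source_timecourses(d, dyn, seed=5)
        x = bandpass_theta(truth.signals[:, 0, :], d.fs)
        win = (d.times > 0.3) & (d.times < 3.4)
        rms = np.sqrt((x[:, win] ** 2).mean(axis=1))
        ratio = (rms[truth.condition == "CS-"].mean()
                 / rms[truth.condition == "CS+"].mean())
        cfg = dyn.theta_power_cs_minus / dyn.theta_power_cs_plus
        assert abs(ratio - cfg) / cfg < 0.05

    def test_zero_coupling_gives_near_zero_pli(self):
        d = ExperimentDesign(blocks_per_phase=2, trials_per_block=20)
        dyn = SourceDynamics(coupling_base=0.0, coupling_gain_per_block=0.0,
                             gamma_amps=(0.0, 0.0))
        truth = simulate_source_timecourses(d, dyn, seed=6)
        ph = instantaneous_phase(bandpass_theta(truth.signals[:, 0], d.fs))
        pa = instantaneous_phase(bandpass_theta(truth.signals[:, 2], d.fs))
        signed = pli(ph, pa, signed=True)
        assert abs(signed.mean()) < 0.1

    def test_full_coupling_gives_pli_one(self):
        d = ExperimentDesign(blocks_per_phase=1, trials_per_block=10)
        dyn = SourceDynamics(coupling_base=1.0, coupling_gain_per_block=0.0,
                             gamma_amps=(0.0, 0.0))
        truth = simulate_source_timecourses(d, dyn, seed=7)
        win = (d.times >= 0) & (d.times <= 3.5)
        ph = instantaneous_phase(bandpass_theta(truth.signals[:, 0], d.fs))
        pa = instantaneous_phase(bandpass_theta(truth.signals[:, 2], d.fs))
        vals = pli(ph[:, win], pa[:, win])
        assert np.all(vals > 0.98)

    @pytest.mark.parametrize("strength", [0.0, 0.3, 0.6, 1.0])
    def test_injected_coupling_matches_closed_form(self, strength):
        """Monte-Carlo check of the von-Mises phase-injection model
        against its closed-form expected PLI (on ground-truth phases)."""
        lag = np.pi / 4
        kappa = coupling_kappa(strength, lag)
        rng = np.random.default_rng(int(strength * 10) + 1)
        n_trials, n_draws = 300, 18
        signed = np.empty(n_trials)
        for i in range(n_trials):
            if np.isinf(kappa):
                eps = np.zeros(n_draws)
            elif kappa == 0:
                eps = rng.uniform(-np.pi, np.pi, n_draws)
            else:
                eps = rng.vonmises(0.0, kappa, n_draws)
            d = np.angle(np.exp(1j * (lag + eps)))
            signed[i] = np.sign(d).mean()
        se = signed.std() / np.sqrt(n_trials)
        assert abs(abs(signed.mean()) - strength) < max(3 * se, 0.01)

    def test_zero_lag_coupling_warns(self):
        d = ExperimentDesign(blocks_per_phase=1, trials_per_block=2)
        with pytest.warns(UserWarning, match="zero-lag"):
            simulate_source_timecourses(
                d, SourceDynamics(coupling_lag=0.0), seed=0)

    def test_coupling_strength_grows_on_csplus_only(self):
        dyn = SourceDynamics()
        assert dyn.coupling_strength(10, True) > dyn.coupling_strength(1, True)
        assert dyn.coupling_strength(10, False) == dyn.coupling_strength(1, False)
        assert dyn.coupling_strength(1000, True) <= 1.0

    def test_expected_pli_limits(self):
        assert expected_pli(np.pi / 4, 0.0) == pytest.approx(0.0, abs=1e-12)
        assert expected_pli(np.pi / 4, np.inf) == 1.0


def test_vertex_assignment_respects_regions(anatomy):
    truth = simulate_source_timecourses(
        ExperimentDesign(blocks_per_phase=1, trials_per_block=2),
        SourceDynamics(), seed=0)
    assign_source_vertices(truth, anatomy, np.random.default_rng(0))
    for lbl, v in zip(truth.source_labels, truth.source_vertices):
        region = lbl if lbl in DEEP_LABELS else "cortex"
        sl = anatomy.vertex_slice(region)
        assert sl.start <= v < sl.stop
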