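"""Synthetic two-condition (CS+/CS−) delay-conditioning MEG experiments.

The generator emulates the statistical structure the downstream analysis
assumes: condition-modulated deep theta (CS− > CS+ from ~130 ms after cue
onset), deep gamma, hippocampus–amygdala theta phase coupling whose
strength grows over blocks on CS+ trials only, 1/f cortical background
activity, an evoked broadband burst for the reinforced (US) trials, and
white sensor noise at a configured SNR.  A ground-truth sidecar records
everything needed to reconstruct the noiseless sensor data exactly.

Coupling is injected by construction: the amygdala theta phase equals the
hippocampal phase minus a fixed lag plus von-Mises jitter drawn once per
theta cycle, with the concentration chosen so that the expected
within-trial phase-lag index equals the requested coupling strength —
this gives a closed-form oracle for connectivity tests
(see :func:`coupling_kappa`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.stats import vonmises

from .anatomy import AnatomicalModel
from .forward import LeadField

DEEP_LABELS = ("hippocampus_L", "hippocampus_R", "amygdala_L", "amygdala_R")


@dataclass
class ExperimentDesign:
    """Trial arithmetic of one experimental phase.

    Defaults reproduce the conditioning design: 4 s cues, US onset at
    3.5 s on 50% of CS+ trials during maintenance (never on CS−, never in
    extinction), blocks of 40 trials with equal CS+/CS− counts, 10 blocks
    per phase, epochs of −1..4 s at 600 Hz.
    """

    phase: str = "maintenance"
    blocks_per_phase: int = 10
    trials_per_block: int = 40
    cs_duration: float = 4.0
    us_onset: float = 3.5
    us_duration: float = 0.5
    reinforcement_rate: float = 0.5
    epoch_window: tuple = (-1.0, 4.0)
    fs: float = 600.0

    def __post_init__(self):
        if self.phase not in ("maintenance", "extinction"):
            raise ValueError(f"unknown phase: {self.phase}")
        if self.trials_per_block % 2:
            raise ValueError("trials_per_block must be even (equal CS+/CS-)")

    @property
    def n_trials(self) -> int:
        return self.blocks_per_phase * self.trials_per_block

    @property
    def times(self) -> np.ndarray:
        t0, t1 = self.epoch_window
        n = int(round((t1 - t0) * self.fs))
        return t0 + np.arange(n) / self.fs


@dataclass
class SourceDynamics:
    """Oscillatory content of the simulated deep and cortical sources.

    Amplitudes are in the same arbitrary current units throughout; the
    deep theta amplitudes exceed the per-source cortical background on the
    grounds that the deep structures' high neuronal density lets a small
    activated volume produce a disproportionate source moment.
    """

    theta_freq: float = 5.0
    theta_power_cs_minus: float = 4.5     # CS- theta amplitude (safety)
    theta_power_cs_plus: float = 3.0      # CS+ theta amplitude (threat)
    theta_baseline: float = 3.6           # pre-cue / pre-effect amplitude
    effect_onset: float = 0.13            # s after cue onset
    gamma_freqs: tuple = (40.0, 90.0)
    gamma_amps: tuple = (1.2, 0.9)
    coupling_lag: float = np.pi / 4       # H->A theta phase lag, radians
    coupling_base: float = 0.1            # PLI-scale strength, block 1
    coupling_gain_per_block: float = 0.07  # CS+ increment per block
    n_background_cortical_sources: int = 100
    background_spectrum: float = 1.0      # 1/f exponent
    background_amp: float = 0.45          # RMS per cortical source
    us_burst_amp: float = 2.0
    source_extent_sigma: float = 0.6      # cortical patch extent (0 = points)
    deep_source_extent_sigma: float = 0.2  # deep activated-volume extent

    def __post_init__(self):
        if min(self.theta_power_cs_minus, self.theta_power_cs_plus,
               self.theta_baseline, self.background_amp) < 0:
            raise ValueError("amplitudes must be non-negative")

    def coupling_strength(self, block: int, is_csplus: bool) -> float:
        s = self.coupling_base
        if is_csplus:
            s += self.coupling_gain_per_block * (block - 1)
        return float(np.clip(s, 0.0, 1.0))


@dataclass
class GroundTruth:
    """Oracle sidecar: everything needed to rebuild the noiseless data.

    ``source_patterns`` holds one source-space column per simulated
    source (the spatial extent of the activated patch around its centre
    vertex); the noiseless sensor data are exactly
    gain @ source_patterns @ signals.
    """

    source_labels: list                  # per simulated source
    source_vertices: np.ndarray          # patch centre vertex per source
    signals: np.ndarray                  # (trials, sources, samples)
    condition: np.ndarray                # 'CS+' / 'CS-' per trial
    block: np.ndarray                    # 1-based block per trial
    reinforced: np.ndarray               # bool per trial
    coupling: np.ndarray                 # injected PLI-scale strength per trial
    noise_sigma: float = 0.0
    eyeblink_trials: np.ndarray = field(default_factory=lambda: np.array([], int))
    seed: int = 0
    source_patterns: Optional[np.ndarray] = None   # (n_model_vertices, n_src)


@dataclass
class EpochsData:
    """Trials x channels x samples sensor epochs with labels."""

    data: np.ndarray
    fs: float
    times: np.ndarray
    condition: np.ndarray
    block: np.ndarray
    reinforced: np.ndarray
    participant: str = "P00"
    channel_names: list = field(default_factory=list)
    ground_truth: Optional[GroundTruth] = None

    def __post_init__(self):
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis does not match data")
        if not self.channel_names:
            self.channel_names = [f"MEG{i:03d}" for i in range(self.data.shape[1])]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "EpochsData":
        return EpochsData(self.data.copy(), self.fs, self.times.copy(),
                          self.condition.copy(), self.block.copy(),
                          self.reinforced.copy(), self.participant,
                          list(self.channel_names), self.ground_truth)


# ---------------------------------------------------------------------------
# coupling closed form


def expected_pli(lag: float, kappa: float) -> float:
    """Expected |mean sign of wrapped phase difference| when the phase
    difference is lag + vonMises(0, kappa) jitter, per independent draw."""
    if kappa > 700:
        return 1.0 if np.sin(lag) != 0 else 0.0
    # P(wrapped(lag + eps) in (0, pi]) with eps ~ VM(0, kappa)
    lo = -((lag % (2 * np.pi)))
    p_pos = vonmises.cdf(lo + np.pi, kappa) - vonmises.cdf(lo, kappa)
    return abs(2.0 * p_pos - 1.0)


_KAPPA_CACHE: dict = {}


def coupling_kappa(strength: float, lag: float) -> float:
    """Von-Mises concentration giving an expected PLI equal to ``strength``."""
    if strength <= 0:
        return 0.0
    if strength >= 1 - 1e-9:
        return np.inf
    key = (round(strength, 12), round(lag, 12))
    if key not in _KAPPA_CACHE:
        f = lambda k: expected_pli(lag, k) - strength
        _KAPPA_CACHE[key] = brentq(f, 1e-6, 700.0)
    return _KAPPA_CACHE[key]


# ---------------------------------------------------------------------------
# trial schedule and source signals


def trial_schedule(design: ExperimentDesign, rng: np.random.Generator):
    """Seeded per-trial condition / block / reinforcement labels."""
    n = design.n_trials
    condition = np.empty(n, dtype=object)
    block = np.empty(n, int)
    reinforced = np.zeros(n, bool)
    half = design.trials_per_block // 2
    for b in range(design.blocks_per_phase):
        labels = np.array(["CS+"] * half + ["CS-"] * half, dtype=object)
        rng.shuffle(labels)
        sl = slice(b * design.trials_per_block, (b + 1) * design.trials_per_block)
        condition[sl] = labels
        block[sl] = b + 1
        if design.phase == "maintenance":
            plus = np.flatnonzero(labels == "CS+") + sl.start
            n_reinf = int(round(design.reinforcement_rate * len(plus)))
            reinforced[rng.choice(plus, n_reinf, replace=False)] = True
    return condition.astype(str), block, reinforced


def _one_over_f(rng, n_samples, fs, exponent, n_series):
    """Unit-RMS 1/f^exponent noise via FFT spectral shaping."""
    white = rng.standard_normal((n_series, n_samples))
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(np.fft.rfft(white, axis=1) * shape, n=n_samples, axis=1)
    rms = x.std(axis=1, keepdims=True)
    return x / np.maximum(rms, 1e-30)


def _theta_envelope(times, design, dynamics, amp_cond):
    """Baseline amplitude, 50 ms raised-cosine ramp to the condition
    amplitude starting at the effect onset, held until cue end."""
    a = np.full_like(times, dynamics.theta_baseline)
    t0 = dynamics.effect_onset
    ramp = 0.05
    w = np.clip((times - t0) / ramp, 0.0, 1.0)
    w = 0.5 - 0.5 * np.cos(np.pi * w)
    on = (times >= t0) & (times <= design.cs_duration)
    a[on] = (1 - w[on]) * dynamics.theta_baseline + w[on] * amp_cond
    return a


def simulate_source_timecourses(design: ExperimentDesign,
                                dynamics: SourceDynamics,
                                seed: int = 0) -> GroundTruth:
    """Per-trial current time courses for the deep and background sources.

    Sources (in order): the four deep structures (left/right hemispheres
    of each region share one signal so the injected effects survive
    hemisphere selection downstream), then the cortical background
    sources.  Vertex assignment is done later by the experiment
    orchestrator; ``source_vertices`` is left unset (-1) here.
    """
    import warnings as _w

    if dynamics.coupling_lag == 0 and (
            dynamics.coupling_base > 0 or dynamics.coupling_gain_per_block > 0):
        _w.warn("zero-lag coupling requested: invisible to the phase lag index")

    rng = np.random.default_rng(seed)
    condition, block, reinforced = trial_schedule(design, rng)
    times = design.times
    n_samples = len(times)
    n_trials = design.n_trials
    nb = dynamics.n_background_cortical_sources
    labels = list(DEEP_LABELS) + [f"cortex_bg{i}" for i in range(nb)]
    n_src = len(labels)

    signals = np.zeros((n_trials, n_src, n_samples))
    coupling = np.zeros(n_trials)
    f = dynamics.theta_freq
    cycle = 1.0 / f

    for i in range(n_trials):
        plus = condition[i] == "CS+"
        amp_cond = (dynamics.theta_power_cs_plus if plus
                    else dynamics.theta_power_cs_minus)
        env = _theta_envelope(times, design, dynamics, amp_cond)

        phase0 = rng.uniform(0, 2 * np.pi)
        phi_h = 2 * np.pi * f * times + phase0

        s = dynamics.coupling_strength(block[i], plus)
        coupling[i] = s
        # at exactly zero lag the expected PLI is 0 for any concentration;
        # fall back to the quarter-cycle mapping for the jitter width
        lag_for_kappa = dynamics.coupling_lag or np.pi / 4
        kappa = coupling_kappa(s, lag_for_kappa)
        n_cycles = int(np.ceil((times[-1] - times[0]) / cycle)) + 1
        if np.isinf(kappa):
            eps_c = np.zeros(n_cycles)
        elif kappa == 0:
            eps_c = rng.uniform(-np.pi, np.pi, n_cycles)
        else:
            eps_c = rng.vonmises(0.0, kappa, n_cycles)
        idx = np.minimum(((times - times[0]) / cycle).astype(int), n_cycles - 1)
        phi_a = phi_h - dynamics.coupling_lag + eps_c[idx]

        theta_h = env * np.sin(phi_h)
        theta_a = env * np.sin(phi_a)

        gam = np.zeros(n_samples)
        for gf, ga in zip(dynamics.gamma_freqs, dynamics.gamma_amps):
            gam = gam + ga * np.sin(2 * np.pi * gf * times + rng.uniform(0, 2 * np.pi))
        gam2 = np.zeros(n_samples)
        for gf, ga in zip(dynamics.gamma_freqs, dynamics.gamma_amps):
            gam2 = gam2 + ga * np.sin(2 * np.pi * gf * times + rng.uniform(0, 2 * np.pi))

        signals[i, 0] = theta_h + gam     # hippocampus L
        signals[i, 1] = theta_h + gam     # hippocampus R
        signals[i, 2] = theta_a + gam2    # amygdala L
        signals[i, 3] = theta_a + gam2    # amygdala R

        if nb:
            signals[i, 4:] = dynamics.background_amp * _one_over_f(
                rng, n_samples, design.fs, dynamics.background_spectrum, nb)

        if reinforced[i]:
            on = (times >= design.us_onset) & (times < design.us_onset
                                               + design.us_duration)
            burst = dynamics.us_burst_amp * rng.standard_normal(on.sum())
            for j in range(min(4 + min(nb, 4), n_src)):
                signals[i, j, on] += burst

    return GroundTruth(
        source_labels=labels,
        source_vertices=np.full(n_src, -1, int),
        signals=signals,
        condition=condition,
        block=block,
        reinforced=reinforced,
        coupling=coupling,
        seed=seed,
    )


def assign_source_vertices(truth: GroundTruth, anatomy: AnatomicalModel,
                           rng: np.random.Generator,
                           green: np.ndarray | None = None,
                           gain: np.ndarray | None = None,
                           visibility_quantile: float = 0.5,
                           deep_green: np.ndarray | None = None) -> None:
    """Place each simulated source on a random vertex of its mesh
    (cortical background sources anywhere on the cortex, without
    replacement).

    If a Green's-function matrix is given, each source is an extended
    patch around its centre vertex (unit-norm column of ``green``) —
    emulating an activated cortical/subcortical volume rather than a
    point current.  Otherwise sources are point dipoles.

    If a gain matrix is given, active deep vertices are drawn from the
    sensor-visible part of each mesh (patch lead-field norm above the
    within-mesh ``visibility_quantile``): in a spherical conductor a
    near-radially oriented patch is silent by physics, and the emulated
    experiment presumes a measurable deep signal (coherently oriented,
    dense subnuclei), not a degenerate invisible one.

    ``deep_green`` sets a separate (typically much smaller) extent for
    the deep sources — the activated deep volume is small compared to a
    cortical background patch.
    """
    n_deep = sum(1 for l in truth.source_labels if l in DEEP_LABELS)
    verts = []
    for lbl in truth.source_labels:
        if lbl in DEEP_LABELS:
            sl = anatomy.vertex_slice(lbl)
            pool = np.arange(sl.start, sl.stop)
            if gain is not None:
                ref = deep_green if deep_green is not None else green
                cols = (gain @ ref[:, pool] if ref is not None
                        else gain[:, pool])
                norms = np.linalg.norm(cols, axis=0)
                pool = pool[norms >= np.quantile(norms, visibility_quantile)]
            verts.append(int(rng.choice(pool)))
    n_bg = sum(1 for l in truth.source_labels if l.startswith("cortex_bg"))
    sl = anatomy.vertex_slice("cortex")
    bg = rng.choice(np.arange(sl.start, sl.stop), size=n_bg, replace=False)
    truth.source_vertices = np.array(verts + list(bg), int)

    def patterns_for(indices, g):
        if g is None:
            out = np.zeros((anatomy.n_vertices, len(indices)))
            out[indices, np.arange(len(indices))] = 1.0
            return out
        cols = g[:, indices]
        return cols / np.linalg.norm(cols, axis=0)

    truth.source_patterns = np.hstack([
        patterns_for(truth.source_vertices[:n_deep], deep_green),
        patterns_for(truth.source_vertices[n_deep:], green),
    ])


def project_and_noise(truth: GroundTruth, leadfield: LeadField,
                      design: ExperimentDesign, snr_db: float = 0.0,
                      seed: int = 0, participant: str = "P00",
                      eyeblink_rate: float = 0.0,
                      channel_names=None) -> EpochsData:
    """Project ground-truth sources through the lead field and add white
    sensor noise so the trial-average signal/noise variance ratio equals
    ``snr_db``.  Optionally injects stereotyped low-frequency transients
    on the frontal-most channel on a random subset of trials (eyeblinks).
    """
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    if np.any(truth.source_vertices < 0):
        raise ValueError("source vertices not assigned; run "
                         "assign_source_vertices first")
    rng = np.random.default_rng(seed)
    if truth.source_patterns is not None:
        G = leadfield.gain @ truth.source_patterns         # (Ns, n_src)
    else:
        G = leadfield.gain[:, truth.source_vertices]
    n_trials, _, n_samples = truth.signals.shape
    data = np.matmul(G, truth.signals)                     # (trials, Ns, n)

    sig_var = float(np.mean(data ** 2))
    noise_var = sig_var / (10.0 ** (snr_db / 10.0))
    sigma = np.sqrt(noise_var)
    data += sigma * rng.standard_normal(data.shape)
    truth.noise_sigma = sigma

    if eyeblink_rate > 0:
        n_blink = int(round(eyeblink_rate * n_trials))
        blink_trials = np.sort(rng.choice(n_trials, n_blink, replace=False))
        times = design.times
        t0s = rng.uniform(times[0] + 0.3, times[-1] - 0.3, n_blink)
        # blink artefact lands on channel 0 (the designated frontal channel)
        amp = 20.0 * np.sqrt(sig_var + noise_var)
        for bt, t0 in zip(blink_trials, t0s):
            w = np.exp(-0.5 * ((times - t0) / 0.06) ** 2)
            data[bt, 0] += amp * w
        truth.eyeblink_trials = blink_trials

    return EpochsData(
        data=data, fs=design.fs, times=design.times,
        condition=truth.condition, block=truth.block,
        reinforced=truth.reinforced, participant=participant,
        channel_names=list(channel_names) if channel_names else [],
        ground_truth=truth,
    )


_GREEN_CACHE: dict = {}


def _source_green(anatomy: AnatomicalModel, sigma: float) -> np.ndarray | None:
    """Cached Green's function for extended-source simulation."""
    if sigma == 0:
        return None
    key = (id(anatomy), round(sigma, 6))
    if key not in _GREEN_CACHE:
        from .forward import patch_basis

        # keep only the current anatomy resident
        for k in [k for k in _GREEN_CACHE if k[0] != id(anatomy)]:
            del _GREEN_CACHE[k]
        _GREEN_CACHE[key] = patch_basis(anatomy, sigma).green
    return _GREEN_CACHE[key]


def simulate_experiment(anatomy: AnatomicalModel, leadfield: LeadField,
                        design: ExperimentDesign, dynamics: SourceDynamics,
                        snr_db: float = 0.0, n_participants: int = 5,
                        seed: int = 0,
                        eyeblink_rate: float = 0.0) -> list[EpochsData]:
    """Simulate a cohort: per participant, fresh (jittered) source-vertex
    placement, fresh trial schedule and fresh noise, all derived from the
    master seed.  Sources are extended patches when
    ``dynamics.source_extent_sigma > 0`` (activated volumes, not point
    currents)."""
    ss = np.random.SeedSequence(seed)
    green = _source_green(anatomy, dynamics.source_extent_sigma)
    deep_green = _source_green(anatomy, dynamics.deep_source_extent_sigma)
    out = []
    for p, child in enumerate(ss.spawn(n_participants)):
        s1, s2, s3 = child.generate_state(3) % (2 ** 31)
        truth = simulate_source_timecourses(design, dynamics, seed=int(s1))
        assign_source_vertices(truth, anatomy, np.random.default_rng(int(s2)),
                               green=green, gain=leadfield.gain,
                               deep_green=deep_green)
        out.append(project_and_noise(
            truth, leadfield, design, snr_db=snr_db, seed=int(s3),
            participant=f"P{p:02d}", eyeblink_rate=eyeblink_rate))
    return out
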