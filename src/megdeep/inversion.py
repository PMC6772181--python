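"""Sparse-prior Bayesian source inversion scored by variational free energy.

The generative model for reduced sensor data Y (spatial modes x temporal
modes, per trial) is Y = L J + E with a source covariance built from a
mixture of smooth patch components and an IID sensor noise term:

    Sigma_y = sum_i exp(lambda_i) Q_i ,

where each MSP component Q_i = v_i v_i' is the (rank-one) sensor
projection of one smooth source patch, and one dense component is the
identity (noise).  The log hyperparameters lambda carry Gaussian priors
(shrinkage towards a small value — automatic relevance determination:
patches the data do not support collapse towards the prior).  They are
optimised by Fisher-scoring restricted maximum likelihood, i.e. ascent
on the variational (Laplace) free energy

    F = accuracy - complexity
    accuracy   = -(N_t/2) [ tr(C_y Sigma_y^-1) + ln|Sigma_y| + N_c ln 2*pi ]
    complexity = 1/2 (mu-eta)' Pi (mu-eta) - 1/2 ln|Sigma_lambda Pi|

with C_y the running-average sample covariance and N_t the number of
accumulated samples (trials x temporal modes).  F approximates the log
model evidence and is the model-comparison score.

All components are normalised to unit trace, so the hyperparameter
priors are scale-relative and deep patches are not penalised merely for
their weaker lead fields.

The Empirical Bayesian Beamformer (EBB) replaces the patch mixture by a
single empirical prior whose source variance is the unit-gain beamformer
power estimate q_v = 1/(l_v' C_y^-1 l_v), leaving two hyperparameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .forward import LeadField, PatchBasis
from .preprocess import ReducedData
from .simulate import EpochsData

LN2PI = float(np.log(2.0 * np.pi))


@dataclass
class HyperPriors:
    """Gaussian priors on log hyperparameters (shrinkage / ARD)."""

    eta: float = -4.0
    variance: float = 16.0

    @property
    def precision(self) -> float:
        return 1.0 / self.variance


@dataclass
class HyperParameterState:
    mu: np.ndarray                 # posterior means, log scale
    cov: np.ndarray                # posterior covariance Sigma_lambda
    prior_mean: np.ndarray         # eta
    prior_precision: np.ndarray    # diagonal of Pi


@dataclass
class CovarianceComponents:
    """Sensor-level covariance components with their source-level duals.

    ``sensor_rank1``: (N_c, k) matrix whose column i is v_i with
    Q_i = v_i v_i' (unit trace: |v_i| = 1).  ``source_rank1`` holds the
    matching source patterns g_i (scaled by the same normaliser), so
    C_J = source_rank1 @ diag(exp mu) @ source_rank1'.  Dense components
    (noise identity, EBB empirical prior) follow, with optional diagonal
    source-variance duals.
    """

    sensor_rank1: np.ndarray
    source_rank1: Optional[np.ndarray]
    sensor_dense: list = field(default_factory=list)
    source_diag: list = field(default_factory=list)
    provenance: list = field(default_factory=list)

    @property
    def n_rank1(self) -> int:
        return 0 if self.sensor_rank1 is None else self.sensor_rank1.shape[1]

    @property
    def n_components(self) -> int:
        return self.n_rank1 + len(self.sensor_dense)

    @property
    def n_channels(self) -> int:
        if self.sensor_rank1 is not None and self.sensor_rank1.size:
            return self.sensor_rank1.shape[0]
        return self.sensor_dense[0].shape[0]


@dataclass
class InversionResult:
    F: float
    accuracy: float
    complexity: float
    state: HyperParameterState
    Sigma_y: np.ndarray            # model covariance of the scaled data
    C_y: np.ndarray                # scaled sample covariance
    scale: float                   # C_y_scaled = scale * C_y_raw
    M: np.ndarray                  # inverse operator: sources x spatial modes
    components: CovarianceComponents
    reduced: ReducedData
    converged: bool = True
    F_trajectory: np.ndarray = field(default_factory=lambda: np.array([]))
    restart_F: np.ndarray = field(default_factory=lambda: np.array([]))
    prior_vertices: np.ndarray = field(default_factory=lambda: np.array([], int))
    model_name: str = ""
    algorithm: str = "MSP"

    def currents(self, trial_coefficients: np.ndarray) -> np.ndarray:
        """Posterior currents for reduced coefficients (n_spatial x k)."""
        return self.M @ trial_coefficients

    def expand_currents(self, J_modes: np.ndarray) -> np.ndarray:
        """Expand temporal-mode current coefficients to the sample domain
        through the (rank-limited) temporal basis."""
        return J_modes @ self.reduced.temporal_basis


# ---------------------------------------------------------------------------
# covariance and free energy


def sample_covariance(reduced: ReducedData) -> np.ndarray:
    """Running-average sensor covariance in reduced space:
    C_y = 1/(n_trials * n_temporal) * sum_t Y_t Y_t'."""
    Y = reduced.coefficients
    if Y.shape[0] == 0:
        raise ValueError("no trials to accumulate")
    C = np.einsum("tmk,tnk->mn", Y, Y) / reduced.n_effective
    return 0.5 * (C + C.T)


def _chol_inverse(S: np.ndarray):
    """Cholesky-based inverse and log determinant with escalating jitter."""
    n = S.shape[0]
    jitter = 0.0
    base = max(np.trace(S) / n, 1e-300)
    for _ in range(8):
        try:
            Lc = np.linalg.cholesky(S + jitter * np.eye(n))
            logdet = 2.0 * np.log(np.diag(Lc)).sum()
            inv = np.linalg.inv(Lc)
            return inv.T @ inv, logdet, jitter
        except np.linalg.LinAlgError:
            jitter = base * 1e-10 if jitter == 0 else jitter * 100
    raise np.linalg.LinAlgError("covariance not positive definite")


def free_energy(C_y: np.ndarray, Sigma_y: np.ndarray,
                state: HyperParameterState, N_t: int):
    """Variational free energy F = accuracy - complexity.

    accuracy is the expected Gaussian log likelihood of the N_t reduced
    data vectors under N(0, Sigma_y); complexity is the KL divergence of
    the hyperparameter posterior from its prior.
    """
    n_c = C_y.shape[0]
    try:
        P, logdet, jitter = _chol_inverse(Sigma_y)
    except np.linalg.LinAlgError as e:
        raise FloatingPointError(f"model covariance not PD: {e}") from e
    if jitter > 0:
        raise FloatingPointError("model covariance numerically singular")
    accuracy = -(N_t / 2.0) * (float(np.sum(P * C_y)) + logdet + n_c * LN2PI)
    d = state.mu - state.prior_mean
    pi = state.prior_precision
    sign, logdet_cov = np.linalg.slogdet(state.cov)
    complexity = 0.5 * float(d @ (pi * d)) \
        - 0.5 * (logdet_cov + float(np.log(pi).sum()))
    return accuracy - complexity, accuracy, complexity


# ---------------------------------------------------------------------------
# ReML / variational Laplace


def _build_sigma(comp: CovarianceComponents, lam: np.ndarray) -> np.ndarray:
    k = comp.n_rank1
    n = comp.n_channels
    S = np.zeros((n, n))
    if k:
        V = comp.sensor_rank1
        S += (V * np.exp(lam[:k])[None, :]) @ V.T
    for j, D in enumerate(comp.sensor_dense):
        S += np.exp(lam[k + j]) * D
    return 0.5 * (S + S.T)


def reml_optimize(C_y: np.ndarray, comp: CovarianceComponents, N_t: int,
                  hyperpriors: HyperPriors | None = None,
                  max_iter: int = 128, tol: float = 1e-3,
                  init: np.ndarray | None = None):
    """Fisher-scoring ascent of the free energy over log hyperparameters.

    Returns (state, F, accuracy, complexity, trajectory, converged).
    Components unsupported by the data shrink towards the prior mean
    (ARD).  Steps are halved until F does not decrease, so the returned
    trajectory is non-decreasing to numerical precision.
    """
    hp = hyperpriors or HyperPriors()
    m = comp.n_components
    k = comp.n_rank1
    eta = np.full(m, hp.eta)
    pi = np.full(m, hp.precision)

    lam = eta.copy() if init is None else np.asarray(init, float).copy()
    # start the dense (noise-like) components at the data scale
    n_c = C_y.shape[0]
    for j, D in enumerate(comp.sensor_dense):
        lam[k + j] = max(np.log(max(np.trace(C_y), 1e-300) / max(np.trace(D), 1e-300)) - np.log(2.0), eta[k + j])

    def fisher_and_grad(lam):
        S = _build_sigma(comp, lam)
        P, logdet, jitter = _chol_inverse(S)
        if jitter:
            warnings.warn("jitter regularisation applied to Sigma_y")
        PC = P @ C_y
        w = np.exp(lam)
        g = np.empty(m)
        # Fisher information I_ij = N/2 w_i w_j tr(P Q_i P Q_j) + Pi_ij
        I = np.empty((m, m))
        if k:
            V = comp.sensor_rank1
            PV = P @ V
            # gradients for rank-1 components
            tPQ = np.einsum("ci,ci->i", V, PV)
            PCPV = PC @ PV
            tPCPQ = np.einsum("ci,ci->i", V, PCPV)
            g[:k] = 0.5 * N_t * (tPCPQ - tPQ) * w[:k]
            W = V.T @ PV               # (k, k): v_i' P v_j
            I[:k, :k] = 0.5 * N_t * (W ** 2) * np.outer(w[:k], w[:k])
        for j, D in enumerate(comp.sensor_dense):
            PD = P @ D
            tPQ = np.trace(PD)
            tPCPQ = float(np.sum(PC * PD.T))
            g[k + j] = 0.5 * N_t * (tPCPQ - tPQ) * w[k + j]
            if k:
                V = comp.sensor_rank1
                PV = P @ V
                cross = np.einsum("ci,ci->i", PV, D @ PV)
                I[:k, k + j] = 0.5 * N_t * cross * w[:k] * w[k + j]
                I[k + j, :k] = I[:k, k + j]
            for j2, D2 in enumerate(comp.sensor_dense):
                t = float(np.sum(PD * (P @ D2).T))
                I[k + j, k + j2] = 0.5 * N_t * t * w[k + j] * w[k + j2]
        g -= pi * (lam - eta)
        I[np.diag_indices(m)] += pi
        return g, I

    def f_of(lam):
        S = _build_sigma(comp, lam)
        g, I = fisher_and_grad(lam)
        cov = np.linalg.inv(I)
        state = HyperParameterState(lam.copy(), cov, eta, pi)
        F, acc, cx = free_energy(C_y, S, state, N_t)
        return F, acc, cx, state, g, I

    F, acc, cx, state, g, I = f_of(lam)
    traj = [F]
    converged = False
    for _ in range(max_iter):
        step = np.linalg.solve(I, g)
        step = np.clip(step, -8.0, 8.0)
        # backtracking to guarantee ascent
        improved = False
        for _ in range(24):
            lam_new = lam + step
            try:
                F_new, acc_n, cx_n, state_n, g_n, I_n = f_of(lam_new)
            except (np.linalg.LinAlgError, FloatingPointError):
                step *= 0.5
                continue
            if F_new >= F - 1e-9:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        dF = F_new - F
        lam, F, acc, cx, state, g, I = lam_new, F_new, acc_n, cx_n, state_n, g_n, I_n
        traj.append(F)
        if abs(dF) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("ReML did not converge within max_iter")
    return state, F, acc, cx, np.array(traj), converged


# ---------------------------------------------------------------------------
# component construction


def msp_components(L_modes: np.ndarray, patches: PatchBasis,
                   prior_vertices: np.ndarray) -> CovarianceComponents:
    """One rank-one covariance component per patch seed vertex, plus the
    noise identity.  L_modes is the spatial-mode lead field (N_c x Nsrc)."""
    Gp = patches.green[:, prior_vertices]          # (Nsrc, k)
    V = L_modes @ Gp                               # (N_c, k)
    nrm = np.linalg.norm(V, axis=0)
    keep = nrm > 1e-12 * max(nrm.max(), 1e-300)
    if not np.all(keep):
        warnings.warn(f"dropping {int((~keep).sum())} silent patch components")
    V = V[:, keep] / nrm[keep]
    Gs = Gp[:, keep] / nrm[keep]
    n_c = L_modes.shape[0]
    prov = [{"kind": "patch", "seed_vertex": int(v)}
            for v, k_ in zip(prior_vertices, keep) if k_]
    prov.append({"kind": "noise"})
    return CovarianceComponents(
        sensor_rank1=V, source_rank1=Gs,
        sensor_dense=[np.eye(n_c) / n_c], source_diag=[None],
        provenance=prov,
    )


def ebb_components(L_modes: np.ndarray, C_y: np.ndarray) -> CovarianceComponents:
    """Empirical beamformer-power prior: q_v = 1/(l_v' C_y^-1 l_v)."""
    P, _, _ = _chol_inverse(C_y)
    q = 1.0 / np.einsum("cv,cv->v", L_modes, P @ L_modes)
    Q = (L_modes * q[None, :]) @ L_modes.T
    tr = np.trace(Q)
    n_c = L_modes.shape[0]
    return CovarianceComponents(
        sensor_rank1=np.zeros((n_c, 0)), source_rank1=None,
        sensor_dense=[Q / tr, np.eye(n_c) / n_c],
        source_diag=[q / tr, None],
        provenance=[{"kind": "ebb_prior"}, {"kind": "noise"}],
    )


def _inverse_operator(comp: CovarianceComponents, state: HyperParameterState,
                      L_modes: np.ndarray, Sigma_y: np.ndarray) -> np.ndarray:
    """M = C_J L' Sigma_y^-1 in spatial-mode space (the data scale factor
    cancels between C_J and Sigma_y^-1)."""
    P, _, _ = _chol_inverse(Sigma_y)
    w = np.exp(state.mu)
    k = comp.n_rank1
    M = np.zeros((L_modes.shape[1], L_modes.shape[0]))
    if k:
        V = comp.sensor_rank1
        M += (comp.source_rank1 * w[:k][None, :]) @ (V.T @ P)
    for j, qdiag in enumerate(comp.source_diag):
        if qdiag is not None:
            M += w[k + j] * (qdiag[:, None] * (L_modes.T @ P))
    return M


# ---------------------------------------------------------------------------
# inversion drivers


def _prepare(reduced: ReducedData, L: LeadField):
    L_modes = reduced.spatial_projector.T @ L.gain
    C_raw = sample_covariance(reduced)
    n_c = C_raw.shape[0]
    scale = n_c / max(np.trace(C_raw), 1e-300)
    return L_modes, scale * C_raw, scale


def restart_prior_sets(anatomy, model_name: str, n_priors: int,
                       n_restarts: int, seed: int) -> list:
    """The pseudorandom prior seed-vertex sets of the restart scheme
    (one per restart, fixed allocation proportions)."""
    from .models import allocate_priors

    restart_seeds = np.random.SeedSequence(seed).generate_state(n_restarts) % (2 ** 31)
    return [allocate_priors(model_name, anatomy, n_priors, int(rs))
            for rs in restart_seeds]


def msp_invert(reduced: ReducedData, L: LeadField, patches: PatchBasis,
               anatomy, model_name: str = "HA", n_priors: int = 100,
               n_restarts: int = 16, hyperpriors: HyperPriors | None = None,
               seed: int = 0, max_iter: int = 128, tol: float = 1e-3,
               prior_sets: list | None = None) -> InversionResult:
    """Multiple-sparse-priors inversion with pseudorandom restarts.

    Each restart draws a fresh prior seed set under the model's fixed
    allocation proportions; the restart maximising the free energy is
    retained (all restart F values are returned).  ``prior_sets``
    overrides the drawing — used by the displacement sweep, which must
    evaluate the same mesh-relative prior locations under a moved
    anatomy.
    """
    L_modes, C_y, scale = _prepare(reduced, L)
    N_t = reduced.n_effective
    if prior_sets is None:
        prior_sets = restart_prior_sets(anatomy, model_name, n_priors,
                                        n_restarts, seed)

    best = None
    all_F = []
    for priors in prior_sets:
        comp = msp_components(L_modes, patches, priors.vertices)
        state, F, acc, cx, traj, conv = reml_optimize(
            C_y, comp, N_t, hyperpriors, max_iter=max_iter, tol=tol)
        all_F.append(F)
        if best is None or F > best[1]:
            best = (state, F, acc, cx, traj, conv, comp, priors)
    state, F, acc, cx, traj, conv, comp, priors = best
    Sigma_y = _build_sigma(comp, state.mu)
    M = _inverse_operator(comp, state, L_modes, Sigma_y)
    return InversionResult(
        F=F, accuracy=acc, complexity=cx, state=state, Sigma_y=Sigma_y,
        C_y=C_y, scale=scale, M=M, components=comp, reduced=reduced,
        converged=conv, F_trajectory=traj, restart_F=np.array(all_F),
        prior_vertices=priors.vertices, model_name=model_name,
        algorithm="MSP",
    )


def ebb_invert(reduced: ReducedData, L: LeadField,
               hyperpriors: HyperPriors | None = None,
               model_name: str = "HA", max_iter: int = 128,
               tol: float = 1e-3) -> InversionResult:
    """Empirical Bayesian beamformer inversion (two hyperparameters)."""
    L_modes, C_y, scale = _prepare(reduced, L)
    N_t = reduced.n_effective
    comp = ebb_components(L_modes, C_y)
    state, F, acc, cx, traj, conv = reml_optimize(
        C_y, comp, N_t, hyperpriors, max_iter=max_iter, tol=tol)
    Sigma_y = _build_sigma(comp, state.mu)
    M = _inverse_operator(comp, state, L_modes, Sigma_y)
    return InversionResult(
        F=F, accuracy=acc, complexity=cx, state=state, Sigma_y=Sigma_y,
        C_y=C_y, scale=scale, M=M, components=comp, reduced=reduced,
        converged=conv, F_trajectory=traj, restart_F=np.array([F]),
        model_name=model_name, algorithm="EBB",
    )


def apply_inverse(M: np.ndarray, reduced_or_epochs,
                  spatial_projector: np.ndarray | None = None,
                  vertices: np.ndarray | None = None) -> np.ndarray:
    """Linear read-out of posterior currents.

    For :class:`ReducedData`, returns (trials, sources, n_temporal)
    coefficient currents.  For :class:`EpochsData`, projects each trial
    onto the spatial modes and returns full-band currents
    (trials, sources, samples) — the read-out used for time-frequency
    and connectivity analysis.  ``vertices`` restricts the output rows.
    """
    Msel = M if vertices is None else M[vertices]
    if isinstance(reduced_or_epochs, ReducedData):
        red = reduced_or_epochs
        return np.einsum("vm,tmk->tvk", Msel, red.coefficients)
    epochs: EpochsData = reduced_or_epochs
    if spatial_projector is None:
        raise ValueError("spatial_projector required for full-band read-out")
    if spatial_projector.shape[0] != epochs.n_channels:
        raise ValueError("projector/channel dimension mismatch")
    MU = Msel @ spatial_projector.T        # (V, channels)
    return np.einsum("vc,tcn->tvn", MU, epochs.data)
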