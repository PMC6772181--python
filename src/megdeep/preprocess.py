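"""Sensor-space preprocessing and reduction to spatial/temporal modes.

All filters are zero-phase (applied forward and backward), so in-band
components keep their timing — a requirement for the later phase-based
connectivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .simulate import EpochsData


@dataclass
class ReducedData:
    """Data projected onto orthonormal spatial and temporal modes.

    ``coefficients`` are (trials, n_spatial, n_temporal); the temporal
    basis (n_temporal, n_window_samples) is computed once from the
    trial-averaged, spatially projected data over the analysis window and
    applied identically to every trial, so all trials share one
    covariance model.  ``n_effective`` = trials x n_temporal is the
    sample count entering covariance normalisation.
    """

    coefficients: np.ndarray
    spatial_projector: np.ndarray        # (channels, n_spatial)
    temporal_basis: np.ndarray           # (n_temporal, n_win)
    window: tuple
    fs: float
    n_spatial: int
    n_temporal: int
    condition: np.ndarray = field(default_factory=lambda: np.array([]))
    block: np.ndarray = field(default_factory=lambda: np.array([]))
    participant: str = ""

    @property
    def n_trials(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_effective(self) -> int:
        return self.n_trials * self.n_temporal


def notch_filter(epochs: EpochsData, f0: float = 50.0, q: float = 35.0) -> EpochsData:
    """Zero-phase IIR notch around ``f0`` (second-order section applied
    forward-backward; narrow Q keeps theta-band gain within 2%)."""
    if f0 >= epochs.fs / 2:
        raise ValueError(f"notch frequency {f0} Hz at or above Nyquist")
    b, a = sps.iirnotch(f0, q, fs=epochs.fs)
    out = epochs.copy()
    out.data = sps.filtfilt(b, a, out.data, axis=-1)
    return out


def resample(epochs: EpochsData, fs_new: float = 300.0) -> EpochsData:
    """Polyphase anti-aliased downsampling; sample count scales by
    fs_new/fs (upsampling is refused)."""
    if fs_new > epochs.fs:
        raise ValueError("resample only downsamples (fs_new > fs)")
    if fs_new == epochs.fs:
        return epochs.copy()
    from fractions import Fraction

    frac = Fraction(fs_new / epochs.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = epochs.copy()
    out.data = sps.resample_poly(epochs.data, up, down, axis=-1)
    n_new = out.data.shape[-1]
    out.times = epochs.times[0] + np.arange(n_new) / fs_new
    out.fs = fs_new
    return out


def detect_eyeblinks(epochs: EpochsData, channel: int | str = 0,
                     band: tuple = (1.0, 15.0), z: float = 4.0) -> np.ndarray:
    """Flag trials whose band-filtered designated (frontal) channel
    exceeds ``z`` standard deviations of the pooled trial-by-trial
    distribution.  Flags are returned; trials are never removed."""
    if isinstance(channel, str):
        channel = epochs.channel_names.index(channel)
    x = epochs.data[:, channel, :]
    sos = sps.butter(4, band, btype="bandpass", fs=epochs.fs, output="sos")
    xf = sps.sosfiltfilt(sos, x, axis=-1)
    sd = xf.std()
    if sd == 0:
        raise ValueError("designated channel has zero variance")
    if np.isinf(z):
        return np.zeros(epochs.n_trials, bool)
    return (np.abs(xf) > z * sd).any(axis=1)


def reduce_modes(epochs: EpochsData, projector: np.ndarray,
                 n_temporal: int = 4,
                 window: tuple = (0.0, 3.5)) -> ReducedData:
    """Project epochs onto spatial modes and a shared temporal basis.

    The temporal basis is the top right singular vectors of the
    trial-averaged spatially-projected data over the analysis window;
    the same basis is applied to every trial.
    """
    mask = (epochs.times >= window[0]) & (epochs.times <= window[1])
    n_win = int(mask.sum())
    if n_temporal > n_win:
        raise ValueError(f"n_temporal={n_temporal} exceeds {n_win} samples")
    proj = np.einsum("cm,tcn->tmn", projector, epochs.data[:, :, mask])
    avg = proj.mean(axis=0)
    # full_matrices completes the basis beyond the rank of the average, so
    # n_temporal = n_samples recovers every trial exactly
    full = n_temporal > min(avg.shape)
    _, _, Vt = np.linalg.svd(avg, full_matrices=full)
    basis = Vt[:n_temporal]
    coeff = np.einsum("tmn,kn->tmk", proj, basis)
    return ReducedData(
        coefficients=coeff,
        spatial_projector=projector,
        temporal_basis=basis,
        window=window,
        fs=epochs.fs,
        n_spatial=projector.shape[1],
        n_temporal=n_temporal,
        condition=epochs.condition,
        block=epochs.block,
        participant=epochs.participant,
    )


def preprocess(epochs: EpochsData, notch_f0: float = 50.0,
               fs_new: float = 300.0) -> tuple[EpochsData, dict]:
    """Standard chain: notch, downsample; returns data and a parameter log."""
    out = notch_filter(epochs, notch_f0)
    out = resample(out, fs_new)
    log = {"notch_f0": notch_f0, "notch_q": 35.0, "fs_in": epochs.fs,
           "fs_out": fs_new, "zero_phase": True}
    return out, log
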