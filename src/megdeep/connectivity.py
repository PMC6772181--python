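"""Theta-band phase lag index between hippocampal and amygdalar sources.

The phase lag index (PLI) of two signals is the absolute mean sign of
their wrapped instantaneous phase difference,

    PLI = | (1/T) sum_t sign( wrap(phi_H(t) - phi_A(t)) ) | ,

computed per trial over the post-stimulus window.  It is 0 for no
consistent lag (and, by design, for exactly zero lag — volume-conduction
-like coupling is invisible) and 1 for a constant nonzero phase
difference.  Phases come from the Hilbert transform of the theta-band
(1–8 Hz) signal after a fourth-order bidirectional Butterworth filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

from .oscillations import RegionTimecourse


@dataclass
class PLIRecord:
    trial: int
    condition: str
    block: int
    participant: str
    pli: float


def bandpass_theta(x: np.ndarray, fs: float, band: tuple = (1.0, 8.0),
                   order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass of the stated order per pass."""
    if band[1] >= fs / 2:
        raise ValueError(f"band edge {band[1]} Hz at or above Nyquist")
    sos = butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x, axis=-1)


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Phase angle of the analytic signal, in (-pi, pi]; amplitude
    invariant.

    The analytic signal of a finite window is distorted near its edges;
    callers should supply input extending beyond the interval they
    score (the pipeline's epochs carry a 1 s pre-cue baseline and a
    post-window tail for exactly this reason).
    """
    x = np.asarray(x, float)
    if not np.any(x):
        raise ValueError("phase undefined for all-zero input")
    return np.angle(hilbert(x, axis=-1))


def pli(phase_a: np.ndarray, phase_b: np.ndarray, axis: int = -1,
        signed: bool = False) -> np.ndarray | float:
    """Phase lag index of two equal-length phase series.

    The phase difference is wrapped to (-pi, pi] before taking the sign
    (sign(0) = 0).  ``signed=True`` returns the mean sign without the
    modulus (antisymmetric under swapping the inputs).
    """
    phase_a, phase_b = np.asarray(phase_a), np.asarray(phase_b)
    if phase_a.shape != phase_b.shape:
        raise ValueError("phase series have different shapes")
    d = np.angle(np.exp(1j * (phase_a - phase_b)))
    m = np.mean(np.sign(d), axis=axis)
    return m if signed else np.abs(m)


def trial_pli(tc_a: RegionTimecourse, tc_b: RegionTimecourse,
              window: tuple = (0.0, 3.5), band: tuple = (1.0, 8.0),
              order: int = 4) -> np.ndarray:
    """Per-trial theta PLI between two region time courses.

    Filtering and the Hilbert transform run over the full epoch (the
    baseline second absorbs edge effects); the sign average uses only the
    post-stimulus window.
    """
    if tc_a.series.shape != tc_b.series.shape:
        raise ValueError("region time courses have different shapes")
    pa = instantaneous_phase(bandpass_theta(tc_a.series, tc_a.fs, band, order))
    pb = instantaneous_phase(bandpass_theta(tc_b.series, tc_b.fs, band, order))
    mask = (tc_a.times >= window[0]) & (tc_a.times <= window[1])
    return pli(pa[:, mask], pb[:, mask], axis=-1)


def pli_table(tc_h: RegionTimecourse, tc_a: RegionTimecourse,
              window: tuple = (0.0, 3.5)) -> pd.DataFrame:
    """Tidy per-trial hippocampus–amygdala PLI rows."""
    vals = trial_pli(tc_h, tc_a, window)
    return pd.DataFrame({
        "participant": tc_h.participant,
        "trial": np.arange(len(vals)),
        "condition": tc_h.condition,
        "block": tc_h.block.astype(int),
        "pli": vals,
    })
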