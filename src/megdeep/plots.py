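"""Figures: TF condition-contrast maps and block-trend plots."""

from __future__ import annotations

import numpy as np

from .oscillations import TFDecomposition


def tf_contrast_map(tf: TFDecomposition, cluster_result=None, path=None,
                    fmax: float | None = None):
    """Mean log-power difference between the two conditions over the TF
    plane, with significant-cluster outlines overlaid if a cluster test
    result is supplied.  Saves to ``path`` (PNG/SVG by extension) when
    given; returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    levels = np.unique(tf.condition)
    if len(levels) != 2:
        raise ValueError("need exactly two conditions to contrast")
    eps = tf.power[tf.power > 0].min() * 1e-3 if np.any(tf.power > 0) else 1.0
    logp = np.log(np.maximum(tf.power, eps))
    diff = (logp[tf.condition == levels[0]].mean(axis=0)
            - logp[tf.condition == levels[1]].mean(axis=0))
    fig, ax = plt.subplots(figsize=(7, 4))
    vmax = np.abs(diff).max() or 1.0
    im = ax.pcolormesh(tf.times_ms, tf.freqs, diff, cmap="RdBu_r",
                       vmin=-vmax, vmax=vmax, shading="nearest")
    if cluster_result is not None:
        for c in cluster_result.significant:
            mask = np.zeros(diff.shape, bool)
            mask[c.bins[:, 0], c.bins[:, 1]] = True
            ax.contour(tf.times_ms, tf.freqs, mask, levels=[0.5],
                       colors="grey", linewidths=1.0)
    if fmax:
        ax.set_ylim(tf.freqs[0], fmax)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(f"{tf.region}: mean log power, {levels[0]} - {levels[1]}")
    fig.colorbar(im, ax=ax, label="log-power difference")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def block_trend_plot(table, value: str, path=None, by: str = "condition"):
    """Per-block means of a trial-level value with least-squares linear
    fits, one line per condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for level, sub in table.groupby(by):
        means = sub.groupby("block")[value].mean()
        ax.plot(means.index, means.values, "o", label=str(level))
        slope, icept = np.polyfit(sub["block"].astype(float), sub[value], 1)
        x = np.array([means.index.min(), means.index.max()], float)
        ax.plot(x, icept + slope * x, "-", color=ax.lines[-1].get_color())
    ax.set_xlabel("block")
    ax.set_ylabel(value)
    ax.legend()
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
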