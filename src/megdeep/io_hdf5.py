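"""HDF5 serialisation of epochs and inversion results."""

from __future__ import annotations

import numpy as np

from .simulate import EpochsData, GroundTruth


def save_epochs(path, epochs: EpochsData) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("time", data=epochs.times)
        f.attrs["fs"] = epochs.fs
        f.attrs["participant"] = epochs.participant
        lab = f.create_group("labels")
        lab.create_dataset("condition",
                           data=np.array(epochs.condition, dtype="S"))
        lab.create_dataset("block", data=epochs.block)
        lab.create_dataset("reinforced", data=epochs.reinforced)
        lab.create_dataset("channel",
                           data=np.array(epochs.channel_names, dtype="S"))
        gt = epochs.ground_truth
        if gt is not None:
            g = f.create_group("ground_truth")
            g.create_dataset("signals", data=gt.signals)
            g.create_dataset("source_vertices", data=gt.source_vertices)
            g.create_dataset("source_labels",
                             data=np.array(gt.source_labels, dtype="S"))
            g.create_dataset("coupling", data=gt.coupling)
            if gt.source_patterns is not None:
                g.create_dataset("source_patterns", data=gt.source_patterns)
            g.create_dataset("eyeblink_trials", data=gt.eyeblink_trials)
            g.attrs["noise_sigma"] = gt.noise_sigma
            g.attrs["seed"] = gt.seed


def load_epochs(path) -> EpochsData:
    import h5py

    with h5py.File(path, "r") as f:
        gt = None
        if "ground_truth" in f:
            g = f["ground_truth"]
            gt = GroundTruth(
                source_labels=[s.decode() for s in g["source_labels"][()]],
                source_vertices=g["source_vertices"][()],
                signals=g["signals"][()],
                condition=np.array([s.decode() for s in f["labels/condition"][()]]),
                block=f["labels/block"][()],
                reinforced=f["labels/reinforced"][()],
                coupling=g["coupling"][()],
                noise_sigma=float(g.attrs["noise_sigma"]),
                eyeblink_trials=g["eyeblink_trials"][()],
                seed=int(g.attrs["seed"]),
                source_patterns=(g["source_patterns"][()]
                                 if "source_patterns" in g else None),
            )
        return EpochsData(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            times=f["time"][()],
            condition=np.array([s.decode() for s in f["labels/condition"][()]]),
            block=f["labels/block"][()],
            reinforced=f["labels/reinforced"][()],
            participant=str(f.attrs["participant"]),
            channel_names=[s.decode() for s in f["labels/channel"][()]],
            ground_truth=gt,
        )


def save_leadfield(path, leadfield) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=leadfield.gain)
        f.create_dataset("source_index", data=leadfield.source_index)


def load_leadfield(path):
    import h5py

    from .forward import LeadField

    with h5py.File(path, "r") as f:
        return LeadField(f["gain"][()], f["source_index"][()])


def save_tf(path, tf) -> None:
    """Serialise a TFDecomposition (power + axes + labels)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=tf.power)
        f.create_dataset("freqs", data=tf.freqs)
        f.create_dataset("times_ms", data=tf.times_ms)
        f.attrs["region"] = tf.region
        f.attrs["normalised"] = tf.normalised
        f.attrs["participant"] = tf.participant
        if len(tf.condition):
            f.create_dataset("condition", data=np.array(tf.condition, dtype="S"))
            f.create_dataset("block", data=np.asarray(tf.block, int))


def load_tf(path):
    import h5py

    from .oscillations import TFDecomposition

    with h5py.File(path, "r") as f:
        cond = (np.array([s.decode() for s in f["condition"][()]])
                if "condition" in f else np.array([]))
        block = f["block"][()] if "block" in f else np.array([])
        return TFDecomposition(
            f["power"][()], f["freqs"][()], f["times_ms"][()],
            str(f.attrs["region"]), bool(f.attrs["normalised"]),
            cond, block, str(f.attrs["participant"]))


def save_inversion(path, result) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for k in ("F", "accuracy", "complexity", "scale"):
            f.attrs[k] = getattr(result, k)
        f.attrs["model_name"] = result.model_name
        f.attrs["algorithm"] = result.algorithm
        f.attrs["converged"] = result.converged
        f.create_dataset("M", data=result.M)
        f.create_dataset("Sigma_y", data=result.Sigma_y)
        f.create_dataset("C_y", data=result.C_y)
        f.create_dataset("restart_F", data=result.restart_F)
        f.create_dataset("F_trajectory", data=result.F_trajectory)
        f.create_dataset("prior_vertices", data=result.prior_vertices)
        g = f.create_group("hyperparameters")
        g.create_dataset("mu", data=result.state.mu)
        g.create_dataset("cov", data=result.state.cov)
        g.create_dataset("prior_mean", data=result.state.prior_mean)
        g.create_dataset("prior_precision", data=result.state.prior_precision)
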