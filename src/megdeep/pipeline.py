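"""End-to-end orchestration: simulate -> preprocess -> invert -> compare ->
oscillations -> connectivity -> statistics, from one JSON config.

Every stage writes its artefacts (HDF5/CSV/JSON) into the run directory
and the final summary names the file behind every number it reports.
All randomness descends from the single master seed, so a rerun with
the same config is reproducible.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .anatomy import GeometryConfig, build_synthetic_anatomy
from .connectivity import pli_table
from .forward import (fit_sphere, helmet_sensors, leadfield_sphere,
                      patch_basis, spatial_projector)
from .inversion import msp_invert
from .io_hdf5 import save_epochs, save_inversion
from .models import InversionConfig, compare_models, displacement_sweep
from .oscillations import band_power_table, morlet_tf, normalize_power, select_max_source
from .preprocess import preprocess, reduce_modes
from .simulate import ExperimentDesign, SourceDynamics, simulate_experiment
from .stats import bonferroni, pli_lme, posthoc_time_trend, power_lme


@dataclass
class RunConfig:
    """Validated top-level configuration (JSON-serialisable)."""

    seed: int = 0
    n_participants: int = 2
    n_sensors: int = 100
    helmet_radius: float = 55.0
    snr_db: float = 0.0
    n_spatial_modes: int = 120
    n_temporal_modes: int = 4
    geometry: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)
    dynamics: dict = field(default_factory=dict)
    inversion: dict = field(default_factory=dict)
    models: list = field(default_factory=lambda: ["C", "H", "A", "HA"])
    sweep_axes: list = field(default_factory=lambda: ["AP"])
    sweep_distances: list = field(default_factory=lambda: [0, 1, 2, 3, 5, 10])
    run_sweep: bool = False
    tf_window: list = field(default_factory=lambda: [-1.0, 3.5])
    pli_window: list = field(default_factory=lambda: [0.0, 3.5])
    analysis_model: str = "HA"

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        bad = sorted(set(raw) - known)
        if bad:
            raise ValueError(f"unknown config keys: {bad}")
        for block, allowed in (
                ("geometry", GeometryConfig.__dataclass_fields__),
                ("design", ExperimentDesign.__dataclass_fields__),
                ("dynamics", SourceDynamics.__dataclass_fields__),
                ("inversion", InversionConfig.__dataclass_fields__)):
            bad = sorted(set(raw.get(block, {})) - set(allowed))
            if bad:
                raise ValueError(f"unknown keys in config block "
                                 f"'{block}': {bad}")
        return cls(**raw)


class StageError(RuntimeError):
    pass


def run_pipeline(config: RunConfig | dict | str, outdir,
                 stages=("simulate", "compare", "sweep", "oscillations",
                         "stats")) -> dict:
    """Run the pipeline and return the summary dict (also written to
    ``summary.json``)."""
    if isinstance(config, (str, Path)):
        config = RunConfig.from_json(config)
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    summary: dict = {"version": __version__, "seed": config.seed,
                     "config": asdict(config), "artefacts": {}}

    # --- geometry / forward (deterministic given seed) -------------------
    geo = GeometryConfig(**config.geometry)
    anatomy = build_synthetic_anatomy(geo, seed=config.seed)
    center, _ = fit_sphere(anatomy)
    sensors = helmet_sensors(config.n_sensors, radius=config.helmet_radius,
                             sphere_origin=center)
    L = leadfield_sphere(anatomy, sensors)
    U = spatial_projector(L, min(config.n_spatial_modes, sensors.n_sensors))
    design = ExperimentDesign(**config.design)
    dynamics = SourceDynamics(**config.dynamics)
    inv_cfg = InversionConfig(**config.inversion)

    # --- simulate + preprocess -------------------------------------------
    if "simulate" not in stages:
        raise StageError("resume without the simulate stage is not "
                         "supported: upstream epochs are not on disk")
    cohort = simulate_experiment(anatomy, L, design, dynamics,
                                 snr_db=config.snr_db,
                                 n_participants=config.n_participants,
                                 seed=config.seed)
    reduced_task, reduced_full, epochs_pp = [], [], []
    for ep in cohort:
        save_epochs(out / f"epochs_{ep.participant}.h5", ep)
        pp, _ = preprocess(ep)
        epochs_pp.append(pp)
        reduced_task.append(reduce_modes(pp, U, config.n_temporal_modes,
                                         window=(0.0, design.us_onset)))
        reduced_full.append(reduce_modes(pp, U, config.n_temporal_modes,
                                         window=tuple(config.tf_window)))
    summary["artefacts"]["epochs"] = [f"epochs_{ep.participant}.h5"
                                      for ep in cohort]

    # --- model comparison -------------------------------------------------
    if "compare" in stages:
        cmp_ = compare_models(reduced_task, anatomy, sensors,
                              tuple(config.models), inv_cfg,
                              seed=config.seed, leadfield=L)
        cmp_.table().to_csv(out / "model_comparison.csv", index=False)
        summary["artefacts"]["model_comparison"] = "model_comparison.csv"
        summary["model_comparison"] = {
            "F_sum": cmp_.F_sum, "dF": cmp_.dF,
            "decisive": cmp_.decisive, "winner": cmp_.winner}

    # --- displacement sweep ----------------------------------------------
    if "sweep" in stages and config.run_sweep:
        sw = displacement_sweep(reduced_task, anatomy, sensors,
                                axes=tuple(config.sweep_axes),
                                distances=tuple(config.sweep_distances),
                                config=inv_cfg, seed=config.seed)
        pd.concat([s.to_frame() for s in sw]).to_csv(
            out / "displacement_sweep.csv", index=False)
        summary["artefacts"]["displacement_sweep"] = "displacement_sweep.csv"
        summary["displacement_sweep"] = {
            s.axis: {"distances": s.distances.tolist(),
                     "dF": s.dF.tolist()} for s in sw}

    if not ({"oscillations", "stats"} & set(stages)):
        summary["runtime_s"] = time.time() - t_start
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        return summary

    # --- oscillations + PLI on the analysis model -------------------------
    patches = patch_basis(anatomy, inv_cfg.sigma)
    power_rows, pli_rows = [], []
    for pp, red in zip(epochs_pp, reduced_full):
        res = msp_invert(red, L, patches, anatomy, config.analysis_model,
                         n_priors=inv_cfg.n_priors,
                         n_restarts=inv_cfg.n_restarts,
                         hyperpriors=inv_cfg.hyperpriors, seed=config.seed)
        save_inversion(out / f"inversion_{pp.participant}.h5", res)
        tcs = {r: select_max_source(res, pp, anatomy, r)
               for r in ("hippocampus", "amygdala")}
        tfs = [morlet_tf(tc.series, pp.fs, pp.times, region=r,
                         condition=tc.condition, block=tc.block,
                         participant=pp.participant)
               for r, tc in tcs.items()]
        tfs = normalize_power(tfs)
        last_tfs = tfs
        power_rows.append(band_power_table(tfs))
        pli_rows.append(pli_table(tcs["hippocampus"], tcs["amygdala"],
                                  window=tuple(config.pli_window)))
    power_tbl = pd.concat(power_rows, ignore_index=True)
    pli_tbl = pd.concat(pli_rows, ignore_index=True)
    power_tbl.to_csv(out / "band_power.csv", index=False)
    pli_tbl.to_csv(out / "pli.csv", index=False)
    summary["artefacts"]["band_power"] = "band_power.csv"
    summary["artefacts"]["pli"] = "pli.csv"

    from .plots import block_trend_plot, tf_contrast_map

    tf_contrast_map(last_tfs[-1], path=out / "tf_contrast.png", fmax=30)
    block_trend_plot(pli_tbl, "pli", path=out / "pli_block_trend.png")
    summary["artefacts"]["figures"] = ["tf_contrast.png",
                                       "pli_block_trend.png"]

    # --- statistics --------------------------------------------------------
    if "stats" in stages:
        stats_report = {}
        if config.n_participants >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                band_res = {}
                for band in ("theta", "low_gamma", "high_gamma"):
                    r = power_lme(power_tbl, band)
                    band_res[band] = {
                        "terms": r.terms.to_dict("records"),
                        "CS_p_bonferroni": bonferroni(
                            min(max(r.p("CS"), 1e-300), 1.0), 3),
                        "converged": r.converged}
                stats_report["power_lme"] = band_res
                rp = pli_lme(pli_tbl)
                stats_report["pli_lme"] = {
                    "terms": rp.terms.to_dict("records"),
                    "converged": rp.converged}
                post = {}
                for cond in ("CS+", "CS-"):
                    rt = posthoc_time_trend(pli_tbl, cond)
                    post[cond] = {"slope": rt.estimate("Time"),
                                  "p": rt.p("Time")}
                stats_report["pli_posthoc_time"] = post
        with open(out / "stats_report.json", "w") as fh:
            json.dump(stats_report, fh, indent=2, default=str)
        summary["artefacts"]["stats_report"] = "stats_report.json"
        summary["stats"] = stats_report

    summary["runtime_s"] = time.time() - t_start
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
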