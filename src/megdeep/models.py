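"""Anatomical model variants, free-energy comparison and displacement sweep.

All MSP model variants share one head model (every mesh) and one lead
field; a variant is defined purely by how the fixed number of sparse
priors is allocated across meshes (all-cortex for model C; 10% moved to
the hippocampus and/or amygdala for H, A, HA).  Keeping the component
count, restart count and mode counts identical across variants makes the
model comparison an equal-complexity comparison by construction.

A free-energy difference of 3 log units (about 20:1 evidence ratio) is
treated as decisive.  For group conclusions F is summed across
participants (fixed-effects convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anatomy import (AXES, AnatomicalModel, GeometryError,
                      displace_deep_meshes, points_inside_surface)
from .forward import LeadField, PatchBasis, leadfield_sphere, patch_basis
from .inversion import HyperPriors, InversionResult, ebb_invert, msp_invert
from .preprocess import ReducedData

DECISIVE_DF = 3.0  # log-evidence units; exp(3) ~ 20:1

MODEL_ALLOCATIONS = {
    "C": {"cortex": 1.0},
    "H": {"cortex": 0.9, "hippocampus": 0.1},
    "A": {"cortex": 0.9, "amygdala": 0.1},
    "HA": {"cortex": 0.8, "hippocampus": 0.1, "amygdala": 0.1},
}


@dataclass
class PriorSet:
    vertices: np.ndarray           # global seed vertex indices
    allocation: dict               # proportion per region
    n_priors: int
    seed: int


@dataclass
class ModelComparison:
    models: list
    F: pd.DataFrame                # rows: participant, columns: model
    F_sum: dict
    dF: dict                       # vs reference model C (summed)
    decisive: dict
    winner: str
    reference: str = "C"
    results: dict = field(default_factory=dict)   # model -> list[InversionResult]

    def table(self) -> pd.DataFrame:
        rows = []
        for m in self.models:
            for p in self.F.index:
                rows.append({"model": m, "participant": p,
                             "F": self.F.loc[p, m],
                             "dF": self.F.loc[p, m] - self.F.loc[p, self.reference]})
            rows.append({"model": m, "participant": "sum",
                         "F": self.F_sum[m], "dF": self.dF[m],
                         "decisive": self.decisive[m]})
        return pd.DataFrame(rows)


def allocate_priors(model_name: str, anatomy: AnatomicalModel,
                    n_priors: int = 100, seed: int = 0) -> PriorSet:
    """Draw pseudorandom prior seed vertices under a model's fixed
    allocation proportions.

    Deep-region allocations are split evenly between hemispheres;
    sampling is uniform over mesh vertices without replacement.  A deep
    mesh smaller than its allocation is sampled with replacement and
    collapsed to the unique set (with a warning), as can happen for a
    coarse amygdala with many priors.
    """
    if model_name not in MODEL_ALLOCATIONS:
        raise ValueError(f"unknown model '{model_name}'")
    alloc = MODEL_ALLOCATIONS[model_name]
    rng = np.random.default_rng(seed)

    deep_counts = {}
    for region, prop in alloc.items():
        if region != "cortex":
            deep_counts[region] = int(round(prop * n_priors))
    n_cortex = n_priors - sum(deep_counts.values())

    chosen = []
    sl = anatomy.vertex_slice("cortex")
    pool = np.arange(sl.start, sl.stop)
    if n_cortex > len(pool):
        raise ValueError("cortex mesh smaller than its prior allocation")
    chosen.append(rng.choice(pool, n_cortex, replace=False))

    for region, count in deep_counts.items():
        halves = (count // 2, count - count // 2)
        for hemi, c in zip(("L", "R"), halves):
            sl = anatomy.vertex_slice(f"{region}_{hemi}")
            pool = np.arange(sl.start, sl.stop)
            if c <= len(pool):
                chosen.append(rng.choice(pool, c, replace=False))
            else:
                warnings.warn(
                    f"{region}_{hemi} has {len(pool)} vertices for {c} "
                    "priors; sampling with replacement, collapsed to the "
                    "unique set")
                chosen.append(np.unique(rng.choice(pool, c, replace=True)))
    return PriorSet(np.concatenate(chosen), alloc, n_priors, seed)


@dataclass
class InversionConfig:
    algorithm: str = "MSP"
    n_priors: int = 100
    n_restarts: int = 16
    sigma: float = 0.6
    hyperpriors: HyperPriors = field(default_factory=HyperPriors)
    max_iter: int = 128
    tol: float = 1e-3


def _invert_one(reduced: ReducedData, anatomy: AnatomicalModel,
                L: LeadField, patches: PatchBasis, model_name: str,
                cfg: InversionConfig, seed: int) -> InversionResult:
    if cfg.algorithm.upper() == "MSP":
        return msp_invert(reduced, L, patches, anatomy, model_name,
                          n_priors=cfg.n_priors, n_restarts=cfg.n_restarts,
                          hyperpriors=cfg.hyperpriors, seed=seed,
                          max_iter=cfg.max_iter, tol=cfg.tol)
    if cfg.algorithm.upper() == "EBB":
        labels = ["cortex"]
        if "H" in model_name:
            labels += ["hippocampus_L", "hippocampus_R"]
        if "A" in model_name:
            labels += ["amygdala_L", "amygdala_R"]
        idx = anatomy.global_indices(labels)
        Lsub = LeadField(L.gain[:, idx], idx)
        res = ebb_invert(reduced, Lsub, cfg.hyperpriors, model_name,
                         max_iter=cfg.max_iter, tol=cfg.tol)
        return res
    raise ValueError(f"unknown algorithm '{cfg.algorithm}'")


def compare_models(reduced, anatomy: AnatomicalModel, sensors,
                   model_names=("C", "H", "A", "HA"),
                   config: InversionConfig | None = None, seed: int = 0,
                   leadfield: LeadField | None = None,
                   patches: PatchBasis | None = None,
                   reference: str = "C") -> ModelComparison:
    """Invert every model variant on the same data and compare free
    energies against the reference (cortex-only) model.

    ``reduced`` may be one ReducedData or a list (one per participant);
    group F values are summed across participants.  Restart seeds are
    paired across models (restart k uses the same seed in every model).
    """
    cfg = config or InversionConfig()
    if reference not in model_names:
        raise ValueError(f"reference model '{reference}' not among {model_names}")
    red_list = reduced if isinstance(reduced, (list, tuple)) else [reduced]
    mode_counts = {(r.n_spatial, r.n_temporal) for r in red_list}
    if len(mode_counts) != 1:
        raise ValueError("inconsistent mode counts across participants")

    L = leadfield if leadfield is not None else leadfield_sphere(anatomy, sensors)
    P = patches if patches is not None else patch_basis(anatomy, cfg.sigma)

    F = pd.DataFrame(index=[r.participant or f"P{i:02d}"
                            for i, r in enumerate(red_list)],
                     columns=list(model_names), dtype=float)
    results = {m: [] for m in model_names}
    for i, red in enumerate(red_list):
        part_seed = (seed + 7919 * i) % (2 ** 31)
        for m in model_names:
            res = _invert_one(red, anatomy, L, P, m, cfg, part_seed)
            results[m].append(res)
            F.iloc[i, F.columns.get_loc(m)] = res.F

    # equal-complexity guard: identical component/restart/mode counts
    counts = {m: (results[m][0].components.n_components,
                  len(results[m][0].restart_F)) for m in model_names}
    if cfg.algorithm.upper() == "MSP" and len(set(counts.values())) != 1:
        warnings.warn(f"component counts differ across models: {counts}")

    F_sum = {m: float(F[m].sum()) for m in model_names}
    dF = {m: F_sum[m] - F_sum[reference] for m in model_names}
    decisive = {m: bool(abs(dF[m]) >= DECISIVE_DF) for m in model_names}
    winner = max(F_sum, key=F_sum.get)
    return ModelComparison(list(model_names), F, F_sum, dF, decisive,
                           winner, reference, results)


@dataclass
class DisplacementResult:
    axis: str
    distances: np.ndarray
    F: np.ndarray                  # per distance (summed over participants)
    F0: float                      # undisplaced

    @property
    def dF(self) -> np.ndarray:
        return self.F - self.F0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"axis": self.axis, "distance_mm": self.distances,
                             "F": self.F, "dF": self.dF})


def displacement_sweep(reduced, anatomy: AnatomicalModel, sensors,
                       axes=("AP",), distances=(0, 1, 2, 3, 5, 10),
                       config: InversionConfig | None = None, seed: int = 0,
                       model_name: str = "HA") -> list[DisplacementResult]:
    """Model-evidence cost of rigidly mistranslating the deep meshes.

    For each displacement the deep meshes (and the sources riding on
    them) move; the lead field is rebuilt; the same prior seed vertices
    are reused (mesh-relative locations), and the drop in free energy
    relative to the true anatomy is recorded.  Displacements that push a
    deep mesh outside the cortical shell are skipped with a warning.
    """
    from .inversion import restart_prior_sets

    cfg = config or InversionConfig()
    red_list = reduced if isinstance(reduced, (list, tuple)) else [reduced]
    patches = patch_basis(anatomy, cfg.sigma)   # translation-invariant
    cortex = anatomy.mesh("cortex")

    # the same mesh-relative prior seed sets are evaluated under every
    # displacement (the sources ride with the meshes); only the lead
    # field changes, so the comparison is free of restart-draw noise
    part_priors = [restart_prior_sets(anatomy, model_name, cfg.n_priors,
                                      cfg.n_restarts,
                                      (seed + 7919 * i) % (2 ** 31))
                   for i in range(len(red_list))]

    L0 = leadfield_sphere(anatomy, sensors)
    F0 = 0.0
    for i, red in enumerate(red_list):
        F0 += msp_invert(red, L0, patches, anatomy, model_name,
                         n_priors=cfg.n_priors, hyperpriors=cfg.hyperpriors,
                         max_iter=cfg.max_iter, tol=cfg.tol,
                         prior_sets=part_priors[i]).F

    out = []
    for axis_name in axes:
        axis = AXES[axis_name] if isinstance(axis_name, str) else np.asarray(axis_name)
        ds, Fs = [], []
        for d in distances:
            if d == 0:
                ds.append(0.0)
                Fs.append(F0)
                continue
            moved = displace_deep_meshes(anatomy, axis, float(d))
            deep_ok = all(
                points_inside_surface(m.vertices, cortex).all()
                for m in moved.meshes if m.label != "cortex")
            if not deep_ok:
                warnings.warn(f"displacement {d} mm along {axis_name} "
                              "pushes a deep mesh outside the cortex; skipped")
                continue
            try:
                Ld = leadfield_sphere(moved, sensors)
            except ValueError:
                warnings.warn(f"displacement {d} mm along {axis_name} "
                              "leaves the conductor sphere; skipped")
                continue
            Fd = 0.0
            for i, red in enumerate(red_list):
                Fd += msp_invert(red, Ld, patches, moved, model_name,
                                 n_priors=cfg.n_priors,
                                 hyperpriors=cfg.hyperpriors,
                                 max_iter=cfg.max_iter, tol=cfg.tol,
                                 prior_sets=part_priors[i]).F
            ds.append(float(d))
            Fs.append(Fd)
        if not ds:
            raise GeometryError(f"all displacements along {axis_name} skipped")
        out.append(DisplacementResult(str(axis_name), np.array(ds),
                                      np.array(Fs), F0))
    return out
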