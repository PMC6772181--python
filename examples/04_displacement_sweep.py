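"""Spatial sensitivity: what mislocating the deep meshes costs in evidence.

Re-inverts the same data after rigidly displacing the hippocampus and
amygdala meshes along the anterior-posterior axis, reusing the same
prior seed vertices (the sources ride with the meshes).  Prints the
free-energy drop per displacement; a drop beyond 3 log units is a
decisive worsening.
"""

import warnings

from megdeep import (ExperimentDesign, InversionConfig, SourceDynamics,
                     build_synthetic_anatomy, displacement_sweep, fit_sphere,
                     helmet_sensors, leadfield_sphere, preprocess,
                     reduce_modes, simulate_experiment, spatial_projector)

warnings.simplefilter("ignore")

anatomy = build_synthetic_anatomy(seed=0)
center, _ = fit_sphere(anatomy)
sensors = helmet_sensors(100, radius=55.0, sphere_origin=center)
L = leadfield_sphere(anatomy, sensors)
U = spatial_projector(L, 120)

design = ExperimentDesign(trials_per_block=10)     # 100 trials
epochs = simulate_experiment(anatomy, L, design, SourceDynamics(),
                             snr_db=0.0, n_participants=1, seed=11)[0]
pp, _ = preprocess(epochs)
reduced = reduce_modes(pp, U, 4, window=(0.0, 3.5))

sweep = displacement_sweep(reduced, anatomy, sensors, axes=("AP",),
                           distances=(0, 1, 2, 3, 5, 10),
                           config=InversionConfig(n_restarts=8), seed=5)[0]
print(sweep.to_frame().to_string(index=False))
print("\ndF is the evidence lost by mistranslating the deep meshes; a"
      "\ndecisive (< -3) drop within a few mm shows the reconstruction is"
      "\nsensitive to the true deep anatomy.  Single datasets are noisy -"
      "\nthe validation suite uses the median curve over seeded datasets.")
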