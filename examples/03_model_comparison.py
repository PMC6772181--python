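"""Anatomical model comparison by variational free energy.

Simulates a participant with active deep sources, inverts the data under
the four model variants — priors all on the cortex (C), or with 10%
moved to the hippocampus (H), amygdala (A), or both (HA) — and compares
free energies against the cortex-only baseline.  A difference of 3 log
units (~20:1 evidence) is decisive.
"""

import warnings

from megdeep import (ExperimentDesign, InversionConfig, SourceDynamics,
                     build_synthetic_anatomy, compare_models, fit_sphere,
                     helmet_sensors, leadfield_sphere, preprocess,
                     reduce_modes, simulate_experiment, spatial_projector)

warnings.simplefilter("ignore")

anatomy = build_synthetic_anatomy(seed=0)
center, _ = fit_sphere(anatomy)
sensors = helmet_sensors(100, radius=55.0, sphere_origin=center)
L = leadfield_sphere(anatomy, sensors)
U = spatial_projector(L, 120)

design = ExperimentDesign(trials_per_block=20)     # 200 trials
epochs = simulate_experiment(anatomy, L, design, SourceDynamics(),
                             snr_db=0.0, n_participants=1, seed=42)[0]
pp, _ = preprocess(epochs)                         # notch + 300 Hz
reduced = reduce_modes(pp, U, 4, window=(0.0, 3.5))

cmp_ = compare_models(reduced, anatomy, sensors, ("C", "H", "A", "HA"),
                      InversionConfig(n_restarts=16), seed=7, leadfield=L)
print("model  F (rel. to C)  decisive")
for m in cmp_.models:
    print(f"  {m:3s}  {cmp_.dF[m]:12.1f}  {cmp_.decisive[m]}")
print(f"winner: {cmp_.winner}")
print("\nPositive dF means the variant explains the sensor data better"
      "\nthan cortex-only priors at identical model complexity; with the"
      "\ngenerator's active deep sources the deep variants win decisively.")
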