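"""Build the synthetic head model and inspect its forward physics.

Constructs the labelled source space (deformed-sphere cortex plus
ellipsoidal hippocampi and amygdalae), fits the conductor sphere, places
a gradiometer helmet and computes the lead field.  Prints mesh statistics
and the depth penalty: how much weaker deep sources are at the sensors.
"""

import numpy as np

from megdeep import (build_synthetic_anatomy, fit_sphere, helmet_sensors,
                     leadfield_sphere, mesh_stats)

anatomy = build_synthetic_anatomy(seed=0)
print("source space:")
for mesh in anatomy.meshes:
    s = mesh_stats(mesh)
    print(f"  {mesh.label:15s} {s.vertex_count:4d} vertices, "
          f"mean edge {s.mean_edge_length:.2f} mm, "
          f"volume {s.volume:8.1f} mm^3")

center, radius = fit_sphere(anatomy)
print(f"\nconductor sphere: centre {np.round(center, 1)} mm, "
      f"radius {radius:.1f} mm")

sensors = helmet_sensors(100, radius=55.0, sphere_origin=center)
L = leadfield_sphere(anatomy, sensors)
print(f"lead field: {L.gain.shape[0]} sensors x {L.gain.shape[1]} sources")

norms = np.linalg.norm(L.gain, axis=0)
for label in anatomy.labels:
    sl = anatomy.vertex_slice(label)
    print(f"  median |gain| {label:15s} {np.median(norms[sl]):.2e}")
print("\nThe deep-structure gains are of the same order as cortical ones"
      "\nhere because the near-radial cortical normals are partly silent"
      "\nin a spherical conductor; depth alone attenuates deep sources.")
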