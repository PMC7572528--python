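"""Guiding larvae across the display with a moving ring of light.

A white annulus (17 mm inner / 47 mm outer diameter) translates at
0.17 mm/s.  Photo-avoiding larvae placed in the dark safe zone turn away
whenever they approach the lit ring, so the moving pattern drags them
along; light-indifferent controls wander off.  The confinement is scored
by the prisoner index (time inside the safe zone / total time) and the
mean x-velocity, which for confined animals must match the ring speed.
"""

import numpy as np

from optoscreen import mean_x_velocity, prisoner_index, t_statistics
from optoscreen.simulator import ring_experiment, simulate

for mode, label in (("avoid", "photo-avoiding"), ("none", "control")):
    config, params, safe = ring_experiment(mode=mode, n_agents=10, seed=11)
    tracks = simulate(config, params)
    pis = [prisoner_index(tr, safe) for tr in tracks]
    vxs = [mean_x_velocity(tr) for tr in tracks]
    sem = lambda v: np.std(v, ddof=1) / np.sqrt(len(v))
    print(f"{label} cohort (n=10, 21.5 min):")
    print(f"  prisoner index  {np.mean(pis):.2f} +/- {sem(pis):.2f}")
    print(f"  <v_x>           {np.mean(vxs):.3f} +/- {sem(vxs):.3f} mm/s "
          f"(ring speed 0.17 mm/s)")
    t, df, p = t_statistics(vxs, 0.0)
    print(f"  one-sample t vs 0 mm/s: t={t:.1f}, p={p:.2g}\n")

print("Avoiders are dragged along at the ring speed (prisoner index 1.0);")
print("controls drift at ~0 mm/s and leave the safe zone almost immediately.")
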