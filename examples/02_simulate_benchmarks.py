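"""Generate the two synthetic reaction-diffusion benchmarks.

The 2-D system couples two species through a saturating rational
interaction; the 1-D system is a pollen-tube-type model with a fractional
power, a nonlocal integral term and a rational calcium feedback.  Both are
integrated with the zero-flux (mirror) boundary and observed with
proportional Gaussian noise.
"""

import numpy as np

from fracpde import datagen as dg

d1 = dg.make_example_dataset(1, noise_level=0.05, seed=0, n_init=4,
                             n_space=32, sizes=(2, 1, 1))
tr = d1["train"]
print("2-D benchmark (scaled): train", tr.u.shape,
      f"u in [{tr.u.min():.2f}, {tr.u.max():.2f}]",
      f"dt_obs={d1['dt_obs']}, grid {d1['grid'].n_points}^2")

d2 = dg.make_example_dataset(2, noise_level=0.01, seed=0, n_init=6,
                             sizes=(4, 1, 1))
tr2 = d2["train"]
print("1-D benchmark: train", tr2.u.shape,
      f"u in [{tr2.u.min():.4f}, {tr2.u.max():.4f}]",
      f"dt_obs={d2['dt_obs']}, grid {d2['grid'].n_points}")
mass = (tr2.u[:, 0] * d2["grid"].quad_weights).sum(axis=-1)
print("per-trajectory initial mass of u:", np.round(mass, 3))
print(
    "\nThe 1-D trajectories mix relaxed pattern states (burn-in) with"
    "\nlong-wavelength transient states of diverse mass; the transients"
    "\ncarry the information that identifies the large diffusivity and the"
    "\nnonlocal term."
)
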