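"""Repeated-discovery stability study (optional, slow).

Runs the 1-D discovery pipeline over several random seeds and tabulates
which terms are recovered and how the key coefficients spread.  Increase
``N_REPLICATES`` for a fuller picture; each replicate takes a few minutes.
"""

import numpy as np

from fracpde import datagen as dg
from fracpde.pipeline import ExperimentConfig, fit_pipeline

N_REPLICATES = 3

rows = []
for seed in range(1, N_REPLICATES + 1):
    cfg = ExperimentConfig(example=2, noise_level=0.01, seed=seed, n_init=6,
                           sizes=(4, 1, 1))
    data = dg.make_example_dataset(2, 0.01, seed, n_init=6, sizes=(4, 1, 1))
    fit = fit_pipeline(data, cfg)
    r1, r2 = fit["final"]
    d2 = next((t.coeff for t in r2.terms if "v_xx" in t.label), np.nan)
    has_rational = any(t.den_var == "v" for t in r1.terms)
    rows.append((seed, r1.alpha, d2, len(r1.terms), has_rational))
    print(f"seed {seed}: alpha={r1.alpha:.3f}  d2={d2:.3f}  "
          f"|F1|={len(r1.terms)} terms  rational={'yes' if has_rational else 'no'}")

alphas = [r[1] for r in rows]
d2s = [r[2] for r in rows]
print(f"\nalpha: median {np.median(alphas):.3f}, spread "
      f"[{min(alphas):.3f}, {max(alphas):.3f}]")
print(f"d2:    median {np.median(d2s):.3f}, spread "
      f"[{min(d2s):.3f}, {max(d2s):.3f}]")
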