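#!/usr/bin/env python
"""Validate the polarimetric measurement chain on a phantom.

Simulates the 24 PSG/PSA intensity images of a phantom's ideal-depolarizer
Mueller field, reconstructs the per-pixel Mueller matrices, Lu-Chipman
decomposes them, and measures how accurately the known depolarization map is
recovered, at zero noise and at increasing intensity-noise levels.  Writes
results/polarimetry_accuracy.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from polseg import (PhantomSpec, forward_simulate, generate,
                    make_mueller_phantom, polar_decompose,
                    reconstruct_mueller)

ROOT = Path(__file__).resolve().parents[1]

phantom = generate(PhantomSpec(height=128, width=128,
                               tissue_axes=(56.0, 50.0),
                               core_axes=(21.0, 17.0), rim_width=6.0,
                               core_center=(61.0, 66.0),
                               tissue_center=(64.0, 64.0)), seed=42)
mueller = make_mueller_phantom(phantom.delta)
mask = phantom.delta.mask

rows = []
for noise_sd in (0.0, 0.005, 0.01, 0.02, 0.05):
    images = forward_simulate(mueller, noise_sd=noise_sd, seed=7)
    dec = polar_decompose(reconstruct_mueller(images), mask=mask)
    err = np.abs(dec.delta_total[mask] - phantom.delta.delta[mask])
    rows.append({"noise_sd": noise_sd,
                 "mean_abs_delta_error": err.mean(),
                 "max_abs_delta_error": err.max(),
                 "n_pixels": int(mask.sum())})

df = pd.DataFrame(rows)
out = ROOT / "results" / "polarimetry_accuracy.csv"
out.parent.mkdir(exist_ok=True)
df.to_csv(out, index=False, float_format="%.3e")

print(df.to_string(index=False, float_format=lambda x: f"{x:.3e}"))
print(f"\nnoiseless chain is exact to {df.loc[0, 'max_abs_delta_error']:.1e}; "
      f"error grows monotonically with intensity noise -> {out}")
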