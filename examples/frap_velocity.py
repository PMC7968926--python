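"""FRAP transport velocities to cytoneme tips.

Simulates photobleach-recovery recordings (5 s baseline, 120 s recovery
at 277 ms/frame) for vehicle-treated cytonemes transporting cargo at
0.25 um/s, and for an ionomycin-treated batch where tip-ward transport
is blocked. Each ROI's halftime is fit with a single-exponential
recovery after bleach correction, converted to v = distance / tau_1/2,
and averaged per cytoneme.
"""

import pandas as pd

from cytoquant.frap import frap_pipeline
from cytoquant.simulate import FrapSimParams, gen_frap_dataset

vehicle, _ = gen_frap_dataset(
    FrapSimParams(true_velocity=0.25, n_cytonemes=20), seed=1
)
iono, _ = gen_frap_dataset(
    FrapSimParams(n_cytonemes=20, recovery=False), seed=2,
    cytoneme_prefix="iono",
)
result = frap_pipeline(pd.concat([vehicle, iono], ignore_index=True))

for cond, stats in result.comparison["conditions"].items():
    mv = stats["mean_velocity_um_per_s"]
    shown = f"{mv:.3f} um/s" if mv is not None else "no recovery"
    print(f"{cond:10s}: {shown:14s} "
          f"(recovered {stats['n_recovered']}/{stats['n_cytonemes']})")

# Vehicle cytonemes recover with a mean velocity near the true
# 0.25 um/s; ionomycin curves are classified non-recovered (fitted
# plateau below 20%), mirroring the loss of motor-driven transport.
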