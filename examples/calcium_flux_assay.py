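"""Ca2+ flux scoring in the cytoneme contact assay.

Simulates 27 reporter cells touching control (GFP) cytonemes and 15
touching SHH-bearing cytonemes (15 min at 1.7 s/frame), then runs the
full flux pipeline: per-cell min-max normalization, event detection at
the threshold of 50 with 20 s gap-merging, exclusion of never-fluxing
cells, the rank-sum condition contrast, the self-paired signed-rank
deposit contrast, and the control percentile bracketing of the
threshold.
"""

import numpy as np

from cytoquant.flux import flux_pipeline
from cytoquant.simulate import simulate_flux_study

table, deposits, truth = simulate_flux_study(seed=1)
result = flux_pipeline(table, deposits)

df = result.summaries
case = df.loc[df.condition == "SHH", "flux_rate"]
ctrl = df.loc[df.condition == "GFP", "flux_rate"]
print(f"GFP-contact flux rate : {ctrl.mean():.3f} +/- {ctrl.std():.3f} /min "
      f"(n={len(ctrl)})")
print(f"SHH-contact flux rate : {case.mean():.3f} +/- {case.std():.3f} /min "
      f"(n={len(case)})")
print(f"fold change           : {case.mean() / ctrl.mean():.2f}x")

p90, p95 = result.percentiles
print(f"control pooled P90/P95: {p90:.1f} / {p95:.1f} "
      f"(threshold 50 bracketed: {result.threshold_validated})")

t = result.deposit_test
print(f"signed-rank, in- vs out-of-window flux per cell: "
      f"p = {t.pvalue:.2e} ({t.method}, n={t.n[0]} cells)")
print(f"excluded (no flux): {len(result.excluded_cells)} cells")

# A fold change above 2 reproduces the more-than-twofold response of
# ligand-contacted reporters; the bracketing shows why 50 separates
# signal from the control intensity range; the tiny signed-rank p says
# flux concentrates in the 20 s windows after a deposit.
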