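# cytoquant

Quantification of cytoneme-mediated morphogen delivery.

Cytonemes are thin (< 200 nm diameter), long (≥ 10 µm) specialized
filopodia that ferry ligands such as Sonic Hedgehog (SHH) from producing
to receiving cells. Measuring that delivery route from live microscopy
requires a chain of quantitative steps that are usually scattered across
ad-hoc scripts. `cytoquant` packages them as a tested Python library for
cell biologists analyzing cytoneme imaging data:

- **Ca²⁺ flux scoring** for contact-activation assays with a genetically
  encoded reporter (R-GECO): per-cell traces are min–max normalized to
  [0, 100]; a flux event is a supra-threshold episode (threshold 50),
  with episodes separated by less than 20 s merged — maintained
  fluorescence over 20 s counts once. Per-cell outputs are the event
  rate per minute, total time in flux, and the proportion of flux time
  inside vs outside the 20 s windows following each ligand deposit.
  Never-fluxing cells are excluded. Inference: Wilcoxon rank-sum between
  conditions, Wilcoxon signed-rank for the self-paired deposit contrast
  (exact null distributions at small n), and percentile bracketing that
  checks the threshold lies between the 90th and 95th percentiles of the
  pooled control distribution.
- **Deposit calling** from cytoneme line scans (kymographs): puncta are
  intensity maxima > 1.5× background, linked into tracks; a deposit is an
  anterograde track that reaches the tip zone and disappears in the next
  frame without retrograde movement.
- **FRAP transport velocity**: recovery curves are corrected for
  acquisition bleaching against a reference region, normalized
  (pre-bleach = 100%, first post-bleach frame = 0%), fit with
  R(t) = P·(1 − 2^(−t/τ)), and converted to v = d / τ½ for each ROI at
  distance d from the cell body, averaged per cytoneme. Curves whose
  achieved recovery stays below 20% are classified non-recovered (the
  ionomycin phenotype).
- **Masked colocalization**: cytonemes are segmented from a membrane
  channel (Otsu threshold, skeleton length ≥ 10 µm, width ≤ 0.2 µm) and
  Pearson's r between two fluorophores is computed over mask pixels, or
  restricted to pixels in contact with segmented ligand puncta.
- **Morphometry and occurrence**: cytoneme scoring by the length / width
  / substrate-contact criteria, occurrence rates with Wilson confidence
  intervals, cytoneme-to-cell-body intensity ratios, and the standard
  group comparisons (two-tailed t-test; one-way ANOVA with Tukey HSD).
- **Synthetic data generators** (`cytoquant.simulate`) that emulate every
  raw input — reporter traces with deposit-coupled transients (10–20 s
  latency), FRAP curves with bleaching, kymographs with retrograde
  distractors, correlated multi-channel fields, occurrence counts — each
  emitting its ground truth, so every stage is testable end to end
  without microscope data.

## Worked example

`examples/calcium_flux_assay.py` simulates the contact assay — 27
reporter cells touching control (GFP) cytonemes, 15 touching SHH
cytonemes that also deliver deposits — and runs the full flux pipeline:

```
GFP-contact flux rate : 0.271 +/- 0.084 /min (n=27)
SHH-contact flux rate : 0.590 +/- 0.149 /min (n=15)
fold change           : 2.18x
control pooled P90/P95: 39.0 / 58.8 (threshold 50 bracketed: True)
signed-rank, in- vs out-of-window flux per cell: p = 6.10e-05 (exact, n=15 cells)
excluded (no flux): 0 cells
```

Reporter cells contacted by ligand-bearing cytonemes flux at more than
twice the control rate; the flux threshold of 50 falls between the 90th
and 95th percentiles of the pooled control distribution (so supra-50
flux is rare in controls); and with all 15 cells fluxing more inside
their post-deposit windows than outside, the exact signed-rank p equals
2/2¹⁵ ≈ 6.1 × 10⁻⁵.

The other examples cover FRAP velocities (`frap_velocity.py`), deposit
calling (`deposit_calling.py`), colocalization (`colocalization.py`),
and occurrence statistics (`occurrence_morphometry.py`). A thin CLI
wraps the same pipelines (`cytoquant simulate calcium`, `cytoquant flux
--traces … --deposits …`, `cytoquant frap`, `cytoquant deposit`,
`cytoquant coloc`, `cytoquant occurrence`); every command writes CSV
results plus a JSON summary embedding the configuration snapshot used.

## Documentation

`docs/methods.md` describes the models and estimation procedures, the
parameters that matter and their defaults, what the synthetic data do
and do not emulate, and known limitations.
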