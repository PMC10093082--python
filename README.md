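# mitopotential

High-content image analysis of mitochondrial membrane potential (ΔΨm)
from TMRM fluorescence, for plate-based microscopy of 2D monolayers,
3D aggregates and spheroids, isolated muscle fibers, and marker-free
co-cultures.

Mitochondrial membrane potential drives ATP synthesis and is a core
readout of mitochondrial fitness. In non-quenching mode, the
cell-permeant dye TMRM accumulates in mitochondria in proportion to
ΔΨm: the signal rises on hyperpolarization (e.g. the ATP-synthase
inhibitor oligomycin) and collapses on depolarization (the uncoupler
FCCP). This package turns multi-channel plate images
(brightfield / Hoechst 33342 / TMRM, multi-field, multi-timepoint,
optionally Z-stacked) into per-cell, per-structure or per-population
kinetic traces, with every stage testable against a synthetic image
generator that records its ground truth.

## What the pipeline computes

For each object *i* detected in the Hoechst channel, TMRM photometry is

```
corrected_i(t) = mean(TMRM over cell region_i) − mean(TMRM over background ring_i)
normalized_i(t) = corrected_i(t) / corrected_ref(basal)
```

where the cell region is the nucleus grown by `r_cell` px (competition
resolved by nearest-nucleus assignment) and the background ring is an
annulus outside it, excluding all cell regions. Treatment responses
are summarized as `oligo_ratio` (mean normalized level under
oligomycin; > 1 ⇒ hyperpolarized) and `fccp_ratio` (< 1 ⇒ depolarized).

Workflow-specific stages:

- **Aggregates (3D cultures):** Z-stacks are max-projected; contiguous
  Hoechst structures are classed by projected area in multiples of the
  median single-nucleus area — `single < a1 ≤ grouped < a2 ≤ aggregate
  < a3 ≤ spheroid` (defaults a1, a2, a3 = 2, 10, 60).
- **Myofibers:** brightfield planes are flatfield-corrected, background
  is removed by a sliding-paraboloid opening (curvature 3), candidates
  are the cross-plane union of thresholded planes, and true fibers must
  pass conjunctive area / aspect-ratio (≥ 5) / striation gates, the
  latter scored as the spectral power fraction of the axial intensity
  profile inside the sarcomere period band.
- **Co-cultures:** each nucleus gets a 28-feature vector (morphology,
  intensity, GLCM texture, symmetry, threshold compactness); a dense
  network (BatchNorm → five dense+dropout pairs of 350/224/128/96/96
  ReLU units, dropout 0.01, sigmoid output; SGD, lr 0.01, ≤ 250 epochs,
  early-stopping patience 25) scores each cell in [0, 1]; cells scoring
  below 0.6 for both populations are discarded before per-population
  kinetics.
- **Cell cycle:** integrated nuclear Hoechst intensity scales with DNA
  content; the G0/G1 mode *m* is located by KDE and cells are gated at
  1.4·m and 1.75·m into G0/G1, S and G2/M fractions.

## Worked example

```python
from mitopotential.pipeline import RunConfig, run_workflow

res = run_workflow(RunConfig(
    workflow="monolayer", seed=2,
    params={"generator_params": {"n_cells": 100, "shape": (512, 512)}}))
s = res["summaries"][0]
print("oligo_ratio", round(s.oligo_ratio, 4), "fccp_ratio", round(s.fccp_ratio, 4))
```

prints

```
oligo_ratio 1.2986 fccp_ratio 0.4005
```

The synthetic plate was generated with latent response factors
f_o = 1.3 (oligomycin) and f_f = 0.4 (FCCP); the pipeline re-detects
the 100 cells at every timepoint, performs ring-corrected photometry
and recovers both factors to within 0.2%. Similarly, gating a
10,000-cell synthetic DNA-content mixture generated at fractions
(0.60, 0.10, 0.30):

```python
from mitopotential import generate_dna_content
from mitopotential.cellcycle import gate_cell_cycle

vals, _ = generate_dna_content(10000, 0.6, 0.1, 0.3, cv=0.05, seed=2)
print([round(f, 4) for f in gate_cell_cycle(vals).fractions])
# [0.6005, 0.0922, 0.3073]
```

Everything is also reachable from the `mitopotential` command line
(`synth`, `segment`, `kinetics`, `aggregates`, `fibers`, `classify`,
`cellcycle`, `run`); see `mitopotential --help`.

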