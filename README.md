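# smadtrace

Single-cell analysis of dynamic TGF-β/SMAD3 transcriptional reporter
time-lapse movies: simulation of destabilized-GFP reporter kinetics in
motile cell populations, rendering of synthetic two-channel microscopy
stacks, Gaussian-mixture nuclei tracking, per-cell trace extraction with
responder classification, and screening-quality statistics.

## The problem

Conventional fluorescent transcriptional reporters mature slowly and
persist for more than a day, so they integrate signalling activity and hide
its dynamics. A destabilized reporter — superfolder GFP fused to a PEST
degron, driven by twelve tandem SMAD3/4-binding CAGA elements ("dynGFP") —
matures in minutes and turns over with a ~4 h half-life, making
transcriptional dynamics visible in single living cells. Analysing such
movies requires tracking hundreds of motile nuclei for 24 h, reading the
reporter through each nucleus mask, and classifying cells into early, late
and non-responders by the temporal shape of their traces.

`smadtrace` implements that pipeline end to end, together with a
ground-truth simulator so every stage can be validated quantitatively.

## Models

**Reporter kinetics** (per cell, pathway activity `S(t) ∈ [0,1]`):

    dm/dt = α·S(t) − δm·m
    dp/dt = β(t)·m − (κ + δp)·p
    df/dt = κ·p − δp·f

`m` mRNA, `p` immature protein, `f` mature fluorophore; `κ` encodes
folding speed, `δp` PEST-mediated turnover. Piecewise-constant
perturbations model ligand addition/washout, receptor-kinase inhibition
(`S → 0`, translation continues on decaying mRNA) and cycloheximide
(`β → 0`). Solved exactly by piecewise matrix exponentials. Half-lives are
estimated from chase data by regressing log fraction-remaining through the
origin, `t½ = ln2/(−k)`.

**Tracking** models each nucleus as a 2D Gaussian, fitted per frame
(batched Gauss–Newton with deblending and a joint multi-Gaussian
refinement of overlapping groups) and forwarded frame-to-frame by
maximum-a-posteriori assignment under Gaussian priors on displacement and
log-changes of shape and intensity (Hungarian matching with gating,
gap closing, ride-alongs through transient merges, fragment relinking and
appearance-based swap repair).

**Classification** min–max normalises each trace, clusters whole traces by
Euclidean-distance hierarchical clustering (k = 3), separates
non-responders by a robust range-versus-noise-floor rule, and labels the
remaining clusters early/late by median onset (first sustained crossing of
half the per-cell range).

**Screen statistics**: percent positive above a control-derived cut-off,
trapezoidal AUC, signal-over-background, and `Z′ = 1 − 3(σ₊+σ₋)/|μ₊−μ₋|`.

## Worked example

```python
import numpy as np
from smadtrace import kinetics
from smadtrace.kinetics import PRESETS, PerturbationSchedule

# half-life from a cycloheximide chase: 48% of signal left after 4 h
half_life = kinetics.estimate_half_life([(4.0, 0.48)])
print(f"fitted dynGFP half-life: {half_life:.2f} h")

drop = 100.0 * (1.0 - kinetics.fraction_remaining_at([(4.0, 0.48)], 8.0))
print(f"extrapolated 8 h signal drop: {drop:.1f} %")

# single-cell response to a 6 h transcriptional pulse
t = np.arange(0.0, 1441.0, 3.0)
series = kinetics.simulate_reporter(
    PRESETS["dynGFP"], PerturbationSchedule.pulse(0.0, 360.0), t
)
print(f"pulse response peaks at {t[series.f.argmax()]:.0f} min, "
      f"amplitude {series.f.max():.0f} units")
```

prints

```
fitted dynGFP half-life: 3.78 h
extrapolated 8 h signal drop: 77.0 %
pulse response peaks at 468 min, amplitude 27146 units
```

The 3.78 h fit is what a "~4 h" half-life looks like before rounding; the
77% extrapolated drop corresponds to the "~80% after 8 h" behaviour of a
destabilized reporter; and a 6 h transcriptional pulse peaks roughly 7.8 h
after stimulus because maturation is fast but the mRNA and protein pools
integrate the pulse.

The full pipeline runs from the shell:

```bash
smadtrace pipeline --seed 7 --out runs/demo          # all stages
smadtrace simulate --seed 7 --out runs/demo          # or stage by stage
smadtrace track    --seed 7 --out runs/demo
```

Each stage writes plain files (`ground_truth.json`, `stack.tif`,
`tracks.csv`, `traces.csv`, `features.csv`, `heatmap.png`, `stats.json`,
`manifest.json` with content hashes); re-running any stage with the same
config and seed reproduces its outputs bit-exactly.

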