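# Methods

`smadtrace` simulates and analyses single-cell time-lapse recordings of a
destabilized TGF-β/SMAD3 transcriptional reporter (a superfolder GFP fused
to a PEST degron, here called dynGFP) in motile cell populations carrying a
constitutive nuclear marker. This note describes the models, the default
parameters and why they were chosen, the numerical choices, and what the
synthetic data can and cannot establish.

## Reporter kinetics

Per cell, reporter expression is a three-compartment linear ODE driven by
the pathway activity `S(t) ∈ [0, 1]`:

    dm/dt = α·S(t) − δm·m          (reporter mRNA)
    dp/dt = β(t)·m − (κ + δp)·p    (immature, non-fluorescent protein)
    df/dt = κ·p − δp·f             (mature fluorophore)

with `m = p = f = 0` at `t = 0`. `κ` encodes folding/maturation (the
superfolder mutations), `δp` proteasomal turnover (the PEST degron). The
degron is applied to the immature and mature pools alike — whether PEST
acts on unfolded protein is biologically open; the symmetric choice is the
minimal one and is easy to change (`delta_p` enters both equations).

Perturbations are piecewise constant: ligand on/off switches `S`; a
receptor-kinase inhibitor clamps `S = 0` while existing mRNA continues to
be translated as it decays; a translation block (cycloheximide) clamps
`β = 0` immediately. These two modes differ exactly in the window where
mRNA still produces protein, which is why an inhibitor chase decays more
slowly than a translation chase at every time point.

Because `S` and `β` are piecewise constant, the system is linear with
constant coefficients on every segment and is propagated **exactly** with
the matrix exponential of the affine-augmented 4×4 system, segment by
segment, caching the propagator per unique step size. No step-size control
is needed and the solution is exact to rounding; tests verify it against a
fixed-step explicit-Euler integration (at the tolerance set by Euler's own
first-order error) and against closed forms (steady state, pure
exponential decay).

Default presets (rates per minute):

| preset   | κ (maturation) | δp (turnover) | protein t½ | maturation t½ |
|----------|----------------|---------------|-----------|----------------|
| dynGFP   | ln2/6          | ln2/227       | 3.78 h    | 6 min          |
| GFP      | ln2/40         | ln2/1800      | 30 h      | 40 min         |
| TdTomato | ln2/60         | ln2/1800      | 30 h      | 60 min         |

All presets share `α = 1`, `β = 1`, `δm = ln2/120` (2 h mRNA half-life) so
that differences between presets reflect the fluorophore alone. The dynGFP
turnover reproduces a single-exponential chase in which 48% of signal
remains after 4 h; the slow variants reproduce half-lives beyond a day.

**Half-life estimation** regresses `ln(fraction remaining)` against time
through the origin (the chase normalisation fixes the intercept at 0),
`t½ = ln2/(−slope)`; a single point `(t, q)` reduces to `t·ln2/ln(1/q)`.
Fractions ≥ 1 mixed into a decaying series are kept with a warning; an
all-flat series raises a no-decay error.

## Synthetic populations and movies

`PopulationParams` defaults describe the scaled-down study conditions: 250
cells in a 512×512 px field (1.4 µm/px), imaged for 480 frames at 3-minute
cadence (24 h), mixing 45% early responders, 35% late responders and 20%
non-responders.

**Onsets.** Early and late responders have observed trace onsets drawn
from Normal(300, 50) and Normal(700, 70) minutes (truncated at zero). The
onset is defined in *observed-trace time* — the time at which the
reporter trace first reaches half of its eventual peak — because that is
the feature visible in single-cell data. Since the reporter integrates
transcription with a ~4 h protein half-life, the generator places each
cell's transcription start earlier by the class template's half-rise lag
(computed once per class by simulating the template on a 1-minute grid;
`response_onset_lag`). The onset SDs are not measured quantities; they
were chosen once to match the roughly 1–2 h spread visible in published
peak-time histograms.

**Adaptation.** Responding cells receive a transcription pulse of
`signal_duration = 360` min rather than sustained activity. Single-cell
reporter traces under continuous ligand rise, peak and decline
(SMAD signalling adapts, e.g. via SMAD7 induction); a sustained-activity
model would place every trace's peak at the final frame and erase the
early-vs-late peak-time ordering. Non-responders never activate the
pathway and have identically zero induced trace.

**Motility.** A reflecting-boundary Gaussian random walk with
`motion_sd = 1` px/frame/axis. Real melanoma cells migrate with
directional persistence; a pure random walk is the simpler model, with the
caveat noted under Limitations that diffusive motion maximises the time
nearby nuclei spend overlapping.

**Imaging.** Nuclei render as isotropic 2D Gaussians (σ ≈ 3 px ≈ 4.2 µm,
i.e. a 10–15 µm nucleus; amplitude lognormal around 500 counts with 15%
spread — stable per cell, which later serves as an identity cue). The
reporter channel adds a Gaussian of width `gfp_psf_sigma = 4` px scaled by
`photons_per_unit = 0.012` times the cell's current mature-fluorophore
amount, putting peak reporter amplitudes a few hundred counts over the
100-count background. Each pixel's expected value λ becomes
`Poisson(λ) + Normal(0, 3)`, clipped and quantised to 16 bits. With noise
disabled the expected counts are returned unquantised in float64, so that
extraction can be validated to 1e-6 relative error on static,
well-separated scenes.

All randomness flows from one seed through named substreams (simulate,
render, snapshot, screen), so every stage is reproducible in isolation and
ground truth plus rendered stacks are bit-reproducible from (params, seed).

## Nuclei detection

Per frame, candidate peaks are local maxima exceeding the frame median by
`min_amplitude` (default 50 counts) with separation ≥ `min_separation`
(default 5 px). Each candidate is fitted with
`A·exp(−(dx²/2sx² + dy²/2sy²)) + b` by a damped Gauss–Newton iteration,
batched across all windows with an active-set scheme (converged windows
freeze). The first pass uses a tight window (≈3σ wide) so neighbours
cannot skew the fit; subsequent passes use the full ≈6σ window.

Overlapping nuclei need more care, and most of the detector is about them:

1. groups of fits whose two-sigma ellipses intersect and that collapsed
   onto one blob (near-duplicate centres or inflated widths) are restarted
   from their distinct seed peaks;
2. flagged windows are refit with the neighbouring fitted Gaussians
   subtracted from the data (alternating deblending); a symmetric
   over-subtraction can annihilate a whole group, in which case the
   brightest original fit is restored;
3. nuclei hidden inside a brighter neighbour's blob are recovered from the
   model residual (same amplitude bar) and refit;
4. every overlapping group is finally refit **jointly** (all its Gaussians
   plus a shared background in one least-squares problem), which removes
   the percent-level amplitude crosstalk the alternating scheme leaves;
5. near-duplicate fits are suppressed, keeping the brighter.

On noiseless isolated nuclei the fit recovers centre, widths and amplitude
to machine precision; on the default noisy movie, matched-detection
amplitude errors have median ≈1%.

`detect_sequence` optionally *forwards* each frame's Gaussians as softly
anchored seeds for the next frame (a quadratic positional prior with SD
`anchor_sd` added to the normal equations, weighted like a MAP term).
Forwarding keeps two components alive while nuclei overlap completely; on
the default movie it performs comparably to per-frame detection and is off
in the default pipeline.

## Tracking

Linking is maximum-a-posteriori assignment under independent Gaussian
transition priors: cost = ‖Δcentre‖²/2σ_pos² + Σ ln²(s'/s)/2σ_shape² +
ln²(A'/A)/2σ_int², solved per frame pair as an optimal bipartite matching
with explicit birth/death alternatives priced at half the gate (default
gate 9 ≈ a combined 3σ). For ≤6 detections a side this equals exhaustive
search over gated matchings, which the tests verify.

Defaults: `pos_sd = 2` px (twice the motion SD, leaving room for fit
noise), `logshape_sd = 0.08`, `logint_sd = 0.1` — tight, because fitted
amplitudes are accurate and per-cell brightness is a strong identity cue.
Inside the tracker the appearance terms are referenced to the track's
*appearance memory* (its last clean detection, refreshed only when the new
detection is no appearance outlier) and capped at gate/2, so a transiently
blended blob cannot push an otherwise certain link past the gate while
clean competitors still feel the full prior.

Track building chains these assignments and adds, in order: gap closing
(a track missing for g ≤ `max_gap` = 4 frames catches an unmatched
detection with the positional prior widened by √g); ride-alongs (a track
that finds no free detection may share an already-claimed one within the
gate, keeping its pre-merge appearance reference — merged evidence is
forwarded rather than dropped); removal of shadow tracks that mostly ride
a longer track's detections; stitching of fragment pairs that briefly
shadow one nucleus; global relinking of fragment ends to fragment starts
across up to 60 frames, matched by a diffusion-widened positional prior
plus the distance between median appearance signatures; and a swap-repair
pass that exchanges track tails at close encounters when the crossed
pairing of before/after appearance signatures is decisively more
consistent than the straight one and both exchanged junctions are
spatially continuous. Tracks with detections in fewer than 80% of their
spanned frames are discarded.

A ground-truth cell counts as **successfully tracked** when one single
track has detections within `match_radius` = 5 px of the cell's true
position in at least 80% of the cell's frames.

## Trace extraction and classification

The reporter trace of a track is the background-subtracted mean of the
reporter channel over the track's two-sigma nuclear mask per frame
(per-frame background = median over mask-free pixels); gap frames are
linearly interpolated and frames outside the track's span are edge
extensions, recorded as such (`first_frame`/`last_frame`). When a
neighbouring track's nucleus is within reach of the mask, the pipeline
unmixes the overlap: the reporter point-spread functions of the cell and
its neighbours are fitted jointly by linear least squares over the mask
pixels and only the cell's own component enters the trace, which removes
the neighbour glow that otherwise leaks in whenever cells pass each other.

Traces are min–max normalised per cell (a constant trace maps to zero).
Cells observed over at least 80% of the movie enter Euclidean-distance
agglomerative clustering (average linkage by default; Ward and complete
via config) of the whole normalised time course, cut at k = 3.

Classification is range-vs-noise based rather than purely
cluster-membership based so it tolerates a misspecified k: a cell is a
non-responder when the robust range (2.5–97.5 percentile span of a
9-frame median-filtered copy) of its trace stays below a per-trace noise
floor. The floor is the robust per-frame noise SD (median absolute
frame-to-frame difference / 0.954) scaled by `3·√(2·ln n)` — the expected
extreme range of n independent Gaussian samples with margin — so that a
pure-noise trace of any length stays below it with high probability.
Onset is the earliest time the normalised (median-filtered) trace holds
≥ 0.5 for two consecutive frames; an onset coinciding with a track's first
observed frame is censored (the cell was already bright when observation
began). Remaining clusters map onto early/late by median onset, with
intermediate clusters collapsed toward the nearer extreme. Peak times are
read from the median-filtered trace so contamination transients cannot
displace them.

## Screen statistics

Percent-positive uses a cut-off at the 99.5th percentile of unstimulated
control intensities (linearly interpolated order statistic, ≥20 controls
required). AUC is the trapezoidal integral of a summary time course.
`Z′ = 1 − 3(σ₊+σ₋)/|μ₊−μ₋|` with sample SDs; s/b is the ratio of mean
stimulated to mean unstimulated intensity. The simulated screen emulates a
plate imager: three wells per condition, each an independent population
draw, well readout = autofluorescence baseline (50 counts/cell) plus mean
per-cell reporter intensity at 24 h, with 3% multiplicative well-to-well
noise. Screen quality is computed on these well-level readouts — per-cell
readouts would fold the genuine responder heterogeneity into σ₊ and say
nothing about assay quality.

## Problem sizes in the test suite

Unit and property tests run on small scenes (8–30 cells, 40–60 frames,
128–256 px fields) so the whole suite stays within desk-scale runtimes;
the acceptance tests run one full default movie (250 cells, 512 px, 480
frames) plus two replicates at the same areal density on a 360 px field.

## Limitations

* **Identity retention at nucleus–nucleus merges is the binding
  constraint on long movies.** Per-frame detection recall is ≈0.96 and
  60-frame tracking is ≈0.9, but under diffusive motion nearby nuclei
  re-contact repeatedly and stay blended for tens of frames, and each deep
  merge carries a chance of an identity error that the appearance-based
  repairs cannot always undo (per-cell brightness differences are the only
  identity cue while positions are degenerate, and ~20% of random cell
  pairs differ by less than the fit noise allows to distinguish reliably).
  Over 480 frames these events accumulate, so the fraction of cells covered
  ≥80% by a single track on the default movie is ≈0.6 — substantially
  below what the same machinery achieves on shorter movies. Real migrating
  cells move with directional persistence, which shortens contact times;
  the random-walk motility model is the worst case in this respect.
* The generator does not model cell division, death, confluency effects,
  photobleaching, cytoplasmic reporter distribution or out-of-focus light;
  passing tests therefore say nothing about those aspects of real data.
* Trace unmixing assumes the rendered Gaussian PSF; on real data the PSF
  would need calibration.
* The kinetic model is deterministic; transcriptional bursting and
  extrinsic noise beyond the lognormal amplitude/size factors are not
  represented.
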