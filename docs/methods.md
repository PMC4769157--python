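# Methods

## Scope and model

The package analyzes two-channel (donor Cy3 / acceptor Cy5) intensity
time series from surface-immobilized mononucleosomes being remodeled by
an SHL2-engaging translocase. The underlying physical picture: the
enzyme translocates DNA across the octamer in small discrete steps
separated by exponentially distributed pauses; the labeled DNA end
therefore traces a piecewise-constant FRET trajectory whose plateau
values follow a linear FRET-vs-linker-length calibration. Analysis
recovers the step size (in ΔFRET and bp), the probability of missing a
step, and the mean pause lifetime.

FRET is computed as the uncorrected proximity ratio
`E = I_A / (I_A + I_D)`, clipped to [0, 1], with no gamma or crosstalk
correction — the proximity ratio matches the FRET ranges this assay
reports, and all downstream quantities are calibrated empirically
against linker length, which absorbs any fixed detection-efficiency
factor.

## Trace processing

- **Single-molecule selection.** A trace is kept when its total
  intensity shows exactly one discrete drop to a stable baseline
  (one-step photobleaching). The drop test idealizes the total signal
  with the chi-square step finder and counts downward level changes
  exceeding 3× the idealization's residual SD. The post-bleach segment
  (≥ 10 frames) provides the per-channel background, whose mean is
  subtracted everywhere; the subtraction is idempotent to within noise.
- **Validity masking.** Frames after the bleach, and frames with
  non-positive total intensity, are masked rather than treated as zero
  FRET — bleaching and remodeling are otherwise confusable.
- **Initial/final FRET** are means of the first/last 10 valid frames
  (window configurable; the choice only matters for classification
  thresholds, which are 0.07–0.1 ΔFRET).
- **Median filters** use windows that truncate at the series edges, and
  the median of an even number of points is the mean of the two central
  values. Filtering (3-point) is applied for classification and display
  only; step finders run on unfiltered values because they model the
  noise explicitly, and a median pre-filter would correlate it.
- **Population gates.** Octamer–octamer constructs keep FRET > 0.2
  (H2A/H2A) or > 0.1 (H2B/H2B); DNA-labeled constructs keep the
  proximal-donor population via a configurable window (default
  [0.2, 1.0] in the pipeline).

## Classification

A trace is entry-side when ≥ 3 consecutive valid (3-pt filtered) points
exceed `initial FRET + threshold` before the trace settles into its
final plateau; otherwise exit-side. Threshold 0.1 ΔFRET, or 0.07 for
the internally backbone-labeled geometry, where the rise/fall mapping
also inverts. Two operationalizations the rule itself leaves open:

- "Before reaching the final FRET value" = before the start of the
  terminal run of points within ±0.05 of the final FRET.
- Traces are auto-gated as exhibiting remodeling when the total FRET
  change exceeds 0.15 (replacing manual curation, for reproducibility);
  smaller changes return "unclassified".

The small apparent FRET dip caused by donor brightening at enzyme
binding does not affect the rule, which only tests upward excursions.

## Chi-square step finder

Greedy placement: change points are inserted one at a time at the
position that most reduces the total squared residual about segment
means (computed in O(1) per candidate via prefix sums), followed by
coordinate-descent refinement of all points. Two guards control model
size:

1. **Insertion significance.** An insertion must gain more SSE than the
   expected maximum gain of a spurious split under pure noise,
   `σ̂² (2 ln n + 6)`, with σ̂² taken from the current fit's residuals
   (un-captured steps only inflate σ̂², so the gate errs toward
   rejection early and sharpens as the fit improves).
2. **Counter-fit quality.** The final model must beat a counter-fit —
   plateaus forced to break at the midpoints of the fitted plateaus —
   by an SSE ratio of at least 1.3; otherwise zero steps are returned.
   Real steps make the counter-fit much worse than the fit; on pure
   noise the ratio is ≈ 1.

Plateau levels are arithmetic segment means (the quantity the χ²
objective optimizes). A hard cap of 30 steps per trace applies. On
noiseless data both guards reduce to exact recovery, and for traces
with ≤ 2 true steps the result equals exhaustive enumeration over all
change-point placements (verified against a brute-force oracle).

## HMM step finder

Gaussian-emission HMMs with 1..10 states fitted by EM (hmmlearn), 3
restarts per state count with means initialized on data quantiles
(jittered on restarts), covariances initialized at the robust noise
level, and a sticky transition matrix (0.95 self-transition) reflecting
multi-frame plateaus. The state count minimizes BIC with an effective
parameter count of `4k − 2` (mean, variance, initial weight and one
exit rate per state): staircase trajectories visit each state in one
run, so penalizing the dense k² transition matrix systematically merges
adjacent plateau levels on traces of a few hundred frames. The state
scan stops after two consecutive BIC worsenings. The Viterbi path is
decoded and runs of identical states merged into plateaus whose levels
are state means.

## Step acceptance

A step enters the histogram only when both flanking pauses last
≥ 5 frames (the detection limit used throughout) and both flanking
plateau FRET values lie inside the calibration curve's linear range.
Steps against the expected translocation direction (FRET-increasing for
exit-side; for entry-side, direction flips at the highest plateau) are
tallied as backward and excluded.

## Missed-step mixture (step-size model)

Observed step sizes are fitted to a train of evenly spaced Gaussians,
`y(x) = Σ_{n=1..6} A f^{n−1} exp(−(x − n c)²/2s²)`: a uniform
fundamental step `c` with probability `f` that the pause between two
steps is too short to resolve, so merged steps appear at integer
multiples of `c`. Histograms use 0.02 ΔFRET bins from zero (bin
assignment is edge-tolerant so a value exactly on an edge lands in the
bin it opens). The fit is unweighted nonlinear least squares on bin
counts (zero-count bins included), multi-started over a grid of
candidate `c` values and two width seeds, keeping the best residual; `s`
is shared globally across all histograms of the same movement type
(entry or exit), and a single histogram degenerates to an independent
fit. Parameter SEs come from the fit covariance; an `f` pinned at its
bounds is flagged.

## Calibration and conversions

Mean FRET per linker length comes from single-Gaussian fits to the
per-length FRET histograms (with an R² diagnostic that flags non-
unimodal samples); the calibration line is ordinary least squares with
the slope SE from the regression, and its linear range is the interval
of fitted means. ΔFRET converts to bp as `c / |slope|` with relative
errors combined in quadrature, reported to one decimal. Slopes are
treated as magnitudes — entry- and exit-side geometries give opposite
signs for the same physical step. Published per-construct slopes
(0.053, 0.059, 0.057, 0.055, 0.048 per bp; enzyme-bound variant 0.047
for the first) are bundled as `REFERENCE_SLOPES` with the free-enzyme
values used by default, the enzyme-bound set behind a flag. Dye
separation follows `r = R0 (1/E − 1)^{1/6}` with R0 = 6 nm (Cy3–Cy5),
assuming orientation-averaged point dyes with no linker correction.

## Pause lifetimes

Detected pauses are exponential left-truncated at the 5-frame detection
limit; by memorylessness `τ̂ = mean(durations) − threshold`, with SE
`τ̂/√n`. The implied missed-event fraction is the exponential CDF at
the threshold, `1 − exp(−threshold/τ)` (0.221 at τ = 20 frames).
Whether real data's censoring is sharp at the threshold is an
idealization; the step finder's short-pause rejections make it exact
for this pipeline.

## Synthetic data generator

The generator produces what the analysis assumes, with exact ground
truth: piecewise-constant FRET staircases on the calibration line,
exponential pauses (default mean 20 frames at 1 Hz), a configurable
emission distribution of bp per observable translocation event (default
2 bp — the major observed step — on a 1 bp fundamental unit), donor
emission multiplied by 1.10 from the enzyme-binding frame onward with
the acceptor untouched (reproducing the photophysical pre-rise dip in
the proximity ratio without any distance change), at most one
memoryless per-frame bleaching event per trace (donor bleach zeroes
both channels; acceptor bleach routes all emission to the donor), and
additive Gaussian camera noise (default SD 5 on a total intensity of
100, i.e. FRET noise ≈ 0.04). Entry-side trajectories rise along the
calibration line until the linker is exhausted, then fall in equal
ΔFRET steps to the entry-product level (0.17); exit-side trajectories
fall monotonically and clamp at zero FRET. A gap at SHL−2/SHL+2 forces
exit/entry-side movement respectively; otherwise the movement class is
Bernoulli with the construct's `movement_bias`.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: photon-counting/EMCCD noise statistics,
spectral crosstalk and gamma factors, baseline drift, blinking,
multi-molecule spots, heterogeneous step sizes, and ATP-dependent
kinetics (the pause mean is exposed directly rather than via a rate
law).

## Numerical choices and limitations

- All randomness flows through `numpy.random.default_rng` seeds;
  identical seeds give bit-identical traces and, at the level of fitted
  parameters, deterministic summaries.
- Problem sizes in the test and acceptance runs (200 traces per
  dataset, 1000 mixture draws, 10⁴ pause samples) were chosen to put
  Monte-Carlo error well inside the assertion tolerances.
- End-to-end estimates carry small known biases the per-stage tests do
  not: merged steps pull the fitted `c` a few percent above the
  fundamental ΔFRET step, and pauses flanking merged steps concatenate,
  biasing τ̂ upward by ~10–25% at the default pause/frame-rate ratio.
  These are properties of the measurement process being modeled (the
  mixture's `f` exists precisely because of them), not of the
  implementation.
- The chi-square stop thresholds (quality ratio 1.3, null margin
  `2 ln n + 6`) and the HMM restart/early-stop settings were set for the
  generator's SNR regime (step/noise ≈ 3); substantially noisier data
  may need the thresholds relaxed via the exposed parameters.
- The H2A/H2A and H2B/H2B octamer–octamer constructs are represented
  with an `octamer` acceptor placement so the population gates apply to
  them; they do not participate in translocation simulation.
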