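# nucstep

Single-molecule FRET analysis of stepwise nucleosomal DNA translocation
by chromatin remodelers.

## The problem

SWI/SNF-family remodelers such as yeast RSC reposition nucleosomes by
pulling DNA across the histone octamer from an internal engagement site
(SHL2, two helical turns from the dyad). In an smFRET assay, a donor dye
(Cy3) on the octamer and an acceptor (Cy5) on the DNA report the motion
of the DNA relative to the octamer in real time: the labeled DNA end
either moves *out* of the nucleosome (monotonic FRET decrease) or *into*
it (FRET rise, then fall). Because FRET varies approximately linearly
with linker DNA length over the measured range, the size of each
discrete FRET step can be converted to base pairs, revealing that the
DNA advances in ~1–2 bp increments.

This package implements that analysis end to end for users of camera-based
TIRF smFRET data — and, because raw microscope traces for this assay are
generally not redistributable, it includes a first-class synthetic trace
generator with exact ground truth for validating every stage.

## What it computes

- **Trace selection and processing** — one-step photobleach detection
  (the single-molecule criterion), post-bleach background subtraction,
  proximity-ratio FRET `E = I_A / (I_A + I_D)`, running median filters,
  and construct-specific population gates.
- **Entry/exit classification** — the three-consecutive-points rule: a
  trace showing 3 points above its initial FRET by 0.1 (0.07 for the
  inverted internal-label geometry) before reaching its final plateau
  carries the rise signature of entry-side movement.
- **Step detection** — two independent idealization algorithms: a greedy
  chi-square-minimization step finder with counter-fit model selection,
  and a Gaussian-emission HMM (BIC-selected state count, Viterbi-decoded
  plateaus). Steps are accepted only when flanking pauses last ≥ 5
  frames and plateau FRET lies inside the calibration range; backward
  steps are tallied and excluded.
- **Step-size statistics** — the missed-step mixture model

  `y(x) = Σ_{n=1..6} A f^(n−1) exp(−(x − n c)² / 2s²)`

  fitted to step-size histograms (with the width `s` shared globally
  across histograms of the same movement type), where `c` is the
  fundamental ΔFRET step and `f` the probability that a pause is missed.
- **Calibration and conversions** — FRET-vs-linker-length regression,
  ΔFRET → bp conversion (`bp = c / |slope|`, errors in quadrature), and
  Förster conversion `r = R0 (1/E − 1)^{1/6}` with R0 = 6 nm.
- **Pause lifetimes** — exponential mean lifetime with left-truncation
  at the 5-frame detection limit (`τ̂ = mean − threshold`) and the
  implied missed-event fraction `1 − exp(−threshold/τ)`.

## Worked example

Simulate and analyze 200 exit-side traces (ssDNA gap at SHL−2 forces
exit-side movement; observable steps are 2 bp ≈ 0.106 ΔFRET on the
default calibration; mean pause 20 frames):

```python
import nucstep as ns

cfg = ns.RunConfig(out_dir="runs/demo", n_traces=200, seed=1,
                   gap="SHL-2", bleach_rate=0.003)
ns.run_pipeline(cfg)
print(ns.report("runs/demo"))
```

prints (abridged):

```
## Trace accounting
- traces in: 200
- passed processing (bleach/background/FRET): 184
- passed population gate: 183
- classified entry/exit: 161

## Movement fractions
- entry: 0.012 ± 0.009
- exit: 0.988 ± 0.009

## Step-size fit (exit-side)
- steps: 218
- c = 0.1145 ± 0.0010 ΔFRET, f = 0.09, s = 0.0166
- step size: 2.2 ± 0.2 bp

## Pause lifetimes
- tau = 25.6 ± 1.7 frames (25.6 s), n = 218
- expected missed fraction = 0.177
```

Nearly every trace classifies as exit-side (the gap blocks entry-side
engagement), the fitted ΔFRET step of 0.114 converts to 2.2 bp against
the 0.053 per-bp calibration slope (truth: 2 bp), and the pause lifetime
is recovered near the generated 20-frame mean (slightly long because
pauses flanking merged steps concatenate).

The same stages are available from the shell:

```sh
nucstep simulate --n-traces 100 --seed 2 --out data/
nucstep analyze  --out runs/demo --seed 1
nucstep calibrate --seed 3
nucstep report runs/demo
```

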