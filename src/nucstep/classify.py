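"""Entry-side vs exit-side classification of remodeling traces.

The labeled DNA end either moves out of the nucleosome (monotonic FRET
decrease) or into it (FRET rise, then fall as the label passes the edge
and approaches the internal ATPase site).  The rule: a trace showing 3
consecutive points above the initial FRET by a threshold (0.1; 0.07 for
the inverted H2A/[backbone,-15] geometry) *before* first reaching its
final FRET plateau carries the "rise" signature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constructs import ConstructSpec
from .traces import FretTrace, median_filter


@dataclass
class ClassificationResult:
    label: str  # entry | exit | unclassified
    rise_detected: bool
    rise_frames: tuple[int, ...]
    threshold_used: float
    final_fret: float


def default_threshold(construct: ConstructSpec) -> float:
    return 0.07 if construct.inverted_classification else 0.1


def classify_trace(fret: FretTrace, construct: ConstructSpec,
                   threshold: float | None = None,
                   plateau_tol: float = 0.05,
                   min_total_change: float = 0.15,
                   consecutive: int = 3,
                   prefiltered: bool = False) -> ClassificationResult:
    """Label a remodeling trace as entry- or exit-side movement.

    The trace is 3-point median filtered (unless ``prefiltered``), and a
    rise is detected when ``consecutive`` successive valid points exceed
    ``initial_fret + threshold`` before the filtered trace settles into
    its final plateau (operationally: before the start of the terminal
    run of points within ±``plateau_tol`` of ``final_fret``).  For
    end-labeled constructs rise ⇒ entry; for internally backbone-labeled
    constructs the mapping inverts.  Traces whose total FRET change is
    below ``min_total_change`` show no remodeling transition and are
    returned unclassified.
    """
    if threshold is None:
        threshold = default_threshold(construct)
    y = fret.fret if prefiltered else median_filter(fret.fret, 3)
    initial = fret.initial_fret
    final = fret.final_fret
    if abs(initial - final) < min_total_change:
        return ClassificationResult("unclassified", False, (), threshold, final)

    valid_idx = np.flatnonzero(fret.valid_mask)
    yv = y[valid_idx]
    # first index of the terminal run that stays within tol of the final level
    off = np.flatnonzero(np.abs(yv - final) > plateau_tol)
    t_final = 0 if off.size == 0 else int(off[-1]) + 1

    above = yv[:t_final] > initial + threshold
    rise_frames: tuple[int, ...] = ()
    if above.size >= consecutive:
        window_hits = np.convolve(above.astype(int),
                                  np.ones(consecutive, dtype=int), "valid")
        hit = np.flatnonzero(window_hits == consecutive)
        if hit.size:
            j = int(hit[0])
            rise_frames = tuple(int(valid_idx[j + k]) for k in range(consecutive))
    rise = bool(rise_frames)
    if construct.inverted_classification:
        label = "exit" if rise else "entry"
    else:
        label = "entry" if rise else "exit"
    return ClassificationResult(label, rise, rise_frames, threshold, final)


def movement_fractions(labels) -> dict[str, tuple[float, float]]:
    """Entry/exit fractions ± binomial standard error over classified
    traces (unclassified labels are excluded from the denominator)."""
    labels = list(labels)
    if not labels:
        raise ValueError("no traces to summarize")
    n_entry = sum(1 for l in labels if l == "entry")
    n_exit = sum(1 for l in labels if l == "exit")
    n = n_entry + n_exit
    if n == 0:
        raise ValueError("no classified traces")
    out = {}
    for name, k in (("entry", n_entry), ("exit", n_exit)):
        p = k / n
        out[name] = (p, math.sqrt(p * (1 - p) / n))
    return out
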