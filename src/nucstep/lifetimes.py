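"""Pause-lifetime analysis with detection censoring.

In a memoryless stepping model pause durations are exponential with
mean τ.  The step finder only resolves pauses of at least the detection
threshold (5 frames by default), so observed durations are the
exponential left-truncated at the threshold; by memorylessness the
truncated mean exceeds τ by exactly the threshold, giving the estimator
τ̂ = mean(durations) − threshold.  The fraction of pauses expected to be
missed is the exponential CDF at the threshold, 1 − exp(−threshold/τ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class PauseLifetimeFit:
    tau_frames: float
    tau_se_frames: float
    tau_seconds: float
    detection_threshold: int
    missed_fraction: float
    n: int


def missed_fraction(tau_frames: float, threshold: float = 5.0) -> float:
    """Probability that an exponential pause is shorter than the
    detection threshold: 1 - exp(-threshold/τ)."""
    if tau_frames <= 0:
        raise ValueError("tau must be positive")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return 1.0 - math.exp(-threshold / tau_frames)


def fit_pause_lifetimes(durations, frame_rate: float = 1.0,
                        threshold: int = 5) -> PauseLifetimeFit:
    """Exponential mean lifetime from left-truncated pause durations.

    All durations must already satisfy the detection threshold (shorter
    pauses are unobservable and must be filtered upstream).
    """
    d = np.asarray(durations, dtype=float)
    if d.size < 20:
        raise ValueError("need >= 20 pause durations")
    if np.any(d < threshold):
        raise ValueError("durations below the detection threshold present; "
                         "filter them upstream")
    tau = float(np.mean(d)) - threshold
    if tau <= 0:
        raise ValueError("degenerate sample: truncated mean at the threshold")
    se = tau / math.sqrt(d.size)
    return PauseLifetimeFit(
        tau_frames=tau,
        tau_se_frames=se,
        tau_seconds=tau / frame_rate,
        detection_threshold=threshold,
        missed_fraction=missed_fraction(tau, threshold),
        n=int(d.size),
    )
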