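"""Seeded synthetic smFRET trace generation with ground truth.

The generator emulates the statistical structure the analysis assumes:
piecewise-constant FRET trajectories whose plateau values follow a
linear FRET-vs-linker-length calibration, exponentially distributed
pause durations, 1–2 bp observable translocation steps, a multiplicative
donor brightening upon enzyme binding (the Cy3 photophysical artifact),
single-step photobleaching, and additive Gaussian camera noise.  It does
not model raw movies, spot PSFs, drift, or photon-counting noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .calibrate import CalibrationCurve
from .constructs import ConstructSpec
from .traces import IntensityTrace

#: FRET level the entry-side product settles at, with the labeled DNA
#: end parked at the internal ATPase engagement site.
ENTRY_FINAL_FRET = 0.17

#: FRET below which an exit-side trace is considered to have reached the
#: zero-FRET product state.
EXIT_FLOOR_FRET = 0.02


@dataclass
class SimulationParams:
    """Knobs of the trace generator.

    Defaults emulate the 1 Hz acquisitions: exponential pauses with a
    20-frame mean, 2 bp per observable translocation event, total
    intensity 100 a.u. with Gaussian channel noise of 5 a.u. (FRET noise
    ≈ 0.04), a 10% donor brightening at enzyme binding, and a small
    per-frame, per-dye bleaching probability.
    """

    frame_rate: float = 1.0
    trace_length: int = 500
    pause_mean_tau: float = 20.0
    fundamental_step_bp: float = 1.0
    steps_per_emission_dist: dict[int, float] = field(
        default_factory=lambda: {2: 1.0})
    noise_sd: float = 5.0
    donor_enhancement: float = 1.1
    bleach_rate: float = 0.0
    total_intensity: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.trace_length < 2:
            raise ValueError("trace_length must be >= 2 frames")
        if self.pause_mean_tau <= 0:
            raise ValueError("pause_mean_tau must be positive")
        if self.fundamental_step_bp <= 0:
            raise ValueError("fundamental_step_bp must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.donor_enhancement <= 0:
            raise ValueError("donor_enhancement must be positive")
        if not 0.0 <= self.bleach_rate < 1.0:
            raise ValueError("bleach_rate must lie in [0, 1)")
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be positive")
        probs = np.array(list(self.steps_per_emission_dist.values()), float)
        keys = list(self.steps_per_emission_dist.keys())
        if len(keys) == 0 or any(k < 1 for k in keys):
            raise ValueError("emission distribution needs multiplicities >= 1")
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("emission distribution must be a probability vector")


@dataclass
class GroundTruth:
    """Exact simulation record for scoring recovered quantities."""

    movement_class: str
    true_change_points: list[int]
    true_step_sizes_bp: list[float]
    true_step_sizes_fret: list[float]
    binding_frame: int
    bleach_frame: int | None
    bleach_channel: str | None
    truncated: bool

    def __post_init__(self) -> None:
        cps = self.true_change_points
        if any(b <= a for a, b in zip(cps[:-1], cps[1:])):
            raise ValueError("change points must be strictly increasing")
        if not (len(cps) == len(self.true_step_sizes_bp)
                == len(self.true_step_sizes_fret)):
            raise ValueError("step-size sequences must match change points")

    def to_dict(self) -> dict:
        return asdict(self)


def _draw_multiplicity(dist: dict[int, float], rng) -> int:
    keys = np.array(list(dist.keys()))
    probs = np.array(list(dist.values()), float)
    return int(rng.choice(keys, p=probs / probs.sum()))


def _plan_levels(construct: ConstructSpec, params: SimulationParams,
                 calibration: CalibrationCurve, rng,
                 movement: str) -> tuple[list[float], list[float], bool]:
    """FRET plateau sequence and signed bp steps for one engagement."""
    slope = abs(calibration.slope)
    L0 = construct.initial_linker_bp
    f0 = float(calibration.predict(L0))
    truncated = False
    if not calibration.contains(f0):
        raise ValueError(
            f"calibration does not cover the starting FRET {f0:.3f} "
            f"for linker {L0} bp"
        )
    levels = [f0]
    steps_bp: list[float] = []
    if movement == "exit":
        f = f0
        while f > EXIT_FLOOR_FRET:
            nbp = _draw_multiplicity(params.steps_per_emission_dist, rng) \
                * params.fundamental_step_bp
            f2 = max(f - slope * nbp, 0.0)
            steps_bp.append(-nbp)
            levels.append(f2)
            f = f2
    else:
        # rise: linker shortens to zero along the calibration line
        L = float(L0)
        while L > 0:
            nbp = _draw_multiplicity(params.steps_per_emission_dist, rng) \
                * params.fundamental_step_bp
            nbp = min(nbp, L)
            L -= nbp
            steps_bp.append(nbp)
            levels.append(float(calibration.predict(L)))
        # fall: label moves past the edge toward the internal site
        f = levels[-1]
        while f > ENTRY_FINAL_FRET + 1e-9:
            nbp = _draw_multiplicity(params.steps_per_emission_dist, rng) \
                * params.fundamental_step_bp
            f2 = max(f - slope * nbp, ENTRY_FINAL_FRET)
            steps_bp.append(-nbp)
            levels.append(f2)
            f = f2
    return levels, steps_bp, truncated


def simulate_remodeling_trace(
    construct: ConstructSpec,
    params: SimulationParams,
    calibration: CalibrationCurve,
    rng: np.random.Generator | None = None,
) -> tuple[IntensityTrace, GroundTruth]:
    """Simulate one remodeling trace and its exact ground truth.

    The noiseless FRET trajectory is piecewise constant; plateau values
    follow the calibration line at the current linker length.  Exit-side
    trajectories fall monotonically to the zero-FRET product; entry-side
    trajectories rise while the linker shortens, then fall to the
    entry-side product level.  Donor emission is multiplied by
    ``donor_enhancement`` from the enzyme binding frame onward (acceptor
    unchanged).  At most one dye bleaches; the bleached channel drops to
    background.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    movement = construct.forced_movement()
    if movement is None:
        movement = "entry" if rng.random() < construct.movement_bias else "exit"

    levels, steps_bp, truncated = _plan_levels(
        construct, params, calibration, rng, movement)

    T = params.trace_length
    binding_frame = min(
        1 + int(np.ceil(rng.exponential(params.pause_mean_tau))), T - 1)
    cps: list[int] = []
    t = binding_frame
    for _ in steps_bp:
        dwell = max(1, int(round(rng.exponential(params.pause_mean_tau))))
        t += dwell
        if t >= T:
            truncated = truncated or True
            break
        cps.append(t)
    n_kept = len(cps)
    kept_levels = levels[: n_kept + 1]
    kept_bp = steps_bp[:n_kept]
    truncated = truncated or (n_kept < len(steps_bp))

    fret = np.empty(T)
    fret[: cps[0] if cps else T] = kept_levels[0]
    for lvl, a, b in zip(kept_levels[1:], cps, [*cps[1:], T]):
        fret[a:b] = lvl

    I0 = params.total_intensity
    donor = (1.0 - fret) * I0
    acceptor = fret * I0
    donor[binding_frame:] *= params.donor_enhancement

    bleach_frame = None
    bleach_channel = None
    if params.bleach_rate > 0:
        t_d = int(rng.geometric(params.bleach_rate))
        t_a = int(rng.geometric(params.bleach_rate))
        tb = min(t_d, t_a)
        if tb < T:
            bleach_frame = tb
            bleach_channel = "donor" if t_d <= t_a else "acceptor"
            if bleach_channel == "donor":
                donor[tb:] = 0.0
                acceptor[tb:] = 0.0
            else:
                acceptor[tb:] = 0.0
                enh = np.where(np.arange(T) >= binding_frame,
                               params.donor_enhancement, 1.0)
                donor[tb:] = I0 * enh[tb:]

    if params.noise_sd > 0:
        donor = donor + rng.normal(0.0, params.noise_sd, T)
        acceptor = acceptor + rng.normal(0.0, params.noise_sd, T)

    trace = IntensityTrace(donor=donor, acceptor=acceptor,
                           frame_rate=params.frame_rate,
                           construct=construct)
    truth = GroundTruth(
        movement_class=movement,
        true_change_points=list(map(int, cps)),
        true_step_sizes_bp=[float(b) for b in kept_bp],
        true_step_sizes_fret=[float(b - a) for a, b in
                              zip(kept_levels[:-1], kept_levels[1:])],
        binding_frame=int(binding_frame),
        bleach_frame=bleach_frame,
        bleach_channel=bleach_channel,
        truncated=bool(truncated),
    )
    return trace, truth


def simulate_dataset(construct, params, calibration, n_traces: int,
                     seed: int | None = None):
    """Simulate ``n_traces`` independent traces with per-trace RNG
    streams spawned from one seed."""
    root = np.random.default_rng(params.seed if seed is None else seed)
    out = []
    for _ in range(n_traces):
        out.append(simulate_remodeling_trace(
            construct, params, calibration,
            rng=np.random.default_rng(root.integers(2**31 - 1))))
    return out


def simulate_step_observations(c: float, f: float, s: float, n_obs: int,
                               n_max: int = 6, seed: int = 0) -> np.ndarray:
    """Draw observed step sizes from the missed-step mixture.

    Each observation picks a multiplicity n in {1..n_max} with
    probability proportional to f^(n-1), then draws Normal(n·c, s).
    """
    if not 0.0 <= f < 1.0:
        raise ValueError("f must lie in [0, 1)")
    if c <= 0 or s <= 0:
        raise ValueError("c and s must be positive")
    if n_obs < 0:
        raise ValueError("n_obs must be non-negative")
    if n_obs == 0:
        return np.array([])
    rng = np.random.default_rng(seed)
    ns = np.arange(1, n_max + 1)
    w = f ** (ns - 1)
    mult = rng.choice(ns, size=n_obs, p=w / w.sum())
    return rng.normal(mult * c, s)


def simulate_pause_lifetimes(tau: float, n: int, seed: int = 0) -> np.ndarray:
    """i.i.d. exponential pause durations with mean ``tau`` frames."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if n < 0:
        raise ValueError("n must be non-negative")
    return np.random.default_rng(seed).exponential(tau, n)


def simulate_calibration_dataset(slope: float, intercept: float,
                                 linker_lengths, sd: float,
                                 n_per_length: int,
                                 seed: int = 0) -> pd.DataFrame:
    """Per-molecule FRET samples at several linker lengths.

    Samples Normal(slope·L + intercept, sd) for each length; all true
    means must be valid FRET efficiencies.
    """
    lengths = np.asarray(linker_lengths, dtype=float)
    means = slope * lengths + intercept
    if np.any((means < 0) | (means > 1)):
        raise ValueError("calibration means fall outside [0, 1]")
    if sd < 0 or n_per_length < 1:
        raise ValueError("sd must be >= 0 and n_per_length >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for L, m in zip(lengths, means):
        fr = rng.normal(m, sd, n_per_length) if sd > 0 else np.full(n_per_length, m)
        rows.append(pd.DataFrame({"linker_bp": L, "fret": fr}))
    return pd.concat(rows, ignore_index=True)


def default_calibration(slope: float = -0.053, intercept: float = 0.9,
                        slope_se: float = 0.004,
                        max_linker_bp: int = 12) -> CalibrationCurve:
    """Calibration line used by the simulator by default: FRET 0.9 at
    zero linker, falling 0.053 per bp over the measured linker range."""
    lo = float(intercept + slope * max_linker_bp)
    hi = float(intercept)
    return CalibrationCurve(slope=slope, intercept=intercept,
                            slope_se=slope_se,
                            fret_range=(min(lo, hi), max(lo, hi)))
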