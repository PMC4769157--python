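"""Idealization of FRET traces into plateaus (pauses) and steps.

Two independent algorithms are provided: a chi-square-minimization step
finder that greedily inserts change points and selects the model size by
a counter-fit quality ratio, and a Gaussian-emission hidden Markov model
whose state count is chosen by BIC and whose Viterbi path is collapsed
into plateaus.  Both run on the raw (unfiltered) FRET series, since the
noise is modeled explicitly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import GaussianHMM

# EM restarts legitimately hit the iteration cap; the monitor's log spam
# is not actionable here
logging.getLogger("hmmlearn").setLevel(logging.ERROR)

from . import _stepcore
from .calibrate import CalibrationCurve
from .traces import FretTrace


@dataclass
class StepFitResult:
    """Piecewise-constant idealization of one trace.

    ``change_points`` are absolute frame indices (first frame of each new
    plateau); ``pause_durations`` are plateau lengths in frames.
    """

    change_points: np.ndarray
    plateau_levels: np.ndarray
    pause_durations: np.ndarray
    method: str
    fit_quality: float
    offset: int = 0

    def __post_init__(self) -> None:
        self.change_points = np.asarray(self.change_points, dtype=int)
        self.plateau_levels = np.asarray(self.plateau_levels, dtype=float)
        self.pause_durations = np.asarray(self.pause_durations, dtype=int)
        if self.plateau_levels.size != self.change_points.size + 1:
            raise ValueError("need exactly one more plateau than change points")

    @property
    def step_sizes(self) -> np.ndarray:
        """Signed ΔFRET between consecutive plateaus."""
        return np.diff(self.plateau_levels)

    @property
    def n_steps(self) -> int:
        return self.change_points.size

    def idealized(self, n_frames: int | None = None) -> np.ndarray:
        """Piecewise-constant series over the fitted region."""
        n = int(self.pause_durations.sum()) if n_frames is None else n_frames
        out = np.empty(n)
        bounds = [0, *(self.change_points - self.offset), n]
        for lvl, a, b in zip(self.plateau_levels, bounds[:-1], bounds[1:]):
            out[a:b] = lvl
        return out


@dataclass
class AcceptedSteps:
    """Steps surviving the acceptance filters, with exclusion tallies."""

    steps: np.ndarray
    pause_durations: np.ndarray
    n_rejected_short: int
    n_rejected_range: int
    n_backward: int

    @property
    def backward_fraction(self) -> float:
        total = self.steps.size + self.n_backward
        return self.n_backward / total if total else 0.0


def _as_segment(fret) -> tuple[np.ndarray, int]:
    if isinstance(fret, FretTrace):
        a, b = fret.valid_slice()
        return fret.fret[a:b], a
    return np.asarray(fret, dtype=float), 0


def find_steps_chisq(fret, max_steps: int = 30,
                     quality_threshold: float = 1.3) -> StepFitResult:
    """Chi-square-minimization step finder.

    Change points are placed one at a time at the globally best SSE-
    reducing position, refined by coordinate descent, and the number of
    steps is selected where the counter-fit quality ratio peaks (see
    :mod:`nucstep._stepcore`).  Plateau levels are segment means.
    """
    y, offset = _as_segment(fret)
    if y.size < 10:
        raise ValueError("valid FRET segment shorter than 10 frames")
    cps, sse = _stepcore.greedy_change_points(
        y, max_steps=max_steps, quality_threshold=quality_threshold
    )
    levels = _stepcore.plateau_means(y, cps)
    bounds = [0, *cps, y.size]
    durations = np.diff(bounds)
    return StepFitResult(
        change_points=np.asarray(cps, dtype=int) + offset,
        plateau_levels=levels,
        pause_durations=durations,
        method="chisq",
        fit_quality=sse,
        offset=offset,
    )


def _hmm_bic(ll: float, n_states: int, n_obs: int) -> float:
    # effective free params: mean + var per state, initial distribution,
    # and one exit rate per state — staircase dynamics visit each state
    # once, so the k^2 dense-transition count would badly over-penalize
    p = 4 * n_states - 2
    return -2.0 * ll + p * np.log(n_obs)


def find_steps_hmm(fret, max_states: int = 10, restarts: int = 3,
                   n_iter: int = 100, tol: float = 1e-3,
                   seed: int = 0) -> StepFitResult:
    """HMM-based step finder.

    Gaussian-emission HMMs with 1..max_states states are fitted by EM
    (several random restarts, means initialized on data quantiles); the
    state count is selected by BIC, scanning upward and stopping after
    two consecutive worsenings.  The Viterbi path is decoded and runs of
    identical states merged into plateaus whose levels are the state
    means.
    """
    y, offset = _as_segment(fret)
    if y.size < 10:
        raise ValueError("valid FRET segment shorter than 10 frames")
    n = y.size
    if np.ptp(y) < 1e-12:
        return StepFitResult(
            change_points=np.array([], dtype=int),
            plateau_levels=np.array([float(y[0])]),
            pause_durations=np.array([n]),
            method="hmm", fit_quality=0.0, offset=offset,
        )
    X = y.reshape(-1, 1)
    rng = np.random.default_rng(seed)
    var0 = max(float(np.var(y)), 1e-8)
    # plateau-to-plateau noise, so EM starts with state widths at the
    # noise scale rather than the full signal spread
    noise_var = max(_stepcore.robust_noise_sd(y) ** 2, var0 / 100.0, 1e-10)

    best = None  # (bic, model)
    worse_streak = 0
    for k in range(1, max_states + 1):
        best_ll, best_model = -np.inf, None
        q = np.quantile(y, (np.arange(k) + 0.5) / k)
        for r in range(restarts):
            model = GaussianHMM(
                n_components=k, covariance_type="diag",
                n_iter=n_iter, tol=tol, init_params="s",
                random_state=int(rng.integers(2**31 - 1)),
            )
            jitter = 0.0 if r == 0 else rng.normal(0.0, 0.25 * np.sqrt(var0), k)
            model.means_ = (q + jitter).reshape(-1, 1)
            model.covars_ = np.full((k, 1), noise_var)
            # sticky dynamics: plateaus persist for many frames
            stay = 0.95
            model.transmat_ = np.full((k, k), (1 - stay) / max(k - 1, 1))
            np.fill_diagonal(model.transmat_, stay if k > 1 else 1.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    model.fit(X)
                    ll = float(model.score(X))
                except (ValueError, np.linalg.LinAlgError):
                    continue
            if ll > best_ll:
                best_ll, best_model = ll, model
        if best_model is None:
            continue
        bic = _hmm_bic(best_ll, k, n)
        if best is None or bic < best[0]:
            best = (bic, best_model)
            worse_streak = 0
        else:
            worse_streak += 1
            if worse_streak >= 2:
                break
    if best is None:
        raise RuntimeError("HMM fitting failed to converge for all state counts")

    model = best[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        path = model.predict(X)
    means = model.means_.ravel()
    change = np.flatnonzero(np.diff(path) != 0) + 1
    bounds = [0, *change.tolist(), n]
    levels = np.array([means[path[a]] for a in bounds[:-1]])
    durations = np.diff(bounds)
    return StepFitResult(
        change_points=change.astype(int) + offset,
        plateau_levels=levels,
        pause_durations=durations,
        method="hmm",
        fit_quality=float(model.score(X)),
        offset=offset,
    )


def filter_steps(fit: StepFitResult, calibration: CalibrationCurve,
                 min_pause: int = 5, forward_sign: int = -1,
                 turning_point: int | None = None) -> AcceptedSteps:
    """Apply the step-acceptance criteria to an idealized trace.

    A step is kept only if (1) both flanking pauses last at least
    ``min_pause`` frames and (2) both flanking plateau FRET levels lie
    inside the calibration curve's linear range.  Steps against the
    expected translocation direction are tallied as backward and
    excluded.  ``forward_sign`` is the expected sign of ΔFRET (-1 for
    exit-side movement of end-labeled constructs); for entry-side
    rise-then-fall traces pass ``turning_point`` (a frame index) and the
    expected sign flips from +1 to -1 there.

    Pause durations flanking accepted steps are returned for lifetime
    analysis.
    """
    steps = []
    pauses: list[int] = []
    n_short = n_range = n_back = 0
    for i, size in enumerate(fit.step_sizes):
        d_before = fit.pause_durations[i]
        d_after = fit.pause_durations[i + 1]
        if d_before < min_pause or d_after < min_pause:
            n_short += 1
            continue
        lvl_before = fit.plateau_levels[i]
        lvl_after = fit.plateau_levels[i + 1]
        if not (calibration.contains(lvl_before) and calibration.contains(lvl_after)):
            n_range += 1
            continue
        if turning_point is None:
            expected = forward_sign
        else:
            expected = 1 if fit.change_points[i] <= turning_point else -1
        if np.sign(size) != np.sign(expected):
            n_back += 1
            continue
        steps.append(size)
        pauses.append(int(d_before))
    return AcceptedSteps(
        steps=np.asarray(steps, dtype=float),
        pause_durations=np.asarray(pauses, dtype=int),
        n_rejected_short=n_short,
        n_rejected_range=n_range,
        n_backward=n_back,
    )
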