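"""Step-size histograms and the missed-step Gaussian mixture model.

With a uniform fundamental step of size ``c`` (in ΔFRET) and a
probability ``f`` that the pause between two steps is too short to
detect, the observed step-size distribution is a train of evenly spaced
Gaussian peaks at n·c whose amplitudes fall geometrically:

    y(x) = Σ_{n=1..n_max} A · f^(n-1) · exp(-(x - n·c)² / (2 s²))

where ``s`` is the standard deviation of the step size.  ``s`` is fitted
globally across all histograms of the same movement type.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

from .stepfind import AcceptedSteps


@dataclass
class StepSizeHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    movement_type: str = ""
    construct: str = ""

    @property
    def x(self) -> np.ndarray:
        """Bin centers, the model's abscissa."""
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def n_steps(self) -> int:
        return int(self.counts.sum())


@dataclass
class EqOneFit:
    """Fitted missed-step mixture parameters for one histogram."""

    A: float
    f: float
    c: float
    s: float
    A_se: float
    f_se: float
    c_se: float
    s_se: float
    n_max: int
    shared_s: bool
    redchi: float
    f_at_bound: bool

    def model(self, x) -> np.ndarray:
        return step_mixture_model(np.asarray(x, float), self.A, self.f,
                                  self.c, self.s, self.n_max)


def step_mixture_model(x, A, f, c, s, n_max: int = 6):
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x)
    for n in range(1, n_max + 1):
        y += A * f ** (n - 1) * np.exp(-((x - n * c) ** 2) / (2.0 * s**2))
    return y


def build_step_histogram(steps, bin_width: float = 0.02,
                         movement_type: str = "",
                         construct: str = "") -> StepSizeHistogram:
    """Histogram of step-size magnitudes with fixed bin width from 0."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if isinstance(steps, AcceptedSteps):
        values = np.abs(steps.steps)
    else:
        values = np.abs(np.asarray(steps, dtype=float))
    if values.size == 0:
        raise ValueError("no accepted steps to histogram")
    # tolerant bin assignment so a value exactly on an edge (e.g. 0.10
    # with width 0.02) lands in the bin it opens despite float rounding
    idx = np.floor(values / bin_width + 1e-9).astype(int)
    nbins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=nbins)
    edges = bin_width * np.arange(nbins + 1)
    return StepSizeHistogram(bin_edges=edges, counts=counts,
                             movement_type=movement_type, construct=construct)


def _make_params(hists, n_max, shared_s, s0):
    params = lmfit.Parameters()
    params.add("s", value=s0, min=1e-4, max=0.2)
    for i, h in enumerate(hists):
        peak = float(h.x[np.argmax(h.counts)]) if h.counts.max() > 0 else 0.1
        params.add(f"A{i}", value=float(max(h.counts.max(), 1.0)), min=0.0)
        params.add(f"f{i}", value=0.3, min=0.0, max=0.999)
        params.add(f"c{i}", value=max(peak, 0.02), min=1e-3, max=0.5)
        if not shared_s:
            params.add(f"s{i}", value=s0, min=1e-4, max=0.2)
    return params


def _residual(params, hists, n_max, shared_s):
    res = []
    for i, h in enumerate(hists):
        s = params["s"].value if shared_s else params[f"s{i}"].value
        y = step_mixture_model(h.x, params[f"A{i}"].value, params[f"f{i}"].value,
                               params[f"c{i}"].value, s, n_max)
        res.append(y - h.counts)
    return np.concatenate(res)


def fit_eq1(histograms, n_max: int = 6, shared_s: bool = True,
            c_starts=None) -> list[EqOneFit]:
    """Fit the missed-step mixture to one or more step-size histograms.

    Nonlinear least squares on bin counts, jointly over histograms with a
    single shared width ``s`` (and per-histogram amplitude, missed-step
    probability and step size).  Initialization is multi-start over a
    grid of candidate step sizes; the best-residual solution is kept.
    Parameter standard errors come from the fit covariance.

    A single histogram degenerates to an independent fit.
    """
    if isinstance(histograms, StepSizeHistogram):
        histograms = [histograms]
    hists = list(histograms)
    if not hists:
        raise ValueError("no histograms given")
    types = {h.movement_type for h in hists}
    if len(types) > 1:
        raise ValueError(f"histograms mix movement types {sorted(types)}; "
                         "the shared width is only meaningful within one type")
    for h in hists:
        if np.count_nonzero(h.counts) < 10 and h.n_steps < 100:
            raise ValueError(
                "histogram too sparse to fit (< 10 nonzero bins and < 100 steps)"
            )
    bw = hists[0].bin_width
    if c_starts is None:
        peaks = [float(h.x[np.argmax(h.counts)]) for h in hists]
        base = float(np.median([p for p in peaks if p > 0] or [0.1]))
        c_starts = sorted({round(v, 4) for v in
                           [0.5 * base, 0.75 * base, base, 1.25 * base,
                            0.04, 0.06, 0.08, 0.10, 0.12] if v >= 1e-3})

    best = None
    for c0 in c_starts:
        for s0 in (bw, 1.5 * bw):
            params = _make_params(hists, n_max, shared_s, s0)
            for i in range(len(hists)):
                params[f"c{i}"].value = c0
            try:
                out = lmfit.minimize(_residual, params,
                                     args=(hists, n_max, shared_s),
                                     method="leastsq", xtol=1e-12, ftol=1e-12)
            except Exception:
                continue
            if best is None or out.chisqr < best.chisqr:
                best = out
    if best is None:
        raise RuntimeError("mixture fit failed to converge from all starts")

    def _se(par):
        return float(par.stderr) if par.stderr is not None else float("nan")

    results = []
    for i, h in enumerate(hists):
        p = best.params
        s_par = p["s"] if shared_s else p[f"s{i}"]
        f_par = p[f"f{i}"]
        results.append(EqOneFit(
            A=float(p[f"A{i}"].value), f=float(f_par.value),
            c=float(p[f"c{i}"].value), s=float(s_par.value),
            A_se=_se(p[f"A{i}"]), f_se=_se(f_par),
            c_se=_se(p[f"c{i}"]), s_se=_se(s_par),
            n_max=n_max, shared_s=shared_s,
            redchi=float(best.redchi),
            f_at_bound=bool(f_par.value <= f_par.min + 1e-9
                            or f_par.value >= f_par.max - 1e-9),
        ))
    return results
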