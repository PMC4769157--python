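"""Piecewise-constant least-squares fitting primitives.

Shared by the chi-square step finder and photobleach detection.  All
routines work on plain 1-D arrays; change points are indices ``k`` such
that segments are the half-open intervals ``[prev, k)`` and ``[k, next)``
(``k`` is the first frame of the new plateau).
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def prefix_sums(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    cs = np.concatenate(([0.0], np.cumsum(y)))
    cs2 = np.concatenate(([0.0], np.cumsum(y * y)))
    return cs, cs2


def segment_sse(cs: np.ndarray, cs2: np.ndarray, i: int, j: int) -> float:
    """Sum of squared residuals of y[i:j] about its mean."""
    n = j - i
    if n <= 1:
        return 0.0
    s = cs[j] - cs[i]
    s2 = cs2[j] - cs2[i]
    return max(s2 - s * s / n, 0.0)


def best_split(cs: np.ndarray, cs2: np.ndarray, i: int, j: int) -> tuple[int, float]:
    """Optimal single change point inside [i, j).

    Returns ``(k, sse)`` where ``k`` minimizes the two-plateau SSE.
    Requires ``j - i >= 2``.
    """
    ks = np.arange(i + 1, j)
    n1 = ks - i
    n2 = j - ks
    s1 = cs[ks] - cs[i]
    s2 = cs[j] - cs[ks]
    q1 = cs2[ks] - cs2[i]
    q2 = cs2[j] - cs2[ks]
    sse = (q1 - s1 * s1 / n1) + (q2 - s2 * s2 / n2)
    m = int(np.argmin(sse))
    return int(ks[m]), float(max(sse[m], 0.0))


def piecewise_sse(cs: np.ndarray, cs2: np.ndarray, cps, n: int) -> float:
    segs = [0, *cps, n]
    return sum(segment_sse(cs, cs2, a, b) for a, b in zip(segs[:-1], segs[1:]))


def plateau_means(y: np.ndarray, cps) -> np.ndarray:
    segs = [0, *cps, len(y)]
    return np.array([np.mean(y[a:b]) for a, b in zip(segs[:-1], segs[1:])])


def refine_change_points(cs, cs2, cps, n: int, max_iter: int = 20) -> list[int]:
    """Coordinate-descent re-optimization of each change point between its
    neighbors; converges to a local SSE minimum."""
    cps = list(cps)
    for _ in range(max_iter):
        moved = False
        for idx in range(len(cps)):
            a = cps[idx - 1] if idx > 0 else 0
            b = cps[idx + 1] if idx + 1 < len(cps) else n
            if b - a < 2:
                continue
            k, _ = best_split(cs, cs2, a, b)
            if k != cps[idx]:
                cps[idx] = k
                moved = True
        if not moved:
            break
    return sorted(cps)


def counterfit_sse(cs, cs2, cps, n: int) -> float:
    """SSE of the counter-fit: plateaus forced to break at the midpoints
    of the best fit's plateaus.  Real steps make this fit much worse than
    the best fit; pure noise makes the two comparable."""
    segs = [0, *cps, n]
    mids = sorted({(a + b) // 2 for a, b in zip(segs[:-1], segs[1:])} - {0, n})
    return piecewise_sse(cs, cs2, mids, n)


def robust_noise_sd(y: np.ndarray) -> float:
    """Noise SD from the median absolute first difference.

    Frame-to-frame differences of a piecewise-constant signal are pure
    noise except at the (few) change points, which the median ignores;
    1.4826 * MAD / sqrt(2) converts to the per-frame SD.
    """
    d = np.diff(np.asarray(y, dtype=float))
    if d.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d))) / np.sqrt(2.0)


def greedy_change_points(
    y: np.ndarray,
    max_steps: int = 30,
    quality_threshold: float = 1.3,
    refine: bool = True,
) -> tuple[list[int], float]:
    """Greedy chi-square-minimizing step placement with counter-fit
    model selection.

    Change points are inserted one at a time, each at the position that
    most reduces the total SSE (always inside the currently worst-fit
    segment).  An insertion is made only when its SSE gain exceeds the
    largest gain expected from pure noise over the trace (roughly
    2·σ²·ln n for Gaussian noise of variance σ², estimated robustly from
    first differences, plus safety margin).  The accepted model must
    additionally beat the counter-fit — the same number of plateaus
    broken at the fit's plateau midpoints — by the quality ratio
    ``SSE(counter-fit) / SSE(fit) >= quality_threshold``; otherwise zero
    steps are returned.

    Returns ``(change_points, sse)``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    cs, cs2 = prefix_sums(y)
    sse0 = segment_sse(cs, cs2, 0, n)
    scale = max(sse0, _EPS)
    null_factor = 2.0 * np.log(max(n, 2)) + 6.0

    cps: list[int] = []
    sse = sse0
    while len(cps) < max_steps:
        # noise variance from the current fit's residuals; un-captured
        # steps only inflate it, so the gate errs toward rejection
        sigma2 = sse / max(n - len(cps) - 1, 1)
        min_gain = max(sigma2 * null_factor, _EPS * scale)
        segs = [0, *cps, n]
        best_gain, best_k = 0.0, None
        for a, b in zip(segs[:-1], segs[1:]):
            if b - a < 2:
                continue
            k, s_after = best_split(cs, cs2, a, b)
            gain = segment_sse(cs, cs2, a, b) - s_after
            if gain > best_gain:
                best_gain, best_k = gain, k
        if best_k is None or best_gain < min_gain:
            break
        cps = sorted([*cps, best_k])
        if refine:
            cps = refine_change_points(cs, cs2, cps, n)
        sse = piecewise_sse(cs, cs2, cps, n)
        if sse <= _EPS * scale:
            break
    if not cps:
        return [], sse0
    cf = counterfit_sse(cs, cs2, cps, n)
    quality = np.inf if sse <= _EPS * scale else cf / sse
    if quality < quality_threshold:
        return [], sse0
    return cps, sse
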