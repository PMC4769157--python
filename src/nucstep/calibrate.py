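"""FRET-vs-linker-length calibration and unit conversions.

End-labeled nucleosome constructs show an approximately linear relation
between linker DNA length and mean FRET over the measured range, so a
translocation step of ``d`` bp produces a FRET change of ``|slope| * d``.
The calibration line is used both to convert fitted ΔFRET step sizes to
bp and to define the FRET interval inside which detected steps are
trusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit.models import GaussianModel
from scipy import stats


@dataclass
class CalibrationCurve:
    """Linear model FRET = intercept + slope * linker_bp.

    ``slope`` is signed as fitted; conversions to bp use its magnitude.
    ``fret_range`` is the FRET interval spanned by the calibration
    points, i.e. where the linear approximation holds.
    """

    slope: float
    intercept: float
    slope_se: float = 0.0
    fret_range: tuple[float, float] = (0.0, 1.0)
    points: pd.DataFrame | None = None
    enzyme_bound: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.slope) or self.slope == 0:
            raise ValueError("calibration slope must be finite and nonzero")
        lo, hi = self.fret_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("fret_range must be an increasing interval in [0, 1]")

    def predict(self, linker_bp) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(linker_bp, dtype=float)

    def contains(self, fret: float, tol: float = 1e-9) -> bool:
        lo, hi = self.fret_range
        return (lo - tol) <= fret <= (hi + tol)


#: Calibration slopes (FRET per bp, magnitude ± SE) measured for free
#: nucleosomes, per construct.  These are the slopes used by default to
#: convert ΔFRET step sizes to bp.
REFERENCE_SLOPES: dict[str, tuple[float, float]] = {
    "H2A/[end,+6]": (0.053, 0.004),
    "H3/[end,+6]": (0.059, 0.005),
    "H2A/[backbone,+6]": (0.057, 0.002),
    "H2A/[end,+12]": (0.055, 0.002),
    "H3/[end,+9]": (0.048, 0.004),
}

#: Slopes remeasured with the remodeler bound (donor photophysics shifts
#: the apparent FRET slightly); selectable via ``enzyme_bound=True``.
ENZYME_BOUND_SLOPES: dict[str, tuple[float, float]] = {
    "H2A/[end,+6]": (0.047, 0.005),
}


def reference_slope(construct_name: str, enzyme_bound: bool = False) -> tuple[float, float]:
    table = ENZYME_BOUND_SLOPES if enzyme_bound else REFERENCE_SLOPES
    if construct_name not in table:
        raise KeyError(f"no reference calibration slope for {construct_name!r}")
    return table[construct_name]


def fit_calibration(points, enzyme_bound: bool = False) -> CalibrationCurve:
    """Ordinary least-squares line through (linker_bp, mean FRET) points.

    Parameters
    ----------
    points
        Sequence of ``(linker_bp, mean_fret)`` or
        ``(linker_bp, mean_fret, sd)`` tuples, or a DataFrame with
        columns ``linker_bp`` and ``mean_fret``.  At least 3 distinct
        linker lengths are required.

    Returns
    -------
    CalibrationCurve
        With slope standard error from the regression and ``fret_range``
        set from the fitted means at the measured lengths.
    """
    if isinstance(points, pd.DataFrame):
        df = points[["linker_bp", "mean_fret"]].copy()
    else:
        rows = [(p[0], p[1]) for p in points]
        df = pd.DataFrame(rows, columns=["linker_bp", "mean_fret"])
    if df["linker_bp"].nunique() < 3:
        raise ValueError("calibration requires >= 3 distinct linker lengths")
    res = stats.linregress(df["linker_bp"].to_numpy(float),
                           df["mean_fret"].to_numpy(float))
    fitted = res.intercept + res.slope * df["linker_bp"].to_numpy(float)
    lo, hi = float(np.min(fitted)), float(np.max(fitted))
    lo = max(lo, 0.0)
    hi = min(hi, 1.0)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        fret_range=(lo, hi),
        points=df,
        enzyme_bound=enzyme_bound,
    )


@dataclass
class GaussianFretFit:
    mean: float
    sd: float
    amplitude: float
    r_squared: float
    good_fit: bool


def fit_gaussian_fret(samples, bins: int | str = "auto",
                      min_r_squared: float = 0.8) -> GaussianFretFit:
    """Fit a single Gaussian to the histogram of FRET samples.

    Returns the fitted mean and SD.  ``good_fit`` is False when the
    residuals indicate the distribution is not unimodal Gaussian
    (e.g. bimodal input), judged by R² of the histogram fit.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 20:
        raise ValueError("need >= 20 samples for a Gaussian fit")
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate (zero-variance) sample")
    counts, edges = np.histogram(x, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    model = GaussianModel()
    params = model.guess(counts.astype(float), x=centers)
    out = model.fit(counts.astype(float), params, x=centers)
    ss_res = float(np.sum(out.residual**2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return GaussianFretFit(
        mean=float(out.params["center"].value),
        sd=abs(float(out.params["sigma"].value)),
        amplitude=float(out.params["amplitude"].value),
        r_squared=r2,
        good_fit=r2 >= min_r_squared,
    )


def convert_step_to_bp(c: float, c_se: float,
                       calibration: CalibrationCurve) -> tuple[float, float]:
    """Convert a ΔFRET step size ± SE to bp ± SE.

    bp = c / |slope|; the relative errors of step size and slope combine
    in quadrature.  Report the result rounded to one decimal.
    """
    slope = abs(calibration.slope)
    if slope == 0:
        raise ValueError("calibration slope is zero")
    bp = c / slope
    if c == 0:
        return 0.0, 0.0
    rel = math.hypot(c_se / c, calibration.slope_se / slope)
    return bp, abs(bp) * rel


def calibration_from_slope(slope: float, slope_se: float = 0.0,
                           intercept: float = 0.0,
                           fret_range: tuple[float, float] = (0.0, 1.0),
                           enzyme_bound: bool = False) -> CalibrationCurve:
    """Convenience constructor when only a slope (e.g. a published value)
    is available."""
    return CalibrationCurve(slope=slope, intercept=intercept,
                            slope_se=slope_se, fret_range=fret_range,
                            enzyme_bound=enzyme_bound)


def fret_to_distance(fret: float, r0_nm: float = 6.0) -> float:
    """Dye separation from FRET efficiency: r = R0 * (1/E - 1)^(1/6).

    R0 defaults to 6 nm, the Förster radius of the Cy3-Cy5 pair.
    """
    if not 0.0 < fret < 1.0:
        raise ValueError("FRET must lie strictly between 0 and 1")
    if r0_nm <= 0:
        raise ValueError("Förster radius must be positive")
    return r0_nm * (1.0 / fret - 1.0) ** (1.0 / 6.0)


def distance_to_fret(r_nm: float, r0_nm: float = 6.0) -> float:
    if r_nm <= 0:
        raise ValueError("distance must be positive")
    return 1.0 / (1.0 + (r_nm / r0_nm) ** 6)


def distance_change(fret1: float, fret2: float, r0_nm: float = 6.0) -> float:
    """Change in dye separation (nm) for a FRET change fret1 -> fret2."""
    return fret_to_distance(fret2, r0_nm) - fret_to_distance(fret1, r0_nm)
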