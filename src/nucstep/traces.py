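"""Intensity traces, FRET computation, and single-molecule selection.

The raw unit of analysis is a two-channel (donor Cy3 / acceptor Cy5)
intensity time series for one immobilized nucleosome.  Traces are kept
only if the total fluorescence shows one-step photobleaching — the
signature of a single molecule — and the post-bleach segment provides
the background that is subtracted from both channels.  FRET is then the
uncorrected proximity ratio acceptor / (acceptor + donor).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _stepcore
from .constructs import ConstructSpec, get_construct

TRACE_COLUMNS = ["frame", "time_s", "donor", "acceptor"]


@dataclass
class IntensityTrace:
    """Per-frame donor/acceptor intensities with acquisition metadata."""

    donor: np.ndarray
    acceptor: np.ndarray
    frame_rate: float
    construct: ConstructSpec | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape or self.donor.ndim != 1:
            raise ValueError(
                f"trace {self.name!r}: donor/acceptor channels must be equal-length 1-D arrays"
            )
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return self.donor.size

    @property
    def frame(self) -> np.ndarray:
        return np.arange(self.donor.size)

    @property
    def time(self) -> np.ndarray:
        return self.frame / self.frame_rate

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": self.frame, "time_s": self.time,
             "donor": self.donor, "acceptor": self.acceptor}
        )


@dataclass
class FretTrace:
    """Background-corrected FRET efficiency series with validity mask."""

    fret: np.ndarray
    valid_mask: np.ndarray
    frame_rate: float
    initial_fret: float
    final_fret: float
    source: IntensityTrace | None = None

    def valid_values(self) -> np.ndarray:
        return self.fret[self.valid_mask]

    def valid_slice(self) -> tuple[int, int]:
        """Longest contiguous run of valid frames as [start, stop)."""
        idx = np.flatnonzero(self.valid_mask)
        if idx.size == 0:
            raise ValueError("no valid frames")
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        stops = np.concatenate((breaks + 1, [idx.size]))
        lengths = stops - starts
        i = int(np.argmax(lengths))
        return int(idx[starts[i]]), int(idx[stops[i] - 1]) + 1


@dataclass
class BleachCall:
    """Outcome of the one-step photobleaching test on a trace."""

    bleach_frame: int | None
    channel: str | None
    n_drops: int
    accepted: bool


# ---------------------------------------------------------------------------
# I/O

def write_traces(traces, directory, manifest_name: str = "manifest.yaml",
                 ground_truths=None) -> Path:
    """Write one TSV per trace plus a dataset manifest.

    Returns the manifest path.  Ground truths, if given (parallel to
    ``traces``), are stored as JSON files referenced from the manifest.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, trace in enumerate(traces):
        name = trace.name or f"trace_{i:04d}"
        fname = f"{name}.tsv"
        trace.to_frame().to_csv(directory / fname, sep="\t", index=False,
                                float_format="%.6f")
        entry = {
            "file": fname,
            "construct": trace.construct.name if trace.construct else None,
            "frame_rate": trace.frame_rate,
        }
        if ground_truths is not None:
            gt = ground_truths[i]
            gt_name = f"{name}.truth.json"
            with open(directory / gt_name, "w") as fh:
                json.dump(gt.to_dict() if hasattr(gt, "to_dict") else gt, fh,
                          indent=1)
            entry["ground_truth"] = gt_name
        entries.append(entry)
    manifest = {"traces": entries}
    path = directory / manifest_name
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def read_traces(manifest_path) -> list[IntensityTrace]:
    """Load all traces listed in a dataset manifest (YAML or JSON)."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        if manifest_path.suffix == ".json":
            manifest = json.load(fh)
        else:
            manifest = yaml.safe_load(fh)
    directory = manifest_path.parent
    traces = []
    for entry in manifest["traces"]:
        fpath = directory / entry["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"manifest references missing trace file: {fpath}")
        df = pd.read_csv(fpath, sep="\t")
        missing = [c for c in TRACE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{fpath}: missing columns {missing}")
        if df[TRACE_COLUMNS].isna().any().any():
            bad = int(df[TRACE_COLUMNS].isna().any(axis=1).idxmax())
            raise ValueError(f"{fpath}: malformed or unequal-length data near row {bad}")
        construct = None
        if entry.get("construct"):
            construct = get_construct(entry["construct"])
        traces.append(IntensityTrace(
            donor=df["donor"].to_numpy(),
            acceptor=df["acceptor"].to_numpy(),
            frame_rate=float(entry.get("frame_rate", 1.0)),
            construct=construct,
            name=fpath.stem,
        ))
    return traces


# ---------------------------------------------------------------------------
# Processing

def detect_photobleach(trace: IntensityTrace, max_steps: int = 8,
                       quality_threshold: float = 1.3,
                       min_drop_sigma: float = 3.0) -> BleachCall:
    """Test a trace for one-step photobleaching of the total intensity.

    The total (donor + acceptor) signal is idealized with the chi-square
    step finder; discrete downward level changes larger than
    ``min_drop_sigma`` times the final-plateau noise count as drops.  The
    trace is accepted only when exactly one drop exists and the signal
    stays at the post-drop baseline; the bleach frame is the first
    post-drop frame.
    """
    if len(trace) < 10:
        raise ValueError("trace too short for bleach detection (< 10 frames)")
    total = trace.total
    cps, _ = _stepcore.greedy_change_points(total, max_steps=max_steps,
                                            quality_threshold=quality_threshold)
    if not cps:
        return BleachCall(None, None, 0, False)
    levels = _stepcore.plateau_means(total, cps)
    segs = [0, *cps, len(total)]
    resid = total - np.repeat(levels, np.diff(segs))
    dof = max(len(total) - len(levels), 1)
    noise = float(np.sqrt(np.sum(resid**2) / dof))
    min_drop = max(min_drop_sigma * noise, 1e-9)
    steps = np.diff(levels)
    drop_idx = [i for i, s in enumerate(steps) if s < -min_drop]
    rise_idx = [i for i, s in enumerate(steps) if s > min_drop]
    n_drops = len(drop_idx)
    if n_drops != 1:
        return BleachCall(None, None, n_drops, False)
    i = drop_idx[0]
    bleach_frame = cps[i]
    # must drop to the final baseline and stay there
    stays = not any(j > i for j in rise_idx) and np.isclose(
        levels[i + 1], levels[-1], atol=max(min_drop, 1e-9)
    )
    # which channel vanished: larger fractional loss across the drop
    pre_d = float(np.mean(trace.donor[segs[i]:bleach_frame]))
    post_d = float(np.mean(trace.donor[bleach_frame:segs[i + 2]]))
    pre_a = float(np.mean(trace.acceptor[segs[i]:bleach_frame]))
    post_a = float(np.mean(trace.acceptor[bleach_frame:segs[i + 2]]))
    loss_d = pre_d - post_d
    loss_a = pre_a - post_a
    channel = "donor" if loss_d >= loss_a else "acceptor"
    return BleachCall(int(bleach_frame), channel, 1, bool(stays))


def subtract_background(trace: IntensityTrace, bleach: BleachCall,
                        min_post_frames: int = 10) -> IntensityTrace:
    """Subtract the per-channel mean of the post-bleach segment.

    The fluorescence after photobleaching is the camera/buffer
    background; its mean is removed from each channel over the whole
    trace.  Negative corrected values are ordinary noise.
    """
    if not bleach.accepted or bleach.bleach_frame is None:
        raise ValueError("background subtraction requires an accepted one-step bleach")
    post = slice(bleach.bleach_frame, len(trace))
    if len(trace) - bleach.bleach_frame < min_post_frames:
        raise ValueError(
            f"only {len(trace) - bleach.bleach_frame} post-bleach frames "
            f"(need >= {min_post_frames})"
        )
    return IntensityTrace(
        donor=trace.donor - np.mean(trace.donor[post]),
        acceptor=trace.acceptor - np.mean(trace.acceptor[post]),
        frame_rate=trace.frame_rate,
        construct=trace.construct,
        name=trace.name,
    )


def compute_fret(trace: IntensityTrace, bleach: BleachCall | None = None,
                 initial_window: int = 10) -> FretTrace:
    """Proximity-ratio FRET from a background-corrected trace.

    FRET = acceptor / (acceptor + donor), clipped to [0, 1].  Frames
    with non-positive total intensity, and all frames from the bleach
    frame on, are masked invalid.  ``initial_fret`` is the mean of the
    first ``initial_window`` valid frames, ``final_fret`` of the last.
    """
    total = trace.total
    valid = total > 0
    if bleach is not None and bleach.bleach_frame is not None:
        valid[bleach.bleach_frame:] = False
    fret = np.zeros(len(trace))
    np.divide(trace.acceptor, total, out=fret, where=valid)
    fret = np.clip(fret, 0.0, 1.0)
    fret[~valid] = np.nan
    vv = fret[valid]
    if vv.size == 0:
        raise ValueError("no valid frames for FRET computation")
    w = min(initial_window, vv.size)
    return FretTrace(
        fret=fret,
        valid_mask=valid,
        frame_rate=trace.frame_rate,
        initial_fret=float(np.mean(vv[:w])),
        final_fret=float(np.mean(vv[-w:])),
        source=trace,
    )


def median_filter(series, window: int = 3) -> np.ndarray:
    """Running median whose window truncates at the series edges.

    The median of an even number of points is the mean of the two
    central values.  NaNs (invalid frames) propagate unchanged.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    y = np.asarray(series, dtype=float)
    h = window // 2
    out = np.empty_like(y)
    for i in range(y.size):
        lo = max(0, i - h)
        win = y[lo:i + h + 1]
        if np.isnan(y[i]) or np.isnan(win).all():
            out[i] = y[i]
        else:
            out[i] = np.median(win[~np.isnan(win)])
    return out


def select_population(initial_fret: float, construct: ConstructSpec,
                      proximal_window: tuple[float, float] = (0.3, 1.0)) -> bool:
    """Population gate on the pre-remodeling FRET value.

    Octamer–octamer constructs keep molecules carrying both dyes
    (H2A/H2A: FRET > 0.2; H2B/H2B: FRET > 0.1).  DNA-labeled constructs
    keep only the proximal-donor population, which gives the highest
    FRET, via a configurable window.
    """
    if not np.isfinite(initial_fret):
        raise ValueError("initial_fret undefined")
    if construct.acceptor_placement == "octamer":
        if construct.donor_site == "H2A":
            return initial_fret > 0.2
        if construct.donor_site == "H2B":
            return initial_fret > 0.1
        raise ValueError(f"no population gate configured for {construct.name!r}")
    lo, hi = proximal_window
    return lo <= initial_fret <= hi


def intensity_ratio(trace: IntensityTrace, event_frame: int,
                    window: int = 10) -> tuple[float, float]:
    """Per-channel mean(after)/mean(before) around an event frame.

    Used to separate dye photophysics from distance changes: a genuine
    FRET change anticorrelates the channels, whereas donor brightening
    upon enzyme binding raises donor without lowering acceptor.
    """
    if event_frame - window < 0 or event_frame + window > len(trace):
        raise ValueError("insufficient frames on one side of event_frame")
    before = slice(event_frame - window, event_frame)
    after = slice(event_frame, event_frame + window)
    d0 = float(np.mean(trace.donor[before]))
    a0 = float(np.mean(trace.acceptor[before]))
    if d0 == 0 or a0 == 0:
        raise ValueError("zero mean intensity in the before-window")
    return (float(np.mean(trace.donor[after])) / d0,
            float(np.mean(trace.acceptor[after])) / a0)


def sum_singles(traces) -> np.ndarray:
    """Per-frame sum of acceptor channels over many single-molecule
    traces — the single-molecule reconstruction of the ensemble decay."""
    n = min(len(t) for t in traces)
    return np.sum([t.acceptor[:n] for t in traces], axis=0)


def normalize_ensemble(curve, window: int = 10) -> np.ndarray:
    """Affine rescale of an acceptor decay so the initial steady state is
    1 and the final steady state is 0."""
    y = np.asarray(curve, dtype=float)
    if y.size < 2 * window:
        raise ValueError("curve too short to define initial and final levels")
    y0 = float(np.mean(y[:window]))
    y1 = float(np.mean(y[-window:]))
    if np.isclose(y0, y1):
        raise ValueError("degenerate normalization: initial and final levels equal")
    return (y - y1) / (y0 - y1)
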