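"""Core data types for calcium-imaging trace analysis.

A recording is a per-soma fluorescence intensity series sampled at a fixed
frame interval (0.478 s for the recordings this package targets).  The
spontaneous-activity segment before ionomycin application is the *analysis
window*; the post-ionomycin saturation plateau defines the maximal
fluorescence Fmax used for normalization.

Conventions used throughout the package:

* frame indexing is 0-based;
* analysis windows ``[a, b]`` are inclusive at both ends;
* window duration is ``(b - a + 1) * dt`` seconds;
* firing rates are reported per minute;
* a metric that cannot be computed (e.g. mean clearance time of a cell with
  no transients) is ``None`` in memory and an empty field in tables — never
  a fake zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("catrace")

#: Frame interval (seconds) of the recordings this package was written for.
DEFAULT_DT = 0.478

#: Headroom allowed above 1.0 for normalized traces: plateau shot noise puts
#: individual frames slightly above the estimated Fmax.
SATURATION_TOL = 0.1

METRICS_COLUMNS = [
    "cell_id",
    "n_transients",
    "firing_rate_per_min",
    "clearance_time_s",
    "amplitude",
    "mean_signal",
]


class TraceValidationError(ValueError):
    """An input trace violates a structural invariant."""


@dataclass(frozen=True)
class FluorescenceTrace:
    """One cell's fluorescence intensity series.

    Parameters
    ----------
    cell_id
        Identifier of the soma ROI the trace was extracted from.
    values
        Intensity per frame; arbitrary fluorescence units, or dimensionless
        F/Fmax once ``normalized`` is set.
    dt
        Frame interval in seconds.
    analysis_window
        Inclusive frame range ``(a, b)`` of the spontaneous-activity segment
        (before ionomycin).  Defaults to the whole trace.
    normalized
        True once values are F/Fmax.
    """

    cell_id: str
    values: np.ndarray
    dt: float = DEFAULT_DT
    analysis_window: tuple[int, int] | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.array(self.values, dtype=float, copy=True)
        if v.ndim != 1:
            raise TraceValidationError("trace values must be one-dimensional")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)
        if self.analysis_window is None:
            object.__setattr__(self, "analysis_window", (0, len(v) - 1))
        else:
            a, b = self.analysis_window
            object.__setattr__(self, "analysis_window", (int(a), int(b)))

    @property
    def n_frames(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds."""
        return np.arange(self.n_frames) * self.dt

    @property
    def window_duration_s(self) -> float:
        a, b = self.analysis_window
        return (b - a + 1) * self.dt

    @property
    def window_values(self) -> np.ndarray:
        a, b = self.analysis_window
        return self.values[a : b + 1]


def validate_trace(
    trace: FluorescenceTrace, saturation_tol: float = SATURATION_TOL
) -> FluorescenceTrace:
    """Check all structural invariants; return the trace unchanged if valid.

    Raises
    ------
    TraceValidationError
        Naming the first violated invariant: empty series, non-finite or
        negative value (with the offending frame), window out of range,
        non-positive frame interval, or a normalized trace exceeding the
        saturation ceiling.
    """
    v = trace.values
    if len(v) == 0:
        raise TraceValidationError(f"{trace.cell_id}: empty trace")
    bad = np.flatnonzero(~np.isfinite(v))
    if bad.size:
        raise TraceValidationError(
            f"{trace.cell_id}: non-finite value at frame {bad[0]}"
        )
    neg = np.flatnonzero(v < 0)
    if neg.size:
        raise TraceValidationError(
            f"{trace.cell_id}: negative value at frame {neg[0]}"
        )
    if not trace.dt > 0:
        raise TraceValidationError(
            f"{trace.cell_id}: non-positive frame interval dt={trace.dt}"
        )
    a, b = trace.analysis_window
    if not (0 <= a <= b < len(v)):
        raise TraceValidationError(
            f"{trace.cell_id}: window out of range: [{a}, {b}] for {len(v)} frames"
        )
    if trace.normalized and v.max() > 1.0 + saturation_tol:
        raise TraceValidationError(
            f"{trace.cell_id}: normalized trace exceeds 1 + {saturation_tol} "
            f"(max {v.max():.4g})"
        )
    return trace


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the windowed transient-detection rule.

    A frame ``n`` is a transient candidate when it is a local maximum over
    ``[n - delta, n + delta]`` and its value exceeds ``(1 + gamma)`` times
    the local mean over ``[n - theta, n + theta]``.  Runs of candidate
    frames separated by at most ``merge_gap`` frames collapse to a single
    event (``merge_gap`` defaults to ``delta``).
    """

    delta: int = 3
    theta: int = 7
    gamma: float = 0.25
    merge_gap: int | None = None

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.theta < 1:
            raise ValueError("theta must be >= 1")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.merge_gap is not None and self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")

    @property
    def gap(self) -> int:
        """Effective merge gap in frames."""
        return self.delta if self.merge_gap is None else self.merge_gap

    @property
    def margin(self) -> int:
        """Half-width of the largest neighbourhood the rule inspects."""
        return max(self.delta, self.theta)


@dataclass(frozen=True)
class TransientEvent:
    """One detected calcium transient.

    ``half_decay_s`` is the time from the peak to the first crossing of
    ``baseline + amplitude / 2``, or ``None`` when the signal never falls
    that far before the next event or the end of the analysis window.
    """

    peak_frame: int
    peak_value: float
    baseline: float
    amplitude: float
    half_decay_s: float | None

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.half_decay_s is not None and self.half_decay_s < 0:
            raise ValueError("half_decay_s must be >= 0 when present")


@dataclass(frozen=True)
class CellMetrics:
    """Per-cell activity summary over the analysis window.

    ``clearance_time_s`` and ``amplitude`` are ``None`` exactly when no
    qualifying transient exists (no transient at all for the amplitude; no
    transient with a defined half-decay for the clearance time).
    """

    cell_id: str
    n_transients: int
    firing_rate_per_min: float
    clearance_time_s: float | None
    amplitude: float | None
    mean_signal: float


@dataclass(frozen=True)
class CalibrationParams:
    """Single-wavelength indicator calibration.

    ``f_min`` is the fluorescence in the zero-calcium / BAPTA condition,
    ``f_max`` the calcium-saturated (ionomycin) fluorescence, and ``kd_nM``
    the indicator dissociation constant.  No default Kd is baked in; a
    typical literature value for the Fluo-4 class of indicators is around
    345 nM, but it must be supplied explicitly.
    """

    f_min: float
    f_max: float
    kd_nM: float

    def __post_init__(self) -> None:
        if not self.f_min >= 0:
            raise ValueError("f_min must be >= 0")
        if not self.f_max > self.f_min:
            raise ValueError("f_max must be > f_min")
        if not self.kd_nM > 0:
            raise ValueError("kd_nM must be > 0")


# ---------------------------------------------------------------------------
# Table input/output
# ---------------------------------------------------------------------------

def write_traces(traces: Sequence[FluorescenceTrace], path: str | Path) -> None:
    """Write traces as a wide CSV: ``time_s`` column plus one column per cell.

    All traces must share frame count and frame interval.  Values are
    written with full repr precision so a round trip is exact.
    """
    if not traces:
        raise ValueError("no traces to write")
    n = traces[0].n_frames
    dt = traces[0].dt
    for t in traces:
        if t.n_frames != n or t.dt != dt:
            raise ValueError("all traces in one table must share length and dt")
    data = {"time_s": np.arange(n) * dt}
    for t in traces:
        data[t.cell_id] = t.values
    # %.17g round-trips every IEEE double exactly
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_traces(
    path: str | Path,
    analysis_window: tuple[int, int] | None = None,
    normalized: bool = False,
) -> list[FluorescenceTrace]:
    """Read a wide trace CSV (first column ``time_s``, one column per cell).

    Lines starting with ``#`` are ignored.  The frame interval is inferred
    from the ``time_s`` column.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.shape[1] < 2:
        raise TraceValidationError(f"{path}: expected time_s plus >=1 cell column")
    time_col = df.columns[0]
    tt = df[time_col].to_numpy(dtype=float)
    dt = float(np.median(np.diff(tt))) if len(tt) > 1 else DEFAULT_DT
    return [
        FluorescenceTrace(
            cell_id=str(c),
            values=df[c].to_numpy(dtype=float),
            dt=dt,
            analysis_window=analysis_window,
            normalized=normalized,
        )
        for c in df.columns[1:]
    ]


def metrics_to_frame(metrics: Sequence[CellMetrics]) -> pd.DataFrame:
    """Tabulate per-cell metrics; missing values become NaN."""
    rows = [
        {
            "cell_id": m.cell_id,
            "n_transients": m.n_transients,
            "firing_rate_per_min": m.firing_rate_per_min,
            "clearance_time_s": np.nan if m.clearance_time_s is None else m.clearance_time_s,
            "amplitude": np.nan if m.amplitude is None else m.amplitude,
            "mean_signal": m.mean_signal,
        }
        for m in metrics
    ]
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def write_metrics(metrics: Sequence[CellMetrics], path: str | Path) -> None:
    """Write the per-cell metrics table (tab-separated, empty field = missing)."""
    metrics_to_frame(metrics).to_csv(path, sep="\t", index=False, na_rep="")


def read_metrics(path: str | Path) -> list[CellMetrics]:
    """Read a metrics table written by :func:`write_metrics`."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(
            CellMetrics(
                cell_id=str(r["cell_id"]),
                n_transients=int(r["n_transients"]),
                firing_rate_per_min=float(r["firing_rate_per_min"]),
                clearance_time_s=None if pd.isna(r["clearance_time_s"]) else float(r["clearance_time_s"]),
                amplitude=None if pd.isna(r["amplitude"]) else float(r["amplitude"]),
                mean_signal=float(r["mean_signal"]),
            )
        )
    return out
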