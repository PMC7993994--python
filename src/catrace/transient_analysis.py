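"""Transient detection and per-cell activity statistics.

The detection rule marks frame ``n`` as a transient when both hold:

(i)  ``F(n) >= F(a)`` for every ``a`` in ``[n - delta, n + delta]``
     (local maximum, ties allowed), and
(ii) ``F(n) > (1 + gamma) / (2*theta + 1) * sum_{j=n-theta}^{n+theta} F(j)``
     (the frame exceeds its local mean by the relative margin ``gamma``).

Both conditions are homogeneous in F, so detection is invariant under
rescaling (in particular under Fmax normalization) but not under additive
offsets — a large constant makes condition (ii) strictly harder, which is
why normalization precedes detection in the standard workflow.

Frames closer than ``max(delta, theta)`` to either end of the analysis
window are never tested (complete-window rule), and runs of qualifying
frames separated by at most ``merge_gap`` frames collapse to one event at
the highest-F frame (earliest on exact ties), so a flat-topped transient
counts once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.stats import ttest_ind

from .trace_model import (
    CellMetrics,
    DetectionParams,
    FluorescenceTrace,
    TransientEvent,
)
from .normalization import estimate_baseline

log = logging.getLogger("catrace")


@dataclass(frozen=True)
class DetectionResult:
    """Ordered transient events detected in one cell's analysis window."""

    cell_id: str
    events: tuple[TransientEvent, ...]
    params: DetectionParams
    window: tuple[int, int]

    @property
    def peak_frames(self) -> list[int]:
        return [e.peak_frame for e in self.events]


def is_transient_frame(
    trace: FluorescenceTrace, n: int, params: DetectionParams
) -> bool:
    """Evaluate the two detection conditions at a single frame.

    Pure function of the ``2 * max(delta, theta) + 1`` values surrounding
    ``n``; requires the full neighbourhood to exist.
    """
    m = params.margin
    if n - m < 0 or n + m >= trace.n_frames:
        raise ValueError(
            f"frame {n} lacks a complete +/-{m} neighbourhood "
            f"(trace has {trace.n_frames} frames)"
        )
    v = trace.values
    d, t = params.delta, params.theta
    if v[n] < v[n - d : n + d + 1].max():
        return False
    local_sum = float(v[n - t : n + t + 1].sum())
    return v[n] > (1.0 + params.gamma) / (2 * t + 1) * local_sum


def _qualifying_frames(
    values: np.ndarray, a: int, b: int, params: DetectionParams
) -> np.ndarray:
    """Frames in [a + margin, b - margin] passing both conditions (pre-merge)."""
    m = params.margin
    lo, hi = a + m, b - m
    if lo > hi:
        return np.empty(0, dtype=int)
    d, t = params.delta, params.theta
    # both filters only touch frames inside [a, b] for candidates in [lo, hi]
    local_max = maximum_filter1d(values, size=2 * d + 1, mode="nearest")
    win = np.lib.stride_tricks.sliding_window_view(values, 2 * t + 1)
    local_sum = win.sum(axis=1)  # local_sum[k] covers frames [k, k + 2t]
    idx = np.arange(lo, hi + 1)
    cond_i = values[idx] >= local_max[idx]
    cond_ii = values[idx] > (1.0 + params.gamma) / (2 * t + 1) * local_sum[idx - t]
    return idx[cond_i & cond_ii]


def _merge_qualifying(
    values: np.ndarray, frames: np.ndarray, gap: int
) -> list[int]:
    """Collapse runs of qualifying frames separated by <= gap frames.

    Each run is represented by its highest-F frame, earliest on exact ties.
    """
    peaks: list[int] = []
    group: list[int] = []
    for f in frames:
        if group and f - group[-1] > gap:
            peaks.append(max(group, key=lambda j: (values[j], -j)))
            group = []
        group.append(int(f))
    if group:
        peaks.append(max(group, key=lambda j: (values[j], -j)))
    return peaks


def clearance_time(
    trace: FluorescenceTrace,
    event: TransientEvent,
    truncate_frame: int | None = None,
) -> float | None:
    """Time (s) from the peak to the first crossing of half amplitude.

    The reference level is ``baseline + amplitude / 2``; the crossing
    instant is located by linear interpolation between the bracketing
    frames.  The search stops at ``truncate_frame`` (inclusive; typically
    the next event's peak) or the end of the analysis window, and returns
    ``None`` when the level is not reached before truncation.
    """
    v = trace.values
    p = event.peak_frame
    level = event.baseline + event.amplitude / 2.0
    last = trace.analysis_window[1] if truncate_frame is None else truncate_frame
    last = min(last, trace.n_frames - 1)
    if event.amplitude == 0:
        return 0.0
    prev = v[p]
    for j in range(p + 1, last + 1):
        if v[j] <= level:
            frac = (prev - level) / (prev - v[j]) if prev > v[j] else 1.0
            return ((j - 1 - p) + frac) * trace.dt
        prev = v[j]
    return None


def detect_transients(
    trace: FluorescenceTrace,
    params: DetectionParams | None = None,
    baseline: np.ndarray | None = None,
    baseline_window: int = 21,
    baseline_percentile: float = 20.0,
) -> DetectionResult:
    """Detect transients in the analysis window and annotate each event.

    Events carry the rolling-percentile baseline at the peak, the amplitude
    above that baseline (floored at zero), and the half-decay time
    truncated at the next event's peak.  The rule is scale-invariant, so
    raw traces are permitted, but operating on non-normalized input is
    logged.
    """
    if params is None:
        params = DetectionParams()
    if trace.n_frames <= 2 * params.margin:
        raise ValueError(
            f"trace too short: {trace.n_frames} frames <= 2*max(delta, theta)"
        )
    if not trace.normalized:
        log.info("%s: detecting on a non-normalized trace", trace.cell_id)
    a, b = trace.analysis_window
    frames = _qualifying_frames(trace.values, a, b, params)
    peaks = _merge_qualifying(trace.values, frames, params.gap)
    if baseline is None:
        baseline = estimate_baseline(
            trace, window_frames=baseline_window, percentile=baseline_percentile
        )
    events = []
    for k, p in enumerate(peaks):
        base = float(baseline[p])
        peak_value = float(trace.values[p])
        amplitude = max(0.0, peak_value - base)
        stub = TransientEvent(
            peak_frame=p,
            peak_value=peak_value,
            baseline=base,
            amplitude=amplitude,
            half_decay_s=None,
        )
        trunc = peaks[k + 1] if k + 1 < len(peaks) else b
        events.append(
            TransientEvent(
                peak_frame=p,
                peak_value=peak_value,
                baseline=base,
                amplitude=amplitude,
                half_decay_s=clearance_time(trace, stub, truncate_frame=trunc),
            )
        )
    return DetectionResult(
        cell_id=trace.cell_id, events=tuple(events), params=params, window=(a, b)
    )


def summarize_cell(
    result: DetectionResult, trace: FluorescenceTrace
) -> CellMetrics:
    """Per-cell summary: count, firing rate, mean clearance time, mean
    amplitude, mean signal over the analysis window.

    The firing rate divides the transient count by the window duration in
    minutes.  Cells without qualifying transients report missing (``None``)
    clearance time / amplitude rather than zero.
    """
    if result.cell_id != trace.cell_id:
        raise ValueError(
            f"cell_id mismatch: result {result.cell_id!r} vs trace {trace.cell_id!r}"
        )
    n = len(result.events)
    minutes = trace.window_duration_s / 60.0
    decays = [e.half_decay_s for e in result.events if e.half_decay_s is not None]
    amps = [e.amplitude for e in result.events]
    if n == 0:
        log.warning("%s: no transients detected", trace.cell_id)
    return CellMetrics(
        cell_id=trace.cell_id,
        n_transients=n,
        firing_rate_per_min=n / minutes,
        clearance_time_s=float(np.mean(decays)) if decays else None,
        amplitude=float(np.mean(amps)) if amps else None,
        mean_signal=float(trace.window_values.mean()),
    )


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample unpaired t-test on a per-cell metric."""

    field: str
    statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    n_missing_a: int
    n_missing_b: int
    equal_var: bool


def _field_values(metrics: Sequence[CellMetrics], field: str) -> tuple[np.ndarray, int]:
    vals = [getattr(m, field) for m in metrics]
    present = np.array([v for v in vals if v is not None], dtype=float)
    return present, len(vals) - len(present)


def compare_groups(
    metrics_a: Sequence[CellMetrics],
    metrics_b: Sequence[CellMetrics],
    field: str,
    equal_var: bool = False,
) -> GroupComparison:
    """Unpaired two-tailed t-test between two groups of cells.

    Welch's variant is the default; ``equal_var=True`` gives the classic
    pooled-variance Student test.  Missing per-cell values are excluded and
    counted.
    """
    va, ma = _field_values(metrics_a, field)
    vb, mb = _field_values(metrics_b, field)
    if len(va) < 2 or len(vb) < 2:
        raise ValueError(
            f"need >=2 non-missing values per group for {field!r} "
            f"(got {len(va)} and {len(vb)})"
        )
    res = ttest_ind(va, vb, equal_var=equal_var)
    sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(len(x)))
    return GroupComparison(
        field=field,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_a=float(va.mean()),
        mean_b=float(vb.mean()),
        sem_a=sem(va),
        sem_b=sem(vb),
        n_a=len(va),
        n_b=len(vb),
        n_missing_a=ma,
        n_missing_b=mb,
        equal_var=equal_var,
    )
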