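"""Fmax normalization, baseline estimation and absolute-calcium calibration.

Ionomycin saturates the indicator at the end of each recording; the plateau
it produces defines the maximal fluorescence Fmax, and dividing the whole
trace by Fmax makes signals comparable across cells.  A zero-calcium /
BAPTA condition defines the floor Fmin, and the standard single-wavelength
dye equation

    [Ca2+] = Kd * (F - Fmin) / (Fmax - F)

converts fluorescence to absolute concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import percentile_filter

from .trace_model import CalibrationParams, FluorescenceTrace

_FMAX_STATS = {"median": np.median, "mean": np.mean, "max": np.max}


@dataclass(frozen=True)
class SaturationSegment:
    """Inclusive frame range of the post-ionomycin plateau used for Fmax."""

    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ValueError("start_frame must be <= end_frame")


def estimate_fmax(
    trace: FluorescenceTrace,
    segment: SaturationSegment,
    stat: str = "median",
) -> float:
    """Summarize the saturation plateau into a scalar Fmax.

    The default statistic is the median, which is robust to shot noise on
    the plateau; ``mean`` and ``max`` are also available.
    """
    if stat not in _FMAX_STATS:
        raise ValueError(f"unknown fmax statistic {stat!r}")
    if not (0 <= segment.start_frame <= segment.end_frame < trace.n_frames):
        raise ValueError(
            f"saturation segment [{segment.start_frame}, {segment.end_frame}] "
            f"out of range for {trace.n_frames} frames"
        )
    a, b = trace.analysis_window
    if segment.start_frame <= b:
        raise ValueError("saturation segment must lie after the analysis window")
    return float(_FMAX_STATS[stat](trace.values[segment.start_frame : segment.end_frame + 1]))


def normalize_to_fmax(trace: FluorescenceTrace, fmax: float) -> FluorescenceTrace:
    """Divide every value by ``fmax`` and set the normalized flag.

    The frame interval, analysis window and cell id are unchanged.
    """
    if not fmax > 0:
        raise ValueError("fmax must be > 0")
    return replace(trace, values=trace.values / fmax, normalized=True)


def estimate_baseline(
    trace: FluorescenceTrace,
    method: str = "rolling_percentile",
    window_frames: int = 21,
    percentile: float = 20.0,
) -> np.ndarray:
    """Per-frame baseline estimate.

    A centered rolling-percentile filter (default: 20th percentile over 21
    frames, about 10 s at 0.478 s per frame) tracks slow baseline drift
    while staying below sparse transients.  Edges repeat the nearest
    complete window.  For a constant trace the baseline equals that
    constant everywhere.
    """
    if method != "rolling_percentile":
        raise ValueError(f"unknown baseline method {method!r}")
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    if window_frames > trace.n_frames:
        raise ValueError(
            f"baseline window ({window_frames} frames) larger than trace "
            f"({trace.n_frames} frames)"
        )
    return percentile_filter(
        trace.values, percentile, size=window_frames, mode="nearest"
    )


def absolute_calcium(f: float, calib: CalibrationParams) -> float:
    """Convert normalized-or-raw fluorescence to absolute [Ca2+] in nM.

    Implements ``Kd * (F - Fmin) / (Fmax - F)``, valid for
    ``f_min <= f < f_max``; strictly increasing in ``f`` and divergent as
    ``f`` approaches saturation.
    """
    f = float(f)
    if f < calib.f_min:
        raise ValueError(f"fluorescence {f} below calibration floor f_min={calib.f_min}")
    if f >= calib.f_max:
        raise ValueError(f"fluorescence {f} at or above saturation f_max={calib.f_max}")
    return calib.kd_nM * (f - calib.f_min) / (calib.f_max - f)
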