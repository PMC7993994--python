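"""Minimal diagnostic plots (requires matplotlib)."""

from __future__ import annotations

from .trace_model import FluorescenceTrace
from .transient_analysis import DetectionResult


def plot_trace(trace: FluorescenceTrace, result: DetectionResult | None = None, ax=None):
    """Plot one trace with its analysis window and detected peaks."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    ax.plot(trace.times, trace.values, lw=0.8, color="tab:blue")
    a, b = trace.analysis_window
    ax.axvspan(a * trace.dt, b * trace.dt, color="0.92", zorder=0)
    if result is not None:
        pf = result.peak_frames
        ax.plot([p * trace.dt for p in pf], trace.values[pf], "v",
                color="tab:red", ms=5, label=f"{len(pf)} transients")
        ax.legend(loc="upper left", frameon=False)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("F/Fmax" if trace.normalized else "F (a.u.)")
    ax.set_title(trace.cell_id)
    return ax
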