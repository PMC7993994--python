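"""Synthetic fluorescence traces with ground truth.

Emulates recordings of spontaneously active cortical neurons: a 478 s
analysis window sampled every 478 ms, sparse calcium transients with a
one-frame rise and exponential decay, lognormal event amplitudes, slow
sinusoidal baseline drift, additive Gaussian noise, and (optionally) a
terminal ionomycin saturation plateau at Fmax.  Event times follow a
Poisson process thinned by a hard refractory gap, so the expected realized
rate is ``lambda / (1 + lambda * refractory)`` for Poisson intensity
``lambda``.

Every cell is a pure function of ``(spec.seed, cell_index)``; regenerating
a cohort is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .trace_model import FluorescenceTrace
from .transient_analysis import DetectionResult


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters of one synthetic cohort.

    Rates are per minute, times in seconds, signal levels in normalized
    (fraction-of-Fmax) units; ``fmax_raw`` scales the assembled normalized
    signal into raw fluorescence units.
    """

    n_cells: int = 50
    duration_s: float = 478.0
    dt: float = 0.478
    event_rate_per_min: float = 6.0
    refractory_s: float = 3.0
    amplitude_mean: float = 0.3
    amplitude_cv: float = 0.25
    tau_s: float = 1.5
    rise_frames: int = 1
    baseline_level: float = 0.15
    noise_sd: float = 0.02
    drift_amplitude: float = 0.01
    drift_period_s: float = 120.0
    edge_guard_s: float = 5.0
    ionomycin: bool = True
    ramp_s: float = 10.0
    plateau_s: float = 60.0
    fmax_raw: float = 2.0
    fmin_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not (self.dt > 0 and self.duration_s > 0 and self.tau_s > 0):
            raise ValueError("dt, duration_s and tau_s must be > 0")
        for name in (
            "event_rate_per_min", "refractory_s", "amplitude_mean",
            "amplitude_cv", "baseline_level", "noise_sd", "drift_amplitude",
            "edge_guard_s", "ramp_s", "plateau_s", "fmin_frac",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rise_frames < 0:
            raise ValueError("rise_frames must be >= 0")
        if not self.fmax_raw > 0:
            raise ValueError("fmax_raw must be > 0")

    @property
    def n_frames(self) -> int:
        """Frames in the analysis window."""
        return int(round(self.duration_s / self.dt))

    @property
    def event_span_s(self) -> float:
        """Length of the interval events are drawn on (window minus guards)."""
        return max(0.0, self.duration_s - 2.0 * self.edge_guard_s)

    @property
    def thinned_rate_per_min(self) -> float:
        """Long-run event rate of the refractory-thinned Poisson process."""
        lam = self.event_rate_per_min / 60.0
        return 60.0 * lam / (1.0 + lam * self.refractory_s)

    @property
    def expected_rate_per_min(self) -> float:
        """Expected realized events per minute of analysis window.

        The thinned long-run rate scaled by the fraction of the window the
        edge guard leaves available.
        """
        if self.duration_s == 0:
            return 0.0
        return self.thinned_rate_per_min * self.event_span_s / self.duration_s


@dataclass(frozen=True)
class GroundTruth:
    """True event table and generative levels for one synthetic cell."""

    cell_id: str
    event_times_s: np.ndarray
    event_frames: np.ndarray
    event_amplitudes: np.ndarray
    tau_s: float
    baseline: np.ndarray  # noise-free baseline + drift, normalized units
    fmax: float
    fmin: float


def _thin_refractory(times: np.ndarray, refractory_s: float) -> np.ndarray:
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= refractory_s:
            kept.append(float(t))
    return np.asarray(kept)


def simulate_cell(
    spec: SyntheticSpec,
    cell_index: int,
    event_frames: Sequence[int] | None = None,
    event_amplitudes: Sequence[float] | None = None,
) -> tuple[FluorescenceTrace, GroundTruth]:
    """Generate one cell's raw-unit trace and its ground truth.

    The normalized signal is ``clip(baseline + drift + sum of event
    kernels + noise, 0, inf)`` scaled by ``fmax_raw``; each kernel rises
    linearly over ``rise_frames`` frames and decays as ``exp(-t / tau_s)``
    with the peak value equal to the drawn amplitude.  When ``ionomycin``
    is set, a linear onset ramp and a noisy plateau at Fmax follow the
    analysis window.

    ``event_frames`` (with optional ``event_amplitudes``) bypasses the
    stochastic point process and plants events at known frames — useful
    for constructing exactly known test traces.
    """
    rng = np.random.default_rng([spec.seed, cell_index])
    n = spec.n_frames
    cell_id = f"cell{cell_index:03d}"

    lam = spec.event_rate_per_min / 60.0
    if event_frames is not None:
        frames = np.asarray(event_frames, dtype=int)
        times = frames * spec.dt
    else:
        # event times: Poisson process on the guarded interval, thinned by
        # the refractory gap; the edge guard keeps every event's local
        # neighbourhood inside the analysis window
        g = spec.edge_guard_s
        n_pts = rng.poisson(lam * spec.event_span_s)
        times = _thin_refractory(
            np.sort(rng.uniform(g, g + spec.event_span_s, n_pts)),
            spec.refractory_s,
        )
        frames = np.round(times / spec.dt).astype(int)
        keep = frames < n
        times, frames = times[keep], frames[keep]
    if event_amplitudes is not None:
        amps = np.asarray(event_amplitudes, dtype=float)
    elif spec.amplitude_cv == 0:
        amps = np.full(len(frames), spec.amplitude_mean)
    else:
        sig_ln = np.sqrt(np.log1p(spec.amplitude_cv**2))
        amps = rng.lognormal(np.log(spec.amplitude_mean) - 0.5 * sig_ln**2,
                             sig_ln, len(frames)) if len(frames) else np.empty(0)

    t_grid = np.arange(n) * spec.dt
    phase = rng.uniform(0.0, 2.0 * np.pi)
    baseline = spec.baseline_level + spec.drift_amplitude * np.sin(
        2.0 * np.pi * t_grid / spec.drift_period_s + phase
    )
    signal = baseline.copy()
    r = spec.rise_frames
    for p, a in zip(frames, amps):
        decay = a * np.exp(-np.arange(n - p) * spec.dt / spec.tau_s)
        signal[p:] += decay
        for j in range(1, r + 1):
            if p - j >= 0:
                signal[p - j] += a * (r + 1 - j) / (r + 1)
    signal = signal + rng.normal(0.0, spec.noise_sd, n)

    if spec.ionomycin:
        n_ramp = int(round(spec.ramp_s / spec.dt))
        n_plat = max(1, int(round(spec.plateau_s / spec.dt)))
        ramp = np.linspace(signal[-1] if n else spec.baseline_level, 1.0,
                           n_ramp, endpoint=False)
        plat = 1.0 + rng.normal(0.0, spec.noise_sd, n_plat)
        signal = np.concatenate([signal, ramp, plat])

    values = spec.fmax_raw * np.clip(signal, 0.0, None)
    trace = FluorescenceTrace(
        cell_id=cell_id,
        values=values,
        dt=spec.dt,
        analysis_window=(0, n - 1),
        normalized=False,
    )
    truth = GroundTruth(
        cell_id=cell_id,
        event_times_s=times,
        event_frames=frames,
        event_amplitudes=amps,
        tau_s=spec.tau_s,
        baseline=baseline,
        fmax=spec.fmax_raw,
        fmin=spec.fmin_frac * spec.fmax_raw,
    )
    return trace, truth


def simulate_cohort(
    spec: SyntheticSpec,
) -> tuple[list[FluorescenceTrace], list[GroundTruth]]:
    """Generate all cells of the cohort (deterministic in the spec)."""
    pairs = [simulate_cell(spec, i) for i in range(spec.n_cells)]
    return [p[0] for p in pairs], [p[1] for p in pairs]


@dataclass(frozen=True)
class DetectionScore:
    """Ground-truth match of one cell's detections.

    ``sensitivity`` is matched/true (``None`` without true events);
    ``precision`` is matched/detected (``None`` without detections).
    """

    sensitivity: float | None
    precision: float | None
    matched: tuple[tuple[int, int], ...]  # (true_frame, detected_frame)


def score_detection(
    truth: GroundTruth, result: DetectionResult, tol_frames: int
) -> DetectionScore:
    """Greedy one-to-one matching of detected peaks to true events.

    Candidate pairs within ``tol_frames`` are accepted in order of
    increasing frame distance; each true event and each detection matches
    at most once.
    """
    if truth.cell_id != result.cell_id:
        raise ValueError("cell_id mismatch between truth and detection result")
    if tol_frames < 0:
        raise ValueError("tol_frames must be >= 0")
    det = result.peak_frames
    pairs = sorted(
        (abs(d - t), int(t), int(d))
        for t in truth.event_frames
        for d in det
        if abs(d - t) <= tol_frames
    )
    used_t: set[int] = set()
    used_d: set[int] = set()
    matched: list[tuple[int, int]] = []
    for _, t, d in pairs:
        if t not in used_t and d not in used_d:
            used_t.add(t)
            used_d.add(d)
            matched.append((t, d))
    n_true, n_det, n_match = len(truth.event_frames), len(det), len(matched)
    return DetectionScore(
        sensitivity=n_match / n_true if n_true else None,
        precision=n_match / n_det if n_det else None,
        matched=tuple(matched),
    )


def write_truth(truths: Sequence[GroundTruth], path: str | Path) -> None:
    """Serialize per-cell ground truth as JSON."""
    payload = [
        {
            "cell_id": t.cell_id,
            "event_times_s": t.event_times_s.tolist(),
            "event_frames": t.event_frames.tolist(),
            "event_amplitudes": t.event_amplitudes.tolist(),
            "tau_s": t.tau_s,
            "fmax": t.fmax,
            "fmin": t.fmin,
        }
        for t in truths
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> list[GroundTruth]:
    """Read ground truth written by :func:`write_truth`.

    The per-frame baseline series is not serialized; it is restored as an
    empty array.
    """
    out = []
    for d in json.loads(Path(path).read_text()):
        out.append(
            GroundTruth(
                cell_id=d["cell_id"],
                event_times_s=np.asarray(d["event_times_s"], dtype=float),
                event_frames=np.asarray(d["event_frames"], dtype=int),
                event_amplitudes=np.asarray(d["event_amplitudes"], dtype=float),
                tau_s=float(d["tau_s"]),
                baseline=np.empty(0),
                fmax=float(d["fmax"]),
                fmin=float(d["fmin"]),
            )
        )
    return out
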