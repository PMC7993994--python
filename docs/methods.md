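# Methods

## What the package computes

`catrace` quantifies spontaneous calcium activity of cultured neurons from
per-soma fluorescence time series. A recording consists of an analysis
window of spontaneous activity (by convention the first 478 s, 1000 frames
at 0.478 s per frame) followed by an ionomycin application that saturates
the indicator and defines the maximal fluorescence Fmax. The pipeline is:

1. **Validation** — traces must be finite, non-negative, with a window
   `[a, b]` inside the trace and `dt > 0`.
2. **Fmax normalization** — a scalar Fmax is estimated per cell from a
   user-specified saturation segment (median by default; mean and max
   available) and the whole trace is divided by it.
3. **Transient detection** — frame `n` is a transient candidate iff

   * `F(n) ≥ F(a)` for every `a ∈ [n−δ, n+δ]` (local maximum, ties
     allowed), and
   * `F(n) > (1+γ)/(2θ+1) · Σ_{j=n−θ}^{n+θ} F(j)` (exceeds the local mean
     by the relative margin γ),

   with defaults δ=3, θ=7, γ=0.25. Only frames whose full ±max(δ,θ)
   neighbourhood lies inside `[a, b]` are tested (complete-window rule).
   Because the ≥ in the first condition admits flat-topped transients at
   several frames, runs of candidates separated by ≤ `merge_gap` frames
   (default: δ) collapse to one event at the highest-F frame, earliest on
   exact ties.
4. **Event annotation** — each event carries a baseline (rolling
   20th-percentile filter over 21 frames ≈ 10 s, centered, nearest-edge
   padding), an amplitude `Fp = F(peak) − baseline(peak)` floored at zero,
   and a half-decay time: the linearly interpolated instant at which the
   signal first falls to `baseline + Fp/2`, searched up to the next
   event's peak or the window end, and reported as missing if never
   reached (so interrupted transients do not bias the mean downward).
5. **Per-cell metrics** — transient count `N`; firing rate
   `N / window-minutes` (per-minute is this package's unit choice);
   clearance time `T` = mean half-decay over events where it is defined;
   amplitude `A` = mean `Fp`; mean signal = arithmetic mean of F over the
   inclusive window. Cells with no qualifying events report missing, never
   zero, so group means are not diluted.
6. **Group comparison** — unpaired two-tailed t-test per metric on
   per-cell values; Welch's variant by default (the pooled-variance
   classic test via `--pooled`), missing values excluded with counts
   reported.
7. **Absolute calcium** (optional) — for single-wavelength indicators,
   `[Ca²⁺] = Kd·(F − Fmin)/(Fmax − F)` with Fmin from a zero-calcium /
   BAPTA condition. Kd is deliberately a required parameter: it depends on
   the indicator and conditions (values around 345 nM are typical for the
   Fluo-4 class), and no default is baked into the computation.

Both detection conditions are homogeneous in F, so detection is invariant
under rescaling (normalization does not change which frames qualify) but
**not** under additive offsets — adding a constant makes the relative
threshold strictly harder, which is why normalization precedes detection.

## Synthetic data and what it does (not) show

The generator emulates the target recordings: per-cell event times from a
Poisson process (default 6 events/min) with a hard 3 s refractory gap,
lognormal event amplitudes (mean 0.3, CV 0.25 in normalized units), a
one-frame linear rise and exponential decay (τ = 1.5 s), baseline 0.15
with slow sinusoidal drift (amplitude 0.01, period 120 s, random phase),
additive Gaussian noise (σ 0.02), zero-clipping, a raw-unit scale factor
Fmax = 2.0, and an appended ionomycin segment (10 s onset ramp, 60 s
plateau at Fmax with the same noise). Everything is a pure function of
`(seed, cell_index)`, and the realized event table is returned as ground
truth.

Events are drawn on `[guard, duration − guard]` (guard 5 s ≈ 10 frames):
the complete-window rule cannot see peaks within max(δ,θ) frames of the
window edge, so planting events there would make ground truth partly
unobservable by construction. Recovery expectations therefore use the
guard-corrected rate `λ/(1+λτ_r) · (duration − 2·guard)/duration`.

For a refractory-thinned Poisson process the expected long-run rate is
`λ/(1 + λ·τ_r)` (after a kept event, the next arrives after the dead time
plus an exponential wait); at the defaults this is 4.62 events/min. The
tests verify this against an independent simulation of the point process
alone.

What the generator does **not** model: photobleaching, indicator binding
kinetics, movement artefacts, correlated (network) activity across cells,
non-Gaussian shot noise, or cell-to-cell variability in τ and rate beyond
Poisson sampling. Passing tests therefore show the analysis is correct for
sparse, exponentially decaying transients on a slowly drifting baseline —
not that detection performance transfers to arbitrary real recordings.

## Behaviour of the detection rule at the default regime

One property of the rule matters for interpreting synthetic benchmarks:
the second condition thresholds relative to the **local mean**, not the
noise. At baseline 0.15 and γ = 0.25 the required excess is ≈ 0.0375
normalized units — about 1.9 noise SD at σ = 0.02 — so isolated noise
maxima occasionally qualify (on the order of one spurious event per
minute on otherwise quiet stretches). Sensitivity at the published
parameters is near 1.0 and precision just above 0.8 on the default
regime; the spurious events carry near-zero amplitude and very short
half-decays, which inflates recovered firing rates by ~20-25% and deflates
mean amplitudes by ~15% relative to generator truth, while leaving the
mean clearance time within two frames of `τ·ln 2`. The package reports the
rule faithfully rather than adding an amplitude cut that the rule does not
contain; users who need higher precision should raise γ (detections at a
larger γ are always a subset of those at a smaller one).

## Numerical choices

* Half-decay of a sampled exponential: the closed form is `τ·ln 2`; with
  linear interpolation the error is below one frame interval whenever
  `τ/dt ≥ 1` in practice (tested for τ from 0.5 to 3 s at dt = 0.478 s).
* Fmax by plateau median: sampling error ≈ `1.25·σ/√n`; the default 60 s
  plateau (≈126 frames) puts it well below plateau noise.
* Trace CSVs are written with `%.17g` and read with round-trip float
  parsing, so a write/read cycle is bit-exact.
* Degenerate inputs: empty traces, out-of-range windows, non-finite or
  negative values, saturation segments overlapping the analysis window,
  and fluorescence at/above Fmax in the calibration all raise errors that
  name the violated constraint; "no events" is a warning, not an error.
* All randomness (generator, evaluation replicates) flows from explicit
  integer seeds; cohort replicate `r` uses `seed + r`.

## Problem sizes used in the shipped checks

Desk-scale defaults keep everything fast and deterministic: oracle
equivalence on 1000 random traces (lengths 200-2000) against a literal
frame-by-frame transcription of the rule; detection performance on 20
cohorts × 3 cells (seeds 1-20); parameter recovery on one 50-cell cohort;
type-I error of the group test over 1000 null replicates of 20 + 20
cells; power on 50 + 50 cells with τ = 1.5 vs 1.0 s. The full suite runs
in well under a minute on one CPU.

## Known limitations

* Fmax is computed per cell; if the original analysis used a per-field
  Fmax the normalized scales differ slightly.
* `Fp` is measured from the rolling-percentile baseline; on zero-baseline
  traces this reduces to the peak value, but for crowded traces the
  percentile baseline can ride up on overlapping tails.
* The half-decay time equals the decay constant times ln 2 only for pure
  exponential recovery; no exponential fit is performed.
* The t-test pools cells across recordings; nested (per-culture) structure
  is not modelled.
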