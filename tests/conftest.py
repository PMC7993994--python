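"""Shared fixtures and the independent brute-force detection oracle."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from catrace import FluorescenceTrace

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_trace(values, cell_id="c0", dt=0.478, window=None, normalized=False):
    return FluorescenceTrace(
        cell_id=cell_id,
        values=np.asarray(values, dtype=float),
        dt=dt,
        analysis_window=window,
        normalized=normalized,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# Brute-force oracle: a direct, frame-by-frame transcription of the
# detection rule plus merging, written independently of the package's
# vectorized implementation.
# ---------------------------------------------------------------------------

def brute_force_events(values, a, b, delta, theta, gamma, merge_gap):
    """Event peak frames by literal evaluation of the detection rule.

    Frame n qualifies when F(n) >= F(j) for every j in [n-delta, n+delta]
    and F(n) > (1+gamma)/(2*theta+1) * sum_{j=n-theta}^{n+theta} F(j);
    only frames with complete neighbourhoods inside [a, b] are tested.
    Runs of qualifying frames separated by <= merge_gap frames collapse to
    the highest-valued frame, earliest on ties.
    """
    vals = [float(x) for x in values]
    m = max(delta, theta)
    qualifying = []
    for n in range(a + m, b - m + 1):
        if vals[n] < max(vals[n - delta : n + delta + 1]):
            continue
        if vals[n] > (1.0 + gamma) / (2 * theta + 1) * sum(vals[n - theta : n + theta + 1]):
            qualifying.append(n)
    events = []
    group = []
    for n in qualifying:
        if group and n - group[-1] > merge_gap:
            events.append(_representative(group, vals))
            group = []
        group.append(n)
    if group:
        events.append(_representative(group, vals))
    return events


def _representative(group, vals):
    best = group[0]
    for j in group[1:]:
        if vals[j] > vals[best]:
            best = j
    return best
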