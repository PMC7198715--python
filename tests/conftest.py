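"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from microca.synth import TraceGenParams, simulate_trace
from microca.traces import process_trace


# ---------------------------------------------------------------------------
# Independent brute-force implementation of the half-maximum-decay rule,
# written recursively (find the first boundary, recurse on the remainder) as
# a structurally different counterpart to the production state machine.
# ---------------------------------------------------------------------------

def brute_force_first_boundary(seg: np.ndarray, delta: float):
    """First split index under the half-max rule, or None."""
    m = seg[0]
    j = 1
    while j < len(seg):
        if seg[j] >= m:
            m = seg[j]
            j += 1
            continue
        if seg[j] >= m / 2.0:
            j += 1
            continue
        # below-half episode starting at j
        k = j
        run_min_idx = j
        while k < len(seg):
            if seg[k] < seg[run_min_idx]:
                run_min_idx = k
            if seg[k] - seg[run_min_idx] > delta:
                return run_min_idx
            if seg[k] >= m / 2.0:
                break
            k += 1
        if k == len(seg):
            return None
        m = max(m, seg[k])
        j = k + 1
    return None


def brute_force_half_max_split(seg: np.ndarray, delta: float):
    """Recursive brute-force segmentation; returns (start, end) index pairs."""
    seg = np.asarray(seg, dtype=float)
    b = brute_force_first_boundary(seg, delta)
    if b is None:
        return [(0, len(seg) - 1)]
    rest = brute_force_half_max_split(seg[b:], delta)
    return [(0, b)] + [(s + b, e + b) for s, e in rest]


def random_piecewise_linear_region(rng: np.random.Generator) -> np.ndarray:
    """A random positive piecewise-linear segment mimicking a detected region."""
    n_knots = rng.integers(2, 9)
    knot_x = np.sort(rng.uniform(0, 1, n_knots))
    knot_x = np.concatenate([[0.0], knot_x, [1.0]])
    knot_y = rng.uniform(0.05, 10.0, len(knot_x))
    n = int(rng.integers(20, 200))
    x = np.linspace(0, 1, n)
    return np.interp(x, knot_x, knot_y)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def processed_default_trace():
    """One default synthetic trace, fully processed, with its ground truth."""
    trace, truth = simulate_trace(TraceGenParams(seed=42))
    process_trace(trace)
    return trace, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
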