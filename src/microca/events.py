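"""Ca²⁺ transient detection and characterisation.

Detection criterion: a fluorescence change counts as a Ca²⁺ transient when
its amplitude exceeds k×SD of the baseline noise (k = 6 by default). Event
support is delimited by crossings of a lower sub-threshold (2×SD) around
each suprathreshold excursion, so T-half and AUC capture the full transient
rather than only its suprathreshold portion. Within a suprathreshold
region, a transient whose fluorescence decays below half of its running
maximum before rising again is closed there — each such excursion counts as
a single event (the half-maximum-decay rule).

Per-event metrics (all on the filtered ΔF/F trace):

* amplitude — peak ΔF/F × 100 (%ΔF/F);
* T-half — time spanned above half the peak, linearly interpolated at the
  half-maximum crossings (s);
* AUC — trapezoidal integral of ΔF/F (fraction) over the event support
  (ΔF/F·s).

Cells with ≥ 1 event in the recording are "spontaneously active"; per-cell
medians and per-mouse active fractions feed the cohort statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .traces import FluorescenceTrace

__all__ = [
    "CaEvent",
    "CellSummary",
    "MouseActivity",
    "split_by_half_max",
    "detect_events",
    "measure_event",
    "summarize_cell",
    "fraction_active_per_mouse",
    "match_events",
    "DEFAULT_K_SD",
    "DEFAULT_CROSSING_K",
]

DEFAULT_K_SD = 6.0  # amplitude criterion: peak > 6 × baseline-noise SD
DEFAULT_CROSSING_K = 2.0  # event support delimited at 2 × SD
DEFAULT_DURATION_MIN = 15.0


@dataclass
class CaEvent:
    """One detected Ca²⁺ transient."""

    onset_s: float
    peak_s: float
    end_s: float
    amplitude_pct: float
    t_half_s: float
    auc: float
    edge_truncated: bool = False

    def __post_init__(self) -> None:
        if not (self.onset_s <= self.peak_s <= self.end_s):
            raise ValueError("need onset_s <= peak_s <= end_s")


@dataclass
class CellSummary:
    cell_id: str
    mouse_id: str
    sex: str
    age_group: str
    diet: str
    n_events: int
    frequency_per_min: float
    is_active: bool
    median_amplitude_pct: Optional[float]
    median_t_half_s: Optional[float]
    median_auc: Optional[float]
    recording_duration_min: float


@dataclass
class MouseActivity:
    mouse_id: str
    sex: str
    age_group: str
    diet: str
    n_cells: int
    fraction_active_pct: float


# ---------------------------------------------------------------------------
# Segmentation: the half-maximum-decay rule
# ---------------------------------------------------------------------------

def split_by_half_max(
    region: np.ndarray, rise_delta: float = 0.0
) -> list[tuple[int, int]]:
    """Split one suprathreshold region into single events.

    Left-to-right scan tracking the current event's running maximum M. When
    the signal falls below M/2 and subsequently rises by more than
    ``rise_delta`` above the running minimum since the drop, the current
    event is closed at that minimum (earliest index on ties) and a new event
    opens there. If the signal recovers above M/2 without such a rise, the
    event simply continues. Deterministic; returns (start, end) index pairs,
    end-inclusive, covering the region.
    """
    y = np.asarray(region, dtype=float)
    if y.size == 0:
        raise ValueError("empty region")
    bounds: list[tuple[int, int]] = []
    start = 0
    m = y[0]
    below = False
    run_min = np.inf
    run_argmin = -1
    for i in range(1, len(y)):
        v = y[i]
        if not below:
            if v < m / 2.0:
                below = True
                run_min = v
                run_argmin = i
            else:
                m = max(m, v)
        else:
            if v - run_min > rise_delta:
                # rise after half-max decay: close event at the minimum
                bounds.append((start, run_argmin))
                start = run_argmin
                m = float(np.max(y[run_argmin : i + 1]))
                below = v < m / 2.0
                if below:
                    run_min = v
                    run_argmin = i
            elif v >= m / 2.0:
                below = False
                m = max(m, v)
            elif v < run_min:
                run_min = v
                run_argmin = i
    bounds.append((start, len(y) - 1))
    return bounds


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def measure_event(
    trace: FluorescenceTrace, start: int, end: int, baseline: float = 0.0
) -> tuple[float, float, float]:
    """Amplitude (%ΔF/F), T-half (s) and AUC (ΔF/F·s) for one event.

    Bounds are sample indices into the filtered trace, end-inclusive.
    ``baseline`` (ΔF/F) is subtracted first so metrics are referenced to the
    trace's resting level rather than to an absolute zero, which removes the
    small positive bias a percentile F0 estimate leaves on noisy traces.
    T-half uses linear interpolation at the half-maximum crossings; if the
    signal does not drop below half within the bounds on one side
    (edge-truncated events), the bound itself is used.
    """
    if end <= start:
        raise ValueError("degenerate single-sample event")
    y = trace.dff_filtered[start : end + 1] - baseline
    t = trace.t_s[start : end + 1]
    ipk = int(np.argmax(y))
    peak = float(y[ipk])
    if peak <= 0:
        raise ValueError("event peak must be positive")
    half = peak / 2.0

    # left half-max crossing
    left = t[0]
    for i in range(ipk, 0, -1):
        if y[i - 1] < half <= y[i]:
            frac = (half - y[i - 1]) / (y[i] - y[i - 1])
            left = t[i - 1] + frac * (t[i] - t[i - 1])
            break
    # right half-max crossing
    right = t[-1]
    for i in range(ipk, len(y) - 1):
        if y[i] >= half > y[i + 1]:
            frac = (y[i] - half) / (y[i] - y[i + 1])
            right = t[i] + frac * (t[i + 1] - t[i])
            break

    auc = float(np.trapezoid(y, t))
    return peak * 100.0, float(right - left), auc


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_events(
    trace: FluorescenceTrace,
    k_sd: float = DEFAULT_K_SD,
    crossing_k: float = DEFAULT_CROSSING_K,
    noise_sd: Optional[float] = None,
) -> list[CaEvent]:
    """Detect Ca²⁺ transients on a processed trace.

    The filtered ΔF/F is first referenced to its median (the resting
    baseline), so thresholds measure excursion above baseline rather than
    above zero. Candidate regions are maximal runs of the baseline-corrected
    trace above the crossing threshold (``crossing_k`` × SD) that contain at
    least one sample above the amplitude criterion (``k_sd`` × SD). Each region is
    split into single events by the half-maximum-decay rule; the re-rise that
    opens a new event must itself exceed the amplitude criterion above the
    trough (a smaller rise is indistinguishable from noise riding the decay
    tail), and sub-events whose peak does not exceed the amplitude criterion
    are discarded.
    Events touching the recording edges are flagged ``edge_truncated``.

    Event onsets are refined on the *unfiltered* ΔF/F (last crossing of the
    raw crossing threshold before the peak): the zero-phase filter spreads
    each rising edge backward by a second or two, which would bias the
    filtered-trace crossing early.

    ``noise_sd`` overrides the trace's stored filtered-noise SD (needed when
    it is zero, e.g. on noiseless synthetic traces).
    """
    if trace.dff_filtered is None:
        raise ValueError("trace has no filtered ΔF/F; run process_trace first")
    sd = trace.noise_sd if noise_sd is None else noise_sd
    if sd is None:
        raise ValueError("trace has no noise_sd; run process_trace first")
    baseline = float(np.median(trace.dff_filtered))
    y = trace.dff_filtered - baseline
    if sd == 0:
        if np.any(y > 0):
            raise ValueError(
                "baseline-noise SD is zero but the trace is not flat; "
                "pass an explicit noise_sd threshold"
            )
        return []
    thr_hi = k_sd * sd
    thr_lo = crossing_k * sd

    above = y > thr_lo
    if not np.any(above):
        return []
    edges = np.diff(above.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0])
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(y) - 1)

    # raw-trace reference for onset refinement
    raw = trace.dff
    raw_thr = None
    if raw is not None and trace.noise_sd_raw:
        raw_thr = float(np.median(raw)) + crossing_k * trace.noise_sd_raw

    events: list[CaEvent] = []
    for s, e in zip(starts, ends):
        if e <= s:
            continue
        seg = y[s : e + 1]
        if np.max(seg) <= thr_hi:
            continue
        for a, b in split_by_half_max(seg, rise_delta=thr_hi):
            if b <= a:
                continue
            if np.max(seg[a : b + 1]) <= thr_hi:
                continue
            ipk = s + a + int(np.argmax(seg[a : b + 1]))
            onset_idx = s + a
            if raw_thr is not None:
                below = np.where(raw[s + a : ipk + 1] < raw_thr)[0]
                if len(below):
                    onset_idx = min(s + a + below[-1] + 1, ipk)
            amp, t_half, auc = measure_event(trace, s + a, s + b, baseline=baseline)
            events.append(
                CaEvent(
                    onset_s=float(trace.t_s[onset_idx]),
                    peak_s=float(trace.t_s[ipk]),
                    end_s=float(trace.t_s[s + b]),
                    amplitude_pct=amp,
                    t_half_s=t_half,
                    auc=auc,
                    edge_truncated=(s == 0 and a == 0) or (e == len(y) - 1 and b == e - s),
                )
            )
    events.sort(key=lambda ev: ev.onset_s)
    return events


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_cell(
    events: Sequence[CaEvent],
    metadata: dict,
    duration_min: float = DEFAULT_DURATION_MIN,
    exclude_truncated_metrics: bool = True,
) -> CellSummary:
    """Per-cell frequency, activity flag and median event metrics.

    All detected events count toward the frequency and the activity flag.
    Edge-truncated events are excluded from the T-half/AUC/amplitude medians
    by default (their shape metrics are incomplete). Cells with zero events
    contribute no metric medians.
    """
    if duration_min <= 0:
        raise ValueError("duration_min must be positive")
    n = len(events)
    usable = [
        ev for ev in events if not (exclude_truncated_metrics and ev.edge_truncated)
    ]
    med = lambda xs: float(np.median(xs)) if xs else None  # noqa: E731
    return CellSummary(
        cell_id=metadata.get("cell_id", "?"),
        mouse_id=metadata.get("mouse_id", "?"),
        sex=metadata.get("sex", "?"),
        age_group=metadata.get("age_group", "?"),
        diet=metadata.get("diet", "?"),
        n_events=n,
        frequency_per_min=n / duration_min,
        is_active=n >= 1,
        median_amplitude_pct=med([ev.amplitude_pct for ev in usable]),
        median_t_half_s=med([ev.t_half_s for ev in usable]),
        median_auc=med([ev.auc for ev in usable]),
        recording_duration_min=duration_min,
    )


def fraction_active_per_mouse(
    cells: Sequence[CellSummary],
) -> list[MouseActivity]:
    """Per-mouse percentage of spontaneously active cells."""
    by_mouse: dict[str, list[CellSummary]] = {}
    for c in cells:
        by_mouse.setdefault(c.mouse_id, []).append(c)
    out = []
    for mouse_id, cs in by_mouse.items():
        if not cs:
            warnings.warn(f"mouse {mouse_id} has no cells; excluded", stacklevel=2)
            continue
        n_active = sum(c.is_active for c in cs)
        first = cs[0]
        out.append(
            MouseActivity(
                mouse_id=mouse_id,
                sex=first.sex,
                age_group=first.age_group,
                diet=first.diet,
                n_cells=len(cs),
                fraction_active_pct=100.0 * n_active / len(cs),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Scoring against ground truth
# ---------------------------------------------------------------------------

def match_events(
    detected_onsets: np.ndarray,
    true_onsets: np.ndarray,
    tolerance_s: float = 2.0,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected to true event onsets.

    Returns (n_matched, n_detected, n_true); recall = matched/true,
    precision = matched/detected. A detected onset matches the nearest
    unmatched true onset within ``tolerance_s``.
    """
    det = np.sort(np.asarray(detected_onsets, dtype=float))
    tru = np.sort(np.asarray(true_onsets, dtype=float))
    used = np.zeros(len(tru), dtype=bool)
    matched = 0
    for d in det:
        if len(tru) == 0:
            break
        dist = np.abs(tru - d)
        dist[used] = np.inf
        j = int(np.argmin(dist))
        if dist[j] <= tolerance_s:
            used[j] = True
            matched += 1
    return matched, len(det), len(tru)
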