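"""Somatic fluorescence trace processing.

Converts raw ROI mean fluorescence into background-subtracted, low-pass
filtered ΔF/F traces and estimates the baseline noise level used by the
transient detector.

Conventions
-----------
* ΔF/F = F / F0 − 1, where F is the background-subtracted fluorescence and
  F0 its basal level. ΔF/F is kept as a dimensionless *fraction* throughout
  this module; percent conversion happens only at reporting time.
* The background is the mean fluorescence of a blood-vessel ROI; by default
  a single constant (its median) is subtracted, a time-resolved subtraction
  is selectable.
* Filtering is a 2nd-order Butterworth low-pass applied forward-backward
  (zero phase), cutoff 0.2 Hz by default, so event timing is not skewed by
  phase delay.
* Baseline noise is a robust SD (1.4826 × MAD about a rolling median),
  estimated on both the unfiltered and the filtered ΔF/F; the detector
  compares the filtered trace against the filtered-noise SD so criterion and
  signal stay consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "FluorescenceTrace",
    "compute_dff",
    "lowpass_filter",
    "estimate_baseline_noise",
    "process_trace",
]

DEFAULT_CUTOFF_HZ = 0.2
DEFAULT_F0_METHOD = "percentile20"

F0Method = Literal["percentile20", "lowest_quartile_mean", "window"]


@dataclass
class FluorescenceTrace:
    """One cell's fluorescence time series and derived ΔF/F signals.

    Attributes
    ----------
    t_s : ndarray
        Sample times in seconds, uniform grid.
    f_raw : ndarray
        Raw ROI mean fluorescence (arbitrary units).
    f_background : ndarray
        Blood-vessel background fluorescence (arbitrary units), same length.
    dt_s : float
        Sampling interval in seconds.
    dff, dff_filtered : ndarray or None
        ΔF/F (fraction) before / after zero-phase low-pass filtering.
    f0 : float or None
        Estimated basal fluorescence after background subtraction.
    noise_sd : float or None
        Robust baseline-noise SD of the *filtered* ΔF/F (the detector's
        reference by default).
    noise_sd_raw : float or None
        Robust baseline-noise SD of the unfiltered ΔF/F, reported alongside.
    """

    t_s: np.ndarray
    f_raw: np.ndarray
    f_background: np.ndarray
    dt_s: float
    dff: Optional[np.ndarray] = None
    dff_filtered: Optional[np.ndarray] = None
    f0: Optional[float] = None
    noise_sd: Optional[float] = None
    noise_sd_raw: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.f_raw = np.asarray(self.f_raw, dtype=float)
        self.f_background = np.asarray(self.f_background, dtype=float)
        if not (len(self.t_s) == len(self.f_raw) == len(self.f_background)):
            raise ValueError("t_s, f_raw and f_background must have equal length")
        if len(self.t_s) >= 2:
            dt = np.diff(self.t_s)
            if np.max(np.abs(dt - self.dt_s)) > 1e-9 * self.dt_s:
                raise ValueError("t_s must be a uniform grid with spacing dt_s")

    @property
    def duration_s(self) -> float:
        return float(len(self.t_s) * self.dt_s)

    @property
    def n_samples(self) -> int:
        return len(self.t_s)


def compute_dff(
    f_raw: np.ndarray,
    f_background: np.ndarray,
    f0_method: F0Method = DEFAULT_F0_METHOD,
    *,
    background_mode: Literal["constant", "timewise"] = "constant",
    f0_window: Optional[tuple[int, int]] = None,
) -> tuple[np.ndarray, float]:
    """Background-subtract and normalise a fluorescence trace to ΔF/F.

    F := f_raw − background (constant median of the vessel ROI by default);
    F0 is estimated from F over the whole recording; ΔF/F = F / F0 − 1.

    Parameters
    ----------
    f0_method
        ``"percentile20"`` (default): 20th percentile of F — robust to
        active periods. ``"lowest_quartile_mean"``: mean of the lowest
        quartile of F. ``"window"``: mean of F over ``f0_window`` (sample
        index range, end-exclusive).

    Returns
    -------
    (dff, f0)

    Raises
    ------
    ValueError
        On length mismatch or a non-positive F0 estimate (trace unusable).
    """
    f_raw = np.asarray(f_raw, dtype=float)
    f_background = np.asarray(f_background, dtype=float)
    if f_raw.shape != f_background.shape:
        raise ValueError(
            f"length mismatch: f_raw has {f_raw.shape}, f_background has {f_background.shape}"
        )
    if background_mode == "constant":
        f = f_raw - float(np.median(f_background))
    elif background_mode == "timewise":
        f = f_raw - f_background
    else:
        raise ValueError(f"unknown background_mode {background_mode!r}")

    if f0_method == "percentile20":
        f0 = float(np.percentile(f, 20))
    elif f0_method == "lowest_quartile_mean":
        q1 = np.percentile(f, 25)
        f0 = float(np.mean(f[f <= q1]))
    elif f0_method == "window":
        if f0_window is None:
            raise ValueError("f0_method='window' requires f0_window=(start, stop)")
        lo, hi = f0_window
        f0 = float(np.mean(f[lo:hi]))
    else:
        raise ValueError(f"unknown f0_method {f0_method!r}")

    if f0 <= 0:
        raise ValueError(
            f"estimated F0 = {f0:.4g} is not positive; background exceeds signal "
            "or the ROI is unusable"
        )
    return f / f0 - 1.0, f0


def lowpass_filter(
    dff: np.ndarray,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    dt_s: float = 0.5,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase low-pass filter (Butterworth, forward-backward).

    Output has the same length as the input; unit gain at DC; phase is not
    distorted, so transient timing metrics are unaffected.

    Raises
    ------
    ValueError
        If ``cutoff_hz`` is at or above the Nyquist frequency 1/(2 dt).
    """
    dff = np.asarray(dff, dtype=float)
    nyquist = 0.5 / dt_s
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below Nyquist {nyquist} Hz (dt = {dt_s} s)"
        )
    b, a = signal.butter(order, cutoff_hz, btype="low", fs=1.0 / dt_s)
    # Gustafsson edge handling avoids the spurious start/end excursions that
    # reflection padding produces on noisy recordings
    return signal.filtfilt(b, a, dff, method="gust")


def estimate_baseline_noise(
    dff: np.ndarray,
    event_mask: Optional[np.ndarray] = None,
    *,
    rolling_window_s: float = 10.0,
    dt_s: float = 0.5,
    min_baseline_samples: int = 50,
) -> float:
    """Robust SD of the event-free baseline of a ΔF/F trace.

    Detrends with a rolling median (window ``rolling_window_s``) and returns
    1.4826 × the median absolute deviation of the residual, over samples
    outside ``event_mask`` (boolean, True = inside an event) if given.

    Raises
    ------
    ValueError
        If fewer than ``min_baseline_samples`` samples remain outside the mask.
    """
    dff = np.asarray(dff, dtype=float)
    win = max(3, int(round(rolling_window_s / dt_s)) | 1)  # odd window
    rolling_med = ndimage.median_filter(dff, size=win, mode="nearest")
    resid = dff - rolling_med
    if event_mask is not None:
        event_mask = np.asarray(event_mask, dtype=bool)
        if event_mask.shape != dff.shape:
            raise ValueError("event_mask must match dff in length")
        resid = resid[~event_mask]
    if resid.size < min_baseline_samples:
        raise ValueError(
            f"only {resid.size} baseline samples available; "
            f"need at least {min_baseline_samples}"
        )
    return float(1.4826 * np.median(np.abs(resid - np.median(resid))))


def process_trace(
    trace: FluorescenceTrace,
    *,
    f0_method: F0Method = DEFAULT_F0_METHOD,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    background_mode: Literal["constant", "timewise"] = "constant",
) -> FluorescenceTrace:
    """Fill a trace's derived fields in place: ΔF/F, filtered ΔF/F, F0, noise SDs.

    Returns the same object for chaining.
    """
    trace.dff, trace.f0 = compute_dff(
        trace.f_raw, trace.f_background, f0_method, background_mode=background_mode
    )
    trace.dff_filtered = lowpass_filter(trace.dff, cutoff_hz, trace.dt_s)
    trace.noise_sd_raw = estimate_baseline_noise(trace.dff, dt_s=trace.dt_s)
    trace.noise_sd = estimate_baseline_noise(trace.dff_filtered, dt_s=trace.dt_s)
    return trace
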