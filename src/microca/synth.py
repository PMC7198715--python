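"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure of an in vivo two-photon microglia study
so that every analysis stage — ΔF/F processing, transient detection,
chemotaxis quantification and the cohort statistics — can be exercised
end-to-end without any recorded data:

* somatic Ca²⁺ traces: Poisson-timed transients with a sharp-rise /
  exponential-decay kernel (difference of exponentials, peak-normalised),
  amplitudes drawn in %ΔF/F, additive white Gaussian noise, a constant
  blood-vessel background;
* ATP chemotaxis: a containment boundary shrinking linearly from an initial
  to a final diameter around the pipette tip, and tracked process tips
  whose radial velocity is linearly coupled to their initial distance
  (v = β·d + ε), the coupling degraded or restored per group;
* cohorts: an age × sex × diet design with a bell-shaped event-rate profile
  (middle-aged > young ≈ old) and a degraded-then-restored distance–velocity
  correlation profile (old < middle; caloric restriction ≈ middle), the
  qualitative pattern the analysis is meant to detect.

Every simulated object carries its ground truth (event times and analytic
metrics; initial distances and true velocities) so detector performance can
be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .chemotaxis import ChemotaxisRecording, ProcessTrack
from .traces import FluorescenceTrace

__all__ = [
    "TraceGenParams",
    "ChemoGenParams",
    "GroupSpec",
    "CohortDesign",
    "GroundTruth",
    "CohortBundle",
    "kernel_t_half",
    "kernel_integral",
    "simulate_trace",
    "simulate_chemotaxis",
    "calibrate_velocity_noise",
    "default_cohort_design",
    "simulate_cohort",
    "write_cohort",
    "load_design",
    "save_design",
]

AGE_GROUPS = ("young", "middle", "old")
SEXES = ("male", "female")
DIETS = ("AL", "CR3", "CR6", "CR18")


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass
class TraceGenParams:
    """Generative parameters for one somatic fluorescence trace.

    Defaults describe a 15-min recording sampled at 2 Hz with transients of
    ~20 %ΔF/F riding on ~2 %ΔF/F white noise (amplitude SNR ≈ 10).
    """

    duration_s: float = 900.0
    dt_s: float = 0.5
    event_rate_per_min: float = 0.2
    amp_mean_pct: float = 20.0
    amp_sd_pct: float = 5.0
    decay_tau_s: float = 8.0
    rise_tau_s: float = 0.8
    noise_sd_pct: float = 2.0
    f0: float = 100.0
    background_level: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0 or self.dt_s <= 0:
            raise ValueError("duration_s and dt_s must be positive")
        if self.event_rate_per_min < 0:
            raise ValueError("event_rate_per_min must be >= 0")
        if self.amp_mean_pct <= 0:
            raise ValueError("amp_mean_pct must be > 0")
        if not (self.decay_tau_s > self.rise_tau_s > 0):
            raise ValueError("need decay_tau_s > rise_tau_s > 0")
        if self.noise_sd_pct < 0:
            raise ValueError("noise_sd_pct must be >= 0")


@dataclass
class ChemoGenParams:
    """Generative parameters for one ATP-application recording.

    ``velocity_slope_per_min`` is β in v = β·d + ε (units 1/min: μm/min of
    velocity per μm of initial distance); ``velocity_noise_sd_um_per_min``
    is the SD of ε. Containment shrinks linearly from ``d0_um`` to
    ``d_final_um`` at ``shrink_rate_um_per_min``.
    """

    n_processes: int = 20
    frame_interval_s: float = 30.0
    n_frames: int = 31
    initial_distance_range_um: tuple[float, float] = (20.0, 60.0)
    velocity_slope_per_min: float = 0.05
    velocity_noise_sd_um_per_min: float = 0.3
    d0_um: float = 100.0
    d_final_um: float = 30.0
    shrink_rate_um_per_min: float = 5.0
    n_boundary_points: int = 16
    boundary_noise_sd_um: float = 0.5
    axis_imbalance: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if not (self.d0_um > self.d_final_um > 0):
            raise ValueError("need d0_um > d_final_um > 0")
        if self.n_frames < 7:
            raise ValueError("n_frames must be >= 7")
        if self.velocity_slope_per_min < 0:
            raise ValueError("velocity_slope_per_min must be >= 0")
        lo, hi = self.initial_distance_range_um
        if not (0 < lo < hi):
            raise ValueError("initial_distance_range_um must be 0 < min < max")
        if not (0 <= self.axis_imbalance < 1):
            raise ValueError("axis_imbalance must be in [0, 1)")


@dataclass
class GroupSpec:
    """One cohort cell: an (age, sex-balanced, diet) group of mice."""

    age_group: str
    diet: str
    n_mice: int
    cells_per_mouse: int
    trace_params: TraceGenParams
    chemo_params: ChemoGenParams
    silent_cell_prob: float = 0.0
    target_r: Optional[float] = None  # documented calibration target, if any

    def validate(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age_group {self.age_group!r}")
        if self.diet not in DIETS:
            raise ValueError(f"unknown diet {self.diet!r}")
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        if not (0 <= self.silent_cell_prob < 1):
            raise ValueError("silent_cell_prob must be in [0, 1)")
        self.trace_params.validate()
        self.chemo_params.validate()


@dataclass
class CohortDesign:
    """Full cohort specification: groups plus a master seed."""

    groups: list[GroupSpec]
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("design has no groups")
        for g in self.groups:
            g.validate()


@dataclass
class GroundTruth:
    """Ground truth for one simulated object.

    ``events``: per-event onset, analytic amplitude/T-half/AUC.
    ``tracks``: per-track initial distance and true mean velocity.
    """

    events: Optional[pd.DataFrame] = None
    tracks: Optional[pd.DataFrame] = None
    info: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Transient kernel (difference of exponentials, peak-normalised)
# ---------------------------------------------------------------------------

def _kernel_peak(rise_tau_s: float, decay_tau_s: float) -> tuple[float, float]:
    """(time of peak, unnormalised peak value) of exp(-t/τd) − exp(-t/τr)."""
    tr, td = rise_tau_s, decay_tau_s
    t_peak = tr * td / (td - tr) * np.log(td / tr)
    peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    return t_peak, peak


def kernel_t_half(rise_tau_s: float, decay_tau_s: float) -> float:
    """Full width at half maximum of the peak-normalised transient kernel.

    For rise_tau → 0 this converges to the single-exponential value
    decay_tau · ln 2.
    """
    t_peak, peak = _kernel_peak(rise_tau_s, decay_tau_s)

    def g(t: float) -> float:
        return (np.exp(-t / decay_tau_s) - np.exp(-t / rise_tau_s)) / peak - 0.5

    t_left = brentq(g, 0.0, t_peak) if g(0.0) < 0 else 0.0
    hi = t_peak + 60.0 * decay_tau_s
    t_right = brentq(g, t_peak, hi)
    return float(t_right - t_left)


def kernel_integral(rise_tau_s: float, decay_tau_s: float) -> float:
    """Integral of the peak-normalised kernel (units of seconds).

    An event of amplitude A (ΔF/F fraction) has analytic AUC
    A × kernel_integral; for rise_tau → 0 this is A·decay_tau.
    """
    _, peak = _kernel_peak(rise_tau_s, decay_tau_s)
    return float((decay_tau_s - rise_tau_s) / peak)


# ---------------------------------------------------------------------------
# Trace simulation
# ---------------------------------------------------------------------------

def simulate_trace(
    params: TraceGenParams, rng: Optional[np.random.Generator] = None
) -> tuple[FluorescenceTrace, GroundTruth]:
    """Simulate one somatic trace with Poisson-timed transients.

    The raw trace is f0·(1 + Σ events + noise) + background, where events
    are peak-normalised difference-of-exponential kernels scaled by drawn
    amplitudes (%ΔF/F → fraction) and the noise is white Gaussian with SD
    noise_sd_pct·f0/100. A constant background trace is emitted alongside.
    Ground truth lists every injected event with its analytic amplitude,
    T-half (kernel full width at half maximum) and AUC (kernel integral ×
    amplitude, ΔF/F·s with ΔF/F as a fraction).
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)

    n = int(round(params.duration_s / params.dt_s))
    t = np.arange(n) * params.dt_s
    dff_true = np.zeros(n)

    n_events = rng.poisson(params.event_rate_per_min * params.duration_s / 60.0)
    onsets = np.sort(rng.uniform(0.0, params.duration_s, size=n_events))
    amps_pct = np.empty(n_events)
    for i in range(n_events):
        for _ in range(100):
            a = rng.normal(params.amp_mean_pct, params.amp_sd_pct)
            if a > 0:
                amps_pct[i] = a
                break
        else:
            raise ValueError(
                "could not draw a positive amplitude in 100 tries; "
                "check amp_mean_pct / amp_sd_pct"
            )

    _, peak = _kernel_peak(params.rise_tau_s, params.decay_tau_s)
    support_s = 60.0 * params.decay_tau_s  # kernel support used for rendering
    for t0, a_pct in zip(onsets, amps_pct):
        i0 = int(np.ceil(t0 / params.dt_s))
        i1 = min(n, int(np.ceil((t0 + support_s) / params.dt_s)))
        if i0 >= n:
            continue
        tt = t[i0:i1] - t0
        kern = (np.exp(-tt / params.decay_tau_s) - np.exp(-tt / params.rise_tau_s)) / peak
        dff_true[i0:i1] += (a_pct / 100.0) * kern

    noise = rng.normal(0.0, params.noise_sd_pct / 100.0 * params.f0, size=n)
    f_signal = params.f0 * (1.0 + dff_true) + noise
    f_raw = f_signal + params.background_level
    f_background = np.full(n, params.background_level)

    t_half = kernel_t_half(params.rise_tau_s, params.decay_tau_s)
    integral = kernel_integral(params.rise_tau_s, params.decay_tau_s)
    truth = GroundTruth(
        events=pd.DataFrame(
            {
                "onset_s": onsets,
                "amplitude_pct": amps_pct,
                "t_half_s": np.full(n_events, t_half),
                "auc": amps_pct / 100.0 * integral,
            }
        ),
        info={"dff_true": dff_true, "params": asdict(params)},
    )
    trace = FluorescenceTrace(
        t_s=t, f_raw=f_raw, f_background=f_background, dt_s=params.dt_s
    )
    return trace, truth


# ---------------------------------------------------------------------------
# Chemotaxis simulation
# ---------------------------------------------------------------------------

def _containment_diameter(params: ChemoGenParams, t_min: np.ndarray) -> np.ndarray:
    return np.maximum(
        params.d_final_um, params.d0_um - params.shrink_rate_um_per_min * t_min
    )


def simulate_chemotaxis(
    params: ChemoGenParams,
    rng: Optional[np.random.Generator] = None,
    mouse_id: str = "m0",
) -> tuple[ChemotaxisRecording, list[ProcessTrack], GroundTruth]:
    """Simulate one ATP application: containment boundary + tracked tips.

    The pipette tip sits at the origin. The containment boundary at each
    frame is a mildly eccentric ellipse (major + minor diameters summing to
    twice the current containment diameter) sampled at jittered angles with
    radial noise; its diameter shrinks linearly from d0 to d_final. Tracked
    processes start at drawn initial distances with random angles and move
    radially inward at constant velocity v = β·d + ε (clamped at ≥ 0;
    position clipped at the tip). Ground truth records each track's initial
    distance and true mean velocity over the recording.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)

    t_s = np.arange(params.n_frames) * params.frame_interval_s
    t_min = t_s / 60.0
    diam = _containment_diameter(params, t_min)

    # containment boundary point clouds
    frames = []
    phase = rng.uniform(0.0, 2.0 * np.pi)
    for k in range(params.n_frames):
        nb = params.n_boundary_points
        ang = (
            np.linspace(0.0, 2.0 * np.pi, nb, endpoint=False)
            + phase
            + rng.uniform(-0.5, 0.5, nb) * (2.0 * np.pi / nb)
        )
        semi_major = diam[k] * (1.0 + params.axis_imbalance) / 2.0
        semi_minor = diam[k] * (1.0 - params.axis_imbalance) / 2.0
        r = (semi_major * semi_minor) / np.sqrt(
            (semi_minor * np.cos(ang)) ** 2 + (semi_major * np.sin(ang)) ** 2
        )
        r = r + rng.normal(0.0, params.boundary_noise_sd_um, nb)
        frames.append((float(t_s[k]), np.column_stack([r * np.cos(ang), r * np.sin(ang)])))

    recording = ChemotaxisRecording(
        mouse_id=mouse_id,
        pipette_xy_um=np.zeros(2),
        frames=frames,
        meta={"params": asdict(params)},
    )

    # tracked process tips
    lo, hi = params.initial_distance_range_um
    d0 = rng.uniform(lo, hi, params.n_processes)
    theta = rng.uniform(0.0, 2.0 * np.pi, params.n_processes)
    eps = rng.normal(0.0, params.velocity_noise_sd_um_per_min, params.n_processes)
    v = np.maximum(params.velocity_slope_per_min * d0 + eps, 0.0)

    tracks: list[ProcessTrack] = []
    total_min = t_min[-1]
    for j in range(params.n_processes):
        radius = np.maximum(d0[j] - v[j] * t_min, 0.0)
        xy = np.column_stack(
            [radius * np.cos(theta[j]), radius * np.sin(theta[j])]
        )
        tracks.append(
            ProcessTrack(
                track_id=f"{mouse_id}_tr{j:03d}",
                mouse_id=mouse_id,
                t_s=t_s.copy(),
                xy_um=xy,
            )
        )
    # true mean velocity accounts for clipping at the tip
    v_true = np.minimum(v, d0 / total_min) if total_min > 0 else v
    truth = GroundTruth(
        tracks=pd.DataFrame(
            {
                "track_id": [tr.track_id for tr in tracks],
                "initial_distance_um": d0,
                "true_velocity_um_per_min": v_true,
            }
        ),
        info={
            "diameter_um": diam,
            "beta": params.velocity_slope_per_min,
            "params": asdict(params),
        },
    )
    return recording, tracks, truth


def _measured_velocity(
    d0: np.ndarray, v: np.ndarray, total_min: float
) -> np.ndarray:
    """Mean track velocity the pipeline would measure for radial motion."""
    return np.minimum(np.maximum(v, 0.0), d0 / total_min)


def calibrate_velocity_noise(
    target_median_r: float,
    params: ChemoGenParams,
    n_mice: int = 8,
    n_reps: int = 20,
    seed: int = 321,
) -> float:
    """Pilot-sweep calibration of the velocity noise SD for a Spearman target.

    Bisects the noise SD so that the median per-mouse Spearman correlation
    between initial distance and measured mean velocity (simulated with the
    same draw scheme as :func:`simulate_chemotaxis`, including velocity
    clamping and tip clipping) hits ``target_median_r``. The relation is
    monotone decreasing in the noise SD.
    """
    if not (0 < target_median_r < 1):
        raise ValueError("target_median_r must be in (0, 1)")
    lo_d, hi_d = params.initial_distance_range_um
    beta = params.velocity_slope_per_min
    if beta <= 0:
        raise ValueError("calibration needs velocity_slope_per_min > 0")
    total_min = (params.n_frames - 1) * params.frame_interval_s / 60.0
    from scipy.stats import spearmanr

    def median_r(sigma: float) -> float:
        rng = np.random.default_rng(seed)
        rs = []
        for _ in range(n_reps):
            per_mouse = []
            for _ in range(n_mice):
                d0 = rng.uniform(lo_d, hi_d, params.n_processes)
                eps = rng.normal(0.0, sigma, params.n_processes)
                vm = _measured_velocity(d0, beta * d0 + eps, total_min)
                per_mouse.append(spearmanr(d0, vm).statistic)
            rs.append(np.median(per_mouse))
        return float(np.median(rs))

    sig_lo, sig_hi = 1e-4, 50.0 * beta * (hi_d - lo_d)
    if median_r(sig_lo) < target_median_r:
        return sig_lo
    for _ in range(40):
        mid = np.sqrt(sig_lo * sig_hi)
        if median_r(mid) > target_median_r:
            sig_lo = mid
        else:
            sig_hi = mid
    return float(np.sqrt(sig_lo * sig_hi))


# ---------------------------------------------------------------------------
# Cohort design and simulation
# ---------------------------------------------------------------------------

# Event rates (events/min among non-silent cells) follow the bell-shaped age
# profile; silent-cell probabilities put per-mouse active fractions in a
# realistic 45-80% range. Spearman targets follow the degraded-then-restored
# coordination profile. All are order-of-magnitude choices: the source study
# reports these quantities only graphically.
_DEFAULT_GROUPS: list[dict] = [
    dict(age_group="young", diet="AL", n_mice=11, cells_per_mouse=4,
         rate=0.10, silent=0.40, target_r=0.75),
    dict(age_group="middle", diet="AL", n_mice=10, cells_per_mouse=3,
         rate=0.40, silent=0.35, target_r=0.82),
    dict(age_group="old", diet="AL", n_mice=14, cells_per_mouse=3,
         rate=0.12, silent=0.25, target_r=0.55),
    dict(age_group="middle", diet="CR3", n_mice=7, cells_per_mouse=4,
         rate=0.12, silent=0.40, target_r=0.82),
    dict(age_group="old", diet="CR6", n_mice=8, cells_per_mouse=3,
         rate=0.15, silent=0.30, target_r=0.90),
    dict(age_group="old", diet="CR18", n_mice=10, cells_per_mouse=3,
         rate=0.12, silent=0.30, target_r=0.90),
]


@lru_cache(maxsize=None)
def _calibrated_sigma(target_r: float, tracks_per_mouse: int) -> float:
    """Cached pilot-sweep calibration for the default design's groups."""
    return calibrate_velocity_noise(
        target_r, ChemoGenParams(n_processes=tracks_per_mouse)
    )


def default_cohort_design(seed: int = 0, tracks_per_mouse: int = 20) -> CohortDesign:
    """The default age × sex × diet cohort with calibrated chemotaxis noise.

    Group sizes mirror the study design (e.g. 11 young / 10 middle-aged /
    14 old control mice). Each group's velocity-noise SD is calibrated by a
    pilot sweep so the per-mouse median Spearman r hits the group's target.
    """
    groups = []
    for spec in _DEFAULT_GROUPS:
        tp = TraceGenParams(event_rate_per_min=spec["rate"])
        cp = ChemoGenParams(n_processes=tracks_per_mouse)
        cp.velocity_noise_sd_um_per_min = _calibrated_sigma(
            spec["target_r"], tracks_per_mouse
        )
        groups.append(
            GroupSpec(
                age_group=spec["age_group"],
                diet=spec["diet"],
                n_mice=spec["n_mice"],
                cells_per_mouse=spec["cells_per_mouse"],
                trace_params=tp,
                chemo_params=cp,
                silent_cell_prob=spec["silent"],
                target_r=spec["target_r"],
            )
        )
    return CohortDesign(groups=groups, seed=seed)


@dataclass
class CohortBundle:
    """All simulated objects of one cohort plus long-format table exports."""

    cells: list[dict]  # mouse_id, cell_id, sex, age_group, diet, trace, truth
    chemo: list[dict]  # mouse_id, recording, tracks, truth
    metadata: pd.DataFrame
    design: CohortDesign

    def traces_table(self) -> pd.DataFrame:
        parts = []
        for c in self.cells:
            tr: FluorescenceTrace = c["trace"]
            parts.append(
                pd.DataFrame(
                    {
                        "cell_id": c["cell_id"],
                        "t_s": tr.t_s,
                        "f_raw": tr.f_raw,
                        "f_background": tr.f_background,
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)

    def tracks_table(self) -> pd.DataFrame:
        rows = []
        for ch in self.chemo:
            for tr in ch["tracks"]:
                for i in range(tr.n_points):
                    rows.append(
                        (
                            tr.track_id,
                            ch["mouse_id"],
                            i,
                            tr.t_s[i],
                            tr.xy_um[i, 0],
                            tr.xy_um[i, 1],
                        )
                    )
        return pd.DataFrame(
            rows,
            columns=["track_id", "mouse_id", "point_index", "t_s", "x_um", "y_um"],
        )

    def containment_table(self) -> pd.DataFrame:
        rows = []
        for ch in self.chemo:
            for t, pts in ch["recording"].frames:
                for x, y in pts:
                    rows.append((ch["mouse_id"], t, x, y))
        return pd.DataFrame(rows, columns=["mouse_id", "t_s", "x_um", "y_um"])

    def truth_events_table(self) -> pd.DataFrame:
        parts = []
        for c in self.cells:
            ev = c["truth"].events
            if ev is not None and len(ev):
                parts.append(ev.assign(cell_id=c["cell_id"]))
        if not parts:
            return pd.DataFrame(
                columns=["onset_s", "amplitude_pct", "t_half_s", "auc", "cell_id"]
            )
        return pd.concat(parts, ignore_index=True)

    def truth_tracks_table(self) -> pd.DataFrame:
        parts = []
        for ch in self.chemo:
            parts.append(ch["truth"].tracks.assign(mouse_id=ch["mouse_id"]))
        return pd.concat(parts, ignore_index=True)


def simulate_cohort(design: CohortDesign) -> CohortBundle:
    """Simulate a full cohort: traces, chemotaxis and metadata tables.

    Reproducible: the master seed is split hierarchically (group → mouse →
    cell/recording) so any subset is regenerated identically. Mice within a
    group alternate male/female.
    """
    design.validate()
    master = np.random.SeedSequence(design.seed)
    group_seeds = master.spawn(len(design.groups))

    cells: list[dict] = []
    chemo: list[dict] = []
    meta_rows = []
    for g, gseed in zip(design.groups, group_seeds):
        mouse_seeds = gseed.spawn(g.n_mice)
        for m, mseed in enumerate(mouse_seeds):
            mouse_id = f"{g.age_group}_{g.diet}_m{m:02d}"
            sex = SEXES[m % 2]
            sub = mseed.spawn(g.cells_per_mouse + 1)
            mouse_rng = np.random.default_rng(mseed)
            for c in range(g.cells_per_mouse):
                cell_id = f"{mouse_id}_c{c:02d}"
                cell_rng = np.random.default_rng(sub[c])
                tp = g.trace_params
                if mouse_rng.uniform() < g.silent_cell_prob:
                    tp = replace(tp, event_rate_per_min=0.0)
                trace, truth = simulate_trace(tp, rng=cell_rng)
                cells.append(
                    dict(
                        mouse_id=mouse_id,
                        cell_id=cell_id,
                        sex=sex,
                        age_group=g.age_group,
                        diet=g.diet,
                        trace=trace,
                        truth=truth,
                    )
                )
                meta_rows.append((mouse_id, cell_id, sex, g.age_group, g.diet))
            rec, tracks, truth = simulate_chemotaxis(
                g.chemo_params,
                rng=np.random.default_rng(sub[-1]),
                mouse_id=mouse_id,
            )
            rec.meta.update(sex=sex, age_group=g.age_group, diet=g.diet)
            chemo.append(
                dict(
                    mouse_id=mouse_id,
                    sex=sex,
                    age_group=g.age_group,
                    diet=g.diet,
                    recording=rec,
                    tracks=tracks,
                    truth=truth,
                )
            )
    metadata = pd.DataFrame(
        meta_rows, columns=["mouse_id", "cell_id", "sex", "age_group", "diet"]
    )
    return CohortBundle(cells=cells, chemo=chemo, metadata=metadata, design=design)


# ---------------------------------------------------------------------------
# File export / design (de)serialisation
# ---------------------------------------------------------------------------

def write_cohort(bundle: CohortBundle, outdir) -> None:
    """Write a cohort as plain-text tables.

    traces.csv (cell_id, t_s, f_raw, f_background), tracks.tsv (MTrackJ-style
    columns plus mouse_id), containment.csv, metadata.csv, ground-truth CSVs,
    and design.yaml (fully specifies the cohort).
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.traces_table().to_csv(out / "traces.csv", index=False)
    bundle.tracks_table().to_csv(out / "tracks.tsv", sep="\t", index=False)
    bundle.containment_table().to_csv(out / "containment.csv", index=False)
    bundle.metadata.to_csv(out / "metadata.csv", index=False)
    bundle.truth_events_table().to_csv(out / "truth_events.csv", index=False)
    bundle.truth_tracks_table().to_csv(out / "truth_tracks.csv", index=False)
    save_design(bundle.design, out / "design.yaml")


def save_design(design: CohortDesign, path) -> None:
    doc = {
        "seed": design.seed,
        "groups": [
            {
                "age_group": g.age_group,
                "diet": g.diet,
                "n_mice": g.n_mice,
                "cells_per_mouse": g.cells_per_mouse,
                "silent_cell_prob": g.silent_cell_prob,
                "target_r": g.target_r,
                "trace_params": asdict(g.trace_params),
                "chemo_params": asdict(g.chemo_params),
            }
            for g in design.groups
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_design(path) -> CohortDesign:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    groups = []
    for g in doc["groups"]:
        cp = dict(g["chemo_params"])
        if "initial_distance_range_um" in cp:
            cp["initial_distance_range_um"] = tuple(cp["initial_distance_range_um"])
        groups.append(
            GroupSpec(
                age_group=g["age_group"],
                diet=g["diet"],
                n_mice=g["n_mice"],
                cells_per_mouse=g["cells_per_mouse"],
                trace_params=TraceGenParams(**g["trace_params"]),
                chemo_params=ChemoGenParams(**cp),
                silent_cell_prob=g.get("silent_cell_prob", 0.0),
                target_r=g.get("target_r"),
            )
        )
    design = CohortDesign(groups=groups, seed=doc.get("seed", 0))
    design.validate()
    return design
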