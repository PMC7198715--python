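"""ATP-directed process chemotaxis quantification.

Quantifies how microglial processes converge on a local ATP source (a
pipette tip acting as a DAMP point source):

* a direct least-squares ellipse fit to the containment boundary points at
  each frame; the containment diameter is the mean of the fitted major and
  minor diameters;
* the final containment diameter (mean over the terminal plateau of the
  diameter time course) and the containment formation velocity (diameter
  reduction per minute up to the plateau);
* per-process mean velocities from MTrackJ-style tip tracks (Euclidean step
  length per frame interval, tracks with ≥ 7 consecutive timepoints only);
* the per-mouse Spearman rank correlation between a process's initial
  distance to the pipette tip and its mean velocity — the paper-level
  readout of chemotactic coordination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sstats

__all__ = [
    "ChemotaxisRecording",
    "ProcessTrack",
    "MouseChemotaxisSummary",
    "fit_ellipse",
    "containment_timecourse",
    "final_diameter",
    "formation_velocity",
    "track_velocity",
    "distance_velocity_correlation",
    "analyze_recording",
    "MIN_TRACK_POINTS",
]

MIN_TRACK_POINTS = 7  # tracks must span ≥ 7 consecutive timepoints
PLATEAU_TOL = 0.05  # "remained constant": < 5% change per frame


@dataclass
class ChemotaxisRecording:
    """Per-timepoint containment boundary point clouds around a pipette tip.

    ``frames`` is a list of ``(t_s, points)`` with ``points`` an (N, 2)
    array of μm coordinates; t = 0 is the moment of ATP application.
    Derived fields are filled by :func:`analyze_recording`.
    """

    mouse_id: str
    pipette_xy_um: np.ndarray
    frames: list[tuple[float, np.ndarray]]
    meta: dict = field(default_factory=dict)
    ellipses: Optional[list] = None  # per frame: (major_d, minor_d, center) or None
    mean_diameter_um: Optional[np.ndarray] = None
    final_diameter_um: Optional[float] = None
    formation_velocity_um_per_min: Optional[float] = None
    plateau_warning: bool = False

    @property
    def t_s(self) -> np.ndarray:
        return np.array([t for t, _ in self.frames], dtype=float)


@dataclass
class ProcessTrack:
    """One tracked process tip over consecutive frames (MTrackJ-style)."""

    track_id: str
    mouse_id: str
    t_s: np.ndarray
    xy_um: np.ndarray
    initial_distance_um: Optional[float] = None
    mean_velocity_um_per_min: Optional[float] = None
    included: bool = False
    exclusion_reason: Optional[str] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return len(self.t_s)


@dataclass
class MouseChemotaxisSummary:
    mouse_id: str
    spearman_r: float
    n_tracks: int
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Ellipse fitting (direct least-squares conic fit constrained to ellipses)
# ---------------------------------------------------------------------------

def fit_ellipse(points: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Fit an ellipse to 2D points by the stable direct least-squares method.

    Solves the constrained conic least-squares problem (4AC − B² = 1) via
    the Halir–Flusser block decomposition, which is numerically stable and
    always returns an ellipse when one exists. Points are centred and scaled
    before fitting so the result is invariant to translation, rotation and
    point ordering to near machine precision.

    Parameters
    ----------
    points : (N, 2) array
        Boundary coordinates in μm, N ≥ 5, not collinear.

    Returns
    -------
    (major_d_um, minor_d_um, center)
        Full axis lengths (diameters, major ≥ minor) and the ellipse centre.

    Raises
    ------
    ValueError
        For fewer than 5 points, degenerate configurations, or a conic
        solution that is not an ellipse.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (N, 2) array")
    if len(pts) < 5:
        raise ValueError(f"need at least 5 points to fit an ellipse, got {len(pts)}")

    centroid = pts.mean(axis=0)
    xy = pts - centroid
    scale = float(np.sqrt(np.mean(np.sum(xy**2, axis=1))))
    if scale <= 0:
        raise ValueError("degenerate point configuration (all points coincide)")
    x, y = (xy / scale).T

    # Halir & Flusser block decomposition of the Fitzgibbon fit
    d1 = np.column_stack([x * x, x * y, y * y])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t_mat = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate point configuration (collinear points?)") from exc
    m = s1 + s2 @ t_mat
    # premultiply by inv(C1), C1 = [[0,0,2],[0,-1,0],[2,0,0]]
    m = np.array([m[2] / 2.0, -m[1], m[0] / 2.0])
    eigval, eigvec = np.linalg.eig(m)
    # the valid solution satisfies the ellipse constraint 4ac − b² > 0
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    ok = np.where(np.isreal(eigval) & (cond > 0))[0]
    if len(ok) == 0:
        raise ValueError("no elliptical solution for these points")
    a1 = np.real(eigvec[:, ok[0]])
    a2 = t_mat @ a1
    A, B, C = a1
    D, E, F = a2

    # conic -> geometric parameters
    den = B * B - 4.0 * A * C
    if den >= 0:
        raise ValueError("conic solution is not an ellipse")
    cx = (2.0 * C * D - B * E) / den
    cy = (2.0 * A * E - B * D) / den
    # evaluate conic at centre to get the scaled radii
    f_c = A * cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F
    # semi-axes from the eigenvalues of the quadratic-form matrix
    q = np.array([[A, B / 2.0], [B / 2.0, C]])
    lam = np.linalg.eigvalsh(q)
    if np.any(lam * -f_c <= 0):
        raise ValueError("degenerate conic (zero-size ellipse)")
    semi = np.sqrt(-f_c / lam)  # in scaled units
    semi = np.sort(semi)[::-1] * scale
    center = np.array([cx, cy]) * scale + centroid
    return float(2.0 * semi[0]), float(2.0 * semi[1]), center


# ---------------------------------------------------------------------------
# Containment time course
# ---------------------------------------------------------------------------

def containment_timecourse(recording: ChemotaxisRecording) -> np.ndarray:
    """Per-frame mean containment diameter, (major + minor) / 2, in μm.

    Fits an ellipse to each frame's point cloud. Frames whose fit fails are
    recorded as NaN — never interpolated. Fills ``recording.ellipses`` and
    ``recording.mean_diameter_um`` and returns the diameter series.
    """
    ellipses: list = []
    diam = np.full(len(recording.frames), np.nan)
    for i, (_, pts) in enumerate(recording.frames):
        try:
            major, minor, center = fit_ellipse(pts)
        except ValueError:
            ellipses.append(None)
            continue
        ellipses.append((major, minor, center))
        diam[i] = 0.5 * (major + minor)
    recording.ellipses = ellipses
    recording.mean_diameter_um = diam
    return diam


def final_diameter(
    series: np.ndarray, tol: float = PLATEAU_TOL
) -> tuple[float, int, bool]:
    """Mean containment diameter over the terminal plateau.

    The plateau is the longest terminal run in which each successive
    diameter changes by less than ``tol`` (fraction of the current value)
    per frame. If no plateau exists (e.g. the containment is still
    shrinking at the end of the recording) the mean of the last 3 valid
    frames is returned with a warning flag.

    Returns
    -------
    (final_diameter_um, plateau_start_index, warning)
        ``plateau_start_index`` indexes the original series.
    """
    series = np.asarray(series, dtype=float)
    valid = np.where(np.isfinite(series))[0]
    if len(valid) < 5:
        raise ValueError(f"need at least 5 fitted frames, got {len(valid)}")
    vals = series[valid]
    # walk backwards while successive change stays below tolerance
    start = len(vals) - 1
    while start > 0 and abs(vals[start] - vals[start - 1]) < tol * vals[start - 1]:
        start -= 1
    if start == len(vals) - 1:  # not even the last pair is stable
        warnings.warn(
            "no terminal plateau found; using mean of last 3 frames", stacklevel=2
        )
        return float(np.mean(vals[-3:])), int(valid[-3]), True
    return float(np.mean(vals[start:])), int(valid[start]), False


def formation_velocity(
    series: np.ndarray, t_s: np.ndarray, plateau_start: int
) -> float:
    """Containment formation velocity in μm/min.

    The reduction of the mean diameter from ATP application (t = 0) to the
    start of the plateau, divided by the elapsed time in minutes. A plateau
    at frame 0 (no shrinkage) gives 0.
    """
    series = np.asarray(series, dtype=float)
    t_s = np.asarray(t_s, dtype=float)
    if plateau_start == 0:
        return 0.0
    first = np.where(np.isfinite(series))[0][0]
    dt_min = (t_s[plateau_start] - t_s[first]) / 60.0
    if dt_min <= 0:
        return 0.0
    return float((series[first] - series[plateau_start]) / dt_min)


def analyze_recording(
    recording: ChemotaxisRecording, plateau_tol: float = PLATEAU_TOL
) -> ChemotaxisRecording:
    """Run the full containment analysis on one recording, in place."""
    diam = containment_timecourse(recording)
    final, start, warn = final_diameter(diam, tol=plateau_tol)
    recording.final_diameter_um = final
    recording.plateau_warning = warn
    recording.formation_velocity_um_per_min = formation_velocity(
        diam, recording.t_s, start
    )
    return recording


# ---------------------------------------------------------------------------
# Process tracks
# ---------------------------------------------------------------------------

def track_velocity(
    track: ProcessTrack,
    pipette_xy: np.ndarray,
    min_points: int = MIN_TRACK_POINTS,
) -> ProcessTrack:
    """Derive a track's initial distance and mean velocity; apply inclusion rules.

    The mean process velocity is the average Euclidean distance travelled by
    the tip between consecutive timepoints, per minute; the initial distance
    is from the first tracked point to the pipette tip. Tracks shorter than
    ``min_points`` or with non-consecutive (non-uniform) timepoints are
    excluded with a reason, mirroring the manual-tracking inclusion rule.
    """
    track.t_s = np.asarray(track.t_s, dtype=float)
    track.xy_um = np.asarray(track.xy_um, dtype=float)
    pipette_xy = np.asarray(pipette_xy, dtype=float)
    n = track.n_points
    if n < min_points:
        track.included = False
        track.exclusion_reason = f"only {n} timepoints (< {min_points})"
        return track
    dt = np.diff(track.t_s)
    if np.any(dt <= 0) or np.max(np.abs(dt - dt[0])) > 1e-6 * dt[0]:
        track.included = False
        track.exclusion_reason = "non-consecutive timepoints"
        return track
    steps = np.linalg.norm(np.diff(track.xy_um, axis=0), axis=1)
    track.mean_velocity_um_per_min = float(np.mean(steps) / (dt[0] / 60.0))
    track.initial_distance_um = float(np.linalg.norm(track.xy_um[0] - pipette_xy))
    track.included = True
    track.exclusion_reason = None
    return track


def distance_velocity_correlation(
    tracks: Sequence[ProcessTrack],
    mouse_id: Optional[str] = None,
    min_tracks: int = 3,
) -> Optional[MouseChemotaxisSummary]:
    """Spearman rank correlation between initial distance and mean velocity.

    Uses only included tracks of one mouse; average ranks for ties. With
    fewer than ``min_tracks`` usable tracks the correlation is undefined and
    ``None`` is returned with a warning (never imputed).
    """
    usable = [t for t in tracks if t.included]
    if mouse_id is not None:
        usable = [t for t in usable if t.mouse_id == mouse_id]
    else:
        ids = {t.mouse_id for t in usable}
        if len(ids) > 1:
            raise ValueError("tracks from several mice; pass mouse_id explicitly")
        mouse_id = ids.pop() if ids else "?"
    if len(usable) < min_tracks:
        warnings.warn(
            f"mouse {mouse_id}: only {len(usable)} usable tracks, "
            "Spearman r undefined",
            stacklevel=2,
        )
        return None
    d = np.array([t.initial_distance_um for t in usable])
    v = np.array([t.mean_velocity_um_per_min for t in usable])
    r = sstats.spearmanr(d, v).statistic
    return MouseChemotaxisSummary(
        mouse_id=mouse_id, spearman_r=float(r), n_tracks=len(usable)
    )
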