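"""End-to-end orchestration: configuration, file I/O and the two pipelines.

``run_calcium_pipeline`` takes traces to group statistics:
traces → ΔF/F → low-pass filter → transient detection → per-event metrics →
per-cell / per-mouse summaries → nonparametric group comparisons.

``run_chemotaxis_pipeline`` takes tracks and containment point clouds to
per-mouse chemotaxis summaries and their comparisons.

Inputs are either plain-text tables (traces CSV, MTrackJ-style tracks TSV,
metadata CSV, containment CSV) or a synthetic cohort design; runs are
deterministic given the configuration and seed, and every output table row
is traceable to a mouse/cell/track id. A JSON run manifest records the
parameters needed to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import chemotaxis as chemo_mod
from . import events as events_mod
from . import stats as stats_mod
from . import synth as synth_mod
from . import traces as traces_mod
from .chemotaxis import ChemotaxisRecording, ProcessTrack
from .traces import FluorescenceTrace

logger = logging.getLogger("microca")

__all__ = [
    "RunConfig",
    "ResultsBundle",
    "load_traces_csv",
    "load_tracks_tsv",
    "load_metadata_csv",
    "load_containment_csv",
    "run_calcium_pipeline",
    "run_chemotaxis_pipeline",
    "run_all",
]

# CR protocols compared against their age-matched ad libitum controls
CR_PAIRS = [("middle", "CR3"), ("old", "CR6"), ("old", "CR18")]


@dataclass
class RunConfig:
    """Run parameters; exactly one input source (files XOR synthetic design)."""

    traces_csv: Optional[str] = None
    tracks_tsv: Optional[str] = None
    metadata_csv: Optional[str] = None
    containment_csv: Optional[str] = None
    design: Optional[synth_mod.CohortDesign] = None
    use_default_design: bool = False

    f0_method: str = traces_mod.DEFAULT_F0_METHOD
    cutoff_hz: float = traces_mod.DEFAULT_CUTOFF_HZ
    k_sd: float = events_mod.DEFAULT_K_SD
    crossing_k: float = events_mod.DEFAULT_CROSSING_K
    plateau_tol: float = chemo_mod.PLATEAU_TOL
    min_track_points: int = chemo_mod.MIN_TRACK_POINTS
    duration_min: float = events_mod.DEFAULT_DURATION_MIN
    pipette_x_um: float = 0.0
    pipette_y_um: float = 0.0

    outlier_removal: bool = False
    alpha: float = stats_mod.ALPHA

    out_dir: Optional[str] = None
    seed: int = 0

    def validate(self) -> None:
        has_files = any([self.traces_csv, self.tracks_tsv, self.metadata_csv])
        has_synth = self.design is not None or self.use_default_design
        if has_files == has_synth:
            raise ValueError(
                "exactly one input source required: file paths XOR a synthetic design"
            )
        if not 0 < self.cutoff_hz:
            raise ValueError("cutoff_hz must be positive")
        if self.k_sd <= 0 or self.crossing_k <= 0 or self.k_sd < self.crossing_k:
            raise ValueError("need k_sd >= crossing_k > 0")
        if self.min_track_points < 2:
            raise ValueError("min_track_points must be >= 2")
        if self.duration_min <= 0:
            raise ValueError("duration_min must be positive")

    @property
    def pipette_xy(self) -> np.ndarray:
        return np.array([self.pipette_x_um, self.pipette_y_um])

    def resolved_design(self) -> Optional[synth_mod.CohortDesign]:
        if self.design is not None:
            d = self.design
        elif self.use_default_design:
            d = synth_mod.default_cohort_design()
        else:
            return None
        return dataclasses.replace(d, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        design = None
        if "design" in doc:
            dd = doc.pop("design")
            if dd == "default":
                doc["use_default_design"] = True
            elif isinstance(dd, str):
                design = synth_mod.load_design(dd)
            elif dd is not None:
                raise ValueError("design must be a path or the string 'default'")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(design=design, **doc)

    def manifest(self) -> dict:
        from importlib.metadata import version, PackageNotFoundError

        try:
            ver = version("microca")
        except PackageNotFoundError:  # pragma: no cover
            ver = "unknown"
        d = dataclasses.asdict(self)
        d["design"] = None if self.design is None else "inline design (see design.yaml)"
        return {"package_version": ver, "config": d, "seed": self.seed}


@dataclass
class ResultsBundle:
    """Output tables plus the run manifest."""

    tables: dict = field(default_factory=dict)  # name -> DataFrame
    manifest: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in sorted(self.tables.items()):
            df.to_csv(out / f"{name}.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# Loading plain-text inputs
# ---------------------------------------------------------------------------

def load_metadata_csv(path) -> pd.DataFrame:
    """Load cohort metadata; rows with missing fields are rejected with a reason."""
    df = pd.read_csv(path, dtype=str)
    required = ["mouse_id", "sex", "age_group", "diet"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"metadata is missing columns: {missing_cols}")
    bad = df[required].isna().any(axis=1)
    if bad.any():
        for idx in df.index[bad]:
            logger.warning("metadata row %d rejected: missing fields", idx)
        df = df[~bad]
    return df.reset_index(drop=True)


def load_traces_csv(path) -> dict[str, FluorescenceTrace]:
    """Load long-format traces (cell_id, t_s, f_raw, f_background)."""
    df = pd.read_csv(path)
    required = {"cell_id", "t_s", "f_raw", "f_background"}
    if not required.issubset(df.columns):
        raise ValueError(f"traces CSV must have columns {sorted(required)}")
    out: dict[str, FluorescenceTrace] = {}
    for cell_id, sub in df.groupby("cell_id", sort=True):
        sub = sub.sort_values("t_s")
        t = sub["t_s"].to_numpy(dtype=float)
        if len(t) < 2:
            logger.warning("trace %s rejected: fewer than 2 samples", cell_id)
            continue
        dt = float(t[1] - t[0])
        out[str(cell_id)] = FluorescenceTrace(
            t_s=t,
            f_raw=sub["f_raw"].to_numpy(dtype=float),
            f_background=sub["f_background"].to_numpy(dtype=float),
            dt_s=dt,
        )
    return out


def load_tracks_tsv(path, default_mouse_id: str = "m0") -> list[ProcessTrack]:
    """Load MTrackJ-style tracks (track_id, point_index, t_s, x_um, y_um [, mouse_id])."""
    df = pd.read_csv(path, sep="\t")
    required = {"track_id", "point_index", "t_s", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"tracks TSV must have columns {sorted(required)}")
    has_mouse = "mouse_id" in df.columns
    tracks = []
    for track_id, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("point_index")
        mouse = str(sub["mouse_id"].iloc[0]) if has_mouse else default_mouse_id
        tracks.append(
            ProcessTrack(
                track_id=str(track_id),
                mouse_id=mouse,
                t_s=sub["t_s"].to_numpy(dtype=float),
                xy_um=sub[["x_um", "y_um"]].to_numpy(dtype=float),
            )
        )
    return tracks


def load_containment_csv(path) -> list[ChemotaxisRecording]:
    """Load containment boundary points (mouse_id, t_s, x_um, y_um)."""
    df = pd.read_csv(path)
    required = {"mouse_id", "t_s", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"containment CSV must have columns {sorted(required)}")
    recs = []
    for mouse_id, sub in df.groupby("mouse_id", sort=True):
        frames = [
            (float(t), g[["x_um", "y_um"]].to_numpy(dtype=float))
            for t, g in sub.groupby("t_s", sort=True)
        ]
        recs.append(
            ChemotaxisRecording(
                mouse_id=str(mouse_id), pipette_xy_um=np.zeros(2), frames=frames
            )
        )
    return recs


# ---------------------------------------------------------------------------
# Comparison helpers
# ---------------------------------------------------------------------------

def _apply_outliers(values: np.ndarray, enabled: bool) -> np.ndarray:
    if not enabled or len(values) < 4:
        return values
    mask = stats_mod.tukey_outliers(values)
    if not mask.all():
        logger.info("outlier removal: dropped %d of %d values",
                    int((~mask).sum()), len(values))
    return values[mask]


def _comparison_rows(analysis: str, level: str, res: stats_mod.ComparisonResult):
    rows = [
        dict(
            analysis=analysis,
            level=level,
            test=res.test_name,
            group_a="",
            group_b="",
            statistic=res.statistic,
            p_value=res.p_value,
            adjusted_p=np.nan,
        )
    ]
    for a, b, p_adj in res.pairwise:
        rows.append(
            dict(
                analysis=analysis,
                level=level,
                test=res.test_name + "_posthoc",
                group_a=a,
                group_b=b,
                statistic=np.nan,
                p_value=np.nan,
                adjusted_p=p_adj,
            )
        )
    return rows


def _age_and_cr_comparisons(
    df: pd.DataFrame,
    value_col: str,
    analysis: str,
    level: str,
    config: RunConfig,
) -> list[dict]:
    """KW+Dunn across ages (AL diet) and MW for each CR-vs-control pair."""
    rows: list[dict] = []
    sub = df.dropna(subset=[value_col])
    al = sub[sub["diet"] == "AL"]
    age_groups = [g for g in synth_mod.AGE_GROUPS if (al["age_group"] == g).sum() >= 3]
    if len(age_groups) >= 3:
        vals, labs = [], []
        for g in age_groups:
            v = _apply_outliers(
                al.loc[al["age_group"] == g, value_col].to_numpy(),
                config.outlier_removal,
            )
            vals.append(v)
            labs.append(np.full(len(v), g))
        try:
            res = stats_mod.kruskal_dunn(
                stats_mod.GroupedValues(
                    np.concatenate(vals), np.concatenate(labs), level=level
                ),
                alpha=config.alpha,
            )
            rows += _comparison_rows(f"{analysis}_by_age", level, res)
        except ValueError as exc:
            logger.warning("KW skipped for %s: %s", analysis, exc)
    for age, cr_diet in CR_PAIRS:
        ctrl = sub[(sub["diet"] == "AL") & (sub["age_group"] == age)][value_col]
        cr = sub[(sub["diet"] == cr_diet) & (sub["age_group"] == age)][value_col]
        if len(ctrl) >= 3 and len(cr) >= 3:
            a = _apply_outliers(ctrl.to_numpy(), config.outlier_removal)
            b = _apply_outliers(cr.to_numpy(), config.outlier_removal)
            res = stats_mod.mann_whitney(a, b, alpha=config.alpha)
            rows += _comparison_rows(
                f"{analysis}_{age}_AL_vs_{cr_diet}", level, res
            )
    return rows


# ---------------------------------------------------------------------------
# Calcium pipeline
# ---------------------------------------------------------------------------

def run_calcium_pipeline(config: RunConfig) -> ResultsBundle:
    """Traces → events → summaries → group comparisons."""
    config.validate()
    design = config.resolved_design()
    if design is not None:
        bundle = synth_mod.simulate_cohort(design)
        cell_inputs = [
            (c["cell_id"], c["trace"],
             {k: c[k] for k in ("mouse_id", "cell_id", "sex", "age_group", "diet")})
            for c in bundle.cells
        ]
    else:
        if not (config.traces_csv and config.metadata_csv):
            raise ValueError("calcium pipeline needs traces_csv and metadata_csv")
        traces = load_traces_csv(config.traces_csv)
        meta = load_metadata_csv(config.metadata_csv)
        if "cell_id" not in meta.columns:
            raise ValueError("metadata must include cell_id for the calcium pipeline")
        meta_by_cell = {row.cell_id: row._asdict() for row in meta.itertuples(index=False)}
        cell_inputs = []
        for cell_id, trace in traces.items():
            if cell_id not in meta_by_cell:
                logger.warning("trace %s rejected: no metadata row", cell_id)
                continue
            cell_inputs.append((cell_id, trace, meta_by_cell[cell_id]))

    event_rows, cell_summaries = [], []
    n_failed = 0
    for cell_id, trace, md in cell_inputs:
        try:
            traces_mod.process_trace(
                trace, f0_method=config.f0_method, cutoff_hz=config.cutoff_hz
            )
            evs = events_mod.detect_events(
                trace, k_sd=config.k_sd, crossing_k=config.crossing_k
            )
        except (ValueError, RuntimeError) as exc:
            logger.warning("trace %s failed: %s", cell_id, exc)
            n_failed += 1
            continue
        duration_min = trace.duration_s / 60.0
        cell_summaries.append(
            events_mod.summarize_cell(evs, md, duration_min=duration_min)
        )
        for ev in evs:
            event_rows.append(
                dict(
                    cell_id=cell_id,
                    mouse_id=md["mouse_id"],
                    onset_s=ev.onset_s,
                    peak_s=ev.peak_s,
                    end_s=ev.end_s,
                    amplitude_pct=ev.amplitude_pct,
                    t_half_s=ev.t_half_s,
                    auc=ev.auc,
                    edge_truncated=ev.edge_truncated,
                )
            )
    if cell_inputs and n_failed > 0.5 * len(cell_inputs):
        raise RuntimeError(
            f"{n_failed}/{len(cell_inputs)} traces failed; aborting run"
        )
    logger.info("calcium: %d traces processed, %d failed, %d events",
                len(cell_summaries), n_failed, len(event_rows))

    events_df = pd.DataFrame(
        event_rows,
        columns=["cell_id", "mouse_id", "onset_s", "peak_s", "end_s",
                 "amplitude_pct", "t_half_s", "auc", "edge_truncated"],
    ).sort_values(["cell_id", "onset_s"]).reset_index(drop=True)
    cells_df = pd.DataFrame([dataclasses.asdict(c) for c in cell_summaries])
    if len(cells_df):
        cells_df = cells_df.sort_values("cell_id").reset_index(drop=True)
    activity = events_mod.fraction_active_per_mouse(cell_summaries)
    mouse_df = pd.DataFrame([dataclasses.asdict(a) for a in activity])
    if len(mouse_df):
        mouse_df = mouse_df.sort_values("mouse_id").reset_index(drop=True)

    comp_rows: list[dict] = []
    if len(cells_df):
        active = cells_df[cells_df["is_active"]]
        # frequency: active cells only; shape metrics: cells with a defined median
        comp_rows += _age_and_cr_comparisons(
            active, "frequency_per_min", "frequency", "per_cell", config
        )
        for col, name in [
            ("median_amplitude_pct", "amplitude"),
            ("median_t_half_s", "t_half"),
            ("median_auc", "auc"),
        ]:
            comp_rows += _age_and_cr_comparisons(
                active, col, name, "per_cell", config
            )
    if len(mouse_df):
        comp_rows += _age_and_cr_comparisons(
            mouse_df, "fraction_active_pct", "fraction_active", "per_mouse", config
        )
        # age × sex interaction on the per-mouse active fraction (controls only)
        al = mouse_df[mouse_df["diet"] == "AL"]
        if al["sex"].nunique() == 2 and al["age_group"].nunique() >= 2:
            try:
                res = stats_mod.twoway_bonferroni(
                    stats_mod.GroupedValues(
                        al["fraction_active_pct"].to_numpy(),
                        al["age_group"].to_numpy(),
                        level="per_mouse",
                        labels2=al["sex"].to_numpy(),
                    ),
                    alpha=config.alpha,
                )
                comp_rows += _comparison_rows(
                    "fraction_active_age_x_sex", "per_mouse", res
                )
            except ValueError as exc:
                logger.warning("two-way ANOVA skipped: %s", exc)
    comparisons_df = pd.DataFrame(
        comp_rows,
        columns=["analysis", "level", "test", "group_a", "group_b",
                 "statistic", "p_value", "adjusted_p"],
    )

    return ResultsBundle(
        tables={
            "events": events_df,
            "cells": cells_df,
            "mouse_activity": mouse_df,
            "calcium_comparisons": comparisons_df,
        },
        manifest=config.manifest(),
    )


# ---------------------------------------------------------------------------
# Chemotaxis pipeline
# ---------------------------------------------------------------------------

def run_chemotaxis_pipeline(config: RunConfig) -> ResultsBundle:
    """Tracks + containment → per-mouse chemotaxis summaries → comparisons."""
    config.validate()
    design = config.resolved_design()
    if design is not None:
        bundle = synth_mod.simulate_cohort(design)
        mouse_inputs = [
            (ch["mouse_id"], ch["tracks"], ch["recording"],
             {k: ch[k] for k in ("sex", "age_group", "diet")})
            for ch in bundle.chemo
        ]
    else:
        if not (config.tracks_tsv and config.metadata_csv):
            raise ValueError("chemotaxis pipeline needs tracks_tsv and metadata_csv")
        tracks = load_tracks_tsv(config.tracks_tsv)
        meta = load_metadata_csv(config.metadata_csv)
        meta_by_mouse = {
            row.mouse_id: row._asdict()
            for row in meta.drop_duplicates("mouse_id").itertuples(index=False)
        }
        recordings = (
            {r.mouse_id: r for r in load_containment_csv(config.containment_csv)}
            if config.containment_csv
            else {}
        )
        by_mouse: dict[str, list[ProcessTrack]] = {}
        for tr in tracks:
            by_mouse.setdefault(tr.mouse_id, []).append(tr)
        mouse_inputs = []
        for mouse_id, trs in by_mouse.items():
            if mouse_id not in meta_by_mouse:
                logger.warning("tracks for %s rejected: no metadata row", mouse_id)
                continue
            mouse_inputs.append(
                (mouse_id, trs, recordings.get(mouse_id), meta_by_mouse[mouse_id])
            )

    track_rows, mouse_rows = [], []
    n_inc = n_exc = 0
    for mouse_id, tracks, recording, md in mouse_inputs:
        for tr in tracks:
            chemo_mod.track_velocity(
                tr, config.pipette_xy, min_points=config.min_track_points
            )
            n_inc += tr.included
            n_exc += not tr.included
            track_rows.append(
                dict(
                    track_id=tr.track_id,
                    mouse_id=mouse_id,
                    n_points=tr.n_points,
                    included=tr.included,
                    exclusion_reason=tr.exclusion_reason or "",
                    initial_distance_um=tr.initial_distance_um,
                    mean_velocity_um_per_min=tr.mean_velocity_um_per_min,
                )
            )
        summary = chemo_mod.distance_velocity_correlation(tracks, mouse_id=mouse_id)
        row = dict(
            mouse_id=mouse_id,
            sex=md.get("sex", "?"),
            age_group=md.get("age_group", "?"),
            diet=md.get("diet", "?"),
            spearman_r=np.nan if summary is None else summary.spearman_r,
            n_tracks=0 if summary is None else summary.n_tracks,
            final_diameter_um=np.nan,
            formation_velocity_um_per_min=np.nan,
        )
        if recording is not None and len(recording.frames):
            try:
                chemo_mod.analyze_recording(recording, plateau_tol=config.plateau_tol)
                row["final_diameter_um"] = recording.final_diameter_um
                row["formation_velocity_um_per_min"] = (
                    recording.formation_velocity_um_per_min
                )
            except ValueError as exc:
                logger.warning("containment analysis failed for %s: %s", mouse_id, exc)
        mouse_rows.append(row)
    logger.info("chemotaxis: %d tracks included, %d excluded", n_inc, n_exc)

    tracks_df = pd.DataFrame(
        track_rows,
        columns=["track_id", "mouse_id", "n_points", "included", "exclusion_reason",
                 "initial_distance_um", "mean_velocity_um_per_min"],
    )
    if len(tracks_df):
        tracks_df = tracks_df.sort_values("track_id").reset_index(drop=True)
    mouse_df = pd.DataFrame(mouse_rows)
    if len(mouse_df):
        mouse_df = mouse_df.sort_values("mouse_id").reset_index(drop=True)

    comp_rows: list[dict] = []
    if len(mouse_df):
        for col, name in [
            ("spearman_r", "spearman_r"),
            ("formation_velocity_um_per_min", "formation_velocity"),
            ("final_diameter_um", "final_diameter"),
        ]:
            comp_rows += _age_and_cr_comparisons(
                mouse_df, col, name, "per_mouse", config
            )
    comparisons_df = pd.DataFrame(
        comp_rows,
        columns=["analysis", "level", "test", "group_a", "group_b",
                 "statistic", "p_value", "adjusted_p"],
    )

    return ResultsBundle(
        tables={
            "tracks": tracks_df,
            "mouse_chemotaxis": mouse_df,
            "chemotaxis_comparisons": comparisons_df,
        },
        manifest=config.manifest(),
    )


def run_all(config: RunConfig) -> ResultsBundle:
    """Both pipelines; merged tables, one manifest."""
    ca = run_calcium_pipeline(config)
    ch = run_chemotaxis_pipeline(config)
    return ResultsBundle(tables={**ca.tables, **ch.tables}, manifest=config.manifest())
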