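# microca

Quantification of in vivo microglial function from two-photon imaging:
spontaneous somatic **Ca²⁺ transients** and ATP-directed **process
chemotaxis**, with the nonparametric cohort statistics used in aging /
caloric-restriction study designs. Written for imaging labs that score
microglial "alertness" (fraction of spontaneously active cells, transient
frequency and shape) and directed process motility (containment formation,
distance–velocity coordination) from ROI traces and manual tip tracks.

## What it computes

**Ca²⁺ transients.** Raw ROI fluorescence is background-subtracted
(blood-vessel ROI), converted to ΔF/F = F/F₀ − 1, and low-pass filtered
(2nd-order Butterworth, 0.2 Hz, zero-phase). A fluorescence change counts
as a transient when its amplitude exceeds 6 × SD of the baseline noise
(robust MAD estimate). Within a suprathreshold excursion, a transient whose
fluorescence decays below half of its running maximum before rising again
is closed there — each such excursion is one event. Per event: amplitude
(peak %ΔF/F), T-half (width at half-maximum, s), AUC (∫ΔF/F dt, ΔF/F·s).
Cells with ≥ 1 event in a 15-min recording are "spontaneously active";
summaries are per-cell medians and per-mouse active fractions.

**Process chemotaxis.** An ellipse is fitted (stable direct least-squares
conic fit) to the containment boundary around the ATP pipette at each
frame; the containment diameter is the mean of the major and minor
diameters. The analysis reports the final diameter (mean over the terminal
plateau), the formation velocity (diameter reduction per minute), and — per
tracked process with ≥ 7 consecutive timepoints — the mean tip velocity
(Euclidean step length per frame interval) and its initial distance to the
pipette. The per-mouse readout of chemotactic coordination is Spearman's
rank correlation r between initial distance and mean velocity.

**Statistics.** Median ± IQR summaries, Tukey outlier fences, KS normality
screening, Kruskal–Wallis with Dunn's post hoc (Bonferroni family-wise),
Mann–Whitney U for control-vs-CR comparisons, and two-way ANOVA (Type II)
with Bonferroni post hoc for age × sex interactions. Per-cell and per-mouse
analysis levels are kept separate.

**Synthetic cohorts.** A generator emulates the study structure — Poisson-
timed transients with a sharp-rise/exponential-decay kernel, white
measurement noise, and an age × sex × diet cohort with a bell-shaped event-
rate profile (middle-aged > young ≈ old) and a degraded-then-restored
distance–velocity coupling (old < middle, restored under caloric
restriction) — with full ground truth, so every pipeline stage is testable
without recorded data.

## Worked example

```python
import numpy as np
from microca import (TraceGenParams, simulate_trace, process_trace, detect_events,
                     ChemoGenParams, simulate_chemotaxis, track_velocity,
                     distance_velocity_correlation, analyze_recording)

trace, truth = simulate_trace(TraceGenParams(seed=3))   # 15-min recording, 2 Hz
process_trace(trace)                                    # dF/F, filter, noise SD
events = detect_events(trace)                           # 6 x SD criterion
print(f"F0 = {trace.f0:.1f} a.u.; baseline noise SD = {trace.noise_sd:.4f}")
for ev in events:
    print(f"onset {ev.onset_s:.1f} s  amplitude {ev.amplitude_pct:.1f}%  "
          f"T-half {ev.t_half_s:.2f} s  AUC {ev.auc:.2f}")

rec, tracks, _ = simulate_chemotaxis(ChemoGenParams(seed=3), mouse_id="demo")
analyze_recording(rec)
for tr in tracks:
    track_velocity(tr, np.zeros(2))
s = distance_velocity_correlation(tracks, mouse_id="demo")
print(f"formation {rec.formation_velocity_um_per_min:.2f} um/min, "
      f"final diameter {rec.final_diameter_um:.1f} um, Spearman r = {s.spearman_r:.3f}")
```

prints

```
F0 = 98.4 a.u.; baseline noise SD = 0.0055
onset 721.5 s  amplitude 17.7%  T-half 7.70 s  AUC 1.71
formation 5.02 um/min, final diameter 30.2 um, Spearman r = 0.901
```

i.e. the one injected transient is recovered with its shape metrics, the
containment shrinking at 5 μm/min to a 30-μm plateau is measured to within
fit noise, and this mouse's 20 tracks show tightly distance-coupled
velocities (r ≈ 0.9).

A command-line interface wraps the same pipelines:

```bash
microca simulate --seed 1 --out cohort/        # write a synthetic cohort
microca calcium --config run.yaml --out out/   # trace pipeline
microca chemotaxis --config run.yaml --out out/
microca --show-defaults
```

Input formats: traces CSV (`cell_id,t_s,f_raw,f_background`), MTrackJ-style
tracks TSV (`track_id,point_index,t_s,x_um,y_um[,mouse_id]`), metadata CSV
(`mouse_id,cell_id,sex,age_group,diet`), containment points CSV. Outputs
are per-event / per-cell / per-mouse CSV tables plus a JSON run manifest
that fully reproduces the run.

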