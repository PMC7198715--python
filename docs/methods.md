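# Methods

This note documents the models and procedures implemented in `microca`, the
parameter choices that matter, the design decisions taken where the
conventions of the field leave room, and what the synthetic validation does
and does not establish about real recordings.

## Ca²⁺ trace processing

**ΔF/F.** The somatic ROI trace is background-subtracted using a
blood-vessel ROI. By default the background is treated as a constant (the
median of the vessel trace); sample-wise subtraction is selectable
(`background_mode="timewise"`), trading noise doubling against robustness
to slow shared drifts. The basal fluorescence F₀ is the 20th percentile of
the background-subtracted trace — robust to the presence of transients,
which occupy a small duty cycle at physiological event rates. Alternatives
(mean of the lowest quartile, a user-specified quiet window) are available
through `f0_method`. ΔF/F = F/F₀ − 1 is kept as a dimensionless fraction
internally; amplitudes are reported in % only at the interface.

A percentile-based F₀ sits slightly below the true resting level on noisy
data, leaving a small positive offset on the ΔF/F baseline. Event detection
and event metrics are therefore referenced to the *median* of the filtered
ΔF/F (the resting level), not to absolute zero; without this, the offset
(≈ 0.8 noise SD for white noise) silently eats into the detection margin.

**Filtering.** "Low-pass IIR at 0.2 Hz" underdetermines the filter; we use
a 2nd-order Butterworth applied forward–backward (zero phase), so transient
timing and width metrics are not skewed by phase delay. Edge transients are
suppressed with Gustafsson's method — reflection padding can fabricate
excursions of several noise SDs in the first/last seconds of a recording,
which a 6×SD criterion will pick up as events.

**Baseline noise.** The noise SD is a robust estimate: 1.4826 × MAD of the
trace about a 10-s rolling median, ignoring samples inside an optional
event mask. It is computed on both the unfiltered and the filtered ΔF/F and
both are stored. The detector compares the *filtered* trace against 6 × the
*filtered-trace* SD, keeping criterion and signal consistent: filtering
shrinks white noise by roughly ×3 at these rates, so mixing scales would
make the effective criterion ~18×SD (missing small events) or ~2×SD
(admitting noise).

## Event detection and metrics

A candidate region is a maximal run of the baseline-referenced filtered
trace above a crossing threshold (2×SD by default), accepted if it contains
at least one sample above the amplitude criterion (6×SD). The crossing
sub-threshold defines the event *support*, so T-half and AUC describe the
full transient, not only its suprathreshold portion.

**Half-maximum-decay rule.** Within a region, the signal is scanned left to
right tracking the current event's running maximum M; when it falls below
M/2 and subsequently re-rises, the event is closed at the intervening
minimum (earliest index on ties) and a new event opens there. The re-rise
must exceed the amplitude criterion (6×SD) above the trough: filtered noise
riding a decay tail readily produces 2×SD re-rises, and with the weaker
guard the detector's false-positive rate rises roughly sixfold at SNR 10.
A re-rise below the criterion is, by the detector's own definition, not
evidence of a new transient. Sub-events whose peak does not exceed the
amplitude criterion are discarded. The state machine is verified against an
independently written brute-force implementation of the same rule on
randomized piecewise-linear segments.

**Onset refinement.** The zero-phase filter spreads rising edges ~1–2 s
backward, so the filtered-trace threshold crossing is systematically early.
Reported onsets are refined on the *unfiltered* ΔF/F: the sample after the
last sub-threshold (2×raw-SD) sample before the peak.

**Metrics.** Amplitude = peak ΔF/F × 100 (%); T-half = time above half the
peak with linear interpolation at the crossings (s); AUC = trapezoidal
∫ΔF/F dt over the support, with ΔF/F as a fraction (ΔF/F·s) — the ×100
convention difference between amplitude and AUC is deliberate and matches
the field's axis labels. Events touching the recording edges are kept and
flagged `edge_truncated`; they count toward frequency and the activity flag
but are excluded from per-cell shape-metric medians by default, since their
widths and areas are incomplete.

**Summaries.** Per-cell: frequency = events / recording duration (15 min by
default), activity flag (≥ 1 event), and per-cell medians of the three
shape metrics (undefined for silent cells — silent cells contribute to
active fractions but not to shape comparisons). Per-mouse: percentage of
active cells.

## Chemotaxis quantification

**Ellipse fit.** Containment boundary points are fitted with the stable
direct least-squares conic fit (Halir–Flusser block decomposition of the
Fitzgibbon constraint 4AC − B² = 1), which returns an ellipse whenever one
exists and needs no iteration. Points are centred and scaled before solving
— without this, rotation invariance degrades to ~1e-6 relative; with it,
exact inputs are recovered to ~1e-12. Inputs may be synthetic boundary
points or boundary samples from any external segmentation; pixel-level
segmentation is out of scope.

**Containment time course.** Per frame, the mean diameter is
(major + minor)/2, with t = 0 at ATP application. Frames whose fit fails
are recorded as missing, never interpolated. The *final diameter* is the
mean over the terminal plateau — the longest terminal run in which each
successive diameter changes by < 5% of the current value per frame
(configurable); with no plateau (still shrinking at the end), the mean of
the last three frames is returned with a warning flag. The *formation
velocity* is the diameter reduction from t = 0 to plateau onset divided by
the elapsed minutes; a plateau at frame 0 gives 0.

**Tracks.** Only processes tracked over ≥ 7 consecutive timepoints are
included (non-uniform timepoint spacing rejects the track, with the reason
recorded). Mean velocity is the average Euclidean step length per frame
interval, in μm/min — "distance travelled", so back-and-forth motion
inflates it; this matches the standard manual-tracking definition and is
deliberate. Initial distance is from the first tracked point to the
pipette tip. Per mouse, chemotactic coordination is Spearman's rank
correlation (average ranks for ties) between initial distance and mean
velocity; with fewer than 3 usable tracks it is undefined and the mouse is
excluded rather than imputed.

## Statistics

Data are summarised as median ± IQR (linear-interpolated quartiles; 10/90
percentiles reported for whisker plots). Tukey fences (Q1 − 1.5·IQR,
Q3 + 1.5·IQR) flag outliers; removal is off by default and applied to
comparisons only when enabled in the run configuration. The one-sample KS
test against a normal with the sample's mean/SD is available as a normality
screen (estimating parameters from the sample makes it conservative; it is
a screen, not a verdict).

Age groups are compared with the Kruskal–Wallis test (tie-corrected H).
The omnibus p is exact — full enumeration of group assignments — for total
N ≤ 12, where the χ² approximation is seriously anticonservative (for three
fully separated groups of 3, χ² gives 0.027 against an exact 0.0036); the
χ² approximation is used for larger samples, where null simulations show
the 5% level is held to within ±2%. When the omnibus test is significant,
Dunn's pairwise z tests are run over all pairs with Bonferroni family-wise
adjustment (the "Dunn's multiple comparisons" convention of common GUI
statistics packages). Control-vs-CR comparisons use the two-sided
Mann–Whitney U test (exact for small tie-free samples, normal approximation
with tie/continuity correction otherwise). Age × sex interactions use
two-way ANOVA with interaction and Type II sums of squares (groups are
unbalanced; Type II equals Type I on balanced designs), with Bonferroni-
adjusted pairwise t comparisons (pooled residual MSE) within the factor of
interest at each level of the other.

The analysis level is explicit throughout: frequency, amplitude, T-half and
AUC are per-cell quantities; active fraction, Spearman r, formation
velocity and final diameter are per-mouse. The pipeline never mixes levels
in one comparison.

## Synthetic data: what it emulates, and what it does not

**Traces.** Transients are difference-of-exponentials kernels
(exp(−t/τ_d) − exp(−t/τ_r), peak-normalised) — the minimal sharp-rise /
slow-decay shape — with Poisson event times, amplitudes drawn from a
truncated normal, additive white Gaussian noise, and a constant vessel
background. Events superpose additively with no refractory period, so
overlap handling is exercised in the detector rather than hidden by the
generator. Ground truth carries each event's analytic amplitude, T-half
(kernel FWHM; → τ_d ln 2 as τ_r → 0) and AUC (amplitude × kernel integral;
→ A·τ_d).

Defaults: 15-min recordings at dt = 0.5 s (the sampling rate of such
recordings is rarely reported; 2 Hz is typical for resonant-averaged
microglia somata and is configurable), amplitude 20 ± 5 %ΔF/F, τ_d = 8 s,
τ_r = 0.8 s, noise 2 %ΔF/F (amplitude SNR 10). Event-shape and noise
defaults are order-of-magnitude choices: the source study reports these
quantities graphically, not numerically.

**Chemotaxis.** The pipette tip sits at the origin (2D, as tracks are
measured on maximum-intensity projections). The containment boundary is a
mildly eccentric ellipse (axis imbalance 10%, radial jitter 0.5 μm) whose
diameter shrinks linearly from 100 μm at 5 μm/min to a 30-μm plateau.
Tracked tips start at uniform distances in [20, 60] μm with random angles
and move radially inward at constant velocity v = β·d + ε (β = 0.05/min;
v clamped at ≥ 0; position clipped at the tip), so measured mean velocity
equals min(v, d/T) exactly and the distance–velocity coupling is controlled
by the noise SD of ε. The noise SD for a given Spearman target is set by a
pilot-sweep bisection against the same measurement the pipeline performs;
targets 0.75 / 0.82 / 0.55 / 0.9 reproduce the coordination profile
(young / middle / old / restored under CR).

**Cohort.** The default design mirrors the study's group sizes (11 young,
10 middle-aged, 14 old control mice; 7 CR3, 8 CR6, 10 CR18; mice alternate
male/female; 3–4 cells and 20 tracks per mouse). Event rates are
bell-shaped over age (0.10 / 0.40 / 0.12 events/min among non-silent cells,
CR groups restored toward the younger profile), and a per-group silent-cell
probability (0.25–0.40) puts per-mouse active fractions in the realistic
45–80% range — a homogeneous Poisson rate cannot produce both plausible
active fractions and plausible active-cell frequencies. Seeding is
hierarchical (master → group → mouse → cell/recording), so any subset
regenerates identically.

**Not emulated:** sex-specific effect sizes within groups (metadata carries
sex, but rates differ only by group), estrous/hormonal state, amplitude or
kinetics differences across groups (only rates and coupling differ),
colored noise, bleaching and drift, z-motion artifacts, and pixel-level
morphology. Passing the synthetic validation therefore establishes the
*correctness of the computations* under the stated generative assumptions —
not detector performance on recordings whose noise is structured, whose
baselines drift, or whose transients deviate from the two-exponential
shape.

## Numerical choices and degenerate inputs

- Detection with zero noise SD on a non-flat trace is an error directing
  the user to an explicit threshold (a zero denominator is never treated as
  "detect everything").
- Split ties (multiple equal minima) break to the earliest index.
- T-half for events truncated at a region edge uses the available bound.
- Quartiles everywhere use linear interpolation (the convention of the
  common GUI packages).
- Ellipse fits with < 5 points, collinear points, or non-elliptical conic
  solutions raise; containment frames that fail to fit become NaN.
- A mouse with < 3 usable tracks has undefined Spearman r (excluded with a
  warning); a two-way ANOVA cell with n < 2, or an empty design cell, is an
  error naming the cell; identical-everywhere values short-circuit the
  ANOVA to F = 0, p = 1.
- Pipelines log and skip failing traces, aborting only if > 50% fail; reruns
  with the same configuration and seed are byte-identical.

## Validation problem sizes

The shipped validation uses 200 recordings for detector recall/precision
(±2 s onset tolerance), 500 recordings for the activity law, 50 seeded
cohorts for the qualitative aging/CR pattern, 50 seeds × 8 mice for each
Spearman target, and 1000 null replications for test calibration — sizes
at which the binomial/Monte-Carlo error of each check is several times
smaller than the margin being asserted.

## Known limitations

- Recall of the event detector is bounded by the half-maximum rule itself:
  transient pairs closer than ~12 s (at τ_d = 8 s and 0.2 Hz filtering)
  merge into one event by definition. At 0.2 events/min this costs ~4% of
  events; at higher rates the bias grows and frequency estimates saturate.
- The velocity definition (path length per time) is upward-biased for
  meandering processes; it is kept because it is the field's standard and
  comparisons across groups share the bias.
- The KS normality screen with estimated parameters is conservative; it is
  not a substitute for a Lilliefors-corrected test and is not used to gate
  any downstream analysis automatically.
- The exact Kruskal–Wallis enumeration is limited to N ≤ 12 (1,680–34,650
  assignments); beyond that the χ² approximation is used.
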