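# Methods

This note documents the models, conventions and numerical choices behind
`flyca`, and what the synthetic-data validation does and does not show.

## Stimulus protocols

Protocols are ordered epoch lists with a trial structure and display
geometry. The flash builder produces `2·n_trials` alternating full-contrast
ON/OFF epochs (defaults: 5 s epochs, 7 trials — the standard full-field
flash design). The edge builder crosses {bright, dark} × 8 directions
(45° spacing) × repetitions (default 3) in a seeded random order with an
intermediate gray epoch before every edge; each edge epoch lasts exactly
`field_span / speed` (3.0 s at 20°/s on a 60° field), so epoch duration ×
speed = field span is an identity, not an approximation. The
randomization seed is stored on the protocol so analysis code can re-sync
epoch identity.

## Response model (synthetic data)

A cell's flash response is a calibrated two-term kernel

    r(t) = P · rise(t; τ_rise) + c · rise(t; τ_rise) · exp(−t / τ_transient)

with `rise(t; τ) = 1 − e^{−t/τ}`. The transient scale `c` is solved
numerically (fixed-point on a fine grid) so that the kernel's true maximum
is exactly `amp_transient` and its asymptote exactly `amp_plateau`; the
amplitudes are therefore by construction the quantities the step and
plateau metrics are defined to recover. Defaults τ_rise = 0.1 s,
τ_transient = 0.8 s give a transient that settles to the plateau within
2 s, matching the described response shape; the paper states no time
constants, so both are configuration. Flash responses are truncated at
epoch offset (offset kinetics idealized as instantaneous); OFF-polarity
cells respond to the complementary epochs.

Edge responses are transient-only kernels triggered when the edge front
crosses the cell's receptive-field center (the front travels the field
span along the motion axis over the epoch) and decay freely into the
following gray epoch, as indicator decay outlasts the stimulus. Tuned
cells scale edge responses by `max(0, cos(direction − preferred))`.

**Drug model.** Each cell carries receptor weights `(w_glu, w_gaba)`
summing to 1. A condition specifies blocked fractions of each pathway;
an `insensitive_*` flag (modelling the PTX-insensitive point mutants
GluClα^S278T and Rdl^MDRR) forces that pathway's effective block to zero,
so doubly-insensitive cells recover gain 1 under any block. The default
model is a scalar gain `g = w_glu(1−b_glu) + w_gaba(1−b_gaba)` on the whole
response. The optional split-component mode instead routes the fast
transient kernel through the glutamatergic gain and a slower-rising
(τ_plateau = 0.5 s) sustained kernel through the GABAergic gain. This is a
deliberately minimal, linear toy — not a biophysical claim — chosen as the
smallest model that reproduces the observed step-vs-plateau dissociation:
with the transient carried by GluClα, a PTX-insensitive GluClα restores
the step almost fully under full block, and a PTX-insensitive Rdl restores
the plateau, while the scalar model caps any single-pathway rescue at its
weight.

**Rendering.** Pixels are a uniform background plus
`f_baseline · (1 + ΔF/F)` on each cell disc, scaled by `photon_gain`
(expected counts per unit fluorescence), with Poisson shot noise in counts
and additive Gaussian read noise. Motion is a global integer-pixel random
walk (steps `round(N(0, sd))`) reflected at ±`motion_walk_max_px`
(default 8): in-vivo drift under a head-fixed preparation is bounded, and
the bound keeps the default search radius (10 px) well posed. Identical
config + seed reproduce movies bit for bit. Movies write as 16-bit
multi-page TIFF (rounded/clipped) with a JSON timestamp sidecar; ROI masks
as integer label TIFF. The default acquisition rate is 15 Hz, the top of
the typical 10–15 Hz two-photon band; being commensurate with the 10 Hz
analysis grid, it also avoids systematic peak clipping when sharp
transients are linearly interpolated. The trace-level simulator
(`simulate_trace_set`) adds white Gaussian noise in ΔF/F units directly to
per-ROI traces; it is the movie pipeline's noiseless-limit equivalent and
is used for population-scale experiments where rendering every movie would
add nothing but runtime.

Not modelled: optics (PSF, bleaching, z-drift), morphology beyond discs,
non-rigid or subpixel motion, correlated noise, neuropil contamination.
Passing recovery tests therefore demonstrates the correctness of the
analysis chain under its own assumptions, not robustness to every artifact
of real recordings.

## Registration

Alignment is rigid, translational and integer-pixel, matching the
simulator's motion model and admitting an exact oracle. Each frame's
central window (inset by the search radius) is matched against the
reference by normalized cross-correlation at every offset within the
radius (FFT-based template matching); ties break toward the smallest shift
norm, then row-major order. Zero-variance frames return (0, 0) with a
warning. The reference is the pixel-wise max projection of the first 30
frames; frames 2–30 are first rigidly pre-aligned to frame 1 so that
motion during the reference window neither smears the projection nor
introduces a constant shift bias (the estimates stay anchored to the first
frame's position). Correction translates by the negated estimate, filling
exposed borders with the frame median — neutral for max projections and
ROI means; interior pixels are moved, never altered.

## Traces and ΔF/F

ROI values are per-frame means over the label mask minus the mean of the
background region (default: everything outside the ROIs; an explicit
region can be given). Traces are linearly interpolated — shape-preserving
and exact on affine signals — onto a 10 Hz grid whose phase is locked to
each epoch onset, so the 500 ms metric windows always contain exactly 5
samples. Each epoch segment carries up to 2 s of pre-onset context where
recorded; epochs extending beyond the recording are dropped with a
warning. Interpolation and background subtraction commute (both linear),
so their order is immaterial.

Two F₀ conventions: for flashes, the mean of the ROI's full
background-subtracted native trace (computed before segmentation); for
edges, the mean of the last second of the gray epoch preceding each edge.
ROIs with non-positive F₀ are excluded with a warning rather than
producing unbounded ΔF/F. For ground-truth recovery on synthetic data,
`compute_dff` also accepts explicit per-ROI F₀ values: the whole-trace-mean
convention divides by `1 + mean(r)` and so compresses absolute ΔF/F of
strongly responding cells by design; the compression cancels in
within-experiment ratios but not in absolute amplitude recovery, which is
therefore checked against the known baseline.

Trial averages are pointwise means over trials of the same epoch kind
(flashes) or the same contrast × direction (edges), aligned at onset; the
first epoch of a recording has no pre-onset context, so pre-onset samples
average over the trials that reach them.

## ROI quality control

Three rules, combined by intersection (hence commuting, and monotone in
every threshold): positive Pearson correlation of the trial-averaged
ON+OFF cycle with a ±1 square-wave regressor (the minimal "the stimulus"
reference; zero-variance traces fail with a warning), a standard-deviation
ceiling (default 0.2 ΔF/F) over the 2 s pre-stimulus window to discard
noisy ROIs, and a peak-|ΔF/F| floor (default 0.5) to keep well-responding
ROIs. Four named presets encode the experiment types: `mi1_pharma` (all
three rules, paired), `unpaired` (no response floor), `t4t5` (no
correlation filter — both polarities expected), `iglusnfr` (response floor
only). Dropping the response floor when a condition shows full response
loss is an explicit policy choice, never automatic. In paired pharmacology,
filters run on the pre-drug data only; the surviving ROI ids are carried
unchanged to the post-drug condition.

## Metrics and summaries

Step, plateau and integral are defined on the trial-averaged 10 Hz
segments as in the README; the integral is reported in ΔF/F·samples
(50 samples per 5 s epoch) with a per-second variant available. Negative
steps are meaningful (suppression). Population edge traces can be averaged
after circularly shifting each trace's peak to the median peak index.
Direction tuning requires the 8-direction design; PD ties break toward the
smallest angle, and a non-positive PD response flags the DSI as undefined.
Edge amplitudes are computed per ROI before any peak alignment. Fly-level
summaries average ROIs within each fly first (equal-fly weighting), then
report mean ± SEM across flies; SEM is undefined for a single fly.
Condition normalization divides post-drug per-fly metrics by the pre-drug
group mean of the same genotype (the denominator choice is not dictated by
the source figures; the group mean is used and documented). The oocyte
helper normalizes the peak current under agonist + antagonist to the mean
peak after antagonist wash-out.

## Statistics

Unpaired t tests default to the classical pooled-variance Student form (a
Welch flag exists). Holm's adjustment is implemented by its definition
(sort, scale by remaining comparisons, running maximum, cap at 1) and is
cross-checked against statsmodels in the tests. The two-way ANOVA uses
Type II sums of squares via an OLS fit — the standard choice when the
interaction is not the primary question — including the interaction
whenever every cell is populated (dropped with a warning otherwise, and
reported either way). Tukey–Kramer comparisons on the A × B cell means use
the studentized-range distribution with the unequal-n standard error; for
two cells the q statistic reduces to |t|·√2. The Lilliefors test computes
the KS distance from the standardized sample to the standard normal and
draws its p value from a seeded Monte-Carlo null (default 10,000
replicates) rather than table interpolation — exact at any n and
reproducible; a critical-value helper supports screening many datasets
under a shared null. Its null rejection rate calibrates to α; power
against light-tailed alternatives such as the uniform is inherently
moderate (~0.64 at n = 100), which matches statsmodels' table-based
implementation.

## qPCR

Technical replicates are averaged per (condition, gene, biological
replicate). The percent transcript difference uses the printed base-2
formula per disrupted replicate against the mean control ΔCt, then
mean ± SEM over biological replicates; normalization to the control-group
mean maps controls to 100%. The efficiency-corrected mode
(`E_target`, `E_reference`, Pfaffl-style) reproduces base-2 exactly at
E = 2; the shipped default efficiencies (1.91 target, 1.96 reference) are
the measured primer values for the GluClα/GAPDH2 pair. A standard-curve
helper estimates E = 10^(−1/slope) from dilution series.

## Validation experiment sizes

The `flyca.validation` experiments use problem sizes chosen to keep the
whole harness under a minute on one CPU while leaving the statistical
checks well powered: a 600-frame 64×64 registration movie (walk sd 1 px,
photon gain 100, six aperiodically placed cells — a periodic mosaic would
alias under translation); a noiseless 48×48 movie for metric recovery with
the integral checked against adaptive quadrature of the ideal kernel;
8 flies × 30 ROIs × 4 conditions for the rescue pattern (trace-level
simulation, split-component drug model, weights (0.6, 0.4), amplitude
scale 1.5); 50 ROIs for the QC population; 8 tuned + 50 isotropic cells
for direction selectivity; 10,000 Monte-Carlo datasets for the Lilliefors
calibration and 2,000 null simulations for the ANOVA→Holm chain's type-I
error; 15 Hz acquisition for the retinotopic timing check so frame
quantization stays well inside the ±0.1 s tolerance.

## Known limitations

Integer-pixel registration cannot represent subpixel or non-rigid motion;
the whole-trace-mean F₀ convention biases absolute ΔF/F amplitudes
multiplicatively (documented above); the drug model is linear and
phenomenological; the background estimator is a region mean; ROI
segmentation is out of scope (masks are inputs, as in manual ROI
selection).
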