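# Methods

This note records the models, parameter choices, and numerical decisions
behind each pipeline, and what the synthetic benchmarks do and do not
demonstrate.

## Puncta quantification

Images are background-corrected with the rolling-ball algorithm
(`skimage.restoration.rolling_ball`, radius 50 px by default). For radii
above 16 px the background is estimated on a proportionally downscaled copy
and resized back — the background is smooth by construction, and this keeps
the cost independent of radius; the estimate is clipped from above by the
image so the subtraction never goes negative. A grayscale opening with a
disk gives an independent cross-check in the tests.

Thresholding happens inside the cell mask only. The default is Otsu on the
in-mask histogram (reproducible and parameter-free), overridable by a fixed
intensity or a quantile (`"q0.99"`). Otsu assumes a reasonably bimodal
histogram; on sparse images (few puncta over many background pixels) it can
drift into the noise, so comparative experiments in `studies` use one fixed
threshold shared by all groups — half the nominal spot peak — which is how
thresholded group comparisons should be run anyway. Connected components use
8-connectivity, and components outside 0.2–1.0 µm² are discarded. Density is
count divided by the mask area of the same zone; the perisomatic zone is the
closed disk of diameter 30 µm around the soma center, neurite the 30–100 µm
annulus, with boundary ties assigned inward. Both radii are configurable
because "within a diameter of 30 µm" could also be read as a radius.

## Distribution index

`DI = mean(|I/Ī − 1|)` over a 15 µm dendritic line profile sampled at
1-pixel steps with bilinear interpolation (line width 1 px). The deviation
is taken around the normalized mean — the literal reading of "mean absolute
deviation"; a median-centered variant sits behind `center="median"` since
MAD is ambiguous in common usage. DI is 0 iff the profile is constant,
invariant under intensity rescaling, and bounded by 2(1 − 1/N). Profiles
should start ≥10 µm from the soma; this is validated as a warning, not
enforced geometry. An all-zero profile is an error (normalization
undefined).

## MEA metrics

Spike detection band-passes at 200–3000 Hz (Butterworth order 3, applied
forward-backward for zero phase) and thresholds at 6× a robust SD
(median absolute deviation × 1.4826) — a plain SD is inflated by the spikes
themselves. Both polarities trigger by default. The dead time is 3 ms: the
~1 ms biphasic waveform spans ~3 ms after zero-phase filtering, and a new
spike is only accepted after the trace has stayed sub-threshold for a full
dead time (re-arming), so filter ringing is never double-counted even in
the noiseless limit. Spike times are the filtered-trace extremum within the
dead-time window.

Bursts are maximal runs of ≥5 spikes with every ISI strictly below 100 ms
(an ISI of exactly 100 ms breaks the run). Network bursts pool all
electrodes (simultaneous spikes ordered by electrode id for determinism),
apply the same run rule with ≥50 spikes, and require ≥35% electrode
participation. The participation denominator is the well's electrode count —
this is what makes 6/16 = 0.375 pass and 5/16 fail — with an
active-electrode denominator available as an option.

The synchrony index forms, for every unordered electrode pair, the
histogram of spike-time differences within ±0.5 s at 1 ms bins, normalizes
each pair's histogram to unit mass, averages across pairs, and sums the
mass within ±20 ms. It is 1.0 for coincident trains, and window/max_lag
(0.04) in the independent-Poisson limit. The vendor's exact normalization
is not public; unit mass per pair is this package's documented stand-in and
gives a dimensionless index in [0, 1].

Wells are included when *more than* 12 electrodes are active (strict), an
electrode being active at ≥5 spikes/min. Group normalization divides every
well by the control-group mean of the same batch.

## Calcium pipeline

ΔF/F uses F₀ = the 10th percentile of the whole trace. Event detection
lightly smooths the trace (0.15 s moving average) and takes local maxima
above median + 4×MAD (MAD unscaled, matching the vendor parameter name; a
Gaussian-consistency factor is available via `mad_scale`). Three shape
filters separate transients from noise and from spurious maxima riding an
earlier transient's decay:

1. the candidate must rise 4×MAD above the minimum since the previous
   candidate (bounded at 1 s back) — decay-shoulder bumps fail this;
2. the smoothed trace must stay above the 1/e level, relative to the local
   pre-event baseline (median of the preceding 0.5 s), for ≥0.20 s;
3. the raw trace's mean over the 0.25 s after the peak must hold ≥50% of
   the peak height above baseline — single-frame noise spikes fail this.

Surviving events closer than 0.20 s are merged keeping the larger peak.
A bare maxima-plus-1/e-crossing detector mis-handled both tails (spurious
shoulder peaks; true events rejected when one noisy sample dipped below the
1/e level), which is why the filters are formulated on robust quantities
(window means and medians rather than single samples). At the benchmark
conditions (20 frames/s, τ = 0.5 s, amplitude 10× noise MAD) net detection
bias is −1 to −3%, dominated by genuinely unresolvable event pairs closer
than the 0.20 s merge distance; the false-positive rate on pure noise at
MAD 4 is ≈0.004 Hz. No threshold makes it exactly zero: a median+3·MAD
cut sits near 2σ, where noise excursions are routine, so claims of
literally zero detections on noise hold only per-trace, not as a rate.

Movement epochs are maximal intervals with speed > 10 cm/s sustained ≥ 1 s;
stationary epochs are the complement under the same persistence rule, and
shorter intervals stay unassigned. Speed comes from centrally differenced
positions after a 0.25 s centered moving average (tracker-jitter
suppression); the behavioral track keeps its own timebase (25 Hz default)
independent of the 20 Hz imaging. State rates divide events inside a
state's epochs by the summed time in that state. The source text defines
"stationarity" with "velocity >10 cm/s", which contradicts itself; the
physically sensible reading (movement = fast) is implemented, and the
movement/stationary ratio would simply invert under the other reading.

## Synthetic data

The generators define the benchmark conditions:

* **Spike wells** — homogeneous Poisson background per electrode with
  exactly specified injected bursts (arithmetic spike sequences) and
  network bursts (round-robin over participating electrodes). Background
  spikes within 2 ms of an injected spike are dropped so injected bursts
  stay verbatim; overlapping injections on one electrode are an error.
  Random burst injection for group studies thins a Poisson process so
  consecutive bursts stay >120 ms apart (never merged), a ~2% rate loss at
  0.1 bursts/s.
* **Raw traces** — white noise plus a one-cycle biphasic sine (1 ms,
  negative first) at each spike time, 12.5 kHz.
* **Calcium sessions** — instant-rise, exponential-decay transients
  (defaults: τ 0.5 s, amplitude 0.2 ΔF/F = 10× the noise MAD at
  noise_sd 0.03) at Poisson times, homogeneous or per-state when an epoch
  plan is given; raw fluorescence F = F₀(1 + ΔF/F). The position track
  integrates the epoch plan's speeds with 2% jitter; only the heading
  meanders (steered back toward the arena center near walls), so the
  finite-difference speed reproduces the plan and epoch boundaries are
  recoverable to ~2 track frames (session edges carry a ~0.5 s smoothing
  artifact).
* **Images** — isotropic 2-D Gaussian spots on a soma + dendrite mask over
  a sloped, noisy background; "area" is the footprint above half maximum,
  so σ = √(area_px / (2π ln 2)). Random placement uses minimum-separation
  rejection sampling (3.5× the largest spot σ) so recovery is limited by
  the pipeline rather than by overlapping spots; an interior-only mode
  additionally keeps footprints clear of the mask edge for area-accuracy
  checks. Requested areas below 4 px² are rejected as unresolvable.
* **Line profiles** — clustered mode is baseline plus Gaussian bumps;
  diffuse mode is a constant matched to the clustered mean, plus noise.

What passing these benchmarks does **not** show: the generators contain no
photon statistics, out-of-focus light, bleaching, motion artifacts,
electrode drift, spike-waveform variability, or neuropil contamination, and
calcium event times are Poisson rather than burst-structured. Recovery here
demonstrates the correctness of the quantification chain, not robustness to
every failure mode of real recordings.

## Group statistics

`compare_groups` defaults to the unpaired two-tailed pooled-variance
Student's t (Welch and Wilcoxon rank-sum by tag), reports means ± SEM, a
D'Agostino–Pearson normality p per group (NaN below n = 8), and the percent
change relative to the first (control) group. Two constant equal groups are
flagged degenerate with p = 1 by convention. No multiple-testing correction
is applied by default; a Bonferroni helper exists for per-bin panels.

## Benchmark problem sizes

The simulation studies run at: 160 cells × 300 s per calcium condition in
the acceptance script (60 in the test suite), 100 cells for state-resolved
sessions (60 in tests), 20 images per puncta group, and 40 wells × 600 s
per MEA genotype. Detection is scored against each session's realized
ground truth; at these sizes the realized Poisson rate itself sits about
one SEM from the programmed value, so the realized rate is the recoverable
quantity, while the recovered values are reported against the programmed
(printed) effect sizes.
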