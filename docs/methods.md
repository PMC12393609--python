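# Methods

This note documents the models, conventions, and numerical choices behind
each stage, what the synthetic generators emulate (and do not), and the
known limitations.

## Coordinate, unit and sign conventions

- Reference space: 1 × 1 × 2 µm voxels on a 500 × 1000 × 200-voxel grid
  (500 × 1000 × 400 µm). Voxel indices are 0-based; a point in µm maps to
  the voxel containing it (floor of position / voxel size).
- Tail angles are degrees. The head points toward −x, image y grows
  downward, and a positive angle means deflection toward the animal's
  right. Nothing in the raw data fixes this sign; mirroring the skeleton's
  y-coordinates negates every angle and swaps left/right flip labels,
  which the tests assert.
- 1-Hz resampling bins are [t, t + 1) s aligned to the first frame.

## Free-swimming behavior

Wells are found on a background image (max projection of the first and
last minute) by Gaussian smoothing and Otsu's threshold with a 1.2
multiplier; exactly the configured well count must emerge or the stage
fails loudly. Larvae are visible only as a dark eye cluster; a pixel
qualifies when it is ≥ 10 grey levels darker than the well's per-frame
median, and the darkest morphologically-cleaned blob wins. Missing frames
are filled from the nearest valid frame (no interpolation — interpolating
would invent motion); > 20% missing flags the trajectory.

Metric conventions the source analysis leaves open, fixed here and
config-exposed:

- **Bout**: inter-frame speed > 2 mm/s for ≥ 3 consecutive analysis
  frames, closed by ≥ 100 ms below threshold. Bout amplitude is the net
  displacement over the bout; % active duration is the fraction of frames
  inside bouts (this also operationalizes "active swimming", which has no
  stated speed threshold); the inter-bout interval is offset→onset.
- **Exploration grid**: 1.75-mm square bins (20 × 20 in a 35-mm well).
- **Analysis rate**: tracking metrics assume ~40 Hz input; higher-rate
  video should be decimated first (raw ~240 fps is noise-dominated at
  0.14 mm/px).
- Outlier exclusion uses |v − median| > 3 × 1.4826·MAD with a strict
  inequality, so an all-equal cohort excludes nothing while a
  majority-identical cohort still rejects a discrepant value.

## Tail kinematics

Skeleton points are ordered base→tip by greedy nearest-neighbour from the
leftmost point and split into 8 segments *by point count*; the first
(n mod 8) segments absorb the remainder (17 points → 3,2,2,2,2,2,2,2).
Per segment a cubic is fitted along the dominant axis, a line is fitted to
the evaluated cubic, and its angle to the x-axis is reported. The single
per-frame angle is the slope angle of the line from the user-fixed base
point to the mean position of segments 4–7.

Baseline removal uses a centred 60-s windowed **median** (the statistic is
our choice; events occupy far less than half of any window, so the median
ignores them). For frame rates above 20 Hz the median is evaluated on a
decimated copy and linearly interpolated back — the baseline is
band-limited well below that, so only runtime changes. Two caveats are
inherent to any centred robust estimator and are reflected in the tests:
the first/last half-window is biased, and a second pass is only
approximately a no-op (idempotence holds to ~2% of amplitude in the
interior, not to machine precision).

Max-resampling to 1 Hz: per bin, samples with |angle| above the within-bin
90th percentile (linear-interpolation quantile) are dropped as tracking
outliers, then the largest remaining |angle| is reported with its sign.
A bin never empties itself; single-sample bins pass through. Plain
interpolation is deliberately avoided: tail beats last tens of
milliseconds and interpolation collapses their amplitude.

## Tail events

The noise floor NF is the RMS of the whole baseline-corrected trace,
computed once per recording. Detection finds peaks of |angle| > 3×NF with
prominence > NF; an event spans from the last pre-peak crossing of 1×NF to
the first post-peak crossing, truncated at the midpoint between adjacent
peaks so events never overlap. Events separated by < 2 s merge
transitively. Classification order: struggle (both extremes beyond 10×NF
— about 45° at a typical ~4.5° noise floor), then flip (the supra-3×NF
angle sum on one side > 20× the other; a purely one-sided event has an
infinite ratio and is a flip), else swim. The classes are exhaustive and
mutually exclusive, and all thresholds scale with the trace, so amplitude
units cancel.

## Calcium processing

Curation drops footprints outside 4–400 px, with compactness (area over
circumscribing-circle area) below 0.15, or with peak-over-MAD activity SNR
below 5; pairs merge when centroids are within 8 µm, traces correlate at
r > 0.9, and footprints touch (8-adjacency), with footprint-weighted mean
traces. Relaxing the SNR threshold never removes a previously kept neuron.

Each trace is min-max normalized to [0, 1]; the baseline is a
morphological-opening-style estimate over a centred 120-s window: a
running 8th percentile (sits below transients) followed by a running 92nd
percentile of that series, which cancels the half-window lag a single
percentile pass leaves on a moving drift. Cumulative ΔF/F is the time-sum
per neuron, z-scored across the larva's neuron population with the
population (n) denominator; the z-reference is per-larva (a pooled mode is
available by config).

### Constrained AR1 deconvolution

Model: c_t = γ·c_{t−1} + s_t, s_t ≥ 0, y = c + ε with white ε of sd σ.
γ is estimated per neuron from the autocovariance ratio acov(2)/acov(1)
(noise-free under the model), clipped to [0.5, 0.99]; σ from scaled-MAD
first differences. The L1-penalized problem is solved exactly by an online
pool-adjacent-violators sweep (pools carry value, weight, start, length;
a violation of s ≥ 0 at a boundary merges pools); the solver matches a
direct NNLS solve of the same program to machine precision. The
noise-constrained solution takes the largest sparsity weight whose
residual sum of squares stays within σ²T, found by doubling then
bisection (relative tolerance 2%); failure to bracket flags the record
rather than returning silent zeros. On a noiseless AR1 trace the
unpenalized solve returns the generating spikes exactly.

Spike peaks are local maxima of the deconvolved amplitude sequence above a
dust threshold of k·σ (k = 1.5 by default, config-exposed). A threshold on
the MAD of the nonzero amplitudes was considered and rejected: it removes
genuine spikes when amplitudes are homogeneous and sits inside the dust
when dust dominates. The noise-scaled rule is exactly zero for noiseless
input and, in generator-model simulations at SNR 5 (unit spikes, σ = 0.2,
0.05 Hz, 1445 s), leaves a mean rate bias of about −5%, dominated by
genuinely unresolvable same-/adjacent-frame spike pairs at 1 Hz sampling.
Firing rate is the peak count divided by the recording duration (1445 s
for a standard session).

## Atlas mapping

A neuron's cube is its (z-offset by +5 µm, half the volumetric z step)
centroid voxel ± 2 in x, y and ± 1 in z — exactly 5 × 5 × 3 = 75 voxels —
with out-of-volume voxels dropped (a face centroid keeps 50). Assignment
to a mask requires ≥ 10 overlapping voxels; masks may overlap, so
assignment is many-to-many. Assignments equal a brute-force per-voxel
membership scan on toy atlases (tested). Regions get a
fore/mid/hindbrain label when > 50% of their volume lies in one division.

Ablation quantification thresholds 0–1-normalized stacks at 0.2 and
counts suprathreshold voxels per composite mask and larva; the threshold
is searched over 0.1–0.5 in 0.05 steps for the value minimizing 3-scaled-
MAD outlier counts across larvae (ties resolve toward 0.2 — the exact
iterative schedule is unspecified upstream, so this loop is a declared,
overridable convention). Loss = 100·(a − b)/a on group means.

## Group comparison

Heatmaps live on a ceil(extent/12)-shaped 12-µm grid (voxel index =
floor(position/12) after the same z offset as mask assignment). Count and
ΔF/F layers treat absent neurons as zero; rate voxels with no neurons are
missing, not zero, and a rate voxel is tested only with ≥ 2 values per
group. Per-voxel comparison is a two-sided Wilcoxon rank-sum at α = 0.05
with no multiple-testing correction (deliberately matching the upstream
convention; an FDR mode exists but is off by default); the rank-sum is
exact for group sizes ≤ 10 without ties, tie-corrected normal otherwise,
and is validated against full enumeration. The permutation test enumerates
all label splits when ≤ 20000 exist (3-vs-3 is fully exhaustive) and
otherwise uses seeded sampling with p ≥ 1/(n_perm + 1); region tests
report the larger of the two p-values. Mask-level Relevance is the sum of
|summed significant-voxel differences| over three metrics × two
directions; it is invariant to component sign flips.

## Motor clustering

Neuron rows are z-scored over time then rescaled to [0, 1]; the |tail
angle| row (min-max normalized) is appended last. One average-linkage tree
is built on 1 − Spearman ρ (average ranks for ties). The tree is cut at
t = 3, 4, … clusters; the tail-containing cluster's size is compared with
the *previous* cut (both the +1 increment and the previous-vs-initial
reference are config-exposed; the source procedure states neither), and
the first > 20% drop stops iteration, returning the previous assignment.
With fully i.i.d. non-motor rows the top of the tree is degenerate (all
average distances ≈ 1) and unrelated rows can ride in the tail cluster;
with structured non-motor populations — the realistic case — the rule
isolates tail-locked neurons exactly, which is how the oracle test is
constructed. Connectivity between regions is the percentage of
cross-region neuron pairs (within-region pairs excluded) with Spearman
ρ > 0.8; it is symmetric by construction.

## Synthetic data: what it emulates, and what it does not

- **Calcium cohorts** invert the inference model: Bernoulli spikes
  (0.05 Hz; amplitudes U(0.8, 1.2)), AR1 calcium (γ = 0.9, matching
  nuclear GCaMP6s at 1 Hz), sinusoidal drift (amplitude 0.1, period 800 s
  — slow enough for a 2-minute baseline window, consistent with
  bleaching/z-creep over a 24-minute session), and white noise of sd
  1/SNR (SNR 5 default). Cohort sizes default to the recorded study's
  11 control vs 9 deficient; planted effects are +30% active neurons and
  −25% event rate in affected regions of the deficient group, mirroring
  the reported effect-size scale. Per-region active counts are Poisson.
- **Tail traces**: swims are enveloped 15–25-Hz oscillations, flips
  one-sided humps, struggles large square-ish oscillations; amplitudes
  are set in multiples of the nominal noise sd so each classifier
  threshold can be straddled deliberately. Measurement noise is low-pass
  (~15 Hz) Gaussian jitter clipped at ±2.5 sd — tail-angle noise
  originates in pixel-level skeleton jitter, which is smooth and bounded,
  not heavy-tailed. The standard recovery condition plants 30 events per
  24-minute 200-Hz trace at ≥ 4× the realized noise floor with ≥ 3-s
  spacing.
- **Toy atlas**: 10 disjoint y-slab regions on a 120 × 240 × 60-voxel
  grid (1 × 1 × 2 µm semantics) with deterministic neurotransmitter-class
  submask fills (30/40/20%), small enough to brute-force and still
  exercising the 75-voxel cube and 12-µm downsampling. Full-scale grids
  are supported.
- **Rendered movies**: a Gaussian eye blob of configurable contrast on a
  noisy bright background with dark walls.

Not emulated: optics (PSF, scattering), motion artifacts, neuropil
contamination, correlated network activity beyond the planted structure,
photorealistic larvae. Passing tests therefore demonstrate correctness of
the *analysis chain* under its own model assumptions, not robustness to
every pathology of real recordings.

## Problem sizes used in automated checks

Event recovery runs 50 seeded 24-minute 200-Hz traces; deconvolution
checks use 100 neurons at 1445 samples; the two-group power check runs
100 replicate cohorts of 10 + 10 larvae with 400 neurons over 200-s
traces (counts and planted-truth spike rates do not depend on trace
length, so short traces keep the replicate loop at desk scale — the
acceptance script uses 30 replicates and 12 traces for the same
quantities); the demo pipeline uses 3 + 3 larvae, 60 neurons, 300 s.
These sizes are the package's own choices for routine verification; all
generators accept full-scale parameters.

## Known limitations

- The 1-Hz deconvolution cannot separate spikes landing in the same or
  adjacent frames; rate estimates carry a small negative bias.
- The greedy skeleton ordering assumes a non-self-crossing tail; extreme
  curls could mis-order points.
- The clustering stop rule depends on tree shape near the root and is
  only meaningful when non-motor activity has structure.
- Heatmap shape uses ceil(extent/12) per axis; other published shapes for
  the same extent imply an undocumented crop and are not forced.
- Registration is consumed, not computed: all coordinates and masks must
  already live in the reference space.
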