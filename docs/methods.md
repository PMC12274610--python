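# Methods

## Scope and data model

`phasedecode` analyzes epoched multi-subject EEG organized as
subject × stimulus × repetition × electrode × sample, with time measured in
seconds relative to stimulus onset (onset = 0, sample s at
`epoch_start + s / sampling_rate`). Inputs are assumed to be clean epochs:
filtering, artifact removal and bad-channel interpolation are out of scope.
Missing trials are tracked with an explicit mask and never dropped silently;
operations that need complete trial pools (grouping, coherence) raise
instead. The on-disk container is one `data.npy` plus a versioned JSON
sidecar; any 1.x schema loads. MNE `Epochs` objects can be mapped into the
container (`phasedecode.io_mne`) as an optional import path.

## Time–frequency decomposition

Phases come from a sliding-window convolution with a Hanning-tapered complex
exponential of fixed length `cycles / f` seconds (default 3 cycles). The
window is symmetric, odd-length in samples and normalized to unit sum; the
phase convention is anchored to absolute time, so a pure cosine
`cos(2πfτ + φ₀)` yields θ(t) = 2πft + φ₀. Grids:

| grid      | frequencies               | time centers            | use |
|-----------|---------------------------|-------------------------|-----|
| spectrum  | 1–45 Hz, 0.8 Hz (56 bins) | 1.4–59.6 s, 0.2 s (292) | dissimilarity spectra |
| classify  | 1–8 Hz, 0.5 Hz (15 bins)  | 1.4–59.6 s, 0.2 s (292) | templates/decoding |
| lag       | 1–8 Hz, 1 Hz (8 bins)     | 1.4–59.6 s, 0.05 s (1165) | lagged correlation |

The stated ranges ("1.4 s to 60 s") admit several uniform spacings; these
are the only ones consistent with the printed bin counts (56, 292, 1165, 15),
with last time center 59.6 s. The analysis start of 1.4 s skips the
event-related transient after onset. On shorter epochs `fit_window` trims
the time grid so the widest (lowest-frequency) taper still fits, with a
warning. Coefficients with amplitude below 1e−12 × the trial RMS get an
undefined (NaN) phase rather than an arbitrary angle; undefined bins
propagate explicitly (scalar `cphase` raises; template similarity excludes
them from its average).

## Coherence, dissimilarity and cluster inference

Cross-subject phase coherence is the resultant length of the unit phasors of
the N trials in a group; under uniform phases its expectation is √(π/4N)
(the Monte-Carlo suite checks this for N = 10, 51, 200). The dissimilarity
spectrum contrasts, per electrode × frequency bin, the time-averaged
within-group coherence with the mean over surrogate across-group partitions
of the same trial pool (default 1000 partitions; the per-partition values
form the null). Per-bin z-scores feed a one-tailed cluster-based permutation
test: bins are thresholded at the per-bin null (1−α) quantile, adjacent
suprathreshold bins form clusters (Delaunay triangulation of the 2-D
electrode layout × chain adjacency over frequency bins), cluster mass is the
sum of the statistic, and masses are compared against the null distribution
of the per-surrogate maximum mass; clusters with p < α (default 0.025) are
significant. The neighborhood structure and the mass statistic are package
choices where the procedure is otherwise standard — quantile thresholding
rather than a fixed z cut keeps the cluster-forming step calibrated at any
surrogate count.

Electrode selection averages dissimilarity over the significant 1–8 Hz band
and returns the top-n labels (descending, ties broken by label order).

## Lagged phase correlation

Wrapped angles do not admit Pearson correlation, so each trial is reduced to
the cosine of its electrode-averaged, band-collapsed resultant phase — a
real, bounded trajectory. The cosine representation is a package choice; the
resultant magnitudes are deliberately discarded so only phase information is
correlated. Correlations use only the overlapping samples at each lag
(±1.5 s on the lag grid's 0.05 s step); absolute values are averaged over
all unordered within-stimulus pairs and stimuli. The null shuffles the
trial→stimulus assignment (default 100 shuffles); since trajectories are
per-trial, the implementation computes the all-pairs lag-correlation matrix
once and re-selects within-group pairs per shuffle, which is mathematically
identical to recomputing the pipeline per shuffle and makes the calibration
suites affordable. Significance uses the same cluster machinery along the
lag axis (chain adjacency, α = 0.01), run per band. Constant trajectories
yield undefined correlations; such pairs are skipped and counted.

## Nearest-template decoding

The similarity between a test trial and a template at one bin is the
two-element phasor resultant |cos((θ₁−θ₂)/2)|, averaged over time,
electrodes and frequency. Averaged (subject-independent) templates are
circular means — the angle of the mean unit phasor across the selected
trials — with the resultant length stored but not used as a weight, so a
single-trial template reduces exactly to the two-trial formula. Ties in the
argmax resolve to the lowest class index for determinism. The
subject-specific harness redraws one template trial per class 200 times and
averages accuracy; the electrode set is fixed once per dataset (from the
dissimilarity selector), not per draw. The subject-independent harness tests
all of the held-out subject's trials against templates from the remaining
subjects. Template-count sweeps draw template trials uniformly without
replacement over the (subject, repetition) pool, which covers counts not
divisible by the repetition count (e.g. 1).

Chance levels are computed by direct summation of the binomial PMF — the
smallest success count whose CDF reaches the threshold p (default 0.99),
scaled to percent — and are recomputed for every test-trial count so
duration and template sweeps stay calibrated. Cohen's kappa uses this
binomial chance level as the expected agreement, which is the convention
that reproduces the package's reference conversions; it is reported rounded
to two decimals.

## Correlation features and the two alternative decoders

Cosine and sine phase components are electrode-averaged per trial, then
averaged across training subjects per (stimulus, repetition, component) —
K·R·2 templates (132 at study scale) with the frequency axis retained.
Features are Pearson correlations in the time domain between a trial's
component series and every template, averaged over frequency, repetition and
component: one value per stimulus and window. Windows are the full grid plus
its first and second halves (midpoint bin assigned to the first half),
giving 3K features (66). Correlations against constant series contribute 0
and are counted via the module logger.

The linear decoder is a one-vs-all L2 logistic regression; the inverse
regularization strength is chosen by stratified 5-fold cross-validation on
training subjects only (grid 0.01–100). No kernel method is implemented —
the regularization search is read as an L2 strength grid only.

The network is implemented in numpy (it is tiny): two dense layers of 44
units, each followed by batch normalization, ELU (α = 1.0) and dropout 0.2,
then a 22-unit softmax head; training is momentum SGD (momentum 0.9 — a
conventional default, as no value is standard-cited — learning rate 0.01,
batch 64, 50 epochs), with validation every 50 mini-batches and early
stopping after 15 non-improving validation steps, restoring the
best-validation weights. Training data is augmented by treating each
electrode's signal as an independent sample (features then use
single-electrode components; test trials use the standard electrode-averaged
features); provenance is kept so validation folds always split by subject —
never by electrode — preventing leakage. The 8-fold subject scheme sizes a
single seeded validation fold (≈ 1/8 of training subjects, at least one)
used for early stopping; training eight networks per held-out subject would
multiply compute without changing what the fold is for.

## Synthetic study conditions

The generator emulates the structure the method assumes: per stimulus, a
fixed latent drive of 3 sinusoids with frequencies uniform in the entrained
band (default 1–8 Hz) and fixed phases, shared by all subjects; per trial, a
common von Mises phase offset per component (concentration κ) on the first
`n_entrained_electrodes` (frontal-style labels, so selection tests have
ground truth); background is 1/f-shaped Gaussian noise (exponent 1.0) with a
10 % white-noise admixture, fresh per trial and electrode, unit RMS. The
drive is active only after stimulus onset and scaled to `entrainment_snr`
times the background RMS. The null generator resamples the drive per trial
with uniform offsets, leaving no stimulus-locked structure at identical
marginal power. Everything is reproducible from the config seed; data are
stored float32 (analyses compute in float64).

Presets: `paper_config` mirrors the study design (17 subjects × 22
stimuli × 3 repetitions × 59 electrodes, 200 Hz, epochs −3…61 s, 20
entrained electrodes); `small_config` (6 × 8 × 3 × 16, 100 Hz, −1…31 s, 6
entrained) carries the recovery suites; `tiny_config` (3 × 4 × 2 × 8,
−0.5…10.5 s) carries the 200-repetition calibration loops.

Condition defaults κ = 4.0 and snr = 0.1 were calibrated once, over a small
grid, against the phenomenology the generator is meant to emulate: because
the fixed-cycles taper's bandwidth grows with frequency, a too-strong drive
leaks detectably into bins up to ~3× its top frequency, whereas real
speech-tracking entrainment is weak; at these defaults significance is
confined below ~15 Hz, the electrode selector recovers the entrained set
exactly, and the subject-independent > subject-specific > chance ordering
holds with clear margins. The defaults were frozen before the acceptance
thresholds and are not tuned per test.

What the generator does **not** emulate: real speech-envelope acoustics (the
drive is abstract), inter-subject latency/topography differences, artifacts,
non-stationary noise, or volume-conduction correlations between electrodes.
Passing recovery tests therefore shows the chain is correct and calibrated
under its own assumptions, not that real-data accuracies are reproduced.

## Problem sizes and numerical choices

The test and calibration suites run the small and tiny presets with reduced
surrogate counts (≥ 100, the cluster test's precondition; API defaults keep
the study-scale 1000/100/200), chosen so the whole suite runs in minutes on
one CPU; the statistical assertions (binomial CIs, calibration bounds) are
sized to those counts. Tie-breaks are deterministic everywhere (lowest
index / label order). Degenerate inputs — zero signals, antipodal phasor
cancellations, constant trajectories — map to explicit NaN/undefined states
rather than arbitrary values, and each analysis documents how it treats
them.

## Known limitations

- The subject-independent decoder assumes stimulus-locked phase is shared
  across subjects up to jitter; systematic per-subject latency shifts would
  need alignment the package does not provide.
- Cluster-based inference controls family-wise error at the cluster level;
  the extent of a significant cluster (which exact bins/electrodes) is not
  an exact-coverage statement, and isolated neighbor bins can join a strong
  cluster.
- The lag-correlation surrogate keeps trajectories fixed and shuffles
  assignments; it does not test against phase-randomized surrogates.
- At full study scale the all-pairs lag-correlation matrix is large
  (~0.6 GB per band for 1,122 trials); per-group computation would be the
  memory-lean alternative.
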