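# phasedecode

Cross-subject EEG phase-entrainment analysis and single-trial speech-stimulus
decoding.

When different listeners hear the same naturalistic speech, the phase of
their low-frequency (delta/theta, 1–8 Hz) EEG locks to the stimulus in a way
that is consistent *across* listeners, not just across repetitions within one
listener. `phasedecode` implements the full analysis chain that quantifies
this cross-subject phase alignment and exploits it to decode which stimulus a
listener heard from a single EEG trial — including a subject-independent
decoder that needs no training data from the test listener — together with a
seeded synthetic phase-entrained EEG generator so the entire chain can be
validated end-to-end without any recordings.

## The method

**Phase extraction.** Epoched trials are decomposed with a sliding
Hanning-tapered window of fixed length 3 cycles per frequency
(window = 3/f s), yielding phase θ and amplitude per
trial × electrode × frequency × time. The default spectrum grid covers
1–45 Hz (56 bins) at time centers 1.4–59.6 s (292 bins).

**Cross-subject phase coherence.** For a group of N trials (all trials from
all subjects for one stimulus) at one bin,

    CPhase = | Σₙ exp(i θₙ) | / N  ∈ [0, 1],

the resultant length of the trials' unit phasors: 1 for perfect alignment,
≈ √(π/4N) for random phases.

**Phase dissimilarity.** Per electrode and frequency bin, the time-averaged
within-group CPhase (trials grouped by true stimulus; K groups of N) minus
the same quantity for random re-partitions of the trial pool
("across-groups"). 1000 surrogate partitions form the null for per-bin
z-scores and a one-tailed cluster-based permutation test (α = 0.025,
Delaunay electrode adjacency × chain frequency adjacency, max-cluster-mass
null). The electrodes with the largest 1–8 Hz band-averaged dissimilarity
are selected for decoding.

**Lagged phase correlation.** Per frequency band (delta 1–4 Hz, theta
4–8 Hz), each trial becomes the cosine of its electrode-averaged,
band-collapsed phase; Pearson correlations over lags ±1.5 s are averaged
over all unordered within-stimulus pairs (1,275 pairs for 51 trials) and
tested against a trial/stimulus-shuffled null (100 shuffles, cluster test at
α = 0.01).

**Nearest-template decoding.** Similarity between a test trial and a class
template is the two-phasor resultant |cos((θ_test − θ_template)/2)| averaged
over time, electrodes and frequency; the predicted class maximizes it. The
*subject-specific* model draws one template trial per class from the same
listener (200 random draws); the *subject-independent* model uses circular-
mean templates averaged over all other listeners' trials and needs no
iteration. Accuracy is referenced to the binomial inverse-CDF chance level

    chance = min{ k : BinomCDF(k; n, 1/K) ≥ 0.99 } × 100 / n ,

not the naive 100/K — e.g. 13.64 % for n = 44 test trials over 22 classes
and 10.61 % for n = 66 — and summarized with Cohen's kappa
κ = (acc − chance)/(100 − chance). Harnesses sweep the decoded segment
duration and the number of trials averaged per template.

**Correlation-feature classifiers.** Cosine/sine phase components, averaged
across electrodes and then across training subjects per (stimulus,
repetition, component), give 132 templates at study scale; Pearson
correlations against them, averaged over frequency, repetition and
component, give one feature per stimulus and time window (full, first half,
second half → 66 features). A one-vs-all L2 logistic regression (5-fold CV
over the regularization grid) and a small fully connected network
(44-44 hidden units, batch norm, ELU, dropout 0.2, momentum SGD, early
stopping) decode these features leave-one-subject-out.

## Worked example

`examples/04_nearest_template_decoding.py` generates the small synthetic
preset (6 subjects × 8 stimuli × 3 repetitions, 16 electrodes of which 6
entrained, 30-s epochs), extracts classification-grid phases on the
entrained electrodes and runs both decoders:

```
S01: subject-specific  52.4% (chance 31.25%, kappa 0.31) | subject-independent 100.0% (chance 29.17%, kappa 1.00)
S02: subject-specific  50.2% (chance 31.25%, kappa 0.28) | subject-independent 100.0% (chance 29.17%, kappa 1.00)
...
mean subject-specific:    54.7%
mean subject-independent: 100.0%
random-label baseline:    12.3% (expected 100/K = 12.5%)
```

Single-trial templates carry the full per-trial phase jitter and background
noise, so the within-subject decoder is noisy; averaging 15 trials per class
from the *other* listeners suppresses that noise, and the subject-independent
decoder dominates — the method's central point. Both clear their binomial
chance thresholds (31.25 % at n = 16, 29.17 % at n = 24), while the
random-label baseline sits at 100/K.

The other examples cover the generator (`01`), the dissimilarity spectrum
with cluster statistics and electrode selection (`02`), lagged phase
correlations (`03`), duration/template-count sweeps (`04`/`05`) and the
correlation-feature classifiers (`06`). A thin CLI mirrors the library:
`phasedecode simulate | info | convert | tfr | dissimilarity | xcorr |
classify | sweep | ml`.

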