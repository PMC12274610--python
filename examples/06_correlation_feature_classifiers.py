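"""Correlation-feature decoders: one-vs-all logistic regression and a small
fully connected network.

Cosine/sine phase components are correlated against per-(stimulus,
repetition, component) templates averaged over training subjects; the
correlations, averaged over frequency, repetition and component, become the
feature vector (one value per stimulus and time window). Both classifiers
are evaluated leave-one-subject-out and should clear the binomial chance
threshold comfortably on entrained data.
"""

import warnings

from phasedecode import (
    CLASSIFY_WINDOW,
    compute_tfr,
    evaluate_fcnn,
    evaluate_logreg,
    fit_window,
    generate_dataset,
    select_electrodes,
    small_config,
)

cfg = small_config(seed=1)
ds = generate_dataset(cfg)
sub = select_electrodes(ds, ds.electrode_labels[: cfg.n_entrained_electrodes])
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    pt = compute_tfr(sub, fit_window(sub, CLASSIFY_WINDOW))

for subject in ds.subject_ids[:3]:
    rl = evaluate_logreg(pt, subject, seed=8)
    rf = evaluate_fcnn(pt, subject, seed=8)
    print(f"{subject}: logistic regression {rl.accuracy:5.1f}% | "
          f"network {rf.accuracy:5.1f}% | chance {rl.chance_level:.2f}%")
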