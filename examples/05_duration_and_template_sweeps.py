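"""How decoding accuracy depends on segment duration and template count.

Accuracy grows with the duration of the decoded EEG segment (more
phase-alignment evidence per trial) and with the number of trials averaged
into each subject-independent template (less single-trial noise). The last
table reports, per subject, the smallest template count that beats that
subject's own within-subject decoder. Runtime: a couple of minutes.
"""

import warnings

from phasedecode import (
    duration_sweep,
    generate_dataset,
    min_templates_to_beat,
    small_config,
    template_count_sweep,
)

cfg = small_config(seed=1)
ds = generate_dataset(cfg)
entrained = ds.electrode_labels[: cfg.n_entrained_electrodes]

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    dur = duration_sweep(ds, durations=(10, 20, 30),
                         model="subject_independent", electrodes=entrained)
    dur_s = duration_sweep(ds, durations=(30,), model="subject_specific",
                           electrodes=entrained, n_iterations=100, seed=6)
    cnt = template_count_sweep(ds, counts=(1, 3, 6, 15), n_draws=3, seed=7,
                               durations=(30,), electrodes=entrained)

print("subject-independent accuracy by segment duration:")
print(dur.groupby("duration").accuracy.mean().round(1).to_string())
print("\nsubject-independent accuracy by template count (30-s segments):")
print(cnt.groupby("count").accuracy.mean().round(1).to_string())
print("\nminimum templates to beat the subject-specific decoder:")
print(min_templates_to_beat(cnt, dur_s).to_string(index=False))
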