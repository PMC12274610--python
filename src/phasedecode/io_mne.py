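"""Optional import of standard epoched-EEG formats via MNE.

These helpers map an :class:`mne.Epochs`-like object (e.g. loaded from a
``-epo.fif`` file) into the canonical :class:`EpochedDataset`.  Event IDs
become stimulus identifiers and successive occurrences of the same event
become repetitions; the caller names the subject.  Multi-subject datasets are
assembled by stacking per-subject imports with :func:`combine_subjects`.
"""

from __future__ import annotations

import numpy as np

from .data_model import EpochedDataset
from .errors import ValidationError


def from_mne_epochs(epochs, subject_id: str) -> EpochedDataset:
    """Convert one subject's MNE Epochs into an EpochedDataset."""
    event_id = epochs.event_id
    if not event_id:
        raise ValidationError("epochs carry no event_id mapping")
    stimulus_ids = sorted(event_id, key=event_id.get)
    codes = epochs.events[:, 2]
    counts = {s: int(np.sum(codes == event_id[s])) for s in stimulus_ids}
    n_rep = max(counts.values())
    info = epochs.info
    labels = list(epochs.ch_names)
    # 2-D positions from the montage when available, zeros otherwise
    positions = np.zeros((len(labels), 2))
    montage = info.get_montage() if hasattr(info, "get_montage") else None
    if montage is not None:
        pos3d = montage.get_positions()["ch_pos"]
        for i, lab in enumerate(labels):
            if lab in pos3d and np.isfinite(pos3d[lab][:2]).all():
                positions[i] = pos3d[lab][:2]
    data_in = epochs.get_data(copy=True)
    n_samp = data_in.shape[-1]
    data = np.zeros((1, len(stimulus_ids), n_rep, len(labels), n_samp),
                    dtype=np.float32)
    missing = np.ones((1, len(stimulus_ids), n_rep), dtype=bool)
    for ki, stim in enumerate(stimulus_ids):
        rows = np.flatnonzero(codes == event_id[stim])
        for ri, row in enumerate(rows):
            data[0, ki, ri] = data_in[row]
            missing[0, ki, ri] = False
    return EpochedDataset(
        subject_ids=[subject_id],
        stimulus_ids=stimulus_ids,
        n_repetitions=n_rep,
        electrode_labels=labels,
        electrode_positions=positions,
        sampling_rate=float(info["sfreq"]),
        epoch_start=float(epochs.times[0]),
        data=data,
        missing_mask=missing,
    )


def combine_subjects(datasets: list) -> EpochedDataset:
    """Stack per-subject datasets sharing stimuli, electrodes and timing."""
    if not datasets:
        raise ValidationError("no datasets to combine")
    ref = datasets[0]
    for d in datasets[1:]:
        if (d.stimulus_ids != ref.stimulus_ids
                or d.electrode_labels != ref.electrode_labels
                or d.n_repetitions != ref.n_repetitions
                or d.sampling_rate != ref.sampling_rate
                or d.n_samples != ref.n_samples
                or not np.isclose(d.epoch_start, ref.epoch_start)):
            raise ValidationError("datasets disagree on structure or timing")
    return EpochedDataset(
        subject_ids=[s for d in datasets for s in d.subject_ids],
        stimulus_ids=ref.stimulus_ids,
        n_repetitions=ref.n_repetitions,
        electrode_labels=ref.electrode_labels,
        electrode_positions=ref.electrode_positions,
        sampling_rate=ref.sampling_rate,
        epoch_start=ref.epoch_start,
        data=np.concatenate([d.data for d in datasets], axis=0),
        missing_mask=np.concatenate([d.missing_mask for d in datasets], axis=0),
    )
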