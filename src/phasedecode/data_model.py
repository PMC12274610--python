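"""Core domain types and the portable epoched-EEG container.

An :class:`EpochedDataset` holds multi-subject epoched EEG as a five-way
array indexed ``subject x stimulus x repetition x electrode x sample`` with an
onset-relative time axis (stimulus onset at t = 0, sample ``s`` at
``epoch_start + s / sampling_rate``).  Datasets round-trip losslessly through
a versioned on-disk container: one binary array file (``data.npy``) plus a
JSON metadata sidecar (``meta.json``).

Missing trials are carried via a boolean mask and never silently dropped;
operations that require complete trial pools raise instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import BoundsError, SchemaError, ValidationError

SCHEMA_VERSION = "1.0"

_REQUIRED_META = [
    "schema_version",
    "subject_ids",
    "stimulus_ids",
    "n_repetitions",
    "electrode_labels",
    "electrode_positions",
    "sampling_rate",
    "epoch_start",
    "missing_mask",
]


@dataclass
class EpochedDataset:
    """Multi-subject epoched EEG trials with onset-relative timing.

    data has shape (n_subjects, n_stimuli, n_repetitions, n_electrodes,
    n_samples) in microvolt-scale arbitrary units.  ``missing_mask`` is True
    for (subject, stimulus, repetition) cells that hold no valid trial.
    """

    subject_ids: list
    stimulus_ids: list
    n_repetitions: int
    electrode_labels: list
    electrode_positions: np.ndarray
    sampling_rate: float
    epoch_start: float
    data: np.ndarray
    missing_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValidationError(
                f"data must be 5-D (subject x stimulus x repetition x "
                f"electrode x sample), got {self.data.ndim}-D"
            )
        s, k, r, e, _ = self.data.shape
        if s != len(self.subject_ids):
            raise ValidationError("data axis 0 does not match subject_ids")
        if k != len(self.stimulus_ids):
            raise ValidationError("data axis 1 does not match stimulus_ids")
        if r != self.n_repetitions:
            raise ValidationError("data axis 2 does not match n_repetitions")
        if e != len(self.electrode_labels):
            raise ValidationError("data axis 3 does not match electrode_labels")
        if len(set(self.electrode_labels)) != e:
            raise ValidationError("electrode_labels must be unique")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be positive")
        self.electrode_positions = np.asarray(self.electrode_positions, float)
        if self.electrode_positions.shape != (e, 2):
            raise ValidationError("electrode_positions must have shape (n_electrodes, 2)")
        if self.missing_mask is None:
            self.missing_mask = np.zeros((s, k, r), dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != (s, k, r):
                raise ValidationError(
                    "missing_mask must have shape (n_subjects, n_stimuli, n_repetitions)"
                )

    # -- derived geometry -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_stimuli(self) -> int:
        return len(self.stimulus_ids)

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_labels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[-1]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return self.epoch_start + np.arange(self.n_samples) / self.sampling_rate

    @property
    def epoch_end(self) -> float:
        return float(self.times[-1])

    def trial_index(self) -> list:
        """(subject_id, stimulus_id, repetition) for every non-missing trial."""
        out = []
        for si, sub in enumerate(self.subject_ids):
            for ki, stim in enumerate(self.stimulus_ids):
                for ri in range(self.n_repetitions):
                    if not self.missing_mask[si, ki, ri]:
                        out.append((sub, stim, ri))
        return out


@dataclass
class GroupAssignment:
    """A partition of trials into K groups of N for coherence analysis.

    Each member is a (subject_id, stimulus_id, repetition) trial index.
    Within-groups collect all trials of one stimulus; across-groups are
    random re-partitions of the same pool (the surrogate null).
    """

    n_groups: int
    members: list  # list (per group) of lists of (subject, stimulus, rep)
    group_labels: list = None

    def __post_init__(self):
        if len(self.members) != self.n_groups:
            raise ValidationError("members must list one trial set per group")
        sizes = {len(m) for m in self.members}
        if len(sizes) != 1:
            raise ValidationError(f"groups must have equal size, got sizes {sorted(sizes)}")
        flat = [t for m in self.members for t in m]
        if len(set(flat)) != len(flat):
            raise ValidationError("groups must be disjoint")
        if self.group_labels is None:
            self.group_labels = list(range(self.n_groups))

    @property
    def group_size(self) -> int:
        return len(self.members[0])


@dataclass
class AnalysisWindow:
    """Uniform time/frequency grids for the sliding-window transform.

    All bounds are closed intervals of bin centers; times in seconds relative
    to stimulus onset, frequencies in Hz.
    """

    t_start: float
    t_end: float
    t_step: float
    f_start: float
    f_end: float
    f_step: float

    def __post_init__(self):
        if not self.t_start < self.t_end + 1e-12:
            raise ValidationError("t_start must not exceed t_end")
        if self.t_step <= 0 or self.f_step <= 0:
            raise ValidationError("grid steps must be positive")
        if self.f_start > self.f_end:
            raise ValidationError("f_start must not exceed f_end")
        if self.f_start <= 0:
            raise ValidationError("frequencies must be positive")

    @property
    def time_grid(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.t_step)) + 1
        return self.t_start + self.t_step * np.arange(n)

    @property
    def freq_grid(self) -> np.ndarray:
        n = int(round((self.f_end - self.f_start) / self.f_step)) + 1
        return self.f_start + self.f_step * np.arange(n)


# -- operations ------------------------------------------------------------

def take_segment(dataset: EpochedDataset, duration: float) -> EpochedDataset:
    """Truncate post-onset data to the first ``duration`` seconds.

    Pre-onset padding and all metadata are preserved; the post-onset sample
    count becomes ``round(duration * sampling_rate)``.
    """
    fs = dataset.sampling_rate
    n_pre = int(np.sum(dataset.times < 0))
    n_post = int(round(duration * fs))
    available = dataset.n_samples - n_pre
    if n_post > available:
        raise BoundsError(
            f"requested {duration} s ({n_post} samples) post-onset but only "
            f"{available / fs:.3f} s available"
        )
    return replace(dataset, data=dataset.data[..., : n_pre + n_post])


def select_electrodes(dataset: EpochedDataset, labels: list) -> EpochedDataset:
    """Reduce and reorder the electrode axis to ``labels``."""
    unknown = [lab for lab in labels if lab not in dataset.electrode_labels]
    if unknown:
        raise ValidationError(f"unknown electrode label(s): {unknown}")
    idx = [dataset.electrode_labels.index(lab) for lab in labels]
    return replace(
        dataset,
        electrode_labels=list(labels),
        electrode_positions=dataset.electrode_positions[idx],
        data=dataset.data[..., idx, :],
    )


def within_groups(dataset: EpochedDataset) -> GroupAssignment:
    """Group all non-missing trials by their true stimulus."""
    members = []
    for ki, stim in enumerate(dataset.stimulus_ids):
        grp = [
            (sub, stim, ri)
            for si, sub in enumerate(dataset.subject_ids)
            for ri in range(dataset.n_repetitions)
            if not dataset.missing_mask[si, ki, ri]
        ]
        members.append(grp)
    return GroupAssignment(
        n_groups=dataset.n_stimuli, members=members, group_labels=list(dataset.stimulus_ids)
    )


# -- container I/O ---------------------------------------------------------

def save_container(dataset: EpochedDataset, path) -> None:
    """Write the canonical container: ``data.npy`` + versioned ``meta.json``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "data.npy", dataset.data)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "subject_ids": list(dataset.subject_ids),
        "stimulus_ids": list(dataset.stimulus_ids),
        "n_repetitions": int(dataset.n_repetitions),
        "electrode_labels": list(dataset.electrode_labels),
        "electrode_positions": dataset.electrode_positions.tolist(),
        "sampling_rate": float(dataset.sampling_rate),
        "epoch_start": float(dataset.epoch_start),
        "missing_mask": dataset.missing_mask.tolist(),
    }
    (path / "meta.json").write_text(json.dumps(meta))


def load_container(path) -> EpochedDataset:
    """Load a container written by :func:`save_container`.

    Containers from any 1.x schema minor version load; malformed metadata
    raises :class:`SchemaError` naming the missing field.
    """
    path = Path(path)
    meta_path = path / "meta.json"
    data_path = path / "data.npy"
    if not meta_path.exists():
        raise SchemaError(f"container at {path} has no meta.json")
    if not data_path.exists():
        raise SchemaError(f"container at {path} has no data.npy")
    meta = json.loads(meta_path.read_text())
    for key in _REQUIRED_META:
        if key not in meta:
            raise SchemaError(f"container metadata missing required field '{key}'")
    major = str(meta["schema_version"]).split(".")[0]
    if major != SCHEMA_VERSION.split(".")[0]:
        raise SchemaError(
            f"unsupported container schema version {meta['schema_version']}"
        )
    data = np.load(data_path)
    return EpochedDataset(
        subject_ids=list(meta["subject_ids"]),
        stimulus_ids=list(meta["stimulus_ids"]),
        n_repetitions=int(meta["n_repetitions"]),
        electrode_labels=list(meta["electrode_labels"]),
        electrode_positions=np.asarray(meta["electrode_positions"], float),
        sampling_rate=float(meta["sampling_rate"]),
        epoch_start=float(meta["epoch_start"]),
        data=data,
        missing_mask=np.asarray(meta["missing_mask"], bool),
    )
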