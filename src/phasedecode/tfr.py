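"""Sliding-window Hanning-taper time-frequency decomposition and phase extraction.

At each analysis frequency f the signal is convolved with a Hanning-tapered
complex exponential whose length is a fixed number of cycles (default 3, i.e.
window length 3/f seconds).  The complex coefficient at time center t is

    c(f, t) = sum_tau  hann(tau - t; cycles/f) * x(tau) * exp(-i 2 pi f (tau - t))

with the window symmetric, odd-length in samples and normalized to unit sum.
The phase convention is fixed so that a pure cosine cos(2 pi f tau + phi0)
yields theta(t) = 2 pi f t + phi0 (phase advancing at rate 2 pi f).

Phases are undefined (NaN) wherever the amplitude falls below a degeneracy
floor of 1e-12 times the trial RMS, never silently zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.signal.windows import hann

from .data_model import AnalysisWindow, EpochedDataset
from .errors import BoundsError, SchemaError, ValidationError

#: Default grids.  The spectrum grid spans 1-45 Hz in 0.8-Hz steps (56 bins)
#: with time centers 1.4-59.6 s in 0.2-s steps (292 bins); the classification
#: grid restricts frequencies to the entrained 1-8 Hz band in 0.5-Hz steps
#: (15 bins); the lag-analysis grid refines time to 0.05-s steps (1165 bins).
SPECTRUM_WINDOW = AnalysisWindow(1.4, 59.6, 0.2, 1.0, 45.0, 0.8)
CLASSIFY_WINDOW = AnalysisWindow(1.4, 59.6, 0.2, 1.0, 8.0, 0.5)
LAG_WINDOW = AnalysisWindow(1.4, 59.6, 0.05, 1.0, 8.0, 1.0)

DEGENERACY_FLOOR = 1e-12


@dataclass
class PhaseTensor:
    """Phase angles and amplitudes over trial x electrode x frequency x time."""

    phases: np.ndarray  # radians in (-pi, pi], NaN where undefined
    amplitudes: np.ndarray
    freq_grid: np.ndarray
    time_grid: np.ndarray
    trial_index: list  # (subject_id, stimulus_id, repetition) per trial
    electrode_labels: list
    electrode_positions: np.ndarray

    def __post_init__(self):
        if self.phases.shape != self.amplitudes.shape:
            raise ValidationError("phases and amplitudes must share a shape")
        if self.phases.ndim != 4:
            raise ValidationError("phase tensor must be 4-D (trial, electrode, freq, time)")
        n, e, f, t = self.phases.shape
        if n != len(self.trial_index):
            raise ValidationError("trial axis does not match trial_index")
        if e != len(self.electrode_labels):
            raise ValidationError("electrode axis does not match electrode_labels")
        if f != len(self.freq_grid) or t != len(self.time_grid):
            raise ValidationError("frequency/time axes do not match grids")

    @property
    def n_trials(self) -> int:
        return self.phases.shape[0]

    def select_electrodes(self, labels: list) -> "PhaseTensor":
        unknown = [lab for lab in labels if lab not in self.electrode_labels]
        if unknown:
            raise ValidationError(f"unknown electrode label(s): {unknown}")
        idx = [self.electrode_labels.index(lab) for lab in labels]
        return replace(
            self,
            phases=self.phases[:, idx],
            amplitudes=self.amplitudes[:, idx],
            electrode_labels=list(labels),
            electrode_positions=self.electrode_positions[idx],
        )

    def select_trials(self, mask_or_idx) -> "PhaseTensor":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            phases=self.phases[idx],
            amplitudes=self.amplitudes[idx],
            trial_index=[self.trial_index[i] for i in idx],
        )


def _window_length_samples(freq: float, cycles: int, fs: float) -> int:
    length = int(round(cycles / freq * fs))
    if length % 2 == 0:
        length += 1
    return max(length, 3)


def fit_window(
    dataset: EpochedDataset, window: AnalysisWindow, cycles: int = 3
) -> AnalysisWindow:
    """Shrink a window's time range so every tapered window fits the epoch.

    The widest taper belongs to the lowest frequency; time centers whose
    ``cycles/f_start`` window would cross the epoch edges are dropped.  Emits
    a warning when the grid shrinks; raises :class:`BoundsError` when no
    center fits.
    """
    half = (_window_length_samples(window.f_start, cycles, dataset.sampling_rate) - 1) / 2
    half_s = half / dataset.sampling_rate
    lo = dataset.epoch_start + half_s
    hi = dataset.epoch_end - half_s
    grid = window.time_grid
    keep = grid[(grid >= lo - 1e-9) & (grid <= hi + 1e-9)]
    if keep.size == 0:
        raise BoundsError(
            f"no time center in [{window.t_start}, {window.t_end}] fits a "
            f"{cycles}-cycle window at {window.f_start} Hz inside the epoch "
            f"[{dataset.epoch_start}, {dataset.epoch_end:.3f}] s"
        )
    t_start, t_end = float(keep[0]), float(keep[-1])
    if t_start != grid[0] or t_end != grid[-1]:
        warnings.warn(
            f"analysis time grid shrunk to [{t_start}, {t_end}] s to fit "
            f"{cycles}-cycle windows inside the epoch",
            stacklevel=2,
        )
    return AnalysisWindow(
        t_start, t_end, window.t_step, window.f_start, window.f_end, window.f_step
    )


def compute_tfr(
    dataset: EpochedDataset, window: AnalysisWindow, cycles: int = 3
) -> PhaseTensor:
    """Hanning-taper sliding-window phase/amplitude decomposition.

    Every (frequency, time-center) pair must admit a full ``cycles/f`` window
    inside the epoch; otherwise a :class:`BoundsError` names the offending
    pair.  Missing trials are excluded from the trial axis.
    """
    fs = dataset.sampling_rate
    freqs = window.freq_grid
    times = window.time_grid
    centers = np.round((times - dataset.epoch_start) * fs).astype(int)

    present = ~dataset.missing_mask
    x = dataset.data[..., :].astype(np.float64)
    s, k, r, e, n_samp = x.shape
    x = x.reshape(s * k * r, e, n_samp)[present.reshape(-1)]
    trial_index = dataset.trial_index()
    n_trials = x.shape[0]

    rms = np.sqrt(np.mean(x**2, axis=-1))  # per (trial, electrode)
    floor = DEGENERACY_FLOOR * rms[:, :, None, None]

    coeffs = np.empty((n_trials, e, freqs.size, times.size), dtype=np.complex128)
    flat = x.reshape(n_trials * e, n_samp)
    for fi, f in enumerate(freqs):
        length = _window_length_samples(f, cycles, fs)
        half = (length - 1) // 2
        bad_lo = centers - half < 0
        bad_hi = centers + half > n_samp - 1
        if bad_lo.any() or bad_hi.any():
            j = int(np.argmax(bad_lo | bad_hi))
            raise BoundsError(
                f"{cycles}-cycle window at f={f:g} Hz, t={times[j]:g} s "
                f"exceeds the epoch bounds"
            )
        taper = hann(length, sym=True)
        taper = taper / taper.sum()
        m = np.arange(-half, half + 1)
        kernel = taper * np.exp(-2j * np.pi * f * m / fs)
        idx = centers[:, None] + m[None, :]  # (n_times, length)
        # chunk the gather to bound memory at ~tens of MB
        out = np.empty((flat.shape[0], times.size), dtype=np.complex128)
        chunk = max(1, int(4e6 // (times.size * length)) or 1)
        for start in range(0, flat.shape[0], chunk):
            seg = flat[start : start + chunk]
            out[start : start + chunk] = seg[:, idx] @ kernel
        coeffs[:, :, fi, :] = out.reshape(n_trials, e, times.size)

    amplitudes = np.abs(coeffs)
    phases = np.angle(coeffs)
    phases[amplitudes <= floor] = np.nan
    return PhaseTensor(
        phases=phases,
        amplitudes=amplitudes,
        freq_grid=freqs,
        time_grid=times,
        trial_index=trial_index,
        electrode_labels=list(dataset.electrode_labels),
        electrode_positions=np.asarray(dataset.electrode_positions, float),
    )


def band_average_phasors(pt: PhaseTensor, bands) -> PhaseTensor:
    """Collapse the frequency axis by averaging unit phasors within bands.

    ``bands`` is one ``(f_lo, f_hi)`` pair or a list of pairs (closed
    intervals on the frequency grid).  The collapsed phase is the resultant
    angle of the in-band unit phasors and the amplitude is the resultant
    length; full cancellation flags the phase undefined.
    """
    if np.ndim(bands) == 1:
        bands = [tuple(bands)]
    band_phases = []
    band_amps = []
    centers = []
    for lo, hi in bands:
        sel = (pt.freq_grid >= lo - 1e-9) & (pt.freq_grid <= hi + 1e-9)
        if not sel.any():
            raise ValidationError(f"band ({lo}, {hi}) Hz intersects no frequency bin")
        z = np.exp(1j * pt.phases[:, :, sel, :]).mean(axis=2)
        amp = np.abs(z)
        ang = np.angle(z)
        ang[amp < 1e-9] = np.nan
        band_phases.append(ang)
        band_amps.append(amp)
        centers.append(0.5 * (lo + hi))
    return replace(
        pt,
        phases=np.stack(band_phases, axis=2),
        amplitudes=np.stack(band_amps, axis=2),
        freq_grid=np.asarray(centers, float),
    )


# -- phase-tensor container I/O -------------------------------------------

def save_phase_tensor(pt: PhaseTensor, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "phases.npy", pt.phases)
    np.save(path / "amplitudes.npy", pt.amplitudes)
    meta = {
        "schema_version": "1.0",
        "freq_grid": pt.freq_grid.tolist(),
        "time_grid": pt.time_grid.tolist(),
        "trial_index": [list(t) for t in pt.trial_index],
        "electrode_labels": list(pt.electrode_labels),
        "electrode_positions": pt.electrode_positions.tolist(),
    }
    (path / "meta.json").write_text(json.dumps(meta))


def load_phase_tensor(path) -> PhaseTensor:
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise SchemaError(f"phase-tensor container at {path} has no meta.json")
    meta = json.loads(meta_path.read_text())
    for key in ("freq_grid", "time_grid", "trial_index", "electrode_labels",
                "electrode_positions"):
        if key not in meta:
            raise SchemaError(f"phase-tensor metadata missing required field '{key}'")
    return PhaseTensor(
        phases=np.load(path / "phases.npy"),
        amplitudes=np.load(path / "amplitudes.npy"),
        freq_grid=np.asarray(meta["freq_grid"], float),
        time_grid=np.asarray(meta["time_grid"], float),
        trial_index=[tuple(t) for t in meta["trial_index"]],
        electrode_labels=list(meta["electrode_labels"]),
        electrode_positions=np.asarray(meta["electrode_positions"], float),
    )
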