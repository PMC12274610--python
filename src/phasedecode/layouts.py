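"""Standard 10-20/10-10 electrode labels and 2-D layout coordinates.

The label order is frontal-first so that synthetic datasets can place the
entrained signal on the leading electrodes and electrode-selection tests have
a known ground truth.  Coordinates come from MNE's standard 10-20 montage
(projected to the x/y plane); if the montage cannot be loaded a deterministic
schematic layout is used instead.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

# Frontal-first ordering of a 59-channel cap (10-10 subset).
STANDARD_59 = [
    "Fp1", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T7", "T8",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP7", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "PO4", "PO8", "O1", "Oz", "O2",
]

_MONTAGE_CACHE: dict[str, np.ndarray] | None = None


def _montage_positions() -> dict[str, np.ndarray]:
    global _MONTAGE_CACHE
    if _MONTAGE_CACHE is None:
        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            montage = mne.channels.make_standard_montage("standard_1020")
        pos3d = montage.get_positions()["ch_pos"]
        _MONTAGE_CACHE = {name: np.asarray(p[:2], float) for name, p in pos3d.items()}
    return _MONTAGE_CACHE


def _schematic_positions(labels: list[str]) -> np.ndarray:
    # Deterministic fallback: points on concentric rings, front of head up.
    n = len(labels)
    pts = []
    for i in range(n):
        ring = 1 + i // 12
        ang = 2 * math.pi * (i % 12) / 12.0
        pts.append([0.02 * ring * math.sin(ang), 0.02 * ring * math.cos(ang)])
    return np.asarray(pts, float)


def standard_layout(n_electrodes: int) -> tuple[list[str], np.ndarray]:
    """Return ``(labels, positions)`` for an ``n_electrodes``-channel cap.

    Labels are drawn frontal-first from a 59-channel 10-10 subset; requests
    beyond 59 channels append generic ``E##`` labels on an outer ring.
    Positions are 2-D coordinates in arbitrary head units, suitable for
    Delaunay adjacency and topographic plots.
    """
    labels = list(STANDARD_59[:n_electrodes])
    while len(labels) < n_electrodes:
        labels.append(f"E{len(labels) + 1:02d}")
    try:
        montage = _montage_positions()
    except Exception:  # pragma: no cover - montage files missing
        montage = {}
    positions = np.zeros((n_electrodes, 2))
    fallback = _schematic_positions(labels)
    for i, lab in enumerate(labels):
        positions[i] = montage.get(lab, fallback[i])
    return labels, positions
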