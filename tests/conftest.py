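"""Shared fixtures: synthetic study-condition datasets and phase tensors.

Heavy objects (spectrum-grid decompositions, dissimilarity spectra) are
session-scoped so the entrained small-preset pipeline is computed once and
shared between the unit suite and the acceptance suite.
"""

import warnings

import numpy as np
import pytest

from phasedecode import (
    CLASSIFY_WINDOW,
    SPECTRUM_WINDOW,
    PhaseTensor,
    compute_dissimilarity,
    compute_tfr,
    fit_window,
    generate_dataset,
    select_electrodes,
    select_top_electrodes,
    small_config,
    tiny_config,
    within_groups,
)

SMALL_SEED = 101
TINY_SEED = 103


@pytest.fixture(scope="session")
def small_entrained():
    """Entrained small preset (6 subjects x 8 stimuli x 3 reps, 30-s epochs)."""
    return generate_dataset(small_config(seed=SMALL_SEED), return_drives=True)


@pytest.fixture(scope="session")
def spectrum_pt(small_entrained):
    ds, _ = small_entrained
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        win = fit_window(ds, SPECTRUM_WINDOW)
        return compute_tfr(ds, win)


@pytest.fixture(scope="session")
def dissim_spec(small_entrained, spectrum_pt):
    ds, _ = small_entrained
    return compute_dissimilarity(
        spectrum_pt, within_groups(ds), n_surrogates=150, seed=SMALL_SEED + 1
    )


@pytest.fixture(scope="session")
def top_electrodes(dissim_spec, small_entrained):
    ds, _ = small_entrained
    return select_top_electrodes(
        dissim_spec, band=(1.0, 8.0), n=small_config().n_entrained_electrodes
    )


@pytest.fixture(scope="session")
def classify_pt_top(small_entrained, top_electrodes):
    """Classification-grid phases on the selected electrodes."""
    ds, _ = small_entrained
    sub = select_electrodes(ds, top_electrodes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        win = fit_window(sub, CLASSIFY_WINDOW)
        return compute_tfr(sub, win)


@pytest.fixture(scope="session")
def lag_pt_small(small_entrained):
    """Lag-analysis-grid phases (0.05-s steps) of the small entrained preset."""
    from phasedecode import LAG_WINDOW

    ds, _ = small_entrained
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        win = fit_window(ds, LAG_WINDOW)
        return compute_tfr(ds, win)


@pytest.fixture(scope="session")
def tiny_entrained():
    return generate_dataset(tiny_config(seed=TINY_SEED), return_drives=True)


@pytest.fixture(scope="session")
def tiny_classify_pt(tiny_entrained):
    ds, _ = tiny_entrained
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        win = fit_window(ds, CLASSIFY_WINDOW)
        return compute_tfr(ds, win)


def make_phase_tensor(
    n_subjects=2,
    n_stimuli=3,
    n_repetitions=3,
    n_electrodes=2,
    n_freqs=2,
    n_times=4,
    seed=0,
    locked=False,
):
    """Random (or class-locked) phase tensor for classifier/feature tests.

    With ``locked=True`` every trial of a stimulus shares that stimulus's
    phase pattern exactly (noiseless decoding ground truth).
    """
    rng = np.random.default_rng(seed)
    shape = (n_electrodes, n_freqs, n_times)
    trial_index = []
    phases = []
    class_patterns = rng.uniform(-np.pi, np.pi, size=(n_stimuli, *shape))
    for si in range(n_subjects):
        for ki in range(n_stimuli):
            for ri in range(n_repetitions):
                trial_index.append((f"S{si + 1:02d}", f"stim{ki + 1:02d}", ri))
                if locked:
                    phases.append(class_patterns[ki])
                else:
                    phases.append(rng.uniform(-np.pi, np.pi, size=shape))
    phases = np.stack(phases)
    return PhaseTensor(
        phases=phases,
        amplitudes=np.ones_like(phases),
        freq_grid=1.0 + np.arange(n_freqs),
        time_grid=0.5 * np.arange(n_times),
        trial_index=trial_index,
        electrode_labels=[f"E{i}" for i in range(n_electrodes)],
        electrode_positions=np.c_[np.arange(n_electrodes), np.zeros(n_electrodes)],
    )
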