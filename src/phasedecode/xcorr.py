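"""Cross-subject lagged correlation of band-limited phase trajectories.

For each frequency band, every trial is reduced to a real bounded trajectory:
unit phasors are averaged across electrodes, collapsed across the band's
frequency bins, and the cosine of the resultant angle is taken (Pearson
correlation of wrapped angles is ill-defined; the cosine gives a linear,
bounded representation of the phase trajectory).  Pearson cross-correlations
over lags of up to +-1.5 s are computed for every unordered pair of trials
within a stimulus, their absolute values averaged across pairs and stimuli,
and compared against a surrogate null built by shuffling the trial-stimulus
assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .coherence import chain_adjacency, cluster_permutation_test
from .errors import ValidationError
from .tfr import PhaseTensor, band_average_phasors

logger = logging.getLogger(__name__)

DEFAULT_BANDS = ((1.0, 4.0), (4.0, 8.0))  # delta, theta


@dataclass
class LagCorrelation:
    """Mean absolute pairwise lagged correlation per band, with its null."""

    bands: list  # list of (f_lo, f_hi)
    lags: np.ndarray  # seconds, symmetric about 0
    mean_abs_corr: np.ndarray  # (n_bands, n_lags)
    n_pairs: int  # unordered pairs per stimulus group
    n_skipped: int = 0  # pairs skipped for constant trajectories
    surrogate_corr: np.ndarray = None  # (S, n_bands, n_lags)
    significant_mask: np.ndarray = None  # (n_bands, n_lags)


def phase_trajectory(pt: PhaseTensor, bands=DEFAULT_BANDS) -> np.ndarray:
    """Per-trial band-limited phase trajectories, shape (n_trials, n_bands, T).

    Electrode-averaged unit phasors are band-collapsed and the cosine of the
    resultant angle returned; samples where the phasors cancel are NaN.
    """
    if np.ndim(bands) == 1:
        bands = [tuple(bands)]
    z_el = np.exp(1j * pt.phases).mean(axis=1)  # (N, F, J)
    amp = np.abs(z_el)
    ang = np.angle(z_el)
    ang[amp < 1e-9] = np.nan
    collapsed = band_average_phasors(
        PhaseTensor(
            phases=ang[:, None, :, :],
            amplitudes=amp[:, None, :, :],
            freq_grid=pt.freq_grid,
            time_grid=pt.time_grid,
            trial_index=pt.trial_index,
            electrode_labels=["avg"],
            electrode_positions=np.zeros((1, 2)),
        ),
        list(bands),
    )
    return np.cos(collapsed.phases[:, 0, :, :])  # (N, n_bands, T)


def _all_pairs_lagged_corr(X: np.ndarray, max_lag_samples: int) -> np.ndarray:
    """Pearson correlation for all ordered series pairs at all lags.

    X: (M, T).  Returns C with shape (M, M, 2*max_lag+1) where
    C[i, j, L + lam] = Pearson(x_i[: T - lam], x_j[lam :]) for lam >= 0 and
    C[i, j, L - lam] = C[j, i, L + lam].  Only overlapping samples enter each
    lag's normalization.  Constant segments give NaN.
    """
    M, T = X.shape
    L = max_lag_samples
    if T <= L:
        raise ValidationError("max_lag exceeds the trajectory length")
    C = np.full((M, M, 2 * L + 1), np.nan)
    for lam in range(L + 1):
        a = X[:, : T - lam] if lam else X
        b = X[:, lam:] if lam else X
        ac = a - a.mean(axis=1, keepdims=True)
        bc = b - b.mean(axis=1, keepdims=True)
        na = np.linalg.norm(ac, axis=1)
        nb = np.linalg.norm(bc, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = (ac @ bc.T) / np.outer(na, nb)
        corr[na == 0, :] = np.nan
        corr[:, nb == 0] = np.nan
        C[:, :, L + lam] = corr
        if lam:
            C[:, :, L - lam] = corr.T
    return C


def _group_pair_mean(C: np.ndarray, group_ids: np.ndarray):
    """Mean |corr| over unordered within-group pairs; returns (curve, n_pairs,
    n_skipped) with curve shape (n_lags,)."""
    M = C.shape[0]
    iu, ju = np.triu_indices(M, k=1)
    same = group_ids[iu] == group_ids[ju]
    sel = np.abs(C[iu[same], ju[same], :])  # (n_pairs, n_lags)
    finite = np.isfinite(sel).all(axis=1)
    n_skipped = int(np.sum(~finite))
    if n_skipped:
        logger.warning("skipped %d constant-trajectory pair(s)", n_skipped)
    return np.nanmean(sel, axis=0), int(same.sum()), n_skipped


def pairwise_lagged_correlation(
    trajectories: np.ndarray,
    group_ids,
    time_step: float,
    max_lag: float = 1.5,
) -> LagCorrelation:
    """Mean absolute Pearson cross-correlation over within-group trial pairs.

    ``trajectories`` has shape (n_trials, n_bands, T) (from
    :func:`phase_trajectory`); ``group_ids`` assigns each trial to a stimulus
    group.  With N trials per group this averages N(N-1)/2 unordered pairs
    per group (1,275 pairs for 51 trials), per lag on the +-``max_lag`` grid.
    """
    trajectories = np.asarray(trajectories, float)
    if trajectories.ndim != 3:
        raise ValidationError("trajectories must be (n_trials, n_bands, T)")
    if trajectories.shape[0] < 2:
        raise ValidationError("need at least two trajectories")
    group_ids = np.asarray(group_ids)
    L = int(round(max_lag / time_step))
    lags = time_step * np.arange(-L, L + 1)
    n_bands = trajectories.shape[1]
    curves = np.empty((n_bands, lags.size))
    n_skipped = 0
    for b in range(n_bands):
        C = _all_pairs_lagged_corr(trajectories[:, b, :], L)
        curves[b], n_within, skipped = _group_pair_mean(C, group_ids)
        n_skipped += skipped
    _, counts = np.unique(group_ids, return_counts=True)
    n = int(counts[0])
    return LagCorrelation(
        bands=None,
        lags=lags,
        mean_abs_corr=curves,
        n_pairs=n * (n - 1) // 2,
        n_skipped=n_skipped,
    )


def xcorr_surrogate_null(
    trajectories: np.ndarray,
    group_ids,
    time_step: float,
    n_surrogates: int = 100,
    seed=None,
    max_lag: float = 1.5,
) -> np.ndarray:
    """Surrogate mean-|corr| curves under shuffled trial-stimulus assignment.

    Returns an array (n_surrogates, n_bands, n_lags).  Shuffling permutes the
    group assignment over trials; since trajectories are per-trial, this is
    identical to re-running the full pipeline on shuffled data.  No trial is
    ever paired with itself.
    """
    trajectories = np.asarray(trajectories, float)
    group_ids = np.asarray(group_ids)
    rng = np.random.default_rng(seed)
    L = int(round(max_lag / time_step))
    n_bands = trajectories.shape[1]
    mats = [
        _all_pairs_lagged_corr(trajectories[:, b, :], L) for b in range(n_bands)
    ]
    out = np.empty((n_surrogates, n_bands, 2 * L + 1))
    for s in range(n_surrogates):
        shuffled = group_ids[rng.permutation(group_ids.size)]
        for b in range(n_bands):
            out[s, b], _, _ = _group_pair_mean(mats[b], shuffled)
    return out


def xcorr_significance(
    obs: LagCorrelation, null: np.ndarray, alpha: float = 0.01
) -> np.ndarray:
    """Cluster test along the lag axis (chain adjacency), upper tail.

    Fills and returns ``obs.significant_mask`` of shape (n_bands, n_lags).
    """
    null = np.asarray(null, float)
    n_bands, n_lags = obs.mean_abs_corr.shape
    adj = chain_adjacency(n_lags)
    mask = np.zeros((n_bands, n_lags), dtype=bool)
    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_obs = np.where(sd > 0, (obs.mean_abs_corr - mu) / sd, 0.0)
        z_null = np.where(sd > 0, (null - mu) / sd, 0.0)
    for b in range(n_bands):
        mask[b] = cluster_permutation_test(
            z_obs[b], z_null[:, b, :], adj, alpha=alpha
        )
    obs.surrogate_corr = null
    obs.significant_mask = mask
    return mask


def run_lag_analysis(
    pt: PhaseTensor,
    bands=DEFAULT_BANDS,
    n_surrogates: int = 100,
    alpha: float = 0.01,
    seed=None,
    max_lag: float = 1.5,
) -> LagCorrelation:
    """End-to-end lagged-correlation analysis of a lag-grid phase tensor."""
    stimuli = [t[1] for t in pt.trial_index]
    uniq = {s: i for i, s in enumerate(dict.fromkeys(stimuli))}
    group_ids = np.asarray([uniq[s] for s in stimuli])
    step = float(np.median(np.diff(pt.time_grid)))
    traj = phase_trajectory(pt, bands)
    obs = pairwise_lagged_correlation(traj, group_ids, step, max_lag)
    obs.bands = list(bands)
    null = xcorr_surrogate_null(traj, group_ids, step, n_surrogates, seed, max_lag)
    xcorr_significance(obs, null, alpha)
    return obs
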