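"""Cross-subject phase coherence, dissimilarity spectra and cluster statistics.

The cross-subject phase coherence of a group of N trials at one
(electrode, frequency, time) bin is the resultant length of the trials' unit
phasors,

    CPhase = |sum_n exp(i theta_n)| / N  in [0, 1],

1 for perfectly aligned phases and ~1/sqrt(N) for random ones (the expected
resultant under uniform phases is sqrt(pi / (4 N))).

Phase dissimilarity contrasts, per electrode and frequency bin, the
time-averaged CPhase of within-groups (all trials sharing a stimulus) with
that of across-groups (random re-partitions of the same trial pool).  The
across-group values over many surrogate partitions form the null for a
z-score and for a one-tailed cluster-based permutation test over the
electrode x frequency grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError

from .data_model import GroupAssignment
from .errors import InsufficientNullError, UndefinedPhaseError, ValidationError
from .tfr import PhaseTensor


@dataclass
class CoherenceTensor:
    """CPhase values over group x electrode x frequency x time."""

    values: np.ndarray  # (K, E, F, J) in [0, 1]
    group_labels: list
    freq_grid: np.ndarray
    time_grid: np.ndarray
    n_per_group: int

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValidationError("coherence needs at least 2 trials per group")


@dataclass
class DissimilaritySpectrum:
    """Per-electrode, per-frequency dissimilarity with its surrogate null."""

    D: np.ndarray  # (E, F): observed within minus mean-across
    surrogate_D: np.ndarray  # (S, E, F): per-surrogate across term, centered
    z: np.ndarray  # (E, F)
    freq_grid: np.ndarray
    electrode_labels: list
    n_surrogates: int
    alpha: float = None
    significant_mask: np.ndarray = None  # (E, F)
    electrode_mask: np.ndarray = None  # (E,) any significant frequency bin


def cphase(phases, axis: int = 0) -> np.ndarray:
    """Resultant length of unit phasors across trials (Eq.-style CPhase).

    Invariant to a common rotation of all phases and to trial permutation.
    Undefined (NaN) phases raise; callers must mask them out first.
    """
    phases = np.asarray(phases, float)
    if phases.shape[axis] < 1:
        raise ValidationError("cphase needs at least one phase")
    if np.isnan(phases).any():
        raise UndefinedPhaseError("undefined phase (NaN) passed to cphase")
    z = np.exp(1j * phases).mean(axis=axis)
    return np.abs(z)


def _flat_positions(pt: PhaseTensor) -> dict:
    return {t: i for i, t in enumerate(pt.trial_index)}


def _group_positions(pt: PhaseTensor, groups: GroupAssignment) -> np.ndarray:
    lookup = _flat_positions(pt)
    idx = np.empty((groups.n_groups, groups.group_size), dtype=int)
    for gi, members in enumerate(groups.members):
        for mi, t in enumerate(members):
            if t not in lookup:
                raise ValidationError(f"group member {t} not present in phase tensor")
            idx[gi, mi] = lookup[t]
    return idx


def within_group_coherence(
    pt: PhaseTensor, groups: GroupAssignment
) -> CoherenceTensor:
    """CPhase per (group, electrode, frequency, time) over each group's trials."""
    idx = _group_positions(pt, groups)
    z = np.exp(1j * pt.phases)
    values = np.abs(z[idx].mean(axis=1))  # (K, E, F, J)
    return CoherenceTensor(
        values=values,
        group_labels=list(groups.group_labels),
        freq_grid=pt.freq_grid,
        time_grid=pt.time_grid,
        n_per_group=groups.group_size,
    )


def make_across_groups(
    pool: list, K: int, N: int, n_surrogates: int = 1000, seed=None
) -> list:
    """Uniformly random partitions of ``pool`` into K groups of N.

    ``pool`` is the full list of trial indices (e.g. 1,122 trials = 22
    stimuli x 3 repetitions x 17 subjects at study scale); each surrogate
    uses every pool trial exactly once.
    """
    pool = list(pool)
    if len(pool) != K * N:
        raise ValidationError(
            f"pool has {len(pool)} trials but K*N = {K * N}"
        )
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_surrogates):
        perm = rng.permutation(len(pool))
        members = [[pool[j] for j in perm[g * N : (g + 1) * N]] for g in range(K)]
        out.append(GroupAssignment(n_groups=K, members=members))
    return out


def _mean_coherence_per_partition(
    z: np.ndarray, idx: np.ndarray
) -> np.ndarray:
    """Time- and group-averaged CPhase for one partition.

    z: (n_trials, E, F, J) unit phasors; idx: (K, N) flat positions.
    Returns (E, F).
    """
    K, N = idx.shape
    acc = None
    for g in range(K):
        r = np.abs(z[idx[g]].mean(axis=0))  # (E, F, J)
        term = r.mean(axis=-1)  # time average -> (E, F)
        acc = term if acc is None else acc + term
    return acc / K


def dissimilarity_spectrum(
    within: CoherenceTensor,
    across: list,
) -> DissimilaritySpectrum:
    """Within minus across time-averaged CPhase per electrode and frequency.

    The across term is the mean over all surrogate partitions; the
    per-surrogate values populate ``surrogate_D`` and yield
    ``z = (D_obs - mean surrogate) / sd surrogate`` per bin.
    """
    if len(across) < 2:
        raise InsufficientNullError("need at least 2 across-group surrogates")
    shapes = {a.values.shape for a in across}
    if shapes != {within.values.shape}:
        raise ValidationError("within/across coherence shapes disagree")
    W = within.values.mean(axis=-1).mean(axis=0)  # (E, F)
    A = np.stack([a.values.mean(axis=-1).mean(axis=0) for a in across])  # (S, E, F)
    return _assemble_spectrum(W, A, within.freq_grid, None)


def _assemble_spectrum(W, A, freq_grid, electrode_labels) -> DissimilaritySpectrum:
    A_mean = A.mean(axis=0)
    A_sd = A.std(axis=0, ddof=1)
    D = W - A_mean
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(
            A_sd > 0, D / A_sd, np.where(D == 0, 0.0, np.sign(D) * np.inf)
        )
    return DissimilaritySpectrum(
        D=D,
        surrogate_D=A - A_mean,
        z=z,
        freq_grid=np.asarray(freq_grid, float),
        electrode_labels=electrode_labels,
        n_surrogates=A.shape[0],
    )


def compute_dissimilarity(
    pt: PhaseTensor,
    groups: GroupAssignment,
    n_surrogates: int = 1000,
    seed=None,
    alpha: float = 0.025,
    cluster: bool = True,
) -> DissimilaritySpectrum:
    """End-to-end dissimilarity spectrum from a phase tensor.

    Builds the within-group coherence from ``groups``, draws ``n_surrogates``
    random across-group partitions of the same trial pool, forms the
    dissimilarity spectrum and (optionally) runs the cluster-based
    permutation test over the electrode x frequency grid at ``alpha``.

    The surrogate loop shares one phasor tensor, so it costs one pass of
    group-sums per partition rather than a full recomputation.
    """
    idx_within = _group_positions(pt, groups)
    K, N = idx_within.shape
    pool = [t for m in groups.members for t in m]
    lookup = _flat_positions(pt)
    pool_idx = np.asarray([lookup[t] for t in pool])
    rng = np.random.default_rng(seed)

    z = np.exp(1j * pt.phases)
    W = _mean_coherence_per_partition(z, idx_within)
    A = np.empty((n_surrogates, *W.shape))
    for s in range(n_surrogates):
        perm = pool_idx[rng.permutation(pool_idx.size)].reshape(K, N)
        A[s] = _mean_coherence_per_partition(z, perm)
    spec = _assemble_spectrum(W, A, pt.freq_grid, list(pt.electrode_labels))
    spec.alpha = alpha
    if cluster:
        el_adj = delaunay_adjacency(pt.electrode_positions)
        adj = grid_adjacency(el_adj, len(pt.freq_grid))
        null_z = _surrogate_z(A)
        mask = cluster_permutation_test(
            spec.z.ravel(), null_z.reshape(n_surrogates, -1), adj, alpha=alpha
        )
        spec.significant_mask = mask.reshape(spec.z.shape)
        spec.electrode_mask = spec.significant_mask.any(axis=1)
    return spec


def _surrogate_z(A: np.ndarray) -> np.ndarray:
    """Z-score each surrogate against the surrogate distribution."""
    A_mean = A.mean(axis=0)
    A_sd = A.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        zs = np.where(A_sd > 0, (A - A_mean) / A_sd, 0.0)
    return zs


# -- adjacency helpers -----------------------------------------------------

def chain_adjacency(n: int) -> sp.csr_matrix:
    """1-D chain adjacency (i adjacent to i-1 and i+1)."""
    if n < 1:
        raise ValidationError("chain adjacency needs at least one node")
    diag = np.ones(n - 1)
    return sp.diags([diag, diag], offsets=[-1, 1], format="csr")


def delaunay_adjacency(positions: np.ndarray) -> sp.csr_matrix:
    """Electrode adjacency from a Delaunay triangulation of the 2-D layout.

    Degenerate layouts (fewer than 4 points or collinear positions) fall
    back to a fully connected graph.
    """
    positions = np.asarray(positions, float)
    n = positions.shape[0]
    if n < 2:
        return sp.csr_matrix((n, n))
    try:
        tri = Delaunay(positions)
        rows, cols = [], []
        for simplex in tri.simplices:
            for a in simplex:
                for b in simplex:
                    if a != b:
                        rows.append(a)
                        cols.append(b)
        adj = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )
        adj.data[:] = 1.0
        return adj
    except (QhullError, ValueError):
        full = np.ones((n, n)) - np.eye(n)
        return sp.csr_matrix(full)


def grid_adjacency(electrode_adjacency: sp.spmatrix, n_freq: int) -> sp.csr_matrix:
    """Adjacency over the flattened electrode x frequency grid.

    Bins are neighbors when they share an electrode and sit in adjacent
    frequency bins, or share a frequency bin on adjacent electrodes.  Bin
    order is ``electrode * n_freq + freq`` (C order of an (E, F) array).
    """
    E = electrode_adjacency.shape[0]
    eye_e = sp.identity(E, format="csr")
    eye_f = sp.identity(n_freq, format="csr")
    chain_f = chain_adjacency(n_freq) if n_freq > 1 else sp.csr_matrix((1, 1))
    return (sp.kron(eye_e, chain_f) + sp.kron(electrode_adjacency, eye_f)).tocsr()


# -- cluster-based permutation test ---------------------------------------

def cluster_permutation_test(
    observed: np.ndarray,
    null_samples: np.ndarray,
    adjacency: sp.spmatrix,
    alpha: float = 0.025,
    tail: str = "upper",
) -> np.ndarray:
    """One-tailed cluster-based permutation test over an adjacency graph.

    Bins are thresholded at the per-bin (1 - alpha) null quantile; adjacent
    suprathreshold bins form clusters whose mass (sum of the statistic) is
    compared to the null distribution of the maximum cluster mass across
    surrogates.  Returns a boolean mask, True only inside clusters with
    p < alpha.
    """
    observed = np.asarray(observed, float).ravel()
    null_samples = np.asarray(null_samples, float)
    if null_samples.ndim != 2 or null_samples.shape[1] != observed.size:
        raise ValidationError("null_samples must have shape (n_samples, n_bins)")
    if null_samples.shape[0] < 100:
        raise ValidationError("cluster test needs at least 100 null samples")
    if adjacency.shape != (observed.size, observed.size):
        raise ValidationError("adjacency shape does not match the bin count")
    if observed.size == 0:
        raise ValidationError("empty adjacency / zero bins")
    adjacency = sp.csr_matrix(adjacency)
    if (abs(adjacency - adjacency.T) > 1e-12).nnz:
        raise ValidationError("adjacency must be symmetric")
    if tail == "lower":
        observed = -observed
        null_samples = -null_samples
    elif tail != "upper":
        raise ValidationError(f"unknown tail '{tail}'")

    thresh = np.quantile(null_samples, 1.0 - alpha, axis=0)

    def clusters_of(values: np.ndarray):
        supra = values > thresh
        nodes = np.flatnonzero(supra)
        if nodes.size == 0:
            return []
        sub = adjacency[nodes][:, nodes]
        n_comp, labels = connected_components(sub, directed=False)
        out = []
        for c in range(n_comp):
            members = nodes[labels == c]
            out.append((members, float(values[members].sum())))
        return out

    obs_clusters = clusters_of(observed)
    mask = np.zeros(observed.size, dtype=bool)
    if not obs_clusters:
        return mask

    S = null_samples.shape[0]
    null_max = np.zeros(S)
    for s in range(S):
        cl = clusters_of(null_samples[s])
        if cl:
            null_max[s] = max(mass for _, mass in cl)
    for members, mass in obs_clusters:
        p = (1.0 + np.sum(null_max >= mass)) / (1.0 + S)
        if p < alpha:
            mask[members] = True
    return mask


def select_top_electrodes(
    ds: DissimilaritySpectrum, band=(1.0, 8.0), n: int = 20
) -> list:
    """Labels of the n electrodes with the largest band-averaged dissimilarity.

    Averages D over frequency bins inside the closed ``band`` and returns
    labels in descending order of that average; exact ties break by original
    label order (deterministic).
    """
    if ds.electrode_labels is None:
        raise ValidationError("spectrum carries no electrode labels")
    if n > len(ds.electrode_labels):
        raise ValidationError("n exceeds the number of electrodes")
    lo, hi = band
    sel = (ds.freq_grid >= lo - 1e-9) & (ds.freq_grid <= hi + 1e-9)
    if not sel.any():
        raise ValidationError(f"band ({lo}, {hi}) Hz intersects no frequency bin")
    score = ds.D[:, sel].mean(axis=1)
    order = sorted(range(len(score)), key=lambda e: (-score[e], e))
    return [ds.electrode_labels[e] for e in order[:n]]
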