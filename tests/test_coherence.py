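"""Circular statistics, surrogate partitions and cluster inference."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from phasedecode import (
    CoherenceTensor,
    GroupAssignment,
    InsufficientNullError,
    UndefinedPhaseError,
    ValidationError,
    chain_adjacency,
    cluster_permutation_test,
    cphase,
    delaunay_adjacency,
    dissimilarity_spectrum,
    grid_adjacency,
    make_across_groups,
    select_top_electrodes,
    within_group_coherence,
)
from phasedecode.coherence import DissimilaritySpectrum

from conftest import make_phase_tensor


class TestCphase:
    def test_identical_angles_give_one(self):
        assert cphase(np.full(51, 0.37)) == pytest.approx(1.0)

    def test_antipodal_pair_cancels(self):
        assert cphase(np.array([0.0, np.pi])) == pytest.approx(0.0, abs=1e-12)

    def test_right_angle_pair(self):
        assert cphase(np.array([0.0, np.pi / 2])) == pytest.approx(
            np.sqrt(2) / 2, abs=1e-12
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        angles=arrays(
            float,
            st.integers(2, 20),
            elements=st.floats(-np.pi, np.pi, allow_nan=False),
        ),
        rot=st.floats(-np.pi, np.pi, allow_nan=False),
    )
    def test_bounds_rotation_and_permutation_invariance(self, angles, rot):
        r = cphase(angles)
        assert 0.0 <= r <= 1.0 + 1e-12
        assert cphase(angles + rot) == pytest.approx(r, abs=1e-9)
        assert cphase(angles[::-1].copy()) == pytest.approx(r, abs=1e-12)

    def test_undefined_phase_rejected(self):
        with pytest.raises(UndefinedPhaseError):
            cphase(np.array([0.0, np.nan]))


class TestWithinGroupCoherence:
    def test_duplicated_trials_give_unit_coherence(self):
        pt = make_phase_tensor(n_subjects=2, n_stimuli=2, locked=True, seed=1)
        groups = GroupAssignment(
            n_groups=2,
            members=[
                [t for t in pt.trial_index if t[1] == s]
                for s in ("stim01", "stim02")
            ],
        )
        coh = within_group_coherence(pt, groups)
        np.testing.assert_allclose(coh.values, 1.0, atol=1e-12)
        assert coh.values.shape == (2, 2, 2, 4)

    def test_matches_binwise_loop_oracle(self):
        pt = make_phase_tensor(n_subjects=1, n_stimuli=2, n_repetitions=3, seed=5)
        groups = GroupAssignment(
            n_groups=2,
            members=[
                [t for t in pt.trial_index if t[1] == s]
                for s in ("stim01", "stim02")
            ],
        )
        coh = within_group_coherence(pt, groups)
        lookup = {t: i for i, t in enumerate(pt.trial_index)}
        for gi, members in enumerate(groups.members):
            rows = [lookup[t] for t in members]
            for e in range(pt.phases.shape[1]):
                for fi in range(pt.phases.shape[2]):
                    for ti in range(pt.phases.shape[3]):
                        expected = cphase(pt.phases[rows, e, fi, ti])
                        assert coh.values[gi, e, fi, ti] == pytest.approx(
                            expected, abs=1e-12
                        )

    def test_group_size_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            GroupAssignment(n_groups=2, members=[[("a", "s", 0)], []])


class TestAcrossGroups:
    def test_each_surrogate_is_a_partition(self):
        pool = [("S", f"x{i}", 0) for i in range(12)]
        for g in make_across_groups(pool, K=3, N=4, n_surrogates=5, seed=0):
            flat = [t for m in g.members for t in m]
            assert sorted(flat) == sorted(pool)
            assert g.group_size == 4

    def test_different_seeds_differ(self):
        pool = [("S", f"x{i}", 0) for i in range(12)]
        a = make_across_groups(pool, 3, 4, n_surrogates=1, seed=1)[0]
        b = make_across_groups(pool, 3, 4, n_surrogates=1, seed=2)[0]
        assert a.members != b.members

    def test_study_scale_pool_partitions(self):
        # 1,122 trials (22 stimuli x 3 repetitions x 17 subjects) -> 22 x 51
        pool = [(f"S{s}", f"stim{k}", r) for s in range(17) for k in range(22)
                for r in range(3)]
        groups = make_across_groups(pool, K=22, N=51, n_surrogates=3, seed=0)
        assert len(groups) == 3
        assert all(g.n_groups == 22 and g.group_size == 51 for g in groups)

    def test_pool_size_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            make_across_groups([("S", "x", 0)] * 10, K=3, N=4)


def fake_coherence(values):
    values = np.asarray(values, float)
    return CoherenceTensor(
        values=values,
        group_labels=list(range(values.shape[0])),
        freq_grid=np.arange(values.shape[2], dtype=float) + 1,
        time_grid=np.arange(values.shape[3], dtype=float),
        n_per_group=51,
    )


class TestDissimilaritySpectrum:
    def test_identical_within_and_across_give_zero(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 1, size=(3, 2, 4, 5))
        spec = dissimilarity_spectrum(fake_coherence(v), [fake_coherence(v)] * 3)
        np.testing.assert_allclose(spec.D, 0.0, atol=1e-12)

    def test_uniform_phase_null_expectation(self):
        # within perfectly coherent (CPhase 1), across built from uniform
        # phases with N = 51: D should approach 1 - sqrt(pi / (4 * 51))
        rng = np.random.default_rng(42)
        N, reps = 51, 400
        within = fake_coherence(np.ones((1, 1, 1, reps)))
        across = []
        for _ in range(20):
            angles = rng.uniform(-np.pi, np.pi, size=(N, reps))
            r = np.abs(np.exp(1j * angles).mean(axis=0))
            across.append(fake_coherence(r.reshape(1, 1, 1, reps)))
        spec = dissimilarity_spectrum(within, across)
        expected = 1.0 - np.sqrt(np.pi / (4 * N))
        assert spec.D[0, 0] == pytest.approx(expected, abs=0.005)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        w = rng.uniform(0, 1, size=(2, 2, 3, 4))
        a = [rng.uniform(0, 1, size=(2, 2, 3, 4)) for _ in range(4)]
        fwd = dissimilarity_spectrum(fake_coherence(w), [fake_coherence(x) for x in a])
        mean_a = np.mean(a, axis=0)
        rev = dissimilarity_spectrum(
            fake_coherence(mean_a), [fake_coherence(w)] * 4
        )
        np.testing.assert_allclose(fwd.D, -rev.D, atol=1e-12)

    def test_insufficient_null_rejected(self):
        v = np.ones((1, 1, 1, 2))
        with pytest.raises(InsufficientNullError):
            dissimilarity_spectrum(fake_coherence(v), [fake_coherence(v)])


class TestClusterPermutation:
    def test_constant_inputs_yield_no_clusters(self):
        obs = np.zeros(10)
        null = np.zeros((120, 10))
        mask = cluster_permutation_test(obs, null, chain_adjacency(10))
        assert not mask.any()

    def test_injected_cluster_detected(self):
        rng = np.random.default_rng(0)
        null = rng.standard_normal((300, 40))
        obs = rng.standard_normal(40)
        obs[10:15] += 10.0  # far above any null excursion
        mask = cluster_permutation_test(obs, null, chain_adjacency(40), alpha=0.025)
        assert mask[10:15].all()
        assert mask.sum() <= 8  # no blanket significance

    def test_null_draw_calibration(self):
        # observed drawn from its own null: family-wise error <= alpha
        rng = np.random.default_rng(7)
        adj = chain_adjacency(30)
        hits = 0
        reps = 200
        for _ in range(reps):
            null = rng.standard_normal((120, 30))
            obs = rng.standard_normal(30)
            hits += cluster_permutation_test(obs, null, adj, alpha=0.05).any()
        from scipy.stats import binom

        assert hits <= binom.ppf(0.995, reps, 0.05)

    def test_preconditions(self):
        with pytest.raises(ValidationError):
            cluster_permutation_test(
                np.zeros(5), np.zeros((10, 5)), chain_adjacency(5)
            )
        asym = sp.csr_matrix(np.triu(np.ones((5, 5)), 1))
        with pytest.raises(ValidationError):
            cluster_permutation_test(np.zeros(5), np.zeros((120, 5)), asym)


class TestAdjacency:
    def test_chain_structure(self):
        adj = chain_adjacency(4).toarray()
        assert adj[0, 1] == 1 and adj[0, 2] == 0
        np.testing.assert_array_equal(adj, adj.T)

    def test_delaunay_is_symmetric_and_local(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(size=(12, 2))
        adj = delaunay_adjacency(pos)
        assert (abs(adj - adj.T) > 0).nnz == 0
        assert 0 < adj.nnz < 12 * 11  # sparser than complete graph

    def test_degenerate_layout_falls_back_to_complete(self):
        pos = np.c_[np.arange(5), np.zeros(5)]  # collinear
        adj = delaunay_adjacency(pos).toarray()
        assert adj.sum() == 5 * 4

    def test_grid_adjacency_neighbors(self):
        el = chain_adjacency(3)  # electrodes 0-1-2 in a chain
        adj = grid_adjacency(el, n_freq=4).toarray()
        # same electrode, adjacent frequencies
        assert adj[0 * 4 + 1, 0 * 4 + 2] == 1
        # adjacent electrodes, same frequency
        assert adj[0 * 4 + 1, 1 * 4 + 1] == 1
        # diagonal moves are not neighbors
        assert adj[0 * 4 + 1, 1 * 4 + 2] == 0


class TestSelectTopElectrodes:
    def spectrum(self, D, labels):
        D = np.asarray(D, float)
        return DissimilaritySpectrum(
            D=D,
            surrogate_D=np.zeros((2, *D.shape)),
            z=np.zeros_like(D),
            freq_grid=np.arange(D.shape[1], dtype=float) + 1,
            electrode_labels=labels,
            n_surrogates=2,
        )

    def test_descending_selection(self):
        spec = self.spectrum([[0.1], [0.5], [0.3]], ["A", "B", "C"])
        assert select_top_electrodes(spec, band=(1, 1), n=2) == ["B", "C"]

    def test_all_electrodes_when_n_equals_count(self):
        spec = self.spectrum([[0.1], [0.5]], ["A", "B"])
        assert set(select_top_electrodes(spec, band=(1, 1), n=2)) == {"A", "B"}

    def test_tie_breaks_by_label_order(self):
        spec = self.spectrum([[0.5], [0.5], [0.1]], ["B", "A", "C"])
        assert select_top_electrodes(spec, band=(1, 1), n=1) == ["B"]
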