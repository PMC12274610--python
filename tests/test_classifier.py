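"""Template similarity, decoding harnesses, chance levels and kappa."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasedecode import (
    TemplateSet,
    ValidationError,
    build_independent_templates,
    chance_level,
    classify,
    cohen_kappa,
    min_templates_to_beat,
    random_baseline,
    subject_independent_eval,
    subject_specific_eval,
    template_similarity,
)
from conftest import make_phase_tensor


def template_set_from(phases, **kw):
    phases = np.asarray(phases, float)
    return TemplateSet(
        phases=phases,
        class_ids=list(range(phases.shape[0])),
        freq_grid=np.arange(phases.shape[2], dtype=float) + 1,
        time_grid=np.arange(phases.shape[3], dtype=float),
        electrode_labels=[f"E{i}" for i in range(phases.shape[1])],
        **kw,
    )


class TestTemplateSimilarity:
    def test_equal_patterns_score_one(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-np.pi, np.pi, size=(2, 3, 4))
        assert template_similarity(x, x) == pytest.approx(1.0)

    def test_antipodal_patterns_score_zero(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-np.pi, np.pi, size=(2, 3, 4))
        assert template_similarity(x, x + np.pi) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_bin_loop(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(-np.pi, np.pi, size=(2, 3, 4))
        b = rng.uniform(-np.pi, np.pi, size=(2, 3, 4))
        acc = []
        for e in range(2):
            for f in range(3):
                for t in range(4):
                    acc.append(
                        abs(np.exp(1j * a[e, f, t]) + np.exp(1j * b[e, f, t])) / 2
                    )
        assert template_similarity(a, b) == pytest.approx(np.mean(acc), abs=1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            template_similarity(np.zeros((1, 2, 3)), np.zeros((1, 2, 4)))

    def test_undefined_bins_are_excluded(self):
        a = np.zeros((1, 1, 2))
        b = np.array([[[0.0, np.nan]]])
        assert template_similarity(a, b) == pytest.approx(1.0)


class TestClassify:
    def test_trial_identical_to_template_is_predicted(self):
        rng = np.random.default_rng(3)
        tpl = rng.uniform(-np.pi, np.pi, size=(8, 2, 3, 4))
        templates = template_set_from(tpl)
        pred = classify(tpl[7][None], templates)
        assert pred[0] == 7

    def test_tied_templates_pick_lowest_class_index(self):
        tpl = np.zeros((3, 1, 1, 2))
        tpl[2] += 1.0
        templates = template_set_from(tpl)
        pred = classify(np.zeros((1, 1, 1, 2)), templates)
        assert pred[0] == 0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(rot=st.floats(-np.pi, np.pi, allow_nan=False), seed=st.integers(0, 50))
    def test_common_rotation_invariance(self, rot, seed):
        rng = np.random.default_rng(seed)
        tpl = rng.uniform(-np.pi, np.pi, size=(4, 1, 2, 3))
        tests = rng.uniform(-np.pi, np.pi, size=(5, 1, 2, 3))
        base = classify(tests, template_set_from(tpl))
        rotated = classify(
            np.angle(np.exp(1j * (tests + rot))),
            template_set_from(np.angle(np.exp(1j * (tpl + rot)))),
        )
        np.testing.assert_array_equal(base, rotated)


class TestChanceLevel:
    def test_matches_brute_force_cdf_summation(self):
        # independent oracle: exact CDF accumulation with math.comb
        def oracle(n, c, p):
            ps = 1.0 / c
            acc = 0.0
            for k in range(n + 1):
                acc += math.comb(n, k) * ps**k * (1 - ps) ** (n - k)
                if acc >= p - 1e-12:
                    return k * 100.0 / n
            return 100.0

        for n in [1, 7, 44, 66, 100, 251, 500]:
            for c in [2, 5, 22]:
                for p in [0.5, 0.95, 0.99]:
                    assert chance_level(n, c, p).level == pytest.approx(
                        oracle(n, c, p), abs=1e-9
                    )

    def test_symmetric_binomial_median(self):
        assert chance_level(100, 2, 0.5).level == pytest.approx(50.0)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValidationError):
            chance_level(10, 2, 1.0)
        with pytest.raises(ValidationError):
            chance_level(0, 2, 0.5)


class TestCohenKappa:
    def test_accuracy_at_chance_is_zero(self):
        assert cohen_kappa(10.61, 10.61) == 0.0

    def test_perfect_accuracy_is_one(self):
        assert cohen_kappa(100.0, 10.61) == 1.0

    def test_literature_conversions(self):
        # reported multi-class accuracies against their naive chance levels
        assert cohen_kappa(30.0, 100.0 / 6) == 0.16
        assert cohen_kappa(15.3, 100.0 / 10) == 0.06
        assert cohen_kappa(60.0, 100.0 / 2) == 0.20
        assert cohen_kappa(15.0, 100.0 / 30) == 0.12
        # accuracy exactly at chance (3-class case reported as kappa 0.00)
        assert cohen_kappa(100.0 / 3, 100.0 / 3) == 0.0

    def test_chance_at_hundred_rejected(self):
        with pytest.raises(ValidationError):
            cohen_kappa(50.0, 100.0)


class TestSubjectSpecific:
    def test_study_scale_template_and_test_counts(self):
        pt = make_phase_tensor(
            n_subjects=1, n_stimuli=22, n_repetitions=3, n_electrodes=1,
            n_freqs=1, n_times=2, seed=0,
        )
        res = subject_specific_eval(pt, "S01", n_iterations=2, seed=0)
        assert res.n_test == 44  # 22 classes x 2 held-out repetitions
        assert res.confusion.sum() == 2 * 44

    def test_noiseless_repetitions_decode_perfectly(self):
        pt = make_phase_tensor(n_subjects=1, n_stimuli=4, locked=True, seed=1)
        res = subject_specific_eval(pt, "S01", n_iterations=5, seed=0)
        assert res.accuracy == 100.0
        assert res.kappa == 1.0

    def test_seeded_determinism(self):
        pt = make_phase_tensor(n_subjects=1, n_stimuli=4, seed=2)
        a = subject_specific_eval(pt, "S01", n_iterations=10, seed=5)
        b = subject_specific_eval(pt, "S01", n_iterations=10, seed=5)
        assert a.accuracy == b.accuracy
        np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_single_repetition_rejected(self):
        pt = make_phase_tensor(n_subjects=1, n_stimuli=3, n_repetitions=1)
        with pytest.raises(ValidationError):
            subject_specific_eval(pt, "S01")


class TestIndependentTemplates:
    def test_identical_trials_average_to_themselves(self):
        pt = make_phase_tensor(n_subjects=3, n_stimuli=2, locked=True, seed=3)
        tpl = build_independent_templates(pt, "S03")
        np.testing.assert_allclose(tpl.resultant, 1.0, atol=1e-12)
        first = [i for i, t in enumerate(pt.trial_index) if t[:2] == ("S01", "stim01")][0]
        np.testing.assert_allclose(
            np.angle(np.exp(1j * (tpl.phases[0] - pt.phases[first]))), 0, atol=1e-9
        )

    def test_study_scale_pool_is_48_trials_per_class(self):
        pt = make_phase_tensor(
            n_subjects=17, n_stimuli=2, n_repetitions=3, n_electrodes=1,
            n_freqs=1, n_times=1, seed=4,
        )
        tpl = build_independent_templates(pt, "S17")
        assert all(len(p) == 48 for p in tpl.provenance)

    def test_antipodal_pair_flags_undefined_bin(self):
        pt = make_phase_tensor(n_subjects=2, n_stimuli=1, n_repetitions=1,
                               n_electrodes=1, n_freqs=1, n_times=2, seed=5)
        pt.phases[0] = 0.0
        pt.phases[1, ..., 0] = np.pi  # antipodal at the first bin only
        pt.phases[1, ..., 1] = 0.0
        pt.trial_index = [("S01", "stim01", 0), ("S02", "stim01", 0)]
        tpl = build_independent_templates(pt, held_out_subject="S99")
        assert np.isnan(tpl.phases[0, 0, 0, 0])
        assert tpl.resultant[0, 0, 0, 0] < 1e-9
        assert not np.isnan(tpl.phases[0, 0, 0, 1])

    def test_oversized_draw_rejected(self):
        pt = make_phase_tensor(n_subjects=2, n_stimuli=2, seed=6)
        with pytest.raises(ValidationError):
            build_independent_templates(pt, "S02", n_templates=10)


class TestSubjectIndependentEval:
    def test_study_scale_test_count(self):
        pt = make_phase_tensor(
            n_subjects=3, n_stimuli=22, n_repetitions=3, n_electrodes=1,
            n_freqs=1, n_times=1, seed=7,
        )
        res = subject_independent_eval(pt, "S03")
        assert res.n_test == 66
        assert res.chance_level == pytest.approx(10.61, abs=0.005)

    def test_locked_phases_decode_perfectly(self):
        pt = make_phase_tensor(n_subjects=3, n_stimuli=5, locked=True, seed=8)
        res = subject_independent_eval(pt, "S03")
        assert res.accuracy == 100.0


class TestRandomBaseline:
    def test_expected_accuracy_near_uniform(self):
        res = random_baseline(K=22, n_test=44, n_iterations=200, seed=0)
        se = 100 * np.sqrt((1 / 22) * (21 / 22) / (200 * 44))
        assert abs(res.accuracy - 100 / 22) < 4 * se

    def test_single_class_is_always_correct(self):
        assert random_baseline(K=1, n_test=10, n_iterations=3, seed=0).accuracy == 100.0

    def test_seeded_determinism(self):
        a = random_baseline(22, 44, 20, seed=9)
        b = random_baseline(22, 44, 20, seed=9)
        assert a.accuracy == b.accuracy


class TestSweepBookkeeping:
    def test_min_templates_to_beat(self):
        counts = pd.DataFrame(
            dict(subject=["A"] * 3, duration=[30.0] * 3, count=[1, 3, 6],
                 accuracy=[10.0, 35.0, 50.0])
        )
        specific = pd.DataFrame(dict(subject=["A"], duration=[30.0], accuracy=[30.0]))
        out = min_templates_to_beat(counts, specific)
        assert out.min_count.iloc[0] == 3

    def test_min_templates_nan_when_never_beaten(self):
        counts = pd.DataFrame(
            dict(subject=["A"] * 2, duration=[30.0] * 2, count=[1, 3],
                 accuracy=[10.0, 20.0])
        )
        specific = pd.DataFrame(dict(subject=["A"], duration=[30.0], accuracy=[90.0]))
        out = min_templates_to_beat(counts, specific)
        assert np.isnan(out.min_count.iloc[0])

    def test_full_pool_draw_equals_all_template_eval(self):
        pt = make_phase_tensor(n_subjects=3, n_stimuli=4, n_repetitions=2, seed=10)
        full = subject_independent_eval(pt, "S01")
        drawn = subject_independent_eval(pt, "S01", n_templates=4, seed=0)
        assert drawn.accuracy == full.accuracy
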