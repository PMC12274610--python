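"""Nearest-template phase decoding, chance levels and evaluation harnesses.

A template is a per-class phase pattern on the classification grid (a single
trial, or the circular mean of many trials).  The similarity between a test
trial and a template at one bin is the two-element phasor resultant

    |exp(i theta_test) + exp(i theta_template)| / 2 = |cos((theta_test - theta_template) / 2)|,

averaged over time, electrodes and frequency bins to one score per class; the
predicted class maximizes the score (ties break to the lowest class index).

Chance levels come from the binomial inverse CDF: the smallest success count
k whose Binomial(n, 1/n_classes) CDF reaches the cumulative threshold p
(default 0.99), expressed as a percentage of the n test trials.  Cohen's
kappa is chance-corrected accuracy, (acc - chance) / (100 - chance), with the
binomial chance level as the expected agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import EpochedDataset, select_electrodes, take_segment
from .errors import BoundsError, ValidationError
from .tfr import CLASSIFY_WINDOW, PhaseTensor, compute_tfr, fit_window


@dataclass
class TemplateSet:
    """One phase template per class on a common grid.

    ``phases`` has shape (K, E, F, J); undefined bins (NaN, e.g. full phasor
    cancellation in an average) are excluded from similarity averaging.
    ``resultant`` stores the per-bin resultant length of averaged templates
    (1.0 for single-trial templates).
    """

    phases: np.ndarray
    class_ids: list
    freq_grid: np.ndarray
    time_grid: np.ndarray
    electrode_labels: list
    resultant: np.ndarray = None
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        if self.phases.ndim != 4 or self.phases.shape[0] != len(self.class_ids):
            raise ValidationError("templates must be (n_classes, E, F, J)")
        if self.resultant is None:
            self.resultant = np.ones_like(self.phases)


@dataclass
class ClassificationResult:
    """Confusion counts (rows = true class), accuracy and chance accounting."""

    confusion: np.ndarray  # (K, K) counts, possibly summed over iterations
    accuracy: float  # percent
    per_class_accuracy: np.ndarray  # percent per class
    chance_level: float  # percent
    kappa: float
    n_test: int
    n_iterations: int = 1
    class_ids: list = None


@dataclass
class ChanceSpec:
    n: int
    p_succ: float
    p: float
    k_crit: int
    level: float  # percent


# -- chance and kappa ------------------------------------------------------

def chance_level(n: int, n_classes: int, p: float = 0.99) -> ChanceSpec:
    """Binomial inverse-CDF chance level for n test trials over n_classes.

    The CDF is accumulated by direct summation of binomial probabilities (no
    normal approximation); the level is ``k_crit * 100 / n`` percent.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 0 < p < 1:
        raise ValidationError("cumulative threshold p must be in (0, 1)")
    if n_classes < 1:
        raise ValidationError("n_classes must be >= 1")
    p_succ = 1.0 / n_classes
    pmf = stats.binom.pmf(np.arange(n + 1), n, p_succ)
    cdf = np.cumsum(pmf)
    k_crit = int(np.argmax(cdf >= p - 1e-12))
    return ChanceSpec(n=n, p_succ=p_succ, p=p, k_crit=k_crit, level=k_crit * 100.0 / n)


def cohen_kappa(accuracy_percent: float, chance_percent: float) -> float:
    """Chance-corrected agreement on the percent scale, rounded to 2 decimals."""
    if chance_percent >= 100:
        raise ValidationError("chance level must be below 100%")
    return round((accuracy_percent - chance_percent) / (100.0 - chance_percent), 2)


# -- similarity and prediction --------------------------------------------

def template_similarity(test: np.ndarray, template: np.ndarray) -> float:
    """Mean two-phasor resultant between a trial and a template, in [0, 1]."""
    test = np.asarray(test, float)
    template = np.asarray(template, float)
    if test.shape != template.shape:
        raise ValidationError(
            f"grid mismatch: test {test.shape} vs template {template.shape}"
        )
    sim = np.abs(np.cos((test - template) / 2.0))
    return float(np.nanmean(sim))


def _similarity_matrix(tests: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """(n_tests, n_classes) mean similarity, chunked to bound memory."""
    n_tests = tests.shape[0]
    K = templates.shape[0]
    out = np.empty((n_tests, K))
    bins = int(np.prod(tests.shape[1:]))
    chunk = max(1, int(2e7 // max(1, K * bins)))
    t_flat = tests.reshape(n_tests, -1)
    tpl_flat = templates.reshape(K, -1)
    for start in range(0, n_tests, chunk):
        seg = t_flat[start : start + chunk]
        diff = seg[:, None, :] - tpl_flat[None, :, :]
        sim = np.abs(np.cos(diff / 2.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[start : start + chunk] = np.nanmean(sim, axis=-1)
    return out


def classify(tests: np.ndarray, templates: TemplateSet) -> np.ndarray:
    """Predicted class indices by maximum template similarity.

    Exact ties resolve to the lowest class index (np.argmax convention).
    """
    if templates.phases.shape[0] < 1:
        raise ValidationError("need at least one template")
    if tests.shape[1:] != templates.phases.shape[1:]:
        raise ValidationError("test/template grids do not match")
    scores = _similarity_matrix(tests, templates.phases)
    return np.argmax(scores, axis=1)


# -- evaluation helpers ----------------------------------------------------

def _result_from_counts(
    confusion: np.ndarray,
    accuracies: list,
    n_test: int,
    n_classes: int,
    n_iterations: int,
    class_ids=None,
    p: float = 0.99,
) -> ClassificationResult:
    acc = float(np.mean(accuracies))
    chance = chance_level(n_test, n_classes, p).level
    kappa = cohen_kappa(acc, chance) if chance < 100 else np.nan
    row = confusion.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_class = np.where(row > 0, 100.0 * np.diag(confusion) / row, np.nan)
    return ClassificationResult(
        confusion=confusion,
        accuracy=acc,
        per_class_accuracy=per_class,
        chance_level=chance,
        kappa=kappa,
        n_test=n_test,
        n_iterations=n_iterations,
        class_ids=class_ids,
    )


def _subject_trials(pt: PhaseTensor, subject):
    idx = [i for i, t in enumerate(pt.trial_index) if t[0] == subject]
    if not idx:
        raise ValidationError(f"no trials for subject {subject!r}")
    return idx


def _class_order(pt: PhaseTensor):
    return list(dict.fromkeys(t[1] for t in pt.trial_index))


def subject_specific_eval(
    pt: PhaseTensor, subject, n_iterations: int = 200, seed=None
) -> ClassificationResult:
    """Within-subject nearest-template decoding with random template draws.

    Per iteration one random trial per class serves as template and the
    remaining repetitions are tested (22 templates and 44 test trials at
    study scale); the accuracy is averaged over iterations and confusion
    counts summed.  The full result is deterministic given ``seed``.
    """
    classes = _class_order(pt)
    K = len(classes)
    idx = _subject_trials(pt, subject)
    by_class = {c: [i for i in idx if pt.trial_index[i][1] == c] for c in classes}
    reps = {c: len(v) for c, v in by_class.items()}
    if min(reps.values()) < 2:
        raise ValidationError(
            "subject-specific evaluation needs >= 2 repetitions per class"
        )
    # all trials of this subject, and their pairwise similarity (templates are
    # single trials, so every iteration only re-indexes this matrix)
    sub_pt = pt.phases[idx]
    sim = _similarity_matrix(sub_pt, sub_pt)
    local = {g: j for j, g in enumerate(idx)}
    rng = np.random.default_rng(seed)
    confusion = np.zeros((K, K), dtype=int)
    accuracies = []
    n_test = sum(r - 1 for r in reps.values())
    for _ in range(n_iterations):
        tpl = [by_class[c][rng.integers(len(by_class[c]))] for c in classes]
        tpl_local = [local[g] for g in tpl]
        hits = 0
        for ci, c in enumerate(classes):
            for g in by_class[c]:
                if g == tpl[ci]:
                    continue
                scores = sim[local[g], tpl_local]
                pred = int(np.argmax(scores))
                confusion[ci, pred] += 1
                hits += pred == ci
        accuracies.append(100.0 * hits / n_test)
    return _result_from_counts(
        confusion, accuracies, n_test, K, n_iterations, class_ids=classes
    )


def build_independent_templates(
    pt: PhaseTensor, held_out_subject, n_templates="all", seed=None
) -> TemplateSet:
    """Per-class circular-mean templates from all non-held-out subjects.

    The template phase at each bin is the angle of the mean unit phasor over
    the selected trials (48 trials per class at study scale: 16 subjects x 3
    repetitions); the resultant length is stored and bins with full
    cancellation are flagged undefined.  ``n_templates`` smaller than the
    pool draws that many trials per class uniformly without replacement
    (seeded), as in the template-count sweep.
    """
    classes = _class_order(pt)
    pool = [
        i for i, t in enumerate(pt.trial_index) if t[0] != held_out_subject
    ]
    if not pool:
        raise ValidationError("no training subject left after hold-out")
    rng = np.random.default_rng(seed)
    tpl_phases = []
    tpl_res = []
    provenance = []
    for c in classes:
        cand = [i for i in pool if pt.trial_index[i][1] == c]
        if n_templates == "all":
            chosen = cand
        else:
            if n_templates > len(cand):
                raise ValidationError(
                    f"requested {n_templates} templates but only {len(cand)} "
                    f"trials available for class {c!r}"
                )
            chosen = list(rng.choice(len(cand), size=n_templates, replace=False))
            chosen = [cand[j] for j in chosen]
        z = np.exp(1j * pt.phases[chosen]).mean(axis=0)
        res = np.abs(z)
        ang = np.angle(z)
        ang[res < 1e-9] = np.nan
        tpl_phases.append(ang)
        tpl_res.append(res)
        provenance.append([pt.trial_index[i] for i in chosen])
    return TemplateSet(
        phases=np.stack(tpl_phases),
        class_ids=classes,
        freq_grid=pt.freq_grid,
        time_grid=pt.time_grid,
        electrode_labels=list(pt.electrode_labels),
        resultant=np.stack(tpl_res),
        provenance=provenance,
    )


def subject_independent_eval(
    pt: PhaseTensor, held_out_subject, templates: TemplateSet = None,
    n_templates="all", seed=None,
) -> ClassificationResult:
    """Decode every trial of the held-out subject against averaged templates.

    No iteration is involved: the templates are fixed by the training
    subjects (66 test trials at study scale).
    """
    if templates is None:
        templates = build_independent_templates(
            pt, held_out_subject, n_templates=n_templates, seed=seed
        )
    classes = templates.class_ids
    K = len(classes)
    test_idx = _subject_trials(pt, held_out_subject)
    tests = pt.phases[test_idx]
    true = np.asarray([classes.index(pt.trial_index[i][1]) for i in test_idx])
    pred = classify(tests, templates)
    confusion = np.zeros((K, K), dtype=int)
    np.add.at(confusion, (true, pred), 1)
    acc = [100.0 * float(np.mean(pred == true))]
    return _result_from_counts(confusion, acc, len(test_idx), K, 1, class_ids=classes)


def random_baseline(
    K: int, n_test: int, n_iterations: int = 200, seed=None
) -> ClassificationResult:
    """Uniform random-label classifier over balanced test trials."""
    if K < 1 or n_test < 1:
        raise ValidationError("K and n_test must be positive")
    rng = np.random.default_rng(seed)
    true = np.arange(n_test) % K
    confusion = np.zeros((K, K), dtype=int)
    accuracies = []
    for _ in range(n_iterations):
        pred = rng.integers(K, size=n_test)
        np.add.at(confusion, (true, pred), 1)
        accuracies.append(100.0 * float(np.mean(pred == true)))
    return _result_from_counts(confusion, accuracies, n_test, K, n_iterations)


# -- sweep harnesses -------------------------------------------------------

def _classification_tensor(
    dataset: EpochedDataset,
    duration=None,
    electrodes=None,
    window=CLASSIFY_WINDOW,
    cycles: int = 3,
) -> PhaseTensor:
    ds = dataset
    if electrodes is not None:
        ds = select_electrodes(ds, electrodes)
    if duration is not None:
        ds = take_segment(ds, duration)
    win = fit_window(ds, window, cycles)
    return compute_tfr(ds, win, cycles)


def duration_sweep(
    dataset: EpochedDataset,
    durations=(5, 10, 20, 30, 40, 50, 60),
    model: str = "subject_independent",
    electrodes=None,
    window=CLASSIFY_WINDOW,
    n_iterations: int = 200,
    seed=None,
) -> pd.DataFrame:
    """Accuracy per subject per post-onset segment duration.

    Each duration truncates the epochs, refits the analysis grid, recomputes
    the phase decomposition, evaluates the chosen model for every subject and
    recomputes the chance level for the resulting test count.  Returns a
    DataFrame with columns subject, duration, accuracy, chance, kappa.
    """
    if model not in ("subject_specific", "subject_independent"):
        raise ValidationError(f"unknown model '{model}'")
    rows = []
    for d in durations:
        if d > dataset.epoch_end:
            raise BoundsError(f"duration {d} s exceeds the epoch")
        pt = _classification_tensor(dataset, d, electrodes, window)
        for subject in dataset.subject_ids:
            if model == "subject_specific":
                res = subject_specific_eval(pt, subject, n_iterations, seed)
            else:
                res = subject_independent_eval(pt, subject)
            rows.append(
                dict(subject=subject, duration=d, accuracy=res.accuracy,
                     chance=res.chance_level, kappa=res.kappa)
            )
    return pd.DataFrame(rows)


def template_count_sweep(
    dataset: EpochedDataset,
    counts=(1, 3, 6, 9, 12, 24, 48),
    n_draws: int = 5,
    seed=None,
    durations=(None,),
    electrodes=None,
    window=CLASSIFY_WINDOW,
) -> pd.DataFrame:
    """Subject-independent accuracy as the per-class template count grows.

    For each count, ``n_draws`` random template subsets (uniform without
    replacement over the non-held-out subject x repetition pool) are averaged
    into templates and evaluated; accuracies are averaged over draws.
    ``durations`` of None means the full epoch.  Returns a DataFrame with
    columns subject, duration, count, accuracy, chance, kappa.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for d in durations:
        pt = _classification_tensor(dataset, d, electrodes, window)
        pool_per_class = (len(dataset.subject_ids) - 1) * dataset.n_repetitions
        for count in counts:
            if count > pool_per_class:
                raise ValidationError(
                    f"count {count} exceeds the {pool_per_class}-trial template pool"
                )
            for subject in dataset.subject_ids:
                accs = []
                n_eff = 1 if count == pool_per_class else n_draws
                for _ in range(n_eff):
                    res = subject_independent_eval(
                        pt, subject,
                        n_templates="all" if count == pool_per_class else count,
                        seed=rng.integers(2**31 - 1),
                    )
                    accs.append(res.accuracy)
                acc = float(np.mean(accs))
                rows.append(
                    dict(subject=subject,
                         duration=d if d is not None else dataset.epoch_end,
                         count=count, accuracy=acc, chance=res.chance_level,
                         kappa=cohen_kappa(acc, res.chance_level))
                )
    return pd.DataFrame(rows)


def min_templates_to_beat(
    count_sweep: pd.DataFrame, subject_specific: pd.DataFrame
) -> pd.DataFrame:
    """Smallest template count beating each subject's within-subject accuracy.

    Joins the count sweep with the subject-specific results on (subject,
    duration) and returns a DataFrame subject, duration, min_count (NaN when
    no count in the sweep exceeds the subject-specific accuracy).
    """
    rows = []
    for (subject, duration), grp in count_sweep.groupby(["subject", "duration"]):
        ref = subject_specific[
            (subject_specific.subject == subject)
            & (np.isclose(subject_specific.duration, duration))
        ]
        if ref.empty:
            continue
        target = float(ref.accuracy.iloc[0])
        beat = grp[grp.accuracy > target].sort_values("count")
        rows.append(
            dict(subject=subject, duration=duration,
                 min_count=int(beat["count"].iloc[0]) if not beat.empty else np.nan,
                 subject_specific_accuracy=target)
        )
    return pd.DataFrame(rows)
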