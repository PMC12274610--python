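"""Correlation features and the two alternative subject-independent decoders.

Instead of matching phases directly, these decoders correlate each trial's
phase components against class templates.  From the phase tensor the cosine
(real part) and sine (imaginary part) components are extracted and averaged
across electrodes; templates average those component series across training
subjects for every (stimulus, repetition, component) triple — 132 templates
at study scale (22 stimuli x 3 repetitions x 2 components).  Pearson
correlations in the time domain between a trial and every template, averaged
over frequency, repetition and component, yield one feature per stimulus;
repeating the analysis on the full trial and on its first and second halves
gives 66 features at study scale.

Two classifiers consume the features: a one-vs-all L2 logistic regression
(regularization chosen by stratified 5-fold cross-validation on training
subjects) and a small fully connected network trained on
electrode-as-sample restructured data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier

from .classifier import ClassificationResult, _result_from_counts
from .errors import ValidationError
from .nn import FullyConnectedClassifier
from .tfr import PhaseTensor

logger = logging.getLogger(__name__)

DEFAULT_WINDOWS = ("full", "first_half", "second_half")


@dataclass
class CorrelationFeatureConfig:
    """Feature-extraction layout for the correlation-based classifiers."""

    n_stimuli: int = 22
    n_repetitions: int = 3
    components: tuple = ("cosine", "sine")
    windows: tuple = DEFAULT_WINDOWS
    cv_folds: int = 5
    regularization_grid: tuple = (0.01, 0.1, 1.0, 10.0, 100.0)  # inverse L2 strength

    @property
    def n_templates(self) -> int:
        return self.n_stimuli * self.n_repetitions * len(self.components)

    @property
    def n_features(self) -> int:
        return self.n_stimuli * len(self.windows)


@dataclass
class NetworkConfig:
    """Architecture and training schedule of the fully connected network."""

    hidden: tuple = (44, 44)
    elu_alpha: float = 1.0
    dropout: float = 0.2
    momentum: float = 0.9
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 0.01
    val_every: int = 50  # mini-batches between validation passes
    patience: int = 15  # validation steps without improvement
    cv_folds: int = 8  # subject folds carving the validation split


@dataclass
class ComponentTemplates:
    """Electrode-averaged cosine/sine templates per (class, repetition)."""

    values: np.ndarray  # (K, R, 2, F, J)
    class_ids: list
    freq_grid: np.ndarray
    time_grid: np.ndarray

    @property
    def n_templates(self) -> int:
        k, r, c = self.values.shape[:3]
        return k * r * c


def _trial_components(phases: np.ndarray) -> np.ndarray:
    """Electrode-averaged cosine and sine series: (E, F, J) -> (2, F, J)."""
    return np.stack(
        [np.nanmean(np.cos(phases), axis=0), np.nanmean(np.sin(phases), axis=0)]
    )


def build_component_templates(pt: PhaseTensor) -> ComponentTemplates:
    """Average per-trial component series across training subjects.

    Yields one template per (stimulus, repetition, component) — K*R*2 in
    total — with the frequency axis retained until feature averaging.
    """
    if pt.n_trials == 0:
        raise ValidationError("empty training set")
    classes = list(dict.fromkeys(t[1] for t in pt.trial_index))
    reps = sorted({t[2] for t in pt.trial_index})
    F, J = len(pt.freq_grid), len(pt.time_grid)
    values = np.zeros((len(classes), len(reps), 2, F, J))
    for ki, c in enumerate(classes):
        for ri, r in enumerate(reps):
            idx = [
                i for i, t in enumerate(pt.trial_index) if t[1] == c and t[2] == r
            ]
            if not idx:
                raise ValidationError(
                    f"no training trial for class {c!r}, repetition {r}"
                )
            comps = np.stack([_trial_components(pt.phases[i]) for i in idx])
            values[ki, ri] = comps.mean(axis=0)
    return ComponentTemplates(
        values=values, class_ids=classes,
        freq_grid=pt.freq_grid, time_grid=pt.time_grid,
    )


def _window_slices(n_times: int, windows) -> list:
    mid = (n_times + 1) // 2  # midpoint bin belongs to the first half
    table = {
        "full": slice(0, n_times),
        "first_half": slice(0, mid),
        "second_half": slice(mid, n_times),
    }
    try:
        return [table[w] for w in windows]
    except KeyError as err:
        raise ValidationError(f"unknown window {err.args[0]!r}") from None


def correlation_features(
    trial_phases: np.ndarray,
    templates: ComponentTemplates,
    windows=DEFAULT_WINDOWS,
) -> np.ndarray:
    """Correlation feature vector of one trial: n_stimuli * n_windows values.

    Pearson correlations between the trial's electrode-averaged component
    series and every template, per frequency bin and time window, averaged
    over frequency, repetition and component.  Constant series contribute 0
    (counted via the module logger).  Features are invariant to affine
    rescaling of the trial signal.
    """
    comps = (
        trial_phases
        if trial_phases.ndim == 3 and trial_phases.shape[0] == 2
        else _trial_components(trial_phases)
    )
    return _features_from_components(comps, templates, windows)


def _features_from_components(comps, templates, windows) -> np.ndarray:
    K, R, C, F, J = templates.values.shape
    if comps.shape != (C, F, J):
        raise ValidationError(
            f"component grid {comps.shape} does not match templates {(C, F, J)}"
        )
    feats = []
    n_const = 0
    for sl in _window_slices(J, windows):
        a = comps[..., sl]  # (C, F, T)
        b = templates.values[..., sl]  # (K, R, C, F, T)
        ac = a - a.mean(axis=-1, keepdims=True)
        bc = b - b.mean(axis=-1, keepdims=True)
        na = np.linalg.norm(ac, axis=-1)
        nb = np.linalg.norm(bc, axis=-1)
        # correlation per (K, R, C, F): align trial comps with template comps
        num = (bc * ac[None, None]).sum(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = num / (nb * na[None, None])
        bad = ~np.isfinite(corr)
        n_const += int(bad.sum())
        corr = np.where(bad, 0.0, corr)
        feats.append(corr.mean(axis=(1, 2, 3)))  # -> (K,)
    if n_const:
        logger.debug("zeroed %d correlations against constant series", n_const)
    return np.concatenate(feats)


def extract_features(
    pt: PhaseTensor,
    templates: ComponentTemplates,
    windows=DEFAULT_WINDOWS,
) -> tuple:
    """Feature matrix and integer labels for every trial in ``pt``."""
    classes = templates.class_ids
    X = np.stack(
        [correlation_features(pt.phases[i], templates, windows)
         for i in range(pt.n_trials)]
    )
    y = np.asarray([classes.index(t[1]) for t in pt.trial_index])
    return X, y


def restructure_electrodes_as_samples(pt: PhaseTensor) -> PhaseTensor:
    """Treat each electrode's signal as an independent trial.

    The trial axis grows by a factor of n_electrodes and the electrode axis
    collapses to one; trial provenance (subject, stimulus, repetition) is
    replicated so that validation folds can still split by subject.
    """
    n, e, f, j = pt.phases.shape
    phases = np.transpose(pt.phases, (0, 1, 2, 3)).reshape(n * e, 1, f, j)
    amps = pt.amplitudes.reshape(n * e, 1, f, j)
    index = [t for t in pt.trial_index for _ in range(e)]
    return replace(
        pt,
        phases=phases,
        amplitudes=amps,
        trial_index=index,
        electrode_labels=["pooled"],
        electrode_positions=np.zeros((1, 2)),
    )


# -- logistic regression ---------------------------------------------------

def train_logreg_ova(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: CorrelationFeatureConfig = None,
    seed=None,
):
    """One-vs-all L2 logistic regression with cross-validated regularization.

    The inverse regularization strength is chosen by stratified
    ``cfg.cv_folds``-fold cross-validation on the training data only; fold
    assignment is seeded and deterministic.
    """
    cfg = cfg or CorrelationFeatureConfig()
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValidationError("need at least two classes to train")
    # L2-penalized by default; C comes from the cross-validated grid
    base = OneVsRestClassifier(LogisticRegression(solver="lbfgs", max_iter=2000))
    # stratified folding enforced; shrink folds when classes have few trials
    _, counts = np.unique(labels, return_counts=True)
    n_splits = int(min(cfg.cv_folds, counts.min()))
    if n_splits < 2:
        raise ValidationError("need >= 2 trials per class for cross-validation")
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=_derive(seed))
    search = GridSearchCV(
        base,
        param_grid={"estimator__C": list(cfg.regularization_grid)},
        cv=cv,
        n_jobs=None,
    )
    search.fit(features, labels)
    return search


def evaluate_model(model, features, labels, n_classes: int) -> ClassificationResult:
    """Fill a ClassificationResult (binomial chance level) from predictions."""
    pred = np.asarray(model.predict(features))
    labels = np.asarray(labels)
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(confusion, (labels, pred), 1)
    acc = [100.0 * float(np.mean(pred == labels))]
    return _result_from_counts(confusion, acc, len(labels), n_classes, 1)


def _derive(seed):
    if seed is None:
        return None
    return int(np.random.default_rng(seed).integers(2**31 - 1))


# -- leave-one-subject-out harnesses --------------------------------------

def evaluate_logreg(
    pt: PhaseTensor,
    held_out_subject,
    cfg: CorrelationFeatureConfig = None,
    seed=None,
) -> ClassificationResult:
    """Leave-one-subject-out logistic-regression decoding."""
    cfg = cfg or CorrelationFeatureConfig()
    train_idx = [i for i, t in enumerate(pt.trial_index) if t[0] != held_out_subject]
    test_idx = [i for i, t in enumerate(pt.trial_index) if t[0] == held_out_subject]
    if not train_idx or not test_idx:
        raise ValidationError("hold-out split left an empty train or test set")
    train_pt = pt.select_trials(train_idx)
    test_pt = pt.select_trials(test_idx)
    templates = build_component_templates(train_pt)
    X_tr, y_tr = extract_features(train_pt, templates, cfg.windows)
    X_te, y_te = extract_features(test_pt, templates, cfg.windows)
    model = train_logreg_ova(X_tr, y_tr, cfg, seed=seed)
    return evaluate_model(model, X_te, y_te, len(templates.class_ids))


def train_fcnn(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: NetworkConfig = None,
    seed=None,
    validation=None,
) -> FullyConnectedClassifier:
    """Train the fully connected network per the configured schedule.

    ``validation`` is an optional (X_val, y_val) pair used for periodic
    validation and early stopping; the best-validation weights are returned.
    """
    cfg = cfg or NetworkConfig()
    features = np.asarray(features, float)
    labels = np.asarray(labels, int)
    n_classes = int(labels.max()) + 1
    net = FullyConnectedClassifier(
        n_features=features.shape[1],
        n_classes=n_classes,
        hidden=cfg.hidden,
        elu_alpha=cfg.elu_alpha,
        dropout=cfg.dropout,
        seed=seed,
    )
    X_val, y_val = validation if validation is not None else (None, None)
    net.fit(
        features, labels, X_val, y_val,
        epochs=cfg.epochs, batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate, momentum=cfg.momentum,
        val_every=cfg.val_every, patience=cfg.patience,
    )
    return net


def evaluate_fcnn(
    pt: PhaseTensor,
    held_out_subject,
    net_cfg: NetworkConfig = None,
    seed=None,
) -> ClassificationResult:
    """Leave-one-subject-out network decoding with electrode-as-sample training.

    Training data from the non-held-out subjects is restructured so each
    electrode contributes an independent sample; a seeded subject fold
    (about 1/cv_folds of the training subjects, at least one) is held aside
    for early-stopping validation.  Test features use the standard
    electrode-averaged full-window correlation features.
    """
    net_cfg = net_cfg or NetworkConfig()
    train_idx = [i for i, t in enumerate(pt.trial_index) if t[0] != held_out_subject]
    test_idx = [i for i, t in enumerate(pt.trial_index) if t[0] == held_out_subject]
    if not train_idx or not test_idx:
        raise ValidationError("hold-out split left an empty train or test set")
    train_pt = pt.select_trials(train_idx)
    test_pt = pt.select_trials(test_idx)
    templates = build_component_templates(train_pt)

    subjects = list(dict.fromkeys(t[0] for t in train_pt.trial_index))
    rng = np.random.default_rng(_derive(seed))
    n_val = max(1, round(len(subjects) / net_cfg.cv_folds))
    val_subjects = set(
        np.asarray(subjects)[rng.choice(len(subjects), size=n_val, replace=False)]
    )

    pooled = restructure_electrodes_as_samples(train_pt)
    X, y = extract_features(pooled, templates, windows=("full",))
    is_val = np.asarray([t[0] in val_subjects for t in pooled.trial_index])
    net = train_fcnn(
        X[~is_val], y[~is_val], net_cfg, seed=_derive(seed),
        validation=(X[is_val], y[is_val]),
    )
    X_te, y_te = extract_features(test_pt, templates, windows=("full",))
    return evaluate_model(net, X_te, y_te, len(templates.class_ids))
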