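"""Leakage-safe evaluation harness.

Protocol: stratified k-fold split of the pooled dataset, oversampling applied
to the training fold only, classifiers fit on the augmented fold and scored on
the untouched test fold; the whole procedure repeated with fresh random fold
assignments. Scores are the class-frequency-weighted F1 / recall / precision

    F1 = Σ_i 2 w_i P_i R_i / (P_i + R_i),   w_i = n_i / N  (from y_true),

with a per-class term of 0 whenever P_i + R_i = 0 and precision 0 for classes
never predicted. Under these weights the weighted recall equals plain
accuracy.

Every (repetition, fold, method) run passes through ``leakage_guard``; a
guard failure raises, because a leaking harness invalidates every score it
produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .datasets import FeatureDataset, SamplerSpec, make_rng
from .hybrids import HYBRID_CONSTITUENTS, hybrid_oversample, leakage_guard
from .samplers import oversample

__all__ = [
    "weighted_scores",
    "ScoreReport",
    "make_folds",
    "default_classifiers",
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
]


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass
class ScoreReport:
    """Weighted scores plus the per-class precision/recall/F1 table."""

    weighted_f1: float
    weighted_recall: float
    weighted_precision: float
    per_class: pd.DataFrame  # index = class name; columns: n, precision, recall, f1


def weighted_scores(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    class_names: Sequence[str],
) -> ScoreReport:
    """Class-frequency-weighted F1, recall and precision.

    ``y_true``/``y_pred`` are integer label arrays indexing ``class_names``.
    Weights come from the true labels; classes absent from ``y_true`` get
    weight 0 and thus never contribute.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) == 0:
        raise ValueError("empty label sequences")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    k = len(class_names)
    n_i = np.bincount(y_true, minlength=k).astype(float)
    N = n_i.sum()
    tp = np.zeros(k)
    pred_pos = np.bincount(y_pred, minlength=k).astype(float)
    for c in range(k):
        tp[c] = float(np.sum((y_true == c) & (y_pred == c)))
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_pos > 0, tp / np.maximum(pred_pos, 1e-300), 0.0)
        recall = np.where(n_i > 0, tp / np.maximum(n_i, 1e-300), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.maximum(pr, 1e-300), 0.0)
    w = n_i / N
    per_class = pd.DataFrame(
        {"n": n_i.astype(int), "precision": precision, "recall": recall, "f1": f1},
        index=list(class_names),
    )
    return ScoreReport(
        weighted_f1=float(np.sum(w * f1)),
        weighted_recall=float(np.sum(w * recall)),
        weighted_precision=float(np.sum(w * precision)),
        per_class=per_class,
    )


# ---------------------------------------------------------------------------
# folding
# ---------------------------------------------------------------------------

def make_folds(
    ds: FeatureDataset, n_folds: int, rng
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified folds with shuffled assignment.

    Test sets are pairwise disjoint and cover every row. Every class must
    have at least ``n_folds`` members; the error names the first class that
    does not.
    """
    counts = np.bincount(ds.y, minlength=len(ds.class_names))
    for c, k in zip(ds.class_names, counts):
        if 0 < k < n_folds:
            raise ValueError(
                f"class {c!r} has only {int(k)} rows; cannot stratify into "
                f"{n_folds} folds"
            )
    seed = int(make_rng(rng).integers(2**31))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(ds.X, ds.y)]


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def default_classifiers() -> dict[str, Callable[[int], object]]:
    """The pluggable classifier roster: name -> factory(seed) -> estimator.

    KNN, LR, SVM and RF use library defaults (LR gets a raised iteration cap
    so it converges on small feature tables). The MLP uses one hidden layer of
    100 ReLU units, Adam, learning rate 0.001, L2 penalty and 200 epochs.
    """
    return {
        "knn": lambda seed: KNeighborsClassifier(),
        "lr": lambda seed: LogisticRegression(max_iter=1000),
        "svm": lambda seed: SVC(random_state=seed),
        "rf": lambda seed: RandomForestClassifier(random_state=seed),
        "mlp": lambda seed: MLPClassifier(
            hidden_layer_sizes=(100,),
            activation="relu",
            solver="adam",
            learning_rate_init=0.001,
            alpha=0.0001,  # L2 penalty
            max_iter=200,
            random_state=seed,
        ),
    }


# ---------------------------------------------------------------------------
# experiment
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """One pooled-subject cross-validation experiment.

    ``samplers`` are method names ("baseline" = no resampling, single methods,
    or hybrids). Defaults follow the evaluation protocol: 3 folds, 30
    repetitions with different random fold assignments.
    """

    samplers: tuple[str, ...] = ("baseline",)
    classifiers: tuple[str, ...] = ("mlp",)
    n_folds: int = 3
    n_repetitions: int = 30
    seed: int = 0
    alpha: float = 1.0
    k_neighbors: int = 5
    max_levels: int = 5
    theta: float = 1.0
    cluster_threshold_factor: float = 3.0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


@dataclass
class ExperimentResult:
    """Aggregated and raw scores of one experiment.

    ``f1_mean`` etc. are classifiers × samplers DataFrames (mean over folds,
    then over repetitions). ``raw`` maps (classifier, sampler) to an
    (n_repetitions, n_folds) array of weighted F1 values; ``per_class_f1``
    maps the same key to the mean per-class F1 vector. Cells whose classifier
    failed to fit hold NaN and an entry in ``errors``.
    """

    config: ExperimentConfig
    class_names: tuple[str, ...]
    f1_mean: pd.DataFrame
    f1_sd: pd.DataFrame
    recall_mean: pd.DataFrame
    precision_mean: pd.DataFrame
    raw: dict[tuple[str, str], np.ndarray]
    per_class_f1: dict[tuple[str, str], np.ndarray]
    leakage_checks: int
    leakage_failures: int
    errors: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def score_matrix(self, metric: str = "f1") -> pd.DataFrame:
        return {"f1": self.f1_mean, "recall": self.recall_mean, "precision": self.precision_mean}[metric]


def _resample_train(train: FeatureDataset, name: str, cfg: ExperimentConfig, rng):
    """Returns (augmented_train, batches) for one sampler name."""
    if name == "baseline":
        return train, ()
    if name in HYBRID_CONSTITUENTS:
        res = hybrid_oversample(
            train,
            name,
            alpha=cfg.alpha,
            rng=rng,
            k_neighbors=cfg.k_neighbors,
            max_levels=cfg.max_levels,
            theta=cfg.theta,
            cluster_threshold_factor=cfg.cluster_threshold_factor,
        )
        return res.augmented_train, res.batches
    spec = SamplerSpec(
        name,
        k_neighbors=cfg.k_neighbors,
        alpha=cfg.alpha,
        max_levels=cfg.max_levels,
        theta=cfg.theta,
        cluster_threshold_factor=cfg.cluster_threshold_factor,
    )
    augmented, batch, _ = oversample(train, spec, rng)
    return augmented, (batch,)


def run_experiment(ds: FeatureDataset, cfg: ExperimentConfig) -> ExperimentResult:
    """Fold → oversample the training fold only → fit → score, repeated.

    Deterministic: every source of randomness (fold assignment, sampler
    draws, classifier initialisation) derives from ``cfg.seed``. Raises if
    the leakage guard fails on any fold.
    """
    k_classes = len(ds.class_names)
    f1_raw = {
        (clf, s): np.full((cfg.n_repetitions, cfg.n_folds), np.nan)
        for clf in cfg.classifiers
        for s in cfg.samplers
    }
    rec_raw = {k: np.full((cfg.n_repetitions, cfg.n_folds), np.nan) for k in f1_raw}
    prec_raw = {k: np.full((cfg.n_repetitions, cfg.n_folds), np.nan) for k in f1_raw}
    pcf1_acc = {k: np.zeros(k_classes) for k in f1_raw}
    pcf1_cnt = {k: 0 for k in f1_raw}
    errors: dict[tuple[str, str], list[str]] = {}
    factories = default_classifiers()
    unknown = [c for c in cfg.classifiers if c not in factories]
    if unknown:
        raise ValueError(f"unknown classifier(s) {unknown}; available: {sorted(factories)}")

    master = np.random.SeedSequence(cfg.seed)
    rep_seeds = master.spawn(cfg.n_repetitions)
    leakage_checks = 0
    leakage_failures = 0
    for r, rep_ss in enumerate(rep_seeds):
        rep_rng = np.random.default_rng(rep_ss)
        folds = make_folds(ds, cfg.n_folds, rep_rng)
        for f, (tr_idx, te_idx) in enumerate(folds):
            train, test = ds.subset(tr_idx), ds.subset(te_idx)
            for s_name in cfg.samplers:
                sampler_rng = np.random.default_rng(
                    np.random.SeedSequence(
                        entropy=cfg.seed, spawn_key=(1, r, f, cfg.samplers.index(s_name))
                    )
                )
                augmented, batches = _resample_train(train, s_name, cfg, sampler_rng)
                report = leakage_guard(train, test, augmented, batches)
                leakage_checks += 1
                if not report.passed:
                    leakage_failures += 1
                    raise AssertionError(
                        f"leakage guard failed (rep {r}, fold {f}, sampler {s_name}): "
                        + "; ".join(report.failures[:3])
                    )
                for c_name in cfg.classifiers:
                    clf_seed = int(
                        np.random.default_rng(
                            np.random.SeedSequence(
                                entropy=cfg.seed,
                                spawn_key=(2, r, f, cfg.samplers.index(s_name),
                                           cfg.classifiers.index(c_name)),
                            )
                        ).integers(2**31)
                    )
                    est = factories[c_name](clf_seed)
                    key = (c_name, s_name)
                    try:
                        est.fit(augmented.X, augmented.y)
                        pred = est.predict(test.X)
                    except Exception as exc:  # noqa: BLE001 - cell marked missing
                        errors.setdefault(key, []).append(f"rep {r} fold {f}: {exc}")
                        continue
                    sc = weighted_scores(test.y, pred, ds.class_names)
                    f1_raw[key][r, f] = sc.weighted_f1
                    rec_raw[key][r, f] = sc.weighted_recall
                    prec_raw[key][r, f] = sc.weighted_precision
                    pcf1_acc[key] += sc.per_class["f1"].to_numpy()
                    pcf1_cnt[key] += 1

    def table(raw: dict, stat: str) -> pd.DataFrame:
        data = {}
        for s in cfg.samplers:
            col = []
            for clf in cfg.classifiers:
                per_rep = np.nanmean(raw[(clf, s)], axis=1)
                col.append(np.nanmean(per_rep) if stat == "mean" else np.nanstd(per_rep))
            data[s] = col
        return pd.DataFrame(data, index=list(cfg.classifiers))

    per_class_f1 = {
        k: (pcf1_acc[k] / pcf1_cnt[k] if pcf1_cnt[k] else np.full(k_classes, np.nan))
        for k in pcf1_acc
    }
    return ExperimentResult(
        config=cfg,
        class_names=ds.class_names,
        f1_mean=table(f1_raw, "mean"),
        f1_sd=table(f1_raw, "sd"),
        recall_mean=table(rec_raw, "mean"),
        precision_mean=table(prec_raw, "mean"),
        raw=f1_raw,
        per_class_f1=per_class_f1,
        leakage_checks=leakage_checks,
        leakage_failures=leakage_failures,
        errors=errors,
    )
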