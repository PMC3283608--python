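"""Performance metrics and cross-validation protocols.

Overall accuracy is the exact ratio of correctly predicted samples to all
tested samples; per-class stability is measured by the Matthews correlation
coefficient computed one-vs-rest from the confusion counts::

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with the conventional value 0 when any marginal factor vanishes.  Per-class
ACC is the within-class coverage TP/(TP+FN), the form in which family-
classification studies report per-class success rates.

The jackknife (leave-one-out) protocol follows the two-step convention of
this literature: hyperparameters (C, gamma) are selected once on the full
dataset by 5-fold grid search, then each sample in turn is predicted by a
model retrained on the remaining samples with those hyperparameters held
fixed.  This keeps the jackknife unique and deterministic.  A strict mode
re-searches inside every fold for a leakage-free estimate; it is off by
default and flagged in the report.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold

from .encoding import PhysChemEncoder
from .exceptions import EmptyEvaluation, TooFewSamples
from .model import (
    GridSearchResult,
    ModelConfig,
    TwoLevelNRClassifier,
    grid_search,
    _make_pipeline,
)
from .properties import PROPERTY_IDS
from .seqio import NON_NR_LABEL, SUBFAMILIES, SequenceDataset


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a designated positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion_counts(y_true, y_pred, positive) -> ConfusionCounts:
    yt = np.asarray(y_true, dtype=object) == positive
    yp = np.asarray(y_pred, dtype=object) == positive
    return ConfusionCounts(
        TP=int((yt & yp).sum()),
        TN=int((~yt & ~yp).sum()),
        FP=int((~yt & yp).sum()),
        FN=int((yt & ~yp).sum()),
    )


def accuracy(n_correct: int, n_total: int) -> float:
    """Exact overall accuracy, the fraction correct/total."""
    if n_total < 1:
        raise EmptyEvaluation("cannot compute accuracy over zero samples")
    if not 0 <= n_correct <= n_total:
        raise ValueError("n_correct must lie in [0, n_total]")
    return n_correct / n_total


def format_percent(fraction: float) -> str:
    """Render a fraction the way success rates are reported: '98.16%'."""
    return f"{100.0 * fraction:.2f}%"


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient with the 0-on-degenerate convention."""
    marginals = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if marginals == 0:
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / math.sqrt(marginals)


@dataclass
class ClassMetrics:
    acc: float  # within-class coverage TP/(TP+FN)
    mcc: float
    counts: ConfusionCounts


@dataclass
class EvalReport:
    """Aggregated evaluation with raw per-sample predictions retained."""

    protocol: str
    ids: list[str]
    y_true: list[str]
    y_pred: list[str]
    per_class: dict[str, ClassMetrics] = field(default_factory=dict)
    overall_acc: float = 0.0
    overall_mcc: float = 0.0
    hyperparams: dict = field(default_factory=dict)
    strict_search: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def n_evaluated(self) -> int:
        return len(self.y_true)

    def validate(self) -> None:
        """Self-consistency: stored aggregates match brute-force recomputation."""
        correct = sum(t == p for t, p in zip(self.y_true, self.y_pred))
        assert self.overall_acc == accuracy(correct, self.n_evaluated)
        for label, m in self.per_class.items():
            c = confusion_counts(self.y_true, self.y_pred, label)
            assert m.counts == c and m.mcc == mcc(c)
            assert c.total == self.n_evaluated

    def to_rows(self) -> list[tuple[str, str, str]]:
        """(class, ACC, MCC) rows plus an overall row, report-style."""
        rows = [
            (label, format_percent(m.acc), f"{m.mcc:.2f}")
            for label, m in self.per_class.items()
        ]
        rows.append(("Overall", format_percent(self.overall_acc), f"{self.overall_mcc:.2f}"))
        return rows


def _build_report(protocol, ids, y_true, y_pred, hyperparams, class_order=None,
                  strict_search=False, warn=()) -> EvalReport:
    y_true = list(y_true)
    y_pred = list(y_pred)
    if not y_true:
        raise EmptyEvaluation("no samples evaluated")
    labels = class_order if class_order is not None else sorted(set(y_true))
    per_class = {}
    for label in labels:
        c = confusion_counts(y_true, y_pred, label)
        cov = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else float("nan")
        per_class[label] = ClassMetrics(acc=cov, mcc=mcc(c), counts=c)
    correct = sum(t == p for t, p in zip(y_true, y_pred))
    overall_acc = accuracy(correct, len(y_true))
    if len(set(y_true) | set(y_pred)) <= 1:
        overall_mcc = 0.0
    else:
        overall_mcc = float(matthews_corrcoef(y_true, y_pred))
    return EvalReport(
        protocol=protocol,
        ids=list(ids),
        y_true=y_true,
        y_pred=y_pred,
        per_class=per_class,
        overall_acc=overall_acc,
        overall_mcc=overall_mcc,
        hyperparams=hyperparams,
        strict_search=strict_search,
        warnings=list(warn),
    )


def _class_order(y) -> list[str]:
    order = [NON_NR_LABEL] + list(SUBFAMILIES)
    present = set(y)
    return [l for l in order if l in present]


@dataclass
class LabeledFeatures:
    """Feature matrix with manifest labels, the unit evaluation works on."""

    ids: list[str]
    X: np.ndarray
    y: list[str]

    def __len__(self) -> int:
        return len(self.y)


def encode_dataset(dataset: SequenceDataset, encoder: PhysChemEncoder | None = None) -> LabeledFeatures:
    encoder = encoder or PhysChemEncoder()
    encoder.fit()
    return LabeledFeatures(
        ids=list(dataset.ids), X=encoder.transform(dataset.sequences), y=list(dataset.labels)
    )


def select_hyperparams(data: LabeledFeatures, cfg: ModelConfig) -> dict[int, GridSearchResult]:
    """Grid-search (C, gamma) once per level on the full dataset."""
    y = np.asarray(data.y, dtype=object)
    y1 = (y != NON_NR_LABEL).astype(int)
    params = {1: grid_search(data.X, y1, cfg)}
    nr = y != NON_NR_LABEL
    if nr.any() and len(set(y[nr])) >= 2:
        params[2] = grid_search(data.X[nr], y[nr], cfg)
    else:
        params[2] = params[1]  # degenerate: no multi-class task to tune
    return params


def _fit_predict_two_level(X_tr, y_tr, X_te, cfg, fixed) -> np.ndarray:
    clf = TwoLevelNRClassifier(
        C_grid=cfg.C_grid,
        gamma_grid=cfg.gamma_grid,
        cv_folds=cfg.cv_folds,
        random_state=cfg.rng_seed,
        feature_scaling=cfg.feature_scaling,
        class_weight=cfg.class_weight,
    )
    clf.fit(X_tr, y_tr, search=fixed)
    return clf.predict(X_te)


def jackknife(
    data: LabeledFeatures,
    cfg: ModelConfig | None = None,
    fixed_params: dict[int, GridSearchResult] | None = None,
    strict_search: bool = False,
) -> EvalReport:
    """Leave-one-out evaluation of the two-level flow.

    Every sample is predicted by a model retrained on the other n-1 samples
    with (C, gamma) fixed per level (selected once on the full dataset
    unless supplied).  With ``strict_search`` the grid search is instead
    repeated inside every fold.
    """
    cfg = cfg or ModelConfig()
    if len(data) < 3:
        raise TooFewSamples("jackknife needs at least 3 samples")
    if fixed_params is None and not strict_search:
        fixed_params = select_hyperparams(data, cfg)

    y = np.asarray(data.y, dtype=object)
    warn: list[str] = []
    preds = []
    for i in range(len(data)):
        mask = np.ones(len(data), dtype=bool)
        mask[i] = False
        y_tr = y[mask]
        nr_tr = y_tr[y_tr != NON_NR_LABEL]
        if len(set(nr_tr)) < len(set(y[y != NON_NR_LABEL])):
            warn.append(f"fold {i}: training slice lost a level-2 class; proceeding")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if strict_search:
                sub = LabeledFeatures(
                    ids=[d for d, m in zip(data.ids, mask) if m], X=data.X[mask], y=list(y_tr)
                )
                fold_params = select_hyperparams(sub, cfg)
            else:
                fold_params = fixed_params
            preds.append(
                _fit_predict_two_level(data.X[mask], y_tr, data.X[i : i + 1], cfg, fold_params)[0]
            )
    hyper = (
        {}
        if strict_search
        else {lvl: p.__dict__ for lvl, p in fixed_params.items()}
    )
    return _build_report(
        "jackknife", data.ids, data.y, preds, hyper,
        class_order=_class_order(data.y), strict_search=strict_search, warn=warn,
    )


def kfold(
    data: LabeledFeatures,
    cfg: ModelConfig | None = None,
    k: int = 5,
    fixed_params: dict[int, GridSearchResult] | None = None,
) -> EvalReport:
    """Stratified k-fold evaluation with the same aggregation as jackknife.

    ``k == n`` degenerates to the leave-one-out partition.
    """
    cfg = cfg or ModelConfig()
    if k < 2:
        raise TooFewSamples("k must be >= 2")
    if len(data) < k:
        raise TooFewSamples(f"{len(data)} samples cannot fill {k} folds")
    if fixed_params is None:
        fixed_params = select_hyperparams(data, cfg)
    if k == len(data):
        report = jackknife(data, cfg, fixed_params=fixed_params)
        report.protocol = f"kfold({k})"
        return report

    y = np.asarray(data.y, dtype=object)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.rng_seed)
    y_pred = np.empty(len(data), dtype=object)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tr, te in splitter.split(data.X, y):
            y_pred[te] = _fit_predict_two_level(data.X[tr], y[tr], data.X[te], cfg, fixed_params)
    return _build_report(
        f"kfold({k})", data.ids, data.y, y_pred, {l: p.__dict__ for l, p in fixed_params.items()},
        class_order=_class_order(data.y),
    )


# -- single-task jackknife used by the property-impact ranking -------------

def _task_jackknife_accuracy(X, y, cfg: ModelConfig) -> float:
    """LOO accuracy of a single SVM task with freshly grid-searched params."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params = grid_search(X, y, cfg)
        correct = 0
        for i in range(len(y)):
            mask = np.ones(len(y), dtype=bool)
            mask[i] = False
            pipe = _make_pipeline(params.C, params.gamma, cfg)
            pipe.fit(X[mask], y[mask])
            correct += int(pipe.predict(X[i : i + 1])[0] == y[i])
    return accuracy(correct, len(y))


@dataclass(frozen=True)
class ImpactEntry:
    property_id: str
    accuracy_drop: float
    rank: int  # competition ranking; equal drops share a rank


def rank_property_impact(
    dataset: SequenceDataset,
    cfg: ModelConfig | None = None,
    level: int = 1,
    max_lag: int = 10,
) -> list[ImpactEntry]:
    """Leave-one-property-out impact ranking.

    For each of the ten property scales the dataset is re-encoded with the
    nine remaining scales (feature dimension 81 * max_lag), hyperparameters
    are re-searched, and the level's task is evaluated by jackknife; the
    impact of a property is the drop of overall accuracy relative to the
    ten-property baseline.  The property whose removal drops the success
    rate the most ranks first; exactly equal drops share a rank.

    ``level=1`` ranks on the binary NR/non-NR task over all samples;
    ``level=2`` on the subfamily task over NR samples only.
    """
    cfg = cfg or ModelConfig()
    if level not in (1, 2):
        raise ValueError("level must be 1 or 2")

    y_all = np.asarray(dataset.labels, dtype=object)
    if level == 1:
        seqs = list(dataset.sequences)
        y = (y_all != NON_NR_LABEL).astype(int)
    else:
        keep = y_all != NON_NR_LABEL
        seqs = [s for s, k in zip(dataset.sequences, keep) if k]
        y = y_all[keep]
        if len(set(y)) < 2:
            raise TooFewSamples("level-2 ranking needs >= 2 subfamilies")

    def acc_for(property_ids) -> float:
        enc = PhysChemEncoder(max_lag=max_lag, property_ids=property_ids).fit()
        return _task_jackknife_accuracy(enc.transform(seqs), y, cfg)

    baseline = acc_for(None)
    drops = []
    for p in PROPERTY_IDS:
        remaining = [q for q in PROPERTY_IDS if q != p]
        drops.append((p, baseline - acc_for(remaining)))

    drops.sort(key=lambda t: (-t[1], PROPERTY_IDS.index(t[0])))
    entries: list[ImpactEntry] = []
    for pos, (p, drop) in enumerate(drops):
        if entries and drop == drops[pos - 1][1]:
            rank = entries[-1].rank
        else:
            rank = pos + 1
        entries.append(ImpactEntry(property_id=p, accuracy_drop=drop, rank=rank))
    return entries
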