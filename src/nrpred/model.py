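"""Two-level RBF-SVM classifier for nuclear-receptor identification.

Level 1 is a binary support-vector machine separating nuclear receptors
(NR) from non-receptors over all training samples; level 2 is a
multi-class SVM (libsvm's pairwise one-vs-one voting) over the NR samples
only, assigning one of the seven subfamilies NR1..NR6, NR0.  Both levels
use the RBF kernel, per-feature z-scoring fitted on their own training
slice, and hyperparameters (C, gamma) chosen independently per level by a
2-D grid search maximizing mean stratified 5-fold cross-validation
accuracy.  Ties in the grid prefer smaller C, then smaller gamma (the
smoother model); fold assignment is seeded, so the whole pipeline is
deterministic for a fixed dataset and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import __version__
from .encoding import EncoderConfig, PhysChemEncoder, ProteinSequence, sanitize_sequence
from .exceptions import BatchTooLarge, ModelMismatch, NrpredError, TooFewSamples
from .seqio import NON_NR_LABEL, SUBFAMILIES, SequenceDataset

#: Maximum query sequences per prediction batch.
BATCH_CAP = 500

#: Default 2-D search grids: C = 2^-5..2^15, gamma = 2^-15..2^3 (steps of 2^2).
DEFAULT_C_GRID: tuple[float, ...] = tuple(float(2.0**k) for k in range(-5, 16, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(float(2.0**k) for k in range(-15, 4, 2))

_SUBFAMILY_INDEX = {s: i for i, s in enumerate(SUBFAMILIES)}


@dataclass(frozen=True)
class ClassLabel:
    """Two-level prediction: NR/non-NR, plus subfamily when NR."""

    level1: str  # "NR" or "non-NR"
    level2: str | None = None  # subfamily, present iff level1 == "NR"

    def __post_init__(self):
        if (self.level1 == "NR") != (self.level2 is not None):
            raise ValueError("level2 must be present exactly when level1 == 'NR'")

    def __str__(self) -> str:
        return "non-NR" if self.level2 is None else f"NR:{self.level2}"


@dataclass(frozen=True)
class ModelConfig:
    """Training configuration (grids, CV folds, seed, scaling)."""

    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    cv_folds: int = 5
    rng_seed: int = 0
    feature_scaling: bool = True
    class_weight: str | None = None  # None or "balanced"

    def __post_init__(self):
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("grids must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass(frozen=True)
class GridSearchResult:
    C: float
    gamma: float
    cv_accuracy: float
    n_folds: int


def _make_pipeline(C: float, gamma: float, cfg: ModelConfig) -> Pipeline:
    steps = []
    if cfg.feature_scaling:
        steps.append(("scale", StandardScaler()))
    steps.append(
        ("svm", SVC(C=C, gamma=gamma, kernel="rbf", class_weight=cfg.class_weight))
    )
    return Pipeline(steps)


def _effective_folds(y: np.ndarray, cfg: ModelConfig) -> int:
    _, counts = np.unique(y, return_counts=True)
    smallest = int(counts.min())
    if smallest < 2:
        raise TooFewSamples(
            f"smallest class has {smallest} sample(s); at least 2 are required"
        )
    folds = min(cfg.cv_folds, smallest)
    if folds < cfg.cv_folds:
        warnings.warn(
            f"reducing CV folds from {cfg.cv_folds} to {folds} (smallest class size)"
        )
    return folds


def grid_search(X, y, cfg: ModelConfig | None = None) -> GridSearchResult:
    """Pick (C, gamma) maximizing mean stratified k-fold CV accuracy.

    Grid cells are visited with C ascending, then gamma ascending, and only
    a strictly better score replaces the incumbent — so exact ties resolve
    to the smallest C, then the smallest gamma.
    """
    cfg = cfg or ModelConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = _effective_folds(y, cfg)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.rng_seed)

    best: GridSearchResult | None = None
    for C in sorted(cfg.C_grid):
        for gamma in sorted(cfg.gamma_grid):
            pipe = _make_pipeline(C, gamma, cfg)
            score = float(cross_val_score(pipe, X, y, cv=splitter, scoring="accuracy").mean())
            if best is None or score > best.cv_accuracy + 1e-12:
                best = GridSearchResult(C=C, gamma=gamma, cv_accuracy=score, n_folds=folds)
    return best


class TwoLevelNRClassifier(BaseEstimator, ClassifierMixin):
    """Hierarchical NR / subfamily classifier over precomputed feature vectors.

    Parameters mirror :class:`ModelConfig`; ``fit`` expects ``y`` drawn from
    the closed vocabulary {nonNR, NR1..NR6, NR0} and trains the binary
    level-1 machine on all rows and the multi-class level-2 machine on the
    NR rows only, each with its own grid search and scaling statistics.

    Fitted attributes: ``level1_``, ``level2_`` (pipelines), ``level1_search_``,
    ``level2_search_`` (chosen C/gamma with CV score), ``classes_``,
    ``subfamilies_``, ``n_features_in_``.
    """

    def __init__(
        self,
        C_grid=DEFAULT_C_GRID,
        gamma_grid=DEFAULT_GAMMA_GRID,
        cv_folds: int = 5,
        random_state: int = 0,
        feature_scaling: bool = True,
        class_weight: str | None = None,
    ):
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.cv_folds = cv_folds
        self.random_state = random_state
        self.feature_scaling = feature_scaling
        self.class_weight = class_weight

    def _config(self) -> ModelConfig:
        return ModelConfig(
            C_grid=tuple(self.C_grid),
            gamma_grid=tuple(self.gamma_grid),
            cv_folds=self.cv_folds,
            rng_seed=self.random_state,
            feature_scaling=self.feature_scaling,
            class_weight=self.class_weight,
        )

    def fit(self, X, y, search: dict[int, GridSearchResult] | None = None):
        """Fit both levels.

        ``search`` may supply pre-selected per-level hyperparameters
        (keys 1 and 2), in which case the grid search is skipped — this is
        how the jackknife protocol retrains with fixed (C, gamma).
        """
        cfg = self._config()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.unique(y)

        is_nr = y != NON_NR_LABEL
        if not is_nr.any():
            raise NrpredError("training data contains no NR samples")
        if is_nr.all():
            raise NrpredError("training data contains no non-NR samples")
        y1 = is_nr.astype(int)  # 1 = NR

        nr_labels = y[is_nr]
        self.subfamilies_ = tuple(sorted(set(nr_labels), key=_SUBFAMILY_INDEX.__getitem__))
        if len(self.subfamilies_) < 2:
            raise NrpredError("NR samples must cover at least 2 subfamilies")
        # canonical integer codes => libsvm's one-vs-one vote ties resolve to
        # the lowest index in NR1..NR6, NR0 order
        y2 = np.array([_SUBFAMILY_INDEX[l] for l in nr_labels])

        if search is None:
            self.level1_search_ = grid_search(X, y1, cfg)
            self.level2_search_ = grid_search(X[is_nr], y2, cfg)
        else:
            self.level1_search_ = search[1]
            self.level2_search_ = search[2]

        self.level1_ = _make_pipeline(self.level1_search_.C, self.level1_search_.gamma, cfg)
        self.level1_.fit(X, y1)
        self.level2_ = _make_pipeline(self.level2_search_.C, self.level2_search_.gamma, cfg)
        self.level2_.fit(X[is_nr], y2)
        return self

    def predict(self, X) -> np.ndarray:
        """Manifest-vocabulary labels: 'nonNR' or a subfamily code."""
        X = np.asarray(X, dtype=float)
        p1 = self.level1_.predict(X)
        out = np.full(X.shape[0], NON_NR_LABEL, dtype=object)
        nr_mask = p1 == 1
        if nr_mask.any():
            codes = self.level2_.predict(X[nr_mask])
            out[nr_mask] = [SUBFAMILIES[c] for c in codes]
        return out

    def predict_labels(self, X) -> list[ClassLabel]:
        """Two-level :class:`ClassLabel` objects instead of flat strings."""
        return [
            ClassLabel("non-NR") if l == NON_NR_LABEL else ClassLabel("NR", l)
            for l in self.predict(X)
        ]


@dataclass
class TwoLevelModel:
    """A trained classifier bundled with its encoder and provenance."""

    classifier: TwoLevelNRClassifier
    encoder: PhysChemEncoder
    table_version: str
    config: ModelConfig
    metadata: dict = field(default_factory=dict)

    @property
    def level1_params(self) -> GridSearchResult:
        return self.classifier.level1_search_

    @property
    def level2_params(self) -> GridSearchResult:
        return self.classifier.level2_search_


def train(dataset: SequenceDataset, cfg: ModelConfig | None = None,
          encoder: PhysChemEncoder | None = None) -> TwoLevelModel:
    """Encode a labeled sequence dataset and fit the two-level classifier."""
    cfg = cfg or ModelConfig()
    encoder = encoder or PhysChemEncoder()
    encoder.fit()
    X = encoder.transform(dataset.sequences)
    clf = TwoLevelNRClassifier(
        C_grid=cfg.C_grid,
        gamma_grid=cfg.gamma_grid,
        cv_folds=cfg.cv_folds,
        random_state=cfg.rng_seed,
        feature_scaling=cfg.feature_scaling,
        class_weight=cfg.class_weight,
    )
    clf.fit(X, np.asarray(dataset.labels, dtype=object))
    return TwoLevelModel(
        classifier=clf,
        encoder=encoder,
        table_version=encoder.table_.version,
        config=cfg,
        metadata={
            "n_samples": len(dataset),
            "seed": cfg.rng_seed,
            "level1": clf.level1_search_.__dict__,
            "level2": clf.level2_search_.__dict__,
        },
    )


@dataclass(frozen=True)
class PredictionRecord:
    """Per-sequence outcome; ``error`` set when encoding failed for it."""

    id: str
    label: ClassLabel | None
    error: str | None = None


def predict(model: TwoLevelModel, seqs: list, batch_cap: int = BATCH_CAP) -> list[PredictionRecord]:
    """Two-level prediction for a batch of raw strings or ProteinSequences.

    Per-sequence encoder failures (too short, too ambiguous, empty) are
    reported in the corresponding record without aborting the batch; a
    batch larger than ``batch_cap`` is rejected outright.
    """
    if len(seqs) > batch_cap:
        raise BatchTooLarge(f"{len(seqs)} sequences exceed the batch cap of {batch_cap}")
    records: list[PredictionRecord] = []
    rows: list[np.ndarray] = []
    row_at: list[int] = []
    for k, s in enumerate(seqs):
        seq_id = s.id if isinstance(s, ProteinSequence) else f"query_{k + 1}"
        try:
            seq = s if isinstance(s, ProteinSequence) else sanitize_sequence(str(s), id=seq_id)
            rows.append(model.encoder.transform([seq])[0])
            row_at.append(k)
            records.append(PredictionRecord(id=seq.id or seq_id, label=None))
        except NrpredError as exc:
            records.append(PredictionRecord(id=seq_id, label=None, error=str(exc)))
    if rows:
        labels = model.classifier.predict_labels(np.asarray(rows))
        for k, lab in zip(row_at, labels):
            records[k] = PredictionRecord(id=records[k].id, label=lab)
    return records


# -- persistence -----------------------------------------------------------

_ARCHIVE_FORMAT = 1


def save_model(model: TwoLevelModel, path: str | Path) -> None:
    """Persist a trained model as a single joblib archive."""
    joblib.dump(
        {
            "format": _ARCHIVE_FORMAT,
            "package_version": __version__,
            "table_version": model.table_version,
            "encoder_params": model.encoder.get_params(),
            "encoder_max_lag": model.encoder.max_lag,
            "model": model,
        },
        path,
    )


def load_model(path: str | Path, encoder_config: EncoderConfig | None = None) -> TwoLevelModel:
    """Load an archive, refusing encoder-config or format mismatches."""
    payload = joblib.load(path)
    if payload.get("format") != _ARCHIVE_FORMAT:
        raise ModelMismatch(f"unsupported archive format {payload.get('format')!r}")
    expected = encoder_config or EncoderConfig()
    if payload["encoder_max_lag"] != expected.max_lag:
        raise ModelMismatch(
            f"archive encoder max_lag={payload['encoder_max_lag']} does not match "
            f"running config max_lag={expected.max_lag}"
        )
    return payload["model"]
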