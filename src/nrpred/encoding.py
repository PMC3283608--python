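"""Sequence encoding: physicochemical matrix and auto/cross-covariance features.

A protein of length L is first mapped to a 10 x L matrix M whose row i holds
the standardized value of property PC^i at each residue.  The fixed-length
descriptor is then built from lagged covariances of the rows:

* auto-covariance, same property i at positions j and j+g::

      AC(i, g) = 1/(L-g) * sum_{j=1..L-g} (M[i,j] - mu_i) (M[i,j+g] - mu_i)

* cross-covariance, two different properties i1 != i2::

      CC(i1, i2, g) = 1/(L-g) * sum_{j=1..L-g} (M[i1,j] - mu_i1) (M[i2,j+g] - mu_i2)

where mu_i is the mean of row i over the whole sequence.  CC is direction
dependent: CC(i1, i2, g) != CC(i2, i1, g) in general, and both directions
are kept.  With P properties and lags g = 1..LG this yields
P*LG + P*(P-1)*LG = P^2*LG components; the defaults (P=10, LG=10) give the
1000-dimensional pseudo amino acid composition used throughout.

Canonical component order (also the feature-matrix header order):
first the AC block, ordered by (property, lag); then the CC block, ordered
by (i1, i2 skipping i1==i2, lag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    AmbiguousResidue,
    EmptySequence,
    LagTooLarge,
    SameProperty,
    SequenceTooShort,
    TooManyAmbiguous,
)
from .properties import AMINO_ACIDS, PropertyTable, load_reference_table

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
#: Ambiguity/non-canonical codes that sanitization drops (or rejects in strict mode).
NON_CANONICAL = set("BJOUXZ*")


@dataclass(frozen=True)
class ProteinSequence:
    """A sanitized protein sequence over the 20 canonical one-letter codes."""

    id: str
    residues: str
    n_dropped: int = 0  # non-canonical residues removed during sanitization

    def __post_init__(self):
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-canonical residues in ProteinSequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class EncoderConfig:
    """Encoding parameters.

    max_lag is the largest positional separation LG used in the covariance
    transform; sequences must satisfy L >= max_lag + 1 so that every lag has
    at least one product term.  The feature dimension is P^2 * max_lag for P
    properties (1000 at the defaults).
    """

    max_lag: int = 10
    strict: bool = False  # reject rather than drop non-canonical residues

    def __post_init__(self):
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")

    @property
    def min_length(self) -> int:
        return self.max_lag + 1


@dataclass(frozen=True)
class FeatureTag:
    """Identity of one feature component."""

    kind: str  # "AC" or "CC"
    property_1: str
    property_2: str | None  # None for AC
    lag: int

    def __str__(self) -> str:
        if self.kind == "AC":
            return f"AC:{self.property_1}:lag{self.lag}"
        return f"CC:{self.property_1}:{self.property_2}:lag{self.lag}"


@dataclass
class PhysChemMatrix:
    """Per-sequence property matrix (n_properties x L) plus its row means."""

    values: np.ndarray
    row_means: np.ndarray
    property_ids: tuple[str, ...]

    @property
    def length(self) -> int:
        return self.values.shape[1]


def sanitize_sequence(raw: str, id: str = "", strict: bool = False) -> ProteinSequence:
    """Normalize a raw residue string to the canonical 20-letter alphabet.

    Uppercases, strips whitespace and digits, and drops non-canonical codes
    (B, J, O, U, X, Z, ``*``) with a warning; in strict mode any such code
    raises instead.  More than 10% non-canonical residues raises
    :class:`TooManyAmbiguous`.
    """
    stripped = "".join(ch for ch in raw if not ch.isspace())
    if not stripped:
        raise EmptySequence(f"sequence {id!r} is empty after whitespace removal")
    stripped = "".join(ch for ch in stripped if not ch.isdigit()).upper()
    if not stripped:
        raise EmptySequence(f"sequence {id!r} contains no residues")

    kept, dropped = [], 0
    for ch in stripped:
        if ch in _AA_INDEX:
            kept.append(ch)
        else:
            if strict:
                raise AmbiguousResidue(f"sequence {id!r}: non-canonical residue {ch!r}")
            dropped += 1
    if dropped > 0.10 * len(stripped):
        raise TooManyAmbiguous(
            f"sequence {id!r}: {dropped}/{len(stripped)} residues are non-canonical (>10%)"
        )
    if dropped:
        warnings.warn(f"sequence {id!r}: dropped {dropped} non-canonical residue(s)")
    if not kept:
        raise EmptySequence(f"sequence {id!r} has no canonical residues")
    return ProteinSequence(id=id, residues="".join(kept), n_dropped=dropped)


def build_matrix(
    seq: ProteinSequence,
    table: PropertyTable | None = None,
    property_ids=None,
) -> PhysChemMatrix:
    """Evaluate each standardized property scale along the sequence."""
    table = table or load_reference_table()
    ids = tuple(property_ids) if property_ids is not None else table.property_ids
    std = table.standardized_matrix(ids)  # (P, 20)
    idx = np.fromiter((_AA_INDEX[r] for r in seq.residues), dtype=np.intp, count=len(seq))
    values = std[:, idx]
    return PhysChemMatrix(values=values, row_means=values.mean(axis=1), property_ids=ids)


def _check_lag(m: PhysChemMatrix, g: int) -> None:
    if not 1 <= g:
        raise ValueError("lag must be >= 1")
    if g >= m.length:
        raise LagTooLarge(f"lag {g} >= sequence length {m.length}")


def auto_covariance(m: PhysChemMatrix, property_id: str, lag: int) -> float:
    """Lagged covariance of one property row with itself (see module docs)."""
    _check_lag(m, lag)
    i = m.property_ids.index(property_id)
    d = m.values[i] - m.row_means[i]
    return float(d[: m.length - lag] @ d[lag:] / (m.length - lag))


def cross_covariance(m: PhysChemMatrix, property_1: str, property_2: str, lag: int) -> float:
    """Lagged covariance between two different property rows (directional)."""
    if property_1 == property_2:
        raise SameProperty(f"{property_1!r} on both sides; use auto_covariance")
    _check_lag(m, lag)
    i1 = m.property_ids.index(property_1)
    i2 = m.property_ids.index(property_2)
    d1 = m.values[i1] - m.row_means[i1]
    d2 = m.values[i2] - m.row_means[i2]
    return float(d1[: m.length - lag] @ d2[lag:] / (m.length - lag))


def feature_tags(cfg: EncoderConfig | None = None, property_ids=None) -> list[FeatureTag]:
    """Canonical-order tags for every component of the feature vector."""
    cfg = cfg or EncoderConfig()
    ids = tuple(property_ids) if property_ids is not None else tuple(load_reference_table().property_ids)
    tags = [
        FeatureTag("AC", p, None, g)
        for p in ids
        for g in range(1, cfg.max_lag + 1)
    ]
    tags += [
        FeatureTag("CC", p1, p2, g)
        for p1 in ids
        for p2 in ids
        if p2 != p1
        for g in range(1, cfg.max_lag + 1)
    ]
    return tags


def encode(
    seq: ProteinSequence,
    cfg: EncoderConfig | None = None,
    table: PropertyTable | None = None,
    property_ids=None,
) -> np.ndarray:
    """Encode one sequence as its AC/CC feature vector (canonical order).

    Raises :class:`SequenceTooShort` if L <= max_lag, since the largest lag
    would then have an empty covariance sum.
    """
    cfg = cfg or EncoderConfig()
    if len(seq) < cfg.min_length:
        raise SequenceTooShort(
            f"sequence {seq.id!r}: length {len(seq)} < minimum {cfg.min_length} "
            f"(max lag {cfg.max_lag})"
        )
    m = build_matrix(seq, table=table, property_ids=property_ids)
    P, L = m.values.shape
    LG = cfg.max_lag
    d = m.values - m.row_means[:, None]

    ac = np.empty((P, LG))
    cc = np.empty((P, P, LG))
    for g in range(1, LG + 1):
        # cov[i1, i2] = 1/(L-g) sum_j d[i1, j] * d[i2, j+g]
        cov = d[:, : L - g] @ d[:, g:].T / (L - g)
        ac[:, g - 1] = np.diag(cov)
        cc[:, :, g - 1] = cov

    off = ~np.eye(P, dtype=bool)
    return np.concatenate([ac.ravel(), cc[off].reshape(P * (P - 1), LG).ravel()])


def encode_many(seqs, cfg=None, table=None, property_ids=None) -> np.ndarray:
    """Stack :func:`encode` over an iterable of sequences into an (n, d) array."""
    return np.asarray([encode(s, cfg=cfg, table=table, property_ids=property_ids) for s in seqs])


class PhysChemEncoder:
    """scikit-learn style transformer: protein sequences -> AC/CC features.

    Parameters
    ----------
    max_lag : int, default 10
        Largest lag LG of the covariance transform.
    property_ids : sequence of str or None
        Subset of property scales to use (None = all ten).  With P
        properties the output has P**2 * max_lag columns.
    table : PropertyTable or None
        Custom property table; None uses the embedded reference scales.
    strict : bool, default False
        Reject sequences containing non-canonical residues instead of
        dropping them.

    ``transform`` accepts raw strings or :class:`ProteinSequence` objects.
    """

    def __init__(self, max_lag: int = 10, property_ids=None, table=None, strict: bool = False):
        self.max_lag = max_lag
        self.property_ids = property_ids
        self.table = table
        self.strict = strict

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "max_lag": self.max_lag,
            "property_ids": self.property_ids,
            "table": self.table,
            "strict": self.strict,
        }

    def set_params(self, **params) -> "PhysChemEncoder":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ----------------------------------------------------------------------
    def fit(self, X=None, y=None) -> "PhysChemEncoder":
        self.table_ = self.table or load_reference_table()
        ids = self.property_ids if self.property_ids is not None else self.table_.property_ids
        self.property_ids_ = tuple(ids)
        self.config_ = EncoderConfig(max_lag=self.max_lag, strict=self.strict)
        self.feature_tags_ = feature_tags(self.config_, self.property_ids_)
        self.feature_names_ = [str(t) for t in self.feature_tags_]
        self.n_features_out_ = len(self.feature_tags_)
        return self

    def _as_sequence(self, x) -> ProteinSequence:
        if isinstance(x, ProteinSequence):
            return x
        return sanitize_sequence(str(x), strict=self.strict)

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "table_"):
            self.fit()
        seqs = [self._as_sequence(x) for x in X]
        return encode_many(
            seqs, cfg=self.config_, table=self.table_, property_ids=self.property_ids_
        )

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit().transform(X)
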