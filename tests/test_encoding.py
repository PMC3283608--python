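"""Sequence sanitization, the property matrix, and the AC/CC feature vector.

The covariance operations are pinned against an independent brute-force
oracle written as plain double loops over the matrix entries.
"""

import numpy as np
import pytest

from nrpred.encoding import (
    EncoderConfig,
    PhysChemEncoder,
    ProteinSequence,
    auto_covariance,
    build_matrix,
    cross_covariance,
    encode,
    feature_tags,
    sanitize_sequence,
)
from nrpred.exceptions import (
    AmbiguousResidue,
    EmptySequence,
    LagTooLarge,
    SameProperty,
    SequenceTooShort,
    TooManyAmbiguous,
)
from nrpred.properties import PROPERTY_IDS

from conftest import random_sequence


# -- independent oracle ----------------------------------------------------

def oracle_auto_cov(m, i, g):
    """Brute-force: mean over j of centered products at lag g, same row."""
    L = m.values.shape[1]
    mu = sum(m.values[i]) / L
    total = 0.0
    for j in range(L - g):
        total += (m.values[i][j] - mu) * (m.values[i][j + g] - mu)
    return total / (L - g)


def oracle_cross_cov(m, i1, i2, g):
    L = m.values.shape[1]
    mu1 = sum(m.values[i1]) / L
    mu2 = sum(m.values[i2]) / L
    total = 0.0
    for j in range(L - g):
        total += (m.values[i1][j] - mu1) * (m.values[i2][j + g] - mu2)
    return total / (L - g)


def oracle_encode(seq, table, max_lag=10):
    """Assemble the whole vector from the scalar oracles, canonical order."""
    m = build_matrix(seq, table)
    out = []
    for i, _ in enumerate(PROPERTY_IDS):
        for g in range(1, max_lag + 1):
            out.append(oracle_auto_cov(m, i, g))
    for i1 in range(len(PROPERTY_IDS)):
        for i2 in range(len(PROPERTY_IDS)):
            if i1 == i2:
                continue
            for g in range(1, max_lag + 1):
                out.append(oracle_cross_cov(m, i1, i2, g))
    return np.array(out)


# -- sanitization ----------------------------------------------------------

@pytest.mark.parametrize(
    "raw,expected",
    [
        ("acdEFG", "ACDEFG"),
        ("AC DE\n FG", "ACDEFG"),
        ("ac1de2", "ACDE"),
    ],
)
def test_sanitize_normalizes(raw, expected):
    seq = sanitize_sequence(raw)
    assert seq.residues == expected
    assert len(seq) == len(expected)
    assert seq.n_dropped == 0


def test_sanitize_drops_noncanonical_with_count():
    with pytest.warns(UserWarning, match="dropped 1"):
        seq = sanitize_sequence("ACXDEFGHIK")
    assert seq.residues == "ACDEFGHIK"
    assert seq.n_dropped == 1


def test_sanitize_strict_mode_rejects():
    with pytest.raises(AmbiguousResidue):
        sanitize_sequence("ACXDEFGHIK", strict=True)


def test_sanitize_too_many_ambiguous():
    with pytest.raises(TooManyAmbiguous):
        sanitize_sequence("AXXXC")


def test_sanitize_empty():
    with pytest.raises(EmptySequence):
        sanitize_sequence("  \n\t ")


# -- matrix ----------------------------------------------------------------

def test_matrix_shape_and_homopolymer(table):
    m = build_matrix(ProteinSequence("h", "A" * 30), table)
    assert m.values.shape == (10, 30)
    # every column identical; row means equal the standardized value of A
    for i, prop in enumerate(PROPERTY_IDS):
        assert np.allclose(m.values[i], table.standardized.loc["A", prop])
        assert np.isclose(m.row_means[i], table.standardized.loc["A", prop])


def test_matrix_row_means_match_direct_loop(table, rng):
    seq = random_sequence(rng, 41)
    m = build_matrix(seq, table)
    for i in range(10):
        assert np.isclose(m.row_means[i], sum(m.values[i]) / 41, atol=1e-9)


# -- covariance scalars ----------------------------------------------------

def test_auto_covariance_zero_for_homopolymer(table):
    m = build_matrix(ProteinSequence("h", "C" * 25), table)
    for prop in PROPERTY_IDS:
        for g in (1, 5, 10):
            assert auto_covariance(m, prop, g) == pytest.approx(0.0, abs=1e-12)


def test_auto_covariance_single_term_at_max_lag(table, rng):
    seq = random_sequence(rng, 12)
    m = build_matrix(seq, table)
    g = 11  # L = g + 1: single product term
    expected = (m.values[0][0] - m.row_means[0]) * (m.values[0][11] - m.row_means[0])
    assert auto_covariance(m, "PC1", g) == pytest.approx(expected, abs=1e-12)


def test_covariances_match_oracle(table, rng):
    seq = random_sequence(rng, 25)
    m = build_matrix(seq, table)
    for i, prop in enumerate(PROPERTY_IDS):
        for g in range(1, 11):
            assert auto_covariance(m, prop, g) == pytest.approx(
                oracle_auto_cov(m, i, g), abs=1e-12
            )
    for i1, i2 in [(0, 1), (1, 0), (3, 7), (9, 2), (5, 6)]:
        for g in (1, 4, 10):
            assert cross_covariance(m, PROPERTY_IDS[i1], PROPERTY_IDS[i2], g) == pytest.approx(
                oracle_cross_cov(m, i1, i2, g), abs=1e-12
            )


def test_cross_covariance_is_directional(table, rng):
    seq = random_sequence(rng, 30)
    m = build_matrix(seq, table)
    asym = [
        abs(cross_covariance(m, p1, p2, g) - cross_covariance(m, p2, p1, g))
        for p1, p2 in [("PC1", "PC2"), ("PC3", "PC9"), ("PC4", "PC6")]
        for g in (1, 3)
    ]
    assert max(asym) > 1e-6


def test_covariance_errors(table, rng):
    m = build_matrix(random_sequence(rng, 15), table)
    with pytest.raises(LagTooLarge):
        auto_covariance(m, "PC1", 15)
    with pytest.raises(SameProperty):
        cross_covariance(m, "PC2", "PC2", 1)


# -- full encoding ---------------------------------------------------------

def test_encode_dimension_and_tags():
    tags = feature_tags()
    assert len(tags) == 1000
    assert sum(t.kind == "AC" for t in tags) == 100
    assert sum(t.kind == "CC" for t in tags) == 900
    assert len({str(t) for t in tags}) == 1000  # bijective index map


@pytest.mark.parametrize("max_lag", [1, 2, 3, 4, 5, 10])
def test_encode_dimension_law(max_lag, rng):
    seq = random_sequence(rng, 40)
    v = encode(seq, EncoderConfig(max_lag=max_lag))
    assert v.shape == (100 * max_lag,)


def test_encode_homopolymer_is_zero_vector():
    assert np.allclose(encode(ProteinSequence("h", "A" * 20)), 0.0)


def test_encode_rejects_short_sequences(rng):
    with pytest.raises(SequenceTooShort):
        encode(random_sequence(rng, 10))
    # L = max_lag + 1 is the shortest accepted length
    assert encode(random_sequence(rng, 11)).shape == (1000,)


def test_encode_matches_oracle_over_random_sequences(table):
    rng = np.random.default_rng(7)
    for k in range(10):
        seq = random_sequence(rng, int(rng.integers(11, 61)), f"s{k}")
        got = encode(seq, table=table)
        want = oracle_encode(seq, table)
        assert np.max(np.abs(got - want)) < 1e-12


def test_encode_deterministic(rng):
    seq = random_sequence(rng, 55)
    a = encode(seq)
    b = encode(seq)
    assert np.array_equal(a, b)


# -- sklearn transformer ---------------------------------------------------

def test_encoder_transformer_roundtrip(rng):
    enc = PhysChemEncoder()
    X = enc.fit_transform(["ACDEFGHIKLMNPQRSTVWY", random_sequence(rng, 30)])
    assert X.shape == (2, 1000)
    assert enc.n_features_out_ == 1000
    assert enc.feature_names_[0] == "AC:PC1:lag1"
    assert enc.feature_names_[-1] == "CC:PC10:PC9:lag10"


def test_encoder_property_subset_dimension(rng):
    enc = PhysChemEncoder(property_ids=[p for p in PROPERTY_IDS if p != "PC4"])
    X = enc.fit_transform([random_sequence(rng, 40)])
    assert X.shape == (1, 9 * 9 * 10)


def test_encoder_get_set_params():
    enc = PhysChemEncoder(max_lag=5)
    assert enc.get_params()["max_lag"] == 5
    enc.set_params(max_lag=3)
    assert enc.fit().n_features_out_ == 300
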