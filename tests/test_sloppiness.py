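"""Fisher information, influence scores and sloppiness classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cvsloppy as cv
from cvsloppy.sloppiness import EigenSpectrum


def _random_psd(rng, n=5):
    A = rng.normal(size=(n, n))
    return A.T @ A


def _influence_bruteforce(F):
    """Direct evaluation of the eigenvalue-weighted influence formula,
    independent of the package implementation."""
    w, Q = np.linalg.eigh(F)
    thr = max(w.max(), 0.0) * F.shape[0] * np.finfo(float).eps
    keep = w > thr
    w, Q = w[keep], Q[:, keep]
    return np.array([
        sum(abs(w[j] * Q[i, j]) for j in range(len(w))) / sum(abs(w))
        for i in range(F.shape[0])])


# ---------------------------------------------------------------------------
# Fisher information
# ---------------------------------------------------------------------------

def test_fim_identity_and_rank_one():
    fim = cv.fisher_information(np.eye(3))
    np.testing.assert_array_equal(fim.F, np.eye(3))
    s = np.array([[1.0, 2.0, 2.0]])
    fim1 = cv.fisher_information(s)
    spec = cv.eigenspectrum(fim1)
    assert spec.n_retained == 1
    assert spec.eigenvalues[0] == pytest.approx(9.0)   # ||s||^2


def test_fim_hand_product():
    fim = cv.fisher_information(np.array([[1.0, 2.0], [3.0, 4.0]]))
    np.testing.assert_allclose(fim.F, [[10.0, 14.0], [14.0, 20.0]])


def test_fim_drops_undefined_rows():
    S = np.array([[1.0, 0.0], [np.nan, 1.0], [0.0, 2.0]])
    fim = cv.fisher_information(S)
    assert fim.dropped_outputs == (1,)
    np.testing.assert_allclose(fim.F, [[1.0, 0.0], [0.0, 4.0]])


def test_fim_symmetry_and_psd_on_random_inputs():
    rng = np.random.default_rng(0)
    for _ in range(20):
        S = rng.normal(size=(7, 4))
        fim = cv.fisher_information(S)
        assert np.abs(fim.F - fim.F.T).max() <= 1e-12
        w = np.linalg.eigvalsh(fim.F)
        assert w.min() >= -1e-10 * max(w.max(), 1.0)


# ---------------------------------------------------------------------------
# Eigen-spectrum
# ---------------------------------------------------------------------------

def test_eigenspectrum_diagonal():
    spec = cv.eigenspectrum(cv.fisher_information(np.diag([2.0, 1.0])))
    np.testing.assert_allclose(spec.eigenvalues, [4.0, 1.0])
    np.testing.assert_allclose(np.abs(spec.eigenvectors), np.eye(2),
                               atol=1e-14)


def test_eigenspectrum_worked_2x2():
    # F = [[10, 14], [14, 20]]: lambda^2 - 30 lambda + 4 = 0
    fim = cv.fisher_information(np.array([[1.0, 2.0], [3.0, 4.0]]))
    spec = cv.eigenspectrum(fim)
    want = np.array([15.0 + np.sqrt(221.0), 15.0 - np.sqrt(221.0)])
    np.testing.assert_allclose(spec.eigenvalues, want, rtol=1e-12)
    # eigen-equation residual
    r = fim.F @ spec.eigenvectors - spec.eigenvectors * spec.eigenvalues
    assert np.abs(r).max() < 1e-8 * spec.eigenvalues[0]
    # orthonormal columns
    np.testing.assert_allclose(spec.eigenvectors.T @ spec.eigenvectors,
                               np.eye(2), atol=1e-12)


def test_eigenvector_sign_canonicalisation():
    rng = np.random.default_rng(3)
    F = _random_psd(rng)
    spec = cv.eigenspectrum(cv.fisher_information(
        np.linalg.cholesky(F + 1e-9 * np.eye(5)).T))
    for j in range(5):
        col = spec.eigenvectors[:, j]
        assert col[np.argmax(np.abs(col))] >= 0


# ---------------------------------------------------------------------------
# Influence scores
# ---------------------------------------------------------------------------

def test_influence_diagonal_fim():
    # diagonal F: Q = identity, so E_i = mu_i / sum(mu)
    spec = cv.eigenspectrum(cv.fisher_information(np.diag([3.0, 1.0])))
    ranking = cv.influence_scores(spec)
    np.testing.assert_allclose(ranking.scores, [0.9, 0.1])


def test_influence_zero_sensitivity_parameter():
    S = np.array([[0.5, 0.0], [0.7, 0.0]])
    spec = cv.eigenspectrum(cv.fisher_information(S))
    ranking = cv.influence_scores(spec)
    assert ranking.scores[1] == pytest.approx(0.0, abs=1e-14)


def test_influence_matches_bruteforce_on_random_psd():
    rng = np.random.default_rng(7)
    for _ in range(25):
        F = _random_psd(rng)
        spec = cv.eigenspectrum(cv.fisher_information(
            np.linalg.cholesky(F).T))
        got = cv.influence_scores(spec).scores
        want = _influence_bruteforce(F)
        np.testing.assert_allclose(got, want, atol=1e-12)
        assert np.all(got >= 0.0) and np.all(got <= 1.0 + 1e-12)


def test_influence_worked_2x2():
    fim = cv.fisher_information(np.array([[1.0, 2.0], [3.0, 4.0]]))
    spec = cv.eigenspectrum(fim)
    got = cv.influence_scores(spec).scores
    np.testing.assert_allclose(got, _influence_bruteforce(fim.F),
                               atol=1e-14)


@given(st.integers(0, 10 ** 6), st.floats(1.5, 10.0))
@settings(max_examples=30, derandomize=True)
def test_influence_monotone_under_column_scaling(seed, k):
    """Scaling one column of S by k > 1 never decreases that parameter's
    influence score."""
    rng = np.random.default_rng(seed)
    S = rng.uniform(0.0, 1.0, size=(4, 3))
    before = cv.influence_scores(
        cv.eigenspectrum(cv.fisher_information(S))).scores
    S2 = S.copy()
    S2[:, 1] *= k
    after = cv.influence_scores(
        cv.eigenspectrum(cv.fisher_information(S2))).scores
    assert after[1] >= before[1] - 1e-9


def test_rank_influential_threshold_and_ties():
    ranking = cv.InfluenceRanking(np.array([0.8, 0.6, 0.009]),
                                  ("b", "a", "c"))
    table = cv.rank_influential(ranking)
    assert list(table["parameter"]) == ["b", "a"]
    assert list(table["E_2dp"]) == ["0.80", "0.60"]
    empty = cv.rank_influential(
        cv.InfluenceRanking(np.array([0.001, 0.002]), ("a", "b")))
    assert len(empty) == 0
    tied = cv.rank_influential(
        cv.InfluenceRanking(np.array([0.5, 0.5]), ("z", "a")))
    assert list(tied["parameter"]) == ["a", "z"]
    assert cv.rank_influential(
        cv.InfluenceRanking(np.array([0.804]), ("x",)))["E_2dp"][0] == "0.80"


# ---------------------------------------------------------------------------
# Span and classification
# ---------------------------------------------------------------------------

def _spec_from_eigs(vals):
    vals = np.asarray(vals, dtype=float)
    n = len(vals)
    return EigenSpectrum(vals, np.eye(n), tuple(f"p{i}" for i in range(n)),
                         zero_threshold=vals.max() * n *
                         np.finfo(float).eps)


@pytest.mark.parametrize("vals, expected", [
    ([1.0, 1e-12], 12.0),
    ([5.0, 5.0, 5.0], 0.0),
    ([1e2, 1.0, 1e-14], 16.0),
])
def test_spectrum_span(vals, expected):
    assert cv.spectrum_span(_spec_from_eigs(vals)) == pytest.approx(expected)


def test_spectrum_span_needs_two_positive():
    with pytest.raises(ValueError):
        cv.spectrum_span(_spec_from_eigs([1.0, 0.0]))


def test_classify_log_uniform_ladder_is_sloppy():
    v = cv.classify_sloppiness(_spec_from_eigs(
        [10.0 ** (-2 * k) for k in range(7)]))
    assert v.sloppy
    assert v.span_decades == pytest.approx(12.0)
    assert v.void_fraction == pytest.approx(2.0 / 12.0)


def test_classify_narrow_span_not_sloppy():
    v = cv.classify_sloppiness(_spec_from_eigs([1.0, 0.5, 0.25, 0.125]))
    assert not v.sloppy
    assert v.span_decades < 1.0


def test_classify_nonuniform_gap_not_sloppy():
    v = cv.classify_sloppiness(_spec_from_eigs([1.0, 1e-1, 1e-9]))
    assert not v.sloppy
    assert v.span_decades == pytest.approx(9.0)
    assert v.void_fraction == pytest.approx(8.0 / 9.0)
    assert "not uniform" in v.note


def test_classify_too_few_retained_not_sloppy():
    v = cv.classify_sloppiness(_spec_from_eigs([4.0, 1.0]))
    assert not v.sloppy
    assert v.n_retained == 2
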