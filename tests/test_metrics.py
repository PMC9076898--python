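import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from envphylo import (
    METRICS,
    DistanceMatrix,
    ValidationError,
    chebyshev,
    cosine_dissimilarity,
    cosine_similarity,
    distance_matrix,
    jensen_shannon,
)

count_vectors = arrays(
    np.int64, st.integers(2, 12), elements=st.integers(0, 50)
).filter(lambda v: v.sum() > 0)


def test_cosine_identity_and_orthogonality():
    u = np.array([3.0, 1.0, 2.0])
    assert cosine_similarity(u, u) == pytest.approx(1.0)
    assert cosine_similarity([1, 0], [0, 1]) == 0.0
    assert cosine_similarity(u, 2 * u) == pytest.approx(1.0)


def test_cosine_dissimilarity_printed_values():
    u = np.array([5.0, 2.0, 9.0])
    assert cosine_dissimilarity(u, u) == pytest.approx(0.0, abs=1e-12)
    # genome duplication: direction-only dependence
    assert cosine_dissimilarity(u, 2 * u) == pytest.approx(0.0, abs=1e-12)
    assert cosine_dissimilarity([1, 0], [0, 1]) == pytest.approx(np.log(2), abs=1e-12)
    # antipodal input stays finite thanks to the clamp
    assert np.isfinite(cosine_dissimilarity([1.0, 0.0], [-1.0, 0.0]))


def test_zero_vector_is_a_domain_error():
    with pytest.raises(ValidationError):
        cosine_dissimilarity([0, 0], [1, 2])
    with pytest.raises(ValidationError):
        jensen_shannon([0, 0], [1, 2])
    with pytest.raises(ValidationError):
        chebyshev([1, 1], [0, 0])
    with pytest.raises(ValidationError):
        jensen_shannon([1, -1], [1, 1])


@given(u=count_vectors, a=st.integers(1, 9), b=st.integers(1, 9))
def test_cosine_dissimilarity_scale_invariance(u, a, b):
    v = u + 1  # strictly positive second vector of same dimension
    assert cosine_dissimilarity(a * u, b * v) == pytest.approx(
        cosine_dissimilarity(u, v), abs=1e-12
    )


def test_jsd_closed_forms():
    assert jensen_shannon([2, 3, 5], [2, 3, 5]) == 0.0
    # disjoint supports reach the base-2 maximum
    assert jensen_shannon([1, 0], [0, 1]) == pytest.approx(1.0)
    assert chebyshev([1, 0], [0, 1]) == pytest.approx(1.0)


@given(u=count_vectors)
def test_jsd_and_chebyshev_axioms(u):
    v = np.roll(u, 1) + 1
    for fn in (jensen_shannon, chebyshev):
        duv = fn(u, v)
        assert duv >= 0
        assert fn(v, u) == pytest.approx(duv, abs=1e-12)
        assert fn(u, u) == pytest.approx(0.0, abs=1e-12)
    assert jensen_shannon(u, v) <= 1.0 + 1e-12


def test_chebyshev_triangle_inequality_and_manhattan_bound(rng):
    for _ in range(50):
        p, q, r = (rng.integers(0, 20, size=8) + 1 for _ in range(3))
        assert chebyshev(p, q) <= chebyshev(p, r) + chebyshev(r, q) + 1e-12
        manhattan = METRICS["manhattan"]
        assert chebyshev(p, q) <= manhattan(p, q) + 1e-12


def test_registry_metrics_vanish_on_identical_and_are_symmetric(rng):
    u = rng.integers(0, 30, size=15) + 1
    v = rng.integers(0, 30, size=15) + 1
    for name, fn in METRICS.items():
        assert fn(u, u) == pytest.approx(0.0, abs=1e-12), name
        assert fn(u, v) == pytest.approx(fn(v, u), abs=1e-12), name


def test_distance_matrix_contracts(rng):
    cols = rng.integers(0, 40, size=(12, 5)) + 1
    D = distance_matrix(cols, "cosine")
    assert np.array_equal(D.values, D.values.T)
    assert np.all(np.diag(D.values) == 0)
    # oracle: per-pair direct evaluation
    for i in range(5):
        for j in range(i + 1, 5):
            assert D.values[i, j] == pytest.approx(
                cosine_dissimilarity(cols[:, i], cols[:, j])
            )


def test_distance_matrix_identical_columns_and_bad_metric():
    cols = np.tile(np.array([[1], [2], [3]]), (1, 2))
    D = distance_matrix(cols, "cosine")
    assert np.all(D.values == 0)
    with pytest.raises(ValidationError, match="available"):
        distance_matrix(cols, "nope")


def test_phylip_and_tsv_round_trip(tmp_path, rng):
    cols = rng.integers(0, 30, size=(10, 4)) + 1
    D = distance_matrix(cols, "jsd", labels=["w", "x", "y", "z"])
    p = tmp_path / "d.phy"
    D.to_phylip(p)
    back = DistanceMatrix.from_phylip(p)
    assert back.labels == D.labels
    assert np.abs(back.values - D.values).max() < 1e-9
    t = tmp_path / "d.tsv"
    D.to_tsv(t)
    back2 = DistanceMatrix.from_tsv(t)
    assert np.abs(back2.values - D.values).max() < 1e-9
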