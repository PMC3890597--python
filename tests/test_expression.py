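"""Normalization, the 2-rpm filter, Pearson-distance clustering and the
summary transforms of the expression-profiling stage."""

import numpy as np
import pandas as pd
import pytest

from pnpkit.expression import (
    RAW,
    RPM,
    CountMatrix,
    cluster_profiles,
    filter_min_expression,
    fraction_transform,
    normalize_counts,
    pearson_distance_matrix,
    stage_totals,
)


def _matrix(values, libs=None, lengths=None, genes=None, stages=None, norm=RAW):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    stages = stages or [f"s{j}" for j in range(values.shape[1])]
    return CountMatrix(
        data=pd.DataFrame(values, index=genes, columns=stages),
        library_sizes=pd.Series(libs, index=stages) if libs is not None else None,
        lengths=pd.Series(lengths, index=genes) if lengths is not None else None,
        normalization=norm,
    )


# ---------------------------------------------------------------------------
# normalization


def test_rpm_and_rpkm_toy_values():
    m = _matrix([[2.0]], libs=[1e6], lengths=[500.0])
    rpm = normalize_counts(m, "rpm")
    assert rpm.data.iloc[0, 0] == pytest.approx(2.0)
    rpkm = normalize_counts(m, "rpkm")
    assert rpkm.data.iloc[0, 0] == pytest.approx(4.0)  # 2 rpm * 1e3 / 500 b


def test_normalization_matches_arithmetic_oracle():
    """Random 50 x 13 matrix: every cell equals the per-cell formula."""
    rng = np.random.default_rng(8)
    raw = rng.integers(0, 5000, size=(50, 13)).astype(float)
    libs = rng.integers(100_000, 2_000_000, size=13).astype(float)
    lengths = rng.integers(200, 4000, size=50).astype(float)
    m = _matrix(raw, libs=libs, lengths=lengths)
    rpm = normalize_counts(m, "rpm")
    rpkm = normalize_counts(m, "rpkm")
    for g in range(50):
        for s in range(13):
            expected_rpm = raw[g, s] / libs[s] * 1e6
            assert rpm.data.iloc[g, s] == pytest.approx(expected_rpm)
            assert rpkm.data.iloc[g, s] == pytest.approx(
                expected_rpm * 1e3 / lengths[g]
            )
    # column sums scale like the library sizes
    for s in range(13):
        assert rpm.data.iloc[:, s].sum() == pytest.approx(
            raw[:, s].sum() / libs[s] * 1e6
        )


def test_normalization_errors():
    with pytest.raises(ValueError):
        normalize_counts(_matrix([[1.0]]), "rpm")  # no library sizes
    with pytest.raises(ValueError):
        normalize_counts(_matrix([[1.0]], libs=[0.0]), "rpm")
    with pytest.raises(ValueError):
        normalize_counts(_matrix([[1.0]], libs=[1e6]), "rpkm")  # no lengths


# ---------------------------------------------------------------------------
# the >= 2 rpm filter


def test_filter_boundary_is_inclusive():
    m = _matrix([[1.9, 0.0], [2.0, 0.0], [0.0, 5.0]], norm=RPM)
    kept = filter_min_expression(m, 2.0)
    assert kept.gene_ids == ["g1", "g2"]


def test_filter_all_zero_matrix():
    m = _matrix(np.zeros((4, 3)), norm=RPM)
    assert filter_min_expression(m, 2.0).gene_ids == []


def test_filter_monotone_in_threshold():
    rng = np.random.default_rng(3)
    m = _matrix(rng.uniform(0, 10, size=(30, 5)), norm=RPM)
    previous = set(m.gene_ids)
    for threshold in (0.5, 2.0, 5.0, 9.0):
        kept = set(filter_min_expression(m, threshold).gene_ids)
        assert kept <= previous
        previous = kept


def test_filter_requires_rpm_input():
    with pytest.raises(ValueError):
        filter_min_expression(_matrix([[1.0]]), 2.0)


# ---------------------------------------------------------------------------
# clustering


def naive_average_linkage_heights(dist):
    """O(n^3) agglomeration oracle: average linkage over a dissimilarity."""
    clusters = {i: [i] for i in range(len(dist))}
    heights = []
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights


def test_identical_profiles_merge_at_zero():
    m = _matrix([[1, 2, 3], [1, 2, 3]], norm=RPM)
    result = cluster_profiles(m)
    assert result.merge_tree[0, 2] == pytest.approx(0.0)


def test_anticorrelated_profiles_have_distance_two():
    d = pearson_distance_matrix(np.array([[1.0, 2, 3], [3, 2, 1]]))
    assert d[0, 1] == pytest.approx(2.0)


def test_zero_variance_rows_get_unit_distance():
    d = pearson_distance_matrix(np.array([[5.0, 5, 5], [1, 2, 3], [2.0, 2, 2]]))
    assert d[0, 1] == pytest.approx(1.0)
    assert d[0, 2] == pytest.approx(1.0)
    assert d[0, 0] == pytest.approx(0.0)


def test_single_gene_is_an_error():
    with pytest.raises(ValueError):
        cluster_profiles(_matrix([[1, 2, 3]], norm=RPM))


def test_merge_heights_match_naive_agglomeration_oracle():
    """40 random profiles: scipy-backed merges equal the O(n^3) oracle."""
    rng = np.random.default_rng(40)
    m = _matrix(rng.uniform(0, 100, size=(40, 13)), norm=RPM)
    result = cluster_profiles(m, linkage="average")
    dist = pearson_distance_matrix(m.data.sort_index().values)
    expected = naive_average_linkage_heights(dist)
    assert np.allclose(sorted(result.merge_tree[:, 2]), sorted(expected))
    # heights are non-decreasing along the merge sequence
    assert np.all(np.diff(result.merge_tree[:, 2]) >= -1e-12)


def test_cluster_result_invariant_under_row_permutation():
    rng = np.random.default_rng(77)
    values = rng.uniform(0, 50, size=(15, 6))
    m = _matrix(values, norm=RPM)
    shuffled = m.data.sample(frac=1.0, random_state=5)
    m2 = CountMatrix(data=shuffled, normalization=RPM)
    a, b = cluster_profiles(m), cluster_profiles(m2)
    assert a.gene_ids == b.gene_ids
    assert np.allclose(a.merge_tree, b.merge_tree)
    assert a.leaf_order == b.leaf_order


# ---------------------------------------------------------------------------
# stage totals and the fraction-of-1 transform


def test_stage_totals_examples():
    m = _matrix(np.ones((98, 13)), norm=RPM)
    totals = stage_totals(m)
    assert (totals == 98.0).all()
    single = stage_totals(m, ["g7"])
    assert (single == 1.0).all()
    with pytest.raises(KeyError):
        stage_totals(m, ["nope"])


def test_stage_totals_column_sum_oracle():
    rng = np.random.default_rng(6)
    values = rng.uniform(0, 10, size=(20, 13))
    m = _matrix(values, norm=RPM)
    subset = [f"g{i}" for i in range(0, 20, 3)]
    totals = stage_totals(m, subset)
    expected = values[[int(g[1:]) for g in subset]].sum(axis=0)
    assert np.allclose(totals.values, expected)


def test_fraction_transform_rows():
    m = _matrix([[1.0, 1.0, 2.0], [0.0, 0.0, 0.0]], norm=RPM)
    frac = fraction_transform(m)
    assert np.allclose(frac.data.iloc[0], [0.25, 0.25, 0.5])
    assert np.allclose(frac.data.iloc[1], [0.0, 0.0, 0.0])
    assert frac.normalization == "fraction"


def test_fraction_transform_idempotent_and_sums_to_one():
    rng = np.random.default_rng(2)
    m = _matrix(rng.uniform(0, 10, size=(25, 13)), norm=RPM)
    once = fraction_transform(m)
    sums = once.data.sum(axis=1)
    assert np.allclose(sums, 1.0, atol=1e-9)
    twice = fraction_transform(once)
    assert np.allclose(once.data.values, twice.data.values)


def test_fraction_transform_max_mode():
    m = _matrix([[1.0, 4.0, 2.0]], norm=RPM)
    frac = fraction_transform(m, mode="max")
    assert np.allclose(frac.data.iloc[0], [0.25, 1.0, 0.5])
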