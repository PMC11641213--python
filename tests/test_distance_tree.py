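"""Nei distance, UPGMA and PCoA: worked examples, properties, cross-checks."""

import numpy as np
import pandas as pd
import pytest

from ssrpg.distance_tree import (
    NEI_CEILING,
    DistanceMatrix,
    cut_clusters,
    nei_distance,
    nei_distance_from_matrix,
    pcoa,
    shared_allele_distance,
    upgma,
)
from ssrpg.diversity import FrequencyTable

from conftest import make_matrix


def ftable(**loci):
    return FrequencyTable(
        {l: pd.Series(f) for l, f in loci.items()},
        {l: (1 if f else 0) for l, f in loci.items()},
    )


def test_nei_identical_units_zero():
    t = ftable(L1={1: 0.5, 2: 0.5}, L2={3: 1.0})
    dm = nei_distance({"x": t, "y": t})
    assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_nei_hand_value():
    """x=(0.5,0.5), y=(1,0): I = 0.5/sqrt(0.5) so D = ln sqrt(2) = 0.3466."""
    a = ftable(L={1: 0.5, 2: 0.5})
    b = ftable(L={1: 1.0})
    dm = nei_distance({"a": a, "b": b})
    assert dm.values[0, 1] == pytest.approx(-np.log(0.5 / np.sqrt(0.5)), abs=1e-12)


def test_nei_disjoint_alleles_capped():
    a = ftable(L={1: 1.0})
    b = ftable(L={2: 1.0})
    assert nei_distance({"a": a, "b": b}).values[0, 1] == NEI_CEILING


def test_nei_no_shared_loci_undefined():
    a = ftable(L1={1: 1.0}, L2={})
    b = ftable(L1={}, L2={2: 1.0})
    with pytest.warns(UserWarning, match="no scored loci"):
        dm = nei_distance({"a": a, "b": b})
    assert np.isnan(dm.values[0, 1])


def test_nei_pairwise_locus_exclusion():
    """A locus missing in one unit is dropped from the pair's J sums."""
    a = ftable(L1={1: 1.0}, L2={5: 1.0})
    b = ftable(L1={1: 1.0}, L2={})
    dm = nei_distance({"a": a, "b": b})
    assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_nei_permutation_equivariant():
    rng = np.random.default_rng(0)
    calls = rng.integers(1, 5, size=(6, 3, 2))
    m = make_matrix(calls)
    dm = nei_distance_from_matrix(m, level="individual")
    perm = [3, 0, 5, 1, 4, 2]
    m2 = m.subset([m.accession_ids[i] for i in perm])
    dm2 = nei_distance_from_matrix(m2, level="individual")
    assert np.allclose(dm.values[np.ix_(perm, perm)], dm2.values)


def test_shared_allele_distance_basics():
    m = make_matrix([[(1, 2)], [(1, 2)], [(3, 4)], [(1, 3)]])
    d = shared_allele_distance(m)
    assert d.values[0, 1] == 0.0
    assert d.values[0, 2] == 1.0
    assert d.values[0, 3] == 0.5


# ----------------------------------------------------------------------
# UPGMA
# ----------------------------------------------------------------------

def test_upgma_worked_example():
    dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
    tree = upgma(dm)
    assert tree.to_newick() == "((A:1,B:1):1,C:2);"
    assert cut_clusters(tree, 2) == {"A": 1, "B": 1, "C": 2}


def test_upgma_all_zero_distances():
    dm = DistanceMatrix(["b", "a", "c"], np.zeros((3, 3)))
    tree = upgma(dm)
    assert tree.root.height == 0.0
    # tie-break merges the lexicographically smallest pair first
    assert set(tree.merge_order[0].leaves()) == {"a", "b"}


def test_upgma_cut_extremes():
    dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 1, 3], [1, 0, 3], [3, 3, 0]], float))
    tree = upgma(dm)
    assert set(cut_clusters(tree, 1).values()) == {1}
    assert sorted(cut_clusters(tree, 3).values()) == [1, 2, 3]
    with pytest.raises(ValueError, match="k must be"):
        cut_clusters(tree, 4)


def test_upgma_rejects_undefined_entries():
    vals = np.array([[0, np.nan], [np.nan, 0]])
    dm = DistanceMatrix(["a", "b"], vals)
    with pytest.raises(ValueError, match="undefined"):
        upgma(dm)


def test_upgma_cophenetic_recovers_ultrametric_input():
    """Cophenetic distances equal the input exactly when it is ultrametric."""
    # build an ultrametric matrix from a known tree: ((A,B):h1, (C,D):h2):h3
    d = np.array(
        [
            [0.0, 1.0, 4.0, 4.0],
            [1.0, 0.0, 4.0, 4.0],
            [4.0, 4.0, 0.0, 2.0],
            [4.0, 4.0, 2.0, 0.0],
        ]
    )
    dm = DistanceMatrix(list("ABCD"), d)
    coph = upgma(dm).cophenetic()
    assert np.allclose(coph.to_frame().loc[list("ABCD"), list("ABCD")].to_numpy(), d)


def test_upgma_ultrametric_property():
    """Every leaf is equidistant from the root."""
    rng = np.random.default_rng(5)
    for _ in range(10):
        n = rng.integers(3, 12)
        x = rng.random((n, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        tree = upgma(DistanceMatrix([f"t{i}" for i in range(n)], d))
        coph = tree.cophenetic().values
        depths = coph.max(axis=1)  # 2 * root height for every leaf
        assert np.ptp(depths) < 1e-9


def test_upgma_matches_scipy_average_linkage():
    """Cophenetic distances agree with scipy's average linkage on tie-free data."""
    import scipy.cluster.hierarchy as sch
    import scipy.spatial.distance as ssd

    rng = np.random.default_rng(6)
    x = rng.random((9, 4))
    d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
    tree = upgma(DistanceMatrix([f"t{i}" for i in range(9)], d))
    ours = tree.cophenetic().to_frame().loc[
        [f"t{i}" for i in range(9)], [f"t{i}" for i in range(9)]
    ].to_numpy()
    Z = sch.linkage(ssd.squareform(d), method="average")
    theirs = ssd.squareform(sch.cophenet(Z))
    assert np.allclose(ours, theirs, atol=1e-9)


# ----------------------------------------------------------------------
# PCoA
# ----------------------------------------------------------------------

def test_pcoa_two_points_closed_form():
    dm = DistanceMatrix(["x", "y"], np.array([[0.0, 3.0], [3.0, 0.0]]))
    res = pcoa(dm, axes=1)
    assert sorted(res.coordinates.ravel()) == pytest.approx([-1.5, 1.5])
    assert res.eigenvalues[0] == pytest.approx(4.5)


def test_pcoa_zero_matrix():
    dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
    with pytest.warns(UserWarning, match="positive eigenvalues"):
        res = pcoa(dm, axes=2)
    assert np.allclose(res.eigenvalues, 0.0, atol=1e-12)
    assert res.coordinates.shape[1] == 0


def test_pcoa_euclidean_exactness():
    """Classical scaling reproduces Euclidean distances to 1e-9."""
    rng = np.random.default_rng(7)
    x = rng.random((10, 4))
    d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
    res = pcoa(DistanceMatrix([f"p{i}" for i in range(10)], d), axes=9)
    c = res.coordinates
    d2 = np.sqrt(((c[:, None] - c[None]) ** 2).sum(-1))
    assert np.allclose(d, d2, atol=1e-9)


def test_pcoa_eigenvalue_sum_equals_trace():
    rng = np.random.default_rng(8)
    x = rng.random((8, 3))
    d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
    dm = DistanceMatrix([f"p{i}" for i in range(8)], d)
    res = pcoa(dm, axes=2)
    n = dm.n
    C = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * C @ (d**2) @ C
    assert res.eigenvalues.sum() == pytest.approx(np.trace(B), abs=1e-9)
    pos = res.eigenvalues > 0
    assert res.percent_variance[pos].sum() == pytest.approx(100.0)


def test_pcoa_matches_reference_implementation():
    """Coordinates agree (up to sign) with scikit-bio's PCoA."""
    skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
    from skbio import DistanceMatrix as SkbioDM

    rng = np.random.default_rng(9)
    x = rng.random((7, 3))
    d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
    ours = pcoa(DistanceMatrix([f"p{i}" for i in range(7)], d), axes=3)
    ref = skbio_pcoa(SkbioDM(d, ids=[f"p{i}" for i in range(7)]))
    for j in range(3):
        a = ours.coordinates[:, j]
        b = ref.samples.iloc[:, j].to_numpy()
        assert np.allclose(np.abs(a), np.abs(b), atol=1e-8)
        assert ours.eigenvalues[j] == pytest.approx(ref.eigvals.iloc[j], abs=1e-8)
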