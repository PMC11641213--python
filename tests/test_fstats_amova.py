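"""F-statistics and AMOVA: edge cases, arithmetic, and brute-force oracle."""

import numpy as np
import pytest

from ssrpg.fstats_amova import AmovaError, amova, f_statistics, nm_from_fst, pairwise_fst
from ssrpg.synthetic_data import SimParams, simulate_dataset

from conftest import make_matrix


def test_maximal_differentiation():
    """Two pops fixed for different alleles: Hs=0, Ht=0.5, Fst=1, Nm=0."""
    m = make_matrix(
        [[(1, 1)], [(1, 1)], [(2, 2)], [(2, 2)]], pops=["a", "a", "b", "b"]
    )
    row = f_statistics(m).loc["L1"]
    assert row["Hs"] == 0.0
    assert row["Ht"] == pytest.approx(0.5)
    assert row["Fst"] == pytest.approx(1.0)
    assert row["Nm"] == pytest.approx(0.0)
    assert np.isnan(row["Fis"])  # undefined at Hs = 0


def test_excess_heterozygosity_edge():
    """Identical pops, all heterozygous: Fis=-1, Fst=0, Nm=inf."""
    m = make_matrix(
        [[(1, 2)], [(1, 2)], [(1, 2)], [(1, 2)]], pops=["a", "a", "b", "b"]
    )
    row = f_statistics(m).loc["L1"]
    assert row["Hi"] == 1.0
    assert row["Hs"] == pytest.approx(0.5)
    assert row["Fis"] == pytest.approx(-1.0)
    assert row["Fst"] == pytest.approx(0.0)
    assert np.isinf(row["Nm"])


def test_island_model_arithmetic():
    assert nm_from_fst(0.05) == pytest.approx(4.75)


def test_mean_nm_is_mean_of_per_locus_nm():
    m = make_matrix(
        [[(1, 1), (1, 2)], [(1, 2), (1, 1)], [(2, 2), (2, 2)], [(1, 2), (1, 2)]],
        pops=["a", "a", "b", "b"],
    )
    df = f_statistics(m)
    per_locus = df.loc[["L1", "L2"], "Nm"]
    if np.isfinite(per_locus).all():
        assert df.loc["Mean", "Nm"] == pytest.approx(per_locus.mean())


def test_pairwise_fst_properties():
    rng = np.random.default_rng(1)
    calls = rng.integers(1, 5, size=(12, 3, 2))
    m = make_matrix(calls, pops=["a"] * 4 + ["b"] * 4 + ["c"] * 4)
    pw = pairwise_fst(m)
    assert (np.diag(pw.to_numpy()) == 0).all()
    assert np.allclose(pw.to_numpy(), pw.to_numpy().T)


def test_pairwise_fst_duplicated_population_zero():
    calls = [[(1, 2)], [(1, 1)], [(1, 2)], [(1, 1)]]
    m = make_matrix(calls, pops=["a", "a", "b", "b"])
    assert pairwise_fst(m).loc["a", "b"] == pytest.approx(0.0)


def test_pairwise_fst_divergent_population():
    """A,B share frequencies; C is divergent: Fst(A,B) < Fst(A,C), Fst(B,C)."""
    ab = [[(1, 1)], [(1, 2)], [(2, 2)], [(1, 2)]]
    c = [[(3, 3)], [(3, 3)], [(3, 4)], [(3, 4)]]
    m = make_matrix(ab + ab + c, pops=["A"] * 4 + ["B"] * 4 + ["C"] * 4)
    pw = pairwise_fst(m)
    assert pw.loc["A", "B"] < pw.loc["A", "C"]
    assert pw.loc["A", "B"] < pw.loc["B", "C"]


def test_pairwise_agrees_with_pooled_two_pop_fstats():
    rng = np.random.default_rng(2)
    calls = rng.integers(1, 4, size=(10, 2, 2))
    m = make_matrix(calls, pops=["a"] * 5 + ["b"] * 5)
    pw = pairwise_fst(m)
    assert pw.loc["a", "b"] == pytest.approx(
        f_statistics(m).loc["Mean", "Fst"], abs=1e-12
    )


# ----------------------------------------------------------------------
# AMOVA
# ----------------------------------------------------------------------

def _brute_amova_ss(m):
    """Pairwise-squared-distance AMOVA SS (no missing data assumed)."""
    n, L = m.n_accessions, m.n_loci
    vecs = []
    for i in range(n):
        copies = []
        for s in range(2):
            v = []
            for j in range(L):
                codes = sorted(set(m.calls[:, j, :].ravel()))
                x = np.zeros(len(codes))
                x[codes.index(m.calls[i, j, s])] = 1.0
                v.append(x)
            copies.append(np.concatenate(v))
        vecs.append(copies)
    flat = [c for pair in vecs for c in pair]

    def ss_group(copies):
        k = len(copies)
        return sum(
            np.sum((copies[i] - copies[j]) ** 2)
            for i in range(k)
            for j in range(i + 1, k)
        ) / k

    ss_total = ss_group(flat)
    ss_within_ind = sum(ss_group(pair) for pair in vecs)
    pops = m.population_labels
    ss_within_pop = 0.0
    for p in pops:
        idx = m.population_indices(p)
        ss_within_pop += ss_group([c for i in idx for c in vecs[i]])
    ss_among_pop = ss_total - ss_within_pop
    ss_among_ind = ss_within_pop - ss_within_ind
    return 0.5 * ss_among_pop, 0.5 * ss_among_ind, 0.5 * ss_within_ind


def test_amova_ss_matches_brute_force_pairwise():
    rng = np.random.default_rng(3)
    calls = rng.integers(1, 4, size=(12, 2, 2))
    m = make_matrix(calls, pops=["a"] * 4 + ["b"] * 4 + ["c"] * 4)
    table = amova(m).table
    ap, ai, wi = _brute_amova_ss(m)
    assert table.loc["Among Pops", "SS"] == pytest.approx(ap, abs=1e-9)
    assert table.loc["Among Indiv", "SS"] == pytest.approx(ai, abs=1e-9)
    assert table.loc["Within Indiv", "SS"] == pytest.approx(wi, abs=1e-9)


def test_amova_df_bookkeeping():
    rng = np.random.default_rng(4)
    calls = rng.integers(1, 4, size=(9, 2, 2))
    m = make_matrix(calls, pops=["a"] * 2 + ["b"] * 3 + ["c"] * 4)
    table = amova(m).table
    assert list(table["df"]) == [2, 6, 9, 17]
    assert table.loc["Total", "SS"] == pytest.approx(
        table.loc[["Among Pops", "Among Indiv", "Within Indiv"], "SS"].sum()
    )


def test_amova_no_variation():
    m = make_matrix([[(1, 1)], [(1, 1)], [(1, 1)], [(1, 1)]], pops=["a", "a", "b", "b"])
    with pytest.warns(UserWarning, match="no molecular variation"):
        table = amova(m).table
    assert (table["SS"] == 0).all()
    assert (table["%"] == 0).all()


def test_amova_single_population_rejected():
    m = make_matrix([[(1, 2)], [(1, 1)]])
    with pytest.raises(AmovaError, match="two-level"):
        amova(m)


def test_amova_differentiation_monotone_in_target():
    """Among-pops percent: ~0 at F=0; larger at F=0.3 than at F=0.04."""
    def pct_among(F, seed):
        params = SimParams(
            pop_sizes=(40, 40, 40), alleles_per_locus=(5,) * 8,
            fst_target=F, seed=seed,
        )
        return amova(simulate_dataset(params)).table.loc["Among Pops", "%"]

    at_zero = [pct_among(0.0, s) for s in range(5)]
    assert np.mean(at_zero) <= 2.0
    at_low = np.mean([pct_among(0.04, s) for s in range(5)])
    at_high = np.mean([pct_among(0.3, s) for s in range(5)])
    assert at_high > at_low
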