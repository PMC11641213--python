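"""Greedy heterozygosity-based core selection: oracles and contracts."""

import itertools

import numpy as np
import pytest

from ssrpg.core_collection import (
    core_vs_original_test,
    rank_by_het,
    retention_report,
    select_candidates,
    subset_size,
)
from ssrpg.diversity import locus_summaries
from ssrpg.synthetic_data import SimParams, simulate_dataset

from conftest import make_matrix


def mean_he(matrix, ids):
    return locus_summaries(matrix.subset(list(ids)), mean_row=False)["He"].mean()


@pytest.fixture
def small_random():
    rng = np.random.default_rng(12)
    calls = rng.integers(1, 5, size=(8, 3, 2))
    return make_matrix(calls)


def test_duplicate_accession_removed_first():
    """An exact duplicate contributes nothing: one copy goes before any unique."""
    rng = np.random.default_rng(1)
    calls = rng.integers(1, 6, size=(5, 3, 2))
    calls[1] = calls[0]  # A2 duplicates A1
    order = rank_by_het(make_matrix(calls))
    assert order[0] in {"A1", "A2"}


def test_first_removal_matches_enumeration_oracle(small_random):
    """Greedy first choice equals the best single removal by brute force."""
    m = small_random
    loo = {
        a: mean_he(m, [x for x in m.accession_ids if x != a])
        for a in m.accession_ids
    }
    best = max(loo.values())
    oracle = min(a for a, v in loo.items() if v == pytest.approx(best, abs=1e-12))
    assert rank_by_het(m)[0] == oracle


def test_two_accessions_order():
    m = make_matrix([[(1, 1)], [(1, 2)]])
    order = rank_by_het(m)
    # removing the homozygote leaves He = 0.5; it contributes less
    assert order == ["A1", "A2"]


def test_all_identical_pure_tiebreak():
    m = make_matrix([[(1, 1)]] * 4)
    with pytest.warns(UserWarning, match="identical"):
        order = rank_by_het(m)
    assert order == ["A1", "A2", "A3", "A4"]


def test_determinism(small_random):
    assert rank_by_het(small_random) == rank_by_het(small_random)


def test_subset_sizes_study_grid():
    sizes = [subset_size(416, p) for p in (0.50, 0.45, 0.40, 0.35, 0.30,
                                           0.25, 0.20, 0.15, 0.10, 0.05)]
    assert sizes == [208, 187, 166, 146, 125, 104, 83, 62, 42, 21]


def test_select_candidates_nested(small_random):
    sel = select_candidates(small_random, proportions=(0.75, 0.5, 0.25))
    assert set(sel.subsets[0.25]) <= set(sel.subsets[0.5]) <= set(sel.subsets[0.75])
    assert len(sel.subsets[0.5]) == subset_size(8, 0.5)


def test_select_full_proportion_retains_everything(small_random):
    sel = select_candidates(small_random, proportions=(1.0,))
    assert sorted(sel.subsets[1.0]) == sorted(small_random.accession_ids)
    ret = sel.retention.loc[1.0]
    for param in ("Na", "Ne", "I", "Ho", "He", "PIC"):
        assert ret[param] == pytest.approx(100.0)


def test_zero_size_proportion_rejected(small_random):
    with pytest.raises(ValueError, match="empty subset"):
        select_candidates(small_random, proportions=(0.01,))


def test_retention_arithmetic():
    assert retention_report({"Na": 8.75}, {"Na": 10.0})["Na"] == pytest.approx(87.50)
    assert retention_report({"x": 3.0}, {"x": 3.0})["x"] == pytest.approx(100.0)
    assert np.isnan(retention_report({"x": 3.0}, {"x": 0.0})["x"])


def test_greedy_beats_random_subsets():
    """Greedy core He >= 95th percentile of 200 random equal-size subsets."""
    params = SimParams(pop_sizes=(30, 30), alleles_per_locus=(6,) * 8,
                       fst_target=0.05, seed=21)
    m = simulate_dataset(params)
    sel = select_candidates(m, proportions=(0.25,))
    greedy = mean_he(m, sel.subsets[0.25])
    size = len(sel.subsets[0.25])
    rng = np.random.default_rng(0)
    rand = [
        mean_he(m, rng.choice(m.accession_ids, size=size, replace=False))
        for _ in range(200)
    ]
    assert greedy >= np.percentile(rand, 95)


def test_greedy_near_exhaustive_optimum():
    """Greedy He >= 0.99 x the exhaustive best subset on 16-locus instances.

    Instances mirror the study's marker-panel shape (16 loci, 4-8 alleles)
    at an exhaustively enumerable size (10 accessions, cores of 5).
    """
    rng = np.random.default_rng(0)
    for trial in range(10):
        calls = np.stack(
            [rng.integers(1, rng.integers(4, 9), size=(10, 2)) for _ in range(16)],
            axis=1,
        )
        m = make_matrix(calls)
        greedy = mean_he(m, rank_by_het(m)[-5:])
        best = max(
            mean_he(m, combo)
            for combo in itertools.combinations(m.accession_ids, 5)
        )
        assert greedy >= 0.99 * best


@pytest.mark.parametrize("paired", [True, False])
def test_core_equals_original_gives_p_one(small_random, paired):
    tt = core_vs_original_test(small_random, small_random.accession_ids, paired=paired)
    assert (tt["t"] == 0).all()
    assert (tt["p"] == 1).all()


def test_paired_t_zero_mean_differences():
    """Per-locus differences symmetric around 0 give t = 0, p = 1."""
    import scipy.stats

    t, p = scipy.stats.ttest_rel([0.6, 0.4, 0.5], [0.5, 0.5, 0.5])
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_study_like_core_not_significantly_different():
    """25% greedy core: diversity parameters non-significant in most seeds."""
    from ssrpg.synthetic_data import study_like_dataset

    wins = 0
    for seed in range(5):
        m = study_like_dataset(seed=seed)
        sel = select_candidates(m, proportions=(0.25,))
        tt = core_vs_original_test(m, sel.subsets[0.25])
        if (tt.loc[["Na", "Ne", "I", "He", "PIC"], "p"] > 0.05).all():
            wins += 1
    assert wins >= 3
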