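"""Core-collection construction by stepwise expected-heterozygosity ranking.

The greedy backward-elimination strategy: at every step, each remaining
accession's contribution to diversity is measured by leaving it out,
recomputing the set-level allele frequencies, and taking the mean
expected heterozygosity over loci; the accession whose removal leaves
the highest mean He (i.e. the lowest contributor) is removed, and the
process repeats down to a single survivor.  The removal order yields a
nested family of candidate cores: the core at proportion *p* consists of
the last ``round(p·N)`` accessions removed.

Each candidate core is evaluated with the full diversity panel (Na, Ne,
I, Ho, He, PIC means over loci, plus mean Fst when at least two
populations survive) and with per-parameter retention rates relative to
the original collection; a paired t-test across loci compares core and
original per-locus values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .diversity import locus_summaries
from .fstats_amova import AmovaError, f_statistics
from .matrix import GenotypeMatrix

__all__ = [
    "CoreSelectionResult",
    "rank_by_het",
    "select_candidates",
    "retention_report",
    "core_vs_original_test",
    "subset_size",
    "DEFAULT_PROPORTIONS",
]

#: The candidate sampling-ratio grid scanned by the emulated study.
DEFAULT_PROPORTIONS: tuple[float, ...] = (
    0.50, 0.45, 0.40, 0.35, 0.30, 0.25, 0.20, 0.15, 0.10, 0.05,
)

EVAL_PARAMS = ["Na", "Ne", "I", "Ho", "He", "PIC"]


def subset_size(n: int, proportion: float) -> int:
    """Half-up rounding of ``proportion * n`` (416 × 0.25 → 104, × 0.05 → 21)."""
    return int(np.floor(proportion * n + 0.5))


@dataclass
class CoreSelectionResult:
    """Removal order, nested candidate subsets, and their evaluation."""

    removal_order: list[str]
    subsets: dict[float, list[str]]
    evaluation: pd.DataFrame   # proportion × parameter means
    retention: pd.DataFrame    # proportion × parameter percent-of-original


def rank_by_het(matrix: GenotypeMatrix) -> list[str]:
    """Accessions in removal order (first removed = lowest He contribution).

    Deterministic: exact ties in the leave-one-out mean He are broken by
    ascending accession id.  Loci whose remaining copy count would drop
    to zero are excluded from that candidate's mean.
    """
    n, L = matrix.n_accessions, matrix.n_loci
    if n < 2:
        raise ValueError("need at least 2 accessions to rank")
    ids = np.array(matrix.accession_ids)

    # integer-code alleles per locus for count bookkeeping
    coded = np.full((n, L, 2), -1, dtype=np.int64)
    n_codes = np.zeros(L, dtype=np.int64)
    for j in range(L):
        calls = matrix.calls[:, j, :]
        scored = calls[:, 0] != 0
        if scored.any():
            codes, inv = np.unique(calls[scored], return_inverse=True)
            coded[scored, j, :] = inv.reshape(-1, 2)
            n_codes[j] = codes.size
    Amax = max(int(n_codes.max()), 1)
    counts = np.zeros((L, Amax))
    for j in range(L):
        scored = coded[:, j, 0] >= 0
        np.add.at(counts[j], coded[scored, j, :].ravel(), 1.0)
    copies = counts.sum(axis=1)            # 2 × scored individuals per locus
    sumsq = (counts**2).sum(axis=1)

    a1, a2 = coded[:, :, 0], coded[:, :, 1]          # (n, L)
    scored_il = a1 >= 0
    remaining = list(range(n))
    order: list[str] = []

    if len(set(map(tuple, np.sort(matrix.calls, axis=2).reshape(n, -1)))) == 1:
        warnings.warn("all accessions identical; removal order is pure tie-break order")

    while len(remaining) > 1:
        rem = np.array(remaining)
        c1 = counts[np.arange(L)[None, :], np.maximum(a1[rem], 0)]   # (r, L)
        c2 = counts[np.arange(L)[None, :], np.maximum(a2[rem], 0)]
        hom = a1[rem] == a2[rem]
        # change in Σc² when removing this accession's copies at the locus
        d_hom = (c1 - 2.0) ** 2 - c1**2
        d_het = ((c1 - 1.0) ** 2 - c1**2) + ((c2 - 1.0) ** 2 - c2**2)
        delta = np.where(hom, d_hom, d_het)
        sc = scored_il[rem]
        new_sumsq = sumsq[None, :] + np.where(sc, delta, 0.0)
        new_copies = copies[None, :] - np.where(sc, 2.0, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            he = 1.0 - new_sumsq / new_copies**2
        he[new_copies <= 0] = np.nan
        valid = ~np.isnan(he)
        n_valid = valid.sum(axis=1)
        mean_he = np.where(
            n_valid > 0,
            np.nansum(np.where(valid, he, 0.0), axis=1) / np.maximum(n_valid, 1),
            -np.inf,
        )

        best = mean_he.max()
        tied = np.flatnonzero(mean_he == best)
        pick = min(tied, key=lambda t: ids[rem[t]]) if tied.size > 1 else tied[0]
        victim = int(rem[pick])

        # commit removal
        for j in np.flatnonzero(scored_il[victim]):
            for a in (a1[victim, j], a2[victim, j]):
                sumsq[j] += (counts[j, a] - 1.0) ** 2 - counts[j, a] ** 2
                counts[j, a] -= 1.0
            copies[j] -= 2.0
        order.append(str(ids[victim]))
        remaining.remove(victim)
    order.append(str(ids[remaining[0]]))
    return order


def _evaluate(matrix: GenotypeMatrix) -> dict[str, float]:
    """Mean-over-loci diversity panel plus mean Fst for a collection."""
    means = locus_summaries(matrix).loc["Mean"]
    out = {p: float(means[p]) for p in EVAL_PARAMS}
    try:
        out["Fst"] = float(f_statistics(matrix).loc["Mean", "Fst"])
    except AmovaError:
        out["Fst"] = np.nan
    return out


def select_candidates(
    matrix: GenotypeMatrix,
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS,
    removal_order: list[str] | None = None,
) -> CoreSelectionResult:
    """Nested candidate cores along the greedy removal order.

    The subset at proportion ``p`` is the tail of the removal order of
    size ``round(p·N)``; every subset is re-evaluated with the full
    diversity panel and retention rates against the original collection.
    """
    if any(not 0.0 < p <= 1.0 for p in proportions):
        raise ValueError("proportions must lie in (0, 1]")
    n = matrix.n_accessions
    sizes = {p: subset_size(n, p) for p in proportions}
    if any(s == 0 for s in sizes.values()):
        bad = min(proportions)
        raise ValueError(f"proportion {bad} yields an empty subset for N={n}")
    order = removal_order if removal_order is not None else rank_by_het(matrix)

    original = _evaluate(matrix)
    eval_rows, ret_rows = {}, {}
    for p in sorted(proportions, reverse=True):
        core_ids = order[n - sizes[p]:]
        stats = _evaluate(matrix.subset(core_ids))
        eval_rows[p] = {"size": sizes[p], **stats}
        ret_rows[p] = {
            "size": sizes[p],
            **retention_report(stats, original),
        }
    evaluation = pd.DataFrame(eval_rows).T.rename_axis("proportion")
    retention = pd.DataFrame(ret_rows).T.rename_axis("proportion")
    subsets = {p: order[n - sizes[p]:] for p in proportions}
    return CoreSelectionResult(order, subsets, evaluation, retention)


def retention_report(
    core_stats: dict[str, float], original_stats: dict[str, float]
) -> dict[str, float]:
    """Percent of the original value retained, per parameter.

    ``100 × core / original``; parameters whose original value is 0 (or
    undefined) get NaN rather than a division error.
    """
    out: dict[str, float] = {}
    for param, orig in original_stats.items():
        core = core_stats.get(param, np.nan)
        if orig == 0 or not np.isfinite(orig):
            out[param] = np.nan
        else:
            out[param] = 100.0 * core / orig
    return out


def core_vs_original_test(
    matrix: GenotypeMatrix, core_ids: list[str], paired: bool = False
) -> pd.DataFrame:
    """Per-parameter t-test of core vs original per-locus diversity values.

    For each parameter the per-locus value vector on the core subset is
    tested against the vector on the full collection.  The default is
    the independent-samples t-test across loci (the convention of the
    statistics package the emulated study used); ``paired=True`` pairs
    by locus, which is far more sensitive to the systematic upward He
    shift a greedy core induces and will typically reject.  All-zero
    paired differences give t = 0, p = 1; zero-variance nonzero
    differences are degenerate and reported as NaN with a warning.
    """
    if matrix.n_loci < 2:
        raise ValueError("t-test needs at least 2 loci")
    core = locus_summaries(matrix.subset(core_ids), mean_row=False)
    orig = locus_summaries(matrix, mean_row=False)
    rows = []
    for param in EVAL_PARAMS:
        x = core[param].to_numpy(dtype=float)
        y = orig[param].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if paired:
            diff = x - y
            if np.allclose(diff, 0.0):
                t, p = 0.0, 1.0
            elif np.std(diff, ddof=1) == 0:
                warnings.warn(f"degenerate paired t-test for {param}: "
                              "constant nonzero differences")
                t, p = np.nan, np.nan
            else:
                t, p = scipy.stats.ttest_rel(x, y)
        elif np.allclose(x, y):
            t, p = 0.0, 1.0
        elif np.std(x, ddof=1) == 0 and np.std(y, ddof=1) == 0:
            warnings.warn(f"degenerate t-test for {param}: both samples constant")
            t, p = np.nan, np.nan
        else:
            t, p = scipy.stats.ttest_ind(x, y, equal_var=True)
        rows.append({"parameter": param, "t": float(t), "p": float(p)})
    return pd.DataFrame(rows).set_index("parameter")
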