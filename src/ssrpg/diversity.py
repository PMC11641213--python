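"""Per-locus and per-population SSR diversity statistics.

For a locus with allele relative frequencies ``p_i`` estimated from the
``2N`` allele copies of the ``N`` non-missing individuals:

* MAF  — major allele frequency, ``max p_i``;
* Na   — observed allele count;
* Ne   — effective allele count ``1 / Σ p_i²``;
* I    — Shannon information index ``−Σ p_i ln p_i``;
* Ho   — observed heterozygosity, heterozygous individuals / N;
* He   — Nei gene diversity ``1 − Σ p_i²`` (the biased estimator, as the
  standard toolchain reports; the unbiased ``2N/(2N−1)`` variant is an
  optional extra column);
* PIC  — Botstein polymorphism information content
  ``1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²``.

Loci with zero non-missing calls propagate NaN rather than zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix

__all__ = [
    "FrequencyTable",
    "allele_frequencies",
    "locus_statistics",
    "locus_summaries",
    "population_summaries",
]

MEAN_LABEL = "Mean"
TOTAL_LABEL = "Total"


@dataclass
class FrequencyTable:
    """Per-locus allele relative frequencies for one unit (group).

    ``freqs[locus]`` maps allele code → relative frequency among the
    non-missing calls; ``n[locus]`` is the number of scored individuals
    (so the frequencies were computed from ``2n`` allele copies). Loci
    with ``n == 0`` have an empty frequency series and are flagged.
    """

    freqs: dict[str, pd.Series]
    n: dict[str, int]

    @property
    def loci(self) -> list[str]:
        return list(self.freqs)

    @property
    def undefined_loci(self) -> list[str]:
        return [l for l, k in self.n.items() if k == 0]

    def vector(self, locus: str, codes: np.ndarray) -> np.ndarray:
        """Frequency vector aligned to the given allele-code order."""
        s = self.freqs[locus]
        return s.reindex(codes, fill_value=0.0).to_numpy()


def _locus_freq(calls_j: np.ndarray) -> tuple[pd.Series, int]:
    """Frequencies and scored-individual count for one locus column."""
    scored = calls_j[calls_j[:, 0] != 0]
    n = scored.shape[0]
    if n == 0:
        return pd.Series(dtype=float), 0
    codes, counts = np.unique(scored.ravel(), return_counts=True)
    return pd.Series(counts / (2 * n), index=codes), n


def allele_frequencies(
    matrix: GenotypeMatrix, by_population: bool = False
) -> FrequencyTable | dict[str, FrequencyTable]:
    """Allele relative frequencies, pooled or per population.

    ``p_i = copies of allele i among non-missing calls / 2N``; missing
    pairs contribute nothing. With ``by_population`` a dict of tables
    keyed by population label (order of first appearance) is returned.
    """
    if by_population:
        return {
            label: allele_frequencies(matrix.restrict_population(label))
            for label in matrix.population_labels
        }
    freqs: dict[str, pd.Series] = {}
    n: dict[str, int] = {}
    for j, locus in enumerate(matrix.locus_names):
        freqs[locus], n[locus] = _locus_freq(matrix.calls[:, j, :])
    table = FrequencyTable(freqs, n)
    if table.undefined_loci:
        warnings.warn(
            f"loci with zero non-missing calls: {table.undefined_loci}",
            stacklevel=2,
        )
    return table


def locus_statistics(p: np.ndarray) -> dict[str, float]:
    """Frequency-based statistics for one locus (p strictly positive)."""
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    sum_p2 = float(np.sum(p**2))
    # Σ_{i<j} 2 p_i² p_j²  =  (Σp²)² − Σp⁴
    het_pairs = float(sum_p2**2 - np.sum(p**4))
    return {
        "MAF": float(p.max()),
        "Na": int(p.size),
        "Ne": 1.0 / sum_p2,
        "I": float(-np.sum(p * np.log(p))),
        "He": 1.0 - sum_p2,
        "PIC": 1.0 - sum_p2 - het_pairs,
    }


def _observed_het(calls_j: np.ndarray) -> float:
    scored = calls_j[calls_j[:, 0] != 0]
    if scored.shape[0] == 0:
        return np.nan
    return float(np.mean(scored[:, 0] != scored[:, 1]))


def locus_summaries(
    matrix: GenotypeMatrix, unbiased_he: bool = False, mean_row: bool = True
) -> pd.DataFrame:
    """Per-locus diversity table from total-sample frequencies.

    Columns: N, MAF, Na, Ne, I, Ho, He, PIC (plus ``He_unbiased`` on
    request), one row per locus plus an arithmetic mean-over-loci row.
    Zero-N loci carry NaN statistics and are excluded from the means.
    """
    table = allele_frequencies(matrix)
    rows = []
    for j, locus in enumerate(matrix.locus_names):
        n = table.n[locus]
        if n == 0:
            row = {"locus": locus, "N": 0, "MAF": np.nan, "Na": np.nan,
                   "Ne": np.nan, "I": np.nan, "Ho": np.nan, "He": np.nan,
                   "PIC": np.nan}
        else:
            stats = locus_statistics(table.freqs[locus].to_numpy())
            row = {"locus": locus, "N": n, **stats,
                   "Ho": _observed_het(matrix.calls[:, j, :])}
            if unbiased_he:
                row["He_unbiased"] = stats["He"] * (2 * n) / (2 * n - 1)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("locus")
    cols = ["N", "MAF", "Na", "Ne", "I", "Ho", "He", "PIC"]
    if unbiased_he:
        cols.append("He_unbiased")
    df = df[cols]
    if mean_row:
        df.loc[MEAN_LABEL] = df.mean(axis=0, skipna=True)
    return df


def population_summaries(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-population over-loci mean diversity, plus an unweighted Total row.

    Locus statistics are recomputed on each population's individuals only
    and averaged over loci; the Total row is the unweighted mean over
    populations (not a pooled recomputation).
    """
    rows = []
    for label in matrix.population_labels:
        sub = matrix.restrict_population(label)
        if sub.n_accessions == 0:  # unreachable via restrict_population; guard
            warnings.warn(f"population {label!r} has no accessions; skipped")
            continue
        per_locus = locus_summaries(sub, mean_row=False)
        means = per_locus[["Na", "Ne", "I", "Ho", "He"]].mean(skipna=True)
        rows.append({"Pop": label, "N": sub.n_accessions,
                     "mean_Na": means["Na"], "mean_Ne": means["Ne"],
                     "I": means["I"], "Ho": means["Ho"], "He": means["He"]})
    df = pd.DataFrame(rows).set_index("Pop")
    total = df[["mean_Na", "mean_Ne", "I", "Ho", "He"]].mean()
    df.loc[TOTAL_LABEL] = {"N": df["N"].sum(), **total.to_dict()}
    df["N"] = df["N"].astype(int)
    return df
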