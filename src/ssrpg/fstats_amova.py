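"""Wright's F-statistics, island-model gene flow, and three-level AMOVA.

F-statistics use Nei's gene-diversity decomposition with unweighted
means over populations (the convention of the standard SSR toolchain;
size-weighted means are available via ``weighted=True``):

* ``Hi`` — mean over populations of observed heterozygosity;
* ``Hs`` — mean over populations of within-population He;
* ``Ht`` — He of the unweighted mean of per-population frequency vectors;
* ``Fis = (Hs − Hi)/Hs``, ``Fit = (Ht − Hi)/Ht``, ``Fst = (Ht − Hs)/Ht``;
* ``Nm = 0.25 (1 − Fst)/Fst`` (island model).

The AMOVA partitions allele-copy variance over a three-level hierarchy
(among populations / among individuals within populations / within
individuals) via allele-indicator ANOVA summed over loci and alleles,
with the squared-distance scale of the codominant convention (a
heterozygous individual-locus call contributes 0.5 to the
within-individual SS).  Individuals missing at a locus are dropped for
that locus only; the df bookkeeping is driven by the total individual
count N: df = (k−1, N−k, N), total 2N−1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import allele_frequencies, locus_statistics
from .matrix import GenotypeMatrix

__all__ = ["f_statistics", "pairwise_fst", "amova", "AmovaError", "nm_from_fst"]

AMOVA_ROWS = ["Among Pops", "Among Indiv", "Within Indiv", "Total"]


class AmovaError(ValueError):
    """The requested variance hierarchy is not computable."""


def nm_from_fst(fst: float) -> float:
    """Island-model gene-flow estimate; +inf at Fst == 0."""
    if fst == 0:
        return np.inf
    return 0.25 * (1.0 - fst) / fst


def _per_pop_arrays(matrix: GenotypeMatrix):
    """Per-population Ho, He and frequency tables for every locus."""
    labels = matrix.population_labels
    tables = allele_frequencies(matrix, by_population=True)
    return labels, tables


def f_statistics(matrix: GenotypeMatrix, weighted: bool = False) -> pd.DataFrame:
    """Per-locus (plus mean-row) Hi, Hs, Ht, Fis, Fit, Fst, Nm.

    Means over loci are arithmetic; the mean Nm is the mean of per-locus
    Nm values, not Nm of the mean Fst.  With ``weighted=True`` the
    population means are weighted by scored sample size.
    """
    labels = matrix.population_labels
    if len(labels) < 2:
        raise AmovaError("F-statistics need at least 2 populations")
    tables = allele_frequencies(matrix, by_population=True)

    rows = []
    for j, locus in enumerate(matrix.locus_names):
        hos, hes, vecs, ns = [], [], [], []
        codes = np.unique(matrix.calls[:, j, :][matrix.calls[:, j, :] > 0])
        for label in labels:
            t = tables[label]
            n = t.n[locus]
            if n == 0:
                continue
            sub_idx = matrix.population_indices(label)
            calls = matrix.calls[sub_idx, j, :]
            scored = calls[calls[:, 0] != 0]
            hos.append(float(np.mean(scored[:, 0] != scored[:, 1])))
            p = t.vector(locus, codes)
            hes.append(1.0 - float(np.sum(p**2)))
            vecs.append(p)
            ns.append(n)
        if len(vecs) < 2:
            rows.append({"locus": locus, "Hi": np.nan, "Hs": np.nan,
                         "Ht": np.nan, "Fis": np.nan, "Fit": np.nan,
                         "Fst": np.nan, "Nm": np.nan})
            continue
        w = np.asarray(ns, float) / sum(ns) if weighted else np.full(len(ns), 1 / len(ns))
        hi = float(w @ hos)
        hs = float(w @ hes)
        pbar = w @ np.vstack(vecs)
        ht = 1.0 - float(np.sum(pbar**2))
        fis = (hs - hi) / hs if hs > 0 else np.nan
        fit = (ht - hi) / ht if ht > 0 else np.nan
        fst = (ht - hs) / ht if ht > 0 else np.nan
        rows.append({"locus": locus, "Hi": hi, "Hs": hs, "Ht": ht,
                     "Fis": fis, "Fit": fit, "Fst": fst,
                     "Nm": nm_from_fst(fst) if ht > 0 else np.nan})
    df = pd.DataFrame(rows).set_index("locus")
    mean = df.mean(axis=0, skipna=True)
    mean["Nm"] = np.inf if np.isinf(df["Nm"]).any() else df["Nm"].mean(skipna=True)
    df.loc["Mean"] = mean
    return df


def pairwise_fst(matrix: GenotypeMatrix, weighted: bool = False) -> pd.DataFrame:
    """Mean-over-loci Fst for each population pair (symmetric, zero diagonal)."""
    labels = matrix.population_labels
    if len(labels) < 2:
        raise AmovaError("pairwise Fst needs at least 2 populations")
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            ids = [
                matrix.accession_ids[i]
                for i, p in enumerate(matrix.populations)
                if p in (labels[a], labels[b])
            ]
            sub = matrix.subset(ids)
            fst = f_statistics(sub, weighted=weighted).loc["Mean", "Fst"]
            out.iloc[a, b] = out.iloc[b, a] = fst
    return out


# ----------------------------------------------------------------------
# AMOVA
# ----------------------------------------------------------------------

@dataclass
class AmovaResult:
    """Three-level AMOVA table plus raw (pre-truncation) components."""

    table: pd.DataFrame
    raw_components: dict[str, float]

    def __repr__(self) -> str:  # pragma: no cover
        return repr(self.table)


def amova(matrix: GenotypeMatrix) -> AmovaResult:
    """Three-level AMOVA on allele copies of codominant diploid data.

    Sums of squares come from the allele-indicator decomposition per
    locus on the locus-wise complete cases, summed over loci, on the
    half-squared-distance scale.  Negative variance components are
    truncated to zero for the percentage column (raw values are kept in
    ``raw_components``).
    """
    labels = matrix.population_labels
    k = len(labels)
    if k < 2:
        raise AmovaError(
            "hierarchical AMOVA needs >= 2 populations; "
            "use a two-level analysis for a single population"
        )
    pop_code = np.array([labels.index(p) for p in matrix.populations])
    N = matrix.n_accessions

    ss_wi = ss_ai = ss_ap = 0.0
    for j in range(matrix.n_loci):
        calls = matrix.calls[:, j, :]
        scored = calls[:, 0] != 0
        if not scored.any():
            warnings.warn(
                f"locus {matrix.locus_names[j]!r} has no data; skipped in AMOVA"
            )
            continue
        codes, inv = np.unique(calls[scored], return_inverse=True)
        inv = inv.reshape(-1, 2)
        A = codes.size
        nj = int(scored.sum())
        # indicator vectors per allele copy: (n_scored, 2, A)
        X = np.zeros((nj, 2, A))
        X[np.arange(nj)[:, None], [0, 1], inv] = 1.0
        ind_mean = X.mean(axis=1)                      # (nj, A)
        grand = X.reshape(-1, A).mean(axis=0)          # (A,)
        pops_j = pop_code[scored]
        ss_wi += ((X - ind_mean[:, None, :]) ** 2).sum()
        for g in np.unique(pops_j):
            sel = pops_j == g
            pop_mean = ind_mean[sel].mean(axis=0)
            ss_ai += 2.0 * ((ind_mean[sel] - pop_mean) ** 2).sum()
            ss_ap += 2.0 * sel.sum() * ((pop_mean - grand) ** 2).sum()
    # half-squared-distance scale of the codominant convention
    ss_wi, ss_ai, ss_ap = 0.5 * ss_wi, 0.5 * ss_ai, 0.5 * ss_ap

    df_ap, df_ai, df_wi = k - 1, N - k, N
    df_tot = 2 * N - 1
    pop_sizes = np.bincount(pop_code, minlength=k).astype(float)
    n_c = (N - float(np.sum(pop_sizes**2)) / N) / (k - 1)

    ms_ap = ss_ap / df_ap
    ms_ai = ss_ai / df_ai
    ms_wi = ss_wi / df_wi
    raw = {
        "Within Indiv": ms_wi,
        "Among Indiv": (ms_ai - ms_wi) / 2.0,
        "Among Pops": (ms_ap - ms_ai) / (2.0 * n_c),
    }
    comp = {r: max(v, 0.0) for r, v in raw.items()}
    total_var = sum(comp.values())
    if total_var == 0:
        warnings.warn("no molecular variation: all components zero")
        pct = {r: 0.0 for r in comp}
    else:
        pct = {r: 100.0 * v / total_var for r, v in comp.items()}

    table = pd.DataFrame(
        {
            "df": [df_ap, df_ai, df_wi, df_tot],
            "SS": [ss_ap, ss_ai, ss_wi, ss_ap + ss_ai + ss_wi],
            "MS": [ms_ap, ms_ai, ms_wi, np.nan],
            "Est.Var": [comp["Among Pops"], comp["Among Indiv"],
                        comp["Within Indiv"], total_var],
            "%": [pct["Among Pops"], pct["Among Indiv"],
                  pct["Within Indiv"],
                  sum(pct.values()) if total_var else 0.0],
        },
        index=AMOVA_ROWS,
    )
    return AmovaResult(table, raw)
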