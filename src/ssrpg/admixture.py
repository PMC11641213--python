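"""Model-based population structure: admixture Gibbs sampler and Evanno ΔK.

The model is the classic admixture mixture for unlinked codominant loci:
individual *i* has ancestry proportions ``q_i`` on the K-simplex, cluster
*k* has allele frequencies ``p_kl`` at locus *l*, and each allele copy
independently picks an origin cluster ``z ~ Categorical(q_i)`` and then
an allele from ``p_{z,l}``.  A Gibbs sampler alternates:

1. ``z`` per allele copy  ∝ ``q_ik · p_kl(a)``;
2. ``p_kl ~ Dirichlet(λ + origin-weighted allele counts)``, λ = 1;
3. ``q_i ~ Dirichlet(α + per-cluster origin counts)``, α fixed.

Missing calls contribute nothing.  The model log-probability reported
for model choice is ``lnPD = mean(lnL) − var(lnL)/2`` over the recorded
post-burn-in trace (the harmonic-style estimator of the standard tool);
the Evanno ΔK table then picks K as ``argmax |L″(K)| / sd(L(K))`` over
interior K values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix

__all__ = [
    "AdmixtureResult",
    "fit_admixture",
    "structure_scan",
    "evanno",
    "align_replicates",
]


@dataclass
class AdmixtureResult:
    """Posterior summaries of one admixture-model run."""

    K: int
    accession_ids: list[str]
    Q: np.ndarray                    # (n, K) posterior-mean ancestry
    P: list[np.ndarray]              # per locus: (K, A) posterior-mean freqs
    lnPD: float
    loglik_trace: np.ndarray
    seed: int
    burn_in: int
    iterations: int

    @property
    def assignments(self) -> np.ndarray:
        """Hard cluster per accession (argmax of Q)."""
        return self.Q.argmax(axis=1)

    def q_frame(self) -> pd.DataFrame:
        cols = [f"Q{k + 1}" for k in range(self.K)]
        return pd.DataFrame(self.Q, index=self.accession_ids, columns=cols)


def _encode(matrix: GenotypeMatrix):
    """Integer-code alleles per locus; -1 marks missing copies."""
    n, L = matrix.n_accessions, matrix.n_loci
    coded = np.full((n, L, 2), -1, dtype=np.int64)
    n_alleles = np.zeros(L, dtype=np.int64)
    for j in range(L):
        calls = matrix.calls[:, j, :]
        scored = calls[:, 0] != 0
        if not scored.any():
            warnings.warn(
                f"locus {matrix.locus_names[j]!r} has no data; skipped"
            )
            continue
        codes, inv = np.unique(calls[scored], return_inverse=True)
        coded[scored, j, :] = inv.reshape(-1, 2)
        n_alleles[j] = codes.size
    keep = n_alleles > 0
    return coded[:, keep, :], n_alleles[keep]


def _dirichlet_rows(rng: np.random.Generator, conc: np.ndarray) -> np.ndarray:
    """Row-wise Dirichlet draws via gamma (vectorized over leading axes)."""
    g = rng.gamma(shape=conc)
    g = np.maximum(g, 1e-300)
    return g / g.sum(axis=-1, keepdims=True)


def fit_admixture(
    matrix: GenotypeMatrix,
    K: int,
    burn_in: int = 2000,
    iterations: int = 8000,
    seed: int = 0,
    alpha: float = 1.0,
    lam: float = 1.0,
    thin: int = 10,
) -> AdmixtureResult:
    """Gibbs-sample the admixture model and return posterior means.

    ``iterations`` is the total chain length including ``burn_in``;
    samples are recorded every ``thin`` sweeps after burn-in.  ``alpha``
    is the (fixed) Dirichlet ancestry concentration, ``lam`` the allele
    frequency prior.  Fully deterministic for a fixed seed.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if iterations <= burn_in + thin:
        raise ValueError("iterations must exceed burn_in by at least one record interval")
    rng = np.random.default_rng(seed)
    coded, n_alleles = _encode(matrix)
    n, L, _ = coded.shape
    Amax = int(n_alleles.max())
    missing = coded < 0
    safe = np.where(missing, 0, coded)  # index-safe; masked out of counts
    l_idx = np.arange(L)

    # init
    Q = np.full((n, K), 1.0 / K)
    P = _dirichlet_rows(rng, np.full((K, L, Amax), lam))
    pad = np.arange(Amax)[None, None, :] >= n_alleles[None, :, None]
    P[np.broadcast_to(pad, P.shape)] = 0.0
    P /= P.sum(axis=2, keepdims=True)

    q_sum = np.zeros((n, K))
    p_sum = np.zeros((K, L, Amax))
    ll_trace: list[float] = []
    n_rec = 0

    for it in range(iterations):
        # P evaluated at each observed allele copy: (n, L, 2, K)
        Pa = P[:, l_idx[None, :, None], safe]          # (K, n, L, 2)
        Pa = np.moveaxis(Pa, 0, -1)                    # (n, L, 2, K)
        W = Q[:, None, None, :] * Pa
        tot = W.sum(axis=3, keepdims=True)
        W = np.where(tot > 0, W / np.maximum(tot, 1e-300), 1.0 / K)
        # sample z via inverse-cdf
        cdf = np.cumsum(W, axis=3)
        u = rng.random((n, L, 2, 1))
        z = (u > cdf).sum(axis=3)                      # (n, L, 2) in 0..K-1
        z = np.minimum(z, K - 1)

        # allele counts per (k, l, a) and origin counts per (i, k)
        counts = np.zeros((K, L, Amax))
        zi = z[~missing]
        li = np.broadcast_to(l_idx[None, :, None], z.shape)[~missing]
        ai = safe[~missing]
        np.add.at(counts, (zi, li, ai), 1.0)
        R = np.zeros((n, K))
        ii = np.broadcast_to(np.arange(n)[:, None, None], z.shape)[~missing]
        np.add.at(R, (ii, zi), 1.0)

        P = _dirichlet_rows(rng, lam + counts)
        P[np.broadcast_to(pad, P.shape)] = 0.0
        P /= P.sum(axis=2, keepdims=True)
        Q = _dirichlet_rows(rng, alpha + R) if K > 1 else np.ones((n, 1))

        if it >= burn_in and (it - burn_in) % thin == 0:
            Pa = np.moveaxis(P[:, l_idx[None, :, None], safe], 0, -1)
            mix = (Q[:, None, None, :] * Pa).sum(axis=3)
            ll = float(np.log(np.maximum(mix[~missing], 1e-300)).sum())
            ll_trace.append(ll)
            q_sum += Q
            p_sum += P
            n_rec += 1

    ll_arr = np.asarray(ll_trace)
    lnpd = float(ll_arr.mean() - ll_arr.var(ddof=0) / 2.0)
    Qm = q_sum / n_rec
    Pm = p_sum / n_rec
    Pm /= Pm.sum(axis=2, keepdims=True)
    P_list = [Pm[:, j, : n_alleles[j]] for j in range(L)]
    return AdmixtureResult(
        K=K, accession_ids=list(matrix.accession_ids), Q=Qm, P=P_list,
        lnPD=lnpd, loglik_trace=ll_arr, seed=seed,
        burn_in=burn_in, iterations=iterations,
    )


def structure_scan(
    matrix: GenotypeMatrix,
    k_values: range | list[int],
    replicates: int = 10,
    seed: int = 0,
    **chain_kwargs,
) -> dict[int, list[AdmixtureResult]]:
    """Replicate runs over a K grid (seeds derived deterministically)."""
    out: dict[int, list[AdmixtureResult]] = {}
    for K in k_values:
        out[K] = [
            fit_admixture(matrix, K, seed=seed + 1000 * K + r, **chain_kwargs)
            for r in range(replicates)
        ]
    return out


# ----------------------------------------------------------------------
# Evanno ΔK
# ----------------------------------------------------------------------

def evanno(lnPD_by_K: dict[int, list[float]]) -> pd.DataFrame:
    """Evanno second-difference table and chosen K.

    ``L'(K) = mean L(K) − mean L(K−1)``; ``|L''(K)| = |L'(K+1) − L'(K)|``;
    ``ΔK = |L''(K)| / sd(L(K))``.  The chosen K (attrs["chosen_k"]) is
    the interior argmax of ΔK; a flat profile (all ΔK equal) is flagged
    ambiguous.  Endpoints have no ΔK entry by construction.
    """
    ks = sorted(lnPD_by_K)
    if len(ks) < 3:
        raise ValueError("Evanno ΔK needs at least 3 consecutive K values")
    if any(ks[i + 1] - ks[i] != 1 for i in range(len(ks) - 1)):
        raise ValueError(f"K values must be consecutive, got {ks}")
    mean = {k: float(np.mean(lnPD_by_K[k])) for k in ks}
    sd = {k: float(np.std(lnPD_by_K[k], ddof=1)) if len(lnPD_by_K[k]) > 1 else np.nan
          for k in ks}
    lp = {k: mean[k] - mean[k - 1] for k in ks[1:]}
    rows = []
    for k in ks:
        row = {"K": k, "reps": len(lnPD_by_K[k]), "mean_lnPD": mean[k],
               "sd_lnPD": sd[k], "Lprime": lp.get(k, np.nan),
               "Lsecond_abs": np.nan, "deltaK": np.nan}
        if k in ks[1:-1]:
            lpp = abs(lp[k + 1] - lp[k])
            row["Lsecond_abs"] = lpp
            if np.isnan(sd[k]):
                raise ValueError(f"K={k} needs >= 2 replicates for sd")
            if sd[k] == 0:
                warnings.warn(f"zero sd of lnPD at K={k}; ΔK set to +inf")
                row["deltaK"] = np.inf if lpp > 0 else np.nan
            else:
                row["deltaK"] = lpp / sd[k]
        rows.append(row)
    df = pd.DataFrame(rows).set_index("K")
    interior = df["deltaK"].dropna()
    if interior.empty or np.ptp(interior.to_numpy()) == 0:
        chosen, ambiguous = (int(interior.index[0]) if not interior.empty else None), True
    else:
        chosen, ambiguous = int(interior.idxmax()), False
    df.attrs["chosen_k"] = chosen
    df.attrs["ambiguous"] = ambiguous
    return df


# ----------------------------------------------------------------------
# replicate alignment (label switching)
# ----------------------------------------------------------------------

def _greedy_permutation(ref: np.ndarray, q: np.ndarray) -> list[int]:
    """Greedy column matching maximizing columnwise correlation with ref."""
    K = ref.shape[1]
    corr = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            ra, qb = ref[:, a], q[:, b]
            if ra.std() == 0 or qb.std() == 0:
                corr[a, b] = -np.inf if not np.allclose(ra, qb) else 1.0
            else:
                corr[a, b] = np.corrcoef(ra, qb)[0, 1]
    perm = [-1] * K
    used_a, used_b = set(), set()
    for _ in range(K):
        best, pair = -np.inf, None
        for a in range(K):
            if a in used_a:
                continue
            for b in range(K):
                if b in used_b:
                    continue
                if corr[a, b] > best:
                    best, pair = corr[a, b], (a, b)
        a, b = pair
        perm[a] = b
        used_a.add(a)
        used_b.add(b)
    return perm


def align_replicates(results: list[AdmixtureResult]) -> np.ndarray:
    """Align replicate Q matrices to the first and return their mean.

    Columns of each replicate are permuted by greedy correlation matching
    against the first replicate, then averaged; a single replicate is
    returned unchanged.
    """
    if not results:
        raise ValueError("no replicates given")
    K = results[0].K
    if any(r.K != K for r in results):
        raise ValueError("replicates have mixed K")
    if any(r.accession_ids != results[0].accession_ids for r in results):
        raise ValueError("replicates cover different accessions")
    ref = results[0].Q
    acc = ref.copy()
    for r in results[1:]:
        perm = _greedy_permutation(ref, r.Q)
        acc += r.Q[:, perm]
    return acc / len(results)
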