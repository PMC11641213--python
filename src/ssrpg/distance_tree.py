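"""Nei genetic distance, UPGMA dendrograms, and principal coordinates.

The distance is Nei's (1972) standard genetic distance
``D = −ln( J_xy / sqrt(J_x J_y) )`` with the gene identities J summed
over loci before the ratio; units (populations or individuals, the
latter with 0/0.5/1 genotype "frequencies") missing a locus are excluded
pairwise.  ``D`` is capped at ``NEI_CEILING`` when units share no
alleles, so downstream clustering stays finite.

UPGMA uses size-weighted average linkage with merge heights at half the
merge distance, so cophenetic distances reproduce average-linkage
distances; ties are broken on the lexicographically smallest label pair,
making the tree fully deterministic.  PCoA is classical metric scaling:
Gower double-centering of ``−½ d²`` followed by an eigendecomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .diversity import FrequencyTable, allele_frequencies
from .matrix import GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "Tree",
    "TreeNode",
    "PCoAResult",
    "nei_distance",
    "shared_allele_distance",
    "individual_frequencies",
    "upgma",
    "cut_clusters",
    "pcoa",
]

#: Cap applied to Nei D when the identity ratio is 0 (disjoint alleles).
NEI_CEILING = 10.0


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    name: str = "distance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        finite = np.isfinite(self.values)
        asym = np.nanmax(np.abs(self.values - self.values.T)) if n else 0.0
        if finite.all() and asym > 1e-12:
            raise ValueError(f"matrix not symmetric (max asymmetry {asym:g})")
        if np.diagonal(self.values).any():
            raise ValueError("nonzero diagonal")
        if (self.values[finite] < 0).any():
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ----------------------------------------------------------------------
# Nei distance
# ----------------------------------------------------------------------

def individual_frequencies(matrix: GenotypeMatrix) -> dict[str, FrequencyTable]:
    """Per-accession allele "frequencies" (0 / 0.5 / 1) per locus."""
    out: dict[str, FrequencyTable] = {}
    for i, acc in enumerate(matrix.accession_ids):
        freqs: dict[str, pd.Series] = {}
        n: dict[str, int] = {}
        for j, locus in enumerate(matrix.locus_names):
            a, b = matrix.calls[i, j]
            if a == 0:
                freqs[locus], n[locus] = pd.Series(dtype=float), 0
            elif a == b:
                freqs[locus], n[locus] = pd.Series({a: 1.0}), 1
            else:
                freqs[locus], n[locus] = pd.Series({a: 0.5, b: 0.5}), 1
        out[acc] = FrequencyTable(freqs, n)
    return out


def nei_distance(
    tables: dict[str, FrequencyTable], ceiling: float = NEI_CEILING
) -> DistanceMatrix:
    """Nei (1972) standard distance between frequency-table units.

    ``J_xy = Σ_l Σ_i x_i y_i`` etc., summed over the loci scored in both
    units; ``D = −ln(J_xy / sqrt(J_x J_y))`` clipped to ``[0, ceiling]``.
    A pair sharing zero scored loci gets a NaN entry with a warning.
    """
    labels = list(tables)
    loci = tables[labels[0]].loci
    n = len(labels)
    # stack frequency vectors over a shared allele-code order
    code_order = {
        l: np.unique(np.concatenate([tables[u].freqs[l].index.to_numpy()
                                     for u in labels
                                     if len(tables[u].freqs[l])] or [np.array([])]))
        for l in loci
    }
    offs, total = {}, 0
    for l in loci:
        offs[l] = total
        total += len(code_order[l])
    F = np.zeros((n, total))
    M = np.zeros((n, len(loci)), dtype=bool)
    S = np.zeros((n, len(loci)))
    for u, lab in enumerate(labels):
        t = tables[lab]
        for jl, l in enumerate(loci):
            if t.n[l] == 0 or len(code_order[l]) == 0:
                continue
            v = t.vector(l, code_order[l])
            F[u, offs[l] : offs[l] + len(v)] = v
            M[u, jl] = True
            S[u, jl] = float(np.sum(v**2))
    jxy = F @ F.T
    jx = S @ M.T  # Σ over shared loci of own squared-frequency sums
    jy = M @ S.T
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = jxy / np.sqrt(jx * jy)
        d = -np.log(ratio)
    shared = (M.astype(int) @ M.T.astype(int)) > 0
    if not shared.all():
        warnings.warn("some unit pairs share no scored loci; entries set to NaN")
        d[~shared] = np.nan
    d = np.where(np.isnan(d) & shared, ceiling, d)
    d = np.clip(d, 0.0, ceiling)
    d[~shared] = np.nan
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # symmetrize away float noise
    return DistanceMatrix(labels, d, name="nei1972")


def nei_distance_from_matrix(
    matrix: GenotypeMatrix, level: str = "population", ceiling: float = NEI_CEILING
) -> DistanceMatrix:
    """Convenience wrapper: Nei distance at population or individual level."""
    if level == "population":
        tables = allele_frequencies(matrix, by_population=True)
    elif level == "individual":
        tables = individual_frequencies(matrix)
    else:
        raise ValueError(f"level must be 'population' or 'individual', got {level!r}")
    return nei_distance(tables, ceiling=ceiling)


def shared_allele_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """1 − proportion of shared alleles, between individuals.

    The alternative individual-level distance: per scored locus the
    shared-allele count between two genotypes is 0, 1, or 2; the
    proportion averages count/2 over pairwise-complete loci.
    """
    n = matrix.n_accessions
    d = np.zeros((n, n))
    calls = np.sort(matrix.calls, axis=2)
    scored = calls[:, :, 0] != 0
    for a in range(n):
        for b in range(a + 1, n):
            both = scored[a] & scored[b]
            if not both.any():
                d[a, b] = d[b, a] = np.nan
                continue
            sh = 0.0
            for j in np.flatnonzero(both):
                x, y = list(calls[a, j]), list(calls[b, j])
                c = 0
                for al in x:
                    if al in y:
                        y.remove(al)
                        c += 1
                sh += c / 2.0
            d[a, b] = d[b, a] = 1.0 - sh / both.sum()
    return DistanceMatrix(list(matrix.accession_ids), d, name="shared_allele")


# ----------------------------------------------------------------------
# UPGMA
# ----------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of an ultrametric dendrogram (height = merge distance / 2)."""

    height: float
    label: str | None = None
    children: tuple["TreeNode", "TreeNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        return [l for c in self.children for l in c.leaves()]


@dataclass
class Tree:
    """Rooted binary-merge dendrogram with ultrametric heights."""

    root: TreeNode
    #: internal nodes in merge order (heights non-decreasing for UPGMA)
    merge_order: list[TreeNode] = field(default_factory=list)

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def to_newick(self) -> str:
        def fmt(node: TreeNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{bl:.6g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{bl:.6g}"

        a, b = self.root.children
        inner = ",".join(fmt(c, self.root.height) for c in (a, b))
        return f"({inner});"

    def cophenetic(self) -> DistanceMatrix:
        """Pairwise 2×(height of the lowest common ancestor)."""
        labels = self.leaves()
        pos = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> list[str]:
            if node.is_leaf:
                return [node.label]
            sides = [walk(c) for c in node.children]
            for la in sides[0]:
                for lb in sides[1]:
                    d[pos[la], pos[lb]] = d[pos[lb], pos[la]] = 2.0 * node.height
            return sides[0] + sides[1]

        walk(self.root)
        return DistanceMatrix(labels, d, name="cophenetic")


def upgma(dm: DistanceMatrix) -> Tree:
    """Size-weighted average-linkage clustering with deterministic ties.

    Repeatedly merges the closest cluster pair; distance of the merged
    cluster to any other is the size-weighted mean of its parts; merge
    height is half the merge distance.  Exact distance ties go to the
    pair whose (sorted) representative labels — the lexicographically
    smallest leaf label in each cluster — compare smallest.
    """
    if dm.n < 2:
        raise ValueError("UPGMA needs at least 2 labels")
    if np.isnan(dm.values).any():
        raise ValueError(
            "distance matrix has undefined entries; impute or cap them first"
        )
    d = dm.values.copy()
    nodes = [TreeNode(0.0, label=l) for l in dm.labels]
    reps = list(dm.labels)  # lexicographic representative per cluster
    sizes = [1] * dm.n
    active = list(range(dm.n))
    merges: list[TreeNode] = []

    while len(active) > 1:
        idx = np.array(active)
        sub = d[np.ix_(idx, idx)]
        iu, ju = np.triu_indices(len(idx), 1)
        vals = sub[iu, ju]
        dist = float(vals.min())
        cand = np.flatnonzero(vals == dist)
        if cand.size == 1:
            a, b = int(idx[iu[cand[0]]]), int(idx[ju[cand[0]]])
        else:
            best_key, a, b = None, -1, -1
            for c in cand:
                ca, cb = int(idx[iu[c]]), int(idx[ju[c]])
                key = tuple(sorted((reps[ca], reps[cb])))
                if best_key is None or key < best_key:
                    best_key, a, b = key, ca, cb
        node = TreeNode(dist / 2.0, children=(nodes[a], nodes[b]))
        merges.append(node)
        # weighted average distance to all other active clusters
        for c in active:
            if c in (a, b):
                continue
            d[a, c] = d[c, a] = (sizes[a] * d[a, c] + sizes[b] * d[b, c]) / (
                sizes[a] + sizes[b]
            )
        nodes[a] = node
        sizes[a] += sizes[b]
        reps[a] = min(reps[a], reps[b])
        active.remove(b)
    return Tree(root=merges[-1], merge_order=merges)


def cut_clusters(tree: Tree, k: int) -> dict[str, int]:
    """Cut the k−1 highest merges; cluster ids assigned in leaf order."""
    leaves = tree.leaves()
    if not 1 <= k <= len(leaves):
        raise ValueError(f"k must be in [1, {len(leaves)}], got {k}")
    cut = set(id(n) for n in tree.merge_order[len(tree.merge_order) - (k - 1):])

    clusters: list[list[str]] = []

    def walk(node: TreeNode) -> None:
        if not node.is_leaf and id(node) in cut:
            for c in node.children:
                walk(c)
        else:
            clusters.append(node.leaves())

    walk(tree.root)
    # ids in leaf order: cluster containing the earliest leaf gets id 1, etc.
    order = {l: i for i, l in enumerate(leaves)}
    clusters.sort(key=lambda c: min(order[l] for l in c))
    return {l: cid + 1 for cid, c in enumerate(clusters) for l in c}


# ----------------------------------------------------------------------
# PCoA
# ----------------------------------------------------------------------

@dataclass
class PCoAResult:
    """Classical-scaling coordinates with eigenvalues and variance shares."""

    labels: list[str]
    coordinates: np.ndarray      # (n, axes)
    eigenvalues: np.ndarray      # all, non-increasing (negatives included)
    percent_variance: np.ndarray  # over positive eigenvalues, sums to 100

    def to_frame(self) -> pd.DataFrame:
        cols = [f"Axis{j + 1}" for j in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def pcoa(dm: DistanceMatrix, axes: int = 2) -> PCoAResult:
    """Principal coordinate analysis via Gower double-centering.

    ``B = −½ C d² C`` with the centering matrix C; coordinates are the
    eigenvectors of B scaled by the square roots of the (positive)
    eigenvalues.  Negative eigenvalues are reported but excluded from
    the coordinates; each axis's sign is fixed so its largest-magnitude
    loading is positive.
    """
    if dm.n < 2:
        raise ValueError("PCoA needs at least 2 labels")
    if np.isnan(dm.values).any():
        raise ValueError("distance matrix has undefined entries")
    n = dm.n
    d2 = dm.values**2
    C = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * C @ d2 @ C
    B = (B + B.T) / 2.0
    evals, evecs = scipy.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12 * max(abs(evals[0]), 1.0), 0.0)
    n_pos = int(pos.sum())
    if axes > n_pos:
        warnings.warn(
            f"requested {axes} axes but only {n_pos} positive eigenvalues; truncated"
        )
        axes = n_pos
    coords = evecs[:, :axes] * np.sqrt(np.clip(evals[:axes], 0.0, None))
    for j in range(axes):
        col = coords[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    pos_sum = evals[pos].sum()
    pct = np.zeros_like(evals)
    if pos_sum > 0:
        pct[pos] = 100.0 * evals[pos] / pos_sum
    return PCoAResult(list(dm.labels), coords, evals, pct)
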