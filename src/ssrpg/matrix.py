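"""Diploid multi-locus SSR genotype matrix — the pipeline's shared currency.

Allele calls are opaque positive integers (in practice, fragment sizes in
bp); 0 is the internal missing sentinel and missingness is pair-level:
a half-missing call is promoted to a fully missing pair at validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Internal missing sentinel for a single allele slot.
MISSING = 0


class GenotypeValidationError(ValueError):
    """A genotype matrix violates a structural invariant."""


@dataclass
class GenotypeMatrix:
    """Codominant diploid genotypes for a set of accessions.

    Parameters
    ----------
    accession_ids
        Ordered unique accession identifiers.
    populations
        Population label per accession (parallel to ``accession_ids``).
    locus_names
        Ordered unique locus names.
    calls
        Integer array of shape ``(n_accessions, n_loci, 2)``; allele codes
        are strictly positive, ``0`` marks a missing call. Missingness is
        pair-level after validation.
    """

    accession_ids: list[str]
    populations: list[str]
    locus_names: list[str]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.populations = [str(p) for p in self.populations]
        self.locus_names = [str(l) for l in self.locus_names]
        self.calls = np.asarray(self.calls, dtype=np.int64)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        n, m = len(self.accession_ids), len(self.locus_names)
        if m == 0:
            raise GenotypeValidationError("matrix has no loci")
        if n == 0:
            raise GenotypeValidationError("matrix has no accessions")
        if len(self.populations) != n:
            raise GenotypeValidationError(
                f"{len(self.populations)} population labels for {n} accessions"
            )
        if self.calls.shape != (n, m, 2):
            raise GenotypeValidationError(
                f"calls shape {self.calls.shape} != {(n, m, 2)}"
            )
        dup = _first_duplicate(self.accession_ids)
        if dup is not None:
            raise GenotypeValidationError(f"duplicate accession id {dup!r}")
        dup = _first_duplicate(self.locus_names)
        if dup is not None:
            raise GenotypeValidationError(f"duplicate locus name {dup!r}")
        if (self.calls < 0).any():
            i, j, _ = np.argwhere(self.calls < 0)[0]
            raise GenotypeValidationError(
                f"negative allele code at accession {self.accession_ids[i]!r}, "
                f"locus {self.locus_names[j]!r}"
            )
        # pair-level missingness: promote half-missing pairs
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, j = np.argwhere(half)[0]
            warnings.warn(
                f"{half.sum()} half-missing call(s) promoted to missing "
                f"(first at accession {self.accession_ids[i]!r}, "
                f"locus {self.locus_names[j]!r})",
                stacklevel=2,
            )
            self.calls[half] = MISSING

    # ------------------------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def population_labels(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_accessions, n_loci)``: True where the pair is missing."""
        return self.calls[:, :, 0] == MISSING

    def population_indices(self, label: str) -> np.ndarray:
        idx = np.array([i for i, p in enumerate(self.populations) if p == label])
        if idx.size == 0:
            raise KeyError(f"no accessions in population {label!r}")
        return idx

    # ------------------------------------------------------------------
    def subset(self, accession_ids) -> "GenotypeMatrix":
        """Restrict to the given accessions (given order preserved)."""
        pos = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            idx = [pos[a] for a in accession_ids]
        except KeyError as e:
            raise KeyError(f"unknown accession id {e.args[0]!r}") from None
        return GenotypeMatrix(
            [self.accession_ids[i] for i in idx],
            [self.populations[i] for i in idx],
            list(self.locus_names),
            self.calls[idx].copy(),
        )

    def restrict_population(self, label: str) -> "GenotypeMatrix":
        idx = self.population_indices(label)
        return self.subset([self.accession_ids[i] for i in idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.accession_ids == other.accession_ids
            and self.populations == other.populations
            and self.locus_names == other.locus_names
            and bool(np.array_equal(_canon(self.calls), _canon(other.calls)))
        )


def _canon(calls: np.ndarray) -> np.ndarray:
    """Sort each allele pair so {a,b} == {b,a}."""
    return np.sort(calls, axis=2)


def _first_duplicate(items) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None
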