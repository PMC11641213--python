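"""Read and write SSR genotype tables in the two community dialects.

Two formats cover the toolchains this kind of study uses:

* a GenAlEx-style codominant CSV — three header lines (counts; titles;
  population names), then one row per individual with two columns per
  locus; ``0`` codes a missing allele;
* the STRUCTURE flat text format — two rows per individual, one allele
  per locus per row, ``-9`` missing, integer population codes.

A long-form CSV (one row per accession/locus/allele-slot) is provided for
spreadsheet work. All I/O is UTF-8 with ``\\n`` newlines; exports are
byte-stable for a fixed matrix.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .matrix import MISSING, GenotypeMatrix

STRUCTURE_MISSING = -9

__all__ = [
    "read_genalex",
    "write_genalex",
    "read_structure",
    "write_structure",
    "write_csv_long",
    "export",
    "FormatError",
]


class FormatError(ValueError):
    """Malformed genotype file."""


# ----------------------------------------------------------------------
# GenAlEx dialect
# ----------------------------------------------------------------------

def read_genalex(path) -> GenotypeMatrix:
    """Parse a GenAlEx-dialect codominant CSV.

    Header line 1: ``n_loci,n_samples,n_pops,size_1,...,size_npops``;
    line 2: ``Sample,Pop`` then each locus name followed by a blank
    column; line 3: two blanks then the population names. Data rows:
    ``id,pop,allele,allele,...``. Population assignment follows the
    header's population blocks; ``0`` is missing.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) < 4:
        raise FormatError(f"{path}: fewer than 4 lines; not a GenAlEx file")
    counts = lines[0].split(",")
    try:
        n_loci, n_samples, n_pops = (int(x) for x in counts[:3])
        pop_sizes = [int(x) for x in counts[3 : 3 + n_pops]]
    except (ValueError, IndexError):
        raise FormatError(f"{path}: bad counts header {lines[0]!r}") from None
    if len(pop_sizes) != n_pops or sum(pop_sizes) != n_samples:
        raise FormatError(
            f"{path}: population sizes {pop_sizes} do not sum to "
            f"declared sample count {n_samples}"
        )
    title = lines[1].split(",")
    locus_names = [title[2 + 2 * j] for j in range(n_loci)]
    if any(not nm for nm in locus_names):
        raise FormatError(f"{path}: empty locus name in title row")
    popline = lines[2].split(",")
    pop_labels = [x for x in popline if x.strip()]
    if len(pop_labels) != n_pops:
        raise FormatError(
            f"{path}: {len(pop_labels)} population names for declared {n_pops}"
        )

    rows = lines[3:]
    if len(rows) != n_samples:
        raise FormatError(
            f"{path}: {len(rows)} data rows but header declares {n_samples} "
            f"samples (first mismatching row is row {min(len(rows), n_samples) + 4})"
        )
    block = np.repeat(pop_labels, pop_sizes)

    ids: list[str] = []
    pops: list[str] = []
    calls = np.zeros((n_samples, n_loci, 2), dtype=np.int64)
    for r, line in enumerate(rows):
        cells = line.split(",")
        if len(cells) < 2 + 2 * n_loci:
            raise FormatError(
                f"{path}: row {r + 4} has {len(cells)} columns, "
                f"expected {2 + 2 * n_loci}"
            )
        ids.append(cells[0].strip())
        pops.append(block[r])
        for j in range(n_loci):
            for s in range(2):
                cell = cells[2 + 2 * j + s].strip()
                try:
                    calls[r, j, s] = int(cell) if cell else MISSING
                except ValueError:
                    raise FormatError(
                        f"{path}: non-integer allele {cell!r} at row {r + 4}, "
                        f"locus {locus_names[j]!r}"
                    ) from None
    return GenotypeMatrix(ids, pops, locus_names, calls)


def write_genalex(matrix: GenotypeMatrix, path) -> None:
    """Write the GenAlEx dialect (deterministic byte-stable output)."""
    labels = matrix.population_labels
    sizes = [len(matrix.population_indices(p)) for p in labels]
    out = [
        ",".join(
            [str(matrix.n_loci), str(matrix.n_accessions), str(len(labels))]
            + [str(s) for s in sizes]
        ),
        ",".join(["Sample", "Pop"] + [c for nm in matrix.locus_names for c in (nm, "")]),
        ",".join(["", ""] + labels),
    ]
    # rows grouped by population block, preserving within-population order
    for label in labels:
        for i in matrix.population_indices(label):
            cells = [matrix.accession_ids[i], label]
            cells += [str(int(a)) for a in matrix.calls[i].ravel()]
            out.append(",".join(cells))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ----------------------------------------------------------------------
# STRUCTURE dialect
# ----------------------------------------------------------------------

def read_structure(path, markers: list[str] | None = None) -> GenotypeMatrix:
    """Parse STRUCTURE two-row-per-individual text.

    Column 1 is the individual id, column 2 an integer population code,
    then one allele per locus; each individual occupies two consecutive
    rows; ``-9`` is missing. Population codes are mapped to labels
    ``"pop<code>"`` in ascending order of first appearance unless the
    codes are resolvable some other way by the caller.
    """
    lines = [ln.split() for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln.strip()]
    if len(lines) % 2:
        raise FormatError(f"{path}: odd number of data rows ({len(lines)})")
    if not lines:
        raise FormatError(f"{path}: empty file")
    n_loci = len(lines[0]) - 2
    if n_loci < 1:
        raise FormatError(f"{path}: rows have no allele columns")
    if markers is None:
        markers = [f"locus{j + 1}" for j in range(n_loci)]
    if len(markers) != n_loci:
        raise FormatError(
            f"{path}: {len(markers)} marker names given for {n_loci} allele columns"
        )
    n = len(lines) // 2
    ids: list[str] = []
    pops: list[str] = []
    calls = np.zeros((n, n_loci, 2), dtype=np.int64)
    for i in range(n):
        row_a, row_b = lines[2 * i], lines[2 * i + 1]
        if row_a[0] != row_b[0]:
            raise FormatError(
                f"{path}: rows {2 * i + 1}/{2 * i + 2} have mismatched ids "
                f"{row_a[0]!r} vs {row_b[0]!r}"
            )
        if len(row_a) != n_loci + 2 or len(row_b) != n_loci + 2:
            raise FormatError(f"{path}: ragged row for individual {row_a[0]!r}")
        ids.append(row_a[0])
        pops.append(f"pop{int(row_a[1])}")
        for j in range(n_loci):
            try:
                a, b = int(row_a[2 + j]), int(row_b[2 + j])
            except ValueError:
                raise FormatError(
                    f"{path}: non-integer allele for individual {row_a[0]!r}, "
                    f"marker {markers[j]!r}"
                ) from None
            if a == STRUCTURE_MISSING or b == STRUCTURE_MISSING:
                a = b = MISSING
            calls[i, j] = (a, b)
    return GenotypeMatrix(ids, pops, markers, calls)


def write_structure(matrix: GenotypeMatrix, path) -> None:
    """Write STRUCTURE two-row format; population codes follow label order."""
    code = {p: k + 1 for k, p in enumerate(matrix.population_labels)}
    out: list[str] = []
    for i, acc in enumerate(matrix.accession_ids):
        for s in range(2):
            cells = [acc, str(code[matrix.populations[i]])]
            for j in range(matrix.n_loci):
                a = int(matrix.calls[i, j, s])
                cells.append(str(STRUCTURE_MISSING if a == MISSING else a))
            out.append(" ".join(cells))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ----------------------------------------------------------------------
# long CSV + dispatch
# ----------------------------------------------------------------------

def write_csv_long(matrix: GenotypeMatrix, path) -> None:
    """One row per accession/locus/allele-slot; missing written as empty."""
    out = ["accession,population,locus,slot,allele"]
    for i, acc in enumerate(matrix.accession_ids):
        for j, loc in enumerate(matrix.locus_names):
            for s in range(2):
                a = int(matrix.calls[i, j, s])
                out.append(
                    f"{acc},{matrix.populations[i]},{loc},{s + 1},"
                    f"{'' if a == MISSING else a}"
                )
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


_WRITERS = {
    "genalex": write_genalex,
    "structure": write_structure,
    "csv_long": write_csv_long,
}


def export(matrix: GenotypeMatrix, format: str, path) -> None:
    """Write ``matrix`` in one of ``genalex``, ``structure``, ``csv_long``."""
    try:
        writer = _WRITERS[format]
    except KeyError:
        raise ValueError(
            f"unknown format {format!r}; expected one of {sorted(_WRITERS)}"
        ) from None
    writer(matrix, path)
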