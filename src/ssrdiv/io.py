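"""Readers and writers for the external formats the pipeline touches.

Formats
-------
* genotype CSV/TSV: header ``id,<locus>.1,<locus>.2,...``; one row per
  individual; two allele-size fields per locus; configurable missing token
  (default ``-9``).
* band CSV/TSV: header ``id,<locus>:<band>,...``; 0/1/missing scores.
* population map TSV: ``individual<TAB>population[<TAB>group]``.
* STRUCTURE flat file: two whitespace-separated rows per individual, each
  ``id pop_code allele_1 ... allele_L`` (one allele copy per row).
* PHYLIP square distance matrix; Newick trees (via dendropy).
"""

from __future__ import annotations

import csv
import io as _io
import math
from pathlib import Path
from typing import Iterable, TextIO, Union

import dendropy
import numpy as np

from .types import (
    DEFAULT_MISSING_TOKEN,
    INF_DISTANCE,
    MISSING_INT,
    AlleleMatrix,
    BandMatrix,
    DataError,
    DistanceMatrix,
    PopulationMap,
)

Source = Union[str, Path, TextIO]


class ParseError(DataError):
    """Raised when an input file cannot be parsed."""


def _read_text(source: Source) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str):
        if "\n" in source:  # file content passed directly
            return source
        p = Path(source)
        if p.exists():
            return p.read_text()
        raise FileNotFoundError(source)
    return source.read()


def _sniff_delimiter(text: str) -> str:
    first = text.splitlines()[0] if text.splitlines() else ""
    return "\t" if "\t" in first else ","


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------


def _parse_allele(token: str, missing_token: str, row: int, col: str) -> int:
    token = token.strip()
    if token == missing_token or token == "":
        return MISSING_INT
    try:
        value = int(token)
    except ValueError:
        raise ParseError(
            f"non-integer allele label {token!r} at data row {row}, column {col}"
        ) from None
    if value <= 0:
        raise ParseError(
            f"allele label must be positive, got {value} at data row {row}, "
            f"column {col}"
        )
    return value


def read_allele_matrix(
    source: Source,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    delimiter: str | None = None,
) -> AlleleMatrix:
    """Parse a genotype CSV/TSV into an :class:`AlleleMatrix`.

    The header is ``id`` followed by two columns per locus named
    ``<locus>.1`` and ``<locus>.2``.  Either allele field equal to
    ``missing_token`` makes the whole call missing.
    """
    text = _read_text(source)
    delim = delimiter or _sniff_delimiter(text)
    rows = [r for r in csv.reader(_io.StringIO(text), delimiter=delim) if r]
    if not rows:
        raise ParseError("empty genotype file")
    header = [h.strip() for h in rows[0]]
    if len(header) < 3 or (len(header) - 1) % 2 != 0:
        raise ParseError(
            "header must be 'id' followed by two columns per locus "
            f"(<locus>.1, <locus>.2); got {len(header)} columns"
        )
    loci = []
    for j in range(1, len(header), 2):
        a, b = header[j], header[j + 1]
        if not (a.endswith(".1") and b.endswith(".2") and a[:-2] == b[:-2]):
            raise ParseError(
                f"header columns {j} and {j + 1} ({a!r}, {b!r}) do not form a "
                "'<locus>.1','<locus>.2' pair"
            )
        loci.append(a[:-2])

    individuals: list[str] = []
    calls = np.full((len(rows) - 1, len(loci), 2), MISSING_INT, dtype=np.int64)
    for r, row in enumerate(rows[1:], start=1):
        if len(row) != len(header):
            raise ParseError(
                f"ragged data row {r}: expected {len(header)} fields, got {len(row)}"
            )
        individuals.append(row[0].strip())
        for l, locus in enumerate(loci):
            a = _parse_allele(row[1 + 2 * l], missing_token, r, f"{locus}.1")
            b = _parse_allele(row[2 + 2 * l], missing_token, r, f"{locus}.2")
            if (a == MISSING_INT) != (b == MISSING_INT):
                # one copy missing makes the diploid call missing
                a = b = MISSING_INT
            calls[r - 1, l] = (a, b)
    try:
        return AlleleMatrix(individuals, loci, calls)
    except DataError as exc:
        raise ParseError(str(exc)) from exc


def write_allele_matrix(
    m: AlleleMatrix,
    dest: Source | None = None,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    delimiter: str = ",",
) -> str:
    """Serialise an :class:`AlleleMatrix` to the genotype CSV/TSV dialect."""
    buf = _io.StringIO()
    w = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    header = ["id"]
    for locus in m.loci:
        header += [f"{locus}.1", f"{locus}.2"]
    w.writerow(header)
    for i, ind in enumerate(m.individuals):
        row = [ind]
        for l in range(m.n_loci):
            a, b = m.calls[i, l]
            row += [missing_token if a == MISSING_INT else str(a),
                    missing_token if b == MISSING_INT else str(b)]
        w.writerow(row)
    return _finish_write(buf.getvalue(), dest)


def _finish_write(text: str, dest: Source | None) -> str:
    if dest is None:
        return text
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)
    return text


# ---------------------------------------------------------------------------
# band matrix
# ---------------------------------------------------------------------------


def read_band_matrix(
    source: Source,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    delimiter: str | None = None,
) -> BandMatrix:
    """Parse a 0/1 band-score CSV/TSV (header ``id,<locus>:<band>,...``)."""
    text = _read_text(source)
    delim = delimiter or _sniff_delimiter(text)
    rows = [r for r in csv.reader(_io.StringIO(text), delimiter=delim) if r]
    if not rows:
        raise ParseError("empty band file")
    header = [h.strip() for h in rows[0]]
    bands: list[tuple[str, int]] = []
    for col in header[1:]:
        if ":" not in col:
            raise ParseError(f"band column {col!r} is not of the form <locus>:<band>")
        locus, _, band = col.rpartition(":")
        try:
            bands.append((locus, int(band)))
        except ValueError:
            raise ParseError(f"band label in column {col!r} is not an integer") from None
    individuals = []
    scores = np.full((len(rows) - 1, len(bands)), MISSING_INT, dtype=np.int8)
    for r, row in enumerate(rows[1:], start=1):
        if len(row) != len(header):
            raise ParseError(
                f"ragged data row {r}: expected {len(header)} fields, got {len(row)}"
            )
        individuals.append(row[0].strip())
        for j, tok in enumerate(row[1:]):
            tok = tok.strip()
            if tok == missing_token or tok == "":
                continue
            if tok not in ("0", "1"):
                raise ParseError(
                    f"band score must be 0/1/{missing_token}, got {tok!r} at "
                    f"data row {r}, column {header[1 + j]}"
                )
            scores[r - 1, j] = int(tok)
    return BandMatrix(individuals, bands, scores)


def write_band_matrix(
    b: BandMatrix,
    dest: Source | None = None,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    delimiter: str = ",",
) -> str:
    buf = _io.StringIO()
    w = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    w.writerow(["id"] + [f"{l}:{band}" for l, band in b.bands])
    for i, ind in enumerate(b.individuals):
        w.writerow(
            [ind]
            + [missing_token if s == MISSING_INT else str(int(s)) for s in b.scores[i]]
        )
    return _finish_write(buf.getvalue(), dest)


# ---------------------------------------------------------------------------
# population map
# ---------------------------------------------------------------------------


def read_population_map(source: Source) -> PopulationMap:
    """Parse a TSV ``individual<TAB>population[<TAB>group]`` file."""
    text = _read_text(source)
    assignment: dict[str, str] = {}
    group: dict[str, str] = {}
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) not in (2, 3):
            raise ParseError(
                f"population map line {ln}: expected 2 or 3 tab-separated "
                f"fields, got {len(parts)}"
            )
        ind, pop = parts[0].strip(), parts[1].strip()
        if ind in assignment:
            raise ParseError(f"duplicate individual {ind!r} at line {ln}")
        assignment[ind] = pop
        if len(parts) == 3:
            group[pop] = parts[2].strip()
    return PopulationMap(assignment, group or None)


def write_population_map(pm: PopulationMap, dest: Source | None = None) -> str:
    lines = []
    for ind, pop in pm.assignment.items():
        if pm.group is not None:
            lines.append(f"{ind}\t{pop}\t{pm.group[pop]}")
        else:
            lines.append(f"{ind}\t{pop}")
    return _finish_write("\n".join(lines) + "\n", dest)


# ---------------------------------------------------------------------------
# STRUCTURE flat file
# ---------------------------------------------------------------------------


def read_structure_format(
    source: Source, missing_token: str = DEFAULT_MISSING_TOKEN
) -> tuple[AlleleMatrix, PopulationMap]:
    """Parse a STRUCTURE flat file (two rows per individual).

    Each data row is ``id pop_code allele_1 ... allele_L`` (whitespace
    separated); consecutive row pairs are the two allele copies of one
    diploid individual.  An optional first line carrying only locus names
    (two fewer tokens than the data rows) is used as the locus header.
    """
    text = _read_text(source)
    lines = [l.split() for l in text.splitlines() if l.strip()]
    if not lines:
        raise ParseError("empty STRUCTURE file")
    loci: list[str] | None = None
    if len(lines) > 1 and len(lines[0]) == len(lines[1]) - 2:
        loci = lines[0]
        lines = lines[1:]
    if len(lines) % 2 != 0:
        raise ParseError(
            f"STRUCTURE file has {len(lines)} data rows; expected an even "
            "count (two rows per individual)"
        )
    n_loci = len(lines[0]) - 2
    if n_loci < 1:
        raise ParseError("STRUCTURE rows must have at least one locus column")
    if loci is None:
        loci = [f"L{j + 1}" for j in range(n_loci)]

    individuals: list[str] = []
    assignment: dict[str, str] = {}
    calls = np.full((len(lines) // 2, n_loci, 2), MISSING_INT, dtype=np.int64)
    for i in range(0, len(lines), 2):
        r1, r2 = lines[i], lines[i + 1]
        if len(r1) != n_loci + 2 or len(r2) != n_loci + 2:
            raise ParseError(f"ragged STRUCTURE rows for individual at row {i + 1}")
        if r1[0] != r2[0] or r1[1] != r2[1]:
            raise ParseError(
                f"row pair at rows {i + 1}-{i + 2} disagree on id/pop "
                f"({r1[0]}/{r1[1]} vs {r2[0]}/{r2[1]})"
            )
        ind = r1[0]
        individuals.append(ind)
        assignment[ind] = r1[1]
        for l in range(n_loci):
            a = _parse_allele(r1[2 + l], missing_token, i + 1, loci[l])
            b = _parse_allele(r2[2 + l], missing_token, i + 2, loci[l])
            if MISSING_INT in (a, b):
                a = b = MISSING_INT
            calls[i // 2, l] = (a, b)
    try:
        return AlleleMatrix(individuals, loci, calls), PopulationMap(assignment)
    except DataError as exc:
        raise ParseError(str(exc)) from exc


def write_structure_format(
    m: AlleleMatrix,
    pm: PopulationMap,
    dest: Source | None = None,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    header: bool = True,
) -> str:
    pm.validate_against(m.individuals)
    pops = pm.populations
    lines = []
    if header:
        lines.append(" ".join(m.loci))
    for i, ind in enumerate(m.individuals):
        code = str(pops.index(pm.population_of(ind)) + 1)
        for copy in (0, 1):
            alleles = [
                missing_token if a == MISSING_INT else str(a)
                for a in m.calls[i, :, copy]
            ]
            lines.append(" ".join([ind, code] + alleles))
    return _finish_write("\n".join(lines) + "\n", dest)


# ---------------------------------------------------------------------------
# dominant -> codominant conversion
# ---------------------------------------------------------------------------


def bands_to_alleles(b: BandMatrix) -> AlleleMatrix:
    """Convert dominant 0/1 band scores into codominant diploid calls.

    One present band at a locus is read as a homozygote for that band's
    allele (appropriate for a predominantly selfing diploid); two present
    bands as a heterozygote; zero present bands, or any missing band score
    at the locus, as a missing call.
    """
    loci = b.loci
    calls = np.full((len(b.individuals), len(loci), 2), MISSING_INT, dtype=np.int64)
    offenders: list[str] = []
    for l, locus in enumerate(loci):
        idx = b.band_indices(locus)
        labels = np.array([b.bands[j][1] for j in idx])
        sub = b.scores[:, idx]
        for i, ind in enumerate(b.individuals):
            row = sub[i]
            if (row == MISSING_INT).any():
                continue
            present = labels[row == 1]
            if len(present) > 2:
                offenders.append(f"{ind}@{locus}")
            elif len(present) == 1:
                calls[i, l] = (present[0], present[0])
            elif len(present) == 2:
                calls[i, l] = (present[0], present[1])
    if offenders:
        raise DataError(
            "more than 2 bands present at a single locus for: "
            + ", ".join(offenders)
        )
    return AlleleMatrix(list(b.individuals), loci, calls)


def alleles_to_bands(m: AlleleMatrix) -> BandMatrix:
    """Derive a band matrix (one band per observed allele) from calls."""
    bands: list[tuple[str, int]] = []
    for l, locus in enumerate(m.loci):
        alleles = np.unique(m.calls[:, l, :])
        for a in alleles[alleles != MISSING_INT]:
            bands.append((locus, int(a)))
    scores = np.zeros((m.n_individuals, len(bands)), dtype=np.int8)
    for j, (locus, band) in enumerate(bands):
        l = m.locus_index(locus)
        present = (m.calls[:, l, :] == band).any(axis=1)
        missing = m.calls[:, l, 0] == MISSING_INT
        scores[:, j] = np.where(missing, MISSING_INT, present.astype(np.int8))
    return BandMatrix(list(m.individuals), bands, scores)


# ---------------------------------------------------------------------------
# trees and distance matrices
# ---------------------------------------------------------------------------


def write_newick(tree: dendropy.Tree, dest: Source | None = None) -> str:
    """Serialise a tree to Newick with branch lengths and support labels."""
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise DataError("every leaf must carry a non-empty label")
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_internal_node_labels=False,
    ).strip() + "\n"
    return _finish_write(text, dest)


def read_newick(source: Source) -> dendropy.Tree:
    text = _read_text(source)
    return dendropy.Tree.get(data=text, schema="newick")


def write_distance_phylip(
    d: DistanceMatrix, dest: Source | None = None, precision: int = 6
) -> str:
    """Serialise a :class:`DistanceMatrix` in square PHYLIP format.

    Infinite entries are written as the literal ``Inf``.
    """
    lines = [f"{d.n}"]
    for label, row in zip(d.labels, d.values):
        if not label:
            raise DataError("empty label in distance matrix")
        cells = ["Inf" if math.isinf(v) else f"{v:.{precision}f}" for v in row]
        lines.append("\t".join([label] + cells))
    return _finish_write("\n".join(lines) + "\n", dest)


def read_distance_phylip(source: Source) -> DistanceMatrix:
    text = _read_text(source)
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines:
        raise ParseError("empty distance file")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise ParseError("first line must be the matrix dimension") from None
    if len(lines) != n + 1:
        raise ParseError(f"expected {n} matrix rows, found {len(lines) - 1}")
    labels, values = [], np.zeros((n, n))
    for i, line in enumerate(lines[1:]):
        parts = line.split()
        if len(parts) != n + 1:
            raise ParseError(f"row {i + 1}: expected label + {n} values")
        labels.append(parts[0])
        values[i] = [
            INF_DISTANCE if p.lower() == "inf" else float(p) for p in parts[1:]
        ]
    return DistanceMatrix(labels, values)
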