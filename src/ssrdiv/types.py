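"""Shared data model for codominant SSR genotypes and derived objects.

Allele calls are stored as integer allele labels (fragment sizes in base
pairs), two per individual per locus.  Missing data uses the internal
sentinel ``MISSING_INT`` (-1) in arrays; external files use a configurable
missing token (default ``"-9"``, the STRUCTURE convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: internal sentinel for a missing allele copy in integer arrays
MISSING_INT = -1

#: default external missing-data token
DEFAULT_MISSING_TOKEN = "-9"

#: sentinel for an infinite genetic distance (zero shared identity)
INF_DISTANCE = np.inf


class DataError(ValueError):
    """Raised when input data violate a structural invariant."""


def _check_unique(names: Sequence[str], what: str) -> None:
    seen = set()
    for n in names:
        if n in seen:
            raise DataError(f"duplicate {what} identifier: {n!r}")
        seen.add(n)


@dataclass
class AlleleMatrix:
    """Diploid codominant genotype matrix (individuals x loci).

    Parameters
    ----------
    individuals : ordered individual identifiers.
    loci : ordered locus identifiers.
    calls : int array of shape (n_individuals, n_loci, 2).  Allele labels are
        positive integers (sizes in bp); a missing call has both entries equal
        to ``MISSING_INT``.  Within a call the two labels are unordered; they
        are normalised to ascending order on construction.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.individuals = list(self.individuals)
        self.loci = list(self.loci)
        _check_unique(self.individuals, "individual")
        _check_unique(self.loci, "locus")
        calls = np.asarray(self.calls, dtype=np.int64)
        if calls.shape != (len(self.individuals), len(self.loci), 2):
            raise DataError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci x 2"
            )
        missing = calls == MISSING_INT
        half_missing = missing[..., 0] ^ missing[..., 1]
        if half_missing.any():
            i, l = np.argwhere(half_missing)[0]
            raise DataError(
                f"half-missing call for individual {self.individuals[i]!r} "
                f"at locus {self.loci[l]!r}: both allele copies must be "
                "present or both missing"
            )
        ok = missing[..., 0] | (calls > 0).all(axis=-1)
        if not ok.all():
            i, l = np.argwhere(~ok)[0]
            raise DataError(
                f"non-positive allele label for individual "
                f"{self.individuals[i]!r} at locus {self.loci[l]!r}"
            )
        self.calls = np.sort(calls, axis=-1)
        # sorting puts MISSING_INT first for missing pairs; that is fine since
        # both slots are MISSING_INT there.

    # -- basic queries -----------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def ploidy(self) -> int:
        return 2

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) mask of missing calls."""
        return self.calls[..., 0] == MISSING_INT

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def individual_index(self, individual: str) -> int:
        try:
            return self.individuals.index(individual)
        except ValueError:
            raise KeyError(f"unknown individual {individual!r}") from None

    def subset(self, individuals: Iterable[str]) -> "AlleleMatrix":
        idx = [self.individual_index(i) for i in individuals]
        return AlleleMatrix(
            [self.individuals[i] for i in idx], list(self.loci), self.calls[idx]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleMatrix):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class BandMatrix:
    """Dominant band-presence scores (individuals x bands).

    Each band is identified by ``(locus id, band label)`` where the band
    label is the fragment size in bp; scores are 0 (absent), 1 (present) or
    ``MISSING_INT``.
    """

    individuals: list[str]
    bands: list[tuple[str, int]]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.individuals = list(self.individuals)
        self.bands = [(str(l), int(b)) for l, b in self.bands]
        _check_unique(self.individuals, "individual")
        _check_unique([f"{l}:{b}" for l, b in self.bands], "band")
        scores = np.asarray(self.scores, dtype=np.int8)
        if scores.shape != (len(self.individuals), len(self.bands)):
            raise DataError(
                f"scores shape {scores.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.bands)} bands"
            )
        bad = ~np.isin(scores, (0, 1, MISSING_INT))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(
                f"band score must be 0, 1 or missing; got {scores[i, j]} for "
                f"individual {self.individuals[i]!r}, band {self.bands[j]!r}"
            )
        self.scores = scores

    @property
    def loci(self) -> list[str]:
        """Ordered unique locus ids, in first-appearance order."""
        out: list[str] = []
        for l, _ in self.bands:
            if l not in out:
                out.append(l)
        return out

    def band_indices(self, locus: str) -> list[int]:
        idx = [j for j, (l, _) in enumerate(self.bands) if l == locus]
        if not idx:
            raise KeyError(f"unknown locus {locus!r}")
        return idx


@dataclass
class PopulationMap:
    """Assignment of individuals to populations (and optionally to groups)."""

    assignment: dict[str, str]
    group: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.assignment = {str(k): str(v) for k, v in self.assignment.items()}
        if self.group is not None:
            self.group = {str(k): str(v) for k, v in self.group.items()}
            missing = set(self.assignment.values()) - set(self.group)
            if missing:
                raise DataError(
                    f"populations without a group assignment: {sorted(missing)}"
                )

    @property
    def populations(self) -> list[str]:
        """Population labels in first-appearance order."""
        out: list[str] = []
        for p in self.assignment.values():
            if p not in out:
                out.append(p)
        return out

    def members(self, population: str) -> list[str]:
        out = [i for i, p in self.assignment.items() if p == population]
        if not out:
            raise KeyError(f"empty or unknown population {population!r}")
        return out

    def population_of(self, individual: str) -> str:
        try:
            return self.assignment[individual]
        except KeyError:
            raise DataError(
                f"individual {individual!r} has no population assignment"
            ) from None

    def validate_against(self, individuals: Sequence[str]) -> None:
        for ind in individuals:
            self.population_of(ind)


@dataclass
class DistanceMatrix:
    """Square symmetric distance matrix with labelled rows/columns.

    Infinite distances (zero genetic identity) are represented by
    ``INF_DISTANCE`` (IEEE infinity) and serialised as the literal ``Inf``.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        _check_unique(self.labels, "label")
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise DataError(f"distance matrix shape {v.shape}, expected ({n}, {n})")
        if not np.allclose(np.diag(v), 0.0):
            raise DataError("distance matrix diagonal must be zero")
        finite = np.isfinite(v)
        if not np.array_equal(finite, finite.T):
            raise DataError("infinite entries must be placed symmetrically")
        sym = finite & finite.T
        if not np.allclose(v[sym], v.T[sym], atol=1e-12):
            raise DataError("distance matrix must be symmetric")
        if np.any(v[finite] < 0):
            raise DataError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def has_infinite(self) -> bool:
        return bool(np.isinf(self.values).any())

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])
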