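"""Nei genetic distances between populations and band-profile distances
between individuals.

The standard distance between populations X and Y is

.. math::

    D = -\\ln \\frac{J_{XY}}{\\sqrt{J_X J_Y}}

where :math:`J_X`, :math:`J_Y` and :math:`J_{XY}` are the expected
homozygosities / cross-population identity, each averaged over loci before
the ratio is taken (the POPGENE convention).  The unbiased variant replaces
the within-population identities with the small-sample estimator
:math:`\\hat J_X = (2N_X \\sum p_i^2 - 1)/(2N_X - 1)` per locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .locus_stats import AlleleFrequencies, allele_frequencies
from .types import (
    INF_DISTANCE,
    MISSING_INT,
    AlleleMatrix,
    BandMatrix,
    DataError,
    DistanceMatrix,
    PopulationMap,
)

#: per-population frequency table: locus id -> AlleleFrequencies
FrequencyEntry = Mapping[str, AlleleFrequencies]


@dataclass
class PopulationFrequencySet:
    """Per-population, per-locus allele frequencies over a shared locus list."""

    loci: list[str]
    entries: dict[str, dict[str, AlleleFrequencies]]

    @classmethod
    def from_matrix(cls, m: AlleleMatrix, pm: PopulationMap) -> "PopulationFrequencySet":
        pm.validate_against(m.individuals)
        entries: dict[str, dict[str, AlleleFrequencies]] = {}
        for pop in pm.populations:
            members = [i for i in m.individuals if pm.population_of(i) == pop]
            table: dict[str, AlleleFrequencies] = {}
            for locus in m.loci:
                try:
                    table[locus] = allele_frequencies(m, locus, members)
                except DataError:
                    continue  # locus untyped in this population
            entries[pop] = table
        return cls(list(m.loci), entries)


def _shared_loci(
    x: FrequencyEntry, y: FrequencyEntry, loci: Sequence[str] | None
) -> list[str]:
    pool = list(loci) if loci is not None else list(x.keys())
    shared = [l for l in pool if l in x and l in y]
    if not shared:
        raise DataError("populations share no typed loci")
    return shared


def _identities(
    x: FrequencyEntry, y: FrequencyEntry, loci: Sequence[str], unbiased: bool
) -> tuple[float, float, float]:
    jx, jy, jxy = [], [], []
    for locus in loci:
        fx, fy = x[locus], y[locus]
        px = fx.freqs
        py = fy.freqs
        sx = sum(p * p for p in px.values())
        sy = sum(p * p for p in py.values())
        if unbiased:
            for f, s in ((fx, sx), (fy, sy)):
                if f.n_gene_copies < 2:
                    raise DataError(
                        f"locus {locus!r}: unbiased identity needs >= 2 gene copies"
                    )
            sx = (fx.n_gene_copies * sx - 1.0) / (fx.n_gene_copies - 1.0)
            sy = (fy.n_gene_copies * sy - 1.0) / (fy.n_gene_copies - 1.0)
        jx.append(sx)
        jy.append(sy)
        jxy.append(sum(px[a] * py.get(a, 0.0) for a in px))
    return float(np.mean(jx)), float(np.mean(jy)), float(np.mean(jxy))


def nei_standard_distance(
    x: FrequencyEntry, y: FrequencyEntry, loci: Sequence[str] | None = None
) -> float:
    """Nei's standard genetic distance between two frequency profiles.

    Returns ``INF_DISTANCE`` when the populations share no alleles
    (cross-identity zero).
    """
    shared = _shared_loci(x, y, loci)
    jx, jy, jxy = _identities(x, y, shared, unbiased=False)
    if jxy == 0.0:
        return INF_DISTANCE
    return max(0.0, float(-np.log(jxy / np.sqrt(jx * jy))))


def nei_unbiased_distance(
    x: FrequencyEntry, y: FrequencyEntry, loci: Sequence[str] | None = None
) -> float:
    """Nei's unbiased genetic distance (small-sample corrected identities).

    The moment estimator can come out marginally negative for very similar
    populations; such values are floored at zero, so identical frequency
    profiles map to distance 0.
    """
    shared = _shared_loci(x, y, loci)
    jx, jy, jxy = _identities(x, y, shared, unbiased=True)
    if jxy == 0.0:
        return INF_DISTANCE
    if jx <= 0 or jy <= 0:
        raise DataError("unbiased within-population identity non-positive")
    return max(0.0, float(-np.log(jxy / np.sqrt(jx * jy))))


def population_distance_matrix(
    m: AlleleMatrix, pm: PopulationMap, method: str = "unbiased"
) -> DistanceMatrix:
    """Pairwise Nei distance matrix between the populations of ``pm``.

    ``method`` is ``"standard"`` or ``"unbiased"``.  Pairs with zero shared
    identity get the infinite-distance sentinel; callers that feed the
    result to tree builders must check :meth:`DistanceMatrix.has_infinite`.
    """
    if method not in ("standard", "unbiased"):
        raise DataError(f"unknown Nei distance method {method!r}")
    fn = nei_standard_distance if method == "standard" else nei_unbiased_distance
    fs = PopulationFrequencySet.from_matrix(m, pm)
    pops = pm.populations
    if len(pops) < 2:
        raise DataError("need at least 2 populations")
    n = len(pops)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = fn(fs.entries[pops[i]], fs.entries[pops[j]], fs.loci)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(pops, values)


def individual_distance_matrix(
    b: BandMatrix, metric: str = "simple_matching"
) -> DistanceMatrix:
    """Pairwise dissimilarity between individuals from 0/1 band profiles.

    ``simple_matching``: proportion of mismatching scores among bands
    non-missing in both individuals.
    """
    if metric != "simple_matching":
        raise DataError(f"unknown metric {metric!r}")
    if len(b.individuals) < 2:
        raise DataError("need at least 2 individuals")
    s = b.scores.astype(float)
    s[b.scores == MISSING_INT] = np.nan
    n = len(b.individuals)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(s[i]) & ~np.isnan(s[j])
            if not both.any():
                raise DataError(
                    f"individuals {b.individuals[i]!r} and {b.individuals[j]!r} "
                    "share no non-missing band scores"
                )
            values[i, j] = values[j, i] = float(
                np.mean(s[i, both] != s[j, both])
            )
    return DistanceMatrix(list(b.individuals), values)
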