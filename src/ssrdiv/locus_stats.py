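"""Per-locus and per-population SSR diversity statistics.

For a locus with allele frequencies :math:`p_1,\\dots,p_k` estimated from
the non-missing calls (pairwise deletion):

* ``Na`` — observed allele count :math:`k`
* ``Ne`` — effective allele count :math:`1/\\sum p_i^2`
* ``I`` — Shannon information index :math:`-\\sum p_i \\ln p_i`
* ``He`` — Nei gene diversity :math:`1 - \\sum p_i^2`
* ``uHe`` — unbiased gene diversity :math:`\\frac{2N}{2N-1} He`
* ``Ho`` — observed heterozygosity (fraction of heterozygous calls)
* ``PIC`` — polymorphism information content (Botstein et al.):
  :math:`1 - \\sum p_i^2 - \\sum_{i<j} 2 p_i^2 p_j^2`
* ``Rp`` — resolving power of a marker's band profile:
  :math:`\\sum_b (1 - 2|0.5 - p_b|)` over its bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .types import MISSING_INT, AlleleMatrix, BandMatrix, DataError, PopulationMap


@dataclass
class AlleleFrequencies:
    """Allele frequency estimate at one locus.

    ``n_gene_copies`` is the number of non-missing allele copies used
    (2 x number of typed individuals).
    """

    locus: str
    freqs: dict[int, float]
    n_gene_copies: int

    def __post_init__(self) -> None:
        if self.n_gene_copies < 2 or self.n_gene_copies % 2 != 0:
            raise DataError(
                f"locus {self.locus!r}: n_gene_copies must be even and >= 2, "
                f"got {self.n_gene_copies}"
            )
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise DataError(
                f"locus {self.locus!r}: frequencies sum to {total}, not 1"
            )
        if any(p <= 0 for p in self.freqs.values()):
            raise DataError(f"locus {self.locus!r}: frequencies must be positive")

    @property
    def p(self) -> np.ndarray:
        return np.array(list(self.freqs.values()), dtype=float)

    @property
    def n_alleles(self) -> int:
        return len(self.freqs)


@dataclass
class LocusSummary:
    """Diversity summary for one locus over a sample of individuals."""

    locus: str
    Na: int
    Ne: float
    I: float
    He: float
    uHe: float
    Ho: float
    PIC: float
    Rp: float | None = None


def _locus_calls(
    m: AlleleMatrix, locus: str, subset: Sequence[str] | None
) -> np.ndarray:
    """Non-missing (n, 2) calls at a locus for a subset of individuals."""
    l = m.locus_index(locus)
    if subset is None:
        calls = m.calls[:, l, :]
    else:
        if not list(subset):
            raise DataError("individual subset must be non-empty")
        idx = [m.individual_index(i) for i in subset]
        calls = m.calls[idx, l, :]
    calls = calls[calls[:, 0] != MISSING_INT]
    if calls.size == 0:
        raise DataError(f"locus {locus!r}: all calls missing in the given subset")
    return calls


def allele_frequencies(
    m: AlleleMatrix, locus: str, subset: Sequence[str] | None = None
) -> AlleleFrequencies:
    """Estimate allele frequencies at a locus by direct gene-copy counting."""
    calls = _locus_calls(m, locus, subset)
    alleles, counts = np.unique(calls, return_counts=True)
    n = int(counts.sum())
    freqs = {int(a): float(c) / n for a, c in zip(alleles, counts)}
    return AlleleFrequencies(locus, freqs, n)


def nei_gene_diversity(f: AlleleFrequencies) -> float:
    """Nei gene diversity He = 1 - sum(p_i^2)."""
    return float(1.0 - np.sum(f.p**2))


def effective_alleles(f: AlleleFrequencies) -> float:
    """Effective allele count Ne = 1 / sum(p_i^2)."""
    return float(1.0 / np.sum(f.p**2))


def shannon_index(f: AlleleFrequencies) -> float:
    """Shannon information index I = -sum(p_i ln p_i)."""
    p = f.p
    return float(-np.sum(p * np.log(p)))


def unbiased_gene_diversity(f: AlleleFrequencies) -> float:
    """Small-sample corrected gene diversity uHe = 2N/(2N-1) * He."""
    n = f.n_gene_copies
    return float(n / (n - 1) * nei_gene_diversity(f))


def observed_heterozygosity(
    m: AlleleMatrix, locus: str, subset: Sequence[str] | None = None
) -> float:
    """Fraction of non-missing calls carrying two distinct alleles."""
    calls = _locus_calls(m, locus, subset)
    return float(np.mean(calls[:, 0] != calls[:, 1]))


def pic(f: AlleleFrequencies, literal: bool = False) -> float:
    """Polymorphism information content.

    The default is Botstein's definition
    ``1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2``.  ``literal=True`` instead
    evaluates the degenerate expression ``1 - sum(p_i) - sum_{i<j} p_i p_j``
    sometimes seen in print, kept only for comparison.
    """
    p = f.p
    if literal:
        cross = (np.sum(p) ** 2 - np.sum(p**2)) / 2.0
        return float(1.0 - np.sum(p) - cross)
    p2 = p**2
    cross = np.sum(p2) ** 2 - np.sum(p2**2)  # = 2 * sum_{i<j} p_i^2 p_j^2
    return float(1.0 - np.sum(p2) - cross)


def band_frequencies(b: BandMatrix, locus: str) -> dict[int, float]:
    """Proportion of scored individuals carrying each band of a locus.

    Bands with no non-missing score are excluded (with a warning via
    ``warnings``), since their informativeness is undefined.
    """
    import warnings

    out: dict[int, float] = {}
    for j in b.band_indices(locus):
        col = b.scores[:, j]
        col = col[col != MISSING_INT]
        if col.size == 0:
            warnings.warn(
                f"band {b.bands[j]} has no non-missing scores; excluded from Rp"
            )
            continue
        out[b.bands[j][1]] = float(np.mean(col))
    if not out:
        raise DataError(f"locus {locus!r}: no scorable bands")
    return out


def resolving_power(b: BandMatrix, locus: str) -> float:
    """Resolving power Rp = sum over bands of 1 - 2|0.5 - p|."""
    return float(
        sum(1.0 - 2.0 * abs(0.5 - p) for p in band_frequencies(b, locus).values())
    )


def locus_summary(
    m: AlleleMatrix,
    locus: str,
    b: BandMatrix | None = None,
    subset: Sequence[str] | None = None,
) -> LocusSummary:
    f = allele_frequencies(m, locus, subset)
    rp = None
    if b is not None and locus in b.loci:
        rp = resolving_power(b, locus)
    return LocusSummary(
        locus=locus,
        Na=f.n_alleles,
        Ne=effective_alleles(f),
        I=shannon_index(f),
        He=nei_gene_diversity(f),
        uHe=unbiased_gene_diversity(f),
        Ho=observed_heterozygosity(m, locus, subset),
        PIC=pic(f),
        Rp=rp,
    )


def locus_summary_table(
    m: AlleleMatrix,
    b: BandMatrix | None = None,
    pm: PopulationMap | None = None,
) -> pd.DataFrame:
    """Per-locus diversity table over all individuals pooled.

    Returns a DataFrame with one row per locus plus `Total`/`Mean` rows for
    the Na column (total allele count over loci and mean alleles per locus).
    If ``pm`` is given it is only validated against the matrix (population
    breakdowns live in :func:`population_summary`).
    """
    if b is not None and list(b.individuals) != list(m.individuals):
        raise DataError("band matrix and allele matrix must share individuals")
    if pm is not None:
        pm.validate_against(m.individuals)
    rows = [locus_summary(m, locus, b) for locus in m.loci]
    df = pd.DataFrame(
        {
            "locus": [r.locus for r in rows],
            "Na": [r.Na for r in rows],
            "Ne": [r.Ne for r in rows],
            "I": [r.I for r in rows],
            "He": [r.He for r in rows],
            "uHe": [r.uHe for r in rows],
            "Ho": [r.Ho for r in rows],
            "PIC": [r.PIC for r in rows],
            "Rp": [r.Rp for r in rows],
        }
    )
    df.attrs["total_Na"] = int(df["Na"].sum())
    df.attrs["mean_Na"] = float(df["Na"].mean())
    return df


def population_summary(m: AlleleMatrix, pm: PopulationMap) -> pd.DataFrame:
    """Per-population means (over loci) of Na, Ne, I and He.

    Statistics are computed within each population locus by locus and then
    averaged across loci.  Loci that are monomorphic within a population
    contribute Na=1, Ne=1, I=0, He=0; loci with no typed individuals in the
    population are skipped for that population.
    """
    pm.validate_against(m.individuals)
    records = []
    for pop in pm.populations:
        members = [i for i in m.individuals if pm.population_of(i) == pop]
        if not members:
            raise DataError(f"population {pop!r} has no individuals in the matrix")
        per_locus = {"Na": [], "Ne": [], "I": [], "He": []}
        for locus in m.loci:
            try:
                f = allele_frequencies(m, locus, members)
            except DataError:
                continue  # untyped locus in this population
            per_locus["Na"].append(f.n_alleles)
            per_locus["Ne"].append(effective_alleles(f))
            per_locus["I"].append(shannon_index(f))
            per_locus["He"].append(nei_gene_diversity(f))
        if not per_locus["Na"]:
            raise DataError(f"population {pop!r} has no typed loci")
        records.append(
            {
                "population": pop,
                "n": len(members),
                "Na": float(np.mean(per_locus["Na"])),
                "Ne": float(np.mean(per_locus["Ne"])),
                "I": float(np.mean(per_locus["I"])),
                "He": float(np.mean(per_locus["He"])),
            }
        )
    return pd.DataFrame.from_records(records)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    factor = 10**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def biallelic_frequencies_for_he(he: float) -> tuple[float, float]:
    """Solve the biallelic frequencies (p, 1-p) implied by He = 1 - p^2 - q^2.

    Uses the root with p >= 0.5; He must lie in [0, 0.5].
    """
    if not 0.0 <= he <= 0.5:
        raise DataError(f"biallelic He must be in [0, 0.5], got {he}")
    p = 0.5 * (1.0 + math.sqrt(1.0 - 2.0 * he))
    return p, 1.0 - p
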