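"""Hierarchical analysis of molecular variance (AMOVA) for diploid
codominant data.

The three-level design partitions the total variance of inter-gene-copy
squared distances into components

* ``sigma_a`` — among populations,
* ``sigma_b`` — among individuals within populations,
* ``sigma_c`` — within individuals,

with degrees of freedom ``P - 1``, ``N - P`` and ``N`` for ``P`` populations
and ``N`` diploid individuals (total ``2N - 1``).  Sums of squares are
computed from squared distances between gene copies,

.. math::

    SS(G) = \\frac{1}{|G|} \\sum_{i<j \\in G} \\delta^2_{ij},

and the components solved from the nested expected mean squares.  The
distance between two gene copies is the number of loci at which their
alleles differ (rescaled to the full locus count when loci are missing),
an infinite-allele-style metric; a squared-size-difference (stepwise)
metric is available via ``metric="stepwise"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import MISSING_INT, AlleleMatrix, DataError, DistanceMatrix, PopulationMap


@dataclass
class AmovaResult:
    """AMOVA table: one entry per hierarchy level plus fixation indices."""

    levels: list[str]
    df: list[int]
    ss: list[float]
    components: list[float]
    percentages: list[float]
    phi_st: float
    phi_is: float
    phi_it: float
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0
    seed: int | None = None
    truncated: bool = False  # negative components truncated for display

    @property
    def total_ss(self) -> float:
        return float(sum(self.ss))

    @property
    def total_component(self) -> float:
        return float(sum(self.components))


def _copy_labels(m: AlleleMatrix) -> list[str]:
    return [f"{ind}.{c}" for ind in m.individuals for c in (1, 2)]


def gene_copy_distances(m: AlleleMatrix, metric: str = "mismatch") -> DistanceMatrix:
    """Squared distances between the 2N gene copies of an allele matrix.

    ``mismatch``: number of loci with differing alleles, rescaled by
    ``n_loci / n_compared`` under missingness.  ``stepwise``: sum of squared
    allele-size differences (same rescaling).
    """
    if metric not in ("mismatch", "stepwise"):
        raise DataError(f"unknown metric {metric!r}")
    mask = m.missing_mask()
    if mask.all(axis=1).any():
        bad = [m.individuals[i] for i in np.where(mask.all(axis=1))[0]]
        raise DataError(f"individuals with no typed loci: {bad}")
    # copies array: (2N, L); copy 2i is individual i's first allele
    copies = m.calls.transpose(0, 2, 1).reshape(2 * m.n_individuals, m.n_loci)
    copies = copies.astype(float)
    copies[copies == MISSING_INT] = np.nan
    typed = ~np.isnan(copies)
    n_loci = m.n_loci

    shared = typed.astype(np.int64) @ typed.astype(np.int64).T
    if (shared == 0).any():
        i, j = np.argwhere(shared == 0)[0]
        labels = _copy_labels(m)
        raise DataError(
            f"gene copies {labels[i]!r} and {labels[j]!r} share no typed loci"
        )
    if metric == "mismatch":
        a = np.nan_to_num(copies, nan=0.0)
        diff = np.zeros(shared.shape, dtype=np.int64)
        # accumulate per-locus mismatches among jointly typed loci
        for l in range(n_loci):
            col = copies[:, l]
            ok = typed[:, l]
            neq = (col[:, None] != col[None, :]) & ok[:, None] & ok[None, :]
            diff += neq
        values = diff * (n_loci / shared)
    else:
        values = np.zeros(shared.shape)
        for l in range(n_loci):
            col = copies[:, l]
            ok = typed[:, l]
            sq = (col[:, None] - col[None, :]) ** 2
            sq[~(ok[:, None] & ok[None, :])] = 0.0
            values += sq
        values = values * (n_loci / shared)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(_copy_labels(m), values)


def _ss_within_groups(values: np.ndarray, groups: list[np.ndarray]) -> float:
    """Sum over groups of (1/|G|) * sum_{i<j in G} d2_ij."""
    total = 0.0
    for idx in groups:
        sub = values[np.ix_(idx, idx)]
        total += sub.sum() / (2.0 * len(idx))
    return total


def _partition_from_values(
    values: np.ndarray, pop_of_ind: np.ndarray, n_pops: int
) -> tuple[list[float], list[float], list[int]]:
    """SS, variance components and df from a 2N x 2N squared-distance array.

    ``pop_of_ind`` gives each *individual's* population index; gene copies
    2i and 2i+1 belong to individual i.
    """
    n_ind = len(pop_of_ind)
    n_copies = 2 * n_ind
    copy_pop = np.repeat(pop_of_ind, 2)

    ss_total = values.sum() / (2.0 * n_copies)
    pop_groups = [np.where(copy_pop == p)[0] for p in range(n_pops)]
    ind_groups = [np.arange(2 * i, 2 * i + 2) for i in range(n_ind)]
    ss_within_pop = _ss_within_groups(values, pop_groups)
    ss_within_ind = _ss_within_groups(values, ind_groups)

    ss_a = ss_total - ss_within_pop
    ss_b = ss_within_pop - ss_within_ind
    ss_c = ss_within_ind
    df_a = n_pops - 1
    df_b = n_ind - n_pops
    df_c = n_ind

    if df_a < 1 or df_b < 1:
        raise DataError(
            "degenerate design: need >= 2 populations and more individuals "
            "than populations"
        )

    sigma_c = ss_c / df_c
    sigma_b = (ss_b / df_b - sigma_c) / 2.0
    pop_copy_counts = np.array([2 * np.sum(pop_of_ind == p) for p in range(n_pops)])
    n_c = (n_copies - np.sum(pop_copy_counts**2) / n_copies) / df_a
    sigma_a = (ss_a / df_a - sigma_c - 2.0 * sigma_b) / n_c
    return (
        [ss_a, ss_b, ss_c],
        [float(sigma_a), float(sigma_b), float(sigma_c)],
        [df_a, df_b, df_c],
    )


def variance_percentages(components: list[float]) -> list[float]:
    """Percentage of total variance per component.

    Negative components are truncated to zero for the percentage display
    (the raw values stay in :attr:`AmovaResult.components`).
    """
    trunc = np.maximum(np.asarray(components, dtype=float), 0.0)
    total = trunc.sum()
    if total <= 0:
        raise DataError("total variance is non-positive")
    return [float(100.0 * c / total) for c in trunc]


def amova_degrees_of_freedom(n_pops: int, n_individuals: int) -> list[int]:
    """df per level for the diploid three-level design: (P-1, N-P, N)."""
    if n_pops < 2 or n_individuals <= n_pops:
        raise DataError("need >= 2 populations and N > P")
    return [n_pops - 1, n_individuals - n_pops, n_individuals]


def amova_partition(
    d: DistanceMatrix, pm: PopulationMap, m: AlleleMatrix | None = None
) -> AmovaResult:
    """Variance-component AMOVA from a gene-copy squared-distance matrix.

    ``d`` must be indexed by gene-copy labels ``<individual>.1/<individual>.2``
    in individual order.  Populations of a single individual leave the
    among-individual component estimable overall but are flagged with a
    warning.
    """
    import warnings

    individuals = [lab[:-2] for lab in d.labels[::2]]
    pm.validate_against(individuals)
    pops = pm.populations
    if len(pops) < 2:
        raise DataError("need at least 2 populations")
    singletons = [p for p in pops if len(pm.members(p)) == 1]
    if singletons:
        warnings.warn(
            f"populations with a single individual: {singletons}; "
            "their within-population term relies on pooling across populations"
        )
    pop_of_ind = np.array([pops.index(pm.population_of(i)) for i in individuals])
    ss, comps, df = _partition_from_values(d.values, pop_of_ind, len(pops))
    percentages = variance_percentages(comps)
    total = sum(max(c, 0.0) for c in comps)
    sigma_a, sigma_b, sigma_c = comps
    phi_st = sigma_a / total if total > 0 else np.nan
    phi_is = (
        sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) > 0 else np.nan
    )
    phi_it = (sigma_a + sigma_b) / total if total > 0 else np.nan
    return AmovaResult(
        levels=[
            "among populations",
            "among individuals within populations",
            "within individuals",
        ],
        df=df,
        ss=[float(s) for s in ss],
        components=comps,
        percentages=percentages,
        phi_st=float(phi_st),
        phi_is=float(phi_is),
        phi_it=float(phi_it),
        truncated=any(c < 0 for c in comps),
    )


def amova(
    m: AlleleMatrix,
    pm: PopulationMap,
    metric: str = "mismatch",
    n_perm: int = 0,
    seed: int | None = None,
) -> AmovaResult:
    """Full AMOVA from genotypes: distances, partition, optional permutations."""
    d = gene_copy_distances(m, metric=metric)
    result = amova_partition(d, pm)
    if n_perm:
        p = amova_permutation_test(m, pm, n_perm=n_perm, seed=seed, metric=metric)
        result.p_values = p
        result.n_permutations = n_perm
        result.seed = seed
    return result


def amova_permutation_test(
    m: AlleleMatrix,
    pm: PopulationMap,
    n_perm: int = 999,
    seed: int | None = None,
    metric: str = "mismatch",
) -> dict[str, float]:
    """Permutation p-values for the among-population and within-individual
    components.

    ``sigma_a``: whole individuals are permuted among populations (sample
    sizes preserved).  ``sigma_c``: allele copies are permuted among
    individuals within each population, testing departure from random mating
    within populations (statistic: Phi_IS).  p = (1 + #{perm >= obs}) /
    (n_perm + 1).
    """
    if n_perm < 99:
        raise DataError("use at least 99 permutations")
    rng = np.random.default_rng(seed)
    d = gene_copy_distances(m, metric=metric)
    pops = pm.populations
    pop_of_ind = np.array(
        [pops.index(pm.population_of(i)) for i in m.individuals]
    )
    n_pops = len(pops)
    def _phi_is(comps: list[float]) -> float:
        denom = comps[1] + comps[2]
        return comps[1] / denom if denom > 0 else 0.0

    _, obs_comps, _ = _partition_from_values(d.values, pop_of_ind, n_pops)
    obs_sigma_a = obs_comps[0]
    obs_phi_is = _phi_is(obs_comps)

    values = d.values
    n_ind = m.n_individuals
    exceed_a = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_ind)
        # moving labels over individuals == moving individuals over labels
        _, comps, _ = _partition_from_values(values, pop_of_ind[perm], n_pops)
        if comps[0] >= obs_sigma_a - 1e-12:
            exceed_a += 1

    # permute gene copies among individuals within populations
    exceed_c = 0
    copy_pop = np.repeat(pop_of_ind, 2)
    for _ in range(n_perm):
        order = np.arange(2 * n_ind)
        for p in range(n_pops):
            idx = np.where(copy_pop == p)[0]
            order[idx] = rng.permutation(idx)
        vperm = values[np.ix_(order, order)]
        _, comps, _ = _partition_from_values(vperm, pop_of_ind, n_pops)
        if _phi_is(comps) >= obs_phi_is - 1e-12:
            exceed_c += 1

    return {
        "sigma_a": (1.0 + exceed_a) / (n_perm + 1.0),
        "sigma_c": (1.0 + exceed_c) / (n_perm + 1.0),
    }
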