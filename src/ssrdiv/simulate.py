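"""Synthetic SSR genotype panels with known ground truth.

The generator emulates a multi-population panel of a predominantly selfing
diploid (a lentil-style germplasm collection): per locus an ancestral allele
frequency vector is drawn from a symmetric Dirichlet, each population's
frequencies drift around it under the F-model
(:math:`p_{pop} \\sim \\mathrm{Dirichlet}(p_{anc}(1-F)/F)`), and genotypes
are drawn with whole-individual selfing: with probability ``selfing_rate``
the two allele copies at every locus of an individual are identical by
descent (a single draw duplicated), otherwise independent draws.

Defaults mirror the study design this package targets: 6 populations of
sizes 26/30/3/6/6/15 (86 individuals), 43 loci with 2-5 alleles each,
divergence F = 0.2, selfing rate 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import alleles_to_bands
from .types import MISSING_INT, AlleleMatrix, BandMatrix, DataError, PopulationMap

#: study-design population sizes (cultivated + 5 wild subspecies/species)
DEFAULT_POP_SIZES = (26, 30, 3, 6, 6, 15)


@dataclass
class SimConfig:
    """Generator settings; defaults are the emulated study conditions."""

    pop_sizes: tuple[int, ...] = DEFAULT_POP_SIZES
    n_loci: int = 43
    alleles_min: int = 2
    alleles_max: int = 5
    divergence_f: float | tuple[float, ...] = 0.2
    selfing_rate: float = 0.95
    admixture_alpha: float | None = None
    missing_rate: float = 0.0
    dirichlet_concentration: float = 1.0
    allele_size_base: int = 100
    allele_size_step: int = 4
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.pop_sizes):
            raise DataError("population sizes must be >= 1")
        if self.n_loci < 1:
            raise DataError("need at least 1 locus")
        if not 2 <= self.alleles_min <= self.alleles_max:
            raise DataError("allele count range must satisfy 2 <= min <= max")
        fs = self.f_per_pop
        if any(not 0.0 < f < 1.0 for f in fs):
            raise DataError("divergence F must lie in (0, 1)")
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise DataError("selfing_rate must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise DataError("missing_rate must be in [0, 1)")
        if self.admixture_alpha is not None and self.admixture_alpha <= 0:
            raise DataError("admixture_alpha must be positive")

    @property
    def n_pops(self) -> int:
        return len(self.pop_sizes)

    @property
    def n_individuals(self) -> int:
        return int(sum(self.pop_sizes))

    @property
    def f_per_pop(self) -> tuple[float, ...]:
        if isinstance(self.divergence_f, (int, float)):
            return tuple([float(self.divergence_f)] * self.n_pops)
        if len(self.divergence_f) != self.n_pops:
            raise DataError("divergence_f must be scalar or one value per population")
        return tuple(float(f) for f in self.divergence_f)


@dataclass
class SimTruth:
    """Ground truth of a simulated panel."""

    ancestral_freqs: list[np.ndarray]  # per locus
    pop_freqs: list[list[np.ndarray]]  # [pop][locus]
    Q: np.ndarray  # (N, n_pops) true ancestry proportions
    configured_f: tuple[float, ...]
    allele_sizes: list[np.ndarray]  # per locus, bp labels


def simulate(
    cfg: SimConfig,
) -> tuple[AlleleMatrix, BandMatrix, PopulationMap, SimTruth]:
    """Draw one synthetic panel; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.f_per_pop
    n_pops, n_ind = cfg.n_pops, cfg.n_individuals

    ancestral, pop_freqs, allele_sizes = [], [[] for _ in range(n_pops)], []
    for l in range(cfg.n_loci):
        k = int(rng.integers(cfg.alleles_min, cfg.alleles_max + 1))
        p_anc = rng.dirichlet(np.full(k, cfg.dirichlet_concentration))
        ancestral.append(p_anc)
        allele_sizes.append(
            cfg.allele_size_base
            + cfg.allele_size_step * np.arange(k)
            + 50 * l  # locus-specific size range
        )
        for pop in range(n_pops):
            conc = p_anc * (1.0 - fs[pop]) / fs[pop]
            pop_freqs[pop].append(rng.dirichlet(conc))

    # population labels and true ancestry
    pop_of_ind = np.repeat(np.arange(n_pops), cfg.pop_sizes)
    if cfg.admixture_alpha is not None:
        Q = rng.dirichlet(np.full(n_pops, cfg.admixture_alpha), size=n_ind)
    else:
        Q = np.zeros((n_ind, n_pops))
        Q[np.arange(n_ind), pop_of_ind] = 1.0

    calls = np.zeros((n_ind, cfg.n_loci, 2), dtype=np.int64)
    selfed = rng.random(n_ind) < cfg.selfing_rate
    for i in range(n_ind):
        for l in range(cfg.n_loci):
            if selfed[i]:
                k = rng.choice(n_pops, p=Q[i])
                a = rng.choice(len(allele_sizes[l]), p=pop_freqs[k][l])
                pair = (a, a)
            else:
                ks = (rng.choice(n_pops, p=Q[i]), rng.choice(n_pops, p=Q[i]))
                pair = tuple(
                    rng.choice(len(allele_sizes[l]), p=pop_freqs[k][l]) for k in ks
                )
            calls[i, l] = (
                allele_sizes[l][pair[0]],
                allele_sizes[l][pair[1]],
            )

    if cfg.missing_rate > 0:
        mask = rng.random((n_ind, cfg.n_loci)) < cfg.missing_rate
        # keep at least one typed locus per individual
        for i in np.where(mask.all(axis=1))[0]:
            mask[i, rng.integers(cfg.n_loci)] = False
        calls[mask] = MISSING_INT

    individuals = [f"ind{i + 1:03d}" for i in range(n_ind)]
    loci = [f"SSR{l + 1:02d}" for l in range(cfg.n_loci)]
    m = AlleleMatrix(individuals, loci, calls)
    pm = PopulationMap(
        {ind: f"pop{p + 1}" for ind, p in zip(individuals, pop_of_ind)}
    )
    truth = SimTruth(
        ancestral_freqs=ancestral,
        pop_freqs=pop_freqs,
        Q=Q,
        configured_f=fs,
        allele_sizes=allele_sizes,
    )
    return m, alleles_to_bands(m), pm, truth


def realized_fst(truth: SimTruth) -> np.ndarray:
    """Per-population realised drift F from the simulated frequencies.

    Method-of-moments estimator matched to the F-model: for each population,
    the mean over loci and alleles of
    :math:`(p - \\bar p)^2 / (\\bar p (1 - \\bar p))` where :math:`\\bar p`
    is the ancestral frequency.  Zero when a population's frequencies equal
    the ancestral ones; increases with configured F.
    """
    n_pops = len(truth.pop_freqs)
    out = np.zeros(n_pops)
    for pop in range(n_pops):
        ratios = []
        for p_anc, p_pop in zip(truth.ancestral_freqs, truth.pop_freqs[pop]):
            denom = p_anc * (1.0 - p_anc)
            ok = denom > 0
            ratios.extend(((p_pop[ok] - p_anc[ok]) ** 2 / denom[ok]).tolist())
        out[pop] = float(np.clip(np.mean(ratios), 0.0, 1.0))
    return out
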