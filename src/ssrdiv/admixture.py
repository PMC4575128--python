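"""Bayesian model-based clustering of multilocus genotypes (admixture model).

Each individual ``i`` carries a vector :math:`q_i` of ancestry proportions
over ``K`` clusters (Dirichlet(:math:`\\alpha`) prior) and each cluster ``k``
carries allele frequencies :math:`p_{kl\\cdot}` per locus
(Dirichlet(:math:`\\lambda`) prior).  A Gibbs sweep

1. samples the cluster of origin ``Z`` of every allele copy with probability
   proportional to :math:`q_{ik} \\, p_{kl a}`,
2. samples ``P`` from Dirichlet(:math:`\\lambda` + cluster allele counts),
3. samples each ``Q`` row from Dirichlet(:math:`\\alpha` + per-cluster copy
   counts),

optionally followed by a random-walk Metropolis update of :math:`\\alpha`
(off by default; held constant otherwise).  Missing allele copies contribute
nothing.  The model-evidence proxy per run is
:math:`\\widehat{\\ln P(D)} = \\overline{\\ell} - \\mathrm{var}(\\ell)/2`
over the post-burn-in likelihood trace, and the Evanno
:math:`\\Delta K` statistic compares it across ``K``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import MISSING_INT, AlleleMatrix, DataError


@dataclass
class AdmixtureConfig:
    """MCMC settings for :func:`gibbs_admixture`.

    ``alpha`` is the symmetric Dirichlet parameter of the ancestry prior
    (held constant unless ``update_alpha``); ``lambda_`` the allele-frequency
    prior parameter; ``freq_model_f`` switches on the correlated-frequency
    prior with the given drift parameter (``None`` = independent
    Dirichlet(lambda) prior, the default).
    """

    K: int
    burnin: int = 5000
    iterations: int = 10000
    alpha: float = 1.0
    update_alpha: bool = False
    alpha_prior_max: float = 10.0
    alpha_prop_sd: float = 0.05
    lambda_: float = 1.0
    freq_model_f: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.K < 1:
            raise DataError("K must be >= 1")
        if self.burnin < 1 or self.iterations < 1:
            raise DataError("burnin and iterations must be >= 1")
        if self.alpha <= 0 or self.lambda_ <= 0:
            raise DataError("alpha and lambda must be positive")


@dataclass
class FrequencyModel:
    """Cluster allele frequencies: ``probs[k, l, a]`` over per-locus labels."""

    loci: list[str]
    allele_labels: list[list[int]]
    probs: np.ndarray  # (K, L, A_max), zero-padded past each locus's alleles

    @property
    def K(self) -> int:
        return self.probs.shape[0]

    def permuted(self, perm: np.ndarray) -> "FrequencyModel":
        return FrequencyModel(self.loci, self.allele_labels, self.probs[perm])


@dataclass
class AdmixtureResult:
    Q: np.ndarray  # (N, K) posterior-mean ancestry proportions
    P: FrequencyModel  # posterior-mean cluster allele frequencies
    alpha_trace: np.ndarray
    loglik_trace: np.ndarray  # post-burnin
    lnPD: float
    K: int
    seed: int | None
    individuals: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# data encoding
# ---------------------------------------------------------------------------


@dataclass
class _Encoded:
    ind_idx: np.ndarray  # (M,) individual index of each non-missing copy
    loc_idx: np.ndarray  # (M,)
    allele_idx: np.ndarray  # (M,) dense per-locus allele index
    n_alleles: np.ndarray  # (L,)
    allele_labels: list[list[int]]
    n_ind: int
    n_loci: int

    @property
    def a_max(self) -> int:
        return int(self.n_alleles.max())


def _encode(m: AlleleMatrix) -> _Encoded:
    if m.missing_mask().all(axis=1).any():
        raise DataError("individuals with no typed loci cannot be clustered")
    allele_labels: list[list[int]] = []
    codes = np.full_like(m.calls, MISSING_INT)
    for l in range(m.n_loci):
        col = m.calls[:, l, :]
        labels = np.unique(col[col != MISSING_INT])
        allele_labels.append([int(a) for a in labels])
        lookup = {a: i for i, a in enumerate(labels)}
        for a, i in lookup.items():
            codes[:, l, :][col == a] = i
        codes[:, l, :][col == MISSING_INT] = MISSING_INT
    ind, loc, _copy = np.nonzero(codes != MISSING_INT)
    return _Encoded(
        ind_idx=ind,
        loc_idx=loc,
        allele_idx=codes[codes != MISSING_INT],
        n_alleles=np.array([len(a) for a in allele_labels]),
        allele_labels=allele_labels,
        n_ind=m.n_individuals,
        n_loci=m.n_loci,
    )


def _valid_mask(enc: _Encoded) -> np.ndarray:
    """(L, A_max) mask of allele slots that exist at each locus."""
    return np.arange(enc.a_max)[None, :] < enc.n_alleles[:, None]


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


def _sample_p(
    counts: np.ndarray,
    prior: float | np.ndarray,
    valid: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample P ~ Dirichlet(prior + counts) per (cluster, locus).

    ``prior`` is either the scalar lambda (independent prior) or an
    (L, A_max) array of pseudo-counts (correlated-frequency prior).
    """
    shape = prior + counts if np.isscalar(prior) else prior[None, :, :] + counts
    g = rng.standard_gamma(np.where(valid[None, :, :], shape, 1.0))
    g *= valid[None, :, :]
    g /= g.sum(axis=2, keepdims=True)
    return g


def _frequency_prior(enc: "_Encoded", cfg: AdmixtureConfig) -> float | np.ndarray:
    """Allele-frequency prior pseudo-counts.

    Independent model: the scalar ``lambda``.  Correlated model
    (``freq_model_f`` set): Dirichlet around the pooled empirical
    frequencies with concentration (1 - F) / F, so clusters are modelled as
    drifted copies of a common ancestral pool.
    """
    if cfg.freq_model_f is None:
        return cfg.lambda_
    f = cfg.freq_model_f
    if not 0.0 < f < 1.0:
        raise DataError("freq_model_f must be in (0, 1)")
    A = enc.a_max
    counts = np.bincount(
        enc.loc_idx * A + enc.allele_idx, minlength=enc.n_loci * A
    ).reshape(enc.n_loci, A).astype(float)
    pooled = counts / counts.sum(axis=1, keepdims=True)
    return pooled * (1.0 - f) / f


def _log_dirichlet_sym(q: np.ndarray, alpha: float) -> float:
    """Sum of log Dirichlet(alpha,...,alpha) densities over rows of q."""
    n, k = q.shape
    const = math.lgamma(k * alpha) - k * math.lgamma(alpha)
    # floor guards against underflowed ancestry entries driving alpha to 0
    return n * const + (alpha - 1.0) * float(np.log(np.clip(q, 1e-12, None)).sum())


def gibbs_admixture(m: AlleleMatrix, cfg: AdmixtureConfig) -> AdmixtureResult:
    """Run the admixture-model Gibbs sampler on a genotype matrix.

    Returns posterior means of ``Q`` and ``P`` over the post-burn-in sweeps,
    the likelihood trace, and the ln P(D) estimate.  Fully deterministic
    given ``cfg.seed``.
    """
    if cfg.K > m.n_individuals:
        raise DataError("K cannot exceed the number of individuals")
    enc = _encode(m)
    if enc.ind_idx.size == 0:
        raise DataError("no non-missing allele copies")
    rng = np.random.default_rng(cfg.seed)
    K, L, A = cfg.K, enc.n_loci, enc.a_max
    N, M = enc.n_ind, enc.ind_idx.size
    valid = _valid_mask(enc)
    prior = _frequency_prior(enc, cfg)
    flat_pa = enc.loc_idx * A + enc.allele_idx  # (locus, allele) flat index

    # initialise from uniform random cluster assignments
    z = rng.integers(0, K, size=M)
    counts_p = np.bincount(z * (L * A) + flat_pa, minlength=K * L * A).reshape(
        K, L, A
    )
    P = _sample_p(counts_p, prior, valid, rng)
    counts_q = np.bincount(enc.ind_idx * K + z, minlength=N * K).reshape(N, K)
    Q = rng.standard_gamma(cfg.alpha + counts_q)
    Q /= Q.sum(axis=1, keepdims=True)

    alpha = cfg.alpha
    total = cfg.burnin + cfg.iterations
    loglik_trace = np.empty(cfg.iterations)
    alpha_trace = np.empty(total)
    q_sum = np.zeros((N, K))
    p_sum = np.zeros((K, L, A))

    for sweep in range(total):
        # (i) sample the origin of every allele copy
        w = Q[enc.ind_idx] * P.reshape(K, L * A)[:, flat_pa].T  # (M, K)
        rowsum = w.sum(axis=1)
        loglik = float(np.log(rowsum).sum())
        r = rng.random(M) * rowsum
        z = np.minimum((np.cumsum(w, axis=1) < r[:, None]).sum(axis=1), K - 1)

        # (ii) sample cluster allele frequencies
        counts_p = np.bincount(
            z * (L * A) + flat_pa, minlength=K * L * A
        ).reshape(K, L, A)
        P = _sample_p(counts_p, prior, valid, rng)

        # (iii) sample ancestry proportions
        counts_q = np.bincount(enc.ind_idx * K + z, minlength=N * K).reshape(N, K)
        Q = rng.standard_gamma(alpha + counts_q)
        Q /= Q.sum(axis=1, keepdims=True)

        if cfg.update_alpha and K > 1:
            prop = alpha + rng.normal(0.0, cfg.alpha_prop_sd)
            if 0.0 < prop <= cfg.alpha_prior_max:
                logr = _log_dirichlet_sym(Q, prop) - _log_dirichlet_sym(Q, alpha)
                if math.log(rng.random()) < logr:
                    alpha = prop
        alpha_trace[sweep] = alpha

        if sweep >= cfg.burnin:
            t = sweep - cfg.burnin
            loglik_trace[t] = loglik
            q_sum += Q
            p_sum += P

    q_mean = q_sum / cfg.iterations
    p_mean = p_sum / cfg.iterations
    return AdmixtureResult(
        Q=q_mean,
        P=FrequencyModel(list(m.loci), enc.allele_labels, p_mean),
        alpha_trace=alpha_trace,
        loglik_trace=loglik_trace,
        lnPD=estimate_lnPD(loglik_trace),
        K=K,
        seed=cfg.seed,
        individuals=list(m.individuals),
    )


def log_likelihood(m: AlleleMatrix, Q: np.ndarray, P: FrequencyModel) -> float:
    """Mixture log likelihood sum over non-missing allele copies.

    Returns ``-inf`` when some observed copy has zero probability under all
    clusters.
    """
    enc = _encode(m)
    if P.loci != list(m.loci):
        raise DataError("frequency model loci do not match the matrix")
    if Q.shape != (m.n_individuals, P.K):
        raise DataError(
            f"Q shape {Q.shape} does not match (n_individuals, K) = "
            f"({m.n_individuals}, {P.K})"
        )
    A = P.probs.shape[2]
    w = Q[enc.ind_idx] * P.probs.reshape(P.K, -1)[:, enc.loc_idx * A + enc.allele_idx].T
    rowsum = w.sum(axis=1)
    if np.any(rowsum <= 0):
        return float("-inf")
    return float(np.log(rowsum).sum())


# ---------------------------------------------------------------------------
# model-evidence proxy and Evanno Delta K
# ---------------------------------------------------------------------------


def estimate_lnPD(loglik_trace: np.ndarray) -> float:
    """ln P(D) proxy: mean of the likelihood trace minus half its variance."""
    trace = np.asarray(loglik_trace, dtype=float)
    if trace.size < 2:
        raise DataError("likelihood trace must have length >= 2")
    return float(trace.mean() - trace.var(ddof=1) / 2.0)


def evanno_delta_k(lnpd_by_k: dict[int, list[float]]) -> pd.DataFrame:
    """Evanno Delta-K table from per-K lists of ln P(D) estimates.

    ``L'(K) = mean L(K) - mean L(K-1)``; ``|L''(K)| = |L'(K+1) - L'(K)|``;
    ``Delta K = |L''(K)| / sd(L(K))``, defined for interior K only.
    Requires >= 3 consecutive K values with >= 2 runs each.
    """
    ks = sorted(lnpd_by_k)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise DataError("need >= 3 consecutive K values")
    for k in ks:
        if len(lnpd_by_k[k]) < 2:
            raise DataError(f"K={k}: need >= 2 runs for Delta K")
    mean = {k: float(np.mean(lnpd_by_k[k])) for k in ks}
    sd = {k: float(np.std(lnpd_by_k[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        lp = mean[k] - mean[k - 1] if k - 1 in mean else np.nan
        lpp = (
            abs(mean[k + 1] - 2.0 * mean[k] + mean[k - 1])
            if (k - 1 in mean and k + 1 in mean)
            else np.nan
        )
        if not np.isnan(lpp):
            if sd[k] == 0.0:
                raise DataError(f"K={k}: sd of ln P(D) is zero; Delta K undefined")
            dk = lpp / sd[k]
        else:
            dk = np.nan
        rows.append(
            {
                "K": k,
                "n_runs": len(lnpd_by_k[k]),
                "mean_lnPD": mean[k],
                "sd_lnPD": sd[k],
                "Lprime": lp,
                "abs_Lsecond": lpp,
                "delta_k": dk,
            }
        )
    df = pd.DataFrame(rows)
    interior = df.dropna(subset=["delta_k"])
    df.attrs["best_k"] = int(interior.loc[interior["delta_k"].idxmax(), "K"])
    return df


# ---------------------------------------------------------------------------
# label-switching alignment and cluster summaries
# ---------------------------------------------------------------------------


def _match_columns(ref: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Greedy permutation matching columns of q to ref by correlation."""
    K = ref.shape[1]
    if K == 1:
        return np.array([0])
    corr = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            a, b = ref[:, i], q[:, j]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                corr[i, j] = -np.inf if i != j else 0.0
            else:
                corr[i, j] = float(np.corrcoef(a, b)[0, 1])
    perm = np.full(K, -1)
    used_i, used_j = set(), set()
    for _ in range(K):
        best, bi, bj = -np.inf, -1, -1
        for i in range(K):
            if i in used_i:
                continue
            for j in range(K):
                if j in used_j:
                    continue
                if corr[i, j] > best:
                    best, bi, bj = corr[i, j], i, j
        perm[bi] = bj
        used_i.add(bi)
        used_j.add(bj)
    return perm


def align_runs(results: list[AdmixtureResult]) -> list[AdmixtureResult]:
    """Resolve label switching across runs against the first run.

    Columns of each run's Q (and the matching P rows) are permuted by a
    greedy best-correlation assignment to the first run's Q columns.
    """
    if not results:
        return []
    K = results[0].K
    if any(r.K != K for r in results):
        raise DataError("all runs must share the same K")
    ref = results[0].Q
    aligned = [results[0]]
    for r in results[1:]:
        perm = _match_columns(ref, r.Q)
        aligned.append(
            AdmixtureResult(
                Q=r.Q[:, perm],
                P=r.P.permuted(perm),
                alpha_trace=r.alpha_trace,
                loglik_trace=r.loglik_trace,
                lnPD=r.lnPD,
                K=r.K,
                seed=r.seed,
                individuals=r.individuals,
            )
        )
    return aligned


def align_to_truth(q: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Permute columns of ``q`` to best match a reference ancestry matrix."""
    perm = _match_columns(truth, q)
    return q[:, perm]


def cluster_divergence(P: FrequencyModel) -> np.ndarray:
    """K x K net allele-frequency divergence between clusters.

    Entry (k, l) is the mean over loci of half the squared frequency
    differences summed over alleles.
    """
    K = P.K
    out = np.zeros((K, K))
    n_alleles = [len(a) for a in P.allele_labels]
    for k in range(K):
        for l in range(k + 1, K):
            per_locus = [
                0.5 * np.sum((P.probs[k, j, : n_alleles[j]] - P.probs[l, j, : n_alleles[j]]) ** 2)
                for j in range(len(P.loci))
            ]
            out[k, l] = out[l, k] = float(np.mean(per_locus))
    return out


def cluster_heterozygosity(P: FrequencyModel) -> np.ndarray:
    """Per-cluster expected heterozygosity, averaged over loci."""
    K = P.K
    n_alleles = [len(a) for a in P.allele_labels]
    out = np.zeros(K)
    for k in range(K):
        per_locus = [
            1.0 - np.sum(P.probs[k, j, : n_alleles[j]] ** 2)
            for j in range(len(P.loci))
        ]
        out[k] = float(np.mean(per_locus))
    return out


# ---------------------------------------------------------------------------
# multi-run driver
# ---------------------------------------------------------------------------


def run_k_range(
    m: AlleleMatrix,
    k_values: list[int],
    n_runs: int = 2,
    burnin: int = 5000,
    iterations: int = 10000,
    alpha: float = 1.0,
    lambda_: float = 1.0,
    seed: int | None = None,
) -> dict[int, list[AdmixtureResult]]:
    """Independent sampler runs for each K, with per-run derived seeds."""
    rng = np.random.default_rng(seed)
    out: dict[int, list[AdmixtureResult]] = {}
    for k in k_values:
        runs = []
        for _ in range(n_runs):
            cfg = AdmixtureConfig(
                K=k,
                burnin=burnin,
                iterations=iterations,
                alpha=alpha,
                lambda_=lambda_,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            runs.append(gibbs_admixture(m, cfg))
        out[k] = runs
    return out
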