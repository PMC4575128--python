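# Methods

## Data model

Genotypes are diploid codominant SSR calls: per individual and locus an
unordered pair of allele labels (fragment sizes in bp, scored against a
50 bp ladder). Dominant 0/1 band scores are supported as a separate matrix
and can be converted to codominant calls under the selfing-panel reading:
one band at a locus = homozygote, two bands = heterozygote, zero bands or
any missing band score = missing call. This is the only interpretation
under which observed heterozygosity is computable from 0/1 scores; it is
an idealisation appropriate for a highly selfing crop where single-band
genotypes are overwhelmingly true homozygotes, and it makes
`bands_to_alleles` and `alleles_to_bands` exact inverses on clean data.

Missing data are handled by pairwise deletion throughout: every statistic
at a locus uses only the non-missing calls at that locus; nothing is
imputed. The external missing token defaults to `-9` (STRUCTURE
convention) and is configurable.

## Locus statistics

`Na`, `Ne = 1/Σp²`, `I = −Σp ln p`, `He = 1 − Σp²`,
`uHe = 2N/(2N−1)·He`, `Ho`, and Botstein's
`PIC = 1 − Σp² − Σ_{i<j} 2p_i²p_j²` are computed from gene-copy counts.
Two deliberate formula choices:

* PIC follows Botstein's definition. A corrupted variant sometimes seen in
  print (`1 − ΣPi − ΣΣPiPj`) is negative for any polymorphic locus; it is
  exposed behind `pic(..., literal=True)` for comparison only.
* Band informativeness uses `Ib = 1 − 2·|0.5 − p|`. Without the absolute
  value the expression exceeds 1 for bands with p > 0.5, violating the
  intended [0, 1] range, so the absolute-value form is used.

Pooled-sample statistics (whole panel) and within-population statistics
(averaged over loci per population) are exposed separately, since both
conventions appear in survey tables. Comparisons against printed tables
use half-up rounding to two decimals (`round_half_up`), matching how such
tables are typeset.

## Nei distances and dendrograms

Identities are averaged over loci *before* the log-ratio (the POPGENE
convention), not per-locus ratios averaged. The unbiased variant applies
the small-sample correction `(2NΣp² − 1)/(2N − 1)` to within-population
identities; because that moment estimator can come out marginally negative
for nearly identical populations, distances are floored at zero so
identical frequency profiles map to exactly 0. A zero cross-identity
(no shared alleles) yields the infinite-distance sentinel `Inf`, which is
serialised literally and rejected by the tree builders with an explicit
error rather than silently truncated.

UPGMA merges the closest cluster pair at half its distance and updates by
size-weighted averaging (the arithmetic mean over all leaf pairs). Ties
are broken by the lexicographically smallest label pair — with the merged
cluster named after its smallest leaf — so trees are bit-reproducible.
Output trees are rooted and ultrametric by construction (asserted in
tests to 1e-9).

Neighbour joining is the Saitou–Nei algorithm; on additive matrices the
tree reproduces input distances exactly (tested to 1e-9). The survey
tradition this package follows used Gascuel's "unweighted" NJ; since no
formulas are fixed by that tradition, classic NJ is the default and a
cluster-size-weighted ("unweighted" in Gascuel's sense of weighting
original leaves equally) distance update is available behind
`unweighted=True`; only its topology, not its branch lengths, is
warranted. Negative branch-length estimates are clamped to zero.

Bootstrap support resamples **loci** with replacement (the standard for
marker trees; "1000 permutations" in survey parlance is read as 1000
bootstrap replicates), rebuilds the tree per replicate, and reports the
percentage of replicates containing each internal-edge bipartition.
Deterministic given a seed.

## AMOVA

Distances between the 2N gene copies default to allele mismatch counts
(an infinite-allele metric), rescaled by loci compared under missingness;
a stepwise squared-size-difference metric is available. The three-level
nested decomposition (among populations / among individuals within
populations / within individuals) uses df = (P−1, N−P, N) and solves the
expected-mean-square equations with the unequal-sample-size coefficient
n_c = (n − Σn_p²/n)/(P−1) in gene copies. Negative variance components
are reported raw and truncated to zero only for the percentage display
(flagged via `truncated`). Permutation tests move whole individuals among
populations (for σ_a) and gene copies among individuals within
populations (for Φ_IS ≈ σ_c), with p = (1 + #{perm ≥ obs})/(n_perm + 1);
default 999 permutations, seed recorded in the result.

## Admixture model

A Gibbs sampler over the standard admixture model: per sweep it samples
the cluster of origin of every allele copy (∝ q_ik·p_kla), cluster allele
frequencies from Dirichlet(prior + counts), and each ancestry row from
Dirichlet(α + counts). α is held constant by default (the protocol of the
surveys this mirrors); a random-walk Metropolis update with uniform prior
on (0, α_max] is available via `update_alpha=True`. The allele-frequency
prior is independent Dirichlet(λ = 1) by default; `freq_model_f` switches
to a correlated prior, Dirichlet around the pooled empirical frequencies
with concentration (1 − F)/F, modelling clusters as drifted copies of a
common pool. Missing copies contribute nothing to assignments,
frequencies, or the likelihood.

ln P(D) is estimated from the post-burn-in likelihood trace as
mean − var/2, and Evanno's ΔK = |L″(K)|/sd(L(K)) is computed from
mean ln P(D) across runs, defined for interior K only; sd = 0 is an error
rather than an infinite ΔK. Label switching across runs is resolved by
greedy best-correlation column matching against the first run.

Module defaults are desk-scale (burn-in 5,000 / 10,000 recorded sweeps);
the sampler is O(N·L·K) per sweep (~0.7 ms at N=90, L=40, K=3), so
production-scale chains (10⁵/10⁵) remain feasible.

## Synthetic panels

The generator draws, per locus, ancestral frequencies from a symmetric
Dirichlet over 2–5 alleles, then population frequencies from the F-model
Dirichlet(p_anc·(1−F)/F) — chosen over a coalescent simulator for its
closed-form expectations. Genotypes are drawn with whole-individual
selfing (with probability `selfing_rate` both copies at every locus are a
single duplicated draw), matching an inbred-line panel rather than
per-locus inbreeding. Defaults emulate the survey design this package
was built around: 6 populations of 26/30/3/6/6/15 individuals, 43 loci,
F = 0.2, selfing 0.95. The band matrix is derived losslessly (one band
per observed allele), which idealises away real gel-scoring issues
(co-migrating fragments, faint bands); passing tests therefore validate
the estimators, not gel scoring.

`realized_fst` recovers the drift parameter from the simulated
frequencies as the mean of (p − p̄)²/(p̄(1−p̄)), the method-of-moments
estimator matched to the F-model.

## Validation scales

The acceptance suite exercises parameter recovery at a deliberately
desk-scale design: three populations of 30, 40 loci, F = 0.25, chains of
400 burn-in + 800 recorded sweeps, 10 runs per K over K = 1..6, ten
seeds. Recovery panels are drawn from the textbook F-model —
random-mating genotypes, exactly the data-generating process the
admixture model assumes — so the benchmark isolates the estimator from
model misspecification; at this design ΔK selects K = 3 in ≥ 8/10 seeds
and the aligned ancestry matrix recovers the truth to mean absolute
error well under 0.08. Recovery runs enable the α update, since
inferring the concentration of near-one-hot ancestry vectors is what
makes the posterior concentrate (with α fixed at 1 the posterior
legitimately spreads ancestry mass). On *selfed* panels (the lentil-style
default) the model is misspecified — duplicated gene copies are treated
as independent — and ΔK becomes less decisive: the uppermost two-group
split then wins for roughly a quarter of simulated panels, a known
behaviour of the ΔK heuristic under hierarchical or weakened signal.
Permutation-test calibration uses 200 null panels of 16 individuals x 6
loci at 99 permutations each.

## Known limitations

* No mutation model (no stepwise mutation), no linkage model, no
  Hardy–Weinberg or LD tests; AMOVA is capped at three levels.
* The Evanno statistic is undefined at boundary K and intrinsically noisy
  with few runs per K; it is a heuristic, not an estimator of K.
* Band-to-allele conversion is undefined for individuals showing >2 bands
  at a locus (rejected with a listing) — true multi-band patterns
  (duplicated loci) are out of scope.
* The greedy run alignment can be suboptimal for strongly admixed Q
  matrices; CLUMPP-style global matching is not implemented.
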