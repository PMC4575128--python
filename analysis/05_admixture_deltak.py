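"""Bayesian admixture clustering of the synthetic panel over K = 1..6 with
Evanno Delta-K model choice, plus cluster divergence/heterozygosity
summaries for the chosen K."""

import numpy as np
import pandas as pd

import ssrdiv as sd
from common import RESULTS, SEED, load_panel

RESULTS.mkdir(parents=True, exist_ok=True)
m, _, pm, _ = load_panel()

runs = sd.run_k_range(
    m, list(range(1, 7)), n_runs=4, burnin=1000, iterations=2000, seed=SEED
)

lnpd = {k: [r.lnPD for r in rs] for k, rs in runs.items()}
dk = sd.evanno_delta_k(lnpd)
dk.to_csv(RESULTS / "deltak.tsv", sep="\t", index=False)
best_k = dk.attrs["best_k"]
print(dk.round(2).to_string(index=False))
print(f"Delta-K selects K = {best_k}")

best_runs = sd.align_runs(runs[best_k])
q_bar = np.mean([r.Q for r in best_runs], axis=0)
q = pd.DataFrame(q_bar, columns=[f"cluster{j+1}" for j in range(best_k)])
q.insert(0, "id", m.individuals)
q.insert(1, "population", [pm.population_of(i) for i in m.individuals])
q.to_csv(RESULTS / f"q_matrix_K{best_k}.tsv", sep="\t", index=False)

# how well do inferred clusters respect the simulated populations?
dominant = q_bar.argmax(axis=1)
crosstab = pd.crosstab(
    pd.Series([pm.population_of(i) for i in m.individuals], name="population"),
    pd.Series([f"cluster{j+1}" for j in dominant], name="dominant cluster"),
)
print(crosstab.to_string())

P = best_runs[0].P
div = sd.cluster_divergence(P)
het = sd.cluster_heterozygosity(P)
off = div[np.triu_indices(best_k, 1)]
print(f"least allele-frequency divergence between clusters: {off.min():.4f}")
print(f"max within-cluster expected heterozygosity: {het.max():.3f}")
print(f"wrote deltak.tsv and q_matrix_K{best_k}.tsv to {RESULTS}")
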