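"""Hierarchical AMOVA of the synthetic panel: how much variance lies among
populations, among individuals within populations, and within individuals."""

import pandas as pd

import ssrdiv as sd
from common import RESULTS, SEED, load_panel

RESULTS.mkdir(parents=True, exist_ok=True)
m, _, pm, _ = load_panel()

res = sd.amova(m, pm, n_perm=999, seed=SEED)

table = pd.DataFrame(
    {
        "level": res.levels + ["total"],
        "df": res.df + [sum(res.df)],
        "SS": [round(x, 3) for x in res.ss] + [round(res.total_ss, 3)],
        "variance_component": [round(x, 5) for x in res.components]
        + [round(res.total_component, 5)],
        "percentage": [round(x, 2) for x in res.percentages] + [100.0],
    }
)
table.to_csv(RESULTS / "amova.tsv", sep="\t", index=False)

print(table.to_string(index=False))
print(f"Phi_ST={res.phi_st:.4f}  Phi_IS={res.phi_is:.4f}  Phi_IT={res.phi_it:.4f}")
print(f"permutation p-values (999 perms): {res.p_values}")
print("note: a selfing panel concentrates variance among individuals, "
      "not within them")
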