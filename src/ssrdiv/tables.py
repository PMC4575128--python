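"""Packaged reference tables for the 43-marker *Lens* SSR survey.

``lens_ssr_panel.tsv`` holds the published per-locus summary (annealing
temperature, PIC, Rp, Na, Ne, I, He) for the 31 EST-SSR + 12 genomic SSR
panel genotyped on 86 *Lens* accessions; ``lens_nei_distances.tsv`` the
published unbiased Nei distance lower triangle among the six
subspecies/species.  They serve as reference inputs for table-arithmetic
cross-checks of the statistics implemented here.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .types import DistanceMatrix

#: published AMOVA variance components (among pops, among individuals
#: within pops, within individuals) for the same survey
REFERENCE_AMOVA_COMPONENTS = (4.05453, 5.3509, 0.5407)
REFERENCE_N_POPULATIONS = 6
REFERENCE_N_INDIVIDUALS = 86


def _read(name: str) -> str:
    return resources.files("ssrdiv.data").joinpath(name).read_text()


def load_reference_panel() -> pd.DataFrame:
    """Per-locus reference summary for the 43-SSR *Lens* panel."""
    import io

    return pd.read_csv(io.StringIO(_read("lens_ssr_panel.tsv")), sep="\t")


def load_reference_distances() -> DistanceMatrix:
    """Published Nei unbiased distances among the six *Lens* taxa."""
    import io

    rows = [
        line.split("\t")
        for line in _read("lens_nei_distances.tsv").strip().splitlines()
    ]
    labels = [r[0] for r in rows[1:]]
    n = len(labels)
    values = np.zeros((n, n))
    for i, r in enumerate(rows[1:]):
        for j, cell in enumerate(r[1:]):
            values[i, j] = values[j, i] = float(cell)
    return DistanceMatrix(labels, values)
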