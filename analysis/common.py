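"""Shared settings for the analysis drivers.

Every driver regenerates the same synthetic panel deterministically, so each
script can be run on its own; outputs land under results/.
"""

from pathlib import Path

import ssrdiv as sd

#: root seed of the whole analysis
SEED = 11

RESULTS = Path(__file__).resolve().parent.parent / "results"


def load_panel():
    """The study-design panel: 86 individuals, 6 populations, 43 SSR loci."""
    return sd.simulate(sd.SimConfig(seed=SEED))
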