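"""Internal-control 8mer fixtures.

Ten control 8mers with previously characterized regulatory effects are
shipped as a ground-truth fixture for simulator calibration tests: three
repressive, two with no effect, five activating. The relative effect sizes
below are fixture choices that preserve the published ordering (AGGUAAGU
most repressive, GUUGCAUU most activating); their absolute values are in
population-SD units of log-GFP.
"""

from __future__ import annotations

import numpy as np

from utrscreen.simulate import ACTIVATING, NEUTRAL, REPRESSIVE, TruthTable

#: (motif, regulatory effect class, role, fixture effect size in SD units)
CONTROL_8MERS: tuple[tuple[str, str, str, float], ...] = (
    ("AGGUAAGU", REPRESSIVE, "novel", -2.0),
    ("ACAGGGUA", REPRESSIVE, "miR-10 target site", -1.4),
    ("CUACCUCA", REPRESSIVE, "let-7 target site", -0.8),
    ("UUCCGUUA", NEUTRAL, "miR-191 target site", 0.0),
    ("UAAUGCCC", NEUTRAL, "novel", 0.0),
    ("UGUACAUA", ACTIVATING, "Pumilio binding motif", 0.6),
    ("UAUUUAUU", ACTIVATING, "AU-rich element", 1.0),
    ("UGUAAAGA", ACTIVATING, "novel", 1.3),
    ("GUGAGUUU", ACTIVATING, "novel", 1.6),
    ("GUUGCAUU", ACTIVATING, "novel", 2.0),
)

#: Reference motifs with no regulatory effect, used to normalize reporter tables.
REFERENCE_MOTIFS: tuple[str, str] = ("UUCCGUUA", "UAAUGCCC")

#: Motifs validated as repressive in endogenous 3'UTR contexts.
VALIDATED_REPRESSIVE: tuple[str, ...] = ("ACAGGGUA", "GAAGGUGA", "AGGUAAGU")

#: Motifs validated as activating in endogenous 3'UTR contexts.
VALIDATED_ACTIVATING: tuple[str, ...] = (
    "GUACUAUU",
    "UGUUCUAU",
    "GUUUAUAU",
    "GUGAGUUU",
    "GUUGCAUU",
)

#: Destabilizing log2(RNA/DNA) effect of the miR-10 target site.
MIR10_LOG2_RATIO: float = -0.55


def control_truth(stability_effects: bool = True) -> TruthTable:
    """The ten control 8mers as a TruthTable.

    With ``stability_effects`` on, the miR-10 site gets its characterized
    log2 RNA/DNA effect (-0.55) and other controls get none.
    """
    motifs = np.array([m for m, _, _, _ in CONTROL_8MERS], dtype=object)
    classes = np.array([c for _, c, _, _ in CONTROL_8MERS], dtype=object)
    effects = np.array([e for _, _, _, e in CONTROL_8MERS], float)
    stab = np.zeros(len(motifs))
    if stability_effects:
        stab[list(motifs).index("ACAGGGUA")] = MIR10_LOG2_RATIO
    return TruthTable(
        motif=motifs,
        expression_effect=effects,
        stability_effect=stab,
        true_class=classes,
    )
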