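"""Cell-cycle phase labels.

Segmented objects carry one of nine labels: the five mother/unbudded phases
plus the four bud mirrors.  A budded cell contributes two segmented objects
(mother + bud); in count tables a whole cell is one sampling unit whose
phase is the mother-side label.
"""

MOTHER_PHASES = ("G1", "S", "G2", "Early-M", "Late-M")
BUD_PHASES = ("S-Bud", "G2-Bud", "Early-M-Bud", "Late-M-Bud")
PHASES = MOTHER_PHASES + BUD_PHASES

#: mother phases whose cells carry a bud (G1 cells are unbudded)
BUDDED_PHASES = ("S", "G2", "Early-M", "Late-M")

COMPARTMENTS = ("whole", "mother", "bud")


def bud_label(mother_phase: str) -> str:
    """Label of the bud paired with a mother in ``mother_phase``."""
    if mother_phase not in BUDDED_PHASES:
        raise ValueError(f"{mother_phase!r} is not a budded mother phase")
    return mother_phase + "-Bud"


def mother_label(phase: str) -> str:
    """Mother-side label for any of the nine phases."""
    if phase not in PHASES:
        raise ValueError(f"unknown phase label {phase!r}")
    return phase[:-4] if phase.endswith("-Bud") else phase
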