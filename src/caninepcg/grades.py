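"""The reduced murmur-intensity scale and its mapping from the Levine scale.

Murmurs are auscultated on the 6-level Levine scale (I-VI; grades V-VI
require a palpable thrill).  For modelling, the scale is collapsed to four
intensity levels plus an explicit "none" class:

    Levine 0 (no murmur) -> none
    Levine I/II          -> soft       (softer than S1/S2)
    Levine III           -> moderate   (equal to S1/S2)
    Levine IV            -> loud       (louder than S1/S2)
    Levine V/VI          -> thrilling  (palpable thrill)

The reduced classes form a total order none < soft < moderate < loud <
thrilling and are indexed 0..4 throughout the package.
"""

from __future__ import annotations

GRADES: tuple[str, ...] = ("none", "soft", "moderate", "loud", "thrilling")
GRADE_INDEX: dict[str, int] = {g: i for i, g in enumerate(GRADES)}

N_GRADES = len(GRADES)

_LEVINE_TO_REDUCED = {0: "none", 1: "soft", 2: "soft", 3: "moderate",
                      4: "loud", 5: "thrilling", 6: "thrilling"}


def reduce_levine(levine: int) -> str:
    """Collapse a Levine grade (0-6, 0 = no murmur) to the reduced scale."""
    try:
        lev = int(levine)
    except (TypeError, ValueError):
        raise ValueError(f"Levine grade must be an integer 0-6, got {levine!r}")
    if lev != levine or not 0 <= lev <= 6:
        raise ValueError(f"Levine grade must be an integer 0-6, got {levine!r}")
    return _LEVINE_TO_REDUCED[lev]


def grade_index(grade: str | int) -> int:
    """Return the ordinal index (0..4) of a reduced grade given by name or index."""
    if isinstance(grade, str):
        try:
            return GRADE_INDEX[grade]
        except KeyError:
            raise ValueError(f"unknown reduced grade {grade!r}; expected one of {GRADES}")
    idx = int(grade)
    if not 0 <= idx < N_GRADES:
        raise ValueError(f"grade index out of range: {grade!r}")
    return idx


def grade_name(grade: str | int) -> str:
    return GRADES[grade_index(grade)]
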