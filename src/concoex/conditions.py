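"""Condition labels and the fixed ordered-pair enumeration.

The study design samples two tissues (root, shoot) at two times of day
(end of day, end of night), giving four conditions:

=====  ==========================
code   meaning
=====  ==========================
DR     end of day, root
DS     end of day, shoot
NR     end of night, root
NS     end of night, shoot
=====  ==========================

The ordering ``(DR, DS, NR, NS)`` is fixed everywhere; so is the
enumeration of the 12 ordered condition pairs ``(j | i)`` used for
condition deviations (reference condition *i* second).
"""

from __future__ import annotations

CONDITIONS: tuple[str, ...] = ("DR", "DS", "NR", "NS")

#: 12 ordered pairs (j, i): deviation of condition j relative to reference i.
#: Fixed enumeration (DS|DR, NR|DR, NS|DR, DR|DS, ..., NR|NS).
PAIR_ORDER: tuple[tuple[str, str], ...] = tuple(
    (j, i) for i in CONDITIONS for j in CONDITIONS if j != i
)

#: Integer index pairs matching PAIR_ORDER, for array code.
PAIR_INDEX: tuple[tuple[int, int], ...] = tuple(
    (CONDITIONS.index(j), CONDITIONS.index(i)) for j, i in PAIR_ORDER
)

PAIR_LABELS: tuple[str, ...] = tuple(f"{j}|{i}" for j, i in PAIR_ORDER)


def condition_index(code: str) -> int:
    """Position of a condition code in the fixed (DR, DS, NR, NS) order."""
    try:
        return CONDITIONS.index(code)
    except ValueError:
        raise ValueError(f"unknown condition label {code!r}; expected one of {CONDITIONS}") from None
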