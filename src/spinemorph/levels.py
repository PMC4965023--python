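"""Vertebral level bookkeeping (T1..L5, plus the S1 sacral plate).

Element ids are either a vertebral level (``"T8"``) or a disc between two
adjacent levels written cranial-first (``"T8-T9"``, ``"L5-S1"``).
"""

from __future__ import annotations

THORACIC = [f"T{i}" for i in range(1, 13)]
LUMBAR = [f"L{i}" for i in range(1, 6)]
#: Craniocaudal order of vertebrae that may carry endplate contours.
VERTEBRA_LEVELS = THORACIC + LUMBAR
#: Same plus S1, which contributes only its superior ("sacral") plate.
ALL_LEVELS = VERTEBRA_LEVELS + ["S1"]

_ORDER = {lv: i for i, lv in enumerate(ALL_LEVELS)}


def level_index(level: str) -> int:
    """Craniocaudal rank of a level (T1 = 0 ... L5 = 16, S1 = 17)."""
    try:
        return _ORDER[level]
    except KeyError:
        raise ValueError(f"unknown vertebral level {level!r}") from None


def is_vertebra(element_id: str) -> bool:
    return "-" not in element_id


def disc_id(upper: str, lower: str) -> str:
    """Disc element id between two adjacent levels, cranial level first."""
    iu, il = level_index(upper), level_index(lower)
    if il != iu + 1:
        raise ValueError(f"{upper} and {lower} are not adjacent levels")
    return f"{upper}-{lower}"


def disc_levels(element_id: str) -> tuple[str, str]:
    upper, lower = element_id.split("-")
    level_index(upper), level_index(lower)
    return upper, lower


def span_elements(upper: str, lower: str) -> list[str]:
    """All elements (vertebrae and intervening discs) from ``upper`` down to
    ``lower`` inclusive, in craniocaudal order."""
    iu, il = level_index(upper), level_index(lower)
    if iu > il:
        raise ValueError(f"{upper} is caudal to {lower}")
    out: list[str] = []
    for i in range(iu, il + 1):
        lv = ALL_LEVELS[i]
        if lv != "S1":
            out.append(lv)
        if i < il:
            out.append(disc_id(ALL_LEVELS[i], ALL_LEVELS[i + 1]))
    return out


def neighbor(level: str, step: int) -> str:
    """Level ``step`` positions caudal (positive) or cranial (negative)."""
    i = level_index(level) + step
    if not 0 <= i < len(ALL_LEVELS):
        raise ValueError(f"no level {step:+d} from {level}")
    return ALL_LEVELS[i]
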