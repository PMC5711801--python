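"""Shared vocabulary for the 2x2x2x2 factorial design.

The experiment crosses four two-level factors: movement instruction
(symmetrical vs. parallel), mirror view (non-mirrored vs. mirrored), pooled
hand posture (same vs. different orientation) and pooled movement speed
(fast vs. slow).  Every module that touches condition labels — the
generator, the scorer, the regression model and the contrast suite — goes
through the level names and +/-1 sum-to-zero codes defined here so that a
beta weight always means the same half-difference of level means on the
logit scale.
"""

from __future__ import annotations

from itertools import combinations, product

MAIN_EFFECTS: tuple[str, ...] = ("instruction", "mirror", "posture", "speed")

#: First listed level codes +1, second -1.
FACTOR_LEVELS: dict[str, tuple[str, str]] = {
    "instruction": ("symmetrical", "parallel"),
    "mirror": ("non-mirrored", "mirrored"),
    "posture": ("same", "different"),
    "speed": ("fast", "slow"),
}

#: Raw four-level hand posture and its pooling onto the two-level factor.
POSTURE_RAW_LEVELS: tuple[str, ...] = (
    "both-down",
    "both-up",
    "left-up-right-down",
    "left-down-right-up",
)
POSTURE_POOL: dict[str, str] = {
    "both-down": "same",
    "both-up": "same",
    "left-up-right-down": "different",
    "left-down-right-up": "different",
}

#: Instructed relative phase (degrees, external space) per instruction.
TARGET_PHASE: dict[str, float] = {"symmetrical": 180.0, "parallel": 0.0}

#: Intercept plus the 15 effects, mains first, then 2-, 3- and 4-way
#: interactions in lexicographic factor order.  This ordering is the stable
#: contract for beta vectors throughout the package.
EFFECT_NAMES: tuple[str, ...] = ("intercept",) + tuple(
    "_".join(c) for k in (1, 2, 3, 4) for c in combinations(MAIN_EFFECTS, k)
)


def level_code(factor: str, level: str) -> int:
    """Return the +/-1 sum-to-zero code of ``level`` on ``factor``."""
    try:
        levels = FACTOR_LEVELS[factor]
    except KeyError:
        raise ValueError(f"unknown factor {factor!r}") from None
    try:
        return (1, -1)[levels.index(level)]
    except ValueError:
        raise ValueError(
            f"unknown level {level!r} for factor {factor!r}; expected one of {levels}"
        ) from None


def effect_code(effect: str, levels: dict[str, str]) -> int:
    """Code of a (possibly interaction) effect at a cell of the design.

    Interaction codes are products of the constituent main-effect codes;
    ``intercept`` codes 1 everywhere.
    """
    if effect == "intercept":
        return 1
    out = 1
    for factor in effect.split("_"):
        out *= level_code(factor, levels[factor])
    return out


def cell_codes(levels: dict[str, str]) -> list[int]:
    """The 16-vector of effect codes (intercept first) at one design cell."""
    return [effect_code(e, levels) for e in EFFECT_NAMES]


def pool_posture(posture_raw: str) -> str:
    try:
        return POSTURE_POOL[posture_raw]
    except KeyError:
        raise ValueError(
            f"unknown raw posture {posture_raw!r}; expected one of {POSTURE_RAW_LEVELS}"
        ) from None


def pool_speed(speed_level: int) -> str:
    """Collapse metronome plateau 1-10 onto slow (1-5) vs. fast (6-10)."""
    if not 1 <= int(speed_level) <= 10:
        raise ValueError(f"speed_level must be in 1..10, got {speed_level}")
    return "slow" if speed_level <= 5 else "fast"


def all_cells() -> list[dict[str, str]]:
    """The 16 pooled-factor cells in a stable order."""
    return [
        dict(zip(MAIN_EFFECTS, levels))
        for levels in product(*(FACTOR_LEVELS[f] for f in MAIN_EFFECTS))
    ]
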