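"""Posterior-predictive cell predictions and credible-difference contrasts.

Cell predictions are group-level linear predictors evaluated per posterior
draw at a design cell's +/-1 codes, with the participant intercept at its
population center (zero).  Leaving a factor unspecified sets its code — and
that of every interaction containing it — to zero, which on the logit scale
equals averaging the two cells.  Credible differences are formed per MCMC
draw (paired, preserving posterior correlation between cells) and
summarized by mean, 95% HDI and the fractions of draws on either side of
zero.  Contrast names follow the ``difference_a_b`` convention: the levels
being subtracted, then the levels held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .factors import EFFECT_NAMES, MAIN_EFFECTS, level_code
from .model import PosteriorSamples, hdi


def logit_to_percent(x):
    """Percent correct implied by a logit: 100 * invlogit(x)."""
    x = np.asarray(x, dtype=float)
    out = 100.0 / (1.0 + np.exp(-x))
    return float(out) if out.ndim == 0 else out


def percent_point_change(base, delta):
    """Percentage-point change when a logit effect is added to a baseline."""
    return logit_to_percent(np.asarray(base) + np.asarray(delta)) - logit_to_percent(base)


@dataclass(frozen=True)
class ContrastResult:
    name: str
    scale: str  # 'logit' or 'percent'
    mean: float
    hdi_low: float
    hdi_high: float
    frac_below_zero: float
    frac_above_zero: float
    frac_zero: float

    @property
    def excludes_zero(self) -> bool:
        return self.hdi_low > 0 or self.hdi_high < 0


def _cell_code_vector(cell: dict[str, str | None]) -> np.ndarray:
    unknown = set(cell) - set(MAIN_EFFECTS)
    if unknown:
        raise ValueError(f"unknown factor(s) in cell: {sorted(unknown)}")
    main = {
        f: (0.0 if cell.get(f) is None else float(level_code(f, cell[f])))
        for f in MAIN_EFFECTS
    }
    codes = np.empty(len(EFFECT_NAMES))
    codes[0] = 1.0
    for k, name in enumerate(EFFECT_NAMES[1:], start=1):
        v = 1.0
        for f in name.split("_"):
            v *= main[f]
        codes[k] = v
    return codes


def cell_prediction(
    post: PosteriorSamples, cell: dict[str, str | None], scale: str = "logit"
) -> np.ndarray:
    """Per-draw prediction at a design cell on the requested scale.

    ``cell`` maps factor name to level; omitted (or ``None``) factors are
    marginalized by zeroing their codes.
    """
    eta = post.beta_flat @ _cell_code_vector(cell)
    if scale == "logit":
        return eta
    if scale == "percent":
        return logit_to_percent(eta)
    raise ValueError(f"unknown scale {scale!r}")


def credible_difference(
    draws_a: np.ndarray, draws_b: np.ndarray, name: str = "difference",
    scale: str = "logit",
) -> ContrastResult:
    """Paired per-draw difference a - b with HDI and tail fractions."""
    a = np.asarray(draws_a, float).ravel()
    b = np.asarray(draws_b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("draws must be paired by MCMC iteration (equal lengths)")
    d = a - b
    lo, hi = hdi(d) if len(d) >= 100 else (float(d.min()), float(d.max()))
    return ContrastResult(
        name=name,
        scale=scale,
        mean=float(d.mean()),
        hdi_low=lo,
        hdi_high=hi,
        frac_below_zero=float((d < 0).mean()),
        frac_above_zero=float((d > 0).mean()),
        frac_zero=float((d == 0).mean()),
    )


def _contrast(post, name, cell_a, cell_b, scale="logit") -> ContrastResult:
    return credible_difference(
        cell_prediction(post, cell_a, scale),
        cell_prediction(post, cell_b, scale),
        name=name,
        scale=scale,
    )


def named_contrast_suite(post: PosteriorSamples, scale: str = "logit") -> list[ContrastResult]:
    """The study's full contrast set (12 results).

    * four homology contrasts: homologous minus non-homologous posture per
      instruction x pooled speed (mirror marginalized);
    * four mirror contrasts: mirrored minus non-mirrored per instruction x
      pooled speed (posture marginalized);
    * two muscle-congruence contrasts within mirrored blocks: congruent
      minus incongruent posture per instruction (speed marginalized);
    * two congruent-mirrored vs congruent-non-mirrored contrasts per
      instruction (speed marginalized).
    """
    out = []
    # homologous minus non-homologous: for symmetrical that is same-different,
    # for parallel different-same
    for speed in ("slow", "fast"):
        out.append(_contrast(
            post, f"same-different_symmetrical_{speed}",
            {"instruction": "symmetrical", "posture": "same", "speed": speed},
            {"instruction": "symmetrical", "posture": "different", "speed": speed},
            scale,
        ))
        out.append(_contrast(
            post, f"different-same_parallel_{speed}",
            {"instruction": "parallel", "posture": "different", "speed": speed},
            {"instruction": "parallel", "posture": "same", "speed": speed},
            scale,
        ))
    # mirrored minus non-mirrored per instruction x speed
    for instruction in ("symmetrical", "parallel"):
        for speed in ("slow", "fast"):
            out.append(_contrast(
                post, f"mirrored-non-mirrored_{instruction}_{speed}",
                {"instruction": instruction, "mirror": "mirrored", "speed": speed},
                {"instruction": instruction, "mirror": "non-mirrored", "speed": speed},
                scale,
            ))
    # muscle congruence within mirrored blocks (congruent minus incongruent)
    out.append(_contrast(
        post, "same-different_symmetrical_mirrored",
        {"instruction": "symmetrical", "mirror": "mirrored", "posture": "same"},
        {"instruction": "symmetrical", "mirror": "mirrored", "posture": "different"},
        scale,
    ))
    out.append(_contrast(
        post, "different-same_parallel_mirrored",
        {"instruction": "parallel", "mirror": "mirrored", "posture": "different"},
        {"instruction": "parallel", "mirror": "mirrored", "posture": "same"},
        scale,
    ))
    # congruent mirrored vs congruent non-mirrored
    out.append(_contrast(
        post, "mirrored-non-mirrored_symmetrical_same",
        {"instruction": "symmetrical", "mirror": "mirrored", "posture": "same"},
        {"instruction": "symmetrical", "mirror": "non-mirrored", "posture": "same"},
        scale,
    ))
    out.append(_contrast(
        post, "mirrored-non-mirrored_parallel_different",
        {"instruction": "parallel", "mirror": "mirrored", "posture": "different"},
        {"instruction": "parallel", "mirror": "non-mirrored", "posture": "different"},
        scale,
    ))
    return out


def contrast_table(results: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [r.name for r in results],
            "scale": [r.scale for r in results],
            "mean": [r.mean for r in results],
            "hdi_low": [r.hdi_low for r in results],
            "hdi_high": [r.hdi_high for r in results],
            "frac_below_zero": [r.frac_below_zero for r in results],
            "frac_above_zero": [r.frac_above_zero for r in results],
            "excludes_zero": [r.excludes_zero for r in results],
        }
    )
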