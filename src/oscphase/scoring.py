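"""Dichotomized accuracy, phase histograms, factor pooling, congruence labels.

A movement cycle counts as correct when its relative phase lies within a
tolerance window (50 deg by default, 20 deg as the stricter alternative)
around the instructed target: 180 deg for symmetrical, 0 deg for parallel
movements, measured as circular distance so phases near the wrap boundary
are scored consistently.  A distance exactly equal to the tolerance counts
as correct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .factors import TARGET_PHASE, pool_posture, pool_speed
from .synth import wrap_phase

HISTOGRAM_EDGES = np.arange(-90.0, 270.0 + 1e-9, 20.0)  # 18 bins over [-90, 270)


def circular_distance(a, b) -> np.ndarray:
    """Smallest absolute angular distance in degrees."""
    return np.abs((np.asarray(a, float) - np.asarray(b, float) + 180.0) % 360.0 - 180.0)


def classify_cycle(relative_phase, instruction: str, tolerance: float = 50.0):
    """1 if the phase is within ``tolerance`` degrees of the instruction's
    target (circular distance, boundary inclusive), else 0.  Vectorized."""
    if not 0 < tolerance < 90:
        raise ValueError("tolerance must be in (0, 90) degrees")
    try:
        target = TARGET_PHASE[instruction]
    except KeyError:
        raise ValueError(f"unknown instruction {instruction!r}") from None
    out = (circular_distance(relative_phase, target) <= tolerance).astype(int)
    return out if out.ndim else int(out)


def phase_histogram(phases) -> tuple[np.ndarray, bool]:
    """Percentages of cycles per 20-degree bin over [-90, 270).

    Input phases are wrapped into the interval first.  Counts are divided by
    the total number of cycles (per participant, by construction of the
    caller) and multiplied by 100.  Returns (percent per bin, empty flag).
    """
    phases = np.atleast_1d(np.asarray(phases, dtype=float))
    if phases.size == 0:
        return np.zeros(len(HISTOGRAM_EDGES) - 1), True
    counts, _ = np.histogram(wrap_phase(phases), bins=HISTOGRAM_EDGES)
    return 100.0 * counts / phases.size, False


def histogram_table(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Per-participant phase histograms, one row per participant x bin."""
    rows = []
    for participant, g in outcomes.groupby("participant"):
        pct, _ = phase_histogram(g["relative_phase"].to_numpy())
        for lo, p in zip(HISTOGRAM_EDGES[:-1], pct):
            rows.append(
                {"participant": participant, "bin_left": lo, "percent": p}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CongruenceLabel:
    """Which aspects of mirrored visual feedback agree with proprioception.

    The mirror always shows two same-oriented hands moving symmetrically, so
    in mirrored blocks congruence of movement direction, hand posture and
    apparent active muscles each depend on what is actually performed;
    without the mirror all three are trivially congruent.  Conditions are
    numbered 1-8 over instruction x pooled posture, odd without mirror and
    even with.
    """

    condition_number: int
    direction_congruent: bool
    posture_congruent: bool
    muscle_congruent: bool
    homologous_required: bool


def homologous_required(instruction: str, posture_pooled: str) -> bool:
    """Symmetrical movements need homologous muscles with same-oriented
    hands; parallel movements need them with differently oriented hands."""
    return (instruction == "symmetrical") == (posture_pooled == "same")


def congruence_labels(
    instruction: str, mirror: str, posture_pooled: str
) -> CongruenceLabel:
    homol = homologous_required(instruction, posture_pooled)
    number = (
        1
        + 4 * (instruction == "parallel")
        + 2 * (posture_pooled == "different")
        + (mirror == "mirrored")
    )
    if mirror == "non-mirrored":
        return CongruenceLabel(number, True, True, True, homol)
    return CongruenceLabel(
        condition_number=number,
        direction_congruent=instruction == "symmetrical",
        posture_congruent=posture_pooled == "same",
        # the mirror image implies homologous muscles, so apparent and true
        # muscle sets agree exactly when homologous muscles are required
        muscle_congruent=homol,
        homologous_required=homol,
    )


def pool_factors(df: pd.DataFrame) -> pd.DataFrame:
    """Add pooled posture and speed columns to a cycle-level table."""
    out = df.copy()
    out["posture"] = df["posture_raw"].map(pool_posture)
    if out["posture"].isna().any():
        bad = df.loc[out["posture"].isna(), "posture_raw"].unique()
        raise ValueError(f"unknown raw posture level(s): {list(bad)}")
    out["speed"] = df["speed_level"].map(pool_speed)
    return out


def exclude_trials(meta: pd.DataFrame) -> pd.DataFrame:
    """Drop flagged trials from the metadata table."""
    if "excluded" not in meta.columns:
        return meta.copy()
    return meta.loc[~meta["excluded"].astype(bool)].reset_index(drop=True)


def build_outcomes(
    cycles: pd.DataFrame, meta: pd.DataFrame, tolerance: float = 50.0
) -> pd.DataFrame:
    """Join cycles with trial metadata, pool factors, classify each cycle.

    Cycles from excluded trials or with invalid fits are dropped.  The
    result is the outcome table the regression model consumes: one row per
    analyzable cycle with the four pooled factors, the relative phase, the
    condition number and the correctness flag.
    """
    meta = exclude_trials(meta)
    cols = ["trial", "instruction", "mirror", "posture_raw"]
    # the metadata table is authoritative for condition labels
    cycles = cycles.drop(columns=[c for c in cols[1:] if c in cycles.columns])
    merged = cycles.merge(meta[cols], on="trial", how="inner")
    if "valid" in merged.columns:
        merged = merged.loc[merged["valid"].astype(bool)]
    merged = pool_factors(merged)
    correct = np.zeros(len(merged), dtype=int)
    for instruction in ("symmetrical", "parallel"):
        m = (merged["instruction"] == instruction).to_numpy()
        correct[m] = classify_cycle(
            merged.loc[m, "relative_phase"].to_numpy(), instruction, tolerance
        )
    merged = merged.assign(correct=correct, tolerance=float(tolerance))
    merged["condition_number"] = [
        congruence_labels(i, m, p).condition_number
        for i, m, p in zip(merged["instruction"], merged["mirror"], merged["posture"])
    ]
    keep = [
        "participant",
        "trial",
        "cycle_index",
        "instruction",
        "mirror",
        "posture_raw",
        "posture",
        "speed_level",
        "speed",
        "condition_number",
        "relative_phase",
        "correct",
        "tolerance",
    ]
    return merged[[c for c in keep if c in merged.columns]].reset_index(drop=True)


def accuracy_by_cell(outcomes: pd.DataFrame, by=("instruction", "mirror", "posture", "speed")) -> pd.DataFrame:
    """Percent-correct summaries per design cell (and any grouping)."""
    g = outcomes.groupby(list(by), observed=True)["correct"]
    out = (100.0 * g.mean()).rename("percent_correct").reset_index()
    out["n_cycles"] = g.size().to_numpy()
    return out
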