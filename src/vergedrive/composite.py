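"""Sign-aligned composite deterioration scores (OVDS / ODPDS).

A composite score summarizes a subject's overall deterioration across a set
of paired impairments (aAC − baseline).  Each variable's impairment column is
z-scored against the cohort (sample SD, n−1), multiplied by its declared
worsening direction so that *more positive always means worse*, and the
per-subject composite is the unweighted mean of the aligned z-scores.  The
cohort mean of each aligned column — and hence of the composite — is zero by
construction.

OVDS (overall visual deterioration score) and ODPDS (overall driving
performance deterioration score) are the same mechanics applied to the
visual and driving variable sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ImpairmentMatrix", "CompositeScore", "build_composite",
           "build_ovds", "build_odpds"]


@dataclass
class ImpairmentMatrix:
    """Per-subject impairments (subjects × variables) with worsening directions.

    ``values`` is a DataFrame indexed by subject id with one column per
    variable; ``directions`` maps each column to +1 (an increase is worse) or
    −1 (a decrease is worse).  Missing cells are allowed (NaN).
    """

    values: pd.DataFrame
    directions: dict[str, int]

    def __post_init__(self):
        if len(self.values) < 2:
            raise ValueError("z-scores need at least 2 subjects")
        missing = set(self.values.columns) - set(self.directions)
        if missing:
            raise ValueError(f"variables without a worsening direction: {sorted(missing)}")
        bad = {k: v for k, v in self.directions.items()
               if k in self.values.columns and v not in (-1, 1)}
        if bad:
            raise ValueError(f"directions must be +1 or -1: {bad}")
        all_nan = [c for c in self.values.columns if self.values[c].isna().all()]
        if all_nan:
            raise ValueError(f"all-missing variables: {all_nan}")


@dataclass
class CompositeScore:
    """Per-subject composite plus the aligned z-matrix retained for audit."""

    scores: pd.Series
    z: pd.DataFrame
    excluded_variables: list[str] = field(default_factory=list)
    flagged_subjects: list = field(default_factory=list)


def build_composite(matrix: ImpairmentMatrix) -> CompositeScore:
    """Aligned-z composite of an impairment matrix.

    Zero-SD variables carry no cohort information and are excluded with a
    warning.  A subject's score is the mean over their available aligned
    z-scores; subjects missing more than half of the variables are flagged.
    """
    vals = matrix.values
    z_cols: dict[str, pd.Series] = {}
    excluded: list[str] = []
    for col in vals.columns:
        x = vals[col].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            excluded.append(col)
            continue
        z_cols[col] = matrix.directions[col] * (x - x.mean()) / sd
    if excluded:
        warnings.warn(f"zero-variance variables excluded from composite: "
                      f"{excluded}", stacklevel=2)
    if not z_cols:
        raise ValueError("no variables with positive variance; composite undefined")
    z = pd.DataFrame(z_cols)
    n_vars = z.shape[1]
    available = z.notna().sum(axis=1)
    flagged = list(z.index[available < n_vars / 2.0])
    if flagged:
        warnings.warn(f"subjects missing more than half the variables: {flagged}",
                      stacklevel=2)
    scores = z.mean(axis=1, skipna=True)
    scores.name = "composite"
    return CompositeScore(scores, z, excluded, flagged)


def build_ovds(matrix: ImpairmentMatrix) -> CompositeScore:
    """Overall visual deterioration score (higher = worse vision after alcohol)."""
    score = build_composite(matrix)
    score.scores.name = "ovds"
    return score


def build_odpds(matrix: ImpairmentMatrix) -> CompositeScore:
    """Overall driving-performance deterioration score (higher = worse driving)."""
    score = build_composite(matrix)
    score.scores.name = "odpds"
    return score
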