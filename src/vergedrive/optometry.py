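"""Clinical binocular-vision and vergence metrics.

Sign conventions used throughout the package:

* horizontal phorias are signed in prism diopters (Δ): esophoria positive,
  exophoria negative;
* vertical phorias: right hyperphoria positive;
* fusional-reserve magnitudes (blur / break / recovery) are stored unsigned,
  with the direction encoded by the field prefix (``nfv_`` base-in,
  ``pfv_`` base-out, ``vfv_`` vertical);
* Sheard's and Percival's comfort criteria are expressed as signed values in
  Δ where a negative value means the phoria is correctly compensated and a
  positive value means a decompensated phoria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "VergenceExam",
    "VisualExam",
    "CriterionResult",
    "IncompleteExamError",
    "calculated_acac",
    "gradient_acac",
    "sheard_criterion",
    "percival_criterion",
    "classify_vergence_facility",
    "impairment",
    "read_vergence_exams",
    "write_vergence_exams",
    "exam_from_row",
]

#: Normal range of near vergence facility, cycles per minute (closed interval).
VERGENCE_FACILITY_NORMAL_RANGE = (10.0, 15.0)


class IncompleteExamError(ValueError):
    """Raised when a criterion needs a fusional-reserve point that was not measured."""


def _present(x) -> bool:
    return x is not None and not (isinstance(x, float) and math.isnan(x))


@dataclass
class VergenceExam:
    """One eye-team vergence examination at a single viewing distance.

    Parameters
    ----------
    distance_m
        Viewing distance in meters (typically 5.5 far, 0.40 near).
    horizontal_phoria, vertical_phoria
        Signed dissociated phorias in prism diopters (eso +, exo −;
        right-hyper +).
    nfv_blur, nfv_break, nfv_recovery
        Negative (base-in) fusional-vergence points, Δ, unsigned magnitudes.
        The blur point may be absent (``None``) — base-in testing at distance
        commonly yields no blur.
    pfv_blur, pfv_break, pfv_recovery
        Positive (base-out) fusional-vergence points, Δ, unsigned magnitudes.
    vfv_break, vfv_recovery
        Vertical fusional-vergence points, Δ, unsigned.
    near_phoria_with_minus1d
        Near horizontal phoria re-measured through a −1.00 D lens (Δ, signed);
        only meaningful on near exams, used for the gradient AC/A.
    vergence_facility_cpm
        Near vergence facility in cycles per minute (3Δ BI / 12Δ BO flippers).
    """

    distance_m: float
    horizontal_phoria: float = 0.0
    vertical_phoria: float = 0.0
    nfv_blur: float | None = None
    nfv_break: float | None = None
    nfv_recovery: float | None = None
    pfv_blur: float | None = None
    pfv_break: float | None = None
    pfv_recovery: float | None = None
    vfv_break: float | None = None
    vfv_recovery: float | None = None
    near_phoria_with_minus1d: float | None = None
    vergence_facility_cpm: float | None = None

    def __post_init__(self) -> None:
        if not self.distance_m > 0:
            raise ValueError(f"distance_m must be positive, got {self.distance_m}")
        for name in (
            "nfv_blur", "nfv_break", "nfv_recovery",
            "pfv_blur", "pfv_break", "pfv_recovery",
            "vfv_break", "vfv_recovery",
        ):
            v = getattr(self, name)
            if _present(v) and v < 0:
                raise ValueError(f"{name} is a magnitude and must be >= 0, got {v}")
        for prefix in ("nfv", "pfv", "vfv"):
            brk = getattr(self, f"{prefix}_break")
            rec = getattr(self, f"{prefix}_recovery")
            blur = getattr(self, f"{prefix}_blur", None)
            if _present(brk) and _present(rec) and rec > brk:
                raise ValueError(f"{prefix}: recovery ({rec}) must not exceed break ({brk})")
            if _present(brk) and _present(blur) and blur > brk:
                raise ValueError(f"{prefix}: blur ({blur}) must not exceed break ({brk})")
        if _present(self.vergence_facility_cpm) and self.vergence_facility_cpm < 0:
            raise ValueError("vergence_facility_cpm must be >= 0")

    def reserve_point(self, side: Literal["nfv", "pfv"]) -> float:
        """Fusional-reserve point used by the comfort criteria.

        Clinical convention: the blur point when one was recorded, otherwise
        the break point.
        """
        blur = getattr(self, f"{side}_blur")
        brk = getattr(self, f"{side}_break")
        if _present(blur):
            return float(blur)
        if _present(brk):
            return float(brk)
        raise IncompleteExamError(
            f"neither blur nor break recorded for {side}; exam is incomplete"
        )


@dataclass
class VisualExam:
    """Non-vergence visual measurements for one subject under one condition."""

    distance_va_decimal: float
    stereo_far_arcsec: float
    stereo_near_arcsec: float
    pupil_mm: float

    def __post_init__(self) -> None:
        for name in ("distance_va_decimal", "stereo_far_arcsec",
                     "stereo_near_arcsec", "pupil_mm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class CriterionResult:
    """Signed comfort-criterion value; negative means the phoria is compensated."""

    criterion_name: Literal["Sheard", "Percival"]
    value_pd: float

    @property
    def compensated(self) -> bool:
        # Strict: a boundary value of exactly 0 counts as NOT compensated.
        return self.value_pd < 0


def calculated_acac(distance_phoria: float, near_phoria: float) -> float:
    """Calculated AC/A ratio (Δ/D) from distance and near phorias.

    ``(15 − distance_phoria + near_phoria) / 2.5`` with signed phorias
    (eso +, exo −).  The constant 15 Δ is the fixed near convergence demand
    (consistent with a 6 cm interpupillary distance at 40 cm) and 2.5 D is the
    accommodative demand difference between 5.5 m and 40 cm fixation.
    """
    return (15.0 - distance_phoria + near_phoria) / 2.5


def gradient_acac(near_phoria: float, near_phoria_with_minus1d: float) -> float:
    """Gradient AC/A ratio (Δ/D): |phoria through −1.00 D lens − habitual phoria|."""
    return abs(near_phoria_with_minus1d - near_phoria)


def sheard_criterion(
    phoria: float,
    exam: VergenceExam,
    formula: Literal["criterion", "prescription"] = "criterion",
) -> CriterionResult:
    """Sheard's comfort criterion for a horizontal phoria.

    The rule: the opposing fusional reserve should be at least twice the
    phoria.  An exophoria (negative) is opposed by the positive (base-out)
    reserve; an esophoria (positive) by the negative (base-in) reserve; an
    orthophoric subject is scored against the smaller of the two reserves
    (conservative).  The reserve point is the blur point if recorded,
    otherwise the break point.

    ``formula="criterion"`` returns ``|phoria| − reserve/2``;
    ``formula="prescription"`` returns Sheard's prism-prescription form
    ``(2·|phoria| − reserve)/3``.  Both are negative exactly when the rule is
    satisfied; only the magnitude scale differs.
    """
    if phoria < 0:
        reserve = exam.reserve_point("pfv")
    elif phoria > 0:
        reserve = exam.reserve_point("nfv")
    else:
        reserve = min(exam.reserve_point("nfv"), exam.reserve_point("pfv"))
    demand = abs(phoria)
    if formula == "criterion":
        value = demand - reserve / 2.0
    elif formula == "prescription":
        value = (2.0 * demand - reserve) / 3.0
    else:
        raise ValueError(f"unknown formula {formula!r}")
    return CriterionResult("Sheard", float(value))


def percival_criterion(exam: VergenceExam) -> CriterionResult:
    """Percival's comfort criterion.

    The point of zero vergence demand should lie in the middle third of the
    total fusional range.  With G and L the greater and lesser of the two
    lateral reserve points, the signed value is ``G/3 − 2L/3``; negative when
    the zero-demand point is inside the middle third (compensated).  Symmetric
    in the two reserves.
    """
    nfv = exam.reserve_point("nfv")
    pfv = exam.reserve_point("pfv")
    g, l = max(nfv, pfv), min(nfv, pfv)
    return CriterionResult("Percival", float(g / 3.0 - 2.0 * l / 3.0))


def classify_vergence_facility(cpm: float) -> str:
    """Classify a near vergence-facility rate against the normal range.

    Returns ``"below_normal"``, ``"normal"`` (10–15 cpm, closed interval) or
    ``"above_normal"``.
    """
    if cpm < 0:
        raise ValueError(f"vergence facility must be >= 0, got {cpm}")
    lo, hi = VERGENCE_FACILITY_NORMAL_RANGE
    if cpm < lo:
        return "below_normal"
    if cpm > hi:
        return "above_normal"
    return "normal"


def impairment(aac_value, baseline_value, *, unit: str | None = None,
               baseline_unit: str | None = None):
    """Signed change after alcohol: ``aAC − baseline``.

    Works element-wise on arrays.  If both unit strings are given they must
    agree; the result carries the common unit's scale.  Antisymmetric under
    swapping the two arguments.
    """
    if unit is not None and baseline_unit is not None and unit != baseline_unit:
        raise ValueError(f"unit mismatch: {unit!r} vs {baseline_unit!r}")
    return np.subtract(aac_value, baseline_value)


# ---------------------------------------------------------------------------
# delimited-text I/O

#: Column order for vergence-exam tables: one row per subject × condition × distance.
VERGENCE_EXAM_COLUMNS = [
    "subject", "condition", "distance_m",
    "horizontal_phoria", "vertical_phoria",
    "nfv_blur", "nfv_break", "nfv_recovery",
    "pfv_blur", "pfv_break", "pfv_recovery",
    "vfv_break", "vfv_recovery",
    "near_phoria_with_minus1d", "vergence_facility_cpm",
]


def exam_from_row(row: pd.Series | dict) -> VergenceExam:
    """Build a validated :class:`VergenceExam` from one table row."""
    kwargs = {}
    for name in VERGENCE_EXAM_COLUMNS[2:]:
        v = row.get(name) if isinstance(row, dict) else (
            row[name] if name in row.index else None)
        if v is not None and not (isinstance(v, float) and math.isnan(v)):
            kwargs[name] = float(v)
    return VergenceExam(**kwargs)


def read_vergence_exams(path) -> pd.DataFrame:
    """Read a vergence-exam CSV (see :data:`VERGENCE_EXAM_COLUMNS`)."""
    df = pd.read_csv(path)
    missing = {"subject", "condition", "distance_m"} - set(df.columns)
    if missing:
        raise ValueError(f"vergence exam table missing columns: {sorted(missing)}")
    return df


def write_vergence_exams(df: pd.DataFrame, path) -> None:
    cols = [c for c in VERGENCE_EXAM_COLUMNS if c in df.columns]
    df.to_csv(path, columns=cols, index=False)


def exams_from_frame(df: pd.DataFrame) -> Iterable[tuple[str, str, VergenceExam]]:
    """Yield ``(subject, condition, exam)`` triples from an exam table."""
    for _, row in df.iterrows():
        yield str(row["subject"]), str(row["condition"]), exam_from_row(row)
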