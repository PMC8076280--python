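"""Reference cohort: variable definitions and group summary statistics.

The package ships the group-level summary statistics (mean ± SD at baseline
and after alcohol consumption, "aAC", at a breath alcohol content of
0.40 mg/l) of a 30-subject paired study cohort of young healthy drivers.
These figures parameterize the synthetic cohort generator and serve as the
worked-example inputs for the analysis pipeline.

Each :class:`VariableDef` records, besides the four moments, how the variable
enters the composite deterioration scores:

* ``direction`` — +1 if an *increase* of the (transformed) impairment means
  worse performance, −1 if a decrease does;
* ``transform`` — ``"signed"`` impairment is ``aAC − baseline``; ``"abs"``
  (phorias) uses ``|aAC| − |baseline|`` so that movement away from
  orthophoria in either direction counts as deterioration;
* ``in_composite`` — whether the variable enters OVDS / ODPDS by default.

``published=True`` marks rows whose four moments are group statistics
reported for the study cohort; ``published=False`` marks variables that the
cohort battery measures but whose group table was not reported numerically —
for those, clinically typical values (Morgan's norms for the reserves,
text-reported phoria shifts) are used as generator defaults.
``reported_impairment`` stores the reported mean change (aAC − baseline)
cell where one exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "VariableDef",
    "VARIABLES",
    "variable_map",
    "visual_variables",
    "driving_variables",
    "composite_variables",
]


@dataclass(frozen=True)
class VariableDef:
    name: str
    label: str
    unit: str
    domain: str                 # 'visual' | 'driving'
    kind: str                   # 'signed' | 'nonneg' | 'count' | 'sum'
    mean_baseline: float
    sd_baseline: float
    mean_aac: float
    sd_aac: float
    direction: int              # +1: increase is worse; -1: decrease is worse
    in_composite: bool
    published: bool
    transform: str = "signed"   # 'signed' | 'abs'
    reported_impairment: float | None = None
    parents: tuple[str, ...] = ()   # for kind == 'sum'

    @property
    def mean_impairment(self) -> float:
        """Population mean impairment implied by the group means."""
        return self.mean_aac - self.mean_baseline


def _v(*args, **kw) -> VariableDef:
    return VariableDef(*args, **kw)


VARIABLES: tuple[VariableDef, ...] = (
    # --- visual battery -----------------------------------------------------
    _v("pupil_mm", "Pupil diameter", "mm", "visual", "nonneg",
       5.6, 0.5, 6.3, 0.6, +1, False, True, reported_impairment=0.7),
    _v("distance_va", "Distance visual acuity", "decimal", "visual", "nonneg",
       1.35, 0.15, 1.09, 0.15, -1, True, True, reported_impairment=-0.26),
    _v("stereo_far", "Distance stereoacuity", "arcsec", "visual", "nonneg",
       25.0, 16.0, 118.0, 91.0, +1, True, True, reported_impairment=94.0),
    _v("stereo_near", "Near stereoacuity (Randot)", "arcsec", "visual", "nonneg",
       20.0, 6.0, 36.0, 13.0, +1, True, True, reported_impairment=16.0),
    # Phorias: far horizontal means are text-reported (−0.1 Δ baseline,
    # 2.9 ± 3.2 Δ aAC); remaining moments are typical clinical values.
    _v("phoria_h_far", "Distance horizontal phoria", "pd", "visual", "signed",
       -0.1, 2.5, 2.9, 3.2, +1, True, False, transform="abs"),
    _v("phoria_h_near", "Near horizontal phoria", "pd", "visual", "signed",
       -3.0, 4.0, -4.6, 5.0, +1, True, False, transform="abs"),
    _v("phoria_v_far", "Distance vertical phoria", "pd", "visual", "signed",
       0.0, 0.4, 0.0, 0.5, +1, True, False, transform="abs"),
    _v("phoria_v_near", "Near vertical phoria", "pd", "visual", "signed",
       0.0, 0.5, 0.1, 0.6, +1, True, False, transform="abs"),
    # Horizontal fusional reserves (break points); defaults from Morgan's
    # norms at baseline with an alcohol-reduced aAC level.
    _v("nfv_break_far", "Distance NFV break", "pd", "visual", "nonneg",
       7.0, 2.5, 4.5, 2.5, -1, True, False),
    _v("pfv_break_far", "Distance PFV break", "pd", "visual", "nonneg",
       19.0, 8.0, 13.0, 7.0, -1, True, False),
    _v("nfv_break_near", "Near NFV break", "pd", "visual", "nonneg",
       21.0, 4.0, 16.0, 5.0, -1, True, False),
    _v("pfv_break_near", "Near PFV break", "pd", "visual", "nonneg",
       21.0, 6.0, 15.0, 6.0, -1, True, False),
    # Vertical fusional vergences.
    _v("vfv_break_far", "Distance vertical FV break", "pd", "visual", "nonneg",
       2.2, 0.6, 0.9, 1.0, -1, True, True, reported_impairment=-1.2),
    _v("vfv_recovery_far", "Distance vertical FV recovery", "pd", "visual", "nonneg",
       0.9, 0.5, 0.1, 0.3, -1, False, True, reported_impairment=-0.8),
    _v("vfv_break_near", "Near vertical FV break", "pd", "visual", "nonneg",
       3.6, 1.3, 2.3, 1.0, -1, True, True, reported_impairment=-1.3),
    _v("vfv_recovery_near", "Near vertical FV recovery", "pd", "visual", "nonneg",
       2.0, 1.0, 0.4, 0.5, -1, False, True, reported_impairment=-1.6),
    _v("vergence_facility", "Near vergence facility", "cpm", "visual", "nonneg",
       14.1, 2.8, 8.6, 3.4, -1, True, True, reported_impairment=-5.5),
    # Comfort criteria and AC/A ratios (derived clinically; carried through
    # the battery but not components of OVDS).
    _v("percival_far", "Percival's criterion (far)", "pd", "visual", "signed",
       -1.4, 2.3, -0.1, 1.4, +1, False, True, reported_impairment=1.3),
    _v("sheard_far", "Sheard's criterion (far)", "pd", "visual", "signed",
       -2.4, 2.3, 1.3, 2.5, +1, False, True, reported_impairment=3.7),
    _v("percival_near", "Percival's criterion (near)", "pd", "visual", "signed",
       -3.8, 2.6, -3.6, 2.9, +1, False, True, reported_impairment=0.2),
    _v("sheard_near", "Sheard's criterion (near)", "pd", "visual", "signed",
       -6.2, 3.5, -4.7, 2.9, +1, False, True, reported_impairment=1.5),
    _v("acac_calculated", "Calculated AC/A ratio", "pd_per_d", "visual", "signed",
       5.3, 1.4, 3.6, 1.5, -1, False, True, reported_impairment=-1.7),
    _v("acac_gradient", "Gradient AC/A ratio", "pd_per_d", "visual", "nonneg",
       4.1, 1.9, 2.3, 1.0, -1, False, True, reported_impairment=-1.8),
    # --- driving battery ----------------------------------------------------
    _v("dc_mean_speed", "Mean speed (dual carriageway)", "km/h", "driving", "nonneg",
       116.9, 4.9, 129.4, 13.9, +1, True, True, reported_impairment=12.5),
    _v("dc_speed_sd", "Speed SD (dual carriageway)", "km/h", "driving", "nonneg",
       8.0, 3.0, 11.5, 4.9, +1, True, True, reported_impairment=3.5),
    _v("dc_sdlp", "SDLP (dual carriageway)", "m", "driving", "nonneg",
       0.54, 0.12, 0.75, 0.22, +1, True, True, reported_impairment=0.21),
    _v("dc_dtis", "DTIS (dual carriageway)", "m", "driving", "nonneg",
       90.0, 119.2, 267.8, 231.3, +1, True, True, reported_impairment=177.8),
    _v("mr_mean_speed", "Mean speed (mountain road)", "km/h", "driving", "nonneg",
       55.5, 1.4, 58.4, 5.4, +1, True, True, reported_impairment=2.8),
    _v("mr_speed_sd", "Speed SD (mountain road)", "km/h", "driving", "nonneg",
       21.4, 2.2, 23.9, 5.0, +1, True, True, reported_impairment=2.5),
    _v("mr_sdlp", "SDLP (mountain road)", "m", "driving", "nonneg",
       0.55, 0.09, 0.76, 0.16, +1, True, True, reported_impairment=0.21),
    _v("mr_dtis", "DTIS (mountain road)", "m", "driving", "nonneg",
       43.0, 58.6, 227.8, 257.3, +1, True, True, reported_impairment=184.8),
    _v("mr_dtiol", "DTIOL (mountain road)", "m", "driving", "nonneg",
       309.4, 241.5, 562.1, 418.2, +1, True, True, reported_impairment=252.7),
    _v("mr_tdtol", "TDTOL (mountain road)", "m", "driving", "sum",
       352.5, 227.9, 789.9, 478.8, +1, True, True, reported_impairment=437.5,
       parents=("mr_dtis", "mr_dtiol")),
    _v("mr_reaction_time", "Brake reaction time (mountain road)", "s", "driving", "nonneg",
       0.82, 0.13, 0.93, 0.14, +1, True, True, reported_impairment=0.11),
    _v("ic_mean_speed", "Mean speed (inner city)", "km/h", "driving", "nonneg",
       30.5, 4.6, 36.1, 6.4, +1, True, True, reported_impairment=5.5),
    _v("ic_speed_sd", "Speed SD (inner city)", "km/h", "driving", "nonneg",
       16.4, 3.4, 21.2, 5.7, +1, True, True, reported_impairment=4.7),
    _v("collisions", "Collisions", "count", "driving", "count",
       0.1, 0.3, 4.3, 3.7, +1, True, True, reported_impairment=4.3),
    _v("signaling_mistakes", "Signaling mistakes", "count", "driving", "count",
       0.0, 0.0, 0.3, 0.8, +1, True, True, reported_impairment=0.3),
    _v("engine_stalls", "Engine stalls", "count", "driving", "count",
       1.3, 1.3, 3.8, 4.4, +1, True, True, reported_impairment=2.5),
)


def variable_map() -> dict[str, VariableDef]:
    return {v.name: v for v in VARIABLES}


def visual_variables() -> tuple[VariableDef, ...]:
    return tuple(v for v in VARIABLES if v.domain == "visual")


def driving_variables() -> tuple[VariableDef, ...]:
    return tuple(v for v in VARIABLES if v.domain == "driving")


def composite_variables(domain: str) -> tuple[VariableDef, ...]:
    """Variables entering the composite score for ``domain`` ('visual'|'driving')."""
    return tuple(v for v in VARIABLES if v.domain == domain and v.in_composite)
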