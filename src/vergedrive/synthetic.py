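"""Seeded synthetic paired cohort, trace generator and alcohol-dose utilities.

The generator emulates a paired two-session design (baseline vs after
alcohol consumption, "aAC") on ``n`` subjects.  For each variable the two
conditions are drawn from a Gaussian copula with within-subject correlation
``r``; the margins reproduce the variable's published group mean and SD.
Non-negative variables use a moment-matched rectified normal (the latent
normal's parameters are solved so that ``max(X, 0)`` has exactly the target
mean and SD) and count variables a moment-matched rounded rectified normal,
so group means — and hence mean impairments — are honored without
truncation bias.

A single pair of latent severity factors, one visual and one driving,
correlated by the coupling parameter ``kappa``, loads every variable's
after-alcohol draw in its worsening direction.  This makes subjects who
deteriorate visually also deteriorate behind the wheel, with a tunable
population association between the two composite scores; ``kappa = 0``
yields independent composites (the null for calibration checks).

The trace generator is the inverse of the metric module: given per-section
targets it builds a trajectory whose computed metrics recover the targets —
lateral offset as a stationary AR(1) process rescaled so the sample SD
equals the target SDLP exactly, excursion episodes injected so the
piecewise-constant accumulation rule returns the requested DTIS/DTIOL
exactly, and brake events placed so the matcher recovers the requested
reaction times.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from . import reference
from .composite import ImpairmentMatrix
from .driving import (DrivingEventLog, DrivingTrace, LaneGeometry,
                      default_geometry)
from .reference import VariableDef

__all__ = [
    "CohortSpec",
    "PairedCohort",
    "generate_cohort",
    "SectionTarget",
    "TraceTargets",
    "generate_trace",
    "brac_to_bac",
    "bac_to_brac",
    "DoseInput",
    "widmark_dose",
    "DEFAULT_COUPLING",
]

#: Default visual–driving coupling.  Calibrated once so that the population
#: Spearman correlation between OVDS and ODPDS under the default variable
#: set is approximately 0.4 (the association strength the analysis pipeline
#: is designed to detect); see docs/methods.md.
DEFAULT_COUPLING = 0.55

#: Default share of the after-alcohol innovation variance carried by the
#: latent severity factor.
DEFAULT_LATENT_WEIGHT = 0.3

SECTION_LENGTHS_M = {
    "dual_carriageway": 4500.0,
    "mountain_road": 6000.0,
    "inner_city": 2000.0,
}


# ---------------------------------------------------------------------------
# moment-matched margins

def _rectified_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Mean and SD of ``max(X, 0)`` for ``X ~ N(mu, sigma)``."""
    a = mu / sigma
    phi, cdf = sps.norm.pdf(a), sps.norm.cdf(a)
    m1 = mu * cdf + sigma * phi
    m2 = (mu * mu + sigma * sigma) * cdf + mu * sigma * phi
    var = max(m2 - m1 * m1, 0.0)
    return m1, math.sqrt(var)


def _rounded_rectified_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Mean and SD of ``round(max(X, 0))`` for ``X ~ N(mu, sigma)``."""
    kmax = max(int(math.ceil(mu + 10 * sigma)), 2)
    k = np.arange(1, kmax + 1)
    sf = sps.norm.sf((k - 0.5 - mu) / sigma)
    m1 = float(sf.sum())
    m2 = float(((2 * k - 1) * sf).sum())
    var = max(m2 - m1 * m1, 0.0)
    return m1, math.sqrt(var)


@lru_cache(maxsize=512)
def _latent_params(mean: float, sd: float, kind: str) -> tuple[float, float]:
    """Latent normal ``(mu, sigma)`` whose rectified (and, for counts,
    rounded) transform has the requested mean and SD."""
    moments = _rectified_moments if kind == "nonneg" else _rounded_rectified_moments
    # If rectification is negligible the identity solution is exact.
    if kind == "nonneg" and mean - 8 * sd > 0:
        return mean, sd

    def resid(x):
        mu, log_sigma = x
        m, s = moments(mu, math.exp(log_sigma))
        return [m - mean, s - sd]

    sol = optimize.least_squares(resid, x0=[mean, math.log(sd)],
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)
    mu, sigma = sol.x[0], math.exp(sol.x[1])
    m, s = moments(mu, sigma)
    if abs(m - mean) > 1e-6 * max(1.0, abs(mean)) or \
       abs(s - sd) > 1e-6 * max(1.0, sd):
        raise ValueError(
            f"no rectified-normal margin matches mean={mean}, sd={sd} ({kind})")
    return float(mu), float(sigma)


def _margin(mean: float, sd: float, kind: str, z: np.ndarray) -> np.ndarray:
    """Transform standard-normal draws into the variable's margin."""
    if sd == 0:
        v = round(mean) if kind == "count" else mean
        return np.full(z.shape, float(v))
    if kind == "signed":
        return mean + sd * z
    mu, sigma = _latent_params(mean, sd, kind)
    x = np.maximum(mu + sigma * z, 0.0)
    return np.round(x) if kind == "count" else x


# ---------------------------------------------------------------------------
# cohort generation

@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of the synthetic paired cohort.

    Defaults reproduce the reference cohort: 30 subjects, the published
    group means/SDs, within-subject correlation 0.6 between the two
    sessions, and a visual–driving coupling calibrated so the population
    OVDS–ODPDS Spearman correlation is about 0.4.
    """

    n_subjects: int = 30
    variables: tuple[VariableDef, ...] = reference.VARIABLES
    within_subject_correlation: float = 0.6
    visual_driving_coupling: float = DEFAULT_COUPLING
    latent_weight: float = DEFAULT_LATENT_WEIGHT

    def __post_init__(self):
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        r = self.within_subject_correlation
        if not 0 <= r < 1:
            raise ValueError("within_subject_correlation must be in [0, 1)")
        if not abs(self.visual_driving_coupling) < 1:
            raise ValueError("|visual_driving_coupling| must be < 1")
        if not 0 <= self.latent_weight <= 1:
            raise ValueError("latent_weight must be in [0, 1]")
        for v in self.variables:
            if v.sd_baseline < 0 or v.sd_aac < 0:
                raise ValueError(f"{v.name}: SDs must be >= 0")
            if v.sd_baseline == 0 and v.kind not in ("count", "sum"):
                raise ValueError(f"{v.name}: zero SD only allowed for counts")

    def null(self) -> "CohortSpec":
        """Null-hypothesis version: aAC margins equal baseline margins and
        the visual–driving coupling is switched off."""
        vars_null = tuple(
            dataclasses.replace(v, mean_aac=v.mean_baseline, sd_aac=v.sd_baseline)
            for v in self.variables)
        return dataclasses.replace(self, variables=vars_null,
                                   visual_driving_coupling=0.0)


@dataclass
class PairedCohort:
    """Paired per-subject measurements under the two conditions."""

    baseline: pd.DataFrame      # subjects × variables
    aac: pd.DataFrame
    spec: CohortSpec

    @property
    def subjects(self) -> pd.Index:
        return self.baseline.index

    def impairments(self) -> pd.DataFrame:
        """Signed per-subject impairment (aAC − baseline) for every variable."""
        return self.aac - self.baseline

    def impairment_matrix(self, domain: str, composite_only: bool = True
                          ) -> ImpairmentMatrix:
        """Impairment matrix for composite scoring.

        Applies each variable's transform: ``abs`` variables (phorias)
        contribute ``|aAC| − |baseline|`` so that movement away from
        orthophoria counts as deterioration regardless of its direction.
        """
        cols: dict[str, pd.Series] = {}
        directions: dict[str, int] = {}
        for v in self.spec.variables:
            if v.domain != domain:
                continue
            if composite_only and not v.in_composite:
                continue
            if v.transform == "abs":
                cols[v.name] = self.aac[v.name].abs() - self.baseline[v.name].abs()
            else:
                cols[v.name] = self.aac[v.name] - self.baseline[v.name]
            directions[v.name] = v.direction
        return ImpairmentMatrix(pd.DataFrame(cols), directions)

    def tidy(self) -> pd.DataFrame:
        """Long format: (subject, condition, variable, value)."""
        frames = []
        for cond, df in (("baseline", self.baseline), ("aac", self.aac)):
            long = df.reset_index(names="subject").melt(
                id_vars="subject", var_name="variable", value_name="value")
            long.insert(1, "condition", cond)
            frames.append(long)
        return pd.concat(frames, ignore_index=True)


def generate_cohort(spec: CohortSpec = CohortSpec(),
                    seed: int | np.random.Generator | None = None
                    ) -> PairedCohort:
    """Draw one paired cohort.  Deterministic for a fixed seed.

    Per variable and subject, the baseline draw is ``T_b(Z_b)`` and the
    after-alcohol draw ``T_a(Z_a)`` with moment-matched margins ``T`` and

    ``Z_a = r·Z_b + sqrt(1−r²)·(sqrt(w)·s·F + sqrt(1−w)·ε)``,

    where ``F`` is the subject's latent severity factor for the variable's
    domain (visual or driving; the two factors have correlation ``kappa``),
    ``w`` the latent weight and ``s`` the loading sign that pushes the
    variable toward deterioration.  ``Z_a`` is marginally standard normal,
    so the aAC margins are honored for any ``r``, ``w``, ``kappa``.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = spec.n_subjects
    r = spec.within_subject_correlation
    w = spec.latent_weight
    kappa = spec.visual_driving_coupling

    f_visual = rng.standard_normal(n)
    f_driving = kappa * f_visual + math.sqrt(1 - kappa ** 2) * rng.standard_normal(n)
    factors = {"visual": f_visual, "driving": f_driving}

    subjects = pd.Index([f"S{i + 1:02d}" for i in range(n)], name="subject")
    base_cols: dict[str, np.ndarray] = {}
    aac_cols: dict[str, np.ndarray] = {}
    for v in spec.variables:
        if v.kind == "sum":
            continue
        zb = rng.standard_normal(n)
        eps = rng.standard_normal(n)
        if v.transform == "abs":
            # push the phoria away from zero toward the side of its aAC mean
            lsign = 1.0 if v.mean_aac >= 0 else -1.0
        else:
            lsign = float(v.direction)
        za = (r * zb + math.sqrt(1 - r * r)
              * (math.sqrt(w) * lsign * factors[v.domain]
                 + math.sqrt(1 - w) * eps))
        base_cols[v.name] = _margin(v.mean_baseline, v.sd_baseline, v.kind, zb)
        aac_cols[v.name] = _margin(v.mean_aac, v.sd_aac, v.kind, za)
    for v in spec.variables:
        if v.kind == "sum":
            base_cols[v.name] = sum(base_cols[p] for p in v.parents)
            aac_cols[v.name] = sum(aac_cols[p] for p in v.parents)
    order = [v.name for v in spec.variables]
    baseline = pd.DataFrame(base_cols, index=subjects)[order]
    aac = pd.DataFrame(aac_cols, index=subjects)[order]
    return PairedCohort(baseline, aac, spec)


# ---------------------------------------------------------------------------
# trace generation

@dataclass(frozen=True)
class SectionTarget:
    """Per-section driving metric targets for trace construction."""

    mean_speed: float            # km/h
    speed_sd: float              # km/h
    sdlp: float                  # m
    dtis: float = 0.0            # m
    dtiol: float = 0.0           # m


@dataclass(frozen=True)
class TraceTargets:
    """Whole-drive targets: per-section metrics, reaction times, counts."""

    sections: dict[str, SectionTarget]
    reaction_times: tuple[float, ...] = ()
    collisions: int = 0
    signaling_mistakes: int = 0
    engine_stalls: int = 0


def default_trace_targets() -> TraceTargets:
    """Targets at the reference cohort's baseline group means."""
    return TraceTargets(
        sections={
            "dual_carriageway": SectionTarget(116.9, 8.0, 0.54, dtis=90.0),
            "mountain_road": SectionTarget(55.5, 21.4, 0.55, dtis=43.0,
                                           dtiol=309.4),
            "inner_city": SectionTarget(30.5, 16.4, 0.30),
        },
        reaction_times=(0.82,) * 5,
        engine_stalls=1,
    )


def _ar1(rng: np.random.Generator, n: int, coef: float) -> np.ndarray:
    e = np.empty(n)
    e[0] = rng.standard_normal() / math.sqrt(1 - coef ** 2)
    innov = rng.standard_normal(n - 1)
    for i in range(1, n):
        e[i] = coef * e[i - 1] + innov[i - 1]
    return e


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def _excursion_window(ds: np.ndarray, start: int, distance: float
                      ) -> tuple[int, int]:
    """Choose interval starts ``start..j`` whose increments cover ``distance``
    and shrink the last increment in place so the sum is exact."""
    acc = 0.0
    j = start
    while acc < distance:
        if j >= ds.size:
            raise ValueError("excursion target exceeds available section length")
        acc += ds[j]
        j += 1
    j -= 1
    ds[j] -= acc - distance            # overshoot < ds[j], stays >= 0
    return start, j


def _solve_lat_scale(e: np.ndarray, free: np.ndarray, fixed: np.ndarray,
                     clip: float, target_sd: float) -> np.ndarray:
    """Scale the AR noise so the section's lateral sample SD is exact."""
    def sd(scale: float) -> float:
        lat = np.empty(free.size + fixed.size)
        lat[:free.size] = np.clip(scale * e, -clip, clip)
        lat[free.size:] = fixed
        return float(np.std(lat, ddof=1))

    lo, hi = 1e-9, 1.0
    while sd(hi) < target_sd and hi < 1e4:
        hi *= 2
    if sd(hi) < target_sd or sd(lo) > target_sd:
        raise ValueError(
            f"target SDLP {target_sd} not attainable with lane clip {clip} "
            "and the requested excursions")
    scale = optimize.brentq(lambda s: sd(s) - target_sd, lo, hi, xtol=1e-12)
    return np.clip(scale * e, -clip, clip)


def generate_trace(targets: TraceTargets,
                   geometry: dict[str, LaneGeometry] | None = None,
                   seed: int | np.random.Generator | None = None,
                   dt: float = 0.1,
                   ar_coef: float = 0.95,
                   section_lengths: dict[str, float] | None = None
                   ) -> tuple[DrivingTrace, DrivingEventLog]:
    """Construct a trajectory and event log that realize the given targets.

    Sampling at ``dt`` seconds (default 10 Hz); lateral offset is a
    stationary AR(1) (autocorrelation ``ar_coef``) clipped inside the lane
    and rescaled so each section's sample SD equals the target SDLP exactly;
    one shoulder and (mountain road) one opposite-lane excursion episode are
    injected and trimmed so the piecewise-constant rule recovers DTIS/DTIOL
    exactly; brake-light onsets are spaced through the mountain section with
    presses at onset + requested reaction time.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    geometry = geometry if geometry is not None else default_geometry()
    lengths = dict(SECTION_LENGTHS_M if section_lengths is None
                   else section_lengths)

    frames = []
    t0 = 0.0
    s0 = 0.0
    section_spans: dict[str, tuple[float, float]] = {}
    for section in ("dual_carriageway", "mountain_road", "inner_city"):
        if section not in targets.sections:
            continue
        tgt = targets.sections[section]
        geom = geometry[section]
        length = lengths[section]
        if tgt.dtis < 0 or tgt.dtiol < 0:
            raise ValueError("excursion distances must be >= 0")
        if tgt.dtis + tgt.dtiol > 0.6 * length:
            raise ValueError(
                f"{section}: excursions {tgt.dtis + tgt.dtiol:.0f} m infeasible "
                f"for a {length:.0f} m section")
        if tgt.dtiol > 0 and geom.opposite_lane_side is None:
            raise ValueError(f"{section}: DTIOL requested but the section has "
                             "no opposite lane")

        n = max(int(round(length / (tgt.mean_speed / 3.6) / dt)) + 1, 64)
        speed = tgt.mean_speed + (
            _standardize(_ar1(rng, n, ar_coef)) * tgt.speed_sd
            if tgt.speed_sd > 0 else np.zeros(n))
        if (speed < 0).any():
            warnings.warn(f"{section}: speed noise clipped at 0; sample SD "
                          "will fall slightly below target", stacklevel=2)
            speed = np.maximum(speed, 0.0)
        ds = speed[:-1] / 3.6 * dt

        windows = []
        if tgt.dtis > 0:
            i0, j0 = _excursion_window(ds, int(0.15 * n), tgt.dtis)
            windows.append((i0, j0, geom.shoulder_side))
        if tgt.dtiol > 0:
            i1, j1 = _excursion_window(ds, int(0.60 * n), tgt.dtiol)
            if windows and i1 <= windows[0][1] + 1:
                raise ValueError(f"{section}: excursion episodes overlap; "
                                 "targets infeasible at this section length")
            windows.append((i1, j1, geom.opposite_lane_side))

        thr = geom.invasion_threshold
        exc_mag = thr + 0.3
        inside = thr - 0.02
        window_mask = np.zeros(n, bool)
        fixed_vals = []
        for i, j, side in windows:
            window_mask[i:j + 1] = True
            fixed_vals.append(np.full(j + 1 - i, side * exc_mag))
        fixed = np.concatenate(fixed_vals) if fixed_vals else np.empty(0)
        e = _standardize(_ar1(rng, n, ar_coef))[~window_mask]
        lat = np.empty(n)
        lat[~window_mask] = _solve_lat_scale(e, e, fixed, inside, tgt.sdlp)
        for i, j, side in windows:
            lat[i:j + 1] = side * exc_mag

        t = t0 + dt * np.arange(n)
        s_path = s0 + np.concatenate([[0.0], np.cumsum(ds)])
        frames.append(pd.DataFrame({
            "t": t, "s_path": s_path, "speed": speed, "lat_offset": lat,
            "section": section}))
        section_spans[section] = (t[0], t[-1])
        t0 = t[-1] + dt
        s0 = s_path[-1] + ds[-1] if ds.size else s_path[-1]

    trace = DrivingTrace(pd.concat(frames, ignore_index=True), geometry)

    events = DrivingEventLog()
    rts = tuple(targets.reaction_times)
    if rts:
        if min(rts) <= 0:
            raise ValueError("reaction times must be positive")
        lo, hi = section_spans.get("mountain_road", trace.time_span)
        gap = (hi - lo) / (len(rts) + 1)
        if gap <= max(rts) + dt:
            raise ValueError("too many brake events for the section duration")
        for k, rt in enumerate(rts):
            onset = lo + (k + 1) * gap
            events.brake_light_onsets.append(onset)
            events.brake_presses.append(onset + rt)
    lo, hi = trace.time_span
    for attr, count in (("collisions", targets.collisions),
                        ("signaling_mistakes", targets.signaling_mistakes),
                        ("engine_stalls", targets.engine_stalls)):
        getattr(events, attr).extend(np.sort(rng.uniform(lo, hi, count)))
    events.__post_init__()
    return trace, events


# ---------------------------------------------------------------------------
# alcohol dosing

#: Widmark distribution factor (l/kg) by sex.
WIDMARK_R = {"M": 0.68, "F": 0.55}


def brac_to_bac(brac_mg_per_l: float) -> float:
    """Breath alcohol (mg/l exhaled air) to blood alcohol (g/l): BAC = 2·BrAC."""
    if brac_mg_per_l < 0:
        raise ValueError("BrAC must be >= 0")
    return 2.0 * brac_mg_per_l


def bac_to_brac(bac_g_per_l: float) -> float:
    """Blood alcohol (g/l) to breath alcohol (mg/l): BrAC = BAC / 2."""
    if bac_g_per_l < 0:
        raise ValueError("BAC must be >= 0")
    return bac_g_per_l / 2.0


@dataclass(frozen=True)
class DoseInput:
    """Inputs for the Widmark dose estimate."""

    weight_kg: float
    sex: str = "M"
    target_brac_mg_per_l: float = 0.40
    widmark_r: float | None = None   # l/kg; default 0.68 (M) / 0.55 (F)


def widmark_dose(inp: DoseInput | float, sex: str = "M",
                 target_brac_mg_per_l: float = 0.40,
                 widmark_r: float | None = None) -> float:
    """Grams of ethanol needed to reach a target BrAC (classic Widmark).

    ``grams = BAC(g/l) · r(l/kg) · weight(kg)`` with the target BAC obtained
    from the 2:1 BAC/BrAC ratio.  No elimination term: the estimate is the
    instantaneous distribution dose.  Accepts a :class:`DoseInput` or a
    weight in kg plus keywords.
    """
    if isinstance(inp, DoseInput):
        weight, sex = inp.weight_kg, inp.sex
        target_brac_mg_per_l = inp.target_brac_mg_per_l
        widmark_r = inp.widmark_r
    else:
        weight = float(inp)
    if weight <= 0:
        raise ValueError("weight must be positive")
    if target_brac_mg_per_l < 0:
        raise ValueError("target BrAC must be >= 0")
    if widmark_r is None:
        try:
            widmark_r = WIDMARK_R[sex.upper()]
        except KeyError:
            raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    return brac_to_bac(target_brac_mg_per_l) * widmark_r * weight
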