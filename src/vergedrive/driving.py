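"""Driving-performance metrics from simulator trajectory and event logs.

A trajectory ("trace") is a time series of samples ``(t, s_path, speed,
lat_offset, section)``: time in seconds, cumulative path distance in meters,
speed in km/h, and the signed lateral offset of the vehicle center from the
lane center in meters.  Sections label the three road environments of the
itinerary (dual carriageway, two-lane mountain road, inner city).

Lane-excursion geometry: the vehicle is modeled as a width interval around
``lat_offset``; a sample *invades* a side when the vehicle edge crosses the
lane boundary on that side, i.e. ``|lat_offset| + vehicle_half_width >
lane_half_width`` with ``sign(lat_offset)`` matching the side.  Distance is
accumulated with a piecewise-constant rule: each inter-sample interval
contributes its path increment iff its *starting* sample is in the invasion
state (no sub-sample interpolation).  This rule makes excursion distances
exactly constructible, which the synthetic trace generator exploits.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SECTIONS",
    "LaneGeometry",
    "DrivingTrace",
    "DrivingEventLog",
    "ReactionTimeResult",
    "mean_speed",
    "speed_sd",
    "sdlp",
    "lane_excursion_distances",
    "reaction_times",
    "count_events",
    "compute_driving_metrics",
    "read_trace_csv",
    "write_trace_csv",
    "read_event_log",
    "write_event_log",
]

SECTIONS = ("dual_carriageway", "mountain_road", "inner_city")

TRACE_COLUMNS = ["t", "s_path", "speed", "lat_offset", "section"]


@dataclass(frozen=True)
class LaneGeometry:
    """Lane geometry for one road section.

    ``shoulder_side`` is the sign of ``lat_offset`` toward the shoulder;
    ``opposite_lane_side`` the sign toward the opposite lane, or ``None`` on
    sections without an adjacent opposite lane (dual carriageway, inner
    city).  Defaults: 3.5 m lane, 1.8 m vehicle.
    """

    lane_half_width: float = 1.75
    vehicle_half_width: float = 0.9
    shoulder_side: int = +1
    opposite_lane_side: int | None = None

    def __post_init__(self):
        if self.lane_half_width <= 0 or self.vehicle_half_width <= 0:
            raise ValueError("lane/vehicle half widths must be positive")
        if self.shoulder_side not in (-1, 1):
            raise ValueError("shoulder_side must be +1 or -1")
        if self.opposite_lane_side not in (None, -1, 1):
            raise ValueError("opposite_lane_side must be None, +1 or -1")

    @property
    def invasion_threshold(self) -> float:
        """|lat_offset| beyond which the vehicle edge is outside the lane."""
        return self.lane_half_width - self.vehicle_half_width


def default_geometry() -> dict[str, LaneGeometry]:
    """Default per-section geometry: opposite lane only on the mountain road."""
    return {
        "dual_carriageway": LaneGeometry(shoulder_side=+1, opposite_lane_side=None),
        "mountain_road": LaneGeometry(shoulder_side=+1, opposite_lane_side=-1),
        "inner_city": LaneGeometry(shoulder_side=+1, opposite_lane_side=None),
    }


@dataclass
class DrivingTrace:
    """Sampled vehicle trajectory plus per-section lane geometry."""

    samples: pd.DataFrame
    geometry: dict[str, LaneGeometry] = field(default_factory=default_geometry)

    def __post_init__(self):
        df = self.samples
        missing = set(TRACE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"trace missing columns: {sorted(missing)}")
        t = df["t"].to_numpy(float)
        s = df["s_path"].to_numpy(float)
        if len(df) and not np.all(np.diff(t) > 0):
            raise ValueError("trace times must be strictly increasing")
        if len(df) and not np.all(np.diff(s) >= 0):
            raise ValueError("s_path must be non-decreasing")
        if len(df) and (df["speed"].to_numpy(float) < 0).any():
            raise ValueError("speeds must be >= 0")
        # sections must be contiguous blocks
        sec = df["section"].to_numpy()
        if len(sec):
            change = np.nonzero(sec[1:] != sec[:-1])[0]
            blocks = [sec[0], *sec[change + 1]]
            if len(blocks) != len(set(blocks)):
                raise ValueError("section labels must form contiguous blocks")

    def section_frame(self, section: str) -> pd.DataFrame:
        sub = self.samples[self.samples["section"] == section]
        if sub.empty:
            raise ValueError(f"trace has no samples in section {section!r}")
        return sub

    def section_geometry(self, section: str) -> LaneGeometry:
        try:
            return self.geometry[section]
        except KeyError:
            raise ValueError(f"no lane geometry configured for section {section!r}")

    @property
    def time_span(self) -> tuple[float, float]:
        t = self.samples["t"]
        return float(t.iloc[0]), float(t.iloc[-1])


@dataclass
class DrivingEventLog:
    """Discrete events recorded during one simulated drive (times in s)."""

    brake_light_onsets: list[float] = field(default_factory=list)
    brake_presses: list[float] = field(default_factory=list)
    collisions: list[float] = field(default_factory=list)
    signaling_mistakes: list[float] = field(default_factory=list)
    engine_stalls: list[float] = field(default_factory=list)

    def __post_init__(self):
        for name in ("brake_light_onsets", "brake_presses", "collisions",
                     "signaling_mistakes", "engine_stalls"):
            setattr(self, name, sorted(float(t) for t in getattr(self, name)))


def _section_speeds(trace: DrivingTrace, section: str) -> np.ndarray:
    sub = trace.section_frame(section)
    if len(sub) < 2:
        raise ValueError(f"section {section!r} needs >= 2 samples")
    return sub["speed"].to_numpy(float)


def mean_speed(trace: DrivingTrace, section: str) -> float:
    """Arithmetic mean of the sampled speeds in a section (km/h)."""
    return float(np.mean(_section_speeds(trace, section)))


def speed_sd(trace: DrivingTrace, section: str) -> float:
    """Sample standard deviation (n−1) of the sampled speeds (km/h)."""
    return float(np.std(_section_speeds(trace, section), ddof=1))


def sdlp(trace: DrivingTrace, section: str) -> float:
    """Standard deviation of lateral position (m), sample SD over the section."""
    sub = trace.section_frame(section)
    if len(sub) < 2:
        raise ValueError(f"section {section!r} needs >= 2 samples for SDLP")
    return float(np.std(sub["lat_offset"].to_numpy(float), ddof=1))


def lane_excursion_distances(trace: DrivingTrace, section: str
                             ) -> tuple[float, float, float]:
    """Distances driven outside the lane in a section: ``(dtis, dtiol, tdtol)``.

    DTIS — distance traveled invading the shoulder; DTIOL — invading the
    opposite lane (0 on sections without one); TDTOL — total outside the
    lane, ``dtis + dtiol`` by construction.
    """
    sub = trace.section_frame(section)
    geom = trace.section_geometry(section)
    lat = sub["lat_offset"].to_numpy(float)
    s = sub["s_path"].to_numpy(float)
    if len(sub) < 2:
        return (0.0, 0.0, 0.0)
    ds = np.diff(s)                    # increment of interval starting at i
    start = lat[:-1]
    thr = geom.invasion_threshold
    outside = np.abs(start) > thr

    def side_distance(side: int) -> float:
        mask = outside & (np.sign(start) == side)
        return float(ds[mask].sum())

    dtis = side_distance(geom.shoulder_side)
    if geom.opposite_lane_side is None:
        opp = outside & (np.sign(start) == -geom.shoulder_side)
        if opp.any():
            warnings.warn(
                f"section {section!r} has no opposite lane; excursions on the "
                "non-shoulder side are not counted in DTIOL", stacklevel=2)
        dtiol = 0.0
    else:
        dtiol = side_distance(geom.opposite_lane_side)
    return dtis, dtiol, dtis + dtiol


@dataclass
class ReactionTimeResult:
    """Brake reaction times: lead-car brake-light onset to brake-pedal press."""

    times: list[float]
    missed_onsets: list[float]
    ignored_presses: list[float]

    @property
    def mean(self) -> float:
        """Mean reaction time over matched events; NaN when none matched."""
        return float(np.mean(self.times)) if self.times else math.nan


def reaction_times(events: DrivingEventLog) -> ReactionTimeResult:
    """Match each brake-light onset to the driver's first subsequent press.

    Each onset is matched to the first unconsumed brake press that falls
    after it and before the next onset; presses are consumed so no press
    answers two onsets.  Onsets with no press in their window are recorded as
    missed and excluded from the mean; presses before the first onset are
    ignored with a warning.
    """
    onsets = events.brake_light_onsets
    presses = list(events.brake_presses)
    times: list[float] = []
    missed: list[float] = []
    ignored = [p for p in presses if onsets and p <= onsets[0]]
    if ignored:
        warnings.warn(f"{len(ignored)} brake press(es) before the first "
                      "brake-light onset were ignored", stacklevel=2)
    j = 0
    for i, onset in enumerate(onsets):
        window_end = onsets[i + 1] if i + 1 < len(onsets) else math.inf
        while j < len(presses) and presses[j] <= onset:
            j += 1
        if j < len(presses) and presses[j] < window_end:
            times.append(presses[j] - onset)
            j += 1
        else:
            missed.append(onset)
    return ReactionTimeResult(times, missed, ignored)


def count_events(events: DrivingEventLog) -> tuple[int, int, int]:
    """Counts of (collisions, signaling mistakes, engine stalls)."""
    return (len(events.collisions), len(events.signaling_mistakes),
            len(events.engine_stalls))


#: map (section, metric) -> canonical variable name in the reference battery
_SECTION_PREFIX = {"dual_carriageway": "dc", "mountain_road": "mr", "inner_city": "ic"}


def compute_driving_metrics(trace: DrivingTrace, events: DrivingEventLog
                            ) -> dict[str, float]:
    """Full per-drive metric set, keyed by the reference variable names.

    Mean speed and speed SD in all three sections; SDLP and DTIS on the dual
    carriageway and mountain road; DTIOL/TDTOL, and brake reaction time on
    the mountain road; event counts for the whole drive.
    """
    out: dict[str, float] = {}
    present = set(trace.samples["section"])
    for section in SECTIONS:
        if section not in present:
            continue
        p = _SECTION_PREFIX[section]
        out[f"{p}_mean_speed"] = mean_speed(trace, section)
        out[f"{p}_speed_sd"] = speed_sd(trace, section)
        if section in ("dual_carriageway", "mountain_road"):
            out[f"{p}_sdlp"] = sdlp(trace, section)
            dtis, dtiol, tdtol = lane_excursion_distances(trace, section)
            out[f"{p}_dtis"] = dtis
            if section == "mountain_road":
                out[f"{p}_dtiol"] = dtiol
                out[f"{p}_tdtol"] = tdtol
    out["mr_reaction_time"] = reaction_times(events).mean
    col, sm, es = count_events(events)
    out["collisions"] = float(col)
    out["signaling_mistakes"] = float(sm)
    out["engine_stalls"] = float(es)
    return out


# ---------------------------------------------------------------------------
# I/O

def read_trace_csv(path, geometry: dict[str, LaneGeometry] | None = None
                   ) -> DrivingTrace:
    df = pd.read_csv(path)
    return DrivingTrace(df[TRACE_COLUMNS],
                        geometry if geometry is not None else default_geometry())


def write_trace_csv(trace: DrivingTrace, path) -> None:
    trace.samples.to_csv(path, columns=TRACE_COLUMNS, index=False)


_EVENT_FIELDS = {
    "brake_light_onset": "brake_light_onsets",
    "brake_press": "brake_presses",
    "collision": "collisions",
    "signaling_mistake": "signaling_mistakes",
    "engine_stall": "engine_stalls",
}


def read_event_log(path) -> DrivingEventLog:
    """Read a line-delimited JSON event log (records ``{"type":..., "t":...}``)."""
    log = DrivingEventLog()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            try:
                attr = _EVENT_FIELDS[rec["type"]]
            except KeyError:
                raise ValueError(f"unknown event type {rec.get('type')!r}")
            getattr(log, attr).append(float(rec["t"]))
    log.__post_init__()
    return log


def write_event_log(events: DrivingEventLog, path) -> None:
    records = []
    for etype, attr in _EVENT_FIELDS.items():
        records.extend({"type": etype, "t": t} for t in getattr(events, attr))
    records.sort(key=lambda r: (r["t"], r["type"]))
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def geometry_from_json(path) -> dict[str, LaneGeometry]:
    """Read per-section lane geometry from a JSON config file."""
    with open(path) as fh:
        raw = json.load(fh)
    return {section: LaneGeometry(**params) for section, params in raw.items()}
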