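"""Camera-trap survey data model, I/O, independence filtering and summaries.

A camera-trap survey produces a stream of triggered detections (photos or
videos) at fixed stations. Because one passing animal can trigger a burst of
records, abundance work counts *independent events* ("Ips" — independent
photographs): detections of the same species at the same station are merged
unless separated by at least a configurable time window. The event counts,
together with camera effort (camera-days), feed the random encounter model in
:mod:`camtrap_rem.rem`.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CameraDeployment",
    "DetectionRecord",
    "IndependentEvent",
    "FilterResult",
    "ReadResult",
    "SurveySummary",
    "GroupComposition",
    "read_deployments",
    "read_detections",
    "filter_independent",
    "classify_daytime",
    "summarize_survey",
    "proportion_report",
    "round_half_up",
    "station_pair_qc",
]

DETECTION_COLUMNS = ["station_id", "timestamp", "species", "group_count", "media_type"]
DEPLOYMENT_COLUMNS = [
    "station_id",
    "survey_area",
    "lon",
    "lat",
    "elevation_m",
    "start_date",
    "end_date",
    "sector_radius_km",
    "sector_angle_rad",
]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero, the convention of printed report tables.

    Python's built-in ``round`` uses banker's rounding (2993.5 -> 2994 but
    0.125 -> 0.12); survey reports round half up.
    """
    factor = 10.0**decimals
    rounded = np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x)
    return float(rounded) if decimals > 0 else float(int(rounded))


@dataclass(frozen=True)
class CameraDeployment:
    """One camera station: location, elevation, active interval, detector geometry."""

    station_id: str
    survey_area: str
    longitude: float
    latitude: float
    elevation: float  # m above sea level
    start_date: dt.date
    end_date: dt.date
    sector_radius: float = 0.01  # km
    sector_angle: float = 0.872  # rad

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError(f"{self.station_id}: end_date before start_date")
        if not 0.0 <= self.elevation <= 9000.0:
            raise ValueError(f"{self.station_id}: elevation {self.elevation} outside [0, 9000] m")
        if self.sector_radius <= 0:
            raise ValueError(f"{self.station_id}: sector_radius must be > 0")
        if not 0.0 < self.sector_angle <= 2.0 * np.pi:
            raise ValueError(f"{self.station_id}: sector_angle outside (0, 2*pi]")

    @property
    def camera_days(self) -> int:
        """Operating days, both endpoints inclusive."""
        return (self.end_date - self.start_date).days + 1

    def contains(self, timestamp: dt.datetime) -> bool:
        return self.start_date <= timestamp.date() <= self.end_date


@dataclass(frozen=True)
class DetectionRecord:
    """One triggered record (photo or video) of one species group."""

    station_id: str
    timestamp: dt.datetime
    species: str
    group_count: int = 1
    media_type: str = "photo"

    def __post_init__(self) -> None:
        if self.group_count < 1:
            raise ValueError("group_count must be >= 1")
        if self.media_type not in ("photo", "video"):
            raise ValueError(f"media_type must be photo|video, got {self.media_type!r}")


@dataclass(frozen=True)
class IndependentEvent:
    """A deduplicated detection event (one 'Ip')."""

    station_id: str
    species: str
    event_start: dt.datetime
    n_records: int = 1
    is_daytime: bool | None = None
    elevation: float | None = None
    group_count: int = 1  # largest simultaneous group seen within the event


@dataclass
class ReadResult:
    """Parsed records plus row-level diagnostics (1-based data line numbers)."""

    records: list[DetectionRecord]
    diagnostics: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator[DetectionRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class FilterResult:
    """Independence-filter output: events plus excluded-record accounting."""

    events: list[IndependentEvent]
    n_input: int
    n_excluded: int = 0
    excluded: list[DetectionRecord] = field(default_factory=list)

    def __iter__(self) -> Iterator[IndependentEvent]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def __getitem__(self, i):
        return self.events[i]


def read_deployments(path) -> list[CameraDeployment]:
    """Read a deployment table (CSV with the documented column names)."""
    df = pd.read_csv(path)
    missing = [c for c in DEPLOYMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"deployment file missing required column(s): {', '.join(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            CameraDeployment(
                station_id=str(row.station_id),
                survey_area=str(row.survey_area),
                longitude=float(row.lon),
                latitude=float(row.lat),
                elevation=float(row.elevation_m),
                start_date=pd.Timestamp(row.start_date).date(),
                end_date=pd.Timestamp(row.end_date).date(),
                sector_radius=float(row.sector_radius_km),
                sector_angle=float(row.sector_angle_rad),
            )
        )
    return out


def read_detections(path) -> ReadResult:
    """Read a detection table; malformed rows become diagnostics, not records.

    Raises ``ValueError`` naming the column if a required column is absent.
    Rows whose timestamp does not parse (ISO 8601) or whose group count is not
    a positive integer are reported with their 1-based data line number.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"detection file missing required column(s): {', '.join(missing)}")
    records: list[DetectionRecord] = []
    diagnostics: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        ts = pd.to_datetime(row.timestamp, errors="coerce")
        if pd.isna(ts):
            diagnostics.append(f"line {i}: unparseable timestamp {row.timestamp!r}")
            continue
        try:
            group = int(row.group_count)
            rec = DetectionRecord(
                station_id=str(row.station_id),
                timestamp=ts.to_pydatetime(),
                species=str(row.species),
                group_count=group,
                media_type=str(row.media_type),
            )
        except (TypeError, ValueError) as exc:
            diagnostics.append(f"line {i}: {exc}")
            continue
        records.append(rec)
    return ReadResult(records=records, diagnostics=diagnostics)


def write_detections(records: Iterable[DetectionRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "station_id": r.station_id,
                "timestamp": r.timestamp.isoformat(),
                "species": r.species,
                "group_count": r.group_count,
                "media_type": r.media_type,
            }
            for r in records
        ],
        columns=DETECTION_COLUMNS,
    ).to_csv(path, index=False)


def classify_daytime(
    timestamp: dt.datetime | dt.time,
    day_start: dt.time = dt.time(6, 0),
    day_end: dt.time = dt.time(18, 0),
) -> bool:
    """True iff the clock time falls in the half-open daytime window [start, end)."""
    if day_start >= day_end:
        raise ValueError("day_start must precede day_end")
    t = timestamp.time() if isinstance(timestamp, dt.datetime) else timestamp
    return day_start <= t < day_end


def filter_independent(
    records: Sequence[DetectionRecord],
    window_minutes: float = 30.0,
    rule: str = "start",
    deployments: Sequence[CameraDeployment] | None = None,
    day_start: dt.time = dt.time(6, 0),
    day_end: dt.time = dt.time(18, 0),
) -> FilterResult:
    """Collapse detection bursts into independent events per station x species.

    Records are grouped by (station, species) and scanned in time order. A
    record opens a new event when its timestamp is at least ``window_minutes``
    after the reference time of the current event; otherwise it joins it. The
    reference time is the event's first record (``rule='start'``, default,
    order-stable) or its most recent record (``rule='last'``, the sliding
    variant).

    If ``deployments`` is given, records outside their station's active
    interval are excluded (flagged and counted, never silently dropped) and
    events gain the station elevation; daytime classification always uses the
    half-open clock window ``[day_start, day_end)``.
    """
    if window_minutes <= 0:
        raise ValueError("window_minutes must be > 0")
    if rule not in ("start", "last"):
        raise ValueError("rule must be 'start' or 'last'")

    by_station = {d.station_id: d for d in deployments} if deployments is not None else None
    window = dt.timedelta(minutes=window_minutes)

    kept: list[DetectionRecord] = []
    excluded: list[DetectionRecord] = []
    for r in records:
        if by_station is not None:
            depl = by_station.get(r.station_id)
            if depl is None or not depl.contains(r.timestamp):
                excluded.append(r)
                continue
        kept.append(r)

    events: list[IndependentEvent] = []
    key = lambda r: (r.station_id, r.species, r.timestamp)
    current: list[DetectionRecord] = []

    def flush() -> None:
        if not current:
            return
        first = current[0]
        elev = None
        if by_station is not None and first.station_id in by_station:
            elev = by_station[first.station_id].elevation
        events.append(
            IndependentEvent(
                station_id=first.station_id,
                species=first.species,
                event_start=first.timestamp,
                n_records=len(current),
                is_daytime=classify_daytime(first.timestamp, day_start, day_end),
                elevation=elev,
                group_count=max(r.group_count for r in current),
            )
        )

    for r in sorted(kept, key=key):
        if current and (
            r.station_id == current[0].station_id
            and r.species == current[0].species
            and r.timestamp - (current[0] if rule == "start" else current[-1]).timestamp < window
        ):
            current.append(r)
        else:
            flush()
            current = [r]
    flush()

    return FilterResult(
        events=events, n_input=len(records), n_excluded=len(excluded), excluded=excluded
    )


@dataclass
class SurveySummary:
    """Per-survey-area effort and event accounting with an exact totals row."""

    per_area: pd.DataFrame  # indexed by survey_area
    species: list[str]

    @property
    def totals(self) -> pd.Series:
        numeric = self.per_area.select_dtypes("number")
        return numeric.sum(axis=0)

    def ips_total(self, species: str) -> int:
        return int(self.per_area[f"ips_{species}"].sum())

    def to_frame(self) -> pd.DataFrame:
        """Per-area rows plus a 'Total' row, mirroring a survey-effort table."""
        df = self.per_area.copy()
        tot = self.totals
        tot.name = "Total"
        df = pd.concat([df, tot.to_frame().T])
        return df


def summarize_survey(
    deployments: Sequence[CameraDeployment],
    records: Sequence[DetectionRecord],
    events: Sequence[IndependentEvent] | FilterResult,
) -> SurveySummary:
    """Aggregate effort (stations, camera-days), records and Ips per survey area."""
    ev = list(events)
    species = sorted({e.species for e in ev})
    station_area = {d.station_id: d.survey_area for d in deployments}
    areas = sorted({d.survey_area for d in deployments})

    rows = []
    for area in areas:
        depls = [d for d in deployments if d.survey_area == area]
        stations = {d.station_id for d in depls}
        recs = [r for r in records if station_area.get(r.station_id) == area]
        row = {
            "n_stations": len(stations),
            "elevation_min": min(d.elevation for d in depls),
            "elevation_max": max(d.elevation for d in depls),
            "camera_days": sum(d.camera_days for d in depls),
            "n_photographs": len(recs),
        }
        for sp in species:
            row[f"ips_{sp}"] = sum(
                1 for e in ev if e.species == sp and station_area.get(e.station_id) == area
            )
        rows.append(row)

    per_area = pd.DataFrame(rows, index=pd.Index(areas, name="survey_area"))
    if per_area.empty:
        per_area = pd.DataFrame(
            columns=["n_stations", "elevation_min", "elevation_max", "camera_days", "n_photographs"]
        )
    return SurveySummary(per_area=per_area, species=species)


@dataclass(frozen=True)
class GroupComposition:
    """Age/sex structure of an observed group, with report-style percentages."""

    adult_male: int
    adult_female: int
    juvenile: int
    subadult: int

    @property
    def total(self) -> int:
        return self.adult_male + self.adult_female + self.juvenile + self.subadult

    def percentages(self) -> dict[str, float]:
        counts = {
            "adult_male": self.adult_male,
            "adult_female": self.adult_female,
            "juvenile": self.juvenile,
            "subadult": self.subadult,
        }
        return {k: proportion_report(v, self.total) for k, v in counts.items()}


def proportion_report(numerator: float, denominator: float, decimals: int = 2) -> float:
    """Report-style percentage: ``round(100*num/den, decimals)``, half up."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if numerator > denominator:
        raise ValueError("numerator exceeds denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)


def station_pair_qc(
    deployments: Sequence[CameraDeployment], min_separation_km: float = 0.5
) -> pd.DataFrame:
    """QC flags for paired stations closer than the paired-camera separation rule.

    Same-transect cameras under ~500 m apart can double-count one passing
    animal; merging is a manual judgement, so this only flags candidate pairs
    (equirectangular distance, adequate at survey scales).
    """
    rows = []
    ds = list(deployments)
    for i in range(len(ds)):
        for j in range(i + 1, len(ds)):
            a, b = ds[i], ds[j]
            lat0 = np.radians((a.latitude + b.latitude) / 2)
            dx = np.radians(b.longitude - a.longitude) * np.cos(lat0) * 6371.0
            dy = np.radians(b.latitude - a.latitude) * 6371.0
            dist = float(np.hypot(dx, dy))
            rows.append(
                {
                    "station_a": a.station_id,
                    "station_b": b.station_id,
                    "distance_km": dist,
                    "needs_review": dist < min_separation_km,
                }
            )
    return pd.DataFrame(rows, columns=["station_a", "station_b", "distance_km", "needs_review"])
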