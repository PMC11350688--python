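"""Survey data model: I/O, independence filtering, summaries, percentages."""

import datetime as dt
import io

import numpy as np
import pytest

from camtrap_rem.survey_data import (
    CameraDeployment,
    DetectionRecord,
    GroupComposition,
    classify_daytime,
    filter_independent,
    proportion_report,
    read_deployments,
    read_detections,
    round_half_up,
    station_pair_qc,
    summarize_survey,
    write_detections,
)

D0 = dt.datetime(2021, 6, 1, 8, 0)


def rec(station="S1", minutes=0, species="takin", **kw):
    return DetectionRecord(
        station_id=station,
        timestamp=D0 + dt.timedelta(minutes=minutes),
        species=species,
        **kw,
    )


def deployment(station="S1", area="A", elev=2500.0, **kw):
    defaults = dict(
        station_id=station,
        survey_area=area,
        longitude=95.0,
        latitude=29.5,
        elevation=elev,
        start_date=dt.date(2021, 1, 1),
        end_date=dt.date(2021, 12, 31),
    )
    defaults.update(kw)
    return CameraDeployment(**defaults)


class TestReadDetections:
    CSV = (
        "station_id,timestamp,species,group_count,media_type\n"
        "S1,2021-06-01T08:00:00,takin,2,photo\n"
        "S1,2021-06-01T08:00:20,takin,2,photo\n"
        "S2,2021-06-01T09:30:00,goral,1,video\n"
    )

    def test_well_formed_rows_become_records(self):
        out = read_detections(io.StringIO(self.CSV))
        assert len(out) == 3 and not out.diagnostics
        assert out.records[2].species == "goral"
        assert out.records[0].group_count == 2

    def test_bad_timestamp_is_reported_not_raised(self):
        bad = self.CSV.replace("2021-06-01T09:30:00", "not-a-time")
        out = read_detections(io.StringIO(bad))
        assert len(out) == 2
        assert len(out.diagnostics) == 1 and "line 3" in out.diagnostics[0]

    def test_missing_column_names_the_column(self):
        with pytest.raises(ValueError, match="species"):
            read_detections(io.StringIO("station_id,timestamp,group_count,media_type\n"))

    def test_round_trip_preserves_records(self, small_survey, tmp_path):
        path = tmp_path / "detections.csv"
        src = read_detections(io.StringIO(small_survey.detections.to_csv(index=False)))
        write_detections(src.records, path)
        back = read_detections(path)
        assert not back.diagnostics
        assert back.records == src.records


def brute_force_event_count(records, window_minutes):
    """Independent oracle: repeatedly peel the earliest record and everything
    within the window of it, one event per peel."""
    window = dt.timedelta(minutes=window_minutes)
    n_events = 0
    for key in {(r.station_id, r.species) for r in records}:
        pool = sorted(
            (r.timestamp for r in records if (r.station_id, r.species) == key)
        )
        while pool:
            start = pool[0]
            pool = [t for t in pool if t - start >= window]
            n_events += 1
    return n_events


class TestFilterIndependent:
    def test_burst_collapses_to_one_event(self):
        records = [rec(minutes=m) for m in (0, 0.5, 1)]
        out = filter_independent(records, window_minutes=30)
        assert len(out) == 1 and out[0].n_records == 3

    def test_same_times_at_two_stations_stay_separate(self):
        out = filter_independent([rec(station="S1"), rec(station="S2")], 30)
        assert len(out) == 2

    def test_gap_measured_from_event_start_by_default(self):
        # records at 0, 20, 40 min: 40 is >= 30 from the first event's start
        out = filter_independent([rec(minutes=m) for m in (0, 20, 40)], 30)
        assert [e.n_records for e in out.events] == [2, 1]
        # sliding rule chains them into one event
        out = filter_independent([rec(minutes=m) for m in (0, 20, 40)], 30, rule="last")
        assert len(out) == 1

    def test_matches_brute_force_on_random_records(self):
        rng = np.random.default_rng(7)
        records = [
            rec(
                station=f"S{rng.integers(3)}",
                species=rng.choice(["takin", "goral"]),
                minutes=float(rng.uniform(0, 24 * 60)),
            )
            for _ in range(200)
        ]
        out = filter_independent(records, window_minutes=30)
        assert len(out) == brute_force_event_count(records, 30)

    def test_partition_and_exclusion_accounting(self):
        records = [rec(minutes=m) for m in (0, 5, 200)]
        records.append(rec(station="S9", minutes=10))  # no deployment for S9
        out = filter_independent(records, 30, deployments=[deployment()])
        assert sum(e.n_records for e in out.events) + out.n_excluded == out.n_input
        assert out.n_excluded == 1 and out.excluded[0].station_id == "S9"

    def test_idempotent_on_event_starts(self):
        rng = np.random.default_rng(3)
        records = [rec(minutes=float(m)) for m in rng.uniform(0, 600, 50)]
        events = filter_independent(records, 30).events
        again = filter_independent(
            [rec(minutes=(e.event_start - D0).total_seconds() / 60) for e in events], 30
        ).events
        assert [e.event_start for e in again] == [e.event_start for e in events]

    def test_event_gains_elevation_and_daytime(self):
        out = filter_independent([rec()], 30, deployments=[deployment(elev=3120.0)])
        assert out[0].elevation == 3120.0 and out[0].is_daytime is True

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            filter_independent([rec()], 0)


@pytest.mark.parametrize(
    "hhmm,expected",
    [((12, 0), True), ((5, 59), False), ((6, 0), True), ((18, 0), False), ((0, 0), False)],
)
def test_classify_daytime_half_open_window(hhmm, expected):
    assert classify_daytime(dt.time(*hhmm)) is expected


class TestSummarizeSurvey:
    def test_empty_inputs_give_all_zero_summary(self):
        s = summarize_survey([], [], [])
        assert s.per_area.empty

    def test_totals_are_exact_column_sums(self, small_survey):
        deployments = read_deployments(
            io.StringIO(small_survey.deployments.to_csv(index=False))
        )
        records = read_detections(
            io.StringIO(small_survey.detections.to_csv(index=False))
        ).records
        events = filter_independent(records, 30, deployments=deployments)
        s = summarize_survey(deployments, records, events)
        assert s.totals["n_stations"] == 12
        assert s.totals["n_photographs"] == len(records)
        assert s.totals["camera_days"] == 12 * 365
        for sp, n in small_survey.truth["n_events"].items():
            assert s.ips_total(sp) == sum(1 for e in events if e.species == sp) == n

    def test_to_frame_appends_total_row(self, small_survey):
        deployments = read_deployments(
            io.StringIO(small_survey.deployments.to_csv(index=False))
        )
        s = summarize_survey(deployments, [], [])
        assert "Total" in s.to_frame().index


@pytest.mark.parametrize(
    "num,den,expected",
    [
        (540, 1210, 44.63),
        (1123, 3365, 33.37),
        (2242, 3365, 66.63),
        (26, 47, 55.32),
        (1, 47, 2.13),
        (9, 47, 19.15),
        (11, 47, 23.40),  # the arithmetic value; a printed 22.40 is a typo
    ],
)
def test_report_percentages(num, den, expected):
    assert proportion_report(num, den) == expected


def test_proportion_report_validates_inputs():
    with pytest.raises(ValueError):
        proportion_report(1, 0)
    with pytest.raises(ValueError):
        proportion_report(5, 4)


def test_round_half_up_is_not_bankers():
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(2993.5) == 2994
    assert round_half_up(-0.125, 2) == -0.13


def test_group_composition_percentages_sum_to_100():
    comp = GroupComposition(adult_male=1, adult_female=26, juvenile=9, subadult=11)
    pct = comp.percentages()
    assert comp.total == 47
    assert pct["adult_female"] == 55.32
    assert abs(sum(pct.values()) - 100.0) < 0.05  # rounding slack only


def test_station_pair_qc_flags_close_pairs():
    a = deployment("S1")
    b = deployment("S2", longitude=95.003)  # ~290 m east
    c = deployment("S3", longitude=95.1)
    qc = station_pair_qc([a, b, c])
    flagged = qc[qc.needs_review]
    assert set(zip(flagged.station_a, flagged.station_b)) == {("S1", "S2")}


def test_deployment_invariants_enforced():
    with pytest.raises(ValueError):
        deployment(end_date=dt.date(2020, 1, 1))
    with pytest.raises(ValueError):
        deployment(elev=9500.0)
    with pytest.raises(ValueError):
        deployment(sector_angle=7.0)
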