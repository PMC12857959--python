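import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from krillspr.ingest import (
    UNASSIGNED,
    LoadReport,
    SchemaError,
    StratumMap,
    assign_strata,
    bin_composition,
    read_length_records,
)


def _write_csv(tmp_path, rows, name="records.csv"):
    path = tmp_path / name
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


class TestReadLengthRecords:
    def test_out_of_window_lengths_dropped_and_counted(self, tmp_path):
        path = _write_csv(
            tmp_path,
            [
                {"length_mm": 42.0, "date": "2019-01-15", "stratum": "BS"},
                {"length_mm": 200.0, "date": "2019-01-15", "stratum": "BS"},
                {"length_mm": 35.5, "date": "2019-02-15", "stratum": "BS"},
            ],
        )
        records, report = read_length_records(path)
        assert len(records) == 2
        assert report.n_read == 3 and report.n_kept == 2
        assert report.dropped["out_of_window"] == 1

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("length_mm,date,stratum\n")
        records, report = read_length_records(path)
        assert records.empty
        assert report.n_read == 0 and report.n_kept == 0

    def test_missing_required_column_names_it(self, tmp_path):
        path = _write_csv(tmp_path, [{"date": "2019-01-15"}])
        with pytest.raises(SchemaError, match="length_mm"):
            read_length_records(path)

    def test_unparseable_date_rejected_per_row(self, tmp_path):
        path = _write_csv(
            tmp_path,
            [
                {"length_mm": 42.0, "date": "2019-01-15"},
                {"length_mm": 43.0, "date": "not-a-date"},
            ],
        )
        records, report = read_length_records(path)
        assert len(records) == 1
        assert report.dropped["unparseable_date"] == 1

    def test_round_trip_of_synthetic_records(self, tmp_path, rng):
        n = 1000
        frame = pd.DataFrame(
            {
                "length_mm": np.round(rng.uniform(12, 68, n), 2),
                "date": pd.to_datetime("2018-01-01")
                + pd.to_timedelta(rng.integers(0, 700, n), unit="D"),
                "stratum": rng.choice(["BS", "EI", "GS"], n),
            }
        )
        path = tmp_path / "rt.csv"
        frame.to_csv(path, index=False)
        records, report = read_length_records(path)
        assert report.n_kept == n and not report.dropped
        assert np.array_equal(records["length_mm"], frame["length_mm"])
        assert (records["stratum"] == frame["stratum"].to_numpy()).all()
        assert (records["date"] == frame["date"].to_numpy()).all()


SQUARES = StratumMap(
    ["WEST", "EAST"],
    [
        Polygon([(0, 0), (1, 0), (1, 1), (0, 1)]),
        Polygon([(1, 0), (2, 0), (2, 1), (1, 1)]),
    ],
)


class TestStratumAssignment:
    def test_centroid_point_assigned_to_its_polygon(self):
        assert SQUARES.locate(0.5, 0.5) == "WEST"
        assert SQUARES.locate(1.5, 0.5) == "EAST"

    def test_explicit_stratum_wins_over_coordinates(self):
        df = pd.DataFrame(
            {"length_mm": [40.0], "stratum": ["GS"], "lat": [0.5], "lon": [0.5]}
        )
        assert assign_strata(df, SQUARES)["stratum"].iloc[0] == "GS"

    def test_explicit_stratum_without_coordinates(self):
        df = pd.DataFrame({"length_mm": [40.0], "stratum": ["GS"]})
        assert assign_strata(df)["stratum"].iloc[0] == "GS"

    def test_shared_boundary_goes_to_first_declared_polygon(self):
        # x = 1 is the shared edge of the two squares
        assert SQUARES.locate(1.0, 0.5) == "WEST"
        df = pd.DataFrame(
            {"length_mm": [40.0], "stratum": [None], "lat": [0.5], "lon": [1.0]}
        )
        assert assign_strata(df, SQUARES)["stratum"].iloc[0] == "WEST"

    def test_no_match_marked_unassigned(self):
        df = pd.DataFrame(
            {"length_mm": [40.0], "stratum": [None], "lat": [9.0], "lon": [9.0]}
        )
        assert assign_strata(df, SQUARES)["stratum"].iloc[0] == UNASSIGNED

    def test_duplicate_names_rejected(self):
        with pytest.raises(Exception):
            StratumMap(["A", "A"], SQUARES.polygons)

    def test_geojson_round_trip(self, tmp_path):
        import json

        gj = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"name": "WEST"},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]]],
                    },
                }
            ],
        }
        path = tmp_path / "strata.geojson"
        path.write_text(json.dumps(gj))
        smap = StratumMap.from_geojson(path)
        assert smap.names == ["WEST"]
        assert smap.locate(0.5, 0.5) == "WEST"


class TestBinComposition:
    def _records(self, lengths, year=2019, stratum="BS"):
        return pd.DataFrame(
            {
                "length_mm": lengths,
                "year": year,
                "month": 1,
                "stratum": stratum,
            }
        )

    def test_half_open_binning_convention(self):
        comps = bin_composition(self._records([36.0, 37.9, 38.0]))
        assert len(comps) == 1
        comp = comps[0]
        lookup = dict(zip(comp.grid.lower_edges, comp.counts))
        assert lookup[36.0] == 2 and lookup[38.0] == 1

    def test_single_record(self):
        comps = bin_composition(self._records([41.2]))
        assert len(comps) == 1 and comps[0].n == 1

    def test_conservation_and_order_independence(self, rng):
        n = 50_000
        frame = pd.DataFrame(
            {
                "length_mm": rng.uniform(15, 65, n),
                "year": rng.choice([2018, 2019, 2020], n),
                "month": rng.integers(1, 7, n),
                "stratum": rng.choice(["BS", "EI", "GS", UNASSIGNED], n),
            }
        )
        comps = bin_composition(frame)
        n_unassigned = int((frame["stratum"] == UNASSIGNED).sum())
        assert sum(c.n for c in comps) == n - n_unassigned
        shuffled = frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
        comps2 = bin_composition(shuffled)
        by_key = {(c.stratum, c.year): c for c in comps}
        for c in comps2:
            ref = by_key[(c.stratum, c.year)]
            assert np.array_equal(ref.counts, c.counts)
            assert np.array_equal(ref.grid.lower_edges, c.grid.lower_edges)

    def test_empty_records(self):
        assert bin_composition(pd.DataFrame()) == []

    def test_monthly_grouping(self):
        frame = pd.concat(
            [
                self._records([40.0, 42.0]).assign(month=1),
                self._records([44.0]).assign(month=2),
            ]
        )
        comps = bin_composition(frame, by=("year", "month", "stratum"))
        assert {(c.month, c.n) for c in comps} == {(1, 2), (2, 1)}


def test_load_report_formats_counts():
    report = LoadReport(n_read=5, n_kept=3)
    report.dropped["out_of_window"] = 2
    assert "out_of_window=2" in str(report)
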