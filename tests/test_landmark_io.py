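import numpy as np
import pytest

import clawmorph as cm
from clawmorph.landmarks import (
    LandmarkParseError,
    LandmarkValidationError,
    read_landmark_csv,
    read_sliders,
    read_tps,
    write_landmark_csv,
    write_sliders,
    write_tps,
)


def _toy_dataset(n=3, k=16, seed=0):
    rng = np.random.default_rng(seed)
    configs = [
        cm.LandmarkConfiguration(
            f"sp{i}", rng.normal(size=(k, 2)), taxon=f"tax{i}",
            digit="II", clade_group="therizinosaurid",
        )
        for i in range(n)
    ]
    return cm.LandmarkDataset(configs)


class TestTPS:
    def test_two_records_parse(self, tmp_path):
        path = tmp_path / "two.tps"
        path.write_text(
            "LM=16\n" + "\n".join(f"{i} {i + 1}" for i in range(16))
            + "\nID=a\n"
            + "LM=16\n" + "\n".join(f"{i} {2 * i}" for i in range(16))
            + "\nID=b\n"
        )
        ds = read_tps(path)
        assert len(ds) == 2
        assert ds.specimen_ids == ["a", "b"]  # order-stable
        assert ds.n_landmarks == 16
        assert ds["a"].coords[3].tolist() == [3.0, 4.0]

    def test_scale_applied(self, tmp_path):
        path = tmp_path / "s.tps"
        path.write_text("LM=2\n10 4\n0 0\nID=x\nSCALE=0.5\n")
        ds = read_tps(path)
        assert np.allclose(ds["x"].coords[0], [5.0, 2.0])

    def test_round_trip_identity(self, tmp_path):
        ds = _toy_dataset()
        path = tmp_path / "rt.tps"
        write_tps(ds, path)
        back = read_tps(path)
        assert back.specimen_ids == ds.specimen_ids
        for a, b in zip(ds, back):
            assert np.allclose(a.coords, b.coords, atol=1e-9)
            assert a.taxon == b.taxon
            assert a.digit == b.digit
            assert a.clade_group == b.clade_group

    def test_lm_count_mismatch_names_record(self, tmp_path):
        path = tmp_path / "bad.tps"
        path.write_text("LM=3\n0 0\n1 1\nID=x\n")
        with pytest.raises(LandmarkParseError, match="record 1"):
            read_tps(path)

    def test_non_numeric_coordinate_reports_line(self, tmp_path):
        path = tmp_path / "bad.tps"
        path.write_text("LM=2\n0 0\n1 oops\nID=x\n")
        with pytest.raises(LandmarkParseError, match="line 3"):
            read_tps(path)

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "dup.tps"
        path.write_text("LM=2\n0 1\n1 0\nID=x\nLM=2\n2 3\n3 2\nID=x\n")
        with pytest.raises(LandmarkValidationError, match="duplicate"):
            read_tps(path)

    def test_flip_y(self, tmp_path):
        path = tmp_path / "f.tps"
        path.write_text("LM=2\n2 3\n4 5\nID=x\n")
        assert np.allclose(
            read_tps(path, flip_y=True)["x"].coords, [[2, -3], [4, -5]]
        )


class TestCSV:
    @pytest.mark.parametrize("schema", ["long", "wide"])
    def test_round_trip(self, tmp_path, schema):
        ds = _toy_dataset()
        path = tmp_path / f"{schema}.csv"
        write_landmark_csv(ds, path, schema=schema)
        back = read_landmark_csv(path, schema=schema)
        assert back.specimen_ids == ds.specimen_ids
        for a, b in zip(ds, back):
            assert np.allclose(a.coords, b.coords, atol=1e-9)
            assert b.clade_group == a.clade_group

    def test_dialect_equivalence(self, tmp_path):
        ds = _toy_dataset()
        long_p = tmp_path / "l.csv"
        wide_p = tmp_path / "w.csv"
        write_landmark_csv(ds, long_p, schema="long")
        write_landmark_csv(ds, wide_p, schema="wide")
        a = read_landmark_csv(long_p, schema="long")
        b = read_landmark_csv(wide_p, schema="wide")
        assert np.allclose(a.coords_array(), b.coords_array(), atol=1e-12)

    def test_ragged_counts_name_offender(self, tmp_path):
        path = tmp_path / "ragged.csv"
        rows = ["specimen,landmark,x,y"]
        for j in range(1, 17):
            rows.append(f"good,{j},{j},{j + 1}")
        for j in range(1, 16):  # one short
            rows.append(f"short,{j},{j},{j + 1}")
        path.write_text("\n".join(rows))
        with pytest.raises(LandmarkValidationError, match="short"):
            read_landmark_csv(path, schema="long")


class TestSliders:
    def test_paper_scheme_twelve_sliders(self, tmp_path):
        table = cm.claw_sliders()
        path = tmp_path / "sl.csv"
        write_sliders(table, path)
        back = read_sliders(path, k=16)
        assert len(back) == 12
        assert back.rows == table.rows

    def test_empty_table_means_plain_gpa(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("before,slide,after\n")
        assert len(read_sliders(path, k=16)) == 0

    def test_slider_equal_to_neighbor_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("before,slide,after\n1,1,2\n")
        with pytest.raises(LandmarkValidationError, match="neighbor"):
            read_sliders(path, k=16)

    def test_out_of_range_and_repeats_rejected(self, tmp_path):
        path = tmp_path / "oor.csv"
        path.write_text("before,slide,after\n1,17,2\n")
        with pytest.raises(LandmarkValidationError, match="outside"):
            read_sliders(path, k=16)
        path.write_text("before,slide,after\n1,2,3\n3,2,4\n")
        with pytest.raises(LandmarkValidationError, match="repeated"):
            read_sliders(path, k=16)


class TestLevers:
    def test_round_trip(self, tmp_path):
        levers = [
            cm.LeverMeasurements("u1", a=10, d=3, theta=40, delta=20,
                                 h=1.0, b=2.0, digit="III",
                                 clade_group="therizinosaurid"),
            cm.LeverMeasurements("u2", a=8, d=2, theta=35, delta=25,
                                 h=0.5, b=1.5),
        ]
        path = tmp_path / "lv.csv"
        cm.write_levers(levers, path)
        back = cm.read_levers(path)
        assert [m.specimen_id for m in back] == ["u1", "u2"]
        assert back[0].digit == cm.Digit.III
        assert back[0].a == 10 and back[1].h == 0.5

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(a=-1, d=3, theta=40, delta=20, h=1, b=2),
            dict(a=1, d=3, theta=170, delta=20, h=1, b=2),
            dict(a=1, d=3, theta=40, delta=20, h=-1, b=2),
            dict(a=1, d=3, theta=40, delta=20, h=1, b=0),
        ],
    )
    def test_invariants_enforced(self, kwargs):
        with pytest.raises(LandmarkValidationError):
            cm.LeverMeasurements("bad", **kwargs)


def test_configuration_rejects_nonfinite_and_degenerate():
    with pytest.raises(LandmarkValidationError):
        cm.LandmarkConfiguration("x", [[0, 0], [np.nan, 1]])
    with pytest.raises(LandmarkValidationError):
        cm.LandmarkConfiguration("x", [[1, 1], [1, 1]])
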