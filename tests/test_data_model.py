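import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chilipcnn.data_model import (
    N_SENSORS,
    SENSOR_NAMES,
    CollectionDesign,
    Dataset,
    FormatError,
    SensorRecord,
    ValidationError,
    read_dataset,
    read_label_map,
    slice_instances,
    write_dataset,
    write_label_map,
)


def make_dataset(n_classes=2, n_bottles=2, n_reps=2, duration=6, seed=0):
    design = CollectionDesign(n_classes, n_bottles, n_reps, duration_s=duration)
    rng = np.random.default_rng(seed)
    records = []
    for c in range(n_classes):
        for b in range(n_bottles):
            for r in range(n_reps):
                records.append(
                    SensorRecord(
                        record_id=f"c{c}b{b}r{r}",
                        class_label=c,
                        bottle_id=b,
                        repetition_id=r,
                        values=rng.uniform(0.1, 5.0, size=(N_SENSORS, duration)),
                    )
                )
    return Dataset(records, design)


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path):
        ds = make_dataset()
        path = tmp_path / "d.csv"
        write_dataset(ds, path)
        back = read_dataset(path, ds.design)
        assert len(back) == len(ds)
        for a, b in zip(ds.records, back.records):
            assert a.record_id == b.record_id
            assert a.class_label == b.class_label
            assert a.bottle_id == b.bottle_id
            assert a.repetition_id == b.repetition_id
            np.testing.assert_allclose(a.values, b.values)

    @settings(max_examples=15, deadline=None)
    @given(
        n_classes=st.integers(1, 3),
        n_bottles=st.integers(1, 3),
        n_reps=st.integers(1, 2),
        duration=st.integers(2, 8),
        seed=st.integers(0, 100),
    )
    def test_roundtrip_property(self, tmp_path_factory, n_classes, n_bottles,
                                n_reps, duration, seed):
        ds = make_dataset(n_classes, n_bottles, n_reps, duration, seed)
        path = tmp_path_factory.mktemp("rt") / "d.csv"
        write_dataset(ds, path)
        back = read_dataset(path, ds.design)
        for a, b in zip(ds.records, back.records):
            np.testing.assert_allclose(a.values, b.values)
            assert a.record_id == b.record_id

    def test_write_is_deterministic(self, tmp_path):
        ds = make_dataset()
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_dataset(ds, p1)
        write_dataset(ds, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_dataset_header_only(self, tmp_path):
        ds = Dataset([], CollectionDesign(2, 2, 2, duration_s=4))
        path = tmp_path / "e.csv"
        write_dataset(ds, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].split(",") == [
            "record_id", "class", "bottle", "repetition", "t", "sensor", "value"
        ]

    def test_full_design_row_count(self, tmp_path):
        # 13 x 10 x 10 design: 1300 records x 10 sensors x duration seconds
        ds = make_dataset(n_classes=2, n_bottles=2, n_reps=2, duration=5)
        path = tmp_path / "d.csv"
        write_dataset(ds, path)
        n_lines = len(path.read_text().strip().splitlines())
        assert n_lines == 1 + len(ds) * N_SENSORS * 5


class TestValidation:
    def test_nonpositive_value_rejected(self, tmp_path):
        ds = make_dataset()
        ds.records[0].values[3, 2] = 0.0
        path = tmp_path / "d.csv"
        ds2 = make_dataset()
        write_dataset(ds2, path)
        import pandas as pd
        df = pd.read_csv(path)
        df.loc[5, "value"] = 0.0
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError):
            read_dataset(path, ds.design)

    def test_incomplete_record_names_culprit(self, tmp_path):
        ds = make_dataset(duration=4)
        path = tmp_path / "d.csv"
        write_dataset(ds, path)
        import pandas as pd
        df = pd.read_csv(path)
        victim = ds.records[1].record_id
        drop = df[(df.record_id == victim) & (df.t == 4)].index[:1]
        df.drop(index=drop).to_csv(path, index=False)
        with pytest.raises(ValidationError, match=victim):
            read_dataset(path, ds.design)

    def test_missing_column_is_format_error(self, tmp_path):
        ds = make_dataset()
        path = tmp_path / "d.csv"
        write_dataset(ds, path)
        import pandas as pd
        pd.read_csv(path).drop(columns=["sensor"]).to_csv(path, index=False)
        with pytest.raises(FormatError):
            read_dataset(path, ds.design)

    def test_duplicate_triple_rejected(self):
        ds = make_dataset()
        ds.records.append(ds.records[0])
        with pytest.raises(ValidationError, match="duplicate"):
            ds.validate()

    def test_design_invariants(self):
        with pytest.raises(ValidationError):
            CollectionDesign(0, 1, 1)
        with pytest.raises(ValidationError):
            CollectionDesign(1, 1, 1, duration_s=3, sample_rate_hz=0.4)


class TestSliceInstances:
    def test_full_window_row_count(self):
        ds = make_dataset(n_classes=1, n_bottles=1, n_reps=1, duration=8)
        table = slice_instances(ds, (1, 8))
        assert len(table) == 8

    def test_trimmed_window_row_count(self):
        # the 21..120 window of a 120 s record keeps 100 seconds
        design = CollectionDesign(1, 1, 1, duration_s=120)
        rng = np.random.default_rng(0)
        ds = Dataset(
            [SensorRecord("r", 0, 0, 0, rng.uniform(0.5, 2, (N_SENSORS, 120)))],
            design,
        )
        assert len(slice_instances(ds, (21, 120))) == 100

    def test_single_second_window(self):
        ds = make_dataset(n_classes=1, n_bottles=1, n_reps=1, duration=8)
        table = slice_instances(ds, (5, 5))
        assert len(table) == 1
        np.testing.assert_allclose(table.X[0], ds.records[0].values[:, 4])
        assert table.t[0] == 5

    def test_row_count_scales_with_records_and_window(self):
        ds = make_dataset(n_classes=2, n_bottles=2, n_reps=2, duration=7)
        table = slice_instances(ds, (3, 6))
        assert len(table) == len(ds.records) * 4

    def test_window_outside_duration(self):
        ds = make_dataset(duration=6)
        with pytest.raises(ValidationError):
            slice_instances(ds, (1, 7))
        with pytest.raises(ValidationError):
            slice_instances(ds, (0, 5))


def test_label_map_roundtrip(tmp_path):
    path = tmp_path / "labels.yaml"
    write_label_map(["alpha", "beta"], path)
    assert read_label_map(path) == {0: "alpha", 1: "beta"}


def test_sensor_order_is_fixed_contract():
    assert SENSOR_NAMES == (
        "W1C", "W5S", "W3C", "W6S", "W5C", "W1S", "W1W", "W2S", "W2W", "W3S"
    )
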