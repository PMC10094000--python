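"""Data model, tabular round-trip, dataset assembly and day splitting."""

import numpy as np
import pandas as pd
import pytest

from enoseml.data import (
    LIQUOR_CLASSES,
    SENSOR_CHANNELS,
    SENSOR_CODES,
    Measurement,
    MeasurementSet,
    SplitSpec,
    assemble_dataset,
    day_split,
    read_measurement_table,
    write_measurement_table,
)

from conftest import make_measurement


class TestDomainTypes:
    def test_sensor_array_is_the_fixed_ten_channel_pen3_layout(self):
        assert len(SENSOR_CHANNELS) == 10
        assert len(set(SENSOR_CODES)) == 10
        assert SENSOR_CODES == ("W1C", "W5S", "W3C", "W6S", "W5C",
                                "W1S", "W1W", "W2S", "W2W", "W3S")

    def test_nine_liquor_classes_six_base_three_commercial(self):
        groups = [c.group for c in LIQUOR_CLASSES.values()]
        assert groups.count("base") == 6
        assert groups.count("commercial") == 3

    def test_commercial_blends_sum_to_100_percent(self):
        for c in LIQUOR_CLASSES.values():
            if c.group == "commercial":
                assert sum(p for _, p in c.blend) == pytest.approx(100.0)

    @pytest.mark.parametrize(
        "bad",
        [
            np.full((99, 10), 1.0),
            np.full((100, 9), 1.0),
            np.full((100, 10), -1.0),
        ],
        ids=["short", "narrow", "negative"],
    )
    def test_invalid_response_matrices_rejected(self, bad):
        with pytest.raises(ValueError):
            make_measurement(bad)

    def test_nonfinite_response_rejected(self):
        bad = np.full((100, 10), 1.0)
        bad[3, 7] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            make_measurement(bad)

    def test_duplicate_ids_rejected(self):
        mset = MeasurementSet([make_measurement(mid="x")])
        with pytest.raises(ValueError, match="duplicate"):
            mset.add(make_measurement(mid="x"))

    def test_overlapping_split_days_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitSpec(train_days={1, 2, 3}, test_days={3, 4})


class TestTableIO:
    def test_round_trip_preserves_everything(self, tiny_set, tmp_path):
        path = tmp_path / "t.csv"
        write_measurement_table(tiny_set, path)
        again = read_measurement_table(path)
        assert again == tiny_set

    def test_full_protocol_round_trip(self, protocol_set, tmp_path):
        path = tmp_path / "full.csv"
        write_measurement_table(protocol_set, path)
        assert read_measurement_table(path) == protocol_set

    def test_empty_set_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_measurement_table(MeasurementSet(), path)
        df = pd.read_csv(path)
        assert df.empty
        assert list(df.columns[-10:]) == list(SENSOR_CODES)
        assert len(read_measurement_table(path)) == 0

    def test_single_measurement_writes_100_rows(self, tmp_path):
        path = tmp_path / "one.csv"
        write_measurement_table(MeasurementSet([make_measurement()]), path)
        assert len(pd.read_csv(path)) == 100

    def test_missing_channel_column_named_in_error(self, tiny_set, tmp_path):
        path = tmp_path / "t.csv"
        write_measurement_table(tiny_set, path)
        df = pd.read_csv(path).drop(columns=["W2S"])
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="W2S"):
            read_measurement_table(path)

    def test_truncated_measurement_named_in_error(self, tiny_set, tmp_path):
        path = tmp_path / "t.csv"
        write_measurement_table(tiny_set, path)
        df = pd.read_csv(path)
        df = df[~((df["id"] == "m0") & (df["t"] == 100))]  # 99 timepoints for m0
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="m0"):
            read_measurement_table(path)

    def test_duplicate_id_t_rejected(self, tiny_set, tmp_path):
        path = tmp_path / "t.csv"
        write_measurement_table(tiny_set, path)
        df = pd.read_csv(path)
        pd.concat([df, df.iloc[[0]]]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_measurement_table(path)


class TestAssemblyAndSplit:
    @pytest.mark.parametrize(
        "variant,expected", [("A", 1350), ("B", 675), ("C", 2025)]
    )
    def test_variant_sizes_on_full_protocol(self, protocol_set, variant, expected):
        assert len(assemble_dataset(protocol_set, variant)) == expected

    def test_a_plus_b_equals_c(self, small_protocol_set):
        a = assemble_dataset(small_protocol_set, "A")
        b = assemble_dataset(small_protocol_set, "B")
        c = assemble_dataset(small_protocol_set, "C")
        assert len(a) + len(b) == len(c)
        assert set(a.ids()) | set(b.ids()) == set(c.ids())

    def test_unknown_variant_rejected(self, small_protocol_set):
        with pytest.raises(ValueError, match="variant"):
            assemble_dataset(small_protocol_set, "D")

    @pytest.mark.parametrize(
        "variant,n_train,n_test", [("A", 1080, 270), ("C", 1620, 405)]
    )
    def test_default_day_split_sizes(self, protocol_set, variant, n_train, n_test):
        ds = assemble_dataset(protocol_set, variant)
        train, test = day_split(ds, SplitSpec())
        assert (len(train), len(test)) == (n_train, n_test)

    def test_day_split_is_a_partition(self, small_protocol_set):
        train, test = day_split(
            small_protocol_set, SplitSpec(train_days={1, 2, 3}, test_days={4, 5})
        )
        assert len(train) + len(test) == len(small_protocol_set)
        assert not set(train.ids()) & set(test.ids())

    def test_all_days_in_train_leaves_test_empty(self, small_protocol_set):
        train, test = day_split(
            small_protocol_set,
            SplitSpec(train_days=set(range(1, 26)), test_days=set()),
        )
        assert len(test) == 0
        assert len(train) == len(small_protocol_set)
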