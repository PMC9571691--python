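"""ECG5000 dialect I/O, relabeling, splitting and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splitbeat import dataset as dio


def _normals(n, length=4):
    """n distinguishable normal records (first sample encodes the index)."""
    records = [
        dio.BeatRecord(label=1, samples=np.array([float(i)] + [0.0] * (length - 1)))
        for i in range(n)
    ]
    return dio.BeatDataset(records=records, length=length)


class TestReader:
    def test_minimal_one_line_file(self, tmp_path):
        path = tmp_path / "one.txt"
        path.write_text("1 " + " ".join(["0.0"] * 140) + "\n")
        ds = dio.read_ecg5000(path)
        assert len(ds) == 1 and ds.length == 140
        assert ds.records[0].label == 1
        np.testing.assert_array_equal(ds.records[0].samples, np.zeros(140))

    def test_comma_delimited_accepted(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("2,0.5,-1.25,3.0\n1,0.0,0.0,1.0\n")
        ds = dio.read_ecg5000(path)
        assert ds.labels.tolist() == [2, 1] and ds.length == 3

    def test_wrong_field_count_names_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("1 0.0 0.0 0.0\n1 0.0 0.0\n")
        with pytest.raises(dio.ParseError, match="line 2"):
            dio.read_ecg5000(path)

    def test_non_numeric_field_rejected(self, tmp_path):
        path = tmp_path / "nan.txt"
        path.write_text("1 0.0 abc 0.0\n")
        with pytest.raises(dio.ParseError, match="line 1"):
            dio.read_ecg5000(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("")
        with pytest.raises(dio.ParseError, match="empty"):
            dio.read_ecg5000(path)

    @pytest.mark.parametrize("label", [0, 6])
    def test_raw_label_outside_1_to_5_rejected(self, tmp_path, label):
        path = tmp_path / "lbl.txt"
        path.write_text(f"{label} 0.0 0.0 0.0\n")
        with pytest.raises(dio.ParseError, match="outside 1..5"):
            dio.read_ecg5000(path)


class TestWriterRoundTrip:
    def test_shape_labels_and_precision(self, tmp_path):
        rng = np.random.default_rng(0)
        records = [
            dio.BeatRecord(label=1 + i % 5, samples=rng.normal(0, 1, 140))
            for i in range(5)
        ]
        ds = dio.BeatDataset(records=records, length=140)
        path = dio.write_ecg5000(ds, tmp_path / "rt.txt")
        lines = path.read_text().splitlines()
        assert len(lines) == 5
        assert all(len(line.split()) == 141 for line in lines)
        back = dio.read_ecg5000(path)
        assert back.labels.tolist() == ds.labels.tolist()
        assert np.max(np.abs(back.to_array() - ds.to_array())) <= 1e-9

    def test_empty_dataset_refused(self, tmp_path):
        with pytest.raises(dio.DatasetError):
            dio.write_ecg5000(dio.BeatDataset(records=[], length=140), tmp_path / "x.txt")


class TestBinarize:
    def test_mapping_and_content_preservation(self):
        rng = np.random.default_rng(1)
        records = [dio.BeatRecord(label=l, samples=rng.normal(0, 1, 6)) for l in (1, 2, 3, 4, 5)]
        ds = dio.BeatDataset(records=records, length=6)
        out = dio.binarize_labels(ds)
        assert out.labels.tolist() == [1, 0, 0, 0, 0]
        np.testing.assert_array_equal(out.to_array(), ds.to_array())

    def test_empty_dataset_passes_through(self):
        out = dio.binarize_labels(dio.BeatDataset(records=[], length=5))
        assert len(out) == 0

    def test_invalid_raw_label_rejected(self):
        ds = dio.BeatDataset(records=[dio.BeatRecord(label=6, samples=np.zeros(3))], length=3)
        with pytest.raises(dio.DatasetError, match="outside 1..5"):
            dio.binarize_labels(ds)


class TestSplitNormals:
    @pytest.mark.parametrize("n,expected", [(2919, (2043, 438, 438)), (100, (70, 15, 15))])
    def test_split_sizes(self, n, expected):
        res = dio.split_normals(_normals(n), train_fraction=0.70, seed=0)
        assert (len(res.train), len(res.validation), len(res.test)) == expected

    def test_remainder_keeps_original_order_validation_first(self):
        res = dio.split_normals(_normals(20), train_fraction=0.5, seed=3)
        rest_ids = [int(r.samples[0]) for r in res.validation.records + res.test.records]
        assert rest_ids == sorted(rest_ids)  # original file order preserved
        assert len(res.validation) == 5 and len(res.test) == 5

    def test_abnormal_records_rejected(self):
        ds = dio.BeatDataset(records=[dio.BeatRecord(label=0, samples=np.zeros(3))], length=3)
        with pytest.raises(dio.DatasetError, match="label 1"):
            dio.split_normals(ds)

    def test_too_small_dataset_needs_allow_empty(self):
        with pytest.raises(dio.DatasetError, match="empty part"):
            dio.split_normals(_normals(2), train_fraction=0.7, seed=0)
        res = dio.split_normals(_normals(2), train_fraction=0.7, seed=0, allow_empty=True)
        assert len(res.train) + len(res.validation) + len(res.test) == 2

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        n=st.integers(min_value=3, max_value=60),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
        fraction=st.floats(min_value=0.35, max_value=0.9),
    )
    def test_partition_conserves_multiset(self, n, seed, fraction):
        ds = _normals(n)
        try:
            res = dio.split_normals(ds, train_fraction=fraction, seed=seed)
        except dio.DatasetError:
            return  # legitimately empty part at this (n, fraction)
        got = sorted(
            int(r.samples[0])
            for part in (res.train, res.validation, res.test)
            for r in part.records
        )
        assert got == list(range(n))


class TestNormalization:
    def test_fit_returns_global_extrema(self):
        ds = dio.BeatDataset(
            records=[
                dio.BeatRecord(label=1, samples=np.array([-5.0, 0.0, 1.0])),
                dio.BeatRecord(label=1, samples=np.array([2.0, 10.0, 3.0])),
            ],
            length=3,
        )
        assert dio.fit_normalization(ds) == (-5.0, 10.0)

    def test_fit_after_apply_is_unit_range(self):
        ds = dio.BeatDataset(
            records=[
                dio.BeatRecord(label=1, samples=np.array([0.0, 0.0])),
                dio.BeatRecord(label=1, samples=np.array([1.0, 0.5])),
            ],
            length=2,
        )
        lo, hi = dio.fit_normalization(ds)
        assert (lo, hi) == (0.0, 1.0)
        assert dio.fit_normalization(dio.apply_normalization(ds, lo, hi)) == (0.0, 1.0)

    def test_constant_dataset_is_degenerate(self):
        ds = dio.BeatDataset(records=[dio.BeatRecord(label=1, samples=np.full(4, 2.0))], length=4)
        with pytest.raises(dio.DatasetError, match="degenerate"):
            dio.fit_normalization(ds)

    def test_apply_affine_and_no_clipping(self):
        ds = dio.BeatDataset(
            records=[dio.BeatRecord(label=1, samples=np.array([0.0, 5.0, 10.0, 20.0]))],
            length=4,
        )
        out = dio.apply_normalization(ds, 0.0, 10.0)
        np.testing.assert_allclose(out.records[0].samples, [0.0, 0.5, 1.0, 2.0])
        assert out.normalization == (0.0, 10.0)

    def test_round_trip_restores_inputs(self):
        rng = np.random.default_rng(4)
        ds = dio.BeatDataset(
            records=[dio.BeatRecord(label=1, samples=rng.normal(3, 7, 50)) for _ in range(4)],
            length=50,
        )
        lo, hi = dio.fit_normalization(ds)
        back = dio.invert_normalization(dio.apply_normalization(ds, lo, hi))
        np.testing.assert_allclose(back.to_array(), ds.to_array(), rtol=1e-9)

    def test_degenerate_parameters_rejected(self):
        ds = _normals(2)
        with pytest.raises(dio.DatasetError):
            dio.apply_normalization(ds, 1.0, 1.0)
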