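import numpy as np
import pytest

from destab import CountMatrix, cpm, read_counts, read_design, size_factors, write_counts
from destab.countdata import GroupDesign, ValidationError


class TestReadCounts:
    def test_parses_small_tsv(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("id\ts1\ts2\ng1\t0\t5\ng2\t3\t1\n")
        cm = read_counts(p)
        assert np.array_equal(cm.counts, [[0, 5], [3, 1]])
        assert cm.feature_ids == ["g1", "g2"]
        assert cm.sample_ids == ["s1", "s2"]

    def test_rejects_decimal_entry(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("id\ts1\ts2\ng1\t2.5\t1\n")
        with pytest.raises(ValidationError, match="non-integer"):
            read_counts(p)

    def test_mtx_expands_implicit_zeros(self, tmp_path):
        (tmp_path / "m.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n4 3 3\n1 1 7\n2 3 4\n4 2 9\n"
        )
        (tmp_path / "m.features.txt").write_text("g1\ng2\ng3\ng4\n")
        (tmp_path / "m.samples.txt").write_text("s1\ns2\ns3\n")
        cm = read_counts(tmp_path / "m.mtx")
        expected = np.zeros((4, 3), dtype=int)
        expected[0, 0], expected[1, 2], expected[3, 1] = 7, 4, 9
        assert np.array_equal(cm.counts, expected)
        assert (cm.counts == 0).sum() == 9

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_counts("/nonexistent/counts.tsv")

    @pytest.mark.parametrize("fmt,suffix", [("tsv", ".tsv"), ("csv", ".csv"), ("mtx", ".mtx")])
    def test_round_trip(self, tmp_path, small_cm, fmt, suffix):
        path = tmp_path / f"rt{suffix}"
        write_counts(small_cm, path, format=fmt)
        back = read_counts(path, format=fmt)
        assert np.array_equal(back.counts, small_cm.counts)
        assert back.feature_ids == small_cm.feature_ids
        assert back.sample_ids == small_cm.sample_ids


class TestValidation:
    def test_duplicate_feature_ids(self):
        with pytest.raises(ValidationError, match="duplicate"):
            CountMatrix(np.ones((2, 2), dtype=int), ["g", "g"], ["a", "b"])

    def test_negative_count_names_cell(self):
        with pytest.raises(ValidationError, match="g2.*b"):
            CountMatrix(np.array([[1, 1], [1, -3]]), ["g1", "g2"], ["a", "b"])

    def test_minimum_shape(self):
        with pytest.raises(ValidationError):
            CountMatrix(np.array([[1], [2]]), ["g1", "g2"], ["only"])


class TestReadDesign:
    def test_two_groups(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("A\nA\nA\nB\nB\nB\n")
        d = read_design(p)
        assert {len(v) for v in d.group_indices.values()} == {3}

    def test_one_label_rejected(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("A\nA\nA\n")
        with pytest.raises(ValidationError, match="exactly two conditions"):
            read_design(p)

    def test_three_labels_listed(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("A\nB\nC\n")
        with pytest.raises(ValidationError, match="A.*B.*C"):
            read_design(p)

    def test_two_column_aligned_to_sample_order(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("s2\tB\ns1\tA\n")
        d = read_design(p, sample_ids=["s1", "s2"])
        assert d.labels == ["A", "B"]

    def test_unknown_sample_id(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("s1\tA\nsX\tB\n")
        with pytest.raises(ValidationError, match="missing sample"):
            read_design(p, sample_ids=["s1", "s2"])


class TestSizeFactors:
    def test_total_count_example(self):
        cm = CountMatrix(np.array([[10, 20], [30, 60]]), ["g1", "g2"], ["a", "b"])
        f = size_factors(cm, "total_count").size_factors
        assert np.allclose(f, [2 / 3, 4 / 3])

    def test_median_ratio_identical_columns(self):
        cm = CountMatrix(np.array([[5, 5], [9, 9]]), ["g1", "g2"], ["a", "b"])
        f = size_factors(cm, "median_ratio").size_factors
        assert np.allclose(f, [1.0, 1.0])

    def test_median_ratio_single_feature(self):
        cm = CountMatrix(np.array([[2, 8]]), ["g1"], ["a", "b"])
        f = size_factors(cm, "median_ratio").size_factors
        assert np.allclose(f, [0.5, 2.0])

    def test_all_zero_sample_rejected(self):
        cm = CountMatrix(np.array([[1, 0], [2, 0]]), ["g1", "g2"], ["a", "b"])
        with pytest.raises(ValidationError, match="all-zero"):
            size_factors(cm)

    def test_fallback_when_no_all_positive_feature(self, caplog):
        cm = CountMatrix(np.array([[3, 0], [0, 4]]), ["g1", "g2"], ["a", "b"])
        with caplog.at_level("WARNING"):
            res = size_factors(cm, "median_ratio")
        assert res.method_name == "total_count"
        assert "falling back" in caplog.text

    def test_total_count_invariances(self, small_cm):
        f = size_factors(small_cm, "total_count").size_factors
        perm = np.random.default_rng(0).permutation(small_cm.n_features)
        shuffled = CountMatrix(
            small_cm.counts[perm],
            [small_cm.feature_ids[i] for i in perm],
            small_cm.sample_ids,
        )
        assert np.allclose(size_factors(shuffled, "total_count").size_factors, f)
        # doubling one sample's column doubles its relative factor
        scaled = small_cm.counts.copy()
        scaled[:, 0] *= 2
        f2 = size_factors(
            CountMatrix(scaled, small_cm.feature_ids, small_cm.sample_ids), "total_count"
        ).size_factors
        assert f2[0] / f2[1] == pytest.approx(2 * f[0] / f[1])


class TestCpm:
    def test_plain_cpm_value(self):
        counts = np.zeros((2, 2), dtype=int)
        counts[0] = [5, 5]
        counts[1] = [10**6 - 5, 10**6 - 5]
        cm = CountMatrix(counts, ["g1", "g2"], ["a", "b"])
        assert cpm(cm)[0, 0] == pytest.approx(5.0)

    def test_log2_prior_example(self):
        counts = np.array([[0, 0], [10**6, 10**6]])
        cm = CountMatrix(counts, ["g1", "g2"], ["a", "b"])
        val = cpm(cm, log2=True, prior_count=0.5)[0, 0]
        assert val == pytest.approx(np.log2(0.5 / (10**6 + 1) * 10**6), abs=1e-9)
        assert val == pytest.approx(-1.0000014, abs=1e-6)

    def test_scale_invariance(self, small_cm):
        base = cpm(small_cm)
        doubled = small_cm.counts.copy()
        doubled[:, 2] *= 2
        cm2 = CountMatrix(doubled, small_cm.feature_ids, small_cm.sample_ids)
        assert np.allclose(cpm(cm2)[:, 2], base[:, 2])

    def test_columns_sum_to_million(self, small_cm):
        assert np.allclose(cpm(small_cm).sum(axis=0), 1e6, rtol=1e-6)


def test_group_design_requires_two_conditions():
    with pytest.raises(ValidationError):
        GroupDesign(["A", "A", "A"])
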