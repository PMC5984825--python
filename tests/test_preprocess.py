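"""Detection filtering, log2/quantile normalization, QC, probe collapsing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from cortexsig import preprocess
from conftest import make_meta


def _det_matrix(detected: np.ndarray, index, columns):
    """0.01 where detected, 0.5 where not."""
    return pd.DataFrame(np.where(detected, 0.01, 0.5), index=index, columns=columns)


class TestDetectionFilter:
    @pytest.fixture
    def eight_meta(self):
        return make_meta([f"s{i}" for i in range(8)],
                         ["autism"] * 4 + ["control"] * 4)

    def _raw(self, n_probes, columns):
        return pd.DataFrame(np.ones((n_probes, len(columns))),
                            index=pd.Index([f"p{i}" for i in range(n_probes)], name="gene_id"),
                            columns=columns)

    def test_detected_in_half_of_one_group_kept(self, eight_meta):
        raw = self._raw(1, eight_meta.index)
        det = _det_matrix(np.array([[1, 1, 0, 0, 0, 0, 0, 0]], bool),
                          raw.index, raw.columns)
        out = preprocess.detection_filter(raw, det, eight_meta)
        assert list(out.index) == ["p0"]

    def test_detected_in_one_of_each_group_removed(self, eight_meta):
        raw = self._raw(1, eight_meta.index)
        det = _det_matrix(np.array([[1, 0, 0, 0, 1, 0, 0, 0]], bool),
                          raw.index, raw.columns)
        out = preprocess.detection_filter(raw, det, eight_meta)
        assert out.empty

    def test_boundary_p_equal_threshold_not_detected(self, eight_meta):
        raw = self._raw(1, eight_meta.index)
        det = pd.DataFrame([[0.05] * 8], index=raw.index, columns=raw.columns)
        out = preprocess.detection_filter(raw, det, eight_meta)
        assert out.empty
        # strictly below the threshold counts
        det2 = pd.DataFrame([[0.049] * 8], index=raw.index, columns=raw.columns)
        assert len(preprocess.detection_filter(raw, det2, eight_meta)) == 1

    def test_fraction_zero_is_identity(self, eight_meta):
        rng = np.random.default_rng(0)
        raw = self._raw(20, eight_meta.index)
        det = pd.DataFrame(rng.uniform(0, 1, (20, 8)), index=raw.index, columns=raw.columns)
        out = preprocess.detection_filter(raw, det, eight_meta, fraction=0.0)
        assert list(out.index) == list(raw.index)

    def test_fraction_one_requires_full_group(self, eight_meta):
        raw = self._raw(2, eight_meta.index)
        det = _det_matrix(np.array([[1, 1, 1, 1, 0, 0, 0, 0],
                                    [1, 1, 1, 0, 1, 1, 1, 0]], bool),
                          raw.index, raw.columns)
        out = preprocess.detection_filter(raw, det, eight_meta, fraction=1.0)
        assert list(out.index) == ["p0"]

    def test_odd_group_size_uses_ceiling(self):
        meta = make_meta([f"s{i}" for i in range(5)], ["autism"] * 3 + ["control"] * 2)
        raw = self._raw(1, meta.index)
        # 1 of 3 autism detected: ceil(1.5)=2 needed -> removed
        det = _det_matrix(np.array([[1, 0, 0, 0, 0]], bool), raw.index, raw.columns)
        assert preprocess.detection_filter(raw, det, meta).empty
        det2 = _det_matrix(np.array([[1, 1, 0, 0, 0]], bool), raw.index, raw.columns)
        assert len(preprocess.detection_filter(raw, det2, meta)) == 1

    def test_missing_diagnosis_errors(self, eight_meta):
        raw = self._raw(1, eight_meta.index)
        det = _det_matrix(np.ones((1, 8), bool), raw.index, raw.columns)
        broken = eight_meta.copy()
        broken.loc[broken.index[0], "diagnosis"] = np.nan
        with pytest.raises(ValueError):
            preprocess.detection_filter(raw, det, broken)


class TestLog2Transform:
    @pytest.mark.parametrize("x,expected", [(1.0, 0.0), (8.0, 3.0), (0.0, 0.0)])
    def test_values_with_floor(self, x, expected):
        m = pd.DataFrame([[x]], index=["g"], columns=["s"])
        assert preprocess.log2_transform(m).iloc[0, 0] == expected

    def test_negative_rejected(self):
        m = pd.DataFrame([[-1.0]], index=["g"], columns=["s"])
        with pytest.raises(ValueError):
            preprocess.log2_transform(m)


class TestQuantileNormalize:
    def test_two_by_two_rank_means(self):
        m = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 4.0]}, index=["g1", "g2"])
        out = preprocess.quantile_normalize(m)
        assert out["a"].tolist() == [1.5, 3.5]
        assert out["b"].tolist() == [1.5, 3.5]

    def test_identical_columns_fixed_point(self):
        m = pd.DataFrame({"a": [5.0, 1.0, 3.0], "b": [5.0, 1.0, 3.0]})
        pd.testing.assert_frame_equal(preprocess.quantile_normalize(m), m)

    def test_ties_get_mean_of_reference_values(self):
        # sorted refs: mean([1,1,2],[1,2,3]) -> [1, 1.5, 2.5]; ties in col a
        # occupy ranks 1,2 -> both get (1+1.5)/2
        m = pd.DataFrame({"a": [1.0, 1.0, 2.0], "b": [1.0, 2.0, 3.0]})
        out = preprocess.quantile_normalize(m)
        assert out["a"].tolist() == [1.25, 1.25, 2.5]
        assert out["b"].tolist() == [1.0, 1.5, 2.5]

    @given(hnp.arrays(float, (7, 4), elements=st.floats(-50, 50)))
    def test_columns_share_sorted_values_and_ranks_preserved(self, arr):
        m = pd.DataFrame(arr, columns=list("abcd"))
        out = preprocess.quantile_normalize(m)
        ref = np.sort(out.to_numpy()[:, 0])
        for j in range(1, 4):
            # tie-averaging can only merge values, never reorder them
            col_in, col_out = m.iloc[:, j], out.iloc[:, j]
            order = np.argsort(col_in.to_numpy(), kind="stable")
            assert (np.diff(col_out.to_numpy()[order]) >= -1e-12).all()
        if len(np.unique(arr)) == arr.size:  # tie-free: exact defining property
            for j in range(1, 4):
                np.testing.assert_allclose(np.sort(out.to_numpy()[:, j]), ref)

    def test_missing_values_rejected(self):
        m = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
        with pytest.raises(ValueError):
            preprocess.quantile_normalize(m)


class TestInterarrayQC:
    def test_noise_column_flagged(self):
        rng = np.random.default_rng(1)
        base = rng.normal(8, 2, 200)
        cols = {f"s{i}": base + rng.normal(0, 0.05, 200) for i in range(3)}
        cols["noise"] = rng.normal(8, 2, 200)
        report = preprocess.interarray_qc(pd.DataFrame(cols))
        assert "noise" in report.samples_flagged

    def test_only_noise_flagged_with_enough_samples(self):
        # with few samples one bad array dilutes everyone's mean correlation;
        # at n=9 the good arrays stay above the threshold
        rng = np.random.default_rng(4)
        base = rng.normal(8, 2, 300)
        cols = {f"s{i}": base + rng.normal(0, 0.1, 300) for i in range(8)}
        cols["noise"] = rng.normal(8, 2, 300)
        report = preprocess.interarray_qc(pd.DataFrame(cols))
        assert set(report.samples_flagged) == {"noise"}

    def test_identical_columns_none_flagged(self):
        rng = np.random.default_rng(2)
        col = rng.normal(0, 1, 50)
        m = pd.DataFrame({f"s{i}": col for i in range(4)})
        report = preprocess.interarray_qc(m)
        assert report.samples_flagged == {}

    def test_two_samples_error(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError):
            preprocess.interarray_qc(m)

    def test_constant_column_zero_variance_reason(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame({"a": rng.normal(0, 1, 30), "b": rng.normal(0, 1, 30),
                          "c": rng.normal(0, 1, 30), "flat": np.zeros(30)})
        report = preprocess.interarray_qc(m)
        assert report.samples_flagged.get("flat") == "zero variance"


class TestCollapseProbes:
    @pytest.fixture
    def matrix(self):
        rng = np.random.default_rng(0)
        return pd.DataFrame(rng.normal(8, 1, (4, 3)),
                            index=pd.Index(["p1", "p2", "p3", "p4"], name="gene_id"),
                            columns=["s1", "s2", "s3"])

    def test_one_to_one_is_rename(self, matrix):
        gm = pd.DataFrame({"probe_id": ["p1", "p2", "p3", "p4"],
                           "gene_id": ["gA", "gB", "gC", "gD"]})
        out = preprocess.collapse_probes(matrix, gm, seed=0)
        assert list(out.index) == ["gA", "gB", "gC", "gD"]
        np.testing.assert_array_equal(out.to_numpy(), matrix.to_numpy())

    def test_same_seed_same_choices(self, matrix):
        gm = pd.DataFrame({"probe_id": ["p1", "p1", "p2", "p3", "p4"],
                           "gene_id": ["gA", "gB", "gC", "gD", "gE"]})
        a = preprocess.collapse_probes(matrix, gm, seed=7)
        b = preprocess.collapse_probes(matrix, gm, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_list_mode_drops_multiprobe_genes(self, matrix):
        gm = pd.DataFrame({"probe_id": ["p1", "p2", "p3", "p4"],
                           "gene_id": ["gA", "gA", "gB", "gC"]})
        out = preprocess.collapse_probes(matrix, gm, seed=0, mode="list")
        assert "gA" not in out.index
        assert set(out.index) == {"gB", "gC"}

    def test_matrix_mode_keeps_max_mean_probe(self, matrix):
        gm = pd.DataFrame({"probe_id": ["p1", "p2", "p3", "p4"],
                           "gene_id": ["gA", "gA", "gB", "gC"]})
        out = preprocess.collapse_probes(matrix, gm, seed=0, mode="matrix")
        winner = "p1" if matrix.loc["p1"].mean() >= matrix.loc["p2"].mean() else "p2"
        np.testing.assert_array_equal(out.loc["gA"].to_numpy(),
                                      matrix.loc[winner].to_numpy())

    def test_empty_coverage_errors(self, matrix):
        gm = pd.DataFrame({"probe_id": ["x1"], "gene_id": ["gA"]})
        with pytest.raises(ValueError):
            preprocess.collapse_probes(matrix, gm, seed=0)
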