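import numpy as np
import pytest

from gnmfclust import (
    CopyNumberMatrix,
    Segment,
    aberration_burden,
    call_aberrations,
    read_matrix,
    read_seg_tables,
    reduce_dimensions,
    write_matrix,
)
from gnmfclust.data_model import CopyNumberError

from conftest import make_grid


class TestMatrixIO:
    def test_round_trip_preserves_values_and_metadata(self, tiny_matrix, tmp_path):
        path = tmp_path / "m.tsv"
        write_matrix(tiny_matrix, path)
        back = read_matrix(path)
        np.testing.assert_allclose(back.values, tiny_matrix.values, rtol=1e-5)
        assert back.sample_ids == tiny_matrix.sample_ids
        assert back.segments == tiny_matrix.segments

    def test_values_at_or_below_floor_are_clamped(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "chrom\tstart\tend\tn_probes\ts1\ts2\n"
            "chr1\t1\t1000\t100\t0.0\t2.0\n"
        )
        m = read_matrix(path, floor=0.01)
        assert m.values[0, 0] == 0.01
        assert m.values[0, 1] == 2.0

    def test_duplicate_sample_column_names_error(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "chrom\tstart\tend\tn_probes\tsA\tsA\n"
            "chr1\t1\t1000\t100\t2.0\t2.0\n"
        )
        with pytest.raises(CopyNumberError, match="sA"):
            read_matrix(path)

    def test_non_numeric_cell_errors(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "chrom\tstart\tend\tn_probes\ts1\n"
            "chr1\t1\t1000\t100\toops\n"
        )
        with pytest.raises(CopyNumberError):
            read_matrix(path)

    def test_overlapping_segments_rejected(self):
        segs = [Segment("chr1", 0, 1000, 100), Segment("chr1", 500, 1500, 100)]
        with pytest.raises(CopyNumberError, match="overlap"):
            CopyNumberMatrix(np.full((2, 2), 2.0), segs, ["a", "b"])


class TestSegTables:
    def _write(self, tmp_path, name, rows):
        path = tmp_path / name
        lines = ["sample\tchrom\tstart\tend\tn_probes\tmean_cn"]
        lines += ["\t".join(str(x) for x in r) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_identity_projection(self, tmp_path):
        grid = make_grid(2)
        p = self._write(tmp_path, "s1.seg", [
            ("s1", "chr1", 1, 1000, 100, 2.5),
            ("s1", "chr1", 1001, 2000, 100, 1.3),
        ])
        m = read_seg_tables([p], grid)
        np.testing.assert_allclose(m.values[:, 0], [2.5, 1.3])

    def test_equal_weight_overlap_averages(self, tmp_path):
        # one 1000bp grid segment covered by two 500bp segments: values 1, 3
        grid = make_grid(1)
        p = self._write(tmp_path, "s1.seg", [
            ("s1", "chr1", 1, 500, 50, 1.0),
            ("s1", "chr1", 501, 1000, 50, 3.0),
        ])
        m = read_seg_tables([p], grid)
        assert m.values[0, 0] == pytest.approx(2.0)

    def test_missing_coverage_fills_diploid(self, tmp_path, caplog):
        grid = make_grid(1) + make_grid(1, chrom="chr22")
        p = self._write(tmp_path, "s1.seg", [("s1", "chr1", 1, 1000, 100, 3.0)])
        with caplog.at_level("WARNING"):
            m = read_seg_tables([p], grid)
        assert m.values[1, 0] == 2.0
        assert any("coverage" in r.message for r in caplog.records)

    def test_unknown_chromosome_errors(self, tmp_path):
        grid = make_grid(1)
        p = self._write(tmp_path, "s1.seg", [("s1", "chrX", 1, 1000, 100, 2.0)])
        with pytest.raises(CopyNumberError, match="chrX"):
            read_seg_tables([p], grid)


class TestAberrationCalls:
    @pytest.mark.parametrize("value,state", [
        (1.5, "loss"), (2.7, "gain"), (2.0, "normal"),
        (1.65, "normal"), (2.65, "normal"),  # strict boundaries
    ])
    def test_threshold_calls(self, value, state):
        m = CopyNumberMatrix(np.array([[value]]), make_grid(1), ["s1"])
        assert call_aberrations(m)[0].state == state

    def test_all_diploid_yields_no_aberrations(self):
        m = CopyNumberMatrix(np.full((5, 4), 2.0), make_grid(5),
                             [f"s{i}" for i in range(4)])
        assert all(c.state == "normal" for c in call_aberrations(m))

    def test_reordering_permutes_calls(self, rng):
        vals = rng.uniform(1.0, 3.5, (6, 4))
        ids = ["a", "b", "c", "d"]
        m = CopyNumberMatrix(vals, make_grid(6), ids)
        perm = [2, 0, 3, 1]
        m2 = m.select_samples([ids[i] for i in perm])
        by_key = {(c.sample_id, c.segment_index): c.state for c in call_aberrations(m)}
        for c in call_aberrations(m2):
            assert by_key[(c.sample_id, c.segment_index)] == c.state

    def test_burden_matches_direct_recount(self, rng):
        vals = rng.uniform(1.0, 3.5, (20, 6))
        m = CopyNumberMatrix(vals, make_grid(20), [f"s{i}" for i in range(6)])
        burden = aberration_burden(call_aberrations(m))
        for j, sid in enumerate(m.sample_ids):
            expected = int(np.sum((vals[:, j] < 1.65) | (vals[:, j] > 2.65)))
            assert burden[sid] == expected


class TestReduceDimensions:
    def test_zero_threshold_is_identity(self, tiny_matrix):
        out = reduce_dimensions(tiny_matrix, 0.0)
        np.testing.assert_array_equal(out.values, tiny_matrix.values)

    def test_constant_segment_dropped(self, rng):
        vals = rng.uniform(1.5, 3.0, (4, 5))
        vals[2, :] = 2.0  # constant
        m = CopyNumberMatrix(vals, make_grid(4), [f"s{i}" for i in range(5)])
        out = reduce_dimensions(m, 0.1)
        assert out.n_segments == 3
        assert m.segments[2] not in out.segments

    def test_matches_brute_force_filter(self, rng):
        vals = rng.uniform(1.0, 3.0, (50, 10))
        m = CopyNumberMatrix(vals, make_grid(50), [f"s{i}" for i in range(10)])
        thr = 0.8
        out = reduce_dimensions(m, thr)
        expected = sum(
            1 for i in range(50) if vals[i].max() - vals[i].min() > thr
        )
        assert out.n_segments == expected

    def test_kept_segments_non_increasing_in_threshold(self, rng):
        vals = rng.uniform(1.0, 3.0, (30, 8))
        m = CopyNumberMatrix(vals, make_grid(30), [f"s{i}" for i in range(8)])
        counts = [reduce_dimensions(m, t).n_segments for t in (0.0, 0.3, 0.6, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_all_dropped_raises_with_advice(self):
        m = CopyNumberMatrix(np.full((3, 3), 2.0), make_grid(3), ["a", "b", "c"])
        with pytest.raises(CopyNumberError, match="min_range"):
            reduce_dimensions(m, 0.5)
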