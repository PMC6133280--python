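import numpy as np
import pytest

from spacc import (FormatError, ProbeMatrix, RegionPartition, RunConfig,
                   ValidationError, read_probe_matrix, read_regions,
                   region_means, write_probe_matrix, write_regions)

TSV = """chrom\tpos\tprobe_id\ts1\ts2
chr1\t100\tp1\t0.2\t0.1
chr1\t200\tp2\t0.4\tNA
chr1\t350\tp3\t0.6\t0.5
"""


def test_read_sets_missing_mask_from_na(tmp_path):
    path = tmp_path / "m.tsv"
    path.write_text(TSV)
    pm = read_probe_matrix(path, data_kind="methylation")
    assert pm.n == 2 and pm.p == 3
    assert pm.missing_mask.sum() == 1
    assert pm.missing_mask[1, 1]
    assert np.isnan(pm.values[1, 1])
    assert list(pm.subject_id) == ["s1", "s2"]


def test_read_sorts_probes_order_invariance(tmp_path):
    shuffled = ("chrom\tpos\tprobe_id\ts1\ts2\n"
                "chr1\t350\tp3\t0.6\t0.5\n"
                "chr1\t100\tp1\t0.2\t0.1\n"
                "chr1\t200\tp2\t0.4\tNA\n")
    a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
    a.write_text(TSV)
    b.write_text(shuffled)
    pa, pb = read_probe_matrix(a), read_probe_matrix(b)
    np.testing.assert_array_equal(pa.pos, pb.pos)
    np.testing.assert_array_equal(pa.probe_id, pb.probe_id)
    np.testing.assert_array_equal(pa.missing_mask, pb.missing_mask)
    np.testing.assert_allclose(pa.values[~pa.missing_mask],
                               pb.values[~pb.missing_mask])


@pytest.mark.parametrize("bad, err", [
    ("chrom\tpos\tprobe_id\ts1\nchr1\t100\tp1\t0.2\nchr1\t100\tp2\t0.3\n",
     ValidationError),                                   # duplicate (chrom,pos)
    ("chr\tpos\tprobe_id\ts1\nchr1\t100\tp1\t0.2\n", FormatError),  # header
    ("chrom\tpos\tprobe_id\ts1\nchr1\t100\tp1\tabc\n", FormatError),  # value
])
def test_read_rejects_malformed_input(tmp_path, bad, err):
    path = tmp_path / "bad.tsv"
    path.write_text(bad)
    with pytest.raises(err):
        read_probe_matrix(path)


def test_round_trip_preserves_everything(tmp_path, rng):
    values = rng.normal(size=(4, 7))
    values[rng.random((4, 7)) < 0.2] = np.nan
    pm = ProbeMatrix.from_arrays(
        values=values,
        chrom=["chr1"] * 3 + ["chr2"] * 4,
        pos=[10, 50, 90, 20, 40, 80, 160])
    path = tmp_path / "rt.tsv"
    write_probe_matrix(pm, path)
    back = read_probe_matrix(path)
    np.testing.assert_array_equal(pm.missing_mask, back.missing_mask)
    np.testing.assert_array_equal(pm.pos, back.pos)
    np.testing.assert_array_equal(pm.chrom, back.chrom)
    obs = ~pm.missing_mask
    np.testing.assert_allclose(pm.values[obs], back.values[obs], rtol=1e-9)


def test_methylation_range_validated():
    with pytest.raises(ValidationError):
        ProbeMatrix.from_arrays(values=np.array([[0.2, 1.4]]),
                                chrom=["chr1"] * 2, pos=[1, 2],
                                data_kind="methylation")


class TestRegionPartition:
    def test_labels_must_be_contiguous_runs(self):
        with pytest.raises(ValidationError):
            RegionPartition(assignment=[0, 1, 0])

    def test_regions_never_span_chromosomes(self):
        part = RegionPartition(assignment=[0, 0, 1, 1])
        with pytest.raises(ValidationError):
            part.attach_chrom(np.array(["chr1", "chr1", "chr1", "chr2"],
                                       dtype=object))

    def test_concatenate_relabels(self):
        a = RegionPartition(assignment=[0, 0, 1])
        b = RegionPartition(assignment=[0, 1, 1])
        c = RegionPartition.concatenate([a, b])
        np.testing.assert_array_equal(c.assignment, [0, 0, 1, 2, 3, 3])
        assert c.n_regions == 4


class TestBedOutput:
    def test_coordinate_conventions(self, tmp_path):
        pm = ProbeMatrix.from_arrays(values=np.zeros((1, 2)),
                                     chrom=["chr17"] * 2, pos=[100, 200])
        part = RegionPartition(assignment=[0, 0])
        part.attach_chrom(pm.chrom)
        out = tmp_path / "r.bed"
        write_regions(part, pm, out)
        assert out.read_text() == "chr17\t99\t200\tregion_1\t2\n"

    def test_singleton_regions_have_width_one(self, tmp_path):
        p = 4
        pm = ProbeMatrix.from_arrays(values=np.zeros((1, p)),
                                     chrom=["chr1"] * p,
                                     pos=[10, 20, 30, 40])
        part = RegionPartition(assignment=np.arange(p))
        part.attach_chrom(pm.chrom)
        out = tmp_path / "s.bed"
        write_regions(part, pm, out)
        lines = out.read_text().splitlines()
        assert len(lines) == p
        for ln in lines:
            chrom, start, end, name, count = ln.split("\t")
            assert int(end) - int(start) == 1 and count == "1"

    def test_no_interval_spans_chromosomes_and_widths_bounded(self, tmp_path, rng):
        chrom = ["chr1"] * 5 + ["chr2"] * 4
        pos = [10, 30, 60, 100, 150, 5, 25, 70, 90]
        pm = ProbeMatrix.from_arrays(values=rng.normal(size=(2, 9)),
                                     chrom=chrom, pos=pos)
        part = RegionPartition(assignment=[0, 0, 1, 1, 1, 2, 2, 3, 3])
        part.attach_chrom(pm.chrom)
        out = tmp_path / "t.bed"
        write_regions(part, pm, out)
        span = {"chr1": (10, 150), "chr2": (5, 90)}
        widths = {"chr1": 0, "chr2": 0}
        for ln in out.read_text().splitlines():
            c, s, e = ln.split("\t")[:3]
            lo, hi = span[c]
            assert lo - 1 <= int(s) < int(e) <= hi
            widths[c] += int(e) - int(s)
        for c, (lo, hi) in span.items():
            assert widths[c] <= hi - (lo - 1)

    def test_bed_round_trip(self, tmp_path, rng):
        pm = ProbeMatrix.from_arrays(values=rng.normal(size=(1, 6)),
                                     chrom=["chr1"] * 6,
                                     pos=[10, 20, 35, 50, 70, 90])
        part = RegionPartition(assignment=[0, 0, 1, 1, 1, 2])
        part.attach_chrom(pm.chrom)
        out = tmp_path / "rt.bed"
        write_regions(part, pm, out)
        back = read_regions(out, pm)
        np.testing.assert_array_equal(back.assignment, part.assignment)

    def test_length_mismatch_rejected(self, tmp_path):
        pm = ProbeMatrix.from_arrays(values=np.zeros((1, 3)),
                                     chrom=["chr1"] * 3, pos=[1, 2, 3])
        part = RegionPartition(assignment=[0, 0])
        with pytest.raises(ValidationError):
            write_regions(part, pm, tmp_path / "x.bed")


class TestRegionMeans:
    def test_singleton_and_two_point_means(self):
        pm = ProbeMatrix.from_arrays(values=np.array([[0.2, 0.4, 0.9]]),
                                     chrom=["chr1"] * 3, pos=[1, 2, 3])
        part = RegionPartition(assignment=[0, 0, 1])
        m = region_means(pm, part)
        np.testing.assert_allclose(m, [[0.3, 0.9]])

    def test_mean_skips_missing(self):
        pm = ProbeMatrix.from_arrays(
            values=np.array([[0.1, np.nan, 0.5]]),
            chrom=["chr1"] * 3, pos=[1, 2, 3])
        part = RegionPartition(assignment=[0, 0, 0])
        np.testing.assert_allclose(region_means(pm, part), [[0.3]])

    def test_all_missing_cell_flagged(self):
        pm = ProbeMatrix.from_arrays(
            values=np.array([[np.nan, np.nan, 0.5],
                             [0.2, 0.4, 0.6]]),
            chrom=["chr1"] * 3, pos=[1, 2, 3])
        part = RegionPartition(assignment=[0, 0, 1])
        m = region_means(pm, part)
        assert np.isnan(m[0, 0]) and m[0, 1] == 0.5
        np.testing.assert_allclose(m[1], [0.3, 0.6])


class TestRunConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValidationError):
            RunConfig(k_folds=1)
        with pytest.raises(ValidationError):
            RunConfig(gamma=-1.0)
        with pytest.raises(ValidationError):
            RunConfig(gamma_grid=[1.0, 0.5])

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("sigma_decay: 1.0e-5\nk_folds: 3\nseed: 7\n")
        cfg = RunConfig.from_yaml(path)
        assert cfg.sigma_decay == 1e-5
        assert cfg.k_folds == 3 and cfg.seed == 7
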