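"""Coverage binning, library-size correction, ratio scan and CNV calling."""

import numpy as np
import pandas as pd
import pytest

from depthratio import coverage, ratio
from depthratio import simulate as sim
from depthratio.coverage import CoverageTrack


def _track(sample, bins, bin_size=1000):
    return CoverageTrack(sample_id=sample, bin_size=bin_size,
                         bins={k: np.asarray(v, dtype=float) for k, v in bins.items()})


# --- binning -----------------------------------------------------------------


def test_bedgraph_overlap_weighted_binning(tmp_path):
    bg = tmp_path / "x.bedgraph"
    bg.write_text("chr1\t0\t500\t4\nchr1\t500\t1500\t8\n")
    track = coverage.bin_bedgraph(bg, {"chr1": 2000}, bin_size=1000)
    # [0,500)*4 + [500,1000)*8 = 6000 ; [1000,1500)*8 = 4000
    assert np.allclose(track.bins["chr1"], [6000, 4000])


def test_bedgraph_unknown_scaffold_listed(tmp_path):
    bg = tmp_path / "x.bedgraph"
    bg.write_text("chrX\t0\t100\t1\n")
    with pytest.raises(ValueError, match="chrX"):
        coverage.bin_bedgraph(bg, {"chr1": 2000}, bin_size=1000)


def test_partial_last_bin_keeps_true_width(tmp_path):
    bg = tmp_path / "x.bedgraph"
    bg.write_text("chr1\t0\t1500\t2\n")
    track = coverage.bin_bedgraph(bg, {"chr1": 1500}, bin_size=1000)
    starts, ends = track.bin_bounds("chr1")
    assert ends[-1] == 1500
    assert np.allclose(track.bins["chr1"], [2000, 1000])


SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:3000\n"


def _sam_line(name, pos, cigar, mapq=60, seq_len=100):
    seq = "A" * seq_len
    return f"{name}\t0\tchr1\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t*\n"


def test_sam_read_depth_summed_per_bin(tmp_path):
    samf = tmp_path / "t.sam"
    samf.write_text(SAM_HEADER + _sam_line("r1", 101, "100M"))
    track = coverage.bin_coverage(samf, bin_size=1000)
    assert track.bins["chr1"].tolist() == [100.0, 0.0, 0.0]


def test_sam_read_spanning_bins_and_mapq_filter(tmp_path):
    samf = tmp_path / "t.sam"
    samf.write_text(
        SAM_HEADER
        + _sam_line("r1", 951, "100M")          # 50 bp in bin 0, 50 in bin 1
        + _sam_line("r2", 1, "100M", mapq=5)    # dropped by MAPQ filter
    )
    track = coverage.bin_coverage(samf, bin_size=1000, min_mapq=20)
    assert track.bins["chr1"].tolist() == [50.0, 50.0, 0.0]


def test_uniform_depth_tiles_bins(tmp_path):
    # 30 stacked reads of 100 bp tiling [0,3000) at depth 1 each position
    lines = [
        _sam_line(f"r{i}_{j}", 1 + j * 100, "100M")
        for i in range(1) for j in range(30)
    ]
    samf = tmp_path / "t.sam"
    samf.write_text(SAM_HEADER + "".join(sorted(lines)))
    track = coverage.bin_coverage(samf, bin_size=1000)
    assert track.bins["chr1"].tolist() == [1000.0, 1000.0, 1000.0]


# --- library scaling ---------------------------------------------------------


def test_identical_tracks_scale_one():
    t = _track("a", {"chr1": [10, 20, 30]})
    for mode in ("totals", "median-recenter"):
        assert ratio.library_scale(t, t, mode=mode) == pytest.approx(1.0)


def test_doubled_comparison_rescales_to_half():
    e = _track("e", {"chr1": np.arange(1, 101)})
    a = _track("a", {"chr1": 2 * np.arange(1, 101)})
    for mode in ("totals", "median-recenter"):
        s = ratio.library_scale(e, a, mode=mode)
        assert s == pytest.approx(0.5)
        df = ratio.ratio_scan(e, a, s=s, min_combined=0)
        assert np.allclose(df["r"], 0.5)


def test_scale_modes_agree_on_mostly_neutral_simulation():
    p = sim.SimParams(n_autosomes=5, n_z_scaffolds=0, scaffold_length=400_000,
                      library_scale_comparison=1.7,
                      cnv_segments=[("autosome_1", 0, 20_000, 2, 4)], seed=13)
    truth = sim.make_truth(p)
    tm = sim.simulate_coverage(p, truth, "male")
    tf = sim.simulate_coverage(p, truth, "female")
    s_tot = ratio.library_scale(tm, tf, mode="totals")
    s_med = ratio.library_scale(tm, tf, mode="median-recenter")
    # doubled CNV on 1% of bins shifts the totals by ~1%: modes agree within 2%
    assert s_med == pytest.approx(s_tot, rel=0.02)
    assert s_med == pytest.approx(1 / 1.7, rel=0.02)


def test_zero_total_errors():
    z = _track("z", {"chr1": [0, 0]})
    t = _track("t", {"chr1": [1, 1]})
    with pytest.raises(ValueError):
        ratio.library_scale(t, z, mode="totals")


# --- ratio scan --------------------------------------------------------------


def test_ratio_values_and_masking():
    e = _track("e", {"chr1": [10, 10, 0]})
    a = _track("a", {"chr1": [10, 20, 0]})
    df = ratio.ratio_scan(e, a, s=1.0, min_combined=10)
    assert df.loc[0, "r"] == pytest.approx(0.5)
    assert df.loc[1, "r"] == pytest.approx(1 / 3)
    assert bool(df.loc[2, "masked"]) is True
    assert np.isnan(df.loc[2, "r"])


def test_swap_symmetry():
    rng = np.random.default_rng(4)
    e = _track("e", {"c": rng.poisson(30_000, 500).astype(float)})
    a = _track("a", {"c": rng.poisson(60_000, 500).astype(float)})
    s = 1.3
    fwd = ratio.ratio_scan(e, a, s=s)
    rev = ratio.ratio_scan(a, e, s=1 / s)
    assert np.allclose(fwd["r"], 1 - rev["r"])
    segs_fwd = ratio.call_cnv(fwd)
    segs_rev = ratio.call_cnv(rev)
    flip = {"comparison_gain": "comparison_loss", "comparison_loss": "comparison_gain"}
    assert [(x.scaffold, x.start, x.end, flip[x.direction]) for x in segs_fwd] == [
        (x.scaffold, x.start, x.end, x.direction) for x in segs_rev
    ]


def test_identical_tracks_all_half_and_no_calls(small_tracks):
    male, _ = small_tracks
    df = ratio.ratio_scan(male, male, s=1.0)
    defined = df[~df["masked"]]
    assert np.allclose(defined["r"], 0.5)
    assert ratio.call_cnv(df) == []


# --- CNV calling -------------------------------------------------------------


def _ratio_frame(rs, masked=None):
    n = len(rs)
    return pd.DataFrame(
        {
            "scaffold": "c",
            "start": np.arange(n) * 1000,
            "end": (np.arange(n) + 1) * 1000,
            "e": 1000.0,
            "a_corrected": 1000.0,
            "r": rs,
            "masked": masked if masked is not None else [False] * n,
        }
    )


def test_short_runs_dropped_and_gaps_bridged():
    rs = [0.5] * 5 + [0.33] * 3 + [0.5] * 5          # 3 deviant bins < min_bins
    assert ratio.call_cnv(_ratio_frame(rs)) == []
    rs = [0.5] * 3 + [0.33] * 4 + [0.5] * 2 + [0.33] * 4 + [0.5] * 3
    segs = ratio.call_cnv(_ratio_frame(rs))          # 8 deviant bins across a 2-gap
    assert len(segs) == 1
    seg = segs[0]
    assert (seg.start, seg.end, seg.n_bins, seg.direction) == (
        3000, 13_000, 8, "comparison_gain"
    )


def test_fold_from_mean_ratio():
    segs = ratio.call_cnv(_ratio_frame([1 / 3] * 8))
    assert len(segs) == 1
    assert segs[0].fold == pytest.approx(2.0)
    segs = ratio.call_cnv(_ratio_frame([2 / 3] * 8))
    assert segs[0].direction == "comparison_loss"
    assert segs[0].fold == pytest.approx(0.5)


def test_planted_duplication_recovered_within_two_bins(small_params, small_tracks):
    male, female = small_tracks
    s = ratio.library_scale(male, female)
    df = ratio.ratio_scan(male, female, s=s)
    auto = df[df["scaffold"].str.startswith("autosome")]
    segs = [x for x in ratio.call_cnv(auto) if x.direction == "comparison_gain"]
    assert len(segs) == 1
    seg = segs[0]
    truth_seg = small_params.cnv_segments[0]
    b = small_params.bin_size
    assert abs(seg.start - truth_seg.start) <= 2 * b
    assert abs(seg.end - truth_seg.end) <= 2 * b
    assert seg.mean_r == pytest.approx(1 / 3, abs=0.02)


def test_bad_thresholds_rejected():
    with pytest.raises(ValueError):
        ratio.call_cnv(_ratio_frame([0.5]), low_thr=0.6, high_thr=0.7)


def test_ratio_and_bed_roundtrip(tmp_path, small_tracks):
    male, female = small_tracks
    df = ratio.ratio_scan(male, female, s=1.0)
    out = tmp_path / "ratios.tsv"
    ratio.write_ratios_tsv(df, out)
    back = pd.read_csv(out, sep="\t")
    assert len(back) == len(df)
    segs = ratio.call_cnv(back)
    bed = tmp_path / "cnv.bed"
    ratio.write_cnv_bed(segs, bed)
    lines = bed.read_text().strip().splitlines()
    assert len(lines) == len(segs)
    assert all(len(l.split("\t")) == 8 for l in lines)
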