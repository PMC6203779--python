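"""Interval algebra against per-base set oracles, parsers against round trips."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from divtx import genomic_io as gio


# ---------------------------------------------------------------------------
# core types


def test_interval_validation():
    with pytest.raises(ValueError):
        gio.GenomicInterval("chr1", 10, 10)
    with pytest.raises(ValueError):
        gio.GenomicInterval("chr1", -1, 5)
    with pytest.raises(ValueError):
        gio.GenomicInterval("", 0, 5)
    with pytest.raises(ValueError):
        gio.GenomicInterval("chr1", 0, 5, strand="x")
    assert gio.GenomicInterval("chr1", 3, 9).width == 6


def test_interval_overlaps():
    a = gio.GenomicInterval("chr1", 10, 20)
    assert a.overlaps(gio.GenomicInterval("chr1", 19, 25))
    assert not a.overlaps(gio.GenomicInterval("chr1", 20, 25))  # half-open
    assert not a.overlaps(gio.GenomicInterval("chr2", 10, 20))


def test_peak_validation():
    iv = gio.GenomicInterval("chr1", 100, 200)
    with pytest.raises(ValueError):
        gio.Peak(iv, summit=100)  # summit is an offset within the interval
    with pytest.raises(ValueError):
        gio.Peak(iv, score=-1.0)
    assert gio.Peak(iv, summit=0).summit == 0


def test_downstream_window_orientation():
    iv = gio.GenomicInterval("chr1", 1000, 1200)
    plus = gio.downstream_window(iv, "+", 300)
    assert (plus.start, plus.end) == (1200, 1500)
    minus = gio.downstream_window(iv, "-", 300)
    assert (minus.start, minus.end) == (700, 1000)
    with pytest.raises(ValueError):
        gio.downstream_window(iv, ".", 300)
    with pytest.raises(ValueError):
        gio.downstream_window(iv, "+", 0)


def test_downstream_window_truncation():
    iv = gio.GenomicInterval("chr1", 100, 200)
    with pytest.warns(UserWarning, match="truncated"):
        win = gio.downstream_window(iv, "-", 300)
    assert (win.start, win.end) == (0, 100)
    with pytest.warns(UserWarning):
        win = gio.downstream_window(iv, "+", 300, chrom_length=250)
    assert (win.start, win.end) == (200, 250)
    iv0 = gio.GenomicInterval("chr1", 0, 50)
    with pytest.warns(UserWarning):
        assert gio.downstream_window(iv0, "-", 10) is None


# ---------------------------------------------------------------------------
# interval algebra vs per-base oracles


def test_extend_and_merge_matches_per_base_oracle():
    rng = np.random.default_rng(0)
    for _ in range(50):
        size = 10_000
        ext = int(rng.integers(0, 200))
        peaks, cov = [], np.zeros(size, dtype=bool)
        for _ in range(int(rng.integers(1, 30))):
            s = int(rng.integers(0, size - 400))
            w = int(rng.integers(1, 400))
            peaks.append(gio.Peak(gio.GenomicInterval("c", s, s + w)))
            cov[max(0, s - ext) : min(size, s + w + ext)] = True
        merged = gio.extend_and_merge(peaks, ext, {"c": size})
        got = np.zeros(size, dtype=bool)
        for m in merged:
            assert not got[m.start : m.end].any(), "merged output overlaps itself"
            got[m.start : m.end] = True
        assert np.array_equal(got, cov)


def test_subtract_intervals_matches_per_base_oracle():
    rng = np.random.default_rng(1)
    for _ in range(50):
        size = 5_000
        t0 = int(rng.integers(0, size - 1000))
        t1 = t0 + int(rng.integers(1, 1000))
        target = gio.GenomicInterval("c", t0, t1)
        others, cov = [], np.zeros(size, dtype=bool)
        for _ in range(int(rng.integers(0, 10))):
            s = int(rng.integers(0, size - 300))
            e = s + int(rng.integers(1, 300))
            others.append(gio.GenomicInterval("c", s, e))
            cov[s:e] = True
        pieces = gio.subtract_intervals(target, others)
        got = np.zeros(size, dtype=bool)
        for p in pieces:
            assert t0 <= p.start < p.end <= t1
            got[p.start : p.end] = True
        want = np.zeros(size, dtype=bool)
        want[t0:t1] = True
        want &= ~cov
        assert np.array_equal(got, want)


def test_subtract_ignores_other_chromosomes():
    target = gio.GenomicInterval("chr1", 0, 100)
    out = gio.subtract_intervals(target, [gio.GenomicInterval("chr2", 0, 100)])
    assert out == [target]


def test_filter_min_width_boundary():
    mk = lambda w: gio.Peak(gio.GenomicInterval("c", 0, w))
    kept = gio.filter_min_width([mk(50), mk(51)], min_width=50)
    assert [p.width for p in kept] == [51]


# ---------------------------------------------------------------------------
# BED I/O


def test_bed_round_trip(tmp_path):
    peaks = [
        gio.Peak(gio.GenomicInterval("chr1", 10, 20, "+"), name="a", score=3.5),
        gio.Peak(gio.GenomicInterval("chr2", 5, 9, "-"), name="b"),
    ]
    path = str(tmp_path / "x.bed")
    gio.write_bed(peaks, path)
    back = gio.read_bed(path)
    assert [(p.chrom, p.start, p.end, p.name, p.score, p.interval.strand) for p in back] == [
        (p.chrom, p.start, p.end, p.name, p.score, p.interval.strand) for p in peaks
    ]


@pytest.mark.parametrize(
    "line,msg",
    [
        ("chr1\t10", "expected >=3"),
        ("chr1\tten\t20", "non-integer"),
        ("chr1\t20\t10", "invalid interval"),
        ("chr1\t10\t20\tname\tNaNx", "non-numeric score"),
    ],
)
def test_read_bed_errors_name_the_line(tmp_path, line, msg):
    path = tmp_path / "bad.bed"
    path.write_text("chr1\t1\t2\n" + line + "\n")
    with pytest.raises(gio.BedParseError, match=msg) as exc:
        gio.read_bed(str(path))
    assert ":2:" in str(exc.value)


def test_read_bed_skips_comments_and_sorts(tmp_path):
    path = tmp_path / "x.bed"
    path.write_text("# comment\ntrack name=x\nchr1\t50\t60\nchr1\t10\t20\n")
    peaks = gio.read_bed(str(path))
    assert [(p.start, p.end) for p in peaks] == [(10, 20), (50, 60)]


# ---------------------------------------------------------------------------
# annotation


def _cfg(d=200):
    return gio.AnnotationConfig(promoter_distance=d)


def test_annotate_promoter_single_strand():
    peak = gio.Peak(gio.GenomicInterval("chr1", 1000, 1300))
    out = gio.annotate_peaks([peak], [gio.TssSite("chr1", 1400, "+")], [], _cfg())
    assert out[0].annotation == gio.PROMOTER
    assert out[0].gene_strand == "+"


def test_annotate_distance_boundary():
    peak = gio.Peak(gio.GenomicInterval("chr1", 1000, 1300))
    # last base is 1299; a site 200 bp away is still a promoter, 201 is not
    at = gio.annotate_peaks([peak], [gio.TssSite("chr1", 1499, "-")], [], _cfg())
    assert at[0].annotation == gio.PROMOTER and at[0].gene_strand == "-"
    beyond = gio.annotate_peaks([peak], [gio.TssSite("chr1", 1500, "-")], [], _cfg())
    assert beyond[0].annotation == gio.INTERGENIC


def test_annotate_bidirectional_removed():
    peak = gio.Peak(gio.GenomicInterval("chr1", 1000, 1300))
    sites = [gio.TssSite("chr1", 950, "-"), gio.TssSite("chr1", 1350, "+")]
    out = gio.annotate_peaks([peak], sites, [], _cfg())
    assert out[0].annotation == gio.BIDIRECTIONAL
    assert out[0].gene_strand is None


def test_annotate_other_vs_intergenic():
    peak = gio.Peak(gio.GenomicInterval("chr1", 1000, 1300))
    body = gio.GenomicInterval("chr1", 1200, 5000)
    assert gio.annotate_peaks([peak], [], [body], _cfg())[0].annotation == gio.OTHER
    far = gio.GenomicInterval("chr1", 9000, 9500)
    assert gio.annotate_peaks([peak], [], [far], _cfg())[0].annotation == gio.INTERGENIC


# ---------------------------------------------------------------------------
# stranded 5'-end track


def test_track_counts_in_matches_dict():
    rng = np.random.default_rng(2)
    plus = {int(p): int(c) for p, c in zip(rng.integers(0, 1000, 50), rng.integers(1, 9, 50))}
    track = gio.StrandedTssTrack.from_dicts({"c": plus}, {"c": {}})
    got = track.counts_in("c", 100, 600, "+")
    want = np.zeros(500, dtype=np.int64)
    for p, c in plus.items():
        if 100 <= p < 600:
            want[p - 100] = c
    assert np.array_equal(got, want)
    assert track.counts_in("c", 0, 10, "-").sum() == 0
    assert track.counts_in("missing", 0, 10, "+").sum() == 0
    assert track.total("+") == sum(plus.values())
    assert track.total() == sum(plus.values())


def test_track_rejects_negative_counts():
    with pytest.raises(ValueError, match="negative"):
        gio.StrandedTssTrack.from_dicts({"c": {5: -1}}, {})


def test_stranded_bedgraph_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    plus = {int(p): int(c) for p, c in zip(rng.choice(2000, 80, replace=False), rng.integers(1, 20, 80))}
    minus = {int(p): int(c) for p, c in zip(rng.choice(2000, 40, replace=False), rng.integers(1, 20, 40))}
    track = gio.StrandedTssTrack.from_dicts({"c": plus}, {"c": minus})
    pp, pm = str(tmp_path / "p.bg"), str(tmp_path / "m.bg")
    gio.write_stranded_bedgraph(track, pp, pm)
    back = gio.read_stranded_bedgraph(pp, pm)
    assert np.array_equal(back.counts_in("c", 0, 2000, "+"), track.counts_in("c", 0, 2000, "+"))
    assert np.array_equal(back.counts_in("c", 0, 2000, "-"), track.counts_in("c", 0, 2000, "-"))


def test_bedgraph_ranged_rows_expand(tmp_path):
    p = tmp_path / "p.bg"
    p.write_text("chr1\t10\t13\t2\n")
    m = tmp_path / "m.bg"
    m.write_text("")
    track = gio.read_stranded_bedgraph(str(p), str(m))
    assert np.array_equal(track.counts_in("chr1", 9, 14, "+"), [0, 2, 2, 2, 0])


@pytest.mark.parametrize(
    "text,msg",
    [
        ("chr1\t10\t13\t2\nchr1\t12\t14\t1\n", "overlapping or unsorted"),
        ("chr1\t10\t13\t-2\n", "negative count"),
        ("chr1\t10\t13\t1.5\n", "non-integer count"),
        ("chr1\t10\t13\n", "expected 4 fields"),
        ("chr1\t13\t10\t1\n", "invalid interval"),
    ],
)
def test_bedgraph_rejects_malformed(tmp_path, text, msg):
    p = tmp_path / "p.bg"
    p.write_text(text)
    m = tmp_path / "m.bg"
    m.write_text("")
    with pytest.raises(gio.BedParseError, match=msg):
        gio.read_stranded_bedgraph(str(p), str(m))


def test_dense_bedgraph_round_trip(tmp_path):
    rng = np.random.default_rng(4)
    sig = {"chr1": rng.integers(0, 5, 500).astype(float)}
    path = str(tmp_path / "d.bg")
    gio.write_bedgraph_dense(sig, path, step=1)
    back = gio.read_bedgraph_dense(path, {"chr1": 500})
    assert np.array_equal(back["chr1"], sig["chr1"])


def test_dense_bedgraph_step_binning(tmp_path):
    # constant within each 10 bp block, so the per-block mean is exact
    vals = np.repeat([1.0, 0.0, 3.0], 10)
    path = str(tmp_path / "d.bg")
    gio.write_bedgraph_dense({"chr1": vals}, path, step=10)
    back = gio.read_bedgraph_dense(path, {"chr1": 30})
    assert np.array_equal(back["chr1"], vals)


def test_dense_bedgraph_unknown_chrom(tmp_path):
    path = tmp_path / "d.bg"
    path.write_text("chrX\t0\t10\t1\n")
    with pytest.raises(gio.BedParseError, match="unknown chromosome"):
        gio.read_bedgraph_dense(str(path), {"chr1": 100})


# ---------------------------------------------------------------------------
# properties


@given(
    st.integers(min_value=0, max_value=10_000),
    st.integers(min_value=1, max_value=500),
    st.integers(min_value=1, max_value=500),
    st.sampled_from(["+", "-"]),
)
def test_downstream_window_is_adjacent_and_sized(start, width, size, strand):
    iv = gio.GenomicInterval("c", start, start + width)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        win = gio.downstream_window(iv, strand, size)
    if win is None:
        assert strand == "-" and start == 0
        return
    assert win.width <= size
    if strand == "+":
        assert win.start == iv.end
    else:
        assert win.end == iv.start
        assert win.start >= 0
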