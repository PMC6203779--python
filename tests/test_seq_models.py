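"""Core-promoter model, motif scan and k-mer/GC statistics against hand oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from divtx import genomic_io as gio
from divtx import seq_models as sm


def test_encode_and_reverse_complement():
    assert list(sm.encode("ACGTN")) == [0, 1, 2, 3, -1]
    assert list(sm.encode("acgt")) == [0, 1, 2, 3]
    assert sm.reverse_complement("ACGTN") == "NACGT"
    assert sm.reverse_complement(sm.reverse_complement("GATTACA")) == "GATTACA"


# ---------------------------------------------------------------------------
# core-promoter model


def test_train_core_model_counts_by_hand():
    # two length-3 windows: ACG and ACG -> deterministic transitions
    model = sm.train_core_model(["ACG", "ACG"], pseudocount=0.5, window_len=3)
    # first position: 2 A out of 2, pseudocount 0.5 -> (2.5)/(2+2) = 0.625
    assert model.first_pos[0] == pytest.approx(2.5 / 4.0)
    # transition A->C at position 1: (2+0.5)/(2+2) = 0.625
    assert model.trans[0, 0, 1] == pytest.approx(2.5 / 4.0)
    # background: A,C,G each twice among 6 bases
    assert model.background[0] == pytest.approx(2.5 / 8.0)
    assert model.n_training == 2


def test_train_core_model_drops_wrong_length_with_warning():
    with pytest.warns(UserWarning, match="length"):
        model = sm.train_core_model(["ACG", "ACGT", "ACG"], window_len=3)
    assert model.n_training == 2
    with pytest.raises(ValueError, match="training windows"):
        sm.train_core_model(["ACG"], window_len=3)
    with pytest.raises(ValueError, match="pseudocount"):
        sm.train_core_model(["ACG", "ACG"], pseudocount=0.0, window_len=3)


def test_score_window_hand_computed():
    model = sm.train_core_model(["ACG", "ACG"], pseudocount=0.5, window_len=3)
    log2 = math.log2
    bg = model.background
    want = (
        log2(model.first_pos[0]) - log2(bg[0])
        + log2(model.trans[0, 0, 1]) - log2(bg[1])
        + log2(model.trans[1, 1, 2]) - log2(bg[2])
    )
    assert sm.score_window(model, "ACG") == pytest.approx(want, abs=1e-12)
    with pytest.raises(ValueError, match="length"):
        sm.score_window(model, "ACGT")


def test_score_window_n_contributes_zero():
    model = sm.train_core_model(["ACG", "ACG", "TTT"], window_len=3)
    full = sm.score_window(model, "ACG")
    with_n = sm.score_window(model, "ANG")
    # the N position and the transition into/out of it drop out
    first_only = math.log2(model.first_pos[0]) - math.log2(model.background[0])
    assert with_n == pytest.approx(first_only, abs=1e-12)
    assert with_n != pytest.approx(full)
    assert sm.score_window(model, "NNN") == 0.0


def test_trained_windows_score_above_random():
    rng = np.random.default_rng(0)
    motif_windows = ["TATAAA" + "".join(rng.choice(list("ACGT"), 5)) for _ in range(40)]
    model = sm.train_core_model(motif_windows, window_len=11)
    rand = ["".join(rng.choice(list("ACGT"), 11)) for _ in range(40)]
    planted = np.mean([sm.score_window(model, w) for w in motif_windows])
    background = np.mean([sm.score_window(model, w) for w in rand])
    assert planted > background + 1.0


def test_extract_window_strand_symmetry_and_edges():
    seq = "AACGTTGCAA"
    plus = sm.extract_window(seq, 4, "+", flank=2)
    assert plus == seq[2:7]
    minus = sm.extract_window(seq, 4, "-", flank=2)
    assert minus == sm.reverse_complement(plus)
    assert sm.extract_window(seq, 1, "+", flank=2) is None
    assert sm.extract_window(seq, 8, "+", flank=2) is None


def test_aggregate_sequence_feature_hand_sum():
    model = sm.train_core_model(["ACG", "ACG", "TTT"], window_len=3)
    # model flank for this window length is 1; patch via direct calls
    chrom_seq = "AAACGTTTAA"
    track = gio.StrandedTssTrack.from_dicts({"c": {3: 2, 5: 1}}, {"c": {}})
    peak = gio.Peak(gio.GenomicInterval("c", 2, 8))
    # aggregate_sequence_feature uses WINDOW_FLANK=50, so read-bearing bases
    # near the start of a short sequence yield no window -> 0
    assert sm.aggregate_sequence_feature(model, track, peak, "+", chrom_seq) == 0.0
    long_seq = "A" * 60 + "ACG" + "A" * 60
    track2 = gio.StrandedTssTrack.from_dicts({"c": {61: 3}}, {"c": {}})
    peak2 = gio.Peak(gio.GenomicInterval("c", 55, 70))
    model101 = sm.train_core_model(
        [sm.extract_window(long_seq, 61, "+"), sm.extract_window(long_seq, 61, "+")]
    )
    want = sm.score_window(model101, sm.extract_window(long_seq, 61, "+")) / peak2.width
    got = sm.aggregate_sequence_feature(model101, track2, peak2, "+", long_seq)
    assert got == pytest.approx(want, abs=1e-12)
    assert sm.aggregate_sequence_feature(model101, track2, peak2, "-", long_seq) == 0.0


# ---------------------------------------------------------------------------
# motif scan


def test_scan_motif_hand_computed_log_odds():
    # single-base motif "T" against a 10-base background of 9 A and 1 T
    pwm = np.array([[0.0, 0.0, 0.0, 1.0]])
    seq = "AAAAATAAAA"
    scores = sm.scan_motif(pwm, seq, bg_window=100)
    assert scores.size == 10
    # bg(T) = (1 + 0.5) / (10 + 2) = 0.125 -> log2(1/0.125) = 3
    assert scores[5] == pytest.approx(3.0, abs=1e-12)
    # placements on A have pwm probability ~0 -> clipped to 0
    assert np.all(scores[np.arange(10) != 5] == 0.0)


def test_scan_motif_context_dependence():
    pwm = np.full((4, 4), 0.02)
    for i, b in enumerate("TATA"):
        pwm[i, "ACGT".index(b)] = 0.94
    at_context = "TA" * 30 + "TATA" + "TA" * 30
    gc_context = "GC" * 30 + "TATA" + "GC" * 30
    s_at = sm.scan_motif(pwm, at_context)[60]
    s_gc = sm.scan_motif(pwm, gc_context)[60]
    assert s_gc > s_at  # TATA stands out more against GC background


def test_scan_motif_shapes_and_validation():
    pwm = np.full((6, 4), 0.25)
    assert sm.scan_motif(pwm, "ACG").size == 0
    with pytest.raises(ValueError, match="shape"):
        sm.scan_motif(np.ones((4, 3)), "ACGTACGT")


def test_max_score_in_range_clamps():
    scores = np.arange(10.0)
    assert sm.max_score_in_range(scores, tss_offset=5, lo=-2, hi=2) == 7.0
    assert sm.max_score_in_range(scores, tss_offset=0, lo=-5, hi=-1) == 0.0
    assert sm.max_score_in_range(scores, tss_offset=9, lo=0, hi=5) == 9.0


# ---------------------------------------------------------------------------
# k-mer asymmetry


def test_kmer_counts_by_hand():
    df = sm.kmer_asymmetry(["ACGTAC"], ["ACGT"], k=2)
    d = df.set_index("kmer")
    assert d.loc["AC", "count_fwd"] == 2 and d.loc["AC", "count_rev"] == 1
    assert d.loc["CG", "count_fwd"] == 1 and d.loc["GT", "count_rev"] == 1
    assert d.loc["TA", "count_fwd"] == 1 and d.loc["TA", "count_rev"] == 0
    assert d.loc["TA", "ratio"] == pytest.approx(2.0)  # (1+1)/(0+1)
    assert d.loc["AC", "ratio"] == pytest.approx(1.5)
    assert int(d.loc["AC", "rank"]) < int(d.loc["GG", "rank"])


def test_kmer_skips_ambiguous_bases():
    df = sm.kmer_asymmetry(["ANA"], [""], k=2)
    assert df["count_fwd"].sum() == 0  # both 2-mers straddle the N


def test_kmer_to_string_round_trip():
    for v in [0, 1, 37, 4**6 - 1]:
        s = sm.kmer_to_string(v, 6)
        codes = sm.encode(s)
        back = int((codes * 4 ** np.arange(5, -1, -1)).sum())
        assert back == v


def test_planted_kmer_ranks_first():
    rng = np.random.default_rng(5)
    mk = lambda: "".join(rng.choice(list("ACGT"), 500))
    fwd, rev = [mk() for _ in range(50)], [mk() for _ in range(50)]
    fwd = [w[:100] + "GTGAGT" + w[106:] for w in fwd]  # planted forward only
    df = sm.kmer_asymmetry(fwd, rev, k=6)
    rank = int(df.set_index("kmer").loc["GTGAGT", "rank"])
    assert rank <= 5


# ---------------------------------------------------------------------------
# GC content and skew


def test_gc_closed_forms():
    prof = sm.gc_profiles(["GGGCAA"], window=4, step=1)
    assert prof.gc_percent == pytest.approx([100.0, 75.0, 50.0])
    assert prof.gc_skew == pytest.approx([0.5, 1 / 3, 0.0])
    poly_g = sm.gc_profiles(["G" * 100], window=50)
    assert np.all(poly_g.gc_skew == 1.0) and np.all(poly_g.gc_percent == 100.0)
    poly_c = sm.gc_profiles(["C" * 100], window=50)
    assert np.all(poly_c.gc_skew == -1.0)


def test_gc_zero_window_warns():
    with pytest.warns(UserWarning, match="undefined"):
        prof = sm.gc_profiles(["AAAATTTT"], window=4)
    assert np.all(prof.gc_skew == 0.0) and np.all(prof.gc_percent == 0.0)


def test_gc_validation():
    with pytest.raises(ValueError, match="no regions"):
        sm.gc_profiles([])
    with pytest.raises(ValueError, match="equal length"):
        sm.gc_profiles(["AAAA", "AAA"], window=2)
    with pytest.raises(ValueError, match="shorter"):
        sm.gc_profiles(["AAA"], window=4)


@given(st.lists(st.sampled_from("ACGTN"), min_size=60, max_size=120))
def test_gc_bounds(bases):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prof = sm.gc_profiles(["".join(bases)], window=50)
    assert np.all((prof.gc_percent >= 0) & (prof.gc_percent <= 100))
    assert np.all((prof.gc_skew >= -1) & (prof.gc_skew <= 1))
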