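"""Core-promoter sequence model, motif scanning and composition profiles.

The core-promoter model is a position-specific first-order (dinucleotide)
Markov chain over a 101-nt window centered on the TSS (offsets -50..+50),
scored as a log2 likelihood ratio against a zero-order background estimated
from the training windows.  High scores mark windows that look like the
initiation sites the model was trained on; midpoints between divergent TSS
pairs serve as negative controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genomic_io import Peak, StrandedTssTrack

BASES = "ACGT"
_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate(BASES):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

WINDOW_FLANK = 50  # window spans TSS-50 .. TSS+50 inclusive
WINDOW_LEN = 2 * WINDOW_FLANK + 1


def encode(seq: str) -> np.ndarray:
    """Map a sequence to integer codes 0..3 (A,C,G,T); anything else -> -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CorePromoterModel:
    """Positional first-order model over a TSS-centered window.

    ``first_pos`` is the marginal base distribution at the first window
    position (which has no preceding base inside the window); ``trans`` has
    shape (window_len - 1, 4, 4) giving P(base at p | base at p-1) for each
    interior position.  ``background`` is the zero-order composition of the
    training windows.
    """

    first_pos: np.ndarray
    trans: np.ndarray
    background: np.ndarray
    pseudocount: float
    n_training: int

    @property
    def window_len(self) -> int:
        return self.trans.shape[0] + 1


def train_core_model(
    sequences: list[str], pseudocount: float = 0.5, window_len: int = WINDOW_LEN
) -> CorePromoterModel:
    """Train the positional dinucleotide model on TSS-centered windows.

    Windows of the wrong length are rejected with a warning; N bases are
    excluded from the counts.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    kept: list[np.ndarray] = []
    for seq in sequences:
        if len(seq) != window_len:
            warnings.warn(
                f"dropping training window of length {len(seq)} != {window_len}",
                stacklevel=2,
            )
            continue
        kept.append(encode(seq))
    if len(kept) < 2:
        raise ValueError("need at least 2 valid training windows")
    mat = np.stack(kept)  # (n, L)

    first_counts = np.bincount(mat[:, 0][mat[:, 0] >= 0], minlength=4).astype(float)
    first_pos = (first_counts + pseudocount) / (first_counts.sum() + 4 * pseudocount)

    trans = np.zeros((window_len - 1, 4, 4))
    for p in range(1, window_len):
        prev, cur = mat[:, p - 1], mat[:, p]
        ok = (prev >= 0) & (cur >= 0)
        counts = np.zeros((4, 4))
        np.add.at(counts, (prev[ok], cur[ok]), 1.0)
        trans[p - 1] = (counts + pseudocount) / (
            counts.sum(axis=1, keepdims=True) + 4 * pseudocount
        )

    flat = mat[mat >= 0]
    bg_counts = np.bincount(flat, minlength=4).astype(float)
    background = (bg_counts + pseudocount) / (bg_counts.sum() + 4 * pseudocount)
    return CorePromoterModel(
        first_pos=first_pos,
        trans=trans,
        background=background,
        pseudocount=pseudocount,
        n_training=len(kept),
    )


def score_window(model: CorePromoterModel, sequence: str) -> float:
    """log2 likelihood ratio of one window under the model vs background.

    Positions holding N (or following an N) contribute 0.
    """
    codes = encode(sequence)
    if codes.size != model.window_len:
        raise ValueError(
            f"sequence length {codes.size} != model window {model.window_len}"
        )
    log_bg = np.log2(model.background)
    score = 0.0
    if codes[0] >= 0:
        score += float(np.log2(model.first_pos[codes[0]]) - log_bg[codes[0]])
    prev, cur = codes[:-1], codes[1:]
    ok = (prev >= 0) & (cur >= 0)
    idx = np.flatnonzero(ok)
    score += float(
        np.log2(model.trans[idx, prev[idx], cur[idx]]).sum() - log_bg[cur[idx]].sum()
    )
    return score


def extract_window(
    chrom_seq: str, center: int, strand: str, flank: int = WINDOW_FLANK
) -> str | None:
    """Strand-oriented window of ``2*flank+1`` nt centered on ``center``.

    Returns None when the window would cross a chromosome edge.
    """
    start, end = center - flank, center + flank + 1
    if start < 0 or end > len(chrom_seq):
        return None
    window = chrom_seq[start:end]
    return window if strand == "+" else reverse_complement(window)


def aggregate_sequence_feature(
    model: CorePromoterModel,
    track: StrandedTssTrack,
    peak: Peak,
    strand: str,
    chrom_seq: str,
) -> float:
    """Per-strand aggregate model score for a peak.

    The model is scored on windows around every base of the peak with at
    least one read 5'-end on ``strand``; the scores are summed and divided
    by the peak width.  Zero qualifying bases give 0.
    """
    counts = track.counts_in(peak.chrom, peak.start, peak.end, strand)
    positions = np.flatnonzero(counts) + peak.start
    total = 0.0
    for pos in positions.tolist():
        window = extract_window(chrom_seq, pos, strand)
        if window is not None:
            total += score_window(model, window)
    return total / peak.width


# ---------------------------------------------------------------------------
# Motif scanning


def scan_motif(
    pwm: np.ndarray, sequence: str, bg_window: int = 100
) -> np.ndarray:
    """Log-odds scan of a probability PWM against a local zero-order background.

    For each placement the background is the base composition of the
    ``bg_window`` bp window centered on the motif (clamped at sequence
    edges).  Scores below zero are set to zero.  Returns one score per
    placement (length len(sequence) - motif_len + 1; empty if the sequence
    is shorter than the motif).
    """
    pwm = np.asarray(pwm, dtype=np.float64)
    if pwm.ndim != 2 or pwm.shape[1] != 4:
        raise ValueError("pwm must have shape (motif_len, 4)")
    codes = encode(sequence)
    L, m = codes.size, pwm.shape[0]
    if L < m:
        return np.empty(0)
    # prefix base counts for O(1) window composition
    onehot = np.zeros((L + 1, 4))
    valid = codes >= 0
    onehot[1:][valid, codes[valid]] = 1.0
    prefix = np.cumsum(onehot, axis=0)

    log_pwm = np.log2(np.clip(pwm, 1e-12, None))
    scores = np.zeros(L - m + 1)
    half = bg_window // 2
    for i in range(L - m + 1):
        center = i + m // 2
        lo, hi = max(0, center - half), min(L, center + half)
        comp = prefix[hi] - prefix[lo]
        tot = comp.sum()
        if tot == 0:
            continue
        bg = (comp + 0.5) / (tot + 2.0)
        window = codes[i : i + m]
        ok = window >= 0
        if not ok.any():
            continue
        j = np.flatnonzero(ok)
        s = float(log_pwm[j, window[j]].sum() - np.log2(bg[window[j]]).sum())
        scores[i] = max(s, 0.0)
    return scores


def max_score_in_range(
    scores: np.ndarray, tss_offset: int, lo: int, hi: int
) -> float:
    """Maximum motif score for placements starting in [lo, hi] relative to a TSS.

    ``tss_offset`` is the index in ``scores`` whose placement starts at the
    TSS; conventional windows are -45..-25 for TATA and +20..+30 for DPE.
    """
    a = max(0, tss_offset + lo)
    b = min(scores.size, tss_offset + hi + 1)
    if a >= b:
        return 0.0
    return float(scores[a:b].max())


# ---------------------------------------------------------------------------
# k-mer strand asymmetry


def _count_kmers(windows: list[str], k: int) -> np.ndarray:
    counts = np.zeros(4**k, dtype=np.int64)
    weights = 4 ** np.arange(k - 1, -1, -1)
    for win in windows:
        codes = encode(win)
        if codes.size < k:
            continue
        # rolling base-4 value over every k-length substring
        view = np.lib.stride_tricks.sliding_window_view(codes, k)
        ok = (view >= 0).all(axis=1)
        vals = (view[ok] * weights).sum(axis=1)
        counts += np.bincount(vals, minlength=4**k)
    return counts


def kmer_to_string(value: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[value % 4])
        value //= 4
    return "".join(reversed(out))


def kmer_asymmetry(fwd_windows: list[str], rev_windows: list[str], k: int = 6):
    """Forward/reverse k-mer occurrence ratios over downstream windows.

    Overlapping occurrences are counted; the ratio uses a pseudocount of 1
    on both counts.  Returns a DataFrame with one row per k-mer, ranked by
    descending ratio (rank 1 = most forward-enriched).
    """
    import pandas as pd

    fwd = _count_kmers(fwd_windows, k)
    rev = _count_kmers(rev_windows, k)
    ratio = (fwd + 1.0) / (rev + 1.0)
    df = pd.DataFrame(
        {
            "kmer": [kmer_to_string(v, k) for v in range(4**k)],
            "count_fwd": fwd,
            "count_rev": rev,
            "ratio": ratio,
        }
    )
    df["rank"] = df["ratio"].rank(ascending=False, method="first").astype(int)
    return df.sort_values("rank").reset_index(drop=True)


# ---------------------------------------------------------------------------
# GC content and skew


@dataclass(frozen=True)
class GcProfile:
    """Positional mean GC% and GC-skew profiles across equal-length regions."""

    gc_percent: np.ndarray
    gc_skew: np.ndarray
    window: int
    step: int


def gc_profiles(
    region_seqs: list[str], window: int = 50, step: int = 1
) -> GcProfile:
    """Sliding-window GC% and skew (g-c)/(g+c), averaged across regions.

    Windows with no G or C get skew 0 (the ratio is undefined there); a
    warning is emitted once if that happens.
    """
    if not region_seqs:
        raise ValueError("no regions")
    lengths = {len(s) for s in region_seqs}
    if len(lengths) != 1:
        raise ValueError("regions must be equal length")
    L = lengths.pop()
    if L < window:
        raise ValueError("regions shorter than the window")
    n_pos = (L - window) // step + 1
    gc_acc = np.zeros(n_pos)
    skew_acc = np.zeros(n_pos)
    warned = False
    for seq in region_seqs:
        codes = encode(seq)
        is_g = (codes == 2).astype(np.float64)
        is_c = (codes == 1).astype(np.float64)
        g_pref = np.concatenate(([0.0], np.cumsum(is_g)))
        c_pref = np.concatenate(([0.0], np.cumsum(is_c)))
        starts = np.arange(n_pos) * step
        g = g_pref[starts + window] - g_pref[starts]
        c = c_pref[starts + window] - c_pref[starts]
        gc_acc += (g + c) / window * 100.0
        denom = g + c
        zero = denom == 0
        if zero.any() and not warned:
            warnings.warn("GC-skew undefined (g+c=0) in some windows; set to 0")
            warned = True
        skew = np.where(zero, 0.0, (g - c) / np.where(zero, 1.0, denom))
        skew_acc += skew
    n = len(region_seqs)
    return GcProfile(gc_percent=gc_acc / n, gc_skew=skew_acc / n, window=window, step=step)
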