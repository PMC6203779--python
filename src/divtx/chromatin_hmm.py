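"""Chromatin-state segmentation with a tied-transition Gaussian HMM.

Histone-mark signal is masked to the marks' own peak calls (signal inside
peaks, zero elsewhere), averaged into 10 bp bins, log-scaled, and split into
contiguous segments wherever at least one mark is non-zero.  A multivariate
(diagonal) Gaussian HMM is trained on segments of at least 500 bp by
Baum-Welch in which the transition matrix is held fixed at 0.9 on the
diagonal and 0.1/(n-1) elsewhere — only emissions and initial probabilities
are re-estimated.  Segmentation uses posterior decoding (per-bin argmax of
the forward-backward posterior), not Viterbi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genomic_io import GenomicInterval

VARIANCE_FLOOR = 1e-3


@dataclass
class Segment:
    """One contiguous run of peak-covered bins."""

    chrom: str
    start: int  # bp of the first bin
    X: np.ndarray  # (n_bins, n_marks) log-scaled signal

    @property
    def n_bins(self) -> int:
        return self.X.shape[0]


@dataclass
class ChromatinMatrix:
    segments: list[Segment]
    mark_names: list[str]
    bin_size: int = 10

    @property
    def n_bins(self) -> int:
        return sum(s.n_bins for s in self.segments)


def tied_transition_matrix(n_states: int, diagonal: float = 0.9) -> np.ndarray:
    if n_states < 2:
        raise ValueError("need at least 2 states")
    off = (1.0 - diagonal) / (n_states - 1)
    A = np.full((n_states, n_states), off)
    np.fill_diagonal(A, diagonal)
    return A


@dataclass
class HmmModel:
    """Gaussian HMM with a fixed tied transition matrix."""

    n_states: int
    transition: np.ndarray
    startprob: np.ndarray
    means: np.ndarray  # (n_states, n_marks)
    variances: np.ndarray  # (n_states, n_marks), diagonal covariance
    mark_names: list[str]
    loglik_history: list[float] = field(default_factory=list)


@dataclass
class StateTrack:
    """Posterior decoding of a ChromatinMatrix."""

    segments: list[Segment]
    states: list[np.ndarray]  # per-segment argmax labels
    posteriors: list[np.ndarray]  # per-segment (n_bins, n_states)
    bin_size: int
    n_states: int

    def lookup(self) -> dict[tuple[str, int], int]:
        """Map (chrom, bin index) -> state label for every decoded bin."""
        out: dict[tuple[str, int], int] = {}
        for seg, st in zip(self.segments, self.states):
            b0 = seg.start // self.bin_size
            for i, s in enumerate(st.tolist()):
                out[(seg.chrom, b0 + i)] = s
        return out


# ---------------------------------------------------------------------------
# Preprocessing


def preprocess(
    mark_signals: dict[str, dict[str, np.ndarray]],
    mark_peaks: dict[str, list[GenomicInterval]],
    bin_size: int = 10,
) -> ChromatinMatrix:
    """Peak-masked, log-scaled, binned mark matrix over contiguous segments.

    ``mark_signals`` maps mark -> chromosome -> dense per-base signal.  Each
    mark's signal is zeroed outside that mark's peaks (a bin belongs to a
    peak if its midpoint lies inside it), averaged per bin, and transformed
    with log(x+1).  Bins where all marks are zero are discarded; the
    remaining bins form maximal contiguous segments.
    """
    marks = sorted(mark_signals)
    if not marks:
        raise ValueError("need at least one mark")
    if set(mark_peaks) != set(marks):
        raise ValueError("mark_signals and mark_peaks must list the same marks")
    chrom_sets = [set(mark_signals[m]) for m in marks]
    if any(cs != chrom_sets[0] for cs in chrom_sets):
        diffs = set.union(*chrom_sets) - set.intersection(*chrom_sets)
        raise ValueError(f"chromosome sets differ between marks: {sorted(diffs)}")

    segments: list[Segment] = []
    for chrom in sorted(chrom_sets[0]):
        n_bins = len(mark_signals[marks[0]][chrom]) // bin_size
        if n_bins == 0:
            continue
        mat = np.zeros((n_bins, len(marks)))
        for j, mark in enumerate(marks):
            sig = mark_signals[mark][chrom][: n_bins * bin_size]
            binned = sig.reshape(n_bins, bin_size).mean(axis=1)
            mask = np.zeros(n_bins, dtype=bool)
            mids = np.arange(n_bins) * bin_size + bin_size // 2
            for peak in mark_peaks[mark]:
                if peak.chrom != chrom:
                    continue
                mask |= (mids >= peak.start) & (mids < peak.end)
            vals = np.where(mask, binned, 0.0)
            mat[:, j] = np.log1p(np.clip(vals, 0.0, None))
        keep = (mat != 0).any(axis=1)
        # contiguous runs of kept bins become segments
        idx = np.flatnonzero(keep)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1) + 1
        for run in np.split(idx, breaks):
            segments.append(Segment(chrom, int(run[0]) * bin_size, mat[run]))
    return ChromatinMatrix(segments=segments, mark_names=marks, bin_size=bin_size)


# ---------------------------------------------------------------------------
# Baum-Welch with fixed transitions


def _log_emission(X: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """(T, K) log density under diagonal Gaussians."""
    T, D = X.shape
    diff = X[:, None, :] - means[None, :, :]  # (T, K, D)
    return -0.5 * (
        (diff**2 / variances[None]).sum(axis=2)
        + np.log(2 * np.pi * variances).sum(axis=1)[None, :]
    )


def _forward_backward(
    X: np.ndarray, A: np.ndarray, pi: np.ndarray, means: np.ndarray, variances: np.ndarray
) -> tuple[float, np.ndarray]:
    """Scaled forward-backward; returns (log-likelihood, posteriors)."""
    logB = _log_emission(X, means, variances)
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])
    T, K = B.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.log(c).sum() + shift.sum())
    return loglik, gamma


def fit_hmm(
    data: ChromatinMatrix,
    n_states: int,
    min_train_len: int = 500,
    max_iter: int = 100,
    tol: float = 1e-5,
    seed: int = 0,
    diagonal: float = 0.9,
    train_chroms: set[str] | None = None,
) -> HmmModel:
    """Baum-Welch training with the transition matrix held at its tied values.

    Only segments spanning at least ``min_train_len`` bp (and, when given,
    lying on ``train_chroms``) enter training.  Means are initialized by
    k-means on a subsample of bins, variances at 1, initial probabilities
    uniform.  Per-iteration total log-likelihood is non-decreasing; training
    stops at relative improvement < ``tol`` or ``max_iter``.
    """
    if n_states < 2:
        raise ValueError("need at least 2 states")
    min_bins = max(1, min_train_len // data.bin_size)
    train = [
        s.X
        for s in data.segments
        if s.n_bins >= min_bins and (train_chroms is None or s.chrom in train_chroms)
    ]
    if not train:
        raise ValueError("no segments long enough for training")
    stacked = np.concatenate(train, axis=0)
    rng = np.random.default_rng(seed)

    from sklearn.cluster import KMeans

    sub = stacked[rng.choice(len(stacked), size=min(len(stacked), 20000), replace=False)]
    km = KMeans(n_clusters=n_states, n_init=5, random_state=int(rng.integers(2**31)))
    km.fit(sub)
    means = km.cluster_centers_.copy()
    variances = np.ones_like(means)
    pi = np.full(n_states, 1.0 / n_states)
    A = tied_transition_matrix(n_states, diagonal)
    A_frozen = A.copy()

    history: list[float] = []
    for iteration in range(max_iter):
        total_ll = 0.0
        gamma_sum = np.zeros(n_states)
        mean_num = np.zeros_like(means)
        sq_num = np.zeros_like(means)
        pi_acc = np.zeros(n_states)
        gammas = []
        for X in train:
            ll, gamma = _forward_backward(X, A, pi, means, variances)
            total_ll += ll
            gammas.append(gamma)
            gamma_sum += gamma.sum(axis=0)
            mean_num += gamma.T @ X
            sq_num += gamma.T @ (X**2)
            pi_acc += gamma[0]
        history.append(total_ll)
        assert np.array_equal(A, A_frozen), "transition matrix must stay tied"
        if len(history) >= 2:
            prev = history[-2]
            if total_ll < prev - 1e-6 * max(1.0, abs(prev)):
                warnings.warn("log-likelihood decreased; stopping")
                break
            if abs(total_ll - prev) < tol * max(1.0, abs(prev)):
                break
        # M-step (emissions and initial probabilities only)
        for k in range(n_states):
            if gamma_sum[k] < 1e-8:
                warnings.warn(f"state {k} lost all responsibility; re-seeding mean")
                means[k] = stacked[rng.integers(len(stacked))]
                variances[k] = 1.0
                continue
            means[k] = mean_num[k] / gamma_sum[k]
            variances[k] = np.maximum(
                sq_num[k] / gamma_sum[k] - means[k] ** 2, VARIANCE_FLOOR
            )
        pi = pi_acc / pi_acc.sum()
    return HmmModel(
        n_states=n_states,
        transition=A,
        startprob=pi,
        means=means,
        variances=variances,
        mark_names=list(data.mark_names),
        loglik_history=history,
    )


def decode(model: HmmModel, data: ChromatinMatrix) -> StateTrack:
    """Posterior decoding: per-bin argmax of the forward-backward posterior."""
    if len(model.mark_names) != len(data.mark_names):
        raise ValueError("mark dimension mismatch between model and data")
    if model.mark_names != list(data.mark_names):
        raise ValueError("mark order mismatch between model and data")
    states, posteriors = [], []
    for seg in data.segments:
        _, gamma = _forward_backward(
            seg.X, model.transition, model.startprob, model.means, model.variances
        )
        states.append(gamma.argmax(axis=1))
        posteriors.append(gamma)
    return StateTrack(
        segments=data.segments,
        states=states,
        posteriors=posteriors,
        bin_size=data.bin_size,
        n_states=model.n_states,
    )


def state_coverage(
    track: StateTrack, anchors: list[tuple[str, int, str]], flank: int
) -> "np.ndarray":
    """Per-state positional coverage around strand-oriented anchor points.

    ``anchors`` are (chrom, position, strand) triples; offsets run from
    -flank to +flank in bin-size steps with positive offsets downstream of
    the anchor with respect to its strand.  Returns an array of shape
    (n_offsets, n_states) of fractions of anchors carrying each state at
    each offset (rows sum to <= 1; bins outside any segment are unlabeled).
    """
    lut = track.lookup()
    bs = track.bin_size
    offsets = np.arange(-flank, flank + 1, bs)
    cov = np.zeros((offsets.size, track.n_states))
    if not anchors:
        return cov
    for chrom, pos, strand in anchors:
        for i, off in enumerate(offsets.tolist()):
            genomic = pos + off if strand == "+" else pos - off
            state = lut.get((chrom, genomic // bs))
            if state is not None:
                cov[i, state] += 1
    return cov / len(anchors)


# ---------------------------------------------------------------------------
# Simulation and evaluation helpers


def simulate_hmm(
    n_segments: int,
    seg_len: int,
    means: np.ndarray,
    variances: np.ndarray,
    seed: int = 0,
    diagonal: float = 0.9,
    bin_size: int = 10,
) -> tuple[ChromatinMatrix, list[np.ndarray]]:
    """Sample segments from a tied-transition diagonal-Gaussian HMM.

    Returns the data and the true per-bin state paths, for parameter- and
    decoding-recovery checks.
    """
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    K, D = means.shape
    A = tied_transition_matrix(K, diagonal)
    rng = np.random.default_rng(seed)
    segments, paths = [], []
    for i in range(n_segments):
        states = np.empty(seg_len, dtype=np.int64)
        states[0] = rng.integers(K)
        for t in range(1, seg_len):
            states[t] = rng.choice(K, p=A[states[t - 1]])
        X = rng.normal(means[states], np.sqrt(variances[states]))
        segments.append(Segment("sim", i * seg_len * bin_size, X))
        paths.append(states)
    marks = [f"mark{j}" for j in range(D)]
    return ChromatinMatrix(segments=segments, mark_names=marks, bin_size=bin_size), paths


def match_states(true_means: np.ndarray, fitted_means: np.ndarray) -> np.ndarray:
    """Permutation mapping fitted state k -> true state, by Hungarian matching
    on Euclidean distance between state means."""
    from scipy.optimize import linear_sum_assignment
    from scipy.spatial.distance import cdist

    cost = cdist(true_means, fitted_means)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(true_means), dtype=np.int64)
    perm[cols] = rows
    return perm
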