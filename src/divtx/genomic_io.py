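"""Interval types, BED/bedGraph readers and writers, and peak annotation.

Coordinates are 0-based half-open (BED convention) everywhere; strand is one
of ``+``, ``-`` or ``.``.  "Downstream" of a minus-strand feature means
decreasing coordinate; every module goes through :func:`downstream_window`
for that, so the convention lives in one place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

VALID_STRANDS = ("+", "-", ".")

# peak annotation labels
PROMOTER = "promoter"
INTERGENIC = "intergenic"
OTHER = "other"
BIDIRECTIONAL = "bidirectional-removed"


class BedParseError(ValueError):
    """A malformed line in a BED or bedGraph file."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open stranded interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """An NDR/accessibility peak with optional summit, score and annotation."""

    interval: GenomicInterval
    summit: int | None = None
    score: float = 0.0
    name: str = "."
    annotation: str | None = None
    gene_strand: str | None = None

    def __post_init__(self) -> None:
        if self.summit is not None and not 0 <= self.summit < self.interval.width:
            raise ValueError("summit offset outside interval")
        if self.score < 0:
            raise ValueError("score must be non-negative")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def width(self) -> int:
        return self.interval.width


@dataclass(frozen=True)
class AnnotationConfig:
    """Distances used to annotate peaks against a transcript annotation.

    ``promoter_distance`` is the maximum distance (bp) between a peak and an
    annotated transcript start for the peak to count as that gene's promoter
    (species presets: 200 human, 400 fly, 500 worm).  ``extension`` is the
    per-side widening applied to called peaks before merging (default 75 bp).
    """

    promoter_distance: int = 200
    extension: int = 75

    def __post_init__(self) -> None:
        if self.promoter_distance <= 0:
            raise ValueError("promoter_distance must be positive")


SPECIES_PRESETS = {
    "human": {"promoter_distance": 200, "quantile": 0.9999},
    "fly": {"promoter_distance": 400, "quantile": 0.999},
    "worm": {"promoter_distance": 500, "quantile": 0.999},
}


def downstream_window(
    interval: GenomicInterval, strand: str, size: int, chrom_length: int | None = None
) -> GenomicInterval | None:
    """Window of ``size`` bp immediately downstream of ``interval`` w.r.t. ``strand``.

    Downstream means higher coordinates on ``+`` and lower coordinates on
    ``-``.  Truncated (with a warning) at position 0 or ``chrom_length``;
    returns None if nothing remains.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    if strand == "+":
        start, end = interval.end, interval.end + size
    elif strand == "-":
        start, end = interval.start - size, interval.start
    else:
        raise ValueError("strand must be + or -")
    clipped_start = max(start, 0)
    clipped_end = min(end, chrom_length) if chrom_length is not None else end
    if (clipped_start, clipped_end) != (start, end):
        warnings.warn(
            f"downstream window of {interval.chrom}:{interval.start}-{interval.end}"
            f" truncated to chromosome bounds",
            stacklevel=2,
        )
    if clipped_start >= clipped_end:
        return None
    return GenomicInterval(interval.chrom, clipped_start, clipped_end, strand)


# ---------------------------------------------------------------------------
# BED I/O


def read_bed(path: str) -> list[Peak]:
    """Read BED3/BED6 into peaks sorted by (chrom, start).

    Raises :class:`BedParseError` naming the offending line for malformed
    records (wrong column count, non-integer coordinates, start >= end).
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            peaks.append(
                Peak(GenomicInterval(chrom, start, end, strand), score=score, name=name)
            )
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    return peaks


def write_bed(peaks: Iterable[Peak], path: str) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t"
                f"{p.interval.strand}\n"
            )


# ---------------------------------------------------------------------------
# Interval algebra


def filter_min_width(peaks: Sequence[Peak], min_width: int = 50) -> list[Peak]:
    """Drop peaks narrower than ``min_width`` bp (applied before extension)."""
    return [p for p in peaks if p.width > min_width]


def extend_and_merge(
    peaks: Sequence[Peak],
    extension: int,
    chrom_sizes: dict[str, int] | None = None,
) -> list[Peak]:
    """Extend each peak by ``extension`` bp per side and merge overlaps.

    Output intervals are disjoint unions of maximal overlapping sets of
    extended inputs, clamped at 0 and (when known) the chromosome end.
    """
    if extension < 0:
        raise ValueError("extension must be >= 0")
    extended = []
    for p in peaks:
        start = max(0, p.start - extension)
        end = p.end + extension
        if chrom_sizes is not None and p.chrom in chrom_sizes:
            end = min(end, chrom_sizes[p.chrom])
        extended.append((p.chrom, start, end))
    extended.sort()
    merged: list[Peak] = []
    cur: list | None = None
    for chrom, start, end in extended:
        if cur is not None and chrom == cur[0] and start <= cur[2]:
            cur[2] = max(cur[2], end)
        else:
            if cur is not None:
                merged.append(Peak(GenomicInterval(cur[0], cur[1], cur[2])))
            cur = [chrom, start, end]
    if cur is not None:
        merged.append(Peak(GenomicInterval(cur[0], cur[1], cur[2])))
    return merged


def subtract_intervals(
    target: GenomicInterval, others: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Pieces of ``target`` not covered by any interval in ``others``."""
    pieces = [(target.start, target.end)]
    for other in sorted(
        (o for o in others if o.chrom == target.chrom), key=lambda o: o.start
    ):
        new: list[tuple[int, int]] = []
        for s, e in pieces:
            if other.end <= s or other.start >= e:
                new.append((s, e))
                continue
            if other.start > s:
                new.append((s, other.start))
            if other.end < e:
                new.append((other.end, e))
        pieces = new
    return [
        GenomicInterval(target.chrom, s, e, target.strand) for s, e in pieces if s < e
    ]


# ---------------------------------------------------------------------------
# Peak annotation


@dataclass(frozen=True)
class TssSite:
    """An annotated transcript/gene start used for promoter annotation."""

    chrom: str
    position: int
    strand: str


def annotate_peaks(
    peaks: Sequence[Peak],
    tss_sites: Sequence[TssSite],
    transcripts: Sequence[GenomicInterval],
    config: AnnotationConfig,
) -> list[Peak]:
    """Label each peak as promoter / bidirectional-removed / intergenic / other.

    A peak is a promoter if an annotated start lies within
    ``promoter_distance`` of the peak on exactly one strand (that strand is
    recorded as ``gene_strand``); starts within distance on both strands mark
    a bidirectional promoter, which is removed from analysis.  A peak that is
    neither and does not intersect any transcript body is intergenic;
    anything else is "other".
    """
    d = config.promoter_distance
    by_chrom_tss: dict[str, list[TssSite]] = {}
    for t in tss_sites:
        by_chrom_tss.setdefault(t.chrom, []).append(t)
    by_chrom_tx: dict[str, list[GenomicInterval]] = {}
    for t in transcripts:
        by_chrom_tx.setdefault(t.chrom, []).append(t)

    out: list[Peak] = []
    for p in peaks:
        near: dict[str, TssSite] = {}
        for site in by_chrom_tss.get(p.chrom, []):
            # distance between a point and a half-open interval
            dist = max(p.start - site.position, site.position - (p.end - 1), 0)
            if dist <= d:
                prev = near.get(site.strand)
                if prev is None or _site_dist(p, site) < _site_dist(p, prev):
                    near[site.strand] = site
        if len(near) >= 2:
            out.append(replace(p, annotation=BIDIRECTIONAL, gene_strand=None))
        elif len(near) == 1:
            strand = next(iter(near))
            out.append(replace(p, annotation=PROMOTER, gene_strand=strand))
        else:
            hits_body = any(p.interval.overlaps(t) for t in by_chrom_tx.get(p.chrom, []))
            out.append(replace(p, annotation=OTHER if hits_body else INTERGENIC))
    return out


def _site_dist(p: Peak, site: TssSite) -> int:
    return max(p.start - site.position, site.position - (p.end - 1), 0)


# ---------------------------------------------------------------------------
# Stranded 5'-end track


class StrandedTssTrack:
    """Sparse per-base read 5'-end counts on the + and - strands.

    Internally one sorted position array and one count array per
    (chromosome, strand); range queries use binary search.
    """

    def __init__(self) -> None:
        self._data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_dicts(
        cls, plus: dict[str, dict[int, int]], minus: dict[str, dict[int, int]]
    ) -> "StrandedTssTrack":
        track = cls()
        for strand, per_chrom in (("+", plus), ("-", minus)):
            for chrom, posmap in per_chrom.items():
                if not posmap:
                    continue
                pos = np.array(sorted(posmap), dtype=np.int64)
                cnt = np.array([posmap[p] for p in pos], dtype=np.int64)
                if (cnt < 0).any():
                    raise ValueError("negative counts are not allowed")
                track._data[(chrom, strand)] = (pos, cnt)
        return track

    def chromosomes(self) -> set[str]:
        return {chrom for chrom, _ in self._data}

    def counts_in(self, chrom: str, start: int, end: int, strand: str) -> np.ndarray:
        """Dense per-base counts over [start, end) on one strand."""
        out = np.zeros(end - start, dtype=np.int64)
        entry = self._data.get((chrom, strand))
        if entry is None:
            return out
        pos, cnt = entry
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        out[pos[lo:hi] - start] = cnt[lo:hi]
        return out

    def total(self, strand: str | None = None) -> int:
        return int(
            sum(c.sum() for (_, s), (_, c) in self._data.items() if strand in (None, s))
        )

    def items(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        entry = self._data.get((chrom, strand))
        if entry is None:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        return entry


def read_stranded_bedgraph(path_plus: str, path_minus: str) -> StrandedTssTrack:
    """Read one per-strand bedGraph pair of per-base integer 5'-end counts.

    Rows may span several bases (the value applies to each base).  Rows that
    overlap on the same strand, or negative values, are rejected.
    """
    plus = _read_count_bedgraph(path_plus)
    minus = _read_count_bedgraph(path_minus)
    return StrandedTssTrack.from_dicts(plus, minus)


def _read_count_bedgraph(path: str) -> dict[str, dict[int, int]]:
    out: dict[str, dict[int, int]] = {}
    last_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            value = float(fields[3])
            if start >= end or start < 0:
                raise BedParseError(f"{path}:{lineno}: invalid interval")
            if value < 0:
                raise BedParseError(f"{path}:{lineno}: negative count {value}")
            if value != int(value):
                raise BedParseError(f"{path}:{lineno}: non-integer count {value}")
            if chrom in last_end and start < last_end[chrom]:
                # bedGraph rows must be sorted and non-overlapping per strand
                raise BedParseError(
                    f"{path}:{lineno}: overlapping or unsorted rows on {chrom}"
                )
            last_end[chrom] = end
            if value == 0:
                continue
            per = out.setdefault(chrom, {})
            for pos in range(start, end):
                per[pos] = int(value)
    return out


def write_stranded_bedgraph(
    track: StrandedTssTrack, path_plus: str, path_minus: str
) -> None:
    for strand, path in (("+", path_plus), ("-", path_minus)):
        with open(path, "w") as fh:
            chroms = sorted(c for c in track.chromosomes())
            for chrom in chroms:
                pos, cnt = track.items(chrom, strand)
                for p, c in zip(pos.tolist(), cnt.tolist()):
                    fh.write(f"{chrom}\t{p}\t{p + 1}\t{c}\n")


# ---------------------------------------------------------------------------
# Dense signal bedGraph (ChIP/accessibility tracks)


def read_bedgraph_dense(
    path: str, chrom_sizes: dict[str, int]
) -> dict[str, np.ndarray]:
    """Read a (possibly ranged) bedGraph into dense per-base float arrays."""
    out = {chrom: np.zeros(size, dtype=np.float64) for chrom, size in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 fields")
            chrom, start, end, value = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                float(fields[3]),
            )
            if chrom not in out:
                raise BedParseError(f"{path}:{lineno}: unknown chromosome {chrom}")
            out[chrom][start : min(end, chrom_sizes[chrom])] = value
    return out


def write_bedgraph_dense(
    signal: dict[str, np.ndarray], path: str, step: int = 1
) -> None:
    """Write dense per-base signal as a run-length-collapsed bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(signal):
            values = signal[chrom]
            if step > 1:
                n = len(values) // step * step
                values = values[:n].reshape(-1, step).mean(axis=1)
            # run-length encode
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(values)]))
            for s, e in zip(starts.tolist(), ends.tolist()):
                v = values[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s * step}\t{e * step}\t{v:g}\n")
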