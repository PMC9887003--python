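"""Genomic interval data model, plain-text I/O and positional queries.

All coordinates are 0-based, half-open (BED convention). A gene's TSS is a
single base-pair point; for minus-strand genes it is the annotated 3' end of
the interval as stored, i.e. whoever builds the :class:`GeneModel` is
responsible for handing in the strand-correct start point. Chromosome names
are matched by exact string equality — no "chr" aliasing.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "SignalTrack",
    "StateAnnotation",
    "STATE_VOCAB",
    "read_intervals",
    "write_intervals",
    "merge_intervals",
    "nearest_feature",
    "extract_binned_signal",
]

#: closed vocabulary of simplified chromatin states
STATE_VOCAB = ("Active", "Bivalent", "Repressed", "Other")


class IntervalError(ValueError):
    """Validation or parse failure in interval handling."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` with optional score and name.

    Ordering is lexicographic on (chrom, start, end), which is the sort
    contract used throughout the package.
    """

    chrom: str
    start: int
    end: int
    score: float | None = field(default=None, compare=False)
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise IntervalError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise IntervalError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.score is not None and self.score < 0:
            raise IntervalError("score must be non-negative")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """Gene anchor: strand-aware TSS point, transcript length, ligand flag."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    length: int
    is_secreted_ligand: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise IntervalError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise IntervalError("tss must be >= 0")
        if self.length <= 0:
            raise IntervalError("length must be > 0")


class SignalTrack:
    """Sparse constant-bin-width signal track.

    Stores, per chromosome, sorted non-overlapping bins of width
    ``bin_width`` with non-negative values; positions not covered by a
    stored bin have signal 0. This matches a bedGraph whose lines are
    aligned to a fixed grid but omit zero runs.
    """

    def __init__(self, bin_width: int) -> None:
        if bin_width <= 0:
            raise IntervalError("bin_width must be positive")
        self.bin_width = int(bin_width)
        self._starts: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        self._pending: dict[str, list[tuple[int, float]]] = {}

    def add(self, chrom: str, start: int, value: float) -> None:
        """Add one bin ``[start, start + bin_width)``."""
        if value < 0:
            raise IntervalError("track values must be >= 0")
        if start % self.bin_width:
            raise IntervalError(
                f"bin start {start} not aligned to width {self.bin_width}"
            )
        self._pending.setdefault(chrom, []).append((int(start), float(value)))
        self._starts.pop(chrom, None)

    def _finalize(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        if chrom not in self._starts:
            pend = sorted(self._pending.get(chrom, ()))
            starts = np.asarray([p[0] for p in pend], dtype=np.int64)
            if starts.size and np.any(np.diff(starts) < self.bin_width):
                raise IntervalError(f"overlapping bins on {chrom}")
            self._starts[chrom] = starts
            self._values[chrom] = np.asarray([p[1] for p in pend], dtype=float)
        return self._starts[chrom], self._values[chrom]

    def chroms(self) -> list[str]:
        return sorted(set(self._pending) | set(self._starts))

    def bins(self, chrom: str) -> Iterable[tuple[int, int, float]]:
        starts, values = self._finalize(chrom)
        for s, v in zip(starts.tolist(), values.tolist()):
            yield s, s + self.bin_width, v

    def integral(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Cumulative signal integral from coordinate 0 to each position.

        Vectorized; positions may be in any order. Signal outside stored
        bins is 0.
        """
        starts, values = self._finalize(chrom)
        pos = np.asarray(positions, dtype=np.int64)
        if starts.size == 0:
            return np.zeros(pos.shape, dtype=float)
        # cum[i] = integral over the first i stored bins (full bins)
        cum = np.concatenate(([0.0], np.cumsum(values) * self.bin_width))
        idx = np.searchsorted(starts, pos, side="right")
        j = np.maximum(idx - 1, 0)
        base = np.where(idx > 0, cum[idx], 0.0)
        # cum[idx] includes all of bin j; subtract the part of bin j that
        # lies at or beyond pos
        tail = np.where(
            idx > 0,
            values[j] * np.clip(starts[j] + self.bin_width - pos, 0, self.bin_width),
            0.0,
        )
        return base - tail


class StateAnnotation:
    """Sorted labelled intervals with states from :data:`STATE_VOCAB`."""

    def __init__(self, entries: Iterable[tuple[GenomicInterval, str]] = ()) -> None:
        self._by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for iv, state in entries:
            self.add(iv, state)

    def add(self, iv: GenomicInterval, state: str) -> None:
        if state not in STATE_VOCAB:
            raise IntervalError(f"unknown state label {state!r}")
        self._by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, state))
        self._by_chrom[iv.chrom].sort()

    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def entries(self, chrom: str) -> list[tuple[int, int, str]]:
        return list(self._by_chrom.get(chrom, ()))

    def overlap_by_state(self, chrom: str, start: int, end: int) -> dict[str, int]:
        """Total bp of each state overlapping ``[start, end)``."""
        out = {s: 0 for s in STATE_VOCAB}
        for s0, e0, state in self._by_chrom.get(chrom, ()):
            if s0 >= end:
                break
            ov = min(e0, end) - max(s0, start)
            if ov > 0:
                out[state] += ov
        return out

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())


DIALECTS = ("bed3", "bed6", "narrowPeak", "bedGraph", "state-bed")


def _parse_int(tok: str, lineno: int, path: str) -> int:
    try:
        return int(tok)
    except ValueError:
        raise IntervalError(f"{path}:{lineno}: cannot parse integer {tok!r}") from None


def read_intervals(path, dialect: str):
    """Read a tab-separated interval file in the given dialect.

    Returns a sorted list of :class:`GenomicInterval` — except for
    ``state-bed``, which returns a :class:`StateAnnotation`, and
    ``bedGraph``, for which score carries the 4th-column value.
    Malformed lines raise :class:`IntervalError` naming the line number.
    """
    if dialect not in DIALECTS:
        raise IntervalError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = str(path)
    out: list[GenomicInterval] = []
    states: list[tuple[GenomicInterval, str]] = []
    min_cols = {"bed3": 3, "bed6": 6, "narrowPeak": 10, "bedGraph": 4, "state-bed": 4}[
        dialect
    ]
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < min_cols:
                raise IntervalError(
                    f"{path}:{lineno}: expected >= {min_cols} columns for "
                    f"{dialect}, got {len(cols)}"
                )
            chrom = cols[0]
            start = _parse_int(cols[1], lineno, path)
            end = _parse_int(cols[2], lineno, path)
            try:
                if dialect == "bed3":
                    iv = GenomicInterval(chrom, start, end)
                elif dialect == "bed6":
                    score = float(cols[4]) if cols[4] != "." else None
                    iv = GenomicInterval(chrom, start, end, score=score, name=cols[3])
                elif dialect == "narrowPeak":
                    # col 7 (0-based index 6) is signalValue
                    iv = GenomicInterval(
                        chrom, start, end, score=float(cols[6]), name=cols[3]
                    )
                elif dialect == "bedGraph":
                    iv = GenomicInterval(chrom, start, end, score=float(cols[3]))
                else:  # state-bed
                    iv = GenomicInterval(chrom, start, end, name=cols[3])
                    states.append((iv, cols[3]))
            except IntervalError as exc:
                raise IntervalError(f"{path}:{lineno}: {exc}") from None
            out.append(iv)
    if dialect == "state-bed":
        ann = StateAnnotation()
        for iv, label in sorted(states, key=lambda t: t[0]):
            ann.add(iv, label)
        return ann
    return sorted(out)


def write_intervals(path, intervals: Sequence[GenomicInterval], dialect: str) -> None:
    """Write intervals in the given dialect (tab-separated, newline-terminated)."""
    if dialect not in DIALECTS:
        raise IntervalError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for iv in intervals:
            if dialect == "bed3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            elif dialect == "bed6":
                score = "." if iv.score is None else _fmt(iv.score)
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t.\n"
                )
            elif dialect == "narrowPeak":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t.\t"
                    f"{_fmt(iv.score if iv.score is not None else 0)}\t-1\t-1\t-1\n"
                )
            elif dialect == "bedGraph":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                    f"{_fmt(iv.score if iv.score is not None else 0)}\n"
                )
            else:  # state-bed
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def merge_intervals(
    intervals: Sequence[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Union-merge intervals whose gap is <= ``max_gap`` bp.

    Output is sorted, pairwise gaps strictly exceed ``max_gap``, coverage is
    the union of the input, and the operation is idempotent.
    """
    if max_gap < 0:
        raise IntervalError("max_gap must be >= 0")
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start - merged[-1].end <= max_gap
        ):
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def nearest_feature(
    chrom: str,
    pos: int,
    features: Sequence[GenomicInterval],
    max_dist: int,
) -> tuple[GenomicInterval, int] | None:
    """Nearest feature to a point, or None beyond ``max_dist`` bp.

    Distance is 0 inside a feature, otherwise the bp gap to the closest
    edge (``start - pos`` upstream, ``pos - end`` downstream). Ties are
    broken toward the feature with the smaller start coordinate. Features
    must be sorted; only features on ``chrom`` are considered.
    """
    cand = [f for f in features if f.chrom == chrom]
    if not cand:
        return None
    starts = [f.start for f in cand]
    i = bisect_right(starts, pos)
    best: tuple[int, int] | None = None  # (distance, index)
    # scan left and right neighbours around the insertion point; intervals
    # may nest, so walk a window rather than a single neighbour each side
    lo = max(0, i - 32)
    hi = min(len(cand), i + 32)
    for j in range(lo, hi):
        f = cand[j]
        if f.start <= pos < f.end:
            d = 0
        elif pos < f.start:
            d = f.start - pos
        else:
            d = pos - f.end
        if best is None or d < best[0] or (d == best[0] and f.start < cand[best[1]].start):
            best = (d, j)
    # widen the window if the boundary features could still be closer
    while lo > 0 and best is not None and pos - cand[lo].end <= best[0]:
        lo -= 1
        f = cand[lo]
        d = 0 if f.start <= pos < f.end else (f.start - pos if pos < f.start else pos - f.end)
        if d < best[0] or (d == best[0] and f.start < cand[best[1]].start):
            best = (d, lo)
    while hi < len(cand) and best is not None and cand[hi].start - pos <= best[0]:
        f = cand[hi]
        d = 0 if f.start <= pos < f.end else (f.start - pos if pos < f.start else pos - f.end)
        if d < best[0] or (d == best[0] and f.start < cand[best[1]].start):
            best = (d, hi)
        hi += 1
    assert best is not None
    if best[0] > max_dist:
        return None
    return cand[best[1]], best[0]


def extract_binned_signal(
    track: SignalTrack, chrom: str, center: int, flank: int, bin_size: int
) -> np.ndarray:
    """Mean track signal in ``2*flank/bin_size`` bins around ``center``.

    The window is ``[center - flank, center + flank)``; positions beyond
    chromosome bounds (negative coordinates or past the last stored bin)
    contribute 0, so output vectors stay rectangular across genes.
    """
    if bin_size <= 0:
        raise IntervalError("bin_size must be positive")
    if flank % bin_size:
        raise IntervalError("flank must be divisible by bin_size")
    n_bins = 2 * flank // bin_size
    edges = center - flank + bin_size * np.arange(n_bins + 1, dtype=np.int64)
    clipped = np.clip(edges, 0, None)
    integ = track.integral(chrom, clipped)
    return np.diff(integ) / bin_size
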