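"""Fragment length distributions, interval statistics, coverage, site profiles.

Interval assignment uses the fragment midpoint ``floor((start + end - 1)/2)``
so that coverage over a tiling of bins partitions the fragment total exactly
(DELFI-style binned counting). Overlap-based counting is available via
``interval_coverage(..., mode="overlap")``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from fragkit.fragio import Fragment, GenomicInterval

__all__ = [
    "LengthHistogram", "SiteProfile",
    "length_histogram", "interval_length_stats", "interval_coverage",
    "site_profile", "coverage_array", "assign_midpoints",
]


@dataclass
class LengthHistogram:
    """Histogram of fragment lengths plus summary statistics of raw lengths.

    ``counts`` maps the left edge of each length bin to its count; summary
    statistics (mean, median, mode, stdev, min, max) are computed on the
    unbinned lengths. Empty input gives an empty histogram with ``summary``
    None. The mode is the smallest length with maximal count.
    """

    bin_size: int = 1
    counts: dict[int, int] = field(default_factory=dict)
    summary: Optional[dict[str, float]] = None

    @property
    def n_fragments(self) -> int:
        return sum(self.counts.values())

    @property
    def mode(self) -> Optional[int]:
        return None if self.summary is None else int(self.summary["mode"])


@dataclass
class SiteProfile:
    """Mean signal at offsets -W..+W relative to site anchors.

    Minus-strand sites are reversed before averaging. ``n_sites`` counts sites
    that contributed; ``n_skipped`` counts sites dropped for running off a
    contig edge.
    """

    offsets: np.ndarray
    values: np.ndarray
    n_sites: int
    n_skipped: int = 0

    @property
    def window(self) -> int:
        return (len(self.offsets) - 1) // 2


def length_histogram(
    fragments: Iterable[Fragment], bin_size: int = 1
) -> LengthHistogram:
    """Bin fragment lengths; each fragment contributes end - start once."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    lengths = np.fromiter((f.length for f in fragments), dtype=np.int64)
    if lengths.size == 0:
        return LengthHistogram(bin_size=bin_size)
    binned = (lengths // bin_size) * bin_size
    uniq, cnt = np.unique(binned, return_counts=True)
    counts = {int(u): int(c) for u, c in zip(uniq, cnt)}
    raw_uniq, raw_cnt = np.unique(lengths, return_counts=True)
    mode = int(raw_uniq[np.argmax(raw_cnt)])  # argmax returns first = smallest tie
    summary = {
        "mean": float(lengths.mean()),
        "median": float(np.median(lengths)),
        "mode": float(mode),
        "stdev": float(lengths.std(ddof=0)),
        "min": float(lengths.min()),
        "max": float(lengths.max()),
    }
    return LengthHistogram(bin_size=bin_size, counts=counts, summary=summary)


def assign_midpoints(
    fragments: Iterable[Fragment], intervals: Sequence[GenomicInterval]
) -> list[list[int]]:
    """Indices of fragments whose midpoint falls in each interval.

    A fragment is assigned to every interval containing its midpoint; for a
    tiling this is a partition.
    """
    frags = list(fragments)
    mids: dict[str, list[tuple[int, int]]] = {}
    for i, f in enumerate(frags):
        mids.setdefault(f.contig, []).append((f.midpoint, i))
    sorted_mids: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig, pairs in mids.items():
        pairs.sort()
        sorted_mids[contig] = (
            np.array([p[0] for p in pairs], dtype=np.int64),
            np.array([p[1] for p in pairs], dtype=np.int64),
        )
    out: list[list[int]] = []
    for iv in intervals:
        if iv.contig not in sorted_mids:
            out.append([])
            continue
        pos, idx = sorted_mids[iv.contig]
        lo = int(np.searchsorted(pos, iv.start, side="left"))
        hi = int(np.searchsorted(pos, iv.end, side="left"))
        out.append([int(j) for j in idx[lo:hi]])
    return out


def interval_length_stats(
    fragments: Iterable[Fragment], intervals: Sequence[GenomicInterval]
):
    """Per-interval fragment count and length summary (midpoint assignment).

    Returns a pandas DataFrame with one row per interval: contig, start, end,
    name, count, mean, median, mode, stdev, min, max (NaN where count is 0).
    """
    import pandas as pd

    frags = list(fragments)
    groups = assign_midpoints(frags, intervals)
    rows = []
    for iv, idxs in zip(intervals, groups):
        row = {
            "contig": iv.contig, "start": iv.start, "end": iv.end,
            "name": iv.name, "count": len(idxs),
        }
        if idxs:
            h = length_histogram(frags[j] for j in idxs)
            row.update(h.summary)
        else:
            row.update({k: np.nan for k in ("mean", "median", "mode", "stdev", "min", "max")})
        rows.append(row)
    return pd.DataFrame(rows)


def interval_coverage(
    fragments: Iterable[Fragment],
    intervals: Sequence[GenomicInterval],
    normalize: Optional[str] = None,
    mode: str = "midpoint",
) -> np.ndarray:
    """Per-interval fragment coverage.

    ``mode="midpoint"`` counts fragments whose midpoint lies in the interval
    (partitioning over a tiling); ``mode="overlap"`` counts any overlap.
    ``normalize="per-million"`` divides by total fragments / 1e6.
    """
    frags = list(fragments)
    if mode == "midpoint":
        counts = np.array(
            [len(g) for g in assign_midpoints(frags, intervals)], dtype=float
        )
    elif mode == "overlap":
        counts = np.zeros(len(intervals))
        for i, iv in enumerate(intervals):
            counts[i] = sum(
                1 for f in frags
                if f.contig == iv.contig and f.start < iv.end and f.end > iv.start
            )
    else:
        raise ValueError(f"unknown coverage mode {mode!r}")
    if normalize == "per-million":
        total = len(frags)
        if total == 0:
            raise ZeroDivisionError("per-million normalization with zero fragments")
        counts = counts / (total / 1e6)
    elif normalize not in (None, "none"):
        raise ValueError(f"unknown normalization {normalize!r}")
    return counts


SignalSource = Union[
    Mapping[str, np.ndarray],
    Callable[[str, int, int], Optional[np.ndarray]],
]


def _fetch_signal(
    signal: SignalSource, contig: str, start: int, end: int
) -> Optional[np.ndarray]:
    """Per-base values over [start, end), or None if off-contig."""
    if callable(signal):
        return signal(contig, start, end)
    if contig not in signal:
        return None
    arr = signal[contig]
    if start < 0 or end > len(arr):
        return None
    return np.asarray(arr[start:end], dtype=float)


def coverage_array(
    fragments: Iterable[Fragment], contig: str, start: int, end: int
) -> np.ndarray:
    """Per-base fragment depth over [start, end) via a difference array."""
    diff = np.zeros(end - start + 1)
    for f in fragments:
        if f.contig != contig or f.end <= start or f.start >= end:
            continue
        diff[max(f.start - start, 0)] += 1
        diff[min(f.end - start, end - start)] -= 1
    return np.cumsum(diff[:-1])


def site_profile(
    signal: SignalSource,
    sites: Sequence[GenomicInterval],
    window: int,
    normalize: bool = False,
) -> SiteProfile:
    """Mean signal around site midpoints, strand-aware.

    Extracts per-base values at offsets -window..+window around each site's
    midpoint, reverses minus-strand sites, and averages over sites. With
    ``normalize``, divides by the window mean so a flat signal maps to 1.0.
    Sites whose window runs off the contig are skipped and counted.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not sites:
        raise ValueError("no sites given")
    total = np.zeros(2 * window + 1)
    n_used = n_skipped = 0
    for site in sites:
        mid = site.midpoint
        vals = _fetch_signal(signal, site.contig, mid - window, mid + window + 1)
        if vals is None or len(vals) != 2 * window + 1:
            n_skipped += 1
            continue
        if site.strand == "-":
            vals = vals[::-1]
        total += vals
        n_used += 1
    if n_used == 0:
        raise ValueError("all sites skipped (off-contig windows)")
    mean = total / n_used
    if normalize:
        overall = mean.mean()
        if overall != 0:
            mean = mean / overall
    offsets = np.arange(-window, window + 1)
    return SiteProfile(offsets=offsets, values=mean, n_sites=n_used, n_skipped=n_skipped)
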