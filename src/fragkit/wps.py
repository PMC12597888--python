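"""Window protection scores (WPS), raw and adjusted.

The raw WPS at position p with protection window w is the number of fragments
completely spanning the w-window centered at p minus the number of fragments
with at least one endpoint inside that window. The window at p is
[p - w/2, p + w/2) in 0-based half-open coordinates; a fragment spans iff
start <= p - w/2 and end >= p + w/2. Spanning takes precedence: a fragment
exactly matching the window counts as +1, and a fragment with both endpoints
inside the window contributes -1 once, not twice.

Peaks in WPS indicate nucleosome protection; the adjusted score subtracts a
running-median background and applies Savitzky-Golay smoothing, following the
convention of the original nucleosome-footprint work (w=120, fragments
120-180 bp, median window 1000, Savitzky-Golay 21/2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
from scipy.signal import savgol_filter

from fragkit.fragio import FilterSpec, Fragment, GenomicInterval, read_fragments
from fragkit.fragstats import SiteProfile

__all__ = ["WpsTrack", "raw_wps", "adjust_wps", "wps_site_aggregate"]

DEFAULT_WINDOW = 120
DEFAULT_LENGTH_BOUNDS = (120, 180)


@dataclass
class WpsTrack:
    """Per-base protection scores over a region."""

    contig: str
    start: int
    scores: np.ndarray
    window: int = DEFAULT_WINDOW
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS

    @property
    def end(self) -> int:
        return self.start + len(self.scores)

    def records(self):
        """Yield (contig, start, end, value) per base, for track writers."""
        for i, v in enumerate(self.scores):
            yield (self.contig, self.start + i, self.start + i + 1, float(v))


def _add_segment(diff: np.ndarray, lo: int, hi: int, value: int, offset: int) -> None:
    """Add ``value`` over inclusive position range [lo, hi] clipped to the track."""
    if hi < lo:
        return
    n = len(diff) - 1
    a = max(lo - offset, 0)
    b = min(hi - offset + 1, n)
    if a < b:
        diff[a] += value
        diff[b] -= value


def raw_wps(
    fragments: Union[Iterable[Fragment], str, Path],
    region: GenomicInterval,
    window: int = DEFAULT_WINDOW,
    length_bounds: Optional[tuple[int, int]] = DEFAULT_LENGTH_BOUNDS,
    filt: Optional[FilterSpec] = None,
) -> WpsTrack:
    """Raw WPS per base over ``region``.

    ``fragments`` may be a file path (fragments are fetched with a margin of
    w/2 + max fragment length so edge scores are exact) or an iterable that
    must already include every fragment able to influence the region.
    """
    if window < 2 or window % 2:
        raise ValueError("window must be even and >= 2")
    h = window // 2
    if isinstance(fragments, (str, Path)):
        max_len = (length_bounds[1] if length_bounds else 500)
        margin = h + max_len
        fetch = GenomicInterval(
            region.contig, max(0, region.start - margin), region.end + margin
        )
        frag_iter: Iterable[Fragment] = read_fragments(fragments, fetch, filt)
    else:
        frag_iter = fragments

    diff = np.zeros(region.length + 1, dtype=np.int64)
    for f in frag_iter:
        if f.contig != region.contig:
            continue
        if length_bounds is not None and not (
            length_bounds[0] <= f.length <= length_bounds[1]
        ):
            continue
        # spanning positions: start + h <= p <= end - h
        span_lo, span_hi = f.start + h, f.end - h
        _add_segment(diff, span_lo, span_hi, 1, region.start)
        # endpoint-inside positions for the two termini (inclusive ranges);
        # the ranges can overlap for short fragments -> take their union,
        # then subtract the spanning range (spanning takes precedence)
        a1, b1 = f.start - h + 1, f.start + h
        a2, b2 = f.end - h, f.end + h - 1
        if a2 <= b1 + 1:  # merged single segment
            segments = [(a1, max(b1, b2))]
        else:
            segments = [(a1, b1), (a2, b2)]
        for lo, hi in segments:
            if span_lo > span_hi or hi < span_lo or lo > span_hi:
                _add_segment(diff, lo, hi, -1, region.start)
            else:  # subtract the overlap with the spanning range
                _add_segment(diff, lo, min(hi, span_lo - 1), -1, region.start)
                _add_segment(diff, max(lo, span_hi + 1), hi, -1, region.start)
    scores = np.cumsum(diff[:-1])
    bounds = length_bounds if length_bounds is not None else (0, 10**9)
    return WpsTrack(region.contig, region.start, scores, window, bounds)


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running median; edges use a symmetrically shrunk window.

    The effective window is 2r+1 points with r = window // 2, shrunk to
    min(r, i, n-1-i) at the edges so the window stays symmetric about i.
    """
    n = len(x)
    r = window // 2
    out = np.empty(n)
    if n >= 2 * r + 1:
        from numpy.lib.stride_tricks import sliding_window_view

        out[r : n - r] = np.median(sliding_window_view(x, 2 * r + 1), axis=1)
        edge = r
    else:
        edge = n
    for i in range(min(edge, n)):
        ri = min(r, i)
        out[i] = np.median(x[i - ri : i + ri + 1])
    for i in range(max(n - edge, 0), n):
        ri = min(r, n - 1 - i)
        out[i] = np.median(x[i - ri : i + ri + 1])
    return out


def adjust_wps(
    track: WpsTrack,
    median_window: int = 1000,
    smoothing_window: int = 21,
    polyorder: int = 2,
) -> WpsTrack:
    """Background-subtract and smooth a raw WPS track.

    Subtracts a running median (window ``median_window``, edges shrunk
    symmetrically), then applies Savitzky-Golay smoothing. Output length
    equals input length.
    """
    if median_window < 3:
        raise ValueError("median_window must be >= 3")
    if smoothing_window % 2 == 0 or smoothing_window <= polyorder:
        raise ValueError("smoothing_window must be odd and > polyorder")
    x = np.asarray(track.scores, dtype=float)
    if len(x) < median_window:
        raise ValueError(
            f"track length {len(x)} shorter than median_window {median_window}"
        )
    detrended = x - _running_median(x, median_window)
    smoothed = savgol_filter(detrended, smoothing_window, polyorder, mode="interp")
    return replace(track, scores=smoothed)


def wps_site_aggregate(
    source: Union[str, Path],
    sites: Iterable[GenomicInterval],
    window: int = 1000,
    wps_window: int = DEFAULT_WINDOW,
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
    median_window: int = 1000,
    smoothing_window: int = 21,
    polyorder: int = 2,
    adjusted: bool = True,
    filt: Optional[FilterSpec] = None,
) -> SiteProfile:
    """Mean (adjusted) WPS at offsets -window..+window around site midpoints.

    Computes WPS per site neighborhood — with enough flanking context for the
    running median — crops to the window, flips minus-strand sites, and
    averages. Sites whose extended window would start before the contig are
    skipped and counted.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("no sites given")
    pad = median_window // 2 + smoothing_window if adjusted else 0
    total = np.zeros(2 * window + 1)
    n_used = n_skipped = 0
    for site in sites:
        mid = site.midpoint
        lo, hi = mid - window - pad, mid + window + pad + 1
        if lo < 0:
            n_skipped += 1
            continue
        region = GenomicInterval(site.contig, lo, hi)
        track = raw_wps(source, region, wps_window, length_bounds, filt)
        if adjusted:
            track = adjust_wps(track, median_window, smoothing_window, polyorder)
        vals = track.scores[pad : pad + 2 * window + 1]
        if site.strand == "-":
            vals = vals[::-1]
        total += vals
        n_used += 1
    if n_used == 0:
        raise ValueError("all sites skipped (off-contig windows)")
    return SiteProfile(
        offsets=np.arange(-window, window + 1),
        values=total / n_used,
        n_sites=n_used,
        n_skipped=n_skipped,
    )
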