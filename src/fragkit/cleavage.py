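"""Per-position cleavage proportion around site lists (CpG sites, CTCF motifs).

At a genomic position p, the cleavage proportion is the number of fragment
termini located exactly at p divided by the number of fragments covering p
(start <= p < end). Both termini of each fragment count; the right terminus
sits at end - 1, the last covered base. Counts are pooled across sites
(after minus-strand reversal) before division, which stabilizes low-depth
positions; a per-site mode averages per-site ratios instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from fragkit.fragio import FilterSpec, Fragment, GenomicInterval, read_fragments

__all__ = ["CleavageProfile", "cleavage_profile"]


@dataclass
class CleavageProfile:
    """Pooled cleavage counts and proportions at offsets -W..+W."""

    offsets: np.ndarray
    ends_count: np.ndarray
    depth_count: np.ndarray
    n_sites: int
    n_skipped: int = 0

    @property
    def window(self) -> int:
        return (len(self.offsets) - 1) // 2

    @property
    def proportions(self) -> np.ndarray:
        """ends/depth where depth > 0, NaN (missing) elsewhere."""
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(
                self.depth_count > 0, self.ends_count / np.maximum(self.depth_count, 1), np.nan
            )
        return p


def _site_arrays(
    source, contig: str, lo: int, hi: int, filt: Optional[FilterSpec]
) -> tuple[np.ndarray, np.ndarray]:
    """(ends, depth) per base over [lo, hi) from fragments overlapping it."""
    n = hi - lo
    ends = np.zeros(n, dtype=np.int64)
    depth_diff = np.zeros(n + 1, dtype=np.int64)
    if isinstance(source, (str, Path)):
        frags: Iterable[Fragment] = read_fragments(
            source, GenomicInterval(contig, max(lo, 0), hi), filt
        )
    else:
        frags = (f for f in source if f.contig == contig and f.start < hi and f.end > lo)
    for f in frags:
        for terminus in (f.start, f.end - 1):
            if lo <= terminus < hi:
                ends[terminus - lo] += 1
        depth_diff[max(f.start - lo, 0)] += 1
        depth_diff[min(f.end - lo, n)] -= 1
    return ends, np.cumsum(depth_diff[:-1])


def cleavage_profile(
    source: Union[Iterable[Fragment], str, Path],
    sites: Sequence[GenomicInterval],
    window: int,
    filt: Optional[FilterSpec] = None,
    pooled: bool = True,
) -> CleavageProfile:
    """Cleavage proportion profile around site midpoints, strand-aware.

    ``source`` is a fragment file path or an iterable containing every
    fragment overlapping the site windows. Sites whose window would run off
    the left contig edge are skipped and counted. With ``pooled`` (default)
    the per-offset counts are summed across sites and divided once; otherwise
    per-site proportions are averaged (positions with zero depth at a site
    are ignored in that site's average weightlessly via NaN means).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    sites = list(sites)
    if not sites:
        raise ValueError("no sites given")
    if not isinstance(source, (str, Path)):
        source = list(source)
    width = 2 * window + 1
    ends_total = np.zeros(width, dtype=np.int64)
    depth_total = np.zeros(width, dtype=np.int64)
    persite_sum = np.zeros(width)
    persite_n = np.zeros(width)
    n_used = n_skipped = 0
    for site in sites:
        mid = site.midpoint
        lo, hi = mid - window, mid + window + 1
        if lo < 0:
            n_skipped += 1
            continue
        ends, depth = _site_arrays(source, site.contig, lo, hi, filt)
        if site.strand == "-":
            ends, depth = ends[::-1], depth[::-1]
        ends_total += ends
        depth_total += depth
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(depth > 0, ends / np.maximum(depth, 1), np.nan)
        ok = ~np.isnan(ratio)
        persite_sum[ok] += ratio[ok]
        persite_n[ok] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("all sites skipped (off-contig windows)")
    profile = CleavageProfile(
        offsets=np.arange(-window, window + 1),
        ends_count=ends_total,
        depth_count=depth_total,
        n_sites=n_used,
        n_skipped=n_skipped,
    )
    if not pooled:
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(persite_n > 0, persite_sum / np.maximum(persite_n, 1), np.nan)
        profile = CleavageProfile(
            offsets=profile.offsets,
            ends_count=ends_total,
            depth_count=depth_total,
            n_sites=n_used,
            n_skipped=n_skipped,
        )
        profile.per_site_mean = mean  # type: ignore[attr-defined]
    return profile
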