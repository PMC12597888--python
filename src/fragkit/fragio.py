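"""Fragment and annotation I/O.

Single source of truth for coordinates, quality filters, and file dialects.
All coordinates are 0-based half-open (BED/frag convention). Fragment files
follow the FinaleDB dialect: bgzip-compressed, tabix-indexed TSV with columns
``contig, start, end, mapq, strand``; extra columns are ignored on read.

BAM/CRAM input is collapsed to one fragment per properly-paired read pair,
taken from the read with positive template length; secondary, supplementary,
unmapped and QC-fail reads are always skipped.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pysam

__all__ = [
    "Fragment", "FilterSpec", "GenomicInterval",
    "read_fragments", "filter_file", "make_genome_bins", "parse_bed",
    "read_chrom_sizes", "write_track", "write_fragfile", "IntervalSet",
]

#: margin (bp) added to the left of a BAM region query so pairs whose leftmost
#: read starts before the region but whose fragment overlaps it are not missed
_BAM_FETCH_MARGIN = 5000


@dataclass(frozen=True, slots=True)
class Fragment:
    """One sequenced cfDNA fragment as a genomic interval.

    ``start`` is the 0-based inclusive 5'-most coordinate, ``end`` the 0-based
    exclusive 3'-most coordinate; the two breakpoints sit at ``start`` and
    ``end - 1``. ``strand`` is the strand of read 1 ('+', '-' or '.').
    """

    contig: str
    start: int
    end: int
    mapq: int = 60
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"fragment end must exceed start: {self}")
        if self.start < 0:
            raise ValueError(f"negative fragment start: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Midpoint base: floor((start + end - 1) / 2)."""
        return (self.start + self.end - 1) // 2


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """0-based half-open region with optional name and strand."""

    contig: str
    start: int
    end: int
    name: Optional[str] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"interval end must exceed start: {self}")
        if self.start < 0:
            raise ValueError(f"negative interval start: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end - 1) // 2


class IntervalSet:
    """Overlap queries against a static interval collection.

    Used for blacklists/whitelists; backed by per-contig sorted arrays with
    binary search, enough for the modest interval lists filters carry.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        import numpy as np

        by_contig: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
        self._starts: dict[str, "np.ndarray"] = {}
        self._ends: dict[str, "np.ndarray"] = {}
        for contig, pairs in by_contig.items():
            pairs.sort()
            merged: list[list[int]] = []
            for s, e in pairs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[contig] = np.array([m[0] for m in merged], dtype=np.int64)
            self._ends[contig] = np.array([m[1] for m in merged], dtype=np.int64)

    def overlaps(self, contig: str, start: int, end: int) -> bool:
        import numpy as np

        if contig not in self._starts:
            return False
        starts, ends = self._starts[contig], self._ends[contig]
        i = int(np.searchsorted(starts, end, side="left"))
        return i > 0 and ends[i - 1] > start

    def overlap_bp(self, contig: str, start: int, end: int) -> int:
        """Total bases of [start, end) covered by the (merged) set."""
        import numpy as np

        if contig not in self._starts:
            return 0
        starts, ends = self._starts[contig], self._ends[contig]
        lo = np.maximum(starts, start)
        hi = np.minimum(ends, end)
        return int(np.clip(hi - lo, 0, None).sum())


@dataclass(slots=True)
class FilterSpec:
    """Quality filters applied conjunctively to fragments.

    Defaults keep high-quality fragments only: mapping quality >= 30,
    properly paired, no duplicates. ``require_proper_pair`` and
    ``exclude_duplicates`` act on BAM/CRAM flags; frag.gz records carry no
    flags and are assumed pre-filtered for pairing/duplication.
    """

    min_mapq: int = 30
    require_proper_pair: bool = True
    exclude_duplicates: bool = True
    min_length: Optional[int] = None
    max_length: Optional[int] = None
    blacklist: Optional[IntervalSet] = None
    whitelist: Optional[IntervalSet] = None

    def __post_init__(self) -> None:
        if (
            self.min_length is not None
            and self.max_length is not None
            and self.min_length > self.max_length
        ):
            raise ValueError("min_length must not exceed max_length")

    def passes(self, frag: Fragment) -> bool:
        if frag.mapq < self.min_mapq:
            return False
        n = frag.length
        if self.min_length is not None and n < self.min_length:
            return False
        if self.max_length is not None and n > self.max_length:
            return False
        if self.blacklist is not None and self.blacklist.overlaps(
            frag.contig, frag.start, frag.end
        ):
            return False
        if self.whitelist is not None and not self.whitelist.overlaps(
            frag.contig, frag.start, frag.end
        ):
            return False
        return True


class FragFileError(ValueError):
    """Malformed fragment file content."""


def _is_alignment(source: str | Path) -> bool:
    s = str(source)
    return s.endswith(".bam") or s.endswith(".cram") or s.endswith(".sam")


def _frag_from_line(line: str, lineno: int) -> Fragment:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise FragFileError(f"line {lineno}: expected >=3 columns, got {len(fields)}")
    contig = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FragFileError(f"line {lineno}: non-integer coordinates") from exc
    if start >= end or start < 0:
        raise FragFileError(f"line {lineno}: invalid interval [{start}, {end})")
    mapq = 60
    if len(fields) > 3 and fields[3] not in (".", ""):
        try:
            mapq = int(fields[3])
        except ValueError as exc:
            raise FragFileError(f"line {lineno}: non-integer mapq {fields[3]!r}") from exc
    strand = fields[4] if len(fields) > 4 and fields[4] else "."
    return Fragment(contig, start, end, mapq, strand)


def _iter_fragfile(
    source: str | Path, region: Optional[GenomicInterval]
) -> Iterator[Fragment]:
    path = str(source)
    if region is not None:
        if not os.path.exists(path + ".tbi") and not os.path.exists(path + ".csi"):
            raise FileNotFoundError(f"tabix index missing for {path}")
        with pysam.TabixFile(path) as tbx:
            if region.contig not in tbx.contigs:
                raise KeyError(f"contig {region.contig!r} not in {path} index")
            for lineno, line in enumerate(
                tbx.fetch(region.contig, region.start, region.end), start=1
            ):
                yield _frag_from_line(line, lineno)
    else:
        opener = pysam.BGZFile if path.endswith((".gz", ".bgz")) else open
        with opener(path) as fh:  # type: ignore[operator]
            for lineno, raw in enumerate(fh, start=1):
                line = raw.decode() if isinstance(raw, bytes) else raw
                if not line.strip() or line.startswith("#"):
                    continue
                yield _frag_from_line(line, lineno)


def _iter_bam(
    source: str | Path,
    region: Optional[GenomicInterval],
    reference: Optional[str],
    filt: FilterSpec,
) -> Iterator[Fragment]:
    kwargs = {"reference_filename": reference} if reference else {}
    with pysam.AlignmentFile(str(source), **kwargs) as bam:
        if region is not None:
            if region.contig not in bam.references:
                raise KeyError(f"contig {region.contig!r} not in {source} header")
            fetch_start = max(0, region.start - _BAM_FETCH_MARGIN)
            reads = bam.fetch(region.contig, fetch_start, region.end)
        else:
            reads = bam.fetch()
        for read in reads:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_qcfail
            ):
                continue
            if filt.exclude_duplicates and read.is_duplicate:
                continue
            if filt.require_proper_pair and not read.is_proper_pair:
                continue
            tlen = read.template_length
            if tlen <= 0:  # emit once per pair, from the leftmost read
                continue
            start = read.reference_start
            end = start + tlen
            strand = "+" if read.is_read1 else "-"
            frag = Fragment(read.reference_name, start, end, read.mapping_quality, strand)
            if region is not None and not (
                frag.start < region.end and frag.end > region.start
            ):
                continue
            yield frag


def read_fragments(
    source: str | Path,
    region: Optional[GenomicInterval] = None,
    filt: Optional[FilterSpec] = None,
    reference: Optional[str] = None,
) -> Iterator[Fragment]:
    """Stream fragments from BAM/CRAM or frag.gz, filtered and coordinate-sorted.

    Yields fragments overlapping ``region`` (all fragments when None), each
    passing ``filt`` (default :class:`FilterSpec`). The same fragments yield
    identical streams whichever dialect encodes them.
    """
    if filt is None:
        filt = FilterSpec()
    if _is_alignment(source):
        it: Iterator[Fragment] = _iter_bam(source, region, reference, filt)
    else:
        it = _iter_fragfile(source, region)
    for frag in it:
        if filt.passes(frag):
            yield frag


def write_fragfile(
    fragments: Iterable[Fragment],
    out: str | Path,
    contig_order: Optional[Sequence[str]] = None,
) -> int:
    """Write fragments as a sorted, bgzipped, tabix-indexed frag.gz.

    Sort order: contig (input order unless ``contig_order`` given), start,
    end, strand. Returns the number of records written.
    """
    frags = list(fragments)
    if contig_order is None:
        contig_order = list(dict.fromkeys(f.contig for f in frags))
    rank = {c: i for i, c in enumerate(contig_order)}
    frags.sort(key=lambda f: (rank.get(f.contig, len(rank)), f.start, f.end, f.strand))

    out = str(out)
    plain = out[:-3] if out.endswith(".gz") else out + ".tmp"
    with open(plain, "w") as fh:
        for f in frags:
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\t{f.mapq}\t{f.strand}\n")
    pysam.tabix_compress(plain, out, force=True)
    os.remove(plain)
    pysam.tabix_index(out, preset="bed", force=True)
    return len(frags)


def filter_file(
    source: str | Path,
    filt: FilterSpec,
    out: str | Path,
    reference: Optional[str] = None,
) -> int:
    """Filter a fragment file; write a sorted indexed frag.gz; return retained count."""
    retained = list(read_fragments(source, filt=filt, reference=reference))
    return write_fragfile(retained, out)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Parse a two-column chrom.sizes TSV into an ordered contig -> length map."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise FragFileError(f"line {lineno}: expected 2 columns")
            name, length = fields[0], int(fields[1])
            if length <= 0:
                raise FragFileError(f"line {lineno}: non-positive length for {name}")
            if name in sizes:
                raise FragFileError(f"line {lineno}: duplicate contig {name}")
            sizes[name] = length
    return sizes


def make_genome_bins(
    sizes: Mapping[str, int],
    bin_size: int,
    contigs: Optional[Sequence[str]] = None,
) -> list[GenomicInterval]:
    """Tile contigs with non-overlapping bins of ``bin_size`` bp.

    The final bin of each contig is truncated at the contig length, so the
    bins partition each selected contig exactly.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    selected = list(contigs) if contigs is not None else list(sizes)
    bins: list[GenomicInterval] = []
    for contig in selected:
        length = sizes[contig]
        for start in range(0, length, bin_size):
            bins.append(GenomicInterval(contig, start, min(start + bin_size, length)))
    return bins


def parse_bed(path: str | Path) -> list[GenomicInterval]:
    """Parse BED3+ into intervals; track/browser/comment lines are skipped."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if (
                not line.strip()
                or line.startswith(("#", "track", "browser"))
            ):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FragFileError(f"line {lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FragFileError(f"line {lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise FragFileError(f"line {lineno}: invalid interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
            intervals.append(GenomicInterval(fields[0], start, end, name, strand))
    return intervals


def _merge_runs(records):
    merged = []
    for contig, start, end, value in records:
        if (
            merged
            and merged[-1][0] == contig
            and merged[-1][2] == start
            and merged[-1][3] == value
        ):
            merged[-1][2] = end
        else:
            merged.append([contig, start, end, value])
    return merged


def write_track(
    records: Iterable[tuple[str, int, int, float]],
    out: str | Path,
    format: str = "bedgraph",
    sizes: Optional[Mapping[str, int]] = None,
) -> None:
    """Write (contig, start, end, value) records as bedGraph or bigWig.

    Records must be coordinate-sorted within each contig. Adjacent equal-value
    runs are merged (value-preserving) in both formats.
    """
    recs = list(records)
    last: dict[str, int] = {}
    for contig, start, end, _ in recs:
        if start < last.get(contig, -1):
            raise ValueError(f"unsorted track records at {contig}:{start}")
        last[contig] = start
    merged = _merge_runs(recs)
    if format == "bedgraph":
        with open(out, "w") as fh:
            for contig, start, end, value in merged:
                fh.write(f"{contig}\t{start}\t{end}\t{value:g}\n")
    elif format == "bigwig":
        import pyBigWig

        if sizes is None:
            raise ValueError("bigWig output requires genome sizes")
        bw = pyBigWig.open(str(out), "w")
        bw.addHeader([(c, length) for c, length in sizes.items()])
        if merged:
            bw.addEntries(
                [m[0] for m in merged],
                [m[1] for m in merged],
                ends=[m[2] for m in merged],
                values=[float(m[3]) for m in merged],
            )
        bw.close()
    else:
        raise ValueError(f"unknown track format {format!r}")


def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    """Read a bedGraph file back into (contig, start, end, value) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            c, s, e, v = line.split("\t")
            out.append((c, int(s), int(e), float(v)))
    return out
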