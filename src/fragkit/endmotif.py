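"""5' end motifs, motif diversity score (MDS), and breakpoint motifs.

Motifs are read from the reference genome at fragment coordinates (fragment
files carry no sequence). Each double-stranded fragment has two 5' termini:
the plus-strand motif is reference[start, start+k) and the minus-strand motif
is the reverse complement of reference[end-k, end); both contribute by
default. Soft-masked bases are uppercased; motifs containing non-ACGT
characters are skipped and counted.

MDS is the Shannon entropy of the end-motif frequency distribution normalized
by log(4^k): 1 for a uniform distribution, 0 for a degenerate one. The log
base cancels in the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Optional, Sequence

import numpy as np

from fragkit.fragio import Fragment, GenomicInterval
from fragkit.fragstats import assign_midpoints

__all__ = [
    "MotifTable", "all_motifs", "end_motifs", "mds",
    "interval_end_motifs", "interval_mds", "breakpoint_motifs",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def all_motifs(k: int) -> list[str]:
    """The 4^k DNA k-mers in lexicographic order."""
    return ["".join(p) for p in product("ACGT", repeat=k)]


@dataclass
class MotifTable:
    """Counts over the full 4^k end-motif alphabet, in lexicographic order."""

    k: int
    counts: dict[str, int] = field(default_factory=dict)
    n_skipped: int = 0

    def __post_init__(self) -> None:
        full = {m: 0 for m in all_motifs(self.k)}
        for m, c in self.counts.items():
            if m not in full:
                raise ValueError(f"{m!r} is not an ACGT {self.k}-mer")
            full[m] = c
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            return {m: 0.0 for m in self.counts}
        return {m: c / t for m, c in self.counts.items()}

    def values(self) -> np.ndarray:
        return np.array(list(self.counts.values()), dtype=np.int64)

    def add(self, other: "MotifTable") -> "MotifTable":
        if other.k != self.k:
            raise ValueError("motif lengths differ")
        summed = {m: self.counts[m] + other.counts[m] for m in self.counts}
        return MotifTable(self.k, summed, self.n_skipped + other.n_skipped)


class _Reference:
    """Uppercased sequence access on a pyfaidx Fasta or a plain dict."""

    def __init__(self, reference):
        if isinstance(reference, (str, bytes)) or hasattr(reference, "__fspath__"):
            from pyfaidx import Fasta

            self._fa = Fasta(str(reference))
            self._dict = None
        elif isinstance(reference, dict):
            self._fa = None
            self._dict = reference
        else:
            self._fa = reference
            self._dict = None

    def fetch(self, contig: str, start: int, end: int) -> Optional[str]:
        """Sequence of [start, end), or None if out of bounds/unknown contig."""
        if start < 0:
            return None
        if self._dict is not None:
            seq = self._dict.get(contig)
            if seq is None:
                raise KeyError(f"contig {contig!r} not in reference")
            if end > len(seq):
                return None
            return seq[start:end].upper()
        if contig not in self._fa:
            raise KeyError(f"contig {contig!r} not in reference")
        rec = self._fa[contig]
        if end > len(rec):
            return None
        return str(rec[start:end]).upper()


def _fragment_end_motifs(
    frag: Fragment, ref: _Reference, k: int, ends: str
) -> tuple[list[str], int]:
    """(valid motifs, skipped-end count) for one fragment."""
    motifs: list[str] = []
    skipped = 0
    plus = ref.fetch(frag.contig, frag.start, frag.start + k)
    if plus is not None and set(plus) <= set("ACGT"):
        motifs.append(plus)
    else:
        skipped += 1
    if ends == "five_prime_both":
        minus_raw = ref.fetch(frag.contig, frag.end - k, frag.end)
        if minus_raw is not None:
            minus = revcomp(minus_raw)
            if set(minus) <= set("ACGT"):
                motifs.append(minus)
            else:
                skipped += 1
        else:
            skipped += 1
    return motifs, skipped


def end_motifs(
    fragments: Iterable[Fragment],
    reference,
    k: int = 4,
    ends: str = "five_prime_both",
) -> MotifTable:
    """Count 5' end motifs of length k over all fragments.

    ``reference`` is a FASTA path, an open pyfaidx Fasta, or a dict of
    contig -> sequence. ``ends`` is ``five_prime_both`` (default; both 5'
    termini of the double-stranded fragment) or ``plus_only``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if ends not in ("five_prime_both", "plus_only"):
        raise ValueError(f"unknown ends mode {ends!r}")
    ref = _Reference(reference)
    counts: dict[str, int] = {}
    skipped = 0
    for frag in fragments:
        motifs, s = _fragment_end_motifs(frag, ref, k, ends)
        skipped += s
        for m in motifs:
            counts[m] = counts.get(m, 0) + 1
    return MotifTable(k, counts, skipped)


def mds(table: MotifTable) -> float:
    """Motif diversity score: normalized Shannon entropy in [0, 1].

    MDS = sum_i -f_i log f_i / log(4^k), with 0 log 0 = 0.
    """
    total = table.total
    if total == 0:
        raise ValueError("MDS undefined for an empty motif table")
    freqs = table.values() / total
    nz = freqs[freqs > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return entropy / np.log(4.0**table.k)


def interval_end_motifs(
    fragments: Iterable[Fragment],
    reference,
    intervals: Sequence[GenomicInterval],
    k: int = 4,
    ends: str = "five_prime_both",
) -> list[MotifTable]:
    """One MotifTable per interval; a fragment's motifs are credited to the
    interval containing the fragment midpoint."""
    frags = list(fragments)
    groups = assign_midpoints(frags, intervals)
    return [
        end_motifs((frags[j] for j in idxs), reference, k, ends) for idxs in groups
    ]


def interval_mds(tables: Sequence[MotifTable]) -> list[Optional[float]]:
    """MDS per interval; intervals with zero motifs yield None, not 0."""
    return [mds(t) if t.total > 0 else None for t in tables]


def breakpoint_motifs(
    fragments: Iterable[Fragment],
    reference,
    upstream: int = 3,
    downstream: int = 3,
) -> MotifTable:
    """Motifs of genomic context spanning each 5' breakpoint.

    For a plus-strand breakpoint at position b the motif is
    reference[b-u, b) + reference[b, b+d); minus-strand breakpoints (at the
    fragment's last covered base, end-1) use the reverse-complemented context
    so upstream/downstream are read in the breakpoint's own orientation.
    With u=0 this reduces exactly to ``end_motifs`` with k=d.
    """
    u, d = upstream, downstream
    if u < 0 or d < 0 or u + d < 1:
        raise ValueError("need upstream, downstream >= 0 and upstream+downstream >= 1")
    ref = _Reference(reference)
    counts: dict[str, int] = {}
    skipped = 0
    for frag in fragments:
        plus = ref.fetch(frag.contig, frag.start - u, frag.start + d)
        if plus is not None and set(plus) <= set("ACGT"):
            counts[plus] = counts.get(plus, 0) + 1
        else:
            skipped += 1
        minus_raw = ref.fetch(frag.contig, frag.end - d, frag.end + u)
        if minus_raw is not None:
            minus = revcomp(minus_raw)
            if set(minus) <= set("ACGT"):
                counts[minus] = counts.get(minus, 0) + 1
            else:
                skipped += 1
        else:
            skipped += 1
    return MotifTable(u + d, counts, skipped)
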